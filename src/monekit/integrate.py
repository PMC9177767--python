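"""Integrative feature-gene-expression analysis.

Slides are paired to expression profiles by vial; genes failing the
zero-fraction or minimum-sd filters are dropped; the slide-feature and gene
vectors are stacked, a Ledoit-Wolf covariance estimated, and the
feature x gene correlation block tested with Fisher-transform statistics
(BH within the block).  Significant bipartite components give
feature-gene clusters; a cluster's features combine into a single
morphology index via the first principal component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.covariance import LedoitWolf
from statsmodels.stats.multitest import multipletests

from .correlation import fisher_test
from .data import CovariateVector, ExpressionMatrix, MoneMatrix

__all__ = [
    "GeneFilterConfig",
    "ClusterScore",
    "filter_genes",
    "mone_gene_correlation",
    "MoneGeneResult",
    "extract_bicluster",
    "cluster_pc1",
    "correlate_with_covariate",
    "ig_score",
]


@dataclass(frozen=True)
class GeneFilterConfig:
    """Gene inclusion thresholds: drop genes zero in more than
    ``max_zero_fraction`` of paired samples or with sd below ``min_sd``."""

    max_zero_fraction: float = 0.5
    min_sd: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.max_zero_fraction <= 1:
            raise ValueError("max_zero_fraction must be in [0, 1]")
        if self.min_sd < 0:
            raise ValueError("min_sd must be non-negative")


def filter_genes(
    expr: ExpressionMatrix, config: GeneFilterConfig = GeneFilterConfig()
) -> ExpressionMatrix:
    """Apply the zero-fraction and minimum-sd gene filters (order preserved)."""
    zero_frac = (expr.values == 0).mean(axis=0)
    sd = expr.values.std(axis=0)
    keep = (zero_frac <= config.max_zero_fraction) & (sd >= config.min_sd)
    if not keep.any():
        raise ValueError("all genes removed by the expression filters")
    return expr.subset_genes([g for g, k in zip(expr.genes, keep) if k])


@dataclass
class MoneGeneResult:
    """Feature x gene correlation block with p/q matrices.

    ``r`` is the Ledoit-Wolf-shrunk estimate; ``r_sample`` the plain sample
    correlation the Fisher tests are computed on (the shrunk value with the
    nominal degrees of freedom would be far too conservative when many null
    genes inflate the shrinkage intensity).
    """

    r: np.ndarray          # (n_features, n_genes), shrunk
    r_sample: np.ndarray   # same block, unshrunk
    p: np.ndarray
    q: np.ndarray
    feature_ids: list[int]
    genes: list[str]
    n: int


def mone_gene_correlation(
    mone_values: np.ndarray,
    feature_ids: list[int],
    expr_values: np.ndarray,
    genes: list[str],
    alpha: float = 0.05,
) -> MoneGeneResult:
    """Correlations between paired slide features and gene expression.

    Rows of ``mone_values`` and ``expr_values`` must already be paired
    sample-for-sample.  The stacked covariance is estimated with
    Ledoit-Wolf shrinkage; Fisher tests and BH adjustment apply to the
    feature x gene block only.
    """
    mone_values = np.asarray(mone_values, dtype=float)
    expr_values = np.asarray(expr_values, dtype=float)
    if mone_values.shape[0] != expr_values.shape[0]:
        raise ValueError("feature and expression row counts differ")
    n = mone_values.shape[0]
    if n < 4:
        raise ValueError("need at least 4 paired samples")
    stacked = np.hstack([mone_values, expr_values])
    cov = LedoitWolf(assume_centered=False).fit(stacked).covariance_
    d = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(d, d)
    m = mone_values.shape[1]
    block = np.clip(corr[:m, m:], -1.0, 1.0)
    sample = np.clip(np.corrcoef(stacked, rowvar=False)[:m, m:], -1.0, 1.0)
    p = np.array(
        [[fisher_test(float(sample[i, j]), n) for j in range(sample.shape[1])]
         for i in range(sample.shape[0])]
    )
    q = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
    return MoneGeneResult(
        r=block, r_sample=sample, p=p, q=q,
        feature_ids=list(feature_ids), genes=list(genes), n=n,
    )


@dataclass
class Bicluster:
    """A connected component of the significant feature-gene bipartite graph."""

    features: list[int]
    genes: list[str]
    mean_abs_r: float


def extract_bicluster(
    result: MoneGeneResult, alpha: float = 0.05, min_mones: int = 2, min_genes: int = 2
) -> list[Bicluster]:
    """Connected components of the q <= alpha bipartite graph.

    Only components with at least ``min_mones`` features and ``min_genes``
    genes are returned, largest first.
    """
    sig = result.q <= alpha
    n_f, n_g = sig.shape
    # union-find over features (0..n_f-1) and genes (n_f..n_f+n_g-1)
    parent = list(range(n_f + n_g))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in zip(*np.nonzero(sig)):
        ra, rb = find(int(i)), find(int(n_f + j))
        if ra != rb:
            parent[ra] = rb

    comps: dict[int, tuple[list[int], list[int]]] = {}
    for i in range(n_f):
        if sig[i].any():
            comps.setdefault(find(i), ([], []))[0].append(i)
    for j in range(n_g):
        if sig[:, j].any():
            comps.setdefault(find(n_f + j), ([], []))[1].append(j)

    out = []
    for feats, gs in comps.values():
        if len(feats) >= min_mones and len(gs) >= min_genes:
            sub = result.r[np.ix_(feats, gs)]
            edge = sig[np.ix_(feats, gs)]
            out.append(
                Bicluster(
                    features=[int(result.feature_ids[i]) for i in feats],
                    genes=[result.genes[j] for j in gs],
                    mean_abs_r=float(np.abs(sub[edge]).mean()),
                )
            )
    out.sort(key=lambda b: -(len(b.features) + len(b.genes)))
    return out


@dataclass
class ClusterScore:
    """First principal component of a correlated feature cluster."""

    members: list[int]
    loadings: np.ndarray
    pc1: np.ndarray
    variance_explained: float


def cluster_pc1(values: np.ndarray, members: list[int]) -> ClusterScore:
    """PC-1 of the member features (centered, unscaled PCA).

    Sign convention: the loading of the member with the smallest id is
    non-negative.  ``values`` holds the member columns in ``members`` order.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[1] != len(members) or len(members) < 2:
        raise ValueError("need >= 2 member features matching the value columns")
    if values.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    centered = values - values.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("degenerate (zero-variance) member set")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = vt[0]
    anchor = int(np.argmin(members))
    if loadings[anchor] < 0:
        loadings = -loadings
    pc1 = centered @ loadings
    var = s**2
    return ClusterScore(
        members=list(members),
        loadings=loadings,
        pc1=pc1,
        variance_explained=float(var[0] / var.sum()),
    )


def correlate_with_covariate(
    score: dict[str, float] | np.ndarray,
    covariate: CovariateVector,
    keys: list[str] | None = None,
    trim_above: float | None = None,
) -> tuple[float, float, int]:
    """Pairwise-complete Pearson correlation of a score with a covariate.

    ``score`` is either a key -> value mapping or an array aligned with
    ``keys``.  ``trim_above`` drops samples whose covariate exceeds the
    threshold before correlating (outlier rule).  Returns (r, p, n_used)
    with a Fisher-transform p-value.
    """
    if isinstance(score, dict):
        score_map = score
    else:
        if keys is None:
            raise ValueError("keys required when score is an array")
        score_map = dict(zip(keys, np.asarray(score, dtype=float)))
    xs, ys = [], []
    for k, v in score_map.items():
        c = covariate.get(k)
        if c is None:
            continue
        if trim_above is not None and c > trim_above:
            continue
        xs.append(v)
        ys.append(c)
    if len(xs) < 4:
        raise ValueError(f"fewer than 4 complete pairs ({len(xs)})")
    x, y = np.asarray(xs), np.asarray(ys)
    r = float(np.corrcoef(x, y)[0, 1])
    p = fisher_test(r, len(x))
    return r, p, len(x)


def ig_score(
    expr: ExpressionMatrix, gene_set: list[str], min_coverage: float = 1.0
) -> np.ndarray:
    """Per-sample mean log-normalized expression of a gene set.

    Missing genes are reported; by default all members are required
    (``min_coverage=1.0``); lower values allow partial sets, never silently.
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    present = [g for g in gene_set if g in expr.genes]
    missing = [g for g in gene_set if g not in expr.genes]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    coverage = len(present) / len(gene_set)
    if coverage < min_coverage:
        raise ValueError(
            f"gene-set coverage {coverage:.2f} below required {min_coverage:.2f}; "
            f"missing: {missing}"
        )
    if missing:
        warnings.warn(f"{len(missing)} gene(s) missing from the matrix: {missing}")
    sub = expr.subset_genes(present)
    return sub.values.mean(axis=1)
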