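"""Shrinkage correlation networks and Fisher-transform significance.

Covariance matrices are estimated with Ledoit-Wolf shrinkage (optimal
blending of the sample covariance with a scaled identity) and converted to
correlations by diagonal normalization.  Significance uses the Fisher
transform z = atanh(r), approximately N(atanh(rho), 1/(n-3)) under a
bivariate-normal null, with Benjamini-Hochberg adjustment over the
upper-triangle family.  Differential correlations compare tumor and normal
matrices via the difference of Fisher z values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.covariance import LedoitWolf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "shrinkage_correlation",
    "fisher_test",
    "correlation_pvalues",
    "correlated_pairs",
    "pooled_correlation",
    "family_preservation",
    "differential_correlation",
]


@dataclass
class CorrelationResult:
    """Symmetric correlation matrix with optional p/q matrices.

    ``p`` and ``q`` are full symmetric matrices (diagonal NaN) populated from
    the upper-triangle test family.  ``n_effective`` is the slide count used
    for the Fisher tests.  ``degenerate`` flags constant features whose
    correlations are reported as 0.
    """

    r: np.ndarray
    n_effective: int
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    degenerate: np.ndarray | None = None


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def shrinkage_correlation(
    values: np.ndarray, shrinkage: float | None = None
) -> CorrelationResult:
    """Ledoit-Wolf-shrunk correlation matrix of a slides x features array.

    ``shrinkage=None`` estimates the optimal intensity from the data;
    ``shrinkage=0.0`` reproduces the plain sample correlation matrix.
    Constant features are flagged and their correlations set to 0.
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if n < 2:
        raise ValueError("need at least 2 slides")
    degenerate = np.ptp(values, axis=0) == 0  # exactly constant columns
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} constant features; correlations set to 0")
    if m == 1:
        return CorrelationResult(r=np.ones((1, 1)), n_effective=n, degenerate=degenerate)
    if shrinkage is None:
        cov = LedoitWolf(assume_centered=False).fit(values).covariance_
    else:
        sample = np.cov(values, rowvar=False, bias=True)
        mu = np.trace(sample) / m
        cov = (1.0 - shrinkage) * sample + shrinkage * mu * np.eye(m)
    r = _cov_to_corr(cov)
    if degenerate.any():
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
        np.fill_diagonal(r, 1.0)
    return CorrelationResult(r=r, n_effective=n, degenerate=degenerate)


def fisher_test(
    r: float, n: int, null_rho: float = 0.0, sided: str = "two"
) -> float:
    """Fisher-transform p-value for a single correlation coefficient.

    For a point null (``null_rho=0``) the statistic is
    (atanh(r) - atanh(rho0)) * sqrt(n - 3).  For a composite null
    |rho| <= rho0 the statistic is evaluated at the boundary carrying the
    sign of r, which is the least-favorable point.  ``sided`` is "two" or
    "greater" (evidence beyond the null in the direction of r).
    """
    if n < 4:
        raise ValueError("need n >= 4 for the Fisher test")
    if abs(r) >= 1.0:
        # perfectly collinear data: the transform diverges; report exact 0
        return 0.0
    boundary = null_rho if null_rho == 0 else abs(null_rho) * np.sign(r if r != 0 else 1.0)
    z = (np.arctanh(r) - np.arctanh(boundary)) * np.sqrt(n - 3)
    if sided == "two":
        return float(2.0 * stats.norm.sf(abs(z)))
    if sided == "greater":
        return float(stats.norm.sf(z * np.sign(r if r != 0 else 1.0)))
    raise ValueError("sided must be 'two' or 'greater'")


def correlation_pvalues(
    r: np.ndarray, n: int, null_rho: float = 0.0, sided: str = "two"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Fisher p and BH q matrices over the upper triangle of r."""
    m = r.shape[0]
    iu = np.triu_indices(m, k=1)
    p_flat = np.array(
        [fisher_test(float(r[i, j]), n, null_rho, sided) for i, j in zip(*iu)]
    )
    q_flat = multipletests(p_flat, method="fdr_bh")[1] if p_flat.size else p_flat
    p = np.full((m, m), np.nan)
    q = np.full((m, m), np.nan)
    p[iu] = p_flat
    q[iu] = q_flat
    p.T[iu] = p_flat
    q.T[iu] = q_flat
    return p, q


def correlated_pairs(
    result: CorrelationResult,
    alpha: float = 0.05,
    null_rho: float = 0.0,
    sided: str = "two",
) -> tuple[set[tuple[int, int]], float]:
    """BH-significant feature pairs and their fraction of all pairs."""
    p, q = correlation_pvalues(result.r, result.n_effective, null_rho, sided)
    result.p, result.q = p, q
    m = result.r.shape[0]
    iu = np.triu_indices(m, k=1)
    sig = {
        (int(i), int(j))
        for i, j in zip(*iu)
        if q[i, j] < alpha
    }
    n_pairs = m * (m - 1) // 2
    return sig, (len(sig) / n_pairs if n_pairs else 0.0)


def pooled_correlation(matrices: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of correlation matrices; diagonal reset to 1."""
    if not matrices:
        raise ValueError("no matrices to pool")
    shape = matrices[0].shape
    for m in matrices:
        if m.shape != shape:
            raise ValueError("correlation matrices differ in shape")
    pooled = np.mean(np.stack(matrices), axis=0)
    np.fill_diagonal(pooled, 1.0)
    return pooled


def family_preservation(per_cancer_pairs: dict[str, set]) -> float | None:
    """Fraction of pairs significant in every cancer among those significant in any."""
    if not per_cancer_pairs:
        return None
    union = set().union(*per_cancer_pairs.values())
    if not union:
        return None
    inter = set.intersection(*per_cancer_pairs.values())
    return len(inter) / len(union)


def differential_correlation(
    tumor: np.ndarray,
    normal: np.ndarray,
    alpha: float = 0.05,
    shrinkage: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tumor-minus-normal correlation differences with Fisher z tests.

    Returns (delta_r, p, q); the statistic per pair is
    (z_t - z_n) / sqrt(1/(n_t - 3) + 1/(n_n - 3)) against a standard normal,
    BH-adjusted over the upper triangle.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    n_t, n_n = tumor.shape[0], normal.shape[0]
    if n_t < 4 or n_n < 4:
        raise ValueError("each group needs at least 4 slides")
    r_t = shrinkage_correlation(tumor, shrinkage).r
    r_n = shrinkage_correlation(normal, shrinkage).r
    delta = r_t - r_n
    m = delta.shape[0]
    iu = np.triu_indices(m, k=1)
    se = np.sqrt(1.0 / (n_t - 3) + 1.0 / (n_n - 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = (np.arctanh(np.clip(r_t[iu], -1 + 1e-15, 1 - 1e-15))
                 - np.arctanh(np.clip(r_n[iu], -1 + 1e-15, 1 - 1e-15))) / se
    p_flat = 2.0 * stats.norm.sf(np.abs(zstat))
    q_flat = multipletests(p_flat, method="fdr_bh")[1] if p_flat.size else p_flat
    p = np.full((m, m), np.nan)
    q = np.full((m, m), np.nan)
    p[iu] = p_flat
    q[iu] = q_flat
    p.T[iu] = p_flat
    q.T[iu] = q_flat
    return delta, p, q
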