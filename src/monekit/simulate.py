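"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, at two levels:

* slide level — each feature has a Gaussian slide-to-slide distribution.
  Marker features shift their mean (and optionally scale their variance) in
  tumor slides of the affected cancers; correlated blocks follow a one-factor
  model (within-block correlation rho, the latent factor shared across the
  cancers that share the block); structure features move their group mean by
  (preparation, lesion) group; everything else is standard normal.
* tile level — a tile's value is its slide's value plus independent Gaussian
  tile noise, so median aggregation is exercised nontrivially.

Expression profiles couple selected genes linearly to a latent factor or to
a feature's slide-level value at a target correlation; the remaining genes
are independent noise, and a configurable fraction is made zero-inflated or
near-constant to exercise the integration filters.

Everything is driven by one integer seed; per-stage child streams are
spawned from it so cohort, expression and covariates regenerate
independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, MoneMatrix, SlideMeta, aggregate_tiles

__all__ = [
    "MarkerSpec",
    "BlockSpec",
    "StructureSpec",
    "GeneCouplingSpec",
    "CovariateCouplingSpec",
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_expression",
    "generate_covariate",
    "delta_for_target_am",
]


@dataclass(frozen=True)
class MarkerSpec:
    """A planted tumor/normal marker.

    Effect size is given either as ``delta`` (tumor mean shift in units of
    the slide-level sd) or as ``target_am`` (the variance-ratio effect size;
    the equivalent delta is solved for the cancer's class sizes).
    ``var_ratio`` scales the tumor-class variance.
    """

    feature: int
    cancers: tuple[str, ...]
    delta: float | None = None
    var_ratio: float = 1.0
    target_am: float | None = None

    def __post_init__(self) -> None:
        if (self.delta is None) == (self.target_am is None):
            raise ValueError("specify exactly one of delta or target_am")
        if self.var_ratio <= 0:
            raise ValueError("var_ratio must be positive")


@dataclass(frozen=True)
class BlockSpec:
    """A block of features correlated at ``rho`` (one-factor model)."""

    features: tuple[int, ...]
    rho: float
    cancers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("block rho must be in [0, 1) (one-factor model)")
        if len(self.features) < 2:
            raise ValueError("a block needs at least 2 features")


@dataclass(frozen=True)
class StructureSpec:
    """Group means for the (frozen-normal, frozen-tumor, FFPE-tumor) groups."""

    feature: int
    structure: str  # one of A, B, C, D
    shift: float = 1.0

    def group_means(self) -> dict[str, float]:
        s = self.shift
        return {
            "A": {"FN": 0.0, "FT": 0.0, "PT": 0.0},
            "B": {"FN": 0.0, "FT": 0.0, "PT": s},
            "C": {"FN": 0.0, "FT": s, "PT": s},
            "D": {"FN": 0.0, "FT": s, "PT": 0.0},
        }[self.structure]


@dataclass(frozen=True)
class TissueSignatureSpec:
    """A tissue-of-origin offset: every slide of ``cancer`` (tumor and
    normal alike) shifts ``feature`` by ``offset``.  Emulates the dominant
    tissue-type component of slide morphology that separates cancers from
    each other independently of lesion status."""

    cancer: str
    feature: int
    offset: float


@dataclass(frozen=True)
class GeneCouplingSpec:
    """Genes coupled to a latent block factor or to a feature's slide value."""

    genes: tuple[str, ...]
    target_r: float
    feature: int | None = None  # couple to this feature's slide-level value
    block: int | None = None    # ... or to this block's latent factor

    def __post_init__(self) -> None:
        if (self.feature is None) == (self.block is None):
            raise ValueError("specify exactly one of feature or block")
        if not -1 < self.target_r < 1:
            raise ValueError("target_r must be in (-1, 1)")


@dataclass(frozen=True)
class CovariateCouplingSpec:
    name: str
    target_r: float
    feature: int | None = None
    block: int | None = None


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Defaults emulate a modest TCGA-like cancer cohort: 50 frozen tumor,
    50 frozen normal and 30 FFPE tumor slides per cancer, 20-40 tiles per
    slide with tile noise sd 0.5 around the slide value, and unit
    slide-level variance.
    """

    n_cancers: int = 2
    cancer_names: tuple[str, ...] | None = None
    n_frozen_tumor: int = 50
    n_frozen_normal: int = 50
    n_ffpe_tumor: int = 30
    tiles_per_slide: tuple[int, int] = (20, 40)
    tile_noise_sd: float = 0.5
    n_features: int = 200
    markers: tuple[MarkerSpec, ...] = ()
    blocks: tuple[BlockSpec, ...] = ()
    structures: tuple[StructureSpec, ...] = ()
    tissue_signatures: tuple[TissueSignatureSpec, ...] = ()
    gene_couplings: tuple[GeneCouplingSpec, ...] = ()
    covariate_couplings: tuple[CovariateCouplingSpec, ...] = ()
    n_genes: int = 200
    gene_mean: float = 2.0
    gene_sd: float = 1.0
    zero_inflated_gene_fraction: float = 0.05
    low_sd_gene_fraction: float = 0.05
    expression_noise_sd: float = 1.0
    seed: int = 0

    def cancers(self) -> tuple[str, ...]:
        if self.cancer_names is not None:
            if len(self.cancer_names) != self.n_cancers:
                raise ValueError("cancer_names length must equal n_cancers")
            return self.cancer_names
        return tuple(f"C{i:02d}" for i in range(self.n_cancers))

    def validate(self) -> None:
        cancers = set(self.cancers())
        for spec in self.markers + self.blocks:
            for c in spec.cancers:
                if c not in cancers:
                    raise ValueError(f"unknown cancer {c!r} in {spec}")
        for tspec in self.tissue_signatures:
            if tspec.cancer not in cancers:
                raise ValueError(f"unknown cancer {tspec.cancer!r} in {tspec}")
            if not 0 <= tspec.feature < self.n_features:
                raise ValueError(f"feature id {tspec.feature} out of range")
        used = [f for b in self.blocks for f in b.features]
        if len(used) != len(set(used)):
            raise ValueError("a feature may belong to at most one block")
        for spec in list(self.markers) + [s for s in self.structures]:
            if not 0 <= spec.feature < self.n_features:
                raise ValueError(f"feature id {spec.feature} out of range")
        for b in self.blocks:
            for f in b.features:
                if not 0 <= f < self.n_features:
                    raise ValueError(f"feature id {f} out of range")
        if self.tiles_per_slide[0] < 1 or self.tiles_per_slide[0] > self.tiles_per_slide[1]:
            raise ValueError("invalid tiles_per_slide range")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated cohort."""

    markers_by_cancer: dict[str, set[int]]
    correlated_pairs_by_cancer: dict[str, set[tuple[int, int]]]
    structure_labels: dict[int, str]
    gene_couplings: dict[str, dict]
    factors: pd.DataFrame  # slide_id x block factors
    slide_values: pd.DataFrame | None = None  # noiseless slide-level features


def delta_for_target_am(target_am: float, n0: int, n1: int) -> float:
    """Mean shift giving population variance-ratio a(m) = target.

    With equal class variances 1 and sample-size weights w_y = n_y / n,
    the population total variance is 1 + w0 w1 delta^2, so
    a = 1 + w0 w1 delta^2.
    """
    if target_am < 1:
        raise ValueError("target a(m) must be >= 1")
    n = n0 + n1
    w0, w1 = n0 / n, n1 / n
    return float(np.sqrt((target_am - 1.0) / (w0 * w1)))


def _spawn(seed: int, stream: str) -> np.random.Generator:
    # stable per-stream entropy (Python's str hash is salted per process)
    tag = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def _make_meta(config: GeneratorConfig) -> list[SlideMeta]:
    meta: list[SlideMeta] = []
    for cancer in config.cancers():
        pid = 0
        # frozen tumor/normal pairs share a patient where possible, mimicking
        # tumor + adjacent-normal sampling from the same resection
        n_paired = min(config.n_frozen_tumor, config.n_frozen_normal)
        for i in range(n_paired):
            patient = f"{cancer}-P{pid:04d}"
            pid += 1
            for lesion, code in (("tumor", "01A"), ("normal", "11A")):
                sid = f"{patient}-{code}-F"
                meta.append(
                    SlideMeta(sid, patient, cancer, lesion, "frozen", f"{patient}-{code}")
                )
        for lesion, extra in (
            ("tumor", config.n_frozen_tumor - n_paired),
            ("normal", config.n_frozen_normal - n_paired),
        ):
            code = "01A" if lesion == "tumor" else "11A"
            for i in range(extra):
                patient = f"{cancer}-P{pid:04d}"
                pid += 1
                meta.append(
                    SlideMeta(
                        f"{patient}-{code}-F", patient, cancer, lesion, "frozen",
                        f"{patient}-{code}",
                    )
                )
        for i in range(config.n_ffpe_tumor):
            patient = f"{cancer}-P{pid:04d}"
            pid += 1
            meta.append(
                SlideMeta(
                    f"{patient}-01A-P", patient, cancer, "tumor", "FFPE",
                    f"{patient}-01A",
                )
            )
    return meta


def _group_of(m: SlideMeta) -> str:
    if m.preparation == "FFPE":
        return "PT" if m.lesion == "tumor" else "PN"
    return "FT" if m.lesion == "tumor" else "FN"


def _slide_values(
    config: GeneratorConfig, meta: list[SlideMeta], rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    n, m = len(meta), config.n_features
    values = rng.standard_normal((n, m))

    # correlated blocks: one latent factor per (block, slide); features of the
    # block mix the factor at sqrt(rho) so within-block correlation is rho
    factors = np.zeros((n, len(config.blocks)))
    for b_idx, block in enumerate(config.blocks):
        f = rng.standard_normal(n)
        factors[:, b_idx] = f
        in_cancer = np.array([mm.cancer_type in block.cancers for mm in meta])
        for feat in block.features:
            mixed = np.sqrt(block.rho) * f + np.sqrt(1 - block.rho) * values[:, feat]
            values[in_cancer, feat] = mixed[in_cancer]

    # markers: tumor mean shift / variance scaling in affected cancers
    for spec in config.markers:
        delta = spec.delta
        if delta is None:
            delta = delta_for_target_am(
                spec.target_am,
                config.n_frozen_normal,
                config.n_frozen_tumor,
            )
        for mm, row in zip(meta, range(n)):
            if mm.cancer_type in spec.cancers and mm.lesion == "tumor":
                values[row, spec.feature] = (
                    values[row, spec.feature] * np.sqrt(spec.var_ratio) + delta
                )

    # tissue-of-origin signatures: per-cancer offsets on all slides
    for tspec in config.tissue_signatures:
        for row, mm in enumerate(meta):
            if mm.cancer_type == tspec.cancer:
                values[row, tspec.feature] += tspec.offset

    # structure features: group means by (preparation, lesion)
    for spec in config.structures:
        means = spec.group_means()
        for row, mm in enumerate(meta):
            g = _group_of(mm)
            values[row, spec.feature] += means.get(g, 0.0)

    fdf = pd.DataFrame(
        factors,
        index=pd.Index([mm.slide_id for mm in meta], name="slide_id"),
        columns=[f"block_{i}" for i in range(len(config.blocks))],
    )
    return values, fdf


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, list[SlideMeta], SyntheticTruth]:
    """Generate the tile table, slide metadata and ground truth.

    Returns ``(tiles, meta, truth)`` where ``tiles`` has columns
    ``slide_id, tile_index, f0..f{M-1}``.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    meta = _make_meta(config)
    rng = _spawn(config.seed, "cohort")
    slide_vals, factors = _slide_values(config, meta, rng)

    lo, hi = config.tiles_per_slide
    tile_counts = rng.integers(lo, hi + 1, size=len(meta))
    frames = []
    for row, (mm, n_tiles) in enumerate(zip(meta, tile_counts)):
        noise = rng.standard_normal((n_tiles, config.n_features)) * config.tile_noise_sd
        tiles = slide_vals[row][None, :] + noise
        df = pd.DataFrame(tiles, columns=[f"f{j}" for j in range(config.n_features)])
        df.insert(0, "tile_index", np.arange(n_tiles))
        df.insert(0, "slide_id", mm.slide_id)
        frames.append(df)
    tile_table = pd.concat(frames, ignore_index=True)

    markers_by_cancer: dict[str, set[int]] = {c: set() for c in config.cancers()}
    for spec in config.markers:
        for c in spec.cancers:
            markers_by_cancer[c].add(spec.feature)
    pairs_by_cancer: dict[str, set[tuple[int, int]]] = {c: set() for c in config.cancers()}
    for block in config.blocks:
        feats = sorted(block.features)
        pairs = {
            (feats[i], feats[j])
            for i in range(len(feats))
            for j in range(i + 1, len(feats))
        }
        for c in block.cancers:
            pairs_by_cancer[c] |= pairs
    structure_labels = {s.feature: s.structure for s in config.structures}

    truth = SyntheticTruth(
        markers_by_cancer=markers_by_cancer,
        correlated_pairs_by_cancer=pairs_by_cancer,
        structure_labels=structure_labels,
        gene_couplings={},
        factors=factors,
        slide_values=pd.DataFrame(
            slide_vals,
            index=factors.index,
            columns=[f"mone_{j}" for j in range(config.n_features)],
        ),
    )
    return tile_table, meta, truth


def _coupling_signal(
    spec, truth: SyntheticTruth, meta: list[SlideMeta]
) -> np.ndarray:
    if spec.block is not None:
        return truth.factors.iloc[:, spec.block].to_numpy()
    return truth.slide_values[f"mone_{spec.feature}"].to_numpy()


def generate_expression(
    truth: SyntheticTruth,
    meta: list[SlideMeta],
    config: GeneratorConfig,
) -> ExpressionMatrix:
    """Expression profiles for every vial in the cohort.

    Coupled genes mix the standardized coupling signal at the target
    correlation; others are independent Gaussian noise on the log scale.
    A configurable fraction of genes is zero-inflated or near-constant to
    exercise the integration filters.  Deterministic given ``config.seed``.
    """
    rng = _spawn(config.seed, "expression")
    vials = list(dict.fromkeys(m.vial_id for m in meta))
    vial_row = {v: i for i, v in enumerate(vials)}
    n = len(vials)

    gene_names = [f"G{j:04d}" for j in range(config.n_genes)]
    values = rng.standard_normal((n, config.n_genes))

    coupled: dict[str, dict] = {}
    for spec in config.gene_couplings:
        signal = _coupling_signal(spec, truth, meta)
        # slide signal -> vial signal (first slide of each vial)
        sig = np.zeros(n)
        seen: set[str] = set()
        for m_i, mm in enumerate(meta):
            if mm.vial_id not in seen:
                sig[vial_row[mm.vial_id]] = signal[m_i]
                seen.add(mm.vial_id)
        sig = (sig - sig.mean()) / sig.std()
        for g in spec.genes:
            j = gene_names.index(g) if g in gene_names else None
            if j is None:
                raise ValueError(f"unknown gene {g!r} in coupling spec")
            r = spec.target_r
            values[:, j] = r * sig + np.sqrt(1 - r * r) * values[:, j]
            coupled[g] = {
                "target_r": r,
                "feature": spec.feature,
                "block": spec.block,
            }

    values = values * config.gene_sd + config.gene_mean

    free = [j for j, g in enumerate(gene_names) if g not in coupled]
    rng.shuffle(free)
    n_zero = int(config.zero_inflated_gene_fraction * config.n_genes)
    n_low = int(config.low_sd_gene_fraction * config.n_genes)
    for j in free[:n_zero]:
        mask = rng.random(n) < 0.7  # zero in 70% of samples -> filtered
        values[mask, j] = 0.0
    for j in free[n_zero : n_zero + n_low]:
        values[:, j] = config.gene_mean + 0.1 * rng.standard_normal(n)

    truth.gene_couplings = coupled
    return ExpressionMatrix(values, vials, gene_names)


def generate_covariate(
    spec: CovariateCouplingSpec,
    truth: SyntheticTruth,
    meta: list[SlideMeta],
    config: GeneratorConfig,
) -> dict[str, float]:
    """A per-slide covariate correlated with a feature or latent factor."""
    rng = _spawn(config.seed, f"covariate:{spec.name}")
    signal = _coupling_signal(spec, truth, meta)
    signal = (signal - signal.mean()) / signal.std()
    r = spec.target_r
    noise = rng.standard_normal(len(meta))
    vals = r * signal + np.sqrt(1 - r * r) * noise
    return {m.slide_id: float(v) for m, v in zip(meta, vals)}
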