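"""Core containers for slide-level image-feature analysis.

A whole-slide image is decomposed into tiles, each tile yields a vector of
M deep-image features ("mones"), and the per-feature median over a slide's
tiles gives the slide-level mone vector.  Slides carry metadata (patient,
cancer type, tumor/normal lesion, frozen/FFPE preparation, and the vial id
that links a slide to its bulk expression profile).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SlideMeta",
    "MoneMatrix",
    "ExpressionMatrix",
    "CovariateVector",
    "aggregate_tiles",
    "match_slides_to_expression",
    "tcga_vial_id",
    "meta_frame",
]

LESIONS = ("tumor", "normal")
PREPARATIONS = ("frozen", "FFPE")


@dataclass(frozen=True)
class SlideMeta:
    """Metadata for one slide."""

    slide_id: str
    patient_id: str
    cancer_type: str
    lesion: str
    preparation: str
    vial_id: str

    def __post_init__(self) -> None:
        if self.lesion not in LESIONS:
            raise ValueError(f"lesion must be one of {LESIONS}, got {self.lesion!r}")
        if self.preparation not in PREPARATIONS:
            raise ValueError(
                f"preparation must be one of {PREPARATIONS}, got {self.preparation!r}"
            )


def meta_frame(meta: Sequence[SlideMeta]) -> pd.DataFrame:
    """Tabular view of a list of :class:`SlideMeta` (one row per slide)."""
    return pd.DataFrame(
        {
            "slide_id": [m.slide_id for m in meta],
            "patient_id": [m.patient_id for m in meta],
            "cancer_type": [m.cancer_type for m in meta],
            "lesion": [m.lesion for m in meta],
            "preparation": [m.preparation for m in meta],
            "vial_id": [m.vial_id for m in meta],
        }
    )


def _check_unique_slides(meta: Sequence[SlideMeta]) -> None:
    ids = [m.slide_id for m in meta]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate slide ids in metadata: {dupes}")


class MoneMatrix:
    """Slides x features matrix with aligned metadata.

    ``values`` is a float array of shape (n_slides, M); row order matches
    ``meta`` exactly; columns are labeled by integer mone ids.
    """

    def __init__(
        self,
        values: np.ndarray,
        meta: Sequence[SlideMeta],
        feature_ids: Sequence[int] | None = None,
    ):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (slides x features)")
        if values.shape[0] != len(meta):
            raise ValueError(
                f"{values.shape[0]} rows but {len(meta)} metadata entries"
            )
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(f"non-finite value at (slide {bad[0]}, feature {bad[1]})")
        _check_unique_slides(meta)
        if feature_ids is None:
            feature_ids = np.arange(values.shape[1])
        feature_ids = np.asarray(feature_ids, dtype=int)
        if len(set(feature_ids.tolist())) != len(feature_ids):
            raise ValueError("feature ids must be unique")
        if len(feature_ids) != values.shape[1]:
            raise ValueError("feature_ids length does not match value columns")
        self.values = values
        self.meta = list(meta)
        self.feature_ids = feature_ids

    @property
    def n_slides(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def slide_ids(self) -> list[str]:
        return [m.slide_id for m in self.meta]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.slide_ids, name="slide_id"),
            columns=[f"mone_{i}" for i in self.feature_ids],
        )

    def subset_slides(self, mask: np.ndarray) -> "MoneMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return MoneMatrix(
            self.values[idx], [self.meta[i] for i in idx], self.feature_ids
        )

    def subset_features(self, feature_ids: Sequence[int]) -> "MoneMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        cols = [pos[f] for f in feature_ids]
        return MoneMatrix(self.values[:, cols], self.meta, list(feature_ids))

    def select(self, **conditions: str) -> "MoneMatrix":
        """Subset slides by metadata equality, e.g. ``select(lesion="tumor")``."""
        mask = np.ones(self.n_slides, dtype=bool)
        for field, value in conditions.items():
            mask &= np.array([getattr(m, field) == value for m in self.meta])
        return self.subset_slides(mask)


class ExpressionMatrix:
    """Samples x genes matrix of log-normalized abundances, keyed by vial id."""

    def __init__(self, values: np.ndarray, vial_ids: Sequence[str], genes: Sequence[str]):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (samples x genes)")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if values.shape != (len(vial_ids), len(genes)):
            raise ValueError("shape does not match key lengths")
        if len(set(genes)) != len(genes):
            raise ValueError("gene symbols must be unique")
        self.values = values
        self.vial_ids = [str(v) for v in vial_ids]
        self.genes = [str(g) for g in genes]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.vial_ids, name="vial_id"), columns=self.genes
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        cols = [pos[g] for g in genes]
        return ExpressionMatrix(self.values[:, cols], self.vial_ids, list(genes))

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = list(idx)
        return ExpressionMatrix(
            self.values[idx], [self.vial_ids[i] for i in idx], self.genes
        )


@dataclass
class CovariateVector:
    """A named per-slide (or per-vial) scalar covariate; missing keys allowed."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"covariate {self.name!r} non-finite at key {k!r}")

    def get(self, key: str) -> float | None:
        return self.values.get(key)


def aggregate_tiles(
    tiles: pd.DataFrame, meta: Sequence[SlideMeta], stat: str = "median"
) -> MoneMatrix:
    """Collapse a tile-level feature table to one row per slide.

    ``tiles`` must have columns ``slide_id``, ``tile_index`` and ``f0..f{M-1}``.
    The only supported statistic is the per-feature median across a slide's
    tiles (even tile counts use the mean of the two central order statistics).
    """
    if stat != "median":
        raise ValueError(f"unsupported aggregation statistic {stat!r}")
    _check_unique_slides(meta)
    feat_cols = [c for c in tiles.columns if re.fullmatch(r"f\d+", str(c))]
    feat_cols.sort(key=lambda c: int(c[1:]))
    if not feat_cols:
        raise ValueError("tile table has no feature columns (expected f0..f{M-1})")
    vals = tiles[feat_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        r, c = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"non-finite feature value at tile row {r}, column {feat_cols[c]}"
        )
    present = set(tiles["slide_id"].astype(str))
    missing = [m.slide_id for m in meta if m.slide_id not in present]
    if missing:
        raise ValueError(f"slides with zero tiles: {missing}")
    med = (
        tiles.assign(slide_id=tiles["slide_id"].astype(str))
        .groupby("slide_id", sort=False)[feat_cols]
        .median()
    )
    ordered = med.loc[[m.slide_id for m in meta]]
    return MoneMatrix(
        ordered.to_numpy(), meta, [int(c[1:]) for c in feat_cols]
    )


def tcga_vial_id(slide_id: str) -> str:
    """Vial-level key of a TCGA-style barcode.

    ``TCGA-A1-A0SB-01A-...`` maps to ``TCGA-A1-A0SB-01A`` (project, site,
    participant, sample+vial).  Ids with fewer than four dash-separated parts
    are returned unchanged (already sample-level keys).
    """
    parts = slide_id.strip().split("-")
    if len(parts) < 4:
        return slide_id.strip()
    return "-".join(parts[:4])


def _norm_key(key: str) -> str:
    return key.strip().upper()


def match_slides_to_expression(
    mones: MoneMatrix,
    expr: ExpressionMatrix,
    key_fn: Callable[[str], str] | None = None,
) -> list[tuple[int, int]]:
    """Pair slide rows with expression rows sharing the same vial id.

    Keys are compared as exact strings after whitespace/case normalization
    (and optional ``key_fn`` extraction on the slide side).  Duplicate vial
    ids on either side raise, so pairing is never ambiguous.
    """
    slide_keys = [m.vial_id for m in mones.meta]
    if key_fn is not None:
        slide_keys = [key_fn(k) for k in slide_keys]
    slide_keys = [_norm_key(k) for k in slide_keys]
    expr_keys = [_norm_key(k) for k in expr.vial_ids]

    for side, keys in (("slide", slide_keys), ("expression", expr_keys)):
        seen: dict[str, int] = {}
        for k in keys:
            seen[k] = seen.get(k, 0) + 1
        dupes = sorted(k for k, n in seen.items() if n > 1)
        if dupes:
            raise ValueError(f"ambiguous vial ids on the {side} side: {dupes}")

    expr_pos = {k: i for i, k in enumerate(expr_keys)}
    pairs = [
        (i, expr_pos[k]) for i, k in enumerate(slide_keys) if k in expr_pos
    ]
    if not pairs:
        warnings.warn("no common vial ids between slides and expression profiles")
    return pairs
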