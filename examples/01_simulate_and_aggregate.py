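"""Simulate a small cohort and aggregate tile features to slide level.

Builds a two-cancer cohort with one planted tumor marker, generates
tile-level feature tables, and collapses them to the slide x feature mone
matrix by per-feature median.
"""

import numpy as np

import monekit as mk

cfg = mk.GeneratorConfig(
    n_cancers=2,
    n_features=50,
    n_frozen_tumor=30,
    n_frozen_normal=30,
    n_ffpe_tumor=10,
    tiles_per_slide=(10, 20),
    markers=(mk.MarkerSpec(feature=7, cancers=("C00",), delta=2.0),),
    seed=1,
)
tiles, meta, truth = mk.generate_cohort(cfg)
mones = mk.aggregate_tiles(tiles, meta)

print(f"cohort: {len(meta)} slides, {len(tiles)} tiles, "
      f"{mones.n_features} features per slide")
c00 = mones.select(cancer_type="C00", preparation="frozen")
tumor = c00.select(lesion="tumor").values[:, 7]
normal = c00.select(lesion="normal").values[:, 7]
print(f"planted marker (feature 7) means: tumor {tumor.mean():.2f}, "
      f"normal {normal.mean():.2f}")
print("The tumor mean sits ~2 slide-level sd above normal — the planted "
      "effect survives the tile-noise + median-aggregation round trip.")
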