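import numpy as np
import pytest

import monekit as mk


@pytest.fixture(scope="session")
def small_cohort():
    """Two-cancer cohort with one marker, one correlated block, one
    structure-B feature and coupled genes; shared across read-only tests."""
    cfg = mk.GeneratorConfig(
        n_cancers=2,
        n_features=40,
        n_frozen_tumor=25,
        n_frozen_normal=25,
        n_ffpe_tumor=15,
        tiles_per_slide=(5, 9),
        markers=(mk.MarkerSpec(feature=3, cancers=("C00",), delta=2.0),),
        blocks=(mk.BlockSpec(features=(10, 11, 12), rho=0.7, cancers=("C00", "C01")),),
        structures=(mk.StructureSpec(feature=20, structure="B", shift=2.0),),
        gene_couplings=(
            mk.GeneCouplingSpec(genes=("G0005", "G0006"), target_r=0.7, block=0),
        ),
        n_genes=60,
        seed=11,
    )
    tiles, meta, truth = mk.generate_cohort(cfg)
    mones = mk.aggregate_tiles(tiles, meta)
    expr = mk.generate_expression(truth, meta, cfg)
    return cfg, tiles, meta, truth, mones, expr


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
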