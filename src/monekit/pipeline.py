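"""End-to-end pipeline: aggregate -> differential (+OBF) -> correlation ->
classification -> integration, with a JSON manifest of outputs."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    class_labels,
    evaluate,
    fit_lr_lasso,
    fit_mlda,
    macro_ovr_auc,
    make_splits,
)
from .correlation import correlated_pairs, differential_correlation, shrinkage_correlation
from .data import MoneMatrix, aggregate_tiles, match_slides_to_expression
from .differential import run_tests, top_k_markers
from .integrate import GeneFilterConfig, extract_bicluster, filter_genes, mone_gene_correlation
from .io import read_expression, read_meta, read_table, write_mones, write_table
from .obf import ObfConfig, obf_scan, select_fdr_obf

log = logging.getLogger("monekit")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, contrasts, stage alphas and toggles for one pipeline run."""

    tiles: str | None = None
    mones: str | None = None
    meta: str = ""
    expression: str | None = None
    out_dir: str = "monekit_out"
    contrast: str = "lesion"  # metadata field giving the two classes
    positive: str = "tumor"
    alpha_differential: float = 0.05
    alpha_correlation: float = 0.05
    alpha_high_correlation: float = 0.001
    alpha_integration: float = 0.05
    frozen_only: bool = True
    seed: int = 0
    n_reps: int = 3
    stages: tuple[str, ...] = (
        "aggregate", "differential", "correlation", "classification", "integration",
    )

    def validate(self) -> None:
        for a in (
            self.alpha_differential,
            self.alpha_correlation,
            self.alpha_high_correlation,
            self.alpha_integration,
        ):
            if not 0 < a < 1:
                raise ValueError("alpha levels must lie in (0, 1)")
        if not self.meta:
            raise ValueError("meta table path is required")
        if self.tiles is None and self.mones is None:
            raise ValueError("either a tile table or a mone matrix is required")
        if "integration" in self.stages and self.expression is None:
            raise ValueError("integration stage enabled but no expression input")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the output manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    manifest_path = out / "manifest.json"

    def _fail(stage: str, err: Exception):
        manifest["failed_stage"] = stage
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    meta = read_meta(config.meta)

    # --- aggregate ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.mones is not None:
            from .io import read_mones

            mones = read_mones(config.mones, meta)
        else:
            tiles = read_table(config.tiles)
            mones = aggregate_tiles(tiles, meta)
            write_mones(mones, out / "mones.tsv")
    except Exception as e:  # noqa: BLE001
        _fail("aggregate", e)
    manifest["stages"]["aggregate"] = {
        "n_slides": mones.n_slides,
        "n_features": mones.n_features,
        "seconds": round(time.perf_counter() - t0, 3),
    }
    log.info("aggregate: %d slides x %d features", mones.n_slides, mones.n_features)

    frozen = mones.select(preparation="frozen") if config.frozen_only else mones
    labels = np.array(
        [getattr(m, config.contrast) == config.positive for m in frozen.meta]
    )

    # --- differential ------------------------------------------------------
    if "differential" in config.stages:
        t0 = time.perf_counter()
        try:
            diff = run_tests(frozen.values, labels, feature_ids=frozen.feature_ids)
            write_table(diff.table.reset_index(), out / "differential.tsv")
            post, am = obf_scan(frozen.values, labels)
            sel = select_fdr_obf(np.nan_to_num(post), config.alpha_differential)
            obf_tbl = pd.DataFrame(
                {"feature": frozen.feature_ids, "posterior": post, "am": am,
                 "fdr_obf_selected": np.isin(np.arange(len(post)), sel)}
            )
            write_table(obf_tbl, out / "obf.tsv")
        except Exception as e:  # noqa: BLE001
            _fail("differential", e)
        n_sig = int((diff.table["q_t"] < config.alpha_differential).sum())
        manifest["stages"]["differential"] = {
            "n_significant_t": n_sig,
            "n_fdr_obf": int(len(sel)),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    # --- correlation -------------------------------------------------------
    if "correlation" in config.stages:
        t0 = time.perf_counter()
        try:
            tumor = frozen.select(lesion="tumor")
            normal = frozen.select(lesion="normal")
            corr = shrinkage_correlation(tumor.values)
            pairs, frac = correlated_pairs(corr, config.alpha_correlation)
            np.save(out / "correlation_tumor.npy", corr.r)
            delta, p, q = differential_correlation(
                tumor.values, normal.values, config.alpha_correlation
            )
            np.save(out / "correlation_delta.npy", delta)
        except Exception as e:  # noqa: BLE001
            _fail("correlation", e)
        manifest["stages"]["correlation"] = {
            "fraction_correlated": frac,
            "n_pairs_significant": len(pairs),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    # --- classification ----------------------------------------------------
    if "classification" in config.stages:
        t0 = time.perf_counter()
        try:
            y = class_labels(mones.meta, "38class")
            plan = make_splits(mones.meta, n_reps=config.n_reps, seed=config.seed)
            reports = {"mlda": [], "lasso": []}
            for train_idx, test_idx in plan:
                X_tr, X_te = mones.values[train_idx], mones.values[test_idx]
                y_tr, y_te = y[train_idx], y[test_idx]
                reports["mlda"].append(evaluate(fit_mlda(X_tr, y_tr), X_te, y_te))
                reports["lasso"].append(
                    evaluate(fit_lr_lasso(X_tr, y_tr, seed=config.seed), X_te, y_te)
                )
        except Exception as e:  # noqa: BLE001
            _fail("classification", e)
        stage = {}
        for name, reps in reports.items():
            mean, sd = macro_ovr_auc(reps)
            stage[f"{name}_macro_ovr_auc_mean"] = mean
            stage[f"{name}_macro_ovr_auc_sd"] = sd
        stage["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"]["classification"] = stage

    # --- integration -------------------------------------------------------
    if "integration" in config.stages:
        t0 = time.perf_counter()
        try:
            expr = read_expression(config.expression)
            pairs_idx = match_slides_to_expression(mones, expr)
            slide_rows = [i for i, _ in pairs_idx]
            expr_rows = [j for _, j in pairs_idx]
            expr_paired = expr.subset_samples(expr_rows)
            expr_f = filter_genes(expr_paired, GeneFilterConfig())
            res = mone_gene_correlation(
                mones.values[slide_rows],
                list(mones.feature_ids),
                expr_f.values,
                expr_f.genes,
                config.alpha_integration,
            )
            clusters = extract_bicluster(res, config.alpha_integration)
        except Exception as e:  # noqa: BLE001
            _fail("integration", e)
        manifest["stages"]["integration"] = {
            "n_paired": len(pairs_idx),
            "n_genes_kept": expr_f.n_genes,
            "n_significant_pairs": int((res.q <= config.alpha_integration).sum()),
            "n_biclusters": len(clusters),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
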