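"""Feature-gene integration: filters, stacked-correlation block, bicluster
extraction, PC-1 cluster scores, covariate correlation and the IG score."""

import numpy as np
import pytest

import monekit as mk
from monekit.data import CovariateVector, ExpressionMatrix
from monekit.integrate import (
    GeneFilterConfig,
    cluster_pc1,
    correlate_with_covariate,
    extract_bicluster,
    filter_genes,
    ig_score,
    mone_gene_correlation,
)


def _expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, [f"V{i}" for i in range(values.shape[0])], genes)


class TestFilterGenes:
    def test_constant_gene_removed(self, rng):
        x = rng.standard_normal((20, 2)) + 3
        x[:, 1] = 5.0
        kept = filter_genes(_expr(x))
        assert kept.genes == ["G0"]

    def test_mostly_zero_gene_removed(self, rng):
        x = np.abs(rng.standard_normal((20, 2))) + 1
        x[:12, 1] = 0.0  # zero in 60% of samples
        kept = filter_genes(_expr(x))
        assert kept.genes == ["G0"]

    def test_borderline_gene_kept(self, rng):
        x = np.abs(rng.standard_normal((50, 1))) + 1
        x[:5, 0] = 0.0  # 10% zeros, sd well above 0.25
        kept = filter_genes(_expr(x))
        assert kept.genes == ["G0"]

    def test_idempotent(self, rng):
        x = rng.standard_normal((30, 5)) + 2
        x[:, 2] = 1.0
        once = filter_genes(_expr(x))
        twice = filter_genes(once)
        assert once.genes == twice.genes
        assert np.array_equal(once.values, twice.values)

    def test_all_removed_is_error(self):
        with pytest.raises(ValueError, match="all genes"):
            filter_genes(_expr(np.ones((10, 2))))


class TestMoneGeneCorrelation:
    def test_gene_copy_of_mone_near_one(self, rng):
        mones = rng.standard_normal((200, 3))
        genes = np.c_[mones[:, 0], rng.standard_normal(200)]
        res = mone_gene_correlation(mones, [0, 1, 2], genes, ["copy", "noise"])
        assert res.r.shape == (3, 2)
        assert res.r_sample[0, 0] > 0.999
        assert res.r[0, 0] > 0.9  # shrinkage pulls the estimate slightly down
        assert res.q[0, 0] < 1e-10

    def test_planted_coupling_detected_null_clean(self):
        r = np.random.default_rng(0)
        factor = r.standard_normal(300)
        mones = np.sqrt(0.7) * factor[:, None] + np.sqrt(0.3) * r.standard_normal((300, 4))
        genes = r.standard_normal((300, 50))
        genes[:, 0] = 0.7 * (factor - factor.mean()) / factor.std() + np.sqrt(1 - 0.49) * genes[:, 0]
        res = mone_gene_correlation(mones, list(range(4)), genes,
                                    [f"G{j}" for j in range(50)])
        assert np.all(res.q[:, 0] < 0.05)          # coupled gene hits all mones
        assert (res.q[:, 1:] < 0.05).mean() < 0.02  # null genes stay null

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="4"):
            mone_gene_correlation(rng.standard_normal((3, 2)), [0, 1],
                                  rng.standard_normal((3, 2)), ["a", "b"])


class TestBicluster:
    def test_empty_graph_empty_list(self):
        from monekit.integrate import MoneGeneResult

        q = np.ones((3, 4))
        res = MoneGeneResult(r=np.zeros((3, 4)), r_sample=np.zeros((3, 4)),
                             p=q, q=q,
                             feature_ids=[0, 1, 2], genes=list("abcd"), n=50)
        assert extract_bicluster(res) == []

    def test_two_disjoint_blocks_two_components(self):
        from monekit.integrate import MoneGeneResult

        q = np.ones((5, 6))
        q[:2, :3] = 0.001   # block 1: mones {0,1} x genes {a,b,c}
        q[3:, 4:] = 0.001   # block 2: mones {3,4} x genes {e,f}
        r = np.where(q < 0.05, 0.9, 0.0)
        res = MoneGeneResult(r=r, r_sample=r, p=q, q=q,
                             feature_ids=list(range(5)), genes=list("abcdef"), n=50)
        comps = extract_bicluster(res, alpha=0.05)
        assert len(comps) == 2
        sizes = sorted((sorted(c.features), sorted(c.genes)) for c in comps)
        assert sizes == [([0, 1], ["a", "b", "c"]), ([3, 4], ["e", "f"])]

    def test_planted_block_recovered_end_to_end(self):
        r = np.random.default_rng(1)
        factor = r.standard_normal(300)
        mones = np.sqrt(0.8) * factor[:, None] + np.sqrt(0.2) * r.standard_normal((300, 5))
        genes = r.standard_normal((300, 208))
        for j in range(8):
            genes[:, j] = 0.7 * (factor - factor.mean()) / factor.std() \
                + np.sqrt(1 - 0.49) * genes[:, j]
        res = mone_gene_correlation(mones, list(range(5)), genes,
                                    [f"G{j}" for j in range(208)])
        comps = extract_bicluster(res, alpha=0.05)
        assert len(comps) >= 1
        main = comps[0]
        coupled = {f"G{j}" for j in range(8)}
        assert len(set(main.genes) & coupled) >= 7  # >= 90% gene recall
        # false-edge proportion of the significance graph stays BH-controlled
        sig = res.q <= 0.05
        edge_fdp = sig[:, 8:].sum() / max(1, sig.sum())
        assert edge_fdp <= 0.1


class TestClusterPc1:
    def test_two_perfectly_correlated_members(self, rng):
        x = rng.standard_normal(50)
        score = cluster_pc1(np.c_[x, 2 * x], [4, 9])
        assert score.variance_explained == pytest.approx(1.0)

    def test_independent_members_share_variance(self, rng):
        score = cluster_pc1(rng.standard_normal((3000, 5)), list(range(5)))
        assert score.variance_explained == pytest.approx(0.2, abs=0.03)

    def test_matches_hand_eigenproblem(self):
        vals = np.array([[1.0, 2.0, 0.5], [2.0, 3.0, 1.5], [3.0, 5.0, 2.0],
                         [4.0, 6.0, 3.5]])
        score = cluster_pc1(vals, [0, 1, 2])
        cov = np.cov(vals, rowvar=False, bias=True)
        w, v = np.linalg.eigh(cov)
        lead = v[:, np.argmax(w)]
        if lead[0] < 0:
            lead = -lead
        assert np.allclose(np.abs(score.loadings), np.abs(lead), atol=1e-10)
        assert score.variance_explained == pytest.approx(w.max() / w.sum())

    def test_sign_convention_smallest_id_non_negative(self, rng):
        x = rng.standard_normal((40, 2))
        score = cluster_pc1(x, [7, 3])
        assert score.loadings[np.argmin([7, 3])] >= 0

    def test_degenerate_member_set_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cluster_pc1(np.ones((10, 2)), [0, 1])

    def test_pc1_tracks_latent_factor(self):
        r = np.random.default_rng(2)
        factor = r.standard_normal(300)
        x = np.sqrt(0.7) * factor[:, None] + np.sqrt(0.3) * r.standard_normal((300, 6))
        score = cluster_pc1(x, list(range(6)))
        assert abs(np.corrcoef(score.pc1, factor)[0, 1]) >= 0.9


class TestCovariateCorrelation:
    def test_affine_transform_r_one(self, rng):
        keys = [f"S{i}" for i in range(30)]
        score = dict(zip(keys, rng.standard_normal(30)))
        cov = CovariateVector("c", {k: 3 * v - 1 for k, v in score.items()})
        r, p, n = correlate_with_covariate(score, cov)
        assert r == pytest.approx(1.0)
        assert n == 30

    def test_independent_draws_usually_small(self):
        small = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            keys = [f"S{i}" for i in range(200)]
            score = dict(zip(keys, r.standard_normal(200)))
            cov = CovariateVector("c", dict(zip(keys, r.standard_normal(200))))
            rr, _, _ = correlate_with_covariate(score, cov)
            small += abs(rr) < 0.2
        assert small >= 19

    def test_trim_rule_drops_exactly_above_threshold(self, rng):
        keys = [f"S{i}" for i in range(10)]
        score = dict(zip(keys, rng.standard_normal(10)))
        cov_vals = dict(zip(keys, [0.01, 0.02, 0.05, 0.01, 0.02, 0.01, 0.02,
                                   0.01, 0.02, 0.01]))
        cov = CovariateVector("bcell", cov_vals)
        _, _, n = correlate_with_covariate(score, cov, trim_above=0.03)
        assert n == 9

    def test_missing_keys_excluded_pairwise(self, rng):
        keys = [f"S{i}" for i in range(8)]
        score = dict(zip(keys, rng.standard_normal(8)))
        cov = CovariateVector("c", {k: 1.0 * i for i, k in enumerate(keys[:5])})
        _, _, n = correlate_with_covariate(score, cov)
        assert n == 5

    def test_too_few_pairs_rejected(self, rng):
        score = {"a": 1.0, "b": 2.0}
        cov = CovariateVector("c", {"a": 1.0, "b": 0.5})
        with pytest.raises(ValueError, match="4"):
            correlate_with_covariate(score, cov)


class TestIgScore:
    def test_all_ones_gives_one(self):
        e = _expr(np.ones((5, 3)) * 1.0, ["IGHA1", "IGHG1", "IGKC"])
        assert np.allclose(ig_score(e, ["IGHA1", "IGHG1", "IGKC"]), 1.0)

    def test_single_gene_identity(self, rng):
        x = rng.standard_normal((10, 2))
        e = _expr(x, ["A", "B"])
        assert np.allclose(ig_score(e, ["B"]), x[:, 1])

    def test_mean_matches_loop_oracle(self, rng):
        x = rng.standard_normal((6, 4))
        e = _expr(x, list("abcd"))
        got = ig_score(e, ["a", "c", "d"])
        manual = np.array([np.mean([x[i, 0], x[i, 2], x[i, 3]]) for i in range(6)])
        assert np.allclose(got, manual)

    def test_missing_genes_reported(self, rng):
        e = _expr(rng.standard_normal((5, 2)), ["A", "B"])
        with pytest.raises(ValueError, match="coverage"):
            ig_score(e, ["A", "MISSING"])
        with pytest.warns(UserWarning, match="MISSING"):
            out = ig_score(e, ["A", "MISSING"], min_coverage=0.5)
        assert out.shape == (5,)
        with pytest.raises(ValueError, match="no gene"):
            ig_score(e, ["X", "Y"])
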