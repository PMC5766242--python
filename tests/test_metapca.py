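"""Meta-PCA: per-tissue PC1, separation filter, alignment, M-scores, validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from chaperoscope import expression as ex
from chaperoscope import metapca as mp
from chaperoscope import synthetic as syn


def _expr(arr, index=None, columns=None):
    arr = np.asarray(arr, dtype=float)
    index = index or list(range(1, arr.shape[0] + 1))
    columns = columns or [f"s{i}" for i in range(arr.shape[1])]
    return ex.ExpressionMatrix(pd.DataFrame(arr, index=index, columns=columns),
                               centered=True)


class TestFitTissuePc1:
    def test_rank_one_family_loads_equally(self):
        base = np.array([0.0, 1.0, -1.0, 2.0, -2.0, 0.5])
        e = _expr(np.vstack([base, base]))           # perfectly correlated pair
        tl = mp.fit_tissue_pc1(e, "F", [1, 2], tissue="T")
        np.testing.assert_allclose(np.abs(tl.loadings),
                                   [1 / np.sqrt(2)] * 2, atol=1e-9)

    def test_loadings_unit_norm(self):
        rng = np.random.default_rng(0)
        e = _expr(rng.normal(size=(6, 10)))
        tl = mp.fit_tissue_pc1(e, "F", list(range(1, 7)))
        assert np.linalg.norm(tl.loadings) == pytest.approx(1.0, abs=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(5, 12))
        a = mp.fit_tissue_pc1(_expr(arr), "F", list(range(1, 6)))
        b = mp.fit_tissue_pc1(_expr(3.7 * arr), "F", list(range(1, 6)))
        assert np.allclose(a.loadings, b.loadings) or \
            np.allclose(a.loadings, -b.loadings)

    def test_too_few_genes_rejected(self):
        e = _expr(np.zeros((3, 5)))
        with pytest.raises(ValueError, match="fewer than 2"):
            mp.fit_tissue_pc1(e, "F", [1])

    def test_missing_genes_recorded(self):
        rng = np.random.default_rng(2)
        e = _expr(rng.normal(size=(3, 6)))
        tl = mp.fit_tissue_pc1(e, "F", [1, 2, 3, 99])
        assert tl.missing_genes == [99]


class TestSeparationFilter:
    def _programmed(self, shift, seed=0, n=20):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(4, 2 * n))
        arr[:, :n] += shift
        e = _expr(arr)
        labels = np.array(["tumor"] * n + ["normal"] * n)
        tl = mp.fit_tissue_pc1(e, "F", [1, 2, 3, 4], tissue="T")
        return mp.separation_filter(tl, labels), labels

    def test_programmed_effect_retained(self):
        tl, _ = self._programmed(3.0)
        assert tl.retained and tl.separation_p <= 1e-4

    def test_null_mostly_not_retained(self):
        retained = sum(self._programmed(0.0, seed=s)[0].retained
                       for s in range(20))
        assert retained <= 1

    def test_threshold_one_retains_everything(self):
        rng = np.random.default_rng(5)
        e = _expr(rng.normal(size=(4, 12)))
        labels = np.array(["tumor"] * 6 + ["normal"] * 6)
        tl = mp.fit_tissue_pc1(e, "F", [1, 2, 3, 4])
        assert mp.separation_filter(tl, labels, threshold=1.0).retained


class TestAlignment:
    def _tl(self, vec, p, tissue):
        v = np.asarray(vec, dtype=float)
        tl = mp.TissueLoadings(family="F", tissue=tissue,
                               genes=list(range(1, len(v) + 1)),
                               loadings=v / np.linalg.norm(v),
                               scores=pd.Series(dtype=float),
                               separation_p=p, retained=True)
        return tl

    def test_opposite_vectors_made_consistent(self):
        v = np.array([0.6, 0.8])
        aligned, ref = mp.align_and_orient(
            [self._tl(v, 1e-9, "A"), self._tl(-v, 1e-5, "B")], [1, 2])
        np.testing.assert_allclose(aligned[0], aligned[1])
        assert ref == "A"

    def test_orientation_anchors_to_positive_loading_mass(self):
        v = np.array([-0.6, -0.8])
        aligned, _ = mp.align_and_orient([self._tl(v, 1e-9, "A")], [1, 2])
        assert np.nansum(aligned[0]) > 0

    def test_combine_mean_and_renormalize(self):
        a = self._tl([1.0, 0.0], 1e-9, "A")
        b = self._tl([0.0, 1.0], 1e-6, "B")
        aligned, ref = mp.align_and_orient([a, b], [1, 2])
        mpc = mp.combine_meta_pc(aligned, "F", [1, 2], ["A", "B"], ref)
        np.testing.assert_allclose(mpc.weights, [1 / np.sqrt(2)] * 2)

    def test_single_tissue_mean_is_itself(self):
        a = self._tl([0.6, 0.8], 1e-9, "A")
        aligned, ref = mp.align_and_orient([a], [1, 2])
        mpc = mp.combine_meta_pc(aligned, "F", [1, 2], ["A"], ref)
        np.testing.assert_allclose(mpc.weights, [0.6, 0.8], atol=1e-12)

    def test_tissue_order_invariance(self):
        tls = [self._tl([0.6, 0.8], 1e-7, "A"),
               self._tl([-0.6, -0.8], 1e-9, "B"),
               self._tl([0.8, 0.6], 1e-5, "C")]
        a1, _ = mp.align_and_orient(tls, [1, 2])
        a2, _ = mp.align_and_orient(tls[::-1], [1, 2])
        m1 = mp.combine_meta_pc(a1, "F", [1, 2], ["A", "B", "C"], "B")
        m2 = mp.combine_meta_pc(a2, "F", [1, 2], ["C", "B", "A"], "B")
        np.testing.assert_allclose(m1.weights, m2.weights)


class TestScoring:
    def test_dot_product(self):
        mpc = mp.MetaPC("F", [1, 2], np.array([0.6, 0.8]), ["A"], "A")
        e = _expr([[1.0], [0.5]])
        out = mp.score_samples(e, {"F": mpc})
        assert out.loc["s0", "F"] == pytest.approx(1.0)

    def test_zero_expression_scores_zero(self):
        mpc = mp.MetaPC("F", [1, 2], np.array([0.6, 0.8]), ["A"], "A")
        e = _expr([[0.0], [0.0]])
        assert mp.score_samples(e, {"F": mpc}).loc["s0", "F"] == 0.0

    def test_missing_genes_flagged(self):
        mpc = mp.MetaPC("F", [1, 2, 3, 4], np.full(4, 0.5), ["A"], "A")
        e = _expr([[1.0]], index=[1])
        out = mp.score_samples(e, {"F": mpc})
        assert out.attrs["quality"]["F"] == "low-coverage"

    def test_downregulated_family_keeps_negative_shift(self):
        spec = syn.CohortSpec(tissues=["T1", "T2"], n_tumor=15, n_normal=15,
                              n_genes=60, families={"DOWN": 10, "UP": 10},
                              effects={"DOWN": -2.0, "UP": 2.0}, seed=8)
        counts, annot, _, fams = syn.simulate_cohort(spec)
        expr = ex.center_genes(ex.log_cpm(counts), annot)
        pcs = mp.fit_meta_pca(expr, annot, fams)
        sc = mp.score_samples(expr, pcs)
        lab = annot.condition_series().loc[sc.index].to_numpy()
        shift = sc[lab == "tumor"].mean() - sc[lab == "normal"].mean()
        assert shift["DOWN"] < 0 < shift["UP"]

    def test_parameter_recovery_rank_correlation(self):
        spec = syn.default_cohort_spec(seed=3)
        counts, annot, _, fams = syn.simulate_cohort(spec)
        expr = ex.center_genes(ex.log_cpm(counts), annot)
        pcs = mp.fit_meta_pca(expr, annot, fams)
        sc = mp.score_samples(expr, pcs)
        lab = annot.condition_series().loc[sc.index].to_numpy()
        shift = sc[lab == "tumor"].mean() - sc[lab == "normal"].mean()
        deltas = [spec.effects[f] for f in shift.index]
        assert spearmanr(deltas, shift.to_numpy()).statistic >= 0.9


class TestPolarSummary:
    def test_constant_scores_collapse(self):
        sc = pd.DataFrame({"F": [2.0] * 6})
        lab = ["tumor"] * 3 + ["normal"] * 3
        out = mp.polar_summary(sc, lab)
        assert (out.loc["F"] == 2.0).all()

    def test_uniform_grid_type7_quantiles(self):
        sc = pd.DataFrame({"F": np.arange(1.0, 101.0)})
        lab = ["tumor"] * 100
        sc2 = pd.concat([sc, sc], ignore_index=True)
        lab = ["tumor"] * 100 + ["normal"] * 100
        out = mp.polar_summary(sc2, lab)
        assert out.loc["F", "tumor_q05"] == pytest.approx(5.95)
        assert out.loc["F", "tumor_q95"] == pytest.approx(95.05)

    def test_swapping_arms_swaps_summaries(self):
        rng = np.random.default_rng(1)
        sc = pd.DataFrame({"F": rng.normal(size=20)})
        lab = np.array(["tumor"] * 10 + ["normal"] * 10)
        swapped = np.where(lab == "tumor", "normal", "tumor")
        a = mp.polar_summary(sc, lab)
        b = mp.polar_summary(sc, swapped)
        assert a.loc["F", "tumor_mean"] == b.loc["F", "normal_mean"]


class TestValidation:
    def _scores(self, separation, seed=0, n=40):
        rng = np.random.default_rng(seed)
        sc = pd.DataFrame(rng.normal(size=(2 * n, 4)),
                          columns=["F1", "F2", "F3", "F4"])
        sc.iloc[:n] += separation
        lab = np.array(["tumor"] * n + ["normal"] * n)
        return sc, lab

    def test_separated_scores_predict_well(self):
        sc, lab = self._scores(4.0)
        rep = mp.validate_mscores(sc, lab, seed=1)
        assert rep["accuracy"] > 0.9

    def test_null_scores_predict_at_chance(self):
        accs = [mp.validate_mscores(*self._scores(0.0, seed=s), seed=s)["accuracy"]
                for s in range(5)]
        assert 0.3 <= float(np.mean(accs)) <= 0.7

    def test_fixed_seed_reproducible(self):
        sc, lab = self._scores(1.0)
        assert (mp.validate_mscores(sc, lab, seed=7)
                == mp.validate_mscores(sc, lab, seed=7))

    def test_small_arms_rejected(self):
        sc, lab = self._scores(1.0, n=4)
        with pytest.raises(ValueError):
            mp.validate_mscores(sc, lab)


def test_meta_pcs_json_round_trip():
    mpc = mp.MetaPC("F", [1, 2], np.array([0.6, 0.8]), ["A", "B"], "A")
    back = mp.meta_pcs_from_json(mp.meta_pcs_to_json({"F": mpc}))
    assert back["F"].genes == [1, 2]
    np.testing.assert_allclose(back["F"].weights, [0.6, 0.8])
    assert back["F"].orientation_reference == "A"
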