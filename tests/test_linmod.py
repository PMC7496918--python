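import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from subsetseq.evaluation import bh_reference_max_error, eb_recovery_errors, null_contrast_pvalues
from subsetseq.io import SampleTable
from subsetseq.linmod import (
    DesignMatrix,
    bh_adjust,
    build_design,
    de_summary,
    estimate_prior,
    fit_models,
)
from subsetseq.linmod import test_contrast as contrast_test
from subsetseq.normalize import NormalizedMatrix

SUBSETS = ("ILC1", "ILC2", "ILCP", "Th1", "Th2", "Th17")


def _toy_norm(y, weights=None):
    genes = [f"g{i}" for i in range(y.shape[0])]
    samples = [f"s{j}" for j in range(y.shape[1])]
    return NormalizedMatrix(
        genes, samples, np.asarray(y, float),
        np.ones_like(y, dtype=float) if weights is None else weights,
        np.ones(y.shape[1]), np.full(y.shape[1], 10_000),
    )


def _two_group_design(n_per=3):
    mat = np.zeros((2 * n_per, 2))
    mat[:n_per, 0] = 1
    mat[n_per:, 1] = 1
    return DesignMatrix(mat, ["A", "B"], [f"s{j}" for j in range(2 * n_per)])


class TestBuildDesign:
    def test_subset_design_shape(self, sim_bundle):
        design = build_design(sim_bundle[1], "subset")
        assert design.matrix.shape == (18, 6)
        assert (design.matrix.sum(axis=0) == 3).all()

    def test_lineage_design_shape(self, sim_bundle):
        design = build_design(sim_bundle[1], "lineage")
        assert design.matrix.shape == (18, 2)
        assert (design.matrix.sum(axis=0) == 9).all()

    def test_empty_group_rejected(self):
        frame = pd.DataFrame(
            {"sample_id": ["a", "b"], "subset": ["ILC1", "ILC2"], "donor": ["d1", "d1"]}
        )
        with pytest.raises(ValueError, match="zero samples"):
            build_design(SampleTable(frame), "subset")

    def test_rank_deficient_design_rejected(self):
        mat = np.ones((4, 2))
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(mat, ["A", "B"], ["s0", "s1", "s2", "s3"])


class TestFitModels:
    def test_unit_weights_recover_group_means(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(20, 6))
        design = _two_group_design()
        fit = fit_models(_toy_norm(y), design)
        assert np.allclose(fit.coef[:, 0], y[:, :3].mean(axis=1), atol=1e-10)
        assert np.allclose(fit.coef[:, 1], y[:, 3:].mean(axis=1), atol=1e-10)

    def test_constant_variances_full_shrinkage(self):
        # zero spread: effectively infinite prior df and the common value as
        # prior variance (up to the O(1/df) log-scale offset of the
        # moment-matching estimator), so every posterior variance collapses
        # onto the prior
        s2 = np.full(500, 0.3)
        d0, s02 = estimate_prior(s2, 100.0)
        assert d0 >= 1e7
        assert s02 == pytest.approx(0.3, rel=0.02)
        fit_like = np.full(500, 0.3)
        post = (d0 * s02 + 100.0 * fit_like) / (d0 + 100.0)
        assert np.allclose(post, s02, rtol=1e-4)

    def test_hyperparameter_recovery(self):
        err_d0, err_s02 = eb_recovery_errors(n_genes=2000, d0=4.0, s02=0.25, df=12.0, seed=1)
        assert err_d0 < 0.25
        assert err_s02 < 0.25

    def test_shrinkage_reduces_variance_spread(self, fitted_bundle):
        fit = fitted_bundle["fit"]
        assert np.var(fit.s2_post) <= np.var(fit.s2)
        lo = np.minimum(fit.s2, fit.s02)
        hi = np.maximum(fit.s2, fit.s02)
        assert ((fit.s2_post >= lo - 1e-12) & (fit.s2_post <= hi + 1e-12)).all()


class TestModeratedT:
    def test_zero_prior_df_gives_ordinary_t(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(50, 6))
        design = _two_group_design()
        fit = fit_models(_toy_norm(y), design).with_prior(0.0, 1.0)
        table = contrast_test(fit, np.array([1.0, -1.0]))
        # ordinary two-sample t with pooled variance, equal n
        a, b = y[:, :3], y[:, 3:]
        sp2 = (a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2
        t_ref = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (2 / 3))
        assert np.allclose(table.frame["t"], t_ref, atol=1e-10)
        p_ref = 2 * stats.t.sf(np.abs(t_ref), 4)
        assert np.allclose(table.frame["p"], p_ref, atol=1e-12)

    def test_infinite_prior_df_gives_pooled_statistic(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(50, 6))
        design = _two_group_design()
        s02 = 0.7
        fit = fit_models(_toy_norm(y), design).with_prior(np.inf, s02)
        table = contrast_test(fit, np.array([1.0, -1.0]))
        t_ref = (y[:, :3].mean(axis=1) - y[:, 3:].mean(axis=1)) / np.sqrt(s02 * (2 / 3))
        assert np.allclose(table.frame["t"], t_ref, atol=1e-8)

    def test_zero_contrast_rejected(self, fitted_bundle):
        with pytest.raises(ValueError, match="zero"):
            contrast_test(fitted_bundle["fit"], np.zeros(6))

    def test_wrong_length_contrast_rejected(self, fitted_bundle):
        with pytest.raises(ValueError, match="length"):
            contrast_test(fitted_bundle["fit"], np.array([1.0, -1.0]))

    def test_null_pvalues_calibrated_and_uniform(self):
        table = null_contrast_pvalues(seed=21, n_genes=5000)
        p = table.frame["p"].to_numpy()
        assert 0.04 <= (p < 0.05).mean() <= 0.06
        assert stats.kstest(p, "uniform").statistic < 0.03


class TestBhAdjust:
    def test_worked_example(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        assert (bh_adjust(np.ones(10)) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.2]))

    def test_matches_closed_form_reference(self):
        assert bh_reference_max_error(n_vectors=200, seed=3) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_statsmodels_and_is_monotone(self, p_list):
        p = np.array(p_list)
        adj = bh_adjust(p)
        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adj, sm_adj, atol=1e-12)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestDeSummary:
    def test_no_signal_zero_counts(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(100, 6))
        fit = fit_models(_toy_norm(y), _two_group_design())
        table = contrast_test(fit, np.array([1.0, -1.0]), "A_vs_B")
        summary = de_summary({"A_vs_B": table})
        assert summary.loc[0, ["n_up", "n_down"]].tolist() == [0, 0]

    def test_sign_symmetry(self, fitted_bundle):
        fit = fitted_bundle["fit"]
        design = fitted_bundle["design"]
        fwd = contrast_test(fit, design.contrast({"ILC2": 1, "Th2": -1}), "fwd")
        rev = contrast_test(fit, design.contrast({"ILC2": -1, "Th2": 1}), "rev")
        s = de_summary({"fwd": fwd, "rev": rev})
        assert s.loc[0, "n_up"] == s.loc[1, "n_down"]
        assert s.loc[0, "n_down"] == s.loc[1, "n_up"]

    def test_mismatched_universe_rejected(self, fitted_bundle):
        table = fitted_bundle["pairwise"][("ILC1", "Th1")]
        clipped = table.frame.iloc[:-1]
        from subsetseq.linmod import ContrastTable

        with pytest.raises(ValueError, match="universe"):
            de_summary({"a": table, "b": ContrastTable("b", clipped)})

    def test_planted_effects_recovered(self, fitted_bundle):
        # genes planted up in ILC2 (subset or ILC-lineage) surface as positive DE
        truth = fitted_bundle["truth"]
        table = fitted_bundle["pairwise"][("ILC2", "Th2")]
        eff = truth.effects.loc[table.frame["gene_id"]]
        truly_up = (eff["ILC2"] > eff["Th2"]).to_numpy()
        sig_up = ((table.frame["adj_p"] < 0.05) & (table.frame["log2_fc"] > 0)).to_numpy()
        assert sig_up[truly_up].mean() > 0.5   # decent power at |log2FC| = 2
        assert sig_up[~truly_up].mean() < 0.01  # and near-zero leakage
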