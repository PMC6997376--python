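"""Negative-binomial GLM, LRT, Wald contrast, outlier handling, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coexdiff as cd
from coexdiff.de import (
    NBFit,
    cooks_outlier_handle,
    exposure_model_matrix,
    fit_nb_glm,
)


def null_config(n_genes, seed, **kw):
    return cd.SimulationConfig(n_genes=n_genes, module_specs=[], de_specs=[],
                               seed=seed, **kw)


class TestDispersion:
    def test_poisson_gene_small_alpha(self):
        rng = np.random.default_rng(0)
        design = cd.simulate_design(null_config(10, 0))
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            counts = pd.DataFrame(
                rng.poisson(100.0, size=(1, 48)), index=["g"], columns=design.index
            )
            alpha = cd.estimate_dispersion(
                counts, design, pd.Series(1.0, index=design.index)
            ).iloc[0]
            hits += alpha < 0.02
        assert hits >= 0.90 * n_rep

    def test_nb_alpha_half_recovered(self):
        rng = np.random.default_rng(1)
        design = cd.simulate_design(null_config(10, 0))
        estimates = []
        for _ in range(100):
            r = 1 / 0.5
            y = rng.negative_binomial(r, r / (r + 100.0), size=(1, 48))
            counts = pd.DataFrame(y, index=["g"], columns=design.index)
            estimates.append(
                cd.estimate_dispersion(
                    counts, design, pd.Series(1.0, index=design.index)
                ).iloc[0]
            )
        assert 0.3 <= np.median(estimates) <= 0.7

    def test_constant_counts_floored(self):
        design = cd.simulate_design(null_config(10, 0))
        counts = pd.DataFrame(np.full((1, 48), 7), index=["g"], columns=design.index)
        alpha = cd.estimate_dispersion(
            counts, design, pd.Series(1.0, index=design.index)
        ).iloc[0]
        assert alpha == pytest.approx(1e-8)


class TestNBFit:
    def test_intercept_only_poisson_closed_form(self):
        y = np.array([3.0, 7.0, 1.0, 9.0, 5.0])
        fit = fit_nb_glm(y, np.ones((5, 1)), dispersion=1e-12)
        assert fit.coef[0] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_all_zero_counts_handled(self):
        y = np.zeros(6)
        fit = fit_nb_glm(y, np.ones((6, 1)), dispersion=0.1)
        assert np.isfinite(fit.coef).all()
        assert fit.mu.max() < 1e-3

    def test_log2fc_parameter_recovery(self):
        """A planted high-dose log2FC of 1 is recovered by the exposure
        coefficient (median over replicates within +-0.15 of ln 2)."""
        rng = np.random.default_rng(2)
        design = cd.simulate_design(null_config(10, 0))
        X, names = exposure_model_matrix(design)
        col = names.index("group[high]")
        high = (design["group"] == "high").to_numpy()
        coefs = []
        for _ in range(100):
            mu = np.where(high, 400.0, 200.0)
            r = 1 / 0.1
            y = rng.negative_binomial(r, r / (r + mu))
            coefs.append(fit_nb_glm(y.astype(float), X, 0.1).coef[col])
        assert np.median(coefs) == pytest.approx(np.log(2.0), abs=0.15)


class TestLRT:
    def test_permuted_labels_keep_p_uniform(self):
        cfg = null_config(300, 3)
        design = cd.simulate_design(cfg)
        counts, _ = cd.simulate_counts(design, cfg)
        kept = cd.filter_low_expression(counts)
        perm = design.copy()
        rng = np.random.default_rng(4)
        perm["group"] = pd.Categorical(
            rng.permutation(design["group"].astype(str)),
            categories=["control", "low", "high"],
        )
        res = cd.lrt_exposure(kept, perm, handle_outliers=False)
        pvals = res["pvalue"].dropna()
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_sex_effect_does_not_inflate_exposure(self):
        """A pure sex effect leaves the exposure LRT calibrated."""
        cfg = null_config(200, 5)
        design = cd.simulate_design(cfg)
        counts, _ = cd.simulate_counts(design, cfg)
        male = (design["sex"] == "M").to_numpy()
        counts.loc[:, :] = np.where(male[None, :], counts * 2, counts).astype(int)
        kept = cd.filter_low_expression(counts)
        res = cd.lrt_exposure(kept, design, handle_outliers=False)
        assert 0.4 <= res["pvalue"].median() <= 0.6

    def test_stat_invariant_to_dummy_recoding(self):
        cfg = null_config(40, 6)
        design = cd.simulate_design(cfg)
        counts, _ = cd.simulate_counts(design, cfg)
        kept = cd.filter_low_expression(counts)
        res_a = cd.lrt_exposure(kept, design, handle_outliers=False)
        recoded = design.copy()
        recoded["group"] = pd.Categorical(
            design["group"].astype(str), categories=["high", "control", "low"]
        )
        res_b = cd.lrt_exposure(kept, recoded, handle_outliers=False)
        np.testing.assert_allclose(res_a["stat"], res_b["stat"], atol=1e-5)

    def test_result_invariants(self, small_dataset):
        _, design, counts, _ = small_dataset
        kept = cd.filter_low_expression(counts)
        res = cd.lrt_exposure(kept, design, handle_outliers=False)
        assert (res["stat"] >= 0).all()
        assert (res["padj"].dropna() >= res["pvalue"].dropna()).all()
        by_p = res.dropna().sort_values("pvalue")
        assert by_p["padj"].is_monotonic_increasing

    def test_opposite_direction_pattern_recovered(self):
        """Planted low = -0.8, high = +0.4 recovered with correct signs."""
        cfg = cd.SimulationConfig(
            n_genes=150, module_specs=[],
            de_specs=[cd.DESpec(30, -0.8, 0.4)], seed=7,
        )
        design = cd.simulate_design(cfg)
        counts, truth = cd.simulate_counts(design, cfg)
        kept = cd.filter_low_expression(counts)
        res = cd.lrt_exposure(kept, design, handle_outliers=False)
        de = res.loc[res.index.intersection(truth.de_log2fc.index)]
        correct = ((de["log2fc_low"] < 0) & (de["log2fc_high"] > 0)).mean()
        assert correct >= 0.90


class TestWald:
    def test_two_level_contrast(self):
        cfg = cd.SimulationConfig(
            n_genes=120, groups=("water", "control"), module_specs=[],
            de_specs=[cd.DESpec(20, 0.0, 0.0)], seed=8,
        )
        design = cd.simulate_design(cfg)
        counts, _ = cd.simulate_counts(design, cfg)
        kept = cd.filter_low_expression(counts, min_samples=16)
        res = cd.wald_control_contrast(kept, design)
        pvals = res["pvalue"].dropna()
        assert 0.01 <= (pvals < 0.05).mean() <= 0.12
        assert ((pvals >= 0) & (pvals <= 1)).all()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(9)
        cfg = cd.SimulationConfig(
            n_genes=60, groups=("water", "control"), module_specs=[], de_specs=[],
            seed=9,
        )
        design = cd.simulate_design(cfg)
        counts, _ = cd.simulate_counts(design, cfg)
        kept = cd.filter_low_expression(counts, min_samples=16)
        shifted = kept.copy()
        is_ctrl = (design["group"] == "control").to_numpy()
        shifted.loc[shifted.index[:20], design.index[is_ctrl]] *= 2
        res_null = cd.wald_control_contrast(kept, design)
        res_shift = cd.wald_control_contrast(shifted, design)
        z_shift = res_shift.loc[shifted.index[:20], "z"].abs().median()
        assert z_shift > res_null["z"].abs().median() + 2

    def test_three_levels_rejected(self, default_design):
        counts = pd.DataFrame(
            np.ones((2, 48), dtype=int) * 50,
            index=["a", "b"], columns=default_design.index,
        )
        with pytest.raises(ValueError, match="two-level"):
            cd.wald_control_contrast(counts, default_design)


class TestCooks:
    def _fit_all(self, counts, design):
        X, names = exposure_model_matrix(design)
        s = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.05, index=counts.index)
        fits = {
            g: fit_nb_glm(counts.loc[g].to_numpy(dtype=float), X, 0.05,
                          np.zeros(len(design)), names=names)
            for g in counts.index
        }
        return fits, disp, s

    def test_clean_gene_unchanged(self, default_design):
        rng = np.random.default_rng(10)
        counts = pd.DataFrame(
            rng.poisson(200, size=(3, 48)), index=list("abc"),
            columns=default_design.index,
        )
        fits, disp, s = self._fit_all(counts, default_design)
        adjusted, flags = cooks_outlier_handle(counts, fits, disp, s)
        assert not flags.any().any()
        pd.testing.assert_frame_equal(adjusted, counts)

    def test_spiked_observation_flagged_and_replaced(self, default_design):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(
            rng.poisson(100, size=(1, 48)), index=["g"], columns=default_design.index
        )
        counts.iloc[0, 5] = 100 * counts.iloc[0].median()
        fits, disp, s = self._fit_all(counts, default_design)
        adjusted, flags = cooks_outlier_handle(counts, fits, disp, s)
        assert flags.iloc[0, 5]
        expected = round(stats.trim_mean(counts.iloc[0] / s.to_numpy(), 0.2) * s.iloc[5])
        assert adjusted.iloc[0, 5] == expected


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(cd.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert cd.bh_fdr([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(cd.bh_fdr([1.0, 1.0]), [1.0, 1.0])
        assert cd.bh_fdr([]).size == 0

    def test_nan_excluded_from_m(self):
        q = cd.bh_fdr([0.01, np.nan, 0.04])
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])
        assert np.isnan(q[1])
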