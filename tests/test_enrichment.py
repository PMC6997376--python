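"""PWF fitting, Wallenius test, sampling oracle, module enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import coexdiff as cd
from coexdiff.enrichment import wallenius_pmf


@pytest.fixture(scope="module")
def toy_universe():
    rng = np.random.default_rng(30)
    genes = [f"g{i:03d}" for i in range(200)]
    lengths = pd.Series(
        np.exp(rng.normal(7.5, 0.7, 200)).round(), index=genes
    )
    return genes, lengths


class TestFilterAnnotation:
    def test_boundary_sizes(self):
        universe = [f"g{i}" for i in range(30)]
        ann = {"nine": set(universe[:9]), "ten": set(universe[:10])}
        out = cd.filter_annotation(ann, universe, min_term_size=10)
        assert set(out) == {"ten"}

    def test_intersection_with_universe(self):
        out = cd.filter_annotation(
            {"t": {"a", "b", "x", "y"}}, ["a", "b", "c"], min_term_size=2
        )
        assert out == {"t": {"a", "b"}}

    def test_toy_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(31)
        ann = {f"t{k}": set(rng.choice(universe, size=rng.integers(2, 15),
                                       replace=False)) for k in range(5)}
        out = cd.filter_annotation(ann, universe, min_term_size=5)
        expected = {t for t, g in ann.items() if len(g) >= 5}
        assert set(out) == expected

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            cd.filter_annotation({"t": {"a"}}, [])


class TestPWF:
    def test_flat_when_lengths_constant(self):
        genes = [f"g{i}" for i in range(50)]
        lengths = pd.Series(1000.0, index=genes)
        flags = pd.Series([i < 10 for i in range(50)], index=genes)
        pwf = cd.fit_pwf(flags, lengths)
        np.testing.assert_allclose(pwf.weights, 0.2)

    def test_independent_membership_gives_flat_pwf(self):
        rng = np.random.default_rng(32)
        genes = [f"g{i}" for i in range(10000)]
        lengths = pd.Series(np.exp(rng.normal(7.5, 0.7, 10000)), index=genes)
        flags = pd.Series(rng.random(10000) < 0.2, index=genes)
        pwf = cd.fit_pwf(flags, lengths)
        rate = flags.mean()
        assert float((pwf.weights - rate).abs().max()) < 0.05
        assert abs(pwf.weights.mean() - rate) < 0.01

    def test_length_biased_membership_monotone(self):
        rng = np.random.default_rng(33)
        genes = [f"g{i}" for i in range(5000)]
        lengths = pd.Series(np.exp(rng.normal(7.5, 0.7, 5000)), index=genes)
        decile = pd.qcut(lengths, 10, labels=False)
        prob = 0.02 * 2 ** (decile / 3.0)
        flags = pd.Series(rng.random(5000) < prob, index=genes)
        pwf = cd.fit_pwf(flags, lengths)
        ordered = pwf.weights[lengths.sort_values().index].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()
        assert ordered[-1] > ordered[0]

    def test_requires_both_classes(self):
        genes = ["a", "b"]
        lengths = pd.Series([100.0, 200.0], index=genes)
        with pytest.raises(ValueError):
            cd.fit_pwf(pd.Series([True, True], index=genes), lengths)


class TestWallenius:
    def test_central_reduction_exact(self):
        N, m1, n = 50, 12, 15
        for x in range(0, m1 + 1):
            assert wallenius_pmf(x, N, m1, n, 1.0) == pytest.approx(
                hypergeom.pmf(x, N, m1, n), abs=1e-10
            )

    @pytest.mark.parametrize("w", [0.5, 1.0, 2.0, 4.0])
    def test_pmf_sums_to_one(self, w):
        N, m1, n = 180, 40, 55
        total = sum(wallenius_pmf(x, N, m1, n, w) for x in range(0, m1 + 1))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_tail_monotone_in_overlap(self, toy_universe):
        genes, lengths = toy_universe
        flags = pd.Series([i < 50 for i in range(200)], index=genes)
        pwf = cd.fit_pwf(flags, lengths)
        module = set(genes[:50])
        term = set(genes[25:75])
        from coexdiff.enrichment import _wallenius_upper_tail

        ps = [_wallenius_upper_tail(x, 200, 50, 50, 1.5) for x in range(0, 51)]
        assert (np.diff(ps) <= 1e-12).all()

    def test_module_is_whole_universe(self, toy_universe):
        genes, lengths = toy_universe
        flags = pd.Series([i < 50 for i in range(200)], index=genes)
        pwf = cd.fit_pwf(flags, lengths)
        assert cd.wallenius_term_test(genes[:30], genes, genes, pwf) == 1.0

    def test_empty_module(self, toy_universe):
        genes, lengths = toy_universe
        flags = pd.Series([i < 50 for i in range(200)], index=genes)
        pwf = cd.fit_pwf(flags, lengths)
        assert cd.wallenius_term_test(genes[:30], [], genes, pwf) == 1.0


class TestSamplingOracle:
    def test_flat_pwf_matches_hypergeometric(self, toy_universe):
        genes, _ = toy_universe
        lengths = pd.Series(1000.0, index=genes)
        flags = pd.Series([i < 40 for i in range(200)], index=genes)
        pwf = cd.fit_pwf(flags, lengths)
        term = set(genes[:30])
        module = set(genes[20:60])
        obs = len(term & module)
        p_mc = cd.sampling_null_test(term, module, genes, pwf, n_draws=20000, seed=2)
        p_hg = hypergeom.sf(obs - 1, 200, 30, 40)
        assert p_mc == pytest.approx(p_hg, abs=0.02)

    def test_seed_reproducible(self, toy_universe):
        genes, lengths = toy_universe
        flags = pd.Series([i < 40 for i in range(200)], index=genes)
        pwf = cd.fit_pwf(flags, lengths)
        a = cd.sampling_null_test(genes[:30], genes[:40], genes, pwf, 2000, seed=5)
        b = cd.sampling_null_test(genes[:30], genes[:40], genes, pwf, 2000, seed=5)
        assert a == b

    def test_agrees_with_wallenius_at_fixed_odds(self, toy_universe):
        """Two-level weights giving exact odds w = 2: the analytic Wallenius
        tail and the weighted-sampling oracle describe the same urn and
        agree to Monte-Carlo precision on a 200-gene universe."""
        genes, _ = toy_universe
        term = set(genes[:60])
        # small two-level weights, ratio 2; the derived odds (2.004) match
        # the sampling weight ratio closely in this small-probability regime
        weights = pd.Series([0.004 if g in term else 0.002 for g in genes], index=genes)
        pwf = cd.enrichment.PWF(weights, np.array([0.0]), np.array([0.0]))
        module = set(genes[30:90])
        p_w = cd.wallenius_term_test(term, module, genes, pwf)
        p_mc = cd.sampling_null_test(term, module, genes, pwf, n_draws=30000, seed=6)
        assert p_w == pytest.approx(p_mc, abs=0.01)

    def test_heterogeneous_pwf_approximation_quality(self, toy_universe):
        """With a fitted, gene-varying PWF the single-odds Wallenius tail is
        an approximation; it stays close to the exact weighted-sampling
        null on a length-biased fixture."""
        genes, lengths = toy_universe
        rng = np.random.default_rng(34)
        prob = np.clip((lengths.rank() / 200) * 0.4, 0.02, 0.98)
        flags = pd.Series(rng.random(200) < prob, index=genes)
        pwf = cd.fit_pwf(flags, lengths)
        module = set(flags.index[flags])
        term = set(genes[50:110])
        p_w = cd.wallenius_term_test(term, module, genes, pwf)
        p_mc = cd.sampling_null_test(term, module, genes, pwf, n_draws=30000, seed=6)
        assert p_w == pytest.approx(p_mc, abs=0.05)

    def test_few_draws_warns(self, toy_universe):
        genes, lengths = toy_universe
        flags = pd.Series([i < 40 for i in range(200)], index=genes)
        pwf = cd.fit_pwf(flags, lengths)
        with pytest.warns(RuntimeWarning, match="draws"):
            cd.sampling_null_test(genes[:30], genes[:40], genes, pwf, n_draws=50)


class TestModuleEnrichment:
    def test_planted_category_has_minimum_p(self):
        """A category equal to a planted module's gene set dominates the
        enrichment ranking for that module and clears the threshold."""
        rng = np.random.default_rng(35)
        genes = [f"g{i:04d}" for i in range(2000)]
        lengths = pd.Series(np.exp(rng.normal(7.5, 0.7, 2000)), index=genes)
        module = set(genes[:50])
        ann = {"planted": set(module)}
        for k in range(30):
            ann[f"rand{k}"] = set(rng.choice(genes, size=60, replace=False))
        res, threshold = cd.module_enrichment({1: module}, ann, genes, lengths)
        best = res.sort_values("pvalue").iloc[0]
        assert best["term"] == "planted"
        assert best["pvalue"] < threshold

    def test_family_size_thresholds(self):
        assert cd.format_threshold(cd.bonferroni_threshold(1497)) == "3.34E-05"
        assert cd.bonferroni_threshold(1) == 0.05

    def test_no_modules_empty_result(self, toy_universe):
        genes, lengths = toy_universe
        res, threshold = cd.module_enrichment({}, {"t": set(genes[:20])}, genes, lengths)
        assert res.empty
        assert np.isnan(threshold)
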