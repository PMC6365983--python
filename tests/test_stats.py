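"""Group statistics: rank tests, AUROC, FDR, empirical Bayes, partial Spearman."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmnloc import stats as gs
from mmnloc.ebi import ebi_fit


def brute_force_auroc(x, y):
    wins = sum((yi > xi) + 0.5 * (yi == xi) for xi in x for yi in y)
    return wins / (len(x) * len(y))


class TestMannWhitney:
    def test_pair_counting_example(self):
        u, p = gs.mann_whitney([1, 2, 3], [2.5, 3.5])
        assert u == 5.0

    def test_identical_groups_give_half_auroc(self):
        assert gs.auroc([1, 2, 2, 3], [1, 2, 2, 3]) == pytest.approx(0.5)

    def test_complete_separation_exact_tail(self):
        u, p = gs.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 9.0
        # 2 of the C(6,3)=20 assignments are at least as extreme (both tails)
        assert p == pytest.approx(2 / 20)

    def test_large_sample_agrees_with_scipy(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.normal(0, 1, 40)
        y = rng.normal(0.7, 1, 55)
        u, p = gs.mann_whitney(x, y)
        ref = mannwhitneyu(y, x, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            gs.mann_whitney([], [1.0])


class TestAuroc:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 5), min_size=1, max_size=8),
        y=st.lists(st.integers(0, 5), min_size=1, max_size=8),
    )
    def test_identity_with_pair_enumeration(self, x, y):
        assert gs.auroc(x, y) == pytest.approx(brute_force_auroc(x, y))

    def test_worked_example(self):
        assert gs.auroc([1, 2, 3], [2.5, 3.5]) == pytest.approx(5 / 6)

    def test_complete_separation(self):
        a, ci, p = gs.bootstrap_auroc([1, 2], [3, 4, 5], B=200, seed=0)
        assert a == 1.0
        assert ci[1] == 1.0

    def test_null_bootstrap_p_uniformish(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 25)
        a, ci, p = gs.bootstrap_auroc(x, y, B=500, seed=1)
        assert ci[0] <= a <= ci[1]
        assert p > 0.01  # null data should rarely look extreme

    def test_small_b_raises(self):
        with pytest.raises(ValueError):
            gs.bootstrap_auroc([1, 2], [3], B=50)


class TestMultiplicity:
    def test_bonferroni_printed_family(self):
        assert gs.bonferroni_threshold(0.05, 20) == pytest.approx(0.0025)
        assert gs.bonferroni_threshold(0.05, 1) == 0.05
        assert gs.bonferroni_threshold(0.10, 4) == pytest.approx(0.025)
        with pytest.raises(ValueError):
            gs.bonferroni_threshold(0.05, 0)

    def test_bh_stepup_by_hand(self):
        flags = gs.bh_fdr([0.001, 0.02, 0.03, 0.5], q=0.1)
        assert list(flags) == [True, True, True, False]

    def test_all_ones_no_discoveries(self):
        assert not gs.bh_fdr(np.ones(10), q=0.1).any()

    def test_monotone_in_q(self, rng):
        p = rng.random(200) ** 2
        small = set(np.flatnonzero(gs.bh_fdr(p, q=0.05)))
        large = set(np.flatnonzero(gs.bh_fdr(p, q=0.20)))
        assert small <= large

    def test_mask_excludes_units_from_family(self):
        p = np.array([0.001, 0.5, np.nan, 0.02])
        mask = np.array([True, True, False, True])
        flags = gs.bh_fdr(p, q=0.1, mask=mask)
        assert not flags[2]

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            gs.bh_fdr([0.5, 1.2], q=0.1)


class TestEbi:
    def test_pure_null_calibration(self):
        z = np.random.default_rng(0).standard_normal(2000)
        fit = ebi_fit(z)
        assert fit.p0 > 0.95
        assert fit.posterior[np.abs(z) < 1.0].max() < 0.5

    def test_mixture_p0_recovery(self):
        r = np.random.default_rng(0)
        z = np.concatenate([r.standard_normal(1600), r.normal(3, 1, 400)])
        fit = ebi_fit(z)
        assert abs(fit.p0 - 0.8) < 0.05

    def test_strong_effects_get_high_posterior(self):
        r = np.random.default_rng(1)
        z = np.concatenate([r.standard_normal(1600), r.normal(3, 1, 400), [5.0]])
        fit = ebi_fit(z)
        assert fit.posterior[-1] > 0.9
        assert 0.0 < fit.achieved_power <= 1.0

    def test_local_fdr_invariant_to_reordering(self):
        r = np.random.default_rng(2)
        z = np.concatenate([r.standard_normal(500), r.normal(3, 1, 100)])
        perm = r.permutation(z.size)
        a = ebi_fit(z)
        b = ebi_fit(z[perm])
        assert np.allclose(a.local_fdr[perm], b.local_fdr, atol=1e-12)

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            ebi_fit(np.ones(500))
        with pytest.raises(ValueError):
            ebi_fit(np.arange(50.0))  # too few units


class TestSpearmanPartial:
    def test_monotone_association(self, rng):
        x = np.arange(30.0)
        y = x**3 + 1
        r = gs.spearman_partial(x, y, rng.standard_normal(30))
        assert r.rho >= 0.99

    def test_no_covariates_equals_plain_spearman(self, rng):
        from scipy.stats import spearmanr

        x = rng.normal(0, 1, 40)
        y = 0.5 * x + rng.normal(0, 1, 40)
        mine = gs.spearman_partial(x, y)
        ref = spearmanr(x, y)
        assert mine.rho == pytest.approx(ref.statistic, abs=1e-10)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        n = 60
        c = rng.standard_normal((n, 2))
        x = c[:, 0] + rng.standard_normal(n)
        y = 0.5 * c[:, 0] - c[:, 1] + rng.standard_normal(n)
        mine = gs.spearman_partial(x, y, c)
        df = pd.DataFrame({"x": x, "y": y, "c1": c[:, 0], "c2": c[:, 1]})
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"], method="spearman")
        assert mine.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_shared_confound_removed(self, rng):
        n = 200
        c = rng.standard_normal(n)
        x = c + 0.1 * rng.standard_normal(n)
        y = c + 0.1 * rng.standard_normal(n)
        r = gs.spearman_partial(x, y, c)
        assert abs(r.rho) < 0.15

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            gs.spearman_partial(np.ones(10), np.arange(10.0))


class TestAssembleStats:
    def test_single_unit_reduces_to_p_threshold(self, rng):
        x = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 12)])[:, None]
        groups = ["control"] * 10 + ["patient"] * 12
        res = gs.assemble_stats(x, groups, q=0.10, use_ebi=False)
        row = res.table.iloc[0]
        assert bool(row["fdr_flag"]) == (row["p"] <= 0.10)

    def test_exchangeable_groups_rarely_discover(self):
        zero_runs = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            vals = r.standard_normal((30, 150))
            groups = ["control"] * 14 + ["patient"] * 16
            res = gs.assemble_stats(vals, groups, q=0.10, use_ebi=False)
            zero_runs += res.n_discoveries == 0
        assert zero_runs >= 15  # BH null: ~90% of runs discover nothing

    def test_auroc_u_identity_and_orientation(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 1, (10, 5)), rng.normal(1.5, 1, (12, 5))], axis=0
        )
        groups = ["control"] * 10 + ["patient"] * 12
        res = gs.assemble_stats(vals, groups, use_ebi=False)
        t = res.table
        assert np.allclose(t["auroc"], t["U"] / (10 * 12))
        assert (t["auroc"] > 0.5).all()  # patients higher by construction

    def test_undefined_units_masked(self, rng):
        vals = rng.standard_normal((20, 4))
        vals[3, 2] = np.nan
        groups = ["control"] * 10 + ["patient"] * 10
        res = gs.assemble_stats(vals, groups, use_ebi=False)
        assert not res.table["defined"][2]
        assert res.table["defined"].sum() == 3

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            gs.assemble_stats(np.zeros((3, 2)), ["control", "patient", "patient"])
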