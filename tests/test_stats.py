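"""Statistical stage: Welch t, BH, mixed models, rank tests, Bayes factors."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pdeeg.stats import (bayes_mannwhitney, bh_adjust, fit_lmm,
                         mann_whitney_W, posthoc_pairwise, welch_t)


class TestWelch:
    def test_identical_samples_give_t0_p1(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        r = welch_t([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert r.p < 0.01

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 9)
        r = welch_t(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1)
                               + vb ** 2 / (len(b) - 1))
        p = 2 * sps.t.sf(abs(t), df)
        assert r.t == pytest.approx(t, abs=1e-10)
        assert r.df == pytest.approx(df, abs=1e-10)
        assert r.p == pytest.approx(p, abs=1e-10)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([2.0, 2.0], [3.0, 3.0])


class TestBHAdjust:
    def test_published_family_reproduced_to_3dp(self):
        adj = bh_adjust([0.007, 0.045, 0.544])
        np.testing.assert_allclose(np.round(adj, 3), [0.021, 0.068, 0.544])

    def test_singleton_family_unchanged(self):
        assert bh_adjust([0.544])[0] == pytest.approx(0.544)

    def test_equal_pvalues_are_fixed_point(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]),
                                   [0.2, 0.2, 0.2])

    def test_uncapped_mode_reproduces_raw_p_times_m_over_rank(self):
        adj = bh_adjust([0.549, 0.607, 0.933], cap=False)
        assert adj[0] == pytest.approx(0.549 * 3)        # 1.647
        assert adj[1] == pytest.approx(0.607 * 3 / 2)    # 0.9105
        assert adj[2] == pytest.approx(0.933)

    def test_matches_brute_force_step_up_on_random_families(self):
        def brute(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            prev = np.inf
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                adj[i] = min(prev, 1.0)
            return adj

        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=4)
            np.testing.assert_allclose(bh_adjust(p), brute(p), atol=1e-12)
        # and over all orderings of one family
        base = [0.01, 0.04, 0.3, 0.9]
        for perm in itertools.permutations(base):
            np.testing.assert_allclose(bh_adjust(list(perm)),
                                       brute(np.array(perm)), atol=1e-12)

    def test_order_equivariant_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=6)
        once = bh_adjust(p)
        assert np.all(once <= 1.0) and np.all(once >= p - 1e-12)
        perm = rng.permutation(6)
        np.testing.assert_allclose(bh_adjust(p[perm]), once[perm],
                                   atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestMannWhitney:
    def test_complete_separation_is_maximal(self):
        W, rb = mann_whitney_W([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert W == 25.0 and rb == pytest.approx(1.0)

    def test_identical_multisets_give_half(self):
        x = [1.0, 2.0, 3.0, 4.0]
        W, rb = mann_whitney_W(x, list(x))
        assert W == pytest.approx(len(x) ** 2 / 2)
        assert rb == pytest.approx(0.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.integers(0, 8, size=rng.integers(2, 13)).astype(float)
            y = rng.integers(0, 8, size=rng.integers(2, 13)).astype(float)
            W, _ = mann_whitney_W(x, y)
            brute = sum((xi > yj) + 0.5 * (xi == yj)
                        for xi in x for yj in y)
            assert W == pytest.approx(brute)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_W([], [1.0])


class TestPosthocPairwise:
    @staticmethod
    def _means_frame(per_subject):
        rows = []
        for subj, (group, by_load) in enumerate(per_subject):
            for load, val in by_load.items():
                rows.append((f"s{subj}", group, load, val))
        return pd.DataFrame(rows,
                            columns=["subject", "group", "load", "value"])

    def test_constructed_ordering_puts_smallest_p_on_high_vs_low(self):
        rng = np.random.default_rng(4)
        subjects = []
        for _ in range(10):
            base = rng.normal(50, 2)
            subjects.append((1.0, {0: base, 1: base + rng.normal(1, 0.5),
                                   2: base + rng.normal(10, 0.5)}))
        table = posthoc_pairwise(self._means_frame(subjects))
        raw = table.set_index("comparison")["p value"]
        assert raw["(high, low)"] == raw.min()

    def test_bh_adjustment_is_within_group_family(self):
        rng = np.random.default_rng(5)
        subjects = [(g, {0: rng.normal(), 1: rng.normal(), 2: rng.normal()})
                    for g in (0.0, 1.0) for _ in range(6)]
        table = posthoc_pairwise(self._means_frame(subjects))
        for _, gdf in table.groupby("group"):
            np.testing.assert_allclose(gdf["p adj BH"].to_numpy(),
                                       bh_adjust(gdf["p value"].to_numpy()),
                                       atol=1e-12)

    def test_missing_level_named_in_error(self):
        df = self._means_frame([(1.0, {0: 1.0, 1: 2.0})])
        with pytest.raises(ValueError, match="2"):
            posthoc_pairwise(df)

    def test_t_matches_paired_scipy(self):
        rng = np.random.default_rng(6)
        subjects = [(0.0, {0: rng.normal(), 1: rng.normal(),
                           2: rng.normal()}) for _ in range(8)]
        df = self._means_frame(subjects)
        table = posthoc_pairwise(df).set_index("comparison")
        wide = df.pivot_table(index="subject", columns="load",
                              values="value")
        t, p = sps.ttest_rel(wide[2], wide[0])
        assert table.loc["(high, low)", "t value"] == pytest.approx(t)
        assert table.loc["(high, low)", "p value"] == pytest.approx(p)


def _simulate_lmm(seed, beta_group=0.0, n_subj=20, n_obs=50, re_sd=(1.0, 0.3),
                  noise=2.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        group = float(s < n_subj // 2)
        u = rng.normal(0, re_sd[0])
        v = rng.normal(0, re_sd[1])
        load = rng.integers(0, 3, size=n_obs).astype(float)
        y = (1.0 + beta_group * group + 0.5 * load + u + v * load
             + rng.normal(0, noise, size=n_obs))
        for li, yi in zip(load, y):
            rows.append((f"s{s}", group, li, yi))
    return pd.DataFrame(rows, columns=["subject", "group", "load", "value"])


class TestFitLmm:
    def test_recovers_known_group_effect(self):
        res = fit_lmm(_simulate_lmm(0, beta_group=3.0))
        eff = res.effect("group")
        assert eff.ci_low < 3.0 < eff.ci_high
        assert eff.p < 0.01

    def test_zero_random_effects_limit_matches_ols(self):
        """With no random effects in the generator the ML mixed fit collapses
        to ordinary least squares."""
        import statsmodels.formula.api as smf
        df = _simulate_lmm(1, beta_group=1.0, re_sd=(0.0, 0.0), noise=1.0,
                           n_obs=300)
        res = fit_lmm(df)
        ols = smf.ols("value ~ group + load", df).fit()
        # ML variance estimates stop at a small positive boundary value, so
        # agreement holds to optimizer precision, not machine precision
        for name in ("Intercept", "group", "load"):
            assert res.effect(name).coef == pytest.approx(ols.params[name],
                                                          abs=1e-3)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            fit_lmm(pd.DataFrame({"subject": [], "group": [], "value": []}))

    def test_single_subject_per_group_rejected(self):
        df = _simulate_lmm(2, n_subj=2)
        with pytest.raises(ValueError):
            fit_lmm(df)

    def test_result_table_structure(self):
        res = fit_lmm(_simulate_lmm(3))
        assert list(res.fixed_effects.index) == ["Intercept", "group", "load"]
        fe = res.fixed_effects
        assert np.all(fe.ci_low <= fe.coef) and np.all(fe.coef <= fe.ci_high)
        assert np.all((fe.p >= 0) & (fe.p <= 1))


class TestBayesMannWhitney:
    def test_bf_identity_and_w_statistic(self):
        rng = np.random.default_rng(7)
        res = bayes_mannwhitney(rng.normal(size=15), rng.normal(size=15),
                                seed=1)
        assert res.BF10 * res.BF01 == pytest.approx(1.0, abs=1e-9)
        assert 0 <= res.W <= 15 * 15
        assert res.chains == 5 and res.iterations_per_chain == 1000

    def test_two_sd_separation_gives_strong_evidence(self):
        rng = np.random.default_rng(8)
        res = bayes_mannwhitney(rng.normal(0, 1, 25), rng.normal(2, 1, 25),
                                seed=2)
        assert res.BF10 > 10.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=10), rng.normal(size=10)
        a = bayes_mannwhitney(x, y, seed=3)
        b = bayes_mannwhitney(x, y, seed=3)
        assert a.BF10 == b.BF10 and a.rhat == b.rhat

    def test_longer_chains_agree_within_monte_carlo_error(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(0, 1, 20), rng.normal(0.8, 1, 20)
        short = bayes_mannwhitney(x, y, seed=4)
        long = bayes_mannwhitney(x, y, iters=2000, seed=5)
        assert np.log(short.BF10) == pytest.approx(np.log(long.BF10),
                                                   abs=0.5)

    def test_ties_are_handled(self):
        res = bayes_mannwhitney([1, 1, 2, 3, 3], [2, 2, 3, 4, 4], seed=6)
        assert np.isfinite(res.BF10)
        assert res.W == mann_whitney_W([1, 1, 2, 3, 3], [2, 2, 3, 4, 4])[0]

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            bayes_mannwhitney([1.0, np.nan, 2.0], [0.0, 1.0], seed=0)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            bayes_mannwhitney([1.0], [1.0, 2.0], seed=0)
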