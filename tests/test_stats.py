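"""Statistical contracts, checked against hand formulas and scipy oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from irquant.stats import (
    benjamini_hochberg,
    one_way_anova_nk,
    pearson_r,
    sidak_adjust,
    two_way_anova_posthoc,
    welch_t_test,
)


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_hand_oracle(self):
        # x=[1,2,3], y=[2,4,6]: t = -2/sqrt(5/3), df = (5/3)^2 / (17/18) = 50/17
        res = welch_t_test([1, 2, 3], [2, 4, 6])
        assert res.statistic == pytest.approx(-2.0 / math.sqrt(5.0 / 3.0), abs=1e-9)
        assert res.df == pytest.approx(50.0 / 17.0, abs=1e-9)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 15))
            y = rng.normal(1.0, 2.0, size=rng.integers(3, 15))
            ours = welch_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(size=5)
        assert welch_t_test(x, y).p_value == pytest.approx(
            welch_t_test(y, x).p_value, rel=1e-12
        )

    def test_null_type_i_error(self):
        # 10,000 null replicates, both arms standard normal, n=20
        from irquant.stats import welch_t_statistic

        rng = np.random.default_rng(2)
        n, reps = 20, 10_000
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        t, df = welch_t_statistic(
            x.mean(1), x.var(1, ddof=1), n, y.mean(1), y.var(1, ddof=1), n
        )
        p = 2 * sps.t.sf(np.abs(t), df)
        rate = np.mean(p < 0.05)
        assert 0.04 <= rate <= 0.06

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestOneWayNk:
    def test_identical_groups(self):
        g = {k: [1.0, 2.0, 3.0] for k in "abc"}
        res = one_way_anova_nk(g)
        assert res.omnibus.statistic == 0.0
        assert not any(d.significant for d in res.pairwise)

    def test_large_shift_all_pairs_significant(self):
        rng = np.random.default_rng(3)
        g = {
            "a": rng.normal(0, 1, 8),
            "b": rng.normal(0, 1, 8),
            "c": rng.normal(10, 1, 8),  # 10 within-group sd away
        }
        res = one_way_anova_nk(g)
        for d in res.pairwise:
            if "c" in (d.group_a, d.group_b):
                assert d.significant

    def test_omnibus_matches_scipy(self):
        rng = np.random.default_rng(4)
        g = {k: rng.normal(i, 1, 7) for i, k in enumerate("abcd")}
        res = one_way_anova_nk(g)
        ref = sps.f_oneway(*g.values())
        assert res.omnibus.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.omnibus.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_omnibus_null_type_i_error(self):
        from irquant.stats import _one_way_f

        rng = np.random.default_rng(5)
        reps, k, n = 5000, 4, 8
        hits = 0
        for _ in range(reps):
            data = rng.normal(size=(k, n))
            _, p, _, _, _ = _one_way_f(list(data))
            hits += p < 0.05
        assert 0.04 <= hits / reps <= 0.06

    def test_tukey_alternative_more_conservative(self):
        rng = np.random.default_rng(6)
        g = {k: rng.normal(0.8 * i, 1, 6) for i, k in enumerate("abcd")}
        nk = {frozenset((d.group_a, d.group_b)): d.significant
              for d in one_way_anova_nk(g, posthoc="newman-keuls").pairwise}
        tk = {frozenset((d.group_a, d.group_b)): d.significant
              for d in one_way_anova_nk(g, posthoc="tukey").pairwise}
        # Tukey never declares significant where NK does not
        for pair, sig in tk.items():
            if sig:
                assert nk[pair]


class TestTwoWay:
    def _data(self, effect=0.0, seed=0, n=4):
        rng = np.random.default_rng(seed)
        rows = []
        for a in ("g1", "g2"):
            for b in ("t1", "t2", "t3"):
                mu = effect if a == "g2" else 0.0
                for v in rng.normal(mu, 1.0, n):
                    rows.append(dict(value=v, group=a, time=b))
        return pd.DataFrame(rows)

    def test_identical_cells_no_effects(self):
        df = self._data()
        df["value"] = 1.0
        res = two_way_anova_posthoc(df, "value", "group", "time")
        for t in res.omnibus:
            assert t.statistic == pytest.approx(0.0, abs=1e-8)

    def test_sidak_identity_k1(self):
        assert sidak_adjust(0.05, 1) == pytest.approx(0.05)

    def test_sidak_formula(self):
        assert sidak_adjust(0.01, 5) == pytest.approx(1 - 0.99**5)

    def test_adjusted_ge_raw(self):
        df = self._data(effect=1.0, seed=1)
        res = two_way_anova_posthoc(df, "value", "group", "time", posthoc="sidak")
        for d in res.pairwise:
            raw = welch_t_test(
                df.loc[(df.group == d.group_a.split("@")[0]) & (df.time == d.group_a.split("@")[1]), "value"],
                df.loc[(df.group == d.group_b.split("@")[0]) & (df.time == d.group_b.split("@")[1]), "value"],
            ).p_value
            assert d.p_value >= raw - 1e-12

    def test_dunnett_against_scipy_direct(self):
        df = self._data(effect=2.0, seed=2)
        res = two_way_anova_posthoc(
            df, "value", "group", "time", posthoc="dunnett", control_level="g1"
        )
        sub = df[df.time == "t1"]
        ref = sps.dunnett(
            sub.loc[sub.group == "g2", "value"].to_numpy(),
            control=sub.loc[sub.group == "g1", "value"].to_numpy(),
            rng=0,
        )
        ours = [d for d in res.pairwise if d.group_a == "g2@t1"][0]
        assert ours.p_value == pytest.approx(float(ref.pvalue[0]), rel=1e-6)

    def test_missing_cell_rejected(self):
        df = self._data().query("~(group == 'g2' and time == 't3')")
        with pytest.raises(ValueError, match="missing cells"):
            two_way_anova_posthoc(df, "value", "group", "time")

    def test_balanced_closed_form_oracle(self):
        # Classical balanced decomposition computed by hand as the oracle.
        df = self._data(effect=1.3, seed=7, n=5)
        res = two_way_anova_posthoc(df, "value", "group", "time")
        y = df["value"].to_numpy().reshape(2, 3, 5)
        grand = y.mean()
        a_m = y.mean(axis=(1, 2))
        b_m = y.mean(axis=(0, 2))
        cell = y.mean(axis=2)
        ss_a = 15 * np.sum((a_m - grand) ** 2)
        ss_b = 10 * np.sum((b_m - grand) ** 2)
        ss_ab = 5 * np.sum((cell - a_m[:, None] - b_m[None, :] + grand) ** 2)
        ss_e = np.sum((y - cell[:, :, None]) ** 2)
        f_a = (ss_a / 1) / (ss_e / 24)
        f_b = (ss_b / 2) / (ss_e / 24)
        f_ab = (ss_ab / 2) / (ss_e / 24)
        by = {t.comparison: t.statistic for t in res.omnibus}
        assert by["group"] == pytest.approx(f_a, rel=1e-8)
        assert by["time"] == pytest.approx(f_b, rel=1e-8)
        assert by["group:time"] == pytest.approx(f_ab, rel=1e-8)

    def test_interaction_null_type_i_error(self):
        # 2x5 layout, n=6/cell; closed-form route verified equal to the
        # module implementation above
        rng = np.random.default_rng(8)
        reps = 2000
        y = rng.normal(size=(reps, 2, 5, 6))
        cell = y.mean(axis=3)
        a_m = y.mean(axis=(2, 3))
        b_m = y.mean(axis=(1, 3))
        grand = y.mean(axis=(1, 2, 3))
        ss_ab = 6 * np.sum(
            (cell - a_m[:, :, None] - b_m[:, None, :] + grand[:, None, None]) ** 2,
            axis=(1, 2),
        )
        ss_e = np.sum((y - cell[:, :, :, None]) ** 2, axis=(1, 2, 3))
        f_ab = (ss_ab / 4) / (ss_e / (2 * 5 * 5))
        p = sps.f.sf(f_ab, 4, 50)
        rate = np.mean(p < 0.05)
        assert 0.035 <= rate <= 0.065


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_perfect_negative(self):
        x = np.arange(5.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=30), rng.normal(size=30)
        ours = pearson_r(x, y)
        ref = sps.pearsonr(x, y)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(10)
        n, reps = 30, 5000
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * sps.t.sf(np.abs(t), n - 2)
        assert 0.04 <= np.mean(p < 0.05) <= 0.06

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAdjustments:
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_bh_within_unit_interval_and_ge_raw_min(self, ps):
        adj = benjamini_hochberg(ps)
        assert np.all((adj >= 0) & (adj <= 1))
        assert np.all(adj >= np.array(ps) / len(ps) - 1e-12)

    @given(st.floats(0.0, 1.0), st.integers(1, 50))
    def test_sidak_monotone_ge_raw(self, p, k):
        assert sidak_adjust(p, k) >= p - 1e-12
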