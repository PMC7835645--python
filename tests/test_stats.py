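"""Tests of the survival and group-comparison statistics.

Independent oracles: a naive risk-set log-rank accumulator, lifelines'
Kaplan-Meier fitter, full permutation enumeration for Mann-Whitney U, and
a hand-rolled balanced mixed-ANOVA sums-of-squares decomposition.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from ca_recovery.stats import (
    SurvivalDataset,
    TestResult,
    km_estimate,
    ks_normality,
    logrank_test,
    mann_whitney_u,
    rm_anova_two_way,
    sidak_posthoc,
    welch_t,
)


def make_survival(times1, events1, times2, events2, g1="control", g2="cr"):
    return SurvivalDataset(
        time=np.concatenate([times1, times2]).astype(float),
        event=np.concatenate([events1, events2]).astype(bool),
        group=np.array([g1] * len(times1) + [g2] * len(times2), dtype=object),
    )


def study_cohort():
    """Control: deaths at 0, 0, 24, 48 h + 10 censored at 72; CR: 14 censored."""
    return make_survival(
        [0, 0, 24, 48] + [72] * 10, [1, 1, 1, 1] + [0] * 10,
        [72] * 14, [0] * 14,
    )


def naive_logrank_chi2(data: SurvivalDataset) -> float:
    """Independent accumulation over explicitly enumerated risk sets."""
    g1 = data.groups[0]
    rows = list(zip(data.time, data.event, data.group))
    event_times = sorted({t for t, e, _ in rows if e})
    O = E = V = 0.0
    for et in event_times:
        risk = [r for r in rows if r[0] >= et]
        n = len(risk)
        n1 = sum(1 for r in risk if r[2] == g1)
        deaths = [r for r in rows if r[0] == et and r[1]]
        d = len(deaths)
        d1 = sum(1 for r in deaths if r[2] == g1)
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n - d) * n1 * (n - n1) / (n * n * (n - 1))
    return (O - E) ** 2 / V


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        ds = make_survival([72] * 5, [0] * 5, [72] * 5, [0] * 5)
        curves = km_estimate(ds)
        assert curves["cr"].at(71.9) == 1.0

    def test_two_deaths_at_zero_among_14(self):
        ds = make_survival([0, 0] + [72] * 12, [1, 1] + [0] * 12, [72] * 3, [0] * 3)
        assert km_estimate(ds)["control"].at(0.0) == pytest.approx(12 / 14)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(40, 30).round(1)
        e = rng.random(30) < 0.7
        ds = make_survival(t, e, [72] * 2, [0] * 2)
        curve = km_estimate(ds)["control"]
        kmf = KaplanMeierFitter().fit(t, e)
        for q in [5.0, 20.0, 50.0]:
            assert curve.at(q) == pytest.approx(
                float(kmf.predict(q)), abs=1e-9
            )

    def test_monotone_nonincreasing(self, rng):
        t = rng.exponential(30, 25)
        e = rng.random(25) < 0.8
        ds = make_survival(t, e, [72], [0])
        s = km_estimate(ds)["control"].survival
        assert (np.diff(s) <= 1e-12).all()


class TestLogrank:
    def test_study_cohort_chi2(self):
        res = logrank_test(study_cohort())
        assert round(res.statistic, 3) == 4.510
        assert res.df == 1
        assert res.p_value < 0.05
        # hand accumulation: O = 4, E ~ 1.901, V ~ 0.976
        assert res.metadata["observed_group1"] == 4
        assert res.metadata["expected_group1"] == pytest.approx(1.9015, abs=5e-4)
        assert res.metadata["variance"] == pytest.approx(0.9764, abs=5e-4)

    def test_mirrored_events_chi2_zero(self):
        ds = make_survival([10, 20, 72, 72], [1, 1, 0, 0], [10, 20, 72, 72], [1, 1, 0, 0])
        assert logrank_test(ds).statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_oracle_small_data(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(3, 5, 2)
            t1 = rng.integers(0, 72, n1).astype(float)
            t2 = rng.integers(0, 72, n2).astype(float)
            e1 = rng.random(n1) < 0.8
            e2 = rng.random(n2) < 0.8
            if not (e1.any() or e2.any()):
                continue
            ds = make_survival(t1, e1, t2, e2)
            try:
                res = logrank_test(ds)
            except ValueError:
                continue  # degenerate variance
            assert res.statistic == pytest.approx(naive_logrank_chi2(ds), rel=1e-12)

    def test_group_label_swap_invariant(self):
        ds = study_cohort()
        swapped = SurvivalDataset(
            time=ds.time, event=ds.event,
            group=np.where(ds.group == "control", "cr", "control").astype(object),
        )
        assert logrank_test(ds).statistic == pytest.approx(
            logrank_test(swapped).statistic
        )

    def test_animal_censored_before_first_event_leaves_chi2_unchanged(self):
        # censoring strictly before every event time keeps the animal out
        # of all risk sets, so the statistic cannot move
        ds = make_survival([10, 10, 24, 48] + [72] * 10, [1] * 4 + [0] * 10,
                           [72] * 14, [0] * 14)
        plus = SurvivalDataset(
            time=np.append(ds.time, 5.0),
            event=np.append(ds.event, False),
            group=np.append(ds.group, "cr"),
        )
        assert logrank_test(plus).statistic == pytest.approx(
            logrank_test(ds).statistic, rel=1e-12
        )

    def test_no_events_undefined(self):
        ds = make_survival([72] * 3, [0] * 3, [72] * 3, [0] * 3)
        with pytest.raises(ValueError):
            logrank_test(ds)

    def test_type_one_error_calibrated_under_null(self):
        # identical exponential groups censored at 72 h
        rng = np.random.default_rng(202)
        rejections = trials = 0
        for _ in range(1000):
            T = rng.exponential(60.0, size=28)
            ds = SurvivalDataset(
                time=np.minimum(T, 72.0),
                event=T <= 72.0,
                group=np.array(["a"] * 14 + ["b"] * 14, dtype=object),
            )
            try:
                rejections += logrank_test(ds).p_value < 0.05
                trials += 1
            except ValueError:
                pass
        assert 0.03 <= rejections / trials <= 0.07


class TestWelch:
    def test_identical_groups_t_zero(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)

    def test_hand_computed_value(self):
        res = welch_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == pytest.approx(-3.674, abs=5e-4)
        assert res.df == pytest.approx(4.0)

    def test_equal_variance_equal_n_df_limit(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.permutation(x) + 5.0  # identical variance
        assert welch_t(x, y).df == pytest.approx(18.0)


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0  # U for group 1
        assert res.metadata["U2"] == 4.0

    def test_identical_groups_u_half(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])
        assert res.statistic + res.metadata["U2"] == 9.0

    def test_exact_reported_for_small_tie_free(self):
        res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert res.metadata["method"] == "exact"

    def test_ties_use_asymptotic_with_correction(self):
        res = mann_whitney_u([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert res.metadata["method"] == "asymptotic"
        assert res.metadata["ties_present"]

    def test_exact_p_equals_permutation_enumeration(self, rng):
        for _ in range(20):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            vals = rng.permutation(np.arange(n1 + n2, dtype=float) * 1.7 + 0.3)
            x, y = vals[:n1], vals[n1:]
            res = mann_whitney_u(x, y)
            assert res.p_value == pytest.approx(
                _enumerated_two_sided_p(x, y), abs=1e-12
            )


def _enumerated_two_sided_p(x, y):
    allv = np.concatenate([x, y])
    n1, n = len(x), len(x) + len(y)
    mean = n1 * (n - n1) / 2

    def u1(idx):
        xs = allv[list(idx)]
        ys = np.delete(allv, list(idx))
        return float((xs[:, None] > ys[None, :]).sum())

    obs = u1(range(n1))
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(u1(idx) - mean) >= abs(obs - mean) - 1e-12:
            hits += 1
    return hits / total


class TestKsNormality:
    def test_normal_samples_pass_gate(self):
        rng = np.random.default_rng(77)
        passes = sum(
            ks_normality(rng.normal(50, 8, 500)).metadata["gate_passes"]
            for _ in range(100)
        )
        assert passes >= 90

    def test_left_skewed_sample_fails_gate(self):
        rng = np.random.default_rng(78)
        v = 70.0 - rng.exponential(8.0, 500)
        assert not ks_normality(v).metadata["gate_passes"]

    def test_constant_sample_degenerate(self):
        res = ks_normality(np.full(20, 5.0))
        assert res.metadata["degenerate"]
        assert not res.metadata["gate_passes"]


class TestRmAnova:
    @staticmethod
    def _balanced_df(rng, a_shift=0.0, int_shift=0.0, n=8):
        rows = []
        for g, gshift in (("g1", 0.0), ("g2", a_shift)):
            for i in range(n):
                subj_eff = rng.normal(0, 2.0)
                for tp, tshift in (("t1", 0.0), ("t2", 3.0)):
                    val = 20.0 + gshift + tshift + subj_eff + rng.normal(0, 1.5)
                    if g == "g2" and tp == "t2":
                        val += int_shift
                    rows.append({"animal": f"{g}{i}", "group": g,
                                 "timepoint": tp, "value": val})
        return pd.DataFrame(rows)

    @staticmethod
    def _glm_oracle(df):
        """Balanced 2x2 mixed-design sums of squares, computed by hand."""
        piv = df.pivot_table(index=["group", "animal"], columns="timepoint",
                             values="value")
        groups = sorted(df["group"].unique())
        times = sorted(df["timepoint"].unique())
        a, b = len(groups), len(times)
        n = piv.loc[groups[0]].shape[0]
        grand = piv.to_numpy().mean()
        m_g = {g: piv.loc[g].to_numpy().mean() for g in groups}
        m_t = {t: piv[t].mean() for t in times}
        m_gt = {(g, t): piv.loc[g][t].mean() for g in groups for t in times}
        m_s = piv.mean(axis=1)

        ss_group = b * n * sum((m_g[g] - grand) ** 2 for g in groups)
        ss_subj = b * sum(
            (m_s[(g, s)] - m_g[g]) ** 2 for g, s in piv.index
        )
        ss_time = a * n * sum((m_t[t] - grand) ** 2 for t in times)
        ss_int = n * sum(
            (m_gt[(g, t)] - m_g[g] - m_t[t] + grand) ** 2
            for g in groups for t in times
        )
        ss_err = sum(
            (piv.loc[(g, s), t] - m_gt[(g, t)] - m_s[(g, s)] + m_g[g]) ** 2
            for g, s in piv.index for t in times
        )
        df_group, df_subj = a - 1, a * (n - 1)
        df_time, df_int, df_err = b - 1, (a - 1) * (b - 1), a * (n - 1) * (b - 1)
        return {
            "group": (ss_group / df_group) / (ss_subj / df_subj),
            "time": (ss_time / df_time) / (ss_err / df_err),
            "interaction": (ss_int / df_int) / (ss_err / df_err),
        }

    def test_matches_glm_oracle_balanced(self, rng):
        df = self._balanced_df(rng, a_shift=2.0, int_shift=4.0)
        res = rm_anova_two_way(df)
        oracle = self._glm_oracle(df)
        for key in ("group", "time", "interaction"):
            assert res[key].statistic == pytest.approx(oracle[key], rel=1e-6)

    def test_listwise_exclusion_of_incomplete_subjects(self, rng):
        df = self._balanced_df(rng)
        df = df[~((df.animal == "g10") & (df.timepoint == "t2"))]
        res = rm_anova_two_way(df)
        assert res["group"].metadata["excluded_subjects"] == ["g10"]
        assert res["group"].metadata["n_subjects"] == 15

    def test_degenerate_zero_variance_flagged(self):
        rows = [
            {"animal": f"{g}{i}", "group": g, "timepoint": t, "value": 5.0}
            for g in ("g1", "g2") for i in range(3) for t in ("t1", "t2")
        ]
        res = rm_anova_two_way(pd.DataFrame(rows))
        assert res["interaction"].metadata["degenerate"]

    def test_single_factor_level_rejected(self):
        rows = [
            {"animal": f"a{i}", "group": "g1", "timepoint": t, "value": float(i)}
            for i in range(4) for t in ("t1", "t2")
        ]
        with pytest.raises(ValueError):
            rm_anova_two_way(pd.DataFrame(rows))


class TestSidak:
    def test_single_comparison_unchanged(self):
        res = sidak_posthoc([0.03], alpha=0.05, m=1)
        assert res.alpha_adjusted == pytest.approx(0.05)
        assert res.p_adjusted[0] == pytest.approx(0.03)

    def test_three_comparisons_alpha_prime(self):
        res = sidak_posthoc([0.01, 0.02, 0.5], alpha=0.05)
        assert res.alpha_adjusted == pytest.approx(0.016952, abs=5e-7)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(20)
        res = sidak_posthoc(p, m=20)
        assert (res.p_adjusted >= p - 1e-12).all()
        assert (res.p_adjusted <= 1.0).all()


def test_testresult_json_roundtrip():
    res = logrank_test(study_cohort())
    back = TestResult.from_json(res.to_json())
    assert back.statistic == res.statistic
    assert back.p_value == res.p_value
    assert back.df == res.df
    assert back.metadata["observed_group1"] == res.metadata["observed_group1"]
    res2 = rm_anova_two_way(
        TestRmAnova._balanced_df(np.random.default_rng(0), 2.0, 3.0)
    )["interaction"]
    back2 = TestResult.from_json(res2.to_json())
    assert back2.df == res2.df  # tuple survives the round trip
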