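import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from speechmarkers.errors import (
    CompletenessError,
    ConfigurationError,
    DegenerateVarianceError,
    SampleSizeError,
)
from speechmarkers.features import FeatureProfile
from speechmarkers.grouping import GroupAssignment
from speechmarkers.stats import (
    CONTRASTS,
    battery_to_frame,
    holm_adjust,
    p_from_t,
    paired_t,
    run_battery,
    welch_t,
)

finite_floats = st.floats(-50, 50, allow_nan=False)


class TestPairedT:
    def test_closed_form_example(self):
        # d = [1, 1, 3]: mean 5/3, sd 2/sqrt(3) -> t = 2.5, df = 2
        res = paired_t([1, 2, 4], [0, 1, 1])
        assert res.t == pytest.approx(2.5, abs=1e-12)
        assert res.df == 2
        # df=2 Student CDF has the closed form F(t) = 1/2 + t / (2*sqrt(2+t^2))
        p_exact = 2 * (1 - (0.5 + 2.5 / (2 * math.sqrt(2 + 2.5 ** 2))))
        assert res.p_two_tailed == pytest.approx(p_exact, abs=1e-12)
        assert p_exact == pytest.approx(0.1296, abs=5e-5)

    def test_shift_invariance(self):
        x, y = [1.0, 2.0, 4.0, 3.0], [0.0, 1.0, 1.0, 5.0]
        shifted = paired_t([v + 7 for v in x], [v + 7 for v in y])
        assert shifted.t == pytest.approx(paired_t(x, y).t, abs=1e-12)

    def test_antisymmetry(self):
        x, y = [1.0, 2.0, 4.0], [0.0, 1.0, 1.0]
        assert paired_t(x, y).t == pytest.approx(-paired_t(y, x).t, abs=1e-12)

    def test_degenerate_and_small_samples(self):
        with pytest.raises(DegenerateVarianceError):
            paired_t([1, 2, 3], [1, 2, 3])
        with pytest.raises(SampleSizeError):
            paired_t([1], [2])

    def test_equals_one_sample_t_on_differences(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=12), rng.normal(size=12)
        res = paired_t(x, y)
        d = x - y
        t_one_sample = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        assert res.t == pytest.approx(t_one_sample, abs=1e-12)


class TestWelchT:
    def test_closed_form_example(self):
        # means 2 and 7, variances 1 and 4 -> t = -sqrt(15), df = 50/17
        res = welch_t([1, 2, 3], [5, 7, 9])
        assert res.t == pytest.approx(-math.sqrt(15.0), abs=1e-9)
        assert res.df == pytest.approx(50.0 / 17.0, abs=1e-9)

    def test_identical_samples(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_scale_invariance(self):
        x, y = [1.0, 2.0, 5.0], [4.0, 7.0, 9.0, 2.0]
        scaled = welch_t([3 * v for v in x], [3 * v for v in y])
        assert scaled.t == pytest.approx(welch_t(x, y).t, abs=1e-12)

    def test_degenerate_variances(self):
        with pytest.raises(DegenerateVarianceError):
            welch_t([2, 2, 2], [5, 5])

    def test_p_matches_permutation_test(self):
        rng = np.random.default_rng(11)
        for shift in (0.0, 0.6, 1.2):
            x = rng.normal(0, 1, 17)
            y = rng.normal(shift, 1.6, 17)
            observed = abs(welch_t(x, y).t)
            pooled = np.concatenate([x, y])
            count = 0
            n_perm = 2000
            for _ in range(n_perm):
                rng.shuffle(pooled)
                if abs(welch_t(pooled[:17], pooled[17:]).t) >= observed:
                    count += 1
            assert welch_t(x, y).p_two_tailed == pytest.approx(count / n_perm, abs=0.05)


class TestPFromT:
    def test_t_zero_gives_one(self):
        for df in (1, 2.5, 33):
            assert p_from_t(0.0, df) == pytest.approx(1.0)

    def test_cauchy_closed_form(self):
        # df=1 is Cauchy: p = 2*(1 - (1/2 + arctan(t)/pi))
        assert p_from_t(1.0, 1.0) == pytest.approx(0.5, abs=1e-12)
        assert p_from_t(2.0, 1.0) == pytest.approx(
            2 * (1 - (0.5 + math.atan(2.0) / math.pi)), abs=1e-12)

    def test_strictly_decreasing_in_abs_t(self):
        for df in (1.0, 4.0, 33.0):
            ps = [p_from_t(t, df) for t in np.linspace(0, 6, 25)]
            assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_matches_scipy_survival_function(self):
        for t in (-3.2, -0.5, 0.7, 2.5, 6.0):
            for df in (1.0, 2.941, 16.0, 33.0):
                assert p_from_t(t, df) == pytest.approx(
                    2 * scipy.stats.t.sf(abs(t), df), abs=1e-12)

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            p_from_t(1.0, 0.0)


def test_both_tests_match_reference_implementation():
    """1,000 random small samples agree with scipy's t-tests to 1e-9."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        n = int(rng.integers(2, 20))
        m = int(rng.integers(2, 20))
        x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n)
        y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n)
        ref = scipy.stats.ttest_rel(x, y)
        res = paired_t(x, y)
        assert res.t == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-9)
        z = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), m)
        ref = scipy.stats.ttest_ind(x, z, equal_var=False)
        res = welch_t(x, z)
        assert res.t == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-9)


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------

def _profile(pid, partner, filler=5.0, proper=1.0, lb=0.1):
    total = 1000
    return FeatureProfile(pid, partner, total,
                          round(filler * 10), round(proper * 10), round(lb * 10),
                          filler, proper, lb)


def _cohort_profiles(rng=None):
    """2 high + 2 low participants; filler human>ai, proper high>low."""
    rng = rng or np.random.default_rng(3)
    profiles, assignments = [], []
    for pid, group in (("A", "high"), ("B", "high"), ("C", "low"), ("D", "low")):
        assignments.append(GroupAssignment(pid, group, 23))
        base_p = 2.0 if group == "high" else 1.0
        noise = rng.normal(0, 0.05, 4)
        lb = rng.uniform(0.0, 0.02, 2)
        profiles.append(_profile(pid, "human", 8.0 + noise[0], base_p + noise[1],
                                 0.1 + lb[0]))
        profiles.append(_profile(pid, "ai", 5.0 + noise[2], base_p + noise[3],
                                 0.2 + lb[1]))
    return profiles, assignments


class TestRunBattery:
    def test_full_grid_in_deterministic_order(self):
        profiles, assignments = _cohort_profiles()
        results = run_battery(profiles, assignments)
        assert len(results) == 18
        assert [(r.feature, r.contrast) for r in results] == [
            (f, c) for f in ("filler", "proper_noun", "listen_back")
            for c in CONTRASTS
        ]

    def test_sign_conventions(self):
        profiles, assignments = _cohort_profiles()
        res = {(r.feature, r.contrast): r.result for r in run_battery(profiles, assignments)}
        assert res[("filler", "partner_all")].t > 0          # human - ai > 0
        assert res[("proper_noun", "group_all")].t > 0       # high - low > 0
        assert res[("listen_back", "partner_all")].t < 0     # ai heavier

    def test_partner_contrast_kinds(self):
        profiles, assignments = _cohort_profiles()
        res = {(r.feature, r.contrast): r.result for r in run_battery(profiles, assignments)}
        assert res[("filler", "partner_all")].kind == "paired"
        assert res[("filler", "group_all")].kind == "welch"
        assert res[("filler", "partner_all")].n_a == 4
        assert res[("filler", "group_within_ai")].n_a == 2

    def test_missing_session_reported_with_ids(self):
        profiles, assignments = _cohort_profiles()
        incomplete = [p for p in profiles if not (p.participant_id == "B" and p.partner == "ai")]
        with pytest.raises(CompletenessError, match="B"):
            run_battery(incomplete, assignments)

    def test_identical_profiles_report_degeneracy_per_contrast(self):
        profiles = []
        assignments = []
        for pid, group in (("A", "high"), ("B", "high"), ("C", "low"), ("D", "low")):
            assignments.append(GroupAssignment(pid, group, 23))
            profiles.append(_profile(pid, "human"))
            profiles.append(_profile(pid, "ai"))
        results = run_battery(profiles, assignments)
        assert len(results) == 18
        assert all(r.result is None and "variance" in r.error for r in results)

    def test_empty_group_yields_skip_records_not_silence(self):
        profiles, assignments = _cohort_profiles()
        high_only = [a for a in assignments if a.group == "high"]
        high_profiles = [p for p in profiles if p.participant_id in {"A", "B"}]
        results = run_battery(high_profiles, high_only)
        assert len(results) == 18
        by = {(r.feature, r.contrast): r for r in results}
        assert by[("filler", "group_all")].result is None
        assert "empty group" in by[("filler", "group_all")].error
        assert by[("filler", "partner_all")].result is not None

    def test_index_pairing_mode(self):
        profiles, assignments = _cohort_profiles()
        res = {(r.feature, r.contrast): r.result
               for r in run_battery(profiles, assignments, group_test="index_paired")}
        assert res[("filler", "group_within_ai")].kind == "paired"
        assert res[("filler", "partner_all")].kind == "paired"

    def test_stack_pooling_doubles_group_all_sample(self):
        profiles, assignments = _cohort_profiles()
        res_mean = {(r.feature, r.contrast): r.result for r in run_battery(profiles, assignments)}
        res_stack = {(r.feature, r.contrast): r.result
                     for r in run_battery(profiles, assignments, pooling="stack")}
        assert res_mean[("filler", "group_all")].n_a == 2
        assert res_stack[("filler", "group_all")].n_a == 4

    def test_unknown_options_rejected(self):
        profiles, assignments = _cohort_profiles()
        with pytest.raises(ConfigurationError):
            run_battery(profiles, assignments, group_test="bootstrap")
        with pytest.raises(ConfigurationError):
            run_battery(profiles, assignments, pooling="median")

    def test_battery_is_deterministic(self):
        profiles, assignments = _cohort_profiles()
        a = battery_to_frame(run_battery(profiles, assignments)).to_csv(index=False)
        b = battery_to_frame(run_battery(profiles, assignments)).to_csv(index=False)
        assert a == b

    def test_holm_adjustment_never_below_raw_p(self):
        profiles, assignments = _cohort_profiles()
        results = run_battery(profiles, assignments)
        adjusted = holm_adjust(results)
        for r in results:
            if r.result is not None:
                assert adjusted[(r.feature, r.contrast)] >= r.result.p_two_tailed - 1e-15


@given(st.lists(st.tuples(finite_floats, finite_floats), min_size=2, max_size=15))
def test_paired_t_matches_reference_on_random_pairs(pairs):
    x = np.array([a for a, _ in pairs])
    y = np.array([b for _, b in pairs])
    if np.std(x - y, ddof=1) == 0:
        with pytest.raises(DegenerateVarianceError):
            paired_t(x, y)
        return
    ref = scipy.stats.ttest_rel(x, y)
    res = paired_t(x, y)
    assert res.t == pytest.approx(ref.statistic, rel=1e-9, abs=1e-9)
    assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-9)
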