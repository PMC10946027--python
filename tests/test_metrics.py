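"""Outcome, exploration, and memory measures against hand and brute-force oracles."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stridelearn import (
    AgentParams,
    PhaseLayout,
    compute_metric_table,
    default_epochs,
    delta_lsl,
    epoch_mean_dlsl,
    match_by_total_variability,
    percent_of_learned,
    percent_success,
    sigma_dlsl,
    sigma_trial_to_trial,
    simulate_cohort,
    simulate_subject,
    target_error,
)
from stridelearn.metrics import absolute_retention_error, epoch_target_error, total_sd_plateau
from stridelearn.protocol import EpochSpec, PostPhase
from conftest import make_series


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def oracle_sigma_t2t(dlsl, flags, base_dlsl, scope_start=1):
    """Explicitly enumerate every (flag, difference) pair, then take SDs."""
    pairs = []
    for s in range(scope_start - 1, len(dlsl) - 1):
        pairs.append((flags[s], dlsl[s + 1] - dlsl[s]))
    succ = [d for f, d in pairs if f]
    fail = [d for f, d in pairs if not f]
    base_diffs = [base_dlsl[i + 1] - base_dlsl[i] for i in range(len(base_dlsl) - 1)]
    den = np.std(base_diffs, ddof=1)
    out = []
    for group in (succ, fail):
        out.append(np.std(group, ddof=1) / den if len(group) >= 2 else float("nan"))
    return tuple(out)


def oracle_greedy_match(values_a, values_b, n_pairs):
    """Re-derive the greedy matching by repeatedly scanning every remaining pair."""
    avail_a = dict(values_a)
    avail_b = dict(values_b)
    pairs = []
    while len(pairs) < n_pairs:
        best = min(
            ((abs(va - vb), tuple(sorted((ia, ib))), ia, ib)
             for ia, va in avail_a.items() for ib, vb in avail_b.items()),
        )
        _, _, ia, ib = best
        pairs.append((ia, ib))
        del avail_a[ia], avail_b[ib]
    return pairs


def series_with_learning(dlsl, flags, base_dlsl, base=0.5):
    """Build a series whose realized baseline mean is exactly `base`."""
    base_vals = base * (1 + np.asarray(base_dlsl) / 100.0)
    base_vals = base_vals - (base_vals.mean() - base)  # pin the realized mean
    learn_vals = base * (1 + np.asarray(dlsl) / 100.0)
    return make_series(
        "S", "RPE",
        {"baseline": base_vals, "learning": learn_vals},
        success={"learning": np.asarray(flags, dtype=float)},
        centers={"learning": np.full(len(dlsl), 10.0)},
    )


class TestDeltaLsl:
    @pytest.mark.parametrize("lsl, base, expected", [
        (0.50, 0.50, 0.0), (0.55, 0.50, 10.0), (0.45, 0.50, -10.0),
    ])
    def test_hand_values(self, lsl, base, expected):
        assert delta_lsl(lsl, base) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True)
    @given(a=st.floats(0.01, 10.0), base=st.floats(0.1, 2.0))
    def test_linearity(self, a, base):
        assert delta_lsl(a * base, base) == pytest.approx((a - 1) * 100, rel=1e-9, abs=1e-9)

    def test_bad_baseline(self):
        with pytest.raises(ValueError):
            delta_lsl(0.5, 0.0)


class TestEpochMeans:
    def test_symmetric_mean(self):
        s = series_with_learning([8, 10, 12], [1, 1, 1], [0, 0, 0, 0])
        spec = EpochSpec("e", "learning", 1, 3)
        assert epoch_mean_dlsl(s, spec) == pytest.approx(10.0)

    def test_perfect_tracker_hits_ten(self):
        # gain-1 tracking lags the target by one stride, so the first plateau
        # stride still executes the 9% target: exact 10s start one stride later
        p = AgentParams(group="TE", baseline_lsl_m=0.6, correction_gain=1.0,
                        baseline_sd_m=0.0, seed=1)
        s = simulate_subject(p)
        assert epoch_mean_dlsl(s, default_epochs()["late_learning"]) == pytest.approx(10.0)
        assert epoch_mean_dlsl(
            s, default_epochs()["early_learning"]) == pytest.approx(10.0, abs=0.025)

    @pytest.mark.parametrize("dlsl, center, expected", [
        (10.0, 10.0, 0.0), (7.5, 10.0, 2.5), (12.2, 10.0, pytest.approx(2.2))])
    def test_target_error(self, dlsl, center, expected):
        assert target_error(dlsl, center) == expected

    @pytest.mark.parametrize("flags, expected", [
        ([1, 1, 0, 1], 75.0), ([0, 0], 0.0), ([1, 1, 1], 100.0)])
    def test_percent_success(self, flags, expected):
        assert percent_success(flags) == expected


class TestSigmaDlsl:
    def base_series(self, learn_pattern, base_pattern):
        base = np.tile(base_pattern, 25)[:50]
        learn = np.tile(learn_pattern, 25)[:50]
        return make_series("S", "RPE", {"baseline": base, "learning": learn})

    def test_hand_ratio_two(self):
        # learning sd 2.191, baseline sd 1.095 on the dLSL scale -> exactly 2
        s = self.base_series([0.58, 0.62], [0.59, 0.61])
        spec = EpochSpec("e", "learning", 1, 50)
        ref = EpochSpec("b", "baseline", 1, 50)
        assert sigma_dlsl(s, spec, ref) == pytest.approx(2.0, rel=1e-12)

    def test_self_normalization(self):
        s = self.base_series([0.59, 0.61], [0.59, 0.61])
        assert sigma_dlsl(s, EpochSpec("e", "learning", 1, 50),
                          EpochSpec("b", "baseline", 1, 50)) == pytest.approx(1.0)

    def test_constant_epoch_is_zero(self):
        s = self.base_series([0.6, 0.6], [0.59, 0.61])
        assert sigma_dlsl(s, EpochSpec("e", "learning", 1, 50),
                          EpochSpec("b", "baseline", 1, 50)) == 0.0

    def test_zero_baseline_sd_rejected(self):
        s = self.base_series([0.59, 0.61], [0.6, 0.6])
        with pytest.raises(ValueError, match="baseline"):
            sigma_dlsl(s, EpochSpec("e", "learning", 1, 50),
                       EpochSpec("b", "baseline", 1, 50))

    @pytest.mark.parametrize("scale", [0.5, 2.0, 3.7])
    def test_scale_free(self, scale):
        rng = np.random.default_rng(0)
        base = 0.6 + 0.01 * rng.standard_normal(50)
        learn = 0.65 + 0.02 * rng.standard_normal(50)
        s1 = make_series("S", "RPE", {"baseline": base, "learning": learn})
        s2 = make_series("S", "RPE", {"baseline": scale * base, "learning": scale * learn})
        spec = EpochSpec("e", "learning", 1, 50)
        ref = EpochSpec("b", "baseline", 1, 50)
        assert sigma_dlsl(s1, spec, ref) == pytest.approx(sigma_dlsl(s2, spec, ref), rel=1e-9)


class TestSigmaTrialToTrial:
    REF = EpochSpec("b", "baseline", 1, 4)

    def test_hand_toy_matches_oracle(self):
        dlsl = [10, 10, 12, 10, 8, 10, 12, 10]
        flags = [1, 0, 1, 0, 1, 0, 1, 0]
        base = [1.0, -1.0, 1.0, -1.0]
        s = series_with_learning(dlsl, flags, base)
        got = sigma_trial_to_trial(s, self.REF, scope_start=1)
        expected = oracle_sigma_t2t(
            np.asarray(dlsl, dtype=float), flags, np.asarray(base, dtype=float))
        assert got == pytest.approx(expected, rel=1e-9)
        # success-conditioned diffs are {0, -2, 2, -2}; failure {2, -2, 2}
        assert got[0] == pytest.approx(np.std([0, -2, 2, -2], ddof=1)
                                       / np.std(np.diff(base), ddof=1), rel=1e-9)

    def test_random_toys_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(30, 61))
            dlsl = rng.normal(10, 3, n)
            flags = rng.integers(0, 2, n)
            if flags[:-1].sum() < 2 or (1 - flags[:-1]).sum() < 2:
                continue
            base = rng.normal(0, 1, 10)
            s = series_with_learning(dlsl, flags, base)
            got = sigma_trial_to_trial(s, EpochSpec("b", "baseline", 1, 10), scope_start=1)
            exp = oracle_sigma_t2t(dlsl, flags, base)
            np.testing.assert_allclose(got, exp, rtol=1e-12)

    def test_all_success_constant_series(self, caplog):
        dlsl = [10.0] * 8
        flags = [1] * 8
        s = series_with_learning(dlsl, flags, [1.0, -1.0, 1.0, -1.0])
        succ, fail = sigma_trial_to_trial(s, self.REF, scope_start=1)
        assert succ == 0.0
        assert np.isnan(fail)

    def test_failure_exploration_signature(self):
        """Agents that explore after failure show larger post-failure variability."""
        epochs = default_epochs()
        wins = 0
        for seed in range(30):
            p = AgentParams(group="RPE", baseline_lsl_m=0.6, explore_sd_scale=3.0, seed=seed)
            s = simulate_subject(p)
            succ, fail = sigma_trial_to_trial(s, epochs["baseline_ref"])
            if fail > succ:
                wins += 1
        assert wins >= 29


class TestPercentOfLearned:
    def make_retention(self, late_dlsl, ret_dlsl, n_ret=25):
        base = np.tile([0.595, 0.605], 25)
        learn = 0.6 * (1 + late_dlsl / 100.0) * np.ones(50)
        ret = 0.6 * (1 + np.asarray(ret_dlsl) / 100.0)
        s = make_series("S", "TE", {"baseline": base, "learning": learn,
                                    "immediate_retention": ret})
        layout = PhaseLayout(baseline_n=50, learning_n=50,
                             posts=(PostPhase("immediate_retention", n_ret),))
        epochs = {
            "baseline_ref": EpochSpec("baseline_ref", "baseline", 1, 50),
            "late_learning": EpochSpec("late_learning", "learning", 1, 50),
            "immediate_retention": EpochSpec("immediate_retention",
                                             "immediate_retention", 1, n_ret),
        }
        return s, epochs

    def test_perfect_retention(self):
        s, epochs = self.make_retention(10.0, np.full(25, 10.0))
        assert percent_of_learned(s, epochs["immediate_retention"], epochs) == pytest.approx(100.0)

    def test_half_retention(self):
        s, epochs = self.make_retention(10.0, np.full(25, 5.0))
        assert percent_of_learned(s, epochs["immediate_retention"], epochs) == pytest.approx(50.0)

    def test_retention_error_hand_value(self):
        s, epochs = self.make_retention(10.0, np.full(25, 8.5))
        assert absolute_retention_error(
            s, epochs["immediate_retention"], epochs) == pytest.approx(1.5)

    def test_recall_bias_recovered_noiselessly(self):
        p = AgentParams(group="TE", baseline_lsl_m=0.6, correction_gain=1.0,
                        baseline_sd_m=0.0, recall_bias_pct=-2.0, seed=1)
        layout = PhaseLayout.retention()
        s = simulate_subject(p, layout=layout)
        epochs = default_epochs(layout)
        assert absolute_retention_error(
            s, epochs["immediate_retention"], epochs) == pytest.approx(2.0)


class TestMatching:
    def cohort_with_sds(self, sds_a, sds_b):
        """Subjects whose plateau dLSL SD is proportional to the requested value."""
        out = []
        for group, sds in (("RPE", sds_a), ("TE", sds_b)):
            for i, sd in enumerate(sds):
                learn = 0.6 * (1 + np.tile([10 - sd, 10 + sd], 30) / 100.0)
                base = np.tile([0.595, 0.605], 5)
                out.append(make_series(f"{group}{i}", group,
                                       {"baseline": base, "learning": learn}))
        return out

    def test_rank_for_rank_on_identical_sets(self):
        cohort = self.cohort_with_sds([1, 2, 3], [1, 2, 3])
        pairs = match_by_total_variability(cohort, 3, plateau_start=1)
        assert sorted(pairs) == [("RPE0", "TE0"), ("RPE1", "TE1"), ("RPE2", "TE2")]

    def test_toy_matches_exhaustive_oracle(self):
        cohort = self.cohort_with_sds([1, 2, 9], [1.1, 2.2, 5])
        pairs = match_by_total_variability(cohort, 3, plateau_start=1)
        values_a = [(f"RPE{i}", v) for i, v in enumerate(
            total_sd_plateau(s, 1) for s in cohort[:3])]
        values_b = [(f"TE{i}", v) for i, v in enumerate(
            total_sd_plateau(s, 1) for s in cohort[3:])]
        assert pairs == oracle_greedy_match(values_a, values_b, 3)
        assert pairs[0] == ("RPE0", "TE0") and pairs[1] == ("RPE1", "TE1")

    def test_six_pairs_from_twelve(self):
        rng = np.random.default_rng(3)
        cohort = self.cohort_with_sds(rng.uniform(1, 4, 12), rng.uniform(1, 4, 12))
        pairs = match_by_total_variability(cohort, 6, plateau_start=1)
        assert len(pairs) == 6
        assert len({p[0] for p in pairs}) == 6 and len({p[1] for p in pairs}) == 6

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(4)
        sds_a, sds_b = rng.uniform(1, 4, 5), rng.uniform(1, 4, 5)
        c1 = self.cohort_with_sds(sds_a, sds_b)
        c2 = self.cohort_with_sds(sds_b, sds_a)  # swapped
        p1 = match_by_total_variability(c1, 3, plateau_start=1)
        p2 = match_by_total_variability(c2, 3, plateau_start=1)
        # same pairings modulo the group swap (RPEi <-> TEi index roles)
        swapped = sorted((b.replace("TE", "RPE"), a.replace("RPE", "TE")) for a, b in p2)
        assert sorted(p1) == swapped

    def test_insufficient_subjects(self):
        cohort = self.cohort_with_sds([1, 2], [1, 2])
        with pytest.raises(ValueError, match="per group"):
            match_by_total_variability(cohort, 3, plateau_start=1)


class TestMetricTable:
    def test_shapes_and_ranges(self):
        layout = PhaseLayout()
        cohort = simulate_cohort((2, 2), layout, seed=9)
        table = compute_metric_table(cohort, layout)
        assert set(table.columns) == {"subject", "group", "measure", "epoch", "value"}
        assert not table.duplicated(subset=["subject", "measure", "epoch"]).any()
        pct = table[table["measure"] == "pct_success"]["value"]
        assert ((0 <= pct) & (pct <= 100)).all()
        sig = table[table["measure"].str.startswith("sigma")]["value"].dropna()
        assert (sig >= 0).all()
        for measure in ("dlsl_early", "dlsl_late", "error", "pct_success",
                        "sigma_dlsl", "sigma_t2t_success", "sigma_t2t_fail",
                        "aftereffect_immediate", "aftereffect_early",
                        "total_sd_plateau", "learning_rate"):
            assert measure in set(table["measure"]), measure

    def test_retention_measures_present(self):
        layout = PhaseLayout.retention()
        cohort = simulate_cohort((1, 1), layout, seed=10)
        table = compute_metric_table(cohort, layout)
        for measure in ("retention_immediate", "retention_24h",
                        "abs_retention_error_immediate", "abs_retention_error_24h"):
            assert measure in set(table["measure"]), measure
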