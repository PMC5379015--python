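"""Scoring engine: onset detection, RT/CT, displacement, commission index.

The onset detector is checked against ``naive_detect``: a deliberately
slow, loop-based re-implementation of the episode definition (sustained
velocity threshold, hysteresis release, rise qualification, backtrack to
movement start) that scans every sample exhaustively.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import DT, make_window, minimum_jerk_rise
from kinectcpt import (
    InvalidTrialError,
    ScoringParams,
    SimConfig,
    TraitProfile,
    UsageError,
    classify_trial,
    commission_index,
    completion_time,
    detect_reaction,
    generate_schedule,
    path_length,
    reaction_time,
    score_session,
    simulate_participant,
    summarize_participant,
)
from kinectcpt.trajectory import segment_trials

PARAMS = ScoringParams()


# ---------------------------------------------------------------------------
# brute-force oracle

def naive_detect(window, p):
    """Exhaustive per-sample scan for rise episodes; returns
    (onset_s, n_reactions, premature, return_s)."""
    t = list(window.pre_t_s[window.pre_tracked]) + list(window.t_s[window.tracked])
    y = list(window.pre_pos[window.pre_tracked, 1]) + list(window.pos[window.tracked, 1])
    n_pre = int(window.pre_tracked.sum())
    base = float(window.baseline_pos[1])
    n = len(t)
    vy = [0.0] * n
    for i in range(n):
        if i == 0:
            vy[i] = (y[1] - y[0]) / (t[1] - t[0])
        elif i == n - 1:
            vy[i] = (y[-1] - y[-2]) / (t[-1] - t[-2])
        else:
            vy[i] = (y[i + 1] - y[i - 1]) / (t[i + 1] - t[i - 1])
    release = p.v_release_ratio * p.v_min_m_s
    episodes = []
    i = 0
    while i <= n - p.k_min_samples:
        if all(vy[i + j] >= p.v_min_m_s for j in range(p.k_min_samples)):
            j = i + p.k_min_samples
            while j < n and vy[j] >= release:
                j += 1
            if max(y[i:j]) >= base + p.rise_min_m:
                episodes.append((i, j))
            i = j
        else:
            i += 1
    premature = any(s < n_pre for s, _ in episodes)
    post = [(s, e) for s, e in episodes if s >= n_pre]
    onset_s = return_s = None
    if post:
        s0 = post[0][0]
        while s0 > 0 and vy[s0 - 1] > p.v_backtrack_m_s:
            s0 -= 1
        onset_s = max(t[s0], window.stimulus.onset_s)
        peak = max(range(s0, n), key=lambda i_: y[i_])
        for i_ in range(peak + 1, n):
            if y[i_] <= base + p.return_band_m:
                return_s = t[i_]
                break
    return onset_s, len(post), premature, return_s


def random_trial_windows(n_trials, seed=0):
    """Raw (unsmoothed) windows from simulated sessions over varied traits."""
    rng = np.random.default_rng(seed)
    windows = []
    sched = generate_schedule("revised-60", seed=seed)
    while len(windows) < n_trials:
        traits = TraitProfile(*rng.uniform(0, 100, size=3))
        cfg = SimConfig(
            seed=int(rng.integers(2**31)),
            noise_sd_m=float(rng.uniform(0, 0.004)),
            omission_base=0.05,
        )
        part = simulate_participant(sched, traits, cfg, int(rng.integers(2**31)))
        windows.extend(segment_trials(part.stream, part.session_schedule))
    return windows[:n_trials]


class TestOnsetDetectorOracle:
    def test_matches_brute_force_on_randomized_trials(self):
        mismatches = 0
        for w in random_trial_windows(300, seed=1):
            ev = detect_reaction(w, PARAMS)
            onset, n_r, prem, ret = naive_detect(w, PARAMS)
            same = (
                (ev.onset_s is None) == (onset is None)
                and (ev.onset_s is None or ev.onset_s == onset)
                and ev.n_reactions == n_r
                and ev.premature == prem
                and (ev.return_s is None) == (ret is None)
                and (ev.return_s is None or ev.return_s == ret)
            )
            mismatches += not same
        assert mismatches == 0

    def test_flat_window_detects_nothing(self):
        w = make_window(np.zeros(60), pre_y=np.zeros(8))
        ev = detect_reaction(w, PARAMS)
        assert ev.onset_s is None and ev.n_reactions == 0 and not ev.premature
        assert ev.peak_elevation_m == 0.0

    def test_minimum_jerk_onset_within_one_sample(self):
        y = minimum_jerk_rise(0.400, window_s=2.0)
        w = make_window(y, pre_y=np.zeros(8))
        ev = detect_reaction(w, PARAMS)
        assert ev.onset_s is not None
        assert abs(ev.onset_s - 0.400) <= DT + 1e-9

    def test_two_raises_counted_as_two_reactions(self):
        y1 = minimum_jerk_rise(0.3, window_s=1.4)
        y2 = minimum_jerk_rise(0.2, window_s=1.4)
        w = make_window(np.concatenate([y1, y2]), pre_y=np.zeros(8))
        ev = detect_reaction(w, PARAMS)
        assert ev.n_reactions == 2
        # oracle agrees on the constructed two-bump trajectory
        assert naive_detect(w, PARAMS)[1] == 2

    def test_premature_rise_flagged(self):
        # movement begins 0.15 s before stimulus onset
        pre = minimum_jerk_rise(0.1, window_s=0.25, baseline_y=0.0)
        y = minimum_jerk_rise(-0.15, window_s=2.0)
        w = make_window(y, pre_y=pre - pre[0])
        ev = detect_reaction(w, PARAMS)
        assert ev.premature

    def test_too_few_tracked_samples_invalid(self):
        w = make_window(np.zeros(5), tracked=[True, False, False, False, False])
        with pytest.raises(InvalidTrialError):
            detect_reaction(w, PARAMS)


class TestReactionAndCompletionTime:
    def test_rt_is_onset_minus_stimulus_onset(self):
        y = minimum_jerk_rise(0.42, window_s=2.0)
        w = make_window(y, onset_s=10.0, pre_y=np.zeros(8))
        ev = detect_reaction(w, PARAMS)
        assert reaction_time(w, ev) == pytest.approx(0.42, abs=DT)

    def test_omission_has_no_rt(self):
        w = make_window(np.zeros(60), pre_y=np.zeros(8))
        assert reaction_time(w, detect_reaction(w, PARAMS)) is None

    def test_premature_only_trial_has_no_rt_and_classifies_premature(self):
        pre = minimum_jerk_rise(0.05, window_s=0.25)
        w = make_window(np.full(60, 0.0), pre_y=pre)
        ev = detect_reaction(w, PARAMS)
        # the rise lives in the buffer; no post-onset episode
        assert ev.premature
        assert reaction_time(w, ev) is None
        assert classify_trial(w.stimulus, ev, None, PARAMS) == "premature_reaction"

    def test_rt_on_x_trial_is_usage_error(self):
        w = make_window(np.zeros(60), is_x=True)
        with pytest.raises(UsageError):
            reaction_time(w, detect_reaction(w, PARAMS))

    def test_ct_is_return_minus_onset(self):
        y = minimum_jerk_rise(0.4, window_s=2.5)
        w = make_window(y, pre_y=np.zeros(8))
        ev = detect_reaction(w, PARAMS)
        assert ev.return_s is not None
        # programmed: 0.35 up + 0.1 hold + 0.35 down from onset
        assert completion_time(ev) == pytest.approx(0.8, abs=3 * DT)

    def test_raise_without_return_has_no_ct(self):
        y = minimum_jerk_rise(0.3, window_s=0.7)  # window ends at the hold
        w = make_window(y[:18], pre_y=np.zeros(8))
        ev = detect_reaction(w, PARAMS)
        assert ev.onset_s is not None and ev.return_s is None
        assert completion_time(ev) is None

    def test_no_onset_no_ct(self):
        w = make_window(np.zeros(60))
        assert completion_time(detect_reaction(w, PARAMS)) is None


class TestPathLength:
    def test_motionless_window_zero(self):
        assert path_length(make_window(np.zeros(30))) == 0.0

    def test_hand_summed_vertical_path(self):
        # up 0.1 + up 0.1 + down 0.1 + down 0.1 = 0.4 m
        w = make_window([0.0, 0.1, 0.2, 0.1, 0.0])
        assert path_length(w) == pytest.approx(0.4)

    def test_single_sample_zero(self):
        assert path_length(make_window([0.5])) == 0.0

    def test_no_tracked_samples_invalid(self):
        w = make_window(np.zeros(5), tracked=np.zeros(5, dtype=bool))
        with pytest.raises(InvalidTrialError):
            path_length(w)

    def test_additive_over_window_splits(self):
        rng = np.random.default_rng(3)
        y = np.cumsum(rng.normal(0, 0.01, size=80))
        whole = path_length(make_window(y))
        left = path_length(make_window(y[:41]))  # split shares sample 40
        right = path_length(make_window(y[40:]))
        assert whole == pytest.approx(left + right)

    def test_peak_metric_is_max_excursion(self):
        w = make_window([0.0, 0.1, 0.2, 0.1])
        assert path_length(w, metric="peak") == pytest.approx(0.2)


class TestCommissionIndex:
    def _triplet(self, x_path_scale):
        prev = make_window([0.0, 0.2, 0.4, 0.2, 0.0])  # path 1.2
        nxt = make_window([0.0, 0.25, 0.5, 0.25, 0.0])  # path 1.5
        x = make_window(
            np.array([0.0, 0.1, 0.2, 0.1, 0.0]) * x_path_scale, is_x=True
        )
        return x, prev, nxt

    def test_ratio_of_paths(self):
        # X path 2 units, neighbours 4 and 5 units -> 0.4
        prev = make_window([0.0, 1.0, 2.0, 1.0, 0.0])
        nxt = make_window([0.0, 1.25, 2.5, 1.25, 0.0])
        x = make_window([0.0, 0.5, 1.0, 0.5, 0.0], is_x=True)
        assert commission_index(x, prev, nxt, PARAMS) == pytest.approx(2.0 / 5.0)

    def test_motionless_x_window_zero(self):
        x, prev, nxt = self._triplet(0.0)
        assert commission_index(x, prev, nxt, PARAMS) == 0.0

    def test_motionless_neighbours_undefined(self):
        x = make_window([0.0, 0.1, 0.2, 0.1, 0.0], is_x=True)
        flat = make_window(np.zeros(5))
        assert commission_index(x, flat, flat, PARAMS) is None

    def test_non_x_trial_is_usage_error(self):
        w = make_window(np.zeros(5))
        with pytest.raises(UsageError):
            commission_index(w, w, w, PARAMS)

    def test_missing_posterior_neighbour_uses_previous_only(self):
        x, prev, _ = self._triplet(1.0)
        ci_both = commission_index(x, prev, None, PARAMS)
        assert ci_both == pytest.approx(path_length(x) / path_length(prev))

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        x, prev, nxt = self._triplet(1.0)
        base = commission_index(x, prev, nxt, PARAMS)
        xs = make_window(x.pos[:, 1] * scale, is_x=True)
        prevs = make_window(prev.pos[:, 1] * scale)
        nxts = make_window(nxt.pos[:, 1] * scale)
        assert commission_index(xs, prevs, nxts, PARAMS) == pytest.approx(base)

    @given(amp=st.floats(0.0, 2.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_x_amplitude(self, amp):
        x, prev, nxt = self._triplet(amp)
        x_bigger = make_window(x.pos[:, 1] * 1.5, is_x=True)
        lo = commission_index(x, prev, nxt, PARAMS)
        hi = commission_index(x_bigger, prev, nxt, PARAMS)
        assert hi >= lo


class TestClassification:
    def test_x_index_below_c_lo_is_correct_inhibition(self):
        w = make_window(np.zeros(5), is_x=True)
        ev = detect_reaction(make_window(np.zeros(60)), PARAMS)
        assert classify_trial(w.stimulus, ev, 0.02, PARAMS) == "correct_inhibition"

    def test_x_index_bands(self):
        stim = make_window(np.zeros(5), is_x=True).stimulus
        ev = detect_reaction(make_window(np.zeros(60)), PARAMS)
        assert classify_trial(stim, ev, 0.3, PARAMS) == "inhibited_commission"
        assert classify_trial(stim, ev, 0.7, PARAMS) == "commission"

    def test_partial_omission_when_no_return(self):
        y = minimum_jerk_rise(0.3, window_s=0.7)[:18]
        w = make_window(y, pre_y=np.zeros(8))
        ev = detect_reaction(w, PARAMS)
        assert classify_trial(w.stimulus, ev, None, PARAMS) == "partial_omission"

    def test_two_rises_classified_multiple_reaction(self):
        y = np.concatenate(
            [minimum_jerk_rise(0.3, window_s=1.4), minimum_jerk_rise(0.2, window_s=1.4)]
        )
        w = make_window(y, pre_y=np.zeros(8))
        ev = detect_reaction(w, PARAMS)
        assert classify_trial(w.stimulus, ev, None, PARAMS) == "multiple_reaction"

    def test_invalid_trial_wins(self):
        stim = make_window(np.zeros(5)).stimulus
        assert classify_trial(stim, None, None, PARAMS, invalid=True) == "invalid_trial"


class TestSummaries:
    def test_compliant_session_counts(self, compliant_participant):
        results = score_session(
            compliant_participant.stream, compliant_participant.session_schedule
        )
        summary = summarize_participant(results)
        assert summary.n_rt_obs == 48
        assert summary.n_ct_obs == 48
        assert summary.n_ci_obs == 12
        assert summary.event_counts["invalid_trial"] == 0

    def test_odd_count_median(self):
        from kinectcpt.scoring import TrialResult
        from kinectcpt.schedule import Stimulus

        def res(i, rt):
            stim = Stimulus(i, "A", False, float(i), 2.0)
            return TrialResult(stim, None, rt, None, 0.0, None, "full_reaction")

        summary = summarize_participant([res(0, 0.3), res(1, 0.5), res(2, 0.4)])
        assert summary.median_rt_s == pytest.approx(0.4)

    def test_even_count_median_is_mean_of_central_pair(self):
        from kinectcpt.scoring import TrialResult
        from kinectcpt.schedule import Stimulus

        def res(i, rt):
            stim = Stimulus(i, "A", False, float(i), 2.0)
            return TrialResult(stim, None, rt, None, 0.0, None, "full_reaction")

        summary = summarize_participant([res(i, v) for i, v in enumerate([0.2, 0.3, 0.5, 0.8])])
        assert summary.median_rt_s == pytest.approx(0.4)

    def test_all_zero_commission_indices(self):
        from kinectcpt.scoring import TrialResult
        from kinectcpt.schedule import Stimulus

        def res(i):
            stim = Stimulus(i, "X", True, float(i), 2.0)
            return TrialResult(stim, None, None, None, 0.0, 0.0, "correct_inhibition")

        summary = summarize_participant([res(i) for i in range(12)])
        assert summary.median_commission_index == 0.0
        assert summary.n_ci_obs == 12

    def test_zero_rt_observations_warn(self):
        summary = summarize_participant([])
        assert summary.median_rt_s is None
        assert any("rt" in w for w in summary.warnings)
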