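"""Per-trial scoring of hand-raise reactions and participant summaries.

The task asks for a hand raise after every go letter and for stillness
after the no-go ``X``.  From each trial window this module derives:

* a :class:`ReactionEvent` — movement onset, peak, return-to-rest, and the
  number of distinct rise episodes, via a sustained vertical-velocity
  threshold with hysteresis;
* the reaction time RT (stimulus onset to movement onset, go trials);
* the completion time CT (movement onset to return to the rest band);
* the hand's displacement (3-D path length) within the window;
* for no-go trials the commission index: the ratio of the displacement
  during the X window to the maximum displacement in the two neighbouring
  trial windows — a continuous measure of failed inhibition (0 = perfect
  stillness, ~1 = a full reaction);
* an event class (full reaction, omission, partial omission, multiple
  reaction, premature reaction; commission / inhibited commission /
  correct inhibition for no-go trials).

A participant is summarised by the median RT, median CT and median
commission index over the valid trials of the session.

Onset detection
---------------
The hand "starts to raise" at the beginning of the first sustained upward
movement after the stimulus: vertical velocity must exceed ``v_min`` for at
least ``k_min_samples`` consecutive samples and the hand must subsequently
rise at least ``rise_min_m`` above the rest baseline.  The reported onset is
then backtracked from the threshold crossing to the start of the movement
(the last preceding sample with near-zero vertical velocity), which removes
the threshold-crossing lag so that noise-free synthetic raises are timed to
within one sample.  Rise episodes end when velocity falls below the
hysteresis release level; each qualifying episode counts one reaction, and
an episode beginning inside the pre-onset buffer marks the trial premature.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .schedule import Stimulus, StimulusSchedule
from .trajectory import TrajectoryStream, TrialWindow, segment_trials

__all__ = [
    "ScoringParams",
    "InvalidTrialError",
    "UsageError",
    "ReactionEvent",
    "TrialResult",
    "ParticipantSummary",
    "EVENT_CLASSES",
    "smooth_stream",
    "detect_reaction",
    "reaction_time",
    "completion_time",
    "path_length",
    "commission_index",
    "classify_trial",
    "score_session",
    "summarize_participant",
]

EVENT_CLASSES = (
    "full_reaction",
    "omission",
    "partial_omission",
    "multiple_reaction",
    "premature_reaction",
    "commission",
    "inhibited_commission",
    "correct_inhibition",
    "invalid_trial",
)


class InvalidTrialError(ValueError):
    """Trial cannot be scored (too few tracked samples)."""


class UsageError(ValueError):
    """Operation applied to the wrong trial type."""


@dataclass(frozen=True)
class ScoringParams:
    """Thresholds of the scoring engine.

    All defaults are engine policy, exposed here because the underlying
    task description leaves them open.

    v_min_m_s : sustained vertical velocity needed to open a rise episode.
    k_min_samples : consecutive samples above ``v_min_m_s`` required.
    rise_min_m : minimum elevation above baseline for a rise to count.
    v_release_ratio : hysteresis; an episode closes when velocity drops
        below ``v_release_ratio * v_min_m_s``.
    v_backtrack_m_s : near-zero velocity level used to backtrack from the
        threshold crossing to the movement start.
    return_band_m : height above baseline below which the hand counts as
        returned to rest.
    c_lo, c_hi : commission-index cuts separating correct inhibition
        (< c_lo), inhibited commission ([c_lo, c_hi)) and commission
        (>= c_hi); medians always use the continuous index.
    d_min_m : minimum neighbour displacement for the commission-index
        denominator; below it the index is undefined.
    max_untracked_s : tracking loss beyond which a trial is invalid.
    smooth_window : centred moving-average width (samples) applied to the
        stream before scoring; 1 disables smoothing.
    displacement_metric : "path" (3-D path length, default) or "peak"
        (maximum excursion from baseline), for sensitivity analyses.
    """

    v_min_m_s: float = 0.15
    k_min_samples: int = 3
    rise_min_m: float = 0.05
    v_release_ratio: float = 0.4
    v_backtrack_m_s: float = 0.02
    return_band_m: float = 0.05
    c_lo: float = 0.1
    c_hi: float = 0.5
    d_min_m: float = 0.05
    max_untracked_s: float = 0.5
    smooth_window: int = 5
    displacement_metric: str = "path"
    pre_buffer_s: float = 0.25


@dataclass(frozen=True)
class ReactionEvent:
    """Kinematic landmarks of the reaction(s) within one trial window."""

    onset_s: float | None
    peak_s: float | None
    return_s: float | None
    peak_elevation_m: float
    n_reactions: int
    premature: bool


@dataclass
class TrialResult:
    """All derived measures for one stimulus."""

    stimulus: Stimulus
    event: ReactionEvent | None
    rt_s: float | None
    ct_s: float | None
    displacement_m: float | None
    commission_index: float | None
    event_class: str
    flags: list[str] = field(default_factory=list)


@dataclass
class ParticipantSummary:
    """Session medians: RT, CT and commission index over valid trials."""

    median_rt_s: float | None
    median_ct_s: float | None
    median_commission_index: float | None
    n_rt_obs: int
    n_ct_obs: int
    n_ci_obs: int
    event_counts: dict[str, int]
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# preprocessing

def smooth_stream(stream: TrajectoryStream, window: int) -> TrajectoryStream:
    """Centred moving-average smoothing of the position channels.

    Untracked samples are excluded from the average (they are bridged by
    linear interpolation before filtering and keep their flag), so sensor
    dropouts do not leak garbage positions into their neighbours.
    """
    if window <= 1 or len(stream) < 3:
        return stream
    pos = stream.pos
    if not stream.tracked.all():
        idx = np.flatnonzero(stream.tracked)
        if idx.size == 0:
            return stream
        pos = pos.copy()
        for axis in range(3):
            pos[:, axis] = np.interp(stream.t_s, stream.t_s[idx], pos[idx, axis])
    sm = uniform_filter1d(pos, size=window, axis=0, mode="nearest")
    return TrajectoryStream(stream.t_s, sm, stream.tracked, stream.nominal_rate_hz)


def _vertical_velocity(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Central-difference vertical velocity (one-sided at the ends)."""
    vy = np.empty_like(y)
    vy[1:-1] = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    vy[0] = (y[1] - y[0]) / (t[1] - t[0])
    vy[-1] = (y[-1] - y[-2]) / (t[-1] - t[-2])
    return vy


# ---------------------------------------------------------------------------
# reaction detection

def _find_episodes(
    vy: np.ndarray, y: np.ndarray, baseline_y: float, params: ScoringParams
) -> list[tuple[int, int]]:
    """Qualifying rise episodes as (start, end) index pairs (end exclusive).

    An episode opens at the first of ``k_min_samples`` consecutive samples
    with ``vy >= v_min`` and closes at the first later sample with
    ``vy < v_release_ratio * v_min``; it qualifies if the hand rises at
    least ``rise_min_m`` above baseline within its span.  Non-qualifying
    spans are skipped, not re-entered.
    """
    n = vy.size
    k = params.k_min_samples
    if n < k:
        return []
    above = vy >= params.v_min_m_s
    sustained = above[: n - k + 1].copy()
    for off in range(1, k):
        sustained &= above[off : n - k + 1 + off]
    starts = np.flatnonzero(sustained)
    if starts.size == 0:
        return []
    below_release = np.flatnonzero(vy < params.v_release_ratio * params.v_min_m_s)
    episodes: list[tuple[int, int]] = []
    resume = 0
    for s in starts:
        if s < resume:
            continue
        j = np.searchsorted(below_release, s)
        end = int(below_release[j]) if j < below_release.size else n
        if y[s:end].max() >= baseline_y + params.rise_min_m:
            episodes.append((int(s), end))
        resume = end
    return episodes


def detect_reaction(window: TrialWindow, params: ScoringParams = ScoringParams()) -> ReactionEvent:
    """Detect rise episodes and kinematic landmarks in one trial window.

    The analysis runs over the tracked samples of the pre-onset buffer plus
    the trial window; the buffer lets movements that began before the
    stimulus be flagged premature.  Raises :class:`InvalidTrialError` when
    fewer than two tracked samples are available.
    """
    if window.n_tracked < 2:
        raise InvalidTrialError(
            f"stimulus {window.stimulus.index}: {window.n_tracked} tracked samples"
        )
    t = np.concatenate([window.pre_t_s[window.pre_tracked], window.t_s[window.tracked]])
    y = np.concatenate(
        [window.pre_pos[window.pre_tracked, 1], window.pos[window.tracked, 1]]
    )
    n_pre = int(window.pre_tracked.sum())
    baseline_y = float(window.baseline_pos[1])

    vy = _vertical_velocity(t, y)
    episodes = _find_episodes(vy, y, baseline_y, params)

    premature = any(s < n_pre for s, _ in episodes)
    post = [(s, e) for s, e in episodes if s >= n_pre]
    n_reactions = len(post)

    onset_s = peak_s = return_s = None
    if post:
        s0, _ = post[0]
        j0 = s0
        while j0 > 0 and vy[j0 - 1] > params.v_backtrack_m_s:
            j0 -= 1
        onset_s = max(float(t[j0]), window.stimulus.onset_s)
        peak_idx = j0 + int(np.argmax(y[j0:]))
        peak_s = float(t[peak_idx])
        peak_elevation = float(y[peak_idx] - baseline_y)
        back = np.flatnonzero(y[peak_idx + 1 :] <= baseline_y + params.return_band_m)
        if back.size:
            return_s = float(t[peak_idx + 1 + int(back[0])])
    else:
        seg = y[n_pre:]
        if seg.size:
            peak_idx = n_pre + int(np.argmax(seg))
            peak_s = float(t[peak_idx])
            peak_elevation = max(0.0, float(y[peak_idx] - baseline_y))
        else:
            peak_elevation = 0.0

    return ReactionEvent(
        onset_s=onset_s,
        peak_s=peak_s,
        return_s=return_s,
        peak_elevation_m=peak_elevation,
        n_reactions=n_reactions,
        premature=premature,
    )


def reaction_time(window: TrialWindow, event: ReactionEvent) -> float | None:
    """RT: stimulus appearance to movement onset, for go trials.

    Absent for omissions and for premature trials (a movement that began
    before the stimulus carries no interpretable latency).  Raises
    :class:`UsageError` on a no-go (X) trial.
    """
    if window.stimulus.is_x:
        raise UsageError("reaction_time is defined for non-X trials only")
    if event.onset_s is None or event.premature:
        return None
    return event.onset_s - window.stimulus.onset_s


def completion_time(event: ReactionEvent) -> float | None:
    """CT: movement onset to return into the rest band; absent if either
    landmark is missing (omission or partial omission)."""
    if event.onset_s is None or event.return_s is None:
        return None
    return event.return_s - event.onset_s


def path_length(window: TrialWindow, metric: str = "path") -> float:
    """Hand displacement within the window, metres.

    ``"path"`` sums Euclidean distances between consecutive tracked
    samples; ``"peak"`` takes the maximum excursion from the trial
    baseline.  Raises :class:`InvalidTrialError` with no tracked samples.
    """
    p = window.pos[window.tracked]
    if p.shape[0] == 0:
        raise InvalidTrialError(f"stimulus {window.stimulus.index}: no tracked samples")
    if metric == "peak":
        return float(np.linalg.norm(p - window.baseline_pos, axis=1).max())
    if metric != "path":
        raise ValueError(f"unknown displacement metric {metric!r}")
    if p.shape[0] == 1:
        return 0.0
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def commission_index(
    x_window: TrialWindow,
    prev_window: TrialWindow | None,
    next_window: TrialWindow | None,
    params: ScoringParams = ScoringParams(),
) -> float | None:
    """Displacement during the X window over the larger neighbour displacement.

    The denominator is the maximum of the previous and posterior trials'
    displacements (only the existing neighbour when the X-stimulus opens or
    closes the session).  Returns None when that maximum is below
    ``d_min_m`` — with both neighbours effectively motionless the ratio
    carries no information.  Raises :class:`UsageError` on a go trial.
    """
    if not x_window.stimulus.is_x:
        raise UsageError("commission_index is defined for X trials only")
    if prev_window is None and next_window is None:
        raise UsageError("commission_index needs at least one neighbouring trial")
    metric = params.displacement_metric
    denom = max(
        path_length(w, metric) for w in (prev_window, next_window) if w is not None
    )
    if denom < params.d_min_m:
        return None
    return path_length(x_window, metric) / denom


def classify_trial(
    stimulus: Stimulus,
    event: ReactionEvent | None,
    ci: float | None,
    params: ScoringParams = ScoringParams(),
    invalid: bool = False,
) -> str:
    """Assign the trial's event class.

    Precedence: invalid trials first; on go trials premature beats multiple
    reaction beats the full/partial/omission split; on no-go trials the
    continuous commission index is cut at ``c_lo``/``c_hi`` (falling back
    to the detected kinematics when the index is undefined).
    """
    if invalid or event is None:
        return "invalid_trial"
    if stimulus.is_x:
        if ci is None:
            # undefined index: judge from the X window's own kinematics
            if event.onset_s is None:
                return "correct_inhibition"
            return "commission" if event.return_s is not None else "inhibited_commission"
        if ci >= params.c_hi:
            return "commission"
        if ci >= params.c_lo:
            return "inhibited_commission"
        return "correct_inhibition"
    if event.premature:
        return "premature_reaction"
    if event.n_reactions >= 2:
        return "multiple_reaction"
    if event.onset_s is None:
        return "omission"
    return "full_reaction" if event.return_s is not None else "partial_omission"


# ---------------------------------------------------------------------------
# session-level driver

def score_session(
    stream: TrajectoryStream,
    schedule: StimulusSchedule,
    params: ScoringParams = ScoringParams(),
) -> list[TrialResult]:
    """Score a whole session: smooth, segment, detect, and classify.

    Returns one :class:`TrialResult` per stimulus, in presentation order.
    Trials with fewer than two tracked samples or more than
    ``max_untracked_s`` of tracking loss come back as ``invalid_trial``.
    """
    sm = smooth_stream(stream, params.smooth_window)
    windows = segment_trials(sm, schedule, pre_buffer_s=params.pre_buffer_s)

    events: list[ReactionEvent | None] = []
    paths: list[float | None] = []
    for w in windows:
        if w.n_tracked < 2 or w.untracked_s > params.max_untracked_s:
            events.append(None)
            paths.append(None)
            continue
        events.append(detect_reaction(w, params))
        paths.append(path_length(w, params.displacement_metric))

    results: list[TrialResult] = []
    for k, w in enumerate(windows):
        ev = events[k]
        flags: list[str] = []
        if ev is None:
            results.append(
                TrialResult(w.stimulus, None, None, None, paths[k], None, "invalid_trial",
                            ["tracking_loss"]))
            continue
        rt = ct = ci = None
        if w.stimulus.is_x:
            # reuse the displacements computed above for the ratio
            neighbor_paths = [
                paths[j]
                for j in (k - 1, k + 1)
                if 0 <= j < len(windows) and paths[j] is not None
            ]
            if not neighbor_paths:
                flags.append("no_valid_neighbor")
            else:
                denom = max(neighbor_paths)
                if denom < params.d_min_m:
                    ci = None
                    flags.append("ci_undefined")
                else:
                    ci = paths[k] / denom
        else:
            rt = reaction_time(w, ev)
            ct = completion_time(ev)
        cls = classify_trial(w.stimulus, ev, ci, params)
        results.append(TrialResult(w.stimulus, ev, rt, ct, paths[k], ci, cls, flags))
    return results


def summarize_participant(results: list[TrialResult]) -> ParticipantSummary:
    """Medians of RT, CT and commission index over the session's valid trials.

    RT and CT come from go trials with the respective landmark present
    (premature trials contribute neither); the commission index comes from
    no-go trials where it is defined.  Even-count medians are the mean of
    the central pair.  A missing pool of observations yields an absent
    median plus a warning flag.
    """
    rts = [r.rt_s for r in results if r.rt_s is not None]
    cts = [r.ct_s for r in results if r.ct_s is not None]
    cis = [r.commission_index for r in results if r.commission_index is not None]
    counts = Counter(r.event_class for r in results)
    warnings = []
    for name, vals in [("rt", rts), ("ct", cts), ("commission_index", cis)]:
        if not vals:
            warnings.append(f"no valid {name} observations")
    return ParticipantSummary(
        median_rt_s=float(np.median(rts)) if rts else None,
        median_ct_s=float(np.median(cts)) if cts else None,
        median_commission_index=float(np.median(cis)) if cis else None,
        n_rt_obs=len(rts),
        n_ct_obs=len(cts),
        n_ci_obs=len(cis),
        event_counts={c: counts.get(c, 0) for c in EVENT_CLASSES},
        warnings=warnings,
    )


def results_to_frame(results: list[TrialResult]):
    """Per-trial results as a tidy DataFrame (one row per stimulus)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "index": [r.stimulus.index for r in results],
            "letter": [r.stimulus.letter for r in results],
            "is_x": [r.stimulus.is_x for r in results],
            "rt_s": [r.rt_s for r in results],
            "ct_s": [r.ct_s for r in results],
            "displacement_m": [r.displacement_m for r in results],
            "commission_index": [r.commission_index for r in results],
            "event_class": [r.event_class for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    )
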