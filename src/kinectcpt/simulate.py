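"""Synthetic participants: hand trajectories plus SWAN item scores.

The generator produces full sessions that the scoring engine can consume,
driven by a latent three-trait profile (inattention, hyperactivity,
impulsivity, each on the 0-100 scale of the web-administered SWAN form):

* go trials emit a minimum-jerk hand raise (rise, brief hold, return) at a
  reaction latency drawn from a shifted lognormal whose log-median
  decreases with impulsivity and hyperactivity — more impulsive profiles
  react faster;
* with a probability that grows with inattention, a go trial is omitted
  (the hand stays at rest);
* no-go (X) trials emit a partial excursion whose amplitude grows with
  impulsivity — from imperceptible twitches (correct inhibition) through
  aborted raises (inhibited commissions) to near-full reactions
  (commissions);
* isotropic Gaussian sensor noise is added to every sample;
* SWAN items are the item's factor trait plus independent Gaussian noise,
  clamped to [0, 100].

All quantitative defaults are generator policy chosen to produce sessions
that look like real recordings (30 Hz, ~0.3 m raises, median RT around
0.5-0.6 s); none are measurements of a clinical population.  Ground truth
(traits, programmed latencies, omissions, amplitudes) is returned alongside
every session so that parameter recovery can be verified end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psychometrics import SwanRecord, score_swan, swan_frame
from .scoring import ScoringParams, score_session, summarize_participant
from .schedule import Stimulus, StimulusSchedule, generate_schedule
from .trajectory import TrajectoryStream

__all__ = [
    "TraitProfile",
    "SimConfig",
    "TraitDistribution",
    "SimulatedParticipant",
    "simulate_trial",
    "simulate_participant",
    "simulate_cohort",
    "score_cohort",
    "minimum_jerk",
]


@dataclass(frozen=True)
class TraitProfile:
    """Latent severity traits, each on the 0-100 SWAN web scale."""

    inattention: float = 50.0
    hyperactivity: float = 50.0
    impulsivity: float = 50.0

    def __post_init__(self) -> None:
        for name in ("inattention", "hyperactivity", "impulsivity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic session.

    RT model: ``rt = rt_shift_s + exp(N(mu, rt_sigma^2))`` with
    ``mu = log(rt_mu0_s) + rt_slope_impulsivity*(imp-50)
    + rt_slope_hyperactivity*(hyp-50)`` — negative slopes make impulsive
    and hyperactive profiles faster.  Omission probability is
    ``omission_base + omission_slope_inattention * inattention`` clamped to
    [0, 1].  X-trial excursion amplitude is
    ``commission_amp_base_m + commission_amp_slope_impulsivity * imp``
    times a lognormal jitter, clipped to the raise height.
    """

    # reaction latency (seconds)
    rt_shift_s: float = 0.15
    rt_mu0_s: float = 0.45
    rt_slope_impulsivity: float = -0.004
    rt_slope_hyperactivity: float = -0.002
    rt_sigma: float = 0.30
    # omissions
    omission_base: float = 0.01
    omission_slope_inattention: float = 0.001
    # no-go excursions
    commission_amp_base_m: float = 0.02
    commission_amp_slope_impulsivity: float = 0.0012
    commission_amp_jitter_sigma: float = 0.5
    # raise kinematics (metres / seconds)
    raise_height_m: float = 0.30
    raise_duration_s: float = 0.35
    hold_s: float = 0.10
    return_duration_s: float = 0.35
    # sensor model
    noise_sd_m: float = 0.002
    rate_hz: float = 30.0
    # session layout
    lead_in_s: float = 2.0
    tail_s: float = 3.0
    # rest position of the hand joint in the camera frame (x, y, z metres)
    rest_pos_m: tuple[float, float, float] = (0.20, 0.90, 1.50)
    # SWAN item noise (0-100 scale units)
    swan_item_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.noise_sd_m < 0:
            raise ValueError("noise_sd_m must be non-negative")
        for name in ("raise_height_m", "raise_duration_s", "return_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile, 0 -> 1 over tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _raise_profile(
    t_rel: np.ndarray, start_s: float, amp_m: float, up_s: float, hold_s: float, down_s: float
) -> np.ndarray:
    """Vertical displacement of a raise-hold-return gesture on ``t_rel``."""
    dy = np.zeros_like(t_rel)
    if amp_m <= 0:
        return dy
    # only the gesture's own span needs evaluating
    i0 = int(np.searchsorted(t_rel, start_s, side="right"))
    i1 = int(np.searchsorted(t_rel, start_s + up_s + hold_s + down_s, side="left"))
    seg = t_rel[i0:i1]
    out = dy[i0:i1]
    tu = (seg - start_s) / up_s
    up = tu < 1
    out[up] = amp_m * minimum_jerk(tu[up])
    hold = (tu >= 1) & (seg < start_s + up_s + hold_s)
    out[hold] = amp_m
    td = (seg - (start_s + up_s + hold_s)) / down_s
    down = td >= 0
    out[down] = amp_m * (1.0 - minimum_jerk(td[down]))
    return dy


def _sample_rt(traits: TraitProfile, cfg: SimConfig, rng: np.random.Generator) -> float:
    mu = (
        np.log(cfg.rt_mu0_s)
        + cfg.rt_slope_impulsivity * (traits.impulsivity - 50.0)
        + cfg.rt_slope_hyperactivity * (traits.hyperactivity - 50.0)
    )
    return cfg.rt_shift_s + float(np.exp(rng.normal(mu, cfg.rt_sigma)))


def simulate_trial(
    stimulus: Stimulus,
    traits: TraitProfile,
    cfg: SimConfig,
    rng: np.random.Generator,
    t_rel: np.ndarray,
) -> tuple[np.ndarray, dict]:
    """Noise-free vertical displacement for one trial on ``t_rel``.

    ``t_rel`` holds sample times relative to the stimulus onset (the
    array may extend past the trial window; later trials overwrite by
    addition in the session builder).  Returns the displacement and a
    ground-truth record with the programmed latency / omission / amplitude.
    """
    truth: dict = {"index": stimulus.index, "is_x": bool(stimulus.is_x)}
    if stimulus.is_x:
        amp = cfg.commission_amp_base_m + cfg.commission_amp_slope_impulsivity * traits.impulsivity
        amp *= float(np.exp(rng.normal(0.0, cfg.commission_amp_jitter_sigma)))
        amp = float(np.clip(amp, 0.0, cfg.raise_height_m))
        latency = _sample_rt(traits, cfg, rng)
        truth.update(rt_s=None, omitted=False, amp_m=amp)
        # an aborted movement: rise toward `amp` and come straight back
        dy = _raise_profile(
            t_rel, latency, amp, cfg.raise_duration_s, 0.0, cfg.return_duration_s
        )
        return dy, truth

    p_omit = float(np.clip(
        cfg.omission_base + cfg.omission_slope_inattention * traits.inattention, 0.0, 1.0
    ))
    # draw in fixed order so the per-trial stream stays reproducible
    omit = bool(rng.random() < p_omit)
    latency = _sample_rt(traits, cfg, rng)
    if omit:
        truth.update(rt_s=None, omitted=True, amp_m=0.0)
        return np.zeros_like(t_rel), truth
    truth.update(rt_s=latency, omitted=False, amp_m=cfg.raise_height_m)
    dy = _raise_profile(
        t_rel, latency, cfg.raise_height_m, cfg.raise_duration_s, cfg.hold_s,
        cfg.return_duration_s,
    )
    return dy, truth


@dataclass
class SimulatedParticipant:
    """One synthetic session: trajectory, SWAN record, and ground truth."""

    stream: TrajectoryStream
    swan: SwanRecord
    session_schedule: StimulusSchedule
    traits: TraitProfile
    trial_truth: pd.DataFrame


def simulate_participant(
    schedule: StimulusSchedule,
    traits: TraitProfile,
    cfg: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> SimulatedParticipant:
    """Simulate a full session for one participant.

    The trajectory starts with ``lead_in_s`` seconds of rest-position
    pre-roll, so the returned ``session_schedule`` is the input schedule
    shifted by the lead-in; score sessions against that copy.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)

    session = schedule.shifted(cfg.lead_in_s)
    dt = 1.0 / cfg.rate_hz
    t_end = session.stimuli[-1].onset_s + cfg.tail_s
    t = np.arange(0.0, t_end + dt / 2, dt)

    y = np.zeros_like(t)
    truths = []
    for stim in session.stimuli:
        i0 = int(np.searchsorted(t, stim.onset_s - 0.5))
        # hand motion may spill a little past the window; cap at ~8 s of span
        i1 = min(t.size, int(np.searchsorted(t, stim.onset_s + 8.0)))
        dy, truth = simulate_trial(stim, traits, cfg, rng, t[i0:i1] - stim.onset_s)
        y[i0:i1] += dy
        truths.append(truth)

    pos = np.empty((t.size, 3))
    pos[:, 0] = cfg.rest_pos_m[0]
    pos[:, 1] = cfg.rest_pos_m[1] + y
    pos[:, 2] = cfg.rest_pos_m[2]
    if cfg.noise_sd_m > 0:
        pos += rng.normal(0.0, cfg.noise_sd_m, size=pos.shape)
    stream = TrajectoryStream(t, pos, np.ones(t.size, dtype=bool), nominal_rate_hz=cfg.rate_hz)

    items = np.empty(18)
    items[0:9] = traits.inattention
    items[9:15] = traits.hyperactivity
    items[15:18] = traits.impulsivity
    if cfg.swan_item_sd > 0:
        items += rng.normal(0.0, cfg.swan_item_sd, size=18)
    swan = score_swan(np.clip(items, 0.0, 100.0))

    return SimulatedParticipant(
        stream=stream,
        swan=swan,
        session_schedule=session,
        traits=traits,
        trial_truth=pd.DataFrame(truths),
    )


@dataclass(frozen=True)
class TraitDistribution:
    """Independent clipped-normal trait sampler (sd 0 gives a point mass)."""

    mean: tuple[float, float, float] = (50.0, 50.0, 50.0)
    sd: tuple[float, float, float] = (20.0, 20.0, 20.0)

    def sample(self, rng: np.random.Generator) -> TraitProfile:
        vals = [
            float(np.clip(rng.normal(m, s), 0.0, 100.0)) if s > 0 else float(m)
            for m, s in zip(self.mean, self.sd)
        ]
        return TraitProfile(*vals)


@dataclass
class Cohort:
    """A simulated cohort with its schedule and logged trait draws."""

    participants: list[SimulatedParticipant]
    schedule: StimulusSchedule
    traits: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_cohort(
    n: int,
    trait_distribution: TraitDistribution = TraitDistribution(),
    cfg: SimConfig = SimConfig(),
    schedule: StimulusSchedule | None = None,
) -> Cohort:
    """Simulate ``n`` independent participants on a shared schedule.

    Per-participant RNGs are spawned from ``cfg.seed`` so each session is
    independent yet fully reproducible.  True trait draws are logged in the
    returned ``traits`` frame for parameter-recovery checks.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if schedule is None:
        schedule = generate_schedule("revised-60", seed=cfg.seed)
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n)
    participants = []
    rows = []
    for pid, child in enumerate(children):
        rng = np.random.default_rng(child)
        traits = trait_distribution.sample(rng)
        participants.append(simulate_participant(schedule, traits, cfg, rng))
        rows.append(
            {
                "participant": pid,
                "inattention": traits.inattention,
                "hyperactivity": traits.hyperactivity,
                "impulsivity": traits.impulsivity,
            }
        )
    return Cohort(participants, schedule, pd.DataFrame(rows))


def score_cohort(cohort: Cohort, params: ScoringParams = ScoringParams()) -> pd.DataFrame:
    """Score every session of a cohort into one tidy frame.

    Columns: participant id, session medians and observation counts, the
    three SWAN factor scores, and the true latent traits — everything the
    validity analysis and parameter-recovery checks need.
    """
    rows = []
    for pid, part in enumerate(cohort.participants):
        results = score_session(part.stream, part.session_schedule, params)
        s = summarize_participant(results)
        rows.append(
            {
                "participant": pid,
                "median_rt_s": s.median_rt_s,
                "median_ct_s": s.median_ct_s,
                "median_commission_index": s.median_commission_index,
                "n_rt_obs": s.n_rt_obs,
                "n_ct_obs": s.n_ct_obs,
                "n_ci_obs": s.n_ci_obs,
            }
        )
    df = pd.DataFrame(rows)
    factors = swan_frame([p.swan for p in cohort.participants])
    return pd.concat([df, factors, cohort.traits.drop(columns=["participant"]).add_prefix("true_")], axis=1)
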