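"""Shared fixtures: schedules, synthetic windows, compliant sessions."""

import numpy as np
import pytest

from kinectcpt import (
    ScoringParams,
    SimConfig,
    Stimulus,
    TraitProfile,
    generate_schedule,
    simulate_participant,
)
from kinectcpt.trajectory import TrialWindow

RATE_HZ = 30.0
DT = 1.0 / RATE_HZ


@pytest.fixture(scope="session")
def revised_schedule():
    return generate_schedule("revised-60", seed=7)


@pytest.fixture
def default_params():
    return ScoringParams()


@pytest.fixture(scope="session")
def compliant_participant(revised_schedule):
    """A fully compliant session: no omissions, no tracking loss, low noise."""
    cfg = SimConfig(seed=11, omission_base=0.0, omission_slope_inattention=0.0)
    return simulate_participant(revised_schedule, TraitProfile(50, 50, 50), cfg, 11)


def make_window(
    y,
    onset_s=0.0,
    baseline=(0.0, 0.0, 0.0),
    pre_y=None,
    x=None,
    z=None,
    is_x=False,
    tracked=None,
    dt=DT,
):
    """Build a TrialWindow from a vertical profile (and optional context).

    ``y`` are heights at ``onset_s, onset_s+dt, ...``; ``pre_y`` (if given)
    fills the pre-onset buffer ending just before the stimulus onset.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    t = onset_s + dt * np.arange(n)
    pos = np.zeros((n, 3))
    pos[:, 0] = baseline[0] if x is None else np.asarray(x, dtype=float)
    pos[:, 1] = y
    pos[:, 2] = baseline[2] if z is None else np.asarray(z, dtype=float)
    if tracked is None:
        tracked = np.ones(n, dtype=bool)
    else:
        tracked = np.asarray(tracked, dtype=bool)
    if pre_y is None:
        pre_y = np.empty(0)
    pre_y = np.asarray(pre_y, dtype=float)
    m = pre_y.size
    pre_t = onset_s - dt * np.arange(m, 0, -1)
    pre_pos = np.zeros((m, 3))
    pre_pos[:, 0] = baseline[0]
    pre_pos[:, 1] = pre_y
    pre_pos[:, 2] = baseline[2]
    stim = Stimulus(
        index=0, letter="X" if is_x else "A", is_x=is_x, onset_s=onset_s, isi_after_s=None
    )
    return TrialWindow(
        stimulus=stim,
        t_s=t,
        pos=pos,
        tracked=tracked,
        baseline_pos=np.asarray(baseline, dtype=float),
        end_s=float(t[-1] + dt) if n else onset_s,
        pre_t_s=pre_t,
        pre_pos=pre_pos,
        pre_tracked=np.ones(m, dtype=bool),
        dt_s=dt,
    )


def minimum_jerk_rise(rt_s, window_s=2.0, height=0.3, up_s=0.35, hold_s=0.1,
                      down_s=0.35, dt=DT, baseline_y=0.0):
    """Noise-free raise-hold-return height profile starting ``rt_s`` after onset."""
    t = dt * np.arange(int(round(window_s / dt)))
    y = np.full_like(t, baseline_y)
    tau_u = (t - rt_s) / up_s
    mj = lambda u: 10 * u**3 - 15 * u**4 + 6 * u**5  # noqa: E731
    rise = (tau_u > 0) & (tau_u < 1)
    y[rise] = baseline_y + height * mj(tau_u[rise])
    hold = (tau_u >= 1) & (t < rt_s + up_s + hold_s)
    y[hold] = baseline_y + height
    tau_d = (t - rt_s - up_s - hold_s) / down_s
    fall = (tau_d >= 0) & (tau_d < 1)
    y[fall] = baseline_y + height * (1 - mj(tau_d[fall]))
    return y
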