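"""Hand-trajectory streams: I/O, gap handling, and per-stimulus segmentation.

A session's behavioural signal is the time series of the dominant-hand
joint position reported by a depth camera at a nominal ~30 Hz.  Positions
are in metres in the camera frame (x lateral, y vertical/up, z depth).
Frames where the sensor lost the joint carry ``tracked == False``.

The on-disk format is a plain CSV with header ``t_s,x_m,y_m,z_m,tracked``
(a JSONL variant with the same keys is also read and written).  Streams are
segmented against a stimulus schedule into half-open trial windows
``[onset, next onset)``; each window also carries a short pre-onset buffer
used to estimate the rest-position baseline and to detect movements that
began before the stimulus appeared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schedule import Stimulus, StimulusSchedule

__all__ = [
    "StreamFormatError",
    "CoverageError",
    "TrajectoryStream",
    "TrialWindow",
    "read_stream",
    "write_stream",
    "interpolate_gaps",
    "segment_trials",
]

_COLUMNS = ["t_s", "x_m", "y_m", "z_m", "tracked"]

#: default length of the pre-onset buffer used for baselines, seconds
DEFAULT_PRE_BUFFER_S = 0.25


class StreamFormatError(ValueError):
    """Malformed trajectory file (missing columns, bad timestamps, empty)."""


class CoverageError(ValueError):
    """Stream too short to cover the schedule; lists the uncovered stimuli."""

    def __init__(self, message: str, uncovered: list[int]):
        super().__init__(message)
        self.uncovered = uncovered


@dataclass
class TrajectoryStream:
    """Time-ordered 3-D hand positions for one session.

    Samples are stored as parallel arrays: ``t_s`` (n,), ``pos`` (n, 3)
    and ``tracked`` (n,) boolean.
    """

    t_s: np.ndarray
    pos: np.ndarray
    tracked: np.ndarray
    nominal_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.tracked = np.asarray(self.tracked, dtype=bool)
        if self.t_s.ndim != 1 or self.pos.shape != (self.t_s.size, 3):
            raise StreamFormatError(
                f"shape mismatch: t_s {self.t_s.shape}, pos {self.pos.shape}"
            )
        if self.tracked.shape != self.t_s.shape:
            raise StreamFormatError("tracked flag shape mismatch")
        if self.nominal_rate_hz <= 0:
            raise StreamFormatError("nominal_rate_hz must be positive")
        if self.t_s.size and (not np.all(np.isfinite(self.t_s)) or self.t_s[0] < 0):
            raise StreamFormatError("timestamps must be finite and non-negative")
        if self.t_s.size > 1:
            d = np.diff(self.t_s)
            if np.any(d <= 0):
                i = int(np.flatnonzero(d <= 0)[0]) + 1
                raise StreamFormatError(
                    f"timestamps not strictly increasing at sample {i} (t={self.t_s[i]})"
                )
        if self.t_s.size and np.any(~np.isfinite(self.pos[self.tracked])):
            raise StreamFormatError("tracked samples must have finite positions")

    def __len__(self) -> int:
        return self.t_s.size

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0]) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "x_m": self.pos[:, 0],
                "y_m": self.pos[:, 1],
                "z_m": self.pos[:, 2],
                "tracked": self.tracked.astype(int),
            }
        )


def _stream_from_frame(df: pd.DataFrame, path: Path, rate_hz: float) -> TrajectoryStream:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise StreamFormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise StreamFormatError(f"{path}: empty stream")
    t = df["t_s"].to_numpy(dtype=float)
    if t.size > 1:
        d = np.diff(t)
        if np.any(d <= 0):
            row = int(np.flatnonzero(d <= 0)[0]) + 1
            raise StreamFormatError(
                f"{path}: non-monotone timestamp at record {row} (t_s={t[row]})"
            )
    pos = df[["x_m", "y_m", "z_m"]].to_numpy(dtype=float)
    tracked = df["tracked"].to_numpy().astype(bool)
    return TrajectoryStream(t, pos, tracked, nominal_rate_hz=rate_hz)


def read_stream(path: str | Path, nominal_rate_hz: float = 30.0) -> TrajectoryStream:
    """Read a trajectory CSV (or ``.jsonl``) into a :class:`TrajectoryStream`.

    Raises :class:`StreamFormatError` naming the first offending record for
    missing columns, empty files, or non-monotone timestamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".jsonl":
        text = path.read_text()
        records = [json.loads(line) for line in text.splitlines() if line.strip()]
        if not records:
            raise StreamFormatError(f"{path}: empty stream")
        df = pd.DataFrame.from_records(records)
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise StreamFormatError(f"{path}: empty stream") from None
    return _stream_from_frame(df, path, nominal_rate_hz)


def write_stream(stream: TrajectoryStream, path: str | Path) -> Path:
    """Write a stream to CSV or ``.jsonl``; positions keep 6 decimal places."""
    if len(stream) == 0:
        raise StreamFormatError("refusing to write a zero-sample stream")
    path = Path(path)
    df = stream.to_frame()
    if path.suffix.lower() == ".jsonl":
        with path.open("w") as fh:
            for rec in df.itertuples(index=False):
                fh.write(
                    json.dumps(
                        {
                            "t_s": round(rec.t_s, 6),
                            "x_m": round(rec.x_m, 6),
                            "y_m": round(rec.y_m, 6),
                            "z_m": round(rec.z_m, 6),
                            "tracked": int(rec.tracked),
                        }
                    )
                    + "\n"
                )
    else:
        df.to_csv(path, index=False, float_format="%.6f")
    return path


def interpolate_gaps(stream: TrajectoryStream, max_gap_s: float = 0.2) -> TrajectoryStream:
    """Fill short tracking losses by linear interpolation.

    Untracked runs whose duration is below ``max_gap_s`` and which are
    bounded by tracked samples on both sides are linearly interpolated and
    re-flagged as tracked; longer (or edge) runs are left untouched.  The
    default of 0.2 s is about six frames at 30 Hz; longer losses are better
    handled by invalidating the affected trial during scoring.
    """
    tracked = stream.tracked.copy()
    pos = stream.pos.copy()
    t = stream.t_s
    n = len(stream)
    i = 0
    while i < n:
        if tracked[i]:
            i += 1
            continue
        j = i
        while j < n and not tracked[j]:
            j += 1
        # run of untracked samples is [i, j)
        if i > 0 and j < n and (t[j] - t[i - 1]) < max_gap_s:
            for axis in range(3):
                pos[i:j, axis] = np.interp(t[i:j], [t[i - 1], t[j]], [pos[i - 1, axis], pos[j, axis]])
            tracked[i:j] = True
        i = j
    return TrajectoryStream(t, pos, tracked, nominal_rate_hz=stream.nominal_rate_hz)


@dataclass
class TrialWindow:
    """Sub-stream for one stimulus: ``[onset, next onset)`` plus context.

    ``pre_t_s``/``pre_pos``/``pre_tracked`` hold the short pre-onset buffer
    (rest-position context); ``baseline_pos`` is the per-trial rest-position
    estimate.  Array fields are views into the parent stream.
    """

    stimulus: Stimulus
    t_s: np.ndarray
    pos: np.ndarray
    tracked: np.ndarray
    baseline_pos: np.ndarray
    end_s: float
    pre_t_s: np.ndarray
    pre_pos: np.ndarray
    pre_tracked: np.ndarray
    dt_s: float

    def __len__(self) -> int:
        return self.t_s.size

    @property
    def n_tracked(self) -> int:
        return int(self.tracked.sum())

    @property
    def untracked_s(self) -> float:
        return float((~self.tracked).sum()) * self.dt_s

    @property
    def window_s(self) -> float:
        return self.end_s - self.stimulus.onset_s


def _session_baseline(stream: TrajectoryStream) -> np.ndarray:
    """Global fallback rest position: median x/z, 10th-percentile height."""
    p = stream.pos[stream.tracked]
    if p.size == 0:
        return np.full(3, np.nan)
    return np.array(
        [np.median(p[:, 0]), np.percentile(p[:, 1], 10), np.median(p[:, 2])]
    )


def segment_trials(
    stream: TrajectoryStream,
    schedule: StimulusSchedule,
    pre_buffer_s: float = DEFAULT_PRE_BUFFER_S,
) -> list[TrialWindow]:
    """Cut a session stream into one half-open window per stimulus.

    Windows partition the span from the first onset to the next onset after
    the last stimulus (the last window runs to the end of the stream).  The
    per-trial rest baseline is the median tracked position over the
    ``pre_buffer_s`` seconds preceding onset, falling back to the
    session-global estimate (median x/z, 10th-percentile height) when the
    buffer holds no tracked samples.

    Raises :class:`CoverageError` listing the stimuli whose windows fall
    beyond the end of the stream.
    """
    if len(stream) == 0:
        raise CoverageError("empty stream covers no stimuli", [s.index for s in schedule.stimuli])
    onsets = schedule.onsets_s
    t = stream.t_s
    uncovered = [int(i) for i in np.flatnonzero(onsets >= t[-1])]
    if uncovered:
        raise CoverageError(
            f"stream ends at t={t[-1]:.3f}s before stimuli {uncovered[0]}-{uncovered[-1]}",
            uncovered,
        )

    dt = 1.0 / stream.nominal_rate_hz
    fallback = _session_baseline(stream)
    starts = np.searchsorted(t, onsets, side="left")
    ends = np.empty(len(onsets), dtype=int)
    ends[:-1] = starts[1:]
    ends[-1] = len(t)
    pre_starts = np.searchsorted(t, onsets - pre_buffer_s, side="left")

    windows: list[TrialWindow] = []
    for k, stim in enumerate(schedule.stimuli):
        i, j, p = int(starts[k]), int(ends[k]), int(pre_starts[k])
        pre_tracked = stream.tracked[p:i]
        if pre_tracked.any():
            baseline = np.median(stream.pos[p:i][pre_tracked], axis=0)
        else:
            baseline = fallback
        end_s = schedule.stimuli[k + 1].onset_s if k + 1 < len(schedule.stimuli) else float(t[-1])
        windows.append(
            TrialWindow(
                stimulus=stim,
                t_s=t[i:j],
                pos=stream.pos[i:j],
                tracked=stream.tracked[i:j],
                baseline_pos=np.asarray(baseline, dtype=float),
                end_s=end_s,
                pre_t_s=t[p:i],
                pre_pos=stream.pos[p:i],
                pre_tracked=stream.tracked[p:i],
                dt_s=dt,
            )
        )
    return windows
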