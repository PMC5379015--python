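"""Stimulus schedules for the motion-capture continuous performance test.

A CPT session presents a stream of single letters; the examinee reacts to
every letter except the forbidden ``X`` (the no-go stimulus), for which any
reaction is an error of commission.  Two presets are provided:

``revised-60``
    3-minute task: 60 letters, 12 of them X-stimuli, inter-stimulus
    intervals drawn from {2, 3, 5} s.
``legacy-360``
    the original ~15-minute task: 360 letters, inter-stimulus intervals
    drawn from {1, 2, 4} s.

Schedules are generated deterministically from a seed and serialised to a
plain JSON file so a session can be replayed and re-scored exactly.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "DesignError",
    "Stimulus",
    "StimulusSchedule",
    "DesignSpec",
    "DESIGN_PRESETS",
    "generate_schedule",
    "validate_schedule",
    "ValidationReport",
]

#: letters available for go trials; X is reserved for the no-go stimulus
_GO_ALPHABET = [c for c in string.ascii_uppercase if c != "X"]


class DesignError(ValueError):
    """Raised for task designs that cannot produce a valid schedule."""


@dataclass(frozen=True)
class Stimulus:
    """One presented letter.

    Attributes
    ----------
    index : int
        0-based position in the presentation order.
    letter : str
        Single uppercase character shown on screen.
    is_x : bool
        True iff this is the forbidden (no-go) stimulus.
    onset_s : float
        Presentation time in seconds from schedule time zero.
    isi_after_s : float or None
        Interval until the next stimulus onset; None for the last stimulus.
    """

    index: int
    letter: str
    is_x: bool
    onset_s: float
    isi_after_s: float | None


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of a CPT task design."""

    total: int
    n_x: int
    isi_set_s: tuple[float, ...]
    name: str = "custom"
    #: sampling weights for the ISI set; None means uniform
    isi_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.total < 1:
            raise DesignError(f"total stimulus count must be >= 1, got {self.total}")
        if not 0 <= self.n_x <= self.total:
            raise DesignError(
                f"X count must lie in [0, total], got {self.n_x} of {self.total}"
            )
        if self.total > 1 and self.n_x > self.total - 1:
            raise DesignError(
                "X count must leave at least the first stimulus non-X "
                f"(got {self.n_x} of {self.total})"
            )
        if not self.isi_set_s:
            raise DesignError("ISI set must be non-empty")
        if any(isi <= 0 for isi in self.isi_set_s):
            raise DesignError(f"ISIs must be positive, got {self.isi_set_s}")
        if self.isi_weights is not None and (
            len(self.isi_weights) != len(self.isi_set_s)
            or any(w < 0 for w in self.isi_weights)
            or sum(self.isi_weights) <= 0
        ):
            raise DesignError("isi_weights must be non-negative and match isi_set_s")


DESIGN_PRESETS: dict[str, DesignSpec] = {
    "revised-60": DesignSpec(total=60, n_x=12, isi_set_s=(2.0, 3.0, 5.0), name="revised-60"),
    # the legacy design's X proportion is kept at the revised design's 20%
    "legacy-360": DesignSpec(total=360, n_x=72, isi_set_s=(1.0, 2.0, 4.0), name="legacy-360"),
}


@dataclass
class StimulusSchedule:
    """An ordered stimulus sequence with onset times.

    ``design_name`` is ``"revised-60"``, ``"legacy-360"`` or ``"custom"``;
    ``seed`` records the generator seed for reproducibility.
    """

    design_name: str
    stimuli: list[Stimulus]
    isi_set_s: tuple[float, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.stimuli)

    @property
    def n_x(self) -> int:
        return sum(s.is_x for s in self.stimuli)

    @property
    def n_non_x(self) -> int:
        return len(self.stimuli) - self.n_x

    @property
    def onsets_s(self) -> np.ndarray:
        return np.array([s.onset_s for s in self.stimuli], dtype=float)

    @property
    def duration_s(self) -> float:
        """Span from the first onset to the last onset."""
        return self.stimuli[-1].onset_s - self.stimuli[0].onset_s

    def shifted(self, dt_s: float) -> "StimulusSchedule":
        """Return a copy with every onset translated by ``dt_s`` seconds.

        Used to place a schedule inside a recording that starts with a
        lead-in of rest-position data before the first stimulus.
        """
        stimuli = [replace(s, onset_s=s.onset_s + dt_s) for s in self.stimuli]
        return StimulusSchedule(self.design_name, stimuli, self.isi_set_s, self.seed)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "design_name": self.design_name,
            "seed": self.seed,
            "isi_set_s": list(self.isi_set_s),
            "stimuli": [
                {
                    "index": s.index,
                    "letter": s.letter,
                    "is_x": s.is_x,
                    "onset_s": round(s.onset_s, 6),
                    "isi_after_s": None if s.isi_after_s is None else round(s.isi_after_s, 6),
                }
                for s in self.stimuli
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        stimuli = [
            Stimulus(
                index=int(s["index"]),
                letter=str(s["letter"]),
                is_x=bool(s["is_x"]),
                onset_s=float(s["onset_s"]),
                isi_after_s=None if s.get("isi_after_s") is None else float(s["isi_after_s"]),
            )
            for s in d["stimuli"]
        ]
        return cls(
            design_name=str(d["design_name"]),
            stimuli=stimuli,
            isi_set_s=tuple(float(x) for x in d["isi_set_s"]),
            seed=int(d["seed"]),
        )

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def read_json(cls, path: str | Path) -> "StimulusSchedule":
        return cls.from_dict(json.loads(Path(path).read_text()))


def generate_schedule(
    design: str | DesignSpec = "revised-60",
    seed: int = 0,
    start_s: float = 0.0,
) -> StimulusSchedule:
    """Generate a randomised schedule for a named preset or custom design.

    X positions are drawn uniformly at random among positions 1..total-1
    (the first stimulus is always a go trial so that every X-stimulus has a
    preceding trial for the commission-index denominator).  Go letters are
    drawn uniformly from A-Z excluding X; each inter-stimulus interval is
    drawn independently from the design's ISI set (uniformly unless the
    design specifies weights).  The result is deterministic in
    ``(design, seed)``.

    Parameters
    ----------
    design : str or DesignSpec
        ``"revised-60"``, ``"legacy-360"`` or an explicit :class:`DesignSpec`.
    seed : int
        Seed for the schedule's random draws.
    start_s : float
        Onset time of the first stimulus (default 0).
    """
    if isinstance(design, str):
        try:
            spec = DESIGN_PRESETS[design]
        except KeyError:
            raise DesignError(
                f"unknown design preset {design!r}; known: {sorted(DESIGN_PRESETS)}"
            ) from None
    else:
        spec = design

    rng = np.random.default_rng(seed)

    total = spec.total
    if total == 1:
        x_positions: set[int] = {0} if spec.n_x == 1 else set()
    else:
        x_positions = set(rng.choice(np.arange(1, total), size=spec.n_x, replace=False).tolist())

    isi_set = np.asarray(spec.isi_set_s, dtype=float)
    if spec.isi_weights is None:
        p = None
    else:
        w = np.asarray(spec.isi_weights, dtype=float)
        p = w / w.sum()
    isis = rng.choice(isi_set, size=total - 1, p=p) if total > 1 else np.empty(0)

    letters = rng.choice(_GO_ALPHABET, size=total)

    stimuli: list[Stimulus] = []
    onset = float(start_s)
    for i in range(total):
        is_x = i in x_positions
        isi_after = float(isis[i]) if i < total - 1 else None
        stimuli.append(
            Stimulus(
                index=i,
                letter="X" if is_x else str(letters[i]),
                is_x=is_x,
                onset_s=onset,
                isi_after_s=isi_after,
            )
        )
        if isi_after is not None:
            onset += isi_after

    return StimulusSchedule(
        design_name=spec.name,
        stimuli=stimuli,
        isi_set_s=tuple(spec.isi_set_s),
        seed=int(seed),
    )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_schedule`; empty ``violations`` means valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


def validate_schedule(s: StimulusSchedule, atol: float = 1e-6) -> ValidationReport:
    """Check every schedule invariant and report all violations found.

    Checks letter/flag consistency, strictly increasing onsets, consistency
    of onsets with the recorded ISIs, ISI membership in the declared set,
    and preset-specific stimulus counts.
    """
    v: list[str] = []

    for st in s.stimuli:
        if st.is_x != (st.letter == "X"):
            v.append(f"stimulus {st.index}: is_x={st.is_x} inconsistent with letter {st.letter!r}")

    onsets = s.onsets_s
    if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
        bad = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
        v.append(f"onsets not strictly increasing (first violation at stimulus {bad})")

    for st, nxt in zip(s.stimuli[:-1], s.stimuli[1:]):
        if st.isi_after_s is None:
            v.append(f"stimulus {st.index}: missing isi_after_s before last stimulus")
            continue
        if not any(abs(st.isi_after_s - isi) <= atol for isi in s.isi_set_s):
            v.append(
                f"stimulus {st.index}: ISI {st.isi_after_s} not in declared set {s.isi_set_s}"
            )
        if abs((nxt.onset_s - st.onset_s) - st.isi_after_s) > atol:
            v.append(
                f"stimulus {st.index}: onset gap {nxt.onset_s - st.onset_s:.6f} "
                f"!= recorded ISI {st.isi_after_s}"
            )
    if s.stimuli and s.stimuli[-1].isi_after_s is not None:
        v.append("last stimulus must not carry isi_after_s")

    preset = DESIGN_PRESETS.get(s.design_name)
    if preset is not None:
        if len(s.stimuli) != preset.total:
            v.append(f"{s.design_name}: expected {preset.total} stimuli, found {len(s.stimuli)}")
        if s.n_x != preset.n_x:
            v.append(f"{s.design_name}: expected {preset.n_x} X-stimuli, found {s.n_x}")
        if tuple(s.isi_set_s) != preset.isi_set_s:
            v.append(
                f"{s.design_name}: ISI set {s.isi_set_s} differs from preset {preset.isi_set_s}"
            )

    return ValidationReport(v)
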