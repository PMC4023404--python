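"""Stimulation / inhibition protocols.

A protocol is a piecewise-constant input-strength schedule plus optional
instantaneous inhibitor events: a MEK catalytic inhibitor (U0126), which
zeroes the ERK-phosphorylation fluxes, and okadaic acid, which zeroes every
ERK- and substrate-dephosphorylation flux. Time is in minutes; t = 0 is the
moment of growth-factor stimulation and the system starts from its basal
(pre-stimulus) steady state.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import VARIANTS


@dataclass
class Protocol:
    """A timed stimulation schedule with optional inhibitor events.

    Parameters
    ----------
    segments : list of (t_start, S)
        Ordered piecewise-constant input-strength segments; the first must
        start at t = 0 and start times must be strictly increasing.
    u0126_time : float or None
        Time (min) at which the MEK inhibitor is added, if any.
    okadaic_time : float or None
        Time (min) at which the phosphatase inhibitor is added, if any.
    t_end : float
        End of the simulated window (min).
    variant : str
        Model variant tag: full, control, importin, combined, or constant_mek.
    """

    segments: list[tuple[float, float]] = field(default_factory=lambda: [(0.0, 1.0)])
    u0126_time: float | None = None
    okadaic_time: float | None = None
    t_end: float = 75.0
    variant: str = "full"

    def __post_init__(self) -> None:
        self.segments = [(float(t), float(s)) for t, s in self.segments]
        self.validate()

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.segments[0][0] != 0.0:
            raise ValueError("first segment must start at t = 0")
        starts = [t for t, _ in self.segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        for name in ("u0126_time", "okadaic_time"):
            t = getattr(self, name)
            if t is not None and not 0.0 <= t <= self.t_end:
                raise ValueError(f"{name}={t} outside [0, {self.t_end}]")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")

    def input_strength(self, t: float) -> float:
        """Input strength S at time t (basal strength applies for t < 0)."""
        s = self.segments[0][1]
        for t_start, val in self.segments:
            if t >= t_start:
                s = val
            else:
                break
        return s

    def event_times(self) -> list[float]:
        """All discontinuity times in (0, t_end), sorted and deduplicated."""
        times = {t for t, _ in self.segments if 0.0 < t < self.t_end}
        for t in (self.u0126_time, self.okadaic_time):
            if t is not None and 0.0 < t < self.t_end:
                times.add(t)
        return sorted(times)

    # ---- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segments"] = [list(seg) for seg in self.segments]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        d = dict(d)
        d["segments"] = [tuple(seg) for seg in d.get("segments", [[0.0, 1.0]])]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Protocol":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def step_stimulus(S: float = 1.0, t_end: float = 75.0, variant: str = "full") -> Protocol:
    """Step from basal to input strength S at t = 0."""
    return Protocol(segments=[(0.0, S)], t_end=t_end, variant=variant)


def mek_inhibition(
    t_inhibit: float, S: float = 1.0, t_end: float = 75.0, variant: str = "full"
) -> Protocol:
    """Step stimulus followed by MEK inhibitor at ``t_inhibit`` minutes."""
    return Protocol(
        segments=[(0.0, S)], u0126_time=t_inhibit, t_end=t_end, variant=variant
    )


def phosphatase_inhibition(
    t_inhibit: float, S: float = 1.0, t_end: float = 75.0, variant: str = "full"
) -> Protocol:
    """Step stimulus followed by okadaic acid at ``t_inhibit`` minutes."""
    return Protocol(
        segments=[(0.0, S)], okadaic_time=t_inhibit, t_end=t_end, variant=variant
    )


def dose_step_up(
    S_low: float = 0.5,
    S_high: float = 1.0,
    t_step: float = 30.0,
    t_end: float = 75.0,
    variant: str = "full",
) -> Protocol:
    """Sub-maximal stimulus followed by a step up to a maximal dose."""
    return Protocol(
        segments=[(0.0, S_low), (t_step, S_high)], t_end=t_end, variant=variant
    )
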