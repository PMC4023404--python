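"""Observation models mapping trajectories onto experimental readouts.

Seven readout families are supported, mirroring what is actually measured in
population biochemistry and live-cell imaging of the ERK pathway:

- ``ppMEK_blot``: diphospho-MEK immunoblot signal (arbitrary units, M2 only;
  the antibody is dual-phospho specific).
- ``ppERK_blot`` / ``ms_ppERK``: whole-cell diphospho-ERK by immunoblot or
  mass spectrometry. Crucially this lysate measurement sums the free *and*
  substrate-bound diphospho pools in both compartments.
- ``ms_pERK``: whole-cell mono-phospho ERK (free pools; the model keeps a
  single mono-phospho state).
- ``nucloc``: mean nuclear ERK concentration divided by whole-cell mean ERK
  concentration, re-normalized by its pre-stimulus value.
- ``ekar_cyt`` / ``ekar_nuc``: compartment-targeted FRET activity reporters,
  modeled as affine functions of the free diphospho-ERK concentration in the
  compartment (the reporter substrate equilibrates rapidly with free active
  ERK), normalized by the pre-stimulus value.
- ``sub_c_phos`` / ``sub_n_phos``: phosphorylated dominant-substrate level per
  compartment (e.g. nuclear Elk-1 phospho-staining), affine and normalized.

The ``t_half`` statistic quantifies post-inhibition decay: the elapsed time
after inhibitor addition at which a trace first falls halfway between its
value just prior to inhibition and the pre-stimulus baseline, located by
linear interpolation between bracketing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Trajectory

READOUTS = (
    "ppMEK_blot", "ppERK_blot", "ms_ppERK", "ms_pERK",
    "nucloc", "ekar_cyt", "ekar_nuc", "sub_c_phos", "sub_n_phos",
)

#: readouts reported in arbitrary units (per-dataset gain fitted analytically)
ARBITRARY_UNIT_READOUTS = ("ppMEK_blot", "ppERK_blot", "ms_ppERK", "ms_pERK")
#: readouts self-normalized to their own pre-stimulus value
NORMALIZED_READOUTS = ("nucloc", "ekar_cyt", "ekar_nuc", "sub_c_phos", "sub_n_phos")


@dataclass
class ObservationParams:
    """Offsets of the affine observation maps.

    rho_c, rho_n are the basal-signal offsets of the cytosolic/nuclear FRET
    reporters in total-ERK-equivalent concentration units; rho_e the analogous
    offset for the substrate-phosphorylation readouts. Larger rho compresses
    the normalized fold-change of the readout.
    """

    rho_c: float = 0.3
    rho_n: float = 0.3
    rho_e: float = 0.2
    scales: dict = field(default_factory=dict)  # arbitrary-unit gains per readout

    def validate(self) -> None:
        for name in ("rho_c", "rho_n", "rho_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {"rho_c": self.rho_c, "rho_n": self.rho_n, "rho_e": self.rho_e,
                "scales": dict(self.scales)}

    @classmethod
    def from_dict(cls, d: dict) -> "ObservationParams":
        obs = cls(**d)
        obs.validate()
        return obs


@dataclass
class ReadoutTrace:
    """One readout's timecourse."""

    readout: str
    times: np.ndarray
    values: np.ndarray

    def value_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))


class ObservationError(ValueError):
    """Raised when a normalization denominator is degenerate."""


def observe(traj: Trajectory, obs: ObservationParams | None = None,
            readouts: tuple[str, ...] = READOUTS) -> dict[str, ReadoutTrace]:
    """Map a trajectory to the requested readout traces.

    The trajectory must include the pre-stimulus point t = 0 (the equilibrated
    state), which anchors every self-normalized readout at exactly 1.
    """
    if obs is None:
        obs = ObservationParams()
    obs.validate()
    if traj.times[0] != 0.0:
        raise ObservationError("trajectory must start at the pre-stimulus point t = 0")

    p = traj.params
    phi_n, phi_c = p.phi_n, 1.0 - p.phi_n
    t = traj.times
    s = lambda r: obs.scales.get(r, 1.0)

    pp_total = (traj["E2c"] + traj["EBc"] + traj["E2n"] + traj["EBn"] + traj["EIn"])
    nuc_conc = (traj["E0n"] + traj["E1n"] + traj["E2n"] + traj["EBn"]
                + traj["EIn"]) / phi_n

    out: dict[str, ReadoutTrace] = {}

    def norm(values: np.ndarray) -> np.ndarray:
        ref = values[0]
        if ref <= 0:
            raise ObservationError(
                "pre-stimulus reference value is zero; the basal input strength "
                "and passive shuttling must give a finite baseline")
        return values / ref

    for r in readouts:
        if r == "ppMEK_blot":
            vals = s(r) * traj["M2"]
        elif r in ("ppERK_blot", "ms_ppERK"):
            vals = s(r) * pp_total
        elif r == "ms_pERK":
            vals = s(r) * (traj["E1c"] + traj["E1n"])
        elif r == "nucloc":
            vals = norm(nuc_conc)
        elif r == "ekar_cyt":
            vals = norm(obs.rho_c + traj["E2c"] / phi_c)
        elif r == "ekar_nuc":
            vals = norm(obs.rho_n + traj["E2n"] / phi_n)
        elif r == "sub_c_phos":
            vals = norm(obs.rho_e + traj["Pc"])
        elif r == "sub_n_phos":
            vals = norm(obs.rho_e + traj["Pn"])
        else:
            raise ValueError(f"unknown readout {r!r}")
        out[r] = ReadoutTrace(readout=r, times=t, values=np.asarray(vals, dtype=float))
    return out


@dataclass
class NoDecay:
    """Returned by :func:`t_half` when the trace never reaches the half level."""

    half_level: float

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return False


def t_half(trace: ReadoutTrace, t_inhibit: float, baseline: float):
    """Post-inhibition half-decay time by linear interpolation.

    The reference ("pre-inhibition") value is the last sample at or before
    ``t_inhibit``. The statistic is the elapsed time after ``t_inhibit`` at
    which the trace first crosses midway between that value and ``baseline``.
    Returns a :class:`NoDecay` sentinel if the trace never crosses the half
    level within the sampled window.
    """
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.values, dtype=float)
    pre_idx = np.nonzero(t <= t_inhibit + 1e-12)[0]
    if pre_idx.size == 0:
        raise ValueError("trace has no sample at or before the inhibition time")
    pre_val = y[pre_idx[-1]]
    if pre_val <= baseline:
        raise ValueError(
            f"pre-inhibition value {pre_val:.4g} must exceed baseline {baseline:.4g}")
    half = 0.5 * (pre_val + baseline)

    after = t > t_inhibit + 1e-12
    ta, ya = t[after], y[after]
    ta = np.concatenate([[t[pre_idx[-1]]], ta])
    ya = np.concatenate([[pre_val], ya])
    below = ya <= half
    if not below.any():
        return NoDecay(half_level=half)
    j = int(np.argmax(below))  # first sample at/below the half level
    if j == 0:
        return 0.0
    t0, t1_, y0, y1 = ta[j - 1], ta[j], ya[j - 1], ya[j]
    t_cross = t0 + (y0 - half) / (y0 - y1) * (t1_ - t0)
    return float(t_cross - t_inhibit)
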