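"""Ensemble analysis: buffering strengths, mode classification, predictions.

The buffering strength of a compartment's dominant substrate is the ratio of
its total concentration to the Michaelis constant of the ERK-substrate
interaction, B = (S_tot / phi) / K_m with K_m = (k_off + k_cat) / k_on. It
measures how strongly the substrate pool can sequester free diphospho ERK:
pools with B >> 1 soak up most of the active kinase until they are
phosphorylated through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import EnsembleResult
from .model import SimulationError, Trajectory, simulate
from .observables import ObservationParams, ReadoutTrace, observe, t_half
from .params import ModelParams
from .protocol import Protocol, dose_step_up, mek_inhibition

INHIBITION_TIMES = (5.0, 10.0, 20.0, 46.0)


def buffering_strengths(params: ModelParams) -> tuple[float, float]:
    """(B_c, B_n): substrate buffering strength per compartment.

    A compartment with substrate present but zero association rate has an
    undefined Michaelis constant; that is flagged invalid rather than treated
    as infinite buffering.
    """
    out = []
    for k_on, k_off, k_cat, s_tot, phi in (
        (params.k_on_c, params.k_off_c, params.k_cat_c, params.Sc_tot, params.phi_c),
        (params.k_on_n, params.k_off_n, params.k_cat_n, params.Sn_tot, params.phi_n),
    ):
        if s_tot == 0.0:
            out.append(0.0)
            continue
        if k_on == 0.0:
            raise ValueError(
                "substrate present with zero association rate: K_m undefined")
        K_m = (k_off + k_cat) / k_on
        out.append((s_tot / phi) / K_m)
    return out[0], out[1]


@dataclass
class BufferingSummary:
    """Per-member buffering strengths and mode labels."""

    table: pd.DataFrame  # columns: B_c, B_n, mode

    def counts(self) -> pd.Series:
        return self.table["mode"].value_counts()

    def median_B_n(self, mode: str | None = "nuclear") -> float:
        sub = self.table if mode is None else self.table[self.table["mode"] == mode]
        return float(sub["B_n"].median())


def classify_mode(B_c: float, B_n: float, boundary: float = 1.0) -> str:
    """Label one member's buffering mode.

    nuclear-dominant: B_c < boundary <= B_n; cytosolic-dominant: B_n < B_c and
    B_c >= boundary; unbuffered: both zero; otherwise mixed.
    """
    if B_c == 0.0 and B_n == 0.0:
        return "unbuffered"
    if B_c < boundary <= B_n:
        return "nuclear"
    if B_n < B_c and B_c >= boundary:
        return "cytosolic"
    return "mixed"


def classify_modes(ensemble: EnsembleResult, boundary: float = 1.0) -> BufferingSummary:
    """Buffering-strength scatter table with a mode label per ensemble member."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    rows = []
    for params, _ in ensemble.members():
        B_c, B_n = buffering_strengths(params)
        rows.append((B_c, B_n, classify_mode(B_c, B_n, boundary)))
    return BufferingSummary(pd.DataFrame(rows, columns=["B_c", "B_n", "mode"]))


SPECIES_POOLS = ("c", "cp", "cpp", "cs", "n", "np", "npp", "ns")


def species_breakdown(traj: Trajectory) -> pd.DataFrame:
    """Partition total ERK into the eight labeled pools over time.

    c/n: cytosolic/nuclear unphosphorylated; cp/np: mono-phosphorylated;
    cpp/npp: diphosphorylated; cs/ns: substrate-bound. Importin-bound nuclear
    ERK, where present, is counted with the bound nuclear pool (ns). The
    fractions sum to 1 at every time point.
    """
    df = pd.DataFrame({
        "time_min": traj.times,
        "c": traj["E0c"], "cp": traj["E1c"], "cpp": traj["E2c"], "cs": traj["EBc"],
        "n": traj["E0n"], "np": traj["E1n"], "npp": traj["E2n"],
        "ns": traj["EBn"] + traj["EIn"],
    })
    return df


@dataclass
class PredictionSummary:
    """Ensemble prediction traces and half-decay statistics.

    ``traces``: per (protocol label, readout) a DataFrame with columns
    time_min, mean, sd, lo, hi (pointwise member envelope).
    ``t_half_stats``: per (protocol label, readout) mean/sd/values of the
    post-inhibition half-decay time over the members that decayed.
    ``n_failed``: members whose simulation failed (dropped, never imputed).
    """

    traces: dict = field(default_factory=dict)
    t_half_stats: dict = field(default_factory=dict)
    n_failed: int = 0

    def trace(self, label: str, readout: str) -> pd.DataFrame:
        return self.traces[(label, readout)]

    def to_csv(self, path_prefix) -> None:
        from pathlib import Path

        prefix = Path(path_prefix)
        for (label, readout), df in self.traces.items():
            df.to_csv(prefix.parent / f"{prefix.name}_{label}_{readout}.csv",
                      index=False)


def default_prediction_protocols() -> dict[str, Protocol]:
    """The prediction battery: dose step-up and the inhibition-timing series."""
    protos = {"dose_stepup": dose_step_up(0.5, 1.0, 30.0, t_end=75.0)}
    for ti in INHIBITION_TIMES:
        protos[f"u0126_{ti:g}min"] = mek_inhibition(ti, t_end=ti + 25.0)
    return protos


def run_predictions(
    members: EnsembleResult | list[tuple[ModelParams, ObservationParams]],
    protocols: dict[str, Protocol] | None = None,
    readouts: tuple[str, ...] = ("nucloc", "ekar_cyt", "ekar_nuc"),
    dt: float = 1.0,
) -> PredictionSummary:
    """Simulate the prediction battery for every ensemble member.

    Readout traces are summarized as the ensemble mean and s.d.; for MEK
    inhibition protocols the post-inhibition half-decay time of each readout
    (baseline 1, the pre-stimulus level of a self-normalized trace) is
    computed per member and summarized. Members whose simulation fails are
    dropped and counted.
    """
    if protocols is None:
        protocols = default_prediction_protocols()
    if isinstance(members, EnsembleResult):
        members = list(members.members())

    summary = PredictionSummary()
    for label, proto in protocols.items():
        grid = np.arange(0.0, proto.t_end + 1e-9, dt)
        values: dict[str, list[np.ndarray]] = {r: [] for r in readouts}
        th: dict[str, list[float]] = {r: [] for r in readouts}
        n_failed = 0
        for params, obs in members:
            try:
                traj = simulate(params, proto, grid)
                traces = observe(traj, obs, readouts=readouts)
            except (SimulationError, ValueError) as exc:
                n_failed += 1
                continue
            for r in readouts:
                values[r].append(traces[r].values)
                if proto.u0126_time is not None:
                    res = t_half(traces[r], proto.u0126_time, baseline=1.0)
                    if isinstance(res, float):
                        th[r].append(res)
        summary.n_failed += n_failed
        for r in readouts:
            if not values[r]:
                continue
            arr = np.vstack(values[r])
            summary.traces[(label, r)] = pd.DataFrame({
                "time_min": grid,
                "mean": arr.mean(axis=0),
                "sd": arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else 0.0,
                "lo": arr.min(axis=0),
                "hi": arr.max(axis=0),
            })
            if proto.u0126_time is not None and th[r]:
                v = np.asarray(th[r])
                summary.t_half_stats[(label, r)] = {
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                    "n": int(v.size),
                    "values": v,
                }
    return summary
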