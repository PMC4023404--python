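"""Synthetic replicate datasets emulating the fitted and prediction experiments.

Each :class:`Design` describes one experiment: a protocol, the readouts
measured, their time grids and replicate counts, and a noise model. Population
readouts (immunoblot, mass spectrometry) get multiplicative lognormal
measurement noise. Single-cell imaging readouts get per-cell lognormal jitter
on amplitude-like parameters (MEK/ERK phosphorylation capacity and substrate
levels) plus measurement noise, and each replicate trace of a self-normalized
readout is re-normalized to its own t = 0 value afterwards — mimicking the
per-cell normalization applied to real imaging data.

Noise-free generation (all CVs zero) is exactly the model observation map, so
the generator is the identity on model observables in that limit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import simulate
from .observables import (
    NORMALIZED_READOUTS,
    ObservationParams,
    observe,
)
from .params import AMPLITUDE_PARAMS, ModelParams
from .protocol import Protocol, dose_step_up, mek_inhibition, step_stimulus

#: default coefficients of variation
BLOT_CV = 0.20       # population (immunoblot / MS) measurement noise
CELL_MEAS_CV = 0.05  # single-cell measurement noise
CELL_JITTER_CV = 0.15  # cell-to-cell parameter jitter (amplitude-like params)

BLOT_GRID = np.array([0.0, 2.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0])
IMAGING_GRID = np.arange(0.0, 75.0 + 1e-9, 2.0)
U0126_GRID = np.arange(0.0, 66.0 + 1e-9, 2.0)
PREDICTION_GRID = np.arange(0.0, 75.0 + 1e-9, 1.0)


@dataclass
class Design:
    """One experiment's measurement design."""

    experiment_id: str
    protocol: Protocol
    readouts: tuple[str, ...]
    time_grid: np.ndarray
    replicates: int
    measurement_cv: float
    jitter_cv: float = 0.0      # > 0 marks a single-cell design
    seed: int = 0               # per-design stream offset
    fitted: bool = True         # part of the global fit (vs prediction battery)

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.measurement_cv < 0 or self.jitter_cv < 0:
            raise ValueError("CVs must be >= 0")
        if self.time_grid[0] != 0.0:
            raise ValueError("every design needs the pre-stimulus t = 0 sample")

    @property
    def single_cell(self) -> bool:
        return self.jitter_cv > 0


def default_designs() -> list[Design]:
    """The seven fitted designs plus the prediction battery.

    Replicate counts follow the corresponding experiments: n = 3 for
    immunoblot and MS timecourses, n = 10 for the nuclear-localization
    imaging, n = 8 / 6 for tandem cytosolic / nuclear activity-reporter
    imaging, and n = 10 / 9 for the MEK-inhibition-at-steady-state series.
    """
    maximal_120 = step_stimulus(1.0, t_end=120.0)
    maximal_75 = step_stimulus(1.0, t_end=75.0)
    u0126_late = mek_inhibition(46.0, t_end=66.0)
    designs = [
        Design("blot", maximal_120, ("ppMEK_blot", "ppERK_blot"),
               BLOT_GRID, 3, BLOT_CV, seed=101),
        Design("ms", maximal_120, ("ms_ppERK", "ms_pERK"),
               BLOT_GRID, 3, BLOT_CV, seed=102),
        Design("nucloc_gfp", maximal_75, ("nucloc",),
               IMAGING_GRID, 10, CELL_MEAS_CV, jitter_cv=CELL_JITTER_CV, seed=103),
        Design("imaging_cyt", maximal_75, ("nucloc", "ekar_cyt"),
               IMAGING_GRID, 8, CELL_MEAS_CV, jitter_cv=CELL_JITTER_CV, seed=104),
        Design("imaging_nuc", maximal_75, ("nucloc", "ekar_nuc"),
               IMAGING_GRID, 6, CELL_MEAS_CV, jitter_cv=CELL_JITTER_CV, seed=105),
        Design("u0126_cyt", u0126_late, ("ekar_cyt",),
               U0126_GRID, 10, CELL_MEAS_CV, jitter_cv=CELL_JITTER_CV, seed=106),
        Design("u0126_nuc", u0126_late, ("ekar_nuc",),
               U0126_GRID, 9, CELL_MEAS_CV, jitter_cv=CELL_JITTER_CV, seed=107),
        # prediction battery (not part of the global fit)
        Design("dose_stepup", dose_step_up(0.5, 1.0, 30.0, t_end=75.0),
               ("nucloc", "ekar_cyt"), IMAGING_GRID, 8, CELL_MEAS_CV,
               jitter_cv=CELL_JITTER_CV, seed=108, fitted=False),
        Design("u0126_early", mek_inhibition(10.0, t_end=40.0),
               ("nucloc", "ekar_nuc"), np.arange(0.0, 40.0 + 1e-9, 1.0), 10,
               CELL_MEAS_CV, jitter_cv=CELL_JITTER_CV, seed=109, fitted=False),
        Design("u0126_late", mek_inhibition(46.0, t_end=66.0),
               ("nucloc", "ekar_nuc"), np.arange(0.0, 66.0 + 1e-9, 1.0), 9,
               CELL_MEAS_CV, jitter_cv=CELL_JITTER_CV, seed=110, fitted=False),
    ]
    return designs


def fitted_designs() -> list[Design]:
    return [d for d in default_designs() if d.fitted]


@dataclass
class Dataset:
    """Replicate observations in long form plus generation metadata.

    ``data`` columns: experiment_id, readout, time_min, replicate, value, sigma.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    COLUMNS = ("experiment_id", "readout", "time_min", "replicate", "value", "sigma")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        if (self.data["sigma"] <= 0).any():
            raise ValueError("all sigma values must be positive")

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False, float_format="%.10g")
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps(self.metadata, indent=2, sort_keys=True,
                                      default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        data = pd.read_csv(path)
        sidecar = path.with_suffix(".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(data=data, metadata=meta)

    def experiments(self) -> list[str]:
        return list(self.data["experiment_id"].unique())


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise whose coefficient of variation is ``cv``."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size))


def generate(theta: ModelParams, design: Design, seed: int,
             obs: ObservationParams | None = None) -> Dataset:
    """Generate one noisy replicate dataset from ground-truth parameters.

    Deterministic given ``seed`` (combined with the design's own stream
    offset, so different designs in one run draw independent streams).
    """
    if obs is None:
        obs = ObservationParams()
    rng = np.random.default_rng((int(seed), int(design.seed)))
    rows = []

    if not design.single_cell:
        traj = simulate(theta, design.protocol, design.time_grid)
        traces = observe(traj, obs, readouts=design.readouts)
        for r_id in design.readouts:
            truth = traces[r_id].values
            for rep in range(design.replicates):
                noise = _lognormal_factor(rng, design.measurement_cv, truth.shape)
                vals = truth * noise
                sigma = np.maximum(design.measurement_cv * np.abs(vals), 1e-3)
                rows.append(_block(design, r_id, rep, vals, sigma))
    else:
        total_cv = float(np.hypot(design.measurement_cv, design.jitter_cv))
        for rep in range(design.replicates):
            jitter = {name: getattr(theta, name)
                      * float(_lognormal_factor(rng, design.jitter_cv, ()))
                      for name in AMPLITUDE_PARAMS}
            theta_cell = theta.replace(**jitter)
            traj = simulate(theta_cell, design.protocol, design.time_grid)
            traces = observe(traj, obs, readouts=design.readouts)
            for r_id in design.readouts:
                vals = traces[r_id].values * _lognormal_factor(
                    rng, design.measurement_cv, design.time_grid.shape)
                if r_id in NORMALIZED_READOUTS:
                    vals = vals / vals[0]  # per-cell re-normalization
                sigma = np.maximum(total_cv * np.abs(vals), 1e-3)
                rows.append(_block(design, r_id, rep, vals, sigma))

    data = pd.concat(rows, ignore_index=True)
    meta = {
        "design": {**dataclasses.asdict(design),
                   "time_grid": design.time_grid.tolist(),
                   "protocol": design.protocol.to_dict()},
        "seed": int(seed),
        "theta_hash": _theta_hash(theta),
    }
    return Dataset(data=data, metadata=meta)


def generate_all(theta: ModelParams, designs: list[Design], seed: int,
                 obs: ObservationParams | None = None) -> dict[str, Dataset]:
    """Generate a dataset per design; keys are experiment ids."""
    return {d.experiment_id: generate(theta, d, seed, obs) for d in designs}


def _block(design: Design, readout: str, rep: int, vals, sigma) -> pd.DataFrame:
    return pd.DataFrame({
        "experiment_id": design.experiment_id,
        "readout": readout,
        "time_min": design.time_grid,
        "replicate": rep,
        "value": vals,
        "sigma": sigma,
    })


def design_from_dict(d: dict) -> Design:
    """Rebuild a :class:`Design` from dataset metadata (inverse of generate)."""
    d = dict(d)
    d["protocol"] = Protocol.from_dict(d["protocol"])
    d["time_grid"] = np.asarray(d["time_grid"], dtype=float)
    d["readouts"] = tuple(d["readouts"])
    return Design(**d)


def _theta_hash(theta: ModelParams) -> str:
    import hashlib

    blob = json.dumps(theta.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
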