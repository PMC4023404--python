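"""Multi-experiment weighted least-squares cost and ensemble fitting.

The fitting strategy follows the Monte-Carlo / simulated-annealing ensemble
approach: rather than a single best fit, an annealing search locates a
near-optimal parameter set, and a threshold-acceptance random walk around it
collects a large ensemble of parameter sets that all fit the data almost
equally well (cost within a fractional margin ``epsilon`` of the minimum).
Predictions are then reported as ensemble means and standard deviations.

Parameters are sampled in log10 space (the nuclear volume fraction in logit
space). Arbitrary-unit readouts (immunoblot, MS) are aligned to the model with
a per-readout gain whose weighted-least-squares optimum is closed-form;
self-normalized readouts use gain 1.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import SimulationError, initial_state, simulate
from .observables import ARBITRARY_UNIT_READOUTS, ObservationParams, observe
from .params import ModelParams
from .protocol import Protocol
from .synthetic import Dataset, Design, design_from_dict

logger = logging.getLogger(__name__)

#: kinetic parameters free by default (log10 space); shuttling geometry and the
#: basal input are held fixed by default
DEFAULT_FREE = (
    "a_M", "d_M", "k_fb", "k_rec", "a_E1", "a_E2",
    "d_c1", "d_c2", "d_n1", "d_n2", "k_in", "k_out",
    "k_on_c", "k_off_c", "k_cat_c", "k_sdp_c", "Sc_tot",
    "k_on_n", "k_off_n", "k_cat_n", "k_sdp_n", "Sn_tot",
    "rho_c", "rho_n",
)

_OBS_FIELDS = ("rho_c", "rho_n", "rho_e")
_LOGIT_FIELDS = ("phi_n",)


class ParamSpace:
    """Bijection between named free parameters and an unconstrained vector.

    Positive parameters map through log10; ``phi_n`` maps through logit.
    Fixed parameters keep the values of the base parameter set.
    """

    def __init__(self, base_params: ModelParams, base_obs: ObservationParams,
                 free: Sequence[str] = DEFAULT_FREE):
        self.base_params = base_params
        self.base_obs = base_obs
        self.free = tuple(free)
        for name in self.free:
            if name not in ModelParams.__dataclass_fields__ and name not in _OBS_FIELDS:
                raise ValueError(f"unknown free parameter {name!r}")

    @property
    def ndim(self) -> int:
        return len(self.free)

    def _get(self, params: ModelParams, obs: ObservationParams, name: str) -> float:
        return getattr(obs if name in _OBS_FIELDS else params, name)

    def to_vector(self, params: ModelParams | None = None,
                  obs: ObservationParams | None = None) -> np.ndarray:
        params = params or self.base_params
        obs = obs or self.base_obs
        x = np.empty(self.ndim)
        for i, name in enumerate(self.free):
            v = self._get(params, obs, name)
            if name in _LOGIT_FIELDS:
                x[i] = np.log10(v / (1.0 - v))
            else:
                if v <= 0:
                    raise ValueError(f"cannot log-transform non-positive {name}={v}")
                x[i] = np.log10(v)
        return x

    def from_vector(self, x: np.ndarray) -> tuple[ModelParams, ObservationParams]:
        pkw, okw = {}, {}
        for name, v in zip(self.free, x):
            if name in _LOGIT_FIELDS:
                val = 1.0 / (1.0 + 10.0 ** (-v))
                # a saturated logit would give exactly 0 or 1 — a degenerate
                # compartment split — so stay strictly inside the interval
                val = min(max(val, 1e-12), 1.0 - 1e-12)
            else:
                val = 10.0 ** v
            (okw if name in _OBS_FIELDS else pkw)[name] = float(val)
        params = self.base_params.replace(**pkw)
        obs = dataclasses.replace(self.base_obs, **okw)
        return params, obs


@dataclass
class CostSpec:
    """Configuration of the multi-dataset cost and the ensemble algorithm."""

    space: ParamSpace
    weights: dict[str, float] = field(default_factory=dict)  # per experiment id
    epsilon: float = 0.25          # acceptance threshold J <= J_min * (1 + epsilon)
    step_width: float = 0.03       # proposal s.d. in log10 units (20-50% acceptance)
    # fitting-grade integration tolerance; data sigmas are >= 1e-3, so 1e-7
    # relative integration error is far below the noise floor
    rtol: float = 1e-7
    atol: float = 1e-9

    def weight(self, experiment_id: str) -> float:
        w = self.weights.get(experiment_id, 1.0)
        if w <= 0:
            raise ValueError(f"weight for {experiment_id} must be > 0")
        return w


def optimal_scale(y: np.ndarray, m: np.ndarray, sigma: np.ndarray) -> float:
    """Closed-form weighted-least-squares gain minimizing sum((s*m - y)^2/sigma^2)."""
    w = 1.0 / sigma ** 2
    denom = np.sum(w * m * m)
    if denom == 0:
        return 1.0
    return float(np.sum(w * y * m) / denom)


def _protocol_key(proto: Protocol) -> str:
    d = proto.to_dict()
    d.pop("t_end")
    return json.dumps(d, sort_keys=True)


def cost(params: ModelParams, obs: ObservationParams,
         datasets: Sequence[Dataset], spec: CostSpec) -> float:
    """Weighted least-squares cost of the model against all datasets.

    J = sum_d w_d sum_i (s_d * m_i - y_i)^2 / sigma_i^2, with the analytic
    optimal gain s_d for arbitrary-unit readouts and s_d = 1 for
    self-normalized readouts. Returns +inf (and logs) if the model cannot be
    simulated at ``params``.
    """
    designs = [design_from_dict(ds.metadata["design"]) for ds in datasets]

    # group datasets sharing a protocol (modulo t_end) into single simulations
    groups: dict[str, dict] = {}
    for ds, dg in zip(datasets, designs):
        key = _protocol_key(dg.protocol)
        g = groups.setdefault(key, {"proto": dg.protocol, "times": set(),
                                    "members": []})
        if dg.protocol.t_end > g["proto"].t_end:
            g["proto"] = dg.protocol
        g["times"].update(dg.time_grid.tolist())
        g["members"].append((ds, dg))

    J = 0.0
    y0_cache: dict[str, np.ndarray] = {}  # steady state shared across groups
    for g in groups.values():
        grid = np.array(sorted(g["times"]))
        proto = g["proto"]
        try:
            if proto.variant not in y0_cache:
                y0_cache[proto.variant] = initial_state(params, proto.variant)
            traj = simulate(params, proto, grid, y0=y0_cache[proto.variant],
                            rtol=spec.rtol, atol=spec.atol)
            readouts = tuple(sorted({r for _, dg in g["members"]
                                     for r in dg.readouts}))
            traces = observe(traj, obs, readouts=readouts)
        except (SimulationError, ValueError, FloatingPointError) as exc:
            logger.info("simulation failed during cost evaluation: %s", exc)
            return np.inf

        pos = {t: i for i, t in enumerate(grid)}
        for ds, dg in g["members"]:
            w = spec.weight(dg.experiment_id)
            for r_id in dg.readouts:
                sub = ds.data[ds.data["readout"] == r_id]
                idx = sub["time_min"].map(pos).to_numpy()
                m = traces[r_id].values[idx]
                y = sub["value"].to_numpy()
                sig = sub["sigma"].to_numpy()
                s = (optimal_scale(y, m, sig)
                     if r_id in ARBITRARY_UNIT_READOUTS else 1.0)
                J += w * float(np.sum(((s * m - y) / sig) ** 2))
    return J


def make_cost_fn(datasets: Sequence[Dataset],
                 spec: CostSpec) -> Callable[[np.ndarray], float]:
    """Vectorized-coordinates view of :func:`cost` over the free-parameter space."""

    def fn(x: np.ndarray) -> float:
        try:
            params, obs = spec.space.from_vector(x)
            params.validate()
            obs.validate()
        except ValueError:
            return np.inf
        return cost(params, obs, datasets, spec)

    return fn


# ---------------------------------------------------------------------------
# annealing and the threshold-acceptance ensemble walk
# ---------------------------------------------------------------------------

def metropolis_anneal(cost_fn: Callable[[np.ndarray], float], x0: np.ndarray,
                      step: float, seed: int, n_iter: int = 1000,
                      t0: float = 1.0, cooling: float = 0.95,
                      cool_every: int = 10) -> tuple[np.ndarray, float]:
    """Simulated annealing in the transformed parameter space.

    Proposals are isotropic normal steps; acceptance follows the Metropolis
    rule under a geometric temperature schedule (T multiplied by ``cooling``
    every ``cool_every`` iterations). Deterministic given ``seed``. Returns
    the best visited point and its cost.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    J = cost_fn(x)
    x_best, J_best = x.copy(), J
    if not np.isfinite(J):
        raise RuntimeError("annealing start point is not simulable")
    T = t0
    n_failed = 0
    for k in range(n_iter):
        x_new = x + step * rng.standard_normal(x.size)
        J_new = cost_fn(x_new)
        if not np.isfinite(J_new):
            n_failed += 1
            if n_failed == n_iter:
                raise RuntimeError("every annealing proposal failed to simulate")
            continue
        if J_new <= J or rng.random() < np.exp(-(J_new - J) / max(T, 1e-12)):
            x, J = x_new, J_new
            if J < J_best:
                x_best, J_best = x.copy(), J
        if (k + 1) % cool_every == 0:
            T *= cooling
    return x_best, J_best


def threshold_walk(cost_fn: Callable[[np.ndarray], float], x0: np.ndarray,
                   step: float, seed: int, n_accept: int, threshold: float,
                   calibration: int = 200, min_rate: float = 0.01,
                   max_proposals: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold-acceptance random walk collecting ``n_accept`` parameter sets.

    A proposal is accepted iff its cost does not exceed ``threshold`` (a hard
    rule, not Metropolis); each accepted move is recorded and becomes the
    nexus for the next proposal. Aborts if the acceptance rate is below
    ``min_rate`` after the calibration phase, advising smaller steps.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    J = cost_fn(x)
    if not J <= threshold:
        raise ValueError(f"walk start has cost {J:.4g} above threshold {threshold:.4g}")
    accepted = np.empty((n_accept, x.size))
    costs = np.empty(n_accept)
    n_acc = 0
    n_prop = 0
    cap = max_proposals or 200 * n_accept
    while n_acc < n_accept:
        if n_prop >= cap:
            raise RuntimeError("proposal budget exhausted before collecting ensemble")
        x_new = x + step * rng.standard_normal(x.size)
        J_new = cost_fn(x_new)
        n_prop += 1
        if np.isfinite(J_new) and J_new <= threshold:
            x, J = x_new, J_new
            accepted[n_acc] = x
            costs[n_acc] = J
            n_acc += 1
        if n_prop == calibration and n_acc / n_prop < min_rate:
            raise RuntimeError(
                f"acceptance rate {n_acc / n_prop:.3f} below {min_rate} after "
                f"{calibration} proposals; reduce the step width")
    return accepted, costs, n_acc / n_prop


@dataclass
class EnsembleResult:
    """Accepted parameter sets (transformed coordinates) with run metadata."""

    table: pd.DataFrame            # free-parameter columns + "cost"
    space: ParamSpace
    seed: int
    J_min: float
    threshold: float
    step_width: float
    acceptance_rate: float

    def __len__(self) -> int:
        return len(self.table)

    def member(self, i: int) -> tuple[ModelParams, ObservationParams]:
        x = self.table.iloc[i][list(self.space.free)].to_numpy(dtype=float)
        return self.space.from_vector(x)

    def members(self):
        for i in range(len(self)):
            yield self.member(i)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.table.to_csv(path, index=False)
        meta = {
            "seed": self.seed, "J_min": self.J_min, "threshold": self.threshold,
            "step_width": self.step_width, "acceptance_rate": self.acceptance_rate,
            "free": list(self.space.free),
            "base_params": self.space.base_params.to_dict(),
            "base_obs": self.space.base_obs.to_dict(),
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "EnsembleResult":
        path = Path(path)
        table = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        base_obs = ObservationParams.from_dict(meta["base_obs"])
        space = ParamSpace(ModelParams.from_dict(meta["base_params"]), base_obs,
                           free=meta["free"])
        return cls(table=table, space=space, seed=meta["seed"],
                   J_min=meta["J_min"], threshold=meta["threshold"],
                   step_width=meta["step_width"],
                   acceptance_rate=meta["acceptance_rate"])


def anneal(datasets: Sequence[Dataset], spec: CostSpec, seed: int,
           init: tuple[ModelParams, ObservationParams] | None = None,
           n_iter: int = 1000, t0: float | None = None,
           cooling: float = 0.95) -> tuple[ModelParams, ObservationParams, float]:
    """Anneal the model against the datasets; returns (params, obs, J_min)."""
    fn = make_cost_fn(datasets, spec)
    if init is None:
        x0 = spec.space.to_vector()
    else:
        x0 = spec.space.to_vector(*init)
    if t0 is None:
        J0 = fn(x0)
        t0 = max(0.05 * J0, 1e-6)
    logger.info("anneal: start, %d iterations", n_iter)
    x_best, J_best = metropolis_anneal(fn, x0, spec.step_width, seed,
                                       n_iter=n_iter, t0=t0, cooling=cooling)
    logger.info("anneal: done, J_min = %.5g", J_best)
    params, obs = spec.space.from_vector(x_best)
    return params, obs, J_best


def ensemble_walk(datasets: Sequence[Dataset], spec: CostSpec, seed: int,
                  start: tuple[ModelParams, ObservationParams], n: int,
                  J_min: float | None = None) -> EnsembleResult:
    """Collect an ensemble of ``n`` accepted parameter sets around ``start``."""
    fn = make_cost_fn(datasets, spec)
    x0 = spec.space.to_vector(*start)
    if J_min is None:
        J_min = fn(x0)
    threshold = J_min * (1.0 + spec.epsilon)
    logger.info("ensemble: J_min = %.5g, threshold = %.5g, target n = %d",
                J_min, threshold, n)
    accepted, costs, rate = threshold_walk(fn, x0, spec.step_width, seed,
                                           n_accept=n, threshold=threshold)
    logger.info("ensemble: done, acceptance rate %.2f", rate)
    table = pd.DataFrame(accepted, columns=list(spec.space.free))
    table["cost"] = costs
    return EnsembleResult(table=table, space=spec.space, seed=seed,
                          J_min=float(J_min), threshold=float(threshold),
                          step_width=spec.step_width, acceptance_rate=rate)
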