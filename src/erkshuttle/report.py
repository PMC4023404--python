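"""End-to-end kinetic-feature report for the packaged reference parameter set.

Computes the headline kinetic features of the model — nuclear-accumulation
peak time, post-inhibition half-decay times, the slow nuclear-activity rise,
the early/late inhibition contrast — both deterministically at the packaged
reference parameter set and as ensemble statistics after refitting to the
packaged synthetic dataset. The report maps each feature to a stable id and
a pass band so a single run documents whether the pipeline reproduces the
expected kinetics.
"""

from __future__ import annotations

import logging

import numpy as np

from .analysis import classify_modes, run_predictions
from .fitting import CostSpec, ParamSpace, anneal, ensemble_walk
from .model import simulate
from .observables import NoDecay, ObservationParams, observe, t_half
from .params import ModelParams
from .protocol import mek_inhibition, step_stimulus
from .reference import load_theta_ref
from .synthetic import fitted_designs, generate_all

logger = logging.getLogger(__name__)

# The packaged synthetic dataset is a frozen study condition: it is always
# generated at this master seed so every fit targets the same data. The
# caller's seed drives only the annealing / ensemble-walk randomness.
REFERENCE_DATA_SEED = 2014

# (comparison, bound(s)) per feature id; "eq" bounds are (lo, hi).
PASS_BANDS = {
    "t1": ("le", 10.0),
    "t2": ("le", 2.0),
    "t5": ("eq", (10.0, 30.0)),
    "t6": ("ge", 3.0),
    "t7": ("eq", (0.7, 2.7)),
    "t8": ("eq", (3.5, 9.5)),
    "t9": ("eq", (10.0, 40.0)),
}


def deterministic_features(
    theta: ModelParams | None = None,
    obs: ObservationParams | None = None,
) -> dict[str, float]:
    """Single-simulation kinetic features at a parameter set (default: reference).

    Returns nucloc_peak_time, ekar_thalf_late (the larger of the nuclear and
    cytosolic free-active-ERK half-decay times after inhibition at 46 min),
    ekar_nuc_t90 (first time ekar_nuc reaches 90% of its 60-min value), and
    nucloc_thalf_ratio (inhibition at 10 min vs 46 min).
    """
    if theta is None or obs is None:
        theta, obs = load_theta_ref()

    grid = np.arange(0.0, 75.0 + 1e-9, 0.5)
    traj = simulate(theta, step_stimulus(1.0, t_end=75.0), grid)
    traces = observe(traj, obs, readouts=("nucloc", "ekar_nuc"))
    nucloc = traces["nucloc"]
    ekar_nuc = traces["ekar_nuc"]

    peak_time = float(nucloc.times[int(np.argmax(nucloc.values))])

    target = 1.0 + 0.9 * (ekar_nuc.value_at(60.0) - 1.0)
    above = np.nonzero(ekar_nuc.values >= target)[0]
    t90 = float(ekar_nuc.times[above[0]]) if above.size else float("nan")

    halves: dict[float, dict[str, float]] = {}
    for t_inh in (10.0, 46.0):
        proto = mek_inhibition(t_inh, t_end=t_inh + 25.0)
        g = np.arange(0.0, proto.t_end + 1e-9, 1.0)
        tr = observe(simulate(theta, proto, g), obs,
                     readouts=("nucloc", "ekar_cyt", "ekar_nuc"))
        halves[t_inh] = {
            r: t_half(tr[r], t_inh, baseline=1.0) for r in tr
        }

    late = halves[46.0]
    ekar_late = [late[r] for r in ("ekar_cyt", "ekar_nuc")
                 if not isinstance(late[r], NoDecay)]
    return {
        "nucloc_peak_time": peak_time,
        "ekar_thalf_late": float(max(ekar_late)) if ekar_late else float("nan"),
        "ekar_nuc_t90": t90,
        "nucloc_thalf_ratio": float(halves[10.0]["nucloc"] / late["nucloc"]),
    }


def ensemble_features(
    seed: int,
    n_ensemble: int = 200,
    anneal_iters: int = 300,
) -> dict[str, float | int]:
    """Refit to the packaged synthetic dataset and summarize the ensemble.

    Generates the synthetic dataset at the frozen data seed, anneals from the
    reference set, runs the threshold-acceptance walk to ``n_ensemble``
    accepted members, then reports the ensemble-mean nucloc half-decay times
    after inhibition at 46 and 10 min and the median nuclear buffering
    strength among nuclear-dominant members.
    """
    theta, obs = load_theta_ref()
    datasets = list(generate_all(theta, fitted_designs(),
                                 REFERENCE_DATA_SEED, obs).values())
    spec = CostSpec(space=ParamSpace(theta, obs))
    logger.info("annealing (%d iterations)", anneal_iters)
    p_star, o_star, j_min = anneal(datasets, spec, seed=seed % 2**31,
                                   init=(theta, obs), n_iter=anneal_iters)
    logger.info("ensemble walk to %d accepted members (J_min=%.1f)",
                n_ensemble, j_min)
    ens = ensemble_walk(datasets, spec, seed=(seed + 1) % 2**31,
                        start=(p_star, o_star), n=n_ensemble, J_min=j_min)

    preds = run_predictions(
        ens,
        protocols={"late": mek_inhibition(46.0, t_end=71.0),
                   "early": mek_inhibition(10.0, t_end=35.0)},
        readouts=("nucloc",),
    )
    late = preds.t_half_stats[("late", "nucloc")]
    early = preds.t_half_stats[("early", "nucloc")]

    summary = classify_modes(ens)
    nuclear = summary.table[summary.table["mode"] == "nuclear"]

    return {
        "nucloc_thalf_late_mean": late["mean"],
        "nucloc_thalf_late_n": late["n"],
        "nucloc_thalf_early_mean": early["mean"],
        "nucloc_thalf_early_n": early["n"],
        "median_B_n_nuclear": float(nuclear["B_n"].median()),
        "n_nuclear": int(len(nuclear)),
        "frac_B_n_buffered": float((summary.table["B_n"] >= 1.0).mean()),
        "n_members": len(ens),
        "j_min": j_min,
    }


def _passes(cmp: str, bound, value: float) -> bool:
    if not np.isfinite(value):
        return False
    if cmp == "le":
        return value <= bound
    if cmp == "ge":
        return value >= bound
    lo, hi = bound
    return lo <= value <= hi


def acceptance_report(
    seed: int,
    n_ensemble: int = 200,
    anneal_iters: int = 300,
    with_pass: bool = False,
) -> dict[str, dict]:
    """Full target report: ``{id: {"value": v, "n": sample size}}``.

    Deterministic features use sample size 1. With ``with_pass`` each entry
    additionally records its pass band and a boolean verdict.
    """
    det = deterministic_features()
    ens = ensemble_features(seed, n_ensemble=n_ensemble,
                            anneal_iters=anneal_iters)
    values = {
        "t1": (det["nucloc_peak_time"], 1),
        "t2": (det["ekar_thalf_late"], 1),
        "t5": (det["ekar_nuc_t90"], 1),
        "t6": (det["nucloc_thalf_ratio"], 1),
        "t7": (ens["nucloc_thalf_late_mean"], ens["nucloc_thalf_late_n"]),
        "t8": (ens["nucloc_thalf_early_mean"], ens["nucloc_thalf_early_n"]),
        "t9": (ens["median_B_n_nuclear"], ens["n_nuclear"]),
    }
    report: dict[str, dict] = {}
    for tid, (value, n) in values.items():
        entry: dict = {"value": float(value), "n": int(n)}
        if with_pass:
            cmp, bound = PASS_BANDS[tid]
            entry["cmp"] = cmp
            entry["bound"] = bound
            entry["pass"] = _passes(cmp, bound, value)
        report[tid] = entry
    return report
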