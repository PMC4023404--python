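"""Compartmental ODE model of ERK phosphorylation, shuttling, and substrate binding.

The model tracks MEK activation by two-site phosphorylation in the cytosol,
negative feedback through a desensitization state driven by free active
cytosolic ERK, two-site distributive ERK phosphorylation, facilitated nuclear
import of free diphospho ERK (plus weak passive shuttling of all free ERK
states), phospho-state-independent nuclear export, and reversible binding of
diphospho ERK to a dominant substrate in each compartment. Bound ERK is
anchored in its compartment and protected from phosphatases; catalysis
releases active ERK and produces phosphorylated substrate.

State components (amounts as fractions of total MEK or total ERK):

======  =====================================================
name    meaning
======  =====================================================
M0-M2   un-, mono-, di-phospho MEK (sum = 1)
D       feedback desensitization state (0..1)
E0c-E2c free cytosolic ERK by phospho-state
EBc     cytosolic substrate-bound diphospho ERK
E0n-E2n free nuclear ERK by phospho-state
EBn     nuclear substrate-bound diphospho ERK
EIn     importin-bound nuclear diphospho ERK (importin variants)
Pc, Pn  phosphorylated substrate per compartment
======  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParams
from .protocol import Protocol

STATE_NAMES = (
    "M0", "M1", "M2", "D",
    "E0c", "E1c", "E2c", "EBc",
    "E0n", "E1n", "E2n", "EBn", "EIn",
    "Pc", "Pn",
)
N_STATES = len(STATE_NAMES)
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}

#: indices of the ERK-containing pools (sum is conserved at 1)
ERK_POOLS = tuple(_IDX[n] for n in ("E0c", "E1c", "E2c", "EBc",
                                    "E0n", "E1n", "E2n", "EBn", "EIn"))
#: indices of phosphorylated-ERK pools (mono + di, free + bound)
PHOSPHO_ERK_POOLS = tuple(_IDX[n] for n in ("E1c", "E2c", "EBc",
                                            "E1n", "E2n", "EBn", "EIn"))


class SimulationError(RuntimeError):
    """Raised when the steady-state solve or the integration fails."""


def _rhs_const(y, p: ModelParams, u: float, inh: float, pho: float,
               use_importin: bool, m2_clamp: float | None):
    """Right-hand side with the piecewise-constant controls resolved.

    ``u`` is the current input strength, ``inh`` gates the ERK-phosphorylation
    fluxes (0 after MEK inhibition), ``pho`` gates every dephosphorylation
    flux (0 after okadaic acid).
    """
    (M0, M1, M2, D, E0c, E1c, E2c, EBc,
     E0n, E1n, E2n, EBn, EIn, Pc, Pn) = y

    phi_c = 1.0 - p.phi_n
    phi_n = p.phi_n

    if m2_clamp is not None:
        M2 = m2_clamp

    v = p.a_M * u * (1.0 - D)
    p1 = inh * p.a_E1 * M2
    p2 = inh * p.a_E2 * M2

    free_Sc = p.Sc_tot - Pc - EBc
    free_Sn = p.Sn_tot - Pn - EBn
    b_c = p.k_on_c * E2c * free_Sc / phi_c
    b_n = p.k_on_n * E2n * free_Sn / phi_n

    dy = np.empty(N_STATES)

    if m2_clamp is not None:
        dy[0] = dy[1] = dy[2] = 0.0
        dy[3] = 0.0
    else:
        dy[0] = -v * M0 + p.d_M * M1
        dy[1] = v * M0 - v * M1 - p.d_M * M1 + p.d_M * M2
        dy[2] = v * M1 - p.d_M * M2
        dy[3] = p.k_fb * E2c * (1.0 - D) - p.k_rec * D

    imp_flux = (p.k_in + p.k_pass) * E2c
    if use_importin:
        j_nuc_in = p.k_rel * EIn
        dy[12] = imp_flux - p.k_rel * EIn
    else:
        j_nuc_in = imp_flux
        dy[12] = 0.0

    dy[4] = -p1 * E0c + pho * p.d_c1 * E1c - p.k_pass * E0c + p.k_out * E0n
    dy[5] = (p1 * E0c - p2 * E1c - pho * p.d_c1 * E1c + pho * p.d_c2 * E2c
             - p.k_pass * E1c + p.k_out * E1n)
    dy[6] = (p2 * E1c - pho * p.d_c2 * E2c - imp_flux + p.k_out * E2n
             - b_c + (p.k_off_c + p.k_cat_c) * EBc)
    dy[7] = b_c - (p.k_off_c + p.k_cat_c) * EBc
    dy[8] = p.k_pass * E0c + pho * p.d_n1 * E1n - p.k_out * E0n
    dy[9] = (p.k_pass * E1c - pho * p.d_n1 * E1n + pho * p.d_n2 * E2n
             - p.k_out * E1n)
    dy[10] = (j_nuc_in - pho * p.d_n2 * E2n - p.k_out * E2n
              - b_n + (p.k_off_n + p.k_cat_n) * EBn)
    dy[11] = b_n - (p.k_off_n + p.k_cat_n) * EBn
    dy[13] = p.k_cat_c * EBc - pho * p.k_sdp_c * Pc
    dy[14] = p.k_cat_n * EBn - pho * p.k_sdp_n * Pn
    return dy


def _effective_params(params: ModelParams, variant: str) -> ModelParams:
    """Apply the variant's structural restrictions to a parameter set."""
    if variant in ("control", "importin"):
        # no substrate interactions in either compartment
        return params.replace(Sc_tot=0.0, Sn_tot=0.0, k_on_c=0.0, k_on_n=0.0)
    return params


def _basal_m2(params: ModelParams) -> float:
    """Basal steady active-MEK fraction with feedback off (constant-MEK variant)."""
    r = params.a_M * params.S_basal / params.d_M if params.d_M > 0 else np.inf
    if np.isinf(r):
        return 1.0
    return r * r / (1.0 + r + r * r)


def rhs(t: float, state: np.ndarray, params: ModelParams,
        protocol: Protocol) -> np.ndarray:
    """Time derivative of the state under the protocol's controls at time ``t``."""
    p = _effective_params(params, protocol.variant)
    u = protocol.input_strength(t)
    inh = 0.0 if (protocol.u0126_time is not None and t >= protocol.u0126_time) else 1.0
    pho = 0.0 if (protocol.okadaic_time is not None and t >= protocol.okadaic_time) else 1.0
    use_imp = protocol.variant in ("importin", "combined")
    m2_clamp = None
    if protocol.variant == "constant_mek":
        m2_clamp = params.M2_const if t >= 0 else _basal_m2(params)
    return _rhs_const(np.asarray(state, dtype=float), p, u, inh, pho,
                      use_imp, m2_clamp)


# ---------------------------------------------------------------------------
# pre-stimulus equilibration
# ---------------------------------------------------------------------------

def _basal_guess(params: ModelParams) -> np.ndarray:
    """Analytic basal state ignoring phosphorylation: passive-shuttling balance."""
    y = np.zeros(N_STATES)
    y[_IDX["M0"]] = 1.0
    ktot = params.k_pass + params.k_out
    if params.k_pass == 0.0 or ktot == 0.0:
        y[_IDX["E0c"]] = 1.0
    else:
        y[_IDX["E0c"]] = params.k_out / ktot
        y[_IDX["E0n"]] = params.k_pass / ktot
    return y


_MEK_POOLS = tuple(_IDX[n] for n in ("M0", "M1", "M2"))


def _project_totals(y: np.ndarray, renorm_mek: bool = True) -> np.ndarray:
    """Rescale the MEK and ERK pools so the conserved totals are exactly 1.

    The dynamics conserve both totals, so any integration drift in them is
    permanent; rhs = 0 alone cannot restore the totals because the steady-state
    set is a family parameterized by them. MEK renormalization is skipped when
    M2 is clamped (constant-MEK variant).
    """
    y = np.array(y, dtype=float)
    if renorm_mek:
        m = y[list(_MEK_POOLS)].sum()
        if m > 0:
            y[list(_MEK_POOLS)] /= m
    e = y[list(ERK_POOLS)].sum()
    if e > 0:
        y[list(ERK_POOLS)] /= e
    return y


def _newton_polish(f, y: np.ndarray, n_iter: int = 25,
                   target: float = 1e-14) -> np.ndarray:
    """Damped Newton refinement of a near-steady state, pure numpy.

    Uses a forward-difference Jacobian and least-squares steps (the Jacobian
    has exactly-zero rows for clamped components in some model variants).
    Returns the best iterate by residual max-norm; never worse than ``y``.
    """
    y = np.array(y, dtype=float)
    fy = f(y)
    best, best_norm = y.copy(), float(np.max(np.abs(fy)))
    n = y.size
    for _ in range(n_iter):
        if best_norm <= target:
            break
        J = np.empty((n, n))
        for j in range(n):
            h = 1e-8 * max(1.0, abs(y[j]))
            yp = y.copy()
            yp[j] += h
            J[:, j] = (f(yp) - fy) / h
        step, *_ = np.linalg.lstsq(J, -fy, rcond=None)
        lam, improved = 1.0, False
        for _ in range(10):
            y_new = y + lam * step
            f_new = f(y_new)
            if np.max(np.abs(f_new)) < np.max(np.abs(fy)):
                y, fy, improved = y_new, f_new, True
                break
            lam *= 0.5
        if not improved:
            break
        norm = float(np.max(np.abs(fy)))
        if norm < best_norm:
            best, best_norm = y.copy(), norm
    return best


def initial_state(params: ModelParams, variant: str = "full",
                  residual_tol: float = 1e-10) -> np.ndarray:
    """Pre-stimulus steady state of the model at input strength ``S_basal``.

    Integrates from the passive-shuttling balance state for a long horizon and
    polishes the result with a damped Newton root solve. Raises
    :class:`SimulationError` if the right-hand-side residual at the returned
    state exceeds ``residual_tol`` in max-norm.
    """
    params.validate()
    p = _effective_params(params, variant)
    use_imp = variant in ("importin", "combined")
    m2_clamp = _basal_m2(params) if variant == "constant_mek" else None

    def f(y):
        return _rhs_const(y, p, p.S_basal, 1.0, 1.0, use_imp, m2_clamp)

    y = _basal_guess(p)
    if m2_clamp is not None:
        y[_IDX["M2"]] = m2_clamp
        y[_IDX["M0"]] = 1.0 - m2_clamp
    sol = solve_ivp(lambda t, y: f(y), (0.0, 1e4), y, method="BDF",
                    rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise SimulationError(
            f"pre-equilibration integration failed for params {params.to_dict()}")
    y = sol.y[:, -1]
    y = _project_totals(y, m2_clamp is None)

    # Newton on the rhs with the redundant rows replaced by the conservation
    # constraints, so the conserved totals stay pinned exactly: the rhs rows
    # of each conserved pool sum to zero, making one row per pool redundant.
    mek_rows = list(_MEK_POOLS)
    erk_rows = list(ERK_POOLS)

    def g(y):
        r = f(y)
        if m2_clamp is None:
            r[_IDX["M0"]] = y[mek_rows].sum() - 1.0
        else:
            r[_IDX["M2"]] = y[_IDX["M2"]] - m2_clamp
        r[_IDX["E0c"]] = y[erk_rows].sum() - 1.0
        return r

    y = _newton_polish(g, y)
    y = np.clip(y, 0.0, None)
    if m2_clamp is not None:
        y[_IDX["M2"]] = m2_clamp

    resid = np.max(np.abs(f(y)))
    if resid > residual_tol:
        raise SimulationError(
            f"steady-state solve did not converge (residual {resid:.2e}) "
            f"for params {params.to_dict()}")
    return y


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """A simulated timecourse: ``states[i]`` is the state at ``times[i]``."""

    times: np.ndarray
    states: np.ndarray  # (n_times, N_STATES)
    params: ModelParams
    protocol: Protocol

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, _IDX[name]]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_min", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate(params: ModelParams, protocol: Protocol,
             t_grid: np.ndarray | None = None,
             y0: np.ndarray | None = None,
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the model over a protocol with event-exact restarts.

    The initial condition is the basal steady state (computed by
    :func:`initial_state` unless ``y0`` is given). Integration restarts exactly
    at each input-strength change and inhibitor event so that no discontinuity
    is smoothed over. Stiff adaptive integration (BDF), chosen over the
    Fortran-backed alternative because its pure-Python implementation is
    bit-reproducible run to run.
    """
    if t_grid is None:
        t_grid = np.arange(0.0, protocol.t_end + 1e-9, 0.5)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size and (t_grid[0] < -1e-12 or t_grid[-1] > protocol.t_end + 1e-9):
        raise ValueError("t_grid must lie within [0, t_end]")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    p = _effective_params(params, protocol.variant)
    use_imp = protocol.variant in ("importin", "combined")
    const_mek = protocol.variant == "constant_mek"

    if y0 is None:
        y0 = initial_state(params, protocol.variant)
    y = np.array(y0, dtype=float)
    if const_mek:
        y[_IDX["M2"]] = params.M2_const

    boundaries = [0.0] + protocol.event_times() + [protocol.t_end]
    out = np.empty((t_grid.size, N_STATES))
    if t_grid.size and t_grid[0] == 0.0:
        out[0] = y
        written = 1
    else:
        written = 0

    for a, b in zip(boundaries[:-1], boundaries[1:]):
        u = protocol.input_strength(a)
        inh = 0.0 if (protocol.u0126_time is not None
                      and a >= protocol.u0126_time - 1e-12) else 1.0
        pho = 0.0 if (protocol.okadaic_time is not None
                      and a >= protocol.okadaic_time - 1e-12) else 1.0
        m2_clamp = params.M2_const if const_mek else None

        fun = lambda t, yy: _rhs_const(yy, p, u, inh, pho, use_imp, m2_clamp)
        mask = (t_grid > a + 1e-12) & (t_grid <= b + 1e-12)
        t_eval = t_grid[mask]
        needs_end = t_eval.size == 0 or abs(t_eval[-1] - b) > 1e-12
        ts = np.concatenate([t_eval, [b]]) if needs_end else t_eval
        sol = solve_ivp(fun, (a, b), y, method="BDF", t_eval=ts,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(
                f"integration failed near t = {sol.t[-1] if sol.t.size else a:.3g} min "
                f"for params {params.to_dict()}")
        n_keep = t_eval.size
        if n_keep:
            out[written:written + n_keep] = sol.y[:, :n_keep].T
            written += n_keep
        y = sol.y[:, -1]

    assert written == t_grid.size
    return Trajectory(times=t_grid, states=out, params=params, protocol=protocol)
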