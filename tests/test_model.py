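import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erkshuttle.model import (
    ERK_POOLS,
    STATE_NAMES,
    SimulationError,
    initial_state,
    rhs,
    simulate,
)
from erkshuttle.params import ModelParams
from erkshuttle.protocol import (
    Protocol,
    phosphatase_inhibition,
    step_stimulus,
)

IDX = {name: i for i, name in enumerate(STATE_NAMES)}
MEK_POOLS = (IDX["M0"], IDX["M1"], IDX["M2"])


def _random_state(rng):
    y = np.zeros(len(STATE_NAMES))
    m = rng.dirichlet(np.ones(3))
    y[list(MEK_POOLS)] = m
    e = rng.dirichlet(np.ones(len(ERK_POOLS)))
    y[list(ERK_POOLS)] = e
    y[IDX["D"]] = rng.uniform(0, 1)
    y[IDX["Pc"]] = rng.uniform(0, 0.01)
    y[IDX["Pn"]] = rng.uniform(0, 0.1)
    return y


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_rhs_conserves_totals_pointwise(seed, theta):
    """Sum of the MEK rows and of the ERK rows is exactly zero."""
    rng = np.random.default_rng(seed)
    y = _random_state(rng)
    proto = step_stimulus(1.0, t_end=75.0)
    dy = rhs(5.0, y, theta, proto)
    assert abs(dy[list(MEK_POOLS)].sum()) < 1e-14
    assert abs(dy[list(ERK_POOLS)].sum()) < 1e-14


def test_rhs_hand_arithmetic():
    """Spot-check individual flux terms against hand-computed values."""
    p = ModelParams(k_fb=2.0, k_rec=0.5, k_cat_c=0.4, k_sdp_c=0.1,
                    k_on_c=1.0, Sc_tot=0.2, k_on_n=0.0, Sn_tot=0.0)
    y = np.zeros(len(STATE_NAMES))
    y[IDX["M0"]] = 1.0
    y[IDX["E2c"]] = 0.3
    y[IDX["EBc"]] = 0.05
    y[IDX["E0c"]] = 0.65
    y[IDX["D"]] = 0.25
    y[IDX["Pc"]] = 0.02
    proto = step_stimulus(1.0, t_end=10.0)
    dy = rhs(1.0, y, p, proto)
    # dD = k_fb*E2c*(1-D) - k_rec*D = 2*0.3*0.75 - 0.5*0.25
    assert dy[IDX["D"]] == pytest.approx(0.45 - 0.125)
    # dPc = k_cat_c*EBc - k_sdp_c*Pc = 0.4*0.05 - 0.1*0.02
    assert dy[IDX["Pc"]] == pytest.approx(0.020 - 0.002)
    # dEBc = k_on_c*E2c*(Sc_tot-Pc-EBc)/phi_c - (k_off_c+k_cat_c)*EBc
    b_c = 1.0 * 0.3 * (0.2 - 0.02 - 0.05) / 0.8
    assert dy[IDX["EBc"]] == pytest.approx(b_c - (1.0 + 0.4) * 0.05)


def test_simulate_conservation_all_variants(theta):
    grid = np.arange(0.0, 75.5, 2.5)
    for variant in ("full", "control", "importin", "combined"):
        proto = step_stimulus(1.0, t_end=75.0, variant=variant)
        traj = simulate(theta, proto, grid)
        erk = traj.states[:, list(ERK_POOLS)].sum(axis=1)
        mek = traj.states[:, list(MEK_POOLS)].sum(axis=1)
        assert np.max(np.abs(erk - 1.0)) < 1e-7, variant
        assert np.max(np.abs(mek - 1.0)) < 1e-7, variant
    # constant-MEK clamps M2, so only ERK is conserved
    proto = step_stimulus(1.0, t_end=75.0, variant="constant_mek")
    traj = simulate(theta.replace(M2_const=0.2), proto, grid)
    erk = traj.states[:, list(ERK_POOLS)].sum(axis=1)
    assert np.max(np.abs(erk - 1.0)) < 1e-7


def test_simulate_nonnegative(theta):
    proto = step_stimulus(1.0, t_end=75.0)
    traj = simulate(theta, proto)
    assert traj.states.min() > -1e-9


def test_full_reduces_to_control_at_zero_substrate(theta):
    """With substrates removed, the full model equals the control variant."""
    p = theta.replace(Sc_tot=0.0, Sn_tot=0.0, k_on_c=0.0, k_on_n=0.0)
    grid = np.arange(0.0, 60.5, 2.0)
    full = simulate(p, step_stimulus(1.0, t_end=60.0, variant="full"), grid)
    ctrl = simulate(p, step_stimulus(1.0, t_end=60.0, variant="control"), grid)
    assert np.max(np.abs(full.states - ctrl.states)) < 1e-12


def test_importin_approaches_control_at_large_k_rel(theta):
    """Instant importin release makes the importin variant collapse to control."""
    p = theta.replace(k_rel=1e4)
    grid = np.arange(0.0, 60.5, 2.0)
    imp = simulate(p, step_stimulus(1.0, t_end=60.0, variant="importin"), grid)
    ctrl = simulate(p, step_stimulus(1.0, t_end=60.0, variant="control"), grid)
    # compare all non-importin states; the transient EIn pool is O(flux/k_rel)
    keep = [i for i in range(len(STATE_NAMES)) if i != IDX["EIn"]]
    diff = np.max(np.abs(imp.states[:, keep] - ctrl.states[:, keep]))
    scale = np.max(np.abs(ctrl.states[:, keep]))
    assert diff / scale < 0.01
    assert imp.states[:, IDX["EIn"]].max() < 1e-3


def test_mek_module_analytic_plateau():
    """With feedback off, steady ppMEK is r^2/(1+r+r^2); r=1 gives 1/3."""
    p = ModelParams(a_M=0.7, d_M=0.7, k_fb=0.0, a_E1=0.0, a_E2=0.0)
    grid = np.arange(0.0, 200.5, 5.0)
    traj = simulate(p, step_stimulus(1.0, t_end=200.0), grid)
    assert traj["M2"][-1] == pytest.approx(1.0 / 3.0, abs=1e-6)


def test_fixed_step_rk4_oracle(theta):
    """Adaptive solution matches a fine fixed-step RK4 integration."""
    proto = step_stimulus(1.0, t_end=10.0)
    grid = np.arange(0.0, 10.0 + 1e-9, 0.5)
    traj = simulate(theta, proto, grid, rtol=1e-10, atol=1e-12)
    y = initial_state(theta, "full")
    h = 1e-3
    f = lambda t, yy: rhs(t, yy, theta, proto)
    out = [y.copy()]
    t = 0.0
    for _ in range(int(10 / h)):
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
        if abs(t / 0.5 - round(t / 0.5)) < 1e-9:
            out.append(y.copy())
    assert np.max(np.abs(np.array(out) - traj.states)) < 1e-6


def test_okadaic_monotonicity(theta):
    """Total phospho-ERK is non-decreasing after phosphatase shutoff."""
    from erkshuttle.model import PHOSPHO_ERK_POOLS

    proto = phosphatase_inhibition(30.0, t_end=60.0)
    grid = np.arange(0.0, 60.5, 1.0)
    traj = simulate(theta, proto, grid)
    phos = traj.states[:, list(PHOSPHO_ERK_POOLS)].sum(axis=1)
    after = grid >= 30.0
    assert np.all(np.diff(phos[after]) > -1e-9)


def test_initial_state_passive_balance():
    """With no stimulation, free ERK partitions by k_pass : k_out exactly."""
    p = ModelParams(S_basal=0.0, k_pass=0.4, k_out=1.6,
                    k_on_c=0.0, k_on_n=0.0, Sc_tot=0.0, Sn_tot=0.0)
    y = initial_state(p, "full")
    assert y[IDX["E0n"]] / y[IDX["E0c"]] == pytest.approx(0.4 / 1.6, abs=1e-9)
    assert y[IDX["M0"]] == pytest.approx(1.0, abs=1e-9)


def test_initial_state_is_steady(theta):
    """Residual at the returned state is below the contract tolerance."""
    proto = step_stimulus(1.0, t_end=75.0)
    y = initial_state(theta, "full")
    # holding the basal input, the state should not move
    basal = Protocol(segments=[(0.0, theta.S_basal)], t_end=50.0)
    traj = simulate(theta, basal, np.arange(0.0, 50.5, 10.0), y0=y)
    assert np.max(np.abs(traj.states - y)) < 1e-7
    del proto


def test_simulate_deterministic_repeat(theta):
    proto = step_stimulus(1.0, t_end=30.0)
    grid = np.arange(0.0, 30.5, 1.0)
    a = simulate(theta, proto, grid)
    b = simulate(theta, proto, grid)
    assert np.array_equal(a.states, b.states)


def test_simulate_rejects_bad_grid(theta):
    proto = step_stimulus(1.0, t_end=10.0)
    with pytest.raises(ValueError, match="increasing"):
        simulate(theta, proto, np.array([0.0, 5.0, 5.0]))
    with pytest.raises(ValueError, match="within"):
        simulate(theta, proto, np.array([0.0, 20.0]))


def test_trajectory_accessors(theta):
    proto = step_stimulus(1.0, t_end=10.0)
    traj = simulate(theta, proto, np.arange(0.0, 10.5, 2.0))
    df = traj.to_dataframe()
    assert list(df.columns)[0] == "time_min"
    assert np.array_equal(df["M2"].to_numpy(), traj["M2"])


def test_steady_state_failure_raises():
    # a_M enormous with zero dephosphorylation cannot satisfy the residual
    p = ModelParams(a_M=1.0, d_M=0.0, S_basal=1.0, a_E1=0.0, a_E2=0.0)
    try:
        y = initial_state(p, "full")
    except SimulationError:
        return
    # if it converged, the state must genuinely be steady
    proto = Protocol(segments=[(0.0, 1.0)], t_end=10.0)
    dy = rhs(0.0, y, p, proto)
    assert np.max(np.abs(dy)) < 1e-8
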