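import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erkshuttle.fitting import (
    CostSpec,
    EnsembleResult,
    ParamSpace,
    cost,
    ensemble_walk,
    make_cost_fn,
    metropolis_anneal,
    optimal_scale,
    threshold_walk,
)
from erkshuttle.observables import ObservationParams
from erkshuttle.params import ModelParams


# ---------------------------------------------------------------------------
# parameter space
# ---------------------------------------------------------------------------

def test_param_space_roundtrip(theta, obs):
    space = ParamSpace(theta, obs)
    x = space.to_vector(theta, obs)
    params, o = space.from_vector(x)
    for name in space.free:
        got = getattr(o if name in ("rho_c", "rho_n", "rho_e") else params, name)
        want = getattr(obs if name in ("rho_c", "rho_n", "rho_e") else theta, name)
        assert got == pytest.approx(want, rel=1e-12), name


def test_param_space_logit_phi_n(theta, obs):
    space = ParamSpace(theta, obs, free=("phi_n",))
    for v in (0.05, 0.2, 0.9):
        x = space.to_vector(theta.replace(phi_n=v), obs)
        p, _ = space.from_vector(x)
        assert p.phi_n == pytest.approx(v, rel=1e-12)
        # any real vector maps into (0, 1)
        p2, _ = space.from_vector(np.array([50.0]))
        assert 0.0 < p2.phi_n < 1.0


def test_param_space_rejects_unknown_name(theta, obs):
    with pytest.raises(ValueError, match="unknown free parameter"):
        ParamSpace(theta, obs, free=("bogus",))


# ---------------------------------------------------------------------------
# optimal scale
# ---------------------------------------------------------------------------

@settings(derandomize=True, max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_optimal_scale_beats_grid_search(seed):
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.1, 2.0, 30)
    y = 1.7 * m * rng.lognormal(0.0, 0.2, 30)
    sigma = rng.uniform(0.05, 0.3, 30)
    s_star = optimal_scale(y, m, sigma)

    def J(s):
        return float(np.sum(((s * m - y) / sigma) ** 2))

    grid = np.linspace(0.2, 5.0, 2001)
    assert J(s_star) <= min(J(s) for s in grid) + 1e-9


def test_optimal_scale_degenerate_model():
    assert optimal_scale(np.ones(3), np.zeros(3), np.ones(3)) == 1.0


# ---------------------------------------------------------------------------
# cost
# ---------------------------------------------------------------------------

def test_cost_zero_at_truth_noise_free(theta, obs, noise_free_datasets):
    """At the generating parameters, noise-free data gives (near-)zero cost."""
    spec = CostSpec(space=ParamSpace(theta, obs), rtol=1e-8, atol=1e-10)
    J = cost(theta, obs, noise_free_datasets, spec)
    assert J < 1e-6


def test_cost_rises_away_from_truth(theta, obs, noise_free_datasets):
    spec = CostSpec(space=ParamSpace(theta, obs), rtol=1e-8, atol=1e-10)
    J0 = cost(theta, obs, noise_free_datasets, spec)
    for name, factor in (("a_M", 1.3), ("k_in", 0.7), ("d_n2", 1.5)):
        J = cost(theta.replace(**{name: getattr(theta, name) * factor}),
                 obs, noise_free_datasets, spec)
        assert J > J0 + 1.0, name


def test_cost_weights_scale_contributions(theta, obs, noise_free_datasets):
    space = ParamSpace(theta, obs)
    p = theta.replace(a_M=theta.a_M * 1.2)
    one = cost(p, obs, noise_free_datasets, CostSpec(space=space))
    ids = {ds.metadata["design"]["experiment_id"] for ds in noise_free_datasets}
    double = cost(p, obs, noise_free_datasets,
                  CostSpec(space=space, weights={i: 2.0 for i in ids}))
    assert double == pytest.approx(2.0 * one, rel=1e-9)


def test_cost_fn_inf_outside_domain(theta, obs, noise_free_datasets):
    spec = CostSpec(space=ParamSpace(theta, obs))
    fn = make_cost_fn(noise_free_datasets, spec)
    x = spec.space.to_vector(theta, obs)
    bad = x.copy()
    bad[:] = 30.0  # rates of 1e30 / min: simulation must fail, not crash
    assert fn(bad) == np.inf


# ---------------------------------------------------------------------------
# annealing and threshold walk on analytic toys
# ---------------------------------------------------------------------------

def _quadratic(x):
    return float(np.sum((x - 3.0) ** 2))


def test_anneal_recovers_quadratic_minimum():
    x0 = np.zeros(4)
    x_best, J_best = metropolis_anneal(_quadratic, x0, step=0.3, seed=1,
                                       n_iter=3000, t0=2.0)
    assert J_best < 0.05
    assert np.allclose(x_best, 3.0, atol=0.2)


def test_anneal_deterministic_given_seed():
    a = metropolis_anneal(_quadratic, np.zeros(3), 0.3, seed=5, n_iter=500)
    b = metropolis_anneal(_quadratic, np.zeros(3), 0.3, seed=5, n_iter=500)
    assert np.array_equal(a[0], b[0]) and a[1] == b[1]


def test_threshold_walk_stays_in_region():
    """1-D quadratic: accepted points are exactly those with J <= threshold."""
    fn = lambda x: float(x[0] ** 2)
    accepted, costs, rate = threshold_walk(fn, np.zeros(1), step=0.4, seed=3,
                                           n_accept=400, threshold=1.0)
    assert np.all(costs <= 1.0)
    assert np.all(np.abs(accepted[:, 0]) <= 1.0)
    # the walk explores most of the acceptance interval [-1, 1]
    assert accepted[:, 0].min() < -0.7 and accepted[:, 0].max() > 0.7
    assert 0.05 < rate <= 1.0


def test_threshold_walk_rejects_bad_start():
    fn = lambda x: float(x[0] ** 2)
    with pytest.raises(ValueError, match="above threshold"):
        threshold_walk(fn, np.array([5.0]), 0.1, seed=1, n_accept=10,
                       threshold=1.0)


def test_threshold_walk_aborts_on_low_acceptance():
    fn = lambda x: float(x[0] ** 2)
    with pytest.raises(RuntimeError, match="acceptance rate"):
        # giant steps: almost every proposal leaves [-1, 1]
        threshold_walk(fn, np.zeros(1), step=500.0, seed=1, n_accept=400,
                       threshold=1.0)


def test_threshold_walk_deterministic_given_seed():
    fn = lambda x: float(np.sum(x ** 2))
    a = threshold_walk(fn, np.zeros(2), 0.4, seed=9, n_accept=50, threshold=1.0)
    b = threshold_walk(fn, np.zeros(2), 0.4, seed=9, n_accept=50, threshold=1.0)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


# ---------------------------------------------------------------------------
# ensemble result round trip
# ---------------------------------------------------------------------------

def test_ensemble_result_csv_roundtrip(tmp_path, theta, obs,
                                       noise_free_datasets):
    spec = CostSpec(space=ParamSpace(theta, obs))
    # generous J_min: this test exercises serialization, not the statistics
    ens = ensemble_walk(noise_free_datasets, spec, seed=2,
                        start=(theta, obs), n=5, J_min=1e6)
    path = tmp_path / "ens.csv"
    ens.to_csv(path)
    back = EnsembleResult.from_csv(path)
    assert len(back) == 5
    assert back.space.free == spec.space.free
    p0, o0 = ens.member(0)
    p1, o1 = back.member(0)
    assert p0.a_M == pytest.approx(p1.a_M, rel=1e-9)
    assert o0.rho_c == pytest.approx(o1.rho_c, rel=1e-9)
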