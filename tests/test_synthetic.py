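import dataclasses

import numpy as np
import pandas as pd
import pytest

from erkshuttle.model import simulate
from erkshuttle.observables import observe
from erkshuttle.synthetic import (
    BLOT_CV,
    Dataset,
    Design,
    default_designs,
    design_from_dict,
    fitted_designs,
    generate,
    generate_all,
)


def _design(name="blot"):
    return next(d for d in default_designs() if d.experiment_id == name)


def test_default_designs_shape():
    designs = default_designs()
    ids = [d.experiment_id for d in designs]
    assert len(ids) == len(set(ids))
    assert len(fitted_designs()) == 7
    assert all(d.fitted for d in fitted_designs())
    assert all(d.time_grid[0] == 0.0 for d in designs)


def test_generate_deterministic(theta, obs):
    d = _design("blot")
    a = generate(theta, d, 42, obs)
    b = generate(theta, d, 42, obs)
    pd.testing.assert_frame_equal(a.data, b.data)


def test_generate_seed_sensitivity(theta, obs):
    d = _design("blot")
    a = generate(theta, d, 42, obs)
    b = generate(theta, d, 43, obs)
    assert not np.allclose(a.data["value"], b.data["value"])


def test_designs_draw_independent_streams(theta, obs):
    """Two designs generated under one master seed use different noise."""
    blot = _design("blot")
    ms = dataclasses.replace(_design("ms"), readouts=("ms_ppERK",),
                             experiment_id="blot")
    a = generate(theta, dataclasses.replace(blot, readouts=("ppERK_blot",)),
                 42, obs)
    b = generate(theta, ms, 42, obs)
    ra = a.data["value"].to_numpy()
    rb = b.data["value"].to_numpy()
    assert ra.shape == rb.shape and not np.allclose(ra, rb)


def test_noise_free_population_identity(theta, obs):
    """With all CVs zero, the generator is exactly the observation map."""
    d = dataclasses.replace(_design("blot"), measurement_cv=0.0, replicates=1)
    ds = generate(theta, d, 1, obs)
    traj = simulate(theta, d.protocol, d.time_grid)
    traces = observe(traj, obs, readouts=d.readouts)
    for r in d.readouts:
        got = ds.data[ds.data["readout"] == r]["value"].to_numpy()
        assert np.array_equal(got, traces[r].values)


def test_noise_free_single_cell_identity(theta, obs):
    d = dataclasses.replace(_design("nucloc_gfp"), measurement_cv=0.0,
                            jitter_cv=0.0, replicates=2)
    ds = generate(theta, d, 1, obs)
    traj = simulate(theta, d.protocol, d.time_grid)
    tr = observe(traj, obs, readouts=("nucloc",))["nucloc"]
    for rep in (0, 1):
        got = ds.data[ds.data["replicate"] == rep]["value"].to_numpy()
        assert np.allclose(got, tr.values, atol=1e-12)


def test_population_noise_cv_calibrated(theta, obs):
    """Empirical replicate CV matches the design CV (lognormal model)."""
    d = dataclasses.replace(_design("blot"), replicates=400,
                            readouts=("ppERK_blot",))
    ds = generate(theta, d, 7, obs)
    sub = ds.data[ds.data["time_min"] == 10.0]["value"].to_numpy()
    cv = sub.std(ddof=1) / sub.mean()
    assert cv == pytest.approx(BLOT_CV, rel=0.2)


def test_single_cell_renormalized_at_t0(theta, obs):
    """Each noisy normalized trace is re-normalized to its own t = 0 sample."""
    d = _design("nucloc_gfp")
    ds = generate(theta, d, 3, obs)
    t0 = ds.data[ds.data["time_min"] == 0.0]
    assert np.allclose(t0["value"].to_numpy(), 1.0)


def test_sigma_positive_floor(theta, obs):
    ds = generate(theta, _design("u0126_nuc"), 5, obs)
    assert (ds.data["sigma"] >= 1e-3 - 1e-15).all()


def test_dataset_csv_roundtrip(tmp_path, theta, obs):
    ds = generate(theta, _design("blot"), 11, obs)
    path = tmp_path / "blot.csv"
    ds.to_csv(path)
    back = Dataset.from_csv(path)
    assert back.metadata["seed"] == 11
    assert np.allclose(back.data["value"], ds.data["value"], rtol=1e-9)
    design = design_from_dict(back.metadata["design"])
    assert design.experiment_id == "blot"
    assert design.protocol == _design("blot").protocol


def test_dataset_rejects_bad_columns():
    with pytest.raises(ValueError, match="missing columns"):
        Dataset(data=pd.DataFrame({"value": [1.0]}))


def test_design_validation():
    with pytest.raises(ValueError, match="replicate"):
        Design("x", _design("blot").protocol, ("nucloc",),
               np.array([0.0, 1.0]), 0, 0.1)
    with pytest.raises(ValueError, match="t = 0"):
        Design("x", _design("blot").protocol, ("nucloc",),
               np.array([1.0, 2.0]), 3, 0.1)


def test_generate_all_keys(theta, obs):
    out = generate_all(theta, fitted_designs(), 9, obs)
    assert set(out) == {d.experiment_id for d in fitted_designs()}
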