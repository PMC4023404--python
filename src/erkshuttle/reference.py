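"""The packaged reference parameter set.

``theta_ref`` is a single full-variant parameter set in the nuclear-dominant
buffering regime (B_n = 20, B_c = 0.3), calibrated once against the waypoint
kinetic features of maximally stimulated fibroblasts (peak times, post-
inhibition half-decay times, nuclear-activity lag) and then frozen. It is the
ground truth for the synthetic-data generator and the default starting point
for fitting. See ``scripts/derive_theta_ref.py`` for its derivation.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import yaml

from .observables import ObservationParams
from .params import ModelParams

_REF_FILE = "theta_ref.yaml"


def _load_raw() -> dict:
    text = resources.files("erkshuttle.data").joinpath(_REF_FILE).read_text()
    return yaml.safe_load(text)


def load_theta_ref() -> tuple[ModelParams, ObservationParams]:
    """Load the packaged reference parameters and observation offsets."""
    raw = _load_raw()
    params = ModelParams.from_dict(raw["params"])
    obs = ObservationParams.from_dict(raw["observation"])
    return params, obs


def theta_ref_hash() -> str:
    """Short content hash of the packaged reference set (dataset provenance)."""
    text = resources.files("erkshuttle.data").joinpath(_REF_FILE).read_text()
    return hashlib.sha256(text.encode()).hexdigest()[:12]
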