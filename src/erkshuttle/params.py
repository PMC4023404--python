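"""Kinetic parameters of the compartmental ERK shuttling model family.

All first-order rate constants are in 1/min. Amounts of ERK species and
substrates are expressed as fractions of total cellular ERK; bimolecular
association coefficients therefore carry units of 1/(concentration * min),
where concentration means total-ERK equivalents per unit compartment volume
(an amount divided by the compartment's volume fraction).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import yaml

#: The five model variants.
VARIANTS = ("full", "control", "importin", "combined", "constant_mek")


@dataclass
class ModelParams:
    """Parameters of the ERK cascade / shuttling / substrate-buffering ODE family.

    Attributes
    ----------
    a_M : float
        Per-site MEK phosphorylation rate coefficient at unit input strength (1/min).
    d_M : float
        Per-site MEK dephosphorylation rate (1/min).
    k_fb : float
        Feedback desensitization rate coefficient (1/min per unit free active
        cytosolic ERK).
    k_rec : float
        Desensitization recovery rate (1/min).
    a_E1, a_E2 : float
        ERK site-1 / site-2 phosphorylation rate coefficients per unit active
        MEK (1/min).
    d_c1, d_c2 : float
        Cytosolic mono- / di-phospho ERK dephosphorylation rates (1/min).
    d_n1, d_n2 : float
        Nuclear counterparts (1/min).
    k_in : float
        Facilitated nuclear import rate of free diphospho cytosolic ERK (1/min).
    k_pass : float
        Passive shuttling rate applied to all free cytosolic ERK states (1/min).
    k_out : float
        Nuclear export rate applied to all free nuclear ERK states (1/min).
    k_on_c, k_on_n : float
        ERK-substrate association coefficients (1/(conc*min)).
    k_off_c, k_off_n : float
        Dissociation rates (1/min).
    k_cat_c, k_cat_n : float
        Substrate phosphorylation (turnover) rates (1/min).
    k_sdp_c, k_sdp_n : float
        Substrate dephosphorylation rates (1/min).
    Sc_tot, Sn_tot : float
        Total substrate amounts per compartment (total-ERK-equivalent units).
    phi_n : float
        Nuclear volume fraction (0 < phi_n < 1); cytosolic fraction is 1 - phi_n.
    k_rel : float
        Importin-release rate (1/min); used only by the importin/combined variants.
    M2_const : float
        Fixed post-stimulus active-MEK level; used only by the constant-MEK variant.
    S_basal : float
        Pre-stimulus input strength (dimensionless).
    """

    a_M: float = 1.0
    d_M: float = 1.0
    k_fb: float = 0.0
    k_rec: float = 0.1
    a_E1: float = 1.0
    a_E2: float = 1.0
    d_c1: float = 0.5
    d_c2: float = 0.5
    d_n1: float = 0.5
    d_n2: float = 0.5
    k_in: float = 1.0
    k_pass: float = 0.1
    k_out: float = 1.0
    k_on_c: float = 0.0
    k_off_c: float = 1.0
    k_cat_c: float = 0.1
    k_sdp_c: float = 0.1
    k_on_n: float = 0.0
    k_off_n: float = 1.0
    k_cat_n: float = 0.1
    k_sdp_n: float = 0.1
    Sc_tot: float = 0.0
    Sn_tot: float = 0.0
    phi_n: float = 0.2
    k_rel: float = 100.0
    M2_const: float = 0.0
    S_basal: float = 0.02

    @property
    def phi_c(self) -> float:
        return 1.0 - self.phi_n

    def validate(self) -> None:
        """Raise ValueError if any invariant is violated."""
        if not 0.0 < self.phi_n < 1.0:
            raise ValueError(f"phi_n must lie in (0, 1), got {self.phi_n}")
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if v < 0.0:
                raise ValueError(f"parameter {name} must be >= 0, got {v}")

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    # ---- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        p = cls(**d)
        p.validate()
        return p

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def __iter__(self) -> Iterator[tuple[str, float]]:
        for f in dataclasses.fields(self):
            yield f.name, getattr(self, f.name)


_RATE_FIELDS = tuple(
    f.name
    for f in dataclasses.fields(ModelParams)
    if f.name not in ("phi_n",)
)

#: Parameter names that scale like amplitudes (targets of cell-to-cell jitter).
AMPLITUDE_PARAMS = ("a_M", "a_E1", "a_E2", "Sn_tot", "Sc_tot")
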