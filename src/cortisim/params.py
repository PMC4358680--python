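"""Model parameters for the corticotroph excitability model.

Units are self-consistent throughout the package: membrane potential in mV,
time in ms, conductance in nS, current in pA, capacitance in pF and calcium
in uM (nS * mV = pA and pA / pF = mV / ms).

The default values reproduce the published parameter table for the basal
condition; ``condition_parameters`` returns the named secretagogue variants
(CRH raises g_Ca and speeds/shifts BK-near; AVP raises g_NS; CRH+AVP is the
union of the two changes).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "PARAM_ORDER",
    "CONDITIONS",
    "condition_parameters",
    "scale_bk",
    "load_parameters",
    "save_parameters",
]

#: Canonical field order used when packing parameters into a flat array for
#: the integration kernel.  Do not reorder without updating ``_kernels``.
PARAM_ORDER = (
    "g_Ca", "g_NS", "g_K", "g_Kir", "g_BKnear", "g_BKfar",
    "V_Ca", "V_NS", "V_K",
    "v_r", "v_m", "v_n", "s_m", "s_n", "s_r",
    "tau_bkn", "tau_bkf", "tau_n",
    "kCa_BKnear", "kCa_BKfar", "k_bk", "V_BK0", "k_shift",
    "A", "k_c", "f", "alpha", "sigma_N", "C_m",
)

# ASCII-transliterated keys used in config files.
_YAML_KEYS = {
    "g_Ca": "gCa", "g_NS": "gNS", "g_K": "gK", "g_Kir": "gKir",
    "g_BKnear": "gBKnear", "g_BKfar": "gBKfar",
    "V_Ca": "VCa", "V_NS": "VNS", "V_K": "VK",
    "v_r": "vr", "v_m": "vm", "v_n": "vn",
    "s_m": "sm", "s_n": "sn", "s_r": "sr",
    "tau_bkn": "taubkn", "tau_bkf": "taubkf", "tau_n": "taun",
    "kCa_BKnear": "kCaBKnear", "kCa_BKfar": "kCaBKfar",
    "k_bk": "kbk", "V_BK0": "VBK0", "k_shift": "kshift",
    "A": "A", "k_c": "kc", "f": "f", "alpha": "alpha",
    "sigma_N": "sigmaN", "C_m": "Cm",
}
_FROM_YAML = {v: k for k, v in _YAML_KEYS.items()}


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the six-current corticotroph model.

    Defaults are the basal-condition values. Conductances in nS, potentials
    in mV, time constants in ms, calcium sensitivities in uM.
    """

    g_Ca: float = 1.8        # L-type Ca2+ conductance (2.2 under CRH)
    g_NS: float = 0.1        # non-selective cation conductance (0.2 under AVP)
    g_K: float = 8.2         # delayed rectifier K+ conductance
    g_Kir: float = 1.0       # inward rectifier K+ conductance
    g_BKnear: float = 2.0    # BK channels at Ca2+ channel microdomains
    g_BKfar: float = 1.0     # BK channels sensing bulk cytosolic Ca2+
    V_Ca: float = 60.0
    V_NS: float = -10.0
    V_K: float = -75.0
    v_r: float = -60.0       # Kir half-activation
    v_m: float = -20.0       # Ca2+ half-activation
    v_n: float = -5.0        # delayed rectifier half-activation
    s_m: float = 10.0
    s_n: float = 10.0
    s_r: float = -1.0        # negative slope: Kir opens under hyperpolarisation
    tau_bkn: float = 20.0    # BK-near activation time constant (4 under CRH)
    tau_bkf: float = 4.0
    tau_n: float = 40.0
    kCa_BKnear: float = 18.0  # BK-near Ca2+ sensitivity (6 under CRH)
    kCa_BKfar: float = 6.0
    k_bk: float = 3.0        # BK voltage slope
    V_BK0: float = 0.1       # BK half-activation at ca = kCa
    k_shift: float = 18.0    # mV shift per e-fold calcium change
    A: float = 0.15          # microdomain [Ca2+] per pA of Ca2+ current
    k_c: float = 0.12        # Ca2+ pump rate, ms^-1
    f: float = 0.01          # fraction of cytosolic Ca2+ that is free
    alpha: float = 0.0015    # current-to-concentration factor, uM pA^-1 ms^-1
    sigma_N: float = 5.0     # channel-noise amplitude, pA
    C_m: float = 6.0         # membrane capacitance, pF

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("g_Ca", "g_NS", "g_K", "g_Kir", "g_BKnear", "g_BKfar"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")
        for name in ("tau_bkn", "tau_bkf", "tau_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be > 0")
        if self.s_m <= 0 or self.s_n <= 0:
            raise ValueError("s_m and s_n must be > 0")
        if self.s_r >= 0:
            raise ValueError("s_r must be < 0 (Kir opens under hyperpolarisation)")
        if self.kCa_BKnear <= 0 or self.kCa_BKfar <= 0 or self.k_bk <= 0:
            raise ValueError("kCa_BKnear, kCa_BKfar and k_bk must be > 0")
        if self.sigma_N < 0:
            raise ValueError("sigma_N must be >= 0")

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_array(self) -> np.ndarray:
        """Pack into a float64 vector in ``PARAM_ORDER`` (kernel layout)."""
        return np.array([getattr(self, k) for k in PARAM_ORDER], dtype=np.float64)

    def to_dict(self) -> dict:
        """Flat dict with ASCII-transliterated config keys."""
        return {_YAML_KEYS[k]: float(getattr(self, k)) for k in PARAM_ORDER}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        unknown = set(d) - set(_FROM_YAML)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{_FROM_YAML[k]: float(v) for k, v in d.items()})


# Named condition variants.  CRH+AVP is the union of the CRH and AVP changes;
# gca_only isolates the L-type conductance increase for the conductance
# dissection (raising g_Ca alone speeds spiking but does not produce bursts).
CONDITIONS: dict[str, dict[str, float]] = {
    "basal": {},
    "crh": {"g_Ca": 2.2, "tau_bkn": 4.0, "kCa_BKnear": 6.0},
    "avp": {"g_NS": 0.2},
    "crh_avp": {"g_Ca": 2.2, "g_NS": 0.2, "tau_bkn": 4.0, "kCa_BKnear": 6.0},
    "gca_only": {"g_Ca": 2.2},
}


def condition_parameters(condition: str = "basal",
                         base: ModelParameters | None = None) -> ModelParameters:
    """Parameter set for a named condition (basal, crh, avp, crh_avp)."""
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}; "
                       f"expected one of {sorted(CONDITIONS)}")
    base = base if base is not None else ModelParameters()
    return base.replace(**CONDITIONS[condition])


def scale_bk(p: ModelParameters, fraction: float) -> ModelParameters:
    """Scale both BK conductances by ``fraction`` in [0, 1].

    fraction=0 removes BK entirely (knockout / paxilline block);
    fraction=0.15 leaves the small residual conductance that yields mixed
    spiking and bursting under stimulation.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    return p.replace(g_BKnear=p.g_BKnear * fraction, g_BKfar=p.g_BKfar * fraction)


def save_parameters(p: ModelParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(p.to_dict(), sort_keys=False))


def load_parameters(path: str | Path | None = None) -> ModelParameters:
    """Load parameters from a YAML file; without a path, the bundled defaults."""
    if path is None:
        text = resources.files("cortisim").joinpath("data/default_parameters.yaml").read_text()
    else:
        text = Path(path).read_text()
    return ModelParameters.from_dict(yaml.safe_load(text))
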