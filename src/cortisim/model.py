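"""Algebraic pieces of the corticotroph model and the deterministic RHS.

The membrane potential obeys

    C_m dV/dt = -(I_Ca + I_Kdr + I_BKnear + I_BKfar + I_Kir + I_NS + I_noise)

with Hodgkin-Huxley style activation for the delayed rectifier and the two
BK populations, instantaneous activation for the Ca2+ and Kir currents, and
a constant-conductance non-selective cation current.  BK gating is calcium
dependent through a shift of the half-activation voltage

    V_half(ca) = V_BK0 - k_shift * ln(ca / kCa)

where BK-near channels see the microdomain calcium c_dom = -A * I_Ca at open
Ca2+ channels and BK-far channels see the bulk cytosolic calcium c, which
follows dc/dt = -f * (alpha * I_Ca + k_c * c).

Sign convention: outward currents are positive, inward negative; the RHS
subtracts the current sum.  All functions accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .params import ModelParameters

__all__ = [
    "ModelState",
    "DerivedQuantities",
    "steady_state_activation",
    "calcium_current",
    "delayed_rectifier_current",
    "inward_rectifier_current",
    "nonselective_current",
    "bk_near_current",
    "bk_far_current",
    "domain_calcium",
    "bk_half_voltage",
    "bk_steady_state",
    "derived_quantities",
    "rhs",
    "steady_gates",
    "find_equilibrium",
    "CA_FLOOR",
]

#: Floor applied to calcium concentrations before taking logs; the BK
#: half-activation shift is undefined at zero calcium.
CA_FLOOR = 1e-9


@dataclass
class ModelState:
    """Dynamical variables at one instant: V (mV), gates in [0,1], c (uM)."""

    V: float
    n: float
    bkn: float
    bkf: float
    c: float

    def __post_init__(self) -> None:
        for name in ("n", "bkn", "bkf"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gating variable {name} must be in [0, 1], got {x}")
        if self.c < 0:
            raise ValueError(f"calcium must be >= 0, got {self.c}")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.n, self.bkn, self.bkf, self.c], dtype=np.float64)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(*(float(x) for x in y))


@dataclass
class DerivedQuantities:
    """Instantaneous currents (pA), microdomain calcium (uM) and BK V_half (mV)."""

    c_dom: float
    I_Ca: float
    I_Kdr: float
    I_Kir: float
    I_BKnear: float
    I_BKfar: float
    I_NS: float
    V_BKnear_half: float
    V_BKfar_half: float

    @property
    def total_current(self) -> float:
        return (self.I_Ca + self.I_Kdr + self.I_BKnear + self.I_BKfar
                + self.I_Kir + self.I_NS)


def steady_state_activation(V, v_x: float, s_x: float):
    """Boltzmann steady-state activation 1 / (1 + exp((v_x - V) / s_x)).

    Increasing in V for s_x > 0, decreasing for s_x < 0 (inward rectifier).
    """
    if s_x == 0:
        raise ValueError("activation slope s_x must be nonzero")
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp((v_x - np.asarray(V, dtype=float)) / s_x))


def calcium_current(V, p: ModelParameters):
    """L-type Ca2+ current g_Ca * m_inf(V) * (V - V_Ca); inward below V_Ca."""
    return p.g_Ca * steady_state_activation(V, p.v_m, p.s_m) * (np.asarray(V, float) - p.V_Ca)


def delayed_rectifier_current(V, n, p: ModelParameters):
    """Delayed rectifier K+ current g_K * n * (V - V_K)."""
    return p.g_K * np.asarray(n, float) * (np.asarray(V, float) - p.V_K)


def inward_rectifier_current(V, p: ModelParameters):
    """Kir current with instantaneous activation r_inf(V)."""
    return p.g_Kir * steady_state_activation(V, p.v_r, p.s_r) * (np.asarray(V, float) - p.V_K)


def nonselective_current(V, p: ModelParameters):
    """Constant-conductance non-selective cation current g_NS * (V - V_NS)."""
    return p.g_NS * (np.asarray(V, float) - p.V_NS)


def bk_near_current(V, bkn, p: ModelParameters):
    return p.g_BKnear * np.asarray(bkn, float) * (np.asarray(V, float) - p.V_K)


def bk_far_current(V, bkf, p: ModelParameters):
    return p.g_BKfar * np.asarray(bkf, float) * (np.asarray(V, float) - p.V_K)


def domain_calcium(V, p: ModelParameters):
    """Microdomain free Ca2+ at open Ca2+ channels: c_dom = -A * I_Ca(V) (uM)."""
    return -p.A * calcium_current(V, p)


def bk_half_voltage(ca, kCa: float, p: ModelParameters):
    """Calcium-dependent BK half-activation voltage V_BK0 - k_shift*ln(ca/kCa).

    Equals V_BK0 at ca = kCa and decreases by k_shift per e-fold calcium rise.
    Raises for non-positive calcium (callers should clamp to CA_FLOOR first
    when ca can legitimately reach zero).
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("BK half-activation voltage requires ca > 0")
    return p.V_BK0 - p.k_shift * np.log(ca / kCa)


def bk_steady_state(V, ca, kCa: float, p: ModelParameters):
    """BK open fraction 1 / (1 + exp(-(V - V_half(ca)) / k_bk)).

    Monotone increasing in both V and ca (higher calcium lowers V_half).
    """
    v_half = bk_half_voltage(ca, kCa, p)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-(np.asarray(V, float) - v_half) / p.k_bk))


def derived_quantities(state: ModelState, p: ModelParameters) -> DerivedQuantities:
    V = state.V
    i_ca = float(calcium_current(V, p))
    c_dom = max(-p.A * i_ca, CA_FLOOR)
    c = max(state.c, CA_FLOOR)
    return DerivedQuantities(
        c_dom=c_dom,
        I_Ca=i_ca,
        I_Kdr=float(delayed_rectifier_current(V, state.n, p)),
        I_Kir=float(inward_rectifier_current(V, p)),
        I_BKnear=float(bk_near_current(V, state.bkn, p)),
        I_BKfar=float(bk_far_current(V, state.bkf, p)),
        I_NS=float(nonselective_current(V, p)),
        V_BKnear_half=float(bk_half_voltage(c_dom, p.kCa_BKnear, p)),
        V_BKfar_half=float(bk_half_voltage(c, p.kCa_BKfar, p)),
    )


def rhs(state: ModelState, p: ModelParameters) -> np.ndarray:
    """Deterministic time derivatives (dV, dn, dbkn, dbkf, dc).

    Noise is added by the integrator, not here.  dV/dt in mV/ms, gating
    derivatives relax toward their voltage/calcium dependent steady states,
    dc/dt = -f * (alpha * I_Ca + k_c * c).
    """
    d = derived_quantities(state, p)
    dV = -d.total_current / p.C_m
    dn = (float(steady_state_activation(state.V, p.v_n, p.s_n)) - state.n) / p.tau_n
    dbkn = (float(bk_steady_state(state.V, d.c_dom, p.kCa_BKnear, p)) - state.bkn) / p.tau_bkn
    dbkf = (float(bk_steady_state(state.V, max(state.c, CA_FLOOR), p.kCa_BKfar, p)) - state.bkf) / p.tau_bkf
    dc = -p.f * (p.alpha * d.I_Ca + p.k_c * state.c)
    return np.array([dV, dn, dbkn, dbkf, dc])


def steady_gates(V: float, c: float, p: ModelParameters) -> ModelState:
    """State with all gating variables at their steady values for (V, c)."""
    c_dom = max(float(domain_calcium(V, p)), CA_FLOOR)
    return ModelState(
        V=V,
        n=float(steady_state_activation(V, p.v_n, p.s_n)),
        bkn=float(bk_steady_state(V, c_dom, p.kCa_BKnear, p)),
        bkf=float(bk_steady_state(V, max(c, CA_FLOOR), p.kCa_BKfar, p)),
        c=c,
    )


def find_equilibrium(p: ModelParameters, guess: ModelState | None = None) -> ModelState:
    """Numerically locate a fixed point of the deterministic system."""
    if guess is None:
        guess = steady_gates(-60.0, 0.05, p)

    def fun(y):
        y = np.clip(y, [-150.0, 0.0, 0.0, 0.0, 0.0], [80.0, 1.0, 1.0, 1.0, np.inf])
        return rhs(ModelState.from_array(y), p)

    sol = optimize.root(fun, guess.as_array(), method="hybr", tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"equilibrium search failed: {sol.message}")
    return ModelState.from_array(np.clip(
        sol.x, [-150.0, 0.0, 0.0, 0.0, 0.0], [80.0, 1.0, 1.0, 1.0, np.inf]))
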