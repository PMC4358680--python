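"""Stochastic time stepping of the corticotroph model under protocols.

Integration is explicit Euler-Maruyama at dt = 0.1 ms by default: the
deterministic increment rhs * dt plus an additive voltage-noise increment
(sigma_N / C_m) * sqrt(dt) * Z with Z standard normal, matching the Wiener
noise current I_noise = sigma_N * omega of the published model.  A trace is
fully determined by (seed, dt, protocol), bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .model import ModelState, steady_gates
from .params import ModelParameters, condition_parameters, scale_bk

__all__ = [
    "NoiseSpec",
    "ProtocolSegment",
    "Protocol",
    "Trace",
    "IntegrationError",
    "integrate",
    "run_protocol",
    "default_initial_state",
    "stimulus_protocol",
]

DEFAULT_DT = 0.1  # ms


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite; carries the failure time."""

    def __init__(self, t_ms: float):
        super().__init__(f"integration diverged at t = {t_ms:.3f} ms")
        self.t_ms = t_ms


@dataclass(frozen=True)
class NoiseSpec:
    """Channel-noise settings: amplitude sigma_N (pA), RNG seed, on/off flag."""

    sigma_N: float = 5.0
    seed: int = 0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.sigma_N < 0:
            raise ValueError("sigma_N must be >= 0")


@dataclass(frozen=True)
class ProtocolSegment:
    """One stretch of the protocol with fixed target parameters.

    ``ramp_ms > 0`` ramps all parameters linearly from the previous
    segment's values to this segment's values over the first ``ramp_ms``
    (used for washout); 0 means an instantaneous step.
    """

    duration_ms: float
    params: ModelParameters
    ramp_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("segment duration must be > 0")
        if not 0.0 <= self.ramp_ms <= self.duration_ms:
            raise ValueError("ramp duration must be within the segment")


@dataclass(frozen=True)
class Protocol:
    segments: tuple[ProtocolSegment, ...]
    name: str = "protocol"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")

    @property
    def duration_ms(self) -> float:
        return sum(s.duration_ms for s in self.segments)

    def boundaries_ms(self) -> list[float]:
        """Segment start times."""
        out, t = [], 0.0
        for s in self.segments:
            out.append(t)
            t += s.duration_ms
        return out

    def describe(self) -> dict:
        return {
            "name": self.name,
            "segments": [
                {"duration_ms": s.duration_ms, "ramp_ms": s.ramp_ms,
                 "params": s.params.to_dict()}
                for s in self.segments
            ],
        }


@dataclass
class Trace:
    """Uniformly sampled voltage time series (mV on a ms grid).

    ``voltages[0]`` is the initial condition at t = 0; sample i sits at
    t = i * dt.  ``states`` optionally holds the gating/calcium trajectories.
    """

    voltages: np.ndarray
    dt: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)
    states: dict[str, np.ndarray] | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.voltages)) * self.dt

    @property
    def duration_ms(self) -> float:
        return (len(self.voltages) - 1) * self.dt

    def __len__(self) -> int:
        return len(self.voltages)


def default_initial_state(p: ModelParameters, V: float = -60.0,
                          c: float = 0.1) -> ModelState:
    """Rest-like initial condition: gates at steady state for V, c = 0.1 uM.

    Attractor statistics are insensitive to this choice after the burn-in
    that callers discard (asserted by the test suite).
    """
    return steady_gates(V, c, p)


def run_protocol(protocol: Protocol, dt: float = DEFAULT_DT,
                 noise: NoiseSpec | None = None,
                 initial: ModelState | None = None,
                 record_full: bool = False) -> Trace:
    """Simulate a multi-segment protocol, carrying state across boundaries.

    One seeded generator supplies the noise for the whole trace; segment
    boundaries do not reseed.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    noise = noise if noise is not None else NoiseSpec()
    if initial is None:
        initial = default_initial_state(protocol.segments[0].params)

    rng = np.random.default_rng(noise.seed)
    sigma = noise.sigma_N if noise.enabled else 0.0

    y = initial.as_array()
    n_total = int(round(protocol.duration_ms / dt))
    v_all = np.empty(n_total + 1)
    v_all[0] = y[0]
    full_all = np.empty((n_total + 1, 4)) if record_full else np.empty((0, 4))
    if record_full:
        full_all[0] = y[1:]

    prev_params = protocol.segments[0].params
    pos = 1
    t_done = 0.0
    for seg in protocol.segments:
        n_steps = int(round(seg.duration_ms / dt))
        if n_steps == 0:
            prev_params = seg.params
            continue
        p1 = seg.params.to_array()
        p0 = prev_params.to_array()
        ramp_steps = int(round(seg.ramp_ms / dt)) if seg.ramp_ms > 0 else 0
        scale = sigma / seg.params.C_m * np.sqrt(dt)
        if sigma > 0:
            noise_inc = rng.standard_normal(n_steps) * scale
        else:
            noise_inc = np.zeros(n_steps)
        v_out = v_all[pos:pos + n_steps]
        full_out = full_all[pos:pos + n_steps] if record_full else np.empty((0, 4))
        status = _kernels.euler_maruyama(y, p0, p1, ramp_steps, dt,
                                         noise_inc, v_out, full_out)
        if status >= 0:
            raise IntegrationError(t_done + (status + 1) * dt)
        pos += n_steps
        t_done += n_steps * dt
        prev_params = seg.params

    states = None
    if record_full:
        states = {"n": full_all[:, 0], "bkn": full_all[:, 1],
                  "bkf": full_all[:, 2], "c": full_all[:, 3]}
    return Trace(
        voltages=v_all[:pos],
        dt=dt,
        seed=noise.seed,
        meta={"protocol": protocol.describe(), "sigma_N": sigma, "dt": dt,
              "seed": noise.seed},
        states=states,
    )


def integrate(initial: ModelState | None, p: ModelParameters, t_end: float,
              dt: float = DEFAULT_DT, noise: NoiseSpec | None = None,
              record_full: bool = False) -> Trace:
    """Single-parameter-set simulation for ``t_end`` ms (degenerate protocol)."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    proto = Protocol((ProtocolSegment(t_end, p),), name="constant")
    return run_protocol(proto, dt=dt, noise=noise, initial=initial,
                        record_full=record_full)


def stimulus_protocol(condition: str = "crh_avp", bk_fraction: float = 1.0,
                      basal_ms: float = 100_000.0, stim_ms: float = 100_000.0,
                      washout_ms: float = 0.0, washout_ramp_ms: float = 60_000.0,
                      burnin_ms: float = 30_000.0,
                      base: ModelParameters | None = None) -> Protocol:
    """Basal -> stimulus -> (optional) washout-ramp protocol.

    The burn-in is prepended to the basal segment; analysis code is expected
    to discard the first ``burnin_ms``.  ``bk_fraction`` scales both BK
    conductances in every segment (1 = intact, 0 = knockout).
    """
    p_basal = scale_bk(condition_parameters("basal", base), bk_fraction)
    p_stim = scale_bk(condition_parameters(condition, base), bk_fraction)
    segments = [ProtocolSegment(burnin_ms + basal_ms, p_basal)]
    if stim_ms > 0:
        segments.append(ProtocolSegment(stim_ms, p_stim))
    if washout_ms > 0:
        ramp = min(washout_ramp_ms, washout_ms)
        segments.append(ProtocolSegment(washout_ms, p_basal, ramp_ms=ramp))
    return Protocol(tuple(segments), name=f"{condition}_bk{bk_fraction:g}")
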