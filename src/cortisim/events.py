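"""Spike/burst event analysis of current-clamp voltage traces.

An event runs from the first sample at least 25 mV above the running
baseline until the first subsequent sample less than 5 mV above it; events
shorter than 100 ms are spikes, all others bursts, and the burstiness factor
of a set of events is the fraction that are bursts.  The baseline is a
trailing-window 10th percentile held frozen during events so that slow
secretagogue-induced depolarisations are tracked and all events are measured
relative to the current membrane potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .simulate import Trace

__all__ = [
    "Event",
    "BlockSummary",
    "estimate_baseline",
    "detect_events",
    "classify_event",
    "burstiness_factor",
    "summarise_block",
    "analyse_trace",
    "SPIKE_BURST_CUTOFF_MS",
    "THRESHOLD_DELTA_MV",
    "REARM_DELTA_MV",
]

THRESHOLD_DELTA_MV = 25.0
REARM_DELTA_MV = 5.0
SPIKE_BURST_CUTOFF_MS = 100.0


@dataclass(frozen=True)
class Event:
    """One detected depolarisation event (times in ms, peak in mV)."""

    t_start: float
    t_end: float
    peak: float
    kind: str  # "spike" or "burst"
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("event must have t_end > t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class BlockSummary:
    """Per-interval statistics; duration/BF are None when no events qualify."""

    start_min: float
    end_min: float
    n_events: int
    frequency_hz: float
    mean_duration_ms: float | None
    burstiness: float | None
    baseline_mv: float

    def as_dict(self) -> dict:
        return {
            "start_min": self.start_min,
            "end_min": self.end_min,
            "n_events": self.n_events,
            "frequency_hz": self.frequency_hz,
            "mean_duration_ms": (np.nan if self.mean_duration_ms is None
                                 else self.mean_duration_ms),
            "burstiness": np.nan if self.burstiness is None else self.burstiness,
            "baseline_mv": self.baseline_mv,
        }


def estimate_baseline(trace: Trace, window_ms: float = 2000.0,
                      rearm_delta: float = REARM_DELTA_MV,
                      percentile: float = 10.0,
                      stride_ms: float = 50.0) -> np.ndarray:
    """Per-sample baseline estimate (mV), same length as the trace.

    Causal trailing-window percentile of V, evaluated every ``stride_ms``
    and held between evaluations, then frozen at its pre-crossing value
    while the trace sits >= ``rearm_delta`` above it (see
    :func:`cortisim._kernels.hold_baseline` for the release rule).  Robust
    to spikes/bursts yet tracks minute-scale depolarisation.  The stride is
    purely a numerical economy: the quiescent membrane potential varies on
    second timescales.
    """
    v = np.asarray(trace.voltages, dtype=np.float64)
    if len(v) == 0:
        raise ValueError("empty trace")
    if window_ms <= 0:
        raise ValueError("window must be > 0")
    if window_ms > trace.duration_ms + trace.dt:
        raise ValueError("window longer than the trace")
    w = max(int(round(window_ms / trace.dt)), 1)
    stride = max(int(round(stride_ms / trace.dt)), 1)
    eval_idx = np.arange(0, len(v), stride)
    vals = np.empty(len(eval_idx))
    head = eval_idx < w - 1  # ragged windows at the start of the trace
    for j in np.nonzero(head)[0]:
        vals[j] = np.percentile(v[:eval_idx[j] + 1], percentile)
    tail = np.nonzero(~head)[0]
    if len(tail):
        windows = np.lib.stride_tricks.sliding_window_view(v, w)
        rows = eval_idx[tail] - w + 1
        # chunked so np.percentile's internal copy stays modest
        for k in range(0, len(rows), 1024):
            sel = rows[k:k + 1024]
            vals[tail[k:k + 1024]] = np.percentile(windows[sel], percentile,
                                                   axis=1)
    raw = np.repeat(vals, stride)[:len(v)]
    return _kernels.hold_baseline(v, raw, float(rearm_delta))


def classify_event(duration_ms: float,
                   cutoff_ms: float = SPIKE_BURST_CUTOFF_MS) -> str:
    """'spike' for events shorter than the cutoff, else 'burst'.

    An event of exactly the cutoff duration counts as a burst.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    return "spike" if duration_ms < cutoff_ms else "burst"


def detect_events(trace: Trace, baseline: np.ndarray,
                  threshold_delta: float = THRESHOLD_DELTA_MV,
                  rearm_delta: float = REARM_DELTA_MV,
                  cutoff_ms: float = SPIKE_BURST_CUTOFF_MS) -> list[Event]:
    """Threshold/re-arm scan of a trace against its baseline series.

    Event boundaries are at sample resolution: t_start is the first sample
    at/above baseline + threshold, t_end the first subsequent sample below
    baseline + re-arm.  An event still open at the end of the trace is
    closed there and flagged truncated.
    """
    if threshold_delta <= 0 or rearm_delta <= 0:
        raise ValueError("deltas must be > 0")
    if threshold_delta <= rearm_delta:
        raise ValueError("threshold_delta must exceed rearm_delta")
    v = np.asarray(trace.voltages, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    if baseline.shape != v.shape:
        raise ValueError("baseline series must match the trace length")
    starts, ends, peaks, trunc_last = _kernels.detect(
        v, baseline, float(threshold_delta), float(rearm_delta))
    events = []
    for k in range(len(starts)):
        t0 = starts[k] * trace.dt
        t1 = ends[k] * trace.dt
        truncated = trunc_last and k == len(starts) - 1
        events.append(Event(t_start=t0, t_end=t1, peak=peaks[k],
                            kind=classify_event(t1 - t0, cutoff_ms),
                            truncated=truncated))
    return events


def burstiness_factor(events: list[Event]) -> float | None:
    """Fraction of events that are bursts; None (undefined) for no events."""
    if not events:
        return None
    return sum(e.kind == "burst" for e in events) / len(events)


def summarise_block(trace: Trace, baseline: np.ndarray, events: list[Event],
                    interval_min: tuple[float, float],
                    include_truncated: bool = False) -> BlockSummary:
    """Statistics over events *starting* within a (start, end) minute window.

    Truncated events count toward the frequency but are excluded from the
    mean duration and BF by default (their true duration is unknown).  The
    membrane-potential summary averages the baseline series, not raw V, so
    events do not bias the depolarisation estimate.
    """
    start_min, end_min = interval_min
    t0, t1 = start_min * 60_000.0, end_min * 60_000.0
    if t1 <= t0:
        raise ValueError("interval must have end > start")
    if t0 < 0 or t1 > trace.duration_ms + trace.dt:
        raise ValueError("interval outside the trace")
    in_block = [e for e in events if t0 <= e.t_start < t1]
    freq = len(in_block) / ((t1 - t0) / 1000.0)
    measured = in_block if include_truncated else [e for e in in_block
                                                  if not e.truncated]
    if measured:
        mean_dur = float(np.mean([e.duration for e in measured]))
        bf = burstiness_factor(measured)
    else:
        mean_dur = None
        bf = None
    i0 = int(round(t0 / trace.dt))
    i1 = min(int(round(t1 / trace.dt)), len(trace.voltages))
    base_mv = float(np.mean(baseline[i0:i1]))
    return BlockSummary(start_min=start_min, end_min=end_min,
                        n_events=len(in_block), frequency_hz=freq,
                        mean_duration_ms=mean_dur, burstiness=bf,
                        baseline_mv=base_mv)


def analyse_trace(trace: Trace, blocks: list[tuple[float, float]],
                  threshold_delta: float = THRESHOLD_DELTA_MV,
                  rearm_delta: float = REARM_DELTA_MV,
                  cutoff_ms: float = SPIKE_BURST_CUTOFF_MS,
                  window_ms: float = 2000.0,
                  include_truncated: bool = False):
    """Baseline + detection + per-block summaries in one call.

    Returns (baseline, events, [BlockSummary per block]).
    """
    baseline = estimate_baseline(trace, window_ms=window_ms,
                                 rearm_delta=rearm_delta)
    events = detect_events(trace, baseline, threshold_delta, rearm_delta,
                           cutoff_ms)
    summaries = [summarise_block(trace, baseline, events, blk,
                                 include_truncated=include_truncated)
                 for blk in blocks]
    return baseline, events, summaries
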