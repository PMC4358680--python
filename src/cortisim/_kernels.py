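"""Numba-compiled inner loops: Euler-Maruyama stepping, baseline hold and
event detection.  Pure-Python fallbacks are used when numba is unavailable.

The integration kernel duplicates the model algebra of :mod:`cortisim.model`
for speed; the test suite asserts single-step agreement between the two.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


from .params import PARAM_ORDER

# Parameter-vector indices (layout defined by params.PARAM_ORDER).
_I_GCA = PARAM_ORDER.index("g_Ca")
_I_GNS = PARAM_ORDER.index("g_NS")
_I_GK = PARAM_ORDER.index("g_K")
_I_GKIR = PARAM_ORDER.index("g_Kir")
_I_GBKN = PARAM_ORDER.index("g_BKnear")
_I_GBKF = PARAM_ORDER.index("g_BKfar")
_I_VCA = PARAM_ORDER.index("V_Ca")
_I_VNS = PARAM_ORDER.index("V_NS")
_I_VK = PARAM_ORDER.index("V_K")
_I_VR = PARAM_ORDER.index("v_r")
_I_VM = PARAM_ORDER.index("v_m")
_I_VN = PARAM_ORDER.index("v_n")
_I_SM = PARAM_ORDER.index("s_m")
_I_SN = PARAM_ORDER.index("s_n")
_I_SR = PARAM_ORDER.index("s_r")
_I_TBKN = PARAM_ORDER.index("tau_bkn")
_I_TBKF = PARAM_ORDER.index("tau_bkf")
_I_TN = PARAM_ORDER.index("tau_n")
_I_KCAN = PARAM_ORDER.index("kCa_BKnear")
_I_KCAF = PARAM_ORDER.index("kCa_BKfar")
_I_KBK = PARAM_ORDER.index("k_bk")
_I_VBK0 = PARAM_ORDER.index("V_BK0")
_I_KSH = PARAM_ORDER.index("k_shift")
_I_A = PARAM_ORDER.index("A")
_I_KC = PARAM_ORDER.index("k_c")
_I_F = PARAM_ORDER.index("f")
_I_ALPHA = PARAM_ORDER.index("alpha")
_I_CM = PARAM_ORDER.index("C_m")

_CA_FLOOR = 1e-9


@njit(cache=True)
def euler_maruyama(y, p0, p1, ramp_steps, dt, noise_inc, v_out, full_out):
    """Advance the state over ``len(v_out)`` Euler steps.

    Parameters ramp linearly from ``p0`` to ``p1`` over the first
    ``ramp_steps`` steps (``ramp_steps == 0`` means ``p1`` throughout).
    ``noise_inc`` holds the pre-scaled voltage noise increments
    (sigma_N / C_m) * sqrt(dt) * Z.  ``full_out`` with shape (n, 4) records
    (n, bkn, bkf, c) when non-empty.  Gating variables are clipped to [0, 1]
    and calcium to >= 0 after every step.  Returns -1 on success or the step
    index at which the state became non-finite.
    """
    V = y[0]
    n = y[1]
    bkn = y[2]
    bkf = y[3]
    c = y[4]
    n_steps = v_out.shape[0]
    record = full_out.shape[0] == n_steps
    for i in range(n_steps):
        if ramp_steps > 0 and i < ramp_steps:
            w = i / ramp_steps
        else:
            w = 1.0
        gCa = p0[_I_GCA] + w * (p1[_I_GCA] - p0[_I_GCA])
        gNS = p0[_I_GNS] + w * (p1[_I_GNS] - p0[_I_GNS])
        gK = p0[_I_GK] + w * (p1[_I_GK] - p0[_I_GK])
        gKir = p0[_I_GKIR] + w * (p1[_I_GKIR] - p0[_I_GKIR])
        gBKn = p0[_I_GBKN] + w * (p1[_I_GBKN] - p0[_I_GBKN])
        gBKf = p0[_I_GBKF] + w * (p1[_I_GBKF] - p0[_I_GBKF])
        VCa = p0[_I_VCA] + w * (p1[_I_VCA] - p0[_I_VCA])
        VNS = p0[_I_VNS] + w * (p1[_I_VNS] - p0[_I_VNS])
        VK = p0[_I_VK] + w * (p1[_I_VK] - p0[_I_VK])
        vr = p0[_I_VR] + w * (p1[_I_VR] - p0[_I_VR])
        vm = p0[_I_VM] + w * (p1[_I_VM] - p0[_I_VM])
        vn = p0[_I_VN] + w * (p1[_I_VN] - p0[_I_VN])
        sm = p0[_I_SM] + w * (p1[_I_SM] - p0[_I_SM])
        sn = p0[_I_SN] + w * (p1[_I_SN] - p0[_I_SN])
        sr = p0[_I_SR] + w * (p1[_I_SR] - p0[_I_SR])
        tbkn = p0[_I_TBKN] + w * (p1[_I_TBKN] - p0[_I_TBKN])
        tbkf = p0[_I_TBKF] + w * (p1[_I_TBKF] - p0[_I_TBKF])
        tn = p0[_I_TN] + w * (p1[_I_TN] - p0[_I_TN])
        kcan = p0[_I_KCAN] + w * (p1[_I_KCAN] - p0[_I_KCAN])
        kcaf = p0[_I_KCAF] + w * (p1[_I_KCAF] - p0[_I_KCAF])
        kbk = p0[_I_KBK] + w * (p1[_I_KBK] - p0[_I_KBK])
        vbk0 = p0[_I_VBK0] + w * (p1[_I_VBK0] - p0[_I_VBK0])
        ksh = p0[_I_KSH] + w * (p1[_I_KSH] - p0[_I_KSH])
        A = p0[_I_A] + w * (p1[_I_A] - p0[_I_A])
        kc = p0[_I_KC] + w * (p1[_I_KC] - p0[_I_KC])
        f = p0[_I_F] + w * (p1[_I_F] - p0[_I_F])
        alpha = p0[_I_ALPHA] + w * (p1[_I_ALPHA] - p0[_I_ALPHA])
        Cm = p0[_I_CM] + w * (p1[_I_CM] - p0[_I_CM])

        minf = 1.0 / (1.0 + math.exp((vm - V) / sm))
        ICa = gCa * minf * (V - VCa)
        ninf = 1.0 / (1.0 + math.exp((vn - V) / sn))
        rinf = 1.0 / (1.0 + math.exp((vr - V) / sr))
        IKdr = gK * n * (V - VK)
        IKir = gKir * rinf * (V - VK)
        INS = gNS * (V - VNS)
        IBKn = gBKn * bkn * (V - VK)
        IBKf = gBKf * bkf * (V - VK)

        cdom = -A * ICa
        if cdom < _CA_FLOOR:
            cdom = _CA_FLOOR
        vhn = vbk0 - ksh * math.log(cdom / kcan)
        bkninf = 1.0 / (1.0 + math.exp(-(V - vhn) / kbk))
        cc = c if c > _CA_FLOOR else _CA_FLOOR
        vhf = vbk0 - ksh * math.log(cc / kcaf)
        bkfinf = 1.0 / (1.0 + math.exp(-(V - vhf) / kbk))

        V = V - (ICa + IKdr + IBKn + IBKf + IKir + INS) / Cm * dt + noise_inc[i]
        n = n + (ninf - n) / tn * dt
        bkn = bkn + (bkninf - bkn) / tbkn * dt
        bkf = bkf + (bkfinf - bkf) / tbkf * dt
        c = c - f * (alpha * ICa + kc * c) * dt

        if n < 0.0:
            n = 0.0
        elif n > 1.0:
            n = 1.0
        if bkn < 0.0:
            bkn = 0.0
        elif bkn > 1.0:
            bkn = 1.0
        if bkf < 0.0:
            bkf = 0.0
        elif bkf > 1.0:
            bkf = 1.0
        if c < 0.0:
            c = 0.0

        v_out[i] = V
        if record:
            full_out[i, 0] = n
            full_out[i, 1] = bkn
            full_out[i, 2] = bkf
            full_out[i, 3] = c
        if not math.isfinite(V):
            return i

    y[0] = V
    y[1] = n
    y[2] = bkn
    y[3] = bkf
    y[4] = c
    return -1


@njit(cache=True)
def hold_baseline(v, raw, rearm):
    """Freeze the baseline at its pre-excursion value during depolarised
    excursions (V at least ``rearm`` above baseline).

    The hold releases when V falls back below frozen + rearm, or when the
    raw trailing-percentile estimate itself catches up to within ``rearm``
    of V (so sustained sub-threshold depolarisations are tracked rather than
    held forever).
    """
    out = np.empty_like(raw)
    out[0] = raw[0]
    held = False
    frozen = raw[0]
    for i in range(1, v.shape[0]):
        if held:
            if v[i] < frozen + rearm or v[i] < raw[i] + rearm:
                held = False
                out[i] = raw[i]
            else:
                out[i] = frozen
        else:
            if v[i] >= out[i - 1] + rearm:
                held = True
                frozen = out[i - 1]
                out[i] = frozen
            else:
                out[i] = raw[i]
    return out


@njit(cache=True)
def detect(v, base, threshold, rearm):
    """Threshold / re-arm event scan.

    Opens an event at the first sample with V >= baseline + threshold and
    closes it at the first subsequent sample with V < baseline + rearm.
    Returns (start_idx, end_idx, peak_V, truncated_last) where an event
    still open at the end of the trace is closed there and flagged.
    """
    nmax = v.shape[0] // 2 + 1
    starts = np.empty(nmax, np.int64)
    ends = np.empty(nmax, np.int64)
    peaks = np.empty(nmax, np.float64)
    count = 0
    in_event = False
    peak = -1e300
    s = 0
    for i in range(v.shape[0]):
        if not in_event:
            if v[i] >= base[i] + threshold:
                in_event = True
                s = i
                peak = v[i]
        else:
            if v[i] < base[i] + rearm:
                starts[count] = s
                ends[count] = i
                peaks[count] = peak
                count += 1
                in_event = False
            elif v[i] > peak:
                peak = v[i]
    truncated = False
    if in_event:
        starts[count] = s
        ends[count] = v.shape[0]
        peaks[count] = peak
        count += 1
        truncated = True
    return starts[:count], ends[:count], peaks[:count], truncated
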