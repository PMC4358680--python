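# Methods

## Model

The simulator integrates a six-current conductance-based model of a
corticotroph cell:

    C_m dV/dt = −(I_Ca + I_K-dr + I_BK-near + I_BK-far + I_K-ir + I_NS + I_noise)

* `I_Ca = g_Ca · m∞(V) · (V − V_Ca)` — high-voltage-activated L-type Ca²⁺
  current, instantaneous activation; the main depolarising current during
  an event.
* `I_K-dr = g_K · n · (V − V_K)` — delayed rectifier,
  `dn/dt = (n∞(V) − n)/τ_n`; drives the spike downstroke.
* `I_K-ir = g_Kir · r∞(V) · (V − V_K)` — inward rectifier with a steep
  negative activation slope (`s_r = −1`), open only when hyperpolarised.
* `I_NS = g_NS · (V − V_NS)` — ohmic non-selective cation current; sets the
  resting potential close to spike threshold.
* Two BK populations, `I_BK = g_BK · bk · (V − V_K)` with
  `dbk/dt = (bk∞ − bk)/τ_bk` and a calcium-dependent half-activation
  voltage `V_half(ca) = V_BK0 − k_shift·ln(ca/kCa)`.  BK-near senses the
  microdomain calcium at open Ca²⁺ channels, modelled algebraically as
  `c_dom = −A·I_Ca(V)`; BK-far senses the bulk cytosolic concentration
  `c`, with `dc/dt = −f(α·I_Ca + k_c·c)`.
* `I_noise = σ_N ω`, a Wiener current representing channel noise.

All gating steady states are Boltzmann curves `1/(1+exp((v_x−V)/s_x))`.
Units are mutually consistent (mV, ms, nS, pA, pF, μM): nS·mV = pA and
pA/pF = mV/ms, so no hidden conversion factors exist anywhere.

### Parameters

Defaults (the `basal` condition) are the reference parameter set of the
corticotroph model; `condition_parameters` exposes the secretagogue
variants:

| change | CRH | AVP |
|---|---|---|
| g_Ca (nS) | 1.8 → 2.2 | — |
| g_NS (nS) | — | 0.1 → 0.2 |
| τ_bkn (ms) | 20 → 4 | — |
| kCa_BKnear (μM) | 18 → 6 | — |

`crh_avp` is the union of both columns, and `gca_only` isolates the g_Ca
change for the conductance dissection.  `scale_bk(p, fraction)` multiplies
both BK conductances (1 = intact, 0.15 = residual conductance, 0 =
knockout/paxilline).  Two readings of the reference parameter set deserve note:

* the calcium pump rate is printed with a concentration unit; dimensional
  consistency of `dc/dt` forces k_c = 0.12 ms⁻¹, which is what we
  implement;
* the accompanying prose describes the CRH effect on BK-near as a "right-shift" of its
  activation curve, but the printed V_half(ca) formula gives a *left*
  shift at fixed calcium when kCa decreases.  We follow the formula; the
  operational effect (faster, more easily activated BK-near that clamps
  spike amplitude) is what produces the modelled CRH response, and the
  implementation reproduces the model's two headline quantities
  (the ~20 mV amplitude drop and ~20 mV baseline rise).

Parameter sets serialise to flat YAML with ASCII key names
(`src/cortisim/data/default_parameters.yaml` reproduces the defaults).

### Integration

Explicit Euler–Maruyama with dt = 0.1 ms (the scheme the model was built around): the
deterministic increment `rhs·dt` plus a voltage-noise increment
`(σ_N/C_m)·√dt·Z`, `Z ~ N(0,1)` drawn from one seeded generator per trace
(`numpy.random.default_rng`; segment boundaries do not reseed).  Gating
variables are clipped to [0, 1] and calcium to ≥ 0 after every step, since
explicit Euler can overshoot at spike peaks.  Calcium concentrations are
floored at 10⁻⁹ μM before logarithms (the BK half-activation shift is
undefined at zero calcium); the floor is six orders of magnitude below
physiological values and never binds during normal dynamics.  A trace is
bit-reproducible from (seed, dt, protocol).  Non-finite state aborts with
the failure time.

Protocols are ordered segments, each with target parameters and either a
step transition or a linear ramp from the previous segment's values (used
for washout, default ramp 60 s — washout recovery in corticotroph recordings is gradual over
tens of seconds).  Initial conditions default to V = −60 mV,
gates at steady state, c = 0.1 μM; experiments discard a 30 s burn-in
before analysis, after which block statistics are insensitive to the
initial state (asserted by test).  The per-step loop is numba-compiled,
with a pure-Python fallback; the test suite pins the kernel to the
reference right-hand side step by step, and the deterministic dynamics
were cross-checked against an adaptive BDF/Adams integration of the same
equations during development.

## Event analysis

* **Baseline.** Causal trailing-window 10th percentile of V (window
  2000 ms), frozen at its pre-crossing value while V sits ≥ 5 mV (the
  re-arm delta) above it.  The hold releases either when V falls back
  below frozen + 5 mV or when the raw percentile itself catches up to
  within 5 mV of V; without the second release a sustained sub-threshold
  depolarisation (which must be *tracked*) would freeze the baseline
  forever.  The percentile is evaluated every 50 ms and held between
  evaluations — a pure numerical economy, since the quiescent potential
  varies on second timescales.
* **Detection.** A state machine opens an event at the first sample
  ≥ baseline + 25 mV and closes it at the first subsequent sample
  < baseline + 5 mV, at sample resolution (no interpolation).  Events
  cannot overlap; an event still open at the trace end is closed there and
  flagged truncated.
* **Classification.** Events shorter than 100 ms are spikes, all others
  bursts; exactly 100 ms counts as a burst (the <100 ms / >100 ms rule leaves
  the boundary unassigned).  The burstiness factor is the fraction of events
  that are bursts, reported as undefined — never zero — when there are no
  events.
* **Blocks.** Per-interval summaries count events by start time; truncated
  events count toward frequency but are excluded from mean duration and BF
  by default (their true duration is unknown).  The membrane-potential
  summary averages the baseline series, not raw V, so events do not bias
  the depolarisation estimate.  BF is computed per trace (per cell), not
  pooled.

### A knife edge worth knowing about

In this model the stimulated (CRH/AVP) state is a nearly continuous
~30 Hz oscillation whose troughs (≈ −47 mV at dt = 0.1 ms) lie close to
baseline + re-arm for any baseline that tracks the depolarisation.  Event
segmentation of that activity is therefore sensitive to the baseline
convention and to integration step: the 10th-percentile baseline yields
many short events (mean ≈ 35 ms) where a visual reading of the same trace
would report long bursts, and halving dt shifts trough depth by a few mV,
which measurably changes stimulated-block statistics.  The amplitude and
baseline *shifts* (the headline quantities) are robust to all of this; the
stimulated-block duration/BF statistics are not, and the corresponding
acceptance tests document the failure rather than hide it.  Basal-block
statistics are step-size robust.

## Synthetic ground truth

`cortisim.synthetic` generates traces with known event structure so the
analysis pipeline is testable in a closed loop: a baseline floor
(−55 mV default) with optional linear drift, triangular spikes (60 mV
amplitude, 2 ms rise), pseudo-plateau bursts (a 30 mV plateau with 7 mV /
10 Hz sinusoidal ripple and step edges), and additive white Gaussian
noise.  Ground-truth boundaries are reported in detector semantics — the
noise-free waveform's threshold/re-arm crossing times, computed in closed
form — so exact-recovery tests compare like with like.  The generator
validates that scheduled waveforms are actually detectable (spike
amplitude above threshold, burst ripple above re-arm).

What it does *not* emulate: biophysical spike shapes, afterhyperpolarisa-
tions, 1/f or seal noise, electrode drift other than a linear term.  A
green recovery test therefore establishes the detector's contract
(threshold/re-arm semantics, classification, boundary accuracy), not
performance on arbitrary recordings.

`generate_cell_population` samples per-cell block summaries (lognormal
frequency and duration, normal membrane potential, clipped-normal BF)
around the scale observed in unstimulated corticotrophs, with stimulus
effects applied as known ratios/shifts — used to exercise aggregation and
summary I/O against known population parameters.

## Experiments

`ExperimentSpec` + `run_experiment` orchestrate simulate → analyse →
summarise over n seeds (default 5; per-seed streams derived from one base
seed via `SeedSequence`), emitting per-seed block rows and across-seed
mean ± SEM (SEM undefined for a single seed).  Default segment lengths are
the 100 s windows of the modelling figures; the 20 min experimental
template (7 min basal, 3 min stimulus, 10 min washout) is available by
setting the durations.  `compare_conditions` tabulates stimulated-minus-
basal contrasts across conditions.  The `cortisim` CLI wraps these
(`simulate`, `analyze`, `run`) with TSV/CSV/JSONL outputs.

## Known limitations

* BK-far is effectively silent at the published parameter values: bulk
  calcium equilibrates near α·|I_Ca|/k_c ≈ 0.5 μM, an order of magnitude
  below kCa_BKfar, so its activation stays ≈ 0 throughout.  Burst
  termination in this implementation is noise- and delayed-rectifier-
  driven.
* The stimulated-state event statistics inherit the segmentation knife
  edge described above; treat stimulated mean duration and BF as
  convention-dependent quantities and prefer the amplitude/baseline
  shifts when comparing conditions.
* No spatial calcium, ER stores, or explicit PKA/PKC kinetics; secretagogue
  action is an instantaneous (or ramped) parameter switch.
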