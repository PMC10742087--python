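# Methods

## Signal model and spectral estimation

The input is a uniformly sampled 3-axis accelerometer series (m/s²). Any
uniform rate ≥ 25 Hz is accepted; the simulator and all defaults use 50 Hz,
which covers the physiological tremor band with ample margin. Irregular
streams are rejected rather than resampled — resampling would silently
alter the very frequencies being measured.

Axes are reduced to one scalar series before analysis. The default is the
per-sample Euclidean magnitude with the series mean subtracted: it is
independent of device orientation and removes the constant gravity offset.
One caveat follows from the geometry: an oscillation exactly perpendicular
to gravity enters the magnitude only through a second-order term and then
appears at twice its frequency. Wrist flexion-extension with the device
strapped to the wrist always modulates the gravity-aligned component, so in
the intended use the dominant magnitude component is at the movement
frequency; for pathological orientations the `dominant_axis` reduction
(the single mean-subtracted axis of greatest variance) is available.

The dominant frequency is the in-band argmax of a Hann-tapered power
spectrum. The FFT is zero-padded so the frequency grid is at least as fine
as 0.1 Hz — a 0.1 Hz error in f₀ perturbs the cue frequencies by at most
0.07 Hz, well inside the gauge's goal range. The search band defaults to
1–12 Hz, bracketing the 3–10 Hz range typical of functional tremor. Ties
in the argmax resolve to the lowest frequency (deterministic). A peak is
*significant* when its power is at least 5× the median in-band power; the
median of a flat noise spectrum is a scale-free noise floor, so pure noise
fails the criterion (verified over 100 seeds) while even a heavily
noise-contaminated oscillation passes it. Non-significant estimates are
reported but flagged, never silently used.

The baseline stage averages a Welch periodogram (Hann sub-windows of 40% of
the 10-second baseline period, 50% overlap, same zero-padding and
prominence rule) rather than taking one long periodogram: averaging is
robust to brief dropouts within the baseline window and still yields a
single defined peak. When the baseline is not significant the protocol
substitutes `f_default` = 4.5 Hz, chosen so that both derived cue
frequencies (3.0 and 1.5 Hz) sit strictly inside the default clamps.

Continuous tracking applies the same estimator in 3-second windows advanced
by 0.5 s: three full cycles at the 1 Hz band floor, while responsive enough
for a live gauge. Windows without a significant peak are NaN in the trace
and shown pegged low on the gauge, so absence of movement stays visible.

## Session protocol

Per session: baseline measurement over the first 10 s, then cues at
⅔·f₀ for the first half of the *treatment* time (total minus baseline) and
⅓·f₀ for the second half. The halves split the post-baseline time equally —
cues cannot precede the baseline estimate, so the baseline period is
excluded from the halves. Phase boundaries are half-open intervals
[start, end); elapsed time is measured from the first sample. Day 1 lasts
3600 s, days 2–7 last 1800 s.

Cue frequencies are clamped to [f_min, f_max], default 1–5 Hz: the floor
keeps cues usable when the computed frequency collapses (or no tremor is
present), the ceiling caps sustained voluntary wrist oscillation at a
tolerable rate. Both clamps are configuration, not physiology, and can be
widened freely.

Cue timestamps start exactly at each phase boundary and advance by the
reciprocal of the phase frequency; the count per phase is
⌊duration × frequency⌋ ± 1. Audio rendering is out of scope — the schedule
is the contract.

A recording shorter than the scheduled session is truncated, never
extrapolated; completion is min(recording duration, scheduled duration)
with a one-sample-period tolerance before a session is marked
`ended_early` (recording durations are quantized to whole samples, and
timestamps in the text format are rounded to nanoseconds).

## Biofeedback gauge

needle = clip((measured − goal) / (0.5 · goal), −1, +1). Normalizing the
error by the goal makes the gauge equally sensitive at a 1.5 Hz and a 4 Hz
goal; full deflection at ±50% relative error is a declared default, not an
inferred one. The needle is exactly zero at the goal for any goal, so the
goal range is always centered. The goal range is ±10% of the goal —
roughly one tracker bin at default settings.

## Simulator

`simulate_tremor` synthesizes s(t) = A·sin(2π∫f dτ + φ₀) +
h·A·sin(4π∫f dτ + 2φ₀) with f(t) = f_tremor + drift·t/60, distributes it
over axes by a unit weight vector, adds 9.81 m/s² on one axis and i.i.d.
Gaussian noise per axis. Gravity is included precisely so the magnitude
reduction's mean subtraction is genuinely exercised. Defaults: amplitude
1 m/s², noise sd 0.1 m/s² (robustness tests use 0.5, half the amplitude),
no harmonic, no drift, equal axis weights, 50 Hz.

`simulate_entrained_subject` models cue-following with the simplest
mechanism exhibiting both an "entrains" and a "fails to entrain" regime:
the instantaneous movement frequency relaxes first-order (time constant
`tracking_lag`, default 1 s, implemented as an exact-step IIR recursion)
toward r·f_cue + (1−r)·f_tremor, where responsiveness r ∈ [0, 1] is a
convex-combination weight. Frequency jitter is Gaussian, low-pass filtered
at 0.5 Hz so each 3-s tracker window remains quasi-stationary, and rescaled
to the requested sd. Everything is reproducible from the scenario seed.

What the simulator does **not** emulate: biomechanical wrist dynamics,
amplitude variation of real tremor, intermittent tremor, sensor dropouts,
or a subject whose responsiveness changes within a session. Passing tests
therefore demonstrate correctness of the estimation and protocol machinery
under the stated signal model, not clinical performance on patient data.

## Logs and adherence

Session logs are append-only JSON-lines with a required schema version;
round-tripping is exact and malformed lines are reported by number. One
session per protocol day is enforced. Adherence is duration-weighted —
completed seconds over scheduled seconds — per day, pooled over the at-home
days 2–7, and overall; a day without an entry counts its full scheduled
duration against adherence. (A count-of-sessions rule was rejected: partial
completions are the interesting signal and a per-session count cannot
express them.)

## Numerical choices and edge cases

* Sample-rate inference from files uses the total time span over the
  sample count, averaging out per-line rounding; spacing must be uniform
  within 1 μs.
* Text round-trips are exact to 1e-9 (nine decimal places written).
* Problem sizes in the test suite and acceptance script: 10–12 s
  recordings for estimator checks, full 1800 s day-2 sessions for the
  end-to-end checks, 100 seeds for the stochastic rates, series ≤ 512
  samples for brute-force DFT cross-checks. The whole suite runs in well
  under a minute.
* Open design points were resolved as follows: the axis-combination rule
  of the original deployed software is unknown, so both reductions are
  offered with `magnitude` as the default and neither asserted as the
  original behavior; no cues are emitted during the baseline period (the
  cue frequency does not exist yet); a restarted session is a new session,
  and duplicate log entries for a day are rejected; the gauge's scale
  endpoints and goal-range width are declared defaults, not inferred ones.
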