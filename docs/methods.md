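# Methods

## Model and estimation procedure

The respiratory system is treated as a single compartment obeying the
equation of motion `P_aw = R_rs·Q + E·V + P_pl`, with the pleural pressure
split into a constant chest-wall part and a breath-specific demand part.
Both pleural terms act on the same inspired volume, so they are folded into
elastance: `P_aw = R_rs·Q + (E_lung + E_chest + E_demand(t))·V`, and the lump
`E_drs(t) = E_lung + E_chest + E_demand(t)` is the estimand.  `E_demand` is a
construct, not a physical elastance: it is negative exactly when the patient
pulls volume in through negative pleural pressure, which is why `E_drs < 0`
at the start of a patient-triggered breath and why the early trajectory
reflects inspiratory demand.

Per breath the estimator computes

```
E_drs(t_k) = (P_aw(t_k) − PEEP − R_rs·Q(t_k)) / V(t_k)
```

over the inspiratory limb only.  Steps and conventions:

* **Segmentation.** Inspiration onset is the sample at which flow crosses
  zero before rising through the trigger threshold `q_on` (0.05 L/s) and
  staying above `−q_on/2` for at least `t_min` (0.2 s); end-inspiration is
  the first subsequent negative-flow sample; candidates shorter than
  `t_min` are discarded.  Backtracking the onset to the zero crossing makes
  the volume integral start where flow actually starts; detected onsets
  match the simulator's effort onsets to within one sample.  The
  noise allowance (`−q_on/2`) makes the breath count invariant to zero-mean
  flow noise of amplitude below `q_on/2`.
* **Volume.** Cumulative trapezoidal integral of flow, reset to zero at each
  onset so cross-breath sensor drift cannot contaminate the denominator.
* **Offset pressure.** PEEP is estimated per breath as the median airway
  pressure over the 0.05 s before onset (median for robustness to brief
  artefacts; falls back to the onset sample at a session start).
* **Resistance.** `R_rs` is fixed at 5 cmH2O·s/L.  Per-sample resistance is
  unidentifiable alongside a time-varying elastance, and a shared constant
  keeps within-patient mode comparisons meaningful; the monotone effect of
  the assumption (higher assumed `R_rs` shifts `E_drs` down wherever flow is
  positive) is an asserted property of the implementation.
* **Low-volume mask.** The ratio is undefined at onset (`V → 0`).  Samples
  with `V < v_min_frac × tidal volume` (`v_min_frac = 0.02`) are masked
  invalid rather than clipped, preserving the genuine negative early
  `E_drs` while discarding meaningless ratios.  The invalid region is a
  prefix of the breath because volume is non-decreasing during inspiration.
* **Normalisation.** Each breath's trace is interpolated linearly onto a
  uniform 100-point grid over normalised inspiratory time `tau ∈ [0, 1]`
  (0–100% of inspiration).  Grid points earlier than the first valid sample
  stay invalid; interpolation is exact at sample positions that land on
  grid nodes, so constants and linear ramps are preserved exactly and two
  breaths sampled from the same function of `t/Ti` normalise identically.

## Summary metrics

Percentiles (5/25/50/75/95 by default) are taken **pointwise across
breaths** at each grid point, using the linear-interpolation empirical
quantile; a grid point needs at least two contributing breaths to be valid.
Pointwise construction is what guarantees smooth per-level curves spanning
the whole axis (ranking whole breaths by a scalar would not).

`AUC E_drs` integrates a curve's linear interpolant over
`tau ∈ [0.3, 1.0]`, with the normalised axis carrying nominal units of
seconds, so a constant elastance `E` gives `0.7·E` cmH2O·s/L.  The window
endpoints are interpolated explicitly, making the quadrature exact for
piecewise-linear curves (closed forms hold to 1e-9).  The window is read as
a *fraction* interval of normalised inspiration: the first 30% is dominated
by the masked low-volume region and the effort transient, and a fraction is
the only reading that is comparable across breaths of different real
duration.  An AUC at or above 25 cmH2O·s/L (boundary inclusive) flags
ARDS-like respiratory-system stiffness.

## Mode comparison

The unit of comparison is one scalar per breath: the median elastance over
the AUC window, evaluated on a 71-point uniform grid spanning the window
(odd count, so the median of a linear ramp is its midpoint).  Pooling raw
samples instead would pseudo-replicate the within-breath correlation.  The
two modes' breath summaries are compared with a two-sample
Kolmogorov–Smirnov test — the primary significance criterion at
alpha = 0.05 — and a two-sample Wilcoxon rank-sum test reported alongside.
The rank-sum (unpaired) form is used because breaths are not paired across
modes.  KS p-values are asymptotic when both modes have ≥ 50 breaths and
exact below that: the exact two-sample distribution is discrete and
measurably conservative at moderate n (type-I ≈ 0.036 at nominal 0.05 for
n = m = 100), while the asymptotic value is well calibrated there
(≈ 0.055, verified by Monte-Carlo on iid samples).  No multiple-testing
correction is applied across patients; results are reported per patient.
Variability is compared as the median (over valid grid points) width of the
5th–95th percentile band.

## Synthetic data generator

The simulator integrates the same single-compartment model forward with a
pressure-source effort term: `R_rs·Q + (E_lung+E_chest)·V + P_mus = P_aw − PEEP`,
`P_mus(t) = −A·sin(pi·t/T_n)` over the neural inspiratory time `T_n`
(non-positive half-sine; `E_demand = P_mus/V` by construction).  Defaults
describe a partially assisted adult: `E_lung+E_chest = 30 cmH2O/L`,
`R_rs = 5`, PEEP 5 cmH2O, support 10 cmH2O, effort 6 cmH2O peak over 0.8 s,
15 breaths/min, 100 Hz sampling, measurement noise 0.15 cmH2O / 0.01 L/s.

Controllers: **PS** raises pressure toward PEEP + support with an 80 ms
exponential rise once effort drives flow through 0.05 L/s (machine-triggered
immediately for a passive patient), holds it for a fixed machine inspiratory
time, then releases; **NAVA** delivers `gain·Eadi(t)` continuously, with
Eadi proportional to the neural drive and the gain matched so the mean
breath peaks at the PS support level.

Breath-to-breath variability is lognormal in three physiological quantities:
neural amplitude (CV 0.25), neural timing (CV 0.12) and neuromechanical
coupling — the ratio of mechanical to neural amplitude (CV 0.2).  Two
choices here are deliberate and worth stating.  First, pure amplitude
variability cannot widen NAVA elastance bands at all: when assist is
proportional to the same amplitude as the effort, volume scales linearly
and `P_mus/V` is amplitude-invariant, so the observed NAVA variability must
enter through timing and coupling, which modulate proportional assist but
not a fixed square support.  Second, under PS all drive CVs are damped by
an entrainment factor 0.5, reflecting the clinical observation that steady
identical support regularises breathing while effort-tracking assist
preserves natural variability.  With these mechanisms the simulated cohort
reproduces the expected contrasts — lower and more variable `E_drs` under
NAVA — as emergent behaviour.

Integration uses an implicit trapezoidal update on the emitted sampling
grid, the same quadrature the estimator applies when re-integrating flow,
so the generative identity `(P_aw−PEEP−R·Q)/V = E_drs(t)` holds at every
emitted sample to float rounding.  Setting `n_substeps > 1` integrates on a
finer internal grid instead, making the truth a near-continuous reference
against which the estimator's quadrature error is visible and shrinks with
the sampling interval (measured ≈ 65× when dt drops from 0.01 to 0.001 s).
Noise is added to the emitted pressure/flow only; the truth stays clean.
Everything is driven by one seed and is bit-reproducible.

What the generator does *not* emulate: nonlinear (volume- or
pressure-dependent) elastance and recruitment dynamics, leaks, expiratory
muscle activity, patient–ventilator asynchrony beyond trigger delay, cardiac
oscillations, and real Eadi noise.  Passing tests therefore demonstrate
correctness of the estimation machinery under the stated model, not
robustness to every artefact of bedside data.

## Numerical choices and edge cases

* Quadratures: trapezoid everywhere (volume, AUC), second-order and
  shape-preserving; AUC inserts the window endpoints explicitly.
* Interpolation is linear; at coincident abscissae the later sample wins
  (numpy convention).
* Degenerate breaths (no usable volume, or fewer than two valid samples)
  raise typed errors; the session-level driver skips them with a logged
  count rather than failing the session.
* Waveform CSVs are written with 17 significant digits and parsed in
  round-trip float mode, so write/read is bit exact; the reader validates
  grid uniformity to 1e-9 s and rejects rather than resamples.
* Problem sizes in the test-suite and acceptance script (10–100 breaths per
  session, 1000 Monte-Carlo replicates, 20-patient cohort) were chosen as
  the smallest sizes at which the corresponding statistical statements are
  stable.

## Known limitations

* `R_rs` is assumed, not estimated; absolute `E_drs` levels inherit that
  assumption (trends and within-patient comparisons do not).
* PEEP removal uses a pre-onset median; intrinsic PEEP (incomplete
  expiration) would bias the baseline.
* The elastance decomposition (`E_lung`, `E_chest`, `E_demand`) is not
  identifiable from airway data; it exists only as simulator ground truth.
* Expiratory mechanics are out of scope: expiration only delimits breaths.
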