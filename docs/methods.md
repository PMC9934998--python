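# Methods

## The measurement model

All times are in milliseconds from the start of the recording; the default
sampling rate is 1 kHz, so one sample is 1 ms and fiducial tolerances are
expressible in samples.  A recording holds one surface ECG lead, ten LV
unipolar electrograms (a duo-decapolar catheter; electrodes numbered 1
distal to 10 proximal) and one RV monophasic action potential, plus the
pacing-spike (or beat-reference) times.

### Fiducial definitions

* **AT** (LV activation time): time of the minimum dV/dt of the electrogram
  within a 160 ms window after the pacing spike, minus the spike time.
  The derivative is a centered finite difference of a 5 ms moving-average
  smoothed trace; ties break to the earliest time; a parabolic vertex fit
  refines the extremum below one sample.
* **ARI** (activation-recovery interval): the Wyatt convention — time of the
  maximum dV/dt inside the T-wave window (end of the QRS window to the next
  beat minus 50 ms) minus the activation time, for either T polarity.  The
  T upslope is found in two stages: a 25 ms-smoothed derivative locates the
  neighbourhood robustly, then the 5 ms-smoothed derivative places the
  extremum within ±5 ms of it.  The two-stage search keeps the noise-free
  error ≤ 0.1 ms while preventing the argmax from wandering across the long
  T window when broadband noise is present.
* **RV AT / MAPD80**: steepest MAP upstroke after the spike; duration to
  the first sustained crossing of baseline + 0.2 × amplitude, with
  baseline = median diastolic level before the upstroke.  The upstroke
  comes from the smoothed derivative (plateaus produced by step-like edges
  resolve to their centre); the threshold crossing is interpolated on the
  *raw* trace — smoothing a step edge would bias the analytic square-pulse
  case by more than a sample.  Fractional thresholds make MAPD invariant
  to amplitude scaling.
* **Surface ECG**: beats are R peaks above 35% of the global maximum with a
  180 ms refractory; QRS bounds and T end are sustained threshold crossings
  (1% and 0.5% of the local amplitude, noise-floored) with linear
  interpolation; the T peak is the largest excursion between QRS end and
  the next onset.  A beat is ectopic when its template correlation,
  QRS width, or polarity deviates, or when both adjacent cycles deviate
  > 25% from the dominant cycle.
* **Intervals** are arithmetic means over five consecutive clean beats —
  the latest artefact-free stretch of the phase; QTc is Van der Water
  (`QT − 0.087 (RR − 1000)`), JTc = QTc − QRS (the only definition
  consistent with the reported symbols).  PP comes from P peaks detected
  with QRS-T regions masked; with dissociated atria, P waves hidden under
  the QRS-T leave gaps, so the atrial cycle is estimated as the fundamental
  of the visible P-peak differences.

### Statistics

* **STV** = Σ|D(n+1) − D(n)| / (N √2).  The default reads "30 consecutive
  beats" as 30 successive differences (31 beats), so every summand matches
  the N = 30 divisor; `mode="literal"` keeps the alternative reading
  (30 beats, 29 differences, same divisor).  For iid Normal(0, σ²)
  perturbations E[STV] = σ √(2/π); this calibration is verified by
  Monte-Carlo in the tests.  LV STV is computed on the
  mean-across-electrodes ARI series, RV STV on the MAPD series.
* **ΔMAPD** = mean LV ARI − RV MAPD, **ΔAT** = LV_AT − RV_AT, with LV
  means over electrodes 2–9 (1 and 10 excluded for P-wave interference in
  the real preparation; the count of electrodes used is reported).
* **AT–ARI slope**: ordinary least squares of per-electrode ARI on AT
  (scipy's linregress; verified against the normal equations to 1e-9).
  When both phases of a recording are measured the slope is re-fitted on
  the intersection of electrodes valid in both, so baseline and dofetilide
  slopes are comparable.
* **Measurement windows**: baseline = the last clean (non-ectopic) stretch
  before infusion start; dofetilide = the clean stretch inside
  (start, start + ramp], truncated at the first ectopic beat — i.e.
  measurements are taken before the first ectopic beat or at the end of
  the 5-min infusion ramp.

### Arrhythmia quantification

Maximal runs of consecutive ectopic beats form events.  TdP = ≥ 5 beats
AND polymorphism index ≥ 0.3, where the index combines (by maximum) the
fraction of within-run beat pairs with opposite dominant QRS polarity and
the depth of the amplitude-envelope modulation; the generator's
monomorphic runs score ≈ 0 and its polymorphic runs ≥ 0.5, so the 0.3
threshold separates them with margin.  Inducibility counts TdP whose
*start* lies in the half-open window (t0, t0 + 600 s] after infusion
start — start-time membership avoids double counting events that span the
boundary.  Episode score = n + 1 (n = ectopic beats), overridden — not
added to — by 50/75/100 points for 1/2/≥ 3 defibrillations, which keeps
scores bounded and ordinal; the final score averages the three most severe
episodes in the window (fewer if fewer occurred, 0 — configurable to 1 —
if none).

### Strain

The LV short-axis is divided into six segments; the septal and free walls
are the pointwise means of their two adjoining segments and the two
intermediate segments are discarded.  PS is the (sub-sample refined)
maximum of the wall trace; TTP its time from the beat reference; onset is
operationalized as the first sustained (≥ 20 ms) crossing of 10% of PS —
the paper-style onset has no published definition, and a fractional
threshold is amplitude-invariant.  Deltas are free wall − septum.  On a
plateau the earlier maximum wins and no sub-sample refinement is applied.

## The synthetic generator

The generator's contract is fiducial placement, not morphology realism:

* EGM depolarization is a biphasic (Gaussian-derivative) wavelet whose
  steepest negative slope falls exactly at beat + AT_k; the T wave is a
  Gaussian whose maximum dV/dt falls exactly at beat + AT_k + ARI, for
  either programmed T polarity.
* True ARI per electrode and beat is
  `ari_base + slope · (AT_k − mean AT) + ε_beat`, ε iid Normal(0, σ²)
  shared across electrodes (a common beat-level repolarization
  perturbation).  After dofetilide start the ARI gains
  `gain · (1 + gw · earliness_k)`, ramped linearly over the 5-min infusion
  and then held — matching the protocol of measuring 5 min after start —
  where earliness is the rank-normalized activation order centred on zero
  (earliest +0.5).  With evenly spaced ATs this steepens the AT–ARI slope
  by exactly −gain · gw / spread, which the group presets invert to hit a
  target post-infusion slope.
* The MAP is a tanh upstroke (steepest slope at beat + RV AT) with a
  cosine phase-3 whose 20%-of-amplitude crossing falls exactly MAPD later.
* The ECG uses half-sine QRS and P lobes and a two-quarter-sine T wave:
  these land with non-zero slope, so threshold-based onset/offset/T-end
  detection recovers the programmed values within ~0.5 ms (a raised-cosine
  landing would bias them by several ms).
* Ectopic runs suspend the regular rhythm and resume on the original grid
  ≥ 0.85 cycles after the run; polymorphic runs rotate QRS polarity and
  amplitude with period 4 (the detectable "twisting" surrogate),
  monomorphic runs do not.  Scripted defibrillation counts travel with the
  ground-truth event log.
* Strain pulses are Gaussian bumps whose peak is the programmed PS at the
  programmed TTP and whose 10%-of-peak crossing falls exactly at the
  programmed onset — generator and extractor share one operational onset
  definition, and the symmetric peak makes sub-sample TTP recovery exact.
* A single seeded generator (numpy `default_rng` with spawned streams in
  fixed order) drives all randomness: identical parameters give
  bit-identical output.
* Broadband Gaussian noise is added per channel; the default SD is 0.01
  (1% of QRS amplitude).  The study reports no noise spectra, so the level
  is a free parameter; 1% keeps the extraction timing jitter of the
  argmax-based ARI well below typical programmed beat-to-beat variability
  while still exercising the robust code paths.

### What the generator does not emulate

Real electrogram morphology (fractionation, ST shifts, drift), rate
dependence and restitution of repolarization, QT prolongation on the
surface ECG under dofetilide, atrial slowing under dofetilide, the RV MAPD
receiving a smaller dofetilide gain than the LV ARI, and mechanical
(image-derived) strain physics.  Passing tests therefore demonstrate that
the *analysis chain* is correct against known ground truth and closed-form
oracles — not that it is robust to every artefact of real recordings.
Group means that depend on the real per-animal data (e.g. the printed QTc
293.1 or LV STV 3.2 ± 1.1, which are per-animal averages of corrected
values) are out of scope; the pipeline's group presets emulate those
conditions but are calibration choices, stated as such.

## Virtual experiments

`pipeline.EP_PRESETS` holds per-group generator settings (rate, interval
baselines, activation spread, ARI/MAPD baselines, STV targets, dofetilide
gain and target post-infusion slope, inducibility probability, atrial
rate).  Per-animal variation applies seeded multiplicative jitter (3–15%
depending on the quantity).  Scripted ectopy: inducible animals get 3–5
polymorphic runs (5 + Poisson(6) beats, defibrillation for runs ≥ 15
beats) starting 60 s after infusion onset with 30–70 s spacing;
non-inducible animals get 0–2 short runs.  Default phase durations follow
the protocol (10 min baseline, 20 min after infusion start); tests and
examples scale these down (45–240 s) to keep runtimes in seconds — the
statistics only need 31 clean beats per phase plus the five-beat averaging
window.  Group summaries report mean, SD (ddof = 1; a single animal
reports SD 0 with n = 1) and inducibility as count/n with the percent
rounded half-up.  Inferential statistics (repeated-measures ANOVA,
McNemar, Wilcoxon) are deliberately not re-implemented; the tidy
per-animal CSVs are ready inputs for standard routines.

## Numerical choices and degenerate inputs

* Extrema are refined by a three-point parabolic vertex, clipped to
  ±0.5 samples; plateaus (tied extrema) resolve to the plateau centre for
  derivatives and to the earlier sample for strain peaks.
* Threshold crossings are linearly interpolated between samples; "missing"
  is returned (NaN, never a guess) when a window is empty, flat, or the
  extremum falls below a slope floor.
* STV raises on series containing missing beats rather than silently
  dropping them; the pipeline feeds it the longest contiguous clean tail.
* The AT–ARI slope raises on fewer than three electrode pairs or zero AT
  variance (undefined slope).
* Flat ECG channels and schedules too short for one beat raise immediately
  with a message naming the problem.

## Known limitations

* PP estimation with dissociated atria is a fundamental-frequency estimate
  from visible P peaks; pathological aliasing between atrial and
  ventricular rates can return a multiple of the true cycle.
* At the default noise level the MAPD80 threshold crossing carries ~1 ms
  beat-to-beat jitter, so extracted RV STV slightly overestimates the
  programmed value; LV STV is less affected because the electrode mean
  averages timing noise.
* The TdP classifier sees the generator's polarity/amplitude rotation
  surrogate; real torsadic twist (continuous axis rotation) would need the
  amplitude-envelope branch of the polymorphism index to carry more
  weight.
* The five-beat ECG averages assume the selected stretch is truly
  artefact-free; no artefact rejection beyond template correlation is
  attempted.
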