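# Methods

## The measurement problem

Continuous IOP telemetry from a sulcus-implanted pressure sensor, read
through an external antenna at a nominal ≈ 9 Hz, during a fixation-wall
protocol: the patient alternates 12-s eccentric-gaze epochs (eight clock
positions per eccentricity, clockwise from superior) with 12-s primary-
position baselines; each eccentricity block closes with a repeated superior
gaze as an internal control, and a subset of sessions appends four 10-s
eyelid-closure epochs.  The quantity of interest is the sustained,
gaze-dependent shift of mean IOP, isolated from saccadic transients, the
ocular pulse, slow drift and measurement noise.

## Estimators

**Analysis interval.**  Epoch intervals are half-open `[start, end)` in
seconds from session start.  The first and last `trim_s = 2` s of every
epoch are excluded, leaving an 8-s analysis interval in a 12-s epoch; the
trim absorbs saccadic transients that are not precisely aligned with the
allotted interval (reaction-time variability).  Baselines are trimmed with
the same rule — applying it symmetrically keeps return-saccade transients
out of the baseline.  Expected sample count is `floor(8 s × 9 Hz) = 72`.

**ΔIOP.**  `ΔIOP = mean(gaze window) − mean(immediately preceding primary
window)`; negative values are IOP decreases.  Referencing each epoch to its
own adjacent baseline cancels slow drift almost completely (for a random
walk, the differencing error has the SD of ~12 s of drift rather than the
session-scale excursion).

**Time course.**  `TW_initial`/`TW_final` are ΔIOP over the first/last 2 s
of the analysis interval, both against the same preceding baseline;
`dΔIOP = TW_initial − TW_final`, so a decline while holding gaze is
positive.  The group-level association between `TW_initial` and `dΔIOP` is
a least-squares fit over the 24 condition means.

**Eyelid closure.**  Per closure epoch, the mean over the *last 2 s of the
epoch* minus the preceding baseline; the initial lid-squeeze peak is
deliberately excluded (the late window approximates the relaxed steady
state).  Per-patient values average the four repetitions.

**QC.**  A window fails when it retains fewer than `min_fraction = 0.5` of
its expected samples (antenna dropout) or overlaps a declared artifact span
(coughs).  The fraction rule replaces manual epoch exclusion with a
reproducible, configurable criterion.  An optional mode drops a whole
(eccentricity, repetition) block when any of its windows fails.  Dropped
samples are removed, never imputed.

**Aggregation.**  Per patient × condition, the mean over qc-passing
repetitions; per condition, mean and SEM (SD/√n) across patients.  The
closing internal-control superior gaze is excluded from condition
aggregation and used only by the first-vs-last contrast.  `Overall` rows
average the eight per-direction group means; their SEM is taken across the
per-patient overall means.  Rounding happens only in the report layer.

## Statistics

**RM-ANOVA.**  ΔIOP is decomposed in a fully within-subject three-way
design (direction × eccentricity × repetition) with subjects as the random
blocking factor.  Each fixed effect E is tested against its own
subject-interaction term, `F = MS_E / MS_{E×S}`, computed from the balanced
cell-mean decomposition (missing cells are imputed from the patient's other
repetitions of the same condition, falling back to the across-patient cell
mean, and counted/flagged).

**Sphericity.**  Per effect, orthonormal within-subject contrasts
`Z = Y Mᵀ` give a contrast covariance C; Greenhouse–Geisser
`ε = tr(C)² / (d·tr C²)` (d = effect df, clipped to `[1/d, 1]`) and
Mauchly's `W = det C / (tr C / d)^d` with the first-order χ² approximation.
The *operative* p-value is GG-corrected when Mauchly rejects at 0.05, and
uncorrected otherwise; both are always reported.  When C is singular
(effect df exceeding subject df, as for the direction × eccentricity
interaction with 11 subjects) sphericity is untestable and GG is always
applied.  Gating matters: with 11 subjects and 8 direction levels the
sample ε is biased far below 1 even under exact sphericity, and an
always-on correction is markedly conservative (empirical type-I ≈ 0.01);
the gated procedure is calibrated (≈ 0.05 on null cohorts, recomputed by
`scripts/acceptance.py`).  Huynh–Feldt ε is out of scope.

**Contrasts.**  Paired/one-sample t statistics are computed directly
(`t = m/(s/√n)`, df = n−1, two-sided), with zero-variance inputs flagged
explicitly.  Families of post-hoc tests are controlled by Bonferroni–Holm:
the k-th smallest p is compared with `α/(m−k+1)` and rejection stops at the
first failure; thresholds are also reported rounded to three decimals, the
convention used when quoting adjusted alphas next to p-values.  The
per-direction ΔIOP contrasts form one family of eight per eccentricity;
the vertical-composite battery (SNT/INT at three eccentricities plus eyelid
closure) forms one family of seven.

**Composites and targeted contrasts.**  SNT/INT composites are built from
last-2-s ΔIOP values (TW_final), matching the windows used in the eyelid
comparison.  The eyelid-vs-downgaze contrast is a paired t of per-patient
eyelid ΔIOP against the INT composite at 25°, on the eyelid subset; a
single-direction variant (inferior only) is available behind a flag since
either reading of "downgaze" is defensible.  The individual-level analysis
pairs repetition-matched ΔIOP of the two group-extreme directions
(superior vs inferonasal at 25°) per patient.  Shapiro–Wilk is run as an
advisory normality screen; the pipeline proceeds regardless and logs the
result.

## The generator

Sample-level model:

```
IOP(t) = IOP₀ + δ(epoch) + A·exp(−(t − t_onset)/τ)
       + (OPA/2)·sin(2π f_heart t) + random-walk drift + white noise
```

* `δ` — additive plateau offset of the current condition: 0 in primary
  position, a direction × eccentricity table for gaze (defaults are the
  published group means of the 11-patient cohort, e.g. +4.4 mm Hg at
  superior/25°, −1.6 at inferonasal/25°), and a steady-state
  `eyelid_offset` (−2.1 mm Hg) under closure.
* Transients — triggered at every condition change and truncated at the
  epoch boundary; gaze spikes are signed toward the new plateau
  (`A = spike_amp·sign(Δδ)`, default 3 mm Hg, τ = 2.5 s), closure spikes
  always positive (deliberate lid squeeze; 4 mm Hg, τ = 2 s).  The 9-Hz
  link undersamples real saccadic spikes, so these amplitudes are free
  parameters, not measured values.
* Ocular pulse — a single sinusoid with peak-to-trough `pulse_amp`
  (default 2 mm Hg) at `heart_rate` 1.2 Hz; richer pulse waveforms are out
  of scope.  At 9 Hz the sampled phases repeat every 15 samples, so the
  sampled peak-to-trough lies in `[OPA·cos(π/15), OPA]` ≈ [1.956, 2].
* Drift — Gaussian random walk, step SD `drift_sd = 0.05` mm Hg/sample, a
  generic stand-in for slow unexplained variation; baseline referencing is
  what keeps it out of ΔIOP.
* Noise — white, SD 0.3 mm Hg.  Sampling times are a uniform 1/9-s grid
  with optional fractional jitter.
* `response_decline_rate` (default 0) scales gaze offsets down linearly
  with session time.  It exists because a purely *additive* session-long
  trend cancels in baseline-referenced ΔIOP (both windows shift equally);
  a declining response *gain* is the mechanism by which sequential effects
  become observable in the internal control, and 0 matches the absence of
  such effects in the recordings that motivated the defaults.

**Cohort layer.**  Patients share the offset table up to (i) a
multiplicative response gain `g ~ N(1, 1)` — patients share the direction
pattern but differ in magnitude, including occasional negative responders —
and (ii) independent per-condition residuals whose SD is chosen so the
*marginal* between-patient SD of each condition reproduces the published
cohort spread (`residual² = SD² − gain_sd²·δ²`, clipped at 0; e.g. marginal
SD 4.9 mm Hg at superior/25°).  Baselines draw from `N(16.5, 4.5)` mm Hg
and eyelid offsets from `N(−2.1, 1.0)`.  Defaults: 11 patients, 3
repetitions, 9-patient eyelid subset.  Child random streams derive from
`SeedSequence(master, spawn_key=(patient, stream))`, so any patient is
reproducible independently of cohort size.

**Artifacts.**  Antenna dropout removes samples inside declared spans
(overlaps merged with a warning); coughs add 0.5-s positive half-sine
transients.

## Validation studies and problem sizes

* *Recovery* (`validate_recovery`, 20 replicates of 11 × 3 cohorts):
  noise, drift, pulse and jitter at defaults, transient amplitudes 0 and a
  homogeneous cohort; per-condition bias, RMSE and 95% CI coverage against
  the realized ground truth.  Transients are excluded deliberately: with
  them on, the 8-s-window mean inherits a systematic leakage bias of
  `A·τ/8·(e^{−2/τ} − e^{−10/τ})` ≈ 0.4 mm Hg per transition — exactly the
  within-epoch drift phenomenon that `dΔIOP` is designed to quantify, not
  an estimator defect.  The same leakage makes the internal-control
  contrast slightly negative when transients are on (the control baseline
  follows a return saccade, the opening one does not).
* *Calibration* (`null_calibration`, 500 null cohorts): empirical type-I
  error of the operative direction test; in band [0.02, 0.08].
* *Power*: the direction × eccentricity interaction of the default offset
  pattern is detected in ≥ 90% of homogeneous-cohort replicates at default
  noise.  With the full between-patient dispersion included the detection
  rate drops to roughly one half — at the published marginal SDs an
  11-patient design is genuinely marginal for the interaction, which is a
  property of the conditions, not of the implementation.

These sizes keep the whole suite and the acceptance script within a few
minutes on one CPU while holding Monte-Carlo error well below the decision
margins (binomial SE ≈ 0.01 at 500 replicates).

## What the simulator does and does not emulate

It reproduces the *signal structure* — plateau offsets, spike-then-decline
morphology in both directions, pulse amplitude and heart-rate coupling,
dropout and cough artifacts, between-patient magnitude variability — and
therefore exercises every code path of the analysis.  It does not model
aqueous-dynamics mechanisms of the post-saccadic decline, Bell's
phenomenon, blink micro-events below the sampling resolution, or real
antenna physics; passing tests validate the estimators and inference under
the stated generative model, not the physiology of any particular device.

## Numerical conventions

Full-precision arithmetic throughout; rounding only in report layers.
Holm ties broken by stable sort on the original index.  Zero-variance t
inputs flagged (`t = 0, p = 1` at zero mean; infinite-t flag otherwise).
Constant ANOVA responses yield SS = 0 with an undefined-F flag.  ε is
clipped to its theoretical range.  Trace text I/O uses `%.17g`, which
round-trips doubles exactly.
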