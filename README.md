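# iopgaze

Analysis of **continuous intraocular-pressure (IOP) telemetry** during
changes of gaze direction and eyelid closure, together with a synthetic
telemetry generator for validating every stage of the pipeline without
patient data.

Implanted telemetric pressure sensors (read out through an external antenna
at ≈ 9 Hz) make it possible to watch IOP respond to eye movements in real
time: a saccadic spike at each gaze change, a slow decline toward a plateau
while the gaze is held, the ocular pulse riding on everything, and sustained
mean shifts that depend on gaze direction and eccentricity.  `iopgaze` is
for researchers who analyse such recordings — or who want to design and
power similar protocols by simulation.

## What it computes

A session alternates primary (straight-ahead) fixation with eccentric gaze
epochs at eight clock positions (S, ST, T, IT, I, IN, N, SN — clockwise from
superior) and three eccentricities (10°, 20°, 25°), plus optional 10-s
eyelid-closure epochs.  For each epoch the first and last 2 s are trimmed
and the response is baseline-referenced:

```
ΔIOP = mean IOP(gaze epoch, 8-s analysis interval)
     − mean IOP(immediately preceding primary baseline)
```

On the ΔIOP records the package runs:

* a fully within-subject three-way repeated-measures ANOVA
  (direction × eccentricity × repetition), each effect tested against its
  subject-interaction error term, with Mauchly's sphericity test and a
  Greenhouse–Geisser correction `ε = tr(C)² / (d·tr(C²))` applied where
  sphericity fails;
* Bonferroni–Holm step-down post-hoc contrasts (rank-k threshold
  `α/(m−k+1)`) per eccentricity family;
* time-course statistics `TW_initial`, `TW_final` and
  `dΔIOP = TW_initial − TW_final` (the within-epoch decline while holding
  gaze) and the correlation of `dΔIOP` with the initial response;
* vertical composites SNT = mean(SN, S, ST) and INT = mean(IT, I, IN),
  the eyelid-closure contrast against the primary baseline and against
  downgaze, per-patient extreme-direction contrasts, and the first-vs-last
  upgaze internal control.

The simulator (`iopgaze.simulate`) generates the same protocol with known
ground truth: plateau offsets per condition, signed saccadic transients
`A·exp(−t/τ)`, a sinusoidal ocular pulse coupled to heart rate, random-walk
drift, white measurement noise, antenna-dropout and cough artifacts, and a
cohort layer with between-patient dispersion.

## Worked example

```python
import iopgaze as ig

results = ig.GazeIOPExperiment.from_simulation(seed=11).fit()
print(results.summary())
```

prints (excerpt):

```
Gaze / eyelid IOP telemetry analysis
====================================================
patients: 11   ΔIOP records: 891 (qc-passing: 891)

Group ΔIOP (mm Hg, mean ± SEM over patients):
  25 deg  S: +6.89±2.07  ST: +4.07±1.48  T: +2.03±0.59  IT: +0.60±0.32
          I: -0.64±0.47  IN: -2.53±0.79  N: -2.22±0.72  SN: +4.03±1.65
          Overall: +1.53±0.58

Within-subject RM-ANOVA (GG-corrected where Mauchly rejects sphericity):
  direction                     F(7,70)   =  11.680  eps = 0.168  p[GG] = 0.004041
  direction x eccentricity_deg  F(14,140) =   6.789  eps = 0.190  p[GG] = 0.002099

TW_initial vs dΔIOP (condition means): R² = 0.78, p = 1.371e-08 (n = 24)

Eyelid closure vs primary gaze: -2.53±0.47 mm Hg, t(8) = -5.39, p = 0.0006522 (n = 9)
Eyelid closure vs downgaze (INT) at 25 deg: -1.98±0.81 mm Hg, t(8) = -2.43, p = 0.0414
```

The simulated cohort (11 patients, 3 repetitions, 9-patient eyelid subset)
reproduces the qualitative structure of real recordings: IOP rises in
up/temporal gaze and falls inferonasally, the rise grows with eccentricity
(the direction × eccentricity interaction), the within-epoch decline tracks
the initial response, and eyelid closure lowers IOP more than downgaze.
`results.to_csv(outdir)` writes the tidy tables (`delta_iop.csv`,
`group_summary.csv`, `anova.csv`, `posthoc.csv`, `time_windows.csv`,
`eyelid.csv`, ...).

The same runs are available from the shell:

```sh
iopgaze simulate -c config.json --seed 1 -o data/
iopgaze analyze --traces data/ --schedules data/ -o out/
iopgaze validate --mode null --replicates 500 --seed 1 -o out/
```

## Documentation

`docs/methods.md` describes the signal model, estimator definitions,
statistical procedures, default parameters and known limitations.
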