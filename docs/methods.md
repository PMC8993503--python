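# Methods

## The simulator

`ecgwaves` generates 12-lead ECGs with a rule-driven expert system, not a
biophysical model. The governing idea is that the ground-truth
segmentation labels must be *exact*: every wave is rendered as a smooth,
compactly supported template (a raised-cosine bump), and the template's
support *is* the labelled interval. No filtering or convolution is
applied to the clean signal, so a sample is labelled "QRS" if and only if
a QRS template contributes to it.

### Beat scheduling

A record is parameterised by a `SimulationConfig` (seed, rhythm,
phenotype, mean heart rate, R-R jitter, wave timings/amplitudes, noise
levels). QRS onset times are laid out left to right:

- **Sinus rhythm (SR):** R-R intervals drawn from a normal distribution
  with coefficient of variation `rr_jitter` (default draw range
  0.01–0.04) truncated at ±2 σ, which bounds the realised CV at ≈ 0.05.
- **Atrial fibrillation (AF):** the same mechanism with CV drawn from
  0.18–0.30 and a physiological floor of 280 ms per interval —
  "irregularly irregular". All P waves are suppressed.

These jitter bands are deliberately disjoint: at a matched mean heart
rate the R-R standard deviation of every AF record exceeds that of every
SR record, which is what makes a dispersion threshold a meaningful
detector feature. Configurations admitting fewer than two beats are
rejected (R-R statistics are undefined).

### Waves, labels, and collisions

Relative to each QRS onset, the supports are placed as
P → P-R segment → QRS → ST segment → T wave, with the T-P segment
(class 6) filling all inter-beat gaps. The QRS is built from three
signed bumps (Q, R, S at 20/45/35 % of the QRS duration). Default
parameter draw ranges (all per record, with ±2 % per-beat jitter):

| parameter | range | unit |
|---|---|---|
| P duration | 80–110 | ms |
| P-R segment | 40–80 | ms |
| QRS duration | 75–105 (LBBB: 125–155) | ms |
| ST duration | 80–120 | ms |
| T duration | 140–200 | ms |
| P amplitude | 0.10–0.22 | mV |
| R amplitude | 0.8–1.6 | mV |
| T amplitude | 0.20–0.45 | mV |
| heart rate | SR 50–95, AF 75–150 | bpm |

Per-lead morphology comes from 12-element multiplier tables (dominant R
laterally, rS in V1, negative aVR), perturbed ±10 % per record so no two
records share identical morphology. Phenotypes modify the tables:

- **LAHB / LPHB:** axis shift implemented as rS patterns in the
  inferior / high-lateral leads respectively with reciprocal R-wave
  accentuation.
- **LBBB:** QRS duration ≥ 120 ms, QS pattern in V1–V3, broad lateral R,
  and discordant T (T polarity opposite the dominant QRS deflection).
- **High take-off / anterior ST-elevation:** an ST-shift envelope in
  V2–V4 that rises across the ST segment and decays across the T wave;
  concave-upsloping for high take-off (0.10–0.25 mV), convex dome for
  infarct-pattern elevation (0.20–0.40 mV) with reciprocal inferior
  depression. The envelope is confined to the ST/T supports, so it never
  changes a label.

Label collisions follow a fixed precedence: QRS > T > P > segments.
Class 7 (T/P overlap) is assigned exactly where a T support intersects
the next beat's P support. At fast AF rates a beat's QRS may legitimately
bury the previous beat's ST/T — precedence handles the labels, and the
record validator exempts such beats from the ordering check.

AF adds a fibrillatory baseline: a 4–9 Hz oscillation of 0.03–0.07 mV
(accentuated in V1) confined to inter-beat spans. The class scheme has
no f-wave class, so these samples keep the inter-beat label (class 6);
labelling them background was the alternative, but that would make the
inter-beat interval class-inconsistent between rhythms.

### Noise model

`add_noise_and_wander` computes
`voltage_scale × (signal + N(0, noise_sd) + wander)` where the wander is
a sinusoid at `wander_freq` (≤ 0.4 Hz) plus a slow random walk, both
scaled to `wander_amplitude`. Labels pass through untouched: they
describe cardiac waves, not artefact, and the masks remain valid
segmentation ground truth for noisy signals.

### Reproducibility

All randomness flows through `numpy.random.default_rng` seeded by
`(record seed, stream id)` — separate streams for config sampling, beat
scheduling, morphology, and noise. Dataset records get independent seeds
from `SeedSequence([dataset_seed, index])` (reduced below 2³¹), so any
record can be regenerated without its neighbours. Class mixes are
apportioned by the largest-remainder method with a deterministic
tie-break.

## Rendering and digitisation

Renders follow clinical paper: 25 mm/s, 10 mm/mV, 1 mm minor / 5 mm
major grid, 3×4 layout (2.5 s per column, lead columns I,II,III |
aVR,aVL,aVF | V1–V3 | V4–V6), optional full-length lead II rhythm strip.
Defaults: 8 px/mm, 30 mm row height, 2 px trace.

The rasteriser is a purpose-built integer column-run routine: each
consecutive sample pair contributes a vertical run, split at the row
midpoint when the pair straddles a column boundary so steep slopes stay
centred. The same routine paints the RGB trace and the class mask
(classes as "colours"), with anti-aliasing deliberately disabled — this
is what makes the mask/trace correspondence exact and testable. The
renderer requires the sampling rate to be at least the horizontal pixel
rate (columns are never skipped); at the defaults, 500 Hz vs 200 px/s.

**Grid calibration.** When layout metadata is absent, `estimate_grid`
recovers px/mm from the calibration grid. Candidate periods (4–20 px/mm
in 0.25 steps) are scored by the best-phase mean of the grid-pixel
column profile over a comb of that spacing, *minus* the best of the
half- and third-period sub-comb scores. The penalty term resolves the
sub-harmonic ambiguity — a comb at twice the true spacing aligns with
every second line and scores as well as the truth on the raw criterion.
The winner is refined locally in 0.01 px steps. On clean renders at
6–12 px/mm recovery is exact to the refinement step.

**Signal read-back.** Per mask column the trace row is the centroid of
non-background pixels (robust to trace width, unlike the topmost pixel);
voltage is `(baseline − row) / px_per_mV`; empty columns are filled by
linear interpolation; the column series is resampled to a fixed output
rate (default 500 Hz, independent of pixel density, because downstream
1-D analysis expects a fixed rate). A lead with > 20 % empty columns is
flagged low-confidence rather than rejected. Label sequences take the
modal non-background class per column. With only a grid calibration and
no layout, the mask is treated as a single lead II strip at standard
paper scales; per-lead boxes cannot be inferred from a bare mask.

Centroid reading low-passes steep deflections (the centroid of a
column's ink is the midpoint of the slope crossing it), so recovered R
amplitudes are slightly attenuated; on clean renders the per-lead
Pearson correlation with the source signal is ≈ 0.97 (median), and
per-sample label agreement ≈ 98.6 %.

## Rule-based AF detection

- `find_qrs_clusters`: maximal runs of class 3, merging runs separated
  by < 20 ms (segmentation dropouts) and discarding runs < 40 ms
  (noise). Verified against a naive run-length oracle.
- `rr_sd`: *population* standard deviation of onset-to-onset intervals
  (masks do not localise R peaks, so onsets stand in for fiducials);
  undefined below 3 clusters.
- `p_preceded_fraction`: fraction of QRS complexes whose 250 ms
  pre-onset window contains a P run ≥ 20 ms; the first complex is
  skipped when its window precedes the record start. The threshold X is
  interpreted as a *fraction* rather than an absolute count, making the
  rule invariant to recording length.
- `classify_rhythm`: AF iff `p_fraction < X` **and** `rr_sd > Y`,
  strict inequalities.
- `fit_thresholds`: exhaustive search over X ∈ {0, 0.05, …, 1.0} ×
  Y ∈ {0, 10, …, 300} ms (651 cells), maximising F1 with respect to AF;
  ties resolved toward smaller X then smaller Y. The 0.05 × 10 ms
  resolution is finer than any plausible decision boundary between the
  two rhythm distributions at negligible cost.

The detector consumes 1-D label sequences; for image masks, lead II (or
the rhythm strip) is first collapsed via `mask_to_label_sequence`.
Records with fewer than 3 QRS clusters are assigned `rr_sd = 0` — without
intervals no irregularity can be asserted, so the AF rule cannot fire.

## Metrics and splitting

F1 is the harmonic mean `2·Sens·PPV / (Sens + PPV)`, defined as 0 when
both inputs are 0 (the score of a degenerate all-negative classifier).
Dice and Jaccard are computed per class with an additive smoothing
constant (default 1) stabilising empty classes, and macro-averaged over
the seven wave classes; with smoothing 0 they satisfy
`dice = 2·iou / (1 + iou)`.

`split_dataset` shuffles with a seeded generator and partitions
60:20:20 by largest remainder, stratified (default on rhythm) so
minority-class test folds are non-empty at small n; a `group_by` option
assigns whole groups (e.g. subjects) to a single fold, for datasets
where one subject contributes several records. Record-level splitting is
the default.

## Problem sizes used in the checks

The bundled verification runs use 200 records for the simulator contract
and separability checks, a 200-record 60:20:20 split for the end-to-end
AF rule, 20 rendered records (8 px/mm) for the digitisation round trip,
and renders at 6/8/10/12 px/mm for calibration recovery. These sizes
give stable statistics for every quantity reported while keeping a full
run in well under a minute on one core.

## What the synthetic data does and does not show

The generator reproduces the *structure* of clinical ECGs — timing,
lead-dependent polarity, rhythm statistics, phenotype signatures — but
its waveforms are idealised bumps: there is no beat-to-beat morphology
memory, no respiratory modulation, no ectopy, no flutter, no paced or
paediatric morphologies, and the AF fibrillatory baseline is a single
sinusoid rather than broadband atrial activity. Tests passing on this
data therefore demonstrate correctness of the *pipeline* (labelling
logic, geometry, calibration, detector rules, metric arithmetic), not
clinical-grade performance on real ECGs; the rule-based detector's
near-perfect F1 on ground-truth labels is an upper bound that real,
model-predicted masks will not reach.

Signal records are stored as raw little-endian float32 arrays with JSON
sidecars and JSON-lines manifests — a deliberately dependency-free
format that any WFDB-style tool chain can ingest after a trivial
conversion.
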