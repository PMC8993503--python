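# ecgwaves

Synthetic 12-lead electrocardiograms with exact wave-segmentation ground
truth, paper-style ECG image rendering and digitisation, and a rule-based
atrial fibrillation detector.

`ecgwaves` is aimed at researchers who train or evaluate ECG wave
delineation and diagnostic models and need unlimited labelled data: every
sample of every generated signal — and every pixel of every rendered
image — carries one of eight wave classes:

```
0 background    1 P wave    2 P-R interval    3 QRS complex
4 ST segment    5 T wave    6 T-P segment     7 T/P overlap
```

## What it does

**Simulation.** A knowledge-based (expert-system) generator assembles
each cardiac cycle from raised-cosine wave templates with hard support
boundaries, so the per-sample labels are exact by construction. Records
are drawn at 500 Hz / 10 s in the standard lead order (I, II, III, aVR,
aVL, aVF, V1–V6), in sinus rhythm (SR) or atrial fibrillation (AF), with
six morphological phenotypes: normal, left anterior/posterior hemiblock,
high take-off, left bundle branch block, anterior ST-elevation. Noise,
baseline wander and random voltage scaling are applied as a separate,
label-preserving step. Everything is driven by a single seed:
identical configurations give bit-identical output.

**Rendering.** Signals are plotted onto clinical ECG paper geometry
(25 mm/s, 10 mm/mV, 1 mm/5 mm calibration grid, conventional 3×4 layout
with optional lead II rhythm strip). The trace and the segmentation mask
are rasterised by the same routine with no anti-aliasing, so the mask is
pixel-aligned with the trace and the grid never leaks into it. Synthetic
print/scan artefacts (rotation, blur, brightness gradients, blotches)
can be applied to images.

**Digitisation.** A mask can be read back into 1-D label sequences and
mV signals. With layout metadata the mapping is exact; without it, the
pixel density is recovered from the calibration grid by a grid search
over candidate px/mm values scored by periodic alignment.

**Rule-based AF detection.** From a label sequence the detector finds
QRS clusters, measures R-R interval dispersion, and searches the ~250 ms
window before each QRS for a P wave. A record is called AF when the
P-preceded fraction is below a threshold X *and* the R-R standard
deviation exceeds a threshold Y; (X, Y) are fitted by exhaustive grid
search maximising F1 on a validation set.

**Evaluation.** Sensitivity, specificity, PPV, F1 (harmonic mean of
sensitivity and PPV), smoothed Dice/Jaccard segmentation overlap, and a
deterministic stratified 60:20:20 train/validation/test splitter.

## Worked example

```python
from ecgwaves import *
from ecgwaves.af import extract_features

cfg = sample_config(seed=11, overrides={"rhythm": "AF"})
sig = synthesize_ecg(cfg)
print("rhythm:", sig.rhythm_label.value, " phenotype:", sig.phenotype_label.value)

p_frac, rr_sd_ms, n_qrs = extract_features(sig.lead_labels("II"), cfg.sampling_rate)
print("QRS complexes: %d   P-preceded fraction: %.2f   R-R sd: %.1f ms"
      % (n_qrs, p_frac, rr_sd_ms))

th = AfThresholds(x_min_p_fraction=0.5, y_rr_sd=50.0)
print("call:", classify_rhythm(p_frac, rr_sd_ms, th, n_qrs).call.value)

image, mask, layout = render_ecg(sig, RenderConfig(px_per_mm=8))
print("estimated px/mm: %.2f" % estimate_grid(image).px_per_mm_est)
```

prints

```
rhythm: AF  phenotype: LBBB
QRS complexes: 19   P-preceded fraction: 0.00   R-R sd: 95.8 ms
call: AF
estimated px/mm: 8.00
```

Seed 11 happens to draw an AF record with left-bundle-branch-block
morphology at ~120 bpm. No P wave precedes any of the 19 QRS complexes
(AF suppresses atrial activity) and the R-R intervals are irregular
(sd 95.8 ms), so the rule fires and the record is called AF. The
renderer's pixel density is recovered from the image's calibration grid
to within rounding.

The same pipeline is available from the shell:

```bash
ecgwaves simulate --n 200 --seed 1 --out data/ --clean
ecgwaves render --manifest data/manifest.jsonl --out images/ --px-per-mm 8
ecgwaves fit-thresholds --manifest data/manifest.jsonl --out thresholds.json
ecgwaves detect-af --labels data/rec0000.lab.u8 --thresholds thresholds.json
ecgwaves evaluate --calls calls.json --truth data/manifest.jsonl
```

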