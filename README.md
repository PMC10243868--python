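# celldet

Detector-agnostic building blocks for **weakly supervised multi-type cell
detection** on partially annotated slide images, and for turning the
detections into clinical readouts such as the bone-marrow nucleated
differential cell count (NDC).

## The problem

Whole-slide images of bone-marrow smears (or mitosis slides) contain tens of
thousands of cells of many types, but human annotation covers only a sparse,
easily identifiable subset. Training a detector on such data poisons the
negative pool: every unlabeled true cell looks like labeled background.
`celldet` implements the sampling, suppression, augmentation and scheduling
machinery that makes cascade detectors work under partial annotation,
independent of any particular network backbone (it emits labels and weights
for an external trainer and consumes detections as COCO-style JSON).

The core pieces, in standard notation:

- **Cascade sample selection.** A cascade of Z classifier stages with
  overlap thresholds φ_z = φ₁ + (z−1)ρ (defaults φ₁ = 0.5, ρ = 0.1, Z = 3)
  splits candidate boxes by their best Jaccard overlap ϖ against the
  reference annotations: positive iff ϖ ≥ φ_z.
- **Dual-layer filtered negative sampling.** Final-stage negatives are
  re-filtered at φ_i = 0.1: negatives with ϖ ≥ φ_i stay as *refined
  negatives*; near-zero-overlap negatives — where unlabeled cells hide — are
  moved to an *ignored* class that contributes nothing to training.
- **Soft-sampling weights.** Instead of discarding background, every
  non-ignored candidate gets an attention weight in (0, 1]: 1 for positives,
  by default w(ϖ) = w_min + (1 − w_min)·ϖ/φ₁ (w_min = 0.1) for the rest;
  the weight function is pluggable.
- **SCNMS / MCNMS.** Greedy non-maximum suppression per class (SCNMS) or
  across all classes jointly (MCNMS) at Jaccard threshold η = 0.3, after a
  confidence cut ϱ = 0.5. MCNMS guarantees no two kept boxes overlap at
  ≥ η, so no cell carries two contradictory class labels.
- **Jaccard-gated augmentation + histogram specification.** Tiles are
  augmented only when their positive fraction η_zk = |h ∩ z_k| / |z_k| is
  > 0 (h = union of annotation boxes): rotations (5°…25° in 5° steps and
  90°/180°/270°), mirror flips, and photometric jitter (±20% contrast and
  saturation, ±12.5% brightness). Color is normalized by per-channel
  quantile matching to a reference CDF.
- **Adaptive learning-rate schedule.** r(Λ) = max(0, 1 − ⌊Λ/ϱ_lr⌋·α) with
  step ϱ_lr = N/α derived from the data size N = I·⌈w/q⌉·⌈h/q⌉ (α = 10%).
- **Reporting.** Greedy IoU matching → recall/precision/F1/accuracy and
  confusion matrices; NDC percentages with the ≥500-cell adequacy rule;
  Cohen's κ with the conventional bands (≤0.20 poor, ≤0.40 fair, ≤0.60
  moderate, ≤0.80 good, else excellent).

A deterministic simulator (`celldet.simulate`) generates multi-class cell
fields with a controllable unlabeled fraction, jittered proposals and
classifier-style detections, so the whole pipeline is testable without any
image download.

## Worked example

```python
from celldet import (FieldSpec, simulate_field, CascadeSampler, NonMaxSuppressor,
                     match_detections, metrics, ndc_report)

# a field where half the true cells are unlabeled
fld = simulate_field(FieldSpec(seed=1, unlabeled_fraction=0.5))
sampler = CascadeSampler().fit()            # phi1=0.5, rho=0.1, Z=3, phi_i=0.1
stage3 = sampler.transform(fld.candidates())[3]
from collections import Counter
print(Counter(a.label.value for a in stage3))
# Counter({'ignored': 75, 'refined_negative': 50, 'positive': 15})

# inference on a fully annotated field
fld0 = simulate_field(FieldSpec(seed=2))
result = NonMaxSuppressor(eta=0.3, varrho=0.5).fit_transform(fld0.detections)
m = match_detections(result.kept, fld0.annotations)
print(metrics(m).loc["average", "recall"])   # 1.0
print(ndc_report(result.kept).adequate)      # False (40 cells < 500)
```

The 75 ignored candidates are exactly the near-zero-overlap negatives in
which the 20 unlabeled cells hide; without the second filtering layer they
would all train as background.

The same operations are available from the shell:

```bash
celldet simulate --seed 3 --out-dir sim --n-cells 15
celldet suppress sim/detections.json --mode mcnms --out kept.json
celldet schedule --n-images 10 --width 2000 --height 2000 --patch-side 500
```

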