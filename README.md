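# lungcad

A tested, reusable pipeline for computer-aided detection (CAD) of lung
nodules in thoracic CT, built to study how **slice thickness** affects CAD
performance and how to train a classifier when the available training scans
have **nonhomogeneous slice thicknesses**.

The package is aimed at medical-image-analysis researchers who want a
transparent, classical CAD baseline whose every stage is exercisable —
without downloading any external dataset — on a built-in synthetic thoracic
phantom generator with exact ground truth.

## What the pipeline computes

1. **Candidate detection** — lungs are segmented from the HU volume; nodule
   candidates are detected *and* segmented simultaneously by multi-gray-level
   thresholding: 15 HU thresholds, each paired with a morphological opening
   (ball radius shrinking as the threshold rises), a size/compactness expert
   filter per intermediate mask, and a logical-OR fusion whose 26-connected
   components become candidates.
2. **Features** — each candidate gets a fixed catalog of geometric,
   intensity, gradient and positional features computed on the raw volume
   and on two local-contrast-enhanced substrates (in-plane windows 11
   and 51).
3. **Selection + classification** — features are shortlisted by the
   orientation-folded Mann–Whitney ROC AUC, then sequential forward
   selection (SFS) grows a subset greedily under the merit that matters for
   free-response detection: the area under the training FROC curve from 0 to
   10 false positives per case. The classifier is a Fisher linear
   discriminant `w = (S_w + λI)⁻¹(μ₁ − μ₀)` on standardized features.
4. **Evaluation** — redundant radiologist markings are merged into single
   targets; a candidate hits a target when its centroid lies within the
   target radius. The FROC curve (sensitivity vs mean FPs/case) is
   summarized by AUC over 0–10 FP/case (max 10) and the ANODE score, the
   mean sensitivity at FP rates 0.125, 0.25, 0.5, 1, 2, 4, 8.
5. **Thickness simulation** — thicker acquisitions are simulated by slab
   averaging: groups of 2/4/8 consecutive 1.25-mm slices are averaged in
   Hounsfield units, turning 1.25-mm data into 2.5/5/10-mm data while cue
   points stay in world mm.
6. **Training regimes** — three ways of using mixed-thickness training data:
   *aggregate* (everything at native thickness), *homogeneous* (only cases
   matching the test thickness) and *common thickness* (everything slab-
   averaged to one thickness, default 2.5 mm), plus k-fold validation with
   per-fold selection.

## Worked example

```python
from lungcad import PhantomSpec, generate_cohort
from lungcad.harness import process_case, train_classifier, evaluate_test_set

cases = generate_cohort(8, PhantomSpec(), (1, 3), seed=42)
processed = [process_case(c.case_id, c.volume, c.annotations) for c in cases]
train, test = processed[:6], processed[6:]
model, trace = train_classifier(train)
print("selected features:", trace.chosen_features)
res = evaluate_test_set(model, test)
print(f"candidate sensitivity: {res['candidate_sensitivity']:.2f}")
print(f"held-out AUC(0-10):    {res['auc_0_10']:.2f}")
print(f"ANODE score:           {res['anode']:.3f}")
```

prints

```
selected features: ['mean_inside_raw']
candidate sensitivity: 0.60
held-out AUC(0-10):    6.00
ANODE score:           0.600
```

Eight phantom cases are rendered at 1.25-mm slices, pushed through
detect → featurize → match, and a classifier is trained on six of them. SFS
stops after a single feature (mean HU inside the candidate — on this easy
phantom, nodules at ≈ −450 HU separate cleanly from +50 HU vessel blobs).
On the two held-out cases the detector proposed candidates covering 60% of
the true nodules (the misses are small 4–5 mm spheres), and the classifier
ranks every hit above every false positive, so the FROC plateaus at 0.60
sensitivity from 0 FPs onward: AUC(0–10) = 10 × 0.60 = 6.0 and the ANODE
mean is likewise 0.600.

A command-line surface mirrors the library
(`lungcad generate / downsample / detect / featurize / train / evaluate /
study-thickness / study-regimes`); study commands take a small YAML config
(keys documented in their `--help` and in `docs/methods.md`).

## Layout

```
src/lungcad/
  volume_io.py   MetaImage I/O, world/voxel transforms, slab averaging
  phantom.py     synthetic thoracic phantoms + LUNA16-dialect annotations CSV
  detection.py   lung segmentation, multi-threshold candidate detector
  features.py    per-candidate feature catalog, local contrast enhancement
  selection.py   ROC shortlist, SFS, Fisher linear discriminant
  evaluation.py  target merging, hit matching, FROC, AUC(0-10), ANODE, CIs
  harness.py     training regimes, thickness study, k-fold, benchmarks
  cli.py         click command-line surface
docs/methods.md  models, parameters, defaults, limitations
```
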