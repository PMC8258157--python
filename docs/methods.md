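# Methods

## Scope and data model

`periograde` implements the post-detection stages of an interpretable
periodontitis-grading pipeline: FDI numbering calibration, alveolar-bone-
loss (ABL) quantification, severity classification, the associated
evaluation metrics, and a synthetic-data generator standing in for
non-public hospital radiographs. Detector training and inference are out of
scope; the package consumes polygon contours (COCO-style `polygon_json`, or
16-bit label-mask PNG + CSV sidecar).

Coordinates are 0-based and pixel-centered, x = column, y = row (y grows
downward); polygons close implicitly. A tooth's *center* is its
bounding-box midpoint, not the centroid — the calibration algorithm is
defined on box centers. Rasterization marks pixels whose centers are inside
or on the polygon (an axis-aligned square with corners (0,0)–(9,9) fills
exactly 100 pixels), so mask areas agree with shoelace areas to within a
perimeter-length band.

## Numbering calibration

Arch geometry is handled in *slot* space: stations 0–15 left-to-right along
each jaw. Under the default orientation (patient's right on the image
left), the upper jaw reads 18…11, 21…28 and the lower 48…41, 31…38; a
`mirrored` flag flips both, since radiograph chirality is a per-site
convention.

Jaw assignment splits the sorted center-y values at the midpoint of their
largest gap. The plain median — the more obvious default — misclassifies
molars whenever the jaws have unequal tooth counts, which is the norm once
teeth are missing; the largest-gap split is what a 1-D two-cluster split
actually calls for. The quadrant comes from the side of the midline
(default: median center x).

Label transfer assigns each labeled sparse-set tooth to its nearest
complete-set center, rejecting matches beyond half the median box width
(without a radius, one far spurious label corrupts the jaw). When two
labels contend for one tooth, the closer wins; duplicate seed codes keep
the higher-score instance.

Inference of unlabeled teeth follows the iterate-until-consistent scheme:
for a tooth with one labeled neighbor, the offset is
`max(1, round_half_up(D_r / D_rr))` — D_r the horizontal distance to the
neighbor, D_rr the reference single-tooth spacing; with two labeled
neighbors the nearer one is used (ties break mesially). Sweeps repeat in
arch order until a pass changes nothing.

**Reference spacing.** The naive D_rr (distance from the neighbor to *its*
next detected tooth) is systematically wrong whenever that pair itself
spans a missing-tooth gap, and a plain median of adjacent gaps inherits the
same bias on short jaws. The package instead estimates the jaw's unit
spacing as the mean of the cluster of adjacent gaps within 1.4× the
smallest gap — with ≤ 10% spacing jitter, true-adjacent gaps fall in
[0.9, 1.1]× the unit while any gap spanning a missing tooth is ≥ 1.8×, so
the cluster contains exactly the true-adjacent pairs. The local D_rr is
used when it is consistent with this unit (0.75–1.35×) or can be normalized
by a known slot difference; otherwise the unit replaces it.

**Repair.** After propagation, a dynamic program selects the strictly
increasing slot assignment (per jaw, 16 stations) minimizing the weighted
number of disagreements with all proposals, with seed labels weighted above
inferred ones and near proposals preferred among equal-cost repairs. This
guarantees the three output invariants — every tooth labeled, no duplicate
codes, FDI order consistent with arch order — while changing seed labels
only when they violate them. Jaws with zero seeds receive positional
fallback numbering (gap-aware relative slots, centered on the arch).
`validate_fdi` independently audits duplicates, domain and order; the
calibration output always passes it.

On jaws of ≤ 8 teeth the result coincides with the exhaustive
minimum-displacement search over all order-preserving labelings consistent
with the seeds, where a labeling's displacement is the summed absolute
difference between each adjacent gap and its implied whole-tooth multiple
of the unit spacing (the tests run this oracle on 500 random jaws).

## ABL ratio

For each tooth the bone reference line passes through two distinct vertices
drawn uniformly (seeded) from the alveolar polyline restricted to the tooth
bbox extended by one bbox width per side — a whole-jaw line is meaningless
on a curved arch. Contour vertices are split into crown (occlusal side of
the line: downward for upper teeth in image coordinates, upward for lower;
on-line vertices count as crown) and root. d_c is the largest distance from
a without-replacement sample of ⌈fraction·n⌉ crown vertices to the line
(default fraction 0.5, mirroring a 50% random sample of contour points);
d_r analogously for the root; `n_draws > 1` averages independent draws,
tightening without biasing. Distance is perpendicular point-to-line
distance — the standard reading of distance "from a point to a line"; a
`vertical_distance` flag offers strict image-vertical distance for
comparison. `sample_fraction=1` is deterministic and equals the all-vertex
maximum; d = d_c/(d_c+d_r) = CRR/(1+CRR) holds identically by
construction.

The clinical staging ratio is referenced to the cemento-enamel junction
(CEJ), whereas d is referenced to the crown top; d is treated as the ABL
feature without asserting clinical equivalence. In particular d has a
geometric floor of crown/(crown+root) ≈ 1/3 for an intact tooth, which is
why the learned classifier — not the fixed-threshold rule — is the right
reader of measured d vectors (see Synthetic data).

## Severity grading

The 32-slot vector D is ordered 11…18, 21…28, 31…38, 41…48. Missing teeth
take the mean of the nearest *measured* neighbor on each side along the
same jaw's arch chain (one-sided at arch ends; a jaw with no measurements
borrows the other jaw's mean), and are flagged imputed. Imputed slots are
excluded from the rule stager's maximum (they are neighborhood means, not
observations) but kept as classifier features.

Rule-based staging uses the worst tooth: 0 → none, (0, 0.15) → mild,
[0.15, 0.33) → moderate, ≥ 0.33 → severe. Boundary values go to the higher
grade; the worst-tooth reading is the only self-consistent interpretation
of per-tooth thresholds, since any severe case also contains teeth below
15%.

SMOTE oversampling brings every class to the majority count with synthetic
samples x + u·(x_nn − x), u ~ U(0,1), x_nn one of the k = 5 nearest
same-class neighbors (k lowered with a warning for tiny classes; a
singleton class is an error). Oversampling is applied to training folds
only. The classifier is XGBoost with 100 rounds, depth 4, learning rate
0.1, softmax objective, fixed seed — deliberately untuned defaults in the
range every gradient-boosting reference uses; the feature space is 32-D and
nearly separable, so hyperparameters are not the bottleneck. Prediction
goes through the native booster (the probabilities are renormalized from
float32), and persisted models carry a JSON sidecar with the class order.

## Evaluation

Dice(all) = 2|X∩Y|/(|X|+|Y|) on pooled binary masks (defined as 1 when both
masks are empty). Dice(single) averages per-tooth Dice over ground-truth
teeth, matching prediction to truth by FDI label and scoring 0 for an
unpredicted tooth. mAP processes each class's predictions in descending
score order, counting a prediction as TP iff its best-IoU unmatched ground
truth exceeds the threshold (default 0.5, polygon IoU); AP is the
all-point-interpolated area under the precision–recall curve, and classes
absent from the ground truth are excluded from the mean. Macro F1 averages
the four class F1 terms with zero-denominator precision/recall counted as
0, so an absent or never-predicted grade drags the score down rather than
disappearing. The repeated-split protocol draws stratified 80/20 splits
(re-drawn with the next seed if a class drops out of a training fold),
evaluates each, and averages arithmetically, retaining per-repeat values.

## Synthetic data

The generator produces geometry and topology only — no image intensities —
which is exactly what the post-detection stages consume.

*Arch scenes*: 16 stations per jaw along parabolic arcs (nominal spacing
50 px, midline 512 on a 1024² frame), with configurable missing teeth,
spacing jitter (each center shifted ±j/2 stations, so adjacent gaps vary
within ±j), sparse seed labels, and label corruption to an *adjacent* FDI
station — the realistic multi-class detector failure. The ground-truth
numbering always passes `validate_fdi`.

*Tooth geometry*: a flat, densely sampled occlusal edge over a tapered root
with a small apex plateau, so that extremal distances survive 50%
subsampling; the bone contour crosses at root-exposure fraction f, giving
the analytic truth d = (crown + f·root)/(crown + root). Defaults: crown
25 px, root 50 px, width 30 px. With `shape_noise=0` and full sampling the
estimate equals the truth to machine precision.

*Ratio cohorts*: grades drawn from the default priors 52/189/43/14 ÷ 298 —
the class mix of a 298-image clinical cohort — with the worst tooth placed
uniformly inside its grade band shrunk by 2σ (σ = 0.02 by default, so noise
cannot cross a staging boundary; larger σ than a third of the narrowest
band is rejected), other teeth below it, and a configurable fraction of
teeth dropped for imputation. By construction the rule stager reproduces
the drawn grade exactly at σ = 0.

*Full scenes* compose arches, tooth geometry and a smooth per-jaw bone
polyline (constant root-exposure fraction per jaw, following the arch
curve) into end-to-end inputs with analytic per-tooth d. The image-level
grade is *clinical* — thresholds applied to the worst root-exposure
fraction f, the CEJ-referenced quantity a dentist grades on — while the
pipeline measures d. A zero-loss jaw has no bone crossing inside any tooth
contour, so geometric scenes cover the three loss-positive grades; the
end-to-end classification check therefore trains the classifier on
measured d vectors against clinical grades and reports macro F1 over the
classes present.

## Problem sizes and determinism

The shipped checks use 500 jaws for oracle equivalence, 200 arches
(~5,600 teeth) for numbering recovery, 100 tooth shapes for ABL error,
500-image cohorts for staging, a 1,000-sample SMOTE audit, and 120
end-to-end scenes — sizes at which every stochastic margin observed is a
multiple of its tolerance away from the threshold. All generators and
estimators take explicit seeds; the pipeline derives per-image seeds from
the master seed and image id (CRC32), so identical configurations produce
byte-identical reports.

## Known limitations

- Arch curvature is ignored in the horizontal-distance offsets, as the
  calibration is defined on horizontal spacing; strongly rotated
  radiographs would need the `mirrored`/orientation handling extended.
- The unit-spacing estimator assumes at least one truly adjacent detected
  pair per jaw; a jaw where *every* adjacent pair spans a missing tooth is
  unidentifiable from spacing alone (any labeling consistent with the gaps
  ties), and the repair then resolves it deterministically but arbitrarily.
- d is crown-top referenced, not CEJ referenced; mapping measured d to
  clinical stages is delegated to the learned classifier, trained per
  cohort.
- Supernumerary and deciduous teeth (FDI 51–85) are out of scope.
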