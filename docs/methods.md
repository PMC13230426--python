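# Methods

## The correction-map model

Let `y_true, y_teach ∈ {0,1}` be the ground-truth and teacher labels of a
voxel. The pair determines a category: TN `(0,0)`, FN `(0,1)`, FP `(1,0)`,
TP `(1,1)`. A correction scheme `S = (fn_code, fp_code, tp_code)` encodes the
pair into the professor's target

```
y_corr = fn_code   if FN
         fp_code   if FP
         tp_code   if TP
         y_teach   otherwise  (TN, i.e. 0)
```

and a decode table maps codes back to actions on the teacher mask: FN and TP
codes → set 1, the FP code → set 0, the background code 0 → keep `y_teach`.
The professor is a segmentation network trained on `(CT, y_teach)` →
`y_corr`; its predicted map edits the teacher mask into the refined
segmentation `y_prof`.

Two properties of this algebra matter and are enforced:

* **Conflict-freedom.** A nonzero code claimed by both a set-1 category and
  the set-0 category is contradictory; constructing such a scheme raises an
  error. Categories sharing a code with the same action merge (Inclusive
  Correction's FN=TP=2 is the published example).
* **Information ceilings.** A category whose code equals 0 is
  indistinguishable from background in the encoded map; decoding keeps the
  teacher value there. Consequently the exact (oracle) round trip
  `apply(encode(y_teach, y_true, S))` returns: `y_true` for Pattern
  Discerner and Inclusive Correction; `y_true OR y_teach` for the
  Underestimation Focuser; `y_teach` for Precision Priority. These
  identities are verified by exhaustive per-voxel enumeration and on 1000
  seeded random 8³ mask pairs, and they bound what a perfectly trained
  professor can achieve under each scheme. An alternative reading of
  Precision Priority — forcing code-0 voxels to background, which would turn
  it into a pure FP-remover — is defensible from the published description;
  the keep rule is implemented because decoding cannot distinguish encoded
  FN/FP voxels from true background, and inventing a third state would
  change the scheme's arity.

Equation-level ambiguities in the source description (a TP-conditioned
branch labelled FN; a transformation listing both "0 if FP" and "1 if FP")
are resolved the only way that keeps the transform a correction: the
TP-conditioned branch *is* TP, and the decode sends FP→0 and TP→1.

## Phantoms: what they emulate and what they do not

`generate_phantom` builds a 48³ volume at 1.5 mm isotropic spacing (72 mm
cube): soft-tissue background (60 HU), one tumor — a sphere of radius
10–16 mm whose local radius is modulated by a smooth Gaussian random field
(`tumor_irregularity = 0.3`), giving the lobulated, irregular boundary of an
infiltrative mass — with −40 HU contrast (hypodense lesion), up to three
ellipsoidal organ-context structures with their own intensity offsets, and
additive Gaussian noise (10 HU). Largest-connected-component selection
guarantees a single tumor component.

`corrupt_segmentation` simulates the teacher, applying in order: lobe
dropout (probability 0.25 of carving a ball of 0.7× the equivalent radius at
a random surface point), erosion then dilation with mm-radius ellipsoidal
structuring elements (per-axis radius = `round(mm / spacing)` voxels, so
anisotropic grids behave correctly), smooth boundary noise added to the
signed distance field (SD 1.0 mm), and Poisson-distributed spurious blobs
(rate 0.3) kept clear of the true tumor. The default regime is
erosion-dominant (3.0 mm), reflecting the finding that under-segmentation is
the teacher's dominant error mode; it is calibrated so the simulated teacher
scores mean DSC ≈ 0.59 ± 0.10 over a default cohort, matching the reported
clinical teacher operating point (≈ 0.60). The corresponding clinical error
distribution is not quantitatively characterized anywhere, so this
calibration targets the one published summary statistic rather than claiming
distributional fidelity.

Not emulated: CT physics (beam hardening, reconstruction kernels), contrast
phases, vascular anatomy, inter-annotator variability. Passing tests
therefore demonstrate that the pipeline's machinery — encoding, learning,
correction, bookkeeping — behaves as specified on data with a recoverable
systematic error; they do not certify clinical performance.

## Networks and training

The compute core is a small numpy reverse-mode autodiff (im2col 3D
convolutions with arbitrary per-axis stride, instance normalization, leaky
ReLU, nearest-neighbour upsampling, concatenation), verified against
finite-difference gradients. U-Nets are built from declarative configs:
encoder stages downsample by strided convolution with per-stage pool
kernels, feature widths double per stage capped at `max_features`, the
decoder upsamples and refines concatenated skips, and 1×1×1 heads provide
deep supervision at every decoder scale. Deep-supervision weights halve per
coarser scale, the coarsest is excluded, and the weights are normalized —
the standard convention where the source states only "deep supervision".

The loss is `0.5·softDice + 0.5·crossEntropy`; the Dice term is computed
per foreground class over the batch as `1 − 2Σpt/(Σp+Σt+ε)`, `ε = 1e-5`,
and averaged over foreground classes (correction-map codes are treated as
nominal classes, one softmax channel per distinct code including 0; no class
reweighting by default). Gradients of the loss are analytic.

Optimization is SGD (momentum 0.99, nesterov, weight decay 3e-5), initial
learning rate 0.01 with polynomial decay `lr₀(1−t/T)^0.9` (exponent 0.9 is
the usual choice where the source states only "polynomial decay"). A third
of training patches are centred on foreground voxels so small tumors are not
starved. Augmentation applies rotation (±30°), scaling (0.7–1.4), mirroring,
Gaussian noise/blur and brightness/contrast; spatial transforms hit all
channels and the target (nearest interpolation for label-like channels),
intensity transforms only the image channels — the professor's teacher-mask
channel enters raw. Prediction tiles volumes with half-overlapping patches
under a Gaussian importance map.

The published architecture presets (teacher cascade low/full resolution,
dual-channel professor with its asymmetric pooling schedule, student
cascade) are shipped as configuration data and asserted field by field; the
cascade's per-stage pooling schedules are not printed in the source and
follow the standard anisotropy-aware pattern (z pooled less often). Training
at those scales is far beyond a desk CPU; all training runs use the
`tiny_test` preset (3 encoder stages, 8 base features, 24³ patches).

## Preprocessing

The professor operates on the crop defined by the bounding box of
`y_true OR y_teach` (half-open `[lo, hi)`, 0-based, z/y/x), padded by a
margin (default 4 voxels for training context; the box itself defaults to
margin 0 where only the literal union box is wanted). At pure inference no
ground truth exists, so the crop falls back to the teacher mask's own box —
a documented divergence forced by deployment. `restore` places a cropped
map back into the full grid with background code 0 outside, which decodes to
keep-the-teacher-value: the professor never edits voxels it never saw.
Normalization is percentile-clip (0.5/99.5 of pooled foreground
intensities) followed by z-scoring with the pooled clipped mean/SD — the
standard CT scheme of the architecture family the teacher belongs to, since
the source defers to "the teacher's initial normalization" without printing
it. Statistics are computed once per training set and stored for reuse at
inference.

## Metrics

Surfaces are mask voxels with a 6-connected neighbour outside the mask (grid
border counts as outside). Distances are Euclidean between surface-voxel
centres in mm, spacing-aware, computed via KD-trees and verified against an
O(n²) pairwise oracle to 1e-9 relative tolerance. HD95 is the
linear-interpolation 95th percentile of the *pooled* bidirectional
distances and MSD their mean — the directed-vs-pooled choice is not stated
in the source; pooled is symmetric and is pinned here by oracle tests.
DSC of two empty masks is 1.0, of one empty mask 0.0; surface metrics are
undefined for empty masks and reported as missing, so control-style
(tumor-free) cases do not crash cohort evaluation.

The Wilcoxon signed-rank test drops zero differences (classic treatment),
midranks ties, and uses the smaller signed-rank sum as statistic. For
n ≤ 25 the exact null is computed by dynamic programming over doubled
midranks (exact also under ties); above that, a normal approximation with
continuity and tie correction. At n = 12 the approximation is typically
within 0.01 of the exact p (it can reach ~0.014 for unfavourable samples —
inherent discreteness, not an implementation artefact).

## Orchestration

Folds are patient-grouped: every scan of a patient shares its fold, folds
are balanced to within one patient, assignment is a seeded permutation.
Phase 1 trains one teacher per fold and emits out-of-fold pseudo-labels;
phase 2 trains one professor per fold per scheme on those pseudo-labels,
scores each scheme by the Dice of corrected out-of-fold segmentations, and
selects the best; phase 3 corrects unlabelled cases with the selected
professor — combining fold models by majority vote over corrected masks,
a deterministic choice where the source keeps one professor without saying
how folds combine — and trains the student on manual plus corrected labels
with per-case label provenance recorded. Control (tumor-free) cases may
enter teacher/student training but never the professor phase. All
randomness derives from one master seed through named substreams.

At desk scale the teacher may be *simulated*: the phantom error model
stands in for trained-teacher pseudo-labels, which decouples testing the
correction machinery from the teacher's training budget. The desk-scale
experiment (40 training + 10 held-out phantoms, two folds, 6 epochs × 25
iterations of professor training) was sized to finish in minutes on one CPU
core while leaving a wide margin on its claims; a representative run lifts
test Dice from 0.66 (simulated teacher) to 0.94 after learned correction.

## Numerical and degenerate-input choices

* float32 throughout the network; loss in float64 where accumulation
  matters.
* Resampling: `scipy.ndimage.zoom`, linear for intensities, nearest for
  labels (never inventing label values); output shape `round(n·s/s')`
  preserves physical extent to within one voxel; only axis-aligned affines
  are accepted at the NIfTI boundary.
* Empty teacher mask at inference: nothing to correct and no crop box — the
  case passes through unchanged.
* Empty union of masks in training: the case is skipped with a log entry.
* Degenerate normalization (empty or constant foreground) and all-zero
  paired differences raise typed errors rather than returning NaNs.

## Known limitations

* The numpy training core is single-threaded and orders of magnitude slower
  than a GPU framework; the full-scale presets are configuration-complete
  but not trainable at that scale here.
* The phantom error model is calibrated to one summary statistic (teacher
  DSC); learned-professor gains on phantoms bound nothing about clinical
  data.
* Majority-vote fold ensembling and the simulated-teacher mode are this
  package's own design choices where the source is silent; both are
  flagged at their definition sites.
* Oblique/rotated NIfTI orientations and DICOM ingestion are out of scope.
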