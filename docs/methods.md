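# Methods

This note documents the models and procedures implemented in `froimal`,
the parameter choices that matter, the design decisions taken where the
design was genuinely open, and the limits of what the synthetic
experiments show.

## Problem setting

All volumes live on one common stereotaxic grid (in practice the MNI152
grid that localizer statistics are warped to; the package performs no
registration). A voxel is *activated* when its Z statistic strictly
exceeds `z_threshold` (default 2.3, i.e. p < 0.01 uncorrected); a voxel
at exactly the threshold is excluded. Reference atlases pair an
activation map with an expert label map; at atlas construction any
labeled voxel at or below the threshold is zeroed (real manual labels
can graze the threshold) and the count logged.

All work is restricted to the **collective mask** — the union of the
requested fROI labels over every atlas in the database. The mask
restricts encoder training by construction; we also restrict the
*target's* candidate voxels to it symmetrically, which is a choice
users should be aware of: labels can never appear outside the union of
the reference fROIs.

## Atlas encoding

Each atlas is encoded as a forest of T axis-aligned decision trees on
the atlas's candidate voxels, with the 3 integer voxel indices as the
only features. Integer indices rather than millimetres: axis-aligned
splits are invariant under monotone per-axis rescaling (covered by a
test), so indices and world coordinates yield the same classifier while
avoiding float comparisons. Z values and appearance features are
deliberately excluded — the delineation criterion being learned is
spatial.

Activated-but-unlabeled voxels inside the mask are *explicit background
training samples*. This matters: it is what allows the fused prediction
to say "no fROI here" inside the mask, and it means a forest's class
list always contains background (padded in even when the atlas had no
background samples).

Forest specifics: each tree is fit on a bootstrap resample of the same
size as the training set; at each node a single candidate coordinate
dimension is drawn uniformly at random and the split maximizes
information gain (entropy impurity); depth is capped at D; leaves are
pure or size-1; no pruning. Defaults T = 30, D = 20 — the evaluation
module's parameter grid shows accuracy is insensitive over
T, D ∈ [10, 40] on low-variability cohorts, so these act as a
capacity ceiling rather than a tuned optimum. Fitting is delegated to
scikit-learn's `RandomForestClassifier` (`max_features=1`,
`criterion="entropy"`, `bootstrap=True`); the fitted trees are then
frozen into plain split/leaf arrays, and all prediction runs through
the package's own vectorized traversal of those arrays. This gives a
single prediction code path, pickle-free JSON serialization (one
versioned file per atlas), and lets the library's own `predict_proba`
serve as an independent cross-check in tests.

Per-voxel prediction averages the leaf class distributions across trees
(soft voting). Whether the original procedure used distribution
averaging or hard per-tree votes is not determinable from its
description; soft voting is the default and hard voting
(`vote="hard"`) is exposed. Determinism: each atlas's forest seed is
derived from the experiment master seed plus a CRC32 of the subject id,
so runs are reproducible and encoders are independent of database
composition.

## Atlas selection

Similarity between a target and an atlas is Pearson's correlation of
the two activation vectors inside the collective mask after clamping
negative Z values to zero. Clamping is applied to *both* maps: the
fROIs are defined by a one-sided contrast, so only positive activation
is informative, and a symmetric definition keeps similarity symmetric.
A constant clamped vector yields similarity 0 (not NaN), sorting
uninformative atlases last. Normalized mutual information
2·I/(H₁+H₂) over 32 equal-width bins spanning the pooled range is
available as an alternative metric; whether to clamp before binning is
exposed as a flag (clamped by default, for consistency with the Pearson
path).

Atlases are ranked descending (ties broken by subject id for
determinism) and the top N retained; N = 0 means "use all". Default
N = 40, the operating point at which ranked selection saturates on the
reference application. In LOSOCV on clustered synthetic cohorts the
Spearman correlation between an atlas's rank and its single-atlas
labeling Dice is strongly negative, and top-ranked subsets dominate
random subsets at every intermediate size — the two facts that justify
the heuristic.

## Fusion, and the image-based baseline

The selected forests' probabilistic maps are averaged voxelwise
(class lists unioned; missing classes contribute zero) and the final
label is the argmax of the mean vector. Ties break toward background
first, then the lowest label id — conservative under ambiguity and
deterministic; since the class list is sorted ascending with background
first, numpy's first-maximum argmax implements the rule directly. For
one-hot inputs this argmax equals plurality voting, which is exactly
how the image-based baseline (direct label transfer under the
one-to-one correspondence assumption) is implemented: each atlas
contributes its own label at each target candidate voxel, averaged and
voted identically. The baseline is mask- and threshold-restricted
exactly like the forest path so the comparison isolates the encoding
scheme. No connected-component post-processing is applied.

## The GSS baseline

The single-atlas comparator builds, per fROI, the voxelwise fraction of
reference subjects labeling each voxel (values exact rationals k/n);
thresholds these probabilities (strictly-below-threshold values are
zeroed, so ≥ survives and threshold 0 keeps everything); assigns each
voxel the surviving fROI of maximal probability (ties to the lowest
label; background competes only through the threshold, not in the
argmax); and intersects the resulting group parcels with the
individual's supra-threshold voxels. Reported GSS accuracy is the mean
Dice across MPM thresholds {0, 0.1, 0.2}, since the threshold trades
parcel extent against precision. GSS+AS restricts the references to
the same top-N, same-mask, same-metric selection as the multi-atlas
path, so the two differ only in what is done with the selected atlases.
In LOSOCV, GSS peak consistency is scored at the middle threshold
(0.1), the geometric compromise between the extremes that define the
Dice average.

## Evaluation

* **Dice** 2|A∩B|/(|A|+|B|); when both regions are empty the value is
  undefined and excluded from averages (counting it as 1 or 0 would
  bias cohorts with absent regions); exactly one empty region scores 0.
* **Peak consistency**: the argmax-Z voxel of the automatic region must
  lie within `peak_match_radius_mm` of the manual region's argmax-Z
  voxel (default radius 0 = identical voxel, the strictest reading;
  argmax ties break lexicographically). Its mean over subjects is the
  "proportion of matched peaks" statistic.
* **LOSOCV** holds each subject out in turn, with a leakage guard
  asserting the held-out id is absent from the references at every
  fold. Encoders are cached across folds — safe because an encoder
  depends only on its own atlas. The collective mask is built once
  from the full database, consistent with that caching.
* **Intensity concordance**: per-subject mean Z inside manually and
  automatically defined regions are correlated (Pearson), and the two
  automated methods' correlations with the manual series are compared
  with Steiger's Z for dependent correlations sharing one variable
  (the Z̄₁\* form: Fisher transforms, covariance correction through the
  pooled r̄ and the inter-method correlation). The statistic is exactly
  0 when the two automated series coincide, and its empirical type-I
  error under a simulated equal-correlation trivariate normal null is
  nominal (≈ 0.05 at α = 0.05; verified by simulation in the test
  suite).

## Synthetic cohorts

Each subject's fROIs are ellipsoids (default: two well-separated blobs
standing in for the right OFA and pFFA) perturbed per subject by a
Normal(0, `translation_sd_mm`) centre displacement per axis, a
Normal(1, `scale_sd`) radial scale, and a boundary jitter obtained by
adding `shape_jitter_sd` times a smoothed unit random field to the
normalized ellipsoid radius before thresholding at 1. The Z map is the
per-ROI bump — peak Normal(`z_peak_mean`=5, `z_peak_sd`), decaying
linearly in normalized radius to the activation threshold at the
boundary — plus smoothed Gaussian background noise (unit-SD field
scaled by `background_noise_sd`, smoothing FWHM 4 mm). The bump decays
to exactly the threshold at the boundary so the supra-threshold set
approximates the ground-truth geometry, while noise adds/removes
boundary voxels — label/activation mismatch exists in real data and is
desirable here. Atlas labels are the ground truth restricted to
supra-threshold voxels, upholding the atlas invariant by construction;
the full pre-threshold geometry is returned separately as ground truth.

With `n_prototypes` > 1, each prototype is a fixed random offset of the
ROI templates (per-axis SD `prototype_offset_mm`, defaulting to twice
the translation SD so subgroups are separated but overlapping) and
subjects are assigned round-robin, giving balanced latent subgroups
whose within-group activation similarity exceeds between-group
similarity — the structure that makes atlas selection demonstrably
useful. Note the prototype offsets are themselves random: occasional
seeds draw widely separated subgroups and yield genuinely harder
cohorts, visible as lower absolute accuracy in the reproduction script.

The default grid is 32×38×28 voxels at 2 mm — roughly a thousandth of
a full-resolution brain — so that complete LOSOCV experiments, sweeps,
and the reproduction script each run in well under a few minutes on one
CPU. The standard experimental cohorts used by the test suite and
`scripts/acceptance.py` are: a zero-variability cohort (10 subjects,
all variability SDs zero) for exact-recovery and parameter-grid
checks, and a clustered cohort (60 subjects, translation SD 4 mm, two
prototypes, scale SD 0.1, jitter SD 0.1, peak SD 0.5) for the
encoding, selection, and baseline comparisons.

**What the synthetic experiments do not show:** the generator has no
cortical geometry, no registration error, no spatially structured
signal dropout, and its "expert labels" are derived from the same
geometry as the activation. Passing tests therefore validate the
algorithmic pipeline and the direction of its effects, not absolute
accuracy on real fMRI.

## Numerical and degenerate-case conventions

* Threshold comparisons: activation strictly greater than
  `z_threshold`; MPM probability ≥ threshold survives.
* Single-class training sets produce valid degenerate encoders
  (probability 1 for that class in-domain).
* Candidate voxels are enumerated in lexicographic (i, j, k) order;
  fusion sums per-atlas predictions in a canonical (sorted-id) order in
  the sweep driver so permutation invariance holds bitwise.
* Probability vectors must sum to 1 within 1e-9; out-of-domain voxels
  carry the degenerate background vector.
* All randomness flows from explicit seeds (cohort seed; forest master
  seed plus per-atlas CRC32 stream; seeded subset draws), making every
  entry point rerun-identical.

## Known limitations

* No weighted or patch-based fusion; plurality voting only.
* Similarity metrics are global within the mask; no hyperalignment or
  local similarity.
* The CLI covers flat NIfTI directories with a JSON manifest; surface
  (GIFTI) data are unsupported.
* Label maps from different experts, multi-rater fusion, and
  inter-rater reliability are out of scope.
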