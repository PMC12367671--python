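# Methods

## Scope and data model

The pipeline operates on per-case 3D CT volumes in Hounsfield units with
co-registered binary masks: the gross tumour and a fixed-size aortic
reference per contrast phase (non-contrast, arterial, venous, delayed).
All processing is in voxel space with 0-based indices; phases are never
resampled onto each other, because each phase is segmented independently.
Masks binarize any nonzero label to foreground, tolerating segmentation-
tool dialects. The aortic reference's size is unconstrained — it enters
the analysis only through its intensity SD — and its voxel count is
logged per case/phase.

Grade (low/high, from the mitotic count on the resected specimen) and
morphological variant (conventional/oncocytic/myxoid) are supplied labels,
never computed.

## Standardization

Intensity variance is standardized per volume against the aortic lumen:
`I_std = μ_image + (I − μ_image)·σ_ref/σ_aorta`, with σ_ref the cohort
mean of per-case aortic SDs, computed separately per phase (overridable in
config for cross-cohort reuse). Two choices were genuinely open:

* **μ_image region** — the mean is taken over the gross tumour VOI, the
  tissue whose texture is analyzed; a config switch (`mu_region="volume"`)
  uses the whole field of view instead. Since the map is affine, the
  choice shifts but never re-ranks intensities.
* **Transform extent** — the whole volume is transformed; voxels outside
  the VOI are discarded later by masking, so outputs are identical either
  way.

The transform is applied post-segmentation and before VOI thresholding and
discretization; the 30 HU necrosis cut therefore acts on standardized
values. Invariants (tested): ROI mean preserved; aorta SD maps exactly
onto σ_ref; σ_aorta = σ_ref is the identity; standardizing a standardized
cohort is a no-op; the map is strictly increasing.

## Volumes of interest

The vital VOI is `gross ∧ (I_std ≥ 30 HU)` — strictly-below voxels are
excluded, a voxel at exactly 30 HU is kept. Thresholding is voxel-wise
with no hole-filling or minimum component size: no processing is invented
beyond the stated rule. An empty vital region is a warning, not an error.
Regions below a configurable floor (default 10 voxels) emit missing
feature values rather than unstable texture estimates, making missingness
explicit in the cohort table.

## Texture features

92 features in six families (18 first-order, 23 GLCM, 16 GLRLM, 16 GLSZM,
14 GLDM, 5 NGTDM), with a frozen name schema. Conventions, chosen to match
the widely used IBSI-aligned extractor defaults and locked by the
brute-force oracle tests:

* Fixed bin width 25 HU: `level = floor((I − min)/w) + 1`; gray levels
  keep their bin values (gaps preserved), Ng = number of occupied levels.
* No isotropic resampling; neighborhoods are Chebyshev-distance-1 on the
  voxel grid (26-connected), 13 unique directions for GLCM/GLRLM with
  feature values averaged over directions (not merged matrices).
* GLSZM zones are 26-connected components per level — note that on a 3D
  checkerboard same-level voxels touch diagonally, so each level forms a
  single zone.
* GLDM α = 0; the matrix column is dependence count + 1, so an isolated
  voxel sits at j = 1 and j-weighted formulas never divide by zero.
* Entropies are base-2 over positive entries. Degenerate conventions:
  zero-variance skewness/kurtosis = 0; single-level GLCM gives
  Correlation = MCC = 1, Imc1 = Imc2 = 0, InverseVariance = 0; NGTDM
  Contrast/Busyness/Strength = 0 on a single level, Coarseness capped at
  1e6; GLCM directions with no voxel pairs are dropped from the average.
* First-order Skewness and Kurtosis use population moments; percentiles
  use linear interpolation; Energy/TotalEnergy use raw HU (no shift).

Every feature is verified against an independent loop-based definitional
implementation on random regions (relative tolerance 1e-6; observed
agreement ~1e-12), plus closed-form cases, 90°-rotation invariance for
direction-averaged families, and translation invariance.

## Feature selection

For every feature pair with |Spearman ρ| above 0.9 the lower-MaxSD member
is dropped, where MaxSD = max pairwise |group mean difference| / pooled SD
and the pooled SD is the k-group, (n_g − 1)-weighted within-group
estimate. The grouping variable is the analysis arm's own target (grade or
variant). The elimination order for correlated clusters is unspecified in
principle; here pairs are processed greedily by descending |ρ| with
lexicographic tie-breaks, and dropped features generate no further
eliminations — deterministic and invariant to column order (tested).
Constant features have undefined ρ and are treated as uncorrelated with a
warning. The selection result records the dropped → kept mapping so any
eliminated feature can be traced to its retained representative.

## Statistics

* Mann–Whitney U: exact enumeration when combined n ≤ 20 without ties,
  otherwise tie-corrected normal approximation with continuity correction.
* Kruskal–Wallis with tie correction; Dunn's post-hoc z on pooled ranks
  with tie correction, optional BH across pairs.
* BH-FDR is applied across features *within* each (phase, VOI kind)
  family, the granularity at which corrected values are interpreted;
  significance is adjusted p < 0.05.
* ROC: AUC by the rank (U-statistic) formulation with ties counted half,
  reported for the chosen direction; the cutoff maximizes Youden's J over
  the observed values in both directions (`>`: positive at score ≥ cutoff),
  ties broken toward higher specificity, then lower cutoff. PPV/NPV follow
  from sensitivity, specificity and cohort prevalence.
* Bootstrap: percentile 95% CIs from 1,000 case-level resamples,
  stratified by class for ROC quantities, with the operating-point search
  re-run per resample; fully seeded.

The pipeline-level false-discovery property — selection followed by
testing does not inflate the family-wise rate of any discovery on null
cohorts — is tested directly on 200 simulated null cohorts.

## Synthetic data

Phantoms emulate the features the analysis relies on, not CT physics: an
ellipsoidal tumour (default 40³ grid at 1 mm, ≈5,000 tumour voxels) filled
with a correlated Gaussian field (smoothing length = texture scale) passed
through the monotone skewing map `z → (exp(d·z) − 1)/d`, rescaled to a
target mean/SD (default 90/20 HU, a typical venous-phase enhancement);
an optional necrotic core — the exact set of round(f·V) voxels nearest the
centre, assigned HU in [0, 25] — with the viable rim clipped to ≥ 40 HU so
the 30 HU rule's behaviour is known to the voxel even after
standardization rescales intensities by a few percent; optional
homogeneous hypodense blobs (≈55 HU); and an aortic cylinder with
controllable SD (default 12 HU). Grade cohorts plant the reported
qualitative signatures — low-grade: skew −0.5, correlation length 1.0
voxel, 5% core; high-grade: skew +0.5, correlation length 2.5, 25% core
plus 8% hypodense zones — at effect sizes chosen to make recovery
unambiguous at n = 15 + 15.

Cohort-level feature tables (no images) draw each feature from a normal
location-scale family calibrated by group medians and IQRs
(σ = IQR/1.349), defaulting to published venous-phase group values for the
grade analysis; exchangeable null features and near-duplicate collinear
partners (ρ ≈ 1) are planted to exercise selection. Zero-effect cohorts
drive the type-I-control check.

What passing these tests does **not** show about real data: phantoms have
no anatomy, no partial-volume or beam-hardening effects, no inter-scanner
histogram differences beyond a variance scale, and normal (not skewed or
heavy-tailed) cohort feature marginals; effect sizes in real cohorts are
far smaller than the planted ones. The tests validate the *machinery* —
formulas, rules, orderings, error control — not clinical performance.

## Problem sizes and determinism

Defaults keep everything desk-scale: 40³ phantoms (≈0.3 s per
case/VOI extraction), 15 + 15 cohorts for end-to-end checks, 200 null
cohorts for FDR control, 1,000 bootstrap resamples. All randomness flows
through `numpy.random.default_rng` seeds; the pipeline writes a provenance
header (config digest, seed, version) with every bundle, and reruns are
byte-identical.

## Known limitations

* NGTDM Coarseness's 1e6 cap is a convention inherited for comparability;
  it makes the feature non-smooth near homogeneous regions.
* Exact Mann–Whitney switches to the asymptotic path whenever ties are
  present, even at small n.
* Bootstrap CIs use the percentile method; with n ≈ 12–15 per class and
  re-estimated cutoffs they are optimistic near perfect separation
  (degenerate zero-width intervals at AUC = 1).
* The variant arm's Dunn tests are reported for raw-p hits, mirroring how
  borderline trends are usually examined; only BH-adjusted Kruskal–Wallis
  p-values flag significance.
* One aorta VOI is required per phase; whether a reference should be
  propagated across phases instead is left to the segmentation upstream.
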