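# Methods

This note documents the models and procedures lesionkit implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design
was genuinely open.

## Spatial model

Every map lives on one shared voxel grid in a left-right aligned
template space. All operations are index-space operations: the package
never resamples, reorients or registers anything, and
`assert_same_grid` rejects inputs whose shapes differ or whose affines
differ by more than 1e-4 mm in any entry (enough to absorb float32
header round-off, tight enough to catch a 1 mm shift). Registration to
the template space is the responsibility of upstream tools.

Axis 0 of the voxel grid is treated as left-right. The enantiomorphic
mirror is taken about the grid mid-plane, (i, j, k) → (S−1−i, j, k), so
the left-right extent must be even and the image must already sit in a
symmetric template. Mirroring about the grid rather than the world
plane x = 0 is deliberate: with registration out of scope, the grid
mid-plane is the only mirror the data themselves define.

## Enantiomorphic filling

A lesion voxel receives the intensity of its mirrored location unless
that location is itself lesioned, in which case the voxel is left
untouched and reported in an "unfillable" mask. Bilateral overlaps are
reported rather than interpolated because inventing intensities would
misrepresent the method — bilateral lesions need a different route
(weighted registration) that this package does not provide. Raw
intensities are copied, not locally smoothed ones; nothing in the
procedure's definition requires smoothing, and raw copy keeps the
operation exactly idempotent and exactly inverse-free on symmetric
inputs.

## Tract disconnection (tractotron)

For each atlas tract the report carries the maximum atlas probability
over lesion voxels, and the tract is called disconnected when that
maximum is *strictly* above the threshold (default 0.5), following the
"above 50%" reading of the rule. The supra-threshold support's lesioned
fraction (`proportion_damaged`) is reported as the natural continuous
companion. Atlas maps whose maximum exceeds 1.5 are treated as
percent-scaled and divided by 100 with a log message; genuinely
out-of-range values are rejected.

## Disconnectome maps

The percentage-overlap map of N binarized visitation maps stores
100·k/N at a voxel visited by k controls. Disconnection status uses the
*inclusive* cutoff value ≥ 50 — the map is read "from 50% to 100%". The
deliberate contrast with tractotron's strict rule mirrors the two
different wordings of the two rules; both thresholds are parameters.

## AnaCOM2

Voxels are grouped into clusters by their exact patient-membership
pattern at the 50% disconnectome cutoff: identical membership implies an
identical split of behavioural scores, so the pattern is the only
computable criterion that guarantees "same score distribution", and it
makes clustering deterministic. Clusters need not be spatially
contiguous; a connected-component label map is written for reporting
only.

Clusters with volume strictly greater than 8 mm³ (a literal reading of
"larger than"; at 2 mm isotropic a single voxel sits exactly at the
boundary and is therefore dropped — the floor is configurable) enter a
three-group Kruskal-Wallis test on disconnected / spared / control
scores. Two Holm families are used: the Kruskal-Wallis p-values are
Holm-corrected across *all* tested clusters; clusters surviving at
alpha then receive a post hoc Mann-Whitney disconnected-vs-controls,
Holm-corrected across *those* clusters only, plus a
disconnected-vs-spared comparison reported uncorrected. A cluster in
which every patient is disconnected has no spared group; it is tested
as a two-group (disconnected vs controls) rank test with a logged
warning rather than crashing or silently pretending a third group
exists. The statistical map carries 1 − p (post hoc Holm p where the
post hoc ran, else the Kruskal-Wallis Holm p) in significant clusters
and 0 elsewhere.

## Rank statistics

The statistics layer is self-contained so that every branch is
verifiable against enumeration:

- Ranks are 1..n with ties averaged.
- Kruskal-Wallis H uses the tie-corrected form; a fully tied pooled
  sample (the correction denominator vanishes) is defined as H = 0,
  p = 1, so a voxelwise loop never crashes on degenerate clusters. The
  p-value is the chi-square upper tail with k−1 degrees of freedom.
- Mann-Whitney U is reported for the first group (the disconnected
  group in the cascade). The p-value is exact — computed from the full
  null distribution of U via the classical counting recursion — when
  n_a·n_b ≤ 400 and the pooled sample is tie-free; otherwise a normal
  approximation with tie-corrected variance and 0.5 continuity
  correction is used, and the result records which route was taken.
  Two-sided by default; the comparisons in the cascade do not declare a
  direction, and two-sided is the conservative choice.
- Holm is the step-down adjustment with running maximum, capped at 1.
- Spearman's rho is the Pearson correlation of tie-averaged ranks, with
  a t-approximation (n−2 df) p-value.

The sign convention of the first eigenvariate (used for WM/CSF confound
summaries) aligns the time course with the mean series of the voxel
set: its correlation with the mean course is non-negative. Negating all
inputs therefore negates the output together with the mean; negating
any subset of voxel series leaves the temporal direction unchanged up
to sign, because the time-domain Gram matrix is unchanged.

## Functional connectivity

The confound matrix has 16 columns: 6 motion parameters, the WM and CSF
first eigenvariates, and the [−1 0 1] central-difference derivative of
each of the 8 (endpoints set to 0; boundary behaviour is not otherwise
defined by the convolution). Regression always includes an intercept
even though it is not a listed confound: residualizing without
demeaning would leave the subsequent correlation step ill-defined for
constant offsets. Rank-deficient designs drop collinear columns via
pivoted QR with a logged warning. The seed summary defaults to the mean
time course (eigenvariate optional): both are defensible readings of
"the time course of the cluster", and the mean is the more common
default. Group networks are voxelwise medians of raw r (the network
threshold is stated on r, so no variance-stabilizing transform is
applied), and network masks keep voxels with r strictly above 0.3,
minus the patient's lesion.

## Entropy

Shannon entropy of a voxel's series is −Σ p·log p over an equal-width
histogram spanning that voxel's own [min, max]. Binning per voxel (not
globally) matches "the probability of the intensity in the voxel" and
buys exact invariance under affine intensity transforms of a voxel's
series. Constant series have entropy 0; the maximum is log(n_bins).
The default bin count is ceil(sqrt(T)) (the square-root rule) and the
default base is natural log, both configurable — the estimator of p and
the base are free choices that only rescale or re-resolve the map, and
none of the invariants depend on them.

## Synthetic data

The generator produces, from a seed, everything the pipeline consumes.
Defaults describe a desk-scale study: a 24×24×24 grid at 2 mm isotropic
(large enough for multi-voxel clusters, small enough for second-scale
tests), cohorts of 20 patients and 20 controls, a planted deficit of
2 SD in the disconnected patients, disconnection probability 0.5, and
200-frame time series at TR 2 s.

- Templates are smoothed white noise symmetrized by averaging with
  their own left-right flip, so mirror symmetry is exact by
  construction.
- Tracts are quadratic curves with Gaussian falloff of distance to the
  core (scale 4 mm), probability 1 on the core.
- Visitation maps thicken or thin the tract tube by a per-control
  random threshold shift (amplitude `jitter`), and are empty when the
  lesion misses the tract core — emulating lesion-seeded tractography's
  inter-control variability without simulating streamlines.
- Patient scores are Gaussian. The statistics under test are rank-based
  and invariant to the generating family, so Gaussian is a free choice
  that simplifies power calibration.
- Patient disconnectome maps are assembled from a library of 8 small
  corridor blobs shared across the cohort, each hit with probability
  0.3 per patient, plus the deficit region at 100% for disconnected
  patients. Shared corridors matter: real disconnectomes overlap
  heavily across patients, and it is the multi-patient membership
  patterns that give the cluster cascade a realistic Holm family
  (around ten clusters, the scale seen in practice). Fully private
  lesion maps would produce only single-patient clusters, which can
  never reach small Kruskal-Wallis p-values and would make the
  family-wise calibration meaningless.
- Time series plant a latent white-noise signal s(t): seed voxels carry
  s plus noise, target voxels carry coupling·s + sqrt(1−coupling²)·noise,
  everything else is independent noise, and six random-walk motion
  series plus two slow sinusoidal "physiological" series are mixed into
  every voxel with random weights — and returned in the confound table,
  so confound regression removes structure that is genuinely present.

What the generator does **not** emulate: realistic lesion shapes or
anatomy, hemodynamic response and autocorrelation of BOLD, scanner
drift, spatial smoothness of noise, registration error, or DWI signal.
Passing tests therefore demonstrate the correctness and calibration of
the *computations* under controlled conditions, not performance on
acquired data.

## Calibration properties and their limits

With the default cohort conditions, the family-wise rate of any
Holm-significant cluster on null cohorts (no planted effect) measures
≈ 0.02–0.04 over 200 seeds — controlled at, and as expected somewhat
below, the nominal 0.05, since the cluster tests share patients and are
positively dependent. Planted-effect recovery (Holm-significant KW and
post hoc MW for the cluster containing the planted region) at 2 SD
measures ≈ 0.90 over large seed sets: with ~10 clusters in the Holm
family, the smallest usable threshold is ≈ 0.005, and the power of a
three-group rank test at that level, with on average 10 disconnected
patients, is itself ≈ 0.9. Recovery estimates over only 50 seeds
therefore fluctuate by several percentage points around that value.
Power is monotone in effect size (≈ 0.0 / 0.15 / 0.9 at 0 / 1 / 2 SD).

## Determinism

All generators are pure functions of (parameters, seed); the CLI
requires a seed for every stochastic subcommand and writes gzipped
NIfTI with a zeroed gzip timestamp, so identical command + seed reruns
are byte-identical in every numeric output. The JSON sidecars record
the invocation (including input paths and hashes) and are the one
output that legitimately differs between runs made from different
directories.
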