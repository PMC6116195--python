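# Methods

This note records the model, the fixed conventions, the synthetic study
conditions, and the design choices that were genuinely open.

## Co-occurrence model

A joint intensity matrix (JIM) is the directional co-occurrence table of
two co-registered, quantized volumes over a region `R`: cell `(i, j)`
counts voxels `x` with level `i` in the first modality whose displaced
partner `x + L(d, θ)` carries level `j` in the second modality, with the
partner required to lie inside `R` (no padding, no wrap). The count matrix
is normalized by the total pair count into a probability table. A GLCM is
the self-paired JIM. Matrices are **not symmetrized**: the JIM's rows and
columns index different modalities, so symmetrization would be meaningless
there, and the GLCM follows the same directional convention for
consistency; averaging quantifiers over the four angles at aggregation time
supplies the usual rotational smoothing.

Conventions fixed here:

* **Quantization.** ROIs arrive min–max normalized to `[0, 1]` at the
  *whole-volume* level (normalize first, then cut the ROI — the reverse
  order would re-stretch each ROI and decouple its bins from the volume).
  Levels are `level(v) = min(floor(v·N) + 1, N)`: uniform bins on the fixed
  global range with a closed top bin so `v = 1` lands in level `N`. Each
  `N` in the bank re-quantizes the stored continuous ROI; coarser levels
  are never produced by merging finer ones, which would compound
  discretization error.
* **Displacements.** The four angles are in-plane:
  0° → `(d, 0, 0)`, 45° → `(d, −d, 0)`, 90° → `(0, −d, 0)`,
  135° → `(−d, −d, 0)` in `(x, y, z)` index steps, diagonals at Chebyshev
  distance `d` (the classic Haralick convention). Counts accumulate over
  every axial slice of the 3D ROI; slice-crossing displacements are not
  used — with only four planar angles defined and a 10-slice ROI this is
  the one internally consistent reading, and it is flagged as an
  interpretation.
* **ROI windows.** A window `w` centered at 0-based voxel index `c` spans
  `[c − (w−1)/2, c + (w−1)/2]` for odd `w` and the half-open
  `[c − w/2, c + w/2)` for even `w` (both give start `c − ⌊w/2⌋`). Windows
  that do not fit raise instead of clipping or padding, because padded
  voxels would inject artificial co-occurrence counts.
* **Resampling.** Trilinear interpolation onto a `ceil(extent/spacing)`
  grid; standard for MRI magnitude images, and no label volumes are ever
  resampled. Resampling at the native spacing is an exact no-op, which
  makes the operation idempotent.

## Haralick quantifiers

The 19 quantifiers use level labels `i, j ∈ {1..N}` (so distance-weighted
features are in level units), logarithms base 2 with `0·log 0 := 0`, and
the following degenerate-input rules chosen to keep every feature finite
and bounded: correlation is 0 when either marginal SD vanishes;
information correlation 1 is 0 when `max(HX, HY) = 0`; information
correlation 2 is clipped below at 0 before the square root. "Sum variance"
is centered on sum average (the variance of the `i+j` marginal), not on sum
entropy — the latter is a known slip in the original formulation.
"Difference variance" is the variance of the `|i−j|` marginal. These
variants are interpretations where the source names 19 functions without
printing formulas; they follow the standard IBSI-consistent readings and
are pinned by an independent naive-transcription oracle in the test suite.

First-order histogram features compute moment statistics (mean, population
variance, Fisher skewness, Pearson kurtosis) from raw voxel values, and
energy/entropy from a 64-bin normalized histogram on `[0, 1]`. The bin
count is a documented configuration default; nothing in the protocol pins
it.

## Signature and aggregation

A tumor's texture signature holds 57 features: the 19 quantifiers averaged
(unweighted arithmetic mean) over the full matrix bank — 5 levels × 4
distances × 4 angles = 80 matrices — separately for GLCM(T2), GLCM(ADC)
and JIM(T2 rows → ADC columns). Aggregation never mixes matrix families.
Features that depend only on the row marginal (e.g. sum-of-squares
variance) coincide between JIM(T2→ADC) and GLCM(T2) by construction; this
is a property of the definitions, not an implementation artifact.

## Statistics

Kruskal–Wallis (mid-ranks, tie-corrected, chi-square approximation with
k−1 df), Spearman rank correlation against the ordinal coding G1=1 < G2=2
< G3=3 (t-approximation), and two-sided Wilcoxon rank-sum (normal
approximation with tie correction) are delegated to scipy behind the module
surface; the Holm–Bonferroni step-down is authored here (sort ascending,
reject while `p(k) ≤ α/(m−k+1)`, stop at the first failure) and
cross-checked against statsmodels in the tests. The correction family is
every feature in the submitted table — 57 for the texture signature — and
the family size `m` is reported with the flags. Approximate (not exact
permutation) p-values match conventional usage at cohort sizes near 100;
exact enumeration appears only as a test oracle at n ≤ 6. A constant
feature gets `(rho, p) = (0, 1)` rather than NaN so screening whole tables
never fails on a degenerate column.

Which "Wilcoxon test" to run on three groups is ambiguous in the protocol;
the package implements the two-sided rank-sum and leaves the group pair to
the caller.

## Classification

Each Gleason grouping is a binary one-vs-all task on balanced splits:
20 positives + 20 negatives train, 10 + 10 test, drawn uniformly without
replacement. The forest is 500 CART trees (scikit-learn trees;
`sqrt(p)` features per split, unlimited depth, bootstrap samples of the
training size — the unstated hyperparameters default to the conventional
choices and live in the config). The bagging loop is explicit so per-tree
bootstrap and out-of-bag (OOB) index sets are first-class: the same
ensemble yields the test AUC (probability averaging over trees) and the
permutation importance.

Importance of feature `f`: for each tree, the increase in OOB
misclassification error (0.5 probability threshold) after permuting `f` on
that tree's OOB cases; the score is the ensemble mean of these increases
divided by their ensemble standard deviation (per-feature SD of the
per-tree increases — the "ensemble SD" normalizer is ambiguous in the
protocol and this per-feature reading is the one implemented). Positive
scores mark predictive features. The OOB error metric ("RF error") is
fixed as misclassification rate at threshold 0.5.

A single 500-tree run on one random split is seed-dependent, so the
default protocol reports mean ± SD over 25 repeated balanced splits;
`n_reps = 1` reproduces the strict single-split emulation. Every reported
number is a deterministic function of (cohort, split spec, seed).

## Synthetic study conditions

The generator emulates the *statistical* structure the method needs —
paired modalities with shared spatial texture and group-dependent
heterogeneity — not prostate anatomy or MRI physics. Per case, a latent
unit-variance Gaussian field (white noise smoothed with a Gaussian kernel,
correlation length 2 voxels, periodic boundaries) is shared between
modalities: modality A adds white noise (SD 0.2 in latent-SD units);
modality B mixes the latent field at coupling ρ = 0.6 with an independent
same-spectrum field and its own noise. Both are min–max normalized. ROIs
are 21×21×10; cohorts default to 30/39/30 cases across G1/G2/G3.

Group structure: the effect scalar δ = 0.3 multiplies the latent
correlation length by `(1+δ)` for G2 and `1/(1+δ)` for G3 (G1 baseline).
A coarser latent field occupies a narrower share of `[0, 1]` after min–max
normalization, so the additive noise claims proportionally more of the
range and co-occurrence contrast rises: contrast orders G2 > G1 > G3,
matching the direction of the reported group medians, while acting on
texture grain rather than mean intensity keeps first-order histogram
features weak discriminators. The sign of this mechanism was established
empirically; the intended ordering, not the sign convention, is the
modeling commitment.

What passing tests on phantoms do **not** show: robustness to
registration error, bias fields, acquisition heterogeneity, or anatomical
context — the phantoms are stationary Gaussian textures and real tumors
are not. They do show that the counting, quantization, statistics and
classification machinery is exact (oracle-verified) and that the pipeline
detects planted cross-modality texture effects at realistic cohort sizes.

Problem sizes used by the reproduction script: the full default cohort
(99 cases, full 80-matrix banks, 500 trees, 25 repeated splits per task).
The test suite uses reduced sizes (smaller ROIs, trimmed banks, fewer
trees) chosen so each property is still sharply tested.

## Known limitations

* Single-split AUCs at test size 20 are coarse (granularity 1/100) and
  seed-sensitive; prefer the repeated-split summary.
* The importance normalizer and the planar-displacement reading are
  documented interpretations of an underspecified protocol.
* DICOM ingestion is out of scope; convert series to NIfTI upstream.
* The phantoms' group effect acts symmetrically on both modalities'
  texture grain, so single-modality GLCM features also separate groups —
  isolating a JIM-only effect requires constructing coupling-only
  contrasts (the classification tests do this with planted feature
  cohorts instead).
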