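# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices and the known limitations of `cartifuse`.

## Study structure and data model

The package targets paired damage/control spectroscopy studies: a set of
knee joints each contributes damaged cylindrical specimens and adjacent
control specimens; every specimen is measured in several modalities (MIR,
NIR, Raman) with a few replicate spectra. The reference design is 10
joints × (6 damaged + 6 control) = 120 specimens, the 60 damaged split
evenly over five treatment subgroups (impact M1, abrasion M2, collagenase
24 h E1, collagenase 90 min E2, trypsin E3), 3 replicates per specimen.
One specimen can be excluded from *all* blocks (multi-block analysis
requires sample-to-sample correspondence), which yields the 59-vs-60
sample sizes used in the fused models.

A `SpectralBlock` is one modality's wide matrix (rows = spectra, columns =
wavenumber channels, strictly ascending axis); a `StudyDesign` carries
sample/joint/class/subgroup/replicate metadata; a `BlockSet` is an ordered,
row-aligned collection of blocks. All I/O is delimited text with the
wavenumbers as the header row.

## Preprocessing

Five per-spectrum stages, applied in the order clip → Savitzky–Golay →
SNV → trim (configurable via `PreprocessSpec.stage_order`):

| modality | derivative | SG window | SG poly | trim (cm⁻¹) |
|----------|-----------:|----------:|--------:|-------------|
| MIR      | 2          | 201       | 3       | 900–1800    |
| NIR      | 0          | 5         | 3       | 4545–8333   |
| Raman    | 1          | 205       | 3       | 800–1800    |

Numerical choices:

* **Derivatives before trimming.** The large SG windows need the wide
  untrimmed axis; differentiating first keeps the filter's edge handling
  (polynomial fits in truncated windows, output length = input length)
  away from the analysis window. Consequence: after SNV + trim, row means
  are *near* zero rather than exactly zero (the test suite asserts
  |mean| < 0.5; in practice it is ~10⁻²).
* **Derivative w.r.t. channel index**, not cm⁻¹: window sizes are given in
  channels and the constant-spacing rescale is absorbed by SNV.
* **SNV uses the sample standard deviation (n − 1).** Either convention
  differs only by a row-constant factor later removed by Frobenius
  scaling; n − 1 fixes the convention [1, 2, 3] → [−1, 0, 1].
* **Replicates are preprocessed individually, then averaged per sample**
  before modelling: model rows must be samples for leave-one-joint-out
  cross-validation to be well defined. (Averaging before preprocessing is
  available by composing the primitives directly.)
* Clipping defaults to no regions; the hook exists for detector-edge or
  spike removal.

Constant rows are rejected by SNV with the offending row named; every
stage is per-row, so row permutations commute with preprocessing.

## PLS1-DA

Single 0/1 response NIPALS PLS (PLS1): for two classes the two-column
dummy variant is equivalent up to an affine map, so the scalar response is
used. X is mean-centred, never autoscaled — SNV and Frobenius scaling
already handle scale, and channel-wise autoscaling would fight derivative
preprocessing. Only X is deflated (y deflation is redundant for PLS1).
Coefficients for any truncation a ≤ A come from b_a = W_a(P_aᵀW_a)⁻¹q_a,
so one fit yields the whole nested model sequence — this is what makes
per-LV cross-validation curves cheap. The classification threshold is
fixed at 0.5; ties go to class 0.

Degenerate inputs raise: single-class y, A > min(n − 1, p), zero-variance
X, and exhausted covariance (‖Xᵀy‖ ≈ 0) during deflation.

Two algebraic facts the test suite relies on: at full rank, PLS1 equals
the minimum-norm least-squares fit; rescaling X by c leaves predictions
unchanged while scores scale by c and coefficients by 1/c (weights are
unit-norm). Note that adding a duplicated channel *does* change a
truncated-A fit (only the full-rank fit is column-space-invariant), and
training misclassification need not be monotone in A (training RSS is).

## Multi-block fusion

Scaled-concatenation MB-PLS: each block is divided by its Frobenius norm
(computed on **uncentred** training entries; test rows are divided by the
training norm), blocks are concatenated and fitted with plain PLS1. This
is the variant whose super-scores equal the concatenated-PLS scores — one
global score vector per LV. Block importance per LV is the squared-norm
share of the super-weight vector; shares are in [0, 1] and sum to 1.

Correlation loadings are plain Pearson correlations of a variable (a
spectral channel, or a supplementary 0/1 design dummy) with the global
score vectors of a chosen LV pair — global rather than block scores, to
match a single global score plot. A zero-variance variable has an
undefined correlation and is reported as missing, never as zero.

## Cross-validation and reporting

One fold per joint. Within each fold the Frobenius norms, centring means
and the PLS fit are computed from training rows only; the fold errors if
its training set is single-class (the joint is named). The LV count A* is
the argmin of the out-of-fold misclassification rate, ties broken toward
fewer LVs; RMSE-based selection is available (`selection="rmse"`). A* is
selected on the same cross-validation used for reporting (non-nested) —
the reported accuracy therefore carries selection optimism, which the
report notes explicitly; nothing in the fold construction leaks, but the
*selection* step sees all folds. Confusion matrices are row-normalised to
integer percentages only at the reporting boundary; accuracy is always
recomputed from unrounded per-class fractions.

## Interpretation

Super-coefficients are sliced at block boundaries and divided by the block
norms, giving per-modality coefficient vectors that apply to
preprocessed-but-unscaled spectra (their concatenation predicts
identically to the fused model). Discriminative bands are local extrema
of |b| (strict neighbour comparison; plateaus keep their leftmost channel;
a constant vector has none), ranked by |b| and greedily thinned so that no
two selected bands lie within `min_separation` (default 10 cm⁻¹) — on
instrument-resolution grids the noise wiggles of one strong band would
otherwise fill the whole list. `min_separation=0` recovers the raw
ranking. The correlation-plot table joins the selected bands with one
dummy per damage subgroup (supplementary variables — the model is fit on
damaged-vs-healthy only) and flags points with r₁² + r₂² < 0.25 as not
explained by the chosen LV pair.

## Synthetic data generator

Each replicate spectrum is a Gaussian-band mixture on a linear baseline
with multiplicative scatter and i.i.d. noise:

    s(ν) = m · Σ_k a_k exp(−(ν − c_k)²/(2w_k²)) + b₀ + b₁ν + ε(ν),
    a_k  = base_k + δ_k·class + subgroup shift_k + joint effect.

* **Band positions** default to features named in the cartilage
  spectroscopy literature: MIR 1740 (ester), 1655 (amide I), 1564
  (amide II), 1245 (amide III); NIR 4726, 4829 (protein combination
  bands); Raman 1004 (phenylalanine), 1250 (amide III), 1665 (amide I) —
  so interpretation tests are anchored to recognisable bands.
* **Axes** are sampled at instrument-like resolution: 0.25 cm⁻¹ for MIR
  (400–4000) and Raman (200–3400), 10 cm⁻¹ for NIR (4000–10000). The SG
  windows are fixed *channel* counts, so the grid must be fine enough that
  a 15–20 cm⁻¹ band spans a substantial part of a 201-channel window;
  coarser grids would flatten every band.
* **Class effect** δ: `default_config` plants δ = 0.06 (3× the replicate
  noise sd 0.02) on two or three bands per modality; `strong_config`
  δ = 0.15 (7.5×); `null_config` δ = 0 everywhere. The E1 subgroup
  carries an extra +0.08 amplitude shift on one band per modality, so the
  model explains E1's variation somewhat better than the other groups'.
* **Joint effect**: one additive amplitude shift per joint (sd 0.05),
  shared by all of that joint's samples and both classes — the minimal
  structure that makes leave-one-joint-out CV different from
  leave-one-sample-out. Within-sample draws (scatter m ∈ [0.8, 1.2],
  baseline offset ∈ [0, 0.2], slope ∈ ±10⁻⁴) are per sample; noise is per
  replicate.
* **Hierarchical seeding**: one study seed spawns per-joint, per-sample
  and per-replicate generators keyed by stable identifiers, so dropping a
  sample leaves every other spectrum bit-identical.
* **Ground truth**: the channels within ±2 widths of any δ ≠ 0 band.

What the generator does *not* emulate: ATR penetration depth, radiative
transfer, cosmic-ray spikes, wavelength-dependent noise, instrument drift,
non-Gaussian lineshapes, and any real biochemical covariance structure
between bands. Passing tests therefore demonstrate the *statistical
machinery* — unbiasedness under the null, power under a planted effect,
leakage-free fold construction, scale invariance — not classifier
performance on real tissue. The replicate-to-sample variance ratio is not
derivable from the study description and was chosen for testability.

## Problem sizes and runtime

Tests and the acceptance script use the reference design (120 samples,
three modalities, ≈8 000 channels after trimming, A_max = 10, 10 folds);
a full seven-family cross-validation takes a few seconds on one CPU, and
the complete suite runs in under a minute.

## Known limitations

* Non-nested LV selection (matching the reporting convention here): the
  reported accuracy at A* is optimistic under the null — a null study's
  selected-LV accuracy averages ≈0.56 rather than 0.50, because A* is the
  argmax over 10 correlated accuracy curves. Use the full accuracy curve
  or nested selection for unbiased estimates.
* Grouped folds make out-of-fold predictions within a joint correlated;
  accuracy therefore has greater-than-binomial variance across studies.
* Two classes only; no probabilistic calibration; no SIMPLS/kernel PLS;
  no sequential or compression-based fusion variants.
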