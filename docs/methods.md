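# Methods

## Problem and model

A transferred blastocyst either implants (urinary hCG ≥ 25 IU/mL at 14
days, "hCG-positive") or does not. The analysis asks whether the raw
pixel brightness of the pre-transfer micrograph carries information
about that outcome which the Gardner grade (expansion 1–6 + ICM/TE
letter grades) does not, and condenses the answer into a single derived
morphological indicator: *graininess* — whether individual cells are
visually distinct in the embryo interior.

The statistical machinery is an eigenface-style decomposition. Each
image is reduced to a circularly masked, 64 × 64, row-major 4096-vector;
the cohort matrix X (n × 4096) is column-mean-centered and factored
X − μ = U S Vᵀ. Rows of Vᵀ are orthonormal *basis images*, S²/ΣS² are
*contribution ratios*, and U S are per-embryo *scores*. Pixels share
units (brightness), so columns are centered but never scaled to unit
variance. All components with nonzero singular value are retained; for
n ≪ 4096 that is at most n − 1 components.

Downstream, per component, the two outcome groups' score distributions
are compared with the two-sample Kolmogorov–Smirnov test; selected
components get an ROC-derived oriented threshold; the OR over those
thresholds is the grainy/non-grainy call; and the call is benchmarked
against the Gardner ≥ 3BB "good quality" rule (expansion ≥ 3 and ICM,
TE ∈ {A, B}) on accuracy, precision, recall, specificity, F₀.₅/F₁/F₂,
McNemar's paired test, abortion rates and maternal-covariate screens.

## Pipeline conventions

* **Coordinates** are (row, col), 0-based, pixel centers at integer
  positions.
* **Circular crop**: the (2r+1)×(2r+1) bounding square, pixels with
  center distance > r zeroed; the boundary pixel (distance = r) is
  kept. The circle must lie inside the image.
* **Resize**: bilinear to 64 × 64 (the default scaling of common image
  tools); output clipped to the input range. After resizing, the
  canonical inscribed-circle mask of the 64-frame (center (31.5, 31.5),
  radius 31.5) is re-applied, so interpolation cannot leak brightness
  into the corners. Both behaviors (re-mask or not) are implemented;
  re-masking is the default.
* **No per-image brightness normalization** by default; a flag exists
  but analysis and tests run without it.
* **PCA determinism**: each component's sign is fixed so its
  largest-magnitude loading is positive; ties resolve to the first
  pixel index. Two fits of the same matrix are bit-identical.
* **Component indexing** is 1-based everywhere a user sees it ("PC3" is
  the third component).
* **KS test**: D is the supremum of |F̂x − F̂y| over pooled points (both
  ECDFs evaluated at every pooled value, so ties are exact); p is the
  plain asymptotic Kolmogorov series at effective size
  nₑ = n₁n₂/(n₁+n₂), clamped to [0, 1]. At ~100 per group this is the
  standard large-sample approximation; it is mildly conservative (the
  measured type-I rate at 60 per group is ≈ 0.045 at nominal 0.05).
  Selection uses the **raw** p-value at α = 0.05 — a deliberately
  liberal, hypothesis-generating screen across all (~n) components —
  with Benjamini–Hochberg adjusted values always reported beside it so
  the multiplicity cost is visible. In realistic cohorts the adjusted
  values rarely survive; the screen is a discovery device, not a
  confirmatory test.
* **ROC**: candidate cutoffs are midpoints between consecutive distinct
  scores plus ±∞; AUC by the Mann–Whitney rank formula with ties as ½
  (exactly the trapezoidal area of the empirical curve); the operating
  point maximizes Youden's J = TPR − FPR (configurable to
  closest-to-top-left), ties broken toward higher TPR then smaller
  |cutoff|. Orientation: the grainy side of each component is the side
  with the higher hCG-positive mean score; when no orientation is
  supplied, the sign giving AUC ≥ 0.5 is used and recorded.
* **OR rule**: grainy iff orientation·(score − cutoff) > 0 on ≥ 1 rule
  component; scores exactly at a cutoff are non-grainy ("exceeding"
  is strict).
* **Rule pruning**: an OR rule loses specificity with every threshold
  it adds, and a KS hit can be a pure spread difference (AUC ≈ 0.5)
  that is useless for a one-sided threshold. `derive_rule` therefore
  keeps the `max_components` (default 2 — the classic two-axis rule)
  selected components with the highest oriented AUC, and drops any
  whose discrimination (AUC − 0.5) is below half the best component's.
  `max_components=None, min_relative_auc=0` restores the unpruned OR
  over everything selected.
* **Combined AUC**: the continuous analogue of the OR rule is the
  maximum over rule components of the standardized oriented exceedance
  (score − cutoff)/SD; its AUC is the "combination" figure. A logistic
  combination of the same standardized scores is provided as an
  alternative; in-sample it never loses appreciable AUC against the
  best single component, whereas the max-rule can when component
  qualities are very unequal. Both methods are recorded in the rule.
* **Selection optimism caveat**: orientations and cutoffs are fit
  in-sample. Under a true null, data-driven orientation alone inflates
  the apparent combined AUC to ≈ 0.56 at n = 120; the package's null
  calibration tests therefore prespecify orientation. Screened-then-
  thresholded AUCs on the training cohort should be read as
  descriptive, not as out-of-sample performance.
* **McNemar**: chi² = (max(|b−c|−1, 0))²/(b+c) with continuity
  correction (default; without, (b−c)²/(b+c)), 1 df upper tail. The
  |b−c|−1 term is clamped at 0 so the correction can only move the
  statistic toward the null.
* **Two-proportion test**: Pearson chi-squared with Yates correction on
  the 2×2 table; p-values below 2.2 × 10⁻¹⁶ are displayed at that
  floor. The abortion comparison — events among predicted-grainy
  implantations vs among all implantations — compares a subset with its
  superset, so this test is conservative there (measured: mean null p
  ≈ 0.8, essentially zero rejections at 0.05); it is reported the way
  the field reports it, with this caveat.
* **Display rounding**: 2 decimals for rates and F-measures, nearest
  percent for abortion rates; full precision is always retained in the
  JSON artifacts.

## Synthetic cohort generator

The generator exists so that every stage is testable without clinical
images. It emulates the *statistical structure* the analysis consumes,
not photorealism.

Each phantom is a disk (radius 80–104 px on a 256-px canvas by default;
the smallest supported canvas is 64 px) on a dark background: a
brighter annular zona ring (outer 14% of the radius) around an interior
cell mosaic — a jittered-grid nearest-site partition (~30 cells per
cross-section, matching a day-5 blastocyst's visible cell count) with
per-cell brightness offsets and darkened cell boundaries, both scaled
by `grain_contrast` (default 40 brightness units). Non-grainy embryos
additionally get (i) a blurred copy blended over the interior with a
radial taper (σ = `smooth_sigma` × a per-embryo factor in [0.7, 1.3];
default σ 6 px), washing out cell boundaries and softening the inner
zona edge while the outer contour stays sharp; (ii) low-contrast debris
speckles; and (iii) a per-embryo uniform interior haze in
[0.05, 0.30] × `grain_contrast`. Additive Gaussian sensor noise
(SD 4) is clipped to the 8-bit range. At `grain_contrast = 0`,
`smooth_sigma = 0`, `noise_sd = 0` the interior is exactly constant.

The per-embryo variation of blur and haze is deliberate: it makes the
two class signatures (edge softening, interior brightness) vary
independently across embryos, so the decomposition spreads them over
*separate* leading components rather than one — the structure the
two-axis rule presumes. At the default contrast, a simple within-embryo
Laplacian-energy statistic separates the latent classes with AUC ≈ 1.0
(the calibration the texture-separation tests assert at > 0.9).

Metadata is drawn per embryo from a per-record substream of one global
seed (reproducible at record granularity): hCG status first (cohort
sizes default 129/105), grainy morphology conditional on hCG (defaults
P(grainy | positive) = 0.65, P(grainy | negative) = 0.38 — the rates
implied by the clinical graininess call's recall and specificity);
fragmentation respects a hard rule — embryos with ≥ 20% fragmentation
are non-grainy, and (at the default `frag_high_rate_nongrainy = 1`)
every non-grainy embryo carries ≥ 20%; the Gardner ≥ 3BB call is drawn
independently of morphology with sensitivity 0.96 and specificity 0.029
for the hCG outcome, and a score string consistent with the binary call
is attached; abortion (implantations only, rate 0.248), age (normal,
means 33.3/34.0 and SDs 3.1/3.3 years by morphology class), BMI
(normal, 21.5 ± 2.5), AMH (lognormal, median ≈ 3 ng/mL) and evaluation
day (5/6/7 at 0.8/0.15/0.05) fill the covariate screens. With
`exact_strata=True` (the "paper-scale" configuration) the per-stratum
counts are rounded deterministic rather than Bernoulli, which pins the
fragmentation cross-tab at exactly 110/110 and 0/124.

What the generator does **not** emulate: optical focus variation,
ICM position and size (not evaluable by this decomposition), zona
thickness variation, real cell-count distributions, or any correlation
between Gardner grade and morphology (independence is the modeled
approximation of the clinical finding that graininess and grade do not
differ significantly). Passing tests therefore show the *pipeline*
recovers planted structure under its own assumptions — they are not
evidence about clinical images.

## Test and calibration sizes

The suite runs on reduced renderings (64-px canvas, radius 20–26 px)
with cohorts of 40–120 embryos, chosen so the full suite and the
acceptance script each complete in well under a minute on one CPU while
leaving every distributional check adequately powered: strong-effect
recovery uses P(grainy | ±) = 0.95/0.05 over 10 seeds (mean combined
AUC ≈ 0.96); the null screen calibration uses 200 label permutations of
one 120-embryo cohort (~24 000 KS tests, measured rate 0.046 against
the asymptotic test's expected ≈ 0.045); the acceptance script itself
runs the full 234-embryo, 256-px configuration.

## Known limitations

* The OR rule and its thresholds are derived and evaluated on the same
  cohort; no cross-validation is built in (out-of-sample scoring is
  available via `project` on held-out matrices).
* The raw-p screen is anti-conservative by construction; BH-adjusted
  values are the honest multiplicity-controlled companion.
* The max-exceedance combination has no no-harm guarantee when
  component qualities differ; the logistic alternative does, in-sample.
* Synthetic Gardner calls are independent of morphology by design, so
  any concordance between graininess and Gardner in synthetic runs is
  sampling noise.
* The abortion-rate comparison inherits the overlapping-groups
  conservatism described above.
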