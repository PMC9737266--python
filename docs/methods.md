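# Methods

## Data model

A `SpectraSet` holds absorbance-like spectra (one row per measurement) on a
strictly descending wavenumber grid, 10,000 → 4,000 cm⁻¹ at 8 cm⁻¹ steps
(751 points), with per-spectrum sample id, replicate index (1–3) and
species label, and a per-sample reference table of 18 lipid parameters.
Replicates are independent rows throughout: all protocol counts
(33 + 4 + 4 calibration spectra out of 48 + 6 + 6) arise only if replicates
are split individually, so nothing in the pipeline averages them.

Five fixed spectral regions partition the informative range (bounds
inclusive, cm⁻¹): R1 [4016, 4961], R2 [4964, 5423], R3 [5427, 6079],
R4 [6083, 7776], R5 [7780, 9975]. R2 and R4 contain the strong water
bands; R1 and R3 the lipid combination/first-overtone bands. Region
subsetting concatenates the chosen regions in descending-wavenumber order
and records block boundaries so windowed operators never act across a gap.
A wavenumber claimed by two regions (impossible on this grid, but guarded)
goes to the lower-numbered region. Grid mismatch between files is an error,
never an interpolation trigger: the pipeline assumes one instrument grid.

## Preprocessing

Operators compose in the listed order; the label `SG(15,2,1) + SNV` means
Savitzky–Golay first, SNV second.

* **SNV** — per-spectrum centering/scaling to unit sample sd (ddof = 1),
  applied to the concatenated selected-region vector (one normalization per
  spectrum): it corrects multiplicative scatter and additive offset, which
  are spectrum-wide effects.
* **Savitzky–Golay** — local polynomial filter parameterized as
  (width, polyorder, derivorder), applied independently within each
  contiguous region block. Edge points are evaluated from the least-squares
  polynomial over the nearest full window (scipy's `mode="interp"`), so
  output length equals input length and the filter is exact on polynomials
  of degree ≤ polyorder everywhere; region blocks can be short, and
  dropping half-window edges per block would bias small regions.
  Derivatives are taken with respect to sample index; the constant 8 cm⁻¹
  spacing makes this a global scale factor on d/dν that centering and
  regression absorb.
* **Mean-centering / autoscaling** — the only fitted steps; column
  statistics are estimated on calibration rows and applied unchanged to new
  rows. They must come last in a pipeline. In the spectral workflows,
  centering is performed by the latent-variable models themselves (which
  store their centering vectors); explicit autoscaling is used for the
  chemical-values workflow.

The model-search grid uses six preprocessing labels: `none`, `SNV`,
`SG(15,2,1)`, `SG(15,2,0) + SNV`, `SG(15,2,1) + SNV`, `SG(15,2,2) + SNV` —
the label set that a width-15, order-2 Savitzky–Golay family combined with
SNV produces in practice. Widths are configurable; regions are cut first
and filters applied per block (the alternative — filter the full spectrum,
then cut — is a documented reproducibility caveat, as the two differ near
block edges).

## Latent-variable engines

**PCA** is computed by SVD of the centered matrix (same subspace as the
iterative form, better conditioning). Explained-variance percentages come
from squared singular values. Outlier screening uses Hotelling's
T²ᵢ = Σₐ t²ᵢₐ/λₐ over the retained components with the F-distribution limit
a(n−1)/(n−a)·F(α; a, n−a), and the Q statistic (squared reconstruction
residual) with the Jackson–Mudholkar limit from the discarded eigenvalues.
The confidence level defaults to 99%; flags are advisory, never an
automatic removal. On clean data, about 1% of spectra per statistic are
expected to exceed the limits marginally; screening is for gross outliers.

**PLS1** uses NIPALS with deflation: per component, w = Xᵀy/‖Xᵀy‖, t = Xw,
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then deflate X and y. The regression vector for
k components is b = W(PᵀW)⁻¹q, so prediction is ŷ = ȳ + (x − x̄)ᵀb. NIPALS
(rather than SIMPLS) makes component-wise truncation during
cross-validation trivial; at one latent variable the two coincide, which
the test suite uses as an oracle, and at full rank NIPALS reproduces
minimum-norm least squares. If the response becomes orthogonal to the
deflated X, fitting stops early with a warning.

**PLS-DA** is PLS2 (NIPALS with an inner convergence loop) on the one-hot
indicator matrix over the fixed class order (Aleppo, Maritime, Brutia).
Assignment is argmax of predicted indicator scores; ties break toward the
earlier class — a deterministic minimal convention. Because the centered
one-hot columns sum to zero, predicted scores sum to 1 for any input.

## Model-optimization protocol

* **Split** — random 70/30 at the spectrum level. Discrimination: per-class
  floor(0.7·n). Regression: rejection-resampling (≤ 10,000 draws) until
  every validation value of the target parameter lies inside the
  calibration range, with a fallback that forces the extreme-holding
  spectra into calibration. Spectrum-level splitting lets replicates of one
  sample straddle the two sets — this is what yields the reference protocol and
  its counts, and is an acknowledged leakage risk; `group_replicates=True`
  gives the sample-level variant. Splits are re-drawn per parameter (the
  range constraint is parameter-specific) via a deterministic
  seed-and-index derivation.
* **Cross-validation** — leave-one-sample-out: folds are the distinct
  calibration samples; a fold holds out every calibration-resident
  replicate of one sample. Fitted column statistics are re-estimated inside
  each fold; SNV and Savitzky–Golay are row-wise and use no cross-spectrum
  information, so they are applied once up front. The per-LV curve is
  pooled RMSECV (regression) or percent-correct (discrimination);
  the chosen LV attains the optimum, smallest LV on ties. The scan is
  capped at the feasible per-fold training rank, with a warning.
* **Grid search** — all 31 non-empty region combinations × the 6
  preprocessing labels by default (186 candidates), each scored by CV on
  calibration rows only. Selection is lexicographic: lowest RMSECV, then
  lowest RMSEC, then fewer LVs, fewer regions, grid order (a
  protocol asking for both "lowest RMSEC and RMSECV" needs a tiebreak; CV
  error leads here because it is the protocol's own guard against
  over-fitting). Discrimination mirrors this with highest CV
  percent-correct, then highest calibration percent-correct. The validation
  rows are untouched until the single final projection. Maximum LV scanned
  defaults to 10.
* **Chemical-values discrimination** — no region/preprocessing grid; the
  replicate-level chemical matrix (assay replicates used directly, never
  averaged) is autoscaled on calibration rows, the LV count chosen by the
  same CV, and parameter influence ranked by the L2 norm of each
  parameter's row of the regression-coefficient matrix across the three
  class columns.

## Figures of merit

RMSE = √(Σ(cᵢ−ĉᵢ)²/n); the RMSEC/RMSECV/RMSEP distinction is purely which
set is evaluated. R² = 1 − SSE/SST about the evaluated set's own mean (the
standard coefficient of determination; a squared-correlation variant sits
behind a flag and the two coincide for least-squares fits evaluated on
their training set). RER = (Ymax − Ymin)/RMSEP with the extremes taken over
the parameter's **full** reference range — the convention under which the
tabulated total-fat and vitamin-E worked examples reproduce exactly.
Reports round errors to 3 significant figures, R² to 2 d.p. and RER to
1 d.p.; stored values are full precision. Confusion matrices have true
classes as rows; cells print as `93.3%(14/15)` and the overall score is
100·trace/total.

## Synthetic-spectra generator

The generator emulates the study design: 16/2/2 samples per species, three
replicate spectra each, on the instrument grid.

**Composition.** Individual fatty acids are drawn uniformly in their
observed ranges and rejection-sampled until each family sum (SFA, MUFA,
PUFA — stored as the exact sums of their constituents) falls in its own
observed range and the grand total lies in (90, 100], as befits relative
percentages. Total fat and vitamin E are drawn uniformly. Species enter
through sub-windows of the global ranges for total fat, vitamin E and
C14:0 (the discriminative acid), and through a per-species multiplier on
the latent cellulose level — so spectra and chemical values both carry a
recoverable species signal, with effect sizes chosen to yield a
diagonal-dominant (not perfect) validation confusion matrix.

**Spectra.** Clean spectra are linear Beer–Lambert mixtures
Σₖ wₖ·cₖ·sₖ(ν) of Gaussian-band component signatures: oil bands at 8300,
5840, 5700, 4640 and 4340 cm⁻¹; protein 4860; cellulose 4255 (+5400);
water 5200 (R2) and 6900 (R4); vitamin E 5520/5410; and a broad static
carbohydrate/protein "matrix" background common to all samples.
Each fatty acid receives a copy of the oil band set with per-band
amplitude jitter (sd 0.15) *and* small center shifts (sd 10 cm⁻¹), fixed
at library creation: the shifts keep the 14 oil/acid signatures linearly
independent — amplitude jitter alone would leave them all in the 5-dim
span of the shared bands, making per-acid recovery impossible even from
noiseless data — while remaining strongly collinear, which is the real
difficulty of resolving acids by NIR. The static matrix background
dominates total absorbance, as the seed matrix does in real reflectance
spectra; it keeps the SNV denominator nearly constant so the mixture stays
close to linear after scatter correction (without it, SNV normalizes the
dominant oil signal away, a closure artefact).

**Replicate disturbances** (defaults in parentheses): lognormal
multiplicative scatter (sd 0.10), additive constant offset (sd 0.02) and
linear-in-index ramp (sd 0.01), white noise per channel (sd 0.008), and a
per-replicate lognormal rescaling of the water contribution (log-sd 0.25)
that makes R2/R4 unreliable — the search learns to avoid them. Scatter +
offset are exactly what SNV removes (a tested invariant), the ramp is what
the first derivative removes. The white-noise sd was calibrated once so
that the best total-fat prediction R² lands in the 0.85–0.95 regime of a
realistic feasibility study, then pinned; with all disturbances off, the
18 independently varying components are recovered exactly at 18 latent
variables (tested to < 10⁻⁶ of the parameter range).

**What the generator does not emulate:** Kubelka–Munk/radiative-transfer
scattering physics, temperature or moisture band shifts, instrument drift,
non-Gaussian band shapes, and any real covariance between fat content and
acid profile. Passing recovery tests therefore demonstrates that the
pipeline's statistics and protocol are implemented correctly under the
assumed data model — not that the same accuracy would be reached on real
seeds.

## Problem sizes and numerical choices

The test suite and acceptance checks run the full pipeline at the study's
design size (60 spectra) with a reduced region search — combinations
{R1, R3, R1+R3, R1+…+R5} × the 6 preprocessing labels — which preserves
every protocol stage while keeping a 10-seed replication fast; the full
31-combination search gives the same qualitative outcome (validation
accuracy 89.5% on the first seed) at ~8× the cost. Ten seeds (0–9) are
used for the median-performance checks; generator defaults are pinned, and
the only pipeline seed inputs are the split seed and generator seed.

Tolerances: orthogonality and identity invariants at 1e-8; oracle
agreement (least squares, SIMPLS, eigendecomposition) at 1e-6–1e-10;
Savitzky–Golay polynomial exactness at 1e-9. Degenerate inputs fail loudly:
zero-variance spectra under SNV, zero-variance columns under autoscaling,
single-class training sets, region blocks shorter than a filter window,
non-monotonic or irregular grids, and mismatched spectrum/metadata
identifiers all raise errors naming the offender. Rank deficits (PCA
components beyond rank, infeasible LV scans, early NIPALS termination)
reduce gracefully with warnings.

## Known limitations

* The spectrum-level split is the protocol's own leakage flaw; the
  sample-level option exists but changes the reference counts.
* RER uses the full reference range, so it is not a pure validation-set
  statistic.
* The Q-limit approximation degrades when few residual eigenvalues remain;
  the limit collapses to 0 when the model captures everything.
* JCAMP-DX support covers only single-block `(X++(Y..Y))` tables —
  enough for simple instrument exports, not the full standard.
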