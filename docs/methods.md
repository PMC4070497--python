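# Methods

## Emission model

Each endogenous fluorophore contributes one asymmetric Gaussian band.  We
use the skew-normal shape — the convolution of a Gaussian with a
half-Gaussian — written in standardized coordinates as
`s(z; τ) = exp(−z²/2) · Φ(τz)`, where Φ is the standard normal CDF and τ
the dimensionless asymmetry (τ = 0 recovers the pure Gaussian; positive τ
skews the band to longer wavelengths).  The location/scale parameters are
*not* exposed directly: for every τ the mode and half-maximum crossings of
`s` are solved numerically (bracketed root finding, cached per τ), and the
profile is rescaled so that `center_nm` and `fwhm_nm` are the **realized**
peak position and full width at half maximum and the peak value equals
`amplitude`.  This makes published (λ, FWHM) constants usable verbatim for
any asymmetry; a dense-grid (0.01 nm) brute-force oracle in the test suite
confirms the realized parameters match the declared ones to 0.1 nm for
|τ| ≤ 1.

The default library holds seven components.  Five have fixed shapes — free
NAD(P)H (463 nm / 115 nm), bound NAD(P)H (444 / 105), flavins (526 / 81),
vitamin A (488 / 102), fatty acids (470 / 90) — and vary only in amplitude.
Protein (collagen-dominated) emission enters the window as a blue tail, so
its center is free in [380, 440] nm (it may sit at or below the grid start,
leaving only the descending limb visible), FWHM free in [60, 140] nm.
Lipofuscin-like lipopigments are chemically heterogeneous: center free in
[560, 620] nm around 587 nm, FWHM free in [50, 110] nm around 80 nm.  Both
free-shape components also get a free asymmetry in [−1, 1]; all other
components default to τ = 0, since only λ and FWHM are established for
them.

Wavelength grids are uniform, inclusive, grid-point-centered; presets are
400–750 nm (fiber-optic, in vivo) and 400–680 nm (microspectrofluorometry
of sections), 1 nm step.  Spectra are peak-normalized to exactly 100 a.u.
before fitting (the maximum sample maps through `x/max·100`, which is
bit-exact at the peak).

## Fitting

The model is linear in the amplitudes and nonlinear only in the free shape
parameters, so the fit uses variable projection: at every evaluation of the
shape parameters θ the amplitude subproblem `min‖B(θ)a − y‖², a ≥ 0` is
solved exactly by NNLS, and the outer bounded least-squares solve
(`scipy.optimize.least_squares`, trust-region reflective — a
Levenberg–Marquardt-type iterative scheme honoring box bounds) sees only θ.
This is strictly stronger than warm-starting amplitudes once and folding
them into the nonlinear vector, and measured ~13× faster on the
seven-component problem.  Convergence: relative χ² change < 1e−10 or
parameter step < 1e−8, at most 500 outer evaluations per start.

A single local solve cannot certify the global χ² minimum, so `n_starts`
(default 5) seeded restarts jitter the free shape parameters uniformly
inside their bounds; the lowest-χ² solution wins, ties broken by first
found.  Purely linear problems (no free shapes) are solved once by NNLS,
which is already exact.  Reported per fit: χ², r² = 1 − χ²/Σ(y−ȳ)²,
residuals (data − model), a Wald–Wolfowitz runs-test z on residual signs
(diagnostic only; r² and the convergence flag are the machine-readable
verdicts), and per-component contributions.

**Contributions** are area-based: each component's trapezoidal integral
over the recorded grid divided by the summed integrals, × 100.  Area (the
emitted signal in-window) rather than peak amplitude is the natural measure
of "contribution to the overall signal"; the choice matters for components
of different widths.

### Conditioning and the noise floor

The five fixed coenzyme/lipid bands overlap strongly; the unit-profile
basis on the 400–750 nm grid has condition number ≈ 6.6 × 10³.  First-order
propagation of additive noise with σ = 1 a.u. (on peak-100 spectra) through
the exact least-squares solution gives amplitude standard deviations of
~294 a.u. for free NAD(P)H and ~171 for bound NAD(P)H — the per-spectrum
shares of these bands are fundamentally noisy, and NNLS frequently parks
one of them at zero.  No fitter can beat this floor; it is a property of
the band geometry, not the optimizer.  Consequences, verified in the test
suite: zero-noise spectra round-trip exactly (≤ 0.5 percentage points per
component across a 6-condition × 5-replicate cohort); at σ = 1 the
well-conditioned bands (flavins, proteins, lipopigments) still recover
within 2 points on average, while the NAD(P)H/fatty-acid/vitamin-A block
carries errors an order of magnitude larger, matching the analytic
propagation oracle.  Group means over replicates average part of this out,
but single-sample redox ratios at this noise level should be treated as
screening values; ratios whose denominator fits to zero are reported as
missing (never ±inf).

## Derived metrics

Bound NAD(P)H emits roughly 3-fold more strongly per unit coenzyme than the
free form, so its fitted signal contribution over-represents its amount.
The bound/free ratio therefore divides the bound contribution by the yield
factor k (default 3, configurable, logged): `(bound/k)/free`.  A higher
emission yield means *less* coenzyme per unit signal, hence division; the
direction is config-exposed for users preferring the opposite convention.
The redox ratio is `flavins/(NAD(P)H_total + flavins)` with
`NAD(P)H_total = bound/k + free` — the corrected total, for consistency
with the corrected ratio (a `use_corrected_total=False` switch gives the
raw sum).  It is bounded in [0, 1], strictly increasing in the flavin
share, decreasing in the NAD(P)H shares.

Nile-red band fractions integrate the recorded fluorochromized-section
spectrum over 480–550 nm (natural-fluorescence tail), 540–600 nm (apolar
lipids, triglycerides) and 600–690 nm (polar lipids, phospholipids).  The
printed band limits overlap at 540–550 nm; each band is integrated exactly
as stated and normalized by the integral over the union of the bands, so
fractions stay ≤ 1 (they sum to 1 only when bands tile without overlap).
Band edges are handled by trapezoidal integration with interpolated
endpoints.

## Hemoglobin-reabsorption QC

Venous blood imprints an absorption dip around 555 nm.  The detector
smooths the spectrum (Savitzky–Golay, 21 nm window, cubic), regresses the
515–595 nm window on a cubic baseline plus a Gaussian notch template
(center 555 nm, FWHM 20 nm), and converts the template coefficient into a
relative depth estimate at the baseline's 555 nm value.  Spectra with
estimated depth > 0.12 are flagged `hb_reabsorption` and excluded from
fitting by default; grids not covering 520–600 nm get `qc_not_applicable`.
A plain second-derivative prominence statistic was evaluated first and
rejected: under σ = 1 additive noise its clean-spectrum and 20 %-notch
distributions overlap, whereas the matched-template estimate separates them
(clean ≤ 0.095, 20 % notch ≥ 0.149 over 500 draws including worst-case
single-component spectra).  The 0.12 threshold was calibrated once on those
synthetic notches: 20 %-depth notches are always flagged, 2 %-depth notches
and clean spectra never.

## Synthetic cohorts

The generator emulates the study design — control plus MCD-diet (a
methionine–choline-deficient diet inducing steatosis) weeks 1, 2, 3, 4 and
8/9 — since no spectra are publicly deposited.  Per condition it holds mean
area shares for the seven components; the default table encodes the
qualitative steatosis trajectory (vitamin A 6→16 %, proteins 15→18 %,
lipopigments 5→7.5 % rising; free NAD(P)H 30→17.5 % falling with the bound
form drifting up 20→22 %; flavins and fatty acids easing down), with each
column summing to 100.  The *directions* follow the reported group
contrasts; the magnitudes are declared assumptions, since the source
reports group values only as figure bars.

Replicate scatter is a Dirichlet draw around the condition means
(concentration 200, giving ~1–3 percentage-point standard deviations on
mid-sized shares), which keeps shares nonnegative and compositional.
Amplitudes are then solved so grid areas match the drawn shares, the
composed spectrum is peak-normalized, and noise is applied: a per-sample
lognormal gain factor (`noise_cv_multiplicative`, default 0.05 — probe
coupling and excitation-intensity variation; removed again by peak
normalization) and per-point additive Gaussian noise (`noise_sd_additive`,
default 1 a.u. on the peak-100 scale, an upper-end but plausible
fluorometer noise level), clipped at zero.  An optional hemoglobin artifact
multiplies by a Gaussian transmission notch (555 nm, FWHM 20 nm, default
depth 20 %) in a seeded `artifact_rate` fraction of samples.  Everything is
reproducible from the scenario seed via per-sample child seeds.

What the generator does *not* emulate: instrument spectral response and
calibration drift, photobleaching kinetics, scattering/inner-filter
distortions beyond the single hemoglobin notch, inter-animal variance
structure (figure error bars are not recoverable), and any deviation of
real fluorophore line shapes from the GMG family.  Passing tests therefore
demonstrate correctness of the decomposition machinery under the model's
own assumptions, not field performance on real tissue spectra.

## Statistics

Each metric's per-condition values are screened with Shapiro–Wilk
(α = 0.05 per group; two-value groups pass by convention since the test
needs n ≥ 3; zero-variance groups count as non-normal).  If all groups
pass: one-way ANOVA, then the Student–Newman–Keuls procedure — means
ordered, each pair spanning p means tested against the studentized range
`q = |Δmean|/√(MSE/n_h)` (harmonic pair size for unbalanced groups) with
`studentized_range.sf(q, p, df_error)`, and a pair declared significant
only when its own test *and* every containing range reject (the stepwise
protection; this guarantees the nested-pair monotonicity property).
Otherwise: Kruskal–Wallis omnibus and Dunn's rank z-tests with tie
correction, Holm-adjusted.  SNK is implemented rather than substituted with
Tukey because the workflow specifies it; the normality screen and the
nonparametric post hoc (Dunn + Holm) are this package's choices where the
workflow names none.  The routed workflow's null rejection rate is checked
empirically (1000 six-group, n = 5 simulations: 0.05 ± 0.02).  No
multiplicity control is applied across metrics, matching the original
workflow.

## Problem sizes and determinism

Default analyses run on 351-point (in vivo) grids with 5-start fits
(~0.2–1 s per spectrum single-threaded); the bundled cohort checks use
6 conditions × 5 replicates, the noise-floor and χ²-calibration checks 50
replicates, and the type-I calibration 1000 simulated experiments.  All
randomness flows through `numpy.random.default_rng` seeds carried in
scenario/fit options; reruns with the same seeds and inputs are
bit-identical, and the pipeline manifest records config hash, seed and
package version.
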