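# afspect

Spectral decomposition of tissue autofluorescence (AF) emission for
label-free "optical biopsy" readouts, built around the liver steatosis use
case: fiber-optic (in vivo, 400–750 nm) or microspectrofluorometric
(ex vivo, 400–680 nm) emission spectra excited at 366 nm are unmixed into a
fixed library of endogenous fluorophores, and the fitted contributions are
turned into metabolic indices and group statistics.

## What it computes

**Peak model.** Each fluorophore's emission band is an asymmetric Gaussian
(the skew-normal family — a Gaussian convolved with a half-Gaussian),
parameterized directly by its *realized* peak center λ and FWHM so the
literature constants plug in verbatim:

| component        | λ (nm) | FWHM (nm) | shape      |
|------------------|--------|-----------|------------|
| free NAD(P)H     | 463    | 115       | fixed      |
| bound NAD(P)H    | 444    | 105       | fixed      |
| flavins          | 526    | 81        | fixed      |
| vitamin A        | 488    | 102       | fixed      |
| fatty acids      | 470    | 90        | fixed      |
| proteins         | ≤ 440  | free      | free shape |
| lipopigments     | ≈ 587  | ≈ 80      | free shape |

**Decomposition.** A peak-100-normalized spectrum `y(λ)` is fitted as
`y(λ) ≈ Σᵢ aᵢ gᵢ(λ; θᵢ)` by bounded nonlinear least squares
(χ² = Σ residuals²) with seeded multistart; amplitudes `aᵢ ≥ 0` are profiled
out exactly by nonnegative least squares at every step (variable
projection). Contributions are area percentages of the total fitted signal.

**Derived metrics.**
- yield-corrected bound/free ratio: `(bound/k) / free`, k = 3 (the bound
  coenzyme emits ≈3× per unit amount);
- optical redox ratio: `flavins / (NAD(P)H_total + flavins)` ∈ [0, 1];
- Nile-red polarity band fractions over 480–550 / 540–600 / 600–690 nm.

**Quality control.** Spectra with a deoxyhemoglobin reabsorption dip near
555 nm are detected by matched-template regression and excluded.

**Statistics.** Per-group Shapiro–Wilk screen routes each metric to one-way
ANOVA + Student–Newman–Keuls pairwise tests (studentized range, stepwise)
or to Kruskal–Wallis + Dunn/Holm, at α = 0.05.

Because no public spectra exist for this assay, a seeded generator
(`afspect.simulate`) produces single-component fixtures, known mixtures,
and multi-condition cohorts (control + MCD-diet weeks 1–4, 8/9) with exact
truth tables.

## Worked example

```python
from afspect import (FitOptions, GRID_PRESETS, default_library,
                     fit_spectrum, make_mixture, normalize_peak)

weights = {"nadph_free": 30, "nadph_bound": 20, "flavins": 12, "vitamin_a": 6,
           "fatty_acids": 12, "proteins": 15, "lipopigments": 5}
spectrum, truth = make_mixture(weights, GRID_PRESETS["in_vivo"], seed=7)
result = fit_spectrum(normalize_peak(spectrum), default_library(),
                      FitOptions(n_starts=5, seed=0))
print(result.r2, result.contributions["flavins"])
```

Running `python examples/01_decompose_spectrum.py` prints:

```
fit converged=True  chi2=0.0  r2=1.0000
component       fitted %   truth %
nadph_free          30.0      30.0
nadph_bound         20.0      20.0
flavins             12.0      12.0
vitamin_a            6.0       6.0
fatty_acids         12.0      12.0
proteins            15.0      15.0
lipopigments         5.0       5.0
```

i.e. on a noiseless mixture the fit recovers every area share exactly
(r² = 1). The other scripts in `examples/` walk through redox metrics
(bound/free = 0.222, redox ratio = 0.247 for the composition above),
Nile-red band fractions, hemoglobin QC, and the full cohort pipeline with
group statistics. The same stages are available from the shell:

```
afspect simulate --seed 3 --out spectra.csv
afspect run spectra.csv --seed 0 --out results/
```

## Layout

- `src/afspect/spectral.py` — peak shape, component library, composition
- `src/afspect/fitting.py` — variable-projection multistart fit, QC
- `src/afspect/metrics.py` — redox ratios, Nile-red bands
- `src/afspect/simulate.py` — synthetic cohorts with truth tables
- `src/afspect/stats.py` — routed ANOVA/SNK and Kruskal–Wallis/Dunn
- `src/afspect/io.py`, `cli.py` — CSV/YAML formats, pipeline, `afspect` CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
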