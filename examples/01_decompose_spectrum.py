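"""Decompose one liver autofluorescence spectrum into fluorophore bands.

Builds a synthetic control-liver emission spectrum (a weighted sum of the
seven-fluorophore library), peak-normalizes it, fits the component model,
and prints each fluorophore's percentage contribution to the total emitted
signal next to the generating truth.
"""

from afspect import (
    FitOptions, GRID_PRESETS, default_library, fit_spectrum, make_mixture,
    normalize_peak,
)

weights = {"nadph_free": 30, "nadph_bound": 20, "flavins": 12, "vitamin_a": 6,
           "fatty_acids": 12, "proteins": 15, "lipopigments": 5}
spectrum, truth = make_mixture(weights, GRID_PRESETS["in_vivo"], seed=7)
result = fit_spectrum(normalize_peak(spectrum), default_library(),
                      FitOptions(n_starts=5, seed=0))

print(f"fit converged={result.converged}  chi2={result.chi2:.1f}  "
      f"r2={result.r2:.4f}")
print(f"{'component':<14}{'fitted %':>10}{'truth %':>10}")
for name, pct in result.contributions.items():
    print(f"{name:<14}{pct:>10.1f}{truth[name]:>10.1f}")
print("\nEach percentage is that fluorophore's share of the total emitted")
print("signal (area under its fitted band over the 400-750 nm window).")
print("On noiseless spectra the decomposition is exact; with measurement")
print("noise the heavily overlapping coenzyme bands become uncertain while")
print("the isolated bands (flavins, lipopigments) stay stable - see")
print("04_cohort_pipeline.py.")
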