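"""Synthetic spectral cohorts for testing the decomposition pipeline.

No public repository of rat-liver autofluorescence spectra exists, so the
generator emulates the study design: a control group and groups fed a
methionine-choline-deficient (MCD) diet for 1, 2, 3, 4 and 8/9 weeks, each
contributing replicate emission spectra that are weighted sums of the
seven-fluorophore library plus measurement noise and, optionally, a
hemoglobin-reabsorption artifact.

The default condition means encode the qualitative steatosis trajectory:
vitamin A, protein and lipopigment shares rise with diet duration, bound
NAD(P)H drifts up while free NAD(P)H drifts down, flavins decline.
Replicate scatter is a Dirichlet draw around the condition means so the
shares stay nonnegative and compositional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .spectral import (
    ComponentLibrary,
    GRID_PRESETS,
    Spectrum,
    WavelengthGrid,
    component_area,
    compose,
    default_library,
    gmg_profile,
    normalize_peak,
)

__all__ = [
    "CohortScenario",
    "DEFAULT_CONDITIONS",
    "DEFAULT_WEIGHT_TABLE",
    "make_component_fixture",
    "make_mixture",
    "make_cohort",
    "apply_hb_notch",
]

DEFAULT_CONDITIONS = (
    "control", "mcd_week_1", "mcd_week_2", "mcd_week_3", "mcd_week_4",
    "mcd_week_8_9",
)

#: mean area-share (%) per component and condition; columns sum to 100
DEFAULT_WEIGHT_TABLE = pd.DataFrame(
    {
        "control":      [30.0, 20.0, 12.0, 6.0, 12.0, 15.0, 5.0],
        "mcd_week_1":   [27.5, 20.4, 11.4, 8.0, 11.6, 15.6, 5.5],
        "mcd_week_2":   [25.0, 20.8, 10.8, 10.0, 11.2, 16.2, 6.0],
        "mcd_week_3":   [22.5, 21.2, 10.2, 12.0, 10.8, 16.8, 6.5],
        "mcd_week_4":   [20.0, 21.6, 9.6, 14.0, 10.4, 17.4, 7.0],
        "mcd_week_8_9": [17.5, 22.0, 9.0, 16.0, 10.0, 18.0, 7.5],
    },
    index=["nadph_free", "nadph_bound", "flavins", "vitamin_a",
           "fatty_acids", "proteins", "lipopigments"],
)

#: hemoglobin artifact: Gaussian transmission notch
NOTCH_CENTER_NM = 555.0
NOTCH_FWHM_NM = 20.0
DEFAULT_NOTCH_DEPTH = 0.20


@dataclass
class CohortScenario:
    """Study design for a simulated multi-condition cohort."""

    conditions: tuple = DEFAULT_CONDITIONS
    weight_table: pd.DataFrame = field(default_factory=lambda: DEFAULT_WEIGHT_TABLE.copy())
    replicate_count: int = 5
    noise_sd_additive: float = 1.0
    noise_cv_multiplicative: float = 0.05
    artifact_rate: float = 0.0
    notch_depth: float = DEFAULT_NOTCH_DEPTH
    dirichlet_concentration: float = 200.0
    grid: WavelengthGrid = GRID_PRESETS["in_vivo"]
    seed: int = 0

    def __post_init__(self):
        if self.replicate_count < 1:
            raise InvalidParameterError("replicate_count must be >= 1")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise InvalidParameterError("artifact_rate must be in [0, 1]")
        missing = [c for c in self.conditions if c not in self.weight_table.columns]
        if missing:
            raise InvalidParameterError(f"weight_table lacks conditions {missing}")
        sums = self.weight_table[list(self.conditions)].sum(axis=0)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise InvalidParameterError(
                f"condition mean shares must each sum to 100, got {sums.to_dict()}"
            )


def make_component_fixture(component_name: str, grid: WavelengthGrid,
                           amplitude: float = 100.0, seed: int = 0,
                           library: ComponentLibrary | None = None) -> Spectrum:
    """Noiseless single-component spectrum with its generating truth recorded."""
    library = library or default_library()
    try:
        comp = library.get(component_name)
    except KeyError:
        raise InvalidParameterError(
            f"unknown component {component_name!r}; library has {library.names()}"
        ) from None
    comp = comp.with_params(amplitude=amplitude)
    spec = compose(ComponentLibrary([comp]), grid,
                   sample_id=f"fixture_{component_name}")
    spec.metadata["truth"] = {
        "component": component_name,
        "center_nm": comp.center_nm,
        "fwhm_nm": comp.fwhm_nm,
        "asymmetry": comp.asymmetry,
        "amplitude": amplitude,
        "seed": seed,
    }
    return spec


def apply_hb_notch(spectrum: Spectrum, depth: float = DEFAULT_NOTCH_DEPTH) -> Spectrum:
    """Multiply by a Gaussian transmission notch at 555 nm (hemoglobin dip)."""
    wl = spectrum.wavelengths()
    transmission = 1.0 - depth * np.exp(
        -4.0 * np.log(2.0) * (wl - NOTCH_CENTER_NM) ** 2 / NOTCH_FWHM_NM**2
    )
    out = Spectrum(
        sample_id=spectrum.sample_id, condition=spectrum.condition,
        grid=spectrum.grid, intensities=spectrum.intensities * transmission,
        qc_flags=set(spectrum.qc_flags), metadata=dict(spectrum.metadata),
    )
    out.metadata["hb_notch_depth"] = depth
    return out


def make_mixture(weights: dict, grid: WavelengthGrid,
                 noise_sd_additive: float = 0.0,
                 noise_cv_multiplicative: float = 0.0,
                 notch_depth: float = 0.0,
                 seed: int = 0,
                 sample_id: str = "mixture",
                 condition: str = "",
                 library: ComponentLibrary | None = None) -> tuple:
    """Compose a mixture whose component *area shares* match ``weights``.

    Amplitudes are solved so each component's trapezoidal area over the
    grid takes the requested share of the total; the composed spectrum is
    scaled to peak 100 before noise.  Additive Gaussian noise models
    detector/background fluctuation; the multiplicative lognormal jitter is
    a per-sample gain factor (probe coupling, excitation intensity).
    Negative noisy intensities are clipped at zero.

    Returns ``(spectrum, truth)`` where ``truth`` records the exact shares.
    """
    library = library or default_library()
    names = library.names()
    unknown = set(weights) - set(names)
    if unknown:
        raise InvalidParameterError(f"unknown components {sorted(unknown)}")
    w = np.array([max(0.0, float(weights.get(n, 0.0))) for n in names])
    if w.sum() <= 0:
        raise InvalidParameterError("weights must not be all zero")
    shares = 100.0 * w / w.sum()

    unit_areas = np.array([
        component_area(c.with_params(amplitude=1.0), grid) for c in library
    ])
    amps = np.where(unit_areas > 0, shares / unit_areas, 0.0)
    comps = [c.with_params(amplitude=a) for c, a in zip(library, amps)]
    spec = compose(ComponentLibrary(comps), grid, sample_id=sample_id,
                   condition=condition)
    spec = normalize_peak(spec)

    rng = np.random.default_rng(seed)
    y = spec.intensities
    if noise_cv_multiplicative > 0:
        y = y * rng.lognormal(mean=0.0, sigma=noise_cv_multiplicative)
    if notch_depth > 0:
        spec = apply_hb_notch(
            Spectrum(sample_id, condition, grid, y, metadata=dict(spec.metadata)),
            notch_depth,
        )
        y = spec.intensities
    if noise_sd_additive > 0:
        y = np.clip(y + rng.normal(0.0, noise_sd_additive, size=y.size), 0.0, None)

    truth = {name: share for name, share in zip(names, shares)}
    out = Spectrum(sample_id=sample_id, condition=condition, grid=grid,
                   intensities=y, metadata=dict(spec.metadata))
    out.metadata["truth_shares"] = truth
    out.metadata["hb_notch_depth"] = notch_depth
    out.metadata["seed"] = seed
    return out, truth


def make_cohort(scenario: CohortScenario,
                library: ComponentLibrary | None = None) -> tuple:
    """Simulate a full cohort.

    Returns ``(spectra, truth_table)``: one spectrum per replicate per
    condition, and a tidy DataFrame with the exact per-sample shares and
    artifact status.  Fully reproducible from ``scenario.seed``.
    """
    library = library or default_library()
    rng = np.random.default_rng(scenario.seed)
    names = library.names()
    spectra = []
    rows = []
    for condition in scenario.conditions:
        mean_shares = scenario.weight_table.loc[names, condition].to_numpy()
        for rep in range(scenario.replicate_count):
            alpha = np.maximum(mean_shares / 100.0, 1e-12) * scenario.dirichlet_concentration
            shares = 100.0 * rng.dirichlet(alpha)
            has_artifact = bool(rng.random() < scenario.artifact_rate)
            sample_id = f"{condition}_r{rep + 1}"
            # child seed keeps every sample independently reproducible
            sample_seed = int(rng.integers(0, 2**31 - 1))
            spec, truth = make_mixture(
                dict(zip(names, shares)), scenario.grid,
                noise_sd_additive=scenario.noise_sd_additive,
                noise_cv_multiplicative=scenario.noise_cv_multiplicative,
                notch_depth=scenario.notch_depth if has_artifact else 0.0,
                seed=sample_seed, sample_id=sample_id, condition=condition,
                library=library,
            )
            spectra.append(spec)
            row = {"sample_id": sample_id, "condition": condition,
                   "has_artifact": has_artifact}
            row.update(truth)
            rows.append(row)
    return spectra, pd.DataFrame(rows)
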