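"""Peak-shape model and component library for tissue autofluorescence spectra.

Each endogenous fluorophore's emission band is modeled with an asymmetric
Gaussian profile (a Gaussian convolved with a half-Gaussian, i.e. the
skew-normal shape family), parameterized directly by the *realized* peak
center wavelength and full width at half maximum so that the literature
constants for each fluorophore (e.g. free NAD(P)H at 463 nm / 115 nm FWHM)
can be used verbatim.  Zero asymmetry recovers the pure Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr  # standard normal CDF, vectorized

from .exceptions import DegenerateSpectrumError, InvalidParameterError

__all__ = [
    "WavelengthGrid",
    "SpectralComponent",
    "ComponentLibrary",
    "Spectrum",
    "GRID_PRESETS",
    "gmg_profile",
    "compose",
    "normalize_peak",
    "component_area",
    "default_library",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform emission wavelength grid in nm, inclusive endpoints."""

    start_nm: float
    stop_nm: float
    step_nm: float = 1.0

    def __post_init__(self):
        if not (self.start_nm < self.stop_nm):
            raise InvalidParameterError("start_nm must be < stop_nm")
        if not self.step_nm > 0:
            raise InvalidParameterError("step_nm must be > 0")

    def wavelengths(self) -> np.ndarray:
        n = int(math.floor((self.stop_nm - self.start_nm) / self.step_nm + 1e-9)) + 1
        return self.start_nm + self.step_nm * np.arange(n)

    def __len__(self) -> int:
        return len(self.wavelengths())

    def covers(self, low_nm: float, high_nm: float) -> bool:
        return self.start_nm <= low_nm and self.stop_nm >= high_nm


#: Canonical acquisition windows: fiber-optic probe measurements on intact
#: tissue ("in_vivo", 400-750 nm) and microspectrofluorometry of tissue
#: sections ("ex_vivo", 400-680 nm).
GRID_PRESETS = {
    "in_vivo": WavelengthGrid(400.0, 750.0, 1.0),
    "ex_vivo": WavelengthGrid(400.0, 680.0, 1.0),
}


@dataclass
class SpectralComponent:
    """One fluorophore's emission band.

    ``center_nm`` and ``fwhm_nm`` are the realized peak position and full
    width at half maximum of the profile, for any asymmetry.  ``asymmetry``
    is the dimensionless skew parameter tau (0 = symmetric Gaussian;
    positive skews the band to the red).  ``*_free`` flags mark parameters
    the fitter may vary; bounds apply only to free parameters.
    """

    name: str
    center_nm: float
    fwhm_nm: float
    asymmetry: float = 0.0
    amplitude: float = 1.0
    center_free: bool = False
    fwhm_free: bool = False
    asymmetry_free: bool = False
    bounds: dict = field(default_factory=dict)

    def __post_init__(self):
        for attr in ("center_nm", "fwhm_nm", "asymmetry", "amplitude"):
            v = getattr(self, attr)
            if not np.isfinite(v):
                raise InvalidParameterError(f"{self.name}: {attr}={v!r} is not finite")
        if self.fwhm_nm <= 0:
            raise InvalidParameterError(f"{self.name}: fwhm_nm must be > 0")
        if self.amplitude < 0:
            raise InvalidParameterError(f"{self.name}: amplitude must be >= 0")

    def param_bounds(self, param: str) -> tuple:
        """Bounds for a parameter; collapses to the value when not free."""
        free = {
            "center_nm": self.center_free,
            "fwhm_nm": self.fwhm_free,
            "asymmetry": self.asymmetry_free,
            "amplitude": True,
        }[param]
        if not free:
            v = getattr(self, param)
            return (v, v)
        if param in self.bounds:
            return tuple(self.bounds[param])
        if param == "amplitude":
            return (0.0, np.inf)
        raise InvalidParameterError(
            f"{self.name}: free parameter {param} declared without bounds"
        )

    def with_params(self, **kwargs) -> "SpectralComponent":
        return replace(self, **kwargs)


@dataclass
class ComponentLibrary:
    """Ordered collection of spectral components with unique names."""

    components: list

    def __post_init__(self):
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise InvalidParameterError("component names must be unique")

    def __iter__(self):
        return iter(self.components)

    def __len__(self):
        return len(self.components)

    def names(self) -> list:
        return [c.name for c in self.components]

    def get(self, name: str) -> SpectralComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def copy(self) -> "ComponentLibrary":
        return ComponentLibrary([replace(c, bounds=dict(c.bounds)) for c in self.components])


@dataclass
class Spectrum:
    """A single sample's emission spectrum on a wavelength grid."""

    sample_id: str
    condition: str
    grid: WavelengthGrid
    intensities: np.ndarray
    qc_flags: set = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.grid),) :
            raise InvalidParameterError(
                f"{self.sample_id}: {self.intensities.size} intensities for a "
                f"{len(self.grid)}-point grid"
            )
        if np.any(self.intensities < 0):
            raise InvalidParameterError(f"{self.sample_id}: negative intensities")

    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths()


@lru_cache(maxsize=8192)
def _std_shape_solution(tau: float) -> tuple:
    """Mode, half-max crossings and peak value of exp(-z^2/2)*Phi(tau*z).

    Solved once per asymmetry value in standardized coordinates; results
    are cached because the optimizer re-evaluates the same tau many times
    while perturbing other parameters.
    """

    def h(z):
        # derivative condition: -z*Phi(tau z) + tau*phi(tau z) = 0
        return -z * ndtr(tau * z) + tau * math.exp(-0.5 * (tau * z) ** 2) / math.sqrt(2 * math.pi)

    z_mode = brentq(h, -8.0, 8.0, xtol=1e-13)
    s_max = math.exp(-0.5 * z_mode**2) * ndtr(tau * z_mode)

    def half(z):
        return math.exp(-0.5 * z * z) * ndtr(tau * z) - 0.5 * s_max

    z_lo = brentq(half, z_mode - 12.0, z_mode, xtol=1e-13)
    z_hi = brentq(half, z_mode, z_mode + 12.0, xtol=1e-13)
    return z_mode, z_lo, z_hi, s_max


def gmg_profile(component: SpectralComponent, grid: WavelengthGrid) -> np.ndarray:
    """Evaluate one component's emission profile on a grid (a.u.).

    The profile is an asymmetric Gaussian (Gaussian x half-Gaussian
    convolution).  The internal location/scale parameters are solved so the
    realized maximum equals ``amplitude`` at ``center_nm`` and the realized
    FWHM equals ``fwhm_nm``, whatever the asymmetry.
    """
    wl = grid.wavelengths()
    tau = component.asymmetry
    if tau == 0.0:
        # exact symmetric limit, bit-reproducible against the analytic Gaussian
        return component.amplitude * np.exp(
            -4.0 * _LN2 * (wl - component.center_nm) ** 2 / component.fwhm_nm**2
        )
    z_mode, z_lo, z_hi, s_max = _std_shape_solution(float(tau))
    omega = component.fwhm_nm / (z_hi - z_lo)
    xi = component.center_nm - omega * z_mode
    z = (wl - xi) / omega
    return component.amplitude / s_max * np.exp(-0.5 * z * z) * ndtr(tau * z)


def compose(library: ComponentLibrary, grid: WavelengthGrid,
            sample_id: str = "composed", condition: str = "") -> Spectrum:
    """Sum the library's component profiles into a model spectrum."""
    if len(library) == 0:
        raise InvalidParameterError("cannot compose an empty library")
    total = np.zeros(len(grid))
    for c in library:
        total += gmg_profile(c, grid)
    return Spectrum(sample_id=sample_id, condition=condition, grid=grid,
                    intensities=total)


def normalize_peak(spectrum: Spectrum, peak: float = 100.0) -> Spectrum:
    """Rescale so the spectrum maximum is exactly ``peak`` (100 a.u.)."""
    m = float(np.max(spectrum.intensities))
    if m <= 0:
        raise DegenerateSpectrumError(
            f"{spectrum.sample_id}: cannot normalize, max intensity is {m}"
        )
    # divide by the max first so the peak sample maps to exactly 1.0 * peak
    scaled = (spectrum.intensities / m) * peak
    return Spectrum(
        sample_id=spectrum.sample_id,
        condition=spectrum.condition,
        grid=spectrum.grid,
        intensities=scaled,
        qc_flags=set(spectrum.qc_flags),
        metadata=dict(spectrum.metadata),
    )


def component_area(component: SpectralComponent, grid: WavelengthGrid) -> float:
    """Trapezoidal integral of the component profile over the grid (a.u. nm)."""
    return float(np.trapezoid(gmg_profile(component, grid), grid.wavelengths()))


def default_library() -> ComponentLibrary:
    """The seven-fluorophore liver autofluorescence library.

    Fixed-shape entries carry the literature emission constants; only their
    amplitudes vary in a fit.  Collagen-dominated protein emission (a blue
    tail entering the window below 440 nm) and lipofuscin-like lipopigments
    have chemically heterogeneous spectra, so their center, width and
    asymmetry stay free within bounds.
    """
    return ComponentLibrary([
        SpectralComponent("nadph_free", 463.0, 115.0),
        SpectralComponent("nadph_bound", 444.0, 105.0),
        SpectralComponent("flavins", 526.0, 81.0),
        SpectralComponent("vitamin_a", 488.0, 102.0),
        SpectralComponent("fatty_acids", 470.0, 90.0),
        SpectralComponent(
            "proteins", 415.0, 100.0,
            center_free=True, fwhm_free=True, asymmetry_free=True,
            bounds={"center_nm": (380.0, 440.0), "fwhm_nm": (60.0, 140.0),
                    "asymmetry": (-1.0, 1.0)},
        ),
        SpectralComponent(
            "lipopigments", 587.0, 80.0,
            center_free=True, fwhm_free=True, asymmetry_free=True,
            bounds={"center_nm": (560.0, 620.0), "fwhm_nm": (50.0, 110.0),
                    "asymmetry": (-1.0, 1.0)},
        ),
    ])
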