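"""Redox summary metrics and Nile-red band fractions.

The bound and free NAD(P)H pools differ in emission yield by roughly a
factor of three, so the bound pool's signal contribution over-represents
its amount.  ``bound_free_ratio`` divides the bound contribution by the
yield factor (default 3) before forming the bound/free ratio, and the
redox ratio flavins / (NAD(P)H_total + flavins) uses the same corrected
total by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import BandCoverageError, UndefinedRatioError
from .fitting import FitResult
from .spectral import Spectrum

__all__ = [
    "RedoxMetrics",
    "BandDefinition",
    "DEFAULT_BANDS",
    "bound_free_ratio",
    "redox_ratio",
    "compute_redox_metrics",
    "band_fractions",
]

BOUND = "nadph_bound"
FREE = "nadph_free"
FLAVINS = "flavins"


@dataclass(frozen=True)
class RedoxMetrics:
    """Per-sample redox summary derived from fitted contributions."""

    sample_id: str
    condition: str
    nadph_bound_corrected: float
    nadph_free: float
    bound_free_ratio: float
    redox_ratio: float
    yield_factor: float


@dataclass(frozen=True)
class BandDefinition:
    """A named emission band [low_nm, high_nm]."""

    name: str
    low_nm: float
    high_nm: float

    def __post_init__(self):
        if not self.low_nm < self.high_nm:
            raise ValueError(f"{self.name}: low_nm must be < high_nm")


#: Nile-red emission bands: natural-fluorescence tail, apolar lipids
#: (triglycerides), polar lipids (phospholipids).  The printed limits
#: overlap at 540-550 nm; bands are integrated as stated and normalized by
#: the union integral.
DEFAULT_BANDS = (
    BandDefinition("natural_tail", 480.0, 550.0),
    BandDefinition("apolar_lipids", 540.0, 600.0),
    BandDefinition("polar_lipids", 600.0, 690.0),
)


def _contribution(result: FitResult, name: str) -> float:
    try:
        return result.contributions[name]
    except KeyError:
        raise UndefinedRatioError(f"fit result lacks component {name!r}") from None


def bound_free_ratio(result: FitResult, yield_factor: float = 3.0) -> float:
    """Yield-corrected NAD(P)H bound/free ratio.

    The bound form emits ``yield_factor``-fold more strongly per unit
    amount, so its fitted signal contribution is divided by the factor
    before the ratio is taken; the result then tracks relative coenzyme
    amounts rather than raw signal.
    """
    if yield_factor <= 0:
        raise ValueError("yield_factor must be > 0")
    bound = _contribution(result, BOUND)
    free = _contribution(result, FREE)
    if free <= 0:
        raise UndefinedRatioError(
            f"{result.sample_id}: free NAD(P)H contribution is zero"
        )
    return (bound / yield_factor) / free


def redox_ratio(result: FitResult, yield_factor: float = 3.0,
                use_corrected_total: bool = True) -> float:
    """Optical redox ratio flavins / (NAD(P)H_total + flavins), in [0, 1].

    ``NAD(P)H_total`` is the yield-corrected bound contribution plus the
    free contribution (set ``use_corrected_total=False`` for the raw sum).
    """
    flavins = _contribution(result, FLAVINS)
    bound = _contribution(result, BOUND)
    free = _contribution(result, FREE)
    n_total = (bound / yield_factor if use_corrected_total else bound) + free
    denom = n_total + flavins
    if denom <= 0:
        raise UndefinedRatioError(
            f"{result.sample_id}: flavin and NAD(P)H contributions are all zero"
        )
    return flavins / denom


def compute_redox_metrics(result: FitResult, yield_factor: float = 3.0) -> RedoxMetrics:
    """Bundle both redox metrics for one fitted sample."""
    bound = _contribution(result, BOUND)
    free = _contribution(result, FREE)
    return RedoxMetrics(
        sample_id=result.sample_id,
        condition=result.condition,
        nadph_bound_corrected=bound / yield_factor,
        nadph_free=free,
        bound_free_ratio=bound_free_ratio(result, yield_factor),
        redox_ratio=redox_ratio(result, yield_factor),
        yield_factor=yield_factor,
    )


def _band_integral(wl: np.ndarray, y: np.ndarray, low: float, high: float) -> float:
    """Trapezoidal integral over [low, high] with interpolated endpoints."""
    inside = (wl > low) & (wl < high)
    xs = np.concatenate(([low], wl[inside], [high]))
    ys = np.concatenate(([np.interp(low, wl, y)], y[inside], [np.interp(high, wl, y)]))
    return float(np.trapezoid(ys, xs))


def band_fractions(spectrum: Spectrum, bands=DEFAULT_BANDS) -> dict:
    """Fraction of emission falling in each band.

    Each band's trapezoidal integral is divided by the integral over the
    union of the band ranges, so overlapping band limits are honored as
    printed while fractions stay <= 1 (and sum to 1 when the bands tile
    the analyzed range without overlap).
    """
    wl = spectrum.wavelengths()
    for b in bands:
        if not spectrum.grid.covers(b.low_nm, b.high_nm):
            raise BandCoverageError(
                f"band {b.name} ({b.low_nm}-{b.high_nm} nm) outside the grid "
                f"({spectrum.grid.start_nm}-{spectrum.grid.stop_nm} nm)"
            )
    # merge band ranges into disjoint union intervals
    intervals = sorted((b.low_nm, b.high_nm) for b in bands)
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    y = spectrum.intensities
    union = sum(_band_integral(wl, y, lo, hi) for lo, hi in merged)
    if union <= 0:
        raise UndefinedRatioError(
            f"{spectrum.sample_id}: zero emission inside the analyzed bands"
        )
    return {b.name: _band_integral(wl, y, b.low_nm, b.high_nm) / union for b in bands}
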