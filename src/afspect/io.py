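"""Readers/writers, configuration, and the end-to-end pipeline.

The canonical spectrum exchange format is a long CSV with header
``sample_id,condition,wavelength_nm,intensity_au`` (one row per grid
point), which streams naturally and allows mixed grids in one file.
Component libraries travel as YAML.  ``run_pipeline`` wires
QC -> normalize -> fit -> contributions -> redox metrics -> group
statistics and writes every table plus a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import SpectraParseError
from .fitting import FitOptions, FitResult, fit_spectrum, qc_hemoglobin
from .spectral import (
    ComponentLibrary,
    GRID_PRESETS,
    SpectralComponent,
    Spectrum,
    WavelengthGrid,
    default_library,
    normalize_peak,
)
from .stats import compare_groups

log = logging.getLogger(__name__)

__all__ = [
    "read_spectra", "write_spectra", "load_library", "save_library",
    "RunConfig", "PipelineResult", "run_pipeline",
]

SPECTRA_COLUMNS = ["sample_id", "condition", "wavelength_nm", "intensity_au"]


def _grid_from_wavelengths(wl: np.ndarray, sample_id: str) -> WavelengthGrid:
    steps = np.diff(wl)
    if steps.size == 0:
        raise SpectraParseError(f"sample {sample_id!r}: single-point spectrum")
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        raise SpectraParseError(f"sample {sample_id!r}: non-uniform wavelength grid")
    return WavelengthGrid(float(wl[0]), float(wl[-1]), float(steps[0]))


def read_spectra(path) -> list:
    """Load spectra from a long-format CSV, one Spectrum per sample_id.

    Wavelengths are validated as strictly increasing per sample (shuffled
    rows are sorted with a warning); duplicate (sample, wavelength) pairs,
    missing columns and non-numeric intensities raise ``SpectraParseError``
    with the offending rows named.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "condition": str})
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraParseError(f"{path}: missing columns {missing}")
    for col in ("wavelength_nm", "intensity_au"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header and 0-base
            raise SpectraParseError(f"{path}: non-numeric {col} at lines {lines}")
        if coerced.isna().any():
            lines = [int(i) + 2 for i in df.index[coerced.isna()][:5]]
            raise SpectraParseError(f"{path}: missing {col} at lines {lines}")
        df[col] = coerced

    spectra = []
    for sample_id, g in df.groupby("sample_id", sort=False):
        if g["wavelength_nm"].duplicated().any():
            dup = g.loc[g["wavelength_nm"].duplicated(), "wavelength_nm"].iloc[0]
            raise SpectraParseError(
                f"{path}: duplicate wavelength {dup} nm for sample {sample_id!r}"
            )
        wl = g["wavelength_nm"].to_numpy()
        if np.any(np.diff(wl) < 0):
            log.warning("sample %r: wavelengths not sorted, sorting on load", sample_id)
            g = g.sort_values("wavelength_nm")
            wl = g["wavelength_nm"].to_numpy()
        condition = str(g["condition"].iloc[0]) if g["condition"].notna().any() else ""
        spectra.append(Spectrum(
            sample_id=str(sample_id), condition=condition,
            grid=_grid_from_wavelengths(wl, str(sample_id)),
            intensities=g["intensity_au"].to_numpy(),
        ))
    return spectra


def write_spectra(spectra, path) -> None:
    """Write spectra to the long CSV format."""
    frames = []
    for s in spectra:
        frames.append(pd.DataFrame({
            "sample_id": s.sample_id,
            "condition": s.condition,
            "wavelength_nm": s.wavelengths(),
            "intensity_au": s.intensities,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _component_to_dict(c: SpectralComponent) -> dict:
    d = {
        "name": c.name, "center_nm": c.center_nm, "fwhm_nm": c.fwhm_nm,
        "asymmetry": c.asymmetry, "amplitude": c.amplitude,
        "center_free": c.center_free, "fwhm_free": c.fwhm_free,
        "asymmetry_free": c.asymmetry_free,
    }
    if c.bounds:
        d["bounds"] = {k: list(v) for k, v in c.bounds.items()}
    return d


def save_library(library: ComponentLibrary, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"components": [_component_to_dict(c) for c in library]},
                       fh, sort_keys=False)


def load_library(path) -> ComponentLibrary:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    comps = []
    for d in doc["components"]:
        bounds = {k: tuple(v) for k, v in d.get("bounds", {}).items()}
        comps.append(SpectralComponent(
            name=d["name"], center_nm=float(d["center_nm"]),
            fwhm_nm=float(d["fwhm_nm"]), asymmetry=float(d.get("asymmetry", 0.0)),
            amplitude=float(d.get("amplitude", 1.0)),
            center_free=bool(d.get("center_free", False)),
            fwhm_free=bool(d.get("fwhm_free", False)),
            asymmetry_free=bool(d.get("asymmetry_free", False)),
            bounds=bounds,
        ))
    return ComponentLibrary(comps)


def default_library_path() -> Path:
    """Path of the packaged default component-library YAML."""
    return Path(__file__).parent / "data" / "default_library.yaml"


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    library_path: str | None = None
    grid_preset: str = "in_vivo"
    n_starts: int = 5
    seed: int = 0
    yield_factor: float = 3.0
    alpha: float = 0.05
    skip_qc: bool = False
    qc_depth_threshold: float = 0.12
    output_dir: str | None = None

    def library(self) -> ComponentLibrary:
        return load_library(self.library_path) if self.library_path else default_library()

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    """Tables produced by one pipeline run."""

    fits: pd.DataFrame
    residuals: pd.DataFrame
    metrics: pd.DataFrame
    comparisons: pd.DataFrame
    discarded: list
    manifest: dict
    fit_results: list = field(default_factory=list)


def fits_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id, "condition": r.condition,
               "chi2": r.chi2, "r2": r.r2, "converged": r.converged,
               "runs_z": r.runs_z}
        for name, pct in r.contributions.items():
            row[f"contribution_{name}"] = pct
        for c in r.fitted_library:
            if c.center_free:
                row[f"{c.name}_center_nm"] = c.center_nm
            if c.fwhm_free:
                row[f"{c.name}_fwhm_nm"] = c.fwhm_nm
            if c.asymmetry_free:
                row[f"{c.name}_asymmetry"] = c.asymmetry
        rows.append(row)
    return pd.DataFrame(rows)


def residuals_table(results) -> pd.DataFrame:
    frames = [
        pd.DataFrame({"sample_id": r.sample_id,
                      "wavelength_nm": r.grid.wavelengths(),
                      "residual_au": r.residuals})
        for r in results
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample_id", "wavelength_nm", "residual_au"])


def metrics_table(results, yield_factor: float = 3.0) -> pd.DataFrame:
    """Per-sample redox metrics; undefined ratios are reported as missing."""
    from .exceptions import UndefinedRatioError
    from .metrics import bound_free_ratio, redox_ratio

    rows = []
    for r in results:
        row = {"sample_id": r.sample_id, "condition": r.condition,
               "yield_factor": yield_factor}
        for name, fn in (("bound_free_ratio", bound_free_ratio),
                         ("redox_ratio", redox_ratio)):
            try:
                row[name] = fn(r, yield_factor)
            except UndefinedRatioError:
                log.warning("%s: %s undefined (zero denominator), reported "
                            "as missing", r.sample_id, name)
                row[name] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", "condition",
                                       "bound_free_ratio", "redox_ratio",
                                       "yield_factor"])


def comparisons_table(fits: pd.DataFrame, metrics: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Compare every metric and contribution column across conditions."""
    rows = []
    merged = fits.merge(metrics[["sample_id", "bound_free_ratio", "redox_ratio"]],
                        on="sample_id", how="left")
    metric_cols = [c for c in merged.columns if c.startswith("contribution_")]
    metric_cols += ["bound_free_ratio", "redox_ratio"]
    counts = merged.groupby("condition")["sample_id"].count()
    usable = counts[counts >= 2].index
    if len(usable) < 2:
        return pd.DataFrame(columns=["metric", "route", "omnibus_p",
                                     "group_a", "group_b", "p_value",
                                     "significant"])
    for col in metric_cols:
        groups = {}
        for cond in usable:
            vals = merged.loc[merged["condition"] == cond, col].to_numpy()
            groups[cond] = vals[np.isfinite(vals)]
        if any(len(v) < 2 for v in groups.values()):
            log.warning("metric %s: fewer than two finite values in some "
                        "group, comparison skipped", col)
            continue
        cmp_ = compare_groups(groups, alpha=alpha, metric_name=col)
        for pr in cmp_.pairwise:
            rows.append({"metric": col, "route": cmp_.route_taken,
                         "omnibus_p": cmp_.omnibus_p,
                         "group_a": pr.group_a, "group_b": pr.group_b,
                         "p_value": pr.p_value,
                         "significant": pr.significant})
    return pd.DataFrame(rows)


def run_pipeline(spectra, config: RunConfig = RunConfig()) -> PipelineResult:
    """Run QC, normalization, fitting, metrics and statistics on spectra.

    ``spectra`` is a list of :class:`Spectrum` or a path to a long CSV.
    When ``config.output_dir`` is set, all tables and a JSON manifest are
    written there.  Deterministic for fixed inputs, seed and config.
    """
    if isinstance(spectra, (str, Path)):
        spectra = read_spectra(spectra)
    manifest = {
        "afspect_version": __version__,
        "config": config.to_dict(),
        "n_input_spectra": len(spectra),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()

    if not spectra:
        log.warning("no input spectra: pipeline is a no-op")
        empty = PipelineResult(
            fits=pd.DataFrame(), residuals=pd.DataFrame(),
            metrics=pd.DataFrame(), comparisons=pd.DataFrame(),
            discarded=[], manifest=manifest,
        )
        if config.output_dir:
            _write_bundle(empty, config.output_dir)
        return empty

    kept, discarded = [], []
    for s in spectra:
        if config.skip_qc:
            kept.append(s)
            continue
        flagged = qc_hemoglobin(s, depth_threshold=config.qc_depth_threshold)
        if "hb_reabsorption" in flagged.qc_flags:
            discarded.append(flagged.sample_id)
        else:
            kept.append(flagged)
    log.info("QC: kept %d spectra, discarded %d (hemoglobin reabsorption)",
             len(kept), len(discarded))
    manifest["n_discarded_qc"] = len(discarded)
    manifest["discarded_sample_ids"] = discarded

    library = config.library()
    options = FitOptions(n_starts=config.n_starts, seed=config.seed)
    results = [fit_spectrum(normalize_peak(s), library, options) for s in kept]

    fits = fits_table(results)
    residuals = residuals_table(results)
    metrics = metrics_table(results, config.yield_factor)
    n_conditions = fits["condition"].nunique() if len(fits) else 0
    comparisons = (comparisons_table(fits, metrics, config.alpha)
                   if n_conditions >= 2 else pd.DataFrame())
    bundle = PipelineResult(fits=fits, residuals=residuals, metrics=metrics,
                            comparisons=comparisons, discarded=discarded,
                            manifest=manifest, fit_results=results)
    if config.output_dir:
        _write_bundle(bundle, config.output_dir)
    return bundle


def _write_bundle(bundle: PipelineResult, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.fits.to_csv(out / "fits.csv", index=False)
    bundle.residuals.to_csv(out / "residuals.csv", index=False)
    bundle.metrics.to_csv(out / "metrics.csv", index=False)
    bundle.comparisons.to_csv(out / "comparisons.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
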