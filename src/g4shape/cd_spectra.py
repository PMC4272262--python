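"""Circular dichroism spectra: molar normalization, composite prediction,
quartet-count amplitude scaling, and parallel-topology classification.

Raw ellipticity theta (millidegrees) is converted to molar circular
dichroism

    delta_eps(lambda) = theta(lambda) / (32980 * c * l)

with c the strand concentration in mol/L and l the path length in cm
(32980 = 3298 L mol^-1 cm^-1 per degree x 10 mdeg/deg).  Composite spectra
for multi-domain structural models are pointwise weighted sums of molar
component spectra; for all-parallel quadruplex assemblies the 260-nm
amplitude scales with the number of stacked G-quartets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "MDEG_TO_MOLAR",
    "normalize_to_molar_cd",
    "composite_spectrum",
    "quartet_scaled_prediction",
    "classify_topology",
    "resample",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

MDEG_TO_MOLAR = 32980.0

DEFAULT_GRID = np.arange(220.0, 341.0, 1.0)


class IncompatibleSpectraError(ValueError):
    pass


class CoverageError(ValueError):
    pass


@dataclass
class Spectrum:
    """A wavelength-indexed CD trace.

    ``units`` is ``"raw"`` (ellipticity, mdeg) or ``"molar"`` (delta-eps,
    L mol^-1 cm^-1).  ``meta`` records provenance such as the strand
    concentration and path length used for normalization.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    units: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and values must be matching 1-D arrays")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")
        if self.units not in ("raw", "molar"):
            raise ValueError("units must be 'raw' or 'molar'")

    def value_at(self, wavelength: float) -> float:
        """Linear interpolation at a single wavelength (no extrapolation)."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength <= hi):
            raise CoverageError(f"{wavelength} nm outside [{lo}, {hi}] nm")
        return float(np.interp(wavelength, self.wavelengths, self.values))


def normalize_to_molar_cd(raw: Spectrum, c: float, path: float) -> Spectrum:
    """Convert raw ellipticity (mdeg) to molar circular dichroism.

    ``c`` is strand concentration in mol/L, ``path`` in cm.
    """
    if raw.units != "raw":
        raise ValueError("spectrum is already in molar units")
    if c <= 0 or path <= 0:
        raise ValueError("concentration and path length must be positive")
    values = raw.values / (MDEG_TO_MOLAR * c * path)
    meta = dict(raw.meta, concentration_M=c, path_cm=path)
    return Spectrum(raw.wavelengths.copy(), values, units="molar", meta=meta)


def resample(spec: Spectrum, grid: np.ndarray | None = None) -> Spectrum:
    """Linear resampling onto a common grid (default 220-340 nm, 1-nm step),
    restricted to the overlap with the spectrum's own coverage."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    mask = (grid >= spec.wavelengths[0]) & (grid <= spec.wavelengths[-1])
    if not mask.any():
        raise IncompatibleSpectraError("no overlap with target grid")
    sub = grid[mask]
    vals = np.interp(sub, spec.wavelengths, spec.values)
    return Spectrum(sub, vals, units=spec.units, meta=dict(spec.meta))


def composite_spectrum(components: list[tuple[Spectrum, float]],
                       grid: np.ndarray | None = None) -> Spectrum:
    """Pointwise weighted sum of molar component spectra.

    Predicts the spectrum of a multi-domain structure as the sum of the
    spectra of its structural units (weights = copy numbers).  Components
    are resampled to a common grid; the grids must fully overlap it.
    """
    if not components:
        raise ValueError("need at least one component")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    total = np.zeros_like(grid)
    for spec, weight in components:
        if spec.units != "molar":
            raise IncompatibleSpectraError("components must be molar spectra")
        if weight < 0:
            raise ValueError("weights must be non-negative")
        rs = resample(spec, grid)
        if rs.wavelengths.shape != grid.shape:
            raise IncompatibleSpectraError(
                "component does not cover the composite grid"
            )
        total += weight * rs.values
    return Spectrum(grid.copy(), total, units="molar",
                    meta={"n_components": len(components)})


def quartet_scaled_prediction(reference: Spectrum, n_target: int,
                              n_ref: int = 3) -> Spectrum:
    """Scale a parallel-quadruplex reference spectrum from ``n_ref`` to
    ``n_target`` stacked G-quartets.

    Amplitude of the parallel CD signature is proportional to the quartet
    count, so the prediction is reference * (n_target / n_ref); peak
    positions are unchanged.
    """
    if n_ref < 1 or n_target < 1:
        raise ValueError("quartet counts must be positive integers")
    scaled = replace(reference,
                     wavelengths=reference.wavelengths.copy(),
                     values=reference.values * (n_target / n_ref),
                     meta=dict(reference.meta, n_ref=n_ref, n_target=n_target))
    return scaled


def classify_topology(spec: Spectrum,
                      max_window: tuple[float, float] = (255.0, 270.0),
                      min_window: tuple[float, float] = (235.0, 245.0)) -> str:
    """Classify a molar CD spectrum as ``"parallel"`` or ``"other"``.

    The all-parallel quadruplex signature is a positive global maximum near
    260 nm together with a negative trough near 240 nm; anything else —
    including antiparallel/hybrid spectra peaking near 290 nm and flat
    spectra — is "other".
    """
    if spec.units != "molar":
        raise ValueError("classification requires a molar spectrum")
    if spec.wavelengths[0] > 230.0 or spec.wavelengths[-1] < 300.0:
        raise CoverageError("spectrum must cover 230-300 nm")
    wl, val = spec.wavelengths, spec.values
    imax = int(np.argmax(val))
    peak_ok = (max_window[0] <= wl[imax] <= max_window[1]) and val[imax] > 0
    trough_mask = (wl >= min_window[0]) & (wl <= min_window[1])
    trough_ok = trough_mask.any() and val[trough_mask].min() < 0
    return "parallel" if (peak_ok and trough_ok) else "other"


def read_spectrum_csv(path, units: str = "raw") -> Spectrum:
    """Read a two-column (wavelength, value) CSV with a header line."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected two columns: wavelength, value")
    order = np.argsort(df.iloc[:, 0].to_numpy())
    return Spectrum(df.iloc[order, 0].to_numpy(dtype=float),
                    df.iloc[order, 1].to_numpy(dtype=float), units=units)


def write_spectrum_csv(spec: Spectrum, path) -> None:
    name = "delta_eps" if spec.units == "molar" else "theta_mdeg"
    pd.DataFrame({"wavelength_nm": spec.wavelengths, name: spec.values}).to_csv(
        path, index=False
    )
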