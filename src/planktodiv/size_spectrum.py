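"""Phytoplankton community size-spectrum slope.

Biomass is summed into the registry's phytoplankton size classes, and the
slope of log(class biomass) against log(class ESD) is estimated with the
Theil-Sen estimator (median of all pairwise slopes; robust to outlying
classes).  The reported spectrum slope is the regression slope plus 3,
converting the per-type biomass spectrum to the abundance spectrum of
spheres: negative reported values indicate relatively more biomass in small
cells.

Empty size classes are dropped from the fit rather than assigned log(0).
The slope is invariant to the logarithm base (the same base is used on both
axes) and to permutations of the points.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .diversity_metrics import presence
from .plankton_data import BiomassField, MetricField, TypeRegistry, period_mean

__all__ = ["FitError", "SizeSpectrum", "bin_by_size", "theil_sen_slope",
           "fit_spectrum", "spectrum_slope", "SPHERICAL_CORRECTION"]

#: Added to the raw log-log slope, assuming purely spherical cells.
SPHERICAL_CORRECTION = 3.0


class FitError(ValueError):
    """Too few distinct points to estimate a slope."""


@dataclass
class SizeSpectrum:
    """Binned spectrum for one cell/period; slopes filled by fit_spectrum."""

    class_esd_um: np.ndarray    # representative ESD per class (NaN if empty)
    class_biomass: np.ndarray   # biomass sum per class
    slope_raw: float | None = None
    slope_reported: float | None = None


def _membership(registry: TypeRegistry) -> np.ndarray:
    """(n_type, n_class) 0/1 matrix mapping phytoplankton types to classes."""
    n_cls = registry.n_size_classes
    M = np.zeros((len(registry), n_cls))
    phyto = registry.phyto_mask
    M[np.arange(len(registry))[phyto], registry.size_class[phyto] - 1] = 1.0
    return M


def bin_by_size(values: np.ndarray, registry: TypeRegistry,
                class_esd: str = "geometric_members") -> SizeSpectrum:
    """Sum a 1-D per-type biomass vector into size classes.

    Zooplankton types are excluded; the total phytoplankton biomass is
    preserved (sum of class sums equals sum over phytoplankton types).
    """
    values = np.asarray(values, float)
    if values.ndim != 1 or len(values) != len(registry):
        raise ValueError("expected a per-type biomass vector matching the registry")
    sums = np.nan_to_num(values, nan=0.0) @ _membership(registry)
    return SizeSpectrum(registry.class_esd(class_esd), sums)


def theil_sen_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Median of all pairwise slopes (y_j - y_i)/(x_j - x_i), i < j.

    Pairs with identical x are skipped; an even number of pairwise slopes
    yields the mean of the two middle values (the standard median).  Raises
    :class:`FitError` with fewer than two finite points or all-identical x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise FitError("need at least 2 finite points")
    i, j = np.triu_indices(len(x), k=1)
    dx = x[j] - x[i]
    nz = dx != 0
    if not nz.any():
        raise FitError("all x values identical")
    return float(np.median((y[j] - y[i])[nz] / dx[nz]))


def fit_spectrum(spectrum: SizeSpectrum) -> SizeSpectrum:
    """Fill in the raw and reported (+3) slopes of a binned spectrum.

    Classes with zero biomass or no representative ESD are excluded.
    """
    keep = (spectrum.class_biomass > 0) & np.isfinite(spectrum.class_esd_um)
    if keep.sum() < 2:
        raise FitError("fewer than 2 non-empty size classes")
    slope = theil_sen_slope(np.log(spectrum.class_esd_um[keep]),
                            np.log(spectrum.class_biomass[keep]))
    return dataclasses.replace(spectrum, slope_raw=slope,
                               slope_reported=slope + SPHERICAL_CORRECTION)


def spectrum_slope(field: BiomassField, period=None,
                   threshold_fraction: float | None = None,
                   class_esd: str = "geometric_members") -> MetricField:
    """Reported size-spectrum slope per grid cell.

    ``period=(start, end)`` averages the field first.  By default all
    biomass enters the bins; passing a ``threshold_fraction`` zeroes
    sub-threshold types before binning (off by default).  Cells with fewer
    than two non-empty classes are NaN.
    """
    f = period_mean(field, *period) if period is not None else field
    vals = f.values
    if threshold_fraction is not None:
        vals = vals * presence(f, threshold_fraction).values
    binned = np.nan_to_num(vals, nan=0.0) @ _membership(f.registry)
    esd = f.registry.class_esd(class_esd)
    nt, nlat, nlon, _ = binned.shape
    out = np.full((nt, nlat, nlon), np.nan)
    log_esd = np.log(esd)
    for t in range(nt):
        for iy in range(nlat):
            for ix in range(nlon):
                if not f.grid.ocean_mask[iy, ix]:
                    continue
                b = binned[t, iy, ix]
                keep = (b > 0) & np.isfinite(esd)
                if keep.sum() < 2:
                    continue
                out[t, iy, ix] = (theil_sen_slope(log_esd[keep], np.log(b[keep]))
                                  + SPHERICAL_CORRECTION)
    return MetricField(out, "size_spectrum_slope", f.grid, units="",
                       period=f.period if period is not None else field.period,
                       time=f.time).squeeze()
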