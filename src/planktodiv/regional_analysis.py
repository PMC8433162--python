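"""Percent-change maps, latitude-band masks, and area-weighted fractions.

This is the layer that turns gridded metric maps into "X% of the ocean area
in region R declines" statements.  Fractions are cos(latitude)-area-weighted
and computed over *valid* cells only: cells where the metric is undefined
(e.g. evenness with richness <= 1) are excluded from numerator and
denominator alike.  "Decline" and "increase" are strict (< 0, > 0); exact
zeros count toward neither.

Latitude bands use the half-open convention [south, north) on cell-centre
latitudes, so touching bands never double-count a row.  The Southern Ocean
boundary (default 45°S) and the subtropical band (default 23°-40°) are
explicit parameters, not facts of nature.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diversity_metrics, size_spectrum
from .plankton_data import BiomassField, Grid, MetricField, ValidationError, period_mean
from .turnover import (DEFAULT_EARLY_PAIR, DEFAULT_LATE_PAIR,
                       turnover_between, turnover_rate_change)

__all__ = [
    "RegionMask", "AreaFractionReport",
    "global_ocean", "lat_band", "abs_lat_band", "polar_or_equatorial",
    "subtropics", "southern_ocean",
    "percent_change", "change", "area_fraction", "summary_report",
]

DEFAULT_BASE_PERIOD = (2005, 2024)
DEFAULT_END_PERIOD = (2081, 2100)


@dataclass(frozen=True)
class RegionMask:
    name: str
    cells: np.ndarray  # (nlat, nlon) bool, subset of the ocean mask

    def __and__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(f"{self.name}&{other.name}", self.cells & other.cells)

    def __or__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(f"{self.name}|{other.name}", self.cells | other.cells)


@dataclass(frozen=True)
class AreaFractionReport:
    region: str
    condition: str
    fraction: float
    n_cells_valid: int


def global_ocean(grid: Grid) -> RegionMask:
    return RegionMask("global", grid.ocean_mask.copy())


def _band_cells(grid: Grid, south: float, north: float) -> np.ndarray:
    inband = (grid.lat >= south) & (grid.lat < north)
    return grid.ocean_mask & inband[:, None]


def lat_band(grid: Grid, south: float, north: float,
             name: str | None = None) -> RegionMask:
    """Ocean cells whose centre latitude lies in [south, north)."""
    return RegionMask(name or f"band({south},{north})",
                      _band_cells(grid, south, north))


def abs_lat_band(grid: Grid, lo: float, hi: float,
                 name: str | None = None) -> RegionMask:
    """Both-hemisphere band: lo <= |lat| < hi."""
    inband = (np.abs(grid.lat) >= lo) & (np.abs(grid.lat) < hi)
    return RegionMask(name or f"|lat| in [{lo},{hi})",
                      grid.ocean_mask & inband[:, None])


def polar_or_equatorial(grid: Grid, polar_edge: float = 55.0,
                        tropics_edge: float = 23.0) -> RegionMask:
    """Poleward of ``polar_edge`` or within ``tropics_edge`` of the equator."""
    sel = (np.abs(grid.lat) >= polar_edge) | (np.abs(grid.lat) < tropics_edge)
    return RegionMask(f"poleward of {polar_edge} or within {tropics_edge} of equator",
                      grid.ocean_mask & sel[:, None])


def subtropics(grid: Grid, lo: float = 23.0, hi: float = 40.0) -> RegionMask:
    return abs_lat_band(grid, lo, hi, name=f"subtropics({lo}-{hi})")


def southern_ocean(grid: Grid, boundary: float = -45.0) -> RegionMask:
    sel = grid.lat < boundary
    return RegionMask(f"southern_ocean(<{boundary})",
                      grid.ocean_mask & sel[:, None])


def _check_same_grid(a: MetricField, b: MetricField) -> None:
    if not a.grid.equals(b.grid):
        raise ValidationError("metric fields are on different grids")


def percent_change(base: MetricField, end: MetricField) -> MetricField:
    """100 x (end - base)/base; NaN where base <= 0 or either input missing."""
    _check_same_grid(base, end)
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = np.isfinite(base.values) & np.isfinite(end.values) & (base.values > 0)
        pc = np.where(ok, 100.0 * (end.values - base.values)
                      / np.where(ok, base.values, 1.0), np.nan)
    return MetricField(pc, f"pct_change_{base.metric_name}", base.grid,
                       units="%", period=(base.period, end.period))


def change(base: MetricField, end: MetricField) -> MetricField:
    """Plain difference end - base (for metrics where % change is meaningless)."""
    _check_same_grid(base, end)
    return MetricField(end.values - base.values,
                       f"change_{base.metric_name}", base.grid,
                       units=base.units, period=(base.period, end.period))


def _condition(condition) -> tuple:
    """Normalize a condition spec to (description, predicate)."""
    if callable(condition):
        return getattr(condition, "__name__", "custom"), condition
    if isinstance(condition, str):
        if condition == "decline":
            return "decline", lambda v: v < 0
        if condition == "increase":
            return "increase", lambda v: v > 0
        if ":" in condition:
            kind, _, val = condition.partition(":")
            condition = (kind, float(val))
        else:
            raise ValueError(f"unknown condition {condition!r}")
    kind, x = condition
    if kind == "below":
        return f"below {x}", lambda v: v < x
    if kind == "above":
        return f"above {x}", lambda v: v > x
    raise ValueError(f"unknown condition kind {kind!r}")


def area_fraction(metric: MetricField, region: RegionMask,
                  condition) -> AreaFractionReport:
    """Area-weighted fraction of the region's valid cells meeting a condition.

    ``condition`` is "decline", "increase", ("below", x), ("above", x), a
    "below:x"/"above:x" string, or a vectorized predicate.
    """
    if not metric.is_map:
        raise ValueError("area_fraction expects a 2-D metric map; reduce the "
                         "time axis first")
    desc, pred = _condition(condition)
    valid = region.cells & np.isfinite(metric.values)
    w = metric.grid.area_weight
    denom = w[valid].sum()
    if denom <= 0:
        raise ValueError(f"region {region.name!r} has no valid cells")
    hit = valid & pred(metric.values)
    return AreaFractionReport(region.name, desc,
                              float(w[hit].sum() / denom),
                              int(valid.sum()))


def area_weighted_mean(metric: MetricField, region: RegionMask) -> float:
    valid = region.cells & np.isfinite(metric.values)
    w = metric.grid.area_weight
    denom = w[valid].sum()
    if denom <= 0:
        raise ValueError(f"region {region.name!r} has no valid cells")
    return float((metric.values[valid] * w[valid]).sum() / denom)


DEFAULT_REPORT_ROWS = (
    # metric, kind, region, condition
    ("total_biomass", "percent_change", "global", "decline"),
    ("total_biomass", "percent_change", "tropics", "decline"),
    ("richness", "percent_change", "northern_midlat", "decline"),
    ("richness", "percent_change", "polar_or_equatorial", "increase"),
    ("shannon", "change", "global", "decline"),
    ("evenness", "change", "global", "decline"),
    ("turnover_rate", "change", "global", "increase"),
    ("size_spectrum_slope", "change", "subtropics", "decline"),
    ("size_spectrum_slope", "change", "southern_ocean", "decline"),
    ("size_spectrum_slope", "change", "global", "increase"),
)


def _total_biomass_map(field: BiomassField, period) -> MetricField:
    pm = period_mean(field, *period)
    vals = np.where(field.grid.ocean_mask, pm.phyto_total()[0], np.nan)
    return MetricField(vals, "total_biomass", field.grid,
                       units=field.units, period=pm.period)


def summary_report(field: BiomassField, config: dict | None = None) -> pd.DataFrame:
    """Area-fraction table over (metric, region, condition) rows.

    The default configuration compares the baseline period (2005-2024 mean)
    with the end of century (2081-2100 mean) for total phytoplankton
    biomass, richness, Shannon, evenness, turnover rate, and the
    size-spectrum slope, over the built-in regions.  ``config`` may override
    periods, band edges, the presence threshold, and the row list.
    """
    cfg = dict(config or {})
    base_p = tuple(cfg.get("base_period", DEFAULT_BASE_PERIOD))
    end_p = tuple(cfg.get("end_period", DEFAULT_END_PERIOD))
    early_pair = tuple(map(tuple, cfg.get("early_pair", DEFAULT_EARLY_PAIR)))
    late_pair = tuple(map(tuple, cfg.get("late_pair", DEFAULT_LATE_PAIR)))
    thr = float(cfg.get("threshold_fraction", diversity_metrics.DEFAULT_THRESHOLD))
    tropics_edge = float(cfg.get("tropics_edge", 23.0))
    polar_edge = float(cfg.get("polar_edge", 55.0))
    sub_lo, sub_hi = cfg.get("subtropics", (23.0, 40.0))
    so_edge = float(cfg.get("southern_ocean_edge", -45.0))
    rows = cfg.get("rows", DEFAULT_REPORT_ROWS)

    grid = field.grid
    regions = {
        "global": global_ocean(grid),
        "tropics": abs_lat_band(grid, 0.0, tropics_edge, name="tropics"),
        "northern_midlat": lat_band(grid, tropics_edge, polar_edge,
                                    name=f"{tropics_edge}N-{polar_edge}N"),
        "polar_or_equatorial": polar_or_equatorial(grid, polar_edge, tropics_edge),
        "subtropics": subtropics(grid, float(sub_lo), float(sub_hi)),
        "southern_ocean": southern_ocean(grid, so_edge),
    }

    base = period_mean(field, *base_p)
    end = period_mean(field, *end_p)

    def metric_pair(name):
        if name == "total_biomass":
            return (_total_biomass_map(field, base_p),
                    _total_biomass_map(field, end_p))
        if name == "richness":
            rich = lambda f: diversity_metrics.richness(
                diversity_metrics.presence(f, thr))
            return rich(base), rich(end)
        if name == "shannon":
            return (diversity_metrics.shannon(base, thr),
                    diversity_metrics.shannon(end, thr))
        if name == "evenness":
            return (diversity_metrics.evenness(base, thr),
                    diversity_metrics.evenness(end, thr))
        if name == "size_spectrum_slope":
            return (size_spectrum.spectrum_slope(field, base_p),
                    size_spectrum.spectrum_slope(field, end_p))
        raise ValueError(f"unknown metric {name!r}")

    cache: dict = {}
    records = []
    for metric_name, kind, region_name, condition in rows:
        key = (metric_name, kind)
        if key not in cache:
            if metric_name == "turnover":
                cache[key] = turnover_between(field, base_p, end_p,
                                              threshold_fraction=thr)
            elif metric_name == "turnover_rate":
                cache[key] = turnover_rate_change(field, early_pair, late_pair,
                                                  threshold_fraction=thr)
            else:
                b, e = metric_pair(metric_name)
                cache[key] = (percent_change(b, e) if kind == "percent_change"
                              else change(b, e))
        region = regions[region_name]
        rep = area_fraction(cache[key], region, condition)
        records.append({
            "metric": metric_name,
            "kind": kind,
            "region": region_name,
            "region_definition": region.name,
            "condition": rep.condition,
            "fraction": rep.fraction,
            "n_cells_valid": rep.n_cells_valid,
        })
    return pd.DataFrame.from_records(records)
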