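"""Thresholded presence, functional richness, Shannon index, evenness, and
per-group appearance/disappearance maps.

A phytoplankton type counts as *present* at a cell and timestep when its
biomass share of the total phytoplankton biomass there is at least the
threshold fraction (default 0.1%); rarer types are excluded from all
diversity metrics.  Shares entering the Shannon index

    H = -sum_i p_i ln p_i        (natural log)

are renormalized over the included types so they sum to one and H <= ln s
holds exactly, with s the thresholded richness.  Evenness is H / ln s,
defined only for s >= 2.  Zooplankton types never enter phytoplankton
presence, shares, or counts.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .plankton_data import (
    PHYTO_GROUPS,
    BiomassField,
    MetricField,
    ValidationError,
)

__all__ = [
    "DEFAULT_THRESHOLD",
    "PresenceField",
    "presence",
    "richness",
    "shannon",
    "evenness",
    "shannon_evenness_richness",
    "appearance_disappearance",
]

DEFAULT_THRESHOLD = 0.001  # 0.1% biomass-share exclusion rule


@dataclass(eq=False)
class PresenceField:
    """Boolean (time, lat, lon, type) presence after thresholding."""

    values: np.ndarray
    threshold_fraction: float
    registry: object
    grid: object
    time: np.ndarray

    def counts(self) -> np.ndarray:
        """Presence count per cell/timestep over phytoplankton types."""
        return self.values.sum(axis=-1)


def presence(field: BiomassField,
             threshold_fraction: float = DEFAULT_THRESHOLD) -> PresenceField:
    """Thresholded presence: biomass share of total phytoplankton >= threshold.

    A share exactly equal to the threshold counts as present ("less than
    0.1% ... excluded").  Cells with zero total phytoplankton biomass have
    no types present; land (NaN) likewise.  With threshold 0, presence
    reduces to strictly positive biomass.
    """
    if not (0.0 <= threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in [0, 1)")
    phyto = field.registry.phyto_mask
    b = np.nan_to_num(field.values, nan=0.0)
    total = b[..., phyto].sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, b / np.where(total > 0, total, 1.0), 0.0)
    present = (b > 0) & (share >= threshold_fraction) & phyto
    return PresenceField(present, threshold_fraction, field.registry,
                         field.grid, field.time)


def _land_nan(values: np.ndarray, grid) -> np.ndarray:
    out = np.asarray(values, float)
    return np.where(grid.ocean_mask, out, np.nan)


def richness(p: PresenceField) -> MetricField:
    """Number of coexisting phytoplankton types per cell/timestep."""
    counts = _land_nan(p.counts(), p.grid)
    return MetricField(counts, "richness", p.grid, units="types",
                       time=p.time).squeeze()


def _shannon_arrays(field: BiomassField, threshold_fraction: float):
    """Return (H, s) arrays over (time, lat, lon)."""
    pres = presence(field, threshold_fraction)
    b = np.nan_to_num(field.values, nan=0.0) * pres.values
    total = b.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, b / np.where(total > 0, total, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    H = -plogp.sum(axis=-1)
    s = pres.counts()
    H = np.where(s >= 2, H, 0.0)  # single-type or empty communities carry no entropy
    return H, s


def shannon(field: BiomassField,
            threshold_fraction: float = DEFAULT_THRESHOLD) -> MetricField:
    """Shannon index (nats) of the thresholded, renormalized biomass shares."""
    H, _ = _shannon_arrays(field, threshold_fraction)
    return MetricField(_land_nan(H, field.grid), "shannon", field.grid,
                       units="nats", period=field.period,
                       time=field.time).squeeze()


def evenness(field: BiomassField,
             threshold_fraction: float = DEFAULT_THRESHOLD) -> MetricField:
    """Pielou-style evenness H/ln(s); undefined (NaN) where s <= 1."""
    H, s = _shannon_arrays(field, threshold_fraction)
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(s >= 2, H / np.log(np.maximum(s, 2)), np.nan)
    return MetricField(_land_nan(J, field.grid), "evenness", field.grid,
                       units="", period=field.period,
                       time=field.time).squeeze()


def shannon_evenness_richness(field: BiomassField,
                              threshold_fraction: float = DEFAULT_THRESHOLD):
    """All three Eq.-layer metrics in one pass (shared thresholding)."""
    return (shannon(field, threshold_fraction),
            evenness(field, threshold_fraction),
            richness(presence(field, threshold_fraction)))


def appearance_disappearance(base: BiomassField, end: BiomassField,
                             group: str,
                             threshold_fraction: float = DEFAULT_THRESHOLD):
    """Count group members crossing the presence threshold between two period
    means.

    Appearance: absent (share below threshold) in the base-period mean and
    present in the end-period mean; disappearance is the converse.  Both
    inputs must be period means (single time slice) on the same grid and
    registry.  Returns ``(appearances, disappearances)`` MetricFields with
    counts bounded by the group size.
    """
    if group not in PHYTO_GROUPS:
        raise ValueError(f"unknown phytoplankton group {group!r}")
    if not base.registry.equals(end.registry):
        raise ValidationError("base and end fields use different registries")
    if not base.grid.equals(end.grid):
        raise ValidationError("base and end fields use different grids")
    if base.values.shape[0] != 1 or end.values.shape[0] != 1:
        raise ValueError("appearance_disappearance expects period-mean fields "
                         "(time length 1); apply period_mean first")
    members = base.registry.group_mask(group)
    pb = presence(base, threshold_fraction).values[0][..., members]
    pe = presence(end, threshold_fraction).values[0][..., members]
    period = (base.period, end.period)
    app = _land_nan((~pb & pe).sum(axis=-1), base.grid)
    dis = _land_nan((pb & ~pe).sum(axis=-1), base.grid)
    return (
        MetricField(app, f"appearance_{group}", base.grid, units="types",
                    period=period),
        MetricField(dis, f"disappearance_{group}", base.grid, units="types",
                    period=period),
    )
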