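"""Community turnover between two timepoints and its change in rate.

Turnover between presence sets A (base) and B (end) is

    turnover = (N_G + N_L) / N_T

with N_G the types gained (in B, not A), N_L the types lost (in A, not B)
and N_T the number of types observed across both timepoints, i.e. the size
of the union.  It runs from 0 (all types persist) to 1 (all types change)
and equals the Jaccard distance between the two presence sets.  Cells where
both sets are empty are undefined (NaN), not 0.

Presence is computed from *period-mean* biomass (two multi-year means are
compared, not per-year turnovers averaged).  The change in turnover rate
compares a late period pair against an early pair; with the default periods
it is turnover(2061-2080 mean, 2081-2100 mean) minus turnover(2011-2030
mean, 2031-2040 mean).
"""
from __future__ import annotations

import numpy as np

from .diversity_metrics import DEFAULT_THRESHOLD, PresenceField, presence
from .plankton_data import BiomassField, MetricField, ValidationError, period_mean

__all__ = ["turnover", "turnover_rate_change",
           "DEFAULT_EARLY_PAIR", "DEFAULT_LATE_PAIR"]

DEFAULT_EARLY_PAIR = ((2011, 2030), (2031, 2040))
DEFAULT_LATE_PAIR = ((2061, 2080), (2081, 2100))


def _squeeze_presence(p: PresenceField) -> np.ndarray:
    v = p.values
    if v.ndim == 4:
        if v.shape[0] != 1:
            raise ValueError("turnover expects single-timepoint (period-mean) "
                             "presence slices")
        v = v[0]
    return v


def turnover(base_presence: PresenceField,
             end_presence: PresenceField) -> MetricField:
    """Gained-plus-lost over union of two presence sets, per cell."""
    if not base_presence.registry.equals(end_presence.registry):
        raise ValidationError("presence fields use different registries")
    A = _squeeze_presence(base_presence)
    B = _squeeze_presence(end_presence)
    gained = (~A & B).sum(axis=-1)
    lost = (A & ~B).sum(axis=-1)
    union = (A | B).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(union > 0, (gained + lost) / np.maximum(union, 1), np.nan)
    grid = base_presence.grid
    t = np.where(grid.ocean_mask, t, np.nan)
    return MetricField(t, "turnover", grid, units="")


def turnover_between(field: BiomassField, base_period, end_period,
                     threshold_fraction: float = DEFAULT_THRESHOLD) -> MetricField:
    """Turnover between the presence sets of two period means of one field."""
    pb = presence(period_mean(field, *base_period), threshold_fraction)
    pe = presence(period_mean(field, *end_period), threshold_fraction)
    out = turnover(pb, pe)
    out.period = (tuple(base_period), tuple(end_period))
    return out


def _check_pair(pair, field: BiomassField, label: str) -> None:
    (a0, a1), (b0, b1) = pair
    for (lo, hi) in ((a0, a1), (b0, b1)):
        if lo > hi:
            raise ValueError(f"{label} period {lo}-{hi} is reversed")
        if lo > field.time.max() or hi < field.time.min():
            raise ValueError(f"{label} period {lo}-{hi} outside the field's "
                             f"time axis")
    if not (a1 < b0 or b1 < a0):
        raise ValueError(f"{label} periods {pair} overlap")


def turnover_rate_change(field: BiomassField,
                         early_pair=DEFAULT_EARLY_PAIR,
                         late_pair=DEFAULT_LATE_PAIR,
                         threshold_fraction: float = DEFAULT_THRESHOLD,
                         ) -> MetricField:
    """Late-pair turnover minus early-pair turnover, in [-1, 1] per cell."""
    _check_pair(early_pair, field, "early")
    _check_pair(late_pair, field, "late")
    early = turnover_between(field, *early_pair,
                             threshold_fraction=threshold_fraction)
    late = turnover_between(field, *late_pair,
                            threshold_fraction=threshold_fraction)
    change = late.values - early.values
    return MetricField(change, "turnover_rate_change", field.grid, units="",
                       period=(tuple(map(tuple, early_pair)),
                               tuple(map(tuple, late_pair))))
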