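"""Domain containers and netCDF I/O for gridded plankton biomass analysis.

The central object is a :class:`BiomassField`: depth-integrated biomass
(mass carbon per unit area) on a regular latitude-longitude grid, resolved
by calendar year and by plankton type.  Types carry metadata in a
:class:`TypeRegistry` (biogeochemical functional group, equivalent
spherical diameter, size class, trophic role); the grid carries
cos(latitude) area weights and an ocean mask.

Files are plain netCDF (classic 64-bit offset, written through xarray's
scipy engine) so that fields and metric maps round-trip without any
compiled netCDF library.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr

__all__ = [
    "FormatError",
    "ValidationError",
    "PeriodError",
    "PHYTO_GROUPS",
    "DEFAULT_GROUP_COUNTS",
    "ZOO_GROUP",
    "ESD_RANGE_UM",
    "N_SIZE_CLASSES",
    "size_class_edges",
    "TypeRegistry",
    "Grid",
    "BiomassField",
    "MetricField",
    "period_mean",
    "read_biomass",
    "write_biomass",
    "read_metric",
    "write_metric",
]


class FormatError(ValueError):
    """A file does not have the expected dimensions or variables."""


class ValidationError(ValueError):
    """Data violate a container invariant (negative biomass, NaN in ocean, ...)."""


class PeriodError(ValueError):
    """A requested year range does not intersect the field's time axis."""


# Biogeochemical functional groups, smallest to largest characteristic size,
# and the number of types per group in the default community.
PHYTO_GROUPS = (
    "prokaryote",
    "picoeukaryote",
    "coccolithophore",
    "diazotroph",
    "diatom",
    "mixotrophic_dinoflagellate",
)
DEFAULT_GROUP_COUNTS = {
    "prokaryote": 2,
    "picoeukaryote": 2,
    "coccolithophore": 5,
    "diazotroph": 5,
    "diatom": 11,
    "mixotrophic_dinoflagellate": 10,
}
ZOO_GROUP = "zooplankton"

#: Full community size range, equivalent spherical diameter in micrometres.
ESD_RANGE_UM = (0.6, 2425.0)
N_SIZE_CLASSES = 16


def size_class_edges(
    n_classes: int = N_SIZE_CLASSES,
    esd_range: tuple[float, float] = ESD_RANGE_UM,
) -> np.ndarray:
    """Log-uniform size-class bin edges over the community ESD range.

    The class boundaries are not pinned down by any single published
    convention, so they are an explicit, configurable choice: ``n_classes``
    bins equally spaced in log(ESD).
    """
    lo, hi = esd_range
    if not (0 < lo < hi):
        raise ValueError("esd_range must be positive and increasing")
    return np.geomspace(lo, hi, n_classes + 1)


def _assign_size_class(esd_um: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """1-based size class per type; values clipped into the outer bins."""
    idx = np.searchsorted(edges, esd_um, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2) + 1


@dataclass(frozen=True, eq=False)
class TypeRegistry:
    """Per-type metadata: name, group, size, size class and trophic role."""

    names: tuple
    group: np.ndarray       # str per type
    esd_um: np.ndarray      # positive, micrometres
    trophic_role: np.ndarray  # "phytoplankton" | "zooplankton"
    size_class: np.ndarray  # 1..n_classes for phytoplankton, 0 for zooplankton
    class_edges: np.ndarray = dc_field(default_factory=size_class_edges)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def phyto_mask(self) -> np.ndarray:
        return self.trophic_role == "phytoplankton"

    @property
    def zoo_mask(self) -> np.ndarray:
        return self.trophic_role == "zooplankton"

    @property
    def n_phyto(self) -> int:
        return int(self.phyto_mask.sum())

    @property
    def n_size_classes(self) -> int:
        return len(self.class_edges) - 1

    def group_mask(self, group: str) -> np.ndarray:
        if group not in PHYTO_GROUPS and group != ZOO_GROUP:
            raise ValueError(f"unknown group {group!r}; expected one of "
                             f"{PHYTO_GROUPS + (ZOO_GROUP,)}")
        return self.group == group

    def group_counts(self) -> dict:
        return {g: int((self.group == g).sum()) for g in PHYTO_GROUPS}

    def class_esd(self, convention: str = "geometric_members") -> np.ndarray:
        """Representative ESD per size class (NaN where no phytoplankton type).

        ``geometric_members``: geometric mean of member-type ESDs (natural on
        a log size axis); ``edges_midpoint``: geometric midpoint of the bin
        edges, independent of which types populate the bin.
        """
        n = self.n_size_classes
        if convention == "edges_midpoint":
            return np.sqrt(self.class_edges[:-1] * self.class_edges[1:])
        if convention != "geometric_members":
            raise ValueError(f"unknown class ESD convention {convention!r}")
        out = np.full(n, np.nan)
        phyto = self.phyto_mask
        for c in range(1, n + 1):
            members = phyto & (self.size_class == c)
            if members.any():
                out[c - 1] = np.exp(np.mean(np.log(self.esd_um[members])))
        return out

    def validate(self, strict_group_counts: bool = True) -> None:
        n = len(self)
        for arr, name in ((self.group, "group"), (self.esd_um, "esd_um"),
                          (self.trophic_role, "trophic_role"),
                          (self.size_class, "size_class")):
            if len(arr) != n:
                raise ValidationError(f"registry field {name} has length "
                                      f"{len(arr)}, expected {n}")
        lo, hi = ESD_RANGE_UM
        if np.any(self.esd_um < lo) or np.any(self.esd_um > hi):
            raise ValidationError(f"esd_um outside [{lo}, {hi}] um")
        phyto = self.phyto_mask
        sc = self.size_class[phyto]
        if np.any((sc < 1) | (sc > self.n_size_classes)):
            raise ValidationError("phytoplankton size_class outside 1..%d"
                                  % self.n_size_classes)
        if strict_group_counts:
            counts = self.group_counts()
            if counts != DEFAULT_GROUP_COUNTS:
                raise ValidationError(
                    "phytoplankton group counts %r differ from the default %r; "
                    "pass strict_group_counts=False for a custom community"
                    % (counts, DEFAULT_GROUP_COUNTS))

    def equals(self, other: "TypeRegistry") -> bool:
        return (
            self.names == other.names
            and np.array_equal(self.group, other.group)
            and np.allclose(self.esd_um, other.esd_um, rtol=1e-6)
            and np.array_equal(self.trophic_role, other.trophic_role)
            and np.array_equal(self.size_class, other.size_class)
            and np.allclose(self.class_edges, other.class_edges, rtol=1e-6)
        )

    @classmethod
    def default(cls) -> "TypeRegistry":
        """The 51-type community: 35 phytoplankton in 6 groups + 16 zooplankton.

        Group ESD spans follow the usual trait-based convention: prokaryotes
        and picoeukaryotes below ~2 um, coccolithophores and diazotrophs a few
        to ~15 um, diatoms up to ~100 um, mixotrophic dinoflagellates up to
        ~230 um, zooplankton size classes up to 2425 um.
        """
        group_esd = {
            "prokaryote": np.array([0.6, 0.9]),
            "picoeukaryote": np.array([1.3, 2.0]),
            "coccolithophore": np.geomspace(3.0, 10.0, 5),
            "diazotroph": np.geomspace(4.0, 15.0, 5),
            "diatom": np.geomspace(4.5, 104.0, 11),
            "mixotrophic_dinoflagellate": np.geomspace(7.0, 228.0, 10),
        }
        names, groups, esds, roles = [], [], [], []
        for g in PHYTO_GROUPS:
            for k, d in enumerate(group_esd[g], start=1):
                names.append(f"{g}_{k:02d}")
                groups.append(g)
                esds.append(float(d))
                roles.append("phytoplankton")
        for k, d in enumerate(np.geomspace(4.5, 2425.0, 16), start=1):
            names.append(f"zooplankton_{k:02d}")
            groups.append(ZOO_GROUP)
            esds.append(float(d))
            roles.append("zooplankton")
        edges = size_class_edges()
        esd = np.asarray(esds)
        role = np.asarray(roles)
        size_class = np.where(role == "phytoplankton",
                              _assign_size_class(esd, edges), 0)
        reg = cls(tuple(names), np.asarray(groups), esd, role, size_class, edges)
        reg.validate()
        return reg

    @classmethod
    def synthetic(cls, n_phyto: int, n_zoo: int = 0,
                  esd_range_phyto: tuple[float, float] = (0.6, 228.0),
                  ) -> "TypeRegistry":
        """A reduced community for fixtures: sizes log-spaced, groups assigned
        in proportion to the default community's group counts."""
        if n_phyto < 1:
            raise ValueError("need at least one phytoplankton type")
        esd_p = np.geomspace(*esd_range_phyto, n_phyto)
        # proportional allocation of group labels, smallest groups first
        weights = np.array([DEFAULT_GROUP_COUNTS[g] for g in PHYTO_GROUPS], float)
        alloc = np.floor(weights / weights.sum() * n_phyto).astype(int)
        alloc = np.maximum(alloc, 1) if n_phyto >= len(PHYTO_GROUPS) else alloc
        while alloc.sum() < n_phyto:
            alloc[np.argmax(weights / np.maximum(alloc, 1))] += 1
        while alloc.sum() > n_phyto:
            alloc[np.argmax(alloc)] -= 1
        names, groups, esds, roles = [], [], [], []
        i = 0
        for g, k in zip(PHYTO_GROUPS, alloc):
            for _ in range(k):
                names.append(f"{g}_{i + 1:02d}")
                groups.append(g)
                esds.append(float(esd_p[i]))
                roles.append("phytoplankton")
                i += 1
        for k in range(n_zoo):
            names.append(f"zooplankton_{k + 1:02d}")
            groups.append(ZOO_GROUP)
            esds.append(float(np.geomspace(4.5, 2425.0, max(n_zoo, 2))[k]))
            roles.append("zooplankton")
        edges = size_class_edges()
        esd = np.asarray(esds)
        role = np.asarray(roles)
        size_class = np.where(role == "phytoplankton",
                              _assign_size_class(esd, edges), 0)
        reg = cls(tuple(names), np.asarray(groups), esd, role, size_class, edges)
        reg.validate(strict_group_counts=False)
        return reg


@dataclass(frozen=True, eq=False)
class Grid:
    """Regular latitude-longitude grid with area weights and ocean mask.

    Area weights are proportional to cos(latitude) x cell angular extent;
    only area *fractions* are ever reported, so the spherical-cap constant
    is irrelevant.  Weights are zero exactly on land.
    """

    lat: np.ndarray        # cell-centre latitudes, degrees
    lon: np.ndarray        # cell-centre longitudes, degrees, in [-180, 180)
    ocean_mask: np.ndarray  # (nlat, nlon) bool
    area_weight: np.ndarray  # (nlat, nlon), > 0 iff ocean

    @property
    def shape(self) -> tuple:
        return (len(self.lat), len(self.lon))

    def validate(self) -> None:
        if self.ocean_mask.shape != self.shape or self.area_weight.shape != self.shape:
            raise ValidationError("mask/weight shape does not match lat x lon")
        if np.any((self.area_weight > 0) != self.ocean_mask):
            raise ValidationError("area_weight must be > 0 exactly on ocean cells")
        tot = self.area_weight.sum()
        if not np.isfinite(tot) or tot <= 0:
            raise ValidationError("total ocean area must be finite and positive")

    def equals(self, other: "Grid") -> bool:
        return (np.allclose(self.lat, other.lat)
                and np.allclose(self.lon, other.lon)
                and np.array_equal(self.ocean_mask, other.ocean_mask))

    @classmethod
    def from_coords(cls, lat: np.ndarray, lon: np.ndarray,
                    ocean_mask: np.ndarray | None = None) -> "Grid":
        lat = np.asarray(lat, float)
        lon = normalize_lon(np.asarray(lon, float))
        if ocean_mask is None:
            ocean_mask = np.ones((len(lat), len(lon)), bool)
        ocean_mask = np.asarray(ocean_mask, bool)
        dlat = float(np.median(np.abs(np.diff(lat)))) if len(lat) > 1 else 1.0
        dlon = float(np.median(np.abs(np.diff(np.sort(lon))))) if len(lon) > 1 else 1.0
        w = np.cos(np.deg2rad(lat))[:, None] * np.ones(len(lon))[None, :]
        w = w * np.deg2rad(dlat) * np.deg2rad(dlon)
        w = np.where(ocean_mask, np.maximum(w, 0.0), 0.0)
        g = cls(lat, lon, ocean_mask, w)
        g.validate()
        return g

    @classmethod
    def regular(cls, nlat: int, nlon: int,
                ocean_mask: np.ndarray | None = None) -> "Grid":
        """Global grid with nlat x nlon equal-angle cells (centres, not edges)."""
        lat = -90.0 + (np.arange(nlat) + 0.5) * (180.0 / nlat)
        lon = -180.0 + (np.arange(nlon) + 0.5) * (360.0 / nlon)
        return cls.from_coords(lat, lon, ocean_mask)


def normalize_lon(lon: np.ndarray) -> np.ndarray:
    """Map longitudes to the internal [-180, 180) convention."""
    return (np.asarray(lon, float) + 180.0) % 360.0 - 180.0


@dataclass(eq=False)
class BiomassField:
    """Depth-integrated biomass, time x lat x lon x type, NaN on land."""

    time: np.ndarray           # calendar years (nt,)
    values: np.ndarray         # (nt, nlat, nlon, ntype), >= 0 on ocean
    registry: TypeRegistry
    grid: Grid
    units: str = "mgC m-2"
    period: tuple | None = None  # (start_year, end_year) if time-averaged

    def validate(self) -> None:
        nt, nlat, nlon, ntype = self.values.shape
        if len(self.time) != nt:
            raise ValidationError("time axis length mismatch")
        if (nlat, nlon) != self.grid.shape:
            raise ValidationError("spatial shape does not match grid")
        if ntype != len(self.registry):
            raise ValidationError(
                f"type dimension {ntype} != registry length {len(self.registry)}")
        ocean = self.grid.ocean_mask
        vals_ocean = self.values[:, ocean, :]
        if np.isnan(vals_ocean).any():
            raise ValidationError("NaN biomass in ocean cells")
        if (vals_ocean < 0).any():
            raise ValidationError("negative biomass in ocean cells")

    @property
    def n_types(self) -> int:
        return self.values.shape[-1]

    def phyto_total(self) -> np.ndarray:
        """Total phytoplankton biomass, (nt, nlat, nlon)."""
        return np.nansum(self.values[..., self.registry.phyto_mask], axis=-1)

    def copy(self) -> "BiomassField":
        return dataclasses.replace(self, values=self.values.copy(),
                                   time=self.time.copy())


@dataclass(eq=False)
class MetricField:
    """Gridded scalar diagnostic ((time,) lat, lon), NaN where undefined."""

    values: np.ndarray
    metric_name: str
    grid: Grid
    units: str = ""
    period: tuple | None = None
    time: np.ndarray | None = None

    @property
    def is_map(self) -> bool:
        return self.values.ndim == 2

    def squeeze(self) -> "MetricField":
        """Drop a singleton time axis."""
        if self.values.ndim == 3 and self.values.shape[0] == 1:
            return dataclasses.replace(self, values=self.values[0], time=None)
        return self


def period_mean(field: BiomassField, start_year: int, end_year: int) -> BiomassField:
    """Arithmetic mean over the inclusive year range [start_year, end_year].

    The time dimension collapses to length 1; the resulting field records the
    averaging period.  Raises :class:`PeriodError` if no year of the field
    falls inside the range.
    """
    sel = (field.time >= start_year) & (field.time <= end_year)
    if not sel.any():
        raise PeriodError(
            f"period {start_year}-{end_year} does not intersect the field's "
            f"time axis ({field.time.min()}-{field.time.max()})")
    mean = field.values[sel].mean(axis=0, keepdims=True)
    return dataclasses.replace(
        field, time=np.array([int(round((start_year + end_year) / 2))]),
        values=mean, period=(int(start_year), int(end_year)))


# ---------------------------------------------------------------------------
# netCDF I/O (classic format through xarray's scipy engine)

DEFAULT_LAYOUT = {
    "time": "time",
    "lat": "lat",
    "lon": "lon",
    "type": "type",
    "biomass": "biomass",
    "esd": "type_esd_um",
    "size_class": "type_size_class",
    "group": "type_group",
    "trophic": "type_trophic",
    "ocean_mask": "ocean_mask",
}

_TROPHIC_CODES = {"phytoplankton": 0, "zooplankton": 1}


def _registry_to_vars(reg: TypeRegistry, layout: dict) -> dict:
    all_groups = PHYTO_GROUPS + (ZOO_GROUP,)
    gcode = np.array([all_groups.index(g) for g in reg.group], np.int32)
    tcode = np.array([_TROPHIC_CODES[t] for t in reg.trophic_role], np.int32)
    return {
        layout["esd"]: (("type",), reg.esd_um.astype(float),
                        {"units": "um", "long_name": "equivalent spherical diameter"}),
        layout["size_class"]: (("type",), reg.size_class.astype(np.int32),
                               {"long_name": "phytoplankton size class (1-based; 0 = zooplankton)"}),
        layout["group"]: (("type",), gcode,
                          {"codes": " ".join(f"{i}={g}" for i, g in enumerate(all_groups))}),
        layout["trophic"]: (("type",), tcode, {"codes": "0=phytoplankton 1=zooplankton"}),
    }


def _registry_from_ds(ds: xr.Dataset, layout: dict) -> TypeRegistry:
    for key in ("esd", "size_class", "group", "trophic"):
        if layout[key] not in ds:
            raise FormatError(f"missing variable {layout[key]!r}")
    gvar = ds[layout[key := "group"]]
    codes = dict(item.split("=") for item in gvar.attrs["codes"].split())
    group = np.array([codes[str(int(c))] for c in gvar.values])
    trophic = np.where(ds[layout["trophic"]].values.astype(int) == 0,
                       "phytoplankton", "zooplankton")
    names_attr = ds.attrs.get("type_names", "")
    names = tuple(names_attr.split(",")) if names_attr else tuple(
        f"type_{i:02d}" for i in range(ds.sizes["type"]))
    edges = np.asarray(ds.attrs.get("size_class_edges", size_class_edges()), float)
    return TypeRegistry(names, group, ds[layout["esd"]].values.astype(float),
                        trophic, ds[layout["size_class"]].values.astype(int), edges)


def write_biomass(field: BiomassField, path) -> None:
    """Write a biomass field as classic netCDF; land cells stored as NaN."""
    field.validate()
    layout = DEFAULT_LAYOUT
    vals = np.where(field.grid.ocean_mask[None, :, :, None],
                    field.values, np.nan)
    data_vars = {
        layout["biomass"]: (("time", "lat", "lon", "type"), vals.astype("f8"),
                            {"units": field.units,
                             "long_name": "depth-integrated biomass"}),
        layout["ocean_mask"]: (("lat", "lon"),
                               field.grid.ocean_mask.astype(np.int32)),
    }
    data_vars.update(_registry_to_vars(field.registry, layout))
    attrs = {
        "type_names": ",".join(field.registry.names),
        "size_class_edges": field.registry.class_edges.astype(float),
    }
    if field.period is not None:
        attrs["period_start"], attrs["period_end"] = map(int, field.period)
    ds = xr.Dataset(
        data_vars,
        coords={"time": ("time", field.time.astype(np.int32), {"units": "year"}),
                "lat": ("lat", field.grid.lat.astype("f8"), {"units": "degrees_north"}),
                "lon": ("lon", field.grid.lon.astype("f8"), {"units": "degrees_east"}),
                "type": ("type", np.arange(len(field.registry), dtype=np.int32))},
        attrs=attrs)
    ds.to_netcdf(path, format="NETCDF3_64BIT", engine="scipy")


def read_biomass(path, layout: dict | None = None,
                 neg_tol: float = 1e-9) -> BiomassField:
    """Read a biomass field written by :func:`write_biomass` (or any netCDF
    matching ``layout``).

    Missing (NaN) columns define land; NaN at ocean cells is a validation
    error.  Negative values no deeper than ``neg_tol`` x the field maximum
    are clamped to zero; deeper negatives are a validation error.
    """
    layout = {**DEFAULT_LAYOUT, **(layout or {})}
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for dim in ("time", "lat", "lon", "type"):
        if layout[dim] not in ds.dims:
            raise FormatError(f"missing dimension {layout[dim]!r}")
    if layout["biomass"] not in ds:
        raise FormatError(f"missing variable {layout['biomass']!r}")
    ds = ds.rename({layout[d]: d for d in ("time", "lat", "lon", "type")
                    if layout[d] != d})
    vals = ds[layout["biomass"]].transpose("time", "lat", "lon", "type").values
    vals = np.asarray(vals, float)
    lat = ds["lat"].values.astype(float)
    lon = normalize_lon(ds["lon"].values)
    if layout["ocean_mask"] in ds:
        ocean = ds[layout["ocean_mask"]].values.astype(bool)
    else:
        ocean = ~np.all(np.isnan(vals), axis=(0, 3))
    if np.isnan(vals[:, ocean, :]).any():
        raise ValidationError("NaN biomass in ocean cells")
    scale = np.nanmax(np.abs(vals)) if np.isfinite(vals).any() else 1.0
    tol = neg_tol * max(scale, 1.0)
    if (vals[:, ocean, :] < -tol).any():
        raise ValidationError(f"negative biomass beyond tolerance {tol:g}")
    vals = np.where(ocean[None, :, :, None], np.clip(vals, 0.0, None), np.nan)
    grid = Grid.from_coords(lat, lon, ocean)
    registry = _registry_from_ds(ds, layout)
    units = ds[layout["biomass"]].attrs.get("units", "mgC m-2")
    period = None
    if "period_start" in ds.attrs:
        period = (int(ds.attrs["period_start"]), int(ds.attrs["period_end"]))
    field = BiomassField(ds["time"].values.astype(int), vals, registry, grid,
                         units=units, period=period)
    field.validate()
    return field


def _flatten_period(period) -> list:
    if period is None:
        return []
    flat = np.ravel(np.asarray(period)).astype(int).tolist()
    return flat


def write_metric(field: MetricField, path) -> None:
    """Write a metric map/series as classic netCDF; NaN is preserved as-is."""
    dims = ("lat", "lon") if field.is_map else ("time", "lat", "lon")
    coords = {"lat": ("lat", field.grid.lat.astype("f8")),
              "lon": ("lon", field.grid.lon.astype("f8"))}
    if not field.is_map:
        coords["time"] = ("time", np.asarray(field.time).astype(np.int32))
    attrs = {"metric_name": field.metric_name, "units": field.units}
    flat = _flatten_period(field.period)
    if flat:
        attrs["period_years"] = np.asarray(flat, np.int32)
    ds = xr.Dataset(
        {"metric": (dims, np.asarray(field.values, "f8")),
         "ocean_mask": (("lat", "lon"), field.grid.ocean_mask.astype(np.int32))},
        coords=coords, attrs=attrs)
    ds.to_netcdf(path, format="NETCDF3_64BIT", engine="scipy")


def read_metric(path) -> MetricField:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if "metric" not in ds:
        raise FormatError("missing variable 'metric'")
    ocean = ds["ocean_mask"].values.astype(bool)
    grid = Grid.from_coords(ds["lat"].values, ds["lon"].values, ocean)
    flat = [int(x) for x in np.ravel(ds.attrs.get("period_years", []))]
    period: tuple | None = None
    if len(flat) == 2:
        period = (flat[0], flat[1])
    elif len(flat) == 4:
        period = ((flat[0], flat[1]), (flat[2], flat[3]))
    elif len(flat) == 8:
        period = (((flat[0], flat[1]), (flat[2], flat[3])),
                  ((flat[4], flat[5]), (flat[6], flat[7])))
    time = ds["time"].values.astype(int) if "time" in ds.dims else None
    return MetricField(ds["metric"].values.astype(float),
                       str(ds.attrs.get("metric_name", "metric")), grid,
                       units=str(ds.attrs.get("units", "")),
                       period=period, time=time)
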