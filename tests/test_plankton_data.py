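import dataclasses

import numpy as np
import pytest

from planktodiv.plankton_data import (
    DEFAULT_GROUP_COUNTS,
    BiomassField,
    FormatError,
    Grid,
    MetricField,
    PeriodError,
    TypeRegistry,
    ValidationError,
    period_mean,
    read_biomass,
    read_metric,
    size_class_edges,
    write_biomass,
    write_metric,
)
from planktodiv.synthetic_community import ParametricScenario, generate_parametric

from conftest import make_field


class TestRegistry:
    def test_default_community_structure(self, registry):
        assert len(registry) == 51
        assert registry.n_phyto == 35
        assert registry.group_counts() == DEFAULT_GROUP_COUNTS
        assert int(registry.zoo_mask.sum()) == 16

    def test_sizes_and_classes(self, registry):
        assert registry.esd_um.min() >= 0.6
        assert registry.esd_um.max() <= 2425.0
        sc = registry.size_class[registry.phyto_mask]
        assert sc.min() >= 1 and sc.max() <= 16
        # every phytoplankton type sits inside its class's edge interval
        edges = registry.class_edges
        esd = registry.esd_um[registry.phyto_mask]
        assert np.all(esd >= edges[sc - 1]) and np.all(esd <= edges[sc])

    def test_rejects_nondefault_group_counts_unless_overridden(self, registry):
        mutated = dataclasses.replace(
            registry, group=np.where(registry.group == "diatom",
                                     "coccolithophore", registry.group))
        with pytest.raises(ValidationError, match="group counts"):
            mutated.validate()
        mutated.validate(strict_group_counts=False)

    def test_class_esd_is_geometric_mean_of_members(self, registry):
        esd = registry.class_esd()
        for c in range(1, 17):
            members = registry.phyto_mask & (registry.size_class == c)
            if members.any():
                expect = np.exp(np.log(registry.esd_um[members]).mean())
                assert esd[c - 1] == pytest.approx(expect)
            else:
                assert np.isnan(esd[c - 1])

    def test_edges_are_log_uniform(self):
        edges = size_class_edges()
        ratios = np.diff(np.log(edges))
        assert np.allclose(ratios, ratios[0])


class TestGrid:
    def test_cos_latitude_weights(self):
        grid = Grid.regular(6, 8)
        w_eq = grid.area_weight[2, 0]   # centre 15S
        w_hi = grid.area_weight[5, 0]   # centre 75N
        assert w_hi / w_eq == pytest.approx(
            np.cos(np.deg2rad(75)) / np.cos(np.deg2rad(15)))

    def test_weights_positive_exactly_on_ocean(self):
        mask = np.ones((4, 4), bool)
        mask[1, 2] = False
        grid = Grid.regular(4, 4, ocean_mask=mask)
        assert np.all((grid.area_weight > 0) == mask)

    def test_longitude_normalized(self):
        grid = Grid.from_coords([0.0], [10.0, 190.0, 350.0])
        assert np.allclose(grid.lon, [10.0, -170.0, -10.0])


class TestPeriodMean:
    def test_two_years_average(self, small_registry):
        f = make_field(np.stack([np.full((1, 1, 6), 2.0),
                                 np.full((1, 1, 6), 4.0)]), small_registry)
        pm = period_mean(f, 2005, 2006)
        assert np.allclose(pm.values, 3.0)
        assert pm.values.shape[0] == 1
        assert pm.period == (2005, 2006)

    def test_constant_field_identity(self, small_registry):
        vals = np.tile(np.arange(1.0, 7.0), (5, 2, 3, 1))
        f = make_field(vals, small_registry)
        pm = period_mean(f, 2005, 2009)
        assert np.allclose(pm.values[0], vals[0])

    def test_mean_of_exactly_twenty_slices(self, small_registry):
        rng = np.random.default_rng(7)
        vals = rng.random((96, 1, 1, 6))
        f = make_field(vals, small_registry, years=np.arange(2005, 2101))
        pm = period_mean(f, 2005, 2024)
        # independent oracle: accumulate the slices year by year
        acc, n = np.zeros((1, 1, 6)), 0
        for yr, sl in zip(f.time, vals):
            if 2005 <= yr <= 2024:
                acc += sl
                n += 1
        assert n == 20
        assert np.allclose(pm.values[0], acc / 20)

    def test_empty_intersection_raises(self, small_registry):
        f = make_field(np.ones((3, 1, 1, 6)), small_registry)
        with pytest.raises(PeriodError):
            period_mean(f, 1990, 2000)

    def test_linearity(self, small_registry):
        rng = np.random.default_rng(11)
        a, b = rng.random((4, 2, 2, 6)), rng.random((4, 2, 2, 6))
        fa, fb = make_field(a, small_registry), make_field(b, small_registry)
        fc = make_field(2.0 * a + 3.0 * b, small_registry)
        lhs = period_mean(fc, 2005, 2008).values
        rhs = (2.0 * period_mean(fa, 2005, 2008).values
               + 3.0 * period_mean(fb, 2005, 2008).values)
        assert np.allclose(lhs, rhs)


class TestBiomassIO:
    def test_round_trip(self, tmp_path):
        mask = np.ones((4, 4), bool)
        mask[0, 0] = False
        scn = ParametricScenario(n_types=8, richness=4, evenness=0.9,
                                 turnover_per_step=0.2, seed=3)
        field = generate_parametric(scn, Grid.regular(4, 4, ocean_mask=mask),
                                    range(2005, 2008))
        path = tmp_path / "field.nc"
        write_biomass(field, path)
        back = read_biomass(path)
        ocean = field.grid.ocean_mask
        assert np.allclose(back.values[:, ocean, :], field.values[:, ocean, :],
                           rtol=1e-6)
        assert np.isnan(back.values[:, ~ocean, :]).all()
        assert np.array_equal(back.time, field.time)
        assert back.registry.equals(field.registry)
        assert back.grid.equals(field.grid)

    def test_generated_fixture_shape(self):
        scn = ParametricScenario(richness=10, evenness=0.9, seed=1)
        field = generate_parametric(scn, Grid.regular(4, 4), range(2005, 2008))
        assert field.values.shape == (3, 4, 4, 51)

    def test_missing_type_dimension_is_format_error(self, tmp_path):
        import xarray as xr
        ds = xr.Dataset({"biomass": (("time", "lat", "lon"),
                                     np.ones((2, 3, 3)))},
                        coords={"time": [2005, 2006],
                                "lat": [0.0, 10.0, 20.0],
                                "lon": [0.0, 10.0, 20.0]})
        path = tmp_path / "bad.nc"
        ds.to_netcdf(path, format="NETCDF3_64BIT", engine="scipy")
        with pytest.raises(FormatError, match="type"):
            read_biomass(path)

    def test_nan_in_ocean_cells_rejected(self, tmp_path, small_registry):
        field = make_field(np.ones((2, 2, 2, 6)), small_registry)
        path = tmp_path / "nan.nc"
        write_biomass(field, path)
        import xarray as xr
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        ds["biomass"].values[0, 0, 0, 2] = np.nan
        ds.to_netcdf(path, format="NETCDF3_64BIT", engine="scipy")
        with pytest.raises(ValidationError, match="NaN"):
            read_biomass(path)

    def test_small_negatives_clamped_to_zero(self, tmp_path, small_registry):
        field = make_field(np.ones((1, 2, 2, 6)), small_registry)
        path = tmp_path / "neg.nc"
        write_biomass(field, path)
        import xarray as xr
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        ds["biomass"].values[0, 0, 0, 0] = -1e-12
        ds.to_netcdf(path, format="NETCDF3_64BIT", engine="scipy")
        back = read_biomass(path)
        assert back.values[0, 0, 0, 0] == 0.0


class TestMetricIO:
    @staticmethod
    def _metric():
        mask = np.ones((3, 4), bool)
        mask[2, 0] = False
        grid = Grid.regular(3, 4, ocean_mask=mask)
        vals = np.arange(12.0).reshape(3, 4)
        vals[~mask] = np.nan
        return MetricField(vals, "richness", grid, units="types",
                           period=(2005, 2024))

    def test_round_trip_preserves_values_and_metadata(self, tmp_path):
        m = self._metric()
        path = tmp_path / "m.nc"
        write_metric(m, path)
        back = read_metric(path)
        assert np.allclose(back.values, m.values, equal_nan=True)
        assert back.metric_name == "richness"
        assert back.units == "types"
        assert back.period == (2005, 2024)

    def test_land_nan_preserved_not_zero_filled(self, tmp_path):
        m = self._metric()
        path = tmp_path / "m.nc"
        write_metric(m, path)
        back = read_metric(path)
        assert np.isnan(back.values[2, 0])

    def test_two_writes_byte_identical(self, tmp_path):
        m = self._metric()
        p1, p2 = tmp_path / "a.nc", tmp_path / "b.nc"
        write_metric(m, p1)
        write_metric(m, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_nested_period_pairs_round_trip(self, tmp_path):
        m = self._metric()
        m.period = (((2011, 2030), (2031, 2040)), ((2061, 2080), (2081, 2100)))
        path = tmp_path / "m.nc"
        write_metric(m, path)
        assert read_metric(path).period == m.period
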