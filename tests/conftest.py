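import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from planktodiv.plankton_data import BiomassField, Grid, TypeRegistry

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry() -> TypeRegistry:
    return TypeRegistry.default()


@pytest.fixture(scope="session")
def small_registry() -> TypeRegistry:
    return TypeRegistry.synthetic(6)


def make_field(values, registry, years=None, ocean_mask=None) -> BiomassField:
    """Wrap a (nt, nlat, nlon, ntype) array into a validated BiomassField."""
    values = np.asarray(values, float)
    nt, nlat, nlon, _ = values.shape
    grid = Grid.regular(nlat, nlon, ocean_mask=ocean_mask)
    if ocean_mask is not None:
        values = np.where(np.asarray(ocean_mask, bool)[None, :, :, None],
                          values, np.nan)
    years = np.arange(2005, 2005 + nt) if years is None else np.asarray(years)
    field = BiomassField(years, values, registry, grid)
    field.validate()
    return field


def cell_field(biomass_vector, registry, years=None) -> BiomassField:
    """Single-cell field from one per-type biomass vector (or a stack)."""
    arr = np.atleast_2d(np.asarray(biomass_vector, float))
    return make_field(arr[:, None, None, :], registry, years=years)
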