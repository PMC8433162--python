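import math
from dataclasses import replace

import numpy as np
import pytest

from planktodiv.diversity_metrics import evenness, presence, richness, shannon
from planktodiv.plankton_data import Grid, TypeRegistry
from planktodiv.synthetic_community import (
    ConfigurationError,
    ParameterError,
    ParametricScenario,
    SimScenario,
    dt_stability_check,
    generate_parametric,
    generate_world,
    geometric_shares,
    min_feasible_evenness,
    preset_paperlike,
    preset_tiny,
    simulate_cell,
)


class TestGeometricShares:
    def test_evenness_one_gives_equal_shares(self):
        p = geometric_shares(5, 1.0)
        assert np.allclose(p, 0.2)

    @pytest.mark.parametrize("r,e", [(10, 0.7), (15, 0.8), (3, 0.95)])
    def test_target_evenness_met(self, r, e):
        p = geometric_shares(r, e)
        H = -(p * np.log(p)).sum()
        assert H / math.log(r) == pytest.approx(e, abs=1e-9)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(np.diff(p) <= 0)

    def test_infeasible_combination_rejected(self):
        floor = min_feasible_evenness(10, 1e-3)
        with pytest.raises(ParameterError, match="share"):
            geometric_shares(10, floor - 0.05, min_share=1e-3)


class TestParametricGenerator:
    def test_richness_five_evenness_one_is_five_equal_shares(self, registry):
        scn = ParametricScenario(richness=5, evenness=1.0,
                                 turnover_per_step=0.0, seed=0)
        f = generate_parametric(scn, Grid.regular(1, 1), range(2005, 2006))
        cell = f.values[0, 0, 0, :35]
        assert (cell > 0).sum() == 5
        assert np.allclose(np.unique(cell[cell > 0]), cell[cell > 0][0])
        assert shannon(f).values[0, 0] == pytest.approx(math.log(5), abs=1e-9)

    def test_zero_turnover_keeps_presence_sets_identical(self):
        scn = ParametricScenario(n_types=10, richness=6, evenness=0.9,
                                 turnover_per_step=0.0, seed=4)
        f = generate_parametric(scn, Grid.regular(2, 2), range(2005, 2015))
        pres = presence(f).values
        assert np.all(pres == pres[0])

    def test_pipeline_recovers_targets_exactly(self):
        scn = ParametricScenario(n_types=20, richness=10, evenness=0.7,
                                 turnover_per_step=0.15, seed=9)
        f = generate_parametric(scn, Grid.regular(3, 3), range(2005, 2013))
        r = richness(presence(f)).values
        assert np.all(r == 10)
        j = evenness(f).values
        assert np.allclose(j, 0.7, atol=1e-6)

    def test_deterministic_given_seed(self):
        scn = ParametricScenario(n_types=12, richness=7, evenness=0.8,
                                 turnover_per_step=0.3, seed=21)
        g = Grid.regular(2, 3)
        a = generate_parametric(scn, g, range(2005, 2010))
        b = generate_parametric(scn, g, range(2005, 2010))
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_replacement_fraction_in_expectation(self):
        # mean gained fraction between consecutive years ~ Binomial CI
        f_target, r = 0.2, 10
        scn = ParametricScenario(n_types=35, richness=r, evenness=0.9,
                                 turnover_per_step=f_target, seed=13)
        field = generate_parametric(scn, Grid.regular(6, 6), range(2005, 2035))
        pres = presence(field).values
        gains = (~pres[:-1] & pres[1:]).sum(axis=-1)  # (29, 6, 6)
        frac = gains / r
        n = frac.size
        se = math.sqrt(f_target * (1 - f_target) / (n * r))
        assert abs(frac.mean() - f_target) < 4 * se + 1.0 / (2 * r * math.sqrt(n))

    def test_infeasible_evenness_raises_at_generation(self):
        scn = ParametricScenario(n_types=20, richness=15, evenness=0.3,
                                 turnover_per_step=0.0)
        with pytest.raises(ParameterError):
            generate_parametric(scn, Grid.regular(1, 1), range(2005, 2006))


class TestSimulatorPhysics:
    def test_feeding_kernel_support_and_peak(self):
        scn = SimScenario()
        phi = scn.feeding_kernel()
        ep, ez = scn.sizes()
        ratio = ez[None, :] / ep[:, None]
        outside = (ratio < 5.0) | (ratio > 15.0)
        assert np.all(phi[outside] == 0.0)
        assert np.all(phi[(ratio > 5.0) & (ratio < 15.0)] > 0.0)
        # kernel evaluated exactly at ratio 10 hits its peak value 1
        scn2 = SimScenario(n_phyto=1, n_zoo=1, esd_phyto=[1.0], esd_zoo=[10.0])
        assert scn2.feeding_kernel()[0, 0] == pytest.approx(1.0)

    def test_arrhenius_raises_growth(self):
        warm = SimScenario(T0=25.0, T1=25.0)
        cold = SimScenario(T0=15.0, T1=15.0)
        a_w = math.exp(warm.E_a * (25 - warm.T_ref))
        a_c = math.exp(cold.E_a * (15 - cold.T_ref))
        assert a_w > 1.0 > a_c

    def test_half_saturation_increases_with_size(self):
        scn = SimScenario()
        assert np.all(np.diff(scn.k_N()) > 0)

    def test_growth_peaks_near_three_microns(self):
        scn = SimScenario()
        ep, _ = scn.sizes()
        mu = scn.mu_max()
        assert abs(math.log(ep[np.argmax(mu)] / 3.0)) == min(
            abs(math.log(d / 3.0)) for d in ep)

    def test_closed_system_conserves_mass(self):
        scn = SimScenario(S0=0.0, S1=0.0, T0=20.0, T1=20.0, remin=1.0,
                          assimilation=1.0, m_P=0.0, m_Z=0.0, spinup_years=0)
        res = simulate_cell(scn, years=1)
        total0 = scn.N_init + scn.n_phyto * scn.P_init + scn.n_zoo * scn.Z_init
        drift = abs(res.final_state.sum() - total0) / total0
        assert drift < 1e-9

    def test_monod_chemostat_matches_closed_form(self):
        scn = SimScenario(n_phyto=1, n_zoo=0, esd_phyto=[3.0], g_max=0.0,
                          S0=0.05, S1=0.05, T0=20.0, T1=20.0, m_P=0.05,
                          remin=0.5, spinup_years=0)
        res = simulate_cell(scn, years=3)
        mu_eff = scn.mu_max()[0]  # a(T_ref) = 1
        n_star = scn.k_N()[0] * scn.m_P / (mu_eff - scn.m_P)
        assert res.final_state[-1] == pytest.approx(n_star, rel=1e-3)
        # steady: relative change of annual means over the last year
        assert abs(res.nutrient[-1] - res.nutrient[-2]) / n_star < 1e-6

    def test_timestep_stability(self):
        scn = SimScenario(n_phyto=8, n_zoo=4,
                          esd_phyto=np.geomspace(0.6, 100, 8),
                          esd_zoo=np.geomspace(6, 1000, 4), spinup_years=0)
        assert dt_stability_check(scn, years=1) < 0.01

    def test_nonnegative_trajectories(self):
        scn = SimScenario(n_phyto=6, n_zoo=3,
                          esd_phyto=np.geomspace(0.6, 50, 6),
                          esd_zoo=np.geomspace(5, 500, 3), spinup_years=0)
        res = simulate_cell(scn, years=2)
        assert np.all(res.phyto >= 0) and np.all(res.zoo >= 0)
        assert np.all(res.nutrient >= 0)


class TestWorld:
    @staticmethod
    def _one_band(seed=0, sigma=0.0):
        grid = Grid.regular(4, 4)
        scn = ParametricScenario(n_types=8, richness=5, evenness=0.85,
                                 turnover_per_step=0.1, seed=1)
        reg = TypeRegistry.synthetic(8)
        return generate_world([((-90.0, 90.1), scn)], grid, seed=seed,
                              years=range(2005, 2015), noise_sigma=sigma,
                              registry=reg)

    def test_same_seed_identical(self):
        a = self._one_band(seed=5, sigma=0.1)
        b = self._one_band(seed=5, sigma=0.1)
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_zero_noise_single_scenario_uniform_metrics(self):
        f = self._one_band(sigma=0.0)
        r = richness(presence(f)).values
        j = evenness(f).values
        assert np.all(r == r[..., :1, :1])
        assert np.allclose(j, j[..., :1, :1])

    def test_unassigned_ocean_cell_rejected(self):
        grid = Grid.regular(4, 4)
        scn = ParametricScenario(n_types=8, richness=4, evenness=0.9)
        with pytest.raises(ConfigurationError, match="no scenario"):
            generate_world([((0.0, 90.1), scn)], grid,
                           registry=TypeRegistry.synthetic(8),
                           years=range(2005, 2010))

    def test_tiny_preset_shapes_and_targets(self):
        f = preset_tiny(seed=2)
        assert f.values.shape == (10, 4, 4, 8)
        assert np.all(richness(presence(f)).values == 5)

    def test_paperlike_tropical_biomass_declines(self):
        from planktodiv.plankton_data import period_mean
        from planktodiv.regional_analysis import (abs_lat_band,
                                                  area_weighted_mean)
        from planktodiv.plankton_data import MetricField
        f = preset_paperlike(seed=3)
        tropics = abs_lat_band(f.grid, 0.0, 23.0, name="tropics")

        def band_mean(period):
            pm = period_mean(f, *period)
            vals = np.where(f.grid.ocean_mask, pm.phyto_total()[0], np.nan)
            return area_weighted_mean(
                MetricField(vals, "biomass", f.grid), tropics)

        assert band_mean((2081, 2100)) < band_mean((2005, 2024))

    def test_evenness_decline_detected_in_95pct_of_cells(self):
        # prescribed monotone decline + default noise; first vs last decade
        grid = Grid.regular(6, 6)
        scn = ParametricScenario(n_types=20, richness=10,
                                 evenness=(0.9, 0.72),
                                 turnover_per_step=0.02, seed=7)
        f = generate_world([((-90.0, 90.1), scn)], grid, seed=11,
                           years=range(2005, 2055), noise_sigma=0.1,
                           registry=TypeRegistry.synthetic(20))
        j = evenness(f).values  # (nt, 6, 6)
        early = np.nanmean(j[:10], axis=0)
        late = np.nanmean(j[-10:], axis=0)
        frac_declining = np.mean(late < early)
        assert frac_declining >= 0.95
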