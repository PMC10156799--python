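"""Hemodynamic maps: dissipation oracles, energetics convergence, summaries."""

import dataclasses

import numpy as np
import pytest

from fontanflow import (FluidProperties, GridSpec, RegionModel,
                        compute_hemodynamic_maps, energy_loss_maps,
                        kinetic_energy_map, make_poiseuille_tube,
                        make_uniform_flow, peak_velocity_map, regional_summary,
                        resample_isotropic, stasis_map,
                        truncate_to_common_fraction, viscous_dissipation)
from fontanflow.phantom import VelocitySeries


def shear_series(k=20.0, shape=(17, 17, 17), spacing=1.0):
    """Simple shear v_z = k*y (k in 1/s): phi_v = k^2 exactly."""
    grid = GridSpec.centered(shape, (spacing,) * 3, n_frames=1)
    series = make_uniform_flow(grid, (0.0, 0.0, 0.0))
    _, ys, _ = grid.coords()
    series.velocity[:, 2] = k * ys / 1000.0
    return series


class TestTruncation:
    def test_minimum_coverage_is_selected(self, tcpc_default):
        series, _, _ = tcpc_default
        a = series.copy()
        b = series.copy()
        b.cycle_fraction_covered = 0.85
        out = truncate_to_common_fraction([a, b])
        assert out[1].n_frames == b.n_frames          # 0.85 keeps all its frames
        # full-coverage scan loses frames down to <= 0.85 of the cycle
        assert out[0].cycle_fraction_covered <= 0.85 + 1e-9
        assert out[0].n_frames == int(np.floor(0.85 * series.n_frames))

    def test_equal_coverage_unchanged(self, tcpc_default):
        series, _, _ = tcpc_default
        out = truncate_to_common_fraction([series.copy(), series.copy()])
        assert all(s.n_frames == series.n_frames for s in out)

    def test_single_series_unchanged(self, tcpc_default):
        series, _, _ = tcpc_default
        out = truncate_to_common_fraction([series])
        assert out[0].n_frames == series.n_frames

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            truncate_to_common_fraction([])


class TestResample:
    def test_identity_at_coincident_grid_points(self, poiseuille_1mm):
        series, _ = poiseuille_1mm
        out = resample_isotropic(series, 1.0)
        assert out.grid.shape == series.grid.shape
        assert np.allclose(out.velocity, series.velocity, atol=1e-12)

    def test_linear_field_reproduced_exactly(self):
        series = shear_series(k=10.0, spacing=2.0)
        out = resample_isotropic(series, 1.0)
        _, ys, _ = out.grid.coords()
        assert np.allclose(out.velocity[0, 2], 10.0 * ys / 1000.0, atol=1e-12)

    def test_poiseuille_peak_recovers_with_resolution(self):
        # 2 mm grid underestimates the centerline peak; 1 mm resampling of
        # the 2 mm data cannot exceed it, but direct 1 mm sampling shows the
        # parabolic peak more sharply; check the resampled peak stays
        # between the coarse and analytic values
        grid2 = GridSpec.centered((15, 15, 25), (2.0, 2.0, 2.0))
        s2, _ = make_poiseuille_tube(grid2, 8.0, 40.0, 0.3)
        fine = resample_isotropic(s2, 1.0)
        assert s2.velocity.max() <= fine.velocity.max() + 1e-12
        assert fine.velocity.max() <= 0.6 + 1e-12


class TestPeakAndStasis:
    def test_steady_uniform_maps(self, uniform_series):
        pv = peak_velocity_map(uniform_series)
        st = stasis_map(uniform_series)
        assert np.allclose(pv, 0.2)
        assert np.allclose(st, 0.0)

    def test_peak_is_max_over_frames(self, small_grid):
        series = make_uniform_flow(small_grid, (0.0, 0.0, 0.0))
        speeds = [0.2, 0.5, 0.3, 0.1]
        for f, s in enumerate(speeds):
            series.velocity[f, 2] = s
        assert np.allclose(peak_velocity_map(series), 0.5)

    def test_stasis_alternating_frames_is_half(self, small_grid):
        series = make_uniform_flow(small_grid, (0.0, 0.0, 0.0))
        for f in range(series.n_frames):
            series.velocity[f, 2] = 0.05 if f % 2 == 0 else 0.2
        assert np.allclose(stasis_map(series), 50.0)

    def test_slow_uniform_flow_is_full_stasis(self, small_grid):
        series = make_uniform_flow(small_grid, (0.0, 0.0, 0.05))
        assert np.allclose(stasis_map(series), 100.0)

    def test_regional_p98_matches_sorted_oracle(self):
        # 100-voxel region, 99 voxels at 0.2 m/s and 1 at 1.0 m/s
        rng = np.random.default_rng(0)
        vals = np.full(100, 0.2)
        vals[37] = 1.0
        # brute-force linear-interpolation percentile
        srt = np.sort(vals)
        pos = 0.98 * (len(vals) - 1)
        lo, w = int(np.floor(pos)), pos - np.floor(pos)
        oracle = srt[lo] * (1 - w) + srt[lo + 1] * w
        assert np.percentile(vals, 98.0) == pytest.approx(oracle, rel=1e-12)


class TestKineticEnergy:
    def test_single_voxel_value_against_hand_computation(self):
        # 1 m/s, 1 mm^3, rho = 1060 -> 0.5*1060*1e-9*1 = 5.3e-7 J per frame
        grid = GridSpec.centered((5, 5, 5), (1.0, 1.0, 1.0), n_frames=1)
        series = make_uniform_flow(grid, (0.0, 0.0, 1.0))
        ke = kinetic_energy_map(series)
        assert np.allclose(ke, 5.3e-7)

    def test_zero_field_gives_zero(self, small_grid):
        series = make_uniform_flow(small_grid, (0.0, 0.0, 0.0))
        assert np.all(kinetic_energy_map(series) == 0.0)

    def test_ke_scales_quartically_with_double_speed(self, poiseuille_1mm):
        series, _ = poiseuille_1mm
        doubled = series.copy()
        doubled.velocity *= 2.0
        assert np.allclose(kinetic_energy_map(doubled),
                           4.0 * kinetic_energy_map(series), rtol=1e-12)

    def test_poiseuille_total_within_three_percent(self, poiseuille_1mm, fluid):
        series, truth = poiseuille_1mm
        ke = kinetic_energy_map(series, fluid).sum()
        assert ke == pytest.approx(truth.analytic_ke, rel=0.03)


class TestEnergyLoss:
    def test_uniform_flow_has_zero_dissipation(self, uniform_series):
        el_tot, el_mean = energy_loss_maps(uniform_series)
        # stencil roundoff on a constant field is ~1e-39 J; zero in substance
        assert el_tot.max() < 1e-30
        assert el_mean.max() < 1e-30

    def test_rigid_rotation_has_zero_interior_dissipation(self, rotation_series):
        from scipy import ndimage
        phi = viscous_dissipation(rotation_series.velocity[0],
                                  rotation_series.mask > 0,
                                  rotation_series.grid.spacing)
        interior = ndimage.binary_erosion(rotation_series.mask > 0, iterations=2)
        shear_ref = 20.0 ** 2                        # phi of a k=20/s shear
        assert np.abs(phi[interior]).max() < 1e-6 * shear_ref

    def test_simple_shear_matches_mu_k_squared(self, fluid):
        from scipy import ndimage
        k = 20.0
        series = shear_series(k=k)
        phi = viscous_dissipation(series.velocity[0], series.mask > 0,
                                  series.grid.spacing)
        interior = ndimage.binary_erosion(series.mask > 0, iterations=1)
        assert np.allclose(phi[interior], k ** 2, rtol=1e-12)
        _, el_mean = energy_loss_maps(series, fluid)
        vox_m3 = series.grid.voxel_volume_mm3 * 1e-9
        assert np.allclose(el_mean[interior] / vox_m3, fluid.viscosity * k ** 2,
                           rtol=1e-12)

    def test_phi_scales_quartically_with_double_speed(self):
        series = shear_series(k=15.0)
        doubled = series.copy()
        doubled.velocity *= 2.0
        phi1 = viscous_dissipation(series.velocity[0], series.mask > 0,
                                   series.grid.spacing)
        phi2 = viscous_dissipation(doubled.velocity[0], series.mask > 0,
                                   series.grid.spacing)
        assert np.allclose(phi2, 4.0 * phi1, rtol=1e-12)

    def test_rotation_invariance_under_quarter_turn(self):
        series = shear_series(k=12.0)
        phi = viscous_dissipation(series.velocity[0], series.mask > 0,
                                  series.grid.spacing)
        # rotate the field and grid 90 degrees about z: (x,y) -> (-y,x),
        # components (vx,vy,vz) -> (-vy,vx,vz)
        vel = series.velocity[0]
        vel_rot = np.empty_like(vel)
        vel_rot[0] = -np.rot90(vel[1], k=1, axes=(0, 1))
        vel_rot[1] = np.rot90(vel[0], k=1, axes=(0, 1))
        vel_rot[2] = np.rot90(vel[2], k=1, axes=(0, 1))
        mask_rot = np.rot90(series.mask > 0, k=1, axes=(0, 1))
        phi_rot = viscous_dissipation(vel_rot, mask_rot, series.grid.spacing)
        assert np.allclose(phi_rot, np.rot90(phi, k=1, axes=(0, 1)), atol=1e-10)

    def test_poiseuille_total_el_within_five_percent(self, poiseuille_1mm, fluid):
        series, truth = poiseuille_1mm
        _, el_mean = energy_loss_maps(series, fluid)
        assert el_mean.sum() == pytest.approx(truth.analytic_el_rate, rel=0.05)

    def test_poiseuille_errors_shrink_with_resolution(self, fluid):
        errs_ke, errs_el = [], []
        for h in (4.0, 2.0, 1.0):
            n_xy = int(np.ceil(16 / h)) + 5
            n_z = int(np.ceil(60 / h)) + 5
            n_xy += (n_xy + 1) % 2
            n_z += (n_z + 1) % 2
            grid = GridSpec.centered((n_xy, n_xy, n_z), (h, h, h))
            series, truth = make_poiseuille_tube(grid, 8.0, 60.0, 0.3, fluid=fluid)
            ke = kinetic_energy_map(series, fluid).sum()
            _, el_mean = energy_loss_maps(series, fluid)
            errs_ke.append(abs(ke - truth.analytic_ke) / truth.analytic_ke)
            errs_el.append(abs(el_mean.sum() - truth.analytic_el_rate)
                           / truth.analytic_el_rate)
        assert errs_ke[0] > errs_ke[1] > errs_ke[2]
        assert errs_el[0] > errs_el[1] > errs_el[2]

    def test_el_mean_times_duration_equals_el_tot(self, tcpc_default):
        series, _, _ = tcpc_default
        el_tot, el_mean = energy_loss_maps(series)
        assert np.allclose(el_mean * series.grid.covered_duration_s, el_tot,
                           rtol=1e-12, atol=1e-30)

    def test_degenerate_mask_rejected(self, small_grid):
        series = make_uniform_flow(small_grid, (0.0, 0.0, 0.1))
        series.mask = np.zeros(small_grid.shape, dtype=np.int16)
        series.mask[3, 3, 3] = 1
        with pytest.raises(ValueError):
            energy_loss_maps(series)


class TestRegionalSummary:
    def _region_model(self, series):
        return RegionModel(labels=series.mask, spacing=series.grid.spacing,
                           origin=series.grid.origin)

    def test_uniform_maps_summarize_to_uniform_values(self, tcpc_default):
        series, _, region = tcpc_default
        maps = compute_hemodynamic_maps(series)
        flat = dataclasses.replace(
            maps,
            peak_velocity=np.where(region.labels > 0, 0.4, 0.0),
            stasis=np.where(region.labels > 0, 25.0, 0.0),
            kinetic_energy=np.where(region.labels > 0, 2e-7, 0.0),
            el_tot=np.where(region.labels > 0, 3e-8, 0.0),
            el_mean=np.where(region.labels > 0, 4e-8, 0.0))
        for s in regional_summary(flat, region):
            assert s.peak_velocity_p98 == pytest.approx(0.4)
            assert s.stasis_mean == pytest.approx(25.0)
            assert s.ke_mean == pytest.approx(2e-7)
            assert s.el_tot_mean == pytest.approx(3e-8)
            assert s.el_mean_mean == pytest.approx(4e-8)

    def test_connection_dissipates_more_than_limbs(self, tcpc_default):
        series, _, region = tcpc_default
        maps = compute_hemodynamic_maps(series)
        summaries = {s.region: s for s in regional_summary(maps, region)}
        # junction shear exceeds the (slip-walled, plug-flow) limb interior
        assert summaries["connection"].el_mean_mean > summaries["IVC"].el_mean_mean

    def test_emits_exactly_five_regions(self, tcpc_default):
        series, _, region = tcpc_default
        maps = compute_hemodynamic_maps(series)
        assert [s.region for s in regional_summary(maps, region)] == \
            ["IVC", "SVC", "connection", "LPA", "RPA"]

    def test_stasis_bounded_and_energies_nonnegative(self, tcpc_default):
        series, _, _ = tcpc_default
        maps = compute_hemodynamic_maps(series)
        assert maps.stasis.min() >= 0.0 and maps.stasis.max() <= 100.0
        assert maps.kinetic_energy.min() >= 0.0
        assert maps.el_tot.min() >= 0.0
        assert maps.el_mean.min() >= 0.0
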