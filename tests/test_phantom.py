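"""Phantom generator: networks, rasterization, speckle, raw-scan forward model."""

import numpy as np
import pytest

import octvessel as ov
from octvessel.phantom import VesselSegment

from conftest import tube_network_spec


class TestGenerateNetwork:
    def test_unbranched_single_vessel(self):
        spec = tube_network_spec(0, n_seed_vessels=1, branching_prob=0.0)
        truth = ov.generate_network(spec)
        assert truth.n_bifurcations == 0
        endpoints = [n for n, d in truth.graph.degree if d == 1]
        assert len(endpoints) == 2

    def test_forced_y_has_one_junction(self):
        segs = ov.make_y_segments()
        from octvessel.phantom import _truth_from_segments

        truth = _truth_from_segments(segs)
        degs = sorted(d for _, d in truth.graph.degree)
        assert truth.n_bifurcations == 1
        assert degs == [1, 1, 1, 3]

    def test_bifurcation_count_matches_degree_enumeration(self):
        spec = tube_network_spec(7, n_seed_vessels=3, branching_prob=0.3)
        truth = ov.generate_network(spec)
        replay = ov.generate_network(spec)
        # brute-force degree count on the generated graph
        by_degree = sum(1 for _, d in truth.graph.degree if d >= 3)
        assert truth.n_bifurcations == by_degree
        assert replay.n_bifurcations == truth.n_bifurcations
        assert [s.start for s in replay.segments] == [s.start for s in truth.segments]

    def test_seed_reproducibility_bitwise(self):
        spec = tube_network_spec(11)
        a = ov.generate_network(spec)
        b = ov.generate_network(spec)
        assert a.segments == b.segments
        assert a.total_length_um == b.total_length_um

    def test_rejects_subvoxel_radius(self):
        spec = tube_network_spec(0, radius_range_um=(0.4, 0.4))
        with pytest.raises(ValueError, match="voxel"):
            ov.generate_network(spec)

    def test_endpoints_inside_volume(self):
        spec = tube_network_spec(5)
        truth = ov.generate_network(spec)
        size = np.asarray(spec.grid_shape) * np.asarray(spec.voxel_spacing)
        for s in truth.segments:
            assert s.radius_um > 0
            for p in (s.start, s.end):
                assert np.all(np.asarray(p) >= 0) and np.all(np.asarray(p) <= size)


class TestRasterize:
    def test_cylinder_voxel_count_matches_analytic(self, cylinder_mask):
        expected = np.pi * 5**2 * 64
        assert abs(cylinder_mask.mask.sum() - expected) / expected < 0.02

    def test_empty_segments_all_false(self):
        mask = ov.rasterize([], (16, 16, 16), (1, 1, 1))
        assert not mask.mask.any()

    def test_subvoxel_radius_raises(self):
        seg = [VesselSegment((2, 2, 2), (10, 2, 2), 0.4)]
        with pytest.raises(ValueError, match="unresolvable"):
            ov.rasterize(seg, (16, 16, 16), (1, 1, 1))

    def test_endpoint_outside_volume_raises(self):
        seg = [VesselSegment((2, 2, 2), (40, 2, 2), 2.0)]
        with pytest.raises(ValueError, match="outside"):
            ov.rasterize(seg, (16, 16, 16), (1, 1, 1))

    @pytest.mark.parametrize("radius", [5.0, 7.0])
    def test_capsule_volume_converges_with_radius(self, radius):
        seg = [VesselSegment((10, 32, 32), (54, 32, 32), radius)]
        mask = ov.rasterize(seg, (64, 64, 64), (1, 1, 1))
        analytic = np.pi * radius**2 * 44 + 4 / 3 * np.pi * radius**3
        # hemispherical caps discretize a little worse than the barrel
        assert abs(mask.mask.sum() - analytic) / analytic < 0.03


class TestRenderVolume:
    def test_exponential_moments(self, cylinder_mask):
        vol = ov.render_volume(cylinder_mask, hydrogel_mean=1.0, lumen_mean=0.1,
                               n_averages=1, seed=0)
        lum = vol.intensity[cylinder_mask.mask]
        gel = vol.intensity[~cylinder_mask.mask]
        assert lum.mean() == pytest.approx(0.1, rel=0.05)
        assert gel.mean() == pytest.approx(1.0, rel=0.05)
        # exponential law: coefficient of variation 1
        assert lum.std() / lum.mean() == pytest.approx(1.0, abs=0.05)

    def test_averaging_shrinks_cov_by_sqrt6(self, cylinder_mask):
        v6 = ov.render_volume(cylinder_mask, n_averages=6, seed=1)
        gel = v6.intensity[~cylinder_mask.mask]
        assert gel.std() / gel.mean() == pytest.approx(1 / np.sqrt(6), rel=0.05)

    def test_lumen_darker_than_hydrogel(self, cylinder_mask):
        from scipy import stats as sps

        vol = ov.render_volume(cylinder_mask, hydrogel_mean=1.0, lumen_mean=0.5,
                               n_averages=1, seed=2)
        lum = vol.intensity[cylinder_mask.mask][:5000]
        gel = vol.intensity[~cylinder_mask.mask][:5000]
        u, p = sps.mannwhitneyu(lum, gel, alternative="less")
        assert p < 1e-6

    def test_rejects_inverted_contrast(self, cylinder_mask):
        with pytest.raises(ValueError, match="dark"):
            ov.render_volume(cylinder_mask, hydrogel_mean=0.1, lumen_mean=1.0)
        with pytest.raises(ValueError, match="positive"):
            ov.render_volume(cylinder_mask, hydrogel_mean=-1.0, lumen_mean=-2.0)

    def test_seeded_render_bit_identical(self, cylinder_mask):
        a = ov.render_volume(cylinder_mask, seed=9)
        b = ov.render_volume(cylinder_mask, seed=9)
        assert np.array_equal(a.intensity, b.intensity)


class TestSimulateRawScan:
    def test_empty_reflectors_gives_envelope(self):
        spec = ov.SpectrometerSpec()
        scan = ov.simulate_raw_scan(ov.ReflectorSet(()), spec)
        assert np.allclose(scan.spectra[0], spec.source_envelope())

    def test_wavelength_grid_is_2001_samples(self):
        spec = ov.SpectrometerSpec()
        lam = spec.wavelength_nm
        assert lam.size == 2001
        assert lam[0] == 450.0 and lam[-1] == 650.0
        assert np.allclose(np.diff(lam), 0.1)

    def test_fringe_period_in_wavenumber(self):
        # one reflector at depth z: S/env - 1 = 2 sqrt(r) cos(2 k z), so the
        # fringe period in k is pi / z
        spec = ov.SpectrometerSpec()
        z = 150.0
        scan = ov.simulate_raw_scan(ov.ReflectorSet(((z, 1.0),)), spec)
        fringes = scan.spectra[0] / spec.source_envelope() - 1.0
        k = spec.wavenumber_um
        # count zero crossings over the k range -> period estimate
        crossings = np.sum(np.diff(np.sign(fringes)) != 0)
        k_range = k.max() - k.min()
        period = 2 * k_range / crossings
        assert period == pytest.approx(np.pi / z, rel=0.01)

    def test_reflector_beyond_range_raises(self):
        spec = ov.SpectrometerSpec()
        with pytest.raises(ValueError, match="unambiguous"):
            ov.simulate_raw_scan(ov.ReflectorSet(((spec.max_depth_um + 1, 0.5),)), spec)


class TestEvolveNetwork:
    def test_control_is_static(self):
        spec = tube_network_spec(2, max_generations=4, branching_prob=0.8)
        truth = ov.generate_network(spec)
        for day in (2, 3, 4, 5):
            ev = ov.evolve_network(truth, "control", day)
            assert len(ev.segments) == sum(
                1 for s in truth.segments if s.generation <= 2
            )
            assert ev.segments[0].radius_um == truth.segments[0].radius_um

    def test_regression_is_monotone_and_never_empties(self):
        spec = tube_network_spec(4, max_generations=4, branching_prob=0.9)
        truth = ov.generate_network(spec)
        prev = None
        for day in (3, 4, 5):
            ev = ov.evolve_network(truth, "high_glucose", day)
            assert len(ev.segments) >= 1
            if prev is not None:
                assert len(ev.segments) <= len(prev.segments)
                assert ev.segments[0].radius_um < prev.segments[0].radius_um
            prev = ev

    def test_growth_adds_generations_and_radius(self):
        spec = tube_network_spec(4, max_generations=5, branching_prob=0.9)
        truth = ov.generate_network(spec)
        d3 = ov.evolve_network(truth, "vegf", 3)
        d5 = ov.evolve_network(truth, "vegf", 5)
        assert len(d5.segments) >= len(d3.segments)
        assert d5.segments[0].radius_um > d3.segments[0].radius_um
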