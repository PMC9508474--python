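"""Flattening, blob detection, Laplace backgrounds, particle metrics."""

import numpy as np
import pytest

from secafm import (
    Topograph,
    background_and_metrics,
    detect_particles,
    filter_particles,
    flatten_topograph,
    gen_topograph,
)
from secafm.detect import ParticleRecord, laplace_interpolate
from tests.conftest import match_particles


def record_for_region(mask: np.ndarray, pixel_nm: float = 1.0) -> ParticleRecord:
    rows, cols = np.nonzero(mask)
    return ParticleRecord(rows=rows, cols=cols, centroid_nm=(0.0, 0.0),
                          seed_scale_px=1.0, seed_response=1.0)


class TestFlatten:
    def test_exact_per_line_quadratic_removed(self):
        x = np.arange(128, dtype=float)
        lines = np.array([0.01 * i * (x - 40) ** 2 / 100 + 0.2 * x - i
                          for i in range(64)])
        flat = flatten_topograph(Topograph(lines, 3.9), order=2)
        assert np.abs(flat.heights).max() < 1e-6

    def test_flat_image_unchanged(self):
        flat = flatten_topograph(Topograph(np.zeros((32, 32)), 1.0))
        assert np.abs(flat.heights).max() < 1e-6

    def test_bump_heights_survive_background_removal(self, fig1b_like_mixture):
        topo, truth = gen_topograph(mixture=fig1b_like_mixture, n_particles=10,
                                    noise_sigma_A=0.0, background=True, seed=21)
        flat = flatten_topograph(topo)
        for (x, y), h in zip(truth.particle_centers_nm,
                             truth.particle_max_heights_A):
            r = int(round(y / topo.pixel_nm))
            c = int(round(x / topo.pixel_nm))
            window = flat.heights[max(r - 4, 0):r + 5, max(c - 4, 0):c + 5]
            assert window.max() == pytest.approx(h, abs=0.5)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            flatten_topograph(Topograph(np.zeros((8, 8)), 1.0), order=3)


class TestDetect:
    def test_flat_noise_free_image_finds_nothing(self):
        assert detect_particles(Topograph(np.zeros((64, 64)), 1.0)) == []

    def test_high_snr_bumps_all_found_no_spurious(self, fig1b_like_mixture):
        topo, truth = gen_topograph(mixture=fig1b_like_mixture, n_particles=20,
                                    noise_sigma_A=1.0, background=False,
                                    seed=31)
        flat = flatten_topograph(topo)
        records = detect_particles(flat)
        pairs, spurious = match_particles(records, truth, topo.pixel_nm,
                                          max_dist_px=1.0)
        assert len(pairs) >= 19
        assert spurious == 0

    def test_two_bumps_three_radii_apart_stay_distinct(self):
        topo, truth = gen_topograph(
            width_px=96, height_px=96, pixel_nm=3.9,
            n_particles=0, noise_sigma_A=0.0, background=False, seed=0)
        grid = topo.heights
        # paint two identical bumps 3 footprint-radii apart by hand
        from secafm.synthdata import _paint_cap
        a_px = 4.0
        _paint_cap(grid, 40.0, 30.0, 25.0, a_px)
        _paint_cap(grid, 40.0, 30.0 + 3 * 2 * a_px, 25.0, a_px)
        records = detect_particles(Topograph(grid, 3.9))
        assert len(records) == 2


class TestLaplaceBackground:
    def test_linear_ramp_reproduced_exactly(self):
        yy, xx = np.mgrid[0:32, 0:32]
        ramp = 0.3 * xx + 0.1 * yy
        image = ramp.copy()
        mask = np.zeros((32, 32), bool)
        mask[10:20, 12:22] = True
        image[mask] += 25.0  # particle on top of the ramp
        rec = record_for_region(mask)
        baseline = laplace_interpolate(image, rec.rows, rec.cols)
        assert np.abs(baseline - ramp[mask]).max() < 1e-8

    def test_maximum_principle(self):
        rng = np.random.default_rng(0)
        image = rng.uniform(0.0, 10.0, (24, 24))
        mask = np.zeros((24, 24), bool)
        mask[8:16, 8:16] = True
        baseline = laplace_interpolate(image, *np.nonzero(mask))
        ring = image[~mask]
        assert baseline.max() <= image.max() + 1e-9
        assert baseline.min() >= image.min() - 1e-9
        assert ring.min() - 1e-9 <= baseline.mean() <= ring.max() + 1e-9

    def test_hemisphere_volume_closed_form(self):
        # hemisphere of radius R on a zero background: V = (2/3) pi R^3
        R = 40.0  # Å
        pixel_A = 4.0  # = R/10
        n = 40
        yy, xx = np.mgrid[0:n, 0:n]
        d2 = ((xx - n / 2) ** 2 + (yy - n / 2) ** 2) * pixel_A**2
        h = np.where(d2 < R**2, np.sqrt(np.maximum(R**2 - d2, 0.0)), 0.0)
        topo = Topograph(h, pixel_A / 10.0)
        mask = h > 0
        # include a margin ring so the baseline is anchored at 0
        from scipy.ndimage import binary_dilation
        mask = binary_dilation(mask, iterations=2)
        rec = record_for_region(mask)
        rec = background_and_metrics(topo, rec)
        assert rec.volume_A3 == pytest.approx(2.0 / 3.0 * np.pi * R**3,
                                              rel=0.02)
        assert rec.max_height_A == pytest.approx(R, abs=0.5)

    def test_bump_on_curved_background_recovers_height(self, fig1b_like_mixture):
        topo, truth = gen_topograph(mixture=fig1b_like_mixture, n_particles=6,
                                    noise_sigma_A=0.0, background=True,
                                    seed=41)
        flat = flatten_topograph(topo)
        records = detect_particles(flat)
        for rec in records:
            background_and_metrics(flat, rec)
        pairs, _ = match_particles(records, truth, topo.pixel_nm)
        assert len(pairs) == 6
        for rec, h in pairs:
            assert rec.max_height_A == pytest.approx(h, abs=0.5)

    def test_edge_region_flagged_but_measured(self):
        h = np.zeros((16, 16))
        h[0:4, 0:4] = 10.0
        mask = np.zeros((16, 16), bool)
        mask[0:5, 0:5] = True
        rec = record_for_region(mask)
        rec.edge_flag = True
        rec = background_and_metrics(Topograph(h, 1.0), rec)
        assert rec.max_height_A is not None
        assert rec.edge_flag


class TestFilter:
    def _records(self, heights):
        recs = []
        for h in heights:
            r = record_for_region(np.ones((2, 2), bool))
            r.max_height_A = h
            r.volume_A3 = 1.0
            recs.append(r)
        return recs

    def test_aggregate_cutoff_drops_tall_particles(self):
        kept = filter_particles(self._records([50.0, 99.0, 150.0]),
                                max_height_cutoff_A=100.0, drop_edge=False)
        assert [r.max_height_A for r in kept] == [50.0, 99.0]

    def test_empty_and_identity(self):
        assert filter_particles([]) == []
        recs = self._records([10.0, 500.0])
        assert filter_particles(recs, max_height_cutoff_A=np.inf,
                                drop_edge=False) == recs

    def test_volume_additive_over_disjoint_particles(self, clean_topograph):
        topo, truth = clean_topograph
        flat = flatten_topograph(topo)
        records = detect_particles(flat)
        for rec in records:
            background_and_metrics(flat, rec)
        pairs, _ = match_particles(records, truth, topo.pixel_nm)
        assert len(pairs) == len(truth.particle_volumes_A3)
        total_est = sum(r.volume_A3 for r, _ in pairs)
        total_truth = sum(truth.particle_volumes_A3)
        assert total_est == pytest.approx(total_truth, rel=0.05)
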