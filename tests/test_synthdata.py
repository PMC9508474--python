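"""Generators: determinism, ground-truth consistency, sampling laws."""

import numpy as np
import pytest
from scipy import stats

from secafm import (
    GammaMixture,
    gen_kymograph,
    gen_sphere_cluster,
    gen_topograph,
    sample_gamma_mixture,
)
from secafm.synthdata import KymographTruth, simulate_markov_path


class TestGenTopograph:
    def test_empty_image_is_identically_zero(self):
        topo, truth = gen_topograph(n_particles=0, noise_sigma_A=0.0,
                                    background=False, seed=0)
        assert np.all(topo.heights == 0.0)
        assert truth.particle_max_heights_A == []

    def test_identical_seed_gives_bitwise_identical_grids(self, fig1b_like_mixture):
        a, _ = gen_topograph(mixture=fig1b_like_mixture, n_particles=10,
                             background=True, seed=1)
        b, _ = gen_topograph(mixture=fig1b_like_mixture, n_particles=10,
                             background=True, seed=1)
        assert np.array_equal(a.heights, b.heights)

    def test_single_particle_peak_matches_requested_height(self):
        topo, _ = gen_topograph(n_particles=1, noise_sigma_A=0.0,
                                background=False, seed=2,
                                heights_A=np.array([30.0]))
        # peak within half a lateral-quantisation step of the cap apex
        assert topo.heights.max() == pytest.approx(30.0, abs=0.5)

    def test_noise_free_footprint_maximum_equals_truth(self, clean_topograph):
        topo, truth = clean_topograph
        for (x, y), h in zip(truth.particle_centers_nm,
                             truth.particle_max_heights_A):
            r, c = int(round(y / topo.pixel_nm)), int(round(x / topo.pixel_nm))
            window = topo.heights[max(r - 6, 0):r + 7, max(c - 6, 0):c + 7]
            assert window.max() == pytest.approx(h, abs=0.5)

    def test_impossible_placement_raises(self, fig1b_like_mixture):
        with pytest.raises(RuntimeError, match="non-overlapping"):
            gen_topograph(width_px=48, height_px=48, mixture=fig1b_like_mixture,
                          n_particles=60, seed=0)


class TestGenKymograph:
    def test_single_state_noise_free_trace_is_constant(self):
        kym, truth = gen_kymograph(state_heights_A=[37.0], dwell_rates_s=[0.3],
                                   noise_sigma_A=0.0, seed=0)
        maxima = kym.heights.max(axis=1)
        assert np.allclose(maxima, maxima[0])
        assert truth.n_transitions == 0

    def test_absorbing_initial_state_never_leaves(self):
        _, truth = gen_kymograph(state_heights_A=[37.0, 62.0],
                                 dwell_rates_s=[0.0, 0.5], seed=3)
        assert truth.n_transitions == 0
        assert np.all(truth.state_path == 0)

    def test_seed_determinism(self):
        a, _ = gen_kymograph(seed=7)
        b, _ = gen_kymograph(seed=7)
        assert np.array_equal(a.heights, b.heights)

    def test_nonpositive_line_time_rejected(self):
        with pytest.raises(ValueError):
            gen_kymograph(line_time_s=0.0, seed=0)

    def test_transition_counts_match_markov_expectation(self):
        # two states, exit rate lambda each: expected sojourns in T seconds
        # ~ Poisson(lambda*T); compare mean over seeds within 3 sigma
        rate, T_lines, lt = 0.5, 400, 0.09
        counts = [
            int(np.sum(np.diff(simulate_markov_path(
                T_lines, lt, np.array([rate, rate]),
                np.random.default_rng(s))) != 0))
            for s in range(50)
        ]
        expected = rate * T_lines * lt
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3.0 * se

    def test_truth_transition_count_invariant(self):
        _, truth = gen_kymograph(seed=12)
        assert truth.n_transitions == int(np.sum(np.diff(truth.state_path) != 0))
        with pytest.raises(ValueError):
            KymographTruth([37.0], [0.1], np.array([0, 0, 0]), 5, 0.09)


class TestSphereCluster:
    def test_single_sphere_and_determinism(self):
        a = gen_sphere_cluster(1, seed=4)
        b = gen_sphere_cluster(1, seed=4)
        assert a.n_atoms == 1
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.radii, b.radii)

    def test_centers_inside_box(self):
        m = gen_sphere_cluster(50, box_nm=10.0, seed=5)
        assert np.all(m.coords >= 0.0)
        assert np.all(m.coords <= 100.0)  # 10 nm in Å


class TestSampleGammaMixture:
    def test_single_component_mean(self):
        mix = GammaMixture([1.0], [4.0], [5.0])
        x = sample_gamma_mixture(mix, 100_000, seed=0)
        se = np.sqrt(4.0) * 5.0 / np.sqrt(x.size)  # sd = sqrt(a)*theta
        assert abs(x.mean() - 20.0) < 3.0 * se

    def test_seeded_single_draw_reproducible(self):
        mix = GammaMixture([1.0], [4.0], [5.0])
        assert sample_gamma_mixture(mix, 1, seed=9)[0] == \
            sample_gamma_mixture(mix, 1, seed=9)[0]

    def test_component_occupancy_matches_weights(self, fig1b_like_mixture):
        n = 20_000
        x = sample_gamma_mixture(fig1b_like_mixture, n, seed=1)
        # the rare 60 Å component is well separated: count its draws
        frac = np.mean(x > 45.0)
        p = 0.02
        tol = 3.0 * np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < tol + stats.gamma.sf(
            45.0 / fig1b_like_mixture.scales[1], fig1b_like_mixture.shapes[1]
        )

    def test_unnormalised_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GammaMixture([0.6, 0.6], [2.0, 2.0], [1.0, 1.0])
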