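import numpy as np
import pytest

from secafm import GammaMixture, gen_topograph


@pytest.fixture
def fig1b_like_mixture() -> GammaMixture:
    """Three conformational-state height mixture (modes 14/27/60 Å,
    weights 0.49/0.49/0.02) used across recovery tests."""
    return GammaMixture.from_modes([14.0, 27.0, 60.0], [0.49, 0.49, 0.02])


@pytest.fixture
def clean_topograph(fig1b_like_mixture):
    """Noise-free, background-free synthetic topograph with truth."""
    return gen_topograph(mixture=fig1b_like_mixture, n_particles=8,
                         noise_sigma_A=0.0, background=False, seed=11)


def match_particles(records, truth, pixel_nm, max_dist_px=2.0):
    """Greedy nearest-centroid matching of detections to truth particles.

    Returns (list of (record, truth_height) pairs, unmatched record
    count).
    """
    pairs = []
    used = set()
    for (x, y), h in zip(truth.particle_centers_nm,
                         truth.particle_max_heights_A):
        best = None
        for i, rec in enumerate(records):
            if i in used:
                continue
            d = np.hypot(rec.centroid_nm[0] - x, rec.centroid_nm[1] - y)
            if best is None or d < best[0]:
                best = (d, i)
        if best is not None and best[0] <= max_dist_px * pixel_nm:
            used.add(best[1])
            pairs.append((records[best[1]], h))
    return pairs, len(records) - len(used)
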