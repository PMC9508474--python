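"""Seeded synthetic data with known ground truth.

Raw AFM recordings of supported-bilayer membrane proteins are not
deposited alongside the analysis they feed, so every downstream stage is
exercised on synthetic stand-ins that emulate their observables:

* topographs — a flat supported-bilayer baseline carrying punctate
  protrusions (spherical-cap bumps) whose maximum heights follow a gamma
  mixture, with optional per-scan-line quadratic background and i.i.d.
  Gaussian height noise;
* kymographs — repeated 1-D scans of one protrusion whose height follows
  a continuous-time Markov chain over a small set of conformational
  states (dwell times of seconds, heights tens of Å);
* sphere clusters — toy "atomic" models for the image-simulation oracle.

All generators are deterministic under an explicit integer seed.
Heights are in Å, lateral lengths in nm, time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .afmsim import AtomModel
from .core import A_PER_NM, Kymograph, Topograph
from .popfit import GammaMixture

__all__ = [
    "TopographTruth",
    "KymographTruth",
    "gen_topograph",
    "gen_kymograph",
    "gen_sphere_cluster",
    "sample_gamma_mixture",
]


@dataclass
class TopographTruth:
    """Ground truth for one synthetic topograph."""

    particle_centers_nm: list[tuple[float, float]]  # (x, y) from image corner
    particle_max_heights_A: list[float]
    particle_volumes_A3: list[float]
    background_coeffs: np.ndarray | None  # (n_rows, order+1) per-line poly
    noise_sigma_A: float

    def __post_init__(self) -> None:
        n = len(self.particle_centers_nm)
        if not (len(self.particle_max_heights_A) == len(self.particle_volumes_A3) == n):
            raise ValueError("truth lists must share one length")
        if any(h <= 0 for h in self.particle_max_heights_A):
            raise ValueError("truth max heights must be positive")


@dataclass
class KymographTruth:
    """Ground truth for one synthetic kymograph."""

    state_heights_A: list[float]
    dwell_rates_s: list[float]  # per-state exit rate (1/s)
    state_path: np.ndarray  # true state index per scan line
    n_transitions: int
    line_time_s: float

    def __post_init__(self) -> None:
        if self.line_time_s <= 0:
            raise ValueError("line time must be positive")
        changes = int(np.sum(np.diff(self.state_path) != 0))
        if changes != self.n_transitions:
            raise ValueError("n_transitions inconsistent with state_path")


def _cap_footprint_radius_A(height_A: float, pixel_A: float,
                            tip_radius_A: float = 40.0) -> float:
    """Footprint radius of a synthetic bump of given max height.

    Sized to mimic tip broadening: twice the geometric contact half-width
    sqrt(2*R_tip*h) of a feature of height h under a tip of radius R_tip
    (so the footprint diameter is ~4x the half-width), floored at 3
    pixels so every bump spans a detectable region.
    """
    return max(2.0 * np.sqrt(2.0 * tip_radius_A * height_A), 3.0 * pixel_A)


def _paint_cap(grid: np.ndarray, r0: float, c0: float, h: float,
               a_px: float) -> float:
    """Add a spherical-cap bump (max height h Å, footprint radius a_px in
    pixels) centred at fractional pixel (r0, c0); returns the painted
    (discrete) bump sum for the truth volume.

    The cap is a laterally rescaled hemisphere, z = h*sqrt(1-(d/a)^2):
    smooth, compactly supported, analytic volume (2/3)*pi*a^2*h.
    """
    nrow, ncol = grid.shape
    lo_r = max(int(np.floor(r0 - a_px)), 0)
    hi_r = min(int(np.ceil(r0 + a_px)), nrow - 1)
    lo_c = max(int(np.floor(c0 - a_px)), 0)
    hi_c = min(int(np.ceil(c0 + a_px)), ncol - 1)
    rr = np.arange(lo_r, hi_r + 1)
    cc = np.arange(lo_c, hi_c + 1)
    d2 = (rr[:, None] - r0) ** 2 + (cc[None, :] - c0) ** 2
    # unit spherical cap: z = sqrt(1 - (d/a)^2) scaled to height h gives a
    # hemisphere-like (semi-ellipsoidal) cap with max h and footprint a
    inside = d2 < a_px**2
    patch = np.zeros_like(d2)
    patch[inside] = h * np.sqrt(1.0 - d2[inside] / a_px**2)
    np.maximum(grid[lo_r : hi_r + 1, lo_c : hi_c + 1], patch,
               out=grid[lo_r : hi_r + 1, lo_c : hi_c + 1])
    return float(patch.sum())


def gen_topograph(
    width_px: int = 256,
    height_px: int = 256,
    pixel_nm: float = 1.0e3 / 256,
    mixture: GammaMixture | None = None,
    n_particles: int = 20,
    noise_sigma_A: float = 1.0,
    background: bool = False,
    line_drift: bool = False,
    seed: int = 0,
    heights_A: np.ndarray | None = None,
    max_attempts: int = 1000,
) -> tuple[Topograph, TopographTruth]:
    """Synthetic bilayer topograph with non-overlapping protrusions.

    Particle maximum heights are drawn from ``mixture`` (or taken from
    ``heights_A`` directly); each particle is a smooth spherical-cap
    bump.  Optional per-line second-order polynomial background and
    line-to-line offset drift emulate scanner bow and creep; i.i.d.
    Gaussian noise of ``noise_sigma_A`` is added last.  Placement is
    rejection-sampled for non-overlap; if a particle cannot be placed in
    ``max_attempts`` draws a RuntimeError is raised.
    """
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    rng = np.random.default_rng(seed)
    pixel_A = pixel_nm * A_PER_NM

    if heights_A is not None:
        hts = np.asarray(heights_A, float)
        if len(hts) != n_particles:
            raise ValueError("heights_A length must equal n_particles")
    elif n_particles > 0:
        if mixture is None:
            raise ValueError("provide a mixture or explicit heights_A")
        hts = sample_gamma_mixture(mixture, n_particles,
                                   seed=rng.integers(2**31))
    else:
        hts = np.empty(0)
    if n_particles and np.any(hts <= 0):
        raise ValueError("particle heights must be positive")

    grid = np.zeros((height_px, width_px))
    centers_px: list[tuple[float, float]] = []
    radii_px: list[float] = []
    volumes: list[float] = []
    for h in hts:
        a_px = _cap_footprint_radius_A(h, pixel_A) / pixel_A
        placed = False
        for _ in range(max_attempts):
            r0 = rng.uniform(a_px + 1, height_px - a_px - 2)
            c0 = rng.uniform(a_px + 1, width_px - a_px - 2)
            if all(
                np.hypot(r0 - rp, c0 - cp) > a_px + ap + 2
                for (rp, cp), ap in zip(centers_px, radii_px)
            ):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {n_particles} non-overlapping particles "
                f"in {max_attempts} attempts"
            )
        bump_sum = _paint_cap(grid, r0, c0, float(h), a_px)
        centers_px.append((r0, c0))
        radii_px.append(a_px)
        volumes.append(bump_sum * pixel_A**2)

    coeffs = None
    if background:
        x = np.arange(width_px)
        xc = (x - width_px / 2) / (width_px / 2)  # normalised [-1, 1]
        c2 = rng.uniform(-4.0, 4.0)  # scanner bow, Å across the line
        c1 = rng.uniform(-2.0, 2.0)
        c0s = rng.uniform(-1.0, 1.0) * np.ones(height_px)
        if line_drift:
            c0s = c0s + np.cumsum(rng.normal(0.0, 0.15, height_px))
        coeffs = np.column_stack(
            [np.full(height_px, c2), np.full(height_px, c1), c0s]
        )
        grid = grid + (c2 * xc**2 + c1 * xc)[None, :] + c0s[:, None]
    if noise_sigma_A > 0:
        grid = grid + rng.normal(0.0, noise_sigma_A, grid.shape)

    centers_nm = [(c * pixel_nm, r * pixel_nm) for r, c in centers_px]
    truth = TopographTruth(centers_nm, [float(h) for h in hts], volumes,
                           coeffs, float(noise_sigma_A))
    topo = Topograph(grid, pixel_nm,
                     {"stage": "synthetic", "seed": int(seed),
                      "background": bool(background)})
    return topo, truth


def _line_profile(n_px: int, center_px: float, width_px: float,
                  height: float) -> np.ndarray:
    x = np.arange(n_px, dtype=float)
    u = (x - center_px) / width_px
    prof = np.zeros(n_px)
    inside = np.abs(u) < 1.0
    prof[inside] = height * np.sqrt(1.0 - u[inside] ** 2)
    return prof


def simulate_markov_path(
    n_lines: int,
    line_time_s: float,
    dwell_rates_s: np.ndarray,
    rng: np.random.Generator,
    initial_state: int = 0,
) -> np.ndarray:
    """Continuous-time Markov chain sampled at scan-line midpoints.

    State ``k`` is left at exponential rate ``dwell_rates_s[k]`` (rate 0
    means absorbing); on exit the chain jumps uniformly to one of the
    other states.
    """
    K = len(dwell_rates_s)
    total = n_lines * line_time_s
    times = [0.0]
    states = [initial_state]
    t, s = 0.0, initial_state
    while t < total:
        rate = dwell_rates_s[s]
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= total:
            break
        if K > 1:
            others = [k for k in range(K) if k != s]
            s = others[rng.integers(len(others))]
        times.append(t)
        states.append(s)
    mid = (np.arange(n_lines) + 0.5) * line_time_s
    idx = np.searchsorted(times, mid, side="right") - 1
    return np.asarray(states, int)[idx]


def gen_kymograph(
    n_lines: int = 222,
    line_time_s: float = 0.09,
    state_heights_A: list[float] = (37.0, 62.0),
    dwell_rates_s: list[float] = (0.33, 0.33),
    profile_width_nm: float = 12.0,
    noise_sigma_A: float = 1.0,
    pixel_nm: float = 1.9,
    n_pixels: int = 64,
    seed: int = 0,
) -> tuple[Kymograph, KymographTruth]:
    """Synthetic kymograph of one protrusion switching between states.

    Defaults mirror the acquisition geometry of the experiments this
    package analyses: 90 ms per line, 1.9 nm 1-D pixel, records of
    10-20 s, conformational states tens of Å high with dwell times of
    seconds.
    """
    if line_time_s <= 0:
        raise ValueError("line time must be positive")
    heights = np.asarray(state_heights_A, float)
    rates = np.asarray(dwell_rates_s, float)
    if len(heights) != len(rates) or len(heights) < 1:
        raise ValueError("state_heights and dwell_rates must match, length >= 1")
    if np.any(heights <= 0):
        raise ValueError("state heights must be positive")
    if n_lines < 1:
        raise ValueError("need at least one scan line")

    rng = np.random.default_rng(seed)
    path = simulate_markov_path(n_lines, line_time_s, rates, rng)
    width_px = profile_width_nm / pixel_nm
    grid = np.empty((n_lines, n_pixels))
    center = n_pixels / 2.0
    for i, s in enumerate(path):
        grid[i] = _line_profile(n_pixels, center, width_px, heights[s])
    if noise_sigma_A > 0:
        grid = grid + rng.normal(0.0, noise_sigma_A, grid.shape)

    truth = KymographTruth(
        [float(h) for h in heights],
        [float(r) for r in rates],
        path,
        int(np.sum(np.diff(path) != 0)),
        float(line_time_s),
    )
    kymo = Kymograph(grid, pixel_nm, line_time_s,
                     {"stage": "synthetic", "seed": int(seed)})
    return kymo, truth


def gen_sphere_cluster(
    n_atoms: int,
    box_nm: float = 10.0,
    radius_range_A: tuple[float, float] = (1.2, 2.3),
    seed: int = 0,
) -> AtomModel:
    """Random cluster of spheres in a cubic box — a toy atomic model used
    as oracle input for surface-map and dilation tests."""
    if n_atoms < 1:
        raise ValueError("need at least one sphere")
    lo, hi = radius_range_A
    if not 0 < lo <= hi:
        raise ValueError("invalid radius range")
    rng = np.random.default_rng(seed)
    box_A = box_nm * A_PER_NM
    coords = rng.uniform(0.0, box_A, size=(n_atoms, 3))
    radii = rng.uniform(lo, hi, size=n_atoms)
    return AtomModel(coords, radii, ["X"] * n_atoms,
                     meta={"synthetic": True, "box_nm": box_nm,
                           "seed": int(seed)})


def sample_gamma_mixture(
    mixture: GammaMixture, n: int, seed: int = 0
) -> np.ndarray:
    """Draw i.i.d. samples: pick a component by weight, then a gamma draw."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(mixture.weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must be normalised")
    rng = np.random.default_rng(seed)
    comp = rng.choice(mixture.n_components, size=n, p=mixture.weights)
    return rng.gamma(mixture.shapes[comp], mixture.scales[comp])
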