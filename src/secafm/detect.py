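"""Particle detection and per-particle metrology on AFM topographs.

The chain is: per-scan-line polynomial flattening; Hessian-blob detection
(local maxima of the scale-normalised determinant of the Hessian in a
Gaussian scale space, each seed grown into a connected region); a local
background under each particle obtained by Laplace interpolation (the
discrete harmonic surface matching a surrounding annulus); and height /
volume measured above that baseline.  Aggregates are removed with a
maximum-height cutoff (default 100 Å).

Conventions: pixel coordinates are 0-based (row, col), row 0 at the top,
physical origin at the image corner; regions are 8-connected; the
Laplacian stencil is the 4-neighbour one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .core import Topograph

__all__ = [
    "ParticleRecord",
    "flatten_topograph",
    "detect_particles",
    "background_and_metrics",
    "filter_particles",
]

EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class ParticleRecord:
    """One detected protrusion.

    ``rows``/``cols`` index the region's pixels; metrics are filled in by
    :func:`background_and_metrics` (None until then).  ``max_height_A``
    is the highest pixel above the interpolated local background.
    """

    rows: np.ndarray
    cols: np.ndarray
    centroid_nm: tuple[float, float]  # (x, y) from the image corner
    seed_scale_px: float
    seed_response: float
    edge_flag: bool = False
    max_height_A: float | None = None
    volume_A3: float | None = None
    background_A: np.ndarray | None = None  # per-region-pixel baseline
    particle_id: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return len(self.rows)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, bool)
        m[self.rows, self.cols] = True
        return m


def flatten_topograph(image: Topograph, order: int = 2) -> Topograph:
    """Remove per-scan-line polynomial background (default second order).

    Each row is fitted with an order-``order`` polynomial using iterative
    feature masking: fit, mask pixels whose residual exceeds 2 sigma,
    refit — three rounds — then the fit is subtracted everywhere.  Rows
    left with fewer than ``order + 2`` unmasked pixels fall back to a
    median subtraction with a warning.  Finally the image median is set
    to zero.
    """
    if order not in (0, 1, 2):
        raise ValueError("flattening order must be 0, 1 or 2")
    h = image.heights
    ncol = h.shape[1]
    x = np.arange(ncol, dtype=float)
    out = np.empty_like(h)
    for i, line in enumerate(h):
        mask = np.ones(ncol, bool)
        fit = np.full(ncol, np.median(line))
        ok = True
        for _ in range(3):
            if mask.sum() < order + 2:
                ok = False
                break
            coef = np.polyfit(x[mask], line[mask], order)
            fit = np.polyval(coef, x)
            resid = line - fit
            # robust scale: particles inflate a plain SD enough to keep
            # their own pixels in the background set
            sigma = 1.4826 * np.median(np.abs(resid[mask]
                                              - np.median(resid[mask])))
            if sigma < 1e-10 * max(1.0, np.abs(line).max()):
                break  # fit already exact to rounding
            mask = np.abs(resid) <= 2.0 * sigma
        if not ok:
            warnings.warn(f"row {i}: too few background pixels; median only")
            fit = np.full(ncol, np.median(line))
        out[i] = line - fit
    out -= np.median(out)
    return image.copy(heights=out, stage="flattened", flatten_order=order)


def _scale_space_response(h: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Scale-normalised determinant-of-Hessian stack, negative where the
    local mean curvature is not bright-blob-like (trace >= 0)."""
    resp = np.empty((len(sigmas),) + h.shape)
    for i, s in enumerate(sigmas):
        lxx = ndimage.gaussian_filter(h, s, order=(0, 2))
        lyy = ndimage.gaussian_filter(h, s, order=(2, 0))
        lxy = ndimage.gaussian_filter(h, s, order=(1, 1))
        det = s**4 * (lxx * lyy - lxy**2)
        bright = (lxx + lyy) < 0
        resp[i] = np.where(bright, det, -np.abs(det))
    return resp


def _image_noise_sigma(h: np.ndarray) -> float:
    """Pixel noise SD from the median absolute along-row difference
    (robust to features): sigma = median(|dh|) / (0.6745 * sqrt(2))."""
    dh = np.abs(np.diff(h, axis=1))
    return float(np.median(dh) / (0.6745 * np.sqrt(2.0)))


def detect_particles(
    image: Topograph,
    min_response: float | str = "auto",
    min_radius_px: float = 1.0,
    max_radius_px: float = 20.0,
    n_scales: int = 6,
    min_pixels: int = 4,
    seed_height_factor: float = 5.0,
    grow_height_factor: float = 3.0,
    height_floor_A: float = 0.5,
) -> list[ParticleRecord]:
    """Hessian-blob particle detection on a flattened topograph.

    Seeds are local maxima over space and scale of the scale-normalised
    determinant-of-Hessian response that pass both a response threshold
    (``"auto"``: per-scale robust mean + 3 SD via median/MAD) and a
    height criterion (pixel height above ``seed_height_factor`` x the
    image noise SD).  Each seed then grows into the 8-connected region
    of pixels above ``grow_height_factor`` x noise SD — down to the
    noise floor, so the region spans the particle's full footprint and
    the later background annulus sits on the surrounding bilayer.
    Overlapping detections keep the stronger seed.  Returns region-only
    records — :func:`background_and_metrics` fills in heights/volumes.
    """
    h = image.heights
    sigmas = np.geomspace(min_radius_px, max_radius_px, n_scales) / np.sqrt(2.0)
    resp = _scale_space_response(h, sigmas)
    noise = _image_noise_sigma(h)

    if min_response == "auto":
        # per-scale robust threshold: detH noise magnitude varies by
        # orders of magnitude across scales
        med = np.median(resp, axis=(1, 2), keepdims=True)
        mad = np.median(np.abs(resp - med), axis=(1, 2), keepdims=True)
        thresh = med + 3.0 * 1.4826 * mad
    else:
        thresh = np.full((len(sigmas), 1, 1), float(min_response))

    # local maxima over (scale, row, col)
    footprint = np.ones((3, 3, 3), bool)
    local_max = (resp == ndimage.maximum_filter(resp, footprint=footprint,
                                                mode="nearest"))
    # the absolute floor keeps noise-free images (sigma ~ 0) from
    # thresholding at numerical rounding residue
    tall = h > max(seed_height_factor * noise, height_floor_A)
    seeds = np.argwhere(local_max & (resp > thresh) & (resp > 0)
                        & tall[None, :, :])
    if len(seeds) == 0:
        return []
    order = np.argsort(-resp[tuple(seeds.T)])
    seeds = seeds[order]

    grow = h > max(grow_height_factor * noise, height_floor_A)
    grow_labels, _ = ndimage.label(grow, structure=EIGHT_CONN)
    claimed = np.zeros(h.shape, bool)
    records: list[ParticleRecord] = []
    nrow, ncol = h.shape
    for s_idx, r, c in seeds:
        if claimed[r, c]:
            continue
        lab = grow_labels[r, c]
        if lab == 0:
            continue
        rows, cols = np.nonzero((grow_labels == lab) & ~claimed)
        if len(rows) < min_pixels:
            continue
        claimed[rows, cols] = True
        w = np.clip(h[rows, cols], 0.0, None) + 1e-12
        cy = float(np.average(rows, weights=w))
        cx = float(np.average(cols, weights=w))
        edge = bool(
            rows.min() == 0 or cols.min() == 0
            or rows.max() == nrow - 1 or cols.max() == ncol - 1
        )
        records.append(
            ParticleRecord(
                rows=rows,
                cols=cols,
                centroid_nm=(cx * image.pixel_nm, cy * image.pixel_nm),
                seed_scale_px=float(sigmas[s_idx] * np.sqrt(2.0)),
                seed_response=float(resp[s_idx, r, c]),
                edge_flag=edge,
            )
        )
    for i, rec in enumerate(records):
        rec.particle_id = i
    return records


def laplace_interpolate(image: np.ndarray, rows: np.ndarray,
                        cols: np.ndarray) -> np.ndarray:
    """Discrete harmonic baseline inside a region.

    Solves the 4-neighbour Laplace equation for the region's pixels with
    Dirichlet values taken from the image just outside the region
    (effectively the surrounding annulus).  Neighbours beyond the image
    border are dropped from the stencil (zero-flux), which only occurs
    for edge-flagged particles.  Returns the baseline per region pixel,
    ordered like ``rows``/``cols``.
    """
    n = len(rows)
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(rows, cols))}
    nrow, ncol = image.shape
    A = sparse.lil_matrix((n, n))
    b = np.zeros(n)
    for i, (r, c) in enumerate(zip(rows, cols)):
        deg = 0
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nrow and 0 <= cc < ncol):
                continue
            deg += 1
            j = index.get((rr, cc))
            if j is None:
                b[i] += image[rr, cc]  # Dirichlet boundary value
            else:
                A[i, j] = -1.0
        A[i, i] = deg if deg > 0 else 1.0
    return spsolve(A.tocsr(), b)


def background_and_metrics(image: Topograph,
                           record: ParticleRecord) -> ParticleRecord:
    """Fill a particle's baseline, maximum height and volume.

    The local background is the Laplace interpolation of the surrounding
    pixels through the particle's footprint; the height is the highest
    pixel above it and the volume integrates the positive excess over
    the region.
    """
    h = image.heights
    if (record.rows.min() < 0 or record.cols.min() < 0
            or record.rows.max() >= h.shape[0]
            or record.cols.max() >= h.shape[1]):
        raise ValueError("particle region lies outside the image")
    baseline = laplace_interpolate(h, record.rows, record.cols)
    excess = h[record.rows, record.cols] - baseline
    record.background_A = baseline
    record.max_height_A = float(excess.max())
    record.volume_A3 = float(np.clip(excess, 0.0, None).sum()
                             * image.pixel_area_A2)
    return record


def filter_particles(
    records: list[ParticleRecord],
    max_height_cutoff_A: float = 100.0,
    drop_edge: bool = True,
) -> list[ParticleRecord]:
    """Drop aggregates (max height above the cutoff, default 100 Å) and,
    optionally, particles touching the image border.  Order preserved."""
    out = []
    for rec in records:
        if rec.max_height_A is None:
            raise ValueError("metrics must be computed before filtering")
        if rec.max_height_A > max_height_cutoff_A:
            continue
        if drop_edge and rec.edge_flag:
            continue
        out.append(rec)
    return out
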