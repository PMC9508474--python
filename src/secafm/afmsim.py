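"""Simulated AFM imaging of membrane-embedded structures.

The simulated topograph is the morphological dilation of the structure's
van-der-Waals-sphere surface by a model AFM tip: what the instrument
records at lateral position x is the lowest height at which the rigid tip
touches the sample,

    image(x) = max_u [ surface(u) - tip_profile(|x - u|) ],

which preserves every local maximum height while inflating lateral widths.

The tip is a blunted cone: a nested pair of spheres (inner apex sphere of
radius R_inner, concentric outer sphere of radius R_outer placed so the
two surfaces intersect in a circle of the stated overlap cross-section)
continued by a cone of given half-angle from the outer sphere's tangent
point.  Defaults R_inner = 4 nm, R_outer = 8 nm, overlap 2.8 nm,
half-angle 17.5 deg.

Heights are measured from the membrane plane of the viewed side; the
bilayer itself contributes height 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy import ndimage

from .core import A_PER_NM, Topograph

__all__ = [
    "AtomModel",
    "MembraneFrame",
    "TipModel",
    "VDW_RADII_A",
    "load_structure",
    "resolve_membrane",
    "surface_height_map",
    "dilate_with_tip",
    "sim_protrusion_metrics",
]

# Bondi van der Waals radii (Å) for elements common in protein structures.
VDW_RADII_A: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "FE": 1.63,
    "MG": 1.73,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
}
FALLBACK_VDW_A = 1.70


@dataclass
class AtomModel:
    """Atoms as van der Waals spheres: coordinates (Å), radii (Å), elements.

    ``dum_coords`` optionally carries OPM-style membrane dummy-atom
    coordinates (with their elements in ``dum_elements``) found in the
    source file; they mark the bilayer boundary planes and never enter
    the imaged surface.
    """

    coords: np.ndarray
    radii: np.ndarray
    elements: list[str]
    dum_coords: np.ndarray | None = None
    dum_elements: list[str] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, float).reshape(-1)
        if len(self.radii) != len(self.coords):
            raise ValueError("coords and radii must share one length")
        if np.any(self.radii <= 0):
            raise ValueError("van der Waals radii must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.radii)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray = None) -> "AtomModel":
        """Rigidly transform the model (rotation matrix, optional shift in Å)."""
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        dum = None if self.dum_coords is None else self.dum_coords @ rotation.T + t
        return AtomModel(
            self.coords @ rotation.T + t,
            self.radii.copy(),
            list(self.elements),
            dum,
            None if self.dum_elements is None else list(self.dum_elements),
            dict(self.meta),
        )


@dataclass
class MembraneFrame:
    """Bilayer geometry in the model's coordinate frame.

    The two planes are given as signed offsets along the (unit) membrane
    normal; atoms with coordinate ``r`` sit at height ``r @ normal -
    offset`` above the respective plane.  Which physical side each plane
    is depends on the deposited orientation; the caller picks the side
    to image.
    """

    normal: np.ndarray
    periplasmic_offset_A: float
    cytoplasmic_offset_A: float
    side: str | None = None

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, float).reshape(3)
        nrm = np.linalg.norm(self.normal)
        if not nrm > 0:
            raise ValueError("membrane normal must be non-zero")
        self.normal = self.normal / nrm

    @property
    def thickness_A(self) -> float:
        return abs(self.periplasmic_offset_A - self.cytoplasmic_offset_A)


@dataclass
class TipModel:
    """Blunted-cone AFM tip: nested spheres continued by a cone.

    The apex follows the inner sphere (radius ``r_inner_nm``); the outer
    sphere (``r_outer_nm``) is concentric on the tip axis, positioned so
    the two sphere surfaces intersect in a circle of diameter
    ``overlap_nm``; beyond its tangent point the profile is a cone of
    ``half_angle_deg`` measured from the tip axis.
    """

    half_angle_deg: float = 17.5
    r_inner_nm: float = 4.0
    r_outer_nm: float = 8.0
    overlap_nm: float = 2.8

    def __post_init__(self) -> None:
        if not 0 < self.half_angle_deg < 90:
            raise ValueError("half-angle must lie in (0, 90) degrees")
        if not self.r_inner_nm < self.r_outer_nm:
            raise ValueError("inner sphere radius must be below outer")
        if not 0 < self.overlap_nm < 2 * self.r_inner_nm:
            raise ValueError("overlap cross-section incompatible with inner sphere")

    def profile_A(self, r_A: np.ndarray) -> np.ndarray:
        """Tip height above its apex (Å) at lateral distance ``r_A`` (Å).

        Rotationally symmetric, zero at the apex, monotone increasing.
        """
        r = np.abs(np.asarray(r_A, float))
        R1 = self.r_inner_nm * A_PER_NM
        R2 = self.r_outer_nm * A_PER_NM
        rho = 0.5 * self.overlap_nm * A_PER_NM
        alpha = np.deg2rad(self.half_angle_deg)
        # outer-sphere centre height: the sphere surfaces meet at radius rho
        z2 = R1 - np.sqrt(R1**2 - rho**2) + np.sqrt(R2**2 - rho**2)
        r_tan = R2 * np.cos(alpha)  # cone tangency on the outer sphere
        h_tan = z2 - R2 * np.sin(alpha)
        cot = 1.0 / np.tan(alpha)

        out = np.empty_like(r)
        inner = r < rho
        sphere = (~inner) & (r <= r_tan)
        cone = r > r_tan
        out[inner] = R1 - np.sqrt(R1**2 - r[inner] ** 2)
        out[sphere] = z2 - np.sqrt(R2**2 - r[sphere] ** 2)
        out[cone] = h_tan + (r[cone] - r_tan) * cot
        return out


def _vdw_radius(element: str) -> float:
    el = element.strip().upper()
    if el in VDW_RADII_A:
        return VDW_RADII_A[el]
    warnings.warn(f"unknown element {element!r}; using fallback vdW radius "
                  f"{FALLBACK_VDW_A} Å")
    return FALLBACK_VDW_A


def load_structure(
    path: str | Path,
    format: str | None = None,
    include_hetero: bool = False,
    include_hydrogens: bool = True,
) -> AtomModel:
    """Load a PDB/mmCIF structure as van der Waals spheres.

    Waters and (by default) other heteroatoms are excluded; OPM-style
    membrane dummy atoms (residue ``DUM``) are split off into
    ``dum_coords`` for :func:`resolve_membrane`.  Unknown elements fall
    back to 1.70 Å with a warning.
    """
    import biotite.structure.io.pdb as pdb
    import biotite.structure.io.pdbx as pdbx

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    elif fmt in {"cif", "mmcif", "pdbx"}:
        arr = pdbx.get_structure(pdbx.CIFFile.read(str(path)), model=1)
    else:
        raise ValueError(f"unsupported structure format: {fmt!r}")
    if arr.array_length() == 0:
        raise ValueError(f"no atoms parsed from {path}")

    res_names = np.char.upper(arr.res_name.astype(str))
    is_dum = res_names == "DUM"
    dum_coords = arr.coord[is_dum] if is_dum.any() else None
    dum_elements = list(arr.element[is_dum]) if is_dum.any() else None

    keep = ~is_dum & (res_names != "HOH") & (res_names != "WAT")
    if not include_hetero:
        keep &= ~arr.hetero
    if not include_hydrogens:
        keep &= np.char.upper(arr.element.astype(str)) != "H"
    arr = arr[keep]
    if arr.array_length() == 0:
        raise ValueError(f"no usable (non-hetero) atoms in {path}")

    elements = [str(e) for e in arr.element]
    radii = np.array([_vdw_radius(e) for e in elements])
    return AtomModel(arr.coord, radii, elements, dum_coords, dum_elements,
                     meta={"source": str(path)})


def resolve_membrane(
    model: AtomModel,
    mode: str = "dum_atoms",
    normal: np.ndarray | None = None,
    periplasmic_offset_A: float | None = None,
    cytoplasmic_offset_A: float | None = None,
) -> MembraneFrame:
    """Locate the bilayer planes for a membrane-oriented structure.

    ``dum_atoms`` mode reads OPM-style dummy layers (normal = +z by that
    convention; the two planes are the mean z of each dummy layer, the
    higher-z plane labelled periplasmic — swap offsets explicitly if the
    deposited orientation is the other way).  ``explicit`` mode echoes
    user-supplied planes and normal.
    """
    if mode == "explicit":
        if normal is None or periplasmic_offset_A is None or cytoplasmic_offset_A is None:
            raise ValueError("explicit mode needs normal and both plane offsets")
        return MembraneFrame(normal, float(periplasmic_offset_A),
                             float(cytoplasmic_offset_A))
    if mode != "dum_atoms":
        raise ValueError(f"unknown membrane mode: {mode!r}")
    if model.dum_coords is None or len(model.dum_coords) == 0:
        raise ValueError(
            "no OPM-style DUM atoms in the model; supply the planes with "
            "mode='explicit' (normal, periplasmic/cytoplasmic offsets)"
        )
    z = model.dum_coords[:, 2]
    mid = 0.5 * (z.min() + z.max())
    upper, lower = z[z >= mid], z[z < mid]
    if len(upper) == 0 or len(lower) == 0:
        raise ValueError("could not separate two dummy-atom layers")
    frame = MembraneFrame(np.array([0.0, 0.0, 1.0]),
                          float(upper.mean()), float(lower.mean()))
    if not 25.0 <= frame.thickness_A <= 45.0:
        warnings.warn(
            f"dummy-layer separation {frame.thickness_A:.1f} Å outside the "
            "usual 25-45 Å bilayer range"
        )
    return frame


def surface_height_map(
    model: AtomModel,
    frame: MembraneFrame,
    side: str = "periplasmic",
    pixel_nm: float = 0.2,
    margin_nm: float = 2.0,
) -> Topograph:
    """Height map of the van-der-Waals surface above one membrane plane.

    Each grid point records the maximum over atoms of the sphere's
    vertical extent there, clamped at 0 (the bilayer).  For the
    cytoplasmic side the geometry is mirrored through the membrane so the
    protrusion points "up" in the image.
    """
    if pixel_nm <= 0:
        raise ValueError("pixel size must be positive")
    if side not in {"periplasmic", "cytoplasmic"}:
        raise ValueError("side must be 'periplasmic' or 'cytoplasmic'")

    nvec = frame.normal
    # orthonormal lateral basis perpendicular to the membrane normal
    ref = np.array([1.0, 0.0, 0.0])
    if abs(nvec @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(nvec, ref)
    u /= np.linalg.norm(u)
    v = np.cross(nvec, u)

    z_all = model.coords @ nvec
    if side == "periplasmic":
        z_rel = z_all - frame.periplasmic_offset_A
    else:
        z_rel = frame.cytoplasmic_offset_A - z_all
    tops = z_rel + model.radii
    active = tops > 0
    if not active.any():
        warnings.warn(f"no atom protrudes above the {side} plane; empty map")

    px = model.coords @ u
    py = model.coords @ v
    pixel_A = pixel_nm * A_PER_NM
    margin_A = margin_nm * A_PER_NM
    sel = active if active.any() else np.ones_like(active)
    x0 = px[sel].min() - margin_A
    x1 = px[sel].max() + margin_A
    y0 = py[sel].min() - margin_A
    y1 = py[sel].max() + margin_A
    ncol = int(np.ceil((x1 - x0) / pixel_A)) + 1
    nrow = int(np.ceil((y1 - y0) / pixel_A)) + 1
    heights = np.zeros((nrow, ncol))

    for xi, yi, zi, ri in zip(px[active], py[active], z_rel[active],
                              model.radii[active]):
        c0 = max(int(np.floor((xi - ri - x0) / pixel_A)), 0)
        c1 = min(int(np.ceil((xi + ri - x0) / pixel_A)), ncol - 1)
        r0 = max(int(np.floor((yi - ri - y0) / pixel_A)), 0)
        r1 = min(int(np.ceil((yi + ri - y0) / pixel_A)), nrow - 1)
        if c1 < c0 or r1 < r0:
            continue
        gx = x0 + np.arange(c0, c1 + 1) * pixel_A
        gy = y0 + np.arange(r0, r1 + 1) * pixel_A
        d2 = (gx[None, :] - xi) ** 2 + (gy[:, None] - yi) ** 2
        inside = d2 <= ri**2
        patch = np.zeros_like(d2)
        patch[inside] = zi + np.sqrt(ri**2 - d2[inside])
        np.maximum(heights[r0 : r1 + 1, c0 : c1 + 1], patch,
                   out=heights[r0 : r1 + 1, c0 : c1 + 1])

    np.maximum(heights, 0.0, out=heights)
    return Topograph(heights, pixel_nm,
                     {"side": side, "stage": "surface", **model.meta})


def dilate_with_tip(surface: Topograph, tip: TipModel) -> Topograph:
    """Morphologically dilate a surface with the tip profile.

    ``out(x) = max_u [surface(u) - tip(|x-u|)]``.  The structuring
    element is truncated at the support radius beyond which the tip
    penalty exceeds the surface's height range (such offsets can never
    win against the zero-offset term, so the truncation is exact).
    """
    pixel_A = surface.pixel_nm * A_PER_NM
    if pixel_A > tip.r_inner_nm * A_PER_NM:
        warnings.warn("pixel size exceeds the inner tip radius; the tip "
                      "apex is undersampled")
    h = surface.heights
    rng_h = float(h.max() - h.min())
    # find the exact truncation radius for this height range
    r = pixel_A
    while tip.profile_A(np.array([r]))[0] <= rng_h:
        r += pixel_A
    w = int(np.ceil(r / pixel_A))
    offs = np.arange(-w, w + 1) * pixel_A
    rr = np.sqrt(offs[:, None] ** 2 + offs[None, :] ** 2)
    structure = -tip.profile_A(rr)
    dilated = ndimage.grey_dilation(h, structure=structure,
                                    mode="constant", cval=-np.inf)
    return surface.copy(heights=dilated, stage="dilated",
                        tip=dict(half_angle_deg=tip.half_angle_deg,
                                 r_inner_nm=tip.r_inner_nm,
                                 r_outer_nm=tip.r_outer_nm,
                                 overlap_nm=tip.overlap_nm))


def sim_protrusion_metrics(
    image: Topograph, connected_only: bool = True
) -> tuple[float, float]:
    """(max height Å, volume Å³) of the simulated protrusion.

    The maximum is the grid maximum; the volume integrates positive
    heights over pixels.  With ``connected_only`` (default) the volume is
    restricted to the 8-connected positive region containing the global
    maximum, so in a multi-protein complex the dominant protrusion is
    measured rather than the whole footprint.
    """
    h = image.heights
    max_h = float(h.max())
    if max_h <= 0:
        return 0.0, 0.0
    positive = h > 0
    if connected_only:
        labels, _ = ndimage.label(positive, structure=np.ones((3, 3), int))
        peak = np.unravel_index(np.argmax(h), h.shape)
        positive = labels == labels[peak]
    volume = float(h[positive].sum() * image.pixel_area_A2)
    return max_h, volume
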