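"""Core grid containers shared by every stage of the pipeline.

Canonical internal units: heights in angstrom (Å), lateral distances in
nanometre (nm), time in seconds.  ``A_PER_NM`` converts between the two
length units; SI export helpers are provided for interoperability with
tools that expect metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

A_PER_NM = 10.0
M_PER_NM = 1e-9
M_PER_A = 1e-10


@dataclass
class Topograph:
    """A 2-D AFM height image.

    Attributes
    ----------
    heights : ndarray, shape (rows, cols)
        Heights in Å.  0 is the reference surface (supported bilayer or
        membrane plane).  Row 0 is the top of the image; coordinates are
        0-based ``(row, col)`` with the physical origin at the image corner.
    pixel_nm : float
        Lateral pixel size in nm (square pixels).
    meta : dict
        Free-form provenance (seed, source structure, processing steps).
    """

    heights: np.ndarray
    pixel_nm: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("topograph heights must be a 2-D grid")
        if not self.pixel_nm > 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def pixel_area_A2(self) -> float:
        """Pixel area in Å² (for volume integrals)."""
        return (self.pixel_nm * A_PER_NM) ** 2

    def copy(self, heights: np.ndarray | None = None, **meta: Any) -> "Topograph":
        h = self.heights.copy() if heights is None else np.asarray(heights, float)
        return Topograph(h, self.pixel_nm, {**self.meta, **meta})


@dataclass
class Kymograph:
    """Repeated 1-D scans over one line, stacked in time.

    ``heights`` has shape (n_lines, n_pixels): axis 0 is time (one scan
    line per row, ``line_time`` seconds apart), axis 1 is space.
    """

    heights: np.ndarray
    pixel_nm: float
    line_time_s: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("kymograph heights must be a 2-D grid")
        if not self.pixel_nm > 0:
            raise ValueError("pixel size must be positive")
        if not self.line_time_s > 0:
            raise ValueError("line time must be positive")

    @property
    def n_lines(self) -> int:
        return self.heights.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_lines * self.line_time_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_lines) * self.line_time_s


def heights_to_si(heights_A: np.ndarray) -> np.ndarray:
    """Convert Å heights to metres for SI-abscissa output."""
    return np.asarray(heights_A, float) * M_PER_A


def volumes_to_si(volumes_A3: np.ndarray) -> np.ndarray:
    """Convert Å³ volumes to m³."""
    return np.asarray(volumes_A3, float) * M_PER_A**3
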