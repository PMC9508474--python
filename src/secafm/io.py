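"""Plain-text interchange: TSV height grids with YAML sidecars, CSV tables.

A topograph ``foo.tsv`` is a rectangular tab-separated grid of heights in
Å; its sidecar ``foo.yaml`` records pixel size, line time (kymographs),
seed and any provenance the producing stage attached.  Truth tables and
particle tables travel as CSV via pandas.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .core import Kymograph, Topograph


def _sidecar_path(grid_path: Path) -> Path:
    return grid_path.with_suffix(".yaml")


def _clean_meta(meta: dict[str, Any]) -> dict[str, Any]:
    """Make metadata YAML-safe (numpy scalars -> python)."""
    out: dict[str, Any] = {}
    for k, v in meta.items():
        if isinstance(v, np.generic):
            v = v.item()
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out


def write_topograph(path: str | Path, topo: Topograph) -> None:
    path = Path(path)
    np.savetxt(path, topo.heights, delimiter="\t", fmt="%.6g")
    sidecar = {
        "kind": "topograph",
        "pixel_nm": float(topo.pixel_nm),
        "height_unit": "A",
        "shape": list(topo.shape),
        "meta": _clean_meta(topo.meta),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_topograph(path: str | Path) -> Topograph:
    path = Path(path)
    heights = np.loadtxt(path, delimiter="\t", ndmin=2)
    side = yaml.safe_load(_sidecar_path(path).read_text())
    return Topograph(heights, float(side["pixel_nm"]), side.get("meta", {}) or {})


def write_kymograph(path: str | Path, kymo: Kymograph) -> None:
    path = Path(path)
    np.savetxt(path, kymo.heights, delimiter="\t", fmt="%.6g")
    sidecar = {
        "kind": "kymograph",
        "pixel_nm": float(kymo.pixel_nm),
        "line_time_s": float(kymo.line_time_s),
        "height_unit": "A",
        "shape": list(kymo.heights.shape),
        "meta": _clean_meta(kymo.meta),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    heights = np.loadtxt(path, delimiter="\t", ndmin=2)
    side = yaml.safe_load(_sidecar_path(path).read_text())
    return Kymograph(
        heights,
        float(side["pixel_nm"]),
        float(side["line_time_s"]),
        side.get("meta", {}) or {},
    )


def write_topograph_truth(path: str | Path, truth) -> None:
    """Ground-truth particle table (CSV: x_nm, y_nm, max_height_A,
    volume_A3)."""
    import pandas as pd

    pd.DataFrame(
        {
            "x_nm": [c[0] for c in truth.particle_centers_nm],
            "y_nm": [c[1] for c in truth.particle_centers_nm],
            "max_height_A": truth.particle_max_heights_A,
            "volume_A3": truth.particle_volumes_A3,
        }
    ).to_csv(path, index=False)


def write_kymograph_truth(path: str | Path, truth) -> None:
    """Ground-truth state path table (CSV: line, state, state_height_A)."""
    import pandas as pd

    pd.DataFrame(
        {
            "line": np.arange(len(truth.state_path)),
            "state": truth.state_path,
            "state_height_A": [truth.state_heights_A[s] for s in truth.state_path],
        }
    ).to_csv(path, index=False)


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of a configuration dict, for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
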