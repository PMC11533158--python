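"""File I/O: images (TIFF / ASCII matrix + JSON sidecar), trajectories, configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .afm import AFMImage
from .model import Configuration, ModelParams
from .mc import MoveParams, Trajectory

__all__ = [
    "write_image",
    "read_image",
    "read_trajectory",
    "write_configuration_csv",
    "read_configuration_csv",
    "faceset_to_records",
    "write_faceset_csv",
    "load_config",
    "save_config",
]


def write_image(img: AFMImage, path, meta: dict | None = None) -> None:
    """Write a height map as single-channel float TIFF (or ``.txt`` matrix)
    plus a JSON sidecar carrying pixel size and metadata."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.height.astype(np.float32))
    else:
        np.savetxt(path, img.height, fmt="%.5f")
    sidecar = {"pixel_size_nm": img.pixel_size, "record": img.record}
    if meta:
        sidecar.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, default=_js, indent=1))


def read_image(path, pixel_size: float | None = None) -> AFMImage:
    """Read a TIFF or whitespace-delimited ASCII height matrix.

    Pixel size comes from the ``<file>.json`` sidecar when present, else
    the ``pixel_size`` argument (nm), else the 3 nm default.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        h = np.asarray(tifffile.imread(path), dtype=float)
    else:
        h = np.loadtxt(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if pixel_size is None and sidecar.exists():
        pixel_size = json.loads(sidecar.read_text()).get("pixel_size_nm")
    return AFMImage(h, pixel_size or 3.0)


def read_trajectory(path) -> Trajectory:
    """Read a JSON-lines trajectory written by ``Trajectory.to_jsonl``."""
    frames = []
    bond_counts = []
    header = None
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            if "header" in d:
                header = d["header"]
                continue
            params = ModelParams.from_dict(header["params"])
            recs = d["particles"]
            pos = np.array([[r["x"], r["y"]] for r in recs])
            ori = np.array([r["theta"] for r in recs])
            act = np.array([r["patch_active"] for r in recs], dtype=bool)
            frames.append((d["sweep"],
                           Configuration(pos, ori, act, params,
                                         check_overlaps=False)))
            bond_counts.append(d["n_bonds"])
    if header is None:
        raise ValueError(f"{path}: no trajectory header found")
    return Trajectory(
        frames=frames, bond_counts=bond_counts,
        params=ModelParams.from_dict(header["params"]),
        moves=MoveParams(**header["moves"]),
        seed=header["seed"], n_sweeps=header["n_sweeps"],
        record_every=header["record_every"],
        acceptance=header.get("acceptance", {}),
        converged=header.get("converged", False),
    )


def write_configuration_csv(c: Configuration, path) -> None:
    """Per-particle table: id, x, y, theta, patch flags."""
    import pandas as pd
    rows = c.to_records()
    for r in rows:
        flags = r.pop("patch_active")
        for k in range(3):
            r[f"patch{k}_active"] = flags[k]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_configuration_csv(path, params: ModelParams) -> Configuration:
    import pandas as pd
    df = pd.read_csv(path)
    pos = df[["x", "y"]].to_numpy(float)
    ori = df["theta"].to_numpy(float)
    act = df[[f"patch{k}_active" for k in range(3)]].to_numpy(bool)
    return Configuration(pos, ori, act, params, check_overlaps=False)


def faceset_to_records(fs) -> list[dict]:
    """Face table: id, size, area, component (units follow the network)."""
    return [{"face_id": i, "size": f.size, "area": f.area,
             "component": f.component} for i, f in enumerate(fs.faces)]


def write_faceset_csv(fs, path) -> None:
    import pandas as pd
    pd.DataFrame(faceset_to_records(fs)).to_csv(path, index=False)


def load_config(path) -> dict:
    """YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def _js(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
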