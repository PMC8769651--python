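"""Readers and writers for the toolkit's on-disk formats.

Images and stacks travel as TIFF (via tifffile), coordinates as small CSV
dialects (via pandas), transforms as JSON, and configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .correlation import CorrelationTransform
from .frames import Affine3D

__all__ = [
    "read_image", "write_image", "read_stack", "write_stack",
    "read_points_csv", "write_points_csv",
    "read_pairs_csv", "write_pairs_csv",
    "read_transform_json", "write_transform_json",
    "load_yaml_config",
]


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image))


def read_stack(path) -> np.ndarray:
    data = tifffile.imread(str(path))
    return data[None] if data.ndim == 2 else data


def write_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack), photometric="minisblack")


def read_points_csv(path) -> np.ndarray:
    """Coordinates CSV with header ``x,y[,z]``, one point per row, pixels."""
    df = pd.read_csv(path)
    cols = ["x", "y"] + (["z"] if "z" in df.columns else [])
    return df[cols].to_numpy(dtype=float)


def write_points_csv(path, points: np.ndarray) -> None:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cols = ["x", "y", "z"][: pts.shape[1]]
    pd.DataFrame(pts, columns=cols).to_csv(path, index=False)


def read_pairs_csv(path):
    """Paired-point CSV ``id,flm_x,flm_y,flm_z,img_x,img_y`` -> (ids, 3D, 2D)."""
    df = pd.read_csv(path)
    return (df["id"].tolist(),
            df[["flm_x", "flm_y", "flm_z"]].to_numpy(dtype=float),
            df[["img_x", "img_y"]].to_numpy(dtype=float))


def write_pairs_csv(path, points3d, points2d, ids=None) -> None:
    p3 = np.atleast_2d(np.asarray(points3d, dtype=float))
    p2 = np.atleast_2d(np.asarray(points2d, dtype=float))
    ids = list(range(len(p3))) if ids is None else list(ids)
    pd.DataFrame({"id": ids,
                  "flm_x": p3[:, 0], "flm_y": p3[:, 1], "flm_z": p3[:, 2],
                  "img_x": p2[:, 0], "img_y": p2[:, 1]}).to_csv(path, index=False)


def write_transform_json(path, transform) -> None:
    Path(path).write_text(transform.to_json() + "\n")


def read_transform_json(path):
    """Load an :class:`Affine3D` or :class:`CorrelationTransform` from JSON."""
    d = json.loads(Path(path).read_text())
    if "quaternion" in d:
        return CorrelationTransform.from_dict(d)
    return Affine3D.from_dict(d)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
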