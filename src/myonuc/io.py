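"""Reading and writing the pipeline's file formats.

Stacks and movies are multi-page TIFF with a YAML sidecar holding the voxel
size and grid origin in µm; nucleus tables are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import GroundTruthNucleus, VoxelStack

__all__ = [
    "write_stack", "read_stack", "write_truth_csv", "read_nuclei_csv",
    "nuclei_to_frame",
]


def write_stack(stack: VoxelStack, tif_path, meta_path=None) -> None:
    """Write a stack as multi-page TIFF (pages = z) plus a metadata sidecar."""
    tif_path = Path(tif_path)
    tifffile.imwrite(tif_path, stack.intensities.astype(np.float32))
    meta_path = Path(meta_path) if meta_path else tif_path.with_suffix(".yaml")
    meta = {
        "voxel_size_um": [float(v) for v in stack.voxel_size],
        "origin_um": [float(v) for v in stack.origin],
        "axis_convention": stack.axis_convention,
        "axes_order": "zyx",
    }
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))


def read_stack(tif_path, meta_path=None) -> VoxelStack:
    tif_path = Path(tif_path)
    img = np.asarray(tifffile.imread(tif_path), dtype=np.float64)
    if img.ndim == 2:
        img = img[None]
    meta_path = Path(meta_path) if meta_path else tif_path.with_suffix(".yaml")
    meta = yaml.safe_load(meta_path.read_text())
    return VoxelStack(
        img,
        tuple(meta["voxel_size_um"]),
        tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
        meta.get("axis_convention", "x-long-axis"),
    )


def nuclei_to_frame(nuclei: list[GroundTruthNucleus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [n.id for n in nuclei],
            "x_um": [n.centroid[0] for n in nuclei],
            "y_um": [n.centroid[1] for n in nuclei],
            "z_um": [n.centroid[2] for n in nuclei],
            "a": [n.semi_axes[0] for n in nuclei],
            "b": [n.semi_axes[1] for n in nuclei],
            "c": [n.semi_axes[2] for n in nuclei],
            "angle_deg": [n.angle_deg for n in nuclei],
        }
    )


def write_truth_csv(nuclei: list[GroundTruthNucleus], path) -> None:
    nuclei_to_frame(nuclei).to_csv(path, index=False)


def read_nuclei_csv(path) -> pd.DataFrame:
    """Read a nucleus table (id, x_um, y_um, z_um, ...)."""
    df = pd.read_csv(path)
    required = {"x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"nuclei CSV missing columns: {sorted(missing)}")
    return df
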