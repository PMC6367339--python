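"""3D nucleus segmentation from confocal-like stacks.

Nuclei are detected as 26-connected components above an intensity threshold
(Otsu by default), filtered by physical volume, with an optional
distance-transform watershed to split touching nuclei.  The geometric
centre of each nucleus is the unweighted mean of its member voxel centres,
converted to µm with the stack's anisotropic voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .simulate import VoxelStack

__all__ = [
    "SegmentationParams",
    "SegmentedNucleus",
    "DegenerateThresholdError",
    "segment_stack",
    "project_xy",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class DegenerateThresholdError(ValueError):
    """Raised when automatic thresholding cannot separate foreground."""


@dataclass
class SegmentationParams:
    threshold_method: str = "otsu"      # "otsu" | "fixed"
    threshold_value: float | None = None  # required for "fixed"
    min_volume: float = 30.0            # µm³, suppress noise specks
    max_volume: float | None = None     # µm³
    split_touching: bool = False        # distance-transform watershed

    def __post_init__(self) -> None:
        if self.min_volume < 0:
            raise ValueError("min_volume must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValueError("fixed thresholding requires threshold_value")


@dataclass
class SegmentedNucleus:
    """One segmented nucleus: voxel mask (within a bounding box) + geometry."""

    id: int
    mask: np.ndarray                 # boolean (z, y, x) array, bounding box
    bbox: tuple[slice, slice, slice]  # bounding box in the parent stack
    centroid_3d: tuple[float, float, float]  # (x, y, z) µm
    volume: float                    # µm³


def _threshold(stack: VoxelStack, params: SegmentationParams) -> float:
    img = stack.intensities
    if params.threshold_method == "fixed":
        t = float(params.threshold_value)
        if not (img.min() <= t <= img.max()):
            raise ValueError(
                f"fixed threshold {t} outside intensity range "
                f"[{img.min()}, {img.max()}]"
            )
        return t
    if img.min() == img.max():
        raise DegenerateThresholdError(
            "constant-intensity stack: Otsu threshold is undefined"
        )
    return float(threshold_otsu(img))


def segment_stack(
    stack: VoxelStack, params: SegmentationParams | None = None
) -> list[SegmentedNucleus]:
    """Detect nuclei in a stack.

    Returns nuclei sorted by descending volume (ties broken by scan order),
    with ids assigned in that order.  An all-background stack yields an
    empty list; a constant stack under Otsu raises
    :class:`DegenerateThresholdError`.
    """
    params = params or SegmentationParams()
    img = stack.intensities
    if params.threshold_method == "otsu" and img.min() == img.max():
        if img.flat[0] == 0:
            return []  # pure background, nothing to segment
        raise DegenerateThresholdError(
            "saturated/constant stack: Otsu threshold is undefined"
        )
    thr = _threshold(stack, params)
    fg = img > thr
    if not fg.any():
        return []

    if params.split_touching:
        labels = _watershed_split(fg, stack.voxel_size)
    else:
        labels, _ = ndimage.label(fg, structure=_CONN26)

    dx, dy, dz = stack.voxel_size
    vox_vol = dx * dy * dz
    objects = ndimage.find_objects(labels)
    x0, y0, z0 = stack.origin

    records = []
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = labels[sl] == lab
        n_vox = int(mask.sum())
        vol = n_vox * vox_vol
        if vol < params.min_volume:
            continue
        if params.max_volume is not None and vol > params.max_volume:
            continue
        zz, yy, xx = np.nonzero(mask)
        zz = zz + sl[0].start
        yy = yy + sl[1].start
        xx = xx + sl[2].start
        centroid = (
            x0 + (xx.mean() + 0.5) * dx,
            y0 + (yy.mean() + 0.5) * dy,
            z0 + (zz.mean() + 0.5) * dz,
        )
        records.append((vol, lab, mask, sl, centroid))

    # descending volume; ties by first-labelled (scan order)
    records.sort(key=lambda r: (-r[0], r[1]))
    return [
        SegmentedNucleus(id=i, mask=mask, bbox=sl, centroid_3d=c, volume=vol)
        for i, (vol, _lab, mask, sl, c) in enumerate(records)
    ]


def _watershed_split(fg: np.ndarray, voxel_size) -> np.ndarray:
    dx, dy, dz = voxel_size
    dist = ndimage.distance_transform_edt(fg, sampling=(dz, dy, dx))
    # seeds: local maxima of the distance map, one marker per smoothed peak
    smoothed = ndimage.gaussian_filter(dist, sigma=1)
    peaks = (smoothed == ndimage.maximum_filter(smoothed, size=5)) & fg
    markers, _ = ndimage.label(peaks, structure=_CONN26)
    return watershed(-dist, markers, mask=fg)


def project_xy(mask: np.ndarray | SegmentedNucleus) -> np.ndarray:
    """XY projection of a 3D mask: union over z of the occupied (y, x) pixels.

    Projecting an already-flat (2D) mask is the identity.
    """
    if isinstance(mask, SegmentedNucleus):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 2:
        if not mask.any():
            raise ValueError("mask is empty")
        return mask
    if mask.ndim != 3:
        raise ValueError("mask must be 2D or 3D")
    if not mask.any():
        raise ValueError("mask is empty")
    return mask.any(axis=0)
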