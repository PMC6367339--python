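"""Per-nucleus shape metrics and per-fibre geometry.

Fibre cross-sections are treated as ellipses: CSA = π (w/2)(t/2) from the
fibre width w and thickness t, and the volume of a 100 µm fibre segment is
CSA × 100.  Nucleus morphometry is measured on the 2D xy projection of each
segmented nucleus: area, best-fit-ellipse major/minor axes (roundness =
minor/major), maximum Feret diameter, and the angle of the maximum-diameter
direction relative to the fibre long axis, summarised as sin(angle) so that
0 means aligned with the fibre and 1 means perpendicular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

__all__ = [
    "FiberGeometry",
    "NucleusMorphometry",
    "compute_csa",
    "compute_volume_per_100um",
    "nucleus_shape_metrics",
    "nuclei_per_100um",
    "nuclei_per_volume",
    "section_counts",
    "fusion_metrics",
]

#: roundness above which the maximum-diameter direction is unreliable
ROUNDNESS_INDETERMINATE = 0.95


@dataclass(frozen=True)
class FiberGeometry:
    """Per-fibre geometry: elliptical cross-section and derived volume."""

    width_w: float          # µm
    thickness_t: float      # µm
    csa: float              # µm²
    volume_per_100um: float  # µm³
    analyzed_length: float  # µm

    @classmethod
    def from_width_thickness(
        cls, width_w: float, thickness_t: float, analyzed_length: float = 0.0
    ) -> "FiberGeometry":
        csa = compute_csa(width_w, thickness_t)
        return cls(width_w, thickness_t, csa, compute_volume_per_100um(csa), analyzed_length)


@dataclass(frozen=True)
class NucleusMorphometry:
    id: int
    area: float            # µm²
    max_diameter: float    # µm (maximum Feret diameter)
    major_axis: float      # µm (best-fit ellipse)
    minor_axis: float      # µm
    roundness: float       # minor/major, in (0, 1]
    angle_deg: float       # max-diameter direction vs fibre axis, [0, 180)
    sinus: float           # sin(angle_deg), [0, 1]
    angle_indeterminate: bool = False


def compute_csa(width_w: float, thickness_t: float) -> float:
    """Elliptical cross-section area, CSA = π (w/2)(t/2), in µm²."""
    if width_w <= 0 or thickness_t <= 0:
        raise ValueError("width and thickness must be > 0")
    return math.pi * (width_w / 2.0) * (thickness_t / 2.0)


def compute_volume_per_100um(csa: float) -> float:
    """Fibre volume of a 100 µm segment, CSA × 100, in µm³."""
    if csa < 0:
        raise ValueError("csa must be >= 0")
    return csa * 100.0


def _max_feret(points: np.ndarray) -> tuple[float, float]:
    """Maximum Feret diameter and its direction (degrees in [0, 180))."""
    if len(points) > 3:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:
            pass  # degenerate (collinear) point sets: brute-force all pairs
    diff = points[:, None, :] - points[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    dvec = points[j] - points[i]
    ang = math.degrees(math.atan2(dvec[1], dvec[0])) % 180.0
    return float(math.sqrt(d2[i, j])), ang


def nucleus_shape_metrics(
    region: np.ndarray,
    pixel_size: tuple[float, float] = (1.0, 1.0),
    fiber_axis_deg: float = 0.0,
    nucleus_id: int = 0,
) -> NucleusMorphometry:
    """Shape metrics of one 2D binary region (a projected nucleus).

    ``region`` is a boolean (y, x) array; ``pixel_size`` is (dx, dy) µm.
    Major/minor axes come from the second central moments of the pixel
    centres (the best-fit-ellipse convention: axis length = 4 sqrt(λ)),
    handling anisotropic pixels by working in µm.  The maximum diameter is
    the maximum Feret diameter over pixel corner points, and its direction,
    taken relative to ``fiber_axis_deg`` and folded into [0, 180), defines
    the orientation angle.  Near-circular regions (roundness > 0.95) have no
    reliable direction; their sinus is reported but flagged indeterminate.
    """
    region = np.asarray(region, dtype=bool)
    if region.ndim != 2:
        raise ValueError("region must be a 2D binary array")
    ii, jj = np.nonzero(region)
    if ii.size == 0:
        raise ValueError("region is empty")
    dx, dy = pixel_size
    area = ii.size * dx * dy
    x = (jj + 0.5) * dx
    y = (ii + 0.5) * dy

    if ii.size == 1:
        pitch = max(dx, dy)
        return NucleusMorphometry(
            id=nucleus_id, area=area, max_diameter=pitch, major_axis=pitch,
            minor_axis=pitch, roundness=1.0, angle_deg=0.0, sinus=0.0,
            angle_indeterminate=True,
        )

    pts = np.column_stack([x, y])
    mu = pts.mean(axis=0)
    centered = pts - mu
    cov = centered.T @ centered / ii.size
    # add the second moment of a unit pixel so thin regions keep finite width
    cov += np.diag([dx**2 / 12.0, dy**2 / 12.0])
    evals = np.linalg.eigvalsh(cov)
    minor = 4.0 * math.sqrt(max(evals[0], 0.0))
    major = 4.0 * math.sqrt(max(evals[1], 0.0))
    roundness = minor / major if major > 0 else 1.0

    # Feret on pixel corners (captures full extent, not just centres)
    corners = np.concatenate(
        [
            np.column_stack([jj * dx, ii * dy]),
            np.column_stack([(jj + 1) * dx, ii * dy]),
            np.column_stack([jj * dx, (ii + 1) * dy]),
            np.column_stack([(jj + 1) * dx, (ii + 1) * dy]),
        ]
    )
    max_diam, feret_ang = _max_feret(corners)
    angle = (feret_ang - fiber_axis_deg) % 180.0
    return NucleusMorphometry(
        id=nucleus_id,
        area=area,
        max_diameter=max_diam,
        major_axis=major,
        minor_axis=minor,
        roundness=roundness,
        angle_deg=angle,
        sinus=abs(math.sin(math.radians(angle))),
        angle_indeterminate=roundness > ROUNDNESS_INDETERMINATE,
    )


def nuclei_per_100um(n_nuclei: int, analyzed_length: float) -> float:
    """Nucleus count per 100 µm of fibre length."""
    if analyzed_length <= 0:
        raise ValueError("analyzed_length must be > 0")
    return n_nuclei * 100.0 / analyzed_length


def nuclei_per_volume(n_nuclei: int, volume: float) -> float:
    """Nucleus count per µm³ of fibre volume."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return n_nuclei / volume


def section_counts(fibers: pd.DataFrame, points: pd.DataFrame) -> float:
    """Satellite cells as a percentage of total fibre number on a section."""
    n_fibers = len(fibers)
    if n_fibers < 1:
        raise ValueError("at least one fibre is required")
    return 100.0 * len(points) / n_fibers


def fusion_metrics(assignments) -> tuple[float, float]:
    """Fusion index of differentiated myotube cultures.

    ``assignments`` maps each nucleus to a myotube id, or None/NaN for
    nuclei outside myotubes.  Returns ``(mean nuclei per myotube, percent of
    nuclei inside myotubes)``.  With no myotube at all the mean is NaN
    (undefined) and the percentage 0.
    """
    vals = list(assignments)
    if not vals:
        raise ValueError("no nuclei in assignment table")
    assigned = [v for v in vals if v is not None and not (isinstance(v, float) and math.isnan(v))]
    pct_inside = 100.0 * len(assigned) / len(vals)
    if not assigned:
        return float("nan"), 0.0
    counts = pd.Series(assigned).value_counts()
    return float(counts.mean()), pct_inside
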