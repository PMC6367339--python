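"""Spatial organization of myonuclei: nearest-neighbour distances and the
slice-based myonuclear domain (MND).

The NN distance of a nucleus is the Euclidean distance from its 3D
geometric centre to the closest other nucleus of the same fibre.  The MND
is estimated on the fibre's long axis: a segment (375 µm by default) is cut
into 20 µm slices, and each occupied slice contributes v/n where v is the
slice volume (CSA × slice length) and n the number of nuclei whose centres
fall in the slice.  Empty slices are excluded from the mean/SD and reported
separately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["NNResult", "MNDResult", "nearest_neighbour", "myonuclear_domain",
           "sinus_distribution", "SINUS_MAIN_RANGES"]


@dataclass
class NNResult:
    """Per-fibre nearest-neighbour distances (µm)."""

    nn_distances: np.ndarray
    nn_mean: float
    nn_sd: float
    defined: bool = True


@dataclass
class MNDResult:
    """Slice-based myonuclear-domain estimate for one fibre."""

    slices: pd.DataFrame          # slice_index, x_start, x_end, volume_um3, n_nuclei, mnd_um3
    mnd_mean: float               # µm³, over occupied slices
    mnd_sd: float                 # µm³
    n_empty_slices: int
    segment_length: float         # µm
    slice_length: float           # µm
    defined: bool = True


def nearest_neighbour(centroids) -> NNResult:
    """NN distance for each nucleus, plus the fibre mean and SD.

    With fewer than two centroids the result is explicitly undefined
    (``defined=False``, NaN statistics), not zero.  Coincident centroids
    yield a zero distance and a warning.
    """
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    if pts.size == 0 or len(pts) < 2:
        return NNResult(np.empty(0), float("nan"), float("nan"), defined=False)
    if pts.shape[1] != 3:
        raise ValueError("centroids must be (n, 3) in µm")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    nn = dist[:, 1]
    if np.any(nn == 0):
        warnings.warn("coincident nucleus centroids: zero NN distance", stacklevel=2)
    sd = float(np.std(nn, ddof=1)) if len(nn) > 1 else float("nan")
    return NNResult(nn, float(np.mean(nn)), sd)


def myonuclear_domain(
    x_coords,
    csa,
    segment_length: float = 375.0,
    slice_length: float = 20.0,
    origin: float = 0.0,
    fiber_length: float | None = None,
    include_partial: bool = True,
) -> MNDResult:
    """Slice-based MND estimate along the fibre long axis.

    ``x_coords`` are nucleus-centre x positions (µm); ``csa`` is the fibre
    cross-section area (µm²), a scalar for uniform fibres or one value per
    slice.  Nuclei are binned into half-open slices [k·L, (k+1)·L) starting
    at ``origin``.  375/20 leaves a 15 µm remainder: the partial slice is
    included with its true volume (CSA × 15) unless ``include_partial`` is
    False.

    Raises ``ValueError`` if the segment exceeds the fibre extent.  Zero
    occupied slices yield an undefined result.
    """
    if slice_length <= 0 or segment_length <= 0:
        raise ValueError("segment_length and slice_length must be > 0")
    if fiber_length is not None and segment_length > fiber_length + 1e-9:
        raise ValueError(
            f"analyzed segment ({segment_length} µm) exceeds fibre length "
            f"({fiber_length} µm)"
        )
    x = np.asarray(x_coords, dtype=float)

    n_full = int(math.floor(segment_length / slice_length))
    rem = segment_length - n_full * slice_length
    lengths = [slice_length] * n_full
    if rem > 1e-9 and include_partial:
        lengths.append(rem)
    edges = origin + np.concatenate([[0.0], np.cumsum(lengths)])

    csa_arr = np.broadcast_to(np.asarray(csa, dtype=float), (len(lengths),))
    volumes = csa_arr * np.asarray(lengths)

    # half-open bins [edge_k, edge_{k+1})
    counts = np.histogram(x[(x >= edges[0]) & (x < edges[-1])], bins=edges)[0]
    # np.histogram closes the last bin; re-impose half-openness on the right
    counts[-1] = int(np.sum((x >= edges[-2]) & (x < edges[-1])))

    occupied = counts > 0
    mnd = np.where(occupied, volumes / np.maximum(counts, 1), np.nan)
    slices = pd.DataFrame(
        {
            "slice_index": np.arange(len(lengths)),
            "x_start": edges[:-1],
            "x_end": edges[1:],
            "volume_um3": volumes,
            "n_nuclei": counts,
            "mnd_um3": mnd,
        }
    )
    n_empty = int((~occupied).sum())
    if not occupied.any():
        return MNDResult(slices, float("nan"), float("nan"), n_empty,
                         segment_length, slice_length, defined=False)
    vals = mnd[occupied]
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    return MNDResult(slices, float(np.mean(vals)), sd, n_empty,
                     segment_length, slice_length)


#: the three aggregate orientation ranges: sinus 0–0.3 (angles within ~20°
#: of the fibre axis), 0.3–0.6, and 0.6–1 (40°–140°)
SINUS_MAIN_RANGES = ((0.0, 0.3), (0.3, 0.6), (0.6, 1.0))


def sinus_distribution(values, bin_width: float = 0.1) -> pd.DataFrame:
    """Histogram of orientation-sinus values as percentages over [0, 1].

    Bins are half-open [k·w, (k+1)·w) with the last bin closed at 1.
    Besides the fine bins, the three aggregate ranges 0–0.3, 0.3–0.6 and
    0.6–1 are returned in the DataFrame attribute ``attrs['main_ranges']``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no sinus values")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("sinus values must lie in [0, 1]")
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = np.histogram(v, bins=edges)[0]  # last bin closed, as required
    pct = 100.0 * counts / v.size
    out = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts,
         "percentage": pct}
    )
    main = {}
    for lo, hi in SINUS_MAIN_RANGES:
        sel = (v >= lo) & ((v < hi) if hi < 1.0 else (v <= hi))
        main[(lo, hi)] = 100.0 * int(sel.sum()) / v.size
    out.attrs["main_ranges"] = main
    return out
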