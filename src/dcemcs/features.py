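"""Morphological and dynamic lesion features.

Morphological (per lesion): slice-wise area (n_k * dx * dy) and perimeter
(boundary-voxel count b_k), aggregated as the median over the slices the
lesion intersects; 3D compactness S^2/V, with surface S = (6-connectivity
boundary-voxel count) * v_size * slice_th and volume V = n_ROI * dx*dy*dz;
and 3D eccentricity sqrt(a^2 - b^2)/a from the principal semi-axes of the
voxel-centre cloud in physical coordinates.

Dynamic (per voxel): basal signal BS, relative enhancement
RE(t_i) = (SI(t_i) - BS)/BS, its least-squares slope over the post-contrast
scans, and the sum-of-intensity-differences SOD.

v_size in the surface formula is the in-plane linear spacing dx (the formula
multiplies by slice thickness separately, so v_size must be a length; dx and
dy are equal in the acquisitions this targets). Perimeter defaults to a bare
boundary-voxel count; ``perimeter_mm=True`` scales by dx.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dce_io import DCESeries, TimeIntensityCurve, VOI, DegenerateInputError
from .segmentation import sod_voxel

__all__ = [
    "MorphFeatures",
    "DynFeatures",
    "slice_area",
    "slice_perimeter",
    "compactness_3d",
    "eccentricity_3d",
    "morph_feature_vector",
    "basal_signal",
    "relative_enhancement",
    "re_slope",
    "dyn_feature_vector",
]

MORPH_FEATURE_NAMES = ["area_median", "perimeter_median", "compactness", "eccentricity"]
DYN_FEATURE_NAMES = ["sod", "bs", "re_slope"]


@dataclass(frozen=True)
class MorphFeatures:
    area_median: float        # mm^2, median over slices
    perimeter_median: float   # boundary-voxel count (or mm, see perimeter_mm)
    compactness: float        # S^2/V, a.u.
    eccentricity: float       # dimensionless, [0, 1)


@dataclass(frozen=True)
class DynFeatures:
    sod: float        # a.u.
    bs: float         # a.u.
    re_slope: float   # 1/s


# ---------------------------------------------------------------------------
# morphological features
# ---------------------------------------------------------------------------

def slice_area(slice_mask: np.ndarray, dx: float, dy: float) -> float:
    """Foreground-voxel count times the in-plane voxel footprint (mm^2)."""
    m = np.asarray(slice_mask, dtype=bool)
    n = int(m.sum())
    if n == 0:
        raise DegenerateInputError("empty slice mask")
    return n * dx * dy


def slice_perimeter(slice_mask: np.ndarray) -> int:
    """Count of foreground voxels with a 4-neighbour outside the mask;
    the grid border counts as outside."""
    m = np.asarray(slice_mask, dtype=bool)
    if not m.any():
        raise DegenerateInputError("empty slice mask")
    padded = np.pad(m, 1)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return int((m & ~interior).sum())


def _boundary_count_3d(mask: np.ndarray) -> int:
    """Foreground voxels with a 6-neighbour outside (border = outside)."""
    padded = np.pad(mask, 1)
    interior = (padded[:-2, 1:-1, 1:-1] & padded[2:, 1:-1, 1:-1]
                & padded[1:-1, :-2, 1:-1] & padded[1:-1, 2:, 1:-1]
                & padded[1:-1, 1:-1, :-2] & padded[1:-1, 1:-1, 2:])
    return int((mask & ~interior).sum())


def _voi_mask(voi: VOI) -> tuple[np.ndarray, np.ndarray]:
    lo = voi.coords.min(axis=0)
    sub = voi.coords - lo
    mask = np.zeros(sub.max(axis=0) + 1, dtype=bool)
    mask[tuple(sub.T)] = True
    return mask, lo


def compactness_3d(voi: VOI, dx: float, dy: float, slice_th: float) -> float:
    """S^2/V with S = boundary count * dx * slice_th and V = n * dx*dy*dz
    (dz = slice thickness: contiguous slices)."""
    if voi.n_voxels == 0:
        raise DegenerateInputError("empty VOI")
    mask, _ = _voi_mask(voi)
    surface = _boundary_count_3d(mask) * dx * slice_th
    volume = voi.n_voxels * dx * dy * slice_th
    return float(surface ** 2 / volume)


def eccentricity_3d(voi: VOI, dx: float, dy: float, slice_th: float) -> float:
    """sqrt(a^2 - b^2)/a from the largest/smallest principal semi-axes of
    the voxel-centre cloud in physical coordinates (semi-axis =
    2 * sqrt(second-moment eigenvalue))."""
    if voi.n_voxels < 4:
        raise DegenerateInputError("eccentricity needs >= 4 voxels")
    pts = voi.coords * np.asarray([dx, dy, slice_th])
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    eigvals = np.sort(np.linalg.eigvalsh(cov))
    if eigvals[0] <= 1e-12:
        raise DegenerateInputError("degenerate (collinear/planar) voxel cloud")
    semi_axes = 2.0 * np.sqrt(eigvals)
    a, b = semi_axes[-1], semi_axes[0]
    return float(np.sqrt(a ** 2 - b ** 2) / a)


def morph_feature_vector(voi: VOI, dx: float, dy: float, slice_th: float,
                         perimeter_mm: bool = False) -> MorphFeatures:
    """Slice-wise area/perimeter medians (even count: mean of the middle
    two) plus whole-volume compactness and eccentricity."""
    mask, _ = _voi_mask(voi)
    areas, perims = [], []
    for k in range(mask.shape[2]):
        sl = mask[:, :, k]
        if sl.any():
            areas.append(slice_area(sl, dx, dy))
            perims.append(slice_perimeter(sl))
    scale = dx if perimeter_mm else 1.0
    return MorphFeatures(
        area_median=float(np.median(areas)),
        perimeter_median=float(np.median(perims)) * scale,
        compactness=compactness_3d(voi, dx, dy, slice_th),
        eccentricity=eccentricity_3d(voi, dx, dy, slice_th),
    )


# ---------------------------------------------------------------------------
# dynamic features
# ---------------------------------------------------------------------------

def basal_signal(tic: TimeIntensityCurve) -> float:
    """Pre-contrast signal intensity (zero baseline is legal but makes
    relative enhancement undefined downstream)."""
    if tic.pre == 0:
        import warnings
        warnings.warn("zero basal signal: relative enhancement undefined",
                      stacklevel=2)
    return float(tic.pre)


def relative_enhancement(tic: TimeIntensityCurve, i: int) -> float:
    """(SI(t_i) - BS)/BS for the i-th post-contrast scan (1-based i)."""
    if tic.pre <= 0:
        raise DegenerateInputError("relative enhancement undefined for BS <= 0")
    if not 1 <= i <= tic.n_post:
        raise ValueError(f"scan index {i} outside 1..{tic.n_post}")
    return float((tic.post[i - 1] - tic.pre) / tic.pre)


def re_slope(tic: TimeIntensityCurve, times: np.ndarray) -> float:
    """OLS slope of RE(t_i) against t_i over all post-contrast scans (1/s).

    ``times`` are the post-contrast scan times (length T).
    """
    if tic.pre <= 0:
        raise DegenerateInputError("relative enhancement undefined for BS <= 0")
    t = np.asarray(times, dtype=float)
    if t.size != tic.n_post or t.size < 2:
        raise ValueError("need one time per post-contrast scan, at least two scans")
    re_vals = (tic.post - tic.pre) / tic.pre
    tc = t - t.mean()
    return float((tc @ (re_vals - re_vals.mean())) / (tc @ tc))


def dyn_feature_vector(voi: VOI, series: DCESeries) -> list[DynFeatures]:
    """One (sod, bs, re_slope) triple per VOI voxel, in coordinate order."""
    if voi.n_voxels == 0:
        raise DegenerateInputError("empty VOI")
    xs, ys, zs = voi.coords.T
    curves = series.voxels[xs, ys, zs, :]           # (N, T+1)
    bs = curves[:, 0]
    post = curves[:, 1:]
    if np.any(bs <= 0):
        raise DegenerateInputError("VOI contains voxels with zero basal signal")
    sod = bs + np.abs(np.diff(curves, axis=1)).sum(axis=1)
    re_vals = (post - bs[:, None]) / bs[:, None]
    t = series.post_times
    tc = t - t.mean()
    slopes = (re_vals - re_vals.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
    return [DynFeatures(sod=float(s), bs=float(b), re_slope=float(sl))
            for s, b, sl in zip(sod, bs, slopes)]
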