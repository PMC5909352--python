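"""Automatic lesion segmentation from a 4D DCE series.

Three steps: (1) a sum-of-intensity-differences (SOD) parametric map is
thresholded with Otsu's method to obtain a breast mask; (2) the mask is
cleaned by morphological closing, hole filling and erosion; (3) voxels whose
time-intensity curve shows significant uptake (max relative enhancement
> 0.3) peaking strictly before the last scan are marked suspicious, and
26-connected components of sufficient size become candidate VOIs.

The SOD of a voxel is its pre-contrast intensity plus the total absolute
inter-scan variation,

    SOD = Pre + sum_{i=1..T} |Post(i) - Post(i-1)|,   Post(0) := Pre,

so a temporally flat voxel keeps its baseline value while any enhancement
history raises it.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .dce_io import (DCESeries, TimeIntensityCurve, VOI, DegenerateInputError)

__all__ = [
    "sod_voxel",
    "sod_map",
    "otsu_threshold",
    "breast_mask",
    "suspicious_voxels",
    "extract_vois",
]

RE_THRESHOLD = 0.3  # C1: max relative enhancement must exceed 30% of baseline


def sod_voxel(tic: TimeIntensityCurve) -> float:
    """Pre-contrast value plus total absolute inter-scan variation."""
    if tic.n_post < 1:
        raise ValueError("empty post-contrast sequence")
    seq = np.concatenate(([tic.pre], tic.post))
    return float(tic.pre + np.abs(np.diff(seq)).sum())


def sod_map(series: DCESeries) -> np.ndarray:
    """Voxel-wise SOD over the whole series (3D map, spatial shape)."""
    diffs = np.abs(np.diff(series.voxels, axis=3))  # Post(0) := Pre via frame 0
    return series.pre + diffs.sum(axis=3)


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Histogram-based Otsu threshold.

    A histogram with ``bins`` equal-width bins over [min, max] is built and
    the interior bin edge maximising the between-class variance
    w0*w1*(mu0 - mu1)^2 is returned (ties broken toward the lowest edge).
    Downstream, foreground means value > threshold.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2 or v.min() == v.max():
        raise DegenerateInputError("Otsu needs at least two distinct values")
    hist, edges = np.histogram(v, bins=bins, range=(v.min(), v.max()))
    hist = hist.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(hist)[:-1]                       # class 0: bins 0..k
    w1 = hist.sum() - w0
    csum = np.cumsum(hist * centers)[:-1]
    total = (hist * centers).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / w0
        mu1 = (total - csum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    # ties (incl. float jitter across empty-bin plateaus) -> lowest threshold
    top = sigma_b.max()
    k = int(np.argmax(sigma_b >= top - 1e-9 * abs(top)))
    return float(edges[k + 1])


def breast_mask(sod: np.ndarray, struct_radius: int = 2,
                bins: int = 256) -> np.ndarray:
    """Breast mask from the SOD map: Otsu threshold, then closing, hole
    filling (2D slice-wise then 3D) and erosion with a ball element."""
    threshold = otsu_threshold(sod, bins=bins)
    mask = sod > threshold
    if not mask.any():
        raise DegenerateInputError("empty mask after Otsu thresholding")
    elem = ball(struct_radius).astype(bool)
    # closing composed by hand: the erosion half must treat out-of-grid as
    # foreground or tissue truncated by the field of view is eaten back
    mask = ndimage.binary_dilation(mask, structure=elem)
    mask = ndimage.binary_erosion(mask, structure=elem, border_value=1)
    for k in range(mask.shape[2]):
        mask[:, :, k] = ndimage.binary_fill_holes(mask[:, :, k])
    mask = ndimage.binary_fill_holes(mask)
    # border_value=1: tissue truncated by the field of view (chest wall,
    # slice-stack faces) is not eroded at the grid border
    mask = ndimage.binary_erosion(mask, structure=elem, border_value=1)
    return mask


def suspicious_voxels(series: DCESeries, within: np.ndarray,
                      re_threshold: float = RE_THRESHOLD) -> np.ndarray:
    """Kinetic suspicious-voxel conditions inside a breast mask.

    A voxel is suspicious iff (C1) the maximum of its relative-enhancement
    curve (SI - BS)/BS exceeds ``re_threshold`` and (C2) the post-contrast
    signal peak occurs strictly before the final scan. Voxels with zero
    baseline are never suspicious (relative enhancement undefined).
    """
    within = np.asarray(within, dtype=bool)
    if within.shape != series.spatial_shape:
        raise ValueError("breast mask shape does not match the series")
    bs = series.pre
    post = series.post
    t_post = post.shape[3]
    valid = bs > 0
    re_max = np.zeros(bs.shape)
    np.divide(post.max(axis=3) - bs, bs, out=re_max, where=valid)
    peak_idx = post.argmax(axis=3)                  # 0-based; final scan = t_post-1
    c1 = re_max > re_threshold
    c2 = peak_idx < t_post - 1
    return within & valid & c1 & c2


def extract_vois(suspicious: np.ndarray, min_size: int = 10) -> list[VOI]:
    """26-connected components of the suspicious mask, >= min_size voxels,
    largest first, provenance 'automatic'."""
    labelled, n = ndimage.label(np.asarray(suspicious, dtype=bool),
                                structure=np.ones((3, 3, 3), dtype=bool))
    vois = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labelled == lab)
        if len(coords) >= min_size:
            vois.append(VOI(coords, provenance="automatic",
                            validate_connectivity=False))
    vois.sort(key=lambda v: -v.n_voxels)
    return vois
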