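"""On-disk artifacts and shared domain types.

A dynamic contrast-enhanced (DCE) MRI study is one pre-contrast 3D volume
followed by T post-contrast volumes of the same grid. Everything downstream
relies on the frame-0 = pre-contrast convention established here; no other
module re-infers it.

Series and masks travel as NIfTI-1; feature tables and cohort manifests as
plain CSV.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ShapeError",
    "DegenerateInputError",
    "DCESeries",
    "TimeIntensityCurve",
    "VOI",
    "LesionFeatureRecord",
    "read_dce_series",
    "write_dce_series",
    "read_mask",
    "write_mask",
    "read_manifest",
    "write_manifest",
    "write_feature_table",
    "read_feature_table",
]


class FormatError(ValueError):
    """A file or header violates the expected on-disk format."""


class ShapeError(ValueError):
    """Spatial shapes of two grids that must match do not."""


class DegenerateInputError(ValueError):
    """Input is valid in type but degenerate for the requested operation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TimeIntensityCurve:
    """One voxel's signal over the scan sequence.

    ``pre`` is the basal (pre-contrast) signal BS; ``post[i-1]`` is the
    signal SI(t_i) of the i-th post-contrast scan.
    """

    pre: float
    post: np.ndarray

    def __post_init__(self) -> None:
        self.post = np.asarray(self.post, dtype=float)
        if self.post.ndim != 1 or self.post.size < 1:
            raise ValueError("post-contrast sequence must be a non-empty 1D array")

    @property
    def bs(self) -> float:
        return float(self.pre)

    @property
    def n_post(self) -> int:
        return int(self.post.size)


@dataclass
class DCESeries:
    """A 4D DCE acquisition: voxels[x, y, z, i], i = 0 pre-contrast."""

    voxels: np.ndarray
    dx: float
    dy: float
    slice_th: float
    times: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.voxels.ndim != 4:
            raise FormatError("series must be 4D (x, y, z, time)")
        if self.voxels.shape[3] < 3:
            raise FormatError("series must contain pre + post frames")
        for name, value in (("dx", self.dx), ("dy", self.dy), ("slice_th", self.slice_th)):
            if not np.isfinite(value) or value <= 0:
                raise FormatError(f"voxel spacing {name} must be positive, got {value!r}")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise FormatError("intensities must be finite and non-negative")
        if self.times.shape != (self.voxels.shape[3],):
            raise FormatError("times must have one entry per frame")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("scan times must be strictly increasing")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_post(self) -> int:
        """T, the number of post-contrast scans."""
        return self.voxels.shape[3] - 1

    @property
    def pre(self) -> np.ndarray:
        return self.voxels[..., 0]

    @property
    def post(self) -> np.ndarray:
        return self.voxels[..., 1:]

    @property
    def post_times(self) -> np.ndarray:
        return self.times[1:]

    def tic(self, x: int, y: int, z: int) -> TimeIntensityCurve:
        return TimeIntensityCurve(float(self.voxels[x, y, z, 0]), self.voxels[x, y, z, 1:])


def _connected_26(coords: np.ndarray) -> bool:
    from scipy import ndimage

    lo = coords.min(axis=0)
    sub = coords - lo
    grid = np.zeros(sub.max(axis=0) + 1, dtype=bool)
    grid[tuple(sub.T)] = True
    _, n = ndimage.label(grid, structure=np.ones((3, 3, 3), dtype=bool))
    return n == 1


@dataclass
class VOI:
    """A connected 3D voxel set taken to be one lesion.

    ``coords`` is an (N, 3) int array of 0-based (x, y, z) indices.
    """

    coords: np.ndarray
    provenance: str = "manual"
    label: str = "unknown"
    validate_connectivity: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) == 0:
            raise ValueError("VOI coordinates must be a non-empty (N, 3) array")
        if np.any(self.coords < 0):
            raise ValueError("VOI coordinates must be non-negative")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("VOI coordinates must be unique")
        if self.provenance not in ("manual", "automatic"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.label not in ("benign", "malignant", "unknown"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.validate_connectivity and not _connected_26(self.coords):
            raise ValueError("VOI must be 26-connected")

    @classmethod
    def from_mask(cls, mask: np.ndarray, provenance: str = "manual",
                  label: str = "unknown", validate_connectivity: bool = True) -> "VOI":
        coords = np.argwhere(np.asarray(mask, dtype=bool))
        if len(coords) == 0:
            raise DegenerateInputError("mask contains no foreground voxels")
        return cls(coords, provenance=provenance, label=label,
                   validate_connectivity=validate_connectivity)

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    def to_mask(self, shape: Sequence[int]) -> np.ndarray:
        shape = tuple(shape)
        if np.any(self.coords >= np.asarray(shape)):
            raise ShapeError("VOI coordinates out of bounds for the given shape")
        mask = np.zeros(shape, dtype=bool)
        mask[tuple(self.coords.T)] = True
        return mask


@dataclass
class LesionFeatureRecord:
    """Selected features for one lesion: four morphological scalars and the
    per-voxel dynamic triples (sod, bs, re_slope)."""

    lesion_id: str
    split: str
    label: str
    morph: object                      # MorphFeatures (features module)
    dyn: list = field(default_factory=list)  # list of DynFeatures, one per voxel


# ---------------------------------------------------------------------------
# NIfTI series / masks
# ---------------------------------------------------------------------------

DEFAULT_SCAN_INTERVAL = 60.0  # s, used when the header carries no time step


def read_dce_series(path: str | Path) -> DCESeries:
    """Read a 4D NIfTI-1 series; frame 0 is pre-contrast by convention."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D series, got {data.ndim}D")
    if data.shape[3] < 3:
        raise FormatError(f"{path}: series must contain pre + post frames")
    zooms = img.header.get_zooms()
    dx, dy, dz = (float(z) for z in zooms[:3])
    dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else DEFAULT_SCAN_INTERVAL
    times = np.arange(data.shape[3], dtype=float) * dt
    return DCESeries(data, dx=dx, dy=dy, slice_th=dz, times=times)


def write_dce_series(series: DCESeries, path: str | Path) -> None:
    affine = np.diag([series.dx, series.dy, series.slice_th, 1.0])
    img = nib.Nifti1Image(series.voxels.astype(np.float64), affine)
    dt = float(np.median(np.diff(series.times)))
    img.header.set_zooms((series.dx, series.dy, series.slice_th, dt))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(path: str | Path, series: DCESeries) -> np.ndarray:
    """Read a 3D binary mask; any nonzero voxel is foreground."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: mask must be 3D, got {data.ndim}D")
    if data.shape != series.spatial_shape:
        raise ShapeError(
            f"{path}: mask shape {data.shape} does not match series "
            f"spatial shape {series.spatial_shape}")
    return data != 0


def write_mask(mask: np.ndarray, path: str | Path,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# manifests and feature tables (CSV)
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["lesion_id", "series_path", "mask_path", "label", "split"]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    bad = set(df["label"]) - {"benign", "malignant"}
    if bad:
        raise FormatError(f"{path}: labels outside benign/malignant: {sorted(bad)}")
    bad = set(df["split"]) - {"train", "test"}
    if bad:
        raise FormatError(f"{path}: splits outside train/test: {sorted(bad)}")
    if check_paths:
        root = Path(path).parent
        for col in ("series_path", "mask_path"):
            for p in df[col]:
                if p == "auto":
                    continue
                candidate = Path(p)
                if not candidate.is_absolute():
                    candidate = root / candidate
                if not candidate.exists():
                    raise FormatError(f"{path}: unresolvable {col} entry {p!r}")
    return df


LESION_FEATURE_COLUMNS = [
    "lesion_id", "split", "label",
    "area_median", "perimeter_median", "compactness", "eccentricity",
    "sod_mean", "bs_mean", "re_slope_mean",
]
VOXEL_FEATURE_COLUMNS = ["lesion_id", "voxel_index", "sod", "bs", "re_slope"]


def _voxel_sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + "_voxels" + path.suffix)


def write_feature_table(records: Sequence[LesionFeatureRecord],
                        path: str | Path) -> None:
    """One CSV row per lesion plus a ``*_voxels`` sidecar with the per-voxel
    dynamic feature rows. Lesion-level dynamic columns are voxel means."""
    if not records:
        raise ValueError("nothing to write: empty record list")
    path = Path(path)
    lesion_rows, voxel_rows = [], []
    for rec in records:
        dyn = rec.dyn
        lesion_rows.append({
            "lesion_id": rec.lesion_id,
            "split": rec.split,
            "label": rec.label,
            "area_median": rec.morph.area_median,
            "perimeter_median": rec.morph.perimeter_median,
            "compactness": rec.morph.compactness,
            "eccentricity": rec.morph.eccentricity,
            "sod_mean": float(np.mean([d.sod for d in dyn])) if dyn else np.nan,
            "bs_mean": float(np.mean([d.bs for d in dyn])) if dyn else np.nan,
            "re_slope_mean": float(np.mean([d.re_slope for d in dyn])) if dyn else np.nan,
        })
        for j, d in enumerate(dyn):
            voxel_rows.append({
                "lesion_id": rec.lesion_id, "voxel_index": j,
                "sod": d.sod, "bs": d.bs, "re_slope": d.re_slope,
            })
    pd.DataFrame(lesion_rows, columns=LESION_FEATURE_COLUMNS).to_csv(
        path, index=False, float_format="%.12g")
    pd.DataFrame(voxel_rows, columns=VOXEL_FEATURE_COLUMNS).to_csv(
        _voxel_sidecar_path(path), index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (lesion table, per-voxel dynamic table)."""
    path = Path(path)
    lesions = pd.read_csv(path)
    voxels = pd.read_csv(_voxel_sidecar_path(path))
    return lesions, voxels
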