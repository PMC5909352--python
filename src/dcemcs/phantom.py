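"""Synthetic DCE-MRI cohorts with ground-truth lesions.

The generator emulates the two clinical archetypes the pipeline is built
around: malignant lesions enhance rapidly and wash out (interior intensity
peak), benign lesions enhance slowly and persist (peak at or near the end of
the acquisition); malignant lesions are irregular in shape, benign ones
round and smooth. Signal follows a saturating-uptake / exponential-washout
curve

    SI(t) = BS0 * (1 + A * (1 - exp(-k_in t)) * exp(-k_out t)),   t > 0

with SI(0) = BS0, plus additive Gaussian noise clipped at zero. This is a
phenomenological curve, not a pharmacokinetic (Tofts-type) model: the
pipeline only consumes intensity ratios and orderings, for which the shape
(monotone rise when k_out = 0; a unique interior maximum at
t* = ln(1 + k_in/k_out)/k_in when k_out > 0) is what matters.

Background anatomy is a half-ellipsoid "breast" of mildly enhancing tissue
against near-zero air, enough for the sum-of-differences map + Otsu step to
find a breast mask. All randomness flows from one integer seed through
per-lesion substreams (seed + lesion index), so cohorts are reproducible
and extensible without reshuffling earlier lesions.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .dce_io import (DCESeries, TimeIntensityCurve, write_dce_series,
                     write_mask, write_manifest)

__all__ = [
    "KineticParams",
    "LesionSpec",
    "CohortResult",
    "kinetic_curve",
    "enhancement_fraction",
    "time_to_peak",
    "make_lesion_mask",
    "breast_region",
    "generate_cohort",
    "save_cohort",
]


@dataclass(frozen=True)
class KineticParams:
    """Parameters of one voxel-class enhancement curve.

    bs0: baseline intensity (a.u., > 0); amplitude: uptake amplitude A as a
    fraction of baseline (>= 0); k_in: uptake rate (1/s, > 0); k_out:
    washout rate (1/s, >= 0; 0 = persistent); noise_sd: additive Gaussian
    noise SD (a.u., >= 0).
    """

    bs0: float
    amplitude: float
    k_in: float
    k_out: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.bs0, self.amplitude, self.k_in, self.k_out, self.noise_sd)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("kinetic parameters must be finite")
        if self.bs0 <= 0:
            raise ValueError("baseline bs0 must be positive")
        if self.amplitude < 0 or self.k_in <= 0 or self.k_out < 0 or self.noise_sd < 0:
            raise ValueError("amplitude, k_out, noise_sd >= 0 and k_in > 0 required")


@dataclass(frozen=True)
class LesionSpec:
    """Geometry + kinetics of one synthetic lesion."""

    centre: tuple[int, int, int]
    radius: float
    cls: str                      # "benign" | "malignant"
    rho: float                    # shape-irregularity amplitude in [0, 1]
    kinetics: KineticParams

    def __post_init__(self) -> None:
        if self.cls not in ("benign", "malignant"):
            raise ValueError(f"unknown lesion class {self.cls!r}")
        if self.radius < 2:
            raise ValueError("lesion radius must be >= 2 voxels")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("shape irregularity rho must lie in [0, 1]")


def enhancement_fraction(p: KineticParams, t: np.ndarray) -> np.ndarray:
    """Noise-free fractional enhancement (SI/BS0 - 1) at times t > 0."""
    t = np.asarray(t, dtype=float)
    return p.amplitude * (1.0 - np.exp(-p.k_in * t)) * np.exp(-p.k_out * t)


def time_to_peak(p: KineticParams) -> float:
    """Continuous-time peak of the noise-free curve; inf when k_out = 0."""
    if p.k_out == 0:
        return np.inf
    return float(np.log1p(p.k_in / p.k_out) / p.k_in)


def kinetic_curve(p: KineticParams, times: np.ndarray,
                  seed: int | np.random.Generator = 0) -> TimeIntensityCurve:
    """Sample one time-intensity curve at the given scan times.

    ``times[0]`` must be 0 (the pre-contrast scan); noise is N(0, noise_sd²)
    per scan, and intensities are clipped at zero.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("scan times must be strictly increasing with >= 2 entries")
    if times[0] != 0:
        raise ValueError("times[0] must be 0 (pre-contrast scan)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    si = p.bs0 * (1.0 + enhancement_fraction(p, times))
    si[0] = p.bs0
    if p.noise_sd > 0:
        si = si + rng.normal(0.0, p.noise_sd, size=si.shape)
    si = np.clip(si, 0.0, None)
    return TimeIntensityCurve(float(si[0]), si[1:])


# ---------------------------------------------------------------------------
# lesion geometry
# ---------------------------------------------------------------------------

def _direction_perturbation(rho: float, rng: np.random.Generator):
    """A smooth random function f(u) on the unit sphere with max|f| = 1,
    built from a few low-frequency directional cosines (spherical-harmonic
    -like in smoothness and order)."""
    n_terms = 6
    dirs = rng.normal(size=(n_terms, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    amps = rng.normal(size=n_terms)
    freqs = rng.integers(1, 4, size=n_terms).astype(float)
    phases = rng.uniform(0, 2 * np.pi, size=n_terms)

    def f(units: np.ndarray) -> np.ndarray:
        proj = units @ dirs.T                       # (N, n_terms)
        vals = (amps * np.cos(freqs * np.pi * proj + phases)).sum(axis=1)
        return vals

    return f


def make_lesion_mask(spec: LesionSpec, grid_shape, seed: int = 0) -> np.ndarray:
    """Rasterise one lesion as a boolean mask on the given spatial grid.

    rho = 0 gives the exact discrete ball {voxel : |voxel - centre| <= r};
    rho > 0 modulates the radius per direction by a seeded low-order
    perturbation of relative amplitude rho. The result is the largest
    26-connected component of the star-shaped raster (discretisation can
    pinch off stray voxels at high rho).
    """
    grid_shape = tuple(grid_shape)
    centre = np.asarray(spec.centre, dtype=float)
    r_max = spec.radius * (1.0 + spec.rho)
    lo = np.floor(centre - r_max).astype(int)
    hi = np.ceil(centre + r_max).astype(int)
    if np.any(lo < 0) or np.any(hi >= np.asarray(grid_shape)):
        raise ValueError("lesion exceeds the grid")

    idx = np.indices(grid_shape).reshape(3, -1).T.astype(float)
    offsets = idx - centre
    dist = np.linalg.norm(offsets, axis=1)
    if spec.rho == 0:
        inside = dist <= spec.radius
    else:
        rng = np.random.default_rng(seed)
        f = _direction_perturbation(spec.rho, rng)
        with np.errstate(invalid="ignore"):
            units = np.where(dist[:, None] > 0, offsets / np.maximum(dist, 1e-12)[:, None], 0.0)
        vals = f(units)
        vals = vals / max(np.max(np.abs(vals)), 1e-12)
        local_r = np.maximum(spec.radius * (1.0 + spec.rho * vals), 1.2)
        inside = dist <= local_r
    mask = inside.reshape(grid_shape)
    labelled, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        sizes = ndimage.sum_labels(mask, labelled, index=np.arange(1, n + 1))
        mask = labelled == (1 + int(np.argmax(sizes)))
    return mask


def breast_region(grid_shape) -> np.ndarray:
    """Half-ellipsoid 'breast' protruding from the y = 0 chest wall."""
    nx, ny, nz = grid_shape
    x, y, z = np.indices(grid_shape).astype(float)
    cx, cz = (nx - 1) / 2.0, (nz - 1) / 2.0
    # spans the whole slice stack (the acquisition covers the breast in z)
    rx, ry, rz = 0.48 * nx, 0.85 * ny, 0.95 * nz
    return ((x - cx) / rx) ** 2 + (y / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    series: list            # list[DCESeries], one per lesion
    truth_masks: list       # list[np.ndarray bool]
    manifest: pd.DataFrame  # lesion_id, series_path, mask_path, label, split
    specs: list             # list[LesionSpec]


def _draw(rng: np.random.Generator, rng_range) -> float:
    lo, hi = float(rng_range[0]), float(rng_range[1])
    return lo if lo == hi else float(rng.uniform(lo, hi))


def _draw_kinetics(cls: str, cfg: dict, rng: np.random.Generator) -> KineticParams:
    bs0 = _draw(rng, cfg["lesion_baseline_range"])
    noise_sd = cfg["noise_frac"] * bs0
    if cls == "malignant":
        amp = _draw(rng, cfg["malignant_amp_range"])
        k_in = _draw(rng, cfg["malignant_k_in_range"])
        t_peak = _draw(rng, cfg["malignant_peak_time_range"])
        # invert t* = ln(1 + k_in/k_out)/k_in for the washout rate
        k_out = k_in / np.expm1(k_in * t_peak)
    else:
        amp = _draw(rng, cfg["benign_amp_range"])
        k_in = _draw(rng, cfg["benign_k_in_range"])
        k_out = _draw(rng, cfg["benign_k_out_range"])
    return KineticParams(bs0=bs0, amplitude=amp, k_in=k_in, k_out=k_out,
                         noise_sd=noise_sd)


def _place_lesion(breast: np.ndarray, margin: float, r_geom: int,
                  rng: np.random.Generator) -> tuple[int, int, int]:
    """Pick a centre at least ``margin`` voxels from air (so the lesion
    survives breast-mask erosion) whose bounding box of half-width
    ``r_geom`` fits inside the grid."""
    dist_in = ndimage.distance_transform_edt(breast)
    feasible = dist_in >= margin
    fits = np.zeros_like(feasible)
    if all(s > 2 * r_geom for s in feasible.shape):
        fits[r_geom:-r_geom, r_geom:-r_geom, r_geom:-r_geom] = True
    candidates = np.argwhere(feasible & fits)
    if len(candidates) == 0:
        raise ValueError("no feasible lesion placement: lesion too large for the breast region")
    centre = candidates[rng.integers(len(candidates))]
    return tuple(int(c) for c in centre)


def _simulate_series(spec: LesionSpec, lesion_mask: np.ndarray, breast: np.ndarray,
                     cfg: dict, times: np.ndarray,
                     rng: np.random.Generator) -> DCESeries:
    grid_shape = breast.shape
    n_frames = times.size

    tissue_amp = _draw(rng, cfg["tissue_amp_range"])
    tissue = KineticParams(bs0=cfg["tissue_baseline"], amplitude=tissue_amp,
                           k_in=0.005, k_out=0.0, noise_sd=0.0)

    bs0 = np.full(grid_shape, cfg["air_baseline"])
    amp = np.zeros(grid_shape)
    k_in = np.full(grid_shape, 1e-3)
    k_out = np.zeros(grid_shape)
    for region, par in ((breast, tissue), (lesion_mask, spec.kinetics)):
        bs0[region], amp[region] = par.bs0, par.amplitude
        k_in[region], k_out[region] = par.k_in, par.k_out

    t = times.reshape((1, 1, 1, -1))
    frac = amp[..., None] * (1 - np.exp(-k_in[..., None] * t)) * np.exp(-k_out[..., None] * t)
    frac[..., 0] = 0.0
    voxels = bs0[..., None] * (1.0 + frac)
    noise_sd = cfg["noise_frac"] * spec.kinetics.bs0
    if noise_sd > 0:
        voxels = voxels + rng.normal(0.0, noise_sd, size=voxels.shape)
    voxels = np.clip(voxels, 0.0, None)
    return DCESeries(voxels, dx=cfg["dx"], dy=cfg["dy"], slice_th=cfg["slice_th"],
                     times=times)


def _stratified_split(labels: list[str], train_frac: float,
                      rng: np.random.Generator) -> list[str]:
    """Per-class floor(frac*n) train members, leftovers to the largest
    fractional remainders until round(frac*n_total) is reached."""
    n_total = len(labels)
    n_train_total = int(round(train_frac * n_total))
    classes = sorted(set(labels))
    per_class = {}
    remainders = []
    for cls in classes:
        n_cls = labels.count(cls)
        exact = train_frac * n_cls
        per_class[cls] = int(np.floor(exact))
        remainders.append((exact - np.floor(exact), cls))
    short = n_train_total - sum(per_class.values())
    for _, cls in sorted(remainders, reverse=True)[:max(short, 0)]:
        per_class[cls] += 1
    split = [""] * n_total
    for cls in classes:
        idx = [i for i, lab in enumerate(labels) if lab == cls]
        order = rng.permutation(len(idx))
        chosen = {idx[j] for j in order[:per_class[cls]]}
        for i in idx:
            split[i] = "train" if i in chosen else "test"
    return split


def generate_cohort(n_benign: int, n_malignant: int, config: dict,
                    seed: int = 0) -> CohortResult:
    """Generate one series per lesion plus ground truth and a manifest.

    ``config`` is the ``phantom`` section of the run configuration.
    Deterministic: the same (counts, config, seed) reproduce the cohort
    byte-for-byte; lesion i always uses substream seed + i.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("need at least one lesion per class")
    cfg = config["phantom"] if "phantom" in config else config
    grid_shape = tuple(cfg["grid_shape"])
    times = np.arange(cfg["n_post"] + 1, dtype=float) * cfg["scan_interval"]
    breast = breast_region(grid_shape)
    labels = ["benign"] * n_benign + ["malignant"] * n_malignant

    series_list, masks, specs = [], [], []
    for i, cls in enumerate(labels):
        rng = np.random.default_rng(seed + i)
        kin = _draw_kinetics(cls, cfg, rng)
        radius = _draw(rng, cfg["radius_range"])
        rho_range = cfg["benign_rho_range"] if cls == "benign" else cfg["malignant_rho_range"]
        rho = _draw(rng, rho_range)
        # margin keeps every lesion voxel inside the eroded breast mask
        r_max = radius * (1.0 + rho)
        margin = r_max + cfg.get("placement_margin", 3.0)
        centre = _place_lesion(breast, margin, int(np.ceil(r_max)), rng)
        spec = LesionSpec(centre=centre, radius=radius, cls=cls, rho=rho, kinetics=kin)
        lesion_mask = make_lesion_mask(spec, grid_shape, seed=seed + i) & breast
        series = _simulate_series(spec, lesion_mask, breast, cfg, times, rng)
        series_list.append(series)
        masks.append(lesion_mask)
        specs.append(spec)

    split = _stratified_split(labels, cfg["train_frac"], np.random.default_rng(seed))
    manifest = pd.DataFrame({
        "lesion_id": [f"lesion_{i:03d}" for i in range(len(labels))],
        "series_path": ["auto"] * len(labels),
        "mask_path": ["auto"] * len(labels),
        "label": labels,
        "split": split,
    })
    return CohortResult(series=series_list, truth_masks=masks,
                        manifest=manifest, specs=specs)


def save_cohort(cohort: CohortResult, out_dir: str | Path) -> Path:
    """Write series/masks as NIfTI and the manifest CSV; returns the
    manifest path. Paths in the written manifest are relative to out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    for i, (series, mask) in enumerate(zip(cohort.series, cohort.truth_masks)):
        sp = f"lesion_{i:03d}_series.nii.gz"
        mp = f"lesion_{i:03d}_mask.nii.gz"
        write_dce_series(series, out_dir / sp)
        write_mask(mask, out_dir / mp, spacing=(series.dx, series.dy, series.slice_th))
        manifest.loc[i, "series_path"] = sp
        manifest.loc[i, "mask_path"] = mp
    manifest_path = out_dir / "manifest.csv"
    write_manifest(manifest, manifest_path)
    return manifest_path
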