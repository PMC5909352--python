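"""Run configuration: one flat YAML namespace per pipeline stage.

Every tunable exposed by the pipeline appears here with its default, so a
config file only needs to state the values it overrides.
"""
from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "phantom": {
        # grid and acquisition
        "grid_shape": [32, 32, 10],
        "dx": 1.3,            # in-plane voxel spacing, mm
        "dy": 1.3,
        "slice_th": 2.0,      # slice thickness, mm (= dz, no gap)
        "n_post": 9,          # post-contrast scans
        "scan_interval": 60.0,  # s between scans; times[0] = 0 (pre-contrast)
        # tissue background
        "tissue_baseline": 100.0,
        "tissue_amp_range": [0.02, 0.10],
        "air_baseline": 5.0,
        # lesion geometry (voxels; radius*(1+rho) must fit the slice stack)
        "radius_range": [2.2, 2.8],
        "benign_rho_range": [0.0, 0.15],
        "malignant_rho_range": [0.15, 0.4],
        # lesion kinetics
        "lesion_baseline_range": [80.0, 120.0],
        "benign_amp_range": [0.35, 0.8],
        "benign_k_in_range": [0.004, 0.010],
        "benign_k_out_range": [0.0, 0.0],          # persistent: peak at final scan
        "malignant_amp_range": [0.8, 1.5],
        "malignant_k_in_range": [0.008, 0.020],
        "malignant_peak_time_range": [120.0, 240.0],  # s; sets k_out (scans 2-4 of 9)
        "noise_frac": 0.02,   # Gaussian noise SD as fraction of baseline
        "train_frac": 2.0 / 3.0,
        "max_placement_retries": 100,
    },
    "segmentation": {
        "struct_radius": 2,       # ball structuring element, voxels
        "min_voi_size": 10,       # voxels
        "re_threshold": 0.3,      # C1: max relative enhancement must exceed this
        "otsu_bins": 256,
    },
    "features": {
        "perimeter_mm": False,    # multiply boundary count by in-plane spacing
    },
    "selection": {
        "bins": 10,               # equal-width discretisation for consistency
        "stall_limit": 5,         # best-first: consecutive non-improving expansions
        "cap": None,              # ranking cut-off (None = largest score drop)
    },
    "classify": {
        "confidence_factor": 0.25,
        "pruned": False,
        "min_leaf": 2,
        "kernel_estimator": False,
        "cv_folds": 10,
    },
    "fusion": {
        "grid_step": 0.05,
        "alpha_on_test": False,   # paper-faithful (test-set) alpha estimation
    },
    "evaluate": {
        "exact_cutoff": 25,       # McNemar: exact binomial below, chi-square above
    },
}

# Overlapping-class phantom conditions: benign lesions plateau (mild washout,
# hence segmentable) and amplitude/shape ranges overlap the malignant ones.
HARD_COHORT_OVERRIDES: dict = {
    "phantom": {
        "grid_shape": [32, 32, 12],
        "radius_range": [2.4, 3.2],
        "benign_amp_range": [0.4, 0.9],
        "benign_k_out_range": [1e-4, 6e-4],
        "malignant_amp_range": [0.6, 1.2],
        "malignant_peak_time_range": [120.0, 300.0],
        "benign_rho_range": [0.0, 0.3],
        "malignant_rho_range": [0.15, 0.55],
        "noise_frac": 0.05,
    },
}


def _deep_merge(base: dict, overlay: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in overlay.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def hard_cohort_config() -> dict:
    """Default config overlaid with the overlapping-class phantom conditions."""
    return _deep_merge(DEFAULTS, HARD_COHORT_OVERRIDES)


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, merged over the defaults.

    A top-level key ``profile: hard_cohort`` in the file (or ``path`` being
    the literal string ``"hard_cohort"``) selects the overlapping-class
    phantom preset before user overrides are applied.
    """
    if path is None:
        return default_config()
    if str(path) == "hard_cohort":
        return hard_cohort_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path!r} must contain a mapping")
    base = DEFAULTS
    if user.pop("profile", None) == "hard_cohort":
        base = hard_cohort_config()
    return _deep_merge(base, user)
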