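"""Weighted-probability fusion of the two channels.

A lesion with dynamic-channel probabilities (D_m, D_b) and morphological-
channel probabilities (M_m, M_b) is called malignant when

    alpha * D_m + beta * M_m  >  alpha * D_b + beta * M_b,   beta = 1 - alpha,

with exact ties resolved to malignant. The mixing coefficient alpha is
chosen on a grid over [0, 1] (step 0.05) by maximising leave-one-out
accuracy; because fusion has no per-lesion fitted parameters, the LOO
accuracy at a fixed alpha equals the plain accuracy. Within the
maximal-accuracy region, alpha* is the midpoint of the widest contiguous
plateau (ties between equally wide plateaus go to the higher-alpha one,
favouring the dynamic channel).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classify import ProbPair

__all__ = ["FusionDecision", "fuse", "select_alpha"]


@dataclass(frozen=True)
class FusionDecision:
    D_m: float
    D_b: float
    M_m: float
    M_b: float
    alpha: float
    beta: float
    score_m: float
    score_b: float
    predicted: str

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")


def fuse(D: ProbPair, M: ProbPair, alpha: float) -> FusionDecision:
    """Apply the weighted rule at a fixed alpha; ties go to malignant."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    beta = 1.0 - alpha
    score_m = alpha * D.p_malignant + beta * M.p_malignant
    score_b = alpha * D.p_benign + beta * M.p_benign
    # >= with tolerance: exact ties (incl. float round-off) go malignant
    predicted = "malignant" if score_m >= score_b - 1e-12 else "benign"
    return FusionDecision(D_m=D.p_malignant, D_b=D.p_benign,
                          M_m=M.p_malignant, M_b=M.p_benign,
                          alpha=alpha, beta=beta,
                          score_m=score_m, score_b=score_b, predicted=predicted)


def select_alpha(lesions: Sequence[tuple[ProbPair, ProbPair, str]],
                 grid_step: float = 0.05) -> tuple[float, np.ndarray, np.ndarray]:
    """Grid-search alpha by leave-one-out fused accuracy.

    ``lesions`` holds (D, M, label) per lesion. Returns
    (alpha_star, alpha grid, accuracy curve). The curve is piecewise
    constant in alpha with at most one breakpoint per lesion.
    """
    labels = [lab for _, _, lab in lesions]
    if len(set(labels)) < 2 or min(labels.count(c) for c in set(labels)) < 2:
        raise ValueError("alpha selection needs >= 2 lesions per class")
    n_steps = int(round(1.0 / grid_step))
    alphas = np.linspace(0.0, 1.0, n_steps + 1)
    accuracy = np.empty_like(alphas)
    for i, alpha in enumerate(alphas):
        correct = sum(fuse(D, M, float(alpha)).predicted == lab
                      for D, M, lab in lesions)
        accuracy[i] = correct / len(lesions)
    best = accuracy.max()
    at_max = np.isclose(accuracy, best, atol=1e-12)
    # widest contiguous run of grid points at the maximum; tie -> last run
    best_run, run_start = None, None
    for i, flag in enumerate(at_max):
        if flag and run_start is None:
            run_start = i
        if (not flag or i == len(at_max) - 1) and run_start is not None:
            run_end = i if flag else i - 1
            if best_run is None or (run_end - run_start) >= (best_run[1] - best_run[0]):
                best_run = (run_start, run_end)
            run_start = None
    lo, hi = best_run
    alpha_star = float(0.5 * (alphas[lo] + alphas[hi]))
    return alpha_star, alphas, accuracy
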