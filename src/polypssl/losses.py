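"""Training losses: supervised binary cross-entropy, perturbation-consistency
mean-squared error, their weighted combination, and the pseudo-label combined
loss.

All losses are means over pixels (and, for the consistency loss, over the
configured perturbations), so values are resolution-independent.  BCE accepts
soft targets in [0, 1], which the pseudo-label stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7

__all__ = [
    "LossReport",
    "supervised_bce",
    "consistency_loss",
    "overall_loss",
    "combined_loss",
    "lambda_schedule",
]


@dataclass
class LossReport:
    supervised: float
    consistency: float
    lambda_weight: float
    overall: float
    pseudo_term: float | None = None
    combined: float | None = None
    epoch: int = 0
    step: int = 0


def supervised_bce(pred: np.ndarray, target: np.ndarray, *, soft: bool = False) -> float:
    """Pixel-mean binary cross-entropy, -mean[y log y' + (1-y) log(1-y')].

    ``pred`` is clamped to [EPS, 1-EPS] so exact 0/1 predictions stay finite.
    ``soft=True`` permits targets anywhere in [0,1] (pseudo-labels); otherwise
    the target must be binary.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    if soft:
        if target.min() < 0 or target.max() > 1:
            raise ValueError("soft targets must lie in [0, 1]")
    elif not np.isin(target, (0.0, 1.0)).all():
        raise ValueError("target mask must be binary {0,1}")
    p = np.clip(pred, EPS, 1.0 - EPS)
    return float(-(target * np.log(p) + (1.0 - target) * np.log1p(-p)).mean())


def consistency_loss(bundle) -> float:
    """Mean over perturbations of the per-pixel-mean squared difference
    between the reference map and each aligned perturbed-branch map."""
    ref = np.asarray(bundle.reference, dtype=np.float64)
    aligned = list(bundle.aligned)
    if not aligned:
        raise ValueError("consistency bundle has no aligned maps")
    total = 0.0
    for a in aligned:
        a = np.asarray(a, dtype=np.float64)
        if a.shape != ref.shape:
            raise ValueError("aligned map shape differs from reference")
        total += float(((ref - a) ** 2).mean())
    return total / len(aligned)


def overall_loss(supervised: float, consistency: float, lambda_weight: float) -> float:
    """Weighted combination L + lambda * CL."""
    if lambda_weight < 0:
        raise ValueError("lambda_weight must be >= 0")
    for v in (supervised, consistency, lambda_weight):
        if not np.isfinite(v):
            raise ValueError("loss components must be finite")
    return float(supervised + lambda_weight * consistency)


def combined_loss(labeled_bce: float, n_labeled: int, pseudo_bce_sum: float, n_pseudo: int) -> float:
    """Set-normalised sum (1/|X|) * labeled term + (1/|Z|) * pseudo term.

    A term whose count is zero is dropped; both zero is an error.
    """
    if n_labeled < 0 or n_pseudo < 0:
        raise ValueError("counts must be >= 0")
    if n_labeled == 0 and n_pseudo == 0:
        raise ValueError("at least one of n_labeled, n_pseudo must be > 0")
    total = 0.0
    if n_labeled > 0:
        total += labeled_bce / n_labeled
    if n_pseudo > 0:
        total += pseudo_bce_sum / n_pseudo
    return float(total)


def lambda_schedule(epoch: int, lambda_max: float = 1.0, ramp_epochs: int = 40) -> float:
    """Sigmoid-shaped ramp of the consistency weight.

    lambda(0) = 0, lambda(e >= ramp_epochs) = lambda_max, non-decreasing;
    uses the standard exp(-5 (1 - e/ramp)^2) warm-up curve.
    """
    if epoch <= 0:
        return 0.0
    if ramp_epochs <= 0:
        return float(lambda_max)
    if epoch >= ramp_epochs:
        return float(lambda_max)
    frac = epoch / ramp_epochs
    return float(lambda_max * np.exp(-5.0 * (1.0 - frac) ** 2))
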