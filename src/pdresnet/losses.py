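"""Loss family for the binary gait classifier.

All losses are expressed through the *degree of correct prediction*

    p' = p+      if y = 1
    p' = 1 - p+  if y = 0,

the probability the network assigns to the true class; p' = 0.5 is a
fully random prediction and p' near 0 a hard or abnormal sample. On p'
the three losses are

    CE(p')  = -log p'
    FL(p')  = (1 - p')**gamma * (-log p')
    IFL(p') = 0                          if p' < tau
            = (1 - p'**2)  * (-log p')   otherwise,

with natural logarithms. The improved focal loss (IFL) keeps the focal
idea of down-weighting easy samples but uses the coefficient (1 - p'^2),
which decays slowly for hard samples and fast for easy ones, and it
assigns exactly zero loss (hence zero gradient) to outliers below the
threshold tau (default 0.05), so training ignores them entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LossParams",
    "degree_of_correct_prediction",
    "cross_entropy",
    "cross_entropy_grad",
    "focal_loss",
    "focal_loss_grad",
    "improved_focal_loss",
    "improved_focal_loss_grad",
    "epoch_loss",
    "get_loss",
    "LOSS_NAMES",
]

_EPS = float(np.finfo(float).eps)
LOSS_NAMES = ("cross_entropy", "focal", "improved_focal")


@dataclass(frozen=True)
class LossParams:
    """Focusing exponent gamma (focal loss) and outlier threshold tau (IFL)."""
    gamma: float = 2.0
    tau: float = 0.05

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not 0.0 <= self.tau < 0.5:
            raise ValueError(f"tau must be in [0, 0.5), got {self.tau}")


def _as_array(p, name: str, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(f"{name} must lie in [{lo}, {hi}]")
    return arr


def _maybe_scalar(out: np.ndarray, *inputs) -> float | np.ndarray:
    if all(np.ndim(x) == 0 for x in inputs):
        return float(out)
    return out


def degree_of_correct_prediction(p_plus, y):
    """p' = p+ when y = 1, 1 - p+ when y = 0."""
    p = _as_array(p_plus, "p_plus")
    yv = np.asarray(y)
    if not np.all(np.isin(yv, (0, 1))):
        raise ValueError("y must be 0 or 1")
    out = np.where(yv == 1, p, 1.0 - p)
    return _maybe_scalar(out, p_plus, y)


def _safe_log(p: np.ndarray) -> np.ndarray:
    clipped = np.maximum(p, _EPS)
    if np.any(p < _EPS):
        logger.debug("loss input clamped to machine epsilon before log")
    return np.log(clipped)


def cross_entropy(p_prime):
    """CE(p') = -log p' (p' = 0 clamped to machine epsilon)."""
    p = _as_array(p_prime, "p_prime")
    return _maybe_scalar(-_safe_log(p), p_prime)


def cross_entropy_grad(p_prime):
    p = np.maximum(_as_array(p_prime, "p_prime"), _EPS)
    return _maybe_scalar(-1.0 / p, p_prime)


def focal_loss(p_prime, gamma: float = 2.0):
    """FL(p') = (1 - p')**gamma * (-log p')."""
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    p = _as_array(p_prime, "p_prime")
    out = (1.0 - p) ** gamma * (-_safe_log(p))
    return _maybe_scalar(out, p_prime)


def focal_loss_grad(p_prime, gamma: float = 2.0):
    p = np.maximum(_as_array(p_prime, "p_prime"), _EPS)
    out = (gamma * (1.0 - p) ** (gamma - 1.0) * np.log(p)
           - (1.0 - p) ** gamma / p)
    return _maybe_scalar(out, p_prime)


def improved_focal_loss(p_prime, tau: float = 0.05):
    """IFL(p'): zero below tau, else (1 - p'^2) * (-log p').

    The boundary p' = tau uses the formula (the zero branch is a strict
    inequality).
    """
    if not 0.0 <= tau < 0.5:
        raise ValueError(f"tau must be in [0, 0.5), got {tau}")
    p = _as_array(p_prime, "p_prime")
    out = np.where(p < tau, 0.0, (1.0 - p ** 2) * (-_safe_log(np.maximum(p, tau))))
    return _maybe_scalar(out, p_prime)


def improved_focal_loss_grad(p_prime, tau: float = 0.05):
    """d IFL / dp' = 2 p' log p' - (1 - p'^2) / p', zero below tau."""
    p = _as_array(p_prime, "p_prime")
    safe = np.maximum(p, max(tau, _EPS))
    out = np.where(p < tau, 0.0,
                   2.0 * safe * np.log(safe) - (1.0 - safe ** 2) / safe)
    return _maybe_scalar(out, p_prime)


def epoch_loss(per_sample_losses) -> float:
    """Epoch loss is the arithmetic mean of the per-sample losses."""
    arr = np.asarray(per_sample_losses, dtype=float)
    if arr.size == 0:
        raise ValueError("epoch_loss requires a non-empty list of losses")
    return float(arr.mean())


def get_loss(name: str, params: LossParams | None = None):
    """Return ``(value_fn, grad_fn)`` for a loss selected by name.

    Both functions take p' (scalar or array) only; gamma/tau are bound
    from ``params``.
    """
    params = params or LossParams()
    if name == "cross_entropy":
        return cross_entropy, cross_entropy_grad
    if name == "focal":
        return (lambda p: focal_loss(p, params.gamma),
                lambda p: focal_loss_grad(p, params.gamma))
    if name == "improved_focal":
        return (lambda p: improved_focal_loss(p, params.tau),
                lambda p: improved_focal_loss_grad(p, params.tau))
    raise ValueError(f"unknown loss {name!r}; choose one of {LOSS_NAMES}")
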