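"""Segmentation losses: soft Dice, cross-entropy, and the multi-network total.

Each network (the multi-modality network and the two single-modality
networks) is optimized with L = L_Dice + L_CE over its own class partition.
The total joint objective balances them with a weight lambda in [0, 1]:

    L_T = lambda * L_MMN + (1 - lambda)/2 * (L_SMN_T1c + L_SMN_Flair)

Conventions: soft Dice is averaged over the Np classes with a small additive
smoothing term so empty classes contribute loss 0 rather than 0/0; the
cross-entropy is normalized by Np*M (class count times voxel count), so a
uniform prediction over 4 classes scores ln(4)/4.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError, InvalidShapeError
from .nn import Tensor, softmax

__all__ = ["LossTerms", "dice_loss", "ce_loss", "compound_loss", "total_loss"]

DICE_EPS = 1e-5
LOG_FLOOR = 1e-12


def _check_pair(logits: Tensor, onehot: np.ndarray) -> np.ndarray:
    onehot = np.asarray(onehot, dtype=np.float32)
    if logits.shape != onehot.shape:
        raise InvalidShapeError(
            f"logits shape {logits.shape} != target shape {onehot.shape}")
    if logits.ndim != 5:
        raise InvalidShapeError(
            f"expected rank-5 (batch, classes, D, H, W), got rank {logits.ndim}")
    return onehot


def dice_loss(logits: Tensor, onehot: np.ndarray, eps: float = DICE_EPS) -> Tensor:
    """1 minus the class-averaged soft Dice overlap.

    Softmax is taken over the class axis; per class c the overlap is
    2*sum(p_c * t_c) / (sum(p_c) + sum(t_c)), summed over batch and voxels,
    with `eps` added to numerator and denominator.
    """
    onehot = _check_pair(logits, onehot)
    probs = softmax(logits, axis=1)
    axes = (0, 2, 3, 4)
    target = Tensor(onehot)
    inter = (probs * target).sum(axis=axes)
    denom = probs.sum(axis=axes) + Tensor(onehot.sum(axis=axes))
    dice_per_class = (inter * 2.0 + eps) / (denom + eps)
    return 1.0 - dice_per_class.mean()


def ce_loss(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Cross-entropy normalized by (class count * voxel count)."""
    onehot = _check_pair(logits, onehot)
    n_classes = logits.shape[1]
    m_voxels = int(np.prod(logits.shape) // n_classes)
    probs = softmax(logits, axis=1)
    ll = (Tensor(onehot) * probs.log(floor=LOG_FLOOR)).sum()
    return -ll * (1.0 / (n_classes * m_voxels))


def compound_loss(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Per-network training loss: Dice + CE with equal unit weights."""
    return dice_loss(logits, onehot) + ce_loss(logits, onehot)


@dataclass
class LossTerms:
    """Per-network loss components and the lambda-weighted total."""

    l_mmn: float
    l_smn_t1c: float
    l_smn_flair: float
    lam: float
    l_total: float

    def as_dict(self) -> dict[str, float]:
        return {"l_mmn": self.l_mmn, "l_smn_t1c": self.l_smn_t1c,
                "l_smn_flair": self.l_smn_flair, "lambda": self.lam,
                "l_total": self.l_total}


def total_loss(l_mmn: Tensor | float, l_smn_t1c: Tensor | float,
               l_smn_flair: Tensor | float, lam: float):
    """Combine per-network compound losses with weight `lam` in [0, 1].

    Returns the total with the same type as the inputs (Tensor in the
    training graph, float for reporting).
    """
    if not (0.0 <= lam <= 1.0):
        raise InvalidConfigError(f"lambda must lie in [0, 1], got {lam}")
    return l_mmn * lam + (l_smn_t1c + l_smn_flair) * ((1.0 - lam) / 2.0)


def loss_terms(l_mmn: float, l_smn_t1c: float, l_smn_flair: float,
               lam: float) -> LossTerms:
    total = total_loss(l_mmn, l_smn_t1c, l_smn_flair, lam)
    return LossTerms(l_mmn=float(l_mmn), l_smn_t1c=float(l_smn_t1c),
                     l_smn_flair=float(l_smn_flair), lam=float(lam),
                     l_total=float(total))
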