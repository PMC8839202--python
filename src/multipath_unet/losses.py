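"""Segmentation losses and metrics.

Training objective: the unweighted sum of a Tversky loss (alpha = beta = 0.5,
where it reduces to a smoothed complement of the Dice similarity coefficient)
and the mean per-pixel categorical cross-entropy.  Evaluation metric: the
Dice similarity coefficient DSC = 2TP / (2TP + FP + FN) computed pixel-wise.

Confusion counts are real-valued so the same formulas serve both hard masks
(exact pixel counts) and soft probability maps (differentiable counts used in
the loss).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: probabilities are clipped to [CLIP_EPS, 1 - CLIP_EPS] inside cross-entropy
CLIP_EPS = 1e-7


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-wise true-positive / false-positive / false-negative counts."""

    tp: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0 or self.fn < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class TverskyParams:
    """Asymmetric FP/FN weights of the Tversky index plus a smoothing term."""

    alpha: float = 0.5
    beta: float = 0.5
    smooth: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.smooth < 0:
            raise ValueError("Tversky parameters must be nonnegative")


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Confusion counts between a prediction and a binary truth mask.

    ``pred`` may be a hard {0,1} mask (exact counts) or a foreground
    probability map in [0,1] (soft counts: TP = sum p*t, FP = sum p*(1-t),
    FN = sum (1-p)*t, which coincide with the hard counts at p in {0,1}).
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return ConfusionCounts(tp=float((p * t).sum()),
                           fp=float((p * (1.0 - t)).sum()),
                           fn=float(((1.0 - p) * t).sum()))


def dice_similarity(c: ConfusionCounts) -> float:
    """DSC = 2TP / (2TP + FP + FN); 1.0 when both masks are empty."""
    denom = 2.0 * c.tp + c.fp + c.fn
    if denom == 0.0:
        return 1.0
    return 2.0 * c.tp / denom


def per_class_dice(pred_mask: np.ndarray, truth: np.ndarray,
                   num_classes: int = 2) -> np.ndarray:
    """DSC per class, treating each class in turn as the positive one."""
    pred_mask = np.asarray(pred_mask)
    truth = np.asarray(truth)
    return np.array([
        dice_similarity(confusion_counts(pred_mask == k, truth == k))
        for k in range(num_classes)])


def tversky_loss(pred: np.ndarray, truth: np.ndarray,
                 params: TverskyParams = TverskyParams()) -> float:
    """1 - (TP + s) / (TP + alpha*FP + beta*FN + s) with soft counts."""
    c = confusion_counts(pred, truth)
    return 1.0 - (c.tp + params.smooth) / (
        c.tp + params.alpha * c.fp + params.beta * c.fn + params.smooth)


def cross_entropy_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean per-pixel categorical cross-entropy.

    ``pred`` has axes (class, row, column) or (example, class, row, column);
    ``truth`` holds integer class labels with matching spatial axes.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth)
    if p.ndim == 3:
        p, t = p[None], t[None]
    if p.ndim != 4 or t.shape != (p.shape[0],) + p.shape[2:]:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth "
                         f"{truth.shape}")
    p = np.clip(p, CLIP_EPS, 1.0 - CLIP_EPS)
    p_true = np.take_along_axis(p, t[:, None].astype(int), axis=1)[:, 0]
    return float(-np.log(p_true).mean())


def combined_loss(pred: np.ndarray, truth: np.ndarray,
                  params: TverskyParams = TverskyParams()) -> float:
    """Tversky + cross-entropy (unweighted sum).

    The Tversky term uses the foreground-class probability channel; both
    terms are computed per image and averaged over the batch.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth)
    if p.ndim == 3:
        p, t = p[None], t[None]
    tv = float(np.mean([tversky_loss(p[i, 1], t[i], params)
                        for i in range(p.shape[0])]))
    return tv + cross_entropy_loss(p, t)


def combined_loss_and_grad(probs: np.ndarray, truth: np.ndarray,
                           params: TverskyParams = TverskyParams()
                           ) -> tuple[float, np.ndarray]:
    """Combined loss plus its gradient with respect to the probability map.

    Returns ``(loss, dprobs)`` where ``dprobs`` has the shape of ``probs``
    (example, class, row, column); feed it to the model's backward pass,
    which chains through the softmax.
    """
    p = np.asarray(probs, dtype=float)
    t = np.asarray(truth)
    n = p.shape[0]
    npix = p.shape[2] * p.shape[3]
    tfl = t.astype(float)

    dprobs = np.zeros_like(p)

    # cross-entropy term (mean over batch, classes gathered by the label)
    pc = np.clip(p, CLIP_EPS, 1.0 - CLIP_EPS)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, t[:, None].astype(int), 1.0, axis=1)
    ce = float(-(onehot * np.log(pc)).sum() / (n * npix))
    dprobs += -(onehot / pc) / (n * npix)

    # Tversky term on the foreground channel, per image then batch mean
    tv_total = 0.0
    for i in range(n):
        pf, ti = p[i, 1], tfl[i]
        tp = float((pf * ti).sum())
        fp = float((pf * (1.0 - ti)).sum())
        fn = float(((1.0 - pf) * ti).sum())
        num = tp + params.smooth
        den = tp + params.alpha * fp + params.beta * fn + params.smooth
        tv_total += 1.0 - num / den
        # den depends on pf through TP (+t), FP (+alpha*(1-t)) and FN (-beta*t)
        dden = ti + params.alpha * (1.0 - ti) - params.beta * ti
        dprobs[i, 1] += -(ti * den - num * dden) / (den * den) / n
    return tv_total / n + ce, dprobs
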