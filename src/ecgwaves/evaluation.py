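"""Classification and segmentation metrics, and deterministic
train/validation/test splitting.

The F1 score is the harmonic mean of sensitivity (recall) and positive
predictive value (precision)::

    F1 = 2 * Sensitivity * PPV / (Sensitivity + PPV)

Segmentation overlap is scored with the smoothed Dice coefficient and
Jaccard index (IoU); the additive ``smooth`` constant stabilises classes
that are absent from both masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np

from .errors import UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "sensitivity",
    "specificity",
    "ppv",
    "f1_score",
    "dice_jaccard",
    "macro_dice_jaccard",
    "split_dataset",
    "SPLIT_NAMES",
]

SPLIT_NAMES = ("TRAIN", "VAL", "TEST")
_SPLIT_FRACTIONS = (0.6, 0.2, 0.2)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN container from which all reported metrics derive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts must not all be zero")


def sensitivity(c: ConfusionCounts) -> float:
    """tp / (tp + fn) — recall with respect to the positive class."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: tp + fn == 0")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """tn / (tn + fp)."""
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: tn + fp == 0")
    return c.tn / (c.tn + c.fp)


def ppv(c: ConfusionCounts) -> float:
    """tp / (tp + fp) — precision."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("ppv undefined: tp + fp == 0")
    return c.tp / (c.tp + c.fp)


def f1_score(sens: float, ppv_val: float) -> float:
    """Harmonic mean of sensitivity and PPV.

    Defined as 0 when both inputs are 0 (the limit of the harmonic mean,
    and the score a degenerate all-negative classifier earns).
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= ppv_val <= 1.0):
        raise ValueError("sensitivity and PPV must lie in [0, 1]")
    if sens == 0.0 and ppv_val == 0.0:
        return 0.0
    return 2.0 * sens * ppv_val / (sens + ppv_val)


def dice_jaccard(
    pred_mask: np.ndarray,
    truth_mask: np.ndarray,
    class_id: int,
    smooth: float = 1.0,
) -> tuple[float, float]:
    """Smoothed Dice and Jaccard (IoU) for one class.

    dice = (2|A&B| + s) / (|A| + |B| + s);  iou = (|A&B| + s) / (|A|B| + s)
    where A, B are the binarised class supports.  With ``smooth`` = 0 the
    identities dice = 2*iou / (1 + iou) hold on non-degenerate inputs.
    """
    pred_mask = np.asarray(pred_mask)
    truth_mask = np.asarray(truth_mask)
    if pred_mask.shape != truth_mask.shape:
        raise ValueError("pred and truth masks must have the same shape")
    a = pred_mask == class_id
    b = truth_mask == class_id
    inter = float(np.logical_and(a, b).sum())
    na, nb = float(a.sum()), float(b.sum())
    union = na + nb - inter
    dice_den = na + nb + smooth
    iou_den = union + smooth
    if dice_den == 0 or iou_den == 0:
        raise UndefinedMetricError(
            "dice/iou undefined: empty masks with smooth=0"
        )
    return (2.0 * inter + smooth) / dice_den, (inter + smooth) / iou_den


def macro_dice_jaccard(
    pred_mask: np.ndarray,
    truth_mask: np.ndarray,
    class_ids: Sequence[int] = range(1, 8),
    smooth: float = 1.0,
) -> tuple[dict[int, tuple[float, float]], tuple[float, float]]:
    """Per-class and macro-averaged (dice, iou) over the wave classes
    (background excluded by default)."""
    per_class = {
        cid: dice_jaccard(pred_mask, truth_mask, cid, smooth)
        for cid in class_ids
    }
    dices = [d for d, _ in per_class.values()]
    ious = [i for _, i in per_class.values()]
    return per_class, (float(np.mean(dices)), float(np.mean(ious)))


def _apportion(n: int) -> tuple[int, int, int]:
    """60:20:20 sizes within +-1 record (largest remainder, train-first)."""
    sizes = [int(np.floor(f * n)) for f in _SPLIT_FRACTIONS]
    rem = [f * n - s for f, s in zip(_SPLIT_FRACTIONS, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(rem))
        sizes[i] += 1
        rem[i] = -1.0
    return tuple(sizes)


def split_dataset(
    manifest: Sequence[Mapping] | Sequence[Hashable],
    seed: int,
    stratify_key: str | None = "rhythm",
    group_by: str | None = None,
) -> dict:
    """Deterministic, stratified 60:20:20 train/validation/test split.

    ``manifest`` is a sequence of record dicts (or bare ids).  Records
    are shuffled with a generator seeded by ``seed`` and partitioned
    within each stratum so per-class proportions track the global 60:20:20
    to within rounding.  ``group_by`` names a key whose equal values must
    never straddle splits (e.g. a subject id); groups are then assigned
    as blocks, unstratified.

    Returns a mapping record-id -> "TRAIN" | "VAL" | "TEST".
    """
    records = list(manifest)
    if len(records) < 5:
        raise ValueError("need at least 5 records for a 60:20:20 split")

    def rid(rec):
        return rec["id"] if isinstance(rec, Mapping) else rec

    rng = np.random.default_rng([int(seed), 17])
    assignment: dict = {}

    if group_by is not None:
        groups: dict = {}
        for rec in records:
            groups.setdefault(rec[group_by], []).append(rid(rec))
        keys = sorted(groups, key=str)
        rng.shuffle(keys)
        sizes = _apportion(len(keys))
        bounds = np.cumsum((0,) + sizes)
        for si, name in enumerate(SPLIT_NAMES):
            for key in keys[bounds[si]:bounds[si + 1]]:
                for record_id in groups[key]:
                    assignment[record_id] = name
        return assignment

    strata: dict = {}
    for rec in records:
        key = rec.get(stratify_key) if (
            stratify_key and isinstance(rec, Mapping)
        ) else None
        strata.setdefault(key, []).append(rid(rec))

    # distribute rounding remainders across strata so the global split is
    # exactly 60:20:20
    totals = np.zeros(3, dtype=int)
    target = np.array(_apportion(len(records)))
    for key in sorted(strata, key=str):
        ids = strata[key]
        order = rng.permutation(len(ids))
        ids = [ids[i] for i in order]
        sizes = list(_apportion(len(ids)))
        for si in range(3):  # nudge toward the global target when over
            while totals[si] + sizes[si] > target[si]:
                j = int(np.argmax(target - totals - sizes))
                sizes[si] -= 1
                sizes[j] += 1
        bounds = np.cumsum([0] + sizes)
        for si, name in enumerate(SPLIT_NAMES):
            for record_id in ids[bounds[si]:bounds[si + 1]]:
                assignment[record_id] = name
        totals += np.array(sizes)
    return assignment
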