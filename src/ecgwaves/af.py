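"""Rule-based atrial fibrillation detection from wave-class label
sequences.

The rule mirrors how a clinician reads a rhythm strip: locate the QRS
complexes (clusters of class-3 samples), measure the irregularity of the
R-R intervals, and look for a P wave in the ~250 ms window before each
QRS.  An ECG is called AF when P waves precede fewer than a fraction X of
the QRS complexes AND the R-R standard deviation exceeds Y ms (strict
inequalities, conjunction).  X and Y are fitted by exhaustive grid search
maximising F1 on a validation set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientBeatsError, UndefinedMetricError
from .evaluation import ConfusionCounts, f1_score, ppv, sensitivity
from .synthesis import RhythmType, WaveClass

__all__ = [
    "QrsCluster",
    "AfThresholds",
    "RhythmCall",
    "find_qrs_clusters",
    "rr_sd",
    "p_preceded_fraction",
    "classify_rhythm",
    "extract_features",
    "fit_thresholds",
    "X_GRID",
    "Y_GRID",
]

#: Brute-force search lattice for the two thresholds: 21 x 31 = 651 cells.
X_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 2)
Y_GRID = np.arange(0.0, 300.0 + 1e-9, 10.0)


@dataclass(frozen=True)
class QrsCluster:
    """Half-open [onset, offset) run of QRS-labelled samples."""

    onset: int
    offset: int
    lead: str = "II"

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")


@dataclass(frozen=True)
class AfThresholds:
    """Fitted decision thresholds: X on the P-preceded fraction, Y on the
    R-R standard deviation (ms)."""

    x_min_p_fraction: float
    y_rr_sd: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_min_p_fraction <= 1.0):
            raise ValueError("x_min_p_fraction must lie in [0, 1]")
        if not np.isfinite(self.y_rr_sd) or self.y_rr_sd < 0:
            raise ValueError("y_rr_sd must be finite and >= 0")


@dataclass(frozen=True)
class RhythmCall:
    call: RhythmType
    p_fraction: float
    rr_sd: float
    n_qrs: int


def _runs(bool_arr: np.ndarray) -> list[tuple[int, int]]:
    """Half-open runs of True."""
    padded = np.diff(np.concatenate(([0], bool_arr.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_qrs_clusters(
    labels: Sequence[int] | np.ndarray,
    fs: float,
    min_dur_ms: float = 40.0,
    merge_gap_ms: float = 20.0,
    lead: str = "II",
) -> list[QrsCluster]:
    """Maximal runs of QRS-class samples, with short-gap merging.

    Runs separated by gaps shorter than ``merge_gap_ms`` are merged
    (a segmentation model may drop a few samples mid-complex), then runs
    shorter than ``min_dur_ms`` are discarded as noise.
    """
    labels = np.asarray(labels)
    runs = _runs(labels == int(WaveClass.QRS))
    if not runs:
        return []
    merge_gap = merge_gap_ms * fs / 1000.0
    merged = [list(runs[0])]
    for start, end in runs[1:]:
        if start - merged[-1][1] < merge_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    min_len = min_dur_ms * fs / 1000.0
    return [
        QrsCluster(onset=a, offset=b, lead=lead)
        for a, b in merged
        if (b - a) >= min_len
    ]


def rr_sd(clusters: Sequence[QrsCluster], fs: float) -> float:
    """Population standard deviation of onset-to-onset intervals, ms."""
    if len(clusters) < 3:
        raise InsufficientBeatsError(
            "R-R standard deviation needs >= 3 QRS clusters"
        )
    onsets = np.array([c.onset for c in clusters], dtype=np.float64)
    intervals_ms = np.diff(onsets) / fs * 1000.0
    return float(np.std(intervals_ms))


def p_preceded_fraction(
    labels: Sequence[int] | np.ndarray,
    clusters: Sequence[QrsCluster],
    fs: float,
    window_ms: float = 250.0,
    min_p_dur_ms: float = 20.0,
) -> float:
    """Fraction of QRS complexes preceded by a P wave.

    For each cluster the window [onset - window, onset) is searched for a
    run of P-wave samples of at least ``min_p_dur_ms``; runs are clipped
    to the window before measuring.  The first cluster is skipped when
    its window would start before sample 0.
    """
    labels = np.asarray(labels)
    window = int(round(window_ms * fs / 1000.0))
    min_p = min_p_dur_ms * fs / 1000.0
    eligible = 0
    hits = 0
    p_like = labels == int(WaveClass.P_WAVE)
    for cluster in clusters:
        lo = cluster.onset - window
        if lo < 0:
            continue
        eligible += 1
        seg = p_like[lo:cluster.onset]
        if any((b - a) >= min_p for a, b in _runs(seg)):
            hits += 1
    if eligible == 0:
        raise UndefinedMetricError("no QRS cluster has a full pre-QRS window")
    return hits / eligible


def classify_rhythm(
    p_fraction: float,
    rr_sd_val: float,
    thresholds: AfThresholds,
    n_qrs: int = 0,
) -> RhythmCall:
    """AF iff p_fraction < X and rr_sd > Y (strict, conjunction)."""
    is_af = (p_fraction < thresholds.x_min_p_fraction) and (
        rr_sd_val > thresholds.y_rr_sd
    )
    return RhythmCall(
        call=RhythmType.AF if is_af else RhythmType.SR,
        p_fraction=float(p_fraction),
        rr_sd=float(rr_sd_val),
        n_qrs=n_qrs,
    )


def extract_features(
    labels: Sequence[int] | np.ndarray, fs: float
) -> tuple[float, float, int]:
    """(p_fraction, rr_sd_ms, n_qrs) for one label sequence.

    A sequence with fewer than 3 QRS clusters gets rr_sd = 0 (no evidence
    of irregularity can be asserted, so the AF rule can never fire), and
    p_fraction = 1 when no cluster has a full pre-QRS window.
    """
    clusters = find_qrs_clusters(labels, fs)
    n = len(clusters)
    sd = rr_sd(clusters, fs) if n >= 3 else 0.0
    try:
        p_frac = p_preceded_fraction(labels, clusters, fs) if n else 1.0
    except UndefinedMetricError:
        p_frac = 1.0
    return p_frac, sd, n


def fit_thresholds(
    validation: Iterable[tuple[tuple[float, float], RhythmType | str]],
) -> AfThresholds:
    """Exhaustive search over the 651-cell (X, Y) grid maximising F1 with
    respect to the AF class; ties broken by smaller X, then smaller Y.

    ``validation`` yields ((p_fraction, rr_sd_ms), truth) pairs and must
    contain both classes.
    """
    feats = []
    truths = []
    for (p_frac, sd), truth in validation:
        feats.append((float(p_frac), float(sd)))
        truths.append(RhythmType(truth))
    if len(set(truths)) < 2:
        raise ValueError("validation set must contain both SR and AF")

    p = np.array([f[0] for f in feats])
    sd = np.array([f[1] for f in feats])
    is_af = np.array([t is RhythmType.AF for t in truths])

    # predictions for every grid cell at once: (nx, ny, n_records)
    pred = (p[None, None, :] < X_GRID[:, None, None]) & (
        sd[None, None, :] > Y_GRID[None, :, None]
    )
    tp = (pred & is_af).sum(axis=2)
    fp = (pred & ~is_af).sum(axis=2)
    fn = (~pred & is_af).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2.0 * tp / (2.0 * tp + fp + fn)
    f1 = np.nan_to_num(f1, nan=0.0)

    best = f1.max()
    xi, yi = np.argwhere(f1 >= best - 1e-12)[0]  # row-major: smallest X then Y
    return AfThresholds(
        x_min_p_fraction=float(X_GRID[xi]), y_rr_sd=float(Y_GRID[yi])
    )
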