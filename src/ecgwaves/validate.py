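"""Structural sanity checks for generated records.

These encode the contract every synthetic record must satisfy: aligned
shapes, label codes in 0..7, no atrial activity (P / P-R classes) in AF,
and the physiological ordering P -> P-R -> QRS -> ST -> T around every
fully contained beat.
"""

from __future__ import annotations

import numpy as np

from .af import find_qrs_clusters
from .synthesis import LabelledSignal, RhythmType, WaveClass

__all__ = ["check_record"]


def check_record(signal: LabelledSignal) -> list[str]:
    """Return a list of violated invariants (empty = record is valid)."""
    problems: list[str] = []
    s, l = signal.samples, signal.labels
    if s.shape != l.shape:
        return [f"shape mismatch: samples {s.shape} vs labels {l.shape}"]
    if s.shape[1] != signal.config.n_samples:
        problems.append("label length != sampling_rate * duration")
    if l.min() < 0 or l.max() > 7:
        problems.append("label codes outside 0..7")
    if not np.all(l == l[0]):
        problems.append("per-lead label rows differ")

    labels = l[0]
    fs = signal.config.sampling_rate
    is_af = signal.rhythm_label is RhythmType.AF
    if is_af and np.isin(
        labels, [int(WaveClass.P_WAVE), int(WaveClass.PR_INTERVAL)]
    ).any():
        problems.append("AF record contains P-wave or P-R samples")

    clusters = find_qrs_clusters(labels, fs)
    if len(clusters) < 2:
        problems.append("fewer than 2 QRS clusters")
        return problems

    pre = int(round(0.300 * fs))   # room for P + P-R before the QRS
    post = int(round(0.450 * fs))  # room for ST + T after it
    n = len(labels)
    onsets = [c.onset for c in clusters]
    for ci, c in enumerate(clusters):
        if c.onset - pre < 0 or c.offset + post > n:
            continue  # truncated first/last beat is exempt
        nxt = onsets[ci + 1] if ci + 1 < len(onsets) else n
        if nxt < c.offset + post:
            continue  # short R-R: next beat legitimately buries the ST/T
        if not is_af:
            if labels[c.onset - 1] != int(WaveClass.PR_INTERVAL):
                problems.append(f"QRS at {c.onset} not preceded by P-R run")
                continue
            pr_start = c.onset
            while pr_start > 0 and labels[pr_start - 1] == int(
                WaveClass.PR_INTERVAL
            ):
                pr_start -= 1
            if labels[pr_start - 1] not in (
                int(WaveClass.P_WAVE), int(WaveClass.TP_OVERLAP)
            ):
                problems.append(f"P-R run at {pr_start} not preceded by P wave")
        st_start = c.offset
        # a previous beat's T wave may overhang the QRS offset (label
        # precedence gives T the collision) — skip any remnant T samples
        while st_start < n and labels[st_start] == int(WaveClass.T_WAVE):
            st_start += 1
        if st_start >= n or labels[st_start] != int(WaveClass.ST_SEGMENT):
            problems.append(f"QRS at {c.onset} not followed by ST segment")
            continue
        st_end = st_start
        while st_end < n and labels[st_end] == int(WaveClass.ST_SEGMENT):
            st_end += 1
        if st_end < n and labels[st_end] != int(WaveClass.T_WAVE):
            problems.append(f"ST segment at {c.offset} not followed by T wave")
    return problems
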