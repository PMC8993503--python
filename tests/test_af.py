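import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgwaves import (
    AfThresholds,
    InsufficientBeatsError,
    QrsCluster,
    RhythmType,
    UndefinedMetricError,
    classify_rhythm,
    find_qrs_clusters,
    fit_thresholds,
    p_preceded_fraction,
    rr_sd,
)
from ecgwaves.af import X_GRID, Y_GRID


def naive_clusters(labels, fs, min_dur_ms=40.0, merge_gap_ms=20.0):
    """Independent run-length oracle: explicit sample-by-sample scan."""
    runs = []
    start = None
    for i, v in enumerate(list(labels) + [0]):
        if v == 3 and start is None:
            start = i
        elif v != 3 and start is not None:
            runs.append([start, i])
            start = None
    merged = []
    gap = merge_gap_ms * fs / 1000.0
    for run in runs:
        if merged and run[0] - merged[-1][1] < gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    min_len = min_dur_ms * fs / 1000.0
    return [(a, b) for a, b in merged if b - a >= min_len]


class TestFindQrsClusters:
    def test_two_well_separated_runs(self):
        labels = np.zeros(5000, dtype=np.uint8)
        labels[100:140] = 3
        labels[600:645] = 3
        clusters = find_qrs_clusters(labels, 500.0)
        assert [(c.onset, c.offset) for c in clusters] == [(100, 140),
                                                           (600, 645)]

    def test_all_background_gives_empty_list(self):
        assert find_qrs_clusters(np.zeros(1000, dtype=np.uint8), 500.0) == []

    def test_short_gap_merged(self):
        labels = np.zeros(1000, dtype=np.uint8)
        labels[100:110] = 3
        labels[112:150] = 3  # 2-sample gap = 4 ms < 20 ms
        clusters = find_qrs_clusters(labels, 500.0)
        assert [(c.onset, c.offset) for c in clusters] == [(100, 150)]

    def test_short_runs_discarded(self):
        labels = np.zeros(1000, dtype=np.uint8)
        labels[100:110] = 3  # 20 ms < 40 ms minimum
        assert find_qrs_clusters(labels, 500.0) == []

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 7), min_size=1, max_size=400),
           st.sampled_from([250.0, 500.0]))
    def test_matches_naive_oracle(self, labels, fs):
        got = [(c.onset, c.offset)
               for c in find_qrs_clusters(labels, fs)]
        assert got == naive_clusters(labels, fs)


class TestRrSd:
    def test_regular_onsets_have_zero_sd(self):
        clusters = [QrsCluster(o, o + 40) for o in (0, 500, 1000)]
        assert rr_sd(clusters, 500.0) == 0.0

    def test_two_point_population_sd(self):
        # intervals 700 ms and 900 ms -> population sd 100 ms
        clusters = [QrsCluster(o, o + 40) for o in (0, 350, 800)]
        assert rr_sd(clusters, 500.0) == pytest.approx(100.0)

    def test_matches_direct_formula(self, rng):
        onsets = np.sort(rng.choice(20000, size=10, replace=False))
        clusters = [QrsCluster(int(o), int(o) + 10) for o in onsets]
        x = np.diff(onsets) / 500.0 * 1000.0
        expected = np.sqrt(np.mean((x - x.mean()) ** 2))
        assert rr_sd(clusters, 500.0) == pytest.approx(expected)

    def test_fewer_than_three_clusters_signalled(self):
        clusters = [QrsCluster(0, 40), QrsCluster(500, 540)]
        with pytest.raises(InsufficientBeatsError):
            rr_sd(clusters, 500.0)


class TestPPrecededFraction:
    @staticmethod
    def _sequence_with_p(n, qrs_onsets, p_for, fs=500.0):
        labels = np.zeros(n, dtype=np.uint8)
        for onset in qrs_onsets:
            labels[onset:onset + 40] = 3
        for onset in p_for:
            # 60 ms P wave ending 120 ms before the QRS onset
            p_end = onset - int(0.120 * fs)
            labels[p_end - int(0.060 * fs):p_end] = 1
        return labels

    def test_every_qrs_preceded(self):
        onsets = [500, 1000, 1500, 2000]
        labels = self._sequence_with_p(3000, onsets, onsets)
        clusters = find_qrs_clusters(labels, 500.0)
        assert p_preceded_fraction(labels, clusters, 500.0) == 1.0

    def test_no_p_anywhere(self):
        onsets = [500, 1000, 1500]
        labels = self._sequence_with_p(3000, onsets, [])
        clusters = find_qrs_clusters(labels, 500.0)
        assert p_preceded_fraction(labels, clusters, 500.0) == 0.0

    def test_half_preceded(self):
        onsets = [500, 1000, 1500, 2000]
        labels = self._sequence_with_p(3000, onsets, onsets[:2])
        clusters = find_qrs_clusters(labels, 500.0)
        assert p_preceded_fraction(labels, clusters, 500.0) == 0.5

    def test_first_cluster_skipped_when_window_precedes_start(self):
        onsets = [50, 1000, 1500]  # 250 ms window would start at -75
        labels = self._sequence_with_p(3000, onsets, onsets[1:])
        clusters = find_qrs_clusters(labels, 500.0)
        assert p_preceded_fraction(labels, clusters, 500.0) == 1.0

    def test_no_eligible_cluster_signalled(self):
        labels = np.zeros(200, dtype=np.uint8)
        labels[20:60] = 3
        clusters = find_qrs_clusters(labels, 500.0)
        with pytest.raises(UndefinedMetricError):
            p_preceded_fraction(labels, clusters, 500.0)


class TestClassifyRhythm:
    thresholds = AfThresholds(x_min_p_fraction=0.5, y_rr_sd=120.0)

    def test_clear_sinus(self):
        call = classify_rhythm(1.0, 5.0, self.thresholds)
        assert call.call is RhythmType.SR

    def test_clear_af(self):
        call = classify_rhythm(0.0, 200.0, self.thresholds)
        assert call.call is RhythmType.AF

    def test_boundary_is_strict(self):
        # rr_sd exactly Y fails the "> Y" condition
        assert classify_rhythm(0.0, 120.0, self.thresholds).call is RhythmType.SR
        # p_fraction exactly X fails the "< X" condition
        assert classify_rhythm(0.5, 200.0, self.thresholds).call is RhythmType.SR

    def test_conjunction_required(self):
        assert classify_rhythm(0.0, 5.0, self.thresholds).call is RhythmType.SR
        assert classify_rhythm(1.0, 200.0, self.thresholds).call is RhythmType.SR


def _grid_oracle(validation):
    """Independent exhaustive enumeration of the full 651-cell grid."""
    best = (-1.0, None)
    for x in X_GRID:
        for y in Y_GRID:
            tp = fp = fn = 0
            for (p, sd), truth in validation:
                pred_af = p < x and sd > y
                truth_af = RhythmType(truth) is RhythmType.AF
                tp += pred_af and truth_af
                fp += pred_af and not truth_af
                fn += (not pred_af) and truth_af
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            if f1 > best[0] + 1e-12:
                best = (f1, (x, y))
    return best


class TestFitThresholds:
    separable = (
        [((0.0, 200.0), "AF")] * 5 + [((1.0, 10.0), "SR")] * 5
    )

    def test_separable_set_reaches_f1_one(self):
        th = fit_thresholds(self.separable)
        correct = sum(
            (classify_rhythm(p, sd, th).call.value == truth)
            for (p, sd), truth in self.separable
        )
        assert correct == len(self.separable)

    def test_deterministic(self):
        assert fit_thresholds(self.separable) == fit_thresholds(self.separable)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_thresholds([((0.0, 200.0), "AF")] * 4)

    def test_attains_independent_grid_maximum(self, rng):
        validation = []
        for _ in range(40):
            if rng.random() < 0.5:
                validation.append(
                    ((rng.uniform(0, 0.4), rng.uniform(60, 250)), "AF"))
            else:
                validation.append(
                    ((rng.uniform(0.6, 1.0), rng.uniform(0, 80)), "SR"))
        best_f1, _ = _grid_oracle(validation)
        th = fit_thresholds(validation)
        tp = fp = fn = 0
        for (p, sd), truth in validation:
            pred_af = classify_rhythm(p, sd, th).call is RhythmType.AF
            truth_af = truth == "AF"
            tp += pred_af and truth_af
            fp += pred_af and not truth_af
            fn += (not pred_af) and truth_af
        fitted_f1 = 2 * tp / (2 * tp + fp + fn)
        assert fitted_f1 == pytest.approx(best_f1)


class TestMonotonicity:
    def test_raising_y_never_increases_af_calls(self, rng):
        feats = [(rng.uniform(0, 1), rng.uniform(0, 300)) for _ in range(200)]
        prev = None
        for y in np.linspace(0, 300, 16):
            th = AfThresholds(0.5, float(y))
            n_af = sum(classify_rhythm(p, sd, th).call is RhythmType.AF
                       for p, sd in feats)
            if prev is not None:
                assert n_af <= prev
            prev = n_af

    def test_lowering_x_never_increases_af_calls(self, rng):
        feats = [(rng.uniform(0, 1), rng.uniform(0, 300)) for _ in range(200)]
        prev = None
        for x in np.linspace(1.0, 0.0, 11):
            th = AfThresholds(float(x), 50.0)
            n_af = sum(classify_rhythm(p, sd, th).call is RhythmType.AF
                       for p, sd in feats)
            if prev is not None:
                assert n_af <= prev
            prev = n_af
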