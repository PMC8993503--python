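import dataclasses

import numpy as np
import pytest

from ecgwaves import (
    ConfigError,
    InsufficientBeatsError,
    Phenotype,
    RhythmType,
    SimulationConfig,
    WaveClass,
    add_noise_and_wander,
    check_record,
    generate_beat_schedule,
    sample_config,
    synthesize_ecg,
)


class TestSampleConfig:
    def test_same_seed_gives_identical_config(self):
        assert sample_config(7) == sample_config(7)

    def test_override_is_verbatim_and_leaves_independent_fields(self):
        base = sample_config(7)
        over = sample_config(7, {"rhythm": RhythmType.AF})
        assert over.rhythm is RhythmType.AF
        # fields independent of rhythm are drawn identically
        assert over.phenotype is base.phenotype
        assert over.noise_sd == base.noise_sd
        assert over.wave_params == base.wave_params
        assert over.voltage_scale == base.voltage_scale

    def test_different_seeds_differ(self):
        a, b = sample_config(7), sample_config(8)
        assert a != b

    def test_unknown_override_rejected_by_name(self):
        with pytest.raises(ConfigError, match="heart_rate_bpm"):
            sample_config(1, {"heart_rate_bpm": 60})

    def test_out_of_range_override_rejected(self):
        with pytest.raises(ConfigError, match="mean_heart_rate"):
            sample_config(1, {"mean_heart_rate": 400})

    @pytest.mark.parametrize(
        "field,value",
        [
            ("sampling_rate", 0), ("duration", -1),
            ("noise_sd", -0.1), ("voltage_scale", 0.0),
        ],
    )
    def test_config_invariants(self, field, value):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, **{field: value})


class TestBeatSchedule:
    def test_regular_sr_at_60_bpm(self):
        cfg = sample_config(3, {"rhythm": "SR", "mean_heart_rate": 60.0,
                                "rr_jitter": 0.0})
        sched = generate_beat_schedule(cfg)
        assert 9 <= len(sched.qrs_onsets) <= 11
        assert all(abs(rr - 1000.0) < 1e-9 for rr in sched.rr_intervals_ms)

    def test_rr_definition_matches_onsets(self):
        cfg = sample_config(4, {"rhythm": "AF"})
        sched = generate_beat_schedule(cfg)
        fs = cfg.sampling_rate
        expected = np.diff(sched.qrs_onsets) / fs * 1000.0
        np.testing.assert_allclose(sched.rr_intervals_ms, expected)

    def test_af_intervals_disperse_and_have_no_p(self):
        cfg = sample_config(4, {"rhythm": "AF"})
        sched = generate_beat_schedule(cfg)
        assert np.std(sched.rr_intervals_ms) > 0
        assert not any(sched.has_p_wave)

    def test_sr_cv_bounded(self):
        for seed in range(10):
            cfg = sample_config(seed, {"rhythm": "SR"})
            rr = np.array(generate_beat_schedule(cfg).rr_intervals_ms)
            assert np.std(rr) / np.mean(rr) <= 0.05

    def test_too_few_beats_rejected(self):
        cfg = sample_config(1, {"mean_heart_rate": 20.0, "duration": 3.0})
        with pytest.raises(InsufficientBeatsError):
            generate_beat_schedule(cfg)


class TestSynthesizeEcg:
    def test_shapes_and_label_range(self, sr_signal):
        assert sr_signal.samples.shape == sr_signal.labels.shape == (12, 5000)
        assert sr_signal.labels.min() >= 0 and sr_signal.labels.max() <= 7

    def test_sinus_beats_have_p_and_pr_before_qrs(self, sr_signal):
        assert check_record(sr_signal) == []

    def test_af_has_no_atrial_classes(self, af_signal):
        assert not np.isin(
            af_signal.labels,
            [int(WaveClass.P_WAVE), int(WaveClass.PR_INTERVAL)],
        ).any()

    def test_deterministic(self):
        cfg = sample_config(11)
        a, b = synthesize_ecg(cfg), synthesize_ecg(cfg)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.labels, b.labels)

    @staticmethod
    def _median_qrs_run_ms(signal):
        labels = signal.labels[0]
        fs = signal.config.sampling_rate
        runs = []
        in_run = start = 0
        for i, v in enumerate(labels):
            if v == int(WaveClass.QRS) and not in_run:
                in_run, start = 1, i
            elif v != int(WaveClass.QRS) and in_run:
                in_run = 0
                runs.append((i - start) / fs * 1000.0)
        return float(np.median(runs))

    def test_lbbb_broadens_qrs(self):
        lbbb = synthesize_ecg(sample_config(5, {"rhythm": "SR",
                                                "phenotype": "LBBB"}))
        normal = synthesize_ecg(sample_config(5, {"rhythm": "SR",
                                                  "phenotype": "NORMAL"}))
        assert self._median_qrs_run_ms(lbbb) >= 120.0
        assert self._median_qrs_run_ms(normal) <= 110.0

    def test_anterior_ste_elevates_st_in_v3(self):
        ste = synthesize_ecg(sample_config(6, {"rhythm": "SR",
                                               "phenotype": "ANTERIOR_STE"}))
        st_mask = ste.labels[0] == int(WaveClass.ST_SEGMENT)
        v3 = ste.lead("V3")
        assert v3[st_mask].mean() > 0.1  # elevated ST take-off in mV

    def test_temporal_ordering_within_beats(self):
        for seed in range(20):
            sig = synthesize_ecg(sample_config(seed))
            assert check_record(sig) == [], f"seed {seed}"


class TestNoiseAndWander:
    def test_identity_when_all_zero(self, sr_signal):
        cfg = dataclasses.replace(sr_signal.config, noise_sd=0.0,
                                  wander_amplitude=0.0, voltage_scale=1.0)
        out = add_noise_and_wander(sr_signal, cfg)
        np.testing.assert_array_equal(out.samples, sr_signal.samples)

    def test_pure_voltage_scaling_doubles(self, sr_signal):
        cfg = dataclasses.replace(sr_signal.config, noise_sd=0.0,
                                  wander_amplitude=0.0, voltage_scale=2.0)
        out = add_noise_and_wander(sr_signal, cfg)
        np.testing.assert_allclose(out.samples, 2.0 * sr_signal.samples)

    def test_noise_statistics_match_generating_distribution(self, sr_signal):
        cfg = dataclasses.replace(sr_signal.config, noise_sd=0.05,
                                  wander_amplitude=0.0, voltage_scale=1.0)
        out = add_noise_and_wander(sr_signal, cfg)
        residual = (out.samples - sr_signal.samples).ravel()
        assert abs(residual.mean()) < 0.005
        assert abs(residual.std() - 0.05) / 0.05 < 0.10

    def test_labels_never_relabelled(self, af_signal):
        cfg = dataclasses.replace(af_signal.config, noise_sd=0.5,
                                  wander_amplitude=0.5)
        out = add_noise_and_wander(af_signal, cfg)
        np.testing.assert_array_equal(out.labels, af_signal.labels)

    def test_negative_noise_rejected(self, sr_signal):
        with pytest.raises(ConfigError):
            dataclasses.replace(sr_signal.config, noise_sd=-1.0)


class TestRhythmDispersion:
    def test_af_rr_sd_exceeds_sr_at_matched_rate(self):
        """At the same mean heart rate, every AF record is more irregular
        than every SR record (default jitter settings)."""
        from ecgwaves.af import extract_features

        sr_sds, af_sds = [], []
        for seed in range(30):
            sr = synthesize_ecg(sample_config(
                seed, {"rhythm": "SR", "mean_heart_rate": 75.0}))
            af = synthesize_ecg(sample_config(
                5000 + seed, {"rhythm": "AF", "mean_heart_rate": 75.0}))
            sr_sds.append(extract_features(sr.labels[1], 500.0)[1])
            af_sds.append(extract_features(af.labels[1], 500.0)[1])
        assert max(sr_sds) < min(af_sds)
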