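"""Protocol arithmetic, driver/kernel physics, cohort generation contracts."""

import numpy as np
import pytest

from edaflow.acquisition import SensorConfig
from edaflow.decomposition import decompose
from edaflow.features import Segment, extract_all
from edaflow.preprocessing import apply_filter, design_lowpass
from edaflow.synthetic import (CohortConfig, ConditionEffect, EffectModel,
                               ProtocolConfig, bateman_kernel, make_schedule,
                               recording_to_conductance, segment_bounds,
                               simulate_cohort, simulate_driver,
                               simulate_recording)


class TestSchedule:
    def test_default_segment_is_70_seconds(self, protocol):
        assert protocol.segment_duration_s == pytest.approx(70.0)

    def test_two_conditions_total_140_seconds_of_stimulation(self, protocol):
        assert protocol.total_stimulus_s == pytest.approx(140.0)

    def test_single_picture_segment_is_7_seconds(self):
        assert ProtocolConfig(n_pictures=1).segment_duration_s == pytest.approx(7.0)

    def test_bounds_match_segment_length(self, protocol):
        _, bounds = make_schedule(protocol, seed=0)
        for cond in protocol.conditions:
            lo, hi = bounds[cond]
            assert hi - lo == pytest.approx(70.0)

    def test_blank_precedes_every_picture(self, protocol):
        sched, _ = make_schedule(protocol, seed=2)
        events = sched.events
        for i, ev in enumerate(events):
            if ev.condition in ("calm", "distress"):
                assert events[i - 1].condition == "blank"
                assert events[i - 1].duration_s == pytest.approx(1.0)

    def test_same_seed_same_schedule(self, protocol):
        a, _ = make_schedule(protocol, seed=9)
        b, _ = make_schedule(protocol, seed=9)
        assert a.to_json_obj() == b.to_json_obj()


class TestDriver:
    def test_zero_rate_gives_empty_driver(self, schedule, effect):
        eff = EffectModel(calm=ConditionEffect(0.0, 0.45),
                          distress=ConditionEffect(0.0, 0.60))
        d = simulate_driver(schedule, eff, "distress", fs=10.0, n_samples=2100, seed=0)
        assert not np.any(d)

    def test_certain_response_fixed_latency(self, schedule):
        eff = EffectModel(calm=ConditionEffect(1.0, 0.45, 1e-12),
                          distress=ConditionEffect(1.0, 0.60, 1e-12),
                          latency_range_s=(2.0, 2.0 + 1e-12))
        d = simulate_driver(schedule, eff, "distress", fs=10.0, n_samples=2100, seed=4)
        onsets = [ev.onset_s for ev in schedule.pictures() if ev.condition == "distress"]
        hits = np.flatnonzero(d)
        assert len(hits) == len(onsets)
        assert np.allclose(hits / 10.0, np.asarray(onsets) + 2.0, atol=0.1)

    def test_driver_nonnegative_and_sparse(self, schedule, effect):
        d = simulate_driver(schedule, effect, "calm", fs=10.0, n_samples=2100, seed=1)
        assert np.all(d >= 0)
        assert np.count_nonzero(d) <= 10

    def test_distress_mass_exceeds_calm_on_average(self, schedule, effect):
        calm, distress = [], []
        for seed in range(100):
            calm.append(simulate_driver(schedule, effect, "calm", 10.0, 2100, seed).sum())
            distress.append(simulate_driver(schedule, effect, "distress", 10.0, 2100, seed).sum())
        assert np.mean(distress) > np.mean(calm)


class TestBatemanKernel:
    def test_unit_area(self):
        k = bateman_kernel()
        assert k.sum() / 10.0 == pytest.approx(1.0, abs=1e-6)

    def test_peak_at_closed_form_mode(self):
        t1, t2, fs = 0.75, 2.0, 100.0
        k = bateman_kernel(t1, t2, fs=fs, duration_s=30.0)
        t_peak = np.log(t2 / t1) * t1 * t2 / (t2 - t1)
        assert np.argmax(k) / fs == pytest.approx(t_peak, abs=1.5 / fs)

    def test_power_concentrated_below_phasic_upper_edge(self):
        k = bateman_kernel()
        spec = np.abs(np.fft.rfft(k)) ** 2
        freqs = np.fft.rfftfreq(len(k), d=0.1)
        assert spec[freqs < 1.5].sum() / spec.sum() >= 0.95

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            bateman_kernel(tau_rise=2.0, tau_decay=0.75)


class TestRecording:
    def test_same_seed_bit_identical(self, protocol, effect, sensor):
        sched, _ = make_schedule(protocol, seed=5)
        a, _ = simulate_recording(sched, effect, sensor, seed=5)
        b, _ = simulate_recording(sched, effect, sensor, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_noise_free_stimulus_free_recording_is_tonic(self, protocol, sensor):
        eff = EffectModel(calm=ConditionEffect(0.0, 0.45),
                          distress=ConditionEffect(0.0, 0.60),
                          noise_sigma_us=0.0)
        sched, _ = make_schedule(protocol, seed=2)
        raw, truth = simulate_recording(sched, eff, sensor, seed=2)
        g = recording_to_conductance(raw, sensor)
        # quantization is the only distortion left
        lsb_us = np.max(np.abs(g.samples - truth["tonic"]))
        assert lsb_us < 0.05
        assert np.array_equal(truth["driver"], np.zeros_like(truth["driver"]))

    def test_tonic_power_confined_below_half_decihertz(self, protocol, effect, sensor):
        sched, _ = make_schedule(protocol, seed=8)
        _, truth = simulate_recording(sched, effect, sensor, seed=8)
        tonic = truth["tonic"] - truth["tonic"].mean()
        spec = np.abs(np.fft.rfft(tonic)) ** 2
        freqs = np.fft.rfftfreq(len(tonic), d=1.0 / sensor.fs)
        assert spec[freqs < 0.05].sum() / spec.sum() >= 0.99

    def test_phasic_power_confined_below_phasic_upper_edge(self, protocol, effect, sensor):
        sched, _ = make_schedule(protocol, seed=8)
        _, truth = simulate_recording(sched, effect, sensor, seed=8)
        phasic = truth["phasic"]
        spec = np.abs(np.fft.rfft(phasic)) ** 2
        freqs = np.fft.rfftfreq(len(phasic), d=1.0 / sensor.fs)
        assert spec[freqs <= 1.5].sum() / spec.sum() >= 0.95


class TestCohort:
    def test_default_exclusions_leave_45_subjects(self):
        cfg = CohortConfig()
        assert cfg.n_valid == 45

    def test_cohort_table_shape_and_log(self):
        table, log = simulate_cohort(CohortConfig(seed=3))
        assert table["subject_id"].nunique() == 45
        assert len(table) == 90
        assert len(log) == 5
        assert set(log["reason"]) == {"screening questionnaire not passed",
                                      "technical failure during acquisition"}

    def test_no_failures_keeps_everyone(self):
        cfg = CohortConfig(n_enrolled=8, n_screening_failures=0,
                           n_technical_failures=0, n_male=4, seed=0)
        table, log = simulate_cohort(cfg)
        assert table["subject_id"].nunique() == 8
        assert log.empty

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_enrolled=5, n_screening_failures=4, n_technical_failures=1)

    def test_feature_means_ordered_distress_above_calm(self):
        # directionality of the condition effect on absolute-level features
        wins = {"INSC": 0, "F2SC": 0, "SKSC": 0}
        n_seeds = 8
        for seed in range(n_seeds):
            table, _ = simulate_cohort(CohortConfig(n_enrolled=24, n_screening_failures=0,
                                                    n_technical_failures=0, n_male=12,
                                                    seed=seed))
            m = table.groupby("condition")[list(wins)].mean()
            for f in wins:
                wins[f] += m.loc["distress", f] > m.loc["calm", f]
        for f, w in wins.items():
            assert w >= n_seeds - 1, f


class TestEndToEndRecovery:
    def test_driver_mass_tracks_recovered_insc(self, protocol, effect, sensor):
        from edaflow.synthetic import _rng

        filt = design_lowpass()
        pairs = []
        for seed in range(50):
            gain = float(_rng(seed, 99).lognormal(0.0, effect.subject_sigma))
            sched, bounds = make_schedule(protocol, seed=seed)
            raw, truth = simulate_recording(sched, effect, sensor,
                                            duration_s=protocol.total_duration_s,
                                            seed=seed, subject_gain=gain)
            g = recording_to_conductance(raw, sensor)
            dec = decompose(apply_filter(g, filt), sched)
            for cond in ("distress", "calm"):
                sl = segment_bounds(bounds, cond, sensor.fs)
                fv = extract_all(Segment(dec.phasic[sl], fs=sensor.fs))
                pairs.append((truth["drivers"][cond].sum(), fv.INSC))
        inj, insc = np.array(pairs).T
        assert np.corrcoef(inj, insc)[0, 1] >= 0.9
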