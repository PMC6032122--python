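"""Velocity-threshold detection, merging, binocular filter, main sequence."""

import dataclasses

import numpy as np
import pytest

from fixsens.msdetect import (Candidate, binocular_filter, detect_candidates,
                              detect_microsaccades, direction_histogram,
                              filter_and_merge, main_sequence, median_sd)
from fixsens.preprocess import compute_velocity
from fixsens.synth import SynthConfig, generate_trace
from fixsens.trace import GazeTrace, Microsaccade


def overlap(a_on, a_off, b_on, b_off, tol=0.002):
    return a_on <= b_off + tol and b_on <= a_off + tol


def match_counts(detected, truth, tol=0.002):
    hits = sum(1 for e in truth
               if any(overlap(d.onset, d.offset, e.onset, e.offset, tol)
                      for d in detected))
    fps = sum(1 for d in detected
              if not any(overlap(d.onset, d.offset, e.onset, e.offset, tol)
                         for e in truth))
    return hits, fps


class TestMedianSd:
    def test_matches_definition_on_gaussian(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 2.0, 100_000)
        est = median_sd(v)
        # for a centered Gaussian, median(v^2) = 0.4549 sigma^2
        assert est == pytest.approx(2.0 * np.sqrt(0.4549), rel=0.02)

    def test_robust_to_single_extreme_outlier(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 0.5, 50_000)
        s0 = median_sd(v)
        v_out = v.copy()
        v_out[0] = 1e4
        assert abs(median_sd(v_out) - s0) / s0 < 0.01


class TestDetectCandidates:
    def test_pure_noise_yields_no_candidates(self):
        # sub-threshold white positional noise never crosses 6 sigma of
        # its own (stationary) velocity distribution for long
        cfg = SynthConfig(session_duration=30.0, ms_rate=0.0, blink_rate=0.0,
                          seed=2)
        trace, _ = generate_trace(cfg)
        det = detect_microsaccades(trace)
        assert det == []

    def test_injected_event_found_once(self):
        cfg = SynthConfig(session_duration=30.0, ms_rate=0.0, blink_rate=0.0,
                          seed=3)
        amp = 0.3
        vp = cfg.main_sequence_k * amp ** cfg.main_sequence_b
        trace, truth = generate_trace(cfg, events=[(12.0, 2 * amp / vp, amp, vp, 45.0)])
        det = detect_microsaccades(trace)
        assert len(det) == 1
        assert overlap(det[0].onset, det[0].offset, truth[0].onset, truth[0].offset)

    def test_flat_trace_rejected(self):
        n = 2000
        tr = GazeTrace(time=np.arange(n) / 500.0, x=np.zeros((n, 2)),
                       y=np.zeros((n, 2)), pupil=np.full((n, 2), 1000.0))
        vel = compute_velocity(tr)
        with pytest.raises(ValueError):
            detect_candidates(vel)


class TestFilterAndMerge:
    @pytest.fixture()
    def event_trace(self):
        # two velocity excursions 30 ms apart in an otherwise quiet eye
        cfg = SynthConfig(session_duration=20.0, ms_rate=0.0, blink_rate=0.0,
                          seed=4, drift_diffusion=0.0005)
        amp, d = 0.2, 0.015
        vp = 2 * amp / d
        ev = [(10.0, d, amp, vp, 0.0), (10.0 + d + 0.030, d, amp, vp, 180.0)]
        trace, _ = generate_trace(cfg, events=ev)
        vel = compute_velocity(trace)
        return trace, vel

    def test_gap_below_50ms_merges(self, event_trace):
        trace, vel = event_trace
        cands, _ = detect_candidates(vel)
        merged = filter_and_merge(cands, trace, vel, merge_gap=0.05,
                                  amplitude_bounds=(0.1, 60.0))
        assert len(merged) == 1

    def test_gap_above_50ms_kept_separate(self, event_trace):
        trace, vel = event_trace
        cands, _ = detect_candidates(vel)
        split = filter_and_merge(cands, trace, vel, merge_gap=0.02)
        assert len(split) == 2

    def test_transitive_chain_merge(self):
        # three candidates each 30 ms apart collapse to one event,
        # matching an interval-merge oracle
        cfg = SynthConfig(session_duration=20.0, ms_rate=0.0, blink_rate=0.0,
                          seed=5, drift_diffusion=0.0005)
        amp, d = 0.2, 0.015
        vp = 2 * amp / d
        ev = [(10.0 + i * (d + 0.030), d, amp, vp, [0, 180, 0][i])
              for i in range(3)]
        trace, _ = generate_trace(cfg, events=ev)
        vel = compute_velocity(trace)
        cands, _ = detect_candidates(vel)
        assert len(cands) >= 3
        merged = filter_and_merge(cands, trace, vel, merge_gap=0.05,
                                  amplitude_bounds=(0.1, 60.0))
        assert len(merged) == 1
        assert merged[0].onset <= ev[0][0] + d
        assert merged[0].offset >= ev[2][0]

    def test_small_amplitude_discarded(self):
        # a 2-arcmin net displacement fails the >= 3 arcmin filter
        cfg = SynthConfig(session_duration=10.0, ms_rate=0.0, blink_rate=0.0,
                          eye_noise_sd=0.0, seed=6, drift_diffusion=0.0002)
        amp = 2.0 / 60.0
        d = 0.01
        trace, _ = generate_trace(cfg, events=[(5.0, d, amp, 2 * amp / d, 0.0)])
        vel = compute_velocity(trace)
        cands, _ = detect_candidates(vel)
        assert len(cands) >= 1
        kept = filter_and_merge(cands, trace, vel)
        assert kept == []

    def test_retained_events_satisfy_invariants(self, detected_events):
        for e in detected_events:
            assert e.offset > e.onset
            assert e.duration >= 0.006
            assert 3.0 <= e.amplitude <= 60.0
            assert e.peak_velocity > 0
            assert 0.0 <= e.direction < 360.0


class TestBinocularFilter:
    def ms(self, onset, offset, eye):
        return Microsaccade(onset=onset, offset=offset, amplitude=10.0,
                            peak_velocity=20.0, direction=0.0, eye=eye)

    def test_identical_lists_all_retained(self):
        left = [self.ms(1.0, 1.02, "left"), self.ms(2.0, 2.02, "left")]
        right = [self.ms(1.0, 1.02, "right"), self.ms(2.0, 2.02, "right")]
        assert len(binocular_filter(left, right)) == 2

    def test_monocular_event_rejected(self):
        left = [self.ms(1.0, 1.02, "left")]
        assert binocular_filter(left, []) == []

    def test_single_sample_overlap_suffices(self):
        left = [self.ms(1.0, 1.020, "left")]
        right = [self.ms(1.020, 1.040, "right")]
        out = binocular_filter(left, right)
        assert len(out) == 1
        # left-eye parameters are the ones reported
        assert out[0].onset == 1.0 and out[0].eye == "binocular"

    def test_disjoint_intervals_rejected(self):
        left = [self.ms(1.0, 1.02, "left")]
        right = [self.ms(1.03, 1.05, "right")]
        assert binocular_filter(left, right) == []


class TestDetectionQuality:
    def test_recall_and_precision_against_ground_truth(self):
        # >= 500 true events at default noise
        cfg = SynthConfig(session_duration=400.0, seed=7)
        trace, truth = generate_trace(cfg)
        assert len(truth) >= 500
        det = detect_microsaccades(trace)
        hits, fps = match_counts(det, truth)
        assert hits / len(truth) >= 0.9
        assert (len(det) - fps) / len(det) >= 0.9

    def test_time_shift_equivariance(self):
        cfg = SynthConfig(session_duration=60.0, seed=8)
        trace, _ = generate_trace(cfg)
        det0 = detect_microsaccades(trace)
        shifted = trace.copy()
        shifted.time = shifted.time + 5.0
        det1 = detect_microsaccades(shifted)
        assert len(det0) == len(det1)
        for a, b in zip(det0, det1):
            assert b.onset == pytest.approx(a.onset + 5.0, abs=1e-9)
            assert b.amplitude == pytest.approx(a.amplitude)


class TestMainSequence:
    def test_noiseless_power_law_gives_r_one(self):
        cfg = SynthConfig(main_sequence_noise_sd=0.0)
        rng = np.random.default_rng(9)
        amps = rng.uniform(3, 60, 200)
        events = [Microsaccade(onset=i, offset=i + 0.02, amplitude=a,
                               peak_velocity=cfg.main_sequence_k
                               * (a / 60.0) ** cfg.main_sequence_b,
                               direction=0.0)
                  for i, a in enumerate(amps)]
        r, slope = main_sequence(events)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(cfg.main_sequence_b, abs=1e-9)

    def test_default_noise_r_above_populations_lower_bound(self, detected_events):
        r, _ = main_sequence(detected_events)
        assert r >= 0.86

    def test_shuffled_pairing_destroys_correlation(self, detected_events):
        rng = np.random.default_rng(10)
        amps = [e.amplitude for e in detected_events]
        vels = [e.peak_velocity for e in detected_events]
        perm = rng.permutation(len(amps))
        shuffled = [dataclasses.replace(e, amplitude=amps[i], peak_velocity=vels[j])
                    for e, i, j in zip(detected_events, range(len(amps)), perm)]
        r, _ = main_sequence(shuffled)
        assert abs(r) < 0.2

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            main_sequence([])


class TestDirectionHistogram:
    def test_single_direction_in_one_bin(self):
        events = [Microsaccade(onset=i, offset=i + 0.02, amplitude=10,
                               peak_velocity=20, direction=0.0)
                  for i in range(10)]
        _, props = direction_histogram(events, n_bins=8)
        assert props[0] == 1.0 and props.sum() == pytest.approx(1.0)

    def test_uniform_directions_near_uniform_bins(self):
        rng = np.random.default_rng(11)
        events = [Microsaccade(onset=i, offset=i + 0.02, amplitude=10,
                               peak_velocity=20, direction=float(d))
                  for i, d in enumerate(rng.uniform(0, 360, 20_000))]
        _, props = direction_histogram(events, n_bins=8)
        assert np.allclose(props, 0.125, atol=0.01)

    def test_generator_bias_gives_horizontal_dominance(self, detected_events):
        centers, props = direction_histogram(detected_events, n_bins=8)
        horizontal = props[centers == 0.0][0] + props[centers == 180.0][0]
        assert horizontal > 0.5

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            direction_histogram([])
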