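"""Spindle-detector tests: power-S track, state machine vs brute-force
oracle, rejection rules, event characterization and metrics."""

import numpy as np
import pytest

from spindlekit.detect import (
    DetectorConfig,
    PowerSTrack,
    SpindleEvent,
    characterize_event,
    compute_power_s_track,
    detect_candidates,
    detect_spindles,
    reject_candidates,
    summarize_metrics,
)
from spindlekit.recordings import AnnotationTrack
from spindlekit.simulate import annotations_from_events


def make_track(ratio, power=None, step=0.2, window_length=1.0, valid=None):
    """Build a PowerSTrack directly from a ratio profile (reference = 1)."""
    ratio = np.asarray(ratio, dtype=float)
    n = len(ratio)
    power = ratio.copy() if power is None else np.asarray(power, dtype=float)
    return PowerSTrack(
        start=np.arange(n) * step,
        power_s=power,
        ratio=ratio,
        alpha_ratio=np.ones(n),
        beta_ratio=np.ones(n),
        reference=np.ones(n),
        epoch_index=(np.arange(n) * step // 30.0).astype(int),
        valid=np.ones(n, dtype=bool) if valid is None else np.asarray(valid),
        window_length=window_length,
        window_step=step,
    )


def brute_force_candidates(track, config=None):
    """Independent enumeration of the printed detection rules.

    Scans every maximal run of consecutive valid supra-threshold windows,
    requires the minimum run length, then walks forward for the first window
    below the higher of the two termination thresholds within the horizon.
    Written as plain loops, separately from the production state machine.
    """
    cfg = config or DetectorConfig()
    n = len(track)
    events = []
    i = 0
    while i < n:
        if not (track.valid[i] and track.ratio[i] > cfg.onset_ratio_threshold):
            i += 1
            continue
        j = i
        while (j + 1 < n and track.valid[j + 1]
               and track.ratio[j + 1] > cfg.onset_ratio_threshold):
            j += 1
        if j - i + 1 < cfg.min_consecutive_windows:
            i = j + 1
            continue
        peak = track.power_s[i]
        term = None
        k = i + 1
        while k < n and track.valid[k]:
            peak = max(peak, track.power_s[k])
            threshold = max(cfg.offset_ratio_threshold * track.reference[k],
                            cfg.offset_power_fraction * peak)
            if track.power_s[k] < threshold:
                if (track.start[k] + track.window_length
                        - track.start[i]) <= cfg.max_termination_horizon + 1e-9:
                    term = k
                break
            k += 1
        if term is None:
            i = k + 1
            continue
        events.append((i, term))
        i = term + 1
    # merge runs resuming at/right after the terminating window
    merged = []
    for ev in events:
        if merged and ev[0] - merged[-1][1] <= 1:
            merged[-1] = (merged[-1][0], ev[1])
        else:
            merged.append(ev)
    return merged


class TestPowerSTrack:
    def test_zero_signal_zero_power_invalid_windows(self, flat_grid):
        grid = flat_grid(2)
        track = compute_power_s_track(np.zeros(6000), grid)
        assert np.all(track.power_s == 0.0)
        assert not track.valid.any()  # undefined reference, excluded not NaN
        assert np.isfinite(track.ratio).all()

    def test_five_window_starts_per_second(self, flat_grid):
        track = compute_power_s_track(np.random.default_rng(0).normal(size=3000),
                                      flat_grid(1))
        per_second = np.sum((track.start >= 1.0) & (track.start < 2.0))
        assert per_second == 5

    def test_stationary_tone_ratio_one(self, flat_grid):
        fs = 100.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 13 * t)
        track = compute_power_s_track(x, flat_grid(2, fs=fs))
        # percentile of a constant is the constant: every ratio is 1
        assert np.allclose(track.ratio[track.valid], 1.0, atol=1e-6)
        # and power_S for a unit tone is its variance 0.5
        assert np.median(track.power_s) == pytest.approx(0.5, rel=0.03)

    def test_burst_ratio_matches_bruteforce_spectral_sum(self, flat_grid):
        fs = 100.0
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.5, int(30 * fs))
        t = np.arange(int(1.0 * fs)) / fs
        burst = 20.0 * np.sin(2 * np.pi * 13 * t)
        x[1000:1100] += burst
        grid = flat_grid(1, fs=fs)
        track = compute_power_s_track(x, grid)
        inside = (track.start >= 10.0) & (track.start < 10.2)
        outside = track.start < 8.0
        assert track.ratio[inside].min() > 3.0
        assert np.median(track.ratio[outside]) < 3.0
        # brute-force window-by-window check of one window's power_S
        k = int(np.flatnonzero(inside)[0])
        seg = x[int(track.start[k] * fs): int(track.start[k] * fs) + 100]
        spec = np.abs(np.fft.rfft(seg)) ** 2
        spec[1:] *= 2
        spec[-1] /= 2
        freqs = np.fft.rfftfreq(100, 1 / fs)
        expect = spec[(freqs >= 10) & (freqs <= 16)].sum() / (100 * 100)
        assert track.power_s[k] == pytest.approx(expect, rel=1e-9)


class TestStateMachine:
    def test_four_supra_windows_no_candidate(self):
        track = make_track([0, 4, 4, 4, 4, 0.5, 0, 0])
        assert detect_candidates(track) == []

    def test_five_supra_windows_candidate_with_ratio_offset(self):
        track = make_track([0, 4, 4, 4, 4, 4, 0.5, 0, 0, 0])
        cands = detect_candidates(track)
        assert len(cands) == 1
        c = cands[0]
        assert c.onset_index == 1
        assert c.offset_index == 6  # first window with ratio < 1.5
        assert c.termination == "ratio"
        assert c.onset == pytest.approx(0.2)
        assert c.offset == pytest.approx(6 * 0.2 + 1.0)

    def test_power_fraction_termination(self):
        # ratio stays above 1.5 but power collapses below 20% of peak
        ratio = [0, 10, 10, 10, 10, 10, 1.9, 1.9, 0, 0]
        track = make_track(ratio)
        cands = detect_candidates(track)
        assert len(cands) == 1
        assert cands[0].offset_index == 6
        assert cands[0].termination == "power_fraction"

    def test_sustained_six_seconds_discarded(self):
        track = make_track([4.0] * 35 + [0.5] * 5)  # supra for 7 s
        assert detect_candidates(track) == []

    def test_termination_just_inside_horizon_kept(self):
        # onset at window 0; termination window 20 ends at 20*0.2+1 = 5.0 s
        track = make_track([4.0] * 20 + [0.5] + [0.5] * 4)
        cands = detect_candidates(track)
        assert len(cands) == 1
        assert cands[0].offset - cands[0].onset == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            ratio = rng.exponential(1.0, size=200)
            bursts = rng.integers(0, 190, size=3)
            for b in bursts:
                ratio[b : b + rng.integers(3, 12)] += rng.exponential(8.0)
            track = make_track(ratio)
            got = [(c.onset_index, c.offset_index)
                   for c in detect_candidates(track)]
            assert got == brute_force_candidates(track)

    def test_raising_onset_threshold_never_adds_events(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            ratio = rng.exponential(1.0, size=150)
            for b in rng.integers(0, 140, size=2):
                ratio[b : b + rng.integers(4, 10)] += rng.exponential(10.0)
            track = make_track(ratio)
            counts = []
            for th in (3.0, 4.0, 6.0):
                cfg = DetectorConfig(onset_ratio_threshold=th)
                counts.append(len(detect_candidates(track, cfg)))
            assert counts[0] >= counts[1] >= counts[2]

    def test_invalid_windows_break_runs(self):
        valid = np.ones(10, dtype=bool)
        valid[4] = False
        track = make_track([4] * 10, valid=valid)
        # neither fragment reaches five consecutive valid windows
        assert detect_candidates(track) == []


class TestRejection:
    def _candidate(self, track):
        cands = detect_candidates(track)
        assert cands
        return cands

    def test_arousal_overlap_deletes(self, flat_grid):
        track = make_track([0, 4, 4, 4, 4, 4, 0.5, 0, 0, 0])
        cands = self._candidate(track)
        arousals = AnnotationTrack([(1.0, 2.0, "arousal")])
        kept, rejected = reject_candidates(cands, track, arousals, flat_grid(1))
        assert kept == []
        assert rejected[0][1] == "arousal"

    def test_dominant_spindle_band_kept(self, flat_grid):
        track = make_track([0, 5, 5, 5, 5, 5, 0.5, 0, 0, 0])
        track.alpha_ratio[:] = 1.2
        track.beta_ratio[:] = 1.1
        kept, _ = reject_candidates(self._candidate(track), track,
                                    AnnotationTrack([]), flat_grid(1))
        assert len(kept) == 1

    def test_alpha_dominated_candidate_deleted(self, flat_grid):
        track = make_track([0, 4, 4, 4, 4, 4, 0.5, 0, 0, 0])
        track.alpha_ratio[:] = 10.0
        kept, rejected = reject_candidates(self._candidate(track), track,
                                           AnnotationTrack([]), flat_grid(1))
        assert kept == []
        assert rejected[0][1] == "alpha_beta"

    def test_alpha_leakage_burst_rejected_from_signal(self, flat_grid):
        # a pure 9 Hz burst leaks into the 10-16 Hz sum but its alpha ratio
        # exceeds the spindle ratio, verified by direct spectral sums
        fs = 100.0
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1.0, int(60 * fs))
        t = np.arange(int(1.5 * fs)) / fs
        env = 0.5 * (1 - np.cos(2 * np.pi * t / 1.5))
        x[2000:2150] += 40.0 * env * np.sin(2 * np.pi * 9.0 * t)
        grid = flat_grid(2, fs=fs)
        track = compute_power_s_track(x, grid)
        burst = (track.start >= 19.5) & (track.start <= 21.5)
        assert track.alpha_ratio[burst].max() > track.ratio[burst].max()
        cands = detect_candidates(track)
        kept, _ = reject_candidates(cands, track, AnnotationTrack([]), grid)
        assert all(not (19.5 <= c.onset <= 21.5) for c in kept)

    def test_non_n2_candidates_excluded(self, flat_grid):
        track = make_track([0, 4, 4, 4, 4, 4, 0.5, 0, 0, 0])
        grid = flat_grid(1, stage="N3")
        kept, rejected = reject_candidates(self._candidate(track), track,
                                           AnnotationTrack([]), grid)
        assert kept == []
        assert rejected[0][1] == "not_n2"


class TestCharacterization:
    def _burst_setup(self, freq, amp=30.0, fs=100.0, flat_grid=None):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1.0, int(30 * fs))
        t = np.arange(int(1.5 * fs)) / fs
        env = 0.5 * (1 - np.cos(2 * np.pi * t / 1.5))
        x[1000:1150] += amp * env * np.sin(2 * np.pi * freq * t)
        grid = flat_grid(1, fs=fs)
        track = compute_power_s_track(x, grid)
        cands = detect_candidates(track)
        assert len(cands) == 1
        return x, fs, cands[0], track

    def test_peak_frequency_within_quarter_hz(self, flat_grid):
        x, fs, cand, track = self._burst_setup(13.0, flat_grid=flat_grid)
        _, freq, fast = characterize_event(x, fs, cand, track)
        assert freq == pytest.approx(13.0, abs=0.25)
        assert fast

    @pytest.mark.parametrize("freq,expected_fast", [(11.5, False), (12.0, True),
                                                    (14.5, True)])
    def test_fast_boundary_inclusive_lower(self, freq, expected_fast, flat_grid):
        x, fs, cand, track = self._burst_setup(freq, flat_grid=flat_grid)
        _, fhat, fast = characterize_event(x, fs, cand, track)
        assert fast == expected_fast

    def test_power_scales_with_amplitude_squared(self, flat_grid):
        x1, fs, c1, t1 = self._burst_setup(13.0, amp=20.0, flat_grid=flat_grid)
        x2, _, c2, t2 = self._burst_setup(13.0, amp=40.0, flat_grid=flat_grid)
        p1, _, _ = characterize_event(x1, fs, c1, t1)
        p2, _, _ = characterize_event(x2, fs, c2, t2)
        assert p2 / p1 == pytest.approx(4.0, rel=0.15)


class TestMetrics:
    def _event(self, freq, fast):
        return SpindleEvent(onset=0.0, offset=1.0, peak_power_s=100.0,
                            peak_frequency=freq, is_fast=fast,
                            channel="C3-M2", epoch_index=0)

    def test_density_is_count_over_n2_minutes(self, flat_grid):
        grid = flat_grid(30)  # 15 N2 minutes
        events = [self._event(13.0, True) for _ in range(30)]
        m = summarize_metrics(events, grid)
        assert m.density == pytest.approx(2.0)
        assert m.n2_minutes == pytest.approx(15.0)

    def test_fast_percent_arithmetic(self, flat_grid):
        events = [self._event(13.0, True)] * 3 + [self._event(11.0, False)]
        m = summarize_metrics(events, flat_grid(2))
        assert m.fast_percent == pytest.approx(75.0)

    def test_zero_n2_minutes_flagged(self, flat_grid):
        with pytest.raises(ValueError, match="N2"):
            summarize_metrics([], flat_grid(2, stage="N3"))


class TestEndToEnd:
    def test_density_recovered_at_high_snr(self, n2_recording):
        events, metrics, _ = detect_spindles(
            n2_recording["filtered"], n2_recording["grid"],
            annotations_from_events(n2_recording["events"]),
        )
        truth_rate = sum(e.kind == "spindle" for e in n2_recording["events"]) / 10.0
        avg = [m for m in metrics if m.channel == "average"][0]
        assert avg.density == pytest.approx(truth_rate, rel=0.10)

    def test_scale_invariance(self, n2_recording):
        from dataclasses import replace

        rec = n2_recording["filtered"]
        grid = n2_recording["grid"]
        ann = annotations_from_events(n2_recording["events"])
        _, m1, _ = detect_spindles(rec, grid, ann)
        scaled = replace(rec, data=rec.data * 3.0)
        _, m3, _ = detect_spindles(scaled, grid, ann)
        a1 = [m for m in m1 if m.channel == "average"][0]
        a3 = [m for m in m3 if m.channel == "average"][0]
        assert a3.density == pytest.approx(a1.density)
        assert a3.mean_frequency == pytest.approx(a1.mean_frequency)
        assert a3.fast_percent == pytest.approx(a1.fast_percent)
        assert a3.mean_power == pytest.approx(9.0 * a1.mean_power, rel=1e-6)
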