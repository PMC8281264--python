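"""Automatic N2 sleep-spindle detection and per-subject spindle metrics.

The detector works on a sliding "power S" track: a 1-s FFT window is
advanced every 0.2 s (five windows per second), the spectral power summed
over the 10.0-16.0 Hz spindle band in each window, and every window's power S
divided by the 30th percentile of power S across the windows of its 30-s
epoch (the power S ratio).  A spindle is identified when the ratio exceeds 3
for five consecutive windows, provided the power subsequently falls below
the higher of 1.5x the reference and 20% of the running peak within 5 s.
Presumptive spindles are deleted if they overlap an arousal, or if their
mean spindle-band ratio is below the analogous alpha- or beta-band ratio
(leakage from neighbouring rhythms), and are restricted to N2.

Four subject-level metrics follow: density (spindles per minute of N2),
mean peak frequency (Hz), mean peak power (uV^2, highest power S within the
spindle), and fast-spindle percent (peak frequency in 12.0-16.0 Hz), each
computed per central channel and averaged across the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .recordings import AnnotationTrack, EpochGrid, SleepRecording

__all__ = [
    "DetectorConfig",
    "PowerSTrack",
    "Candidate",
    "SpindleEvent",
    "SpindleMetrics",
    "compute_power_s_track",
    "detect_candidates",
    "reject_candidates",
    "characterize_event",
    "summarize_metrics",
    "detect_spindles",
    "events_to_frame",
]


@dataclass
class DetectorConfig:
    """Detection thresholds; defaults are the published algorithm constants."""

    spindle_band: tuple[float, float] = (10.0, 16.0)   # Hz, inclusive edges
    fast_band: tuple[float, float] = (12.0, 16.0)      # Hz, inclusive-lower
    window_length: float = 1.0      # s
    window_step: float = 0.2        # s  (five windows per second)
    reference_percentile: float = 30.0   # per 30-s epoch
    onset_ratio_threshold: float = 3.0
    min_consecutive_windows: int = 5
    offset_ratio_threshold: float = 1.5
    offset_power_fraction: float = 0.20  # of running peak power S
    max_termination_horizon: float = 5.0  # s
    # flanking bands for the leakage-rejection rule; half-open toward the
    # spindle band so the three bands do not overlap
    alpha_band: tuple[float, float] = (7.5, 10.0)      # [lo, hi)
    beta_band: tuple[float, float] = (16.0, 25.0)      # (lo, hi]
    arousal_overlap: str = "any"        # or "full": containment required
    ratio_aggregation: str = "mean"     # or "max", for the alpha/beta rule
    freq_zero_pad: int = 4              # x4 zero-padding -> 0.25 Hz bins
    #: taper of the 1-s detection FFT.  "boxcar" keeps a burst's band power
    #: high wherever it sits inside the window, so a brief spindle stays
    #: supra-threshold across the full five-window run; "hann" attenuates
    #: bursts near the window edges and shortens runs below the rule for
    #: sub-second events (available for leakage-sensitive use).
    window_taper: str = "boxcar"

    def __post_init__(self) -> None:
        if not 0 < self.window_step <= self.window_length:
            raise ValueError("require 0 < window_step <= window_length")
        for name in ("onset_ratio_threshold", "offset_ratio_threshold",
                     "offset_power_fraction", "max_termination_horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for band in (self.spindle_band, self.fast_band, self.alpha_band,
                     self.beta_band):
            if not band[0] < band[1]:
                raise ValueError(f"degenerate band {band}")


@dataclass
class PowerSTrack:
    """Sliding-window band powers and per-epoch percentile ratios.

    Windows with an undefined reference (all-zero epoch) carry
    ``valid=False`` and never participate in detection.
    """

    start: np.ndarray        # window start time, s
    power_s: np.ndarray      # uV^2, spindle-band sum
    ratio: np.ndarray        # power_s / per-epoch 30th percentile
    alpha_ratio: np.ndarray
    beta_ratio: np.ndarray
    reference: np.ndarray    # the per-window spindle-band reference value
    epoch_index: np.ndarray
    valid: np.ndarray        # bool
    window_length: float
    window_step: float

    def __len__(self) -> int:
        return len(self.start)


@dataclass
class Candidate:
    """Provisional event: indices into the track, inclusive of the
    terminating window."""

    onset_index: int
    offset_index: int        # terminating window
    onset: float
    offset: float            # end time of the terminating window
    peak_power_s: float
    termination: str         # "ratio", "power_fraction"


@dataclass
class SpindleEvent:
    """One detected spindle on the recording time base."""

    onset: float
    offset: float
    peak_power_s: float      # uV^2
    peak_frequency: float    # Hz
    is_fast: bool
    channel: str
    epoch_index: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class SpindleMetrics:
    """Per-subject N2 spindle summary (one channel or the channel average)."""

    channel: str
    n_events: int
    n2_minutes: float
    density: float           # events / min of N2
    mean_frequency: float    # Hz
    mean_power: float        # uV^2
    fast_percent: float      # %


def _hann(n: int) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))


def _taper(name: str, n: int) -> np.ndarray:
    if name == "hann":
        return _hann(n)
    if name == "boxcar":
        return np.ones(n)
    raise ValueError(f"unknown window taper {name!r}")


def _band_mask(freqs: np.ndarray, band: tuple[float, float],
               lo_inclusive: bool = True, hi_inclusive: bool = True) -> np.ndarray:
    eps = 1e-9
    lo = freqs >= band[0] - eps if lo_inclusive else freqs > band[0] + eps
    hi = freqs <= band[1] + eps if hi_inclusive else freqs < band[1] - eps
    return lo & hi


def _window_band_powers(
    x: np.ndarray, fs: float, starts_idx: np.ndarray, nwin: int,
    bands: list[tuple[tuple[float, float], bool, bool]],
    taper: str = "boxcar",
) -> list[np.ndarray]:
    """Per-window band power sums (uV^2) for several bands.

    Normalized so a stationary sinusoid of amplitude A contributes ~A^2/2
    summed over its band (window-power / Parseval normalization).
    """
    win = _taper(taper, nwin)
    segs = np.stack([x[i : i + nwin] for i in starts_idx]) if len(starts_idx) else \
        np.empty((0, nwin))
    spec = np.fft.rfft(segs * win, axis=1)
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    # one-sided per-bin power with window normalization: sums satisfy
    # sum_k p_k = sum(x_w^2)/sum(w^2) ~ var(x) for stationary x
    p = np.abs(spec) ** 2
    p[:, 1:] *= 2.0
    if nwin % 2 == 0:
        p[:, -1] /= 2.0
    p /= nwin * np.sum(win**2)
    out = []
    for band, lo_inc, hi_inc in bands:
        mask = _band_mask(freqs, band, lo_inc, hi_inc)
        out.append(p[:, mask].sum(axis=1))
    return out


def compute_power_s_track(
    signal: np.ndarray, grid: EpochGrid, config: DetectorConfig | None = None
) -> PowerSTrack:
    """Sliding spindle/alpha/beta band powers with per-epoch ratios.

    One entry per window start within each scored 30-s epoch (windows fit
    fully inside their epoch).  Ratios divide each window's band power by
    the epoch's 30th percentile of that band's power; epochs whose
    reference is zero (e.g. all-zero signal) have their windows marked
    invalid rather than propagating NaN.
    """
    config = config or DetectorConfig()
    fs = grid.sampling_rate
    nwin = int(round(config.window_length * fs))
    step = config.window_step

    # window starts advance continuously every step; a window belongs to the
    # epoch containing its start and may extend into the next epoch
    starts, epochs = [], []
    n_per_epoch = int(round(grid.epoch_length / step))
    for i in range(grid.n_epochs):
        t0, _ = grid.epoch_window(i)
        for k in range(n_per_epoch):
            starts.append(t0 + k * step)
            epochs.append(i)
    starts = np.asarray(starts)
    epochs = np.asarray(epochs, dtype=int)
    starts_idx = np.round(starts * fs).astype(int)
    keep = starts_idx + nwin <= len(signal)
    starts, epochs, starts_idx = starts[keep], epochs[keep], starts_idx[keep]

    p_s, p_a, p_b = _window_band_powers(
        signal, fs, starts_idx, nwin,
        bands=[(config.spindle_band, True, True),
               (config.alpha_band, True, False),
               (config.beta_band, False, True)],
        taper=config.window_taper,
    )

    ratio = np.zeros_like(p_s)
    a_ratio = np.zeros_like(p_s)
    b_ratio = np.zeros_like(p_s)
    reference = np.zeros_like(p_s)
    valid = np.zeros(len(p_s), dtype=bool)
    for i in np.unique(epochs):
        m = epochs == i
        refs = [np.percentile(p[m], config.reference_percentile)
                for p in (p_s, p_a, p_b)]
        if refs[0] <= 0:
            continue  # undefined reference: windows excluded, not NaN
        valid[m] = True
        reference[m] = refs[0]
        ratio[m] = p_s[m] / refs[0]
        a_ratio[m] = p_a[m] / refs[1] if refs[1] > 0 else 0.0
        b_ratio[m] = p_b[m] / refs[2] if refs[2] > 0 else 0.0

    return PowerSTrack(
        start=starts, power_s=p_s, ratio=ratio, alpha_ratio=a_ratio,
        beta_ratio=b_ratio, reference=reference, epoch_index=epochs,
        valid=valid, window_length=config.window_length, window_step=step,
    )


def detect_candidates(
    track: PowerSTrack, config: DetectorConfig | None = None
) -> list[Candidate]:
    """Run the onset/termination state machine over a power-S track.

    A candidate starts at the first window of a run of at least
    ``min_consecutive_windows`` consecutive valid windows with
    ratio > ``onset_ratio_threshold``.  Scanning forward from the onset, the
    event terminates at the first window whose power S drops below the
    higher of ``offset_ratio_threshold`` x reference and
    ``offset_power_fraction`` x the running peak power S; a candidate that
    fails to terminate within ``max_termination_horizon`` of onset is
    discarded.  Candidates separated by less than one window step are merged.
    """
    config = config or DetectorConfig()
    n = len(track)
    out: list[Candidate] = []
    i = 0
    while i < n:
        if not (track.valid[i] and track.ratio[i] > config.onset_ratio_threshold):
            i += 1
            continue
        j = i
        while (j + 1 < n and track.valid[j + 1]
               and track.ratio[j + 1] > config.onset_ratio_threshold):
            j += 1
        run_len = j - i + 1
        if run_len < config.min_consecutive_windows:
            i = j + 1
            continue
        onset = track.start[i]
        peak = track.power_s[i]
        k = i + 1
        term: int | None = None
        term_kind = ""
        while k < n and track.valid[k]:
            peak = max(peak, track.power_s[k])
            below_ratio = track.ratio[k] < config.offset_ratio_threshold
            below_frac = track.power_s[k] < config.offset_power_fraction * peak
            if below_ratio or below_frac:
                offset = track.start[k] + track.window_length
                if offset - onset <= config.max_termination_horizon + 1e-9:
                    term = k
                    term_kind = "ratio" if below_ratio else "power_fraction"
                break
            k += 1
        if term is None:
            i = k + 1  # no in-horizon termination: discard, resume after scan
            continue
        out.append(Candidate(
            onset_index=i, offset_index=term, onset=float(onset),
            offset=float(track.start[term] + track.window_length),
            peak_power_s=float(np.max(track.power_s[i : term + 1])),
            termination=term_kind,
        ))
        i = term + 1

    # merge re-triggers: a run resuming at or right after the previous
    # candidate's terminating window continues the same burst; runs that
    # begin later are distinct events (e.g. an adjacent alpha burst)
    merged: list[Candidate] = []
    for cand in out:
        if merged and cand.onset_index - merged[-1].offset_index <= 1:
            prev = merged[-1]
            merged[-1] = Candidate(
                onset_index=prev.onset_index, offset_index=cand.offset_index,
                onset=prev.onset, offset=cand.offset,
                peak_power_s=max(prev.peak_power_s, cand.peak_power_s),
                termination=cand.termination,
            )
        else:
            merged.append(cand)
    return merged


def reject_candidates(
    candidates: list[Candidate],
    track: PowerSTrack,
    arousals: AnnotationTrack | list[tuple[float, float]],
    grid: EpochGrid,
    config: DetectorConfig | None = None,
) -> tuple[list[Candidate], list[tuple[Candidate, str]]]:
    """Apply the deletion rules to provisional spindles.

    A candidate is deleted if it overlaps an arousal interval, if its
    aggregated spindle-band ratio is below the corresponding alpha- or
    beta-band ratio, or if its midpoint falls outside N2.  Returns
    (kept, [(candidate, reason), ...]).
    """
    config = config or DetectorConfig()
    if isinstance(arousals, AnnotationTrack):
        intervals = arousals.of_kind("arousal")
    else:
        intervals = list(arousals)
    agg = np.mean if config.ratio_aggregation == "mean" else np.max

    kept: list[Candidate] = []
    rejected: list[tuple[Candidate, str]] = []
    for cand in candidates:
        if config.arousal_overlap == "full":
            hit = any(a <= cand.onset and cand.offset <= b for a, b in intervals)
        else:
            hit = any(cand.onset < b and a < cand.offset for a, b in intervals)
        if hit:
            rejected.append((cand, "arousal"))
            continue
        sl = slice(cand.onset_index, cand.offset_index + 1)
        r_s = agg(track.ratio[sl])
        if r_s < agg(track.alpha_ratio[sl]) or r_s < agg(track.beta_ratio[sl]):
            rejected.append((cand, "alpha_beta"))
            continue
        mid_epoch = grid.epoch_of(0.5 * (cand.onset + cand.offset))
        if mid_epoch >= grid.n_epochs or grid.stages[mid_epoch] != "N2":
            rejected.append((cand, "not_n2"))
            continue
        kept.append(cand)
    return kept, rejected


def characterize_event(
    signal: np.ndarray,
    fs: float,
    candidate: Candidate,
    track: PowerSTrack,
    config: DetectorConfig | None = None,
) -> tuple[float, float, bool]:
    """(peak_power_S, peak_frequency, is_fast) for a finalized event.

    Peak power S is the maximum window power within the event.  The peak
    frequency is the maximal spectral bin of the peak window's Hann-tapered
    FFT, zero-padded x``freq_zero_pad`` for sub-bin (0.25 Hz at 1 s)
    resolution, restricted to the spindle band.  Fast spindles have peak
    frequency at or above the 12 Hz fast-band edge.
    """
    config = config or DetectorConfig()
    sl = slice(candidate.onset_index, candidate.offset_index + 1)
    k_peak = candidate.onset_index + int(np.argmax(track.power_s[sl]))
    nwin = int(round(config.window_length * fs))
    i0 = int(round(track.start[k_peak] * fs))
    seg = signal[i0 : i0 + nwin]
    win = _taper(config.window_taper, len(seg))
    nfft = len(seg) * config.freq_zero_pad
    spec = np.abs(np.fft.rfft(seg * win, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    mask = _band_mask(freqs, config.spindle_band)
    peak_freq = float(freqs[mask][int(np.argmax(spec[mask]))])
    is_fast = peak_freq >= config.fast_band[0] - 1e-9
    return float(np.max(track.power_s[sl])), peak_freq, is_fast


def summarize_metrics(
    events: Sequence[SpindleEvent], grid: EpochGrid, channel: str = ""
) -> SpindleMetrics:
    """Density, mean frequency, mean power and fast percent over N2.

    Raises if the grid contains no N2 minutes — an undefined density is a
    flagged condition, never a silent zero.
    """
    n2_min = grid.minutes_in("N2")
    if n2_min <= 0:
        raise ValueError("zero N2 minutes: spindle metrics undefined for subject")
    n = len(events)
    freq = float(np.mean([e.peak_frequency for e in events])) if n else float("nan")
    power = float(np.mean([e.peak_power_s for e in events])) if n else float("nan")
    fast = 100.0 * sum(e.is_fast for e in events) / n if n else float("nan")
    return SpindleMetrics(
        channel=channel, n_events=n, n2_minutes=n2_min,
        density=n / n2_min, mean_frequency=freq, mean_power=power,
        fast_percent=fast,
    )


def detect_spindles(
    recording: SleepRecording,
    grid: EpochGrid,
    annotations: AnnotationTrack | None = None,
    config: DetectorConfig | None = None,
    channels: Sequence[str] | None = None,
) -> tuple[list[SpindleEvent], list[SpindleMetrics], pd.DataFrame]:
    """Full detection on the central channels of a band-limited recording.

    Returns the kept events, per-channel metrics plus a channel-average
    row, and an events table including rejected candidates with their
    rejection reason.
    """
    config = config or DetectorConfig()
    annotations = annotations or AnnotationTrack([])
    channels = list(channels) if channels is not None else list(recording.channels)

    all_events: list[SpindleEvent] = []
    rows = []
    metrics: list[SpindleMetrics] = []
    for ch in channels:
        sig = recording.channel(ch)
        track = compute_power_s_track(sig, grid, config)
        cands = detect_candidates(track, config)
        kept, rejected = reject_candidates(cands, track, annotations, grid, config)
        ch_events = []
        for cand in kept:
            power, freq, fast = characterize_event(sig, grid.sampling_rate,
                                                   cand, track, config)
            ev = SpindleEvent(
                onset=cand.onset, offset=cand.offset, peak_power_s=power,
                peak_frequency=freq, is_fast=fast, channel=ch,
                epoch_index=grid.epoch_of(0.5 * (cand.onset + cand.offset)),
            )
            ch_events.append(ev)
            rows.append((ch, ev.onset, ev.offset, ev.duration, ev.peak_power_s,
                         ev.peak_frequency, ev.is_fast, ev.epoch_index, ""))
        for cand, reason in rejected:
            rows.append((ch, cand.onset, cand.offset, cand.offset - cand.onset,
                         cand.peak_power_s, np.nan, False,
                         grid.epoch_of(0.5 * (cand.onset + cand.offset)), reason))
        all_events.extend(ch_events)
        metrics.append(summarize_metrics(ch_events, grid, channel=ch))

    avg = SpindleMetrics(
        channel="average",
        n_events=int(np.mean([m.n_events for m in metrics])) if metrics else 0,
        n2_minutes=grid.minutes_in("N2"),
        density=float(np.mean([m.density for m in metrics])),
        mean_frequency=float(np.nanmean([m.mean_frequency for m in metrics])),
        mean_power=float(np.nanmean([m.mean_power for m in metrics])),
        fast_percent=float(np.nanmean([m.fast_percent for m in metrics])),
    )
    metrics.append(avg)
    table = pd.DataFrame(rows, columns=[
        "channel", "onset_s", "offset_s", "duration_s", "peak_power_uv2",
        "peak_freq_hz", "is_fast", "epoch_index", "rejected_reason",
    ]).sort_values(["channel", "onset_s"]).reset_index(drop=True)
    return all_events, metrics, table


def events_to_frame(events: Sequence[SpindleEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.channel, e.onset, e.offset, e.duration, e.peak_power_s,
          e.peak_frequency, e.is_fast, e.epoch_index) for e in events],
        columns=["channel", "onset_s", "offset_s", "duration_s",
                 "peak_power_uv2", "peak_freq_hz", "is_fast", "epoch_index"],
    )
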