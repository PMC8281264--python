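"""Absolute NREM sigma-band spectral power.

Per 30-s epoch, 22 overlapping 2.56-s Hann windows (1.28-s step, half
overlap) are FFT'd and averaged into one power spectrum at 1/2.56 s =
0.390625 Hz resolution.  Sigma power is the inclusive bin sum over
11.33-14.84 Hz, averaged over accepted (artifact-free) N2+N3 epochs and
over the two central channels, in uV^2.  The band-limiting stage is an
order-8 Butterworth band-pass at 0.3-30.0 Hz applied zero-phase.

Per-window spectra are normalized so a stationary unit-amplitude in-band
sinusoid sums to its time-domain variance of 0.5 uV^2 across bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .recordings import AnnotationTrack, EpochGrid, SleepRecording

__all__ = [
    "SpectralConfig",
    "EpochSpectrum",
    "SigmaResult",
    "bandpass",
    "epoch_psd",
    "sigma_band_power",
    "sigma_band_indices",
    "flag_artifacts",
    "aggregate_sigma",
    "sigma_power",
]


@dataclass
class SpectralConfig:
    """Spectral-pipeline constants; defaults are the published values."""

    bandpass: tuple[float, float] = (0.3, 30.0)   # Hz
    butter_order: int = 8        # total order of the band-pass stage
    window_length: float = 2.56  # s -> 0.390625 Hz bins
    window_step: float = 1.28    # s, half overlap
    windows_per_epoch: int = 22
    sigma_band: tuple[float, float] = (11.33, 14.84)  # Hz, inclusive
    stages_included: tuple[str, ...] = ("N2", "N3")
    amplitude_threshold: float = 250.0  # uV, movement-artifact rejection
    #: optional hook for ECG-interference correction; receives and returns
    #: the per-channel signal; default is the identity
    ecg_correction: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        span = (self.windows_per_epoch - 1) * self.window_step + self.window_length
        if span > 30.0 + 1e-9:
            raise ValueError("window tiling exceeds the 30-s epoch")
        if not (self.bandpass[0] < self.sigma_band[0]
                < self.sigma_band[1] < self.bandpass[1]):
            raise ValueError("sigma_band must lie inside the bandpass")

    @property
    def bin_resolution(self) -> float:
        """Spectral bin spacing in Hz (1/window_length)."""
        return 1.0 / self.window_length


@dataclass
class EpochSpectrum:
    """Average power spectrum of one 30-s epoch."""

    epoch_index: int
    power: np.ndarray       # per-bin power, uV^2 (bin sum = band power)
    freqs: np.ndarray       # bin centre frequencies, Hz
    accepted: bool = True


@dataclass
class SigmaResult:
    """Subject-level sigma power with per-channel provenance."""

    sigma_power: float               # uV^2, channel average
    per_channel: dict[str, float]
    n_epochs_total: int              # NREM epochs considered (per channel)
    n_epochs_accepted: dict[str, int]
    percent_accepted: float          # % over channels

    def __post_init__(self) -> None:
        if self.sigma_power < 0:
            raise ValueError("sigma_power must be >= 0")


def bandpass(x: np.ndarray, fs: float, config: SpectralConfig | None = None) -> np.ndarray:
    """Zero-phase order-8 Butterworth band-pass (0.3-30.0 Hz)."""
    config = config or SpectralConfig()
    sos = _sig.butter(config.butter_order // 2, config.bandpass,
                      btype="bandpass", fs=fs, output="sos")
    # order/2 per pass: forward-backward filtering doubles the effective order
    return _sig.sosfiltfilt(sos, x)


def epoch_psd(
    signal: np.ndarray,
    grid: EpochGrid,
    config: SpectralConfig | None = None,
    epochs: Sequence[int] | None = None,
) -> list[EpochSpectrum]:
    """Per-epoch average power spectrum from 22 Hann windows.

    Trailing partial epochs (shorter than one window) are skipped.  The
    22 windows are weighted uniformly in the average.
    """
    config = config or SpectralConfig()
    fs = grid.sampling_rate
    nwin = int(round(config.window_length * fs))
    nstep = int(round(config.window_step * fs))
    win = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(nwin) / nwin))
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    norm = nwin * np.sum(win**2)

    out: list[EpochSpectrum] = []
    idx = range(grid.n_epochs) if epochs is None else epochs
    for i in idx:
        sl = grid.epoch_slice(i)
        seg = signal[sl]
        if len(seg) < nwin:
            continue  # trailing partial epoch
        starts = [k * nstep for k in range(config.windows_per_epoch)
                  if k * nstep + nwin <= len(seg)]
        mat = np.stack([seg[s : s + nwin] for s in starts])
        spec = np.abs(np.fft.rfft(mat * win, axis=1)) ** 2
        spec[:, 1:] *= 2.0
        if nwin % 2 == 0:
            spec[:, -1] /= 2.0
        power = spec.mean(axis=0) / norm
        out.append(EpochSpectrum(epoch_index=int(i), power=power, freqs=freqs))
    return out


def sigma_band_indices(freqs: np.ndarray, config: SpectralConfig | None = None
                       ) -> slice:
    """Inclusive bin range for the sigma band.

    The printed 11.33/14.84 Hz edges are rounded bin-centre frequencies on
    the 0.390625 Hz grid (bins 29 and 38); edges are mapped to the nearest
    bin and both included.
    """
    config = config or SpectralConfig()
    df = float(freqs[1] - freqs[0])
    lo = int(round(config.sigma_band[0] / df))
    hi = int(round(config.sigma_band[1] / df))
    return slice(lo, hi + 1)


def sigma_band_power(spectrum: EpochSpectrum,
                     config: SpectralConfig | None = None) -> float:
    """Sum of per-bin power over the sigma band, both edges inclusive (uV^2)."""
    sl = sigma_band_indices(spectrum.freqs, config)
    return float(np.sum(spectrum.power[sl]))


def flag_artifacts(
    signal: np.ndarray,
    grid: EpochGrid,
    annotations: AnnotationTrack | None = None,
    config: SpectralConfig | None = None,
) -> np.ndarray:
    """Per-epoch acceptance flags.

    An epoch is rejected when its peak absolute amplitude exceeds the
    movement-artifact threshold (default 250 uV) or when it intersects an
    annotated artifact interval.
    """
    config = config or SpectralConfig()
    accepted = np.ones(grid.n_epochs, dtype=bool)
    for i in range(grid.n_epochs):
        seg = signal[grid.epoch_slice(i)]
        if len(seg) and np.max(np.abs(seg)) > config.amplitude_threshold:
            accepted[i] = False
    if annotations is not None:
        for i in range(grid.n_epochs):
            a, b = grid.epoch_window(i)
            if annotations.overlaps(a, b, label="artifact"):
                accepted[i] = False
    accepted &= ~grid.artifact_flag[: len(accepted)]
    return accepted


def aggregate_sigma(
    spectra_by_channel: dict[str, list[EpochSpectrum]],
    grid: EpochGrid,
    config: SpectralConfig | None = None,
) -> SigmaResult:
    """Mean sigma band power over accepted NREM epochs, averaged over channels.

    "Adjusting for rejected epochs" is read as averaging over accepted
    epochs only, which keeps the result an intensity (uV^2) independent of
    record length.  Raises when a channel has no accepted NREM epoch.
    """
    config = config or SpectralConfig()
    nrem = set(int(i) for i in grid.indices_of(config.stages_included))
    per_channel: dict[str, float] = {}
    n_acc: dict[str, int] = {}
    for ch, spectra in spectra_by_channel.items():
        vals = [sigma_band_power(s, config) for s in spectra
                if s.epoch_index in nrem and s.accepted]
        if not vals:
            raise ValueError(
                f"channel {ch}: zero accepted NREM epochs, sigma power undefined"
            )
        per_channel[ch] = float(np.mean(vals))
        n_acc[ch] = len(vals)
    n_total = len(nrem)
    pct = 100.0 * np.mean([n_acc[ch] / n_total for ch in n_acc]) if n_total else 0.0
    return SigmaResult(
        sigma_power=float(np.mean(list(per_channel.values()))),
        per_channel=per_channel,
        n_epochs_total=n_total,
        n_epochs_accepted=n_acc,
        percent_accepted=float(pct),
    )


def sigma_power(
    recording: SleepRecording,
    grid: EpochGrid,
    annotations: AnnotationTrack | None = None,
    config: SpectralConfig | None = None,
    channels: Sequence[str] | None = None,
) -> SigmaResult:
    """End-to-end subject sigma power from a raw (unfiltered) recording."""
    config = config or SpectralConfig()
    channels = list(channels) if channels is not None else list(recording.channels)
    spectra: dict[str, list[EpochSpectrum]] = {}
    for ch in channels:
        x = recording.channel(ch)
        if config.ecg_correction is not None:
            x = config.ecg_correction(x)
        xf = bandpass(x, recording.sampling_rate, config)
        accepted = flag_artifacts(xf, grid, annotations, config)
        specs = epoch_psd(xf, grid, config)
        for s in specs:
            s.accepted = bool(accepted[s.epoch_index])
        spectra[ch] = specs
    return aggregate_sigma(spectra, grid, config)


def sigma_result_frame(subject_id: str, result: SigmaResult) -> pd.DataFrame:
    """CSV-ready rows: one per channel plus the channel average."""
    rows = []
    for ch, val in result.per_channel.items():
        rows.append((subject_id, ch, val, result.n_epochs_total,
                     result.n_epochs_accepted[ch],
                     100.0 * result.n_epochs_accepted[ch] / max(result.n_epochs_total, 1)))
    rows.append((subject_id, "average", result.sigma_power,
                 result.n_epochs_total,
                 int(np.mean(list(result.n_epochs_accepted.values()))),
                 result.percent_accepted))
    return pd.DataFrame(rows, columns=[
        "subject_id", "channel", "sigma_power_uv2", "n_epochs", "n_accepted",
        "percent_accepted",
    ])
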