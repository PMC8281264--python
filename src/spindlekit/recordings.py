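"""Recording containers, EDF input/output, epoching and the study-wide band limit.

All time handling uses seconds from recording start, half-open intervals
``[onset, offset)`` and 0-based 30-s epoch indices.  An event ending exactly
at an epoch boundary therefore belongs to the earlier epoch only.
"""

from __future__ import annotations

import datetime as _dt
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "STAGES",
    "SleepRecording",
    "Hypnogram",
    "AnnotationTrack",
    "EpochGrid",
    "EPOCH_LENGTH",
    "normalize_channel_label",
    "select_central_channels",
    "bandlimit",
    "write_edf",
    "read_edf",
    "read_recording",
    "read_hypnogram_tsv",
    "write_hypnogram_tsv",
    "read_annotations_tsv",
    "write_annotations_tsv",
    "make_epoch_grid",
]

#: Sleep stage vocabulary on 30-s epochs (AASM-style).
STAGES = ("W", "N1", "N2", "N3", "R")

#: Fixed scoring epoch length in seconds.
EPOCH_LENGTH = 30.0


@dataclass
class SleepRecording:
    """Multichannel EEG in microvolts on a single sampling rate.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in physical units of microvolts.
    channels : list of str
        Channel labels, e.g. ``C3-M2``.
    sampling_rate : float
        Samples per second (100 or 200 Hz in the study designs supported).
    start_time : datetime, optional
        Recording start; only carried through I/O, all analysis is in
        seconds from start.
    reference_dialect : str
        ``"contralateral"``, ``"ipsilateral"`` or ``"unknown"``; provenance
        of the central derivations, recorded for downstream reporting.
    """

    data: np.ndarray
    channels: list[str]
    sampling_rate: float
    start_time: _dt.datetime | None = None
    reference_dialect: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} signal rows for {len(self.channels)} channel labels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel by (normalized) label."""
        labels = [normalize_channel_label(c) for c in self.channels]
        key = normalize_channel_label(label)
        if key not in labels:
            raise KeyError(f"channel {label!r} not in {self.channels}")
        return self.data[labels.index(key)]


@dataclass
class Hypnogram:
    """Sequence of sleep stages over consecutive 30-s epochs."""

    stages: list[str]
    epoch_length: float = EPOCH_LENGTH

    def __post_init__(self) -> None:
        bad = sorted({s for s in self.stages if s not in STAGES})
        if bad:
            raise ValueError(
                f"unknown sleep stage label(s) {bad}; expected one of {list(STAGES)}"
            )

    def __len__(self) -> int:
        return len(self.stages)

    def minutes_in(self, stage: str) -> float:
        return self.stages.count(stage) * self.epoch_length / 60.0


@dataclass
class AnnotationTrack:
    """Arousal and artifact intervals, half-open [onset, offset) seconds."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for onset, offset, label in self.intervals:
            if not onset < offset:
                raise ValueError(f"annotation onset {onset} !< offset {offset}")

    def of_kind(self, label: str) -> list[tuple[float, float]]:
        return [(a, b) for a, b, k in self.intervals if k == label]

    def overlaps(self, onset: float, offset: float, label: str | None = None) -> bool:
        """True if [onset, offset) intersects any (matching) interval."""
        for a, b, k in self.intervals:
            if label is not None and k != label:
                continue
            if onset < b and a < offset:
                return True
        return False


@dataclass
class EpochGrid:
    """0-based 30-s epoch grid over the scored portion of a recording.

    Epochs partition the scored portion without gaps; trailing samples
    beyond the last scored epoch are excluded downstream.
    """

    stages: np.ndarray          # str array, one per scored epoch
    epoch_length: float
    sampling_rate: float
    artifact_flag: np.ndarray   # bool per epoch (from AnnotationTrack artifacts)

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def epoch_window(self, i: int) -> tuple[float, float]:
        """Half-open [i*30, (i+1)*30) window in seconds."""
        return (i * self.epoch_length, (i + 1) * self.epoch_length)

    def epoch_slice(self, i: int) -> slice:
        n = int(round(self.epoch_length * self.sampling_rate))
        return slice(i * n, (i + 1) * n)

    def epoch_of(self, t: float) -> int:
        """Epoch index containing time t (half-open convention)."""
        return int(np.floor(t / self.epoch_length))

    def minutes_in(self, stage: str) -> float:
        return float(np.sum(self.stages == stage)) * self.epoch_length / 60.0

    def indices_of(self, stages: Iterable[str]) -> np.ndarray:
        wanted = set(stages)
        return np.array([i for i, s in enumerate(self.stages) if s in wanted], dtype=int)


def make_epoch_grid(
    recording: SleepRecording,
    hypnogram: Hypnogram,
    annotations: AnnotationTrack | None = None,
) -> EpochGrid:
    """Align a hypnogram to the recording on a 0-based 30-s epoch grid.

    If the hypnogram is shorter than the recording, the trailing samples
    are unscored and excluded; a hypnogram longer than the recording is
    truncated to the epochs fully covered by signal.
    """
    n_fit = int(np.floor(recording.duration / hypnogram.epoch_length))
    n = min(len(hypnogram), n_fit)
    stages = np.array(hypnogram.stages[:n], dtype=object)
    flags = np.zeros(n, dtype=bool)
    if annotations is not None:
        for i in range(n):
            a, b = i * hypnogram.epoch_length, (i + 1) * hypnogram.epoch_length
            flags[i] = annotations.overlaps(a, b, label="artifact")
    return EpochGrid(
        stages=stages,
        epoch_length=hypnogram.epoch_length,
        sampling_rate=recording.sampling_rate,
        artifact_flag=flags,
    )


# ---------------------------------------------------------------------------
# channel label handling

def normalize_channel_label(label: str) -> str:
    """Map EDF channel-label dialects onto one vocabulary.

    ``A1``/``A2`` mastoid names become ``M1``/``M2``; a leading ``EEG``
    prefix and surrounding whitespace are dropped; case is upper-cased.
    ``"EEG C3-A2"`` -> ``"C3-M2"``.
    """
    lab = label.strip().upper()
    if lab.startswith("EEG"):
        lab = lab[3:].strip()
    lab = lab.replace(" ", "")
    for old, new in (("A1", "M1"), ("A2", "M2")):
        lab = lab.replace(old, new)
    return lab


def _is_contralateral(label: str) -> bool:
    # odd-numbered electrodes (left) reference the right mastoid M2 and
    # vice versa
    try:
        site, ref = label.split("-")
    except ValueError:
        return False
    left = site[-1] in "13579"
    return (left and ref == "M2") or ((not left) and ref == "M1")


def select_central_channels(
    recording: SleepRecording, policy: str = "prefer_contralateral"
) -> tuple[str, str]:
    """Pick the (left, right) central derivations to analyze.

    policy ``prefer_contralateral`` selects C3-M2 / C4-M1 when present and
    falls back to the ipsilateral pair; ``ipsilateral_only`` selects
    C3-M1 / C4-M2.  The chosen reference dialect is recorded on the
    recording for downstream covariate/reporting use.
    """
    if policy not in ("prefer_contralateral", "ipsilateral_only"):
        raise ValueError(f"unknown channel policy {policy!r}")
    labels = [normalize_channel_label(c) for c in recording.channels]

    def _find(site: str, contra: bool) -> str | None:
        for lab in labels:
            if lab.startswith(site + "-") and _is_contralateral(lab) == contra:
                return lab
        return None

    pairs: list[tuple[str | None, str | None, str]] = []
    if policy == "prefer_contralateral":
        pairs.append((_find("C3", True), _find("C4", True), "contralateral"))
    pairs.append((_find("C3", False), _find("C4", False), "ipsilateral"))

    for left, right, dialect in pairs:
        if left is not None and right is not None:
            recording.reference_dialect = dialect
            return (left, right)
    raise ValueError(
        "no central (C3/C4) derivation pair in either reference dialect; "
        f"available channels: {labels}"
    )


# ---------------------------------------------------------------------------
# band limiting

def bandlimit(
    recording: SleepRecording,
    low: float = 0.3,
    high: float = 30.0,
    order: int = 4,
) -> SleepRecording:
    """Apply the study-wide zero-phase Butterworth band-pass (0.3-30.0 Hz).

    Forward-backward (``sosfiltfilt``) filtering preserves event timing;
    DC is removed by the high-pass edge.  ``order`` is per pass.
    """
    if recording.sampling_rate < 100:
        raise ValueError("sampling_rate must be >= 100 Hz")
    sos = _sig.butter(
        order, [low, high], btype="bandpass", fs=recording.sampling_rate, output="sos"
    )
    out = _sig.sosfiltfilt(sos, recording.data, axis=1)
    return SleepRecording(
        data=out,
        channels=list(recording.channels),
        sampling_rate=recording.sampling_rate,
        start_time=recording.start_time,
        reference_dialect=recording.reference_dialect,
    )


# ---------------------------------------------------------------------------
# EDF I/O
#
# Reading goes through mne; writing is a minimal EDF (16-bit) encoder with
# 1-s data records, enough for round-tripping simulated recordings.

_EDF_ALLOWED_DIMS = {"UV", "µV".upper(), "MV"}


def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: SleepRecording, path: str | Path) -> None:
    """Write a 16-bit EDF file with 1-s data records, physical unit uV."""
    path = Path(path)
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    nch = len(recording.channels)
    n_records = recording.n_samples // spr
    data = recording.data[:, : n_records * spr]

    start = recording.start_time or _dt.datetime(2000, 1, 1, 21, 0, 0)
    phys_min, phys_max, dig = [], [], []
    for row in data:
        lo, hi = float(np.min(row)), float(np.max(row))
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        scale = (hi - lo) / (32767 - (-32768))
        d = np.round((row - lo) / scale).astype(np.int64) - 32768
        dig.append(np.clip(d, -32768, 32767).astype("<i2"))

    buf = _io.BytesIO()
    buf.write(_edf_field("0", 8))
    buf.write(_edf_field("X X X X", 80))
    buf.write(_edf_field("Startdate X X X X", 80))
    buf.write(_edf_field(start.strftime("%d.%m.%y"), 8))
    buf.write(_edf_field(start.strftime("%H.%M.%S"), 8))
    buf.write(_edf_field(str(256 * (1 + nch)), 8))
    buf.write(_edf_field("", 44))
    buf.write(_edf_field(str(n_records), 8))
    buf.write(_edf_field("1", 8))
    buf.write(_edf_field(str(nch), 4))
    for lab in recording.channels:
        buf.write(_edf_field(lab, 16))
    for _ in range(nch):
        buf.write(_edf_field("", 80))
    for _ in range(nch):
        buf.write(_edf_field("uV", 8))
    for v in phys_min:
        buf.write(_edf_field(f"{v:.8g}"[:8], 8))
    for v in phys_max:
        buf.write(_edf_field(f"{v:.8g}"[:8], 8))
    for _ in range(nch):
        buf.write(_edf_field("-32768", 8))
    for _ in range(nch):
        buf.write(_edf_field("32767", 8))
    for _ in range(nch):
        buf.write(_edf_field("", 80))
    for _ in range(nch):
        buf.write(_edf_field(str(spr), 8))
    for _ in range(nch):
        buf.write(_edf_field("", 32))
    for r in range(n_records):
        for c in range(nch):
            buf.write(dig[c][r * spr : (r + 1) * spr].tobytes())
    path.write_bytes(buf.getvalue())


def _read_edf_header_units(path: Path) -> list[str]:
    """Physical-dimension strings from the EDF header, one per signal."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError("corrupted EDF header: file shorter than 256 bytes")
        try:
            nch = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ValueError(
                "corrupted EDF header: number-of-signals field is not an integer"
            ) from exc
        sig_head = fh.read(256 * nch)
        if len(sig_head) < 256 * nch:
            raise ValueError("corrupted EDF header: truncated signal header block")
    off = nch * (16 + 80)
    dims = []
    for i in range(nch):
        dims.append(sig_head[off + 8 * i : off + 8 * (i + 1)].decode("ascii", "replace").strip())
    return dims


def read_edf(path: str | Path) -> SleepRecording:
    """Read an EDF file into microvolts via mne.

    Channels whose physical dimension is neither uV nor mV are rejected:
    spindle and sigma power are reported in uV^2 and unit guessing would
    silently corrupt them.
    """
    import mne

    path = Path(path)
    dims = _read_edf_header_units(path)
    bad = sorted({d for d in dims if d.upper() not in _EDF_ALLOWED_DIMS})
    if bad:
        raise ValueError(
            f"EDF physical dimension(s) {bad} not supported; expected uV or mV"
        )
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne converts EEG to volts internally
    meas = raw.info.get("meas_date")
    start = None
    if meas is not None:
        start = meas.replace(tzinfo=None) if isinstance(meas, _dt.datetime) else None
    return SleepRecording(
        data=data,
        channels=[normalize_channel_label(c) for c in raw.ch_names],
        sampling_rate=float(raw.info["sfreq"]),
        start_time=start,
    )


# ---------------------------------------------------------------------------
# sidecar tables

def write_hypnogram_tsv(hypnogram: Hypnogram, path: str | Path) -> None:
    df = pd.DataFrame(
        {"epoch_index": np.arange(len(hypnogram)), "stage": hypnogram.stages}
    )
    df.to_csv(path, sep="\t", index=False)


def read_hypnogram_tsv(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("epoch_index")
    if not np.array_equal(df["epoch_index"].to_numpy(), np.arange(len(df))):
        raise ValueError("hypnogram epoch_index must be contiguous from 0")
    return Hypnogram(stages=[str(s) for s in df["stage"]])


def write_annotations_tsv(annotations: AnnotationTrack, path: str | Path) -> None:
    df = pd.DataFrame(
        annotations.intervals, columns=["onset_s", "offset_s", "label"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path: str | Path) -> AnnotationTrack:
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        return AnnotationTrack([])
    bad = sorted(set(df["label"]) - {"arousal", "artifact"})
    if bad:
        raise ValueError(f"unknown annotation label(s) {bad}")
    return AnnotationTrack(
        [(float(a), float(b), str(k)) for a, b, k in
         zip(df["onset_s"], df["offset_s"], df["label"])]
    )


def read_recording(
    edf_path: str | Path,
    hypnogram_path: str | Path,
    annotations_path: str | Path | None = None,
) -> tuple[SleepRecording, Hypnogram, AnnotationTrack]:
    """Read and harmonize one subject's EDF, hypnogram and annotations."""
    rec = read_edf(edf_path)
    hyp = read_hypnogram_tsv(hypnogram_path)
    ann = AnnotationTrack([])
    if annotations_path is not None and Path(annotations_path).exists():
        ann = read_annotations_tsv(annotations_path)
    return rec, hyp, ann
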