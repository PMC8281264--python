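"""Synthetic staged sleep EEG and cohort tables with known ground truth.

The EEG generator emulates central-derivation pediatric sleep EEG: a 1/f
background, spindle bursts (sinusoid under a raised-cosine envelope) embedded
in N2, alpha-range contaminants, arousals and high-amplitude movement
artifacts, all placed by a homogeneous Poisson process within the eligible
stages.  The cohort generator draws subjects whose outcomes follow known
polynomial age trajectories with covariate effects and Gaussian noise, so
every downstream statistic has a parameter-recovery test surface.

All randomness flows from one integer seed through one numpy Generator;
identical seed + config gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .recordings import (
    STAGES,
    AnnotationTrack,
    Hypnogram,
    SleepRecording,
    write_annotations_tsv,
    write_edf,
    write_hypnogram_tsv,
)

__all__ = [
    "EEGSimConfig",
    "GroundTruthEvent",
    "CohortSimConfig",
    "simulate_sleep_eeg",
    "simulate_cohort",
    "write_simulated_subject",
    "DEFAULT_TRAJECTORIES",
    "OUTCOMES",
]

#: Default staged-night layout, minutes per contiguous stage block.
DEFAULT_STAGE_SEQUENCE: tuple[tuple[str, float], ...] = (
    ("W", 2.0),
    ("N1", 2.0),
    ("N2", 10.0),
    ("N3", 8.0),
    ("N2", 8.0),
    ("R", 4.0),
)


@dataclass
class EEGSimConfig:
    """Knobs for the staged-EEG generator.

    Defaults reflect the recording designs the pipeline targets: 100 Hz
    sampling (the older PSG systems; 200 Hz also supported), ~10 uV
    band-limited background with a 1/f spectrum, spindles at 4 per minute
    of N2 with 11-15 Hz centre frequencies, 0.5-2 s durations and a 30 uV
    peak envelope (3x background RMS, a clearly expressed spindle).
    """

    sampling_rate: float = 100.0
    stage_sequence_spec: tuple[tuple[str, float], ...] = DEFAULT_STAGE_SEQUENCE
    background_slope: float = 1.0     # 1/f exponent of the background PSD
    background_rms: float = 10.0      # uV after band limiting
    spindle_rate: float = 4.0         # events per minute of N2
    spindle_freq_range: tuple[float, float] = (11.0, 15.0)   # Hz, within [10, 16]
    spindle_duration_range: tuple[float, float] = (0.5, 2.0)  # s
    spindle_amplitude: float = 30.0   # uV peak envelope
    alpha_contaminant_rate: float = 0.5   # events per minute (any stage)
    arousal_rate: float = 4.0         # events per hour
    artifact_rate: float = 4.0        # events per hour
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.spindle_freq_range
        if not (10.0 <= lo < hi <= 16.0):
            raise ValueError("spindle_freq_range must lie within [10, 16] Hz")
        dlo, dhi = self.spindle_duration_range
        if not (0 < dlo <= dhi):
            raise ValueError("spindle durations must be positive and ordered")
        for name in ("spindle_rate", "alpha_contaminant_rate", "arousal_rate",
                     "artifact_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for stage, minutes in self.stage_sequence_spec:
            if stage not in STAGES:
                raise ValueError(
                    f"invalid stage label {stage!r} in stage_sequence_spec; "
                    f"expected one of {list(STAGES)}"
                )
            if minutes <= 0:
                raise ValueError("stage block minutes must be > 0")

    @property
    def duration(self) -> float:
        """Total recording length in seconds (sum of the stage blocks)."""
        return 60.0 * sum(m for _, m in self.stage_sequence_spec)


@dataclass(frozen=True)
class GroundTruthEvent:
    """One embedded event, half-open [onset, offset) seconds."""

    onset: float
    offset: float
    center_frequency: float   # Hz; 0 for broadband artifacts/arousals
    amplitude: float          # uV peak envelope
    kind: Literal["spindle", "alpha_burst", "artifact", "arousal"]

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("event onset must precede offset")


def _stage_blocks(config: EEGSimConfig) -> list[tuple[str, float, float]]:
    """(stage, start_s, end_s) for each contiguous block."""
    out, t = [], 0.0
    for stage, minutes in config.stage_sequence_spec:
        out.append((stage, t, t + 60.0 * minutes))
        t += 60.0 * minutes
    return out


def _hypnogram_from_spec(config: EEGSimConfig) -> Hypnogram:
    stages: list[str] = []
    for stage, minutes in config.stage_sequence_spec:
        stages.extend([stage] * int(round(minutes * 2)))
    return Hypnogram(stages=stages)


def _one_over_f_background(
    rng: np.random.Generator, n: int, fs: float, slope: float, rms: float
) -> np.ndarray:
    """Spectrally shaped Gaussian noise with PSD ~ f**(-slope), unit-free
    then rescaled to the requested RMS."""
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-slope / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    x *= rms / np.std(x)
    return x


def _raised_cosine_burst(
    fs: float, duration: float, freq: float, amplitude: float, phase: float
) -> np.ndarray:
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / duration))  # Hann
    return amplitude * envelope * np.sin(2.0 * np.pi * freq * t + phase)


def _poisson_intervals(
    rng: np.random.Generator,
    blocks: list[tuple[str, float, float]],
    eligible: set[str],
    rate_per_s: float,
    duration_sampler,
    existing: list[tuple[float, float]],
    reject_overlap: bool = True,
) -> list[tuple[float, float]]:
    """Homogeneous Poisson placement within eligible stage blocks, with
    rejection of overlaps against ``existing`` (and each other)."""
    placed: list[tuple[float, float]] = []
    if rate_per_s <= 0:
        return placed
    for stage, t0, t1 in blocks:
        if stage not in eligible:
            continue
        n = rng.poisson(rate_per_s * (t1 - t0))
        for _ in range(n):
            dur = float(duration_sampler())
            if t1 - t0 <= dur:
                continue
            for _attempt in range(50):
                onset = float(rng.uniform(t0, t1 - dur))
                iv = (onset, onset + dur)
                clash = any(iv[0] < b and a < iv[1] for a, b in existing + placed)
                if not (reject_overlap and clash):
                    placed.append(iv)
                    break
    return placed


def simulate_sleep_eeg(
    config: EEGSimConfig, return_components: bool = False
) -> (
    tuple[SleepRecording, Hypnogram, list[GroundTruthEvent]]
    | tuple[SleepRecording, Hypnogram, list[GroundTruthEvent], dict[str, np.ndarray]]
):
    """Generate a two-channel (C3-M2, C4-M1) staged recording in uV.

    Returns the recording, its hypnogram (matching ``stage_sequence_spec``),
    and the exact ground-truth event list.  With ``return_components=True`` a
    dict of clean per-source signals (``background``, ``spindles``, ...) is
    appended — the spindle-only component supports oracle checks that recover
    every embedded burst by direct envelope thresholding.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    blocks = _stage_blocks(config)
    hyp = _hypnogram_from_spec(config)

    components = {
        "background": np.stack([
            _one_over_f_background(rng, n, fs, config.background_slope,
                                   config.background_rms)
            for _ in range(2)
        ]),
        "spindles": np.zeros((2, n)),
        "alpha": np.zeros((2, n)),
        "artifacts": np.zeros((2, n)),
    }
    events: list[GroundTruthEvent] = []

    def _add_burst(store: str, onset: float, dur: float, freq: float,
                   amp: float) -> None:
        burst = _raised_cosine_burst(fs, dur, freq, amp,
                                     phase=float(rng.uniform(0, 2 * np.pi)))
        i0 = int(round(onset * fs))
        seg = components[store][:, i0 : i0 + len(burst)]
        seg += burst[: seg.shape[1]]

    # spindles: Poisson within N2 blocks, no overlaps
    spindle_ivs = _poisson_intervals(
        rng, blocks, {"N2"}, config.spindle_rate / 60.0,
        lambda: rng.uniform(*config.spindle_duration_range), existing=[],
    )
    for onset, offset in sorted(spindle_ivs):
        freq = float(rng.uniform(*config.spindle_freq_range))
        _add_burst("spindles", onset, offset - onset, freq, config.spindle_amplitude)
        events.append(GroundTruthEvent(onset, offset, freq,
                                       config.spindle_amplitude, "spindle"))

    # alpha contaminants anywhere, kept clear of spindles
    alpha_ivs = _poisson_intervals(
        rng, blocks, set(STAGES), config.alpha_contaminant_rate / 60.0,
        lambda: rng.uniform(0.5, 1.5), existing=list(spindle_ivs),
    )
    for onset, offset in sorted(alpha_ivs):
        freq = float(rng.uniform(8.0, 9.5))
        _add_burst("alpha", onset, offset - onset, freq, config.spindle_amplitude)
        events.append(GroundTruthEvent(onset, offset, freq,
                                       config.spindle_amplitude, "alpha_burst"))

    # arousals: annotation-only intervals (sleep stages)
    arousal_ivs = _poisson_intervals(
        rng, blocks, {"N1", "N2", "N3", "R"}, config.arousal_rate / 3600.0,
        lambda: rng.uniform(3.0, 10.0), existing=[],
    )
    for onset, offset in sorted(arousal_ivs):
        events.append(GroundTruthEvent(onset, offset, 0.0, 0.0, "arousal"))

    # movement artifacts: large slow transients
    artifact_ivs = _poisson_intervals(
        rng, blocks, set(STAGES), config.artifact_rate / 3600.0,
        lambda: rng.uniform(0.5, 2.0), existing=list(spindle_ivs),
    )
    for onset, offset in sorted(artifact_ivs):
        _add_burst("artifacts", onset, offset - onset, 2.0, 500.0)
        events.append(GroundTruthEvent(onset, offset, 2.0, 500.0, "artifact"))

    events.sort(key=lambda e: e.onset)
    data = sum(components.values())
    rec = SleepRecording(
        data=data, channels=["C3-M2", "C4-M1"], sampling_rate=fs,
        reference_dialect="contralateral",
    )
    if return_components:
        return rec, hyp, events, components
    return rec, hyp, events


def annotations_from_events(events: list[GroundTruthEvent]) -> AnnotationTrack:
    """Arousal/artifact annotation track implied by the ground truth."""
    return AnnotationTrack(
        [(e.onset, e.offset, e.kind) for e in events
         if e.kind in ("arousal", "artifact")]
    )


def write_simulated_subject(
    config: EEGSimConfig, out_dir: str | Path, subject_id: str = "sim01"
) -> dict[str, Path]:
    """Simulate one subject and persist EDF + hypnogram/annotations/events
    sidecar tables; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec, hyp, events = simulate_sleep_eeg(config)
    paths = {
        "edf": out_dir / f"{subject_id}.edf",
        "hypnogram": out_dir / f"{subject_id}_hypnogram.tsv",
        "annotations": out_dir / f"{subject_id}_annotations.tsv",
        "events": out_dir / f"{subject_id}_events.tsv",
    }
    write_edf(rec, paths["edf"])
    write_hypnogram_tsv(hyp, paths["hypnogram"])
    write_annotations_tsv(annotations_from_events(events), paths["annotations"])
    pd.DataFrame(
        [(e.onset, e.offset, e.kind, e.center_frequency, e.amplitude)
         for e in events],
        columns=["onset_s", "offset_s", "kind", "frequency_hz", "amplitude_uv"],
    ).to_csv(paths["events"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# cohort simulation

#: Outcome columns carried by simulated cohorts.
OUTCOMES = ("spindle_density", "spindle_frequency", "spindle_power",
            "fast_percent", "sigma_power")

#: Default generating trajectories: polynomial coefficients in age
#: (intercept, age, age^2, age^3).  Chosen to mirror plausible pediatric
#: central-EEG values: density and sigma power follow inverted-U quadratics
#: peaking in adolescence, frequency rises linearly, power declines linearly.
DEFAULT_TRAJECTORIES: dict[str, tuple[float, ...]] = {
    "spindle_density": (0.648, 0.608, -0.02, 0.0),      # vertex at 15.2 y
    "spindle_frequency": (11.8, 0.06, 0.0, 0.0),        # Hz, linear rise
    "spindle_power": (420.0, -12.0, 0.0, 0.0),          # uV^2, linear decline
    "fast_percent": (-10.0, 7.72, -0.20, 0.0),          # vertex at 19.3 y
    "sigma_power": (8.0, 3.9, -0.15, 0.0),              # vertex at 13.0 y
}

#: Default noise SDs in outcome units.
DEFAULT_NOISE_SD: dict[str, float] = {
    "spindle_density": 1.0,
    "spindle_frequency": 0.5,
    "spindle_power": 90.0,
    "fast_percent": 15.0,
    "sigma_power": 10.0,
}


@dataclass
class CohortSimConfig:
    """Generator for cross-sectional / paired-longitudinal cohort tables.

    Default sizes mirror the pediatric cohort designs this pipeline targets:
    572 cross-sectional subjects aged 6-21, or 332 longitudinal pairs with
    baseline ages 5-12 followed up 6-13 years later at ages 12-22; ~48%
    female; females reach Tanner stages earlier than males.
    """

    n_subjects: int = 572
    age_range: tuple[float, float] = (6.0, 21.0)
    sex_ratio: float = 0.48           # fraction female
    tanner_shift_female: float = 1.5  # years earlier than males
    tanner_midpoint_male: float = 13.5  # age of expected mid-puberty in males
    trajectory_coefficients: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORIES)
    )
    sex_effects: dict[str, float] = field(default_factory=dict)  # female offset
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"bmi": 0.0, "ahi": 0.0, "disorder_flag": 0.0,
                                 "psg_system": 0.0}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD)
    )
    baseline_age_range: tuple[float, float] = (5.0, 12.0)
    followup_interval_range: tuple[float, float] = (6.0, 13.0)
    max_followup_age: float = 22.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not (5.0 <= lo < hi <= 23.0):
            raise ValueError("age_range must lie within [5, 23] years")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be a fraction in [0, 1]")
        for k, v in self.noise_sd.items():
            if v < 0:
                raise ValueError(f"noise_sd[{k!r}] must be >= 0")


def tanner_probabilities(age: float, sex: str, config: CohortSimConfig) -> np.ndarray:
    """P(Tanner stage 1..5 | age, sex) from an ordered-logit ladder.

    Stage thresholds are centred on ``tanner_midpoint_male`` and shifted
    ``tanner_shift_female`` years earlier for females, the canonical
    direction of pubertal timing.
    """
    mid = config.tanner_midpoint_male
    if sex == "female":
        mid -= config.tanner_shift_female
    cuts = np.array([mid - 3.0, mid - 1.0, mid + 0.5, mid + 2.0])
    # P(stage > k) for the four cutpoints
    p_gt = 1.0 / (1.0 + np.exp(-(age - cuts) / 0.8))
    cum = np.concatenate([[1.0], p_gt, [0.0]])
    probs = cum[:-1] - cum[1:]
    return probs / probs.sum()


def _outcome_mean(
    outcome: str, age: np.ndarray, row: pd.DataFrame, config: CohortSimConfig
) -> np.ndarray:
    coef = np.asarray(config.trajectory_coefficients[outcome], dtype=float)
    mean = sum(c * age**p for p, c in enumerate(coef))
    mean = mean + config.sex_effects.get(outcome, 0.0) * (row["sex"] == "female")
    for cov, beta in config.covariate_effects.items():
        vals = row[cov]
        if cov == "psg_system":  # nominal system code enters linearly here
            vals = vals.map({"B1": 0.0, "B2": 1.0, "F": 2.0})
        mean = mean + beta * np.asarray(vals, dtype=float)
    return np.asarray(mean, dtype=float)


def _draw_covariates(rng: np.random.Generator, n: int,
                     config: CohortSimConfig) -> pd.DataFrame:
    sex = np.where(rng.uniform(size=n) < config.sex_ratio, "female", "male")
    race = np.where(rng.uniform(size=n) < 0.26, "minority", "NH-white")
    bmi = np.clip(rng.normal(60.0, 25.0, size=n), 1.0, 99.0)  # BMI percentile
    ahi = np.round(rng.gamma(shape=1.0, scale=1.5, size=n), 2)
    disorder = (rng.uniform(size=n) < 0.2).astype(int)
    psg = rng.choice(["B1", "B2", "F"], size=n, p=[0.35, 0.25, 0.40])
    return pd.DataFrame({
        "sex": sex, "race_ethnicity": race, "bmi": bmi, "ahi": ahi,
        "disorder_flag": disorder, "psg_system": psg,
    })


def simulate_cohort(
    config: CohortSimConfig,
    mode: Literal["cross_sectional", "longitudinal"] = "cross_sectional",
) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table plus the true generating parameters.

    cross_sectional: one row per subject, ``age`` uniform over ``age_range``.
    longitudinal: one row per subject pairing a baseline (``age_baseline``)
    and a follow-up wave; ``age`` is the follow-up age, equal to baseline age
    plus ``followup_years`` drawn from ``followup_interval_range`` (resampled
    so follow-up does not exceed ``max_followup_age``); each outcome carries a
    paired ``<outcome>_baseline`` column drawn from the same trajectories.
    """
    if mode not in ("cross_sectional", "longitudinal"):
        raise ValueError(f"unknown cohort mode {mode!r}")
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    df = _draw_covariates(rng, n, config)
    df.insert(0, "subject_id", [f"S{i:04d}" for i in range(n)])

    if mode == "cross_sectional":
        age = rng.uniform(*config.age_range, size=n)
    else:
        age_base = rng.uniform(*config.baseline_age_range, size=n)
        lo, hi = config.followup_interval_range
        interval = rng.uniform(lo, hi, size=n)
        cap = config.max_followup_age - age_base
        over = interval > cap
        interval[over] = lo + (cap[over] - lo) * rng.uniform(size=int(over.sum()))
        age = age_base + interval
        df["age_baseline"] = age_base
        df["followup_years"] = interval
    df["age"] = age

    # Tanner stage at the (follow-up) age
    tanner = np.empty(n, dtype=int)
    for i in range(n):
        p = tanner_probabilities(float(age[i]), str(df["sex"].iloc[i]), config)
        tanner[i] = rng.choice(np.arange(1, 6), p=p)
    df["tanner"] = tanner

    for outcome in config.trajectory_coefficients:
        sd = config.noise_sd.get(outcome, 0.0)
        df[outcome] = _outcome_mean(outcome, age, df, config) + (
            rng.normal(0.0, sd, size=n) if sd > 0 else 0.0
        )
        if mode == "longitudinal":
            base = _outcome_mean(outcome, df["age_baseline"].to_numpy(), df, config)
            df[f"{outcome}_baseline"] = base + (
                rng.normal(0.0, sd, size=n) if sd > 0 else 0.0
            )

    truth = {
        "trajectory_coefficients": {
            k: tuple(v) for k, v in config.trajectory_coefficients.items()
        },
        "sex_effects": dict(config.sex_effects),
        "covariate_effects": dict(config.covariate_effects),
        "noise_sd": dict(config.noise_sd),
        "mode": mode,
    }
    return df, truth
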