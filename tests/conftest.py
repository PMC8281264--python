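import numpy as np
import pytest

from spindlekit import EEGSimConfig, bandlimit, make_epoch_grid, simulate_sleep_eeg
from spindlekit.recordings import EpochGrid
from spindlekit.simulate import annotations_from_events


@pytest.fixture(scope="session")
def n2_recording():
    """One clean 10-min all-N2 recording with ground truth (session-cached)."""
    cfg = EEGSimConfig(
        seed=11,
        stage_sequence_spec=(("N2", 10.0),),
        arousal_rate=0.0,
        artifact_rate=0.0,
        alpha_contaminant_rate=0.0,
    )
    rec, hyp, events, components = simulate_sleep_eeg(cfg, return_components=True)
    grid = make_epoch_grid(rec, hyp, annotations_from_events(events))
    return {
        "config": cfg,
        "recording": rec,
        "filtered": bandlimit(rec),
        "hypnogram": hyp,
        "grid": grid,
        "events": events,
        "components": components,
    }


@pytest.fixture()
def flat_grid():
    """Factory for an all-N2 epoch grid without a recording."""

    def _make(n_epochs: int, fs: float = 100.0, stage: str = "N2") -> EpochGrid:
        return EpochGrid(
            stages=np.array([stage] * n_epochs, dtype=object),
            epoch_length=30.0,
            sampling_rate=fs,
            artifact_flag=np.zeros(n_epochs, dtype=bool),
        )

    return _make
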