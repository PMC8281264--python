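"""Ground-truth evaluation utilities for the detector.

Event-level matching pairs each true spindle with at most one detection by
greatest temporal overlap; a pair counts as a hit when the overlap covers at
least half of the shorter of the two intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["MatchCounts", "match_events"]


@dataclass
class MatchCounts:
    true_positives: int
    false_negatives: int
    false_positives: int

    @property
    def sensitivity(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else float("nan")

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else float("nan")


def match_events(
    truth: Sequence[tuple[float, float]],
    detected: Sequence[tuple[float, float]],
    min_overlap: float = 0.5,
) -> MatchCounts:
    """One-to-one greedy matching of (onset, offset) intervals."""
    used: set[int] = set()
    tp = 0
    for t_on, t_off in truth:
        best, best_ov = None, 0.0
        for j, (d_on, d_off) in enumerate(detected):
            if j in used:
                continue
            ov = min(t_off, d_off) - max(t_on, d_on)
            if ov > best_ov:
                best_ov, best = ov, j
        if best is not None:
            d_on, d_off = detected[best]
            if best_ov >= min_overlap * min(t_off - t_on, d_off - d_on):
                used.add(best)
                tp += 1
    return MatchCounts(
        true_positives=tp,
        false_negatives=len(truth) - tp,
        false_positives=len(detected) - tp,
    )
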