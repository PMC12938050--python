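"""Four-state Markov chain of group huddling configurations.

The group state (non-huddling, dyad, triad, quartet) is sampled at a fixed
interval (default 60 s; instantaneous sample at the interval start) to give
one discrete-time sequence per recording. Sequences are concatenated for
transition estimation, counting adjacent pairs only within a sequence —
never across recording boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StateSequence", "TransitionMatrix", "sample_states", "estimate_transitions"]

STATE_ORDER = [0, 2, 3, 4]  # NONE, DYAD, TRIAD, QUARTET
STATE_LABELS = ["NONE", "DYAD", "TRIAD", "QUARTET"]
_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}


@dataclass
class StateSequence:
    recording_id: str
    states: np.ndarray  # values in {0, 2, 3, 4}
    interval: float = 60.0  # s

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.size == 0:
            raise ValueError("state sequence must be nonempty")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        bad = set(np.unique(self.states)) - set(STATE_ORDER)
        if bad:
            raise ValueError(f"invalid states {sorted(bad)}")


@dataclass
class TransitionMatrix:
    counts: np.ndarray  # (4, 4) int
    P: np.ndarray  # (4, 4); rows with zero counts are all-zero (undefined)
    state_labels: list[str] = field(default_factory=lambda: list(STATE_LABELS))

    @property
    def undefined_rows(self) -> list[int]:
        return [i for i in range(4) if self.counts[i].sum() == 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.state_labels, columns=self.state_labels)


def sample_states(state_series: np.ndarray, fps: float, interval: float = 60.0,
                  recording_id: str = "rec", anchor_frame: int = 0) -> StateSequence:
    """Instantaneous group state at the first frame of each interval.

    ``anchor_frame`` shifts the sampling origin (e.g. to the first huddle
    onset); the sequence length is ``floor(remaining_frames / (interval*fps))``.
    """
    step = int(round(interval * fps))
    if step < 1:
        raise ValueError("interval * fps must be >= 1")
    series = np.asarray(state_series, dtype=int)[anchor_frame:]
    n = len(series) // step
    if n == 0:
        raise ValueError("series shorter than one interval")
    return StateSequence(recording_id, series[: n * step : step], interval)


def estimate_transitions(sequences: list[StateSequence], alpha: float = 0.0) -> TransitionMatrix:
    """Row-stochastic transition estimate from within-sequence adjacent pairs.

    Rows never visited are left all-zero (undefined), not imputed; ``alpha``
    adds optional Laplace smoothing (default 0, for simulation studies only).
    """
    if not sequences:
        raise ValueError("at least one sequence required")
    counts = np.zeros((4, 4), dtype=int)
    for seq in sequences:
        idx = np.array([_INDEX[s] for s in seq.states])
        np.add.at(counts, (idx[:-1], idx[1:]), 1)
    num = counts + alpha
    rowsum = num.sum(axis=1, keepdims=True)
    P = np.zeros((4, 4))
    defined = (counts.sum(axis=1) > 0) | (alpha > 0)
    P[defined] = num[defined] / rowsum[defined]
    return TransitionMatrix(counts=counts, P=P)
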