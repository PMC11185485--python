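"""Stimulus designs: ordered event tables shared by every modality.

A :class:`StimulusDesign` is the common currency of the pipeline — the fUS
GLM, the facial-expression trial statistics, the head-fixed trial split and
the spike-train trial averaging all consume the same (onset, duration,
condition) event list.  Time intervals are half-open ``[onset, onset +
duration)`` and all frame indexing downstream is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StimulusDesign"]


@dataclass(frozen=True)
class StimulusDesign:
    """Ordered, non-overlapping stimulus events within a recording run.

    Parameters
    ----------
    events
        Sequence of ``(onset_s, duration_s, condition)`` tuples with strictly
        increasing onsets.
    run_length_s
        Total run duration in seconds; every event must end within it.
    """

    events: tuple[tuple[float, float, str], ...]
    run_length_s: float

    def __post_init__(self) -> None:
        events = tuple((float(o), float(d), str(c)) for o, d, c in self.events)
        object.__setattr__(self, "events", events)
        onsets = [o for o, _, _ in events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        for (o, d, _), nxt in zip(events, list(events[1:]) + [None]):
            if d < 0:
                raise ValueError("event durations must be non-negative")
            if o + d > self.run_length_s + 1e-9:
                raise ValueError(
                    f"event at {o} s with duration {d} s exceeds run length "
                    f"{self.run_length_s} s"
                )
            if nxt is not None and o + d > nxt[0] + 1e-9:
                raise ValueError("events overlap")

    @property
    def onsets(self) -> np.ndarray:
        return np.array([o for o, _, _ in self.events])

    @property
    def durations(self) -> np.ndarray:
        return np.array([d for _, d, _ in self.events])

    @property
    def conditions(self) -> list[str]:
        return [c for _, _, c in self.events]

    @property
    def condition_set(self) -> list[str]:
        """Unique condition labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c)
        return list(seen)

    def boxcar(self, t: np.ndarray, condition: str | None = None) -> np.ndarray:
        """Indicator of stimulus-on at each timestamp (half-open windows).

        With ``condition`` given, only that condition's events count.
        """
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=float)
        for onset, dur, cond in self.events:
            if condition is not None and cond != condition:
                continue
            out[(t >= onset) & (t < onset + dur)] = 1.0
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["onset_s", "duration_s", "condition"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, run_length_s: float) -> "StimulusDesign":
        events = tuple(
            (float(r.onset_s), float(r.duration_s), str(r.condition))
            for r in df.itertuples()
        )
        return cls(events=events, run_length_s=float(run_length_s))
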