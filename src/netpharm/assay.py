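"""Behavioural assay metric: novel-object-recognition discrimination index."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AssayTrial", "discrimination_index"]


@dataclass(frozen=True)
class AssayTrial:
    """Exploration times (seconds) of the novel and familiar object."""

    time_novel: float
    time_old: float

    def __post_init__(self):
        if self.time_novel < 0 or self.time_old < 0:
            raise ValueError("exploration times must be non-negative")


def discrimination_index(t: AssayTrial) -> float:
    """(novel − familiar) / (novel + familiar), in [−1, 1].

    Positive values indicate preference for the novel object (intact
    recognition memory); zero means no preference.
    """
    total = t.time_novel + t.time_old
    if total == 0:
        raise ValueError("discrimination index undefined: both times zero")
    return (t.time_novel - t.time_old) / total
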