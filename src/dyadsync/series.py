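"""Uniformly sampled per-participant signals.

A :class:`SignalSeries` holds one participant's recording for one round:
smile intensity (0-100, typically 25 Hz) or heart rate (bpm, typically
0.5 Hz). Sampling is uniform and gap-free; missing interior samples are an
input error, not a representable state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

MODALITIES = ("smile", "hr")


@dataclass
class SignalSeries:
    participant_id: str
    round: int
    modality: str
    rate_hz: float
    values: np.ndarray
    dyad_id: str | None = None
    condition: str | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not self.units:
            self.units = "intensity" if self.modality == "smile" else "bpm"

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at t = 0."""
        return np.arange(self.n_samples) / self.rate_hz

    def replace(self, **changes) -> "SignalSeries":
        """Copy with some fields replaced (metadata preserved by default)."""
        return dataclasses.replace(self, **changes)

    def equals(self, other: "SignalSeries") -> bool:
        if not isinstance(other, SignalSeries):
            return False
        meta = ("participant_id", "round", "modality", "dyad_id", "condition", "units")
        return (
            all(getattr(self, f) == getattr(other, f) for f in meta)
            and np.isclose(self.rate_hz, other.rate_hz)
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
        )
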