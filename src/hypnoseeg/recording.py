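"""In-memory containers for continuous EEG and event annotations.

A :class:`RawRecording` is a channels x samples matrix in microvolts with
channel names from the 10-20 system, a sampling rate, a reference state and
an append-only processing history. Event annotations are onset times in
seconds paired with a binary driving-state label (``RH`` road hypnosis /
``ND`` normal driving).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Default 8-channel frontal montage (frontal pole, frontal, frontocentral).
DEFAULT_EEG_CHANNELS = ("Fp2", "Fpz", "Fp1", "F4", "Fz", "F3", "FC2", "FC1")
#: Bilateral mastoid reference channels.
DEFAULT_MASTOIDS = ("M1", "M2")

#: Class labels; road hypnosis (positive class) first.
CLASSES = ("RH", "ND")

REF_AS_RECORDED = "as-recorded"
REF_MASTOID = "mastoid-average"


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts."""

    data: np.ndarray  # (n_channels, n_samples), float
    fs: float  # Hz
    channel_names: tuple[str, ...]
    reference: str = REF_AS_RECORDED
    history: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValidationError(f"data must be 2-D, got shape {self.data.shape}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    @property
    def nyquist(self) -> float:
        """Nyquist frequency fs/2 in Hz (250 Hz at the standard 500 Hz rate)."""
        return self.fs / 2.0

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ValidationError(
                f"channel {name!r} not in recording "
                f"(have: {', '.join(self.channel_names)})"
            ) from None

    def with_data(self, data: np.ndarray, step: str, **changes) -> "RawRecording":
        """Functional update appending *step* to the history."""
        return replace(
            self, data=data, history=self.history + (step,), **changes
        )


@dataclass
class EventList:
    """Event annotations: onsets in seconds with RH/ND labels."""

    onsets: np.ndarray  # seconds, sorted ascending
    labels: np.ndarray  # unicode, values in CLASSES

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype="U2")
        if self.onsets.shape != self.labels.shape or self.onsets.ndim != 1:
            raise ValidationError("onsets and labels must be 1-D and equal length")
        if np.any(np.diff(self.onsets) < 0):
            raise ValidationError("event onsets must be sorted ascending")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValidationError(f"unknown event labels: {sorted(bad)}")

    def __len__(self) -> int:
        return self.onsets.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"onset_s": self.onsets, "label": self.labels})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventList":
        return cls(
            onsets=frame["onset_s"].to_numpy(dtype=float),
            labels=frame["label"].to_numpy(dtype="U2"),
        )


@dataclass
class StateTimeline:
    """Piecewise-constant driving-state timeline over [0, duration].

    Segment i covers ``[edges[i], edges[i+1])`` with state ``states[i]``.
    """

    edges: np.ndarray  # length n_segments + 1, edges[0] == 0
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.float64)
        self.states = tuple(self.states)
        if self.edges.ndim != 1 or self.edges.size != len(self.states) + 1:
            raise ValidationError("need n_segments + 1 edges")
        if self.edges[0] != 0 or np.any(np.diff(self.edges) <= 0):
            raise ValidationError(
                "timeline edges must start at 0 and increase strictly"
            )
        bad = set(self.states) - set(CLASSES)
        if bad:
            raise ValidationError(f"unknown states: {sorted(bad)}")

    @property
    def duration(self) -> float:
        return float(self.edges[-1])

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """State label for each time in *t* (right-open segments)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.duration):
            raise ValidationError("times outside the timeline range")
        idx = np.clip(
            np.searchsorted(self.edges, t, side="right") - 1,
            0,
            len(self.states) - 1,
        )
        return np.asarray(self.states, dtype="U2")[idx]

    @classmethod
    def alternating(
        cls, duration: float, block_s: float, first: str = "ND"
    ) -> "StateTimeline":
        """Blocks of *block_s* seconds alternating between the two states."""
        n_blocks = int(np.ceil(duration / block_s))
        edges = np.minimum(np.arange(n_blocks + 1) * block_s, duration)
        other = "RH" if first == "ND" else "ND"
        states = tuple(first if i % 2 == 0 else other for i in range(n_blocks))
        return cls(edges=edges, states=states)
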