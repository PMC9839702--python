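"""Core in-memory containers shared across the pipeline.

The raw substrate of every calcium analysis is a rectangular
neurons x frames fluorescence matrix recorded at a fixed frame rate
(miniscope recordings here run at 6 frames/s), plus a typed schedule of
the stimuli and behaviors that occurred during the recording (tone CS,
foot-shock US, hot-plate contact, freezing bouts, post-injection blocks).
Normalized traces and peri-event tensors are thin, validated wrappers
around numpy arrays; tabular data (region counts, starter cells,
sections, projections) live in plain pandas DataFrames with documented
column schemas defined in :mod:`ceatopo.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


class DegenerateBaselineError(ValueError):
    """Raised when a normalization baseline has zero mean or zero spread."""


class OutOfRangeError(ValueError):
    """Raised when a requested peri-event window falls outside the recording."""


class SchemaError(ValueError):
    """Raised when tabular input does not match the documented schema."""


class InsufficientDataError(ValueError):
    """Raised when too few trials/pairs/subjects are available for a test."""


@dataclass(frozen=True)
class Event:
    """A single timestamped stimulus/behavior interval, in seconds."""

    label: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.offset < self.onset:
            raise ValueError(
                f"event {self.label!r}: offset {self.offset} precedes onset {self.onset}"
            )


@dataclass(frozen=True)
class EventSchedule:
    """Ordered collection of events for one recording session."""

    events: tuple[Event, ...]

    def __init__(self, events: Sequence[Event | tuple]) -> None:
        evs = tuple(e if isinstance(e, Event) else Event(*e) for e in events)
        object.__setattr__(self, "events", evs)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def select(self, label: str) -> "EventSchedule":
        return EventSchedule([e for e in self.events if e.label == label])


@dataclass
class TraceMatrix:
    """Raw fluorescence, one row per neuron, one column per frame.

    Parameters
    ----------
    values
        Array of shape (n_neurons, n_frames), arbitrary fluorescence units.
    frame_rate
        Acquisition rate in frames per second (default 6, the miniscope
        convention used throughout).
    neuron_ids
        Optional identifiers; defaults to 0..n-1.
    t0
        Recording start time in seconds.
    """

    values: np.ndarray
    frame_rate: float = 6.0
    neuron_ids: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trace matrix must be 2-D (neurons x frames)")
        if not np.isfinite(self.values).all():
            raise ValueError("trace matrix contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.values.shape[0])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
            if self.neuron_ids.shape[0] != self.values.shape[0]:
                raise ValueError("neuron_ids length does not match matrix rows")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds relative to the session clock."""
        return self.t0 + np.arange(self.n_frames) / self.frame_rate

    def frame_at(self, t: float) -> int:
        """Index of the first frame at or after time ``t`` (onset convention)."""
        return int(np.ceil((t - self.t0) * self.frame_rate - 1e-9))


@dataclass
class NormalizedTrace:
    """Dimensionless traces: recording-wide dF/F or baseline-referenced z-scores."""

    values: np.ndarray
    frame_rate: float
    mode: str  # "dff" | "zscore"
    neuron_ids: np.ndarray | None = None
    t0: float = 0.0
    baseline_window: tuple[float, float] | None = None
    degenerate: np.ndarray | None = None  # per-neuron flag where baseline failed

    def __post_init__(self) -> None:
        if self.mode not in ("dff", "zscore"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.values.shape[0])

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.frame_rate

    def frame_at(self, t: float) -> int:
        return int(np.ceil((t - self.t0) * self.frame_rate - 1e-9))


@dataclass
class PeriEventTensor:
    """Event-aligned snippets: (neuron, event instance, relative frame).

    Relative frame 0 is the event-onset frame; the window spans
    ``pre`` seconds before to ``post`` seconds after onset, inclusive of
    the onset frame.
    """

    values: np.ndarray
    frame_rate: float
    window: tuple[float, float]  # (pre, post) in seconds, both >= 0
    alignment: str = ""
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("peri-event tensor must be 3-D (neuron, event, frame)")
        pre, post = self.window
        expected = int(round(pre * self.frame_rate)) + int(round(post * self.frame_rate)) + 1
        if self.values.shape[2] not in (expected, 0):
            raise ValueError(
                f"window ({pre}, {post}) s at {self.frame_rate} fps implies "
                f"{expected} frames, got {self.values.shape[2]}"
            )
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.values.shape[0])

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_events(self) -> int:
        return self.values.shape[1]

    @property
    def rel_times(self) -> np.ndarray:
        """Relative frame times in seconds; 0 at event onset."""
        pre = int(round(self.window[0] * self.frame_rate))
        return (np.arange(self.values.shape[2]) - pre) / self.frame_rate

    def mean_over_events(self) -> np.ndarray:
        """Per-neuron event-averaged response, shape (neuron, frame)."""
        return self.values.mean(axis=1)

    def frames_in(self, t_start: float, t_stop: float) -> np.ndarray:
        """Boolean mask of relative frames with t_start <= t <= t_stop."""
        t = self.rel_times
        return (t >= t_start - 1e-9) & (t <= t_stop + 1e-9)
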