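"""Repetition segmentation, duration normalization and per-set averaging.

A recorded set is cut into repetitions at the push-button marker events,
every repetition is linearly resampled onto the time grid of the longest
repetition of the set (100% duration), and the repetitions are averaged
sample-wise into a single 9-channel trace per set.  Averaging over the six
repetitions is the study's only outlier handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .synthetic import SessionRecording

__all__ = [
    "RepetitionSegment",
    "AveragedSet",
    "segment_repetitions",
    "normalize_and_average",
    "preprocess_cohort",
]


@dataclass
class RepetitionSegment:
    """One repetition cut out of a session: a (9, n) channel block."""

    subject_id: str
    exercise: str
    category: str
    set_index: int
    repetition_index: int  # 1-based
    channels: np.ndarray

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != 9:
            raise ValueError("channels must be a (9, n) array")
        if self.n_samples < 2:
            raise ValueError("a repetition needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]


@dataclass
class AveragedSet:
    """One set's repetitions averaged on a common normalized-time grid."""

    subject_id: str
    exercise: str
    category: str
    set_index: int
    channels: np.ndarray  # (9, grid_length)

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != 9:
            raise ValueError("channels must be a (9, grid_length) array")

    @property
    def grid_length(self) -> int:
        return self.channels.shape[1]

    @property
    def norm_time_pct(self) -> np.ndarray:
        """Normalized time axis, 0-100% of repetition duration."""
        return np.linspace(0.0, 100.0, self.grid_length)


def segment_repetitions(rec: SessionRecording) -> list[RepetitionSegment]:
    """Cut a session into repetitions at the marker events.

    ``k`` markers delimit ``k - 1`` repetitions; repetition ``i`` spans the
    half-open sample interval ``[marker_i, marker_{i+1})``.
    """
    markers = np.asarray(rec.markers, dtype=np.int64)
    if markers.size < 2:
        raise ValueError("at least 2 markers are required to segment a set")
    if np.any(np.diff(markers) <= 0):
        raise ValueError("markers must be strictly increasing")
    if markers[0] < 0 or markers[-1] > rec.n_samples:
        raise ValueError("markers outside signal range")
    segments = []
    for i in range(markers.size - 1):
        segments.append(
            RepetitionSegment(
                subject_id=rec.subject_id,
                exercise=rec.exercise,
                category=rec.category,
                set_index=rec.set_index,
                repetition_index=i + 1,
                channels=rec.channels[:, markers[i] : markers[i + 1]],
            )
        )
    return segments


def normalize_and_average(segments: Sequence[RepetitionSegment]) -> AveragedSet:
    """Resample every repetition to the longest one's length and average.

    The longest repetition of the set defines the reference grid (100%
    duration); every repetition is linearly interpolated onto that grid in
    normalized time, then the channels are averaged sample-wise.
    """
    if len(segments) == 0:
        raise ValueError("at least one repetition segment is required")
    grid_length = max(s.n_samples for s in segments)
    x_dst = np.linspace(0.0, 1.0, grid_length)
    acc = np.zeros((9, grid_length))
    for seg in segments:
        x_src = np.linspace(0.0, 1.0, seg.n_samples)
        for ch in range(9):
            acc[ch] += np.interp(x_dst, x_src, seg.channels[ch])
    acc /= len(segments)
    first = segments[0]
    return AveragedSet(
        subject_id=first.subject_id,
        exercise=first.exercise,
        category=first.category,
        set_index=first.set_index,
        channels=acc,
    )


def preprocess_cohort(recordings: Iterable[SessionRecording]) -> list[AveragedSet]:
    """Segment, normalize and average every recording: one AveragedSet each."""
    return [normalize_and_average(segment_repetitions(rec)) for rec in recordings]
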