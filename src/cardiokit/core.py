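"""Core value types shared across the pipeline.

Sample indices are 0-based throughout; every interval duration is expressed
in seconds (samples / fs) so that the clinical rule thresholds are directly
comparable regardless of the recording's sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ECGSignal:
    """A uniformly sampled single-lead voltage series.

    Parameters
    ----------
    samples : ndarray of float
        Voltage samples in original (or normalized, dimensionless) units.
    fs : float
        Sampling frequency in samples/second.
    record_id : str
        Identifier of the source record.
    """

    samples: np.ndarray
    fs: float
    record_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("ECG signal must be one-dimensional")
        if samples.size < 2:
            raise ValueError("ECG signal must contain at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("ECG signal contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("sampling frequency must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def replace(self, samples: np.ndarray) -> "ECGSignal":
        """Return a copy carrying new samples but the same fs and record id."""
        return ECGSignal(np.asarray(samples, dtype=float), self.fs, self.record_id)


@dataclass(frozen=True)
class RPeakSet:
    """Ordered R-peak locations with their signed amplitudes (the "lrp" store).

    Indices are strictly increasing, each within the signal bounds, and
    consecutive peaks respect the 0.2 s physiological refractory period.
    """

    record_id: str
    indices: np.ndarray
    amplitudes: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        amp = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "amplitudes", amp)
        if idx.shape != amp.shape:
            raise ValueError("indices and amplitudes must have equal length")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size

    @property
    def rr_intervals_s(self) -> np.ndarray:
        """RR intervals in seconds; defined from the second beat onward."""
        return np.diff(self.indices) / self.fs


@dataclass(frozen=True)
class ExtremaSequence:
    """Alternating local maxima/minima of a signal as (index, amplitude) pairs."""

    indices: np.ndarray
    amplitudes: np.ndarray
    is_max: np.ndarray  # boolean; True where the extremum is a local maximum

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        amp = np.asarray(self.amplitudes, dtype=float)
        kind = np.asarray(self.is_max, dtype=bool)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "is_max", kind)
        if not (idx.shape == amp.shape == kind.shape):
            raise ValueError("component arrays must share a shape")
        if idx.size > 1:
            if np.any(np.diff(idx) <= 0):
                raise ValueError("extrema indices must be strictly increasing")
            if np.any(kind[1:] == kind[:-1]):
                raise ValueError("extrema must strictly alternate max/min")

    def __len__(self) -> int:
        return self.indices.size

    def adjacent_differences(self) -> np.ndarray:
        """|amplitude| differences of adjacent max/min pairs (pairing persistence)."""
        if len(self) < 2:
            return np.empty(0)
        return np.abs(np.diff(self.amplitudes))


@dataclass(frozen=True)
class ClusterSplit:
    """A 1-D two-cluster partition of peak amplitudes with its midpoint threshold."""

    w0: np.ndarray  # low-amplitude cluster
    w1: np.ndarray  # high-amplitude cluster
    th: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "w0", np.asarray(self.w0, dtype=float))
        object.__setattr__(self, "w1", np.asarray(self.w1, dtype=float))


@dataclass(frozen=True)
class BeatWindow:
    """A fixed-length analysis window [start, stop) centred asymmetrically on R."""

    r_index: int
    start: int
    stop: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.stop - self.start != self.samples.size:
            raise ValueError("window bounds inconsistent with sample count")
        if not (self.start <= self.r_index < self.stop):
            raise ValueError("R index must lie inside the window")

    @property
    def r_offset(self) -> int:
        return self.r_index - self.start


@dataclass(frozen=True)
class BeatFiducials:
    """Per-beat landmark sample indices; P and T may be absent (None)."""

    r: int
    q: int
    s: int
    p: int | None = None
    t: int | None = None
    t_offset: int | None = None  # half-amplitude decay point after the T peak
    p_onset: int | None = None
    p_offset: int | None = None
    t_onset: int | None = None

    def __post_init__(self) -> None:
        if not (self.q < self.r < self.s):
            raise ValueError("require q < r < s")
        if self.p is not None and not self.p < self.q:
            raise ValueError("require p < q when P is present")
        if self.t is not None and not self.s < self.t:
            raise ValueError("require s < t when T is present")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts (abnormal = positive class)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


BEAT_LABELS = ("normal", "abnormal", "arrhythmic")
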