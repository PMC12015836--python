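"""In-memory data model shared by every pipeline stage.

Conventions
-----------
* All signal values are in microvolts (µV).
* Epoch time axes are in milliseconds, strictly increasing with uniform
  spacing ``1000 / sampling_rate``; the epoch window is half-open
  ``[t_start, t_end)`` so that at 500 Hz a −200…1000 ms epoch holds exactly
  600 samples and sample ``k`` sits at ``t_start + k * 2`` ms.
* Analysis windows quoted in ms (e.g. 350–410 ms) are closed on both ends
  and converted to samples by nearest-sample rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "TseTraces",
    "PhaseSet",
    "PeakMeasure",
    "WindowMeasure",
    "window_to_slice",
    "window_indices",
]


def window_indices(times: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    """Indices of the closed analysis window ``[lo, hi]`` on a ms time axis.

    Endpoints are resolved by nearest-sample rounding, then every sample
    between (and including) the two resolved endpoints is returned.
    """
    lo, hi = window_ms
    if hi < lo:
        raise ValueError(f"empty window: {window_ms}")
    i0 = int(np.argmin(np.abs(times - lo)))
    i1 = int(np.argmin(np.abs(times - hi)))
    if i1 < i0:
        raise ValueError(f"window {window_ms} resolves to no samples")
    return np.arange(i0, i1 + 1)


def window_to_slice(times: np.ndarray, window_ms: tuple[float, float]) -> slice:
    idx = window_indices(times, window_ms)
    return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class ContinuousRecording:
    """Multi-channel continuous EEG with event markers.

    data : (n_channels, n_samples) µV
    markers : list of ``(sample_index, label)`` pairs
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    markers: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels × samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} labels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = self.data.shape[1]
        for s, lab in self.markers:
            if not 0 <= s < n:
                raise ValueError(f"marker {lab!r} at sample {s} outside 0..{n - 1}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            self.data.copy(), self.sampling_rate, list(self.channel_labels),
            list(self.markers),
        )


@dataclass
class EpochSet:
    """Epoched EEG: trials × channels × samples, plus a rejection mask.

    ``reject_mask[i]`` is True when trial ``i`` has been excluded from all
    downstream averages; rejection is mask-based (non-destructive) so counts
    can be audited.
    """

    data: np.ndarray
    times: np.ndarray
    channel_labels: list[str]
    condition: str = ""
    subject_id: str = ""
    reject_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials × channels × samples")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel count mismatch")
        if self.data.shape[2] != self.times.size:
            raise ValueError("sample count mismatch with time axis")
        dt = np.diff(self.times)
        if self.times.size > 1 and (dt.min() <= 0 or not np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing and uniform")
        if self.reject_mask is None:
            self.reject_mask = np.zeros(self.data.shape[0], dtype=bool)
        else:
            self.reject_mask = np.asarray(self.reject_mask, dtype=bool)
            if self.reject_mask.shape != (self.data.shape[0],):
                raise ValueError("reject_mask length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def sampling_rate(self) -> float:
        return 1000.0 / float(self.times[1] - self.times[0])

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def good_data(self) -> np.ndarray:
        """Data restricted to non-rejected trials."""
        return self.data[~self.reject_mask]

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), self.times.copy(), list(self.channel_labels),
            self.condition, self.subject_id, self.reject_mask.copy(),
        )

    def with_data(self, data: np.ndarray) -> "EpochSet":
        out = replace(self, data=np.asarray(data, dtype=float))
        out.reject_mask = self.reject_mask.copy()
        return out


@dataclass
class TseTraces:
    """Rectified alpha-amplitude time courses (channels × samples, µV).

    ``induced = total - evoked`` holds exactly by construction; both input
    traces are baseline-corrected over ``baseline_window`` before the
    subtraction, so each trace has (numerically) zero mean in that window.
    """

    evoked: np.ndarray
    total: np.ndarray
    induced: np.ndarray
    times: np.ndarray
    channel_labels: list[str]
    baseline_window: tuple[float, float]
    n_trials_used: int

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in traces") from None

    def trace(self, kind: str) -> np.ndarray:
        if kind not in ("evoked", "total", "induced"):
            raise ValueError(f"unknown trace kind {kind!r}")
        return getattr(self, kind)


@dataclass
class PhaseSet:
    """Per-trial (or per-subject) circular phase summary in a window.

    phases : radians in (−π, π], one per trial
    low_amplitude_flags : trials whose window-mean envelope fell below the
        exclusion threshold; they do not enter the resultant.
    """

    phases: np.ndarray
    low_amplitude_flags: np.ndarray
    resultant_length: float
    circular_mean: float
    n: int
    channel: str = ""
    window_ms: tuple[float, float] = (0.0, 0.0)
    condition: str = ""
    subject_id: str = ""
    kind: str = ""


@dataclass
class PeakMeasure:
    """A peak latency/amplitude extracted in a search window at one electrode."""

    subject_id: str
    condition: str
    signal_kind: str
    electrode: str
    latency_ms: float
    amplitude_uv: float
    polarity: str
    search_window_ms: tuple[float, float]
    degenerate: bool = False


@dataclass
class WindowMeasure:
    """A mean amplitude over a closed window at one electrode."""

    subject_id: str
    condition: str
    signal_kind: str
    electrode: str
    window_ms: tuple[float, float]
    amplitude_uv: float
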