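"""Peak latency / mean amplitude extraction in named windows and electrodes.

Default measurement profile (closed ms windows, nearest-sample endpoints):
P3 350–410 ms at Pz (positive peak); evoked alpha 140–155 ms and induced
alpha 165–200 ms at PO6. The measurement electrode is fixed from the grand
average of the target conditions (largest window extremum), and latencies
are reported on the sample grid without interpolation; ties break to the
earliest sample so results are deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import montage
from .containers import PeakMeasure, WindowMeasure, window_indices

__all__ = [
    "MEASUREMENT_WINDOWS_MS",
    "MEASUREMENT_ELECTRODES",
    "ElectrodeMatrix",
    "peak_latency",
    "mean_amplitude",
    "grand_average",
    "pick_measurement_electrode",
    "matrix_amplitudes",
]

#: printed measurement windows, closed on both ends
MEASUREMENT_WINDOWS_MS = {
    "P3": (350.0, 410.0),
    "evoked_alpha": (140.0, 155.0),
    "induced_alpha": (165.0, 200.0),
}

MEASUREMENT_ELECTRODES = {"P3": "Pz", "evoked_alpha": "PO6", "induced_alpha": "PO6"}

#: default peak polarity per signal kind; the induced measure defaults to the
#: signed extremum of largest absolute deviation (the desynchronization is a
#: trough but measured in a "maximum amplitude" window) — overridable.
DEFAULT_POLARITY = {"P3": "max", "evoked_alpha": "max", "induced_alpha": "absmax"}


@dataclass
class ElectrodeMatrix:
    """The 6 × 7 grid (AP rows F…PO × lateral lines L5…L6) for topographic
    statistics."""

    labels: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.labels) != 6 or any(len(r) != 7 for r in self.labels):
            raise ValueError("electrode matrix must be 6 × 7")

    @classmethod
    def default(cls) -> "ElectrodeMatrix":
        return cls(montage.matrix_labels())

    @property
    def flat(self) -> list[str]:
        return [lab for row in self.labels for lab in row]

    def require_present(self, channels: list[str]) -> None:
        missing = [lab for lab in self.flat if lab not in channels]
        if missing:
            raise KeyError(f"matrix electrodes missing from montage: {missing}")


def peak_latency(trace: np.ndarray, times: np.ndarray,
                 window_ms: tuple[float, float], polarity: str = "max",
                 subject_id: str = "", condition: str = "",
                 signal_kind: str = "", electrode: str = "") -> PeakMeasure:
    """Peak latency/amplitude within a closed window.

    polarity: "max" (argmax), "min" (argmin) or "absmax" (signed extremum of
    largest absolute value). Ties break to the earliest sample; a flat
    window returns its first sample with ``degenerate`` set.
    """
    trace = np.asarray(trace, dtype=float)
    idx = window_indices(np.asarray(times, dtype=float), window_ms)
    seg = trace[idx]
    if polarity == "max":
        k = int(np.argmax(seg))
    elif polarity == "min":
        k = int(np.argmin(seg))
    elif polarity == "absmax":
        k = int(np.argmax(np.abs(seg)))
    else:
        raise ValueError(f"polarity must be max|min|absmax, got {polarity!r}")
    degenerate = bool(np.all(seg == seg[0]))
    i = int(idx[k])
    return PeakMeasure(
        subject_id=subject_id, condition=condition, signal_kind=signal_kind,
        electrode=electrode, latency_ms=float(times[i]),
        amplitude_uv=float(trace[i]), polarity=polarity,
        search_window_ms=tuple(window_ms), degenerate=degenerate,
    )


def mean_amplitude(trace: np.ndarray, times: np.ndarray,
                   window_ms: tuple[float, float]) -> float:
    """Arithmetic mean of the samples in the closed window (µV)."""
    idx = window_indices(np.asarray(times, dtype=float), window_ms)
    return float(np.asarray(trace, dtype=float)[idx].mean())


def grand_average(traces: list[np.ndarray]) -> np.ndarray:
    """Pointwise mean across subjects (shapes must match)."""
    if not traces:
        raise ValueError("need ≥1 subject trace")
    arr = np.stack([np.asarray(t, dtype=float) for t in traces])
    return arr.mean(axis=0)


def pick_measurement_electrode(grand: np.ndarray, channel_labels: list[str],
                               times: np.ndarray,
                               window_ms: tuple[float, float],
                               polarity: str = "max") -> str:
    """Channel with the largest window-extremum magnitude in the grand average.

    Fixes the measurement electrode for every subject, following the
    convention of measuring at the grand-average maximum.
    """
    grand = np.asarray(grand, dtype=float)
    idx = window_indices(np.asarray(times, dtype=float), window_ms)
    seg = grand[:, idx]
    if polarity == "max":
        score = seg.max(axis=-1)
    elif polarity == "min":
        score = -seg.min(axis=-1)
    else:
        score = np.abs(seg).max(axis=-1)
    return channel_labels[int(np.argmax(score))]


def matrix_amplitudes(traces_by_subject: dict[tuple[str, str], np.ndarray],
                      channel_labels: list[str], times: np.ndarray,
                      window_ms: tuple[float, float],
                      matrix: ElectrodeMatrix | None = None) -> pd.DataFrame:
    """Window-mean amplitude per subject × condition × matrix cell.

    ``traces_by_subject`` maps ``(subject, condition)`` to a channels ×
    samples trace. Returns a long-format table keyed (subject, condition,
    ap, lm) for the repeated-measures ANOVA.
    """
    matrix = matrix or ElectrodeMatrix.default()
    matrix.require_present(channel_labels)
    rows = []
    for (subject, condition), trace in sorted(traces_by_subject.items()):
        for ri, row in enumerate(matrix.labels):
            for ci, lab in enumerate(row):
                ich = channel_labels.index(lab)
                rows.append({
                    "subject": subject, "condition": condition,
                    "ap": montage.MATRIX_ROWS[ri],
                    "lm": "L" + montage.MATRIX_LINES[ci]
                          if montage.MATRIX_LINES[ci] != "z" else "z",
                    "electrode": lab,
                    "amplitude_uv": mean_amplitude(trace[ich], times, window_ms),
                })
    return pd.DataFrame(rows)
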