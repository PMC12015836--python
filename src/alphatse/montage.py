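"""The 58-channel 10–10 scalp montage and schematic channel geometry.

The montage is the 6 × 7 analysis grid (anterior–posterior rows F, FC, C,
CP, P, PO crossed with lateral lines 5, 3, 1, z, 2, 4, 6) plus 16 outer
derivations, with bipolar VEOG/HEOG appended for ocular monitoring.

Channel coordinates are schematic grid positions (x: left − / right +,
y: anterior + / posterior −), sufficient for smooth synthetic topographies
and for the minimal scalp-grid export; this is not a head model.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MATRIX_ROWS",
    "MATRIX_LINES",
    "matrix_labels",
    "scalp_channels",
    "eog_channels",
    "default_channels",
    "channel_position",
    "gaussian_topography",
    "blink_propagation",
]

MATRIX_ROWS = ["F", "FC", "C", "CP", "P", "PO"]
#: lateral–medial lines in left→right order: L5, L3, L1, midline, L2, L4, L6
MATRIX_LINES = ["5", "3", "1", "z", "2", "4", "6"]

_OUTER = [
    "Fp1", "Fpz", "Fp2",
    "F7", "F8", "FT7", "FT8",
    "T7", "T8", "TP7", "TP8",
    "P7", "P8",
    "O1", "Oz", "O2",
]

_ROW_Y = {"Fp": 4.0, "F": 3.0, "FT": 2.0, "FC": 2.0, "T": 1.0, "C": 1.0,
          "TP": 0.0, "CP": 0.0, "P": -1.0, "PO": -2.0, "O": -3.0}


def matrix_labels() -> list[list[str]]:
    """6 × 7 grid of channel names used for topographic statistics."""
    return [[row + line for line in MATRIX_LINES] for row in MATRIX_ROWS]


def scalp_channels() -> list[str]:
    """The 58 scalp derivations (grid channels first, outer ring after)."""
    grid = [lab for row in matrix_labels() for lab in row]
    return grid + list(_OUTER)


def eog_channels() -> list[str]:
    return ["VEOG", "HEOG"]


def default_channels() -> list[str]:
    """58 scalp channels + VEOG + HEOG (60 total)."""
    return scalp_channels() + eog_channels()


def _split(label: str) -> tuple[str, str]:
    i = 0
    while i < len(label) and label[i].isalpha() and label[i] != "z":
        i += 1
    return label[:i], label[i:] or "z"


def channel_position(label: str) -> tuple[float, float]:
    """Schematic (x, y) grid position of a scalp channel."""
    if label in ("VEOG", "HEOG"):
        raise KeyError("EOG channels have no scalp position")
    row, num = _split(label)
    if row not in _ROW_Y:
        raise KeyError(f"unknown channel {label!r}")
    y = _ROW_Y[row]
    if num == "z":
        x = 0.0
    else:
        k = int(num)
        x = ((k + 1) // 2) * (1.0 if k % 2 == 0 else -1.0)
    return x, y


def gaussian_topography(center_label: str, sigma: float = 2.0,
                        channels: list[str] | None = None) -> dict[str, float]:
    """Per-channel weights decaying with grid distance from ``center_label``.

    The weight at the centre channel is exactly 1; EOG channels get 0.
    """
    channels = channels if channels is not None else default_channels()
    cx, cy = channel_position(center_label)
    out: dict[str, float] = {}
    for lab in channels:
        if lab in ("VEOG", "HEOG"):
            out[lab] = 0.0
            continue
        x, y = channel_position(lab)
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        out[lab] = float(np.exp(-d2 / (2.0 * sigma**2)))
    return out


def blink_propagation(front_factor: float = 0.40, decay: float = 3.5,
                      channels: list[str] | None = None) -> dict[str, float]:
    """VEOG→scalp blink propagation factors, largest frontally.

    Exponential decay with anterior–posterior distance from the Fp row,
    in line with the front-to-back gradient of regression-estimated ocular
    propagation. VEOG itself maps to 1 (it carries the source), HEOG to 0.
    """
    channels = channels if channels is not None else default_channels()
    out: dict[str, float] = {}
    for lab in channels:
        if lab == "VEOG":
            out[lab] = 1.0
        elif lab == "HEOG":
            out[lab] = 0.0
        else:
            _, y = channel_position(lab)
            out[lab] = float(front_factor * np.exp(-(4.0 - y) / decay))
    return out
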