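"""BrainVision Core Data Format I/O, epoching, and the internal epoch store.

Reading goes through MNE's BrainVision reader and is re-expressed in the
package's µV-scaled :class:`~alphatse.containers.ContinuousRecording`.
Writing is implemented here (INI-style ``.vhdr``/``.vmrk`` plus little-endian
binary ``.eeg``), supporting the IEEE_FLOAT_32 and INT_16 binary dialects in
both MULTIPLEXED and VECTORIZED orientations; anything else errors clearly.

Epoching follows a half-open ``[t_start, t_end)`` window convention: at
500 Hz a −200…1000 ms window yields exactly 600 samples and the stimulus
marker lands on sample 100.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .containers import ContinuousRecording, EpochSet

__all__ = [
    "read_brainvision",
    "write_brainvision",
    "epoch",
    "save_epochs",
    "load_epochs",
]

logger = logging.getLogger(__name__)

_SUPPORTED_FORMATS = {"IEEE_FLOAT_32": ("<f4", 4), "INT_16": ("<i2", 2)}


def write_brainvision(rec: ContinuousRecording, path: str | Path,
                      binary_format: str = "IEEE_FLOAT_32",
                      orientation: str = "MULTIPLEXED",
                      resolution: float = 1.0) -> list[Path]:
    """Write a recording as a BrainVision triplet ``path.{vhdr,vmrk,eeg}``.

    ``resolution`` is the per-count scale in µV: stored values are
    ``data / resolution`` (rounded for INT_16), readers multiply back.
    Returns the three paths written.
    """
    if binary_format not in _SUPPORTED_FORMATS:
        raise ValueError(f"unsupported BinaryFormat {binary_format!r}; "
                         f"supported: {sorted(_SUPPORTED_FORMATS)}")
    if orientation not in ("MULTIPLEXED", "VECTORIZED"):
        raise ValueError(f"unsupported DataOrientation {orientation!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = (path.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    dtype, _ = _SUPPORTED_FORMATS[binary_format]
    stored = rec.data / resolution
    if binary_format == "INT_16":
        stored = np.round(stored)
        if np.any(np.abs(stored) > 32767):
            raise ValueError("data exceed INT_16 range at this resolution")
    arr = stored.astype(dtype)
    if orientation == "MULTIPLEXED":
        arr = arr.T  # samples × channels, interleaved
    eeg.write_bytes(np.ascontiguousarray(arr).tobytes())

    interval_us = 1e6 / rec.sampling_rate
    interval = (f"{interval_us:.0f}" if abs(interval_us - round(interval_us)) < 1e-9
                else f"{interval_us:.6f}")
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by alphatse",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        f"DataOrientation={orientation}",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    res_str = f"{resolution:g}"
    for i, lab in enumerate(rec.channel_labels):
        lines.append(f"Ch{i + 1}={lab},,{res_str},µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for j, (sample, label) in enumerate(rec.markers):
        # marker positions are 1-based in the format
        mlines.append(f"Mk{j + 2}=Stimulus,{label},{sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return [vhdr, vmrk, eeg]


def read_brainvision(path: str | Path) -> ContinuousRecording:
    """Read a BrainVision triplet (by its ``.vhdr`` path or stem) into µV.

    Stimulus/Response marker annotations are resolved to 0-based sample
    indices; "New Segment" bookkeeping markers are dropped.
    """
    import mne

    path = Path(path)
    if path.suffix != ".vhdr":
        path = path.with_suffix(".vhdr")
    if not path.exists():
        raise FileNotFoundError(f"header file not found: {path}")
    for suffix in (".vmrk", ".eeg"):
        if not path.with_suffix(suffix).exists():
            raise FileNotFoundError(f"missing companion file: {path.with_suffix(suffix)}")
    raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    markers: list[tuple[int, str]] = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc.startswith("New Segment"):
            continue
        label = desc.split("/", 1)[1] if "/" in desc else desc
        markers.append((int(round(onset * raw.info["sfreq"])), label))
    return ContinuousRecording(data_uv, float(raw.info["sfreq"]),
                               list(raw.ch_names), markers)


def epoch(rec: ContinuousRecording, marker_label: str,
          window_ms: tuple[float, float]) -> EpochSet:
    """Cut epochs around every marker with ``marker_label``.

    The window is half-open ``[lo, hi)`` in ms; events whose window would
    leave the recording are dropped (logged). Raises if no marker matches.
    """
    lo, hi = window_ms
    if not lo < hi:
        raise ValueError(f"empty epoch window {window_ms}")
    fs = rec.sampling_rate
    dt = 1000.0 / fs
    offset = int(round(lo / dt))
    n_samp = int(round((hi - lo) / dt))
    events = [s for s, lab in rec.markers if lab == marker_label]
    if not events:
        raise ValueError(f"no markers labelled {marker_label!r} in recording")
    trials = []
    dropped = 0
    for s in sorted(events):
        i0 = s + offset
        if i0 < 0 or i0 + n_samp > rec.n_samples:
            dropped += 1
            continue
        trials.append(rec.data[:, i0:i0 + n_samp])
    if dropped:
        logger.info("epoch: dropped %d event(s) too close to recording edges", dropped)
    if not trials:
        raise ValueError("all matching events fell outside the recording")
    times = lo + dt * np.arange(n_samp)
    return EpochSet(np.stack(trials), times, list(rec.channel_labels))


def save_epochs(es: EpochSet, path: str | Path) -> Path:
    """Single-file epoch store: arrays + JSON metadata in one ``.npz``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "channel_labels": es.channel_labels,
        "condition": es.condition,
        "subject_id": es.subject_id,
    }
    np.savez(path, data=es.data, times=es.times,
             reject_mask=es.reject_mask,
             meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_epochs(path: str | Path) -> EpochSet:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        return EpochSet(z["data"], z["times"], meta["channel_labels"],
                        condition=meta["condition"], subject_id=meta["subject_id"],
                        reject_mask=z["reject_mask"])
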