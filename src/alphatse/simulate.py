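"""Synthetic multi-subject, two-condition epoched EEG with known ground truth.

The generator emulates a 26-subject, two-condition (single-target ST vs
double-target DT) visual go/no-go study: 140 target epochs per condition,
58 scalp channels (10–10 names) plus bipolar VEOG/HEOG, 500 Hz sampling,
epochs −200…1000 ms around target onset. Each epoch is a sum of

* a P3-like parietal slow wave (midline-parietal topography, Pz maximum)
  whose latency and amplitude differ by condition,
* an early phase-locked alpha burst (identical phase on every trial),
* ongoing alpha with uniform-random per-trial phase, multiplied by a
  deterministic desynchronization envelope with a parieto-occipital (PO6)
  topography — the non-phase-locked "induced" component,
* 1/f background noise, and
* ocular artifacts: positive VEOG blink pulses propagated to scalp channels
  by fixed per-channel factors, and HEOG step artifacts on a fraction of
  trials.

All latent values (per-subject latencies, amplitudes, contaminated trials,
propagation factors) are recorded in :class:`GroundTruth` so downstream
stages can be validated by parameter recovery. All randomness flows from a
single seed through ``numpy.random.SeedSequence`` spawn keys, so every
subject × condition stream is independent and reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from . import montage
from .containers import EpochSet

__all__ = [
    "P3Spec",
    "EvokedAlphaSpec",
    "InducedAlphaSpec",
    "NoiseSpec",
    "ArtifactSpec",
    "BehaviorSpec",
    "SimulationParams",
    "SubjectConditionTruth",
    "GroundTruth",
    "generate_subject_condition",
    "iter_dataset",
    "generate_dataset",
    "behavior_table",
    "write_fixture",
    "one_over_f_noise",
    "CONDITIONS",
]

CONDITIONS = ("ST", "DT")


def _per_condition(value) -> dict[str, float]:
    if isinstance(value, dict):
        return {c: float(value[c]) for c in CONDITIONS}
    return {c: float(value) for c in CONDITIONS}


@dataclass
class P3Spec:
    """Condition-dependent parietal slow wave (Gaussian, ``width_ms`` = σ)."""

    latency_mean_ms: dict = field(default_factory=lambda: {"ST": 353.0, "DT": 405.0})
    latency_sd_ms: float = 30.0
    amplitude_uv: dict = field(default_factory=lambda: {"ST": 12.0, "DT": 9.0})
    amplitude_sd_uv: float = 2.0
    width_ms: float = 60.0
    topography_center: str = "Pz"
    topography_sigma: float = 2.5


@dataclass
class EvokedAlphaSpec:
    """Early alpha burst with the same phase on every trial (phase-locked)."""

    frequency_hz: float = 10.0
    burst_center_ms: dict = field(default_factory=lambda: {"ST": 146.0, "DT": 151.0})
    burst_center_sd_ms: float = 12.0
    burst_width_ms: float = 50.0
    amplitude_uv: float = 4.0
    phase_rad: float = 0.0
    topography_center: str = "PO6"
    topography_sigma: float = 2.0


@dataclass
class InducedAlphaSpec:
    """Ongoing alpha (uniform-random phase per trial) times a deterministic
    desynchronization envelope ``1 − depth·exp(−(t−L)²/2σ²)``.

    With ``narrowband_noise=False`` the oscillator is a fixed-frequency
    sinusoid, which keeps the rectified-amplitude ground truth analytic
    (mean of ``|A sin|`` over uniform phase is ``2A/π``); set the flag for a
    filtered-noise oscillator instead.
    """

    ongoing_amplitude_uv: float = 10.0
    frequency_hz: float = 10.0
    trough_latency_ms: dict = field(default_factory=lambda: {"ST": 168.0, "DT": 198.0})
    trough_latency_sd_ms: float = 20.0
    depth: float = 0.8
    trough_width_ms: float = 80.0
    topography_center: str = "PO6"
    topography_sigma: float = 2.0
    narrowband_noise: bool = False


@dataclass
class NoiseSpec:
    exponent: float = 1.0
    rms_uv: float = 5.0


@dataclass
class ArtifactSpec:
    """Ocular artifact model.

    The ocular source (blink pulses + ocular background noise) is recorded
    directly on the bipolar VEOG channel and propagated to each scalp
    channel by a fixed factor, so the propagation factors are an exact
    regression target. HEOG carries step artifacts (saccade-like) on a
    fraction of trials and is used only for rejection.
    """

    blink_rate_per_trial: float = 0.3
    blink_amplitude_uv: float = 400.0
    blink_width_ms: float = 50.0
    propagation: dict | None = None  # None → montage.blink_propagation()
    ocular_noise_rms_uv: float = 5.0
    heog_step_uv: float = 60.0
    heog_fraction: float = 0.1


@dataclass
class BehaviorSpec:
    """Per-condition reaction time (ms) and accuracy (%) distributions."""

    rt_mean_ms: dict = field(default_factory=lambda: {"ST": 384.0, "DT": 447.0})
    rt_sd_ms: dict = field(default_factory=lambda: {"ST": 57.0, "DT": 73.0})
    accuracy_mean: dict = field(default_factory=lambda: {"ST": 99.55, "DT": 99.51})
    accuracy_sd: dict = field(default_factory=lambda: {"ST": 1.21, "DT": 1.33})


@dataclass
class SimulationParams:
    n_subjects: int = 26
    n_trials_per_condition: int = 140
    sampling_rate: float = 500.0
    epoch_window_ms: tuple[float, float] = (-200.0, 1000.0)
    channels: list[str] = field(default_factory=montage.default_channels)
    p3: P3Spec = field(default_factory=P3Spec)
    evoked_alpha: EvokedAlphaSpec = field(default_factory=EvokedAlphaSpec)
    induced_alpha: InducedAlphaSpec = field(default_factory=InducedAlphaSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)
    seed: int = 0

    def validate(self) -> "SimulationParams":
        if self.n_subjects < 1:
            raise ValueError("n_subjects: must be ≥ 1")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition: must be ≥ 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate: must be positive")
        lo, hi = self.epoch_window_ms
        if not (lo < 0.0 < hi):
            raise ValueError("epoch_window_ms: must span stimulus onset (start < 0 < end)")
        if "VEOG" not in self.channels or "HEOG" not in self.channels:
            raise ValueError("channels: must include VEOG and HEOG")
        for name, amp in [
            ("p3.amplitude_uv", min(_per_condition(self.p3.amplitude_uv).values())),
            ("evoked_alpha.amplitude_uv", self.evoked_alpha.amplitude_uv),
            ("induced_alpha.ongoing_amplitude_uv", self.induced_alpha.ongoing_amplitude_uv),
            ("noise.rms_uv", self.noise.rms_uv),
            ("artifacts.blink_amplitude_uv", self.artifacts.blink_amplitude_uv),
        ]:
            if amp < 0:
                raise ValueError(f"{name}: amplitudes must be ≥ 0")
        if not 0.0 <= self.induced_alpha.depth <= 1.0:
            raise ValueError("induced_alpha.depth: must lie in [0, 1]")
        for name, f in [("evoked_alpha.frequency_hz", self.evoked_alpha.frequency_hz),
                        ("induced_alpha.frequency_hz", self.induced_alpha.frequency_hz)]:
            if not 8.0 <= f <= 13.0:
                raise ValueError(f"{name}: must lie in the alpha band [8, 13] Hz")
        return self

    @property
    def times_ms(self) -> np.ndarray:
        lo, hi = self.epoch_window_ms
        dt = 1000.0 / self.sampling_rate
        n = int(round((hi - lo) / dt))  # half-open [lo, hi)
        return lo + dt * np.arange(n)

    def propagation_factors(self) -> dict[str, float]:
        if self.artifacts.propagation is not None:
            return dict(self.artifacts.propagation)
        return montage.blink_propagation(channels=self.channels)


@dataclass
class SubjectConditionTruth:
    subject_id: str
    condition: str
    p3_latency_ms: float
    p3_amplitude_uv: float
    evoked_burst_center_ms: float
    induced_trough_latency_ms: float
    induced_depth: float
    heog_contaminated_trials: list[int]
    blink_trials: list[int]
    rt_ms: float
    accuracy_pct: float


@dataclass
class GroundTruth:
    """All latent values drawn while generating a dataset."""

    entries: dict = field(default_factory=dict)  # (subject_id, condition) → truth
    blink_propagation: dict = field(default_factory=dict)

    def get(self, subject_id: str, condition: str) -> SubjectConditionTruth:
        return self.entries[(subject_id, condition)]

    def add(self, truth: SubjectConditionTruth) -> None:
        self.entries[(truth.subject_id, truth.condition)] = truth

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.entries}, key=lambda s: int(s.lstrip("sub-")))


def subject_id(index: int) -> str:
    return f"sub-{index + 1:02d}"


def _rng(params: SimulationParams, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=key))


def one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                     n_samples: int, fs: float, exponent: float,
                     rms: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of white noise, scaled to RMS."""
    if rms == 0:
        return np.zeros(shape + (n_samples,))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = rng.standard_normal(shape + (freqs.size,)) + 1j * rng.standard_normal(
        shape + (freqs.size,))
    x = np.fft.irfft(spec * amp, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    scale = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    scale[scale == 0] = 1.0
    return rms * x / scale


def _subject_latents(params: SimulationParams, si: int, condition: str) -> dict:
    ci = CONDITIONS.index(condition)
    rng = _rng(params, si, ci, 0)
    p3 = params.p3
    ev = params.evoked_alpha
    ind = params.induced_alpha
    beh = params.behavior
    # correlated RT across conditions via a shared subject factor
    u = np.random.default_rng(
        np.random.SeedSequence(params.seed, spawn_key=(si, 99))).standard_normal()
    lat = {
        "p3_latency_ms": rng.normal(_per_condition(p3.latency_mean_ms)[condition],
                                    p3.latency_sd_ms),
        "p3_amplitude_uv": max(0.0, rng.normal(
            _per_condition(p3.amplitude_uv)[condition], p3.amplitude_sd_uv)),
        "evoked_center_ms": rng.normal(
            _per_condition(ev.burst_center_ms)[condition], ev.burst_center_sd_ms),
        "trough_latency_ms": rng.normal(
            _per_condition(ind.trough_latency_ms)[condition], ind.trough_latency_sd_ms),
        "rt_ms": (_per_condition(beh.rt_mean_ms)[condition]
                  + 0.8 * _per_condition(beh.rt_sd_ms)[condition] * u
                  + 0.6 * _per_condition(beh.rt_sd_ms)[condition]
                  * rng.standard_normal()),
        "accuracy_pct": min(100.0, rng.normal(
            _per_condition(beh.accuracy_mean)[condition],
            _per_condition(beh.accuracy_sd)[condition])),
    }
    return lat


def generate_subject_condition(
        params: SimulationParams, si: int, condition: str,
) -> tuple[EpochSet, SubjectConditionTruth]:
    """Generate one subject × condition EpochSet and its latent ground truth."""
    params.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    ci = CONDITIONS.index(condition)
    times = params.times_ms
    t = times / 1000.0
    n_tr = params.n_trials_per_condition
    chans = params.channels
    n_ch = len(chans)
    n_sp = times.size
    fs = params.sampling_rate
    lat = _subject_latents(params, si, condition)
    rng = _rng(params, si, ci, 1)

    data = np.zeros((n_tr, n_ch, n_sp))
    scalp = np.array([c not in ("VEOG", "HEOG") for c in chans])
    iveog = chans.index("VEOG")
    iheog = chans.index("HEOG")

    # P3 slow wave — identical on all trials of a subject × condition
    p3 = params.p3
    w_p3 = np.array([montage.gaussian_topography(
        p3.topography_center, p3.topography_sigma, chans)[c] for c in chans])
    p3_wave = lat["p3_amplitude_uv"] * np.exp(
        -((times - lat["p3_latency_ms"]) ** 2) / (2.0 * p3.width_ms**2))
    data += (w_p3[:, None] * p3_wave[None, :])[None, :, :]

    # phase-locked alpha burst
    ev = params.evoked_alpha
    w_ev = np.array([montage.gaussian_topography(
        ev.topography_center, ev.topography_sigma, chans)[c] for c in chans])
    env_ev = np.exp(-((times - lat["evoked_center_ms"]) ** 2)
                    / (2.0 * ev.burst_width_ms**2))
    burst = ev.amplitude_uv * env_ev * np.cos(
        2 * np.pi * ev.frequency_hz * (t - lat["evoked_center_ms"] / 1000.0)
        + ev.phase_rad)
    data += (w_ev[:, None] * burst[None, :])[None, :, :]

    # non-phase-locked ongoing alpha × desynchronization envelope
    ind = params.induced_alpha
    w_ind = np.array([montage.gaussian_topography(
        ind.topography_center, ind.topography_sigma, chans)[c] for c in chans])
    env_ind = 1.0 - ind.depth * np.exp(
        -((times - lat["trough_latency_ms"]) ** 2) / (2.0 * ind.trough_width_ms**2))
    if ind.narrowband_noise:
        from .tse import FilterSpec, bandpass_zero_phase
        osc = bandpass_zero_phase(rng.standard_normal((n_tr, n_sp)), fs, FilterSpec())
        osc_rms = np.sqrt(np.mean(osc**2, axis=-1, keepdims=True))
        osc_rms[osc_rms == 0] = 1.0
        osc = ind.ongoing_amplitude_uv / np.sqrt(2.0) * osc / osc_rms
    else:
        phases = rng.uniform(0.0, 2 * np.pi, size=n_tr)
        osc = ind.ongoing_amplitude_uv * np.cos(
            2 * np.pi * ind.frequency_hz * t[None, :] + phases[:, None])
    data += (osc * env_ind[None, :])[:, None, :] * w_ind[None, :, None]

    # 1/f background noise, independent per trial × scalp channel
    noise = params.noise
    if noise.rms_uv > 0:
        nz = one_over_f_noise(rng, (n_tr, int(scalp.sum())), n_sp, fs,
                              noise.exponent, noise.rms_uv)
        data[:, scalp, :] += nz

    # ocular source: blink pulses + ocular background; VEOG records it,
    # scalp channels receive it scaled by the propagation factors
    art = params.artifacts
    prop = params.propagation_factors()
    b = np.array([prop.get(c, 0.0) for c in chans])
    ocular = np.zeros((n_tr, n_sp))
    blink_trials = np.flatnonzero(rng.random(n_tr) < art.blink_rate_per_trial)
    lo, hi = params.epoch_window_ms
    for tr in blink_trials:
        c_ms = rng.uniform(lo + 100.0, hi - 100.0)
        ocular[tr] += art.blink_amplitude_uv * np.exp(
            -((times - c_ms) ** 2) / (2.0 * art.blink_width_ms**2))
    if art.ocular_noise_rms_uv > 0:
        ocular += one_over_f_noise(rng, (n_tr,), n_sp, fs, noise.exponent,
                                   art.ocular_noise_rms_uv)
    data[:, iveog, :] = ocular
    data[:, scalp, :] += b[scalp][None, :, None] * ocular[:, None, :]

    # HEOG: saccade-like steps on a fraction of trials
    heog = np.zeros((n_tr, n_sp))
    if art.ocular_noise_rms_uv > 0:
        heog += one_over_f_noise(rng, (n_tr,), n_sp, fs, noise.exponent,
                                 art.ocular_noise_rms_uv)
    step_trials = np.flatnonzero(rng.random(n_tr) < art.heog_fraction)
    for tr in step_trials:
        onset_ms = rng.uniform(lo + 100.0, hi - 200.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        heog[tr] += sign * art.heog_step_uv * 0.5 * (
            1.0 + np.tanh((times - onset_ms) / 20.0))
    data[:, iheog, :] = heog

    contaminated = [int(tr) for tr in step_trials
                    if np.max(np.abs(heog[tr])) > 50.0]

    epochs = EpochSet(data, times, list(chans), condition=condition,
                      subject_id=subject_id(si))
    truth = SubjectConditionTruth(
        subject_id=subject_id(si),
        condition=condition,
        p3_latency_ms=float(lat["p3_latency_ms"]),
        p3_amplitude_uv=float(lat["p3_amplitude_uv"]),
        evoked_burst_center_ms=float(lat["evoked_center_ms"]),
        induced_trough_latency_ms=float(times[int(np.argmin(env_ind))]),
        induced_depth=float(ind.depth),
        heog_contaminated_trials=contaminated,
        blink_trials=[int(x) for x in blink_trials],
        rt_ms=float(lat["rt_ms"]),
        accuracy_pct=float(lat["accuracy_pct"]),
    )
    return epochs, truth


def iter_dataset(params: SimulationParams) -> Iterator[tuple[EpochSet, SubjectConditionTruth]]:
    """Yield (EpochSet, truth) lazily, one subject × condition at a time.

    Preferred over :func:`generate_dataset` at the full study geometry,
    where materializing every subject would need several gigabytes.
    """
    params.validate()
    for si in range(params.n_subjects):
        for condition in CONDITIONS:
            yield generate_subject_condition(params, si, condition)


def generate_dataset(params: SimulationParams) -> tuple[list[tuple[EpochSet, EpochSet]], GroundTruth]:
    """Materialize the full dataset: one (ST, DT) EpochSet pair per subject."""
    params.validate()
    truth = GroundTruth(blink_propagation=params.propagation_factors())
    pairs: list[tuple[EpochSet, EpochSet]] = []
    for si in range(params.n_subjects):
        es_st, t_st = generate_subject_condition(params, si, "ST")
        es_dt, t_dt = generate_subject_condition(params, si, "DT")
        truth.add(t_st)
        truth.add(t_dt)
        pairs.append((es_st, es_dt))
    return pairs, truth


def behavior_table(truth: GroundTruth) -> pd.DataFrame:
    """Long-format behavioral table (subject, condition, rt_ms, accuracy_pct)."""
    rows = [
        {"subject": s, "condition": c, "rt_ms": e.rt_ms,
         "accuracy_pct": e.accuracy_pct}
        for (s, c), e in sorted(truth.entries.items())
    ]
    return pd.DataFrame(rows)


def write_fixture(pairs: list[tuple[EpochSet, EpochSet]], truth: GroundTruth,
                  path: str | Path, marker_label: str = "S  1") -> list[Path]:
    """Write each subject × condition as a BrainVision triplet plus a JSON
    ground-truth sidecar.

    Epochs are laid out back-to-back in the continuous file with a stimulus
    marker at each trial's 0 ms sample, so epoching the file with the
    original window reproduces the epoch arrays.
    """
    from .io import write_brainvision
    from .containers import ContinuousRecording

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for es_pair in pairs:
        for es in es_pair:
            onset = int(np.argmin(np.abs(es.times)))
            cont = np.concatenate(list(es.data), axis=-1)
            markers = [(tr * es.n_samples + onset, marker_label)
                       for tr in range(es.n_trials)]
            rec = ContinuousRecording(cont, es.sampling_rate,
                                      list(es.channel_labels), markers)
            stem = path / f"{es.subject_id}_{es.condition}"
            written.extend(write_brainvision(rec, stem))
    sidecar = path / "ground_truth.json"
    payload = {
        "n_subjects": len(pairs),
        "blink_propagation": truth.blink_propagation,
        "entries": [dataclasses.asdict(e) for _, e in sorted(truth.entries.items())],
    }
    sidecar.write_text(json.dumps(payload, indent=2))
    written.append(sidecar)
    return written
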