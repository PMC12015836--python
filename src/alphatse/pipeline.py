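"""Reproducible generate → preprocess → decompose → measure → test workflow.

A single YAML/JSON config is the only source of analysis parameters. Each
stage writes its outputs plus a hash of the config subset it depends on
into the run directory; re-running skips stages whose hash matches and
whose outputs exist, and re-running with the same config reproduces every
numeric output bit-identically (all randomness flows from the seed).

Large intermediates are not persisted: stages regenerate the synthetic
epochs deterministically from the seed and keep only traces, tables and the
report on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import measures as meas
from . import simulate as sim
from . import stats as st
from .containers import EpochSet
from .phase import PhaseExtractor, polar_export
from .preprocess import BlinkCorrector, CommonAverageReference, HeogRejector
from .tse import FilterSpec, erp_average, tse_decompose

__all__ = ["DEFAULT_CONFIG", "validate_config", "run", "STAGES"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_subjects": 26,
    "n_trials_per_condition": 140,
    "band_hz": [8.0, 13.0],
    "rolloff_db_oct": 48,
    "spectral_baseline_ms": [-100.0, 0.0],
    "erp_baseline_ms": [-200.0, 0.0],
    "heog_threshold_uv": 50.0,
    "car_exclude": ["VEOG", "HEOG"],
    "blink_correction": True,
    "windows_ms": {
        "P3": [350.0, 410.0],
        "evoked_alpha": [140.0, 155.0],
        "induced_alpha": [165.0, 200.0],
    },
    # per-subject peak-latency search windows; the printed windows above are
    # the mean-amplitude windows, peaks are identified individually
    "latency_windows_ms": {
        "P3": [250.0, 600.0],
        "evoked_alpha": [100.0, 220.0],
        "induced_alpha": [100.0, 320.0],
    },
    "electrodes": {"P3": "Pz", "alpha": "PO6"},
    "pick_electrodes_from_grand_average": True,
    "induced_polarity": "absmax",
    "phase_min_amplitude_uv": 0.05,
    "noise_rms_uv": 5.0,
    "induced_depth": 0.8,
    "equal_condition_parameters": False,
}

_RANGE_CHECKS = {
    "seed": lambda v: isinstance(v, int) and v >= 0,
    "n_subjects": lambda v: isinstance(v, int) and v >= 1,
    "n_trials_per_condition": lambda v: isinstance(v, int) and v >= 1,
    "rolloff_db_oct": lambda v: isinstance(v, int) and v > 0 and v % 6 == 0,
    "heog_threshold_uv": lambda v: isinstance(v, (int, float)) and v > 0,
    "phase_min_amplitude_uv": lambda v: isinstance(v, (int, float)) and v >= 0,
    "noise_rms_uv": lambda v: isinstance(v, (int, float)) and v >= 0,
    "induced_depth": lambda v: isinstance(v, (int, float)) and 0 <= v <= 1,
    "blink_correction": lambda v: isinstance(v, bool),
    "equal_condition_parameters": lambda v: isinstance(v, bool),
    "induced_polarity": lambda v: v in ("max", "min", "absmax"),
}


def validate_config(config: dict | None) -> dict:
    """Fill defaults, reject unknown keys, check types and ranges.

    Returns a normalized copy; errors name the offending field.
    """
    config = dict(config or {})
    errors = []
    unknown = set(config) - set(DEFAULT_CONFIG)
    for key in sorted(unknown):
        errors.append(f"unknown config key: {key!r}")
    out = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in config.items():
        if key in unknown:
            continue
        if key in ("windows_ms", "latency_windows_ms"):
            if not isinstance(value, dict) or set(value) - set(out[key]):
                errors.append(f"{key}: must map P3/evoked_alpha/induced_alpha")
            else:
                out[key].update(
                    {k: [float(v[0]), float(v[1])] for k, v in value.items()})
        elif key == "electrodes":
            if not isinstance(value, dict) or set(value) - {"P3", "alpha"}:
                errors.append("electrodes: must map P3 and/or alpha")
            else:
                out["electrodes"].update(value)
        else:
            out[key] = value
    band = out["band_hz"]
    if not (isinstance(band, (list, tuple)) and len(band) == 2
            and 0 < float(band[0]) < float(band[1])):
        errors.append(f"band_hz: edges must satisfy 0 < low < high, got {band}")
    else:
        out["band_hz"] = [float(band[0]), float(band[1])]
    for key in ("spectral_baseline_ms", "erp_baseline_ms"):
        w = out[key]
        if not (isinstance(w, (list, tuple)) and len(w) == 2
                and float(w[0]) < float(w[1])):
            errors.append(f"{key}: must be an increasing [lo, hi] ms pair")
        else:
            out[key] = [float(w[0]), float(w[1])]
    for key in ("windows_ms", "latency_windows_ms"):
        for name, (lo, hi) in out[key].items():
            if not lo < hi:
                errors.append(f"{key}.{name}: must be an increasing ms pair")
    for key, check in _RANGE_CHECKS.items():
        if not check(out[key]):
            errors.append(f"{key}: invalid value {out[key]!r}")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return out


def _sim_params(cfg: dict) -> sim.SimulationParams:
    p = sim.SimulationParams(
        n_subjects=cfg["n_subjects"],
        n_trials_per_condition=cfg["n_trials_per_condition"],
        seed=cfg["seed"],
    )
    p.noise.rms_uv = float(cfg["noise_rms_uv"])
    p.induced_alpha.depth = float(cfg["induced_depth"])
    if cfg["equal_condition_parameters"]:
        for spec_attr, field_name in [
            ("p3", "latency_mean_ms"), ("p3", "amplitude_uv"),
            ("evoked_alpha", "burst_center_ms"),
            ("induced_alpha", "trough_latency_ms"),
        ]:
            d = getattr(getattr(p, spec_attr), field_name)
            mean = (d["ST"] + d["DT"]) / 2.0
            d["ST"] = d["DT"] = mean
    return p.validate()


def _preprocess(es: EpochSet, cfg: dict) -> tuple[EpochSet, dict]:
    rej = HeogRejector(cfg["heog_threshold_uv"])
    es = rej.transform(es)
    audit = {"n_rejected": rej.n_rejected_, "blink_factors": None}
    if cfg["blink_correction"]:
        bc = BlinkCorrector().fit(es)
        es = bc.transform(es)
        audit["blink_factors"] = bc.propagation_.tolist()
        audit["blink_skipped"] = bool(bc.skipped_)
    es = CommonAverageReference(tuple(cfg["car_exclude"])).transform(es)
    return es, audit


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


def _stage_fresh(stage_dir: Path, dep_hash: str, outputs: list[str]) -> bool:
    marker = stage_dir / "stage.json"
    if not marker.exists():
        return False
    try:
        recorded = json.loads(marker.read_text())["config_hash"]
    except (json.JSONDecodeError, KeyError):
        return False
    return recorded == dep_hash and all((stage_dir / o).exists() for o in outputs)


def _finish_stage(stage_dir: Path, dep_hash: str) -> None:
    (stage_dir / "stage.json").write_text(
        json.dumps({"config_hash": dep_hash}, sort_keys=True))


def _dep_hashes(cfg: dict) -> dict[str, str]:
    sim_keys = {k: cfg[k] for k in ("seed", "n_subjects", "n_trials_per_condition",
                                    "noise_rms_uv", "induced_depth",
                                    "equal_condition_parameters")}
    pre_keys = {**sim_keys, **{k: cfg[k] for k in ("heog_threshold_uv",
                                                   "car_exclude",
                                                   "blink_correction")}}
    tse_keys = {**pre_keys, **{k: cfg[k] for k in ("band_hz", "rolloff_db_oct",
                                                   "spectral_baseline_ms",
                                                   "erp_baseline_ms")}}
    phase_keys = {**pre_keys, "band_hz": cfg["band_hz"],
                  "windows_ms": cfg["windows_ms"],
                  "electrodes": cfg["electrodes"],
                  "phase_min_amplitude_uv": cfg["phase_min_amplitude_uv"]}
    measure_keys = {**tse_keys, "windows_ms": cfg["windows_ms"],
                    "latency_windows_ms": cfg["latency_windows_ms"],
                    "electrodes": cfg["electrodes"],
                    "pick": cfg["pick_electrodes_from_grand_average"],
                    "induced_polarity": cfg["induced_polarity"]}
    stats_keys = {**measure_keys, **phase_keys}
    return {"simulate": _hash(sim_keys), "preprocess": _hash(pre_keys),
            "tse": _hash(tse_keys), "phase": _hash(phase_keys),
            "measure": _hash(measure_keys), "stats": _hash(stats_keys)}


def stage_simulate(cfg: dict, run_dir: Path) -> Path:
    """Ground truth + behavioral table (the epoch data themselves are
    regenerated deterministically by later stages)."""
    out = run_dir / "simulate"
    dep = _dep_hashes(cfg)["simulate"]
    if _stage_fresh(out, dep, ["ground_truth.json", "behavior.tsv"]):
        return out
    out.mkdir(parents=True, exist_ok=True)
    params = _sim_params(cfg)
    truth = sim.GroundTruth(blink_propagation=params.propagation_factors())
    for si in range(params.n_subjects):
        for cond in sim.CONDITIONS:
            truth.add(sim.generate_subject_condition(params, si, cond)[1])
    import dataclasses
    payload = {
        "blink_propagation": truth.blink_propagation,
        "entries": [dataclasses.asdict(e) for _, e in sorted(truth.entries.items())],
    }
    (out / "ground_truth.json").write_text(json.dumps(payload, indent=2,
                                                      sort_keys=True))
    sim.behavior_table(truth).to_csv(out / "behavior.tsv", sep="\t", index=False)
    _finish_stage(out, dep)
    return out


def stage_preprocess(cfg: dict, run_dir: Path) -> Path:
    """Audit outputs of the preprocessing chain (rejections, blink factors)."""
    out = run_dir / "preprocess"
    dep = _dep_hashes(cfg)["preprocess"]
    if _stage_fresh(out, dep, ["rejections.tsv", "blink_factors.tsv"]):
        return out
    out.mkdir(parents=True, exist_ok=True)
    params = _sim_params(cfg)
    rej_rows, blink_rows = [], []
    for es, _ in sim.iter_dataset(params):
        _, audit = _preprocess(es, cfg)
        rej_rows.append({"subject": es.subject_id, "condition": es.condition,
                         "n_rejected": audit["n_rejected"],
                         "n_trials": es.n_trials})
        if audit["blink_factors"] is not None:
            for lab, b in zip(es.channel_labels, audit["blink_factors"]):
                blink_rows.append({"subject": es.subject_id,
                                   "condition": es.condition,
                                   "channel": lab, "factor": b})
        logger.info("preprocess %s %s: rejected %d/%d trials", es.subject_id,
                    es.condition, audit["n_rejected"], es.n_trials)
    pd.DataFrame(rej_rows).to_csv(out / "rejections.tsv", sep="\t", index=False)
    pd.DataFrame(blink_rows).to_csv(out / "blink_factors.tsv", sep="\t",
                                    index=False)
    _finish_stage(out, dep)
    return out


def stage_tse(cfg: dict, run_dir: Path) -> Path:
    """Per subject × condition: ERP and evoked/total/induced TSE traces."""
    out = run_dir / "tse"
    dep = _dep_hashes(cfg)["tse"]
    params = _sim_params(cfg)
    expected = ["times_ms.tsv", "channels.json"] + [
        f"{sim.subject_id(si)}_{cond}.npz"
        for si in range(params.n_subjects) for cond in sim.CONDITIONS]
    if _stage_fresh(out, dep, expected):
        return out
    out.mkdir(parents=True, exist_ok=True)
    spec = FilterSpec(tuple(cfg["band_hz"]), cfg["rolloff_db_oct"])
    for es, _ in sim.iter_dataset(params):
        pre, _ = _preprocess(es, cfg)
        erp = erp_average(pre, baseline_ms=tuple(cfg["erp_baseline_ms"]))
        traces = tse_decompose(pre, spec,
                               baseline_ms=tuple(cfg["spectral_baseline_ms"]),
                               erp_baseline_ms=tuple(cfg["erp_baseline_ms"]))
        np.savez(out / f"{es.subject_id}_{es.condition}.npz",
                 erp=erp, evoked=traces.evoked, total=traces.total,
                 induced=traces.induced,
                 n_trials_used=traces.n_trials_used)
    np.savetxt(out / "times_ms.tsv", params.times_ms[None, :], delimiter="\t")
    (out / "channels.json").write_text(json.dumps(params.channels))
    _finish_stage(out, dep)
    return out


def stage_phase(cfg: dict, run_dir: Path) -> Path:
    """Per-subject circular phases of evoked and induced alpha, per condition."""
    out = run_dir / "phase"
    dep = _dep_hashes(cfg)["phase"]
    if _stage_fresh(out, dep, [f"phase_{c}.tsv" for c in sim.CONDITIONS]):
        return out
    out.mkdir(parents=True, exist_ok=True)
    params = _sim_params(cfg)
    chan = cfg["electrodes"]["alpha"]
    extract_ev = PhaseExtractor(chan, tuple(cfg["windows_ms"]["evoked_alpha"]),
                                tuple(cfg["band_hz"]), remove_evoked=False,
                                min_amplitude_uv=cfg["phase_min_amplitude_uv"])
    extract_in = PhaseExtractor(chan, tuple(cfg["windows_ms"]["induced_alpha"]),
                                tuple(cfg["band_hz"]), remove_evoked=True,
                                min_amplitude_uv=cfg["phase_min_amplitude_uv"])
    sets: dict[str, dict[str, list]] = {c: {"evoked": [], "induced": []}
                                        for c in sim.CONDITIONS}
    for es, _ in sim.iter_dataset(params):
        pre, _ = _preprocess(es, cfg)
        sets[es.condition]["evoked"].append(extract_ev.fit(pre).transform(pre))
        sets[es.condition]["induced"].append(extract_in.fit(pre).transform(pre))
    for cond in sim.CONDITIONS:
        polar_export(sets[cond]["evoked"], sets[cond]["induced"], cond,
                     path=out / f"phase_{cond}.tsv",
                     plot_path=out / f"phase_{cond}.svg")
    _finish_stage(out, dep)
    return out


def stage_measure(cfg: dict, run_dir: Path) -> Path:
    """Grand averages, electrode fixing, per-subject latency and 6×7
    amplitude tables."""
    out = run_dir / "measure"
    dep = _dep_hashes(cfg)["measure"]
    outputs = ["latencies.tsv", "matrix_P3.tsv", "matrix_evoked_alpha.tsv",
               "matrix_induced_alpha.tsv", "electrodes.json"]
    if _stage_fresh(out, dep, outputs):
        return out
    tse_dir = stage_tse(cfg, run_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = _sim_params(cfg)
    times = params.times_ms
    channels = json.loads((tse_dir / "channels.json").read_text())
    subjects = [sim.subject_id(i) for i in range(params.n_subjects)]

    def load(subject: str, cond: str) -> dict[str, np.ndarray]:
        with np.load(tse_dir / f"{subject}_{cond}.npz") as z:
            return {k: z[k] for k in ("erp", "evoked", "total", "induced")}

    kinds = {"P3": "erp", "evoked_alpha": "evoked", "induced_alpha": "induced"}
    polarity = {"P3": "max", "evoked_alpha": "max",
                "induced_alpha": cfg["induced_polarity"]}

    # grand average over subjects and conditions fixes the electrode
    grand: dict[str, np.ndarray] = {}
    all_traces: dict[str, dict[tuple[str, str], np.ndarray]] = {k: {}
                                                                for k in kinds}
    for subject in subjects:
        for cond in sim.CONDITIONS:
            arrs = load(subject, cond)
            for kind, arr_key in kinds.items():
                all_traces[kind][(subject, cond)] = arrs[arr_key]
    electrodes = {}
    scalp_ix = [i for i, c in enumerate(channels)
                if c not in cfg["car_exclude"]]
    scalp_names = [channels[i] for i in scalp_ix]
    for kind in kinds:
        grand[kind] = meas.grand_average(list(all_traces[kind].values()))
        if cfg["pick_electrodes_from_grand_average"]:
            electrodes[kind] = meas.pick_measurement_electrode(
                grand[kind][scalp_ix], scalp_names, times,
                tuple(cfg["windows_ms"][kind]), polarity[kind])
        else:
            electrodes[kind] = (cfg["electrodes"]["P3"] if kind == "P3"
                                else cfg["electrodes"]["alpha"])
        logger.info("measure: %s electrode = %s", kind, electrodes[kind])
    (out / "electrodes.json").write_text(json.dumps(electrodes, sort_keys=True))

    lat_rows = []
    for kind in kinds:
        ich = channels.index(electrodes[kind])
        for (subject, cond), trace in sorted(all_traces[kind].items()):
            pm = meas.peak_latency(trace[ich], times,
                                   tuple(cfg["latency_windows_ms"][kind]),
                                   polarity[kind], subject_id=subject,
                                   condition=cond, signal_kind=kind,
                                   electrode=electrodes[kind])
            lat_rows.append({"subject": subject, "condition": cond,
                             "signal_kind": kind, "electrode": pm.electrode,
                             "latency_ms": pm.latency_ms,
                             "amplitude_uv": pm.amplitude_uv})
    pd.DataFrame(lat_rows).to_csv(out / "latencies.tsv", sep="\t", index=False)

    for kind in kinds:
        table = meas.matrix_amplitudes(all_traces[kind], channels, times,
                                       tuple(cfg["windows_ms"][kind]))
        table.to_csv(out / f"matrix_{kind}.tsv", sep="\t", index=False)
    _finish_stage(out, dep)
    return out


def stage_stats(cfg: dict, run_dir: Path) -> Path:
    """Assemble the full analysis report from the stage outputs."""
    out = run_dir / "stats"
    dep = _dep_hashes(cfg)["stats"]
    if _stage_fresh(out, dep, ["report.json", "report.txt"]):
        return out
    sim_dir = stage_simulate(cfg, run_dir)
    measure_dir = stage_measure(cfg, run_dir)
    phase_dir = stage_phase(cfg, run_dir)
    out.mkdir(parents=True, exist_ok=True)
    behavior = pd.read_csv(sim_dir / "behavior.tsv", sep="\t")
    latencies = pd.read_csv(measure_dir / "latencies.tsv", sep="\t")
    amplitude_tables = {
        kind: pd.read_csv(measure_dir / f"matrix_{kind}.tsv", sep="\t")
        for kind in ("P3", "evoked_alpha", "induced_alpha")
    }
    phase_tables = {c: pd.read_csv(phase_dir / f"phase_{c}.tsv", sep="\t")
                    for c in sim.CONDITIONS}
    report = st.analysis_report(behavior, latencies, amplitude_tables,
                                phase_tables)
    st.validate_report(report)
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True))
    (out / "report.txt").write_text(_format_report(report))
    _finish_stage(out, dep)
    return out


def _format_report(report: dict) -> str:
    lines = ["Analysis report", "=" * 15, ""]
    def _zp(d: dict) -> str:
        if "skipped" in d:
            return "skipped"
        z = d.get("z")
        stat = f"Z={z:.3f}" if z is not None else f"stat={d['statistic']:.3f}"
        return f"{stat}, p={d['p']:.3g}"

    rt = report["behavioral"]["reaction_time"]
    lines.append(
        f"Reaction time: ST {rt['ST']['mean']:.0f}±{rt['ST']['sd']:.1f} ms, "
        f"DT {rt['DT']['mean']:.0f}±{rt['DT']['sd']:.1f} ms "
        f"(Wilcoxon {_zp(rt['wilcoxon'])})")
    acc = report["behavioral"]["accuracy"]
    lines.append(
        f"Accuracy: ST {acc['ST']['mean']:.2f}±{acc['ST']['sd']:.2f} %, "
        f"DT {acc['DT']['mean']:.2f}±{acc['DT']['sd']:.2f} % "
        f"(Wilcoxon {_zp(acc['wilcoxon'])})")
    p3 = report["p3"]["latency"]
    lines.append(
        f"P3 latency: ST {p3['ST']['mean']:.0f}±{p3['ST']['sd']:.0f} ms, "
        f"DT {p3['DT']['mean']:.0f}±{p3['DT']['sd']:.0f} ms "
        f"({_zp(p3['t_test'])})")
    for eff in report["p3"]["amplitude_anova"]:
        if eff["effect"] == "condition":
            lines.append(
                f"P3 amplitude load effect: F(1,{eff['df_den']})="
                f"{eff['F']:.3f}, p_gg={eff['p_gg']:.3g}, "
                f"partial eta^2={eff['partial_eta_sq']:.3f}")
    g = report["alpha_latency"]["grand_ms"]
    lines.append(f"Alpha latency grand means: evoked {g['evoked_alpha']} ms, "
                 f"induced {g['induced_alpha']} ms")
    for eff in report["alpha_latency"]["anova"]:
        lines.append(
            f"Alpha latency ANOVA {eff['effect']}: "
            f"F({eff['df_num']},{eff['df_den']})={eff['F']:.3f}, "
            f"p_gg={eff['p_gg']:.3g}, partial eta^2={eff['partial_eta_sq']:.3f}")
    if "phase" in report:
        for cond, kinds in sorted(report["phase"].items()):
            for kind, r in sorted(kinds.items()):
                lines.append(f"Rayleigh {cond}/{kind}: z={r['rayleigh_z']:.3f}, "
                             f"p={r['p']:.3g} (n={r['n']})")
    return "\n".join(lines) + "\n"


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "tse": stage_tse,
    "phase": stage_phase,
    "measure": stage_measure,
    "stats": stage_stats,
}


def run(config: dict | str | Path | None, out_dir: str | Path,
        stages: list[str] | None = None) -> Path:
    """Run the pipeline (all stages by default) into ``out_dir``.

    ``config`` may be a dict, a YAML/JSON file path, or None for defaults.
    Writes a manifest (config + seed + hash) and a log; returns the run dir.
    """
    if isinstance(config, (str, Path)):
        import yaml
        config = yaml.safe_load(Path(config).read_text())
    cfg = validate_config(config)
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("alphatse")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        (run_dir / "manifest.json").write_text(json.dumps(
            {"config": cfg, "seed": cfg["seed"], "config_hash": _hash(cfg)},
            indent=2, sort_keys=True))
        for name in (stages or list(STAGES)):
            if name not in STAGES:
                raise ValueError(f"unknown stage {name!r}; "
                                 f"choose from {list(STAGES)}")
            logger.info("stage %s", name)
            STAGES[name](cfg, run_dir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return run_dir
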