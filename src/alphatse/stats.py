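"""The statistical layer: normality gate, paired tests, repeated-measures
ANOVA with Greenhouse–Geisser correction, effect sizes, Bonferroni.

The repeated-measures ANOVA is a fully within-subject factorial: for every
effect (main or interaction) the per-subject cell means are projected onto
an orthonormal contrast basis (normalized Helmert per factor, Kronecker
products for interactions); the effect F is the ratio of the between- vs
within-subject variability of those contrast scores, the Greenhouse–Geisser
ε̂ is estimated from the contrast-score covariance, the GG-corrected p uses
ε-scaled degrees of freedom, and partial η² = SS_effect/(SS_effect+SS_error).

The paired two-condition comparison reported as a "Wilcoxon U/Z" in the
behavioral literature is the Wilcoxon signed-rank test with the
normal-approximation Z (continuity and tie corrected); that reading is
implemented here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

__all__ = [
    "TestResult",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "paired_t",
    "paired_test_auto",
    "rm_anova",
    "gg_epsilon",
    "partial_eta_sq_from_f",
    "bonferroni",
    "round_half_up",
    "latency_grand_summary",
    "analysis_report",
    "validate_report",
]

ALPHA = 0.05


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    z: float | None = None
    effect_size: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.n < 1:
            raise ValueError("n must be ≥ 1")

    def as_dict(self) -> dict:
        return {
            "test": self.test_name, "statistic": self.statistic,
            "p": self.p_value, "n": self.n, "z": self.z,
            "effect_size": self.effect_size, "notes": self.notes,
        }


def shapiro_wilk(sample) -> TestResult:
    """Shapiro–Wilk normality test (3 ≤ n ≤ 5000)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro–Wilk needs 3 ≤ n ≤ 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro–Wilk undefined for a zero-variance sample")
    w, p = sps.shapiro(x)
    return TestResult("shapiro_wilk", float(w), float(p), int(x.size))


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Paired Wilcoxon signed-rank with normal-approximation Z.

    ``x`` may be the differences directly, or paired with ``y``. Zero
    differences are dropped; continuity and tie corrections apply. The
    statistic is min(W+, W−). Needs ≥5 nonzero differences.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero")
    if nz.size < 5:
        raise ValueError(f"need ≥5 nonzero differences, got {nz.size}")
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                       alternative="two-sided", method="approx")
    return TestResult("wilcoxon_signed_rank", float(res.statistic),
                      float(res.pvalue), int(nz.size),
                      z=float(res.zstatistic))


def paired_t(x, y=None) -> TestResult:
    """Two-sided paired Student t (df = n − 1)."""
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if d.size < 2:
        raise ValueError("paired t needs n ≥ 2")
    if np.std(d, ddof=1) == 0:
        raise ValueError("paired differences have zero variance")
    t, p = sps.ttest_1samp(d, 0.0)
    return TestResult("paired_t", float(t), float(p), int(d.size))


def paired_test_auto(x, y, alpha: float = ALPHA) -> TestResult:
    """Normality-gated paired comparison, as in the reporting chain:
    Shapiro–Wilk on the differences, then Student t if normality is not
    rejected, Wilcoxon signed-rank otherwise."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    gate = shapiro_wilk(d)
    if gate.p_value < alpha:
        out = wilcoxon_signed_rank(d)
        out.notes = f"normality rejected (Shapiro p={gate.p_value:.3g})"
    else:
        out = paired_t(d)
        out.notes = f"normality not rejected (Shapiro p={gate.p_value:.3g})"
    return out


def _epsilon_from_contrast_cov(s: np.ndarray) -> float:
    q = s.shape[0]
    tr = float(np.trace(s))
    tr2 = float(np.trace(s @ s))
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / (q * tr2)
    return float(min(1.0, max(1.0 / q, eps)))


def gg_epsilon(cell_covariance: np.ndarray) -> float:
    """Greenhouse–Geisser ε̂ from a k×k covariance of the effect's cells.

    The covariance is double-centered (projected onto the contrast space)
    and ε = tr(S̃)² / ((k−1)·tr(S̃²)), clamped to [1/(k−1), 1]. With k=2
    sphericity is trivial and ε = 1.
    """
    s = np.asarray(cell_covariance, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1] or s.shape[0] < 2:
        raise ValueError("need a k×k covariance with k ≥ 2")
    if not np.allclose(s, s.T):
        raise ValueError("covariance must be symmetric")
    lam = np.linalg.eigvalsh(s)
    if lam.min() < -1e-8 * max(1.0, lam.max()):
        raise ValueError("covariance is not positive semidefinite")
    k = s.shape[0]
    h = np.eye(k) - np.full((k, k), 1.0 / k)
    st = h @ s @ h
    tr = float(np.trace(st))
    tr2 = float(np.trace(st @ st))
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / ((k - 1) * tr2)
    return float(min(1.0, max(1.0 / (k - 1), eps)))


def _cell_tensor(table: pd.DataFrame, dv: str, within: list[str],
                 subject: str) -> tuple[np.ndarray, list[list]]:
    levels = [sorted(table[f].unique()) for f in within]
    subjects = sorted(table[subject].unique())
    if len(subjects) < 2:
        raise ValueError("repeated-measures ANOVA needs ≥2 subjects")
    if table.duplicated(subset=[subject] + within).any():
        raise ValueError("more than one observation per subject × cell; "
                         "aggregate first")
    shape = (len(subjects),) + tuple(len(lv) for lv in levels)
    if len(within) == 1:
        cols = pd.Index(levels[0], name=within[0])
    else:
        cols = pd.MultiIndex.from_product(levels, names=within)
    wide = (table.pivot(index=subject, columns=within, values=dv)
            .reindex(index=subjects, columns=cols))
    y = wide.to_numpy(dtype=float).reshape(shape)
    if np.isnan(y).any():
        missing = np.argwhere(np.isnan(y))[0]
        raise ValueError(f"missing cell for subject {subjects[missing[0]]}: "
                         + ", ".join(f"{f}={levels[j][missing[j + 1]]}"
                                     for j, f in enumerate(within)))
    return y, levels


def rm_anova(table: pd.DataFrame, dv: str, within: list[str],
             subject: str = "subject") -> pd.DataFrame:
    """Fully within-subject factorial ANOVA with GG correction.

    ``table`` is long-format with one observation per subject × cell of the
    crossed ``within`` factors. Returns one row per effect with df, SS, F,
    ε̂, uncorrected and GG-corrected p, and partial η².
    """
    y, levels = _cell_tensor(table, dv, within, subject)
    n = y.shape[0]
    yf = y.reshape(n, -1)
    ks = [len(lv) for lv in levels]
    contrasts = [linalg.helmert(k, full=False) for k in ks]  # orthonormal rows
    means = [np.full((1, k), 1.0 / np.sqrt(k)) for k in ks]

    ss_tot = float(((yf - yf.mean()) ** 2).sum())
    tiny = 1e-12 * (ss_tot + 1.0)
    rows = []
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(range(len(within)), r):
            m = np.array([[1.0]])
            for j in range(len(within)):
                m = np.kron(m, contrasts[j] if j in combo else means[j])
            z = yf @ m.T  # n × q contrast scores
            q = z.shape[1]
            zbar = z.mean(axis=0)
            ss_eff = float(n * (zbar @ zbar))
            resid = z - zbar
            ss_err = float((resid**2).sum())
            if ss_eff < tiny:
                ss_eff = 0.0
            df1, df2 = q, q * (n - 1)
            ms_err = ss_err / df2
            f_val = (ss_eff / df1) / ms_err if ms_err > tiny else 0.0
            if q > 1:
                s = np.cov(z, rowvar=False, ddof=1)
                eps = _epsilon_from_contrast_cov(np.atleast_2d(s))
            else:
                eps = 1.0
            p_unc = float(sps.f.sf(f_val, df1, df2)) if ms_err > tiny else 1.0
            p_gg = (float(sps.f.sf(f_val, eps * df1, eps * df2))
                    if ms_err > tiny else 1.0)
            rows.append({
                "effect": " × ".join(within[j] for j in combo),
                "df_num": df1, "df_den": df2,
                "ss_effect": ss_eff, "ss_error": ss_err,
                "F": f_val, "gg_epsilon": eps,
                "p_uncorrected": p_unc, "p_gg": p_gg,
                "partial_eta_sq": ss_eff / (ss_eff + ss_err)
                if (ss_eff + ss_err) > 0 else 0.0,
            })
    return pd.DataFrame(rows)


def partial_eta_sq_from_f(f_value: float, df_num: int, df_den: int) -> float:
    """Partial η² recovered from an F statistic:
    F·df_num / (F·df_num + df_den)."""
    if f_value < 0:
        raise ValueError("F must be ≥ 0")
    if df_num < 1 or df_den < 1:
        raise ValueError("degrees of freedom must be ≥ 1")
    return float(f_value * df_num / (f_value * df_num + df_den))


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, m·p) for each of the m comparisons."""
    p = list(p_values)
    m = len(p) if m is None else m
    if m < 1:
        raise ValueError("m must be ≥ 1")
    if any(not 0.0 <= v <= 1.0 for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, m * v) for v in p]


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (.5 → up)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def latency_grand_summary(st_mean_ms: float, dt_mean_ms: float) -> int:
    """Grand latency in ms: unweighted mean of the two condition means,
    rounded half-up to integer ms."""
    return round_half_up((st_mean_ms + dt_mean_ms) / 2.0)


def _descriptives(values: np.ndarray) -> dict:
    v = np.asarray(values, dtype=float)
    return {"mean": float(v.mean()), "sd": float(v.std(ddof=1)), "n": int(v.size)}


def _paired_from_long(df: pd.DataFrame, value: str) -> tuple[np.ndarray, np.ndarray]:
    wide = df.pivot(index="subject", columns="condition", values=value)
    if not {"ST", "DT"} <= set(wide.columns):
        raise ValueError(f"{value}: need both ST and DT conditions")
    wide = wide.dropna()
    return wide["ST"].to_numpy(), wide["DT"].to_numpy()


def analysis_report(behavior: pd.DataFrame, latencies: pd.DataFrame,
                    amplitude_tables: dict[str, pd.DataFrame],
                    phase_tables: dict[str, pd.DataFrame] | None = None) -> dict:
    """Machine-readable results report mirroring the study's summary table.

    behavior : long table (subject, condition, rt_ms, accuracy_pct)
    latencies : long table (subject, condition, signal_kind, latency_ms)
        with signal kinds P3, evoked_alpha, induced_alpha
    amplitude_tables : kind → long 6×7-matrix table from
        :func:`alphatse.measures.matrix_amplitudes`
    phase_tables : condition → polar table from
        :func:`alphatse.phase.polar_export` (optional)
    """
    from .phase import rayleigh_test

    missing = [name for name, obj in [("behavior", behavior),
                                      ("latencies", latencies)] if obj is None]
    missing += [f"amplitude_tables[{k}]" for k in ("P3", "evoked_alpha",
                                                   "induced_alpha")
                if k not in (amplitude_tables or {})]
    if missing:
        raise ValueError("missing report inputs: " + ", ".join(missing))

    report: dict = {"alpha_level": ALPHA}

    # behavioral: descriptives + normality-gated paired comparison (the
    # study's data fail normality and fall through to Wilcoxon)
    def _try(fn, *args):
        try:
            return fn(*args).as_dict()
        except ValueError as err:
            return {"test": fn.__name__, "skipped": str(err)}

    beh = {}
    for value, label in (("rt_ms", "reaction_time"), ("accuracy_pct", "accuracy")):
        st, dt = _paired_from_long(behavior, value)
        beh[label] = {
            "ST": _descriptives(st), "DT": _descriptives(dt),
            "gated_test": _try(paired_test_auto, st, dt),
            "wilcoxon": _try(wilcoxon_signed_rank, st, dt),
        }
    report["behavioral"] = beh

    # P3: latency paired t; amplitude load × AP × LM rm-ANOVA
    p3_lat = latencies[latencies["signal_kind"] == "P3"]
    st, dt = _paired_from_long(p3_lat, "latency_ms")
    report["p3"] = {
        "latency": {
            "ST": _descriptives(st), "DT": _descriptives(dt),
            "shapiro_diff": _try(shapiro_wilk, st - dt),
            "t_test": _try(paired_t, st, dt),
        },
        "amplitude_anova": rm_anova(
            amplitude_tables["P3"], "amplitude_uv",
            ["condition", "ap", "lm"]).to_dict(orient="records"),
    }

    # alpha latency: 2 (load) × 2 (activity) rm-ANOVA + per-activity paired
    # comparisons (both reported pathways)
    alpha_lat = latencies[latencies["signal_kind"].isin(
        ["evoked_alpha", "induced_alpha"])].rename(
        columns={"signal_kind": "activity"})
    lat_anova = rm_anova(alpha_lat, "latency_ms", ["condition", "activity"])
    per_activity = {}
    cond_means = {}
    for kind in ("evoked_alpha", "induced_alpha"):
        sub = alpha_lat[alpha_lat["activity"] == kind]
        st, dt = _paired_from_long(sub, "latency_ms")
        per_activity[kind] = {
            "ST": _descriptives(st), "DT": _descriptives(dt),
            "t_test": _try(paired_t, st, dt),
        }
        cond_means[kind] = (float(st.mean()), float(dt.mean()))
    report["alpha_latency"] = {
        "anova": lat_anova.to_dict(orient="records"),
        "per_activity": per_activity,
        "grand_ms": {
            kind: latency_grand_summary(*cond_means[kind])
            for kind in cond_means
        },
    }

    # alpha amplitude ANOVAs, one per activity type
    report["alpha_amplitude"] = {
        kind: rm_anova(amplitude_tables[kind], "amplitude_uv",
                       ["condition", "ap", "lm"]).to_dict(orient="records")
        for kind in ("evoked_alpha", "induced_alpha")
    }

    # subject-level phase concentration (Rayleigh) per condition × activity
    if phase_tables:
        phases = {}
        for cond, df in phase_tables.items():
            phases[cond] = {}
            for kind in df["activity"].unique():
                ph = df.loc[df["activity"] == kind, "phase_rad"].to_numpy()
                z, p = rayleigh_test(ph)
                phases[cond][kind] = {"rayleigh_z": z, "p": p, "n": int(ph.size)}
        report["phase"] = phases

    return report


_REQUIRED_REPORT_KEYS = {
    "alpha_level", "behavioral", "p3", "alpha_latency", "alpha_amplitude"}


def validate_report(report: dict) -> None:
    """Raise if the report is missing a required section or malformed."""
    missing = _REQUIRED_REPORT_KEYS - set(report)
    if missing:
        raise ValueError(f"report missing sections: {sorted(missing)}")
    for label in ("reaction_time", "accuracy"):
        if label not in report["behavioral"]:
            raise ValueError(f"behavioral section missing {label}")
    if "grand_ms" not in report["alpha_latency"]:
        raise ValueError("alpha_latency section missing grand_ms")
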