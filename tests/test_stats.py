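"""Statistical layer: paired tests, rm-ANOVA with GG correction, effect sizes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from alphatse.stats import (
    analysis_report,
    bonferroni,
    gg_epsilon,
    latency_grand_summary,
    paired_t,
    paired_test_auto,
    partial_eta_sq_from_f,
    rm_anova,
    round_half_up,
    shapiro_wilk,
    validate_report,
    wilcoxon_signed_rank,
)


class TestShapiroWilk:
    def test_null_p_values_uniform(self, rng):
        ps = [shapiro_wilk(rng.standard_normal(26)).p_value
              for _ in range(1000)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_lognormal_rejected(self, rng):
        hits = sum(shapiro_wilk(rng.lognormal(0.0, 1.5, 26)).p_value < 0.05
                   for _ in range(200))
        assert hits > 0.9 * 200

    def test_linear_transform_invariance(self, rng):
        x = rng.standard_normal(26)
        w1 = shapiro_wilk(x).statistic
        w2 = shapiro_wilk(3.7 * x - 11.0).statistic
        assert w1 == pytest.approx(w2, abs=1e-10)

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="3 ≤ n"):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError, match="zero-variance"):
            shapiro_wilk(np.ones(10))


class TestWilcoxon:
    def test_all_positive_differences_extreme(self):
        d = np.arange(1.0, 27.0)
        res = wilcoxon_signed_rank(d)
        assert res.statistic == 0.0  # min(W+, W−)
        n = 26
        mu = n * (n + 1) / 4.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        z_max = (mu - 0.5) / sd  # continuity-corrected maximal |Z|
        assert abs(res.z) == pytest.approx(z_max, abs=1e-6)

    def test_exact_enumeration_oracle_n8(self, rng):
        # exact two-sided p by enumerating all 2^8 sign assignments
        d = rng.standard_normal(8)
        d[d == 0] = 0.5
        res = wilcoxon_signed_rank(d)
        ranks = sps.rankdata(np.abs(d))
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        ws = []
        for signs in itertools.product([0, 1], repeat=8):
            wp = ranks[np.array(signs, bool)].sum()
            ws.append(min(wp, ranks.sum() - wp))
        exact_p = np.mean([w <= w_obs for w in ws])
        assert res.statistic == w_obs
        assert res.p_value == pytest.approx(exact_p, abs=0.05)

    def test_type_i_error_calibrated(self, rng):
        hits = sum(wilcoxon_signed_rank(rng.standard_normal(26)).p_value < 0.05
                   for _ in range(2000))
        assert 0.035 <= hits / 2000 <= 0.065

    def test_validation(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.zeros(10))
        with pytest.raises(ValueError, match="≥5"):
            wilcoxon_signed_rank([0.0, 0.0, 0.0, 1.0, -2.0, 3.0])


class TestPairedT:
    def test_hand_computed_five_pairs(self):
        x = np.array([10.0, 12.0, 9.0, 11.0, 13.0])
        y = np.array([8.0, 11.0, 10.0, 9.0, 10.0])
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), 4)
        res = paired_t(x, y)
        assert res.statistic == pytest.approx(t_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_constant_differences_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(np.arange(6.0), np.arange(6.0) - 2.0)

    def test_t_squared_equals_two_level_anova_f(self, rng):
        x, y = rng.standard_normal((2, 26))
        rows = ([{"subject": i, "cond": "a", "v": x[i]} for i in range(26)]
                + [{"subject": i, "cond": "b", "v": y[i]} for i in range(26)])
        table = rm_anova(pd.DataFrame(rows), "v", ["cond"])
        t = paired_t(x, y).statistic
        assert table.F.iloc[0] == pytest.approx(t**2, abs=1e-8)


class TestRmAnova:
    def _toy(self, rng, n_subj=4, levels=(2, 3, 2)):
        rows = []
        for s in range(n_subj):
            for cell in itertools.product(*[range(k) for k in levels]):
                rows.append({"subject": s,
                             **{f"f{j}": f"l{v}" for j, v in enumerate(cell)},
                             "y": rng.standard_normal() + 0.5 * cell[0]})
        return pd.DataFrame(rows)

    def test_brute_force_ss_oracle_2x3x2(self, rng):
        # oracle: explicit mean decomposition — effect SS from marginal means,
        # error SS from the effect × subject interaction
        df = self._toy(rng)
        ours = rm_anova(df, "y", ["f0", "f1", "f2"]).set_index("effect")
        y = df.pivot_table(index="subject", columns=["f0", "f1", "f2"],
                           values="y").to_numpy().reshape(4, 2, 3, 2)
        n = 4

        def mean_over(arr, keep):
            axes = tuple(a for a in range(1, 4) if a not in keep)
            return arr.mean(axis=axes, keepdims=True)

        for effect, keep in [("f0", (1,)), ("f1", (2,)), ("f2", (3,)),
                             ("f0 × f1", (1, 2)), ("f0 × f1 × f2", (1, 2, 3))]:
            # marginal effect term via inclusion–exclusion over subsets
            eff = 0.0
            for r in range(len(keep) + 1):
                for sub in itertools.combinations(keep, r):
                    sign = (-1) ** (len(keep) - r)
                    eff = eff + sign * mean_over(y, sub).mean(axis=0,
                                                              keepdims=True)
            cells = int(np.prod(y.shape[1:]))
            reps = cells // eff.size
            ss_eff = n * reps * float(np.sum(eff**2))
            # subject × effect interaction for the error term
            eff_s = 0.0
            for r in range(len(keep) + 1):
                for sub in itertools.combinations(keep, r):
                    sign = (-1) ** (len(keep) - r)
                    eff_s = eff_s + sign * mean_over(y, sub)
            inter = eff_s - eff  # effect × subject interaction
            ss_err = reps * float(np.sum(inter**2))
            assert ours.loc[effect, "ss_effect"] == pytest.approx(ss_eff,
                                                                  rel=1e-9)
            assert ours.loc[effect, "ss_error"] == pytest.approx(ss_err,
                                                                 rel=1e-9)

    def test_zero_cell_differences_give_zero_f(self):
        rows = [{"subject": s, "c": c, "v": float(s)}
                for s in range(4) for c in ("a", "b", "c")]
        out = rm_anova(pd.DataFrame(rows), "v", ["c"])
        assert out.F.iloc[0] == 0.0
        assert out.partial_eta_sq.iloc[0] == 0.0

    def test_matches_pingouin_two_way(self, rng):
        import pingouin as pg

        df = self._toy(rng, n_subj=10, levels=(2, 3, 1)).drop(columns="f2")
        df = df.groupby(["subject", "f0", "f1"], as_index=False)["y"].mean()
        ours = rm_anova(df, "y", ["f0", "f1"]).set_index("effect")
        theirs = pg.rm_anova(dv="y", within=["f0", "f1"], subject="subject",
                             data=df, detailed=True, effsize="np2")
        for src, eff in [("f0", "f0"), ("f1", "f1"), ("f0 * f1", "f0 × f1")]:
            row = theirs[theirs.Source == src].iloc[0]
            assert ours.loc[eff, "F"] == pytest.approx(row["F"], rel=1e-9)
            assert ours.loc[eff, "p_uncorrected"] == pytest.approx(
                row["p_unc"], rel=1e-9)
            assert ours.loc[eff, "partial_eta_sq"] == pytest.approx(
                row["np2"], rel=1e-9)
            if not np.isnan(row["eps"]):
                assert ours.loc[eff, "gg_epsilon"] == pytest.approx(
                    row["eps"], rel=1e-6)

    def test_gg_conservative_where_it_matters(self, rng):
        # scaling dfs by ε raises the p-value throughout the significance
        # tail (p < 0.2); for clearly non-significant effects the correction
        # can go either way, as in SPSS/pingouin
        for _ in range(5):
            df = self._toy(rng, n_subj=8, levels=(2, 4, 3))
            out = rm_anova(df, "y", ["f0", "f1", "f2"])
            tail = out[out.p_uncorrected < 0.2]
            assert (tail.p_gg >= tail.p_uncorrected - 1e-12).all()
            assert ((out.gg_epsilon <= 1.0) & (out.gg_epsilon > 0.0)).all()

    def test_f_eta_roundtrip_identity(self, rng):
        x, y = rng.standard_normal((2, 26))
        rows = ([{"subject": i, "cond": "a", "v": x[i]} for i in range(26)]
                + [{"subject": i, "cond": "b", "v": y[i]} for i in range(26)])
        out = rm_anova(pd.DataFrame(rows), "v", ["cond"]).iloc[0]
        via_f = partial_eta_sq_from_f(out.F, int(out.df_num), int(out.df_den))
        assert via_f == pytest.approx(out.partial_eta_sq, abs=1e-10)

    def test_missing_cell_and_few_subjects_error(self, rng):
        df = self._toy(rng)
        with pytest.raises(ValueError, match="missing cell"):
            rm_anova(df.iloc[:-1], "y", ["f0", "f1", "f2"])
        with pytest.raises(ValueError, match="≥2 subjects"):
            rm_anova(df[df.subject == 0], "y", ["f0", "f1", "f2"])


class TestGgEpsilon:
    def test_two_levels_always_one(self, rng):
        a = rng.standard_normal((2, 2))
        s = a @ a.T
        assert gg_epsilon(s) == 1.0

    def test_compound_symmetry_gives_one(self):
        k = 5
        s = 0.3 * np.ones((k, k)) + 0.7 * np.eye(k)
        assert gg_epsilon(s) == pytest.approx(1.0, abs=1e-12)

    def test_rank_one_centered_gives_lower_bound(self):
        v = np.array([2.0, -1.0, -1.0, 0.0])  # zero-sum → survives centering
        s = np.outer(v, v)
        assert gg_epsilon(s) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="symmetric"):
            gg_epsilon(np.array([[1.0, 2.0], [0.0, 1.0]]))
        with pytest.raises(ValueError, match="semidefinite"):
            gg_epsilon(np.array([[1.0, 0.0], [0.0, -2.0]]))


class TestEffectSizesAndCorrections:
    def test_partial_eta_from_printed_f_values(self):
        assert partial_eta_sq_from_f(14.362, 1, 25) == pytest.approx(0.365,
                                                                     abs=5e-4)
        assert partial_eta_sq_from_f(8.408, 1, 25) == pytest.approx(0.252,
                                                                    abs=5e-4)
        assert partial_eta_sq_from_f(0.0, 3, 40) == 0.0

    def test_bonferroni(self):
        assert bonferroni([0.01], 42) == [pytest.approx(0.42)]
        assert bonferroni([0.5], 3) == [1.0]
        assert bonferroni([0.2, 0.03]) == [pytest.approx(0.4),
                                           pytest.approx(0.06)]
        with pytest.raises(ValueError):
            bonferroni([0.1], 0)

    def test_latency_grand_summaries(self):
        assert latency_grand_summary(146.0, 151.0) == 149
        assert latency_grand_summary(168.0, 198.0) == 183
        assert round_half_up(148.5) == 149
        assert round_half_up(-2.5) == -3


class TestReportingChain:
    def test_gated_chain_type_i_calibrated(self, rng):
        hits = 0
        reps = 1000
        for _ in range(reps):
            res = paired_test_auto(rng.standard_normal(26),
                                   rng.standard_normal(26))
            hits += res.p_value < 0.05
        assert 0.035 <= hits / reps <= 0.065

    def _tables(self, rng, n_subj=8, latency_shift=0.0):
        subs = [f"sub-{i:02d}" for i in range(n_subj)]
        beh = [{"subject": s, "condition": c,
                "rt_ms": rng.normal(400 + (50 if c == "DT" else 0), 30),
                "accuracy_pct": min(100.0, rng.normal(99.5, 1.0))}
               for s in subs for c in ("ST", "DT")]
        lat = [{"subject": s, "condition": c, "signal_kind": k,
                "latency_ms": rng.normal(
                    {"P3": 380.0, "evoked_alpha": 148.0,
                     "induced_alpha": 183.0}[k]
                    + (latency_shift if c == "DT" else 0.0), 15)}
               for s in subs for c in ("ST", "DT")
               for k in ("P3", "evoked_alpha", "induced_alpha")]
        from alphatse.measures import ElectrodeMatrix
        from alphatse import montage
        amp = {}
        for kind in ("P3", "evoked_alpha", "induced_alpha"):
            rows = []
            for s in subs:
                for c in ("ST", "DT"):
                    for ri, row in enumerate(ElectrodeMatrix.default().labels):
                        for ci, lab in enumerate(row):
                            rows.append({
                                "subject": s, "condition": c,
                                "ap": montage.MATRIX_ROWS[ri],
                                "lm": "L" + montage.MATRIX_LINES[ci]
                                if montage.MATRIX_LINES[ci] != "z" else "z",
                                "electrode": lab,
                                "amplitude_uv": rng.standard_normal(),
                            })
            amp[kind] = pd.DataFrame(rows)
        return pd.DataFrame(beh), pd.DataFrame(lat), amp

    def test_report_schema_validates(self, rng):
        beh, lat, amp = self._tables(rng)
        report = analysis_report(beh, lat, amp)
        validate_report(report)
        assert report["alpha_latency"]["grand_ms"].keys() == {
            "evoked_alpha", "induced_alpha"}

    def test_missing_inputs_named(self, rng):
        beh, lat, amp = self._tables(rng)
        amp.pop("evoked_alpha")
        with pytest.raises(ValueError, match="evoked_alpha"):
            analysis_report(beh, lat, amp)

    def test_null_latency_shift_rarely_significant(self, rng):
        sig = 0
        for _ in range(40):
            _, lat, _ = self._tables(rng, n_subj=12, latency_shift=0.0)
            lat = lat[lat.signal_kind.isin(["evoked_alpha", "induced_alpha"])]
            lat = lat.rename(columns={"signal_kind": "activity"})
            out = rm_anova(lat, "latency_ms", ["condition", "activity"])
            sig += bool(out.loc[out.effect == "condition", "p_gg"].iloc[0]
                        < 0.05)
        assert sig <= 0.1 * 40 + 2

    def test_latency_shift_detected_with_power(self, rng):
        detected = 0
        for _ in range(20):
            _, lat, _ = self._tables(rng, n_subj=26, latency_shift=30.0)
            p3 = lat[lat.signal_kind == "P3"]
            wide = p3.pivot(index="subject", columns="condition",
                            values="latency_ms")
            res = paired_t(wide["ST"].to_numpy(), wide["DT"].to_numpy())
            detected += res.p_value < 0.05
        assert detected >= 0.9 * 20
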