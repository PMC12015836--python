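"""Hilbert instantaneous phase and the evoked/induced phase dissociation."""

import numpy as np
import pandas as pd
import pytest

from alphatse.containers import window_indices
from alphatse.phase import (
    PhaseExtractor,
    circular_summary,
    instantaneous_phase,
    phase_at_window,
    polar_export,
    rayleigh_test,
    subtract_evoked,
)

from conftest import make_epochs

FS = 500.0


def _alpha_epochs(phases, freq=10.0, amp=5.0, n_samples=600, noise=None,
                  rng=None):
    times = -200.0 + 2.0 * np.arange(n_samples)
    t = times / 1000.0
    data = amp * np.cos(2 * np.pi * freq * t[None, :] + np.asarray(phases)[:, None])
    if noise:
        data = data + noise * rng.standard_normal(data.shape)
    return make_epochs(data[:, None, :], labels=["PO6"])


class TestSubtractEvoked:
    def test_identical_trials_leave_zero(self, rng):
        trial = rng.standard_normal((2, 80))
        es = make_epochs(np.repeat(trial[None], 6, axis=0))
        out = subtract_evoked(es)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_output_average_exactly_zero(self, rng):
        es = make_epochs(rng.standard_normal((9, 3, 60)))
        out = subtract_evoked(es)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_variance_decomposition(self, rng):
        # removing the across-trial mean keeps the within-trial variance
        es = make_epochs(rng.standard_normal((10, 2, 50)))
        out = subtract_evoked(es)
        np.testing.assert_allclose(out.data.var(axis=0),
                                   es.data.var(axis=0), atol=1e-12)
        # and the residual second moment equals that within-trial variance
        np.testing.assert_allclose(np.mean(out.data**2, axis=0),
                                   es.data.var(axis=0), atol=1e-12)

    def test_needs_two_trials(self, rng):
        es = make_epochs(rng.standard_normal((1, 2, 50)))
        with pytest.raises(ValueError, match="≥2"):
            subtract_evoked(es)


class TestInstantaneousPhase:
    def test_cosine_phase_zero_at_peaks(self):
        times = np.arange(0, 3, 1 / FS)
        x = np.cos(2 * np.pi * 10.0 * times)
        phi, env = instantaneous_phase(x, FS)
        peaks = np.flatnonzero(
            (x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1
        interior = peaks[(peaks > 500) & (peaks < x.size - 500)]
        assert np.max(np.abs(phi[interior])) < 0.02
        assert np.allclose(env[500:-500], 1.0, atol=0.02)

    def test_sine_lags_cosine_by_half_pi(self):
        times = np.arange(0, 3, 1 / FS)
        pc, _ = instantaneous_phase(np.cos(2 * np.pi * 10 * times), FS)
        ps, _ = instantaneous_phase(np.sin(2 * np.pi * 10 * times), FS)
        diff = np.angle(np.exp(1j * (pc - ps)))[500:-500]
        np.testing.assert_allclose(diff, np.pi / 2, atol=0.02)

    def test_agrees_with_local_sinusoid_regression_oracle(self, rng):
        # oracle: fit a·cos + b·sin over a one-cycle window around the probe
        times = np.arange(0, 4, 1 / FS)
        x = (np.cos(2 * np.pi * 10 * times + 0.7)
             + 0.2 * rng.standard_normal(times.size))
        phi, _ = instantaneous_phase(x, FS)
        from alphatse.tse import bandpass_zero_phase
        xf = bandpass_zero_phase(x, FS)
        half = 25  # one 10 Hz cycle = 50 samples
        for probe in (700, 1000, 1300):
            seg = xf[probe - half:probe + half]
            tt = (np.arange(-half, half)) / FS
            design = np.column_stack([np.cos(2 * np.pi * 10 * tt),
                                      np.sin(2 * np.pi * 10 * tt)])
            a, b = np.linalg.lstsq(design, seg, rcond=None)[0]
            oracle = np.arctan2(-b, a)
            err = np.angle(np.exp(1j * (phi[probe] - oracle)))
            assert abs(err) < 0.05


class TestPhaseAtWindow:
    def test_shared_phase_gives_resultant_one(self):
        es = _alpha_epochs(np.full(20, 0.9))
        ps = phase_at_window(es, "PO6", (100.0, 300.0))
        assert ps.resultant_length > 0.999
        assert ps.n == 20
        assert np.all((ps.phases > -np.pi) & (ps.phases <= np.pi))

    def test_uniform_phases_below_rayleigh_bound(self, rng):
        n = 300
        es = _alpha_epochs(rng.uniform(0, 2 * np.pi, n))
        ps = phase_at_window(es, "PO6", (100.0, 300.0))
        assert ps.resultant_length < np.sqrt(-np.log(0.05) / n)

    def test_low_amplitude_trials_flagged_and_excluded(self, rng):
        phases = np.zeros(10)
        es = _alpha_epochs(phases, amp=5.0)
        es.data[5:] *= 1e-4  # essentially silent trials
        ps = phase_at_window(es, "PO6", (100.0, 300.0), min_amplitude_uv=0.05)
        assert ps.low_amplitude_flags.sum() == 5
        assert ps.n == 5

    def test_channel_and_window_validation(self, rng):
        es = _alpha_epochs(np.zeros(5))
        with pytest.raises(KeyError):
            phase_at_window(es, "Oz", (100.0, 200.0))
        with pytest.raises(ValueError):
            phase_at_window(es, "PO6", (300.0, 100.0))


class TestRayleigh:
    def test_uniform_phases_rarely_significant(self, rng):
        hits = 0
        for _ in range(1000):
            _, p = rayleigh_test(rng.uniform(-np.pi, np.pi, 26))
            hits += p > 0.05
        assert hits >= 930

    def test_concentrated_phases_significant(self, rng):
        _, p = rayleigh_test(rng.normal(1.0, 0.2, 26))
        assert p < 1e-4


def test_phase_locked_residual_uniform_over_seeds(rng):
    # phase-locked burst + noise: the average captures the burst, the
    # residual phases carry no concentration
    times = -200.0 + 2.0 * np.arange(600)
    t = times / 1000.0
    burst = 4.0 * np.exp(-((times - 150) ** 2) / (2 * 50.0**2)) * np.cos(
        2 * np.pi * 10 * (t - 0.15))
    ok = 0
    n_seeds = 40
    for seed in range(n_seeds):
        r = np.random.default_rng(9000 + seed)
        data = burst[None, None, :] + 3.0 * r.standard_normal((60, 1, 600))
        es = make_epochs(data, labels=["PO6"])
        resid = subtract_evoked(es)
        alpha_rms = np.sqrt(np.mean(burst**2))
        resid_locked = resid.data.mean(axis=0)
        assert np.sqrt(np.mean(resid_locked**2)) < 0.05 * alpha_rms
        ps = phase_at_window(resid, "PO6", (100.0, 200.0),
                             min_amplitude_uv=0.0)
        if ps.resultant_length < np.sqrt(-np.log(0.05) / ps.n):
            ok += 1
    assert ok >= int(0.9 * n_seeds)


class TestPolarExport:
    def _sets(self, rng, n_subj=5):
        sets_e, sets_i = [], []
        for s in range(n_subj):
            es = _alpha_epochs(rng.uniform(0, 2 * np.pi, 12))
            es.subject_id = f"sub-{s + 1:02d}"
            ext = PhaseExtractor("PO6", (100.0, 300.0))
            sets_e.append(ext.fit(es).transform(es))
            sets_i.append(PhaseExtractor("PO6", (100.0, 300.0),
                                         remove_evoked=True
                                         ).fit(es).transform(es))
        return sets_e, sets_i

    def test_table_shape_range_and_roundtrip(self, rng, tmp_path):
        ev, ind = self._sets(rng)
        df = polar_export(ev, ind, "ST", path=tmp_path / "phases.tsv")
        assert len(df) == 5 * 2  # subjects × activities
        assert ((df["phase_rad"] > -np.pi) & (df["phase_rad"] <= np.pi)).all()
        assert ((df["resultant"] >= 0) & (df["resultant"] <= 1)).all()
        back = pd.read_csv(tmp_path / "phases.tsv", sep="\t")
        pd.testing.assert_frame_equal(back, df)

    def test_svg_plot_written(self, rng, tmp_path):
        ev, ind = self._sets(rng, 3)
        polar_export(ev, ind, "DT", plot_path=tmp_path / "polar.svg")
        assert (tmp_path / "polar.svg").stat().st_size > 0
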