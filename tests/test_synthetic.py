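"""Generator correctness: Markov statistics, RR dynamics, ECG rendering."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d

from somnohr.synthetic import (ConfigError, EcgSynthConfig,
                               HypnogramModelConfig, StageDynamics,
                               StageDynamicsConfig, SubjectMeta,
                               simulate_cohort, simulate_hypnogram,
                               simulate_rr_series, stationary_distribution,
                               synthesize_ecg)


def _single_stage_cfg(stage: str, n_epochs: int, seed: int = 0):
    init = np.zeros(5)
    init[["W", "N1", "N2", "N3", "R"].index(stage)] = 1.0
    return HypnogramModelConfig(transition=np.eye(5), initial=init,
                                n_epochs=n_epochs, seed=seed)


class TestHypnogramModel:
    def test_identity_chain_stays_in_n2(self):
        h = simulate_hypnogram(_single_stage_cfg("N2", 50))
        assert set(h.labels) == {"N2"}

    def test_determinism(self):
        cfg = HypnogramModelConfig(n_epochs=500, seed=11)
        assert simulate_hypnogram(cfg).labels == simulate_hypnogram(cfg).labels

    def test_empirical_frequencies_match_stationary_vector(self):
        """Long-run stage frequencies vs the eigen-analysis oracle."""
        cfg = HypnogramModelConfig(n_epochs=100_000, seed=3)
        h = simulate_hypnogram(cfg)
        pi = stationary_distribution(cfg.transition)
        for i, stage in enumerate(("W", "N1", "N2", "N3", "R")):
            freq = h.labels.count(stage) / len(h)
            assert abs(freq - pi[i]) < 0.01

    def test_non_stochastic_rows_rejected(self):
        bad = np.eye(5)
        bad[0, 0] = 0.5
        with pytest.raises(ConfigError):
            HypnogramModelConfig(transition=bad)


class TestRrDynamics:
    def test_degenerate_config_gives_constant_rr(self):
        dyn = StageDynamicsConfig(stages={
            s: StageDynamics(mean_rr=1080.0 if s == "N3" else 800.0,
                             sdnn=0.0, lf_power=0.0, hf_power=0.0,
                             resp_rate=0.2)
            for s in ("W", "N1", "N2", "N3", "R")})
        r = simulate_rr_series(simulate_hypnogram(_single_stage_cfg("N3", 10)),
                               dyn, seed=1)
        assert np.allclose(r.rr_ms, 1080.0, atol=1e-6)

    def test_rem_lf_hf_band_power_ratio(self):
        """Welch band powers of the generated series recover the configured
        LF/HF contrast within 25% when jitter is absent."""
        base = StageDynamicsConfig().stages
        rem = dataclasses.replace(base["R"], sdnn=float(np.sqrt(1400 + 300)))
        dyn = StageDynamicsConfig(stages={**base, "R": rem})
        h = simulate_hypnogram(_single_stage_cfg("R", 40, seed=5))  # 20 min
        r = simulate_rr_series(h, dyn, seed=6)
        # resample RR onto a uniform 4 Hz grid for the periodogram oracle
        from scipy.interpolate import CubicSpline

        t_grid = np.arange(r.times_s[1], r.times_s[-1], 0.25)
        rr = CubicSpline(r.times_s[1:], np.diff(r.times_s) * 1000.0)(t_grid)
        f, p = sps.welch(rr - rr.mean(), fs=4.0, nperseg=1024)
        lf = np.trapezoid(p[(f >= 0.04) & (f <= 0.15)], f[(f >= 0.04) & (f <= 0.15)])
        hf = np.trapezoid(p[(f >= 0.15) & (f <= 0.40)], f[(f >= 0.15) & (f <= 0.40)])
        target = 1400.0 / 300.0
        assert abs(lf / hf - target) / target < 0.25

    @pytest.mark.parametrize("stage,seed", [("N2", 2), ("R", 3), ("W", 4)])
    def test_stage_mean_rr_within_two_sem(self, stage, seed):
        dyn = StageDynamicsConfig()
        n_epochs = 30  # 15 min -> comfortably over 500 beats
        r = simulate_rr_series(
            simulate_hypnogram(_single_stage_cfg(stage, n_epochs, seed)),
            dyn, seed=seed + 100)
        rr = np.diff(r.times_s) * 1000.0
        assert rr.size > 500
        sem = dyn.stages[stage].sdnn / np.sqrt(rr.size)
        # oscillatory components inflate the effective SEM; allow 2x SEM
        # plus a small allowance for incomplete LF cycles
        assert abs(rr.mean() - dyn.stages[stage].mean_rr) < 2 * sem + 5.0

    def test_beat_times_strictly_increasing_with_refractory_floor(self):
        h = simulate_hypnogram(HypnogramModelConfig(n_epochs=120, seed=9))
        r = simulate_rr_series(h, seed=10)
        d = np.diff(r.times_s)
        assert np.all(d > 0)
        assert d.min() >= 0.3

    def test_empty_hypnogram_rejected(self):
        with pytest.raises(ConfigError):
            HypnogramModelConfig(n_epochs=0)


class TestEcgSynthesis:
    def test_argmax_within_one_sample_of_beat(self):
        h = simulate_hypnogram(_single_stage_cfg("N2", 4, seed=1))
        r = simulate_rr_series(h, seed=2)
        cfg = EcgSynthConfig(fs=256.0, baseline_wander_amp=0.0)
        e = synthesize_ecg(r, cfg)
        for tb in r.times_s[(r.times_s > 0.5) & (r.times_s < e.duration_s - 0.5)]:
            c = int(round(tb * cfg.fs))
            w = e.samples[c - 20:c + 21]
            assert abs((c - 20 + np.argmax(w)) / cfg.fs - tb) <= 1.0 / cfg.fs

    def test_pulse_count_matches_beat_count(self):
        from somnohr.rr_processing import RPeakSeries

        times = np.arange(1.0, 29.5, 0.8)  # interior beats only
        r = RPeakSeries(times_s=times,
                        quality=np.full(times.size, "ok", dtype="<U12"),
                        source_fs=4.0)
        e = synthesize_ecg(r, EcgSynthConfig(baseline_wander_amp=0.0),
                           duration_s=30.0)
        peaks, _ = sps.find_peaks(e.samples, height=0.5, distance=int(0.3 * e.fs))
        assert peaks.size == len(r)

    def test_amplitude_linearity_of_max_filter(self):
        h = simulate_hypnogram(_single_stage_cfg("N2", 4, seed=5))
        r = simulate_rr_series(h, seed=6)
        e1 = synthesize_ecg(r, EcgSynthConfig(qrs_amplitude=1.0,
                                              baseline_wander_amp=0.0))
        e2 = synthesize_ecg(r, EcgSynthConfig(qrs_amplitude=2.0,
                                              baseline_wander_amp=0.0))
        w = int(3 * e1.fs)
        m1 = maximum_filter1d(np.abs(e1.samples), w)
        m2 = maximum_filter1d(np.abs(e2.samples), w)
        assert np.allclose(m2, 2.0 * m1, rtol=1e-12)

    def test_undersampled_pulse_rejected(self):
        with pytest.raises(ConfigError):
            EcgSynthConfig(fs=100.0, qrs_width_ms=39.0)
        with pytest.raises(ConfigError):
            EcgSynthConfig(fs=80.0)

    def test_determinism_of_noise(self):
        h = simulate_hypnogram(_single_stage_cfg("N2", 4, seed=7))
        r = simulate_rr_series(h, seed=8)
        cfg = EcgSynthConfig(noise_segments=[(0.0, 30.0, 0.5)], seed=21)
        assert np.array_equal(synthesize_ecg(r, cfg).samples,
                              synthesize_ecg(r, cfg).samples)


class TestCohort:
    def test_round_robin_strata_balance(self):
        subs = simulate_cohort(4, hyp_cfg=HypnogramModelConfig(n_epochs=20),
                               seed=1)
        sexes = [s.meta.sex for s in subs]
        assert sexes.count("M") == 2 and sexes.count("F") == 2

    def test_planted_effect_requires_populated_stratum(self):
        with pytest.raises(ConfigError, match="stratum"):
            simulate_cohort(4, hyp_cfg=HypnogramModelConfig(n_epochs=20),
                            planted_effects={("age", ">60"): 0.05}, seed=1)

    def test_planted_flip_fraction_controls_accuracy(self):
        subs = simulate_cohort(
            6, hyp_cfg=HypnogramModelConfig(n_epochs=200),
            planted_effects={}, base_flip=0.30, subject_sd=0.0, seed=2)
        from somnohr.evaluation import confusion, metrics

        accs = [metrics(confusion(s.hypnogram, s.predicted4, 4)).accuracy
                for s in subs]
        assert abs(np.mean(accs) - 0.70) < 0.05

    def test_generator_determinism(self):
        a = simulate_cohort(3, hyp_cfg=HypnogramModelConfig(n_epochs=30),
                            signals="rr", seed=5)
        b = simulate_cohort(3, hyp_cfg=HypnogramModelConfig(n_epochs=30),
                            signals="rr", seed=5)
        for sa, sb in zip(a, b):
            assert sa.hypnogram.labels == sb.hypnogram.labels
            assert np.array_equal(sa.rr.times_s, sb.rr.times_s)

    def test_invalid_meta_rejected(self):
        with pytest.raises(ConfigError):
            SubjectMeta("x", "<=40", "mild", "X")
        with pytest.raises(ConfigError):
            SubjectMeta("x", "young", "mild", "M")
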