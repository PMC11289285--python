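"""Simulator contracts: trajectory, session generation, gain manipulation."""

import dataclasses

import numpy as np
import pytest

from placecode.errors import InvalidConfigError, InvalidInputError
from placecode.information import build_trial_tensor, mean_noise_correlation
from placecode.session import bin_position, reconstruct_position
from placecode.synthetic import (
    SyntheticConfig,
    apply_gain,
    expected_rate,
    simulate_session,
    simulate_trajectory,
)


class TestTrajectory:
    def test_noise_free_encoder_matches_true_position(self):
        cfg = SyntheticConfig(n_laps=5, speed_jitter_sd=0.0, rng_seed=1)
        trace = simulate_trajectory(cfg)
        cum = np.cumsum(trace.ticks)
        assert np.allclose(cum, trace.true_position, atol=1e-9)

    def test_mean_per_frame_displacement_matches_speed(self):
        # 421 cm/min at 15 Hz -> 421/900 cm per frame
        cfg = SyntheticConfig(n_laps=10, speed_jitter_sd=0.0, rng_seed=2)
        trace = simulate_trajectory(cfg)
        steps = np.diff(trace.true_position)
        assert np.allclose(steps, 421.0 / 900.0, atol=1e-12)

    def test_jittered_speed_averages_to_mean(self):
        cfg = SyntheticConfig(n_laps=20, rng_seed=3)
        trace = simulate_trajectory(cfg)
        mean_step = np.diff(trace.true_position).mean()
        assert mean_step == pytest.approx(421.0 / 900.0, rel=0.05)

    def test_total_laps_reached(self):
        cfg = SyntheticConfig(n_laps=7, rng_seed=4)
        trace = simulate_trajectory(cfg)
        assert trace.true_position[-1] >= 7 * cfg.belt_length - 1e-9

    def test_rfid_events_at_texture_boundaries(self):
        cfg = SyntheticConfig(n_laps=3, speed_jitter_sd=0.0, rng_seed=5)
        trace = simulate_trajectory(cfg)
        # 4 boundaries per lap on a 4-texture belt
        assert len(trace.rfid_events) == pytest.approx(12, abs=1)
        for s, tag, pos in trace.rfid_events:
            assert pos in (0.0, 45.0, 90.0, 135.0)
            assert tag == int(pos // 45) % 4

    def test_encoder_gain_error_drift_unbounded_without_tags(self):
        cfg = SyntheticConfig(n_laps=10, speed_jitter_sd=0.0,
                              encoder_gain_error=0.01, rng_seed=6)
        trace = simulate_trajectory(cfg)
        # without RFID correction the error grows linearly with distance
        cum = np.cumsum(trace.ticks)
        err = cum - trace.true_position
        assert err[-1] == pytest.approx(0.01 * trace.true_position[-1],
                                        rel=1e-6)
        # with tags the reconstruction error is bounded by drift x spacing
        pos, _ = reconstruct_position(trace, cfg.belt_length)
        true_frames = trace.true_position[cfg.samples_per_frame - 1::
                                          cfg.samples_per_frame]
        circ_err = np.abs(
            (pos - true_frames + 90.0) % 180.0 - 90.0)
        assert circ_err.max() < 0.01 * 45.0 + 0.01

    def test_invalid_speed_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_trajectory(SyntheticConfig(mean_speed=-1.0))
        with pytest.raises(InvalidConfigError):
            simulate_trajectory(SyntheticConfig(frame_rate=0.0))


class TestSession:
    def test_determinism_same_seed(self, base_config, base_session):
        session, truth = base_session
        again, truth2 = simulate_session(base_config)
        assert np.array_equal(session.dff, again.dff)
        assert np.array_equal(session.position, again.position)
        assert np.array_equal(truth.spikes, truth2.spikes)

    def test_untuned_population_is_spatially_flat(self):
        cfg = SyntheticConfig(n_neurons=30, n_laps=25, fraction_tuned=0.0,
                              shared_gain_sd=0.0, rng_seed=7)
        session, truth = simulate_session(cfg)
        assert np.all(truth.amplitude == 0)
        # per-bin spike totals are Poisson with occupancy-proportional
        # expectation for a flat population: chi-square per neuron
        from scipy.stats import chisquare

        bins = bin_position(session.position, 20, cfg.belt_length)
        occupancy = np.bincount(bins, minlength=20)
        rejected = 0
        for n in range(cfg.n_neurons):
            counts = np.bincount(bins, weights=truth.spikes[n], minlength=20)
            if counts.sum() < 40:
                continue
            expected = counts.sum() * occupancy / occupancy.sum()
            p = chisquare(counts, expected).pvalue
            rejected += p < 0.01
        assert rejected <= 3

    def test_zero_gain_gives_pure_noise(self):
        cfg = SyntheticConfig(n_neurons=10, n_laps=5, gain=0.0, rng_seed=8)
        session, truth = simulate_session(cfg)
        assert truth.spikes.sum() == 0
        assert abs(session.dff.mean()) < 3 * cfg.noise_sd / np.sqrt(
            session.dff.size)

    def test_doubling_gain_doubles_mean_rates(self):
        base = SyntheticConfig(n_neurons=20, n_laps=40, shared_gain_sd=0.0,
                               rng_seed=9)
        s1, t1 = simulate_session(base)
        s2, t2 = simulate_session(dataclasses.replace(base, gain=2.0))
        r1 = t1.spikes.mean(axis=1)
        r2 = t2.spikes.mean(axis=1)
        assert r2.sum() / r1.sum() == pytest.approx(2.0, rel=0.05)
        # and per-bin empirical means track the analytic doubled profile
        bins = bin_position(s2.position, 20, base.belt_length)
        lam = expected_rate(dataclasses.replace(base, gain=2.0), s2.position,
                            t2.baseline, t2.amplitude, t2.concentration,
                            t2.preferred_phase)
        emp = np.array([t2.spikes[:, bins == b].mean(axis=1)
                        for b in range(20)]).T * base.frame_rate
        ana = np.array([lam[:, bins == b].mean(axis=1)
                        for b in range(20)]).T
        assert np.corrcoef(emp.ravel(), ana.ravel())[0, 1] > 0.98

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_session(SyntheticConfig(noise_sd=-0.1))
        with pytest.raises(InvalidConfigError):
            simulate_session(SyntheticConfig(decay_tau=0.0))

    def test_occupancy_near_uniform_at_constant_speed(self):
        cfg = SyntheticConfig(n_neurons=2, n_laps=20, speed_jitter_sd=0.0,
                              rng_seed=10)
        session, _ = simulate_session(cfg)
        bins = bin_position(session.position, 20, cfg.belt_length)
        counts = np.bincount(bins, minlength=20)
        assert counts.max() / counts.min() < 1.2

    def test_shared_gain_induces_noise_correlations(self):
        cfg = SyntheticConfig(n_neurons=60, n_laps=25, rng_seed=11,
                              shared_gain_sd=0.3)
        s, _ = simulate_session(cfg)
        nc = mean_noise_correlation(build_trial_tensor(s, 20))
        assert nc > 0.005
        cfg0 = dataclasses.replace(cfg, shared_gain_sd=0.0)
        s0, _ = simulate_session(cfg0)
        nc0 = mean_noise_correlation(build_trial_tensor(s0, 20))
        assert abs(nc0) < 0.005


class TestApplyGain:
    def test_unit_gain_is_identity(self, base_session):
        session, _ = base_session
        same = apply_gain(session, 1.0)
        assert np.array_equal(session.dff, same.dff)

    def test_negative_gain_rejected(self, base_session):
        session, _ = base_session
        with pytest.raises(InvalidInputError):
            apply_gain(session, -0.5)

    def test_gain_scales_tuning_amplitude(self, base_session):
        from placecode.vonmises import build_tuning_curve, fit_von_mises

        session, truth = base_session
        doubled = apply_gain(session, 2.0)
        ratios = []
        for n in np.flatnonzero(truth.tuned):
            a1 = fit_von_mises(build_tuning_curve(session.dff[n], session)).A
            a2 = fit_von_mises(build_tuning_curve(doubled.dff[n], doubled)).A
            if a1 > 0.2:
                ratios.append(a2 / a1)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)

    def test_gain_raises_single_cell_information(self, base_session):
        from placecode.information import single_cell_fisher_info

        session, _ = base_session
        doubled = apply_gain(session, 2.0)
        fi1 = single_cell_fisher_info(build_trial_tensor(session, 20)).mean()
        fi2 = single_cell_fisher_info(build_trial_tensor(doubled, 20)).mean()
        assert fi2 > fi1


class TestParameterRecovery:
    def test_vonmises_fit_recovers_truth_on_long_sessions(self):
        """Tuned cells' preferred position and concentration are recovered
        from deconvolved-rate tuning curves of a 50-lap session."""
        from placecode.tuning import deconvolve
        from placecode.vonmises import build_tuning_curve, fit_von_mises

        cfg = SyntheticConfig(n_neurons=30, n_laps=50, rng_seed=12,
                              shared_gain_sd=0.0)
        session, truth = simulate_session(cfg)
        rates = deconvolve(session.dff, cfg.frame_rate, cfg.decay_tau)
        phi_err, k_err = [], []
        for n in np.flatnonzero(truth.tuned):
            # amplitude-to-noise >= 3 in calcium units (A * tau * amp / sd)
            if truth.amplitude[n] * cfg.decay_tau / cfg.noise_sd < 3:
                continue
            fit = fit_von_mises(build_tuning_curve(rates[n], session))
            d = np.angle(np.exp(1j * (fit.phi - truth.preferred_phase[n])))
            phi_err.append(abs(np.degrees(d)))
            k_err.append(abs(fit.kappa - truth.concentration[n])
                         / truth.concentration[n])
        assert len(phi_err) >= 10
        assert np.median(phi_err) < 5.0
        assert np.median(k_err) < 0.20
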