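"""Decoder, Fisher-information estimators, shuffle surrogates, thresholds."""

import numpy as np
import pytest
from scipy.stats import norm

from placecode.errors import (
    InsufficientTrialsError,
    InvalidConfigError,
    SubsampleThresholdError,
)
from placecode.information import (
    TrialTensor,
    build_trial_tensor,
    decode_position,
    discrimination_threshold,
    mean_noise_correlation,
    population_fisher_info,
    shuffle_noise_correlations,
    single_cell_fisher_info,
    subsample_neurons,
)
from placecode.session import bin_position

from conftest import make_grid_session


def gaussian_tensor(rng, n_neurons, n_bins, n_laps, means, sd=1.0):
    """Tensor with independent Gaussian responses; means is (neurons, bins)."""
    resp = rng.normal(means[:, :, None], sd,
                      (n_neurons, n_bins, n_laps))
    return TrialTensor(resp, belt_length=180.0)


class TestBuildTrialTensor:
    def test_constant_trace_gives_constant_tensor(self):
        session = make_grid_session(n_laps=4, n_neurons=3,
                                    dff=np.full((3, 1200), 0.3))
        t = build_trial_tensor(session)
        assert np.allclose(t.responses, 0.3, atol=1e-12)

    def test_shape_contract(self, base_session):
        session, _ = base_session
        t = build_trial_tensor(session, n_bins=20)
        assert t.responses.shape[0] == session.n_neurons
        assert t.responses.shape[1] == 20
        assert t.n_laps >= 10
        assert t.bin_width == pytest.approx(9.0)

    def test_too_few_laps_rejected(self):
        session = make_grid_session(n_laps=1)
        with pytest.raises(InsufficientTrialsError):
            build_trial_tensor(session)


class TestSubsampleNeurons:
    def test_all_neurons_gives_single_identity_draw(self):
        rng = np.random.default_rng(0)
        t = gaussian_tensor(rng, 10, 20, 5, np.zeros((10, 20)))
        draws = subsample_neurons(t, n=10, n_draws=7, seed=1)
        assert len(draws) == 1
        assert np.array_equal(draws[0].responses, t.responses)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(1)
        t = gaussian_tensor(rng, 50, 20, 5, np.zeros((50, 20)))
        a = subsample_neurons(t, n=10, n_draws=3, seed=5)
        b = subsample_neurons(t, n=10, n_draws=3, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.responses, y.responses)

    def test_threshold_not_met_raises(self):
        rng = np.random.default_rng(2)
        t = gaussian_tensor(rng, 10, 20, 5, np.zeros((10, 20)))
        with pytest.raises(SubsampleThresholdError):
            subsample_neurons(t, n=42)

    def test_averaging_draws_reduces_variance(self, base_session):
        session, _ = base_session
        t = build_trial_tensor(session, 20)
        single, averaged = [], []
        for rep in range(6):
            draws = subsample_neurons(t, n=10, n_draws=8, seed=100 + rep)
            fis = [single_cell_fisher_info(d).mean() for d in draws]
            single.append(fis[0])
            averaged.append(np.mean(fis))
        assert np.var(averaged) < np.var(single)


class TestDecodePosition:
    def test_perfectly_separable_population(self):
        # 20 indicator neurons, one per bin, no noise
        rng = np.random.default_rng(3)
        n_frames = 4000
        y = rng.integers(0, 20, n_frames)
        X = np.eye(20)[y]
        res = decode_position((X, y), n_splits=4, seed=0)
        assert res.accuracy == 1.0
        assert res.weights.shape == (20, 20)

    def test_label_shuffle_decodes_at_chance(self, base_session):
        session, _ = base_session
        rng = np.random.default_rng(4)
        y = bin_position(session.position, 20, session.belt_length)
        y_shuf = rng.permutation(y)
        res = decode_position((session.dff.T, y_shuf), n_splits=5, seed=0)
        assert res.accuracy == pytest.approx(0.05, abs=0.01)

    def test_accuracy_monotone_in_gain(self, base_session):
        from placecode.synthetic import apply_gain

        session, _ = base_session
        accs = []
        for g in (0.5, 1.0, 2.0):
            s = apply_gain(session, g)
            accs.append(decode_position(s, n_splits=4, seed=0).accuracy)
        assert accs[0] < accs[1] < accs[2]


class TestPopulationFisherInfo:
    def test_null_bias_corrected_centred_at_zero(self):
        rng = np.random.default_rng(5)
        vals = []
        w = rng.standard_normal((4, 5))
        for _ in range(400):
            t = gaussian_tensor(rng, 5, 4, 20, np.zeros((5, 4)))
            vals.append(population_fisher_info(t, w).mean)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 2 * se + 1e-3

    def test_matches_analytic_gaussian_population(self):
        """Homogeneous Gaussian population: projected d'^2 equals
        (w.dmu)^2 / (w.C.w) analytically; the estimator agrees at T=100."""
        rng = np.random.default_rng(6)
        n, bins, T = 8, 4, 100
        means = np.linspace(0, 1, bins)[None, :] * np.arange(1, n + 1)[:, None] * 0.2
        reps = 60
        est = []
        d = np.arange(1.0, n + 1.0)          # fixed projection direction
        weights = np.outer(np.arange(bins), d)  # adjacent rows differ by d
        for _ in range(reps):
            t = gaussian_tensor(rng, n, bins, T, means, sd=1.0)
            est.append(population_fisher_info(t, weights).mean)
        # analytic: projected d'^2 = (d.dmu)^2 / (d.C.d) with C = I
        pairs = [(b, (b + 1) % bins) for b in range(bins)]
        ana = []
        for b1, b2 in sorted({tuple(sorted(p)) for p in pairs}):
            dmu = means[:, b2] - means[:, b1]
            ana.append((d @ dmu) ** 2 / (d @ d))
        assert np.mean(est) == pytest.approx(np.mean(ana), rel=0.05)

    def test_population_at_least_max_single_cell(self):
        rng = np.random.default_rng(7)
        n, bins, T = 6, 6, 200
        means = rng.normal(0, 1, (n, bins))
        t = gaussian_tensor(rng, n, bins, T, means, sd=1.0)
        # weights: class templates (independent of the evaluation noise
        # realisation up to estimation error at large T)
        w = means.T
        pop = population_fisher_info(t, w).mean
        single = single_cell_fisher_info(t)
        assert pop >= single.max() * 0.9


class TestSingleCellFisherInfo:
    def test_gaussian_calibration_at_t200(self):
        # d'^2 = 4 for dmu=2, sd=1; bias-corrected estimator mean within 5%
        rng = np.random.default_rng(8)
        est = []
        means = np.array([[0.0, 2.0]])
        for _ in range(200):
            t = gaussian_tensor(rng, 1, 2, 200, means, sd=1.0)
            est.append(single_cell_fisher_info(t)[0])
        assert np.mean(est) == pytest.approx(4.0, rel=0.05)

    def test_null_mean_within_2se_and_naive_positively_biased(self):
        rng = np.random.default_rng(9)
        bc, naive = [], []
        means = np.zeros((1, 2))
        for _ in range(1000):
            t = gaussian_tensor(rng, 1, 2, 20, means, sd=1.0)
            bc.append(single_cell_fisher_info(t)[0])
            naive.append(single_cell_fisher_info(t, bias_corrected=False)[0])
        se = np.std(bc) / np.sqrt(len(bc))
        assert abs(np.mean(bc)) < 2 * se
        # naive estimator is positively biased at small T (E ~ 2/T x inflation)
        assert np.mean(naive) > 5 * se

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        means = np.array([[0.0, 1.0, 0.5]])
        t = gaussian_tensor(rng, 1, 3, 50, means, sd=0.7)
        f1 = single_cell_fisher_info(t)
        t2 = TrialTensor(t.responses * 3.0, t.belt_length)
        f2 = single_cell_fisher_info(t2)
        assert np.allclose(f1, f2, atol=1e-12)


class TestShuffleNoiseCorrelations:
    def test_marginals_exactly_preserved(self, base_session):
        session, _ = base_session
        t = build_trial_tensor(session, 20)
        sh = shuffle_noise_correlations(t, seed=3)
        for n in range(t.n_neurons):
            for b in range(t.n_bins):
                assert np.array_equal(np.sort(t.responses[n, b]),
                                      np.sort(sh.responses[n, b]))

    def test_shuffle_reduces_correlations_below_null_bound(self):
        from placecode.synthetic import SyntheticConfig, simulate_session

        cfg = SyntheticConfig(n_neurons=40, n_laps=25, rng_seed=14,
                              shared_gain_sd=0.4)
        session, _ = simulate_session(cfg)
        t = build_trial_tensor(session, 20)
        before = mean_noise_correlation(t)
        sh = shuffle_noise_correlations(t, seed=0)
        after = abs(mean_noise_correlation(sh))
        assert before > after
        assert after < 2.0 / np.sqrt(t.n_laps)

    def test_different_seeds_same_marginals(self, base_session):
        session, _ = base_session
        t = build_trial_tensor(session, 20)
        a = shuffle_noise_correlations(t, seed=1)
        b = shuffle_noise_correlations(t, seed=2)
        assert np.array_equal(np.sort(a.responses, axis=2),
                              np.sort(b.responses, axis=2))


class TestDiscriminationThreshold:
    def test_normal_quantile_oracle(self):
        # J = 1 cm^-2 at criterion 0.70 -> 2 * Phi^-1(0.7) ~ 1.049 cm
        got = discrimination_threshold(1.0, criterion=0.70)
        assert got == pytest.approx(2 * norm.ppf(0.7), abs=1e-12)
        assert got == pytest.approx(1.049, abs=1e-3)

    def test_strictly_decreasing_in_information(self):
        js = np.array([0.1, 0.5, 1.0, 5.0, 50.0])
        ths = [discrimination_threshold(j) for j in js]
        assert np.all(np.diff(ths) < 0)
        assert ths[-1] < 0.2  # J -> inf drives the threshold to 0

    def test_nonpositive_information_is_infinite(self):
        with pytest.warns(UserWarning):
            assert discrimination_threshold(0.0) == np.inf

    def test_2afc_observer_variant(self):
        single = discrimination_threshold(1.0, observer="single")
        two = discrimination_threshold(1.0, observer="2afc")
        assert two == pytest.approx(single / np.sqrt(2.0))
        with pytest.raises(InvalidConfigError):
            discrimination_threshold(1.0, observer="triangle")
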