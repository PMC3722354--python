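"""Variational inversion: prediction, free energy, parameter recovery."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from conftest import make_desk_dataset
from lexidcm.containers import Evoked
from lexidcm.forward import LeadField
from lexidcm.inversion import (
    PriorSpec,
    build_parameterization,
    free_energy,
    gaussian_kl,
    invert,
    predict_response,
)


@pytest.fixture(scope="module")
def desk_posterior(desk_dataset, desk_space, desk_base_params, desk_true_index):
    (ev_b, ev_m), lf, _ = desk_dataset
    return invert(
        (ev_b, ev_m), desk_space.patterns[desk_true_index], desk_space, lf,
        desk_base_params, model_index=desk_true_index,
    )


class TestPredictResponse:
    def test_unit_gains_give_identical_conditions(self, desk_space, desk_base_params,
                                                  desk_dataset):
        _, lf, _ = desk_dataset
        pat = desk_space.patterns[-1]
        _, preds = predict_response(desk_base_params, pat, desk_space, lf)
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_zero_leadfield_gives_zero_prediction(self, desk_space, desk_base_params,
                                                  desk_dataset):
        _, lf, _ = desk_dataset
        zero_lf = LeadField(np.zeros_like(lf.gain), lf.source_locations_mm,
                            lf.source_orientations)
        _, preds = predict_response(desk_base_params, desk_space.patterns[1],
                                    desk_space, zero_lf)
        assert np.all(preds == 0.0)

    def test_equals_simulator_plus_projection(self, desk_space, desk_base_params,
                                              desk_dataset):
        from lexidcm.dynamics import simulate_sources

        _, lf, _ = desk_dataset
        pat = desk_space.patterns[1]
        times, preds = predict_response(desk_base_params, pat, desk_space, lf,
                                        window_ms=(1.0, 200.0))
        act = simulate_sources(desk_base_params, pat, desk_space, "baseline",
                               duration_ms=205.0)
        m = (act.times_ms >= 1.0 - 1e-9) & (act.times_ms <= 200.0 + 1e-9)
        manual = lf.gain.T @ act.values[m].T
        np.testing.assert_array_equal(preds[0], manual)


class TestGaussianKL:
    def test_kl_of_prior_with_itself_is_zero(self):
        mu = np.zeros(3)
        var = np.full(3, 1 / 16)
        assert gaussian_kl(mu, np.diag(var), mu, var) == pytest.approx(0.0, abs=1e-12)

    def test_matches_sampling_oracle(self):
        rng = np.random.default_rng(0)
        p = 3
        A = rng.normal(size=(p, p))
        cov_q = A @ A.T / p + np.eye(p) * 0.5
        mu_q = rng.normal(size=p) * 0.3
        var_p = np.full(p, 2.0)
        analytic = gaussian_kl(mu_q, cov_q, np.zeros(p), var_p)
        draws = rng.multivariate_normal(mu_q, cov_q, size=200_000)
        lq = multivariate_normal(mu_q, cov_q).logpdf(draws)
        lp = multivariate_normal(np.zeros(p), np.diag(var_p)).logpdf(draws)
        assert analytic == pytest.approx(float(np.mean(lq - lp)), abs=0.01)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gaussian_kl(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]),
                        np.zeros(2), np.ones(2))


class TestInvert:
    def test_self_consistency_at_prior_means(self, desk_space, desk_base_params,
                                             desk_dataset, desk_true_index):
        """Noiseless data generated at the prior means: the posterior stays
        there and perturbing any parameter lowers the free energy."""
        _, lf, _ = desk_dataset
        pat = desk_space.patterns[desk_true_index]
        times, preds = predict_response(desk_base_params, pat, desk_space, lf,
                                        window_ms=(1.0, 200.0))
        evs = tuple(
            Evoked(preds[c], times, cond)
            for c, cond in enumerate(("untrained", "trained"))
        )
        post = invert(evs, pat, desk_space, lf, desk_base_params, max_iter=24)
        assert np.abs(post.mean).max() < 0.01
        f_at_fit = free_energy(post, evs, desk_space, pat, lf, desk_base_params)
        for k in range(len(post.param_names)):
            shifted = post.mean.copy()
            shifted[k] += 0.25
            perturbed = post
            perturbed = type(post)(**{**post.__dict__, "mean": shifted})
            f_shift = free_energy(perturbed, evs, desk_space, pat, lf, desk_base_params)
            assert f_at_fit >= f_shift

    def test_free_energy_recomputable_from_stored_posterior(
        self, desk_posterior, desk_dataset, desk_space, desk_base_params, desk_true_index
    ):
        (ev_b, ev_m), lf, _ = desk_dataset
        pat = desk_space.patterns[desk_true_index]
        f = free_energy(desk_posterior, (ev_b, ev_m), desk_space, pat, lf,
                        desk_base_params)
        assert f == pytest.approx(desk_posterior.free_energy, abs=0.5)

    def test_free_energy_nondecreasing_over_accepted_iterations(self, desk_posterior):
        hist = desk_posterior.f_history
        assert len(hist) >= 2
        assert all(b >= a for a, b in zip(hist, hist[1:]))

    def test_posterior_covariance_psd_and_finite(self, desk_posterior):
        eig = np.linalg.eigvalsh(desk_posterior.cov)
        assert eig.min() > 0
        assert np.isfinite(desk_posterior.free_energy)

    def test_deterministic(self, desk_dataset, desk_space, desk_base_params,
                           desk_true_index):
        (ev_b, ev_m), lf, _ = desk_dataset
        pat = desk_space.patterns[desk_true_index]
        p1 = invert((ev_b, ev_m), pat, desk_space, lf, desk_base_params)
        p2 = invert((ev_b, ev_m), pat, desk_space, lf, desk_base_params)
        np.testing.assert_array_equal(p1.mean, p2.mean)
        assert p1.free_energy == p2.free_energy

    def test_json_round_trip(self, desk_posterior):
        back = type(desk_posterior).from_json(desk_posterior.to_json())
        np.testing.assert_allclose(back.mean, desk_posterior.mean)
        np.testing.assert_allclose(back.cov, desk_posterior.cov)
        assert back.gain_map == desk_posterior.gain_map


class TestRecovery:
    def test_gain_recovered_across_replicates(self, desk_space, desk_sensors,
                                              desk_base_params, desk_true_index):
        """True condition gain 1.5 at SNR 10: the posterior gain lands in
        [1.2, 1.8] in at least 8 of 10 seeded replicates."""
        pat = desk_space.patterns[desk_true_index]
        hits = 0
        errors = []
        for seed in range(10):
            (pair,), lf, _ = (lambda r: (r[0], r[1], r[2]))(
                make_desk_dataset(desk_space, desk_sensors, desk_true_index,
                                  seed=100 + seed)
            )
            post = invert(pair, pat, desk_space, lf, desk_base_params)
            g = np.exp(post.mean[post.param_names.index("b:LOCC->LvOT")])
            errors.append(abs(np.log(g) - np.log(1.5)))
            hits += 1.2 <= g <= 1.8
        assert hits >= 8
        # recovery battery: median absolute log-gain error stays small
        assert np.median(errors) < 0.15

    def test_generating_model_beats_null(self, desk_space, desk_sensors,
                                         desk_base_params, desk_true_index):
        """F(generating pattern) > F(null pattern) in >= 18 of 20 datasets."""
        pat = desk_space.patterns[desk_true_index]
        null = desk_space.patterns[0]
        wins = 0
        for seed in range(20):
            (pair,), lf, _ = make_desk_dataset(
                desk_space, desk_sensors, desk_true_index, seed=300 + seed
            )
            f_gen = invert(pair, pat, desk_space, lf, desk_base_params).free_energy
            f_null = invert(pair, null, desk_space, lf, desk_base_params).free_energy
            wins += f_gen > f_null
        assert wins >= 18

    def test_posterior_shrinks_with_trial_count(self, desk_space, desk_sensors,
                                                desk_base_params, desk_true_index):
        pat = desk_space.patterns[desk_true_index]
        traces = []
        for n_trials in (8, 128):
            (pair,), lf, _ = make_desk_dataset(
                desk_space, desk_sensors, desk_true_index, seed=55, n_trials=n_trials
            )
            post = invert(pair, pat, desk_space, lf, desk_base_params)
            traces.append(np.trace(post.cov))
        assert traces[1] < traces[0]

    def test_noise_only_sensors_lower_free_energy(self, desk_dataset, desk_space,
                                                  desk_base_params, desk_true_index):
        (ev_b, ev_m), lf, _ = desk_dataset
        pat = desk_space.patterns[desk_true_index]
        f_base = invert((ev_b, ev_m), pat, desk_space, lf, desk_base_params).free_energy
        rng = np.random.default_rng(0)
        sd = float(ev_b.data.std())
        ev_b2 = Evoked(np.vstack([ev_b.data,
                                  rng.normal(0, sd, size=(4, ev_b.data.shape[1]))]),
                       ev_b.times_ms, ev_b.condition)
        ev_m2 = Evoked(np.vstack([ev_m.data,
                                  rng.normal(0, sd, size=(4, ev_m.data.shape[1]))]),
                       ev_m.times_ms, ev_m.condition)
        lf2 = LeadField(np.hstack([lf.gain, np.zeros((lf.n_sources, 4))]),
                        lf.source_locations_mm, lf.source_orientations)
        f_noisy = invert((ev_b2, ev_m2), pat, desk_space, lf2,
                         desk_base_params).free_energy
        assert f_noisy < f_base


class TestParameterization:
    def test_standard_space_estimates_self_gains_everywhere(self, standard_network):
        from lexidcm.network import enumerate_model_space

        space = enumerate_model_space(standard_network)
        par = build_parameterization(space, space.patterns[0], PriorSpec())
        self_params = [n for n in par.names if n.startswith("b:self:")]
        assert len(self_params) == 6  # one per node, even in the null model
        assert sum(n.startswith("a:") for n in par.names) == 9

    def test_gain_parameters_follow_pattern(self, desk_space):
        par0 = build_parameterization(desk_space, desk_space.patterns[0], PriorSpec())
        par7 = build_parameterization(desk_space, desk_space.patterns[7], PriorSpec())
        assert not any(n.startswith("b:") for n in par0.names)
        assert {"b:LOCC->LvOT", "b:LvOT->LOCC", "b:self"} <= set(par7.names)

    def test_gain_map_covers_mirrored_pair(self, standard_network):
        from lexidcm.network import enumerate_model_space

        space = enumerate_model_space(standard_network)
        names = [g.name for g in space.groups]
        gi = names.index("LIFG->LOCC+RIFG->ROCC")
        par = build_parameterization(space, space.patterns[1 << gi], PriorSpec())
        key = "b:LIFG->LOCC+RIFG->ROCC"
        assert sorted(par.gain_map[key]) == ["LIFG->LOCC", "RIFG->ROCC"]
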