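import dataclasses

import numpy as np
import pytest

import qtune
from qtune.objective import (
    LossConfig,
    OptimizerSettings,
    _loss_and_grad,
    _prepare,
    ess_penalty,
    pseudo_huber,
)


class TestPseudoHuber:
    def test_zero_at_origin(self):
        assert pseudo_huber(0.0, 1.0) == 0.0

    def test_unit_point_closed_form(self):
        assert pseudo_huber(1.0, 1.0) == pytest.approx(np.sqrt(2) - 1)

    def test_linear_asymptote_slope_delta(self):
        for delta in (0.5, 1.0, 2.0):
            x = 1e6
            assert pseudo_huber(x, delta) / x == pytest.approx(delta, rel=1e-5)

    def test_even_and_monotone(self, rng):
        x = np.sort(np.abs(rng.normal(size=20)))
        vals = pseudo_huber(x, 0.7)
        assert np.all(np.diff(vals) >= 0)
        np.testing.assert_allclose(pseudo_huber(-x, 0.7), vals)


class TestEssPenalty:
    def setup_method(self):
        self.cfg = LossConfig(k_reg=100.0, a_onset=750.0, ess_stop=500.0)

    def test_zero_at_onset(self):
        assert ess_penalty(750.0, self.cfg) == 0.0

    def test_flat_above_onset(self):
        assert ess_penalty(5000.0, self.cfg) == 0.0

    def test_quadratic_arm_unit_deficit(self):
        assert ess_penalty(749.0, self.cfg) == pytest.approx(100.0)

    def test_c1_continuity_at_onset(self):
        eps = 1e-7
        below = ess_penalty(750.0 - eps, self.cfg)
        assert below == pytest.approx(0.0, abs=1e-9)
        # one-sided slopes both ~0 at the onset
        slope_below = (ess_penalty(750.0 - eps, self.cfg) - ess_penalty(750.0 - 2 * eps, self.cfg)) / eps
        assert abs(slope_below) < 1e-3

    def test_smooth_variant_positive_everywhere(self):
        cfg = dataclasses.replace(self.cfg, smooth_penalty=True)
        assert ess_penalty(5000.0, cfg) >= 0.0
        assert ess_penalty(740.0, cfg) > ess_penalty(760.0, cfg)


class TestLossConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            LossConfig(a_onset=400.0, ess_stop=500.0).validate()

    def test_onset_must_fit_frame_count(self):
        with pytest.raises(ValueError):
            LossConfig(a_onset=750.0, ess_stop=500.0).validate(min_n_frames=600)

    def test_delta_defaults_to_kt(self):
        cfg = LossConfig()
        beta = qtune.beta_from_temperature()
        assert cfg.resolved_delta(beta) == pytest.approx(1.0 / beta)


class TestTotalLoss:
    def test_zero_theta_is_baseline_data_loss(self, small_dataset, small_basis,
                                              small_loss_config):
        loss, comp = qtune.total_loss(small_dataset, small_basis,
                                      qtune.FineTuneParams.zeros(3), small_loss_config)
        assert comp["reg"] == 0.0  # ESS = n_frames > a_onset at theta = 0
        beta = small_dataset.beta
        delta = small_loss_config.resolved_delta(beta) * beta
        train = small_dataset.by_split("train")
        expected = np.mean([pseudo_huber(beta * (r.dG_expt - r.dG_calc), delta)
                            for r in train])
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_test_split_residuals_do_not_enter_data_term(self, small_dataset,
                                                         small_basis,
                                                         small_loss_config):
        theta = qtune.FineTuneParams.zeros(3)
        loss_a, _ = qtune.total_loss(small_dataset, small_basis, theta, small_loss_config)
        shifted = []
        for rec in small_dataset:
            if rec.split == "test":
                rec = dataclasses.replace(rec, dG_expt=rec.dG_expt + 100.0)
            shifted.append(rec)
        ds2 = dataclasses.replace(small_dataset, molecules=shifted)
        loss_b, _ = qtune.total_loss(ds2, small_basis, theta, small_loss_config)
        assert loss_b == pytest.approx(loss_a, rel=1e-12)

    def test_zero_residuals_zero_loss(self, small_loss_config):
        cfg = qtune.GeneratorConfig(n_molecules=6, atoms_min=4, atoms_max=6, m=6,
                                    n_clusters=2, n_frames=60, expt_noise_sd=0.0,
                                    seed=5)
        ds = qtune.assign_splits(qtune.generate_dataset(cfg), 0.5, 1)
        basis = qtune.fit_basis(qtune.pool_embeddings(ds), 2)
        loss, _ = qtune.total_loss(ds, basis, qtune.FineTuneParams.zeros(2),
                                   small_loss_config)
        assert loss == 0.0

    def test_infeasible_point_returns_sentinel(self, small_dataset, small_basis,
                                               small_loss_config):
        theta = qtune.FineTuneParams(np.zeros(3), np.full(3, 1e6))
        prep = _prepare(small_dataset, small_basis)
        loss, _, comp = _loss_and_grad(prep, theta.to_flat(), small_loss_config,
                                       small_dataset.beta, want_grad=False)
        assert comp["infeasible"]
        assert loss == pytest.approx(1e10)


class TestGradient:
    def test_matches_finite_differences_random_instances(self):
        """Analytic chain rule through QEq/Zwanzig/ESS vs central differences."""
        rng = np.random.default_rng(99)
        cfg = qtune.GeneratorConfig(n_molecules=4, atoms_min=4, atoms_max=7, m=6,
                                    n_clusters=2, n_frames=40, overlap_scale=4.0,
                                    expt_noise_sd=1.0, seed=17)
        ds = qtune.assign_splits(qtune.generate_dataset(cfg), 0.5, 3)
        basis = qtune.fit_basis(qtune.pool_embeddings(ds), 2)
        lc = LossConfig(a_onset=30.0, ess_stop=10.0)  # penalty active for some draws
        prep = _prepare(ds, basis)
        for _ in range(20):
            x = rng.normal(0, 0.2, size=4)
            _, grad, comp = _loss_and_grad(prep, x, lc, ds.beta, want_grad=True)
            assert not comp["infeasible"]
            h = 1e-6
            for i in range(4):
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                fp = _loss_and_grad(prep, xp, lc, ds.beta, False)[0]
                fm = _loss_and_grad(prep, xm, lc, ds.beta, False)[0]
                fd = (fp - fm) / (2 * h)
                assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_zero_gradient_at_perfect_fit(self, small_loss_config):
        cfg = qtune.GeneratorConfig(n_molecules=5, atoms_min=4, atoms_max=6, m=6,
                                    n_clusters=2, n_frames=60, expt_noise_sd=0.0,
                                    seed=8)
        ds = qtune.assign_splits(qtune.generate_dataset(cfg), 0.5, 1)
        basis = qtune.fit_basis(qtune.pool_embeddings(ds), 2)
        g = qtune.loss_gradient(ds, basis, qtune.FineTuneParams.zeros(2),
                                small_loss_config)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_regularizer_gradient_zero_in_flat_region(self, small_dataset,
                                                      small_basis, small_loss_config):
        # at theta=0 all ESS = n_frames > a_onset: gradient comes from data term only
        data_only = dataclasses.replace(small_loss_config, k_reg=0.0)
        g_full = qtune.loss_gradient(small_dataset, small_basis,
                                     qtune.FineTuneParams.zeros(3), small_loss_config)
        g_data = qtune.loss_gradient(small_dataset, small_basis,
                                     qtune.FineTuneParams.zeros(3), data_only)
        np.testing.assert_allclose(g_full, g_data, atol=1e-15)


class TestFinetune:
    def test_zero_residual_dataset_converges_at_zero(self, small_loss_config):
        cfg = qtune.GeneratorConfig(n_molecules=6, atoms_min=4, atoms_max=6, m=6,
                                    n_clusters=2, n_frames=60, expt_noise_sd=0.0,
                                    seed=21)
        ds = qtune.assign_splits(qtune.generate_dataset(cfg), 0.5, 1)
        basis = qtune.fit_basis(qtune.pool_embeddings(ds), 2)
        theta, trace = qtune.finetune(ds, basis, small_loss_config)
        assert trace.stop_reason == "converged"
        assert theta.norm() == pytest.approx(0.0, abs=1e-8)

    def test_trace_monotone_loss(self, recovery_run):
        losses = [rec["loss"] for rec in recovery_run["trace"].records]
        assert np.all(np.diff(losses) <= 1e-10)

    def test_regularized_run_never_returns_low_ess_theta(self, recovery_run):
        ds = recovery_run["dataset"]
        basis = recovery_run["basis"]
        theta = recovery_run["theta"]
        lc = recovery_run["loss_config"]
        for rec in ds:
            rw = qtune.reweight_molecule(rec, basis, theta, ds.beta)
            assert rw.ess >= lc.ess_stop

    def test_early_stop_returns_last_feasible_iterate(self):
        from qtune.synthetic import fragile_overlap_config

        ds = qtune.assign_splits(qtune.generate_dataset(fragile_overlap_config(2)),
                                 0.5, 2)
        basis = qtune.fit_basis(qtune.pool_embeddings(ds), 4)
        lc = LossConfig(k_reg=0.0, a_onset=750.0, ess_stop=500.0)
        theta, trace = qtune.finetune(ds, basis, lc, OptimizerSettings(max_iter=40))
        assert trace.stop_reason == "early_stop_ess"
        min_ess = min(qtune.reweight_molecule(r, basis, theta, ds.beta).ess for r in ds)
        assert min_ess >= 500.0

    def test_deterministic_given_inputs(self, small_dataset, small_basis,
                                        small_loss_config):
        t1, _ = qtune.finetune(small_dataset, small_basis, small_loss_config,
                               OptimizerSettings(max_iter=15))
        t2, _ = qtune.finetune(small_dataset, small_basis, small_loss_config,
                               OptimizerSettings(max_iter=15))
        np.testing.assert_array_equal(t1.to_flat(), t2.to_flat())
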