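import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qtune
from qtune.electrostatics import (
    InfeasiblePerturbation,
    ToyConfiguration,
    qeq_charges_vjp,
    reference_phi,
)


class TestPerturbParameters:
    def test_zero_theta_is_identity(self, rng):
        e, s = rng.normal(size=5), rng.uniform(1, 3, size=5)
        h_hat = rng.normal(size=(5, 3))
        e_star, s_star = qtune.perturb_parameters(e, s, h_hat, qtune.FineTuneParams.zeros(3))
        np.testing.assert_array_equal(e_star, e)
        np.testing.assert_array_equal(s_star, s)

    def test_hand_inner_products(self):
        theta = qtune.FineTuneParams(np.array([0.5, 9.0]), np.array([-0.5, 9.0]))
        e_star, s_star = qtune.perturb_parameters(
            np.array([1.0]), np.array([2.0]), np.array([[1.0, 0.0]]), theta)
        np.testing.assert_allclose(e_star, [1.5])
        np.testing.assert_allclose(s_star, [1.5])

    def test_orthogonal_features_leave_parameters_unchanged(self, rng):
        theta = qtune.FineTuneParams(np.array([1.0, 0.0]), np.array([2.0, 0.0]))
        h_hat = np.column_stack([np.zeros(4), rng.normal(size=4)])  # orthogonal to rows
        e, s = rng.normal(size=4), rng.uniform(1, 2, size=4)
        e_star, s_star = qtune.perturb_parameters(e, s, h_hat, theta)
        np.testing.assert_allclose(e_star, e)
        np.testing.assert_allclose(s_star, s)

    def test_hardness_floor_is_infeasible(self):
        theta = qtune.FineTuneParams(np.array([0.0]), np.array([-5.0]))
        with pytest.raises(InfeasiblePerturbation):
            qtune.perturb_parameters(np.array([1.0]), np.array([2.0]),
                                     np.array([[1.0]]), theta)


class TestQeqCharges:
    def test_hand_two_atom_case(self):
        np.testing.assert_allclose(qtune.qeq_charges([1.0, 2.0], [1.0, 1.0], 0.0),
                                   [0.5, -0.5], atol=1e-14)

    def test_uniform_parameters_share_charge_equally(self, rng):
        for n in (2, 5, 9):
            q = qtune.qeq_charges(np.full(n, 3.3), np.full(n, 1.7), -2.0)
            np.testing.assert_allclose(q, -2.0 / n, atol=1e-12)

    def test_single_atom_forced_to_total_charge(self):
        np.testing.assert_allclose(qtune.qeq_charges([4.2], [0.3], -1.0), [-1.0])

    def test_charge_conservation_random_draws(self, rng):
        worst = 0.0
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            e = rng.normal(0, 20, size=n)
            s = rng.uniform(0.5, 300, size=n)
            Q = float(rng.normal(0, 2))
            worst = max(worst, abs(qtune.qeq_charges(e, s, Q).sum() - Q))
        assert worst < 1e-10

    def test_translation_covariance_in_e(self, rng):
        e = rng.normal(size=6)
        s = rng.uniform(1, 5, size=6)
        q1 = qtune.qeq_charges(e, s, 0.5)
        q2 = qtune.qeq_charges(e + 17.3, s, 0.5)
        np.testing.assert_allclose(q1, q2, atol=1e-10)

    def test_nonpositive_hardness_rejected(self):
        with pytest.raises(InfeasiblePerturbation):
            qtune.qeq_charges([1.0, 1.0], [1.0, 0.0], 0.0)

    def test_vjp_matches_finite_differences(self, rng):
        n = 5
        e = rng.normal(0, 5, size=n)
        s = rng.uniform(1, 10, size=n)
        Q = 0.7
        g = rng.normal(size=n)
        de, ds = qeq_charges_vjp(e, s, Q, g)
        h = 1e-6
        for i in range(n):
            for arr, grad in ((e, de), (s, ds)):
                ap, am = arr.copy(), arr.copy()
                ap[i] += h
                am[i] -= h
                if arr is e:
                    fd = (g @ qtune.qeq_charges(ap, s, Q) - g @ qtune.qeq_charges(am, s, Q)) / (2 * h)
                else:
                    fd = (g @ qtune.qeq_charges(e, ap, Q) - g @ qtune.qeq_charges(e, am, Q)) / (2 * h)
                assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestPerturbedCharges:
    def test_zero_theta_reproduces_consistent_charges(self, small_dataset, small_basis):
        # generator charges are QEq(e, s, Q) by construction
        rec = small_dataset.molecules[0]
        q = qtune.perturbed_charges(rec, small_basis, qtune.FineTuneParams.zeros(3))
        np.testing.assert_array_equal(q, rec.q)

    def test_consistency_diagnostic_on_inconsistent_record(self, small_dataset, small_basis):
        import dataclasses

        rec = small_dataset.molecules[0]
        q_off = rec.q.copy()
        q_off[0] += 5e-9  # within the charge-sum tolerance but not QEq-consistent
        q_off[1] -= 5e-9
        bad = dataclasses.replace(rec, q=q_off)
        _, max_dev = qtune.perturbed_charges(bad, small_basis,
                                             qtune.FineTuneParams.zeros(3),
                                             check_consistency=True)
        assert max_dev == pytest.approx(5e-9, rel=1e-3)

    def test_matches_generator_ground_truth(self, recovery_run):
        ds = recovery_run["dataset"]
        basis = recovery_run["basis"]
        theta_true = recovery_run["config"].theta_true
        for rec in ds.molecules[:10]:
            q = qtune.perturbed_charges(rec, basis, theta_true)
            q_true = np.asarray(ds.metadata["q_true"][rec.molecule_id])
            np.testing.assert_allclose(q, q_true, atol=1e-12)


class TestReferencePhi:
    def test_unit_charge_at_one_angstrom(self):
        cfg = ToyConfiguration(mol_coords=[[0.0, 0.0, 0.0]],
                               env_coords=[[1.0, 0.0, 0.0]], env_charges=[1.0])
        np.testing.assert_allclose(reference_phi(cfg, switch="none"), [332.0637])

    def test_beyond_cutoff_contributes_nothing(self):
        cfg = ToyConfiguration(mol_coords=[[0.0, 0.0, 0.0]],
                               env_coords=[[13.0, 0.0, 0.0]], env_charges=[1.0],
                               r_cut=12.0)
        np.testing.assert_array_equal(reference_phi(cfg, switch="none"), [0.0])
        np.testing.assert_array_equal(reference_phi(cfg, switch="cos8"), [0.0])

    def test_linearity_in_environment_charges(self, rng):
        mol = rng.uniform(-2, 2, size=(3, 3))
        env = rng.uniform(3, 8, size=(5, 3))
        qe = rng.normal(size=5)
        cfg1 = ToyConfiguration(mol, env, qe)
        cfg2 = ToyConfiguration(mol, env, 2 * qe)
        np.testing.assert_allclose(reference_phi(cfg2), 2 * reference_phi(cfg1))

    def test_switch_vanishes_at_cutoff_and_is_one_at_origin(self):
        from qtune.electrostatics import _switch_cos8

        assert _switch_cos8(np.array([0.0]), 12.0)[0] == 1.0
        assert _switch_cos8(np.array([12.0]), 12.0)[0] == pytest.approx(0.0, abs=1e-30)

    def test_overlapping_atoms_rejected(self):
        cfg = ToyConfiguration(mol_coords=[[0.0, 0.0, 0.0]],
                               env_coords=[[0.0, 0.0, 0.0]], env_charges=[1.0])
        with pytest.raises(ValueError):
            reference_phi(cfg)

    def test_xyz_text_parsing(self):
        cfg = ToyConfiguration.from_xyz_text("0 0 0\n1 1 1", "2 0 0 0.5\n0 3 0 -0.5")
        assert cfg.mol_coords.shape == (2, 3)
        np.testing.assert_array_equal(cfg.env_charges, [0.5, -0.5])

    def test_energy_matches_brute_force_double_loop(self, rng):
        from qtune.constants import COULOMB_KCAL_ANG_E2
        from qtune.electrostatics import _switch_cos8

        mol = rng.uniform(-3, 3, size=(4, 3))
        env = rng.uniform(-10, 10, size=(30, 3))
        qe = rng.normal(size=30)
        qm = rng.normal(size=4)
        cfg = ToyConfiguration(mol, env, qe, r_cut=8.0)
        fast = qtune.electrostatic_energy(qm, reference_phi(cfg, switch="cos8"))
        slow = 0.0
        for i in range(4):
            for j in range(30):
                r = float(np.linalg.norm(mol[i] - env[j]))
                if r < 8.0:
                    f = float(_switch_cos8(np.array([r]), 8.0)[0])
                    slow += qm[i] * qe[j] * COULOMB_KCAL_ANG_E2 * f / r
        assert fast == pytest.approx(slow, abs=1e-9)


class TestElectrostaticEnergy:
    def test_zero_charges_zero_energy(self):
        assert qtune.electrostatic_energy(np.zeros(4), np.ones(4)) == 0.0

    def test_unit_charge_case(self):
        assert qtune.electrostatic_energy([1.0], [332.0637]) == pytest.approx(332.0637)

    def test_additivity_in_charges(self, rng):
        qa, qb, phi = rng.normal(size=(3, 6))
        assert qtune.electrostatic_energy(qa + qb, phi) == pytest.approx(
            qtune.electrostatic_energy(qa, phi) + qtune.electrostatic_energy(qb, phi))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            qtune.electrostatic_energy([1.0], [1.0, 2.0])


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(-10, 10), min_size=2, max_size=8),
       st.floats(-2, 2))
def test_qeq_conserves_charge_property(e_list, Q):
    """QEq output sums to the requested total charge for any feasible input."""
    e = np.asarray(e_list)
    s = np.abs(e) + 1.0  # arbitrary strictly positive hardness
    assert abs(qtune.qeq_charges(e, s, Q).sum() - Q) < 1e-10
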