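"""Electrostatic parameter perturbation, QEq charges and a toy potential calculator.

The fine-tuning model perturbs per-atom electronegativity e_i and
hardness s_i linearly in the low-rank embedding features:

    e_i* = e_i + theta_e . h_hat_i        s_i* = s_i + theta_s . h_hat_i

and regenerates partial charges by charge equilibration (QEq), the
minimizer of the second-order expansion sum_i (e_i* q_i + s_i* q_i^2 / 2)
subject to sum_i q_i = Q:

    q_i* = -e_i*/s_i* + (1/s_i*) * (Q + sum_j e_j*/s_j*) / (sum_j 1/s_j*)

so the total molecular charge is conserved exactly and the map is smooth
in (e*, s*) wherever all s* stay positive.  A closed-form reverse-mode
derivative (vector-Jacobian product) of the QEq map is provided for the
optimizer.

``reference_phi`` is a plain direct-space Coulomb calculator with a
smooth switching cutoff; it exists to build small synthetic fixtures with
a consistent potential definition — real datasets carry precomputed
potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_KCAL_ANG_E2

#: hardness values at or below this are treated as infeasible (QEq divides by s*)
S_FLOOR = 1e-6


class InfeasiblePerturbation(ValueError):
    """A perturbation drove some atom's hardness to or below the feasibility floor."""


@dataclass(eq=False)
class FineTuneParams:
    """The 2 x r perturbation matrix: row theta_e perturbs e, row theta_s perturbs s."""

    theta_e: np.ndarray
    theta_s: np.ndarray

    def __post_init__(self):
        self.theta_e = np.asarray(self.theta_e, dtype=np.float64)
        self.theta_s = np.asarray(self.theta_s, dtype=np.float64)
        if self.theta_e.shape != self.theta_s.shape or self.theta_e.ndim != 1:
            raise ValueError("theta_e and theta_s must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(self.theta_e)) and np.all(np.isfinite(self.theta_s))):
            raise ValueError("fine-tune parameters must be finite")

    @property
    def r(self) -> int:
        return self.theta_e.shape[0]

    @classmethod
    def zeros(cls, r: int) -> "FineTuneParams":
        return cls(np.zeros(r), np.zeros(r))

    @classmethod
    def from_flat(cls, x: np.ndarray) -> "FineTuneParams":
        x = np.asarray(x, dtype=np.float64)
        r = x.shape[0] // 2
        return cls(x[:r].copy(), x[r:].copy())

    def to_flat(self) -> np.ndarray:
        return np.concatenate([self.theta_e, self.theta_s])

    def norm(self) -> float:
        return float(np.sqrt(np.sum(self.theta_e**2) + np.sum(self.theta_s**2)))


def perturb_parameters(e, s, h_hat, theta: FineTuneParams):
    """Apply the low-rank linear perturbation to (e, s).

    Returns ``(e_star, s_star)``.  Raises :class:`InfeasiblePerturbation`
    if any perturbed hardness falls to or below the floor (1e-6): the
    QEq map is singular there and the objective treats such points as
    infeasible.
    """
    e = np.asarray(e, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    h_hat = np.asarray(h_hat, dtype=np.float64)
    if h_hat.shape != (e.shape[0], theta.r):
        raise ValueError(
            f"h_hat shape {h_hat.shape} inconsistent with n_atoms={e.shape[0]}, r={theta.r}")
    e_star = e + h_hat @ theta.theta_e
    s_star = s + h_hat @ theta.theta_s
    if np.any(s_star <= S_FLOOR):
        raise InfeasiblePerturbation(
            f"perturbation drives min hardness to {s_star.min():.3g} <= {S_FLOOR}")
    return e_star, s_star


def qeq_charges(e_star, s_star, Q: float) -> np.ndarray:
    """Charge-equilibration partial charges for perturbed (e*, s*) at total charge Q.

    Conserves sum(q*) = Q to machine precision and is invariant to adding
    a constant to every e* (the global electronegativity shift cancels).
    """
    e_star = np.asarray(e_star, dtype=np.float64)
    s_star = np.asarray(s_star, dtype=np.float64)
    if e_star.shape != s_star.shape:
        raise ValueError("e_star and s_star must have equal shapes")
    if np.any(s_star <= 0):
        raise InfeasiblePerturbation("qeq_charges requires strictly positive hardness")
    u = 1.0 / s_star
    a = e_star * u
    lam = (Q + a.sum()) / u.sum()  # Lagrange multiplier (equalized electronegativity)
    return -a + u * lam


def qeq_charges_vjp(e_star, s_star, Q: float, g) -> tuple:
    """Reverse-mode derivative of :func:`qeq_charges`.

    Given the downstream gradient ``g = dL/dq*``, returns
    ``(dL/de*, dL/ds*)``.  Closed form from q_i* = -a_i + u_i * lam with
    u_i = 1/s_i*, a_i = e_i* u_i, lam = (Q + sum a)/sum u.
    """
    e_star = np.asarray(e_star, dtype=np.float64)
    s_star = np.asarray(s_star, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    u = 1.0 / s_star
    a = e_star * u
    S = u.sum()
    lam = (Q + a.sum()) / S
    G = float(g @ u)
    de = -u * (g - G / S)
    ds = u * (a - lam * u) * (g - G / S)
    return de, ds


def perturbed_charges(record, basis, theta: FineTuneParams,
                      check_consistency: bool = False):
    """Compose projection, parameter perturbation and QEq for one molecule.

    At theta = 0 this returns qeq_charges(e, s, Q) exactly; that equals
    the stored foundation charges whenever they are themselves
    QEq-consistent.  With ``check_consistency=True`` a second return
    value reports max |qeq(e,s,Q) - record.q|.
    """
    from .projection import project  # local to avoid import cycle in docs builds

    h_hat = project(basis, record.embeddings)
    e_star, s_star = perturb_parameters(record.e, record.s, h_hat, theta)
    q_star = qeq_charges(e_star, s_star, record.Q)
    if check_consistency:
        q0 = qeq_charges(record.e, record.s, record.Q)
        return q_star, float(np.max(np.abs(q0 - record.q)))
    return q_star


@dataclass(eq=False)
class ToyConfiguration:
    """A toy molecule-in-environment geometry for the reference potential calculator."""

    mol_coords: np.ndarray  # (n_atoms, 3), Angstrom
    env_coords: np.ndarray  # (n_env, 3), Angstrom
    env_charges: np.ndarray  # (n_env,), elementary charge
    r_cut: float = 12.0

    def __post_init__(self):
        self.mol_coords = np.atleast_2d(np.asarray(self.mol_coords, dtype=np.float64))
        self.env_coords = np.atleast_2d(np.asarray(self.env_coords, dtype=np.float64))
        self.env_charges = np.atleast_1d(np.asarray(self.env_charges, dtype=np.float64))
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")

    @classmethod
    def from_xyz_text(cls, mol_text: str, env_text: str, r_cut: float = 12.0):
        """Build from whitespace-delimited text: molecule rows ``x y z``,
        environment rows ``x y z charge``."""
        mol = np.loadtxt(mol_text.strip().splitlines(), ndmin=2)
        env = np.loadtxt(env_text.strip().splitlines(), ndmin=2)
        return cls(mol_coords=mol[:, :3], env_coords=env[:, :3],
                   env_charges=env[:, 3], r_cut=r_cut)


def _switch_cos8(r: np.ndarray, r_cut: float) -> np.ndarray:
    """Smooth multiplicative switch: 1 at r=0, 0 at r_cut, cos^8((pi/2)(r/rcut)^3)."""
    x = np.clip(r / r_cut, 0.0, 1.0)
    return np.cos(0.5 * np.pi * x**3) ** 8


def reference_phi(config: ToyConfiguration, switch: str = "cos8") -> np.ndarray:
    """Environment electrostatic potential on each molecule atom (kcal mol^-1 e^-1).

    Direct-space Coulomb sum over environment charges within the cutoff,
    optionally damped by the smooth switching function; contributions
    beyond ``r_cut`` are omitted.  Charge-normalized: independent of the
    molecule's own charges, so the molecule-environment energy is the
    inner product of this potential with any charge vector.
    """
    if switch not in ("cos8", "none"):
        raise ValueError(f"unknown switching function {switch!r}")
    diff = config.mol_coords[:, None, :] - config.env_coords[None, :, :]
    r = np.sqrt(np.sum(diff**2, axis=-1))
    if np.any(r == 0):
        raise ValueError("molecule-environment pair at zero distance")
    inside = r < config.r_cut
    f = _switch_cos8(r, config.r_cut) if switch == "cos8" else np.ones_like(r)
    contrib = np.where(inside, COULOMB_KCAL_ANG_E2 * config.env_charges[None, :] * f / r, 0.0)
    return contrib.sum(axis=1)


def electrostatic_energy(q_star, phi_frame) -> float:
    """Total molecule-environment electrostatic energy: sum_i q_i* phi_i (kcal/mol)."""
    q_star = np.asarray(q_star, dtype=np.float64)
    phi_frame = np.asarray(phi_frame, dtype=np.float64)
    if q_star.shape != phi_frame.shape:
        raise ValueError(f"length mismatch: {q_star.shape} vs {phi_frame.shape}")
    return float(q_star @ phi_frame)
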