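"""Zwanzig (exponential-average) reweighting of stored potential frames.

Because the perturbation touches only molecule-environment electrostatics
and that energy is linear in the partial charges, the per-frame energy
change is an inner product of the charge perturbation with the saved
per-atom potentials:

    dU_t = sum_i (q_i* - q_i) phi_{t,i}

The one-shot perturbed free energy is the exponential average over
frames drawn at the unperturbed potential,

    dG_pert = -(1/beta) * ln < exp(-beta dU) >,

with importance weights w_t = exp(-beta dU_t) whose effective sample size
ESS = (sum w)^2 / sum w^2 diagnoses how much of the original ensemble
survives reweighting.  All weight arithmetic is done in log space with a
max shift; ESS is shift-invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .electrostatics import FineTuneParams, perturbed_charges


@dataclass(eq=False)
class ReweightResult:
    """Per-molecule one-shot reweighting outcome."""

    molecule_id: str
    dG_pert: float  # kcal/mol, Zwanzig free-energy perturbation
    dG_reweight: float  # kcal/mol, dG_calc + dG_pert
    ess: float  # effective sample size, in [1, n_frames]
    log_weights: np.ndarray  # (n_frames,), un-normalized log importance weights
    residual: float  # kcal/mol, dG_expt - dG_reweight
    infeasible: bool = False


def delta_energies(record, q_star) -> np.ndarray:
    """Per-frame molecule-environment electrostatic energy change (kcal/mol).

    Solvent-solvent and intramolecular terms cancel in the difference, so
    only the charge perturbation against the saved potentials remains.
    """
    q_star = np.asarray(q_star, dtype=np.float64)
    if q_star.shape != (record.n_atoms,):
        raise ValueError(
            f"q_star has shape {q_star.shape}, expected ({record.n_atoms},)")
    return record.phi @ (q_star - record.q)


def importance_weights(delta_u, beta: float) -> np.ndarray:
    """Un-normalized log importance weights, log w_t = -beta * dU_t."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    return -beta * np.asarray(delta_u, dtype=np.float64)


def effective_sample_size(log_weights) -> float:
    """ESS = (sum w)^2 / sum w^2, computed from max-shifted log weights.

    Lies in [1, N] and is invariant to adding a constant to all
    log-weights (equivalently, to rescaling the weights).
    """
    lw = np.asarray(log_weights, dtype=np.float64)
    if lw.size == 0 or not np.any(np.isfinite(lw)):
        raise ValueError("effective_sample_size needs at least one finite log-weight")
    w = np.exp(lw - lw.max())
    return float(w.sum() ** 2 / np.sum(w**2))


def zwanzig_dg(delta_u, beta: float) -> float:
    """One-sided free-energy perturbation, -(1/beta) [logsumexp(-beta dU) - ln N]."""
    du = np.asarray(delta_u, dtype=np.float64)
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if du.size < 2:
        raise ValueError("zwanzig_dg needs at least 2 frames")
    if not np.all(np.isfinite(du)):
        raise ValueError("zwanzig_dg requires finite energy differences")
    return float(-(logsumexp(-beta * du) - np.log(du.size)) / beta)


def reweight_molecule(record, basis, theta: FineTuneParams, beta: float) -> ReweightResult:
    """Full one-shot pipeline for one molecule: charges, weights, ESS, free energy.

    Pure function of its inputs — identical arguments give bit-identical
    results; no re-simulation is involved.  At theta = 0 (on QEq-consistent
    charges) dG_pert = 0, ESS = n_frames and the residual equals the
    baseline residual dG_expt - dG_calc.
    """
    q_star = perturbed_charges(record, basis, theta)
    du = delta_energies(record, q_star)
    lw = importance_weights(du, beta)
    dg_pert = zwanzig_dg(du, beta)
    ess = effective_sample_size(lw)
    dg_rw = record.dG_calc + dg_pert
    return ReweightResult(
        molecule_id=record.molecule_id,
        dG_pert=dg_pert,
        dG_reweight=dg_rw,
        ess=ess,
        log_weights=lw,
        residual=record.dG_expt - dg_rw,
    )
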