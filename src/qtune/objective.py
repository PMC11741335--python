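"""ESS-regularized loss assembly and BFGS fine-tuning.

The total loss over a split-assigned dataset is

    Loss(Theta) = sum_{j in all molecules} Reg_ESS(ESS_j(Theta))
                + (1/N_train) sum_{i in train} L_delta(beta * resid_i(Theta))

where Reg_ESS is a flat-to-quadratic penalty k*(a - ESS)^2 activating
when a molecule's effective sample size falls below the onset ``a`` (the
penalty is applied to *all* splits so that no molecule's reweighted
prediction silently degrades), and L_delta is the pseudo-Huber loss on
free-energy residuals.  Residuals are expressed in units of kT inside
the loss by default, with the pseudo-Huber scale delta defaulting to
1 kT.

Gradients are exact reverse-mode chain rules through the QEq charge map,
the per-frame energy differences, the Zwanzig logsumexp and the ESS —
all closed form, verified against finite differences in the test suite.

Optimization is a quasi-Newton BFGS loop with a strong-Wolfe line
search, starting from Theta = 0, with early stopping the moment any
molecule's ESS drops below ``ess_stop`` (the run then returns the last
iterate whose minimum ESS still satisfied the threshold).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import line_search as _wolfe_line_search

from .constants import beta_from_temperature
from .data import Dataset
from .electrostatics import (
    S_FLOOR,
    FineTuneParams,
    InfeasiblePerturbation,
    qeq_charges,
    qeq_charges_vjp,
)
from .projection import ProjectionBasis, project

#: large finite loss returned at infeasible parameter points
INFEASIBLE_LOSS = 1e10


@dataclass
class LossConfig:
    """Hyper-parameters of the ESS-regularized loss.

    delta : pseudo-Huber scale in kcal/mol; None means 1 kT (the default).
    k_reg : regularization stiffness (0 disables regularization).
    a_onset : ESS (samples) below which the quadratic penalty activates.
    ess_stop : early-stopping ESS threshold (samples).
    regularize_splits : 'all' (default) or 'train_only'.
    residuals_in_kt : scale residuals (and delta) by beta inside the loss.
    smooth_penalty : replace the C1 hinge-quadratic by a C-infinity
        squared-softplus of the ESS deficit.
    normalize_ess : interpret a_onset/ess_stop as fractions of each
        molecule's frame count instead of raw sample counts.
    """

    delta: Optional[float] = None
    k_reg: float = 100.0
    a_onset: float = 750.0
    ess_stop: float = 500.0
    regularize_splits: str = "all"
    residuals_in_kt: bool = True
    smooth_penalty: bool = False
    normalize_ess: bool = False

    def resolved_delta(self, beta: float) -> float:
        return (1.0 / beta) if self.delta is None else self.delta

    def validate(self, min_n_frames: Optional[int] = None) -> None:
        if self.k_reg < 0:
            raise ValueError("k_reg must be nonnegative")
        if self.ess_stop > self.a_onset:
            raise ValueError(
                f"ess_stop ({self.ess_stop}) must not exceed a_onset ({self.a_onset})")
        if self.regularize_splits not in ("all", "train_only"):
            raise ValueError(f"unknown regularize_splits {self.regularize_splits!r}")
        if (min_n_frames is not None and self.k_reg > 0 and not self.normalize_ess
                and self.a_onset >= min_n_frames):
            raise ValueError(
                f"a_onset ({self.a_onset}) must be below the smallest frame count "
                f"({min_n_frames}); otherwise the penalty never vanishes")


def pseudo_huber(x, delta: float):
    """L_delta(x) = delta^2 (sqrt(1 + (x/delta)^2) - 1).

    Quadratic ~x^2/2 near zero, asymptotically linear with slope delta:
    robust to outlier residuals.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    x = np.asarray(x, dtype=np.float64)
    out = delta**2 * (np.sqrt(1.0 + (x / delta) ** 2) - 1.0)
    return float(out) if out.ndim == 0 else out


def _pseudo_huber_grad(x, delta: float):
    x = np.asarray(x, dtype=np.float64)
    return x / np.sqrt(1.0 + (x / delta) ** 2)


def _softplus(x):
    return np.logaddexp(0.0, x)


def ess_penalty(ess: float, config: LossConfig) -> float:
    """Flat-to-quadratic penalty on low effective sample size.

    Zero for ess >= a_onset, k_reg * (a_onset - ess)^2 below; continuous
    with continuous first derivative at the onset.  The optional smooth
    variant uses k_reg * softplus(a_onset - ess)^2.
    """
    floor = 0.0 if config.normalize_ess else 1.0
    if ess < floor - 1e-9:
        raise ValueError(f"ESS must be >= {floor}, got {ess}")
    if config.smooth_penalty:
        return float(config.k_reg * _softplus(config.a_onset - ess) ** 2)
    deficit = config.a_onset - ess
    return float(config.k_reg * deficit**2) if deficit > 0 else 0.0


def _ess_penalty_grad(ess: float, config: LossConfig) -> float:
    """d penalty / d ess."""
    if config.smooth_penalty:
        z = config.a_onset - ess
        sp = _softplus(z)
        sig = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        return float(-2.0 * config.k_reg * sp * sig)
    deficit = config.a_onset - ess
    return float(-2.0 * config.k_reg * deficit) if deficit > 0 else 0.0


@dataclass
class _PreparedMolecule:
    molecule_id: str
    h_hat: np.ndarray  # (n, r)
    e: np.ndarray
    s: np.ndarray
    q: np.ndarray
    Q: float
    phi: np.ndarray  # (n_frames, n)
    base_residual: float  # dG_expt - dG_calc
    is_train: bool
    n_frames: int


def _prepare(dataset: Dataset, basis: ProjectionBasis) -> list:
    prepared = []
    for rec in dataset:
        prepared.append(_PreparedMolecule(
            molecule_id=rec.molecule_id,
            h_hat=project(basis, rec.embeddings),
            e=rec.e, s=rec.s, q=rec.q, Q=rec.Q, phi=rec.phi,
            base_residual=rec.dG_expt - rec.dG_calc,
            is_train=rec.split == "train",
            n_frames=rec.n_frames,
        ))
    return prepared


def _loss_and_grad(prepared: list, x: np.ndarray, config: LossConfig, beta: float,
                   want_grad: bool):
    """Core loss (and optional analytic gradient) over prepared molecules.

    Returns (loss, grad_or_None, components).  At an infeasible point
    (some s* driven to the floor) returns the large sentinel loss with
    ``components['infeasible']`` set.
    """
    r = x.shape[0] // 2
    theta_e, theta_s = x[:r], x[r:]
    n_train = sum(p.is_train for p in prepared)
    delta_kcal = config.resolved_delta(beta)
    # residuals enter the pseudo-Huber in kT units by default
    res_scale = beta if config.residuals_in_kt else 1.0
    delta_scaled = delta_kcal * res_scale

    grad = np.zeros_like(x) if want_grad else None
    data_term = 0.0
    reg_term = 0.0
    per_mol = {}
    min_ess, min_ess_id = np.inf, None
    max_abs_pert = 0.0

    for p in prepared:
        e_star = p.e + p.h_hat @ theta_e
        s_star = p.s + p.h_hat @ theta_s
        if np.any(s_star <= S_FLOOR):
            components = {
                "infeasible": True,
                "infeasible_molecule": p.molecule_id,
                "data": np.nan, "reg": np.nan,
                "min_ess": np.nan, "min_ess_id": None,
                "max_abs_dG_pert": np.nan, "per_molecule": {},
            }
            return INFEASIBLE_LOSS, (np.zeros_like(x) if want_grad else None), components

        q_star = qeq_charges(e_star, s_star, p.Q)
        du = p.phi @ (q_star - p.q)
        n = du.shape[0]
        z = -beta * du
        zmax = z.max()
        w = np.exp(z - zmax)
        w1 = w.sum()
        w2 = float(np.sum(w**2))
        ess = float(w1**2 / w2)
        dg_pert = -((math.log(w1) + zmax) - math.log(n)) / beta
        residual = p.base_residual - dg_pert

        ess_for_penalty = ess / n if config.normalize_ess else ess
        regularized = config.regularize_splits == "all" or p.is_train
        pen = ess_penalty(ess_for_penalty, config) if regularized else 0.0
        reg_term += pen
        if p.is_train:
            data_term += pseudo_huber(res_scale * residual, delta_scaled) / n_train

        per_mol[p.molecule_id] = {
            "ess": ess, "dG_pert": dg_pert, "residual": residual, "penalty": pen,
        }
        if ess < min_ess:
            min_ess, min_ess_id = ess, p.molecule_id
        max_abs_pert = max(max_abs_pert, abs(dg_pert))

        if want_grad:
            g_du = np.zeros(n)
            if p.is_train:
                dldres = res_scale * _pseudo_huber_grad(res_scale * residual,
                                                        delta_scaled) / n_train
                # d residual / d du_t = -p_t (softmax of -beta*du)
                g_du += dldres * (-(w / w1))
            if regularized and pen != 0.0 or (regularized and config.smooth_penalty):
                dpen_dess = _ess_penalty_grad(ess_for_penalty, config)
                if config.normalize_ess:
                    dpen_dess /= n
                if dpen_dess != 0.0:
                    ratio = w1 / w2
                    dess_ddu = -2.0 * beta * w * ratio * (1.0 - ratio * w)
                    g_du += dpen_dess * dess_ddu
            if np.any(g_du):
                g_q = p.phi.T @ g_du
                g_e, g_s = qeq_charges_vjp(e_star, s_star, p.Q, g_q)
                grad[:r] += p.h_hat.T @ g_e
                grad[r:] += p.h_hat.T @ g_s

    loss = reg_term + data_term
    components = {
        "infeasible": False,
        "data": data_term,
        "reg": reg_term,
        "min_ess": min_ess,
        "min_ess_id": min_ess_id,
        "max_abs_dG_pert": max_abs_pert,
        "per_molecule": per_mol,
    }
    return loss, grad, components


def total_loss(dataset: Dataset, basis: ProjectionBasis, theta: FineTuneParams,
               config: LossConfig):
    """Total ESS-regularized loss and its component breakdown.

    The data term averages pseudo-Huber residual losses over training
    molecules only; the ESS penalty sums over all molecules (default) so
    that no split's reweighted estimates become unreliable.
    """
    prepared = _prepare(dataset, basis)
    if not any(p.is_train for p in prepared):
        raise ValueError("dataset has no training molecules; assign splits first")
    config.validate(min_n_frames=min(p.n_frames for p in prepared))
    loss, _, components = _loss_and_grad(prepared, theta.to_flat(), config,
                                         dataset.beta, want_grad=False)
    return loss, components


def loss_gradient(dataset: Dataset, basis: ProjectionBasis, theta: FineTuneParams,
                  config: LossConfig) -> np.ndarray:
    """Analytic gradient of :func:`total_loss` with respect to Theta, shape (2, r)."""
    prepared = _prepare(dataset, basis)
    config.validate(min_n_frames=min(p.n_frames for p in prepared))
    loss, grad, components = _loss_and_grad(prepared, theta.to_flat(), config,
                                            dataset.beta, want_grad=True)
    if components["infeasible"]:
        raise InfeasiblePerturbation(
            f"gradient requested at infeasible point "
            f"(molecule {components['infeasible_molecule']!r})")
    return grad.reshape(2, -1)


@dataclass
class OptimizerSettings:
    """BFGS settings: gradient-norm tolerance and iteration cap."""

    gtol: float = 1e-6
    max_iter: int = 500


@dataclass
class OptimizationTrace:
    """Per-iteration log of a fine-tuning run.

    Each record holds the iterate's loss decomposition, minimum ESS over
    molecules (with the argmin molecule), the largest |dG_pert| and the
    parameter norm.  ``stop_reason`` is one of 'converged',
    'early_stop_ess', 'max_iter', 'infeasible'.
    """

    records: list = field(default_factory=list)
    stop_reason: str = ""

    def append(self, iteration: int, x: np.ndarray, loss: float, components: dict):
        self.records.append({
            "iteration": iteration,
            "theta": x.copy(),
            "loss": loss,
            "data_loss": components["data"],
            "reg_loss": components["reg"],
            "min_ess": components["min_ess"],
            "min_ess_molecule": components["min_ess_id"],
            "max_abs_dG_pert": components["max_abs_dG_pert"],
            "theta_norm": float(np.linalg.norm(x)),
        })

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    def to_dataframe(self):
        import pandas as pd

        rows = [{k: v for k, v in rec.items() if k != "theta"} for rec in self.records]
        return pd.DataFrame(rows)


def finetune(dataset: Dataset, basis: ProjectionBasis, config: LossConfig,
             opt: Optional[OptimizerSettings] = None):
    """Minimize the ESS-regularized loss by BFGS from Theta = 0.

    Runs a quasi-Newton loop with a strong-Wolfe line search until the
    gradient norm falls below ``opt.gtol`` or ``opt.max_iter`` iterations
    elapse.  After every accepted iterate the minimum ESS over *all*
    molecules is checked; if it drops below ``config.ess_stop`` the run
    stops immediately and returns the last iterate whose minimum ESS
    still met the threshold.  Deterministic given its inputs.

    Returns ``(theta_opt, trace)``.
    """
    opt = opt or OptimizerSettings()
    prepared = _prepare(dataset, basis)
    if not any(p.is_train for p in prepared):
        raise ValueError("dataset has no training molecules; assign splits first")
    config.validate(min_n_frames=min(p.n_frames for p in prepared))
    beta = dataset.beta
    r = basis.r
    ess_stop = config.ess_stop

    n_frames_by_id = {p.molecule_id: p.n_frames for p in prepared}

    def min_ess_of(components):
        if config.normalize_ess:
            # compare fractions against the fractional threshold
            fracs = [v["ess"] / n_frames_by_id[mol_id]
                     for mol_id, v in components["per_molecule"].items()]
            return min(fracs) if fracs else np.inf
        return components["min_ess"]

    def f_only(x):
        loss, _, _ = _loss_and_grad(prepared, x, config, beta, want_grad=False)
        return loss

    def g_only(x):
        _, grad, comp = _loss_and_grad(prepared, x, config, beta, want_grad=True)
        if comp["infeasible"]:
            # line search should treat this as a bad direction, not crash
            return np.full_like(x, np.nan)
        return grad

    x = np.zeros(2 * r)
    loss, grad, components = _loss_and_grad(prepared, x, config, beta, want_grad=True)
    trace = OptimizationTrace()
    if not np.isfinite(loss):
        raise ValueError("loss is non-finite at Theta = 0")
    if components["infeasible"]:
        trace.stop_reason = "infeasible"
        return FineTuneParams.zeros(r), trace
    trace.append(0, x, loss, components)
    if min_ess_of(components) < ess_stop:
        warnings.warn("minimum ESS already below ess_stop at Theta = 0", stacklevel=2)
        trace.stop_reason = "early_stop_ess"
        return FineTuneParams.zeros(r), trace

    last_ok_x = x.copy()
    H = np.eye(2 * r)  # inverse-Hessian approximation
    old_loss = None
    stop_reason = "max_iter"

    for it in range(1, opt.max_iter + 1):
        gnorm = np.linalg.norm(grad, ord=np.inf)
        if gnorm <= opt.gtol:
            stop_reason = "converged"
            break
        direction = -H @ grad
        if not np.all(np.isfinite(direction)) or float(direction @ grad) >= 0:
            H = np.eye(2 * r)
            direction = -grad
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy warns on line-search failure
            alpha, *_rest = _wolfe_line_search(
                f_only, g_only, x, direction, gfk=grad, old_fval=loss,
                old_old_fval=old_loss, maxiter=30)
        if alpha is None:
            # Armijo backtracking fallback
            alpha = 1.0
            slope = float(grad @ direction)
            while alpha > 1e-14 and not (f_only(x + alpha * direction)
                                         <= loss + 1e-4 * alpha * slope):
                alpha *= 0.5
            if alpha <= 1e-14:
                stop_reason = "converged"
                break
        x_new = x + alpha * direction
        loss_new, grad_new, components = _loss_and_grad(prepared, x_new, config, beta,
                                                        want_grad=True)
        if components["infeasible"]:
            stop_reason = "infeasible"
            break
        s_vec = x_new - x
        y_vec = grad_new - grad
        sy = float(s_vec @ y_vec)
        if sy > 1e-12 * float(np.linalg.norm(s_vec) * np.linalg.norm(y_vec) + 1e-300):
            rho = 1.0 / sy
            I = np.eye(2 * r)
            V = I - rho * np.outer(s_vec, y_vec)
            H = V @ H @ V.T + rho * np.outer(s_vec, s_vec)
        old_loss, x, loss, grad = loss, x_new, loss_new, grad_new
        trace.append(it, x, loss, components)
        if min_ess_of(components) < ess_stop:
            stop_reason = "early_stop_ess"
            x = last_ok_x
            break
        last_ok_x = x.copy()

    trace.stop_reason = stop_reason
    return FineTuneParams.from_flat(x if stop_reason != "early_stop_ess" else last_ok_x), trace
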