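"""Accuracy statistics and distribution-shift criteria for fine-tuning runs.

RMSE/MUE with nonparametric bootstrap confidence intervals, empirical
CDFs of absolute free-energy residuals before and after fine-tuning, and
the Cramér-von Mises criterion

    omega^2 = integral (F_post - F_pre)^2 dF_pre

quantifying how far fine-tuning moved the residual distribution.  The
p-value comes from the symmetric two-sample Cramér-von Mises test
(midrank ties, asymptotic null distribution); omega^2 itself is the
directed ECDF integral above and is computed by this module, with the
symmetric rank statistic reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import cramervonmises_2samp, pearsonr

from .data import SPLITS, Dataset
from .electrostatics import FineTuneParams
from .projection import ProjectionBasis
from .reweighting import reweight_molecule
from .synthetic import exact_dg_pert, exact_zwanzig_stderr


def accuracy_stats(residuals, n_boot: int = 1000, seed: int = 0) -> dict:
    """RMSE and MUE of residuals with bootstrap 95% confidence intervals."""
    res = np.asarray(residuals, dtype=np.float64)
    if res.size < 2:
        raise ValueError("need at least 2 residuals")
    rmse = float(np.sqrt(np.mean(res**2)))
    mue = float(np.mean(np.abs(res)))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, res.size, size=(n_boot, res.size))
    boot = res[idx]
    rmse_b = np.sqrt(np.mean(boot**2, axis=1))
    mue_b = np.mean(np.abs(boot), axis=1)
    return {
        "rmse": rmse,
        "mue": mue,
        "rmse_ci95": (float(np.percentile(rmse_b, 2.5)), float(np.percentile(rmse_b, 97.5))),
        "mue_ci95": (float(np.percentile(mue_b, 2.5)), float(np.percentile(mue_b, 97.5))),
        "n": int(res.size),
    }


def _ecdf(sorted_sample: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.searchsorted(sorted_sample, x, side="right") / sorted_sample.size


def cramer_von_mises(sample_a, sample_b) -> tuple:
    """Directed Cramér-von Mises discrepancy and two-sample p-value.

    ``omega2`` integrates the squared ECDF gap of ``sample_a`` (e.g.
    post-fit residuals) against the ECDF measure of ``sample_b`` (e.g.
    pre-fit): zero iff the two empirical CDFs coincide.  The p-value is
    the symmetric two-sample Cramér-von Mises test (asymptotic).
    """
    a = np.sort(np.asarray(sample_a, dtype=np.float64))
    b = np.sort(np.asarray(sample_b, dtype=np.float64))
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    omega2 = float(np.mean((_ecdf(a, b) - _ecdf(b, b)) ** 2))
    res = cramervonmises_2samp(a, b, method="asymptotic")
    return omega2, float(res.pvalue)


@dataclass(eq=False)
class EvalReport:
    """Per-split accuracy and distribution-shift summary with residual table."""

    per_split: dict  # split -> stats dict (or None for degenerate splits)
    table: pd.DataFrame  # per-molecule pre/post residuals
    theta_norm: float = 0.0

    def to_json_dict(self) -> dict:
        return {"per_split": self.per_split, "theta_norm": self.theta_norm}


def _paired_bootstrap_delta_rmse(pre, post, n_boot: int, seed: int) -> tuple:
    """95% CI of RMSE(pre) - RMSE(post) resampling molecules in pairs."""
    pre = np.asarray(pre)
    post = np.asarray(post)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pre.size, size=(n_boot, pre.size))
    delta = np.sqrt(np.mean(pre[idx] ** 2, axis=1)) - np.sqrt(np.mean(post[idx] ** 2, axis=1))
    return float(np.percentile(delta, 2.5)), float(np.percentile(delta, 97.5))


def evaluate_run(dataset: Dataset, basis: ProjectionBasis, theta: FineTuneParams,
                 beta: float, n_boot: int = 1000, seed: int = 0) -> EvalReport:
    """Pre-fit vs post-fit evaluation of a fitted perturbation.

    Pre-fit residuals are the baseline dG_expt - dG_calc (theta = 0);
    post-fit residuals come from one-shot reweighting at ``theta``.  Per
    split the report carries accuracy stats for both, the directed
    omega^2 with its p-value on absolute residuals, and a
    paired-bootstrap 95% CI of the RMSE improvement.
    """
    rows = []
    for rec in dataset:
        rw = reweight_molecule(rec, basis, theta, beta)
        rows.append({
            "molecule_id": rec.molecule_id,
            "split": rec.split,
            "dG_calc": rec.dG_calc,
            "dG_expt": rec.dG_expt,
            "dG_pert": rw.dG_pert,
            "dG_reweight": rw.dG_reweight,
            "ess": rw.ess,
            "residual_pre": rec.dG_expt - rec.dG_calc,
            "residual_post": rw.residual,
        })
    table = pd.DataFrame(rows)

    per_split = {}
    for split in SPLITS:
        sub = table[table["split"] == split]
        if len(sub) < 2:
            warnings.warn(f"split {split!r} has {len(sub)} molecules; "
                          "statistics reported as None", stacklevel=2)
            per_split[split] = None
            continue
        pre = sub["residual_pre"].to_numpy()
        post = sub["residual_post"].to_numpy()
        omega2, pvalue = cramer_von_mises(np.abs(post), np.abs(pre))
        sym = cramervonmises_2samp(np.abs(post), np.abs(pre), method="asymptotic")
        per_split[split] = {
            "pre": accuracy_stats(pre, n_boot=n_boot, seed=seed),
            "post": accuracy_stats(post, n_boot=n_boot, seed=seed + 1),
            "cvm_omega2": omega2,
            "cvm_pvalue": pvalue,
            "cvm_symmetric_stat": float(sym.statistic),
            "delta_rmse_ci95": _paired_bootstrap_delta_rmse(pre, post, n_boot, seed + 2),
            "n": int(len(sub)),
        }
    return EvalReport(per_split=per_split, table=table, theta_norm=theta.norm())


def consistency_check(dataset: Dataset, basis: ProjectionBasis,
                      theta: FineTuneParams, beta: float) -> dict:
    """One-shot reweighted vs exact perturbed free energies on synthetic data.

    For every molecule carrying a Gaussian ensemble spec, compares
    dG_reweight(theta) against dG_calc + the closed-form perturbed free
    energy at the same perturbed charges.  Returns the RMSE of the
    deviations, the pooled exact Zwanzig standard error (RMS of the
    per-molecule analytic standard errors), and the per-molecule table.
    """
    rows = []
    for rec in dataset:
        if rec.ensemble is None:
            continue
        rw = reweight_molecule(rec, basis, theta, beta)
        from .electrostatics import perturbed_charges

        q_star = perturbed_charges(rec, basis, theta)
        exact = rec.dG_calc + exact_dg_pert(rec.ensemble, rec.q, q_star, beta)
        se = exact_zwanzig_stderr(rec.ensemble, rec.q, q_star, beta, rec.n_frames)
        rows.append({
            "molecule_id": rec.molecule_id,
            "split": rec.split,
            "dG_reweight": rw.dG_reweight,
            "dG_exact": exact,
            "deviation": rw.dG_reweight - exact,
            "ess": rw.ess,
            "zwanzig_stderr": se,
        })
    if not rows:
        raise ValueError("dataset carries no synthetic ensemble specifications")
    table = pd.DataFrame(rows)
    dev = table["deviation"].to_numpy()
    se = table["zwanzig_stderr"].to_numpy()
    return {
        "rmse_reweight_vs_exact": float(np.sqrt(np.mean(dev**2))),
        "pooled_zwanzig_stderr": float(np.sqrt(np.mean(se**2))),
        "table": table,
    }


def charge_recovery(dataset: Dataset, basis: ProjectionBasis,
                    theta: FineTuneParams) -> dict:
    """Pearson correlations between recovered and ground-truth charges.

    Pools atoms across molecules; requires generator ground-truth charges
    in ``dataset.metadata['q_true']``.  Reports the correlation of the
    recovered perturbed charges with the true perturbed charges and of
    the recovered charge *changes* with the true changes (the latter is
    the stringent check: baseline charges dominate the former).
    """
    from .electrostatics import perturbed_charges

    q_true_map = dataset.metadata.get("q_true")
    if q_true_map is None:
        raise ValueError("dataset metadata lacks generator ground-truth charges")
    rec_q, true_q, rec_dq, true_dq = [], [], [], []
    for rec in dataset:
        q_star = perturbed_charges(rec, basis, theta)
        q_true = np.asarray(q_true_map[rec.molecule_id], dtype=np.float64)
        rec_q.append(q_star)
        true_q.append(q_true)
        rec_dq.append(q_star - rec.q)
        true_dq.append(q_true - rec.q)
    rec_q = np.concatenate(rec_q)
    true_q = np.concatenate(true_q)
    rec_dq = np.concatenate(rec_dq)
    true_dq = np.concatenate(true_dq)
    out = {"pearson_q": float(pearsonr(rec_q, true_q).statistic)}
    if np.ptp(true_dq) > 0 and np.ptp(rec_dq) > 0:
        out["pearson_dq"] = float(pearsonr(rec_dq, true_dq).statistic)
    else:
        out["pearson_dq"] = float("nan")
    return out
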