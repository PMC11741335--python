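# Methods

This note documents the model, the numerical choices, and what the
synthetic study conditions do and do not establish.

## Model and assumptions

The fine-tuning model is a rank-r linear perturbation of per-atom
electronegativity and hardness, driven by principal-component features
of foundation-model atom embeddings, followed by charge equilibration
(QEq) under a fixed total molecular charge. Free-energy consequences of
the perturbed charges are evaluated purely by Zwanzig (exponential-
average) reweighting of electrostatic potentials saved from equilibrium
sampling at the unperturbed potential. The core assumptions are:

* **Frames are i.i.d.** Saved potential frames are treated as
  decorrelated equilibrium snapshots. No subsampling or autocorrelation
  analysis is applied; data known to be correlated should be thinned
  before ingestion.
* **Only molecule–environment electrostatics change.** Solvent–solvent
  and intramolecular terms cancel in every energy difference, so the
  per-frame perturbation is an inner product of the charge change with
  the stored per-atom potentials.
* **Foundation charges are QEq-consistent.** The Θ = 0 identity
  (perturbed charges equal stored charges) holds exactly only when the
  stored charges equal QEq(e, s, Q). `perturbed_charges` can report the
  maximum deviation; when it is material, the QEq regeneration is the
  Θ = 0 reference.
* **β convention.** β is the *inverse* thermal energy 1/(kB·T),
  1.688 mol kcal⁻¹ at the default T = 298.15 K (a config field stored in
  dataset metadata). Units are fixed dataset-wide: kcal/mol, elementary
  charge, Å.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| r | experiment-specific (5–m) | – | PCA rank; parameter count is 2r |
| δ (pseudo-Huber scale) | 1 kT | kcal/mol | residual scale beyond which the data loss grows linearly |
| k (stiffness) | 100 | – | ESS penalty stiffness; at 100 the penalty acts as a near-hard constraint |
| a (onset) | 750 | samples | ESS below which the quadratic penalty activates |
| ESS stop | 500 | samples | early-stopping threshold, checked over *all* splits after every accepted iterate |
| gtol / max_iter | 1e-6 / 500 | – | BFGS termination |

Residuals enter the pseudo-Huber loss in kT units by default (δ = 1 kT
then means δ = 1 in loss units); a flag keeps them in kcal/mol. The ESS
penalty uses raw sample counts; `normalize_ess` switches both thresholds
to fractions of each molecule's frame count for datasets with unequal
frame counts. The penalty is applied to molecules of every split so that
no molecule's one-shot prediction silently degrades — only the *data*
term is restricted to the training split.

## Design choices where the design was open

* **Penalty orientation and smoothness.** The regularizer is zero at or
  above the onset and k·(a − ESS)² below it: a flat-to-quadratic hinge
  that penalizes *low* ESS. It is C¹, which is sufficient for BFGS with
  a strong-Wolfe line search; a C∞ squared-softplus variant is available
  behind `smooth_penalty`.
* **Centering.** PCA centers the scatter matrix, and by default the
  projection also subtracts the mean embedding (standard PCA scores).
  `center=False` projects raw embeddings onto the same basis for
  compatibility with pipelines that skip centering. The PCA basis is fit
  on all molecules: it is unsupervised and uses no labels.
* **Eigen-solver.** The basis comes from an SVD of the centered data
  matrix (eigenvalues = squared singular values, unnormalized scatter
  convention). Each column's sign is fixed by making its largest-
  magnitude component positive, so repeated fits are bit-identical.
* **Gradients.** The loss gradient is a closed-form reverse-mode chain
  rule through QEq (whose vector-Jacobian product is analytic), the
  per-frame energy differences, the Zwanzig logsumexp and the ESS. It is
  verified against central finite differences at rtol 1e-5.
* **Optimizer.** A standard BFGS inverse-Hessian update with scipy's
  strong-Wolfe line search and an Armijo backtracking fallback. Early
  stopping returns the *last* iterate whose minimum ESS met the
  threshold. Infeasible points (any perturbed hardness ≤ 1e-6, where
  QEq divides by zero) return a large finite sentinel loss (1e10), which
  the line search backtracks away from.
* **Numerics.** All weight arithmetic is in log space with a max shift;
  the ESS is computed from the same shifted weights and is invariant to
  the shift by construction. The Zwanzig estimate uses logsumexp.
* **Toy potential calculator.** `reference_phi` is a direct-space
  Coulomb sum (332.0637 kcal Å mol⁻¹ e⁻², 12 Å cutoff) with a smooth
  multiplicative switch f(r) = cos⁸((π/2)(r/r_cut)³) that is 1 at r = 0
  and 0 at the cutoff. It exists to build self-consistent toy fixtures;
  an optional erfc damping factor is deliberately absent by default
  because real datasets arrive with precomputed potentials and the
  splitting convention is engine-specific. No reciprocal-space term.
* **Splits.** floor(f·N) molecules to train; of the rest, a floored
  quarter to validation and the remainder to test — deterministic given
  the seed, sizes independent of the seed.
* **Cramér-von Mises.** ω² is the directed ECDF integral
  ∫(F_post − F_pre)² dF_pre over absolute residuals, computed in-house
  and cross-checked against a brute-force integration oracle; the
  p-value (and the symmetric statistic, reported alongside) comes from
  the standard two-sample rank test with midrank ties. A paired-
  bootstrap 95 % CI of the RMSE improvement is reported as well, since
  pre/post residuals are paired by molecule.
* **Calibration.** Bootstrap resample size is used as a stand-in for
  ESS on the curve's x-axis (resampling is uniform, appropriate for
  near-uniform weights — an approximation that degrades at low ESS).
  Resampling is of raw frames with the energy differences recomputed at
  the probe parameters. The upper envelope is the 97.5th percentile of
  per-molecule total errors (|bootstrap bias| + bootstrap sd) at each
  grid point; the grid is 20 log-spaced sizes from 10 to the frame
  count, and molecules whose full-sample ESS is below half the frame
  count are excluded from calibration.

## The synthetic ensemble

Per molecule the generator draws cluster archetypes in embedding space
(so a low-rank basis is meaningful), cluster-correlated (e, s) with
hardness clipped at 0.1 kcal mol⁻¹ e⁻², QEq-consistent charges at Q = 0
(neutral molecules), and i.i.d. Gaussian potential frames
φ ~ N(μ₀ − A·q, Σ_φ): a linear response of the mean solvent potential to
the solute charges. Under this ensemble everything is exact:

* perturbed free energy ΔG = Δqᵀμ − (β/2)ΔqᵀΣ_φΔq,
* Zwanzig estimator standard error √(e^(β²σ²_U) − 1)/(β√N) with
  σ²_U = ΔqᵀΣ_φΔq,
* the "re-simulated" ensemble is the exponentially tilted Gaussian
  N(μ₀ − A·q − βΣ_φΔq, Σ_φ),
* ESS/N ≈ e^(−β²σ²_U), which is how the overlap-fragility of a fixture
  is set in advance.

Default study conditions: 200 molecules of 5–30 atoms, m = 64 embedding
dimensions, 8 clusters, 2000 frames per molecule, experimental noise
0.2 kcal/mol, baseline free energies drawn broadly around
−5 ± 3.5 kcal/mol with 0.02 kcal/mol stated uncertainty. The
`recovery_config` preset adds a hidden rank-4 true perturbation whose
scale (0.5) keeps every molecule's ESS above ~90 % of the frame count —
the ground truth sits inside the reweighting trust region, as a
perturbative fine-tuning method presumes. The `fragile_overlap_config`
preset instead uses a 64-fold inflated potential covariance and
2 kcal/mol unfittable experimental noise, chosen via the ESS relation
above so that chasing the residuals drives the unregularized optimizer
through the ESS floor within a few iterations; its benign counterpart
(unit covariance) does not collapse.

**What the synthetic data does not emulate:** real water structure,
conformational slow modes and frame autocorrelation, non-Gaussian
potential fluctuations, conformation-dependent embeddings, charged
molecules, and any systematic (non-zero-mean) experimental error.
Passing tests therefore establish the *estimator and optimizer
machinery* — conservation laws, oracle agreement, trust-region behavior,
recovery under the model's own assumptions — not predictive accuracy on
any real benchmark.

## Problem sizes

The shipped experiments run at desk scale by choice: 200 molecules ×
2000 frames for recovery and consistency, 12 molecules for the
regularization contrast (20 seeds), 12-point bootstrap grids with
150–200 resamples for calibration, and 10⁵-sample Gaussian draws for the
estimator oracle. All are configurable upward; the statistical margins
(3 standard errors, ≥ 90 % coverage over seeds) are chosen so the checks
are stable at these sizes.

## Known limitations

* The hinge penalty makes the loss only C¹ along the ESS-onset surface;
  BFGS handles this in practice but superlinear convergence is not
  guaranteed there.
* ESS is a proxy for reweighting reliability, not a guarantee: it can
  be optimistic when important regions of configuration space were never
  sampled, and it is itself noisy at small effective sizes.
* The calibration curve equates bootstrap resample size with ESS, which
  is increasingly wrong as weights become uneven.
* Early stopping returns the last feasible iterate rather than the best
  feasible iterate by loss; with a monotone line search these coincide.
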