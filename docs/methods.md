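# Methods

This note documents the models, conventions and numerical choices behind
`enzstab`, and what the synthetic-data tests do and do not demonstrate.

## Study model

A stability study stores a population of N vials of enzyme concentrate,
split into H production batches (strata) of N_h vials, at several fixed
temperatures. At each scheduled time a stratified random sample is
assayed for volumetric activity (U L⁻¹). The package's default
conditions mirror the laccase study it was built around: three batches,
N = 1200 (400 per batch), initial activity 16,575.50 ± 268.92 U L⁻¹,
measurement SD 96.6 U L⁻¹ (pooled pilot estimate), sampling monthly for
six months then bimonthly to month twelve, precision target 21.8 U L⁻¹
at 95% confidence.

## Sampling design

* **Pooled pilot SD** — the equal-variance combined estimator
  `s_p = sqrt(Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1))`; each pilot group needs ≥ 2
  replicates.
* **Sample size** — `n₀ = (z·s/d)²` with the finite-population
  correction `n = ⌈n₀/(1+n₀/N)⌉`. z is the standard-normal quantile
  (1.96 at 95%), not Student-t: the design targets the large-N
  estimator, and at the default conditions either choice gives n = 71.
  `s = 0` returns the defined minimum of one vial per stratum.
* **Allocation** — proportional, integerised by largest remainder with
  ties to the lower stratum index; conservation Σn_h = n is exact and
  every stratum receives ≥ 1 vial when n ≥ H.
* **Estimator** — `ȳ_st = ΣW_h ȳ_h`,
  `V̂ = ΣW_h²(1−n_h/N_h)s_h²/n_h`, half-width `z·√V̂`. The variance
  estimator is exactly unbiased for the true design variance (verified
  in the tests by exhaustive enumeration of all stratified samples of a
  toy population). Strata sampled exhaustively contribute zero variance;
  a non-exhaustive stratum with n_h < 2 is an error, not a silent NaN.
* **Stop rule** — the schedule is truncated at the first time the
  stratified-mean relative activity falls strictly below 25% (≈75%
  loss). When that happens before five sampling times, sampling extends
  toward five, but only through months whose relative activity stays at
  or above a feasibility floor (default 5%): once activity has
  collapsed to unmeasurable levels the minimum is abandoned, which is
  what happened in the motivating study when activity fell to 4.8% in
  the first month at the hottest condition.
* **Temperature logs** are averaged in kelvin with their SD. A log is
  rejected as probably mixed-unit if any value is implausible for its
  declared unit (K below 100, °C above 200). Note the conversion is the
  exact +273.15; the package reports what the log implies, and one
  published pairing (24.99 °C with 297.53 K) is internally inconsistent
  by 0.6 K — the tests assert correctness, not that pairing.

## Activity units

The ABTS unit formula as commonly printed is a molar rate; the
implementation includes the explicit 10⁶ μmol/mol factor so outputs are
U L⁻¹ on the scale stability reports use. The ABTS extinction
coefficient at 420 nm defaults to 36,000 M⁻¹cm⁻¹ — an external assay
constant, overridable per protocol. Relative activity is not clamped at
100% (cold storage can transiently activate a preparation).

## Deactivation and thermodynamics

* **Isotherm fit** — OLS of `ln(E/E₀)` on time in months, with a free
  intercept by default: E₀ is itself noisy, and forcing the line
  through zero would propagate its error into the slope (a
  through-origin flag exists for sensitivity checks). k_d = −slope.
  Activity traces that rise (k_d ≤ 0) are flagged "no deactivation
  observed", excluded from the Arrhenius regression with a warning, and
  carry no half-life. A constant trace gets R² = 1 (the constant fit is
  perfect) and k_d = 0.
* **Arrhenius** — OLS of ln k_d on 1/T needs ≥ 3 positive-k_d isotherms;
  E_d = −slope·R. Note the published k_d set this package ships as
  ground truth is itself not perfectly Arrhenius-consistent (refit
  R² ≈ 0.90, E_d ≈ 40.0 kJ mol⁻¹ from the rounded constants vs the
  published 41.40 from unrounded ones), so Arrhenius *predictions*
  smooth over per-isotherm scatter by design.
* **ΔG‡ unit convention** — the Eyring expression is only defined once
  k_d's unit is fixed. Default mode `paper-months` uses k_d in month⁻¹,
  the convention of the storage-stability literature and the one that
  reproduces published tables; `si-seconds` converts with 30-day months
  first and yields values ≈ R·T·ln(2.592×10⁶) ≈ 36 kJ mol⁻¹ higher. The
  mode is recorded on every record.
* **Constants** — R, h, k_B default to the precision quoted in
  stability reports (8.314, 6.626e-34, 1.38e-23) so table reproduction
  is digit-stable; `PhysicalConstants.codata()` switches to
  full-precision values.
* Months convert to seconds at 30 days/month everywhere.

## Michaelis–Menten

Hanes–Woolf regression of S/V₀ on S provides starting values
(V_max = 1/slope, K_M = intercept/slope; slope ≤ 0 means non-saturating
data and is an error); unweighted Levenberg–Marquardt NLS refines them
(default budget 2000 evaluations, tolerance 1e-12, both recorded in the
fit object). Parameter SDs come from the Jacobian at the optimum (NLS)
or the delta method on the regression covariance (Hanes–Woolf). The
default synthetic grid is 8 log-spaced points over the assay's 0.1–3 mM
in triplicate; with K_M ≈ 0.04 mM sitting below that grid, K_M is the
weakly identified parameter — its SD is honest about this, and the
generator accepts any custom grid extending downward.

## Trajectory fluctuation analysis

* **Superposition** — Kabsch via SVD with a proper rotation enforced;
  selections with < 3 atoms or rank < 2 (coincident/collinear) are
  rejected. Hydrogens are excluded everywhere by an atom-name filter.
* **RMSF reference** — deviations are measured from the time-average
  structure after one iterative fit pass (fit all frames to frame one,
  average, refit to the average). Per-residue values average the
  backbone C/CA/N atoms.
* **Finite-sample shrink** — fitting 6 rigid-body parameters and
  estimating the mean structure shrinks measured fluctuations: for
  isotropic per-coordinate noise σ on N atoms over F frames the
  expected per-atom RMSF is `σ√3·√(1 − 6/(3N) − 1/F)`, the closed form
  the tests check against (measured/expected ratio ≈ 1.000 at
  N = 300, F = 1000).
* **ΔRMSF and flagging** — ΔRMSF = RMSF(T) − RMSF(base), base defaulting
  to the lowest temperature label. Flagging computes the per-residue SD
  (ddof = 1) *across* the set of ΔRMSF profiles and selects SD > 0.5 Å:
  it detects temperature-*dependent* fluctuation, so a residue equally
  elevated at every temperature is deliberately not flagged.
* **Regions** — flagged residues merge into maximal intervals tolerating
  gaps ≤ 2 residues; intervals spanning < 2 residues are dropped as
  isolated flags. The motivating study describes regions verbally; these
  two parameters are this package's operationalisation and are
  adjustable.
* **PCA** — eigendecomposition of the 3N×3N covariance of superposed Cα
  coordinates; variance proportions are λᵢ/Σλ over the full spectrum;
  per-residue contribution is the squared norm of the residue's three
  eigenvector entries (summing to 1 per component). The tests verify the
  eigenstructure against an independent SVD route to 1e-8. k must not
  exceed the covariance rank min(F−1, 3N).

## Synthetic data: what it does and does not show

The generators reproduce the *summary statistics* the study reports —
first-order decay at the published k_d, Gaussian measurement noise at
the pilot SD, batch-level scatter of E₀, Michaelis–Menten velocities at
the published parameters, and isotropic Gaussian structural fluctuation.
Real data depart from this in ways the tests therefore cannot probe:
measurement noise may scale with activity rather than being additive,
deactivation may be multi-phase, humidity covaries with temperature, and
real MD ensembles have correlated, anisotropic, non-Gaussian modes (the
published PC1 variance fractions of 12–19% reflect such correlation;
isotropic noise spreads variance thinly by symmetry). Passing
recovery tests demonstrates the estimators are correct and unbiased
under the stated model, not that the model captures every feature of
laboratory data. Negative noise draws are truncated at zero with a
logged count; truncated vials are excluded from log-scale fits.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to keep full
recovery experiments comfortable on one CPU: 15 vials per time point
(the allocation actually measured per month in the motivating design is
71 across three batches), 100 seeds for recovery distributions, 2000
design-coverage replicates, 200 kinetics replicates, and trajectories
of 100 residues × 1000 frames (the motivating simulations used ~500
residues × 1000 frames). All scale linearly if larger runs are wanted.
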