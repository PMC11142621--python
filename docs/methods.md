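# Methods

## Model and estimator

Observations in group k are assumed i.i.d. N(0, Σ₀[k]) with precision
matrix Θ₀[k] = Σ₀[k]⁻¹; a zero off-diagonal entry encodes conditional
independence of the two variables given the rest.  The fused graphical
lasso (FGL) jointly minimizes the penalized negative log-likelihood

    Σ_k { tr(Σ̂[k]Θ[k]) − log det Θ[k] }
      + λ Σ_k ‖offdiag(Θ[k])‖₁ + ρ Σ_{k<k'} ‖offdiag(Θ[k] − Θ[k'])‖₁

over symmetric positive-definite Θ[k].  Only off-diagonals are penalized —
diagonals are neither shrunk nor fused.  The likelihood term is *unscaled*
by n_k; sample size enters through the covariance itself and, explicitly,
through the AIC used for tuning.  Sample covariances are (1/n)Σᵢ xᵢxᵢᵀ,
optionally centered (centering is off in simulations, where the mean is
zero by construction, and on by default for real data).

### ADMM

Scaled consensus ADMM with step μ (default 1):

* **Θ-update** (per group): minimize tr(SΘ) − logdet Θ + (μ/2)‖Θ − C‖²_F
  with C = Z − U.  Eigendecompose μC − S = VDVᵀ; the minimizer has
  eigenvalues (dᵢ + √(dᵢ² + 4μ))/(2μ) — always symmetric positive definite.
* **Z-update**: entrywise exact fused-lasso prox (below) on Θ + U with
  penalties λ/μ, ρ/μ; diagonals pass through.
* **U-update**: U ← U + Θ − Z.

Convergence is declared when the Frobenius primal residual ‖Θ − Z‖ and dual
residual μ‖Z − Zold‖ both fall below 1e-5·p (defaults; max_iter 1000).  A
non-converged solve returns `converged=False` and logs a warning.  The
estimate Θ is dense to machine precision; the reported support (exact
zeros) is read from the consensus Z.

### Fused-lasso prox

The Z-subproblem per entry is min_z ½Σ(z_k−a_k)² + λ'Σ|z_k| +
ρ'Σ_{k<k'}|z_k−z_k'|.  It is solved by composing the fusion-only prox with
soft-thresholding by λ' — exact because soft-thresholding is monotone, so
it can only enlarge the fusion term's subdifferential.  The fusion-only
prox preserves the ordering of the inputs, so the optimum realizes one of
the 2^(K−1) contiguous partitions of the sorted values into fused blocks;
a block spanning positions with n_lower points below and n_higher above
takes the value mean(block) − ρ'(n_lower − n_higher).  All candidates are
enumerated, infeasible (non-monotone) ones discarded, and the objective
minimizer selected — exact for any K and cheap for the K ≤ 3 settings used
here.  K = 2 uses the closed form: fuse to the exact midpoint when
|a₁−a₂| ≤ 2ρ', otherwise move each value ρ' toward the other.  Fused
entries share one bitwise-identical value, which is what lets the KKT
diagnostic classify ties exactly.

### Weighted variant

The weighted FGL penalizes entries on the correlation scale: solve the
plain problem on R̂[k] = Ŵ[k]⁻¹Σ̂[k]Ŵ[k]⁻¹ (Ŵ = diag(Σ̂)^½) to get Θ̂_R[k],
then Θ̂_w[k] = Ŵ[k]⁻¹Θ̂_R[k]Ŵ[k]⁻¹.  The identity Θ̂_R = ŴΘ̂_wŴ is taken as
definitional.  In the weighted test, de-biasing uses Θ̂_w together with the
*covariance* Σ̂ (not R̂), and the variance plug-in uses Θ̂_w.

### KKT diagnostic

At an optimum, Σ̂[k] − Θ̂[k]⁻¹ must be cancelled by a subgradient of the
off-diagonal penalty.  The diagnostic fixes the subgradient where the
consensus pins it (λ·sign at nonzeros, ρ·sign at unequal fused pairs),
grants the corresponding slack interval at zeros/ties (classified with a
1e-9 tolerance), and reports the per-group maximum violation.  Diagonal
entries must satisfy exact stationarity.

## Inference

De-biased estimator: Θ_d[k] = 2Θ̂[k] − Θ̂[k]Σ̂[k]Θ̂[k], symmetrized as
(M+Mᵀ)/2.  For the contrast a = (a₁,…,a_K), the statistic
T_ij = Σ_k a_k(Θ_d[k])_ij is standardized by
se_ij = √(Σ_k a_k²[Θ̂_iiΘ̂_jj + Θ̂_ij²]/n_k); two-sided p-values come from
N(0,1) and CIs are T ± ξ_{α/2}·se with the exact normal quantile
(1.959964… at α = 0.05, not the rounded 1.96).  Two interpretation choices:

* The rejection rule standardizes by σ̂ (the standard error), not σ̂²; the
  variance form is treated as a typo since the CLT and the CI formula both
  use σ̂.
* With unequal group sizes the per-group scaling Σ_k a_k²(·)/n_k is used;
  it reduces to the common √n scaling when all n_k are equal (the theory
  assumes equal sizes; real data rarely comply).

No multiple-testing correction is applied by default — the method's output
is the raw entrywise p-value matrix.  A Benjamini–Hochberg helper is
provided as an optional extension for edge discovery.

## Synthetic ground truth

`generate_precision(p, α̃, seed)` builds a random symmetric graph G with
exactly round(α̃·p(p−1)/2) upper-triangle edges (sampled without
replacement — an exact proportion rather than i.i.d. Bernoulli, for
reproducibility), fills edge (i,j) with m = (u_ij+u_ji)/2, U ~ U(0,1)^{p×p},
subtracting 1 when m < 0.5 so every nonzero weight has |θ| ∈ [0.5, 1) —
signal bounded away from zero.  Non-edges are exactly zero: the
subtract-one rule applies only where g_ij = 1 (applying it to non-edges
would make the matrix dense, defeating the construction's purpose).  The
diagonal shift |Λ_min(Θ̃)| + 0.1 makes the smallest eigenvalue exactly 0.1.

Null scenarios: **equal** (Θ₀[2] = Θ₀[1]), **linear** (Θ₀[2] = c·Θ₀[1],
default c = 0.5, null contrast (1, −1/c)), and **three-sample linear**
(Θ₀[3] = c₁Θ₀[1] + c₂Θ₀[2], defaults (0.6, 0.9), null contrast
(c₁, c₂, −1)).  Coefficients must be positive so all matrices stay positive
definite.  Group samples are drawn from N(0, Θ₀[k]⁻¹) via the
eigendecomposition square root; one integer seed drives graph selection,
weights, and sampling through independent documented substreams
(`numpy.random.SeedSequence.spawn`).

What the generator does *not* emulate: non-Gaussian tails, heteroscedastic
measurement noise, hub/banded topologies, or unequal per-group truth
supports — so passing tests certify the method under its own assumptions,
not robustness to their violation.

## Simulation experiments

**Coverage** (`run_coverage_experiment`): per replication, draw a fresh
ground truth and dataset, fit the FGL, form 95% CIs for the null contrast
(true value zero at every entry), and record per-entry coverage.  Averages
are taken over the support S of the reference matrix — Θ₀[1] for
two-sample nulls, the c₁Θ₀[1] + c₂Θ₀[2] combination for three-sample — and
over Sᶜ.  S includes the diagonal (always nonzero); a toggle excludes it.
Redrawing the truth each replication is the reference behaviour (the
coverage frequency then averages over both sources of randomness); a
fixed-truth mode exists for comparison.  Non-converged replications are
redrawn and counted; more than 10% redraws is an error.

**Fluctuation** (`run_fluctuation_experiment`): the replication sample of
z_ij at chosen entries, with mean, variance and Kolmogorov–Smirnov distance
to N(0,1).

**Tuning inside the loop.** The reference configuration tunes (λ, ρ) by
AIC, AIC = Σ_k [n_k·tr(Σ̂[k]Θ̂[k]) − n_k·logdet Θ̂[k] + 2E_k] with E_k the
upper-triangle edge count of the consensus, over a 30-point grid per axis
from 0.05 to 0.3 (step 0.25/29 ≈ 0.0086; ties break to the smallest λ,
then ρ; the sweep warm-starts along ρ).  The exact AIC variant is an
assumption — the joint-graphical-lasso convention (fit term scaled by n_k,
2 per edge) is adopted.  A full grid per replication costs hours, so the
scaled-down experiment configuration fixes λ = ρ = √(log p / n) and runs
100 replications per cell at p = 100 — a few minutes per cell on one CPU.
Problem sizes in the test suite are chosen the same way: exact identities
at p ≤ 10, Monte-Carlo checks at p ∈ {30, 100} with 20–300 replications.

### Observed behaviour of the scaled-down configuration

With fixed rate-based penalties the equal-null coverage cells land within
about 0.01 of the AIC-tuned reference values, and most linear-null cells
within 0.02.  The sparse linear-null support cell (α̃ = 0.1, n = 200) sits
≈ 0.93–0.95 where the tuned reference is ≈ 0.91: fixed penalties shrink
more than AIC picks there, widening intervals.  Relatedly, the equal-null
standardized statistic is mildly under-dispersed (variance ≈ 0.65–0.8 at
off-diagonal entries) under strong penalization — consistent with the
reference experiments' own over-coverage (≈ 0.988 at nominal 0.95), which
implies the same deflation.  A strict KS test against N(0,1) at a few
hundred replications is therefore borderline at some entries, even though
histograms are visually normal.

## Numerical choices and degenerate inputs

* ADMM step μ = 1; tolerances 1e-5·p on both residuals; tie classification
  in the KKT diagnostic at 1e-9.
* ρ is ignored for K = 1; λ = ρ = 0 reproduces the unpenalized MLE when
  Σ̂ is invertible (and remains well-defined otherwise — the Θ-update's
  eigenvalue map is strictly positive).
* Zero or negative sample variances make the correlation transform
  (and hence the weighted variant) fail loudly.
* Matrices are validated symmetric to 1e-10 on construction; correlation
  inputs must have unit diagonal at the same tolerance.
* CSV reads use round-trip float parsing so write/read cycles are exact;
  missing values and non-numeric columns are rejected with row/column
  locations.

## Known limitations

* The entrywise tests are conservative under heavy penalization
  (over-coverage); calibrated size requires tuning close to the AIC
  optimum.
* Theory assumes equal group sizes; the per-group variance scaling for
  unequal n_k is a pragmatic extension without separate guarantees.
* No missing-data handling, no power analysis under alternatives, and no
  guarantees for non-Gaussian data.
* The K-group fusion prox enumerates 2^(K−1) candidates per entry — exact
  and fast for the intended K ≤ 4, but not meant for dozens of groups.
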