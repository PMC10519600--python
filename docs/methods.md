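# Methods

## Problem and model

A mechanistic ODE model ẋ(t) = f(x(t), u(t), p), observed through
functions y_i(t) = g_i(x(t), p) + ε_{i,t} with known Gaussian errors
ε_{i,t} ~ N(0, σ²_{i,t}), is replicated across n related cell types that
share the structure but may differ in parameter values.  Calibration
minimizes

    χ²(θ) = Σ_{i,t} [y*_{i,t} − y_i(t, θ)]² / (2 σ²_{i,t}),

with all rate-like parameters estimated on the log10 scale.  A designated
subset of parameters (the *specific* parameters) may differ between cell
types; for each such parameter p_i, cell type j carries a log fold change
r_i^(j) with

    log p_i^(j) = log p_i^(1) + r_i^(j),    r_i^(1) ≡ 0,

relative to a *technical reference* cell type (index 1 by convention).

## Clustered penalty

To discover which subsets of cell types share a parameter value without
predefining groups, the objective is amended to L = χ² + λ·ν with the
clustered-LASSO regularizer

    ν(r) = Σ_i Σ_{j<k} |r_i^(j) − r_i^(k)|^q,      0 < q ≤ 1,

summing over all n(n−1)/2 unordered cell-type pairs per parameter
(including pairs with the reference, where the term reduces to |r_i^(j)|^q).
Because every pair is penalized with the same strength, ν is invariant
under relabeling the reference — unlike the standard LASSO baseline
ν = Σ_{i,j} |r_i^(j)|^q, which penalizes only deviations from the
reference and cannot tie two non-reference cell types together except at
the origin.  The default exponent q = 0.8 (an L_q pseudonorm) produces a
gradient field that curves trajectories onto the equality manifolds
Δ = r_i^(j) − r_i^(k) = 0 at smaller λ than q = 1 does; both are supported.

## Optimization

The stacked residual vector contains one standardized data residual
(y* − y)/(√2 σ) per measurement — so its plain sum of squares equals χ²
literally — and one penalty residual ρ_m = √λ·|Δ_m|^{q/2} per pair term,
whose square is exactly λ|Δ_m|^q.  A Levenberg–Marquardt loop with 2-norm
step control minimizes the sum of squares using analytic Jacobians
obtained from forward sensitivities: the augmented system
Ṡ = (∂f/∂x)S + ∂f/∂θ, S(0) = ∂x(0)/∂θ is integrated per cell type (and
condition) with derivatives taken on the log10 scale
(∂/∂log10 p = ln 10 · p · ∂/∂p).  Adjoint methods are unnecessary at these
problem sizes.

The |Δ|^q terms are singular on the equality manifolds, which requires
four departures from a stock least-squares solver (and is why the loop is
custom — stock optimizers expose no hooks for mutating the Jacobian
mid-iteration or truncating steps):

1. **Step truncation.**  Each proposed step is scaled by the largest
   t ∈ (0, 1] such that no fold change and no pairwise difference changes
   sign; the first crossing lands exactly on its manifold.  Coincident
   crossings land simultaneously (whole-vector scaling, never
   per-coordinate clipping).
2. **On-manifold optimality.**  A pair with |Δ| < ε (ε = 1e-10) is
   optimally stuck when the data slope along e_l − e_n is dominated by λ
   times the penalty slope evaluated at ε (the true slope is infinite for
   q < 1).  Off-manifold directions require a vanishing total directional
   derivative; the base-parameter gradient must vanish as well.
3. **Sensitivity merging.**  For dominated pairs, the two Jacobian columns
   are replaced by their columnwise mean (the cluster-wide mean for chains
   of ≥ 3 cell types), so the next step moves the cluster jointly along
   the manifold.  Zeroing the columns instead (the rule appropriate for
   the standard LASSO) would freeze a nonzero cluster permanently and is
   retained only as an ablation (`merge_rule="zero"`); a signed
   maximum-of-absolute-values rule (`"max"`) is available for comparison.
   Clusters containing the reference are pinned by zeroing, since the
   reference fold change is identically 0 and not a parameter.
4. **Release.**  If the data slope at an active pair begins to dominate,
   the penalty residual's Jacobian row is zeroed for that pair so the
   iterates may leave the manifold and explore alternative optima.
   Releases are applied before merges; dominance is recomputed from the
   current gradients every iteration.

Numerical choices: integration uses LSODA with rtol = 1e-8, atol = 1e-10
(at least two orders tighter than optimizer termination); initial damping
1e-3; a step is accepted when achieved/predicted decrease exceeds 1e-4;
gradient tolerance 1e-6 on the directional-derivative scale; at most 500
iterations.  Because the achievable objective resolution is bounded by the
integration accuracy, convergence is also declared when the Gauss–Newton
model cannot decrease the objective by more than 1e-9·(1+|L|).  Trial
steps are evaluated with a cheap state-only integration; acceptance
compares two state-only objectives against each other so the small
systematic accuracy offset between the augmented and the plain system
cannot flip the sign of small true decreases (accepted-step monotonicity
therefore holds to ~1e-7 relative, the integration noise floor).  Penalty
values treat |Δ| < ε as exactly zero (so ν = 0 on the fully clustered
set), while residual and gradient rows clip |Δ| at ε before
exponentiation; the three are mutually consistent off-manifold, where
Σρ² = λν holds to machine precision.  The optimizer is deterministic; an
optional multistart draws perturbed starts from a seeded generator.

## Model selection

For a log-spaced λ grid (default 30 values spanning 1…10⁴; toy examples
use 10⁻¹…10³), each regularized optimum is computed with warm starts
ascending in λ (cold starts are available because new optima can appear
along the path).  Clusters are read off the optimum by union-find over
the relation |Δ| < ε, with |r| < ε tying a cell type to the reference;
chains merge transitively even if an indirect pair is slightly above ε.
Each cluster structure is then refit *without* regularization (nonzero
groups share one free fold change, the reference group is pinned at 0) to
remove the penalty's shrinkage bias, and compared against the
unconstrained fit by a likelihood-ratio test at α = 0.05.  The
parsimonious model is the largest-λ structure not rejected.

Degrees of freedom equal the number of constraints k: tying a nonzero
pair costs 1, setting r^(j) = r^(k) = 0 costs 2 (not 3, although three
pairwise relations then hold); equivalently k = (total fold changes) −
(free fold changes after constraining).  The complementary free-parameter
count m is reported alongside.  Two statistic conventions are provided:
the default compares D = χ²_constrained − χ²_full (on the half-weighted
χ²) against χ²_k, the convention under which the selection procedure was
originally described and validated; since −2Δlog L = 2Δχ², the
Wilks-exact variant (`scale_two=True`) doubles the statistic and is about
twice as strict, roughly halving the λ* it selects.  Structures with
k = 0 are accepted iff their statistic vanishes within tolerance.

## Synthetic data

`toy_scenario` emulates a three-cell-type exponential-decay experiment:
ẋ = −p·x, x(0) = 1, y = x, true log10 p = (−1.5, −1.3, −1.2) — fold
changes r^(2) = 0.2, r^(3) = 0.3, a nearly common "mutation" in cell
types 2 and 3 — with i.i.d. Gaussian noise σ = 10^−1.3 ≈ 0.0501.  The
time grid (t = 0…10, 11 points, one replicate) is a package choice: it
separates cell type 1 from {2, 3} cleanly while leaving the 2-vs-3
difference near the noise floor, the regime in which clustering is
informative.  The variant with the reference rate held at its known value
reproduces the two-dimensional (r^(2), r^(3)) landscape used for
illustration; the fully-free variant is the default for recovery studies.

`receptor_scenario` is a compact receptor-trafficking system (ligand
binding, internalization, recycling, degradation; 4 states, 8 parameters,
2 observables, dose-response × time design) with *planted* fold-change
clusters across n cell types, built for simulation studies of cluster
recovery.  It is a bespoke small model: it preserves the workflow
structure of published receptor benchmarks (multiple observables, doses,
partial identifiability — the off-rate is deliberately sloppy) without
reproducing any published parameterization.  `run_study` loops
generate → scan → tally and reports how often each fold change and each
pairwise difference is constrained to zero, against ground truth.

What the generators do **not** emulate: error-model estimation (σ is
known), replicate correlation structure, dosing schedules beyond constant
inputs, and model misspecification.  Passing tests therefore demonstrate
correct behavior of the estimator under its own assumptions, not
robustness to their violation.

## Problem sizes used in the test suite

The suite runs 100 toy recovery fits, a 50-realization toy selection
study (17-point λ grid), and a 3-realization receptor study
(3 cell types, 2 specific parameters, 8-point grid) — sizes chosen so the
stochastic assertions (majority selection, ≥ 80 % oracle agreement,
detection rates) have adequate margins while the whole suite stays
desk-scale.  The acceptance script averages 200 realizations.

## Known limitations

* With q < 1 the regularized objective is nonconvex; different starts can
  end on different manifolds.  Warm starting mitigates but does not
  remove path dependence.
* The on-manifold dominance test evaluates the penalty slope at ε, so for
  q < 1 an active pair is effectively never released (the true one-sided
  slope is infinite); release is mainly operative for q = 1.
* Near-manifold stalls can terminate with reason ``step-size`` when the
  remaining objective decrease falls below the integration noise floor;
  the endpoint is then accurate to that floor but the gradient criterion
  is not formally met.
* Cluster extraction trusts the optimizer to land exactly on manifolds
  (truncation guarantees this for crossings); an optimum *approached* but
  not crossed — possible for q = 1 at very large λ — may be missed at one
  grid point and picked up at the next.
* The LRT is asymptotic; at small sample sizes its level is approximate,
  and the default (unscaled) convention is conservative in the direction
  of sparser models.
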