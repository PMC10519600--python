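"""Trust-region least-squares optimization with nonsmooth penalty handling.

The objective L(θ) = χ²(θ) + λ·ν(r) is minimized as a stacked sum of squares
(data residuals + penalty residuals) by a Levenberg–Marquardt loop with
2-norm step control.  The |Δ|^q terms of the clustered penalty are singular
on the *equality manifolds* Δ = r_i^(j) − r_i^(k) = 0, which requires four
adaptations beyond a stock solver (none of which a stock solver exposes
hooks for):

* **step truncation** — the whole step is scaled back so that no fold
  change and no pairwise difference changes sign; if a crossing occurs the
  step lands exactly on the first manifold hit;
* **optimality on the manifold** — a pair with |Δ| < ε is optimally stuck
  there iff the data slope along e_l − e_n is dominated by λ times the
  penalty slope (evaluated at ε, where the true slope is infinite for
  q < 1);
* **mean-sensitivity merging** — dominated pairs have their two Jacobian
  columns replaced by the columnwise mean (cluster-wide mean for chains),
  so the next step moves the cluster jointly without leaving the manifold;
  clusters containing the technical reference are pinned by zeroing instead
  (the reference fold change is identically 0 and not a parameter);
* **release** — an active pair whose data slope dominates gets its penalty
  Jacobian row zeroed so the iterates may leave the manifold again.

Releases are applied before merges; dominance is recomputed for all pairs
from the current gradients in every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ModelError, MultiCellModel, ParameterVector
from .penalty import PairTerm, PenaltySpec, pair_terms, penalty_residuals, penalty_value
from .simulate import ATOL, RTOL, IntegrationError, chi_square, data_residuals

__all__ = [
    "OptimizerOptions",
    "ManifoldState",
    "FitResult",
    "truncate_step",
    "merge_sensitivities",
    "release_pair",
    "check_optimality",
    "optimize_regularized",
]


@dataclass(frozen=True)
class OptimizerOptions:
    """All optimizer defaults in one record.

    ``gtol`` applies on the directional-derivative scale of L; ``ftol``
    declares convergence when the Gauss–Newton model cannot decrease the
    objective by more than ``ftol``·(1+|L|) — the decrease achievable below
    the ODE-integration accuracy.  ``mu0`` is the initial
    Levenberg–Marquardt damping; a step is accepted when the
    achieved/predicted decrease ratio exceeds ``accept_ratio``.
    ``merge_rule`` selects the common-value rule for dominated clusters:
    ``"mean"`` (default), ``"max"`` (maximum-of-absolute-values), or
    ``"zero"`` (the standard-LASSO rule; ablation — cannot move a nonzero
    cluster jointly).
    """

    gtol: float = 1e-6
    ftol: float = 1e-9
    max_iter: int = 500
    mu0: float = 1e-3
    accept_ratio: float = 1e-4
    step_tol: float = 1e-12
    mu_max: float = 1e15
    merge_rule: str = "mean"
    rtol: float = RTOL
    atol: float = ATOL
    verbose: int = 0

    def __post_init__(self):
        if self.merge_rule not in ("mean", "max", "zero"):
            raise ValueError(f"unknown merge_rule {self.merge_rule!r}")


@dataclass
class ManifoldState:
    """Active-set bookkeeping at one parameter point.

    ``active`` lists (param, j, k) pairs with |Δ| < ε; ``dominated`` flags
    whether the on-manifold optimality inequality currently holds for each;
    ``active_zero`` lists fold-change names with |r| < ε.
    """

    active: list[tuple[str, int, int]] = field(default_factory=list)
    dominated: dict[tuple[str, int, int], bool] = field(default_factory=dict)
    active_zero: list[str] = field(default_factory=list)

    @property
    def n_active(self) -> int:
        return len(self.active)

    @property
    def all_dominated(self) -> bool:
        return all(self.dominated.values())


@dataclass
class FitResult:
    """Outcome of one regularized (or plain) fit."""

    params: ParameterVector
    chi2: float
    penalty: float  # ν(r)
    objective: float  # L = χ² + λν
    lam: float
    n_iter: int
    termination: str  # gradient | manifold | max-iter | step-size
    manifold: ManifoldState
    grad_norm: float
    spec: PenaltySpec
    log: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# the four manifold primitives
# ---------------------------------------------------------------------------


def truncate_step(
    v: ParameterVector,
    step: np.ndarray,
    terms: Sequence[PairTerm],
    epsilon: float = 1e-10,
) -> tuple[float, np.ndarray]:
    """Scale the whole step so no penalized difference changes sign.

    Returns the scalar fraction t ∈ (0, 1] and the truncated step t·step.
    The first crossing lands exactly on its manifold; coincident crossings
    land simultaneously (whole-vector scaling, never per-coordinate
    clipping).  Differences already on a manifold (|Δ| < ε) do not truncate.
    """
    t = 1.0
    for term in terms:
        d = term.delta(v.values)
        if abs(d) < epsilon:
            continue
        dd = term.delta(step)  # step is a plain offset: Δ moves by this much
        if d * (d + dd) < 0.0:
            t = min(t, -d / dd)
    return t, t * step


def merge_sensitivities(
    jac: np.ndarray,
    clusters: Sequence[tuple[Sequence[int], bool]],
    rule: str = "mean",
) -> np.ndarray:
    """Replace the Jacobian columns of each dominated cluster by a common
    value for every residual row.

    ``clusters`` is a list of (column indices, contains_reference).  For a
    cluster tied to the technical reference the common value must be zero
    (its members' fold changes are pinned at 0); otherwise the columnwise
    mean (or signed max-of-absolute-values under ``rule="max"``) is used,
    which lets the whole cluster keep moving jointly.
    """
    out = jac.copy()
    for cols, has_ref in clusters:
        cols = list(cols)
        if not cols:
            continue
        if has_ref or rule == "zero":
            out[:, cols] = 0.0
        elif rule == "max":
            block = out[:, cols]
            pick = np.argmax(np.abs(block), axis=1)
            common = block[np.arange(block.shape[0]), pick]
            out[:, cols] = common[:, None]
        else:  # mean
            out[:, cols] = out[:, cols].mean(axis=1, keepdims=True)
    return out


def release_pair(jac: np.ndarray, row: int, term: PairTerm) -> np.ndarray:
    """Zero the two member entries of one penalty residual's Jacobian row
    (data rows untouched), allowing exploration away from the manifold."""
    out = jac.copy()
    if term.index_l is not None:
        out[row, term.index_l] = 0.0
    if term.index_n is not None:
        out[row, term.index_n] = 0.0
    return out


# ---------------------------------------------------------------------------
# evaluation machinery
# ---------------------------------------------------------------------------


class _Eval:
    """Residuals, Jacobians and objective decomposition at one point."""

    def __init__(self, m, v, data, spec, conditions, rtol, atol):
        self.data_block = data_residuals(m, v, data, conditions, rtol, atol)
        self.pen_block = penalty_residuals(m, v, spec)
        self.chi2 = float(self.data_block.values @ self.data_block.values)
        self.nu, _ = penalty_value(m, v, spec)
        self.objective = self.chi2 + spec.lam * self.nu


def _objective_only(m, v, data, spec, conditions, rtol, atol) -> float:
    """L = χ² + λν without Jacobians (cheap trial-step evaluation)."""
    c2 = chi_square(m, v, data, conditions, rtol, atol)
    nu, _ = penalty_value(m, v, spec)
    return c2 + spec.lam * nu


def _analyze_manifold(
    m: MultiCellModel,
    v: ParameterVector,
    spec: PenaltySpec,
    ev: _Eval,
    terms: Sequence[PairTerm],
) -> tuple[ManifoldState, list[tuple[list[int], bool]], list[int]]:
    """Classify active pairs as dominated or released and build the merge
    clusters (union-find over dominated pairs, per parameter).

    Returns (state, clusters as (column indices, has_reference), released
    penalty-row indices).
    """
    eps = spec.epsilon
    n = m.n_free
    deltas = np.array([t.delta(v.values) for t in terms])
    active_idx = [i for i, d in enumerate(deltas) if abs(d) < eps]
    state = ManifoldState()
    for p in m.specific:
        for j in m.non_reference:
            if abs(v.values[m.fold_change_index(p, j)]) < eps:
                state.active_zero.append(f"r_{p}__{j}")
    if not active_idx or spec.lam == 0.0:
        for i in active_idx:
            t = terms[i]
            state.active.append((t.param, t.j, t.k))
            state.dominated[(t.param, t.j, t.k)] = True
        return state, [], []

    g_chi2 = 2.0 * ev.data_block.jac.T @ ev.data_block.values
    # penalty gradient from off-manifold terms only
    g_pen_na = np.zeros(n)
    for i, term in enumerate(terms):
        if i in active_idx:
            continue
        d = deltas[i]
        slope = spec.q * abs(d) ** (spec.q - 1.0) * np.sign(d)
        g_pen_na += term.direction(slope, -slope, n)
    resist_slope = spec.q * eps ** (spec.q - 1.0)
    dirs = {i: terms[i].direction(1.0, -1.0, n) for i in active_idx}

    released_rows: list[int] = []
    dominated_idx: list[int] = []
    for i in active_idx:
        term = terms[i]
        u = dirs[i]
        data_slope = float(g_chi2 @ u + spec.lam * (g_pen_na @ u))
        resist = spec.lam * resist_slope * sum(
            abs(float(u @ dirs[j])) for j in active_idx
            if terms[j].param == term.param
        )
        dom = abs(data_slope) < resist
        key = (term.param, term.j, term.k)
        state.active.append(key)
        state.dominated[key] = dom
        if dom:
            dominated_idx.append(i)
        else:
            released_rows.append(i)

    # union-find over dominated pairs, per parameter, nodes = cell types
    clusters: list[tuple[list[int], bool]] = []
    for p in m.specific:
        parent = {j: j for j in m.cell_types}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in dominated_idx:
            t = terms[i]
            if t.param == p:
                parent[find(t.j)] = find(t.k)
        groups: dict[int, list[int]] = {}
        for j in m.cell_types:
            groups.setdefault(find(j), []).append(j)
        for members in groups.values():
            if len(members) < 2:
                continue
            has_ref = m.reference in members
            cols = [
                m.fold_change_index(p, j) for j in members if j != m.reference
            ]
            clusters.append((cols, has_ref))
    return state, clusters, released_rows


def _effective_system(ev: _Eval, terms, clusters, released_rows, rule):
    """Stacked residual vector and manifold-adapted Jacobian."""
    res = np.concatenate([ev.data_block.values, ev.pen_block.values])
    jac = np.vstack([ev.data_block.jac, ev.pen_block.jac])
    n_data = len(ev.data_block.values)
    for i in released_rows:
        jac = release_pair(jac, n_data + i, terms[i])
    if clusters:
        jac = merge_sensitivities(jac, clusters, rule)
    return res, jac


def check_optimality(
    m: MultiCellModel,
    v: ParameterVector,
    data: pd.DataFrame,
    spec: PenaltySpec,
    options: OptimizerOptions = OptimizerOptions(),
    conditions: Mapping | None = None,
) -> tuple[bool, dict]:
    """Three-part optimality report at a parameter point.

    Converged iff (1) the effective objective gradient vanishes over the
    base parameters, and for every penalized pair either (2) the total
    directional derivative along e_l − e_n vanishes while |Δ| > ε, or
    (3) |Δ| ≤ ε and the data slope is strictly dominated by λ times the
    penalty slope (evaluated at ε).
    """
    ev = _Eval(m, v, data, spec, conditions, options.rtol, options.atol)
    terms = pair_terms(m, spec)
    state, clusters, released = _analyze_manifold(m, v, spec, ev, terms)
    res, jac = _effective_system(ev, terms, clusters, released, options.merge_rule)
    g = 2.0 * jac.T @ res
    nb = m.base.n_parameters
    report = {
        "grad_norm": float(np.max(np.abs(g))) if len(g) else 0.0,
        "base_grad_norm": float(np.max(np.abs(g[:nb]))) if nb else 0.0,
        "criterion_1": bool(nb == 0 or np.max(np.abs(g[:nb])) < options.gtol),
        "criterion_2": bool(np.max(np.abs(g), initial=0.0) < options.gtol),
        "criterion_3": state.all_dominated,
        "manifold": state,
    }
    converged = report["criterion_2"] and report["criterion_3"]
    return converged, report


# ---------------------------------------------------------------------------
# the optimizer loop
# ---------------------------------------------------------------------------


def optimize_regularized(
    m: MultiCellModel,
    data: pd.DataFrame,
    spec: PenaltySpec,
    start: ParameterVector,
    options: OptimizerOptions = OptimizerOptions(),
    conditions: Mapping | None = None,
    reduce: np.ndarray | None = None,
    fixed: Sequence[str] = (),
) -> FitResult:
    """Minimize L = χ² + λν over the free parameters.

    ``reduce`` (optional, n_free × n_reduced) reparameterizes the fit onto a
    linear subspace θ_full = R·θ_red — used for cluster-constrained refits
    with λ = 0; the manifold machinery is bypassed in that case and the
    returned parameters are expanded back to the full space.

    ``fixed`` names parameters held at their start value (e.g. a reference
    rate constant assumed known).

    Deterministic: no internal randomness.  The objective never increases
    across accepted steps.
    """
    if not np.all(np.isfinite(start.values)):
        raise ModelError("non-finite start vector")
    terms = pair_terms(m, spec)
    names = m.parameter_names
    fixed_idx = [names.index(f) for f in fixed]
    theta = start.values.copy()
    if reduce is not None:
        if spec.lam != 0.0:
            raise ModelError("reduced-space fits are only supported with lambda = 0")
        red = np.asarray(reduce, float)
        theta_red, _, _, _ = np.linalg.lstsq(red, theta, rcond=None)
        theta = red @ theta_red

    def vec(th):
        return ParameterVector(m.parameter_names, th)

    ev = _Eval(m, vec(theta), data, spec, conditions, options.rtol, options.atol)
    if not np.isfinite(ev.objective):
        raise ModelError(f"non-finite objective at start: {ev.objective}")
    # step acceptance compares state-only integrations against each other so
    # that the (tiny, systematic) accuracy offset between the augmented and
    # the plain system cannot flip the sign of small true decreases
    obj_ref = _objective_only(m, vec(theta), data, spec, conditions, options.rtol, options.atol)

    mu = options.mu0
    log: list[dict] = []
    termination = "max-iter"
    state = ManifoldState()
    grad_norm = np.inf
    n_iter = 0
    manifold_on = spec.lam > 0.0 and reduce is None

    for n_iter in range(1, options.max_iter + 1):
        v = vec(theta)
        if manifold_on:
            state, clusters, released = _analyze_manifold(m, v, spec, ev, terms)
        else:
            state, clusters, released = ManifoldState(), [], []
        res, jac = _effective_system(ev, terms, clusters, released, options.merge_rule)
        if fixed_idx:
            jac = jac.copy()
            jac[:, fixed_idx] = 0.0
        if reduce is not None:
            jac = jac @ red
        g = 2.0 * jac.T @ res
        grad_norm = float(np.max(np.abs(g), initial=0.0))
        B = jac.T @ jac
        h = jac.T @ res
        # Gauss-Newton achievable decrease h' B^+ h; stationarity at
        # numerical precision when it falls below ftol*(1+|L|)
        hb, *_ = np.linalg.lstsq(B, h, rcond=None)
        pred_gn = float(h @ hb)
        if state.all_dominated and (
            grad_norm < options.gtol
            or pred_gn < options.ftol * (1.0 + abs(ev.objective))
        ):
            termination = "manifold" if state.n_active else "gradient"
            break
        accepted = False
        while True:
            try:
                delta = np.linalg.solve(B + mu * np.eye(B.shape[0]), -h)
            except np.linalg.LinAlgError:
                delta, *_ = np.linalg.lstsq(B + mu * np.eye(B.shape[0]), -h, rcond=None)
            if reduce is not None:
                delta_full = red @ delta
            else:
                delta_full = delta
                # keep merged clusters exactly on their manifolds
                for cols, has_ref in clusters:
                    if has_ref or options.merge_rule == "zero":
                        delta_full[cols] = 0.0
                    else:
                        delta_full[cols] = delta_full[cols].mean()
            if manifold_on:
                t, delta_full = truncate_step(v, delta_full, terms, spec.epsilon)
            else:
                t = 1.0
            step_norm = float(np.linalg.norm(delta_full))
            if step_norm < options.step_tol * (1.0 + float(np.linalg.norm(theta))):
                termination = "step-size"
                break
            trial = theta + delta_full
            try:
                if np.max(np.abs(trial)) > 50.0:
                    raise IntegrationError("parameter point out of bounds", trial)
                trial_obj = _objective_only(
                    m, vec(trial), data, spec, conditions, options.rtol, options.atol
                )
                ok = np.isfinite(trial_obj)
            except IntegrationError:
                ok = False
            if ok:
                dred = delta_full if reduce is None else delta
                pred = float(-2.0 * res @ (jac @ dred) - dred @ (B @ dred))
                actual = obj_ref - trial_obj
                ratio = actual / pred if pred > 0 else (1.0 if actual > 0 else -1.0)
            else:
                ratio = -1.0
            if ok and ratio > options.accept_ratio:
                theta = trial
                obj_ref = trial_obj
                ev = _Eval(
                    m, vec(trial), data, spec, conditions, options.rtol, options.atol
                )
                r = min(max(ratio, 0.0), 1.0)
                mu = max(mu * max(1.0 / 3.0, 1.0 - (2.0 * r - 1.0) ** 3), 1e-14)
                accepted = True
                if options.verbose >= 2:
                    print(
                        f"  it {n_iter}: L={ev.objective:.8g} chi2={ev.chi2:.6g} "
                        f"nu={ev.nu:.6g} |step|={step_norm:.3g} t={t:.3g} "
                        f"active={state.n_active}"
                    )
                break
            mu *= 2.0
            if mu > options.mu_max:
                termination = "step-size"
                break
        log.append(
            {
                "iter": n_iter,
                "objective": ev.objective,
                "chi2": ev.chi2,
                "nu": ev.nu,
                "mu": mu,
                "grad_norm": grad_norm,
                "n_active": state.n_active,
                "accepted": accepted,
            }
        )
        if not accepted:
            break

    v = vec(theta)
    if manifold_on:
        state, _, _ = _analyze_manifold(m, v, spec, ev, terms)
    return FitResult(
        params=v,
        chi2=ev.chi2,
        penalty=ev.nu,
        objective=ev.objective,
        lam=spec.lam,
        n_iter=n_iter,
        termination=termination,
        manifold=state,
        grad_norm=grad_norm,
        spec=spec,
        log=log,
    )
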