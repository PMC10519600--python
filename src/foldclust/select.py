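"""Two-step model selection along the regularization path.

For each λ on a grid, the regularized optimum is computed (warm-started
from the previous λ), the cluster structure is read off the equality
manifolds (|r_i^(j) − r_i^(k)| < ε), and the model constrained to those
clusters is refit *without* regularization to obtain unbiased estimates.
A likelihood-ratio test compares each constrained refit against the
unconstrained fit and the parsimonious model is the one at the largest λ
that is not rejected at level α (default 0.05).  The default statistic is
D = χ²_constrained − χ²_full on the half-weighted χ² = Σ(y−y*)²/(2σ²),
compared against a χ²_k quantile with k = number of constraints — the
printed convention of the selection procedure this package implements.
Because −2Δlog L = 2Δχ² for the half-weighted χ², the Wilks-exact variant
multiplies the statistic by 2 (``scale_two=True``); it is stricter and
rejects cluster constraints roughly twice as readily.

Constraint counting follows the pairwise rule: tying a nonzero cluster
{j, k} removes one degree of freedom; setting r^(j) = r^(k) = 0 removes
two (not three, although three pairwise relations hold).  Equivalently
k_λ = (total fold changes) − (free fold changes after constraining); the
complementary free-parameter count m_λ is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelError, MultiCellModel, ParameterVector
from .penalty import PenaltySpec
from .optimize import FitResult, OptimizerOptions, optimize_regularized

__all__ = [
    "ClusterAssignment",
    "SelectionResult",
    "extract_clusters",
    "count_constraints",
    "constrained_refit",
    "lrt_select",
    "lambda_scan",
    "default_lambda_grid",
]


def default_lambda_grid(lo: float = 1.0, hi: float = 1e4, num: int = 30) -> np.ndarray:
    """Log-spaced λ grid; the default spans 1…10⁴ with 30 values."""
    return np.logspace(np.log10(lo), np.log10(hi), num)


@dataclass(frozen=True)
class ClusterAssignment:
    """Per specific parameter: a partition of cell types into groups sharing
    one fold-change value, with the zero group (value tied to 0) flagged.

    ``groups[param]`` is a tuple of sorted cell-type tuples covering all n
    cell types; ``zero_group[param]`` indexes the group whose common value
    is 0 (always present: the reference cell type belongs to it).
    """

    groups: Mapping[str, tuple[tuple[int, ...], ...]]
    zero_group: Mapping[str, int]

    def n_free_fold_changes(self) -> int:
        """One shared value per nonzero group."""
        return sum(
            len(gs) - 1 for gs in self.groups.values()
        )

    def is_zero(self, param: str, cell_type: int) -> bool:
        gi = self.zero_group[param]
        return cell_type in self.groups[param][gi]

    def same_group(self, param: str, j: int, k: int) -> bool:
        return any(j in g and k in g for g in self.groups[param])


def extract_clusters(
    m: MultiCellModel, v: ParameterVector, epsilon: float = 1e-10
) -> ClusterAssignment:
    """Read the cluster structure off a regularized optimum.

    Transitive closure (union-find) of the pairwise relation
    |r_i^(j) − r_i^(k)| < ε, with |r| < ε tying a cell type to the
    reference; chains merge even if an indirect pair is slightly above ε
    (documented convention).
    """
    groups = {}
    zero = {}
    for p in m.specific:
        r = np.zeros(m.n_cell_types + 1)
        for j in m.non_reference:
            r[j] = v.values[m.fold_change_index(p, j)]
        r[m.reference] = 0.0
        parent = {j: j for j in m.cell_types}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for j in m.cell_types:
            for k in range(j + 1, m.n_cell_types + 1):
                if abs(r[j] - r[k]) < epsilon:
                    parent[find(j)] = find(k)
        by_root: dict[int, list[int]] = {}
        for j in m.cell_types:
            by_root.setdefault(find(j), []).append(j)
        gs = tuple(tuple(sorted(g)) for g in by_root.values())
        gs = tuple(sorted(gs))
        groups[p] = gs
        zero[p] = next(i for i, g in enumerate(gs) if m.reference in g)
    return ClusterAssignment(groups, zero)


def count_constraints(clusters: ClusterAssignment, m: MultiCellModel) -> int:
    """Number of equality constraints k imposed by a cluster assignment —
    the degrees of freedom of the likelihood-ratio test.

    k = (total fold changes) − (free fold changes after constraining); a
    nonzero cluster of size s removes s−1, the zero group of size s
    removes s−1 fold changes entirely (the reference contributes none).
    """
    return m.n_fold_changes - clusters.n_free_fold_changes()


def free_parameter_count(clusters: ClusterAssignment, m: MultiCellModel) -> int:
    """The complementary count m_λ of remaining free fold changes."""
    return clusters.n_free_fold_changes()


def _reduction_matrix(
    m: MultiCellModel, clusters: ClusterAssignment
) -> tuple[np.ndarray, list[str]]:
    """θ_full = R·θ_red mapping base parameters plus one shared fold change
    per nonzero cluster group (zero group pinned at 0)."""
    nb = m.base.n_parameters
    red_names = list(m.base.parameters)
    cols: list[np.ndarray] = []
    for i in range(nb):
        e = np.zeros(m.n_free)
        e[i] = 1.0
        cols.append(e)
    for p in m.specific:
        gi_zero = clusters.zero_group[p]
        for gi, g in enumerate(clusters.groups[p]):
            if gi == gi_zero:
                continue
            e = np.zeros(m.n_free)
            for j in g:
                e[m.fold_change_index(p, j)] = 1.0
            cols.append(e)
            red_names.append(f"r_{p}__group{gi}")
    return np.column_stack(cols), red_names


def constrained_refit(
    m: MultiCellModel,
    data: pd.DataFrame,
    clusters: ClusterAssignment,
    start: ParameterVector,
    options: OptimizerOptions = OptimizerOptions(),
    conditions: Mapping | None = None,
    fixed: Sequence[str] = (),
    epsilon: float = 1e-10,
) -> FitResult:
    """Refit without regularization under the cluster constraints, so the
    parameter estimates are unbiased by the penalty.

    Each nonzero cluster shares one free fold-change value; the zero group
    is pinned at 0.  With all-singleton clusters this is the unconstrained
    fit.
    """
    R, _ = _reduction_matrix(m, clusters)
    spec = PenaltySpec(lam=0.0, epsilon=epsilon)
    return optimize_regularized(
        m, data, spec, start, options, conditions, reduce=R, fixed=fixed
    )


@dataclass
class SelectionResult:
    """λ-scan outcome: one row of diagnostics per λ plus the selection."""

    lambdas: np.ndarray
    clusters: list[ClusterAssignment]
    regularized_fits: list[FitResult]
    refits: list[FitResult]
    constraint_counts: list[int]
    statistics: list[float]
    p_values: list[float]
    rejected: list[bool]
    alpha: float
    full_fit: FitResult
    selected_index: int | None

    @property
    def selected_lambda(self) -> float | None:
        if self.selected_index is None:
            return None
        return float(self.lambdas[self.selected_index])

    @property
    def selected_clusters(self) -> ClusterAssignment | None:
        """Clusters of the parsimonious model (None if every λ was rejected,
        i.e. the unconstrained model stands)."""
        if self.selected_index is None:
            return None
        return self.clusters[self.selected_index]

    @property
    def selected_refit(self) -> FitResult:
        if self.selected_index is None:
            return self.full_fit
        return self.refits[self.selected_index]

    def path_table(self, m: MultiCellModel) -> pd.DataFrame:
        """Regularization path: λ against every fold change and pairwise
        difference (for path plots)."""
        rows = []
        for lam, fit in zip(self.lambdas, self.regularized_fits):
            row = {"lambda": lam}
            for p in m.specific:
                vals = {m.reference: 0.0}
                for j in m.non_reference:
                    vals[j] = fit.params.values[m.fold_change_index(p, j)]
                    row[f"r_{p}__{j}"] = vals[j]
                for j in m.cell_types:
                    for k in range(j + 1, m.n_cell_types + 1):
                        row[f"d_{p}__{j}_{k}"] = vals[j] - vals[k]
            rows.append(row)
        return pd.DataFrame(rows)


def lrt_select(
    refits: Sequence[FitResult],
    constraint_counts: Sequence[int],
    full_fit: FitResult,
    alpha: float = 0.05,
    scale_two: bool = False,
) -> tuple[int | None, list[float], list[float], list[bool]]:
    """Likelihood-ratio test per λ and choice of the parsimonious model.

    The statistic D = χ²_constrained − χ²_full (with ``scale_two=True``
    multiplied by 2, converting the half-weighted χ² to the Wilks-exact
    −2Δlog L) is compared against the upper-α χ²_k quantile,
    k = number of constraints.  Unconstrained models (k = 0) are accepted
    iff their statistic is zero within numerical tolerance.  Returns the
    index of the largest-λ non-rejected model.
    """
    if len(refits) == 0:
        raise ModelError("empty scan: no refits to select from")
    factor = 2.0 if scale_two else 1.0
    stats_, pvals, rej = [], [], []
    for fit, k in zip(refits, constraint_counts):
        d = factor * (fit.chi2 - full_fit.chi2)
        stats_.append(d)
        if k <= 0:
            tol = 1e-6 * (1.0 + abs(full_fit.chi2)) * factor
            p = 1.0 if d <= tol else 0.0
            pvals.append(p)
            rej.append(d > tol)
        else:
            p = float(stats.chi2.sf(max(d, 0.0), k))
            pvals.append(p)
            rej.append(p < alpha)
    selected = None
    for i in range(len(refits) - 1, -1, -1):
        if not rej[i]:
            selected = i
            break
    return selected, stats_, pvals, rej


def lambda_scan(
    m: MultiCellModel,
    data: pd.DataFrame,
    spec_template: PenaltySpec,
    lambda_grid: Sequence[float],
    start: ParameterVector,
    options: OptimizerOptions = OptimizerOptions(),
    conditions: Mapping | None = None,
    fixed: Sequence[str] = (),
    alpha: float = 0.05,
    warm_start: bool = True,
    scale_two: bool = False,
    full_fit: FitResult | None = None,
) -> SelectionResult:
    """Full two-step selection: regularized scan → clusters → constrained
    refits → likelihood-ratio tests → parsimonious model.

    λ values are visited in ascending order; with ``warm_start`` each fit
    starts from the previous λ's endpoint (the first from the λ = 0
    optimum).  ``spec_template`` supplies q, ε and mode; its λ is ignored.
    """
    lambdas = np.sort(np.asarray(lambda_grid, float))
    if full_fit is None:
        full_fit = optimize_regularized(
            m, data, spec_template.with_lambda(0.0), start, options, conditions,
            fixed=fixed,
        )
    prev = full_fit.params
    clusters_l, regs, refits, kcounts = [], [], [], []
    for lam in lambdas:
        if lam == 0.0:
            fit = full_fit
        else:
            fit = optimize_regularized(
                m, data, spec_template.with_lambda(lam),
                prev if warm_start else full_fit.params,
                options, conditions, fixed=fixed,
            )
        if warm_start:
            prev = fit.params
        cl = extract_clusters(m, fit.params, spec_template.epsilon)
        refit = constrained_refit(
            m, data, cl, fit.params, options, conditions, fixed,
            spec_template.epsilon,
        )
        clusters_l.append(cl)
        regs.append(fit)
        refits.append(refit)
        kcounts.append(count_constraints(cl, m))
    selected, stats_, pvals, rej = lrt_select(
        refits, kcounts, full_fit, alpha, scale_two
    )
    return SelectionResult(
        lambdas=lambdas,
        clusters=clusters_l,
        regularized_fits=regs,
        refits=refits,
        constraint_counts=kcounts,
        statistics=stats_,
        p_values=pvals,
        rejected=rej,
        alpha=alpha,
        full_fit=full_fit,
        selected_index=selected,
    )
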