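"""Synthetic models and data generators.

Two study systems are provided, with all data generated programmatically:

* :func:`toy_scenario` — exponential decay ẋ = −p·x observed directly, three
  cell types with true log10 p = (−1.5, −1.3, −1.2), i.e. fold changes
  r^(2) = 0.2 and r^(3) = 0.3 with cell type 1 as reference, and Gaussian
  observation noise with σ = 10^−1.3 ≈ 0.0501.  Cell types 2 and 3 carry
  nearly the same decay rate (a "common mutation") clearly different from
  the reference.  The default time grid is t = 0…10 in 11 unit steps with
  one replicate per point, chosen so the unregularized fit separates cell
  type 1 from {2, 3} while the 2-vs-3 difference sits near the noise floor.

* :func:`receptor_scenario` — a small receptor-trafficking model (ligand
  binding, internalization, recycling, degradation; 4 states, 8 parameters,
  2 observables) replicated across n cell types with *planted* parameter
  clusters, observed on a dose-response × time design.  This is a bespoke
  compact system for simulation studies of cluster recovery, not a
  published benchmark model.

:func:`run_study` loops generate → λ-scan → tally, counting how often each
fold change and each pairwise difference is constrained to zero in the
selected parsimonious model, against the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    ModelError,
    MultiCellModel,
    OdeModel,
    ParameterVector,
    replicate_model,
)
from .optimize import OptimizerOptions
from .penalty import PenaltySpec
from .select import lambda_scan
from .simulate import simulate_observables

__all__ = [
    "SimulationScenario",
    "StudyTally",
    "toy_model",
    "toy_scenario",
    "receptor_model",
    "receptor_scenario",
    "run_study",
]

TOY_TRUE_LOGP = (-1.5, -1.3, -1.2)
TOY_LOG_SIGMA = -1.3


@dataclass
class SimulationScenario:
    """A fully specified simulated experiment.

    ``true_params`` is on the estimation (log10) scale.  ``generate()`` is
    deterministic in ``seed``: equal seeds give bit-identical tables.
    ``fixed`` names base parameters conventionally held at truth when
    fitting (empty for the fully-free variant).
    """

    model: MultiCellModel
    true_params: ParameterVector
    sigma: float
    times: np.ndarray
    replicates: int
    seed: int
    conditions: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    fixed: tuple[str, ...] = ()
    planted: Mapping[str, tuple[tuple[tuple[int, ...], float], ...]] | None = None

    def generate(self, noiseless: bool = False) -> pd.DataFrame:
        """Simulate the measurement table (long format)."""
        rng = np.random.default_rng(self.seed)
        rows = []
        cond_items = list(self.conditions.items()) or [("", None)]
        for ct in self.model.cell_types:
            for cond, inputs in cond_items:
                obs_names, y, _ = simulate_observables(
                    self.model, self.true_params, ct, self.times, inputs
                )
                for oi, obs in enumerate(obs_names):
                    for ti, t in enumerate(self.times):
                        for _ in range(self.replicates):
                            val = y[ti, oi]
                            if not noiseless:
                                val += rng.normal(0.0, self.sigma)
                            rows.append(
                                {
                                    "time": float(t),
                                    "observable": obs,
                                    "value": float(val),
                                    "sigma": self.sigma,
                                    "cell_type": ct,
                                    "condition": cond,
                                }
                            )
        return pd.DataFrame(rows)

    def start_vector(self) -> ParameterVector:
        """Conventional start point: true base parameters, all fold changes
        at zero (the shared-model starting guess)."""
        d = self.true_params.as_dict()
        for name in self.model.fold_change_names:
            d[name] = 0.0
        return ParameterVector.from_dict(self.model, d)

    def true_zero_flags(self, tol: float = 1e-12) -> dict[str, bool]:
        """Ground truth for every fold change ("r_<p>__<j>") and pairwise
        difference ("d_<p>__<j>_<k>"): True where it is exactly zero."""
        m = self.model
        flags = {}
        for p in m.specific:
            r = {m.reference: 0.0}
            for j in m.non_reference:
                r[j] = self.true_params.values[m.fold_change_index(p, j)]
                flags[f"r_{p}__{j}"] = bool(abs(r[j]) < tol)
            for j in m.cell_types:
                for k in range(j + 1, m.n_cell_types + 1):
                    flags[f"d_{p}__{j}_{k}"] = bool(abs(r[j] - r[k]) < tol)
        return flags


def toy_model() -> OdeModel:
    """Exponential decay of one species, observed directly."""
    return OdeModel(
        states=("x",),
        rhs={"x": "-p*x"},
        observables={"y": "x"},
        parameters=("p",),
        initials={"x": 1},
    )


def toy_scenario(
    seed: int,
    fix_reference: bool = False,
    n_times: int = 11,
    t_end: float = 10.0,
    replicates: int = 1,
    true_logp: Sequence[float] = TOY_TRUE_LOGP,
    log_sigma: float = TOY_LOG_SIGMA,
) -> SimulationScenario:
    """Three-cell-type decay scenario with a planted {2, 3} cluster.

    ``fix_reference=True`` marks the reference decay rate as known (held at
    truth during fitting), reducing the parameter space to the two fold
    changes — the setting of the illustrative two-dimensional landscape.
    """
    base = toy_model()
    m = replicate_model(base, len(true_logp), {"p"})
    d = {"p": float(true_logp[0])}
    for j in range(2, len(true_logp) + 1):
        d[f"r_p__{j}"] = float(true_logp[j - 1] - true_logp[0])
    v = ParameterVector.from_dict(m, d)
    planted = {
        "p": tuple(
            ((j,), float(true_logp[j - 1] - true_logp[0]))
            for j in range(1, len(true_logp) + 1)
        )
    }
    return SimulationScenario(
        model=m,
        true_params=v,
        sigma=float(10.0 ** log_sigma),
        times=np.linspace(0.0, t_end, n_times),
        replicates=replicates,
        seed=int(seed),
        fixed=("p",) if fix_reference else (),
        planted=planted,
    )


def receptor_model() -> OdeModel:
    """Compact receptor-trafficking system.

    Free surface receptor R binds ligand L (a constant-dose input) to form
    the surface complex C; C internalizes to Ci, which either recycles back
    to R or is degraded into the inert pool D.  Observed are the scaled
    surface amount (R + C) and the scaled internalized complex Ci.
    """
    return OdeModel(
        states=("R", "C", "Ci", "D"),
        rhs={
            "R": "-kon*L*R + koff*C + krec*Ci",
            "C": "kon*L*R - koff*C - ke*C",
            "Ci": "ke*C - krec*Ci - kdeg*Ci",
            "D": "kdeg*Ci",
        },
        observables={
            "surface": "scale_s*(R + C)",
            "internal": "scale_i*Ci",
        },
        parameters=("kon", "koff", "ke", "krec", "kdeg", "R0", "scale_s", "scale_i"),
        inputs=("L",),
        initials={"R": "R0"},
    )


_RECEPTOR_BASE_LOG10 = {
    "kon": 0.0,  # 1.0 /(conc·time)
    "koff": -1.0,  # 0.1 /time
    "ke": -0.5,  # 0.32 /time
    "krec": -1.0,  # 0.1 /time
    "kdeg": -0.7,  # 0.2 /time
    "R0": 0.0,  # 1.0 conc
    "scale_s": 0.0,
    "scale_i": 0.0,
}

_RECEPTOR_DEFAULT_CLUSTERS = {
    "R0": (((1, 4), 0.0), ((2, 3), 0.5), ((5,), -0.4)),
    "ke": (((1, 2, 3, 4, 5), 0.0),),
    "kdeg": (((1,), 0.0), ((2, 3, 4), 0.4), ((5,), 0.8)),
}


def receptor_scenario(
    n_cell_types: int = 5,
    planted_clusters: Mapping[str, Sequence[tuple[Sequence[int], float]]] | None = None,
    seed: int = 0,
    doses: Sequence[float] = (0.1, 1.0),
    times: Sequence[float] | None = None,
    sigma: float = 0.05,
) -> SimulationScenario:
    """Receptor-trafficking scenario with planted fold-change clusters.

    ``planted_clusters`` maps each cell-type specific parameter to a
    partition of 1…n with one fold-change value per group; the group
    containing cell type 1 (the reference) must carry the value 0.
    """
    if planted_clusters is None:
        planted_clusters = {
            p: tuple((tuple(g for g in grp if g <= n_cell_types), val) for grp, val in parts)
            for p, parts in _RECEPTOR_DEFAULT_CLUSTERS.items()
        }
        planted_clusters = {
            p: tuple((g, v) for g, v in parts if g)
            for p, parts in planted_clusters.items()
        }
    base = receptor_model()
    specific = tuple(planted_clusters)
    m = replicate_model(base, n_cell_types, specific)
    d = {p: _RECEPTOR_BASE_LOG10[p] for p in base.parameters}
    for p, parts in planted_clusters.items():
        if len(parts) > n_cell_types:
            raise ModelError(f"infeasible partition for {p!r}: more groups than cell types")
        seen: set[int] = set()
        for grp, val in parts:
            for j in grp:
                if j in seen or not 1 <= j <= n_cell_types:
                    raise ModelError(f"invalid partition for {p!r}")
                seen.add(j)
                if j == m.reference:
                    if val != 0.0:
                        raise ModelError(
                            f"reference group of {p!r} must carry fold change 0"
                        )
                else:
                    d[f"r_{p}__{j}"] = float(val)
        if seen != set(m.cell_types):
            raise ModelError(f"partition for {p!r} does not cover all cell types")
    v = ParameterVector.from_dict(m, d)
    if times is None:
        times = np.linspace(0.0, 8.0, 5)
    conditions = {f"dose_{dose:g}": {"L": float(dose)} for dose in doses}
    return SimulationScenario(
        model=m,
        true_params=v,
        sigma=float(sigma),
        times=np.asarray(times, float),
        replicates=1,
        seed=int(seed),
        conditions=conditions,
        planted={p: tuple((tuple(g), v_) for g, v_ in parts) for p, parts in planted_clusters.items()},
    )


@dataclass
class StudyTally:
    """Per fold change and pairwise difference: how often the selected
    parsimonious model constrained it to zero, with ground-truth flags."""

    counts: pd.DataFrame  # columns: quantity, n_zero, n_runs, truth_zero
    n_runs: int
    n_failures: int
    selections: list

    def rates(self) -> pd.DataFrame:
        """True/false positive rates per quantity ("positive" = constrained
        to zero)."""
        t = self.counts.copy()
        t["rate"] = t["n_zero"] / t["n_runs"].where(t["n_runs"] > 0, 1)
        return t


def run_study(
    scenario_factory: Callable[[int], SimulationScenario],
    n_datasets: int,
    lambda_grid: Sequence[float],
    mode: str = "clustered",
    q: float = 0.8,
    seed: int = 0,
    alpha: float = 0.05,
    options: OptimizerOptions = OptimizerOptions(),
    epsilon: float = 1e-10,
) -> StudyTally:
    """Simulation study: for ``n_datasets`` seeded realizations, run the
    λ-scan and count constrained-to-zero outcomes against ground truth.

    Individual run failures are recorded, not fatal.
    """
    if n_datasets < 1:
        raise ModelError("n_datasets must be >= 1")
    spec = PenaltySpec(q=q, lam=0.0, epsilon=epsilon, mode=mode)
    tally: dict[str, int] = {}
    truth: dict[str, bool] = {}
    n_counted = 0
    failures = 0
    selections = []
    for i in range(n_datasets):
        scen = scenario_factory(seed + i)
        truth = scen.true_zero_flags()
        m = scen.model
        data = scen.generate()
        try:
            res = lambda_scan(
                m, data, spec, lambda_grid, scen.start_vector(),
                options=options, conditions=scen.conditions, fixed=scen.fixed,
                alpha=alpha,
            )
        except Exception:
            failures += 1
            selections.append(None)
            continue
        cl = res.selected_clusters
        selections.append(res)
        n_counted += 1
        for p in m.specific:
            for j in m.non_reference:
                key = f"r_{p}__{j}"
                zero = cl is not None and cl.is_zero(p, j)
                tally[key] = tally.get(key, 0) + int(zero)
            for j in m.cell_types:
                for k in range(j + 1, m.n_cell_types + 1):
                    key = f"d_{p}__{j}_{k}"
                    same = cl is not None and cl.same_group(p, j, k)
                    tally[key] = tally.get(key, 0) + int(same)
    rows = [
        {
            "quantity": key,
            "n_zero": tally.get(key, 0),
            "n_runs": n_counted,
            "truth_zero": truth.get(key, False),
        }
        for key in sorted(truth)
    ]
    return StudyTally(
        counts=pd.DataFrame(rows),
        n_runs=n_counted,
        n_failures=failures,
        selections=selections,
    )
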