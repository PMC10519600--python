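"""ODE integration with forward sensitivities and data residuals.

The augmented system  ẋ = f,  Ṡ = (∂f/∂x)·S + ∂f/∂θ,  S(0) = ∂x(0)/∂θ  is
integrated per cell type (and experimental condition).  Sensitivities are
taken with respect to the estimation-scale parameters: for a log10-scale
parameter the chain rule gives ∂/∂log10 p = ln(10)·p·∂/∂p.  Local (per cell
type) sensitivity columns are mapped onto the global free-parameter vector
(base parameters + fold changes) through the linear fold-change transform.

Data residuals are standardized as  res = (y* − y) / (√2·σ)  so that the
optimizer's plain sum of squares equals the weighted least-squares objective
χ² = Σ (y* − y)² / (2σ²) literally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp

from .model import (
    ModelError,
    MultiCellModel,
    OdeModel,
    ParameterVector,
    natural_parameters,
)

__all__ = [
    "Trajectory",
    "ResidualBlock",
    "IntegrationError",
    "integrate_with_sensitivities",
    "simulate_observables",
    "data_residuals",
    "chi_square",
    "read_experiment_table",
    "write_experiment_table",
    "validate_experiment_table",
]

LN10 = float(np.log(10.0))

#: default integration tolerances; at least two orders of magnitude tighter
#: than the optimizer's termination tolerance.
RTOL = 1e-8
ATOL = 1e-10

TABLE_COLUMNS = ("time", "observable", "value", "sigma", "cell_type")


class IntegrationError(RuntimeError):
    """ODE integration failed (e.g. stiff blow-up) at a parameter point."""

    def __init__(self, message: str, parameters=None):
        super().__init__(message)
        self.parameters = parameters


@dataclass
class Trajectory:
    """States and sensitivities on a time grid.

    ``sens`` has shape (times × states × free parameters), with derivatives
    taken on the estimation (log10) scale of the global parameter vector.
    """

    times: np.ndarray
    states: np.ndarray  # (nt, nx)
    sens: np.ndarray  # (nt, nx, n_free)
    state_names: tuple[str, ...]


@dataclass
class ResidualBlock:
    """A stack of residuals with their Jacobian rows.

    ``jac[m, l] = ∂res_m/∂θ_l`` on the estimation scale; ``tag`` is
    ``"data"`` or ``"penalty"``; ``labels`` identifies each row for audit.
    """

    values: np.ndarray
    jac: np.ndarray
    tag: str
    labels: list

    def __post_init__(self):
        if self.jac.shape[0] != self.values.shape[0]:
            raise ValueError("Jacobian row count must equal residual count")


# ---------------------------------------------------------------------------
# symbolic compilation (cached per OdeModel instance)
# ---------------------------------------------------------------------------


class _Compiled:
    def __init__(self, model: OdeModel):
        x = sp.Matrix([sp.Symbol(s) for s in model.states])
        p = sp.Matrix([sp.Symbol(s) for s in model.parameters])
        u = sp.Matrix([sp.Symbol(s) for s in model.inputs]) if model.inputs else sp.Matrix([])
        f = sp.Matrix([model.rhs[s] for s in model.states])
        g = sp.Matrix([model.observables[o] for o in model.observables])
        x0 = sp.Matrix([model.initials[s] for s in model.states])
        args = (list(x), list(u), list(p))
        self.obs_names = tuple(model.observables)
        self.f = sp.lambdify(args, f, "numpy")
        self.jx = sp.lambdify(args, f.jacobian(x) if len(x) else f, "numpy")
        self.jp = sp.lambdify(args, f.jacobian(p), "numpy")
        self.g = sp.lambdify(args, g, "numpy")
        self.gx = sp.lambdify(args, g.jacobian(x), "numpy")
        self.gp = sp.lambdify(args, g.jacobian(p), "numpy")
        p_args = (list(u), list(p))
        self.x0 = sp.lambdify(p_args, x0, "numpy")
        self.dx0dp = sp.lambdify(p_args, x0.jacobian(p), "numpy")


# keyed by id(); the entry keeps a strong reference to the model so the id
# cannot be recycled for a different instance while cached
_CACHE: dict[int, tuple[OdeModel, _Compiled]] = {}


def _compiled(model: OdeModel) -> _Compiled:
    entry = _CACHE.get(id(model))
    if entry is None or entry[0] is not model:
        entry = _CACHE[id(model)] = (model, _Compiled(model))
    return entry[1]


def _local_scale(model: OdeModel, p_nat: np.ndarray) -> np.ndarray:
    """dp_natural/dθ_local per parameter (ln10·p for log10-scale, 1 else)."""
    return np.array(
        [
            LN10 * p_nat[i] if model.log_scale[name] else 1.0
            for i, name in enumerate(model.parameters)
        ]
    )


def _global_map(m: MultiCellModel, cell_type: int) -> np.ndarray:
    """(n_local × n_free) matrix M with ∂θ_local/∂θ_global entries (0/1)."""
    M = np.zeros((m.base.n_parameters, m.n_free))
    for i in range(m.base.n_parameters):
        M[i, i] = 1.0
    if cell_type != m.reference:
        for p in m.specific:
            i = m.base.parameters.index(p)
            M[i, m.fold_change_index(p, cell_type)] = 1.0
    return M


def _integrate_local(
    model: OdeModel,
    p_nat: np.ndarray,
    u_values: np.ndarray,
    times: np.ndarray,
    rtol: float,
    atol: float,
    with_sens: bool = True,
):
    """Integrate the augmented system; local sensitivities on the estimation
    scale.  Returns (x: (nt,nx), S: (nt,nx,np) or None)."""
    c = _compiled(model)
    nx, np_ = model.n_states, model.n_parameters
    scale = _local_scale(model, p_nat)
    u = list(u_values)
    pl = list(p_nat)
    x0 = np.asarray(c.x0(u, pl), float).ravel()

    if with_sens:
        S0 = np.asarray(c.dx0dp(u, pl), float).reshape(nx, np_) * scale

        def rhs(t, y):
            x = y[:nx]
            S = y[nx:].reshape(nx, np_)
            xl = list(x)
            dx = np.asarray(c.f(xl, u, pl), float).ravel()
            Jx = np.asarray(c.jx(xl, u, pl), float).reshape(nx, nx)
            Jp = np.asarray(c.jp(xl, u, pl), float).reshape(nx, np_) * scale
            dS = Jx @ S + Jp
            return np.concatenate([dx, dS.ravel()])

        y0 = np.concatenate([x0, S0.ravel()])
    else:

        def rhs(t, y):
            return np.asarray(c.f(list(y), u, pl), float).ravel()

        y0 = x0
    if times[-1] == 0.0:
        y = np.repeat(y0[None, :], len(times), axis=0)
    else:
        sol = solve_ivp(
            rhs,
            (0.0, float(times[-1])),
            y0,
            t_eval=times,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed: {sol.message} at p = {p_nat}", p_nat
            )
        y = sol.y.T
    x = y[:, :nx]
    if not with_sens:
        return x, None
    S = y[:, nx:].reshape(len(times), nx, np_)
    return x, S


def integrate_with_sensitivities(
    m: MultiCellModel,
    v: ParameterVector,
    cell_type: int,
    times: Sequence[float],
    inputs: Mapping[str, float] | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Solve the ODE and its forward sensitivities for one cell type.

    ``times`` must be sorted ascending and start at 0.  Sensitivities are
    returned with respect to every global free parameter; columns belonging
    to other cell types' fold changes are exactly zero.
    """
    times = np.asarray(times, float)
    if times.ndim != 1 or len(times) == 0 or np.any(np.diff(times) < 0):
        raise ModelError("times must be sorted ascending")
    if times[0] != 0.0:
        raise ModelError("times must start at 0")
    u = _input_vector(m.base, inputs)
    p_nat = natural_parameters(m, v, cell_type)
    x, S_local = _integrate_local(m.base, p_nat, u, times, rtol, atol)
    M = _global_map(m, cell_type)
    S = S_local @ M  # (nt, nx, n_free)
    return Trajectory(times, x, S, m.base.states)


def _input_vector(model: OdeModel, inputs: Mapping[str, float] | None) -> np.ndarray:
    inputs = inputs or {}
    missing = set(model.inputs) - set(inputs)
    if missing:
        raise ModelError(f"missing input values for {sorted(missing)}")
    return np.array([float(inputs[name]) for name in model.inputs])


def simulate_observables(
    m: MultiCellModel,
    v: ParameterVector,
    cell_type: int,
    times: Sequence[float],
    inputs: Mapping[str, float] | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
):
    """Observable values y_i(t) and their Jacobian ∂y/∂θ (global scale).

    Returns (obs_names, y: (nt, n_obs), dy: (nt, n_obs, n_free)).
    """
    times = np.asarray(times, float)
    traj = integrate_with_sensitivities(m, v, cell_type, times, inputs, rtol, atol)
    c = _compiled(m.base)
    p_nat = natural_parameters(m, v, cell_type)
    scale = _local_scale(m.base, p_nat)
    M = _global_map(m, cell_type)
    u = list(_input_vector(m.base, inputs))
    pl = list(p_nat)
    n_obs = len(c.obs_names)
    y = np.empty((len(times), n_obs))
    dy = np.empty((len(times), n_obs, m.n_free))
    for k in range(len(times)):
        xl = list(traj.states[k])
        y[k] = np.asarray(c.g(xl, u, pl), float).ravel()
        gx = np.asarray(c.gx(xl, u, pl), float).reshape(n_obs, m.base.n_states)
        gp = np.asarray(c.gp(xl, u, pl), float).reshape(n_obs, m.base.n_parameters)
        dy[k] = gx @ traj.sens[k] + (gp * scale) @ M
    return c.obs_names, y, dy


# ---------------------------------------------------------------------------
# experiment tables
# ---------------------------------------------------------------------------


def validate_experiment_table(data: pd.DataFrame, model: OdeModel | None = None) -> pd.DataFrame:
    """Check the long-format measurement table and return a normalized copy
    (adds a blank ``condition`` column when absent)."""
    if len(data) == 0:
        raise ModelError("experiment table is empty")
    missing = set(TABLE_COLUMNS) - set(data.columns)
    if missing:
        raise ModelError(f"experiment table missing columns {sorted(missing)}")
    data = data.copy()
    if "condition" not in data.columns:
        data["condition"] = ""
    else:
        data["condition"] = data["condition"].fillna("").astype(str)
    if (data["sigma"] <= 0).any():
        bad = data.loc[data["sigma"] <= 0].index[0]
        raise ModelError(f"non-positive sigma in experiment table (row {bad})")
    if model is not None:
        unknown = set(data["observable"]) - set(model.observables)
        if unknown:
            raise ModelError(f"observables not defined in model: {sorted(unknown)}")
    return data


def read_experiment_table(path) -> pd.DataFrame:
    """Read a tab-separated long-format table (time, observable, value,
    sigma, cell_type[, condition])."""
    data = pd.read_csv(path, sep="\t")
    return validate_experiment_table(data)


def write_experiment_table(data: pd.DataFrame, path) -> None:
    data.to_csv(path, sep="\t", index=False)


def data_residuals(
    m: MultiCellModel,
    v: ParameterVector,
    data: pd.DataFrame,
    conditions: Mapping[str, Mapping[str, float]] | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> ResidualBlock:
    """Standardized data residuals and their Jacobian.

    One residual per table row:  res = (y* − y(t,θ)) / (√2·σ), so that
    Σ res² equals χ².  ``conditions`` maps each value in the table's
    ``condition`` column to the constant input values of that experiment.
    """
    data = validate_experiment_table(data, m.base)
    values = np.empty(len(data))
    jac = np.zeros((len(data), m.n_free))
    labels = [None] * len(data)
    row_pos = {idx: k for k, idx in enumerate(data.index)}
    for (ct, cond), grp in data.groupby(["cell_type", "condition"], sort=False):
        ct = int(ct)
        inp = (conditions or {}).get(cond) if m.base.inputs else None
        tgrid = np.unique(np.concatenate([[0.0], grp["time"].to_numpy(float)]))
        obs_names, y, dy = simulate_observables(m, v, ct, tgrid, inp, rtol, atol)
        tpos = {t: k for k, t in enumerate(tgrid)}
        opos = {o: k for k, o in enumerate(obs_names)}
        for idx, row in grp.iterrows():
            k = row_pos[idx]
            ti, oi = tpos[float(row["time"])], opos[row["observable"]]
            w = 1.0 / (np.sqrt(2.0) * float(row["sigma"]))
            values[k] = (float(row["value"]) - y[ti, oi]) * w
            jac[k] = -dy[ti, oi] * w
            labels[k] = (row["observable"], float(row["time"]), ct, cond)
    return ResidualBlock(values, jac, "data", labels)


def chi_square(
    m: MultiCellModel,
    v: ParameterVector,
    data: pd.DataFrame,
    conditions=None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> float:
    """χ² = Σ (y* − y)²/(2σ²) at the parameter point ``v``.

    Integrates the plain (non-augmented) system — much cheaper than
    :func:`data_residuals` when no Jacobian is needed.
    """
    data = validate_experiment_table(data, m.base)
    c = _compiled(m.base)
    total = 0.0
    for (ct, cond), grp in data.groupby(["cell_type", "condition"], sort=False):
        ct = int(ct)
        inp = (conditions or {}).get(cond) if m.base.inputs else None
        u = _input_vector(m.base, inp)
        p_nat = natural_parameters(m, v, ct)
        tgrid = np.unique(np.concatenate([[0.0], grp["time"].to_numpy(float)]))
        x, _ = _integrate_local(m.base, p_nat, u, tgrid, rtol, atol, with_sens=False)
        ul, pl = list(u), list(p_nat)
        y = np.array([np.asarray(c.g(list(x[k]), ul, pl), float).ravel() for k in range(len(tgrid))])
        tpos = {t: k for k, t in enumerate(tgrid)}
        opos = {o: k for k, o in enumerate(c.obs_names)}
        for _, row in grp.iterrows():
            r = (float(row["value"]) - y[tpos[float(row["time"])], opos[row["observable"]]]) / (
                np.sqrt(2.0) * float(row["sigma"])
            )
            total += r * r
    return float(total)
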