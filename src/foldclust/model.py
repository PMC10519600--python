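"""Symbolic ODE models replicated across cell types.

An :class:`OdeModel` holds one cell type's structure: states with symbolic
right-hand sides f(x, u, p), constant-in-time inputs u (doses, stimuli),
observation functions g(x, p), and named parameters.  A
:class:`MultiCellModel` replicates that structure across ``n`` cell types
that share all parameters except a designated subset (the *specific*
parameters), which may differ between cell types.  On the log10 scale the
specific parameter of cell type ``j`` is

    log p_i^(j) = log p_i^(1) + r_i^(j),

where ``r_i^(j)`` is the log fold change relating cell type ``j`` to the
*technical reference* cell type (``r`` of the reference is identically 0 and
never a free parameter).  The free parameters of the joint model are the
reference-cell-type base parameters followed by the fold changes, in a fixed
flat ordering shared with all Jacobians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import sympy as sp

__all__ = [
    "OdeModel",
    "MultiCellModel",
    "ParameterVector",
    "ModelError",
    "replicate_model",
    "expand_parameters",
    "relabel_reference",
    "load_model",
    "load_model_file",
]

_TIME = sp.Symbol("t")


class ModelError(ValueError):
    """Raised for structurally invalid model specifications."""


def _sympify(expr, names: Iterable[str] = ()) -> sp.Expr:
    """Parse an expression with all model names bound to plain symbols (so
    state/parameter names can shadow sympy builtins like ``Ci`` or ``E``)."""
    if isinstance(expr, sp.Expr):
        return expr
    if isinstance(expr, (int, float)):
        return sp.sympify(expr, rational=False)
    local = {n: sp.Symbol(n) for n in names}
    local.setdefault("t", _TIME)
    return sp.sympify(expr, locals=local, rational=False)


@dataclass(frozen=True)
class OdeModel:
    """One cell type's ODE structure.

    Parameters flagged log-scale (the default) are estimated as log10 values
    and must be strictly positive on the natural scale; observation offsets
    and similar may opt out via ``log_scale``.
    """

    states: tuple[str, ...]
    rhs: Mapping[str, sp.Expr]
    observables: Mapping[str, sp.Expr]
    parameters: tuple[str, ...]
    inputs: tuple[str, ...] = ()
    initials: Mapping[str, sp.Expr] = field(default_factory=dict)
    log_scale: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "parameters", tuple(self.parameters))
        object.__setattr__(self, "inputs", tuple(self.inputs))
        names = self.states + self.parameters + self.inputs
        object.__setattr__(
            self, "rhs", {s: _sympify(e, names) for s, e in dict(self.rhs).items()}
        )
        object.__setattr__(
            self,
            "observables",
            {o: _sympify(e, names) for o, e in dict(self.observables).items()},
        )
        inits = {s: _sympify(self.initials.get(s, 0), names) for s in self.states}
        object.__setattr__(self, "initials", inits)
        ls = {p: bool(dict(self.log_scale).get(p, True)) for p in self.parameters}
        object.__setattr__(self, "log_scale", ls)
        self._validate()

    def _validate(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ModelError("duplicate state names")
        if len(set(self.parameters)) != len(self.parameters):
            raise ModelError("duplicate parameter names")
        if set(self.rhs) != set(self.states):
            raise ModelError("rhs must define exactly one expression per state")
        known = set(self.states) | set(self.parameters) | set(self.inputs) | {"t"}
        for name, expr in {**self.rhs, **self.observables}.items():
            for sym in expr.free_symbols:
                if str(sym) not in known:
                    raise ModelError(
                        f"unknown symbol {sym!r} in expression for {name!r}"
                    )
        allowed_init = set(self.parameters) | set(self.inputs)
        for name, expr in self.initials.items():
            for sym in expr.free_symbols:
                if str(sym) not in allowed_init:
                    raise ModelError(
                        f"initial of {name!r} references unknown symbol {sym!r}"
                    )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)


@dataclass(frozen=True)
class MultiCellModel:
    """An :class:`OdeModel` replicated across ``n_cell_types`` cell types.

    ``specific`` lists the parameters allowed to differ between cell types;
    each contributes one fold-change parameter per non-reference cell type.
    Cell types are 1-based; ``reference`` defaults to 1.
    """

    base: OdeModel
    n_cell_types: int
    specific: tuple[str, ...]
    reference: int = 1

    def __post_init__(self):
        object.__setattr__(self, "specific", tuple(self.specific))
        if self.n_cell_types < 2:
            raise ModelError("need at least 2 cell types")
        if not 1 <= self.reference <= self.n_cell_types:
            raise ModelError(f"reference {self.reference} outside 1..{self.n_cell_types}")
        unknown = set(self.specific) - set(self.base.parameters)
        if unknown:
            raise ModelError(f"specific parameters not in model: {sorted(unknown)}")
        for p in self.specific:
            if not self.base.log_scale[p]:
                raise ModelError(
                    f"specific parameter {p!r} must be log-scale (fold changes "
                    "are additive on the log scale)"
                )

    @property
    def cell_types(self) -> range:
        return range(1, self.n_cell_types + 1)

    @property
    def non_reference(self) -> tuple[int, ...]:
        return tuple(j for j in self.cell_types if j != self.reference)

    @property
    def fold_change_names(self) -> tuple[str, ...]:
        """Fold changes grouped by parameter, cell types ascending."""
        return tuple(
            f"r_{p}__{j}" for p in self.specific for j in self.non_reference
        )

    @property
    def parameter_names(self) -> tuple[str, ...]:
        """Flat free-parameter ordering: base parameters, then fold changes."""
        return self.base.parameters + self.fold_change_names

    @property
    def n_fold_changes(self) -> int:
        return len(self.specific) * (self.n_cell_types - 1)

    @property
    def n_free(self) -> int:
        return self.base.n_parameters + self.n_fold_changes

    def fold_change_index(self, param: str, cell_type: int) -> int:
        """Flat index (into ``parameter_names``) of ``r_param^(cell_type)``."""
        if cell_type == self.reference:
            raise ModelError("the reference cell type has no fold-change parameter")
        i = self.specific.index(param)
        j = self.non_reference.index(cell_type)
        return self.base.n_parameters + i * (self.n_cell_types - 1) + j


@dataclass
class ParameterVector:
    """Named flat parameter vector (base parameters on log10 scale unless the
    model flags them otherwise, fold changes always on log10 scale)."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.names = tuple(self.names)
        self.values = np.asarray(self.values, dtype=float).copy()
        if self.values.shape != (len(self.names),):
            raise ModelError("parameter vector length mismatch")

    @classmethod
    def from_dict(cls, m: MultiCellModel, d: Mapping[str, float]) -> "ParameterVector":
        names = m.parameter_names
        missing = set(names) - set(d)
        if missing:
            raise ModelError(f"incomplete parameter vector, missing {sorted(missing)}")
        return cls(names, np.array([d[n] for n in names], float))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[self.names.index(name)]

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.names, self.values)


def replicate_model(
    model: OdeModel,
    n: int,
    specific: Iterable[str],
    reference: int = 1,
) -> MultiCellModel:
    """Replicate ``model`` across ``n`` cell types sharing all parameters
    except ``specific``, which get one fold change per non-reference type."""
    return MultiCellModel(model, int(n), tuple(specific), int(reference))


def fold_changes(m: MultiCellModel, v: ParameterVector) -> dict[str, np.ndarray]:
    """Per specific parameter, the length-n vector of fold changes r^(j)
    (reference entry identically 0)."""
    out: dict[str, np.ndarray] = {}
    for p in m.specific:
        r = np.zeros(m.n_cell_types)
        for j in m.non_reference:
            r[j - 1] = v.values[m.fold_change_index(p, j)]
        out[p] = r
    return out


def expand_parameters(
    m: MultiCellModel, v: ParameterVector, cell_type: int
) -> dict[str, float]:
    """Per-cell-type parameter map on the estimation scale (log10 for
    log-scale parameters): specific parameter i is base_i + r_i^(cell_type);
    the reference cell type returns base values unchanged."""
    if not 1 <= cell_type <= m.n_cell_types:
        raise ModelError(f"cell type {cell_type} outside 1..{m.n_cell_types}")
    out = {p: v.values[i] for i, p in enumerate(m.base.parameters)}
    if cell_type != m.reference:
        for p in m.specific:
            out[p] += v.values[m.fold_change_index(p, cell_type)]
    return out


def natural_parameters(
    m: MultiCellModel, v: ParameterVector, cell_type: int
) -> np.ndarray:
    """Natural-scale parameter vector for ``cell_type`` in base declaration
    order (10**value for log-scale parameters)."""
    log_map = expand_parameters(m, v, cell_type)
    return np.array(
        [
            10.0 ** log_map[p] if m.base.log_scale[p] else log_map[p]
            for p in m.base.parameters
        ]
    )


def relabel_reference(
    m: MultiCellModel, new_reference: int, v: ParameterVector
) -> tuple[MultiCellModel, ParameterVector]:
    """Re-express the model/parameter point with another technical reference.

    The per-cell-type expanded parameters are numerically identical before
    and after: base_i' = base_i + r_i^(new), r_i^(j)' = r_i^(j) - r_i^(new).
    """
    if not 1 <= new_reference <= m.n_cell_types:
        raise ModelError(f"cell type {new_reference} outside 1..{m.n_cell_types}")
    m2 = replace(m, reference=new_reference)
    if new_reference == m.reference:
        return m2, v.copy()
    d = v.as_dict()
    out: dict[str, float] = {}
    for i, p in enumerate(m.base.parameters):
        out[p] = d[p]
    r_all = fold_changes(m, v)
    for p in m.specific:
        shift = r_all[p][new_reference - 1]
        out[p] = d[p] + shift
        for j in m2.non_reference:
            out[f"r_{p}__{j}"] = r_all[p][j - 1] - shift
    return m2, ParameterVector.from_dict(m2, out)


# ---------------------------------------------------------------------------
# Model specification files (nested key-value YAML)
# ---------------------------------------------------------------------------

_SECTIONS = ("states", "odes", "observables", "parameters")


def load_model(spec: Mapping) -> OdeModel:
    """Build an :class:`OdeModel` from a nested key-value mapping.

    Required sections: ``states`` (list), ``odes`` (state -> expression),
    ``observables`` (name -> expression), ``parameters`` (list of names, or
    name -> {log_scale: bool}).  Optional: ``inputs`` (list), ``initials``
    (state -> expression).
    """
    for sec in _SECTIONS:
        if sec not in spec:
            raise ModelError(f"model file missing section {sec!r}")
    params = spec["parameters"]
    if isinstance(params, Mapping):
        names = tuple(params)
        log_scale = {
            p: bool((params[p] or {}).get("log_scale", True)) for p in names
        }
    else:
        names = tuple(params)
        log_scale = {p: True for p in names}
    return OdeModel(
        states=tuple(spec["states"]),
        rhs=spec["odes"],
        observables=spec["observables"],
        parameters=names,
        inputs=tuple(spec.get("inputs", ()) or ()),
        initials=spec.get("initials", {}) or {},
        log_scale=log_scale,
    )


def load_model_file(path) -> OdeModel:
    """Load a model specification from a YAML file."""
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, Mapping):
        raise ModelError(f"model file {path} is not a mapping")
    return load_model(spec)
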