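"""Run configuration, validation, and results serialization.

Results are written as structured, human-diffable JSON with canonical
key ordering, so identical runs produce byte-identical files and every
file round-trips load → re-serialize unchanged.  The full configuration
(plus its hash) is recorded into every results file for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .model import ModelError, MultiCellModel, load_model, replicate_model
from .optimize import FitResult, OptimizerOptions
from .penalty import PenaltySpec
from .select import SelectionResult, free_parameter_count

__all__ = [
    "ConfigError",
    "load_config",
    "validate_config",
    "config_hash",
    "load_multicell_file",
    "build_penalty",
    "build_options",
    "lambda_grid_from_config",
    "fit_result_to_dict",
    "selection_result_to_dict",
    "write_json",
    "read_json",
]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


def _err(path: str, msg: str) -> str:
    return f"{path}: {msg}"


_PENALTY_FIELDS = {"mode", "q", "epsilon", "lambda", "lambda_grid"}
_OPT_FIELDS = {
    "gtol", "ftol", "max_iter", "mu0", "accept_ratio", "step_tol", "mu_max",
    "merge_rule", "rtol", "atol", "verbose",
}
_SEL_FIELDS = {"alpha", "scale_two", "warm_start"}
_FIT_FIELDS = {"fixed", "multistart", "seed", "start"}


def validate_config(cfg: Mapping[str, Any]) -> list[str]:
    """Collect human-readable validation errors (empty list = valid)."""
    errors: list[str] = []
    if not isinstance(cfg, Mapping):
        return ["config: not a mapping"]
    if "model" not in cfg:
        errors.append(_err("model", "required (path to model file)"))
    if "data" not in cfg:
        errors.append(_err("data", "required (path to experiment table)"))
    pen = cfg.get("penalty", {}) or {}
    for key in set(pen) - _PENALTY_FIELDS:
        errors.append(_err(f"penalty.{key}", "unknown field"))
    if "mode" in pen and pen["mode"] not in ("clustered", "standard"):
        errors.append(_err("penalty.mode", f"must be clustered|standard, got {pen['mode']!r}"))
    if "q" in pen and not (0 < float(pen["q"]) <= 1):
        errors.append(_err("penalty.q", f"must be in (0, 1], got {pen['q']}"))
    if "epsilon" in pen and float(pen["epsilon"]) <= 0:
        errors.append(_err("penalty.epsilon", "must be > 0"))
    if "lambda" in pen and float(pen["lambda"]) < 0:
        errors.append(_err("penalty.lambda", f"must be >= 0, got {pen['lambda']}"))
    grid = pen.get("lambda_grid")
    if grid is not None:
        if isinstance(grid, Mapping):
            for f in ("lo", "hi"):
                if f in grid and float(grid[f]) <= 0:
                    errors.append(_err(f"penalty.lambda_grid.{f}", "must be > 0"))
            if int(grid.get("num", 30)) < 2:
                errors.append(_err("penalty.lambda_grid.num", "need >= 2 values"))
        elif isinstance(grid, (list, tuple)):
            if any(float(x) < 0 for x in grid):
                errors.append(_err("penalty.lambda_grid", "negative value"))
        else:
            errors.append(_err("penalty.lambda_grid", "must be list or {lo, hi, num}"))
    opt = cfg.get("optimizer", {}) or {}
    for key in set(opt) - _OPT_FIELDS:
        errors.append(_err(f"optimizer.{key}", "unknown field"))
    if "merge_rule" in opt and opt["merge_rule"] not in ("mean", "max", "zero"):
        errors.append(_err("optimizer.merge_rule", "must be mean|max|zero"))
    sel = cfg.get("selection", {}) or {}
    for key in set(sel) - _SEL_FIELDS:
        errors.append(_err(f"selection.{key}", "unknown field"))
    if "alpha" in sel and not (0 < float(sel["alpha"]) < 1):
        errors.append(_err("selection.alpha", "must be in (0, 1)"))
    fit = cfg.get("fit", {}) or {}
    for key in set(fit) - _FIT_FIELDS:
        errors.append(_err(f"fit.{key}", "unknown field"))
    if "multistart" in fit and int(fit["multistart"]) < 1:
        errors.append(_err("fit.multistart", "must be >= 1"))
    return errors


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    errors = validate_config(cfg)
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def config_hash(cfg: Mapping) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_penalty(cfg: Mapping, lam: float | None = None) -> PenaltySpec:
    pen = cfg.get("penalty", {}) or {}
    return PenaltySpec(
        q=float(pen.get("q", 0.8)),
        lam=float(pen.get("lambda", 0.0) if lam is None else lam),
        epsilon=float(pen.get("epsilon", 1e-10)),
        mode=pen.get("mode", "clustered"),
    )


def build_options(cfg: Mapping) -> OptimizerOptions:
    opt = dict(cfg.get("optimizer", {}) or {})
    return OptimizerOptions(**opt)


def lambda_grid_from_config(cfg: Mapping) -> np.ndarray:
    pen = cfg.get("penalty", {}) or {}
    grid = pen.get("lambda_grid")
    if grid is None:
        if "lambda" in pen:
            return np.array([float(pen["lambda"])])
        return np.logspace(0.0, 4.0, 30)
    if isinstance(grid, Mapping):
        return np.logspace(
            np.log10(float(grid.get("lo", 1.0))),
            np.log10(float(grid.get("hi", 1e4))),
            int(grid.get("num", 30)),
        )
    return np.asarray([float(x) for x in grid])


def load_multicell_file(path) -> tuple[MultiCellModel, dict]:
    """Load a model file with a ``cell_types`` section into a
    :class:`MultiCellModel`; returns (model, conditions)."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, Mapping):
        raise ModelError(f"model file {path} is not a mapping")
    base = load_model(spec)
    ct = spec.get("cell_types")
    if not isinstance(ct, Mapping) or "n" not in ct or "specific" not in ct:
        raise ModelError("model file needs a cell_types section with n and specific")
    m = replicate_model(
        base, int(ct["n"]), tuple(ct["specific"]), int(ct.get("reference", 1))
    )
    conditions = spec.get("conditions", {}) or {}
    return m, conditions


# ---------------------------------------------------------------------------
# results serialization
# ---------------------------------------------------------------------------


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "parameters": {n: float(x) for n, x in zip(fit.params.names, fit.params.values)},
        "chi2": float(fit.chi2),
        "penalty_value": float(fit.penalty),
        "objective": float(fit.objective),
        "lambda": float(fit.lam),
        "penalty": {
            "q": fit.spec.q,
            "epsilon": fit.spec.epsilon,
            "mode": fit.spec.mode,
        },
        "n_iter": int(fit.n_iter),
        "termination": fit.termination,
        "grad_norm": float(fit.grad_norm),
        "manifold": {
            "active_pairs": [list(map(str, a)) for a in fit.manifold.active],
            "dominated": {"|".join(map(str, k)): bool(v) for k, v in fit.manifold.dominated.items()},
            "active_zero": list(fit.manifold.active_zero),
        },
        "iterations": [
            {k: (float(v) if isinstance(v, (int, float, np.floating)) and k != "iter" else v)
             for k, v in row.items()}
            for row in fit.log
        ],
    }


def selection_result_to_dict(res: SelectionResult, m: MultiCellModel) -> dict:
    per_lambda = []
    for i, lam in enumerate(res.lambdas):
        cl = res.clusters[i]
        per_lambda.append(
            {
                "lambda": float(lam),
                "clusters": {p: [list(g) for g in cl.groups[p]] for p in cl.groups},
                "zero_group": {p: int(cl.zero_group[p]) for p in cl.zero_group},
                "constraints_k": int(res.constraint_counts[i]),
                "free_fold_changes_m": int(free_parameter_count(cl, m)),
                "refit_chi2": float(res.refits[i].chi2),
                "statistic_D": float(res.statistics[i]),
                "p_value": float(res.p_values[i]),
                "rejected": bool(res.rejected[i]),
            }
        )
    sel = res.selected_clusters
    return {
        "alpha": float(res.alpha),
        "full_chi2": float(res.full_fit.chi2),
        "per_lambda": per_lambda,
        "selected_lambda": res.selected_lambda,
        "selected_clusters": None
        if sel is None
        else {p: [list(g) for g in sel.groups[p]] for p in sel.groups},
        "selected_refit": None
        if res.selected_index is None
        else fit_result_to_dict(res.selected_refit),
    }


def write_json(obj: Mapping, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
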