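"""Run-configuration parsing, validation and deterministic reports.

Configurations are flat YAML (JSON is valid YAML) with blocks ``model``,
``dropout``, ``problem``, ``cost``, ``simulation``, ``output`` and a top
level ``seed``.  Validation is strict: unknown keys are rejected and
errors name the offending key path.  Reports are deterministic — the
same inputs produce byte-identical output — and the text format mimics
the conventional design table: one row of time points per design, then
one expected-pattern-count row per group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .cost import CostModel
from .dropout import DropoutSpec, expected_pattern_counts
from .errors import ConfigError, LMMDesignError
from .information import Design, GroupDesign
from .lmm import CorrelationSpec, FixedEffectsSpec, LMMSpec, RandomEffectsSpec
from .search import DesignProblem, DesignSolution

__all__ = ["RunConfig", "load_config", "write_report", "design_to_dict", "design_from_dict"]

_TOP_KEYS = {"seed", "model", "dropout", "problem", "cost", "simulation", "output"}
_MODEL_KEYS = {"model", "c", "beta", "random_class", "d11", "d22", "d12",
               "sigma2", "corr_kind", "rho"}
_DROPOUT_KEYS = {"family", "coefficients", "baseline_certain"}
_PROBLEM_KEYS = {"time_region", "q", "condition", "fixed_times", "optimize_weights",
                 "fixed_doses", "dose_region", "N", "include_baseline_only",
                 "n_starts"}
_COST_KEYS = {"recruit_cost", "visit_cost", "budget"}
_SIM_KEYS = {"reps", "designs"}
_DESIGN_KEYS = {"times", "w1", "weights", "doses", "N"}
_OUTPUT_KEYS = {"path", "format"}


@dataclass
class RunConfig:
    """Validated configuration for one run."""

    seed: int = 0
    model: LMMSpec | None = None
    dropout: tuple[DropoutSpec, ...] | None = None
    problem: DesignProblem | None = None
    cost: CostModel | None = None
    reps: int = 10_000
    designs: dict[str, Design] = field(default_factory=dict)
    n_starts: int = 20
    output_path: str | None = None
    output_format: str = "json"


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    if not isinstance(block, dict):
        raise ConfigError(f"{where}: expected a mapping")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")


def _require(block: dict, key: str, where: str) -> Any:
    if key not in block:
        raise ConfigError(f"{where}.{key}: required key missing")
    return block[key]


def _build_model(block: dict) -> LMMSpec:
    _check_keys(block, _MODEL_KEYS, "model")
    try:
        fixed = FixedEffectsSpec(
            model=_require(block, "model", "model"),
            c=int(block.get("c", 2)),
            beta=tuple(block["beta"]) if block.get("beta") is not None else None,
        )
        random = RandomEffectsSpec(
            klass=block.get("random_class", "FE"),
            d11=float(block.get("d11", 0.0)),
            d22=float(block.get("d22", 0.0)),
            d12=float(block.get("d12", 0.0)),
        )
        corr = CorrelationSpec(
            kind=block.get("corr_kind", "independent"),
            rho=float(block.get("rho", 0.0)),
        )
        return LMMSpec(fixed=fixed, random=random,
                       sigma2=float(_require(block, "sigma2", "model")), corr=corr)
    except LMMDesignError as exc:
        raise ConfigError(f"model: {exc}") from exc


def _build_dropout(block: Any, c: int) -> tuple[DropoutSpec, ...]:
    blocks = block if isinstance(block, list) else [block]
    specs = []
    for i, b in enumerate(blocks):
        _check_keys(b, _DROPOUT_KEYS, f"dropout[{i}]")
        try:
            specs.append(
                DropoutSpec(
                    family=_require(b, "family", f"dropout[{i}]"),
                    coefficients=tuple(b.get("coefficients", ())),
                    baseline_certain=bool(b.get("baseline_certain", True)),
                )
            )
        except LMMDesignError as exc:
            raise ConfigError(f"dropout[{i}]: {exc}") from exc
    if len(specs) == 1:
        specs = specs * c
    if len(specs) != c:
        raise ConfigError(f"dropout: expected 1 or {c} specs, got {len(specs)}")
    return tuple(specs)


def _build_problem(
    block: dict, model: LMMSpec, dropout: tuple[DropoutSpec, ...]
) -> DesignProblem:
    _check_keys(block, _PROBLEM_KEYS, "problem")
    try:
        ft = block.get("fixed_times", {})
        if isinstance(ft, list):
            fixed_times: Any = tuple({int(k): float(v) for k, v in m.items()} for m in ft)
        else:
            fixed_times = {int(k): float(v) for k, v in ft.items()}
        fd = block.get("fixed_doses")
        return DesignProblem(
            model=model,
            dropout=dropout,
            time_region=tuple(float(x) for x in _require(block, "time_region", "problem")),
            q=int(_require(block, "q", "problem")),
            c=model.fixed.c,
            condition=block.get("condition", "restricted"),
            fixed_times=fixed_times,
            optimize_weights=bool(block.get("optimize_weights", True)),
            fixed_doses=None if fd is None else tuple(
                None if d is None else float(d) for d in fd
            ),
            dose_region=None if block.get("dose_region") is None else tuple(
                float(x) for x in block["dose_region"]
            ),
            N=int(block.get("N", 100)),
            include_baseline_only=bool(block.get("include_baseline_only", True)),
        )
    except LMMDesignError as exc:
        raise ConfigError(f"problem: {exc}") from exc


def design_from_dict(block: dict, name: str = "design") -> Design:
    """Build a Design from a config mapping (times, w1 or weights, doses, N)."""
    _check_keys(block, _DESIGN_KEYS, name)
    raw_times = _require(block, "times", name)
    n = int(_require(block, "N", name))
    if "weights" in block:
        weights = [float(w) for w in block["weights"]]
    else:
        w1 = float(_require(block, "w1", name))
        weights = [w1, 1.0 - w1]
    # a flat vector is a shared schedule; a list of lists is per group
    if raw_times and isinstance(raw_times[0], (list, tuple)):
        times = [np.asarray(t, dtype=float) for t in raw_times]
    else:
        times = [np.asarray(raw_times, dtype=float)] * len(weights)
    doses = block.get("doses", [0.0, 100.0][: len(weights)])
    try:
        groups = tuple(
            GroupDesign(t=t, w=w, dose=None if d is None else float(d))
            for t, w, d in zip(times, weights, doses)
        )
        return Design(groups=groups, N=n)
    except LMMDesignError as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def design_to_dict(design: Design) -> dict:
    return {
        "N": design.N,
        "times": [list(map(float, g.t)) for g in design.groups],
        "weights": [float(g.w) for g in design.groups],
        "doses": [None if g.dose is None else float(g.dose) for g in design.groups],
    }


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raise ConfigError(
            "empty config; required blocks include 'model' plus one of "
            "'problem', 'simulation' or 'cost'"
        )
    _check_keys(raw, _TOP_KEYS, "<top level>")
    cfg = RunConfig(seed=int(raw.get("seed", 0)))
    if "model" in raw:
        cfg.model = _build_model(raw["model"])
    if "dropout" in raw:
        if cfg.model is None:
            raise ConfigError("dropout: requires a model block")
        cfg.dropout = _build_dropout(raw["dropout"], cfg.model.fixed.c)
    if "problem" in raw:
        if cfg.model is None or cfg.dropout is None:
            raise ConfigError("problem: requires model and dropout blocks")
        cfg.problem = _build_problem(raw["problem"], cfg.model, cfg.dropout)
        cfg.n_starts = int(raw["problem"].get("n_starts", 20))
    if "cost" in raw:
        _check_keys(raw["cost"], _COST_KEYS, "cost")
        try:
            cfg.cost = CostModel(**{k: float(v) for k, v in raw["cost"].items()})
        except (TypeError, LMMDesignError) as exc:
            raise ConfigError(f"cost: {exc}") from exc
    if "simulation" in raw:
        _check_keys(raw["simulation"], _SIM_KEYS, "simulation")
        cfg.reps = int(raw["simulation"].get("reps", 10_000))
        for name, d in raw["simulation"].get("designs", {}).items():
            cfg.designs[name] = design_from_dict(d, f"simulation.designs.{name}")
    if "output" in raw:
        _check_keys(raw["output"], _OUTPUT_KEYS, "output")
        cfg.output_path = raw["output"].get("path")
        cfg.output_format = raw["output"].get("format", "json")
    return cfg


# --------------------------------------------------------------------------
# reports


def _solution_payload(sol: DesignSolution) -> dict:
    return {
        "design": design_to_dict(sol.design),
        "criterion_value": float(sol.criterion_value),
        "n_starts": sol.n_starts,
        "converged": bool(sol.converged),
        "start_values": [float(v) for v in sol.start_values],
    }


def _count_table(
    design: Design, dropout: tuple[DropoutSpec, ...], labels=None
) -> list[str]:
    """Table-style report: time points, then expected counts per group."""
    q = design.q
    lines = []
    g1 = design.groups[0]
    head = "  ".join(f"{x:.4f}".rstrip("0").rstrip(".") for x in g1.t)
    lines.append(f"time points: {head}   w1 = {g1.w:.4f}")
    from .information import group_sizes

    sizes = group_sizes(design)
    for k, (g, spec) in enumerate(zip(design.groups, dropout)):
        counts = expected_pattern_counts(spec, g.t, g.dose, sizes[k])
        label = labels[k] if labels else f"group {k + 1}"
        cells = " ".join(f"{c:>3d}" for c in counts.rounded)
        lines.append(f"{label:<16s} {cells}  {int(sizes[k]):>4d}")
    return lines


def write_report(
    obj,
    format: str = "json",
    path: str | Path | None = None,
    dropout: tuple[DropoutSpec, ...] | None = None,
) -> str:
    """Serialize a solution, design or table to a deterministic report.

    ``obj`` may be a DesignSolution, a Design (text format needs the
    per-group ``dropout`` specs for the expected-count rows) or any
    JSON-serializable mapping.  Returns the text; writes it to ``path``
    when given.
    """
    if format not in ("json", "csv", "text"):
        raise ConfigError(f"unknown report format {format!r}")
    if format == "json":
        if isinstance(obj, DesignSolution):
            payload = _solution_payload(obj)
        elif isinstance(obj, Design):
            payload = design_to_dict(obj)
        else:
            payload = obj
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
    elif format == "csv":
        import pandas as pd

        if isinstance(obj, DesignSolution):
            frame = pd.DataFrame([_flat_row(obj.design, obj.criterion_value)])
        elif isinstance(obj, Design):
            frame = pd.DataFrame([_flat_row(obj)])
        elif isinstance(obj, pd.DataFrame):
            frame = obj
        else:
            frame = pd.DataFrame(obj)
        text = frame.to_csv(index=False)
    else:
        design = obj.design if isinstance(obj, DesignSolution) else obj
        if not isinstance(design, Design) or dropout is None:
            raise ConfigError("text reports need a design and dropout specs")
        lines = _count_table(design, dropout)
        if isinstance(obj, DesignSolution):
            lines.append(f"log-det criterion: {obj.criterion_value:.6f}")
        text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _flat_row(design: Design, criterion: float | None = None) -> dict:
    row: dict[str, Any] = {"N": design.N}
    for k, g in enumerate(design.groups, start=1):
        for j, t in enumerate(g.t, start=1):
            row[f"t{k}{j}"] = float(t)
        row[f"w{k}"] = float(g.w)
        row[f"dose{k}"] = None if g.dose is None else float(g.dose)
    if criterion is not None:
        row["criterion"] = float(criterion)
    return row
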