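"""Constrained search for locally D-optimal designs.

The decision variables are the free measurement times of each group (or
of the single shared schedule under the *restricted* condition), the
group allocation weights on the simplex, and — for the dose-response
model — the group dose levels inside the dose region.  The objective is
the log-determinant of the dropout-expected Fisher information.  The
problem is smooth but multimodal, so a multistart SLSQP with random
feasible initial points (plus a deterministic equispaced start) is used,
mirroring common practice with constrained NLP solvers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import minimize

from .dropout import DropoutSpec
from .errors import InfeasibleError, LMMDesignError, SpecificationError
from .information import Design, FisherInfo, GroupDesign, d_criterion, expected_information
from .lmm import LMMSpec

__all__ = ["DesignProblem", "DesignSolution", "optimize_design", "profile_over_rho"]

_PENALTY = 1e10


@dataclass(frozen=True)
class DesignProblem:
    """A D-optimal design problem over times, weights and doses.

    ``fixed_times`` maps occasion index (0-based) to its fixed value; under
    the *restricted* condition a single mapping applies to the shared
    schedule, under *flexible* a sequence of per-group mappings may be
    given (a single mapping is broadcast).  ``fixed_doses`` lists one
    entry per group, ``None`` marking a dose to be optimized (model Md
    only).
    """

    model: LMMSpec
    dropout: DropoutSpec | tuple[DropoutSpec, ...]
    time_region: tuple[float, float]
    q: int
    c: int = 2
    condition: str = "restricted"
    fixed_times: dict[int, float] | tuple[dict[int, float], ...] = field(
        default_factory=dict
    )
    optimize_weights: bool = True
    fixed_doses: tuple[float | None, ...] | None = None
    dose_region: tuple[float, float] | None = None
    N: int = 100
    #: count subjects observed only at baseline towards the criterion;
    #: design searches with fixed first two occasions usually discount them
    include_baseline_only: bool = True

    def __post_init__(self) -> None:
        if self.condition not in ("restricted", "flexible"):
            raise SpecificationError("condition must be 'restricted' or 'flexible'")
        if self.q < 2:
            raise SpecificationError("q must be at least 2")
        if self.c != self.model.fixed.c:
            raise SpecificationError("c must match the model's number of groups")
        lo, hi = self.time_region
        if not lo < hi:
            raise SpecificationError("empty time region")
        if self.model.fixed.model == "Md":
            if self.dose_region is None:
                raise SpecificationError("model Md requires a dose region")
            doses = self.fixed_doses or (None,) * self.c
            if len(doses) != self.c:
                raise SpecificationError("fixed_doses needs one entry per group")
            object.__setattr__(self, "fixed_doses", tuple(doses))
        for ft in self._fixed_times_per_group():
            for idx, val in ft.items():
                if not 0 <= idx < self.q:
                    raise SpecificationError(f"fixed time index {idx} out of range")
                if not lo <= val <= hi:
                    raise SpecificationError(f"fixed time {val} outside region")
            vals = [ft[i] for i in sorted(ft)]
            if np.any(np.diff(vals) <= 0):
                raise InfeasibleError("fixed times violate the strict ordering")

    def _fixed_times_per_group(self) -> list[dict[int, float]]:
        ft = self.fixed_times
        if isinstance(ft, dict):
            return [dict(ft)] * self.c
        if len(ft) != self.c:
            raise SpecificationError("need one fixed-times mapping per group")
        return [dict(m) for m in ft]

    def dropout_specs(self) -> list[DropoutSpec]:
        if isinstance(self.dropout, DropoutSpec):
            return [self.dropout] * self.c
        return list(self.dropout)


@dataclass
class DesignSolution:
    """Best design found, its criterion value and search diagnostics."""

    design: Design
    criterion_value: float
    n_starts: int
    converged: bool
    start_values: list[float]
    info: FisherInfo | None = None


class _Packing:
    """Maps the flat optimizer vector onto a Design and back."""

    def __init__(self, problem: DesignProblem):
        self.pb = problem
        lo, hi = problem.time_region
        self.eps = 1e-6 * (hi - lo)
        fixed = problem._fixed_times_per_group()
        # one schedule under 'restricted', one per group under 'flexible'
        self.n_sched = 1 if problem.condition == "restricted" else problem.c
        self.free_idx: list[list[int]] = [
            [j for j in range(problem.q) if j not in fixed[s]]
            for s in range(self.n_sched)
        ]
        self.fixed = fixed
        self.time_slices: list[slice] = []
        off = 0
        for s in range(self.n_sched):
            n = len(self.free_idx[s])
            self.time_slices.append(slice(off, off + n))
            off += n
        self.w_slice = slice(off, off + (problem.c - 1 if problem.optimize_weights else 0))
        off = self.w_slice.stop
        if problem.model.fixed.model == "Md":
            self.free_dose = [k for k, d in enumerate(problem.fixed_doses) if d is None]
        else:
            self.free_dose = []
        self.dose_slice = slice(off, off + len(self.free_dose))
        self.n_var = self.dose_slice.stop
        if self.n_var == 0:
            raise SpecificationError("design problem has no free variables")

    # -- assembly ------------------------------------------------------
    def schedule(self, x: NDArray, s: int) -> NDArray:
        t = np.empty(self.pb.q)
        for idx, val in self.fixed[s].items():
            t[idx] = val
        t[self.free_idx[s]] = x[self.time_slices[s]]
        return t

    def weights(self, x: NDArray) -> NDArray:
        c = self.pb.c
        if not self.pb.optimize_weights:
            return np.full(c, 1.0 / c)
        w = np.empty(c)
        w[: c - 1] = x[self.w_slice]
        w[c - 1] = 1.0 - w[: c - 1].sum()
        return w

    def doses(self, x: NDArray) -> list[float | None]:
        if self.pb.model.fixed.model != "Md":
            return [None] * self.pb.c
        doses = list(self.pb.fixed_doses)
        for i, k in enumerate(self.free_dose):
            doses[k] = float(x[self.dose_slice][i])
        return doses

    def design(self, x: NDArray) -> Design:
        groups = []
        w = self.weights(x)
        doses = self.doses(x)
        for k in range(self.pb.c):
            s = 0 if self.n_sched == 1 else k
            groups.append(
                GroupDesign(t=self.schedule(x, s), w=float(w[k]), dose=doses[k])
            )
        return Design(groups=tuple(groups), N=self.pb.N)

    # -- constraints ---------------------------------------------------
    def bounds(self) -> list[tuple[float, float]]:
        lo, hi = self.pb.time_region
        b: list[tuple[float, float]] = []
        for s in range(self.n_sched):
            b += [(lo, hi)] * len(self.free_idx[s])
        if self.pb.optimize_weights:
            b += [(1e-4, 1.0 - 1e-4)] * (self.pb.c - 1)
        if self.free_dose:
            b += [self.pb.dose_region] * len(self.free_dose)
        return b

    def constraints(self) -> list[dict]:
        cons = []

        def ordering(x: NDArray) -> NDArray:
            gaps = []
            for s in range(self.n_sched):
                t = self.schedule(x, s)
                gaps.extend(np.diff(t) - self.eps)
            return np.asarray(gaps)

        cons.append({"type": "ineq", "fun": ordering})
        if self.pb.optimize_weights and self.pb.c > 2:
            cons.append(
                {"type": "ineq", "fun": lambda x: 1.0 - 1e-4 - x[self.w_slice].sum()}
            )
        return cons

    # -- starting points ----------------------------------------------
    def _anchors(self, s: int, j: int) -> tuple[float, float]:
        """Nearest fixed times (or region bounds) bracketing free index j."""
        lo, hi = self.pb.time_region
        below = [v for i, v in self.fixed[s].items() if i < j]
        above = [v for i, v in self.fixed[s].items() if i > j]
        return (max(below, default=lo), min(above, default=hi))

    def start(self, rng: np.random.Generator | None) -> NDArray:
        x = np.empty(self.n_var)
        for s in range(self.n_sched):
            idx = self.free_idx[s]
            # partition free indices into runs sharing the same anchor pair,
            # then draw a jointly sorted sample per run so starts are feasible
            runs: dict[tuple[float, float], list[int]] = {}
            for j in idx:
                runs.setdefault(self._anchors(s, j), []).append(j)
            t_free: dict[int, float] = {}
            for (a, b), run in runs.items():
                n = len(run)
                if rng is None:
                    vals = [a + (b - a) * (r + 1) / (n + 1) for r in range(n)]
                else:
                    vals = np.sort(rng.uniform(a + self.eps, b - self.eps, n))
                for j, v in zip(sorted(run), vals):
                    t_free[j] = float(v)
            x[self.time_slices[s]] = [t_free[j] for j in idx]
        if self.pb.optimize_weights:
            c = self.pb.c
            if rng is None:
                x[self.w_slice] = 1.0 / c
            else:
                w = rng.dirichlet(np.ones(c))
                x[self.w_slice] = np.clip(w[: c - 1], 1e-3, 1 - 1e-3)
        if self.free_dose:
            dlo, dhi = self.pb.dose_region
            if rng is None:
                x[self.dose_slice] = 0.5 * (dlo + dhi)
            else:
                x[self.dose_slice] = rng.uniform(dlo, dhi, len(self.free_dose))
        return x


def _objective(pack: _Packing, specs: Sequence[DropoutSpec]):
    pb = pack.pb

    def fun(x: NDArray) -> float:
        try:
            design = pack.design(x)
            crit = d_criterion(
                expected_information(
                    design, pb.model, specs,
                    include_baseline_only=pb.include_baseline_only,
                )
            )
        except LMMDesignError:
            return _PENALTY
        if not np.isfinite(crit):
            return _PENALTY
        return -crit

    return fun


def optimize_design(
    problem: DesignProblem,
    seed: int = 0,
    n_starts: int = 20,
    extra_starts: Sequence[NDArray] | None = None,
) -> DesignSolution:
    """Maximize the D-criterion over the problem's free variables.

    Runs SLSQP from a deterministic equispaced start plus ``n_starts - 1``
    random feasible starts (seeded), keeps the best local optimum, and
    recomputes the reported criterion from scratch on the assembled
    design.
    """
    pack = _Packing(problem)
    specs = problem.dropout_specs()
    fun = _objective(pack, specs)
    bounds = pack.bounds()
    cons = pack.constraints()

    rng = np.random.default_rng(seed)
    starts = [pack.start(None)]
    starts += [pack.start(rng) for _ in range(max(n_starts - 1, 0))]
    if extra_starts is not None:
        starts += [np.asarray(x, dtype=float) for x in extra_starts]

    best_x, best_f = None, np.inf
    values, any_ok = [], False
    for x0 in starts:
        res = minimize(
            fun,
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=cons,
            options={"maxiter": 400, "ftol": 1e-12},
        )
        f = fun(res.x)  # re-evaluate: SLSQP may report the last, not best, iterate
        values.append(-f)
        any_ok = any_ok or (res.success and f < _PENALTY / 2)
        if f < best_f:
            best_f, best_x = f, res.x.copy()
    if best_x is None or best_f >= _PENALTY / 2:
        raise InfeasibleError("no start produced a feasible design")
    # polish from the incumbent
    res = minimize(
        fun,
        best_x,
        method="SLSQP",
        bounds=bounds,
        constraints=cons,
        options={"maxiter": 600, "ftol": 1e-14},
    )
    if fun(res.x) < best_f:
        best_f, best_x = fun(res.x), res.x.copy()

    design = pack.design(best_x)
    info = expected_information(
        design, problem.model, specs,
        include_baseline_only=problem.include_baseline_only,
    )
    return DesignSolution(
        design=design,
        criterion_value=d_criterion(info),
        n_starts=len(starts),
        converged=any_ok,
        start_values=values,
        info=info,
    )


def profile_over_rho(
    problem: DesignProblem,
    rho_grid: Sequence[float],
    seed: int = 0,
    n_starts: int = 20,
) -> list[DesignSolution]:
    """Solve the design problem along a grid of serial-correlation values.

    Each grid point is warm-started from the previous solution in
    addition to the usual multistarts, which keeps the profile of optimal
    time points continuous across rho.
    """
    sols: list[DesignSolution] = []
    warm: NDArray | None = None
    for i, rho in enumerate(rho_grid):
        corr = dataclasses.replace(problem.model.corr, rho=float(rho))
        model = dataclasses.replace(problem.model, corr=corr)
        pb = dataclasses.replace(problem, model=model)
        extra = None if warm is None else [warm]
        sol = optimize_design(pb, seed=seed + i, n_starts=n_starts, extra_starts=extra)
        sols.append(sol)
        warm = _pack_solution(pb, sol)
    return sols


def _pack_solution(problem: DesignProblem, sol: DesignSolution) -> NDArray:
    """Flatten a solution back into the optimizer's variable vector."""
    pack = _Packing(problem)
    x = np.empty(pack.n_var)
    for s in range(pack.n_sched):
        g = sol.design.groups[0 if pack.n_sched == 1 else s]
        x[pack.time_slices[s]] = g.t[pack.free_idx[s]]
    if problem.optimize_weights:
        w = [g.w for g in sol.design.groups]
        x[pack.w_slice] = w[: problem.c - 1]
    for i, k in enumerate(pack.free_dose):
        x[pack.dose_slice][i] = sol.design.groups[k].dose
    return x
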