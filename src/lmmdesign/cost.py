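"""Budget-constrained trade-off between occasions and sample size.

Recruiting a subject (including the baseline measurement) costs more
than one follow-up visit; under a fixed budget, dropping a measurement
occasion therefore buys additional subjects.  ``affordable_n`` converts
a budget into a sample size for a given number of occasions, and
``cost_scan`` re-solves the D-optimal design problem across candidate
occasion counts at the matching sample sizes.

Costing is per *planned* visit: a follow-up visit is budgeted whether or
not the subject has dropped out by then, which is the conservative
choice when the budget must be committed before the trial starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .errors import SpecificationError
from .information import Design, d_criterion, expected_information, relative_d_efficiency
from .search import DesignProblem, DesignSolution, optimize_design

__all__ = ["CostModel", "affordable_n", "cost_scan"]


@dataclass(frozen=True)
class CostModel:
    """Trial budget and unit costs.

    ``recruit_cost`` covers recruitment plus the baseline measurement;
    ``visit_cost`` is one follow-up measurement.  A subject measured at q
    occasions costs recruit_cost + (q - 1) * visit_cost.
    """

    recruit_cost: float
    visit_cost: float
    budget: float

    def __post_init__(self) -> None:
        if min(self.recruit_cost, self.visit_cost, self.budget) <= 0:
            raise SpecificationError("costs and budget must be positive")

    @classmethod
    def from_reference(
        cls, n_ref: int, q_ref: int, ratio: float = 2.0, visit_cost: float = 1.0
    ) -> "CostModel":
        """Budget that exactly funds ``n_ref`` subjects at ``q_ref`` occasions."""
        recruit = ratio * visit_cost
        return cls(
            recruit_cost=recruit,
            visit_cost=visit_cost,
            budget=n_ref * (recruit + (q_ref - 1) * visit_cost),
        )

    def per_subject(self, q: int) -> float:
        return self.recruit_cost + (q - 1) * self.visit_cost


def affordable_n(cost: CostModel, q: int, round_up: bool = False) -> int:
    """Largest sample size affordable with q planned occasions per subject.

    The fractional value budget / per-subject-cost is floored by default;
    ``round_up`` rounds to nearest instead, for exploratory use.
    """
    if q < 2:
        raise SpecificationError("q must be at least 2")
    frac = cost.budget / cost.per_subject(q)
    n = round(frac) if round_up else math.floor(frac)
    if n < 1:
        raise SpecificationError("budget does not cover a single subject")
    return int(n)


def cost_scan(
    problem_factory: Callable[[int, int], DesignProblem],
    cost: CostModel,
    q_values: Sequence[int],
    reference: Design | None = None,
    seed: int = 0,
    n_starts: int = 20,
) -> tuple[pd.DataFrame, dict[int, DesignSolution]]:
    """Optimal design and efficiency for each candidate occasion count.

    For each q the affordable N is computed, ``problem_factory(q, N)``
    builds the corresponding design problem, and the D-optimal design is
    found.  If a ``reference`` design is supplied, each row also reports
    the relative D-efficiency of the reference against the scan's design
    (values below 1: the reference is less efficient), both evaluated
    through the inverse expected information under the scanned problem's
    model and dropout.

    Returns a table with one row per q, plus the full solutions.
    """
    rows = []
    solutions: dict[int, DesignSolution] = {}
    for q in q_values:
        n = affordable_n(cost, q)
        problem = problem_factory(q, n)
        if problem.q != q or problem.N != n:
            raise SpecificationError("problem_factory must honour the given (q, N)")
        sol = optimize_design(problem, seed=seed, n_starts=n_starts)
        solutions[q] = sol
        g1 = sol.design.groups[0]
        row = {
            "q": q,
            "N": n,
            "spent": n * cost.per_subject(q),
            "criterion": sol.criterion_value,
            "w1": g1.w,
            "dose1": g1.dose,
            "times": tuple(round(x, 4) for x in g1.t),
        }
        if reference is not None:
            cov = sol.info.covariance()
            cov_ref = expected_information(
                reference,
                problem.model,
                problem.dropout_specs(),
                include_baseline_only=problem.include_baseline_only,
            ).covariance()
            row["red_reference_vs_optimal"] = relative_d_efficiency(
                cov_ref, cov, problem.model.fixed.p
            )
        rows.append(row)
    return pd.DataFrame(rows), solutions
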