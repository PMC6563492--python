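"""Expected Fisher information under dropout, D-criterion, D-efficiency.

Available-case analysis uses every observed response of every subject.
A subject who leaves after the j-th occasion contributes the information
of the truncated design X[1..j] with the leading j x j block of V (the
marginal covariance of a multivariate normal).  Weighting each pattern
by its expected count m_{k,j} gives the expected information

    M(xi) = sum_k sum_j m_{k,j} X_{k[j]}^T V_{k[j]}^{-1} X_{k[j]},

whose log-determinant is the D-criterion and whose inverse approximates
the covariance of the fixed-effect estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.linalg import cho_factor, cho_solve

from .dropout import DropoutSpec, PatternCounts, expected_pattern_counts
from .errors import CovarianceError, InvalidDesignError, SpecificationError
from .lmm import LMMSpec, build_fixed_design, build_response_covariance

__all__ = [
    "GroupDesign",
    "Design",
    "FisherInfo",
    "pattern_information",
    "expected_information",
    "d_criterion",
    "relative_d_efficiency",
    "group_sizes",
]


@dataclass(frozen=True)
class GroupDesign:
    """Measurement schedule, allocation weight and dose of one group."""

    t: NDArray[np.floating]
    w: float
    dose: float | None = None
    fixed_mask: NDArray[np.bool_] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        if np.any(np.diff(t) <= 0):
            raise InvalidDesignError("group time points must be strictly increasing")
        if not 0.0 <= self.w <= 1.0:
            raise InvalidDesignError(f"group weight must lie in [0, 1], got {self.w}")


@dataclass(frozen=True)
class Design:
    """Approximate design: per-group schedules/doses/weights and total N."""

    groups: tuple[GroupDesign, ...]
    N: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.N <= 0:
            raise InvalidDesignError("N must be positive")
        w = np.array([g.w for g in self.groups])
        if abs(w.sum() - 1.0) > 1e-8:
            raise InvalidDesignError(f"group weights must sum to 1, got {w.sum()}")
        qs = {len(g.t) for g in self.groups}
        if len(qs) != 1:
            raise InvalidDesignError("all groups must share the same number of occasions")

    @property
    def c(self) -> int:
        return len(self.groups)

    @property
    def q(self) -> int:
        return len(self.groups[0].t)


def group_sizes(design: Design) -> NDArray[np.int_]:
    """Integer group sizes by largest-remainder rounding of N * w_k."""
    raw = design.N * np.array([g.w for g in design.groups])
    base = np.floor(raw).astype(int)
    short = design.N - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


@dataclass(frozen=True)
class FisherInfo:
    """Symmetric p x p expected information for the fixed effects."""

    matrix: NDArray[np.floating]
    p: int = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", 0.5 * (m + m.T))
        object.__setattr__(self, "p", m.shape[0])

    def covariance(self) -> NDArray[np.floating]:
        """Inverse information, the large-sample covariance approximation."""
        return np.linalg.inv(self.matrix)


def pattern_information(
    X: ArrayLike, V: ArrayLike, j: int
) -> NDArray[np.floating]:
    """Information X[1..j]^T V[1..j,1..j]^{-1} X[1..j] of a length-j pattern."""
    X = np.asarray(X, dtype=float)
    V = np.asarray(V, dtype=float)
    q = X.shape[0]
    if not 1 <= j <= q:
        raise SpecificationError(f"pattern length j must lie in 1..{q}, got {j}")
    Xj = X[:j]
    try:
        c = cho_factor(V[:j, :j], lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise CovarianceError("leading covariance block is singular") from exc
    return Xj.T @ cho_solve(c, Xj)


def _per_group_dropout(
    dropout: DropoutSpec | Sequence[DropoutSpec], c: int
) -> list[DropoutSpec]:
    if isinstance(dropout, DropoutSpec):
        return [dropout] * c
    specs = list(dropout)
    if len(specs) != c:
        raise SpecificationError(f"need one dropout spec per group ({c}), got {len(specs)}")
    return specs


def expected_information(
    design: Design,
    model: LMMSpec,
    dropout: DropoutSpec | Sequence[DropoutSpec],
    include_baseline_only: bool = True,
) -> FisherInfo:
    """Dropout-expected Fisher information of the fixed effects.

    Sums, over groups and dropout patterns, the pattern information
    weighted by the expected pattern count m_{k,j} computed from the
    group's response-probability function and allocation N * w_k.

    ``include_baseline_only`` controls whether subjects whose only
    observation is the baseline measurement (pattern j = 1, which carries
    intercept information only) contribute to the sum.  When the first
    two occasions are fixed and the design region truncated — the usual
    convention for logistic dropout, which cannot reach probability one
    at baseline — design searches customarily discount this pattern; set
    it to ``False`` to do so.  The pattern mass is dropped, not
    renormalized.
    """
    specs = _per_group_dropout(dropout, design.c)
    p = model.fixed.p
    M = np.zeros((p, p))
    j_start = 1 if include_baseline_only else 2
    for k, (g, spec) in enumerate(zip(design.groups, specs), start=1):
        dose = g.dose if model.fixed.model == "Md" else None
        X = build_fixed_design(model.fixed, g.t, group_index=k, dose=dose)
        V = build_response_covariance(g.t, model.random, model.sigma2, model.corr)
        counts: PatternCounts = expected_pattern_counts(
            spec, g.t, g.dose, design.N * g.w
        )
        for j in range(j_start, design.q + 1):
            if counts.m[j - 1] > 0.0:
                M += counts.m[j - 1] * pattern_information(X, V, j)
    return FisherInfo(matrix=M)


def d_criterion(info: FisherInfo | ArrayLike) -> float:
    """Log-determinant of the information matrix (maximization target).

    Returns ``-inf`` for a singular or indefinite matrix so that an
    optimizer simply rejects the design.
    """
    m = info.matrix if isinstance(info, FisherInfo) else np.asarray(info, dtype=float)
    sign, logdet = np.linalg.slogdet(m)
    if sign <= 0 or not np.isfinite(logdet):
        return -np.inf
    # slogdet is positive for e.g. diag(-1,-1); insist on positive definiteness
    if np.linalg.eigvalsh(m)[0] <= 0:
        return -np.inf
    return float(logdet)


def relative_d_efficiency(
    cov_candidate: ArrayLike, cov_reference: ArrayLike, p: int | None = None
) -> float:
    """Relative D-efficiency (det cov_ref / det cov_candidate)^(1/p).

    Values below 1 mean the candidate design estimates the p fixed
    effects less precisely, per parameter, than the reference.
    """
    A = np.asarray(cov_candidate, dtype=float)
    B = np.asarray(cov_reference, dtype=float)
    if p is None:
        p = A.shape[0]
    for name, m in (("candidate", A), ("reference", B)):
        if np.linalg.eigvalsh(0.5 * (m + m.T))[0] <= 0:
            raise CovarianceError(f"{name} covariance is not positive definite")
    sa, la = np.linalg.slogdet(A)
    sb, lb = np.linalg.slogdet(B)
    return float(np.exp((lb - la) / p))
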