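"""Design-dependent dropout models and expected pattern counts.

Dropout here is noninformative and monotone: a subject observed at the
first j occasions and missing thereafter.  The probability that a
subject in a group is still observed at time t (possibly depending on
the group's dose) is a monotone non-increasing *response-probability*
function p_obs(t, delta).  The number of subjects with exactly j
observed measurements then follows a multinomial distribution whose
event probabilities are successive differences of p_obs over the
measurement schedule.

The logistic family never attains p_obs = 1 at baseline, so its
differences would not sum to one.  With ``baseline_certain=True`` (the
default) the baseline measurement is treated as always observed and the
first event probability becomes 1 - p_obs(t_2); for families that do
reach 1 at the first time point the two conventions coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .errors import DropoutModelError, SpecificationError

__all__ = [
    "DropoutSpec",
    "PatternCounts",
    "response_prob",
    "pattern_probabilities",
    "expected_pattern_counts",
    "round_half_away",
]

_FAMILIES = ("linear", "quadratic", "logistic", "constant_one")
_N_COEF = {"linear": 2, "quadratic": 3, "logistic": 3, "constant_one": 0}


@dataclass(frozen=True)
class DropoutSpec:
    """Response-probability function of one group.

    families
        ``linear``       p = a + b*t               coefficients (a, b)
        ``quadratic``    p = a + b*t + c*t^2       coefficients (a, b, c)
        ``logistic``     p = 1/(1+exp(g0+g1*d+g2*t))  coefficients (g0, g1, g2)
        ``constant_one`` p = 1 (no dropout)
    """

    family: str = "constant_one"
    coefficients: tuple[float, ...] = ()
    baseline_certain: bool = True

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise SpecificationError(f"unknown dropout family {self.family!r}")
        if len(self.coefficients) != _N_COEF[self.family]:
            raise SpecificationError(
                f"family {self.family!r} needs {_N_COEF[self.family]} coefficients"
            )

    def validate_monotone(
        self,
        t_lo: float,
        t_hi: float,
        dose: float | None = None,
        n_grid: int = 1000,
    ) -> None:
        """Check p_obs is within [0,1] and non-increasing on a dense grid."""
        grid = np.linspace(t_lo, t_hi, n_grid)
        p = np.array([response_prob(self, t, dose) for t in grid])
        if np.any(np.diff(p) > 1e-12):
            raise DropoutModelError(
                f"response probability is not non-increasing on [{t_lo}, {t_hi}]"
            )


def response_prob(spec: DropoutSpec, t: float, dose: float | None = None) -> float:
    """Probability that a subject is still observed at time ``t``."""
    if spec.family == "constant_one":
        return 1.0
    if spec.family == "linear":
        a, b = spec.coefficients
        p = a + b * t
    elif spec.family == "quadratic":
        a, b, c = spec.coefficients
        p = a + b * t + c * t * t
    else:  # logistic
        g0, g1, g2 = spec.coefficients
        d = 0.0 if dose is None else float(dose)
        p = 1.0 / (1.0 + np.exp(g0 + g1 * d + g2 * t))
    if p < -1e-12 or p > 1.0 + 1e-12:
        raise DropoutModelError(
            f"response probability {p} at t={t} lies outside [0, 1]"
        )
    return float(min(max(p, 0.0), 1.0))


def pattern_probabilities(
    spec: DropoutSpec, t: ArrayLike, dose: float | None = None
) -> NDArray[np.floating]:
    """Multinomial event probabilities of the q dropout patterns.

    Entry j-1 (j = 1..q) is the probability that a subject has exactly j
    observed measurements.  With ``baseline_certain`` the first entry is
    1 - p(t_2); otherwise the literal difference p(t_1) - p(t_2) is used,
    which requires p(t_1) = 1 (checked to 1e-9) so that the probabilities
    sum to one.
    """
    t = np.asarray(t, dtype=float)
    q = len(t)
    if q < 2:
        raise SpecificationError("at least two time points are required")
    p = np.array([response_prob(spec, tj, dose) for tj in t])
    if spec.baseline_certain:
        head = 1.0 - p[1]
    else:
        if abs(p[0] - 1.0) > 1e-9:
            raise DropoutModelError(
                "without baseline_certain, p_obs(t_1) must equal 1 "
                f"(got {p[0]}); probabilities would not sum to one"
            )
        head = p[0] - p[1]
    pi = np.empty(q)
    pi[0] = head
    pi[1:-1] = p[1:-1] - p[2:]
    pi[-1] = p[-1]
    if np.any(pi < -1e-12):
        raise DropoutModelError(
            f"negative pattern probability {pi.min()}: response probability "
            "is not non-increasing over the schedule"
        )
    return np.clip(pi, 0.0, None)


def round_half_away(x: ArrayLike) -> NDArray[np.int_]:
    """Round half away from zero, elementwise (for human-readable tables)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


@dataclass(frozen=True)
class PatternCounts:
    """Expected dropout-pattern counts of one group.

    ``m[j-1]`` is the expected number of subjects with exactly j observed
    measurements; the entries sum to the group allocation ``n_alloc``.
    """

    m: NDArray[np.floating]
    n_alloc: float
    pattern_probs: NDArray[np.floating]

    @property
    def rounded(self) -> NDArray[np.int_]:
        """Integer report (round half away from zero)."""
        return round_half_away(self.m)


def expected_pattern_counts(
    spec: DropoutSpec,
    t: ArrayLike,
    dose: float | None,
    n_alloc: float,
) -> PatternCounts:
    """Expected number of subjects per dropout pattern, m_j = n * pi_j."""
    if n_alloc < 0:
        raise SpecificationError("group allocation must be nonnegative")
    pi = pattern_probabilities(spec, t, dose)
    return PatternCounts(m=n_alloc * pi, n_alloc=float(n_alloc), pattern_probs=pi)
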