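"""Linear mixed models for repeated-measurements trials.

A subject's responses follow

    y_i = X_i beta + Z_i b_i + eps_i,

with random coefficients b_i ~ N(0, D) and serially correlated errors
eps_i ~ N(0, sigma^2 Psi), so the marginal covariance of y_i is
V_i = Z_i D Z_i^T + sigma^2 Psi.

Two mean structures are supported:

* ``Mg`` — one common intercept and one time slope per group (group
  membership selects which slope column carries the time values), for
  trials whose arms are comparable at baseline;
* ``Md`` — intercept, time slope and dose slope (1, t, delta), for
  dose-finding trials where dose is itself a design variable.

Random-effect classes: ``FE`` (no random effects), ``RI`` (random
intercept), ``RIRS`` (independent random intercept and slope) and
``RIRSc`` (correlated random intercept and slope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .errors import CovarianceError, InvalidDesignError, SpecificationError

__all__ = [
    "CorrelationSpec",
    "RandomEffectsSpec",
    "FixedEffectsSpec",
    "LMMSpec",
    "build_fixed_design",
    "build_response_covariance",
]

#: smallest eigenvalue accepted before a covariance is declared singular
_PD_TOL = 1e-10

_CORR_KINDS = ("independent", "compound_symmetry", "ar1")
_RE_CLASSES = ("FE", "RI", "RIRS", "RIRSc")
_MODELS = ("Mg", "Md")


@dataclass(frozen=True)
class CorrelationSpec:
    """Serial correlation of the observational errors.

    ``ar1`` uses psi(t_j, t_j') = rho**|t_j - t_j'| with time measured on
    whatever scale the caller supplies (no internal rescaling), so rho is
    a per-time-unit correlation.  ``compound_symmetry`` places rho on all
    off-diagonal entries.  rho is ignored for ``independent``.
    """

    kind: str = "independent"
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _CORR_KINDS:
            raise SpecificationError(f"unknown correlation kind {self.kind!r}")
        if self.kind != "independent" and not (0.0 <= self.rho < 1.0):
            raise SpecificationError(f"rho must lie in [0, 1), got {self.rho}")

    def matrix(self, t: NDArray[np.floating]) -> NDArray[np.floating]:
        """Correlation matrix Psi over the time vector ``t``."""
        q = len(t)
        if self.kind == "independent":
            return np.eye(q)
        if self.kind == "compound_symmetry":
            return np.full((q, q), self.rho) + (1.0 - self.rho) * np.eye(q)
        # AR(1); rho = 0 degenerates continuously to the identity (0**0 = 1)
        lag = np.abs(t[:, None] - t[None, :])
        return np.power(self.rho, lag)


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Covariance D of the subject-level random coefficients (b0, b1)."""

    klass: str = "FE"
    d11: float = 0.0
    d22: float = 0.0
    d12: float = 0.0

    def __post_init__(self) -> None:
        if self.klass not in _RE_CLASSES:
            raise SpecificationError(f"unknown random-effects class {self.klass!r}")
        k, d11, d22, d12 = self.klass, self.d11, self.d22, self.d12
        if min(d11, d22) < 0:
            raise SpecificationError("variances d11, d22 must be nonnegative")
        ok = {
            "FE": d11 == 0 and d22 == 0 and d12 == 0,
            "RI": d11 > 0 and d22 == 0 and d12 == 0,
            "RIRS": d11 > 0 and d22 > 0 and d12 == 0,
            "RIRSc": d11 > 0 and d22 > 0 and d12 != 0 and d12**2 < d11 * d22,
        }[k]
        if not ok:
            raise SpecificationError(
                f"(d11={d11}, d22={d22}, d12={d12}) invalid for class {k}"
            )

    @property
    def n_effects(self) -> int:
        return {"FE": 0, "RI": 1, "RIRS": 2, "RIRSc": 2}[self.klass]

    @property
    def D(self) -> NDArray[np.floating]:
        """Covariance matrix of the active random effects."""
        if self.klass == "FE":
            return np.zeros((0, 0))
        if self.klass == "RI":
            return np.array([[self.d11]])
        return np.array([[self.d11, self.d12], [self.d12, self.d22]])

    def z_matrix(self, t: NDArray[np.floating]) -> NDArray[np.floating]:
        """Random-effect design Z: intercept column, plus time for slopes."""
        q = len(t)
        if self.klass == "FE":
            return np.zeros((q, 0))
        if self.klass == "RI":
            return np.ones((q, 1))
        return np.column_stack([np.ones(q), t])


@dataclass(frozen=True)
class FixedEffectsSpec:
    """Mean structure: model family, number of groups and coefficients.

    ``beta`` is only consumed by the trial simulator; design criteria do
    not depend on it (the information matrix of a linear model is free of
    beta).
    """

    model: str = "Md"
    c: int = 2
    beta: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise SpecificationError(f"unknown model {self.model!r}")
        if self.c < 2:
            raise SpecificationError("at least two groups are required")
        if self.beta is not None and len(self.beta) != self.p:
            raise SpecificationError(
                f"beta must have length {self.p} for model {self.model}"
            )

    @property
    def p(self) -> int:
        """Number of fixed effects."""
        return self.c + 1 if self.model == "Mg" else 3


@dataclass(frozen=True)
class LMMSpec:
    """Complete linear mixed model: mean, random effects, error process."""

    fixed: FixedEffectsSpec
    random: RandomEffectsSpec = field(default_factory=RandomEffectsSpec)
    sigma2: float = 1.0
    corr: CorrelationSpec = field(default_factory=CorrelationSpec)

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise SpecificationError("sigma2 must be positive")


def _check_times(t: NDArray[np.floating]) -> NDArray[np.floating]:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or len(t) < 1:
        raise InvalidDesignError("time vector must be one-dimensional")
    if np.any(np.diff(t) <= 0):
        raise InvalidDesignError(f"time points must be strictly increasing, got {t}")
    return t


def build_fixed_design(
    spec: FixedEffectsSpec,
    t: ArrayLike,
    group_index: int = 1,
    dose: float | None = None,
) -> NDArray[np.floating]:
    """Fixed-effect design matrix of one subject in one group.

    Row j is the gradient of the mean response at time t_j with respect
    to the fixed effects.  For ``Mg`` group k it is the unit intercept
    followed by t_j in slope position k; for ``Md`` it is (1, t_j, dose).

    Parameters
    ----------
    spec : FixedEffectsSpec
    t : array-like
        Strictly increasing measurement times.
    group_index : int
        1-based group label (``Mg`` only; ignored for ``Md``).
    dose : float, optional
        Dose level; required for ``Md`` and disallowed for ``Mg``.
    """
    t = _check_times(t)
    q = len(t)
    if spec.model == "Md":
        if dose is None:
            raise SpecificationError("model Md requires a dose level")
        return np.column_stack([np.ones(q), t, np.full(q, float(dose))])
    if dose is not None:
        raise SpecificationError("model Mg does not take a dose level")
    if not 1 <= group_index <= spec.c:
        raise SpecificationError(
            f"group_index must lie in 1..{spec.c}, got {group_index}"
        )
    X = np.zeros((q, spec.p))
    X[:, 0] = 1.0
    X[:, group_index] = t
    return X


def build_response_covariance(
    t: ArrayLike,
    random: RandomEffectsSpec,
    sigma2: float,
    corr: CorrelationSpec,
) -> NDArray[np.floating]:
    """Marginal covariance V = Z D Z^T + sigma^2 Psi over time vector t.

    Raises
    ------
    CovarianceError
        If the assembled matrix is not positive definite (smallest
        eigenvalue below 1e-10); invalid inputs raise rather than being
        regularized.
    """
    t = _check_times(t)
    if sigma2 <= 0:
        raise SpecificationError("sigma2 must be positive")
    Z = random.z_matrix(t)
    V = Z @ random.D @ Z.T + sigma2 * corr.matrix(t)
    V = 0.5 * (V + V.T)
    if np.linalg.eigvalsh(V)[0] < _PD_TOL:
        raise CovarianceError("response covariance is not positive definite")
    return V
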