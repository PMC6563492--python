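"""Worked example: redesigning a one-year Alzheimer's disease trial.

A two-arm, five-occasion trial (placebo vs donepezil-memantine
combination, SMMSE score as outcome) with N = 144 subjects measured at
days 0, 42, 126, 210 and 364.  Pilot estimates from the trial data give
a random-intercept model with AR(1) errors,

    beta = (8.939, -0.0866, 0.01458),  rho = 0.3326,
    d11 = 2.661^2,  sigma^2 = 2.613^2,

and a logistic retention model

    p_obs(t, delta) = 1 / (1 + exp(-2.2332 - 0.0131 delta + 0.0100 t)),

with dose delta in [0, 100] (placebo = 0).  These constants parameterize
the design problems and simulation comparisons used throughout the
documentation and tests; they are inputs here, not estimates this
package produces.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cost import CostModel
from .dropout import DropoutSpec
from .information import Design, GroupDesign
from .lmm import CorrelationSpec, FixedEffectsSpec, LMMSpec, RandomEffectsSpec
from .search import DesignProblem

__all__ = [
    "GAMMA",
    "BETA",
    "model_ri",
    "model_rirs_sensitivity",
    "dropout_logistic",
    "design",
    "XI_ORI",
    "XI_D_STAR",
    "XI_D4_STAR",
    "five_point_problem",
    "four_point_problem",
    "cost_model",
]

#: logistic retention coefficients (gamma0, gamma1, gamma2)
GAMMA = (-2.2332, -0.0131, 0.0100)

#: generative fixed effects (intercept, time slope, dose slope)
BETA = (8.939, -0.0866, 0.01458)

_RHO = 0.3326
_D11 = 2.661**2
_SIGMA2 = 2.613**2


def model_ri(with_beta: bool = False) -> LMMSpec:
    """Random-intercept AR(1) model fitted to the pilot data."""
    return LMMSpec(
        fixed=FixedEffectsSpec(model="Md", c=2, beta=BETA if with_beta else None),
        random=RandomEffectsSpec(klass="RI", d11=_D11),
        sigma2=_SIGMA2,
        corr=CorrelationSpec(kind="ar1", rho=_RHO),
    )


def model_rirs_sensitivity() -> LMMSpec:
    """Sensitivity variant: uncorrelated random intercept and slope (d22 = 2)."""
    base = model_ri()
    return dataclasses.replace(
        base, random=RandomEffectsSpec(klass="RIRS", d11=_D11, d22=2.0)
    )


def dropout_logistic() -> DropoutSpec:
    """Fitted logistic retention model, baseline always observed."""
    return DropoutSpec(family="logistic", coefficients=GAMMA, baseline_certain=True)


def design(times, w1: float, N: int) -> Design:
    """Two-arm design with shared schedule, placebo dose 0 and dose 100."""
    t = np.asarray(times, dtype=float)
    return Design(
        groups=(
            GroupDesign(t=t, w=w1, dose=0.0),
            GroupDesign(t=t, w=1.0 - w1, dose=100.0),
        ),
        N=N,
    )


#: the original trial schedule, equal allocation
XI_ORI = design([0.0, 42.0, 126.0, 210.0, 364.0], 0.5, 144)

#: D-optimal five-occasion redesign under the random-intercept model
XI_D_STAR = design([0.0, 42.0, 285.2340, 355.6943, 364.0], 0.4221, 144)

#: D-optimal four-occasion redesign at the cost-equivalent N = 172
XI_D4_STAR = design([0.0, 42.0, 318.5670, 364.0], 0.4183, 172)


def _problem(model: LMMSpec, q: int, N: int) -> DesignProblem:
    fixed = {0: 0.0, 1: 42.0, q - 1: 364.0}
    return DesignProblem(
        model=model,
        dropout=dropout_logistic(),
        time_region=(0.0, 364.0),
        q=q,
        c=2,
        condition="restricted",
        fixed_times=fixed,
        optimize_weights=True,
        fixed_doses=(None, 100.0),
        dose_region=(0.0, 100.0),
        N=N,
        # with the first two occasions fixed, the design search discounts
        # subjects who contribute a baseline measurement only
        include_baseline_only=False,
    )


def five_point_problem(model: LMMSpec | None = None, N: int = 144) -> DesignProblem:
    """Five-occasion problem: optimize (t3, t4, delta1, w1), endpoints fixed."""
    return _problem(model or model_ri(), 5, N)


def four_point_problem(model: LMMSpec | None = None, N: int = 172) -> DesignProblem:
    """Four-occasion problem at the cost-equivalent sample size."""
    return _problem(model or model_ri(), 4, N)


def cost_model(ratio: float = 2.0) -> CostModel:
    """Budget funding the original design (N=144, q=5) at the given
    recruitment : follow-up cost ratio."""
    return CostModel.from_reference(n_ref=144, q_ref=5, ratio=ratio)
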