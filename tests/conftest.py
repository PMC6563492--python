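import numpy as np
import pytest

from lmmdesign import (
    CorrelationSpec,
    Design,
    DropoutSpec,
    FixedEffectsSpec,
    GroupDesign,
    LMMSpec,
    RandomEffectsSpec,
)


@pytest.fixture
def ri_ar1_model() -> LMMSpec:
    """Random-intercept AR(1) model with the pilot-study variance components."""
    return LMMSpec(
        fixed=FixedEffectsSpec(model="Md", c=2, beta=(8.939, -0.0866, 0.01458)),
        random=RandomEffectsSpec(klass="RI", d11=2.661**2),
        sigma2=2.613**2,
        corr=CorrelationSpec(kind="ar1", rho=0.3326),
    )


@pytest.fixture
def logistic_dropout() -> DropoutSpec:
    """Fitted logistic retention model of the one-year trial."""
    return DropoutSpec(
        family="logistic", coefficients=(-2.2332, -0.0131, 0.0100)
    )


def two_arm_design(times, w1, N, doses=(0.0, 100.0)) -> Design:
    t = np.asarray(times, dtype=float)
    return Design(
        groups=(
            GroupDesign(t=t, w=w1, dose=doses[0]),
            GroupDesign(t=t, w=1.0 - w1, dose=doses[1]),
        ),
        N=N,
    )


@pytest.fixture
def xi_ori() -> Design:
    return two_arm_design([0.0, 42.0, 126.0, 210.0, 364.0], 0.5, 144)


@pytest.fixture
def xi_d_star() -> Design:
    return two_arm_design([0.0, 42.0, 285.2340, 355.6943, 364.0], 0.4221, 144)


@pytest.fixture
def xi_d4_star() -> Design:
    return two_arm_design([0.0, 42.0, 318.5670, 364.0], 0.4183, 172)
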