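import numpy as np
import pytest

from carpmove.hmm import (
    AngleParams,
    HmmParams,
    LinearCoefficients,
    StepCoefficients,
    TransitionCoefficients,
)


def intercept_only_params(
    mean1=0.988,
    mean2=0.026,
    sd1=0.928,
    sd2=0.019,
    psi12=0.0989,
    psi21=0.1824,
    zm=(-8.45, -15.27),
    kappa=(0.00002, 0.0009),
    mu=(-3.1414, -0.00008),
    delta=None,
):
    """Covariate-free two-state parameters; defaults match the field-study
    baseline state distributions (exploratory long steps, encamped short)."""
    from scipy.special import logit

    return HmmParams(
        transition=TransitionCoefficients(
            to_encamped=LinearCoefficients(intercept=float(logit(psi12))),
            to_exploratory=LinearCoefficients(intercept=float(logit(psi21))),
        ),
        step=StepCoefficients(
            mean=(
                LinearCoefficients(intercept=float(np.log(mean1))),
                LinearCoefficients(intercept=float(np.log(mean2))),
            ),
            log_sd=np.log([sd1, sd2]),
            logit_zero_mass=np.array(zm, dtype=float),
        ),
        angle=AngleParams(mu=np.array(mu), kappa=np.array(kappa)),
        delta=None if delta is None else np.asarray(delta, dtype=float),
    )


@pytest.fixture
def baseline_params():
    return intercept_only_params()


@pytest.fixture
def sticky_params():
    """Highly persistent, well-separated states: near-perfect decoding."""
    return intercept_only_params(psi12=0.03, psi21=0.03)


@pytest.fixture
def reference_covariates():
    return {"trial_id": 1, "pump_on": 1, "co2_mgL": 0.0, "temp_C": 0.0}
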