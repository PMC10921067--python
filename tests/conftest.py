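import dataclasses

import pytest

from emaxtraj import CohortSpec, EmaxParams, TestSpec


def make_test(
    name="mmse",
    direction="higher_is_better",
    floor=0.0,
    ceiling=30.0,
    baseline_mean=27.0,
    baseline_sd=2.0,
    ad_params=None,
    control_params=None,
    noise_sd=0.0,
) -> TestSpec:
    flat = EmaxParams(E0=0.0, Emax=0.0, ET50=80.0, h=8.0)
    return TestSpec(
        test_name=name,
        direction=direction,
        score_floor=floor,
        score_ceiling=ceiling,
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        true_emax_params={
            "AD": ad_params or flat,
            "control": control_params or ad_params or flat,
        },
        noise_sd=noise_sd,
    )


@pytest.fixture
def flat_test() -> TestSpec:
    """An instrument whose latent change is (numerically) zero everywhere."""
    return make_test()


@pytest.fixture
def small_spec(flat_test) -> CohortSpec:
    return CohortSpec(n_ad=8, n_control=12, tests=[flat_test], seed=42)


def clone(spec, **kw):
    return dataclasses.replace(spec, **kw)
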