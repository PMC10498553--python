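import pytest

from perspecta.params import (
    DistributionSpec,
    builtin_strategies,
    load_mozambique,
)


@pytest.fixture(scope="session")
def mozambique():
    """(ParameterSet, strategies, RunConfig) of the packaged case."""
    return load_mozambique()


@pytest.fixture(scope="session")
def moz_params(mozambique):
    return mozambique[0]


@pytest.fixture(scope="session")
def strategies():
    return builtin_strategies()


def zero_hazard_params(params, **overrides):
    """All transition hazards off: nobody dies, disengages, switches, or
    drifts. Used to compare the engine against closed-form accrual."""
    zero = DistributionSpec.point(0.0)
    changes = dict(
        mortality_rate_by_cd4_untreated={b: zero for b in params.mortality_rate_by_cd4_untreated},
        cd4_decline_no_art=zero,
        cd4_decline_on_art_failing=zero,
        cd4_gain_on_art=zero,
        ltfu_12m_risk_1month=zero,
        ltfu_rate_community_3m=zero,
        reengage_12m_without_tracing=zero,
        reengage_12m_with_tracing=zero,
        second_line_failure_rate=zero,
        annual_switch_risk_dtg=zero,
        annual_switch_risk_efv=zero,
        pct_first_line=DistributionSpec.point(1.0),
    )
    changes.update(overrides)
    return params.replace(**changes)


@pytest.fixture()
def degenerate_params(moz_params):
    return zero_hazard_params(moz_params)
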