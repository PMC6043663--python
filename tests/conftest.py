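"""Shared fixtures and independent oracles for the test suite."""

from math import comb

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from epitriage import default_panel
from epitriage.simulate import fixture_case_records


def enum_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Independent two-sided Fisher oracle: full enumeration over all 2x2
    tables with the observed margins, summing hypergeometric point
    probabilities not exceeding the observed table's."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)

    def prob(k: int) -> float:
        return comb(r1, k) * comb(r2, c1 - k) / denom

    p_obs = prob(a)
    return sum(
        p
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if (p := prob(k)) <= p_obs * (1 + 1e-9)
    )


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture()
def fixture_records():
    """The 11 packaged worked-example variants, joined."""
    records, _ = fixture_case_records()
    return records


@pytest.fixture()
def fixture_full_cohort():
    """Worked-example variants plus the padded 593-patient phenotype table."""
    return fixture_case_records(full_cohort=True)
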