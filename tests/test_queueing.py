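"""Closed-form M/M/k analytics against independent oracles.

The Erlang B oracle is the direct truncated-sum formula
B = (a^k / k!) / sum_{i<=k} a^i / i!, evaluated with exact factorials —
independent of the recursion the implementation uses. Erlang C follows
from B by its defining identity, evaluated from the oracle B.
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

from tepqueue import (
    DemandModel,
    ValidationError,
    erlang_b,
    erlang_c,
    estimate_rates,
    max_arrival_rate,
    max_supported_units,
    min_servers,
    offered_load,
    performance,
)

A_SINGLE = 0.06765  # 3.96/day * 24.6 min / 1440
A_TWENTY = 1.3530  # twenty districts


def erlang_b_oracle(k: int, a: float) -> float:
    """Brute-force truncated Poisson sum with exact factorials."""
    terms = [a**i / math.factorial(i) for i in range(k + 1)]
    return terms[-1] / sum(terms)


def erlang_c_oracle(k: int, a: float) -> float:
    b = erlang_b_oracle(k, a)
    return k * b / (k - a * (1 - b))


# -- offered load -----------------------------------------------------------


def test_offered_load_values():
    assert offered_load(0, 24.6) == 0.0
    assert offered_load(3.96, 24.6) == pytest.approx(A_SINGLE)
    assert offered_load(20 * 3.96, 24.6) == pytest.approx(A_TWENTY)
    with pytest.raises(ValidationError, match="arrival_rate"):
        offered_load(-1, 24.6)


# -- Erlang B ---------------------------------------------------------------


def test_erlang_b_base_and_closed_form():
    assert erlang_b(0, 2.3) == 1.0
    assert erlang_b(1, 1.0) == pytest.approx(0.5)  # a/(1+a)
    assert erlang_b(2, A_TWENTY) == pytest.approx(0.2800, abs=5e-4)


@pytest.mark.parametrize("a", [0.1, 1.0, 5.0])
@pytest.mark.parametrize("k", range(1, 21))
def test_erlang_b_recursion_matches_factorial_sum(k, a):
    assert erlang_b(k, a) == pytest.approx(erlang_b_oracle(k, a), abs=1e-12)


def test_erlang_b_stable_at_large_k():
    b = erlang_b(10_000, 9_000.0)
    assert 0.0 <= b <= 1.0 and math.isfinite(b)


# -- Erlang C ---------------------------------------------------------------


def test_erlang_c_single_server_equals_load():
    for a in (0.05, A_SINGLE, 0.5, 0.9):
        assert erlang_c(1, a) == pytest.approx(a)


def test_erlang_c_against_oracle_at_twenty_district_load():
    assert erlang_c(3, A_TWENTY) == pytest.approx(0.187, abs=1e-3)
    assert erlang_c(5, A_TWENTY) == pytest.approx(0.0134, abs=1e-3)
    for k in (3, 5):
        assert erlang_c(k, A_TWENTY) == pytest.approx(
            erlang_c_oracle(k, A_TWENTY), abs=1e-12
        )


def test_erlang_c_saturated_returns_one():
    assert erlang_c(2, 2.0) == 1.0
    assert erlang_c(2, 5.0) == 1.0


@given(
    k=st.integers(min_value=1, max_value=30),
    a=st.floats(min_value=1e-3, max_value=25.0),
)
@settings(max_examples=200, derandomize=True)
def test_erlang_inequality_and_monotonicity(k, a):
    """B <= C; both decrease in k and increase in a (stable regime)."""
    b, c = erlang_b(k, a), erlang_c(k, a)
    assert 0.0 <= b <= 1.0
    if a < k:
        assert b <= c <= 1.0
        assert erlang_b(k + 1, a) < b
        assert erlang_c(k + 1, a) < c or c == 0.0
        if a * 1.01 < k:
            assert erlang_c(k, a * 1.01) > c
            assert erlang_b(k, a * 1.01) > b


# -- performance ------------------------------------------------------------


def test_single_server_idle_fraction_matches_headline(default_model):
    p = performance(1, default_model)
    assert p.idle_fraction == pytest.approx(0.93235, abs=1e-5)
    assert p.idle_fraction > 0.90
    assert p.p_wait == pytest.approx(A_SINGLE)


@pytest.mark.parametrize("k", [1, 2, 5])
@pytest.mark.parametrize("rate", [0.5, 3.96, 50.0])
def test_littles_law_and_sojourn_identity(k, rate):
    m = DemandModel(arrival_rate=rate)
    p = performance(k, m)
    if p.saturated:
        assert math.isinf(p.W) and p.p_wait == 1.0
        return
    lam_min = m.arrival_rate_per_min
    assert p.L == pytest.approx(lam_min * p.W, rel=1e-12)
    assert p.Lq == pytest.approx(lam_min * p.Wq, rel=1e-12)
    assert p.W == pytest.approx(p.Wq + m.service_mean, rel=1e-12)


def test_empty_system_limit():
    p = performance(1, DemandModel(arrival_rate=1e-9))
    assert p.p_wait == pytest.approx(0.0, abs=1e-10)
    assert p.idle_fraction == pytest.approx(1.0, abs=1e-10)


def test_saturated_system_flagged_not_raised():
    p = performance(1, DemandModel(arrival_rate=100.0))
    assert p.saturated and math.isinf(p.Wq) and p.p_wait == 1.0


# -- inverse problems -------------------------------------------------------


def test_min_servers_single_district_needs_two(default_model):
    # C(1, a) = a = 0.06765 > 0.05, so one physician misses the target
    assert erlang_c(1, A_SINGLE) > 0.05
    assert min_servers(default_model, 0.05) == 2


def test_min_servers_twenty_districts_needs_five(default_model):
    agg = default_model.scaled(20)
    assert min_servers(agg, 0.05) == 5
    assert erlang_c(4, A_TWENTY) > 0.05 >= erlang_c(5, A_TWENTY)


def test_min_servers_loose_target_gives_bare_stability(default_model):
    agg = default_model.scaled(100)  # a = 6.765
    assert min_servers(agg, 0.999999) == math.floor(agg.offered_load) + 1


def test_max_arrival_rate_closed_form_single_server():
    # k=1: C = rho, so lambda_max = target * 1440 / E[S]
    assert max_arrival_rate(1, 24.6, 0.05) == pytest.approx(2.926829268, rel=1e-6)
    assert max_arrival_rate(1, 24.6, 0.5) == pytest.approx(29.26829268, rel=1e-6)


def test_max_arrival_rate_monotone_in_k():
    rates = [max_arrival_rate(k, 24.6, 0.05) for k in range(1, 8)]
    assert all(b > a for a, b in zip(rates, rates[1:]))


def test_min_servers_and_max_rate_mutually_consistent(default_model):
    for d in (1, 5, 20, 50):
        agg = default_model.scaled(d)
        a = agg.offered_load
        k = min_servers(agg, 0.05)
        assert erlang_c(k, a) <= 0.05
        if k - 1 >= 1:
            assert erlang_c(k - 1, a) > 0.05
        # the pool sized for this demand sustains at least this demand
        assert max_arrival_rate(k, 24.6, 0.05) >= agg.arrival_rate


def test_max_supported_units():
    assert max_supported_units(1, 0.1, 24.6, 0.05) == 29
    assert max_supported_units(1, 5.0, 24.6, 0.05) == 0  # unit rate > capacity
    # doubling the per-unit rate halves the count up to flooring
    n1 = max_supported_units(2, 0.1, 24.6, 0.05)
    n2 = max_supported_units(2, 0.2, 24.6, 0.05)
    assert n2 == n1 // 2 or n2 == (n1 - 1) // 2
    with pytest.raises(ValidationError, match="per_unit_rate"):
        max_supported_units(1, 0.0, 24.6, 0.05)


# -- empirical rate estimation ----------------------------------------------


def test_estimate_rates_arithmetic_and_empty(one_year_log):
    rate, mean = estimate_rates(one_year_log, 365)
    assert rate == pytest.approx(len(one_year_log) / 365)
    assert estimate_rates([], 10) == (0.0, None)


def test_estimate_rates_recovers_defaults_at_long_horizon(default_model):
    from tepqueue import generate_log

    log = generate_log(default_model, 10 * 365, seed=99)
    rate, mean = estimate_rates(log, 10 * 365)
    assert rate == pytest.approx(3.96, rel=0.02)
    assert mean == pytest.approx(24.6, rel=0.02)
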