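"""Currency conversion, annuitization, tax rule and opportunity costs."""

import pytest

from nutricost.codes import Nature
from nutricost.valuation import (
    BeneficiaryTimeProfile,
    Moments,
    NotAnnuitizable,
    ValuationError,
    ValuationParams,
    WorkerEconomicProfile,
    annualize_capital,
    annuity_factor,
    apply_tax_rule,
    hourly_rate_from_monthly_salary,
    to_usd_2019,
    value_beneficiary_time,
    value_worker_economic,
)

PARAMS = ValuationParams()


# ---------------------------------------------------------------------------
# currency / inflation


def test_bdt_conversion_at_programme_rate():
    assert to_usd_2019(84_770.0, "BDT", 2019, PARAMS) == pytest.approx(1000.0)


def test_usd_identity():
    assert to_usd_2019(100.0, "USD", 2019, PARAMS) == pytest.approx(100.0)


def test_deflator_reprices_to_2019():
    params = ValuationParams(
        inflation_index={2017: 0.95, 2018: 1.0, 2019: 1.0, 2016: 1.0, 2020: 1.0}
    )
    assert to_usd_2019(84_770.0, "BDT", 2017, params) == pytest.approx(1000.0 / 0.95)


def test_unknown_year_and_currency_rejected():
    with pytest.raises(ValuationError):
        to_usd_2019(1.0, "BDT", 1999, PARAMS)
    with pytest.raises(ValuationError):
        to_usd_2019(1.0, "EUR", 2019, PARAMS)


# ---------------------------------------------------------------------------
# annuitization


def brute_force_annual_payment(price, rate, n_years):
    """Independent oracle: constant payment a with sum a/(1+r)^t = price."""
    discounted_sum = sum(1.0 / (1.0 + rate) ** t for t in range(1, int(n_years) + 1))
    return price / discounted_sum


def test_annuity_factor_matches_discounted_sum_oracle():
    af = annuity_factor(0.03, 10)
    oracle = sum(1.0 / 1.03**t for t in range(1, 11))
    assert af == pytest.approx(oracle, abs=1e-9)


def test_annualize_capital_base_case():
    annual = annualize_capital(1000.0, PARAMS)
    assert annual == pytest.approx(brute_force_annual_payment(1000.0, 0.03, 10), abs=1e-9)
    assert round(annual, 2) == 117.23


def test_straight_line_limit_at_zero_rate():
    params = ValuationParams().model_copy(update={"discount_rate": 1e-12})
    assert annualize_capital(500.0, params) == pytest.approx(50.0, abs=1e-6)


def test_below_threshold_is_expensed():
    with pytest.raises(NotAnnuitizable):
        annualize_capital(90.0, PARAMS)
    with pytest.raises(NotAnnuitizable):
        annualize_capital(500.0, PARAMS, life_years=1.0)


def test_annual_cost_monotone_in_rate_and_life():
    rates = [0.01, 0.03, 0.05, 0.10]
    annuals = [annualize_capital(1000.0, PARAMS.model_copy(update={"discount_rate": r})) for r in rates]
    assert annuals == sorted(annuals)
    lives = [2, 5, 10, 20]
    annuals = [annualize_capital(1000.0, PARAMS, life_years=n) for n in lives]
    assert annuals == sorted(annuals, reverse=True)


def test_one_year_annuity_factor_is_discount():
    # at n=1 the equivalent annual cost is price * (1+r)
    assert 1000.0 / annuity_factor(0.03, 1) == pytest.approx(1030.0)


# ---------------------------------------------------------------------------
# tax rule


@pytest.mark.parametrize(
    "amount,tax,durable,nature,expected",
    [
        (110.0, 10.0, True, Nature.ECONOMIC, 100.0),  # durable: tax excluded
        (110.0, 10.0, False, Nature.ECONOMIC, 110.0),  # small supply keeps tax
        (110.0, 10.0, True, Nature.FINANCIAL, 110.0),  # financial keeps all
        (110.0, 10.0, False, Nature.FINANCIAL, 110.0),
    ],
)
def test_apply_tax_rule(amount, tax, durable, nature, expected):
    assert apply_tax_rule(amount, tax, durable, nature) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# worker economic costs


def one_worker(rate=1.0, oop_scale=1.0):
    return WorkerEconomicProfile(
        n_workers=1, time_valuation_rate_usd_per_hour=rate, oop_scale=oop_scale
    )


def test_worker_oop_full_window_matches_period_sum():
    # month-by-month: 17 months at 6.55, 16 at 4.31, 7 at 1.45
    val = value_worker_economic(one_worker(), 40)
    assert val.oop_usd == pytest.approx(17 * 6.55 + 16 * 4.31 + 7 * 1.45)
    assert val.oop_usd == pytest.approx(190.46)


def test_worker_oop_partial_window_clips_periods():
    val = value_worker_economic(one_worker(), 34)  # one month into the last period
    assert val.oop_usd == pytest.approx(17 * 6.55 + 16 * 4.31 + 1 * 1.45)


def test_worker_overtime_includes_travel_hours():
    val = value_worker_economic(one_worker(rate=2.0), 10)
    assert val.overtime_usd == pytest.approx((4.24 + 19.65) * 10 * 2.0)


def test_zero_rate_zeroes_overtime():
    assert value_worker_economic(one_worker(rate=0.0), 40).overtime_usd == 0.0


def test_worker_value_linear_in_workers_and_months():
    base = value_worker_economic(one_worker(), 40)
    five = value_worker_economic(
        one_worker().model_copy(update={"n_workers": 5}), 40
    )
    assert five.total_usd == pytest.approx(5 * base.total_usd)
    half_hours = value_worker_economic(one_worker(), 20)
    assert half_hours.overtime_usd == pytest.approx(base.overtime_usd / 2)


def test_oop_periods_must_partition_window():
    profile = WorkerEconomicProfile()
    periods = [p.model_copy(update={"month_end": p.month_end - 1}) for p in profile.oop_periods]
    with pytest.raises(ValueError):
        WorkerEconomicProfile(oop_periods=periods)


def test_hourly_rate_from_contracted_week():
    # monthly salary spread over 36 h/week * 52/12 weeks/month
    assert hourly_rate_from_monthly_salary(156.0) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# beneficiary opportunity costs


def test_beneficiary_time_hand_chain():
    # 1 woman, 40 months at 1.8 h/month = 72 h; 200 BDT/day over 8 h = 25 BDT/h;
    # 1800 BDT at 84.77 BDT/USD = 21.23 USD
    profile = BeneficiaryTimeProfile(daily_wage_bdt={"men": 300.0, "women": 200.0})
    out = value_beneficiary_time(profile, {4: {"women": 1}}, 40, PARAMS)
    assert out[4] == pytest.approx(1800.0 / 84.77)
    assert round(out[4], 2) == 21.23


def test_beneficiary_zero_hours_zero_cost():
    profile = BeneficiaryTimeProfile(
        hours_per_month={"men": Moments(mean=0.0, sd=0.0), "women": Moments(mean=0.0, sd=0.0)}
    )
    out = value_beneficiary_time(profile, {"pooled": {"men": 10, "women": 10}}, 40, PARAMS)
    assert out["pooled"] == 0.0


def test_beneficiary_value_linear_in_wage_and_counts():
    base = BeneficiaryTimeProfile()
    doubled = BeneficiaryTimeProfile(daily_wage_bdt={"men": 600.0, "women": 500.0})
    counts = {"pooled": {"men": 7, "women": 11}}
    v1 = value_beneficiary_time(base, counts, 40, PARAMS)["pooled"]
    v2 = value_beneficiary_time(doubled, counts, 40, PARAMS)["pooled"]
    assert v2 == pytest.approx(2 * v1)
    v3 = value_beneficiary_time(
        base, {"pooled": {"men": 14, "women": 22}}, 40, PARAMS
    )["pooled"]
    assert v3 == pytest.approx(2 * v1)
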