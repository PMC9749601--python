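"""Economic valuation: nominal money and survey time into 2019 USD.

Covers the four valuation rules of the costing framework:

* currency conversion (BDT at 84.77 per USD) and inflation adjustment to a
  2019 price base via an annual deflator series indexed to 2019;
* annuitization of capital goods above the USD 100 threshold over their
  useful life at a 3% discount rate, charged pro rata over the
  implementation window;
* tax treatment — financial costs keep taxes; economic valuation of
  durable goods excludes them; small supplies keep tax in both;
* opportunity-cost valuation of unpaid frontline-worker time (hours above
  the contracted 36-hour week, priced at an hourly rate derived from the
  contracted salary) plus out-of-pocket outlays, and of beneficiary
  participation time priced at local daily agricultural wages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .codes import PROGRAMME_MONTHS, Cadre, Nature

#: Hours of the contracted frontline-worker week.
CONTRACTED_WEEK_HOURS = 36.0
#: Average weeks per month used to convert weekly to monthly hours.
WEEKS_PER_MONTH = 52.0 / 12.0


class ValuationError(ValueError):
    pass


class NotAnnuitizable(ValuationError):
    """Signal that a purchase is an expense, not capital to annuitize."""


class ValuationParams(BaseModel):
    """Programme-wide valuation parameters (2019 USD price base).

    ``inflation_index`` maps calendar year to a price index relative to
    2019 (identity by default); a nominal USD amount from year *y* is
    expressed in 2019 prices as ``amount / inflation_index[y]``.
    """

    model_config = ConfigDict(extra="forbid")

    exchange_rate_bdt_per_usd: float = 84.77
    discount_rate: float = 0.03
    useful_life_years: float = 10.0
    capital_threshold_usd: float = 100.0
    inflation_index: dict[int, float] = {
        2016: 1.0,
        2017: 1.0,
        2018: 1.0,
        2019: 1.0,
        2020: 1.0,
    }
    annualization_months: int = PROGRAMME_MONTHS
    hours_per_workday: float = 8.0

    @model_validator(mode="after")
    def _positive(self) -> "ValuationParams":
        for name in (
            "exchange_rate_bdt_per_usd",
            "discount_rate",
            "useful_life_years",
            "capital_threshold_usd",
            "hours_per_workday",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.annualization_months <= 0:
            raise ValueError("annualization_months must be positive")
        if abs(self.inflation_index.get(2019, 0.0) - 1.0) > 1e-9:
            raise ValueError("inflation_index must be indexed to 2019 (index[2019] == 1)")
        if any(v <= 0 for v in self.inflation_index.values()):
            raise ValueError("inflation index values must be positive")
        return self

    @property
    def years(self) -> float:
        return self.annualization_months / 12.0


def to_usd_2019(
    amount: float, currency: str, year: int, params: ValuationParams
) -> float:
    """Convert a nominal amount to 2019 USD.

    BDT divides by the exchange rate; USD skips conversion; the result is
    deflated/inflated to the 2019 price base by the annual index.
    """
    cur = currency.upper()
    if cur == "BDT":
        usd = amount / params.exchange_rate_bdt_per_usd
    elif cur == "USD":
        usd = amount
    else:
        raise ValuationError(f"unsupported currency {currency!r}")
    if year not in params.inflation_index:
        raise ValuationError(f"no inflation index for calendar year {year}")
    return usd / params.inflation_index[year]


def annuity_factor(rate: float, n_years: float) -> float:
    """Present value of a 1-per-year annuity: (1 - (1+r)^-n) / r (n at r→0)."""
    if n_years <= 0:
        raise ValuationError("annuity horizon must be positive")
    if rate < 0:
        raise ValuationError("discount rate must be nonnegative")
    if rate < 1e-9:  # straight-line limit; avoids catastrophic cancellation
        return float(n_years)
    return (1.0 - (1.0 + rate) ** -n_years) / rate


def annualize_capital(
    price: float, params: ValuationParams, life_years: Optional[float] = None
) -> float:
    """Equivalent annual cost of a capital good: price / annuity factor.

    Raises :class:`NotAnnuitizable` for purchases at or below the capital
    threshold or lasting a year or less — these are expensed in full.  The
    total charged to the programme is the annual value times
    ``params.years``.
    """
    n = params.useful_life_years if life_years is None else life_years
    if price <= params.capital_threshold_usd:
        raise NotAnnuitizable(
            f"price {price:.2f} USD at or below the {params.capital_threshold_usd:.0f} USD "
            "capital threshold: expense, do not annuitize"
        )
    if n <= 1.0:
        raise NotAnnuitizable("useful life of one year or less: expense, do not annuitize")
    return price / annuity_factor(params.discount_rate, n)


def apply_tax_rule(
    amount: float, tax_amount: float, durable: bool, nature: Nature
) -> float:
    """Tax treatment of a valued amount.

    Financial valuation keeps the full amount.  Economic valuation excludes
    the tax component of durable goods; small supplies (non-durables) keep
    tax in both valuations.
    """
    if nature is Nature.FINANCIAL:
        return amount
    if durable:
        return amount - tax_amount
    return amount


# ---------------------------------------------------------------------------
# micro-costing survey profiles


class Moments(BaseModel):
    """A (mean, sd) summary of a nonnegative survey quantity."""

    model_config = ConfigDict(extra="forbid")

    mean: float
    sd: float

    @field_validator("mean", "sd")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("moments must be nonnegative")
        return v


class OopPeriod(BaseModel):
    """One stipend regime: month range (inclusive) and monthly OOP moments.

    The monthly means are treated as already net of travel stipends.
    """

    model_config = ConfigDict(extra="forbid")

    label: str
    month_start: int
    month_end: int
    oop_usd: Moments

    @property
    def n_months(self) -> int:
        return self.month_end - self.month_start + 1


class WorkerEconomicProfile(BaseModel):
    """Survey moments for frontline-worker unpaid time and OOP outlays.

    ``time_valuation_rate_usd_per_hour`` prices hours beyond the contracted
    week (a single rate covers extra work and travel hours);
    ``oop_scale`` rescales the survey OOP means onto the cadre roster
    (calibration factor recorded by the data generator).
    """

    model_config = ConfigDict(extra="forbid")

    cadre: Cadre = Cadre.PK
    n_workers: int = 80
    overtime_hours_per_month: Moments = Moments(mean=4.24, sd=2.34)
    travel_hours_per_month: Moments = Moments(mean=19.65, sd=10.28)
    oop_periods: list[OopPeriod] = [
        OopPeriod(label="before March 2018 (no stipend)", month_start=0, month_end=16,
                  oop_usd=Moments(mean=6.55, sd=3.02)),
        OopPeriod(label="March 2018 - June 2019 (200 BDT stipend)", month_start=17,
                  month_end=32, oop_usd=Moments(mean=4.31, sd=2.78)),
        OopPeriod(label="after June 2019 (500 BDT stipend)", month_start=33,
                  month_end=39, oop_usd=Moments(mean=1.45, sd=2.00)),
    ]
    time_valuation_rate_usd_per_hour: float = 0.25
    oop_scale: float = 1.0

    @model_validator(mode="after")
    def _periods_partition(self) -> "WorkerEconomicProfile":
        if self.n_workers < 0:
            raise ValueError("n_workers must be >= 0")
        if self.time_valuation_rate_usd_per_hour < 0 or self.oop_scale < 0:
            raise ValueError("rates and scales must be nonnegative")
        months: list[int] = []
        for p in self.oop_periods:
            if p.month_end < p.month_start:
                raise ValueError(f"period {p.label!r} has month_end < month_start")
            months.extend(range(p.month_start, p.month_end + 1))
        if sorted(months) != list(range(PROGRAMME_MONTHS)):
            raise ValueError("OOP periods must partition the analysis months 0..39")
        return self


@dataclass
class WorkerEconomicValue:
    overtime_usd: float
    oop_usd: float

    @property
    def total_usd(self) -> float:
        return self.overtime_usd + self.oop_usd


def value_worker_economic(profile: WorkerEconomicProfile, months: int) -> WorkerEconomicValue:
    """Economic cost of one cadre over the first ``months`` of the window.

    Unpaid time = workers x (extra-work + travel hours per month) x months
    x the hourly valuation rate; OOP sums each stipend period's monthly
    mean over the months it overlaps the window.  Linear in ``n_workers``
    and in ``months``.
    """
    if not 0 <= months <= PROGRAMME_MONTHS:
        raise ValuationError(f"months must be in [0, {PROGRAMME_MONTHS}]")
    hours = profile.overtime_hours_per_month.mean + profile.travel_hours_per_month.mean
    overtime = (
        profile.n_workers * hours * months * profile.time_valuation_rate_usd_per_hour
    )
    oop = 0.0
    for p in profile.oop_periods:
        overlap = max(0, min(months - 1, p.month_end) - p.month_start + 1)
        oop += overlap * p.oop_usd.mean
    oop *= profile.n_workers * profile.oop_scale
    return WorkerEconomicValue(overtime_usd=overtime, oop_usd=oop)


def hourly_rate_from_monthly_salary(monthly_salary_usd: float) -> float:
    """Hourly valuation rate implied by a monthly salary and the contracted
    36-hour week (salary / (36 x 52/12))."""
    if monthly_salary_usd < 0:
        raise ValuationError("salary must be >= 0")
    return monthly_salary_usd / (CONTRACTED_WEEK_HOURS * WEEKS_PER_MONTH)


class BeneficiaryTimeProfile(BaseModel):
    """Beneficiary participation time moments and valuation wages by gender.

    Participation hours per person-month come from process-evaluation
    moments; time is priced at mean daily agricultural wages (BDT) divided
    by the standard workday, converted at the programme exchange rate.
    ``wage_scale`` is a recorded calibration factor on the wage bill.
    """

    model_config = ConfigDict(extra="forbid")

    hours_per_month: dict[str, Moments] = {
        "men": Moments(mean=0.96, sd=1.22),
        "women": Moments(mean=1.8, sd=1.66),
    }
    daily_wage_bdt: dict[str, float] = {"men": 300.0, "women": 250.0}
    wage_scale: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "BeneficiaryTimeProfile":
        if set(self.hours_per_month) != {"men", "women"}:
            raise ValueError("hours_per_month requires exactly the keys 'men' and 'women'")
        if set(self.daily_wage_bdt) != {"men", "women"}:
            raise ValueError("daily_wage_bdt requires exactly the keys 'men' and 'women'")
        if any(w <= 0 for w in self.daily_wage_bdt.values()):
            raise ValueError("daily wages must be positive")
        if self.wage_scale < 0:
            raise ValueError("wage_scale must be nonnegative")
        return self

    def hourly_wage_usd(self, gender: str, params: ValuationParams) -> float:
        return (
            self.daily_wage_bdt[gender]
            / params.hours_per_workday
            / params.exchange_rate_bdt_per_usd
        )


def value_beneficiary_time(
    profile: BeneficiaryTimeProfile,
    roster_counts: Mapping,
    months: int,
    params: ValuationParams,
) -> dict:
    """Opportunity cost of beneficiary participation, per roster group.

    ``roster_counts`` maps a group key (e.g. an arm, or ``"pooled"``) to
    ``{"men": count, "women": count}``.  Per person: hours/month x months
    x hourly wage (daily wage / workday hours, converted to USD), scaled
    by the recorded wage calibration factor.  Linear in counts and months.
    """
    if months < 0:
        raise ValuationError("months must be >= 0")
    out = {}
    for group, counts in roster_counts.items():
        total = 0.0
        for gender, n in counts.items():
            if n < 0:
                raise ValuationError("beneficiary counts must be >= 0")
            hours = profile.hours_per_month[gender].mean * months
            total += n * hours * profile.hourly_wage_usd(gender, params)
        out[group] = total * profile.wage_scale
    return out
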