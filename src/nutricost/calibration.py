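"""Calibration of the costing model to a published cost structure.

The programme's reported summary margins — financial costs by activity,
input and stage, economic costs by activity and stream, and annual cost
per household by treatment arm — are the calibration surface for both the
synthetic ledger generator and the base-case economic model.  This module
holds those default targets and the solvers that turn them into a fully
specified :class:`~nutricost.config.AnalysisConfig`:

* the hourly valuation rate for unpaid frontline-worker time and the OOP
  roster scale, solved so the worker economic streams hit their margins;
* the wage scale on beneficiary time, solved so the beneficiary
  opportunity-cost margin is met at the declared synthetic daily wages;
* activity shares for each economic stream, solved under the constraint
  that staff-only activities receive only staff time while beneficiary
  time flows only to field-facing activities;
* the component-scope rule (forced scopes plus residual shares of shared
  costs), solved so the additive-design arm totals reproduce the reported
  annual costs per household.

All solvers are deterministic arithmetic on the targets; nothing here is
fitted to simulation output.
"""

from __future__ import annotations

from typing import Mapping

from pydantic import BaseModel, ConfigDict, model_validator

from .allocation import CodingRules, KeywordRule, ScopeRule, TimeAllocationProfile
from .codes import (
    FIELD_ACTIVITIES,
    ONE_TIME_ACTIVITIES,
    PROGRAMME_MONTHS,
    Activity,
    Cadre,
    ComponentScope,
    InputCategory,
)
from .config import ECON_STREAMS, AnalysisConfig
from .cube import Roster
from .valuation import (
    BeneficiaryTimeProfile,
    ValuationParams,
    WorkerEconomicProfile,
    value_beneficiary_time,
    value_worker_economic,
)

_TOL = 0.02  # dollars; summary margins are printed to cents


class CalibrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# default calibration surface: the programme's reported cost structure
# (3.5-year multisectoral agriculture-nutrition programme, 2019 USD)

DEFAULT_FINANCIAL_INPUT_MARGIN: dict[InputCategory, float] = {
    InputCategory.PERSONNEL_HIRED: 362_654.50,
    InputCategory.SUPPLIES: 56_250.25,
    InputCategory.AGRICULTURE_SUPPLIES: 2_196.27,
    InputCategory.AGRICULTURE_EQUIPMENT: 5.81,
    InputCategory.CONTRACTED_SERVICES: 49_150.36,
    InputCategory.FUEL_MAINTENANCE: 19.69,
    InputCategory.TRAVEL_PERDIEM_ALLOWANCES: 81_937.52,
    InputCategory.OVERHEAD: 46_364.50,
}

DEFAULT_FINANCIAL_ACTIVITY_MARGIN: dict[Activity, float] = {
    Activity.PLANNING_MICROPLANNING: 32_678.56,
    Activity.PROGRAMME_INSTALLATION: 1_171.23,
    Activity.AWARENESS_RAISING: 1_089.92,
    Activity.TRAINING: 74_981.41,
    Activity.MATERIALS_DEVELOPMENT: 10_833.70,
    Activity.MANAGEMENT: 4_493.32,
    Activity.MONITORING_EVALUATION: 72_568.92,
    Activity.PROCUREMENT: 6_724.76,
    Activity.DISTRIBUTION_OF_INPUTS: 5_050.17,
    Activity.SITE_SUPERVISION: 93_101.67,
    Activity.HOME_VISITS_NUTRITION_GENDER: 161_760.07,
    Activity.HOME_VISITS_AGRICULTURE: 60_323.57,
    Activity.COMMUNITY_EVENTS: 30_139.95,
    Activity.INTEGRATION_COORDINATION: 11_076.85,
    Activity.INDIRECT_OVERHEAD: 32_584.80,
}

#: One-time launch spending in the first six months.
DEFAULT_STARTUP_FINANCIAL_TOTAL = 37_950.02

DEFAULT_ECONOMIC_ACTIVITY_MARGIN: dict[Activity, float] = {
    Activity.PLANNING_MICROPLANNING: 757.08,
    Activity.TRAINING: 17_293.66,
    Activity.MONITORING_EVALUATION: 2_649.77,
    Activity.HOME_VISITS_NUTRITION_GENDER: 128_936.16,
    Activity.HOME_VISITS_AGRICULTURE: 33_049.53,
    Activity.COMMUNITY_EVENTS: 13_447.68,
    Activity.INTEGRATION_COORDINATION: 327.56,
}

#: Economic streams and the input-margin totals they must reproduce:
#: unpaid frontline-worker time -> hired personnel; worker OOP -> travel;
#: beneficiary participation time -> beneficiary personnel.
DEFAULT_ECONOMIC_STREAM_TOTALS: dict[str, float] = {
    "overtime": 19_014.29,
    "oop": 15_111.39,
    "beneficiary": 162_335.76,
}

ECON_STREAM_INPUT: dict[str, InputCategory] = {
    "overtime": InputCategory.PERSONNEL_HIRED,
    "oop": InputCategory.TRAVEL_PERDIEM_ALLOWANCES,
    "beneficiary": InputCategory.PERSONNEL_BENEFICIARIES,
}

#: Reported annual incremental cost per household under the additive design.
DEFAULT_ARM_ANNUAL_COST_PER_HOUSEHOLD: dict[int, float] = {2: 36.62, 3: 65.18, 4: 87.50}


class CostStructureTargets(BaseModel):
    """Margin targets the calibrated model (and synthetic ledger) must hit."""

    model_config = ConfigDict(extra="forbid")

    financial_input: dict[InputCategory, float] = dict(DEFAULT_FINANCIAL_INPUT_MARGIN)
    financial_activity: dict[Activity, float] = dict(DEFAULT_FINANCIAL_ACTIVITY_MARGIN)
    startup_financial: float = DEFAULT_STARTUP_FINANCIAL_TOTAL
    economic_activity: dict[Activity, float] = dict(DEFAULT_ECONOMIC_ACTIVITY_MARGIN)
    economic_streams: dict[str, float] = dict(DEFAULT_ECONOMIC_STREAM_TOTALS)
    arm_annual_cost_per_household: dict[int, float] = dict(
        DEFAULT_ARM_ANNUAL_COST_PER_HOUSEHOLD
    )

    @model_validator(mode="after")
    def _consistent(self) -> "CostStructureTargets":
        fin_i = sum(self.financial_input.values())
        fin_a = sum(self.financial_activity.values())
        if abs(fin_i - fin_a) > _TOL:
            raise ValueError(
                "inconsistent financial margins: input total "
                f"{fin_i:.2f} != activity total {fin_a:.2f}"
            )
        eco_s = sum(self.economic_streams.values())
        eco_a = sum(self.economic_activity.values())
        if abs(eco_s - eco_a) > _TOL:
            raise ValueError(
                "inconsistent economic margins: stream total "
                f"{eco_s:.2f} != activity total {eco_a:.2f}"
            )
        if set(self.economic_streams) != set(ECON_STREAMS):
            raise ValueError(f"economic_streams must name exactly {ECON_STREAMS}")
        one_time_fin = sum(
            self.financial_activity.get(a, 0.0) for a in ONE_TIME_ACTIVITIES
        )
        if self.startup_financial > one_time_fin + _TOL:
            raise ValueError(
                "start-up total exceeds spending on one-time launch activities"
            )
        if any(v < 0 for v in self.financial_input.values()):
            raise ValueError("financial input margins must be nonnegative")
        if any(v < 0 for v in self.financial_activity.values()):
            raise ValueError("financial activity margins must be nonnegative")
        return self

    @property
    def financial_total(self) -> float:
        return sum(self.financial_input.values())

    @property
    def economic_total(self) -> float:
        return sum(self.economic_streams.values())

    @property
    def grand_total(self) -> float:
        return self.financial_total + self.economic_total


# ---------------------------------------------------------------------------
# solvers


def solve_worker_profile(
    targets: CostStructureTargets,
    n_workers: int = 80,
    months: int = PROGRAMME_MONTHS,
    base: WorkerEconomicProfile | None = None,
) -> WorkerEconomicProfile:
    """Worker profile whose base-case streams hit the worker margins.

    The hourly rate on unpaid time and the OOP roster scale are the two
    free factors; survey moments stay untouched.
    """
    base = base or WorkerEconomicProfile()
    hours = base.overtime_hours_per_month.mean + base.travel_hours_per_month.mean
    denom = n_workers * hours * months
    if denom <= 0:
        raise CalibrationError("worker overtime denominator is zero")
    rate = targets.economic_streams["overtime"] / denom
    unit = value_worker_economic(
        base.model_copy(update={"n_workers": n_workers, "oop_scale": 1.0}), months
    )
    if unit.oop_usd <= 0:
        raise CalibrationError("worker OOP base value is zero")
    oop_scale = targets.economic_streams["oop"] / unit.oop_usd
    return base.model_copy(
        update={
            "n_workers": n_workers,
            "time_valuation_rate_usd_per_hour": rate,
            "oop_scale": oop_scale,
        }
    )


def pooled_gender_counts(roster: Roster) -> dict[str, int]:
    """Index women (one per household) and their spouses, pooled over arms."""
    women = sum(roster.households.values())
    men = sum(roster.index_pair.values()) - women
    return {"men": men, "women": women}


def solve_beneficiary_profile(
    targets: CostStructureTargets,
    roster: Roster,
    params: ValuationParams,
    months: int = PROGRAMME_MONTHS,
    base: BeneficiaryTimeProfile | None = None,
) -> BeneficiaryTimeProfile:
    """Beneficiary profile whose pooled base-case value hits the margin,
    by solving the wage scale at the declared synthetic daily wages."""
    base = base or BeneficiaryTimeProfile()
    unscaled = value_beneficiary_time(
        base.model_copy(update={"wage_scale": 1.0}),
        {"pooled": pooled_gender_counts(roster)},
        months,
        params,
    )["pooled"]
    if unscaled <= 0:
        raise CalibrationError("beneficiary base value is zero")
    return base.model_copy(
        update={"wage_scale": targets.economic_streams["beneficiary"] / unscaled}
    )


def solve_econ_activity_shares(
    targets: CostStructureTargets,
) -> dict[str, dict[Activity, float]]:
    """Allocate the three economic streams across activities.

    Constraints: staff-only activities (planning, coordination, M&E, ...)
    are served entirely by unpaid staff time; worker OOP and beneficiary
    time flow only to field-facing activities; every activity's economic
    margin is met exactly.  Remaining staff time spreads over field
    activities proportionally to their margins, OOP proportionally to what
    staff time left uncovered, and beneficiary time takes the residual.
    """
    act = {a: v for a, v in targets.economic_activity.items() if v > 0}
    staff = {a: v for a, v in act.items() if a not in FIELD_ACTIVITIES}
    field = {a: v for a, v in act.items() if a in FIELD_ACTIVITIES}
    ot_total = targets.economic_streams["overtime"]
    oop_total = targets.economic_streams["oop"]
    ben_total = targets.economic_streams["beneficiary"]

    staff_sum = sum(staff.values())
    if staff_sum > ot_total + _TOL:
        raise CalibrationError(
            "staff-only economic margins exceed the unpaid staff-time stream"
        )
    alloc_ot: dict[Activity, float] = dict(staff)
    rest_ot = ot_total - staff_sum
    field_sum = sum(field.values())
    if field_sum <= 0 and (rest_ot > _TOL or oop_total > _TOL or ben_total > _TOL):
        raise CalibrationError("no field activities to carry field-facing streams")
    for a, v in field.items():
        alloc_ot[a] = rest_ot * v / field_sum

    resid = {a: field[a] - alloc_ot.get(a, 0.0) for a in field}
    resid_sum = sum(resid.values())
    alloc_oop = (
        {a: oop_total * r / resid_sum for a, r in resid.items()} if resid_sum > 0 else {}
    )

    alloc_ben = {
        a: field[a] - alloc_ot.get(a, 0.0) - alloc_oop.get(a, 0.0) for a in field
    }
    if any(v < -_TOL for v in alloc_ben.values()):
        raise CalibrationError("negative beneficiary-time allocation; margins infeasible")
    ben_sum = sum(alloc_ben.values())
    if abs(ben_sum - ben_total) > _TOL:
        raise CalibrationError(
            f"beneficiary residual {ben_sum:.2f} != stream total {ben_total:.2f}"
        )

    def shares(alloc: Mapping[Activity, float], total: float) -> dict[Activity, float]:
        if total <= 0:
            return {}
        return {a: v / total for a, v in alloc.items() if v > 0}

    return {
        "overtime": shares(alloc_ot, ot_total),
        "oop": shares(alloc_oop, oop_total),
        "beneficiary": shares(alloc_ben, ben_total),
    }


#: Activities pinned to a component by what they are.
FORCED_SCOPE_ACTIVITIES = (
    Activity.HOME_VISITS_AGRICULTURE,
    Activity.DISTRIBUTION_OF_INPUTS,
    Activity.HOME_VISITS_NUTRITION_GENDER,
)


def solve_scope_rule(
    targets: CostStructureTargets,
    roster: Roster,
    nutrition_gender_split: float = 0.8,
    months: int = PROGRAMME_MONTHS,
) -> ScopeRule:
    """Component-scope rule reproducing the reported arm cost gradient.

    Under the additive design with household-proportional arm allocation,
    the reported annual costs per household pin down the totals borne by
    the nutrition/platform, agriculture and gender components.  Activities
    with an intrinsic component keep it (agricultural visits and input
    distribution -> agriculture; combined nutrition/gender home visits
    split by the configured sub-split); the rule solves what share of all
    remaining shared costs each component must carry.
    """
    years = months / 12.0
    hh = roster.households
    hh_total = sum(hh.values())
    t_arm = {
        arm: targets.arm_annual_cost_per_household[arm] * hh[arm] * years
        for arm in (2, 3, 4)
    }
    np_total = t_arm[2] * hh_total / hh[2]
    ag_total = (t_arm[3] - np_total * hh[3] / hh_total) * (hh[3] + hh[4]) / hh[3]
    g_total = t_arm[4] - np_total * hh[4] / hh_total - ag_total * hh[4] / (hh[3] + hh[4])
    if min(np_total, ag_total, g_total) < 0:
        raise CalibrationError("arm cost targets imply a negative component total")

    grand = targets.grand_total
    scale = grand / (np_total + ag_total + g_total)
    np_total, ag_total, g_total = (x * scale for x in (np_total, ag_total, g_total))

    act_total = {
        a: targets.financial_activity.get(a, 0.0) + targets.economic_activity.get(a, 0.0)
        for a in Activity
    }
    forced_ag = (
        act_total[Activity.HOME_VISITS_AGRICULTURE]
        + act_total[Activity.DISTRIBUTION_OF_INPUTS]
    )
    hvn = act_total[Activity.HOME_VISITS_NUTRITION_GENDER]
    forced_n = nutrition_gender_split * hvn
    forced_g = (1.0 - nutrition_gender_split) * hvn

    residual_pool = grand - forced_ag - hvn
    resid = {
        ComponentScope.PLATFORM_WIDE: np_total - forced_n,
        ComponentScope.AGRICULTURE: ag_total - forced_ag,
        ComponentScope.GENDER: g_total - forced_g,
    }
    if any(v < -_TOL for v in resid.values()):
        raise CalibrationError(
            "forced component costs exceed a component total; "
            f"residuals {resid} infeasible"
        )
    if residual_pool <= 0:
        raise CalibrationError("no shared costs left to carry residual components")
    residual_shares = {s: max(v, 0.0) / residual_pool for s, v in resid.items()}
    # absorb float slack so the shares sum to exactly 1
    slack = 1.0 - sum(residual_shares.values())
    residual_shares[ComponentScope.PLATFORM_WIDE] += slack

    forced = {
        Activity.HOME_VISITS_AGRICULTURE: {ComponentScope.AGRICULTURE: 1.0},
        Activity.DISTRIBUTION_OF_INPUTS: {ComponentScope.AGRICULTURE: 1.0},
        Activity.HOME_VISITS_NUTRITION_GENDER: {
            ComponentScope.NUTRITION: nutrition_gender_split,
            ComponentScope.GENDER: 1.0 - nutrition_gender_split,
        },
    }
    return ScopeRule(forced=forced, residual_shares=residual_shares)


# ---------------------------------------------------------------------------
# default profiles and rules


def default_time_profiles() -> dict[Cadre, TimeAllocationProfile]:
    """Cadre time-allocation profiles from the implementer interviews:
    nutrition frontline workers (PKs) spend 80% of programme time on
    nutrition counselling visits, 10% on training, 5% on planning and 5%
    on coordination; district managers put 30% FTE into the programme,
    all supervision; field organisers split extension, supervision and
    community events."""
    return {
        Cadre.PK: TimeAllocationProfile(
            cadre=Cadre.PK,
            fte_share_on_programme=1.0,
            activity_shares={
                Activity.HOME_VISITS_NUTRITION_GENDER: 0.80,
                Activity.TRAINING: 0.10,
                Activity.PLANNING_MICROPLANNING: 0.05,
                Activity.INTEGRATION_COORDINATION: 0.05,
            },
        ),
        Cadre.DM: TimeAllocationProfile(
            cadre=Cadre.DM,
            fte_share_on_programme=0.30,
            activity_shares={Activity.SITE_SUPERVISION: 1.0},
        ),
        Cadre.FO: TimeAllocationProfile(
            cadre=Cadre.FO,
            fte_share_on_programme=1.0,
            activity_shares={
                Activity.HOME_VISITS_AGRICULTURE: 0.60,
                Activity.SITE_SUPERVISION: 0.25,
                Activity.COMMUNITY_EVENTS: 0.15,
            },
        ),
    }


def default_coding_rules() -> CodingRules:
    """Keyword and per-input fallback rules for uncoded line items."""
    return CodingRules(
        version="1",
        keyword_rules=[
            KeywordRule(keywords=["training", "workshop"], activity=Activity.TRAINING),
            KeywordRule(keywords=["supervision"], activity=Activity.SITE_SUPERVISION),
            KeywordRule(
                keywords=["monitoring", "evaluation", "survey"],
                activity=Activity.MONITORING_EVALUATION,
            ),
            KeywordRule(
                keywords=["home visit", "counselling"],
                activity=Activity.HOME_VISITS_NUTRITION_GENDER,
            ),
            KeywordRule(
                keywords=["extension", "poultry", "seed"],
                activity=Activity.HOME_VISITS_AGRICULTURE,
            ),
            KeywordRule(
                keywords=["community event", "forum"], activity=Activity.COMMUNITY_EVENTS
            ),
        ],
        input_defaults={
            InputCategory.OVERHEAD: Activity.INDIRECT_OVERHEAD,
            InputCategory.AGRICULTURE_SUPPLIES: Activity.DISTRIBUTION_OF_INPUTS,
            InputCategory.AGRICULTURE_EQUIPMENT: Activity.DISTRIBUTION_OF_INPUTS,
            InputCategory.FUEL_MAINTENANCE: Activity.SITE_SUPERVISION,
        },
    )


def build_analysis_config(
    targets: CostStructureTargets | None = None,
    roster: Roster | None = None,
    params: ValuationParams | None = None,
    n_workers: int = 80,
    nutrition_gender_split: float = 0.8,
) -> AnalysisConfig:
    """Fully calibrated analysis configuration for a cost structure."""
    targets = targets or CostStructureTargets()
    roster = roster or Roster()
    params = params or ValuationParams()
    months = params.annualization_months
    return AnalysisConfig(
        valuation=params,
        coding_rules=default_coding_rules(),
        time_profiles=default_time_profiles(),
        worker=solve_worker_profile(targets, n_workers=n_workers, months=months),
        beneficiary=solve_beneficiary_profile(targets, roster, params, months=months),
        econ_activity_shares=solve_econ_activity_shares(targets),
        scope=solve_scope_rule(
            targets, roster, nutrition_gender_split=nutrition_gender_split, months=months
        ),
        nutrition_gender_split=nutrition_gender_split,
        roster=roster,
        financial_total_usd=targets.financial_total,
    )
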