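"""End-to-end costing run: ledger + configuration -> cost cube -> reports.

Order of operations: code the ledger, expand personnel lines flagged for
time-share allocation, value every line in 2019 USD (currency, inflation,
capital annuitization, tax rule), add the three economic cost streams
(unpaid worker time, worker OOP, beneficiary time) via their activity
allocation profiles, resolve component scopes, split to treatment arms by
household counts, attach typology weights, and assemble the cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allocation import (
    CodedEntry,
    CostCell,
    allocate_personnel,
    allocate_to_arms,
    assign_codes,
    classify_stage,
    map_typology,
    partition_money,
)
from .calibration import ECON_STREAM_INPUT, pooled_gender_counts
from .codes import (
    Activity,
    InputCategory,
    Nature,
    Stage,
    calendar_year,
)
from .config import AnalysisConfig
from .cube import (
    CostCube,
    Denominator,
    Roster,
    UnitCostReport,
    arm_unit_costs,
    build_cube,
    cost_profile,
    round_percent,
    unit_cost,
)
from .ledger import LedgerEntry
from .uncertainty import (
    OUTCOME_NAMES,
    GammaSpec,
    PSAConfig,
    PSAResult,
    TornadoResult,
    run_psa,
    tornado,
)
from .valuation import (
    annualize_capital,
    to_usd_2019,
    value_beneficiary_time,
    value_worker_economic,
)


class PipelineError(ValueError):
    pass


@dataclass
class CostingResult:
    cube: CostCube
    config: AnalysisConfig
    valued_financial_total: float
    economic_stream_totals: dict[str, float]
    excluded_non_programme: float = 0.0
    unresolved: list[str] = field(default_factory=list)

    @property
    def grand_total(self) -> float:
        return self.cube.total


# ---------------------------------------------------------------------------
# valuation of one coded financial entry


def value_financial_entry(entry: LedgerEntry, config: AnalysisConfig) -> float:
    """2019-USD financial value of one line item.

    Durable goods above the capital threshold (unit price, 2019 USD) and
    lasting over a year are charged their equivalent annual cost times the
    implementation years; everything else is expensed in full.  Financial
    valuation keeps taxes.
    """
    params = config.valuation
    year = calendar_year(entry.month_index)
    base = to_usd_2019(entry.amount_nominal, entry.currency, year, params)
    if entry.durable:
        unit_usd = to_usd_2019(entry.unit_price, entry.currency, year, params)
        if unit_usd > params.capital_threshold_usd and (entry.expected_life_years or 0) > 1:
            annual = annualize_capital(base, params, entry.expected_life_years)
            return annual * params.years
    return base


# ---------------------------------------------------------------------------
# cell emission


def _emit_cells(
    activity: Activity,
    input_code: InputCategory,
    stage: Stage,
    nature: Nature,
    amount: float,
    scope_weights: Mapping,
    config: AnalysisConfig,
) -> list[CostCell]:
    if amount <= 0:
        return []
    typology = map_typology(
        activity, config.typology_component_weights, config.nutrition_gender_split
    )
    cells = []
    for scope, part in partition_money(amount, dict(scope_weights)).items():
        if part <= 0:
            continue
        for arm, arm_amt in allocate_to_arms(part, scope, config.roster.households).items():
            if arm_amt > 0:
                cells.append(
                    CostCell(
                        activity=activity,
                        input=input_code,
                        stage=stage,
                        nature=nature,
                        arm=arm,
                        amount_usd2019=arm_amt,
                        typology_weights=typology,
                    )
                )
    return cells


def _financial_cells(
    coded: Sequence[CodedEntry], config: AnalysisConfig
) -> tuple[list[CostCell], float, float]:
    cells: list[CostCell] = []
    valued_total = 0.0
    excluded = 0.0
    for ce in coded:
        e = ce.entry
        usd = value_financial_entry(e, config)
        scope_w = {e.component_scope: 1.0}
        if ce.needs_time_share:
            profile = config.time_profiles.get(e.cadre)
            if profile is None:
                raise PipelineError(
                    f"entry {e.entry_id}: no time-allocation profile for cadre "
                    f"{e.cadre.value if e.cadre else None}"
                )
            alloc = allocate_personnel(usd, profile)
            excluded += usd - sum(alloc.values())
            valued_total += sum(alloc.values())
            for act, amt in alloc.items():
                cells.extend(
                    _emit_cells(
                        act,
                        e.input_code,
                        classify_stage(act, e.month_index),
                        Nature.FINANCIAL,
                        amt,
                        scope_w,
                        config,
                    )
                )
        else:
            valued_total += usd
            cells.extend(
                _emit_cells(
                    ce.activity, e.input_code, ce.stage, Nature.FINANCIAL, usd, scope_w, config
                )
            )
    return cells, valued_total, excluded


def economic_stream_totals(config: AnalysisConfig) -> dict[str, float]:
    """Base-case 2019-USD totals of the three economic streams."""
    months = config.valuation.annualization_months
    wv = value_worker_economic(config.worker, months)
    ben = value_beneficiary_time(
        config.beneficiary,
        {"pooled": pooled_gender_counts(config.roster)},
        months,
        config.valuation,
    )["pooled"]
    return {"overtime": wv.overtime_usd, "oop": wv.oop_usd, "beneficiary": ben}


def _economic_cells(config: AnalysisConfig) -> tuple[list[CostCell], dict[str, float]]:
    totals = economic_stream_totals(config)
    cells: list[CostCell] = []
    for stream, total in totals.items():
        if total <= 0:
            continue
        shares = config.econ_activity_shares.get(stream)
        if not shares:
            raise PipelineError(
                f"economic stream {stream!r} has a positive total but no "
                "activity allocation profile"
            )
        # exact-float split: activity margins must hold to the cent even
        # after the scope and arm partitions round within each cell
        for act, amt in ((a, total * s) for a, s in shares.items()):
            cells.extend(
                _emit_cells(
                    act,
                    ECON_STREAM_INPUT[stream],
                    Stage.RECURRENT,
                    Nature.ECONOMIC,
                    amt,
                    config.scope.scope_weights(act),
                    config,
                )
            )
    return cells, totals


def run_costing(entries: Sequence[LedgerEntry], config: AnalysisConfig) -> CostingResult:
    """Run the full costing pipeline on a ledger."""
    coded = assign_codes(entries, config.coding_rules)
    fin_cells, valued_total, excluded = _financial_cells(coded, config)
    eco_cells, stream_totals = _economic_cells(config)
    cube = build_cube(fin_cells + eco_cells)

    # conservation: cube total == programme-attributable ledger value + streams
    expected = valued_total + sum(stream_totals.values())
    if abs(cube.total - expected) > 0.01:
        raise PipelineError(
            f"money not conserved: cube total {cube.total:.4f} != "
            f"valued inputs {expected:.4f}"
        )
    return CostingResult(
        cube=cube,
        config=config,
        valued_financial_total=valued_total,
        economic_stream_totals=stream_totals,
        excluded_non_programme=excluded,
    )


# ---------------------------------------------------------------------------
# report frames


def table1_frame(cube: CostCube) -> pd.DataFrame:
    """Three margin panels (input, stage, activity) with financial/economic
    split, totals and whole-percent cost profile."""
    grand = cube.total
    rows = []
    panels = {
        "input": [i.value for i in InputCategory],
        "stage": [s.value for s in Stage],
        "activity": [a.value for a in Activity],
    }
    for panel, categories in panels.items():
        m = cube.margin([panel, "nature"])
        for cat in categories:
            fin = float(m.get((cat, Nature.FINANCIAL.value), 0.0))
            eco = float(m.get((cat, Nature.ECONOMIC.value), 0.0))
            rows.append(
                {
                    "panel": panel,
                    "category": cat,
                    "financial": fin,
                    "economic": eco,
                    "total": fin + eco,
                    "pct": round_percent((fin + eco) / grand) if grand > 0 else 0,
                }
            )
        rows.append(
            {
                "panel": panel,
                "category": "total",
                "financial": cube.nature_total(Nature.FINANCIAL),
                "economic": cube.nature_total(Nature.ECONOMIC),
                "total": grand,
                "pct": 100 if grand > 0 else 0,
            }
        )
    return pd.DataFrame(rows)


def unit_costs_frame(cube: CostCube, roster: Roster, months: int) -> pd.DataFrame:
    reports: list[UnitCostReport] = []
    for denom in Denominator:
        for period in ("total", "annual"):
            reports.append(unit_cost(cube, roster, denom, period, months))
    return pd.DataFrame(
        {
            "scope": r.scope,
            "denominator": r.denominator.value,
            "period": r.period,
            "value": r.value,
        }
        for r in reports
    )


def arm_costs_frame(cube: CostCube, roster: Roster, months: int) -> pd.DataFrame:
    df = arm_unit_costs(cube, roster, months)
    totals = cube.arm_totals()
    df["arm_total"] = df["arm"].map(totals)
    return df


def typology_frame(cube: CostCube) -> pd.DataFrame:
    m = cube.typology_margin()
    total = cube.total
    return pd.DataFrame(
        {
            "typology": m.index,
            "amount": m.values,
            "share_pct": [round_percent(v / total) if total > 0 else 0 for v in m.values],
        }
    )


def profiles_summary(cube: CostCube) -> dict[str, dict[str, float]]:
    return {dim: cost_profile(cube, dim).to_dict() for dim in ("input", "activity", "stage")}


# ---------------------------------------------------------------------------
# uncertainty interface


def psa_parameters(config: AnalysisConfig) -> dict[str, GammaSpec]:
    """Gamma specs for the seven uncertain parameters, from survey moments."""
    w, b = config.worker, config.beneficiary
    p1, p2, p3 = w.oop_periods
    mk = lambda m: GammaSpec(mean=m.mean, sd=m.sd)  # noqa: E731
    return {
        "pk_overtime_hours": mk(w.overtime_hours_per_month),
        "pk_travel_hours": mk(w.travel_hours_per_month),
        "pk_oop_period1": mk(p1.oop_usd),
        "pk_oop_period2": mk(p2.oop_usd),
        "pk_oop_period3": mk(p3.oop_usd),
        "beneficiary_hours_men": mk(b.hours_per_month["men"]),
        "beneficiary_hours_women": mk(b.hours_per_month["women"]),
    }


def make_cost_model(config: AnalysisConfig):
    """Deterministic, vectorized cost-model closure for PSA and tornado.

    Maps the seven uncertain parameters to the outcome set; the financial
    total is held at its base-case value (only micro-costed economic
    inputs carry parameter uncertainty).
    """
    params = config.valuation
    months = params.annualization_months
    years = months / 12.0
    w, b = config.worker, config.beneficiary
    period_overlap = [
        max(0, min(months - 1, p.month_end) - p.month_start + 1) for p in w.oop_periods
    ]
    counts = pooled_gender_counts(config.roster)
    rate_w = b.hourly_wage_usd("women", params)
    rate_m = b.hourly_wage_usd("men", params)
    fin = config.financial_total_usd
    denominators = {
        "annual_cost_households": config.roster.pooled(Denominator.HOUSEHOLDS),
        "annual_cost_index_pair": config.roster.pooled(Denominator.INDEX_PAIR),
        "annual_cost_index_plus_children": config.roster.pooled(
            Denominator.INDEX_PLUS_CHILDREN
        ),
        "annual_cost_all_members": config.roster.pooled(Denominator.ALL_MEMBERS),
    }

    def model(p: Mapping) -> dict:
        ot = np.asarray(p["pk_overtime_hours"], dtype=float)
        tv = np.asarray(p["pk_travel_hours"], dtype=float)
        oop = sum(
            n_m * np.asarray(p[f"pk_oop_period{i + 1}"], dtype=float)
            for i, n_m in enumerate(period_overlap)
        )
        men_h = np.asarray(p["beneficiary_hours_men"], dtype=float)
        women_h = np.asarray(p["beneficiary_hours_women"], dtype=float)

        hired = w.n_workers * months * w.time_valuation_rate_usd_per_hour * (ot + tv)
        oop_usd = w.oop_scale * w.n_workers * oop
        ben = b.wage_scale * months * (
            counts["women"] * women_h * rate_w + counts["men"] * men_h * rate_m
        )
        econ = hired + oop_usd + ben
        total = fin + econ
        out = {"total_economic": econ, "total_incremental": total}
        for name, n in denominators.items():
            out[name] = total / n / years
        return out

    return model


def run_uncertainty(
    config: AnalysisConfig,
    n_sims: int | None = None,
    seed: int = 0,
    keep_draws: bool = False,
) -> tuple[PSAResult, TornadoResult]:
    """Seeded PSA plus tornado ranking for a calibrated configuration."""
    psa_config = PSAConfig(
        n_sims=n_sims or config.psa_n_sims,
        seed=seed,
        parameters=psa_parameters(config),
    )
    model = make_cost_model(config)
    result = run_psa(model, psa_config, keep_draws=keep_draws)
    ranking = tornado(model, psa_config, percentiles=config.tornado_percentiles)
    return result, ranking


__all__ = [
    "CostingResult",
    "PipelineError",
    "run_costing",
    "value_financial_entry",
    "economic_stream_totals",
    "table1_frame",
    "unit_costs_frame",
    "arm_costs_frame",
    "typology_frame",
    "profiles_summary",
    "psa_parameters",
    "make_cost_model",
    "run_uncertainty",
    "OUTCOME_NAMES",
]
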