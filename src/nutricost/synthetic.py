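"""Synthetic inputs with the statistical structure the costing assumes.

Generates every input the pipeline needs with no external data: an
expenditure ledger whose coded, valued financial aggregates reproduce the
configured margin targets to the cent; per-worker survey records and
per-household time-use records drawn from the configured gamma moments;
and the beneficiary roster.  Ledger realism (dates, descriptions, line
granularity) is cosmetic — only the coded margins are contractual.

The ledger construction is deterministic per seed: a rank-one joint
activity x input table matches both financial margins exactly, the
start-up total is filled greedily from one-time launch activities, a
frontline-worker salary pool is carved out and re-emitted as uncoded
cadre-tagged lines (so the pipeline's time-share allocation restores the
margins), and each cell is split into log-normally jittered line items
that are rescaled to the cell total exactly.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .allocation import partition_money
from .calibration import (
    CalibrationError,
    CostStructureTargets,
    build_analysis_config,
    default_time_profiles,
)
from .codes import (
    ONE_TIME_ACTIVITIES,
    START_UP_LAST_MONTH,
    Activity,
    Cadre,
    ComponentScope,
    InputCategory,
    Stage,
    calendar_year,
)
from .config import AnalysisConfig
from .cube import Roster
from .ledger import LedgerEntry
from .uncertainty import GammaSpec
from .valuation import ValuationParams, annuity_factor

#: Greedy fill order for the start-up total.
_STARTUP_ORDER = (
    Activity.PROGRAMME_INSTALLATION,
    Activity.MATERIALS_DEVELOPMENT,
    Activity.PLANNING_MICROPLANNING,
    Activity.TRAINING,
)


class SynthesisError(ValueError):
    pass


class SynthConfig(BaseModel):
    """Generator settings; the defaults are the study conditions."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 1
    targets: CostStructureTargets = CostStructureTargets()
    valuation: ValuationParams = ValuationParams()
    roster_scale: float = 1.0
    n_pk: int = 80
    #: frontline-worker salary emitted as uncoded cadre-tagged lines
    pk_salary_pool_usd: float = 60_000.0
    nutrition_gender_split: float = 0.8
    #: log-normal sigma of line-item amount jitter
    jitter_sigma: float = 0.35
    max_items_per_cell: int = 3
    #: fraction of supply purchase values that is value-added tax
    supplies_tax_rate: float = 0.10

    @field_validator("roster_scale")
    @classmethod
    def _scale_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("roster_scale must be positive")
        return v

    @field_validator("n_pk")
    @classmethod
    def _n_pk_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_pk must be >= 1")
        return v


def generate_roster(config: SynthConfig) -> Roster:
    """Beneficiary roster (exact defaults; scalable for stress tests)."""
    return Roster().scale(config.roster_scale)


def analysis_config_for(config: SynthConfig) -> AnalysisConfig:
    """The calibrated analysis configuration matching a generator config."""
    return build_analysis_config(
        targets=config.targets,
        roster=generate_roster(config),
        params=config.valuation,
        n_workers=config.n_pk,
        nutrition_gender_split=config.nutrition_gender_split,
    )


# ---------------------------------------------------------------------------
# ledger generation


def _startup_by_activity(targets: CostStructureTargets) -> dict[Activity, float]:
    remaining = targets.startup_financial
    out: dict[Activity, float] = {}
    for act in _STARTUP_ORDER:
        if remaining <= 0:
            break
        take = min(targets.financial_activity.get(act, 0.0), remaining)
        if take > 0:
            out[act] = take
            remaining -= take
    if remaining > 0.005:
        raise SynthesisError(
            "stage margin infeasible: start-up total exceeds one-time activity spending"
        )
    return out


def _stage_cells(targets: CostStructureTargets) -> dict[tuple, float]:
    """Rank-one activity x input table, stage-resolved.

    The outer product of the two financial margins (divided by the grand
    total) reproduces both margins exactly; the start-up fraction of each
    one-time activity applies uniformly across its inputs.
    """
    grand = targets.financial_total
    if grand <= 0:
        return {}
    startup = _startup_by_activity(targets)
    cells: dict[tuple, float] = {}
    for act, a_total in targets.financial_activity.items():
        if a_total <= 0:
            continue
        su_frac = startup.get(act, 0.0) / a_total
        for inp, i_total in targets.financial_input.items():
            if i_total <= 0:
                continue
            amount = a_total * i_total / grand
            if su_frac > 0:
                cells[(act, inp, Stage.START_UP)] = amount * su_frac
            if su_frac < 1:
                cells[(act, inp, Stage.RECURRENT)] = amount * (1.0 - su_frac)
    return cells


def _carve_pk_pool(
    cells: dict[tuple, float], pool: float, config: SynthConfig
) -> dict[Activity, float]:
    """Remove the frontline-worker salary pool from recurrent hired-personnel
    cells along the cadre's activity shares; the pool is re-emitted as
    uncoded cadre-tagged entries that the pipeline re-allocates identically."""
    if pool <= 0:
        return {}
    profile = default_time_profiles()[Cadre.PK]
    alloc = partition_money(pool, profile.activity_shares)
    for act, amt in alloc.items():
        key = (act, InputCategory.PERSONNEL_HIRED, Stage.RECURRENT)
        available = cells.get(key, 0.0)
        if amt > available + 1e-9:
            raise SynthesisError(
                f"frontline salary pool exceeds recurrent hired-personnel spending "
                f"on {act.value} ({amt:.2f} > {available:.2f}); lower pk_salary_pool_usd"
            )
        cells[key] = available - amt
    return alloc


def _nominal(usd: float, month: int, params: ValuationParams) -> float:
    """Invert the valuation chain: 2019 USD -> nominal BDT of the entry year."""
    year = calendar_year(month)
    if year not in params.inflation_index:
        raise SynthesisError(f"no inflation index for year {year}")
    return usd * params.exchange_rate_bdt_per_usd * params.inflation_index[year]


def generate_ledger(config: SynthConfig) -> list[LedgerEntry]:
    """Synthetic line-item ledger reproducing the financial margin targets.

    Deterministic per seed; two seeds give different line items with
    identical coded margins (jitter is rescaled exactly within each cell).
    """
    rng = np.random.default_rng(config.seed)
    targets = config.targets
    analysis = analysis_config_for(config)
    scope_rule = analysis.scope
    params = config.valuation

    cells = _stage_cells(targets)
    pk_alloc = _carve_pk_pool(cells, config.pk_salary_pool_usd, config)

    entries: list[LedgerEntry] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"L{counter:05d}"

    def pick_month(act: Activity, stage: Stage) -> int:
        if stage is Stage.START_UP:
            return int(rng.integers(0, START_UP_LAST_MONTH + 1))
        if act in ONE_TIME_ACTIVITIES:
            return int(rng.integers(START_UP_LAST_MONTH + 1, 40))
        return int(rng.integers(0, 40))

    for (act, inp, stage), amount in sorted(
        cells.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value, kv[0][2].value)
    ):
        if amount <= 0.005:
            if amount > 0:
                # keep sub-cent dust on a single plain line
                month = pick_month(act, stage)
                entries.append(
                    LedgerEntry(
                        entry_id=next_id(),
                        month_index=month,
                        description=f"{act.value} {inp.value}",
                        amount_nominal=_nominal(amount, month, params),
                        input_code=inp,
                        activity_hint=act,
                        component_scope=ComponentScope.PLATFORM_WIDE,
                    )
                )
            continue
        for scope, samount in partition_money(
            amount, scope_rule.scope_weights(act)
        ).items():
            if samount <= 0:
                continue
            k = int(rng.integers(1, config.max_items_per_cell + 1))
            weights = rng.lognormal(0.0, config.jitter_sigma, size=k)
            parts = samount * weights / weights.sum()
            for part in parts:
                month = pick_month(act, stage)
                durable = False
                unit_price = None
                life = None
                tax = 0.0
                usd_value = float(part)
                if inp is InputCategory.EQUIPMENT:
                    # capital good: emit the purchase price whose annuitized
                    # charge over the window equals the target cell value
                    life = params.useful_life_years
                    price = part * annuity_factor(params.discount_rate, life) / params.years
                    if price > params.capital_threshold_usd * 1.01:
                        durable = True
                        usd_value = price
                        unit_price = _nominal(usd_value, month, params)
                    else:
                        # slice too small to clear the capital threshold:
                        # expensed directly at the charge value
                        life = None
                elif inp is InputCategory.AGRICULTURE_EQUIPMENT:
                    # small durable below the capital threshold: expensed
                    durable = True
                    life = 3.0
                    unit_price = _nominal(usd_value, month, params)
                nominal = _nominal(usd_value, month, params)
                if inp in (InputCategory.SUPPLIES, InputCategory.AGRICULTURE_SUPPLIES):
                    tax = nominal * config.supplies_tax_rate
                entries.append(
                    LedgerEntry(
                        entry_id=next_id(),
                        month_index=month,
                        description=f"{act.value.replace('_', ' ')} - {inp.value.replace('_', ' ')}",
                        amount_nominal=nominal,
                        input_code=inp,
                        activity_hint=act,
                        component_scope=scope,
                        durable=durable,
                        unit_price=unit_price,
                        expected_life_years=life,
                        tax_amount=tax,
                    )
                )

    # uncoded frontline-worker salary lines, one per component scope the
    # carved allocations would have received
    if pk_alloc:
        scope_totals: dict[ComponentScope, float] = {}
        for act, amt in pk_alloc.items():
            for scope, w in scope_rule.scope_weights(act).items():
                scope_totals[scope] = scope_totals.get(scope, 0.0) + amt * w
        for scope, amt in sorted(scope_totals.items(), key=lambda kv: kv[0].value):
            if amt <= 0:
                continue
            month = int(rng.integers(START_UP_LAST_MONTH + 1, 40))
            entries.append(
                LedgerEntry(
                    entry_id=next_id(),
                    month_index=month,
                    description="PK salaries (allocate by time shares)",
                    amount_nominal=_nominal(amt, month, params),
                    input_code=InputCategory.PERSONNEL_HIRED,
                    cadre=Cadre.PK,
                    component_scope=scope,
                )
            )
    return entries


# ---------------------------------------------------------------------------
# survey generators


def generate_worker_survey(
    config: SynthConfig, n_months: int = 40, n_workers: Optional[int] = None
) -> pd.DataFrame:
    """Per-worker-month gamma draws of extra-work hours, travel hours and
    OOP outlays (period moments applied month by month)."""
    analysis = analysis_config_for(config)
    w = analysis.worker
    n = config.n_pk if n_workers is None else n_workers
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    size = n * n_months
    ot = GammaSpec(**w.overtime_hours_per_month.model_dump()).draw(rng, size)
    tv = GammaSpec(**w.travel_hours_per_month.model_dump()).draw(rng, size)
    months = np.tile(np.arange(n_months), n)
    oop = np.empty(size)
    for p in w.oop_periods:
        mask = (months >= p.month_start) & (months <= p.month_end)
        oop[mask] = GammaSpec(**p.oop_usd.model_dump()).draw(rng, int(mask.sum()))
    return pd.DataFrame(
        {
            "worker_id": np.repeat(np.arange(n), n_months),
            "month": months,
            "overtime_hours": ot,
            "travel_hours": tv,
            "oop_usd": oop,
        }
    )


def generate_beneficiary_timeuse(
    config: SynthConfig, n_households: Optional[int] = None, n_months: int = 40
) -> pd.DataFrame:
    """Per-household monthly participation hours by gender (gamma draws)."""
    analysis = analysis_config_for(config)
    b = analysis.beneficiary
    n = (
        sum(generate_roster(config).households.values())
        if n_households is None
        else n_households
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    size = n * n_months
    men = GammaSpec(**b.hours_per_month["men"].model_dump()).draw(rng, size)
    women = GammaSpec(**b.hours_per_month["women"].model_dump()).draw(rng, size)
    return pd.DataFrame(
        {
            "household_id": np.repeat(np.arange(n), n_months),
            "month": np.tile(np.arange(n_months), n),
            "hours_men": men,
            "hours_women": women,
        }
    )


def summarize_survey(values: np.ndarray) -> dict[str, float]:
    """Sample moments of a survey column (ddof=1)."""
    arr = np.asarray(values, dtype=float)
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1))}


__all__ = [
    "SynthConfig",
    "SynthesisError",
    "CalibrationError",
    "generate_roster",
    "generate_ledger",
    "generate_worker_survey",
    "generate_beneficiary_timeuse",
    "analysis_config_for",
    "summarize_survey",
]
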