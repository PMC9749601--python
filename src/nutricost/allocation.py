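"""Coding and allocation: from ledger lines to standardized cost cells.

Implements the allocation rules of the activity-based-costing ingredients
approach: keyword/lookup coding of line items to activity and stage codes,
time-share allocation of personnel salaries across activities, proportional
splitting of shared costs, component-scope allocation to treatment arms,
and mapping of activities onto the value-chain typology.

All money partitions go through :func:`partition_money`, which rounds to
whole cents by the largest-remainder method while conserving the input
total exactly (any sub-cent residue lands on the final key).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .codes import (
    ONE_TIME_ACTIVITIES,
    SCOPE_ARMS,
    START_UP_LAST_MONTH,
    Activity,
    Cadre,
    ComponentScope,
    InputCategory,
    Nature,
    Stage,
    Typology,
)
from .ledger import LedgerEntry

_SHARE_TOL = 1e-9


class AllocationError(ValueError):
    pass


class UnresolvedEntriesError(AllocationError):
    """Entries that no coding rule could resolve; never silently defaulted."""

    def __init__(self, entry_ids: Sequence[str]):
        self.entry_ids = list(entry_ids)
        super().__init__(f"unresolvable ledger entries: {', '.join(self.entry_ids)}")


# ---------------------------------------------------------------------------
# money partitioning


def partition_money(amount: float, weights: Mapping) -> dict:
    """Split ``amount`` across keys proportionally to ``weights``.

    Weights must be nonnegative and sum to 1 (±1e-9).  Each key receives a
    whole-cent amount chosen by the largest-remainder rule (ties broken by
    key order); the final key additionally absorbs the sub-cent residue so
    that the outputs sum to ``amount`` exactly.  Homogeneous up to cent
    rounding: ``partition_money(k*x, w) == k*partition_money(x, w)`` within
    one cent per key.
    """
    if not weights:
        raise AllocationError("cannot partition over an empty weight map")
    if amount < 0:
        raise AllocationError("cannot partition a negative amount")
    wsum = float(sum(weights.values()))
    if any(w < -_SHARE_TOL for w in weights.values()):
        raise AllocationError("negative weight in partition")
    if abs(wsum - 1.0) > 1e-6:
        raise AllocationError(f"weights sum to {wsum!r}, expected 1")

    keys = list(weights)
    raw_cents = [amount * max(weights[k], 0.0) / wsum * 100.0 for k in keys]
    floors = [math.floor(round(c, 6)) for c in raw_cents]
    remainders = [c - f for c, f in zip(raw_cents, floors)]
    extra = amount * 100.0 - sum(floors)  # cents (plus sub-cent residue) left to place
    n_extra = max(math.floor(round(extra, 6)), 0)
    order = sorted(range(len(keys)), key=lambda i: (-remainders[i], i))
    cents = floors[:]
    for i in order[:n_extra]:
        cents[i] += 1
    out = {k: c / 100.0 for k, c in zip(keys, cents)}
    out[keys[-1]] += amount - sum(out.values())  # sub-cent residue → final key
    return out


# ---------------------------------------------------------------------------
# coding


class KeywordRule(BaseModel):
    """Map a description keyword (case-insensitive substring) to an activity."""

    keywords: list[str]
    activity: Activity


class CodingRules(BaseModel):
    """Editable coding ruleset (shipped as config, never hard-coded).

    Resolution order for an entry's activity:

    1. an explicit ``activity_hint`` passes through;
    2. a set ``cadre`` with no hint flags the entry for time-share
       allocation of personnel salaries (handled downstream);
    3. the first keyword rule whose keyword occurs in the description;
    4. the per-input default activity table.

    Entries that fall through every rule are rejected by entry id.
    """

    model_config = ConfigDict(extra="forbid")

    version: str = "1"
    keyword_rules: list[KeywordRule] = []
    input_defaults: dict[InputCategory, Activity] = {}


@dataclass
class CodedEntry:
    """A ledger entry with resolved activity and stage codes."""

    entry: LedgerEntry
    activity: Optional[Activity]
    stage: Optional[Stage]
    needs_time_share: bool = False


def classify_stage(activity: Activity, month_index: int) -> Stage:
    """Start-up iff the cost falls in the start-up months *and* belongs to a
    one-time launch activity; recurring costs in early months stay recurrent."""
    if month_index <= START_UP_LAST_MONTH and activity in ONE_TIME_ACTIVITIES:
        return Stage.START_UP
    return Stage.RECURRENT


def assign_codes(entries: Sequence[LedgerEntry], rules: CodingRules) -> list[CodedEntry]:
    """Code every entry to exactly one (activity, stage), or flag it for
    personnel time-share allocation.  Raises :class:`UnresolvedEntriesError`
    listing every entry no rule resolves."""
    coded: list[CodedEntry] = []
    unresolved: list[str] = []
    for e in entries:
        if e.activity_hint is not None:
            act = e.activity_hint
        elif e.cadre is not None:
            coded.append(CodedEntry(e, None, None, needs_time_share=True))
            continue
        else:
            act = _resolve_by_rules(e, rules)
            if act is None:
                unresolved.append(e.entry_id)
                continue
        coded.append(CodedEntry(e, act, classify_stage(act, e.month_index)))
    if unresolved:
        raise UnresolvedEntriesError(unresolved)
    return coded


def _resolve_by_rules(e: LedgerEntry, rules: CodingRules) -> Optional[Activity]:
    desc = e.description.lower()
    for rule in rules.keyword_rules:
        if any(kw.lower() in desc for kw in rule.keywords):
            return rule.activity
    return rules.input_defaults.get(e.input_code)


# ---------------------------------------------------------------------------
# personnel, shared and arm allocation


class TimeAllocationProfile(BaseModel):
    """How a worker cadre's paid time divides across programme activities.

    ``fte_share_on_programme`` is the fraction of total paid time spent on
    the programme (part-time staff < 1); ``activity_shares`` splits that
    programme time across activities and must sum to 1.
    """

    model_config = ConfigDict(extra="forbid")

    cadre: Cadre
    fte_share_on_programme: float
    activity_shares: dict[Activity, float]

    @field_validator("fte_share_on_programme")
    @classmethod
    def _fte_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("fte_share_on_programme must be in [0, 1]")
        return v

    @model_validator(mode="after")
    def _shares_sum(self) -> "TimeAllocationProfile":
        s = sum(self.activity_shares.values())
        if abs(s - 1.0) > _SHARE_TOL:
            raise ValueError(f"activity_shares sum to {s!r}, expected 1")
        if any(not 0.0 <= v <= 1.0 for v in self.activity_shares.values()):
            raise ValueError("activity shares must lie in [0, 1]")
        return self


def allocate_personnel(salary_pool: float, profile: TimeAllocationProfile) -> dict[Activity, float]:
    """Allocate a salary pool across activities by the cadre's time shares.

    Returns amounts summing to ``salary_pool * fte_share_on_programme``;
    the non-programme remainder of part-time staff is not a programme cost.
    """
    if salary_pool < 0:
        raise AllocationError("salary_pool must be >= 0")
    programme_pool = salary_pool * profile.fte_share_on_programme
    return partition_money(programme_pool, profile.activity_shares)


def allocate_shared(amount: float, weights: Mapping) -> dict:
    """Proportionally split a shared cost; conserves the amount exactly."""
    return partition_money(amount, weights)


def allocate_to_arms(cell_amount: float, scope: ComponentScope, households: Mapping[int, int]) -> dict[int, float]:
    """Split a cost cell across treatment arms.

    The eligible arm set follows component scope under the additive design
    (nutrition and platform-wide costs reach arms 2-4, agriculture 3-4,
    gender only 4); within the eligible set the split is proportional to
    household counts.
    """
    arms = [a for a in SCOPE_ARMS[scope] if a in households]
    if not arms:
        raise AllocationError(f"no eligible arms with household counts for scope {scope}")
    total_hh = sum(households[a] for a in arms)
    if total_hh <= 0:
        raise AllocationError("household counts must be positive")
    weights = {a: households[a] / total_hh for a in arms}
    return partition_money(cell_amount, weights)


# ---------------------------------------------------------------------------
# typology mapping

# Activities tied to a single value-chain pathway by design.
_DIRECT_TYPOLOGY: dict[Activity, Typology] = {
    Activity.HOME_VISITS_AGRICULTURE: Typology.SUPPLY,
    Activity.DISTRIBUTION_OF_INPUTS: Typology.SUPPLY,
    Activity.AWARENESS_RAISING: Typology.DEMAND,
}


def map_typology(
    activity: Activity,
    component_weights: Mapping[Typology, float],
    nutrition_gender_split: float = 0.8,
) -> dict[Typology, float]:
    """Typology weights for one activity (total function over the closed set).

    Agricultural extension and input distribution are supply-side; awareness
    raising is demand-side; combined nutrition/gender home visits split
    between demand and enabling-environment by the configured sub-split
    (nutrition share ``nutrition_gender_split``).  Every shared activity
    (management, supervision, M&E, training, events, overhead, ...) receives
    the programme-level component weights, which must sum to 1.
    """
    s = sum(component_weights.values())
    if abs(s - 1.0) > 1e-6:
        raise AllocationError(f"component_weights sum to {s!r}, expected 1")
    if activity in _DIRECT_TYPOLOGY:
        return {_DIRECT_TYPOLOGY[activity]: 1.0}
    if activity is Activity.HOME_VISITS_NUTRITION_GENDER:
        if not 0.0 <= nutrition_gender_split <= 1.0:
            raise AllocationError("nutrition_gender_split must be in [0, 1]")
        return {
            Typology.DEMAND: nutrition_gender_split,
            Typology.ENABLING_ENVIRONMENT: 1.0 - nutrition_gender_split,
        }
    return {t: float(w) for t, w in component_weights.items() if w > 0}


# ---------------------------------------------------------------------------
# cost cells


@dataclass
class CostCell:
    """One valued cell of the cost cube (2019 USD)."""

    activity: Activity
    input: InputCategory
    stage: Stage
    nature: Nature
    arm: int  # 2 | 3 | 4
    amount_usd2019: float
    typology_weights: dict[Typology, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.amount_usd2019 < 0:
            raise AllocationError("cost cells must be nonnegative")
        if self.typology_weights:
            s = sum(self.typology_weights.values())
            if abs(s - 1.0) > 1e-6:
                raise AllocationError("typology weights must sum to 1")


class ScopeRule(BaseModel):
    """How activity-level costs map to component scopes.

    ``forced`` pins component-specific activities to their scopes (possibly
    split, e.g. combined nutrition/gender home visits); every other activity
    splits by ``residual_shares`` — the shares of shared programme costs
    attributable to each component.
    """

    model_config = ConfigDict(extra="forbid")

    forced: dict[Activity, dict[ComponentScope, float]] = {}
    residual_shares: dict[ComponentScope, float] = {
        ComponentScope.PLATFORM_WIDE: 1.0
    }

    @model_validator(mode="after")
    def _sums(self) -> "ScopeRule":
        for act, m in self.forced.items():
            if abs(sum(m.values()) - 1.0) > 1e-6:
                raise ValueError(f"forced scope weights for {act} must sum to 1")
        if abs(sum(self.residual_shares.values()) - 1.0) > 1e-6:
            raise ValueError("residual scope shares must sum to 1")
        return self

    def scope_weights(self, activity: Activity) -> dict[ComponentScope, float]:
        if activity in self.forced:
            return dict(self.forced[activity])
        return {s: w for s, w in self.residual_shares.items() if w > 0}
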