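"""The cost cube: margins, cost profiles and unit costs.

The cube is a tidy :class:`pandas.DataFrame` of valued cost cells keyed by
activity x input x stage x arm x nature, with typology weights carried as
three weight columns.  Summary tables (the three margin panels, cost
profiles, unit costs under four beneficiary denominators, per-arm costs)
are all views of this one container, so margin consistency is structural.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Literal, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .allocation import CostCell
from .codes import ARMS, PROGRAMME_MONTHS, Nature, Stage, Typology

CUBE_KEY = ["activity", "input", "stage", "arm", "nature"]
_W_COLS = {t: f"w_{t.value}" for t in Typology}


class CubeError(ValueError):
    pass


class Denominator(str, Enum):
    """The four beneficiary denominator definitions."""

    HOUSEHOLDS = "households"
    INDEX_PAIR = "index_pair"
    INDEX_PLUS_CHILDREN = "index_plus_children"
    ALL_MEMBERS = "all_members"


class Roster(BaseModel):
    """Beneficiary counts by arm under the four denominator definitions."""

    model_config = ConfigDict(extra="forbid")

    households: dict[int, int] = {2: 1260, 3: 1260, 4: 1260}
    index_pair: dict[int, int] = {2: 2353, 3: 2398, 4: 2339}
    index_plus_children: dict[int, int] = {2: 3703, 3: 3703, 4: 3703}
    all_members: dict[int, int] = {2: 5884, 3: 5884, 4: 5884}

    @model_validator(mode="after")
    def _check(self) -> "Roster":
        tables = {
            Denominator.HOUSEHOLDS: self.households,
            Denominator.INDEX_PAIR: self.index_pair,
            Denominator.INDEX_PLUS_CHILDREN: self.index_plus_children,
            Denominator.ALL_MEMBERS: self.all_members,
        }
        for name, t in tables.items():
            if set(t) != set(ARMS):
                raise ValueError(f"{name.value} must cover exactly arms {ARMS}")
            if any(v <= 0 for v in t.values()):
                raise ValueError(f"{name.value} counts must be positive")
        order = list(tables.values())
        for arm in ARMS:
            counts = [t[arm] for t in order]
            if any(a >= b for a, b in zip(counts, counts[1:])):
                raise ValueError(
                    f"arm {arm}: counts must strictly increase across denominator "
                    f"definitions, got {counts}"
                )
        return self

    def counts(self, denominator: Denominator) -> dict[int, int]:
        return {
            Denominator.HOUSEHOLDS: self.households,
            Denominator.INDEX_PAIR: self.index_pair,
            Denominator.INDEX_PLUS_CHILDREN: self.index_plus_children,
            Denominator.ALL_MEMBERS: self.all_members,
        }[denominator]

    def pooled(self, denominator: Denominator) -> int:
        return sum(self.counts(denominator).values())

    def index_women(self, arm: int) -> int:
        """One index woman per household."""
        return self.households[arm]

    def index_men(self, arm: int) -> int:
        """Index spouses = index pair minus the index women."""
        return self.index_pair[arm] - self.households[arm]

    def scale(self, factor: float) -> "Roster":
        """Scaled roster for stress tests; factor must be positive."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")

        def s(t: dict[int, int]) -> dict[int, int]:
            return {k: max(1, round(v * factor)) for k, v in t.items()}

        return Roster(
            households=s(self.households),
            index_pair=s(self.index_pair),
            index_plus_children=s(self.index_plus_children),
            all_members=s(self.all_members),
        )


class CostCube:
    """Immutable collection of valued cost cells with margin accessors."""

    def __init__(self, frame: pd.DataFrame):
        self._df = frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def total(self) -> float:
        return float(self._df["amount"].sum())

    def margin(self, dims: str | Sequence[str]) -> pd.Series:
        """Sum of amounts over any subset of the key dimensions."""
        if isinstance(dims, str):
            dims = [dims]
        bad = [d for d in dims if d not in CUBE_KEY]
        if bad:
            raise CubeError(f"unknown cube dimension(s): {bad}")
        if self._df.empty:
            return pd.Series(dtype=float)
        return self._df.groupby(list(dims), observed=True)["amount"].sum()

    def nature_total(self, nature: Nature) -> float:
        if self._df.empty:
            return 0.0
        return float(self._df.loc[self._df["nature"] == nature.value, "amount"].sum())

    def stage_total(self, stage: Stage) -> float:
        if self._df.empty:
            return 0.0
        return float(self._df.loc[self._df["stage"] == stage.value, "amount"].sum())

    def typology_margin(self) -> pd.Series:
        """Costs by value-chain pathway (weight-spread margin)."""
        if self._df.empty:
            return pd.Series(dtype=float)
        return pd.Series(
            {
                t.value: float((self._df["amount"] * self._df[c]).sum())
                for t, c in _W_COLS.items()
            }
        )

    def arm_totals(self) -> dict[int, float]:
        s = self.margin("arm")
        missing = [a for a in ARMS if a not in s.index]
        if missing:
            raise CubeError(f"cube has no cells for arm(s) {missing}")
        return {int(a): float(v) for a, v in s.items()}


def build_cube(cells: Iterable[CostCell]) -> CostCube:
    """Assemble cells into a cube, merging duplicate keys by summation.

    Rejects negative cells; typology weights of merged cells are combined
    as amount-weighted averages so the weight-spread margin is conserved.
    """
    rows = []
    for c in cells:
        if c.amount_usd2019 < 0:
            raise CubeError(f"negative cost cell: {c}")
        row = {
            "activity": c.activity.value,
            "input": c.input.value,
            "stage": c.stage.value,
            "arm": int(c.arm),
            "nature": c.nature.value,
            "amount": float(c.amount_usd2019),
        }
        for t, col in _W_COLS.items():
            row[col] = float(c.typology_weights.get(t, 0.0)) * row["amount"]
        rows.append(row)
    if not rows:
        return CostCube(pd.DataFrame(columns=CUBE_KEY + ["amount", *_W_COLS.values()]))
    df = pd.DataFrame(rows)
    agg = df.groupby(CUBE_KEY, as_index=False, observed=True).sum()
    for col in _W_COLS.values():  # back to weights, amount-weighted
        agg[col] = (agg[col] / agg["amount"].where(agg["amount"] > 0, 1.0)).fillna(0.0)
    return CostCube(agg)


def cost_profile(cube: CostCube, dimension: str) -> pd.Series:
    """Share of each category in total cost (sums to 1 before rounding)."""
    total = cube.total
    if total <= 0:
        raise CubeError("cost profile undefined for an empty or zero-total cube")
    return cube.margin(dimension) / total


def round_percent(share: float) -> int:
    """Whole-percent report rounding (round half up)."""
    return int(
        decimal.Decimal(share * 100).quantize(
            decimal.Decimal("1"), rounding=decimal.ROUND_HALF_UP
        )
    )


@dataclass
class UnitCostReport:
    scope: str  # "pooled" or "arm{k}"
    denominator: Denominator
    period: Literal["total", "annual"]
    value: float


def unit_cost(
    cube: CostCube,
    roster: Roster,
    denominator: Denominator,
    period: Literal["total", "annual"] = "annual",
    months: int = PROGRAMME_MONTHS,
) -> UnitCostReport:
    """Pooled cost per beneficiary: total cost / denominator count,
    divided by the implementation years (months/12) when annualized."""
    count = roster.pooled(denominator)
    value = cube.total / count
    if period == "annual":
        value /= months / 12.0
    return UnitCostReport("pooled", denominator, period, value)


def arm_unit_costs(
    cube: CostCube, roster: Roster, months: int = PROGRAMME_MONTHS
) -> pd.DataFrame:
    """Annual and whole-period cost per beneficiary, per arm and denominator."""
    totals = cube.arm_totals()
    years = months / 12.0
    rows = []
    for arm in ARMS:
        for denom in Denominator:
            n = roster.counts(denom)[arm]
            rows.append(
                {
                    "arm": arm,
                    "denominator": denom.value,
                    "total_per_beneficiary": totals[arm] / n,
                    "annual_per_beneficiary": totals[arm] / n / years,
                }
            )
    return pd.DataFrame(rows)
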