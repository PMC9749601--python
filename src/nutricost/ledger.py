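"""Expenditure ledger: the line-item atom of activity-based costing.

A :class:`LedgerEntry` is one financial expenditure line together with the
coding hints needed to place it in the cost cube (input category, optional
activity hint, worker cadre, component scope, durable-good flags and tax).
Ledgers are exchanged as UTF-8 CSV with a fixed header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .codes import PROGRAMME_MONTHS, Activity, Cadre, ComponentScope, InputCategory

#: Required CSV column order.
LEDGER_COLUMNS = [
    "entry_id",
    "month_index",
    "description",
    "amount",
    "currency",
    "input_code",
    "activity_hint",
    "cadre",
    "component_scope",
    "durable",
    "unit_price",
    "expected_life_years",
    "tax_amount",
    "payer",
]


class LedgerError(ValueError):
    """Raised when a ledger file or entry fails validation."""


class LedgerEntry(BaseModel):
    """One expenditure line item.

    Amounts are in the nominal source currency (BDT unless the currency
    flag says otherwise).  ``tax_amount`` is the tax component *included*
    in ``amount_nominal``; ``durable`` entries carry a positive expected
    useful life and a unit price used for the capital threshold test.
    """

    model_config = ConfigDict(use_enum_values=False, extra="forbid")

    entry_id: str
    month_index: int
    description: str = ""
    amount_nominal: float
    currency: str = "BDT"
    input_code: InputCategory
    activity_hint: Optional[Activity] = None
    cadre: Optional[Cadre] = None
    component_scope: ComponentScope = ComponentScope.PLATFORM_WIDE
    durable: bool = False
    unit_price: Optional[float] = None
    expected_life_years: Optional[float] = None
    tax_amount: float = 0.0
    payer: str = "BRAC"

    @field_validator("month_index")
    @classmethod
    def _month_in_window(cls, v: int) -> int:
        if not 0 <= v < PROGRAMME_MONTHS:
            raise ValueError(
                f"month_index {v} outside the {PROGRAMME_MONTHS}-month analysis window"
            )
        return v

    @field_validator("amount_nominal")
    @classmethod
    def _amount_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("amount_nominal must be >= 0")
        return v

    @model_validator(mode="after")
    def _cross_checks(self) -> "LedgerEntry":
        if self.tax_amount < 0 or self.tax_amount > self.amount_nominal + 1e-9:
            raise ValueError("tax_amount must lie in [0, amount_nominal]")
        if self.durable:
            if self.expected_life_years is None or self.expected_life_years <= 0:
                raise ValueError("durable entries require a positive expected_life_years")
            if self.unit_price is None or self.unit_price <= 0:
                raise ValueError("durable entries require a positive unit_price")
        return self


def entries_to_frame(entries: Iterable[LedgerEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append(
            {
                "entry_id": e.entry_id,
                "month_index": e.month_index,
                "description": e.description,
                "amount": e.amount_nominal,
                "currency": e.currency,
                "input_code": e.input_code.value,
                "activity_hint": e.activity_hint.value if e.activity_hint else "",
                "cadre": e.cadre.value if e.cadre else "",
                "component_scope": e.component_scope.value,
                "durable": e.durable,
                "unit_price": "" if e.unit_price is None else e.unit_price,
                "expected_life_years": ""
                if e.expected_life_years is None
                else e.expected_life_years,
                "tax_amount": e.tax_amount,
                "payer": e.payer,
            }
        )
    return pd.DataFrame(rows, columns=LEDGER_COLUMNS)


def write_ledger_csv(entries: Sequence[LedgerEntry], path: str | Path) -> None:
    """Write entries as UTF-8 CSV with the canonical header.

    Amounts are written at full float precision: the ledger is input data,
    and sub-cent precision is what keeps downstream conservation checks
    exact.  Report files, by contrast, round money to cents.
    """
    entries_to_frame(entries).to_csv(path, index=False, encoding="utf-8")


def _opt(value, cast):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return cast(value)


def read_ledger_csv(path: str | Path) -> list[LedgerEntry]:
    """Read and validate a ledger CSV; raises :class:`LedgerError` naming
    missing columns or invalid rows."""
    df = pd.read_csv(
        path,
        dtype={"entry_id": str, "description": str},
        encoding="utf-8",
        float_precision="round_trip",
    )
    missing = [c for c in LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise LedgerError(f"ledger CSV missing required column(s): {', '.join(missing)}")

    entries: list[LedgerEntry] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        try:
            entries.append(
                LedgerEntry(
                    entry_id=str(row["entry_id"]),
                    month_index=int(row["month_index"]),
                    description="" if pd.isna(row["description"]) else str(row["description"]),
                    amount_nominal=float(row["amount"]),
                    currency=str(row["currency"]),
                    input_code=InputCategory(row["input_code"]),
                    activity_hint=_opt(row["activity_hint"], Activity),
                    cadre=_opt(row["cadre"], Cadre),
                    component_scope=ComponentScope(row["component_scope"]),
                    durable=bool(row["durable"]),
                    unit_price=_opt(row["unit_price"], float),
                    expected_life_years=_opt(row["expected_life_years"], float),
                    tax_amount=0.0 if pd.isna(row["tax_amount"]) else float(row["tax_amount"]),
                    payer=str(row["payer"]),
                )
            )
        except (ValueError, KeyError) as exc:  # includes pydantic ValidationError
            problems.append(f"row {idx + 2}: {exc}")  # +2: header + 1-based
    if problems:
        raise LedgerError("invalid ledger rows:\n" + "\n".join(problems))
    return entries
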