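"""Analysis configuration: one validated object drives a whole run.

The :class:`AnalysisConfig` bundles valuation parameters, coding rules,
cadre time-allocation profiles, the micro-costing survey profiles with
their recorded calibration factors, the allocation profiles for economic
cost streams, the component-scope rule, typology weights and the
beneficiary roster.  It serializes to YAML with a version field, and its
hash is echoed into every output for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .allocation import CodingRules, ScopeRule, TimeAllocationProfile
from .codes import Activity, Cadre, Typology
from .cube import Roster
from .valuation import BeneficiaryTimeProfile, ValuationParams, WorkerEconomicProfile

#: Names of the three economic cost streams and the input category each feeds.
ECON_STREAMS = ("overtime", "oop", "beneficiary")


class ConfigError(ValueError):
    pass


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    version: str = "1"
    valuation: ValuationParams = ValuationParams()
    coding_rules: CodingRules = CodingRules()
    time_profiles: dict[Cadre, TimeAllocationProfile] = {}
    worker: WorkerEconomicProfile = WorkerEconomicProfile()
    beneficiary: BeneficiaryTimeProfile = BeneficiaryTimeProfile()
    #: activity shares of each economic stream (each sums to 1)
    econ_activity_shares: dict[str, dict[Activity, float]] = {}
    scope: ScopeRule = ScopeRule()
    typology_component_weights: dict[Typology, float] = {
        Typology.SUPPLY: 0.20,
        Typology.DEMAND: 0.35,
        Typology.ENABLING_ENVIRONMENT: 0.45,
    }
    nutrition_gender_split: float = 0.8
    roster: Roster = Roster()
    #: base-case financial total (USD 2019), used by the standalone PSA model
    financial_total_usd: float = 0.0
    psa_n_sims: int = 5000
    tornado_percentiles: tuple[float, float] = (0.10, 0.90)

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        for stream, shares in self.econ_activity_shares.items():
            if stream not in ECON_STREAMS:
                raise ValueError(f"unknown economic stream {stream!r}")
            s = sum(shares.values())
            if shares and abs(s - 1.0) > 1e-6:
                raise ValueError(f"{stream} activity shares sum to {s!r}, expected 1")
        s = sum(self.typology_component_weights.values())
        if abs(s - 1.0) > 1e-6:
            raise ValueError("typology component weights must sum to 1")
        if not 0.0 <= self.nutrition_gender_split <= 1.0:
            raise ValueError("nutrition_gender_split must be in [0, 1]")
        if self.financial_total_usd < 0:
            raise ValueError("financial_total_usd must be >= 0")
        if self.psa_n_sims < 1:
            raise ValueError("psa_n_sims must be >= 1")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} is not a mapping")
    return AnalysisConfig.model_validate(data)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
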