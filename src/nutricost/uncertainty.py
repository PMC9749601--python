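"""Probabilistic sensitivity analysis over the cost model.

Uncertain inputs — frontline-worker extra-work and travel hours, monthly
out-of-pocket outlays in each stipend period, and beneficiary participation
hours by gender — are modelled as gamma distributions matched to survey
moments by the method of moments (shape = (mean/sd)^2, scale = sd^2/mean;
hours and costs are nonnegative, so the gamma support is natural).

:func:`run_psa` propagates independent joint draws through a deterministic
cost-model closure and summarizes each outcome with its base case, mean and
a 95% simulation interval (2.5th/97.5th percentiles).  :func:`tornado`
ranks parameters by the one-at-a-time swing they induce in an outcome when
moved between distribution percentiles (10th/90th by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy import stats

#: Canonical parameter names of the cost model, in reporting order.
PARAM_NAMES = (
    "pk_overtime_hours",
    "pk_travel_hours",
    "pk_oop_period1",
    "pk_oop_period2",
    "pk_oop_period3",
    "beneficiary_hours_men",
    "beneficiary_hours_women",
)

#: Outcomes every cost-model closure must report.
OUTCOME_NAMES = (
    "total_economic",
    "total_incremental",
    "annual_cost_households",
    "annual_cost_index_pair",
    "annual_cost_index_plus_children",
    "annual_cost_all_members",
)

#: A cost model maps named parameter values (scalars or aligned arrays)
#: to named outcomes, deterministically.
CostModel = Callable[[Mapping[str, np.ndarray]], dict[str, np.ndarray]]


class PSAError(ValueError):
    pass


class GammaSpec(BaseModel):
    """A gamma distribution parameterized by its first two moments."""

    model_config = ConfigDict(extra="forbid")

    mean: float
    sd: float

    @field_validator("mean", "sd")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("gamma moments must be strictly positive")
        return v

    @property
    def shape(self) -> float:
        return (self.mean / self.sd) ** 2

    @property
    def scale(self) -> float:
        return self.sd**2 / self.mean

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, size=size)

    def ppf(self, q: float) -> float:
        return float(stats.gamma.ppf(q, a=self.shape, scale=self.scale))


def gamma_from_moments(mean: float, sd: float) -> GammaSpec:
    """Method-of-moments gamma: shape*scale = mean, shape*scale^2 = sd^2."""
    return GammaSpec(mean=mean, sd=sd)


class PSAConfig(BaseModel):
    """Monte Carlo settings and the named parameter distributions."""

    model_config = ConfigDict(extra="forbid")

    n_sims: int = 5000
    seed: int = 0
    parameters: dict[str, GammaSpec]

    @model_validator(mode="after")
    def _complete(self) -> "PSAConfig":
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        missing = [p for p in PARAM_NAMES if p not in self.parameters]
        if missing:
            raise ValueError(f"missing PSA parameter(s): {missing}")
        return self


@dataclass
class PSAResult:
    """Per-outcome simulation summaries; draws retained when requested."""

    summary: pd.DataFrame  # index: outcome; columns: base_case, sim_mean, lower, upper
    n_sims: int
    seed: int
    draws: Optional[pd.DataFrame] = None


def _base_values(config: PSAConfig) -> dict[str, float]:
    return {name: config.parameters[name].mean for name in config.parameters}


def _as_outcome_arrays(
    raw: Mapping[str, np.ndarray], n: int, context: str
) -> dict[str, np.ndarray]:
    out = {}
    for name in OUTCOME_NAMES:
        if name not in raw:
            raise PSAError(f"cost model did not report outcome {name!r} ({context})")
        arr = np.broadcast_to(np.asarray(raw[name], dtype=float), (n,))
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise PSAError(f"cost model returned non-finite {name} at draw {bad} ({context})")
        out[name] = arr
    return out


def run_psa(model: CostModel, config: PSAConfig, keep_draws: bool = False) -> PSAResult:
    """Propagate ``n_sims`` independent joint parameter draws through the model.

    Identical seeds give identical results; parameters are sampled
    independently (no correlation structure is imposed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sims
    draws = {
        name: config.parameters[name].draw(rng, n) for name in PARAM_NAMES
    }
    # any extra configured parameters are sampled after the canonical block
    for name, spec in config.parameters.items():
        if name not in draws:
            draws[name] = spec.draw(rng, n)

    outcomes = _as_outcome_arrays(model(draws), n, "simulation")
    base = _as_outcome_arrays(model(_base_values(config)), 1, "base case")

    rows = {}
    for name in OUTCOME_NAMES:
        arr = outcomes[name]
        rows[name] = {
            "base_case": float(base[name][0]),
            "sim_mean": float(arr.mean()),
            "lower": float(np.percentile(arr, 2.5)),
            "upper": float(np.percentile(arr, 97.5)),
        }
    summary = pd.DataFrame.from_dict(rows, orient="index").loc[list(OUTCOME_NAMES)]
    kept = pd.DataFrame(draws).join(pd.DataFrame(outcomes)) if keep_draws else None
    return PSAResult(summary=summary, n_sims=n, seed=config.seed, draws=kept)


@dataclass
class TornadoResult:
    """One-at-a-time parameter impact ranking, descending swing."""

    table: pd.DataFrame  # columns: parameter, low, high, outcome_at_low, outcome_at_high, swing
    outcome: str
    percentiles: tuple[float, float]


def tornado(
    model: CostModel,
    config: PSAConfig,
    percentiles: tuple[float, float] = (0.10, 0.90),
    outcome: str = "total_incremental",
) -> TornadoResult:
    """Rank parameters by the swing each induces in ``outcome`` when set to
    its low/high distribution percentile with all others at base values."""
    lo_q, hi_q = percentiles
    if not 0.0 < lo_q < hi_q < 1.0:
        raise PSAError("percentiles must satisfy 0 < low < high < 1")
    if outcome not in OUTCOME_NAMES:
        raise PSAError(f"unknown outcome {outcome!r}")
    base = _base_values(config)
    rows = []
    for name in PARAM_NAMES:
        spec = config.parameters[name]
        lo, hi = spec.ppf(lo_q), spec.ppf(hi_q)
        at_low = _as_outcome_arrays(model({**base, name: lo}), 1, name)[outcome][0]
        at_high = _as_outcome_arrays(model({**base, name: hi}), 1, name)[outcome][0]
        rows.append(
            {
                "parameter": name,
                "low": lo,
                "high": hi,
                "outcome_at_low": float(at_low),
                "outcome_at_high": float(at_high),
                "swing": abs(float(at_high) - float(at_low)),
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values("swing", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return TornadoResult(table=table, outcome=outcome, percentiles=(lo_q, hi_q))
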