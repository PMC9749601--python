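"""Gamma parameterization, Monte Carlo propagation and tornado ranking."""

import numpy as np
import pytest
from scipy import stats

from nutricost.uncertainty import (
    PARAM_NAMES,
    GammaSpec,
    PSAConfig,
    PSAError,
    gamma_from_moments,
    run_psa,
    tornado,
)

#: survey moments of the seven uncertain parameters
SURVEY_MOMENTS = {
    "pk_overtime_hours": (4.24, 2.34),
    "pk_travel_hours": (19.65, 10.28),
    "pk_oop_period1": (6.55, 3.02),
    "pk_oop_period2": (4.31, 2.78),
    "pk_oop_period3": (1.45, 2.00),
    "beneficiary_hours_men": (0.96, 1.22),
    "beneficiary_hours_women": (1.8, 1.66),
}


def linear_config(n_sims=200, seed=0):
    return PSAConfig(
        n_sims=n_sims,
        seed=seed,
        parameters={k: GammaSpec(mean=m, sd=s) for k, (m, s) in SURVEY_MOMENTS.items()},
    )


def linear_model(p):
    """Toy cost model: outcomes are a fixed positive combination of params."""
    total = sum(np.asarray(p[k], dtype=float) for k in PARAM_NAMES)
    out = {"total_economic": total, "total_incremental": 100.0 + total}
    for name in (
        "annual_cost_households",
        "annual_cost_index_pair",
        "annual_cost_index_plus_children",
        "annual_cost_all_members",
    ):
        out[name] = (100.0 + total) / 10.0
    return out


# ---------------------------------------------------------------------------
# moment matching


@pytest.mark.parametrize("mean,sd", list(SURVEY_MOMENTS.values()))
def test_gamma_moments_round_trip(mean, sd):
    spec = gamma_from_moments(mean, sd)
    assert spec.shape * spec.scale == pytest.approx(mean, abs=1e-12)
    assert spec.shape * spec.scale**2 == pytest.approx(sd**2, abs=1e-12)


def test_gamma_shape_scale_values():
    men = gamma_from_moments(0.96, 1.22)
    assert (men.shape, men.scale) == (pytest.approx(0.6192, abs=5e-5),
                                      pytest.approx(1.5504, abs=5e-5))
    women = gamma_from_moments(1.8, 1.66)
    assert (women.shape, women.scale) == (pytest.approx(1.1758, abs=5e-5),
                                          pytest.approx(1.5309, abs=5e-5))
    unit = gamma_from_moments(1.0, 1.0)  # exponential
    assert (unit.shape, unit.scale) == (pytest.approx(1.0), pytest.approx(1.0))


def test_gamma_rejects_nonpositive_moments():
    with pytest.raises(ValueError):
        gamma_from_moments(0.0, 1.0)
    with pytest.raises(ValueError):
        gamma_from_moments(1.0, -0.1)


def test_gamma_sampling_matches_cdf():
    """KS distance of 1e5 draws below the alpha=0.01 critical value."""
    spec = gamma_from_moments(1.8, 1.66)
    draws = spec.draw(np.random.default_rng(0), 100_000)
    stat = stats.kstest(draws, "gamma", args=(spec.shape, 0, spec.scale)).statistic
    critical = stats.ksone.ppf(1 - 0.01 / 2, 100_000)
    assert stat < critical


# ---------------------------------------------------------------------------
# PSA


def test_psa_config_requires_all_parameters():
    params = {k: GammaSpec(mean=m, sd=s) for k, (m, s) in SURVEY_MOMENTS.items()}
    del params["pk_travel_hours"]
    with pytest.raises(ValueError, match="pk_travel_hours"):
        PSAConfig(n_sims=10, seed=0, parameters=params)


def test_psa_single_sim_degenerate_limits():
    res = run_psa(linear_model, linear_config(n_sims=1))
    row = res.summary.loc["total_incremental"]
    assert row["lower"] == row["upper"] == row["sim_mean"]


def test_psa_seed_determinism():
    a = run_psa(linear_model, linear_config(n_sims=500, seed=11)).summary
    b = run_psa(linear_model, linear_config(n_sims=500, seed=11)).summary
    assert a.equals(b)
    c = run_psa(linear_model, linear_config(n_sims=500, seed=12)).summary
    assert not a.equals(c)


def test_psa_parameter_means_recovered():
    """Empirical parameter mean within 3 standard errors of the gamma mean."""
    n = 100_000
    res = run_psa(linear_model, linear_config(n_sims=n, seed=3), keep_draws=True)
    for name, (mean, sd) in SURVEY_MOMENTS.items():
        se = sd / np.sqrt(n)
        assert abs(res.draws[name].mean() - mean) < 3 * se


def test_psa_interval_orders_and_base_case():
    res = run_psa(linear_model, linear_config(n_sims=2000, seed=5))
    s = res.summary
    assert (s["lower"] <= s["sim_mean"]).all()
    assert (s["sim_mean"] <= s["upper"]).all()
    base_total = sum(m for m, _ in SURVEY_MOMENTS.values())
    assert s.loc["total_economic", "base_case"] == pytest.approx(base_total)


def test_psa_aborts_on_model_failure_with_draw_index():
    def broken(p):
        out = linear_model(p)
        arr = np.array(out["total_economic"], dtype=float)
        if arr.size > 3:
            arr[3] = np.nan
        out["total_economic"] = arr
        return out

    with pytest.raises(PSAError, match="draw 3"):
        run_psa(broken, linear_config(n_sims=10, seed=0))


# ---------------------------------------------------------------------------
# tornado


def test_tornado_is_permutation_with_nonnegative_swings():
    res = tornado(linear_model, linear_config())
    assert sorted(res.table["parameter"]) == sorted(PARAM_NAMES)
    assert (res.table["swing"] >= 0).all()
    assert res.table["swing"].is_monotonic_decreasing


def test_tornado_tiny_sd_ranks_last():
    cfg = linear_config()
    params = dict(cfg.parameters)
    params["pk_oop_period2"] = GammaSpec(mean=4.31, sd=1e-7)
    cfg = PSAConfig(n_sims=10, seed=0, parameters=params)
    res = tornado(linear_model, cfg)
    assert res.table.iloc[-1]["parameter"] == "pk_oop_period2"
    assert res.table.iloc[-1]["swing"] == pytest.approx(0.0, abs=1e-5)


def test_tornado_swing_weakly_increases_with_sd():
    def swing_for(sd):
        params = dict(linear_config().parameters)
        params["beneficiary_hours_women"] = GammaSpec(mean=1.8, sd=sd)
        cfg = PSAConfig(n_sims=10, seed=0, parameters=params)
        t = tornado(linear_model, cfg).table
        return float(t.set_index("parameter").loc["beneficiary_hours_women", "swing"])

    swings = [swing_for(sd) for sd in (0.5, 1.0, 1.66, 3.32)]
    assert swings == sorted(swings)


def test_tornado_rejects_bad_percentiles():
    with pytest.raises(PSAError):
        tornado(linear_model, linear_config(), percentiles=(0.9, 0.1))
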