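import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from floodmeadow import flowering as flow
from floodmeadow import simulate
from floodmeadow.io import ValidationError


def test_standardize_hand_example():
    z = flow.standardize([0.0, 2.0]).z
    np.testing.assert_allclose(z, [-1 / np.sqrt(2), 1 / np.sqrt(2)])


def test_standardize_idempotent_on_z_scores(rng):
    x = rng.normal(size=50)
    z = flow.standardize(x).z
    np.testing.assert_allclose(flow.standardize(z).z, z, atol=1e-10)
    assert z.mean() == pytest.approx(0, abs=1e-12)


def test_standardize_rejects_constant():
    with pytest.raises(ValidationError):
        flow.standardize([3.0, 3.0, 3.0])


@pytest.fixture(scope="module")
def synthetic_dataset():
    cfg = simulate.FloweringGenConfig(seed=42)
    censuses, weather, truth = simulate.gen_flowering_counts(cfg)
    return cfg, censuses, weather, truth


def test_sigma_zero_matches_poisson_glm_irls(synthetic_dataset):
    cfg, censuses, weather, _ = synthetic_dataset
    y, X, groups, _ = flow.build_design(
        censuses, weather, "mar_apr", "temperature", cfg.elevations
    )
    fit = flow.fit_poisson_glmm_arrays(y, X, groups, fix_sigma=0.0)
    oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    np.testing.assert_allclose(fit.beta.values, oracle.params, atol=1e-6)
    # and the GLMM log-likelihood at σ=0 equals the GLM's
    assert fit.loglik == pytest.approx(oracle.llf, abs=1e-8)


def test_glmm_matches_lme4_glmer(synthetic_dataset, tmp_path):
    """Independent cross-check of the marginal-likelihood fit against lme4."""
    cfg, censuses, weather, _ = synthetic_dataset
    y, X, groups, _ = flow.build_design(
        censuses, weather, "mar_apr", "temperature", cfg.elevations
    )
    fit = flow.fit_poisson_glmm_arrays(y, X, groups, n_quad=25)
    csv = tmp_path / "d.csv"
    pd.DataFrame({"y": y, "clim": X[:, 1], "elev": X[:, 2], "plot": groups}).to_csv(
        csv, index=False
    )
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages(library(lme4))\n"
        f"d <- read.csv('{csv}')\n"
        "m <- glmer(y ~ clim*elev + (1|plot), data=d, family=poisson, nAGQ=25)\n"
        "cat(fixef(m), sqrt(unlist(VarCorr(m))), sep='\\n')\n"
    )
    rscript = shutil.which("Rscript")
    assert rscript is not None, "Rscript interpreter required for the lme4 oracle"
    out = subprocess.run(
        [rscript, str(script)], capture_output=True, text=True, check=True
    )
    vals = [float(v) for v in out.stdout.split()]
    np.testing.assert_allclose(fit.beta.values, vals[:4], atol=2e-4)
    assert fit.sigma_theta == pytest.approx(vals[4], abs=2e-4)


def test_intercept_only_constant_counts():
    y = np.full(30, 7.0)
    X = np.ones((30, 1))
    groups = np.repeat(np.arange(5), 6)
    fit = flow.fit_poisson_glmm_arrays(y, X, groups, effect_names=("intercept",), n_quad=9)
    assert fit.beta["intercept"] == pytest.approx(np.log(7), abs=1e-3)
    assert fit.sigma_theta < 0.02


def test_agq_node_count_converges(synthetic_dataset):
    cfg, censuses, weather, _ = synthetic_dataset
    y, X, groups, _ = flow.build_design(
        censuses, weather, "mar_apr", "temperature", cfg.elevations
    )
    betas = {}
    for n_quad in (1, 15, 25):
        betas[n_quad] = flow.fit_poisson_glmm_arrays(y, X, groups, n_quad=n_quad).beta.values
    np.testing.assert_allclose(betas[25], betas[15], atol=1e-4)
    # Laplace is already close for Poisson counts of this magnitude
    np.testing.assert_allclose(betas[1], betas[25], atol=1e-2)


def test_truth_recovery_within_three_se():
    cfg = simulate.FloweringGenConfig(
        elevations={i + 1: 1.2 + i / 49 for i in range(50)},
        years=tuple(range(1961, 2001)),
        seed=2024,
    )
    censuses, weather, truth = simulate.gen_flowering_counts(cfg)
    fit = flow.fit_poisson_glmm(
        censuses, weather, cfg.period, cfg.variable, cfg.elevations, n_quad=9
    )
    for name, true_val in truth["beta"].items():
        assert abs(fit.beta[name] - true_val) <= 3 * fit.se[name]
    assert abs(fit.sigma_theta - cfg.sigma_theta) <= 0.15


def test_r2_decomposition_against_first_principles(synthetic_dataset):
    cfg, censuses, weather, _ = synthetic_dataset
    fit = flow.fit_poisson_glmm(
        censuses, weather, "mar_apr", "temperature", cfg.elevations, n_quad=15
    )
    r2m, r2c = flow.r2_marginal_conditional(fit, method="trigamma")
    # independent recomputation of the variance components
    from scipy.special import polygamma

    var_f = np.var(fit.linear_predictor_fixed)
    var_re = fit.sigma_theta**2
    lam = np.exp(fit.beta["intercept"] + 0.5 * (var_f + var_re))
    var_d = float(polygamma(1, lam))
    assert r2m == pytest.approx(var_f / (var_f + var_re + var_d), abs=1e-8)
    assert r2c == pytest.approx((var_f + var_re) / (var_f + var_re + var_d), abs=1e-8)
    assert 0 <= r2m <= r2c <= 1
    # lognormal and delta variants stay ordered the same way
    for method in ("lognormal", "delta"):
        m, c = flow.r2_marginal_conditional(fit, method=method)
        assert 0 <= m <= c <= 1


def test_r2_equal_when_no_random_variance(synthetic_dataset):
    cfg, censuses, weather, _ = synthetic_dataset
    fit = flow.fit_poisson_glmm(
        censuses, weather, "mar_apr", "temperature", cfg.elevations, fix_sigma=0.0
    )
    r2m, r2c = flow.r2_marginal_conditional(fit)
    assert r2m == pytest.approx(r2c)


def test_usable_previous_year_census_years():
    years = flow.usable_prev_year_years(simulate.CENSUS_YEARS)
    assert years == list(range(1982, 1989)) + list(range(2017, 2022))
    assert len(years) == 12


def test_prev_year_model_recovers_positive_carryover(rng):
    # autoregressive counts: log-mean tracks the previous year's count
    plots = {1: 1.8, 2: 1.7, 3: 1.5, 4: 1.3}
    years = range(1981, 2011)
    counts = []
    prev = {p: 100.0 for p in plots}
    from floodmeadow.io import FloweringCensus

    for year in years:
        for p in plots:
            mu = np.exp(3.0 + 0.4 * (np.log(prev[p] + 1) - 4.5) + rng.normal(0, 0.1))
            n = int(rng.poisson(mu))
            counts.append(FloweringCensus(plot_id=p, year=year, count_purple=n))
            prev[p] = n
    fit = flow.prev_year_model(counts, plots)
    assert fit.beta["prev"] > 0
    assert fit.beta["prev"] / fit.se["prev"] > 2


def test_prev_year_model_surfaces_constant_predictor():
    from floodmeadow.io import FloweringCensus

    counts = [
        FloweringCensus(plot_id=p, year=y, count_purple=50)
        for p in (1, 2)
        for y in (1981, 1982, 1983)
    ]
    with pytest.raises(ValidationError):
        flow.prev_year_model(counts, {1: 1.8, 2: 1.3})


def test_predictions_at_mean_equal_exp_intercept(synthetic_dataset):
    cfg, censuses, weather, _ = synthetic_dataset
    fit = flow.fit_poisson_glmm(
        censuses, weather, "mar_apr", "temperature", cfg.elevations, n_quad=15
    )
    clim_mean = fit.predictors["clim"].mean
    elev_mean = fit.predictors["elev"].mean
    pred = flow.predict_flower_counts(fit, [clim_mean], [elev_mean])
    assert pred["predicted"].iloc[0] == pytest.approx(float(np.exp(fit.beta["intercept"])))


def test_prediction_interaction_sign(synthetic_dataset):
    cfg, censuses, weather, _ = synthetic_dataset
    fit = flow.fit_poisson_glmm(
        censuses, weather, "mar_apr", "temperature", cfg.elevations, n_quad=15
    )
    assert fit.beta["clim_elev"] < 0  # truth β3 = −0.4
    clim = fit.predictors["clim"]
    lo_c, hi_c = clim.raw.min(), clim.raw.max()
    lo_e, hi_e = 1.30, 1.85
    pred = flow.predict_flower_counts(fit, [lo_c, hi_c], [lo_e, hi_e])
    wide = pred.pivot(index="clim", columns="elevation", values="predicted")
    slope_low = np.log(wide.loc[hi_c, lo_e]) - np.log(wide.loc[lo_c, lo_e])
    slope_high = np.log(wide.loc[hi_c, hi_e]) - np.log(wide.loc[lo_c, hi_e])
    assert slope_high < slope_low


def test_prediction_extrapolation_warns(synthetic_dataset):
    cfg, censuses, weather, _ = synthetic_dataset
    fit = flow.fit_poisson_glmm(
        censuses, weather, "mar_apr", "temperature", cfg.elevations, n_quad=15
    )
    with pytest.warns(UserWarning, match="beyond observed"):
        pred = flow.predict_flower_counts(fit, [99.0], [1.5])
    assert pred["extrapolated"].iloc[0]


def test_predictor_independence_check_limits():
    from floodmeadow.io import WeatherSeries

    years = range(1981, 1991)
    same = [
        WeatherSeries(year=y, period="mar_apr", temperature=float(y % 7), precipitation=float(y % 7))
        for y in years
    ]
    out = flow.predictor_independence_check(same)
    assert out.loc[0, "r"] == pytest.approx(1.0)
    anti = [
        WeatherSeries(year=y, period="mar_apr", temperature=float(y % 7), precipitation=10.0 - (y % 7))
        for y in years
    ]
    out = flow.predictor_independence_check(anti)
    assert out.loc[0, "r"] == pytest.approx(-1.0)
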