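import numpy as np
import pandas as pd
import pytest

from agridiet.data_model import filter_sample
from agridiet.estimators import (
    ConvergenceError,
    Design,
    ModelSpec,
    RankDeficientError,
    build_design,
    cluster_covariance,
    fit_cre,
    fit_fe,
    fit_ols,
    fit_poisson_cre,
    group_comparison,
    ipw_attrition_weights,
    marginal_effects,
)
from agridiet.pipeline import X_COLUMNS, model_frame
from agridiet.scores import score_panel
from agridiet.synthetic import AttritionConfig, GeneratorConfig, generate_panel


def _design(X, y, clusters, names=None, weights=None):
    names = names or [f"x{i}" for i in range(X.shape[1])]
    return Design(
        X=pd.DataFrame(X, columns=names),
        y=np.asarray(y, dtype=float),
        clusters=np.asarray(clusters),
        weights=weights,
        frame=pd.DataFrame(),
        dropped_rows=0,
        dropped_columns=[],
    )


# ----------------------------------------------------------------------
# build_design
# ----------------------------------------------------------------------


def _toy_frame():
    rng = np.random.default_rng(0)
    n_hh, waves = 30, 3
    hh = np.repeat(np.arange(n_hh), waves)
    df = pd.DataFrame(
        {
            "household_id": hh,
            "country": np.where(hh < 15, "A", "B"),
            "wave": np.tile(np.arange(1, waves + 1), n_hh),
            "fpd": rng.poisson(4, n_hh * waves).astype(float),
            "covar": rng.normal(size=n_hh * waves),
            "fixedcov": np.repeat(rng.normal(size=n_hh), waves),
            "dist": np.repeat(rng.gamma(2, 15, n_hh), waves),
        }
    )
    df["y"] = 1 + 0.5 * df.fpd + 0.3 * df.covar + rng.normal(size=len(df))
    return df


def test_mundlak_mean_is_arithmetic_mean_over_observed_waves():
    df = _toy_frame()
    # drop one wave of household 0 -> its mean over the 2 observed rows
    df = df.drop(df[(df.household_id == 0) & (df.wave == 3)].index)
    spec = ModelSpec(outcome="y", focal="fpd", covariates=("covar", "fixedcov"))
    d = build_design(df, spec)
    rows = d.frame.household_id == 0
    expected = df.loc[df.household_id == 0, "fpd"].mean()
    assert np.allclose(d.X.loc[rows.values, "mean_fpd"], expected)


def test_single_country_model_has_no_country_dummies():
    df = _toy_frame()
    sub = df[df.country == "A"]
    d = build_design(sub, ModelSpec(outcome="y", focal="fpd", covariates=("covar",)))
    assert not any(c.startswith("country_") for c in d.names)
    d2 = build_design(df, ModelSpec(outcome="y", focal="fpd", covariates=("covar",)))
    assert "country_B" in d2.names


def test_interaction_column_built_when_requested():
    df = _toy_frame()
    d = build_design(
        df,
        ModelSpec(
            outcome="y", focal="fpd", covariates=("covar",), interaction_with="dist"
        ),
    )
    assert "fpd_x_dist" in d.names
    np.testing.assert_allclose(
        d.X["fpd_x_dist"].values, (d.frame.fpd * d.frame.dist).values
    )


def test_duplicate_user_collinearity_raises():
    df = _toy_frame()
    df["covar2"] = df["covar"]
    with pytest.raises(RankDeficientError):
        build_design(
            df, ModelSpec(outcome="y", focal="fpd", covariates=("covar", "covar2"))
        )


# ----------------------------------------------------------------------
# fit_ols
# ----------------------------------------------------------------------


def test_exact_fit_recovers_coefficient_with_zero_se():
    x = np.arange(1.0, 41.0)
    X = np.column_stack([np.ones(40), x])
    y = 2.0 * x
    fit = fit_ols(_design(X, y, clusters=np.arange(40) % 5, names=["const", "x"]))
    assert fit.params["x"] == pytest.approx(2.0, abs=1e-12)
    assert fit.se["x"] == pytest.approx(0.0, abs=1e-10)


def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(42)
    X = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
    y = rng.normal(size=40)
    beta_oracle = np.linalg.inv(X.T @ X) @ X.T @ y  # explicit (X'X)^-1 X'y
    fit = fit_ols(_design(X, y, clusters=np.arange(40) % 8))
    np.testing.assert_allclose(fit.params.values, beta_oracle, atol=1e-10)


def test_cr1_equals_hc1_with_singleton_clusters():
    rng = np.random.default_rng(7)
    n = 60
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    y = X @ [1.0, 0.5, -0.2] + rng.normal(size=n) * (1 + 0.5 * np.abs(X[:, 1]))
    fit = fit_ols(_design(X, y, clusters=np.arange(n)))  # every row its own cluster
    # HC1: (n/(n-k)) * (X'X)^-1 (X' diag(u^2) X) (X'X)^-1
    u = y - X @ fit.params.values
    bread = np.linalg.inv(X.T @ X)
    hc1 = (n / (n - 3)) * bread @ (X * u[:, None] ** 2).T @ X @ bread
    # CR1 factor with singletons: n/(n-1) * (n-1)/(n-k) = n/(n-k) -> identical
    np.testing.assert_allclose(fit.cov.values, hc1, rtol=1e-10)


def test_ols_cluster_se_matches_statsmodels(linear_frame):
    sm = pytest.importorskip("statsmodels.api")
    spec = ModelSpec(outcome="latent_hdds", focal="fpd_species", covariates=X_COLUMNS)
    d = build_design(linear_frame, spec)
    ours = fit_ols(d, spec)
    ref = sm.OLS(d.y, d.X.values).fit(
        cov_type="cluster", cov_kwds={"groups": d.clusters}, use_t=False
    )
    np.testing.assert_allclose(ours.params.values, ref.params, atol=1e-10)
    np.testing.assert_allclose(ours.se.values, ref.bse, rtol=1e-8)


def test_too_few_clusters_rejected():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.raises(ValueError, match="clusters"):
        fit_ols(_design(X, np.arange(10.0), clusters=np.zeros(10)))


# ----------------------------------------------------------------------
# Mundlak equivalence CRE <-> FE
# ----------------------------------------------------------------------


def _equivalence_frame(unbalanced):
    att = AttritionConfig(base_rate=0.15 if unbalanced else 0.0)
    cfg = GeneratorConfig(
        seed=5,
        districts_per_country=2,
        towns_per_district=2,
        villages_per_town=3,
        households_per_village=9,
        waves_per_country=(3,),
        outcome_mode="linear",
        true_beta_species=0.044,
        attrition=att,
    )
    panel, truth = generate_panel(cfg)
    return model_frame(panel, truth=truth)


@pytest.mark.parametrize("unbalanced", [False, True], ids=["balanced", "unbalanced"])
def test_mundlak_equivalence(unbalanced):
    """CRE equals FE on time-varying coefficients to 1e-8."""
    df = _equivalence_frame(unbalanced)
    spec = ModelSpec(outcome="latent_hdds", focal="fpd_species", covariates=X_COLUMNS)
    cre = fit_cre(df, spec)
    fe = fit_fe(df, ModelSpec(outcome="latent_hdds", focal="fpd_species",
                              covariates=X_COLUMNS, estimator="fe"))
    common = [t for t in fe.params.index if t in cre.params.index]
    assert "fpd_species" in common
    assert (cre.params[common] - fe.params[common]).abs().max() < 1e-8


def test_fe_demeaning_and_invariant_drop():
    df = pd.DataFrame(
        {
            "household_id": [1, 1, 2, 2],
            "country": "A",
            "wave": [1, 2, 1, 2],
            "y": [3.0, 5.0, 1.0, 2.0],
            "x": [1.0, 2.0, 0.0, 3.0],
            "sexhead": [1.0, 1.0, 0.0, 0.0],
        }
    )
    fit = fit_fe(
        df,
        ModelSpec(outcome="y", focal="x", covariates=("sexhead",), estimator="fe",
                  wave_dummies=False),
    )
    assert "sexhead" not in fit.params.index  # annihilated by within transform
    # demeaned regression oracle: household 1 y -> (-1, +1)
    ydm = np.array([-1.0, 1.0, -0.5, 0.5])
    xdm = np.array([-0.5, 0.5, -1.5, 1.5])
    assert fit.params["x"] == pytest.approx((xdm @ ydm) / (xdm @ xdm), abs=1e-12)


def test_fe_requires_within_variation_in_focal():
    df = pd.DataFrame(
        {
            "household_id": [1, 1, 2, 2],
            "country": "A",
            "wave": [1, 2, 1, 2],
            "y": [3.0, 5.0, 1.0, 2.0],
            "x": [2.0, 2.0, 4.0, 4.0],
        }
    )
    with pytest.raises(ValueError, match="within-household variation"):
        fit_fe(df, ModelSpec(outcome="y", focal="x", estimator="fe", wave_dummies=False))


# ----------------------------------------------------------------------
# Poisson
# ----------------------------------------------------------------------


def test_poisson_intercept_only_closed_form():
    X = np.ones((3, 1))
    fit = fit_poisson_cre(_design(X, [1, 2, 3], clusters=[0, 1, 2], names=["const"]))
    assert fit.params["const"] == pytest.approx(np.log(2.0), abs=1e-8)


def test_poisson_recovers_slope_on_simulated_counts():
    rng = np.random.default_rng(11)
    n = 5000
    x = rng.normal(size=n)
    y = rng.poisson(np.exp(0.5 + 0.1 * x))
    X = np.column_stack([np.ones(n), x])
    fit = fit_poisson_cre(_design(X, y, clusters=np.arange(n) % 500, names=["const", "x"]))
    mc_se = fit.se["x"]
    assert abs(fit.params["x"] - 0.1) < 3 * mc_se


def test_poisson_matches_statsmodels_glm(linear_frame):
    sm = pytest.importorskip("statsmodels.api")
    spec = ModelSpec(outcome="hdds", focal="fpd_species", covariates=X_COLUMNS,
                     family="poisson")
    d = build_design(linear_frame, spec)
    ours = fit_poisson_cre(d, spec)
    ref = sm.GLM(d.y, d.X.values, family=sm.families.Poisson()).fit()
    np.testing.assert_allclose(ours.params.values, ref.params, atol=1e-8)


def test_poisson_rejects_bad_outcomes():
    X = np.ones((4, 1))
    with pytest.raises(ValueError, match="non-negative"):
        fit_poisson_cre(_design(X, [-1, 0, 1, 2], clusters=[0, 1, 2, 3], names=["const"]))
    with pytest.raises(ValueError, match="all-zero"):
        fit_poisson_cre(_design(X, [0, 0, 0, 0], clusters=[0, 1, 2, 3], names=["const"]))


# ----------------------------------------------------------------------
# Marginal effects
# ----------------------------------------------------------------------


def _interaction_fit():
    rng = np.random.default_rng(13)
    n = 400
    f = rng.poisson(3, n).astype(float)
    d = rng.gamma(2, 15, n)
    y = 0.10 * f - 0.001 * f * d + rng.normal(size=n)
    X = np.column_stack([np.ones(n), f, f * d, d])
    return fit_ols(
        _design(X, y, clusters=np.arange(n) % 50, names=["const", "f", "f_x_d", "d"])
    )


def test_marginal_effect_arithmetic():
    fit = _interaction_fit()
    me = marginal_effects(fit, "f", "f_x_d", at=[0.0, 50.0])
    b1, b2 = fit.params["f"], fit.params["f_x_d"]
    assert me.effect.iloc[0] == pytest.approx(b1)
    assert me.se.iloc[0] == pytest.approx(fit.se["f"])
    assert me.effect.iloc[1] == pytest.approx(b1 + 50 * b2)


def test_marginal_effect_se_matches_parametric_bootstrap():
    fit = _interaction_fit()
    grid = [0.0, 25.0, 75.0]
    me = marginal_effects(fit, "f", "f_x_d", at=grid)
    rng = np.random.default_rng(17)
    idx = [list(fit.params.index).index(t) for t in ("f", "f_x_d")]
    draws = rng.multivariate_normal(fit.params.values, fit.cov.values, size=5000)
    for j, d in enumerate(grid):
        boot = draws[:, idx[0]] + d * draws[:, idx[1]]
        assert me.se.iloc[j] == pytest.approx(boot.std(ddof=1), rel=0.05)


def test_marginal_effect_requires_interaction():
    X = np.column_stack([np.ones(20), np.arange(20.0)])
    fit = fit_ols(_design(X, np.arange(20.0), clusters=np.arange(20) % 4,
                          names=["const", "f"]))
    with pytest.raises(ValueError, match="interaction"):
        marginal_effects(fit, "f", at=[0.0])


# ----------------------------------------------------------------------
# Group comparison
# ----------------------------------------------------------------------


def test_group_comparison_symmetry_and_power():
    rng = np.random.default_rng(19)
    a = rng.normal(0, 1, 500)
    same = pd.DataFrame({"v": np.concatenate([a, a]),
                         "subsistence": np.repeat([1, 0], 500)})
    res = group_comparison(same, "v")
    assert res["difference"] == pytest.approx(0.0)
    assert res["statistic"] == pytest.approx(0.0)
    # shifted alternative detected
    rejections = 0
    for s in range(50):
        r = np.random.default_rng(s)
        df = pd.DataFrame(
            {
                "v": np.concatenate([r.normal(1, 1, 500), r.normal(0, 1, 500)]),
                "subsistence": np.repeat([1, 0], 500),
            }
        )
        rejections += group_comparison(df, "v")["p_value"] < 0.05
    assert rejections == 50  # power > 99% at delta=1, sigma=1, n=500/500


def test_group_comparison_rejects_degenerate_group():
    df = pd.DataFrame({"v": [1.0, 2.0, 3.0], "subsistence": [1, 0, 0]})
    with pytest.raises(ValueError, match="at least 2"):
        group_comparison(df, "v")


# ----------------------------------------------------------------------
# IPW attrition weights
# ----------------------------------------------------------------------

_RET_COVS = ["head_literate", "phone", "electricity", "landholding", "head_age"]


def _attrition_panel(base_rate, c_slope=0.0, seed=23):
    cfg = GeneratorConfig(
        seed=seed,
        districts_per_country=2,
        towns_per_district=2,
        villages_per_town=4,
        households_per_village=10,
        waves_per_country=(3,),
        outcome_mode="linear",
        true_beta_species=0.044,
        attrition=AttritionConfig(base_rate=base_rate, c_slope=c_slope),
    )
    return generate_panel(cfg)


def test_ipw_no_attrition_gives_unit_weights():
    panel, truth = _attrition_panel(0.0)
    w = ipw_attrition_weights(panel, _RET_COVS)
    np.testing.assert_allclose(w.weight.values, 1.0, atol=1e-12)
    df = model_frame(panel, truth=truth).merge(w, on=["household_id", "wave"])
    spec_u = ModelSpec(outcome="latent_hdds", focal="fpd_species", covariates=X_COLUMNS)
    spec_w = ModelSpec(outcome="latent_hdds", focal="fpd_species", covariates=X_COLUMNS,
                       weights="weight")
    fu, fw = fit_cre(df, spec_u), fit_cre(df, spec_w)
    assert (fu.params - fw.params).abs().max() < 1e-10


def test_ipw_covariate_independent_attrition_leaves_estimate_unchanged():
    """With dropout independent of covariates, true weights are constant
    within wave; estimated weights carry only sampling noise, so the
    weighted point estimate stays within a fraction of one SE."""
    panel, truth = _attrition_panel(0.5)
    w = ipw_attrition_weights(panel, _RET_COVS)
    merged = w.merge(panel.households[["household_id", "wave", "country"]],
                     on=["household_id", "wave"])
    # normalized to mean 1 within country-wave
    means = merged.groupby(["country", "wave"]).weight.mean()
    np.testing.assert_allclose(means.values, 1.0, atol=1e-12)
    df = model_frame(panel, truth=truth).merge(w, on=["household_id", "wave"])
    fu = fit_cre(df, ModelSpec(outcome="latent_hdds", focal="fpd_species",
                               covariates=X_COLUMNS))
    fw = fit_cre(df, ModelSpec(outcome="latent_hdds", focal="fpd_species",
                               covariates=X_COLUMNS, weights="weight"))
    assert abs(fw["fpd_species"] - fu["fpd_species"]) < 0.5 * fu.se["fpd_species"]


def test_ipw_moves_estimate_toward_truth_under_selective_attrition():
    """Dropout loaded on the household effect: weighting on c_i proxies
    (baseline observables incl. landholding) should not hurt and typically
    helps recover the true coefficient."""
    true_beta = 0.044
    biases_u, biases_w = [], []
    for seed in (31, 32, 33):
        panel, truth = _attrition_panel(0.25, c_slope=-1.2, seed=seed)
        w = ipw_attrition_weights(panel, _RET_COVS)
        df = model_frame(panel, truth=truth).merge(w, on=["household_id", "wave"])
        fu = fit_cre(df, ModelSpec(outcome="latent_hdds", focal="fpd_species",
                                   covariates=X_COLUMNS))
        fw = fit_cre(df, ModelSpec(outcome="latent_hdds", focal="fpd_species",
                                   covariates=X_COLUMNS, weights="weight"))
        biases_u.append(fu["fpd_species"] - true_beta)
        biases_w.append(fw["fpd_species"] - true_beta)
    assert abs(np.mean(biases_w)) <= abs(np.mean(biases_u)) + 0.01
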