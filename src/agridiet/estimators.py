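"""Panel estimators: Mundlak CRE, fixed effects, Poisson, cluster-robust SEs.

The workhorse model regresses the household dietary diversity score on a
focal production-diversity regressor and household covariates.  Because
unobserved time-invariant household heterogeneity (ability, preferences,
land quality) is correlated with production diversity, pooled OLS is
biased.  Two devices deal with it:

* **CRE (correlated random effects / Mundlak)** — augment the pooled
  regression with household time-averages of the time-varying regressors.
  Coefficients on time-varying regressors then equal the fixed-effects
  estimates, while coefficients on time-invariant covariates remain
  estimable.
* **FE (within estimator)** — demean outcome and regressors within
  households; time-invariant regressors drop out.

All covariances are CR1 cluster-robust sandwiches (clustered on the
household by default) with the small-sample factor
``G/(G-1) * (N-1)/(N-K)``; confidence intervals use the normal
approximation.  The Poisson variant (for the count outcome) is quasi-ML
with a log link, fitted by Newton–Raphson with analytic derivatives.

Exact FE↔CRE equivalence on *unbalanced* panels additionally requires the
household means of the wave dummies among the Mundlak terms; they are
added automatically and silently pruned when collinear (the balanced
case, where they are constant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

Z975 = 1.96  # normal-approximation 95% CI half-width multiplier


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; message lists candidate columns."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge."""


# ----------------------------------------------------------------------
# Model specification
# ----------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Declarative description of one regression.

    ``mundlak="auto"`` includes household means of the focal regressor(s),
    the interaction term and every time-varying covariate (detected from
    the data).  ``estimator`` ∈ {"cre", "fe", "pooled"};
    ``family`` ∈ {"linear", "poisson"}.
    """

    outcome: str
    focal: Sequence[str] = ()
    covariates: Sequence[str] = ()
    interaction_with: str | None = None
    mundlak: Sequence[str] | str = "auto"
    estimator: str = "cre"
    family: str = "linear"
    country_dummies: bool = True
    wave_dummies: bool = True
    cluster: str = "household_id"
    weights: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.focal, str):
            self.focal = (self.focal,)
        self.focal = tuple(self.focal)
        self.covariates = tuple(self.covariates)
        if self.estimator not in ("cre", "fe", "pooled"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.family not in ("linear", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class Design:
    """Materialized design: X (n×k DataFrame), outcome, clusters, weights."""

    X: pd.DataFrame
    y: np.ndarray
    clusters: np.ndarray
    weights: np.ndarray | None
    frame: pd.DataFrame
    dropped_rows: int
    dropped_columns: list[str]

    @property
    def names(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class FitResult:
    """Coefficients, cluster-robust covariance and fit metadata."""

    params: pd.Series
    cov: pd.DataFrame
    n_obs: int
    n_clusters: int
    family: str
    estimator: str
    residuals: np.ndarray
    r_squared: float | None = None
    loglik: float | None = None
    spec: ModelSpec | None = None
    dropped: dict = field(default_factory=dict)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.values)), index=self.params.index)

    @property
    def table(self) -> pd.DataFrame:
        se = self.se
        z = self.params / se.replace(0.0, np.nan)
        p = 2 * stats.norm.sf(np.abs(z.fillna(np.inf)))
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": se,
                "ci_low": self.params - Z975 * se,
                "ci_high": self.params + Z975 * se,
                "p_value": p,
            }
        )

    def __getitem__(self, name: str) -> float:
        return float(self.params[name])


def _interaction_name(focal: str, with_: str) -> str:
    return f"{focal}_x_{with_}"


def _time_varying(df: pd.DataFrame, columns: Sequence[str], household: str) -> list[str]:
    """Columns with any within-household variation."""
    out = []
    g = df.groupby(household, sort=False)
    for c in columns:
        rng = g[c].transform("max") - g[c].transform("min")
        if (rng.abs() > 1e-12).any():
            out.append(c)
    return out


def build_design(df: pd.DataFrame, spec: ModelSpec) -> Design:
    """Construct the regression design for a CRE or pooled model.

    Columns, in order: intercept, focal regressor(s), interaction,
    covariates, Mundlak household means, country dummies (pooled,
    multi-country only), wave dummies (plus their Mundlak means under
    CRE when the panel is unbalanced).
    """
    if spec.estimator == "fe":
        raise ValueError("use fit_fe for the within estimator")
    id_cols = ["household_id", "country", "wave"]
    if spec.cluster not in id_cols:
        id_cols.append(spec.cluster)
    used = list(
        dict.fromkeys(
            [spec.outcome, *spec.focal, *spec.covariates]
            + ([spec.interaction_with] if spec.interaction_with else [])
            + ([spec.weights] if spec.weights else [])
            + id_cols
        )
    )
    missing = [c for c in used if c not in df.columns]
    if missing:
        raise ValueError(f"model frame lacks columns {missing}")
    d = df[used].dropna()
    dropped_rows = len(df) - len(d)
    if dropped_rows:
        log.info("build_design: dropped %d rows with missing values", dropped_rows)
    if not len(d):
        raise ValueError("empty estimation sample after dropping missing values")

    X = pd.DataFrame(index=d.index)
    X["const"] = 1.0
    for f in spec.focal:
        X[f] = d[f].astype(float)
    inter_cols: list[str] = []
    if spec.interaction_with:
        for f in spec.focal:
            name = _interaction_name(f, spec.interaction_with)
            X[name] = d[f].astype(float) * d[spec.interaction_with].astype(float)
            inter_cols.append(name)
            d = d.assign(**{name: X[name]})
    for c in spec.covariates:
        X[c] = d[c].astype(float)
    if len(set(X.columns)) != len(X.columns):
        raise ValueError("duplicate column names in design")

    # Mundlak household means
    if spec.estimator == "cre":
        if spec.mundlak == "auto":
            candidates = list(spec.focal) + inter_cols + list(spec.covariates)
            mundlak = _time_varying(d, candidates, "household_id")
        else:
            mundlak = list(spec.mundlak)
        g = d.groupby("household_id", sort=False)
        for c in mundlak:
            X[f"mean_{c}"] = g[c].transform("mean").astype(float)
    else:
        mundlak = []

    # fixed-effect dummies (reference = first category, sorted)
    countries = sorted(d["country"].unique())
    if spec.country_dummies and len(countries) > 1:
        for c in countries[1:]:
            X[f"country_{c}"] = (d["country"] == c).astype(float)
    wave_cols: list[str] = []
    if spec.wave_dummies:
        waves = sorted(d["wave"].unique())
        for w in waves[1:]:
            col = f"wave_{w}"
            X[col] = (d["wave"] == w).astype(float)
            wave_cols.append(col)
        if spec.estimator == "cre" and spec.mundlak == "auto" and wave_cols:
            g = X.groupby(d["household_id"].values, sort=False)
            for col in wave_cols:
                X[f"mean_{col}"] = g[col].transform("mean")

    X, dropped_cols = _prune_collinear(X, protected_prefixes=("const",))
    y = d[spec.outcome].to_numpy(dtype=float)
    clusters = d[spec.cluster].to_numpy()
    weights = d[spec.weights].to_numpy(dtype=float) if spec.weights else None
    return Design(
        X=X,
        y=y,
        clusters=clusters,
        weights=weights,
        frame=d,
        dropped_rows=dropped_rows,
        dropped_columns=dropped_cols,
    )


def _rank(X: pd.DataFrame) -> int:
    M = X.to_numpy(dtype=float)
    scale = np.linalg.norm(M, axis=0)
    scale[scale == 0] = 1.0
    from scipy.linalg import qr

    _, R, _ = qr(M / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if not len(diag):
        return 0
    tol = max(M.shape) * np.finfo(float).eps * diag.max()
    return int((diag > tol).sum())


def _prune_collinear(
    X: pd.DataFrame, protected_prefixes: tuple[str, ...] = ()
) -> tuple[pd.DataFrame, list[str]]:
    """Drop automatically-added columns that are collinear.

    Only Mundlak means and fixed-effect dummies (``mean_*``,
    ``country_*``, ``wave_*``) may be pruned — greedily, a redundant
    column at a time — so user-specified regressors are never silently
    removed; if collinearity persists without such a column to blame, a
    :class:`RankDeficientError` is raised.
    """
    dropped: list[str] = []
    rank = _rank(X)
    while rank < len(X.columns):
        candidates = [
            c
            for c in reversed(list(X.columns))
            if c.startswith(("mean_", "country_", "wave_"))
            and not c.startswith(protected_prefixes)
        ]
        for c in candidates:
            without = X.drop(columns=[c])
            if _rank(without) == rank:  # c lies in the span of the rest
                X = without
                dropped.append(c)
                break
        else:
            raise RankDeficientError(
                f"design matrix rank deficient ({rank} < {len(X.columns)}); "
                f"no auto-added column can account for it"
            )
        rank = _rank(X)
    if dropped:
        log.info("build_design: dropped collinear columns %s", dropped)
    return X, dropped


# ----------------------------------------------------------------------
# Cluster-robust covariance
# ----------------------------------------------------------------------


def cluster_covariance(
    X: np.ndarray,
    scores: np.ndarray,
    bread: np.ndarray,
    clusters: np.ndarray,
    k_params: int | None = None,
) -> tuple[np.ndarray, int]:
    """CR1 sandwich: ``c * bread @ (Σ_g s_g s_g') @ bread``.

    ``scores`` holds per-observation score contributions (n×k); they are
    summed within clusters.  ``c = G/(G-1) * (N-1)/(N-K)``.  With singleton
    clusters this reduces to the HC1 heteroskedasticity-robust estimator
    up to the identical finite-sample factor.
    """
    n = X.shape[0]
    k = k_params if k_params is not None else X.shape[1]
    codes, _ = pd.factorize(clusters, sort=False)
    g = codes.max() + 1
    if g < 2:
        raise ValueError("cluster-robust covariance needs at least 2 clusters")
    S = np.zeros((g, scores.shape[1]))
    np.add.at(S, codes, scores)
    meat = S.T @ S
    c = (g / (g - 1)) * ((n - 1) / (n - k))
    cov = c * bread @ meat @ bread
    cov = (cov + cov.T) / 2.0
    return cov, int(g)


# ----------------------------------------------------------------------
# Linear fits
# ----------------------------------------------------------------------


def fit_ols(design: Design, spec: ModelSpec | None = None) -> FitResult:
    """(Weighted) least squares with CR1 cluster-robust covariance.

    Solved via QR decomposition; coefficients match the normal-equations
    solution to numerical precision on full-rank problems.
    """
    X = design.X.to_numpy(dtype=float)
    y = design.y
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n_obs={n} must exceed n_params={k}")
    w = design.weights
    if w is not None:
        if (w <= 0).any():
            raise ValueError("weights must be strictly positive")
        sw = np.sqrt(w)
        Xw, yw = X * sw[:, None], y * sw
    else:
        Xw, yw = X, y
    Q, R = np.linalg.qr(Xw)
    diag = np.abs(np.diag(R))
    if diag.min() < max(n, k) * np.finfo(float).eps * diag.max():
        raise RankDeficientError("design matrix numerically rank deficient in fit_ols")
    beta = np.linalg.solve(R, Q.T @ yw)
    resid = y - X @ beta
    wr = resid if w is None else w * resid
    bread = np.linalg.inv(R.T @ R)  # (X'WX)^{-1}
    scores = X * wr[:, None]
    cov, g = cluster_covariance(X, scores, bread, design.clusters)
    wy = yw
    tss = float(((wy - wy.mean()) ** 2).sum())
    rss = float(((yw - Xw @ beta) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    names = design.names
    return FitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        n_obs=n,
        n_clusters=g,
        family="linear",
        estimator=spec.estimator if spec else "cre",
        residuals=resid,
        r_squared=r2,
        spec=spec,
        dropped={"rows": design.dropped_rows, "columns": design.dropped_columns},
    )


def fit_cre(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Convenience wrapper: build the CRE/pooled design and fit."""
    design = build_design(df, spec)
    if spec.family == "poisson":
        return fit_poisson_cre(design, spec)
    return fit_ols(design, spec)


def fit_fe(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fixed-effects (within) estimator.

    Outcome and regressors are demeaned within households; time-invariant
    regressors are annihilated and dropped (logged); wave dummies are
    demeaned like any other regressor.  The CR1 degrees-of-freedom
    correction counts the absorbed household intercepts.
    """
    if spec.family != "linear":
        raise ValueError("fit_fe implements the linear within estimator only")
    used = list(
        dict.fromkeys(
            [spec.outcome, *spec.focal, *spec.covariates]
            + ([spec.interaction_with] if spec.interaction_with else [])
            + ["household_id", "country", "wave", spec.cluster]
        )
    )
    missing = [c for c in used if c not in df.columns]
    if missing:
        raise ValueError(f"model frame lacks columns {missing}")
    d = df[used].dropna()
    if not len(d):
        raise ValueError("empty estimation sample")

    Xcols = pd.DataFrame(index=d.index)
    for f in spec.focal:
        Xcols[f] = d[f].astype(float)
    if spec.interaction_with:
        for f in spec.focal:
            Xcols[_interaction_name(f, spec.interaction_with)] = d[f].astype(
                float
            ) * d[spec.interaction_with].astype(float)
    for c in spec.covariates:
        Xcols[c] = d[c].astype(float)
    if spec.wave_dummies:
        for w in sorted(d["wave"].unique())[1:]:
            Xcols[f"wave_{w}"] = (d["wave"] == w).astype(float)

    g = Xcols.groupby(d["household_id"].values, sort=False)
    Xdm = Xcols - g.transform("mean")
    within_span = Xdm.abs().max()
    invariant = [c for c in Xcols.columns if within_span[c] < 1e-10]
    if invariant:
        log.info("fit_fe: dropping time-invariant regressors %s", invariant)
    Xdm = Xdm.drop(columns=invariant)
    for f in spec.focal:
        if f in invariant:
            raise ValueError(f"focal regressor {f!r} has no within-household variation")
    if not len(Xdm.columns):
        raise ValueError("no time-varying regressors left for the within estimator")

    ydm = d[spec.outcome].astype(float)
    ydm = (ydm - ydm.groupby(d["household_id"].values).transform("mean")).to_numpy()

    Xdm, dropped_cols = _prune_collinear(Xdm)
    X = Xdm.to_numpy(dtype=float)
    n, k = X.shape
    n_households = d["household_id"].nunique()
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() < max(n, k) * np.finfo(float).eps * diag.max():
        raise RankDeficientError("within-transformed design rank deficient")
    beta = np.linalg.solve(R, Q.T @ ydm)
    resid = ydm - X @ beta
    bread = np.linalg.inv(R.T @ R)
    cov, ng = cluster_covariance(
        X, X * resid[:, None], bread, d[spec.cluster].to_numpy(),
        k_params=min(k + n_households, n - 1),
    )
    names = list(Xdm.columns)
    tss = float((ydm**2).sum())
    rss = float((resid**2).sum())
    return FitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        n_obs=n,
        n_clusters=ng,
        family="linear",
        estimator="fe",
        residuals=resid,
        r_squared=1.0 - rss / tss if tss > 0 else np.nan,
        spec=spec,
        dropped={"columns": invariant + dropped_cols},
    )


# ----------------------------------------------------------------------
# Poisson quasi-ML
# ----------------------------------------------------------------------


def fit_poisson_cre(
    design: Design,
    spec: ModelSpec | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Log-link Poisson quasi-ML by Newton–Raphson with step halving.

    Convergence when the maximum absolute score falls below ``tol``.
    Covariance is the CR1 cluster-robust sandwich
    ``(X'ΛX)^{-1} (Σ_g s_g s_g') (X'ΛX)^{-1}`` with per-observation scores
    ``x_i (y_i - μ_i)``, valid under arbitrary over/under-dispersion.
    """
    X = design.X.to_numpy(dtype=float)
    y = design.y
    if (y < 0).any():
        raise ValueError("Poisson outcome must be non-negative")
    if not np.allclose(y, np.round(y)):
        raise ValueError("Poisson outcome must be integer-valued")
    if y.sum() == 0:
        raise ValueError("all-zero outcome: Poisson mean not representable")
    w = design.weights if design.weights is not None else np.ones(len(y))
    n, k = X.shape

    beta = np.zeros(k)
    names = design.names
    if "const" in names:
        beta[names.index("const")] = np.log(np.average(y, weights=w))

    def loglik(b: np.ndarray) -> float:
        eta = np.clip(X @ b, -30, 30)
        return float(np.sum(w * (y * eta - np.exp(eta))))

    ll = loglik(beta)
    trace = []
    for it in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        score = X.T @ (w * (y - mu))
        max_score = float(np.abs(score).max())
        trace.append(max_score)
        if max_score < tol:
            break
        H = X.T @ (X * (w * mu)[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at iteration {it}") from exc
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            if loglik(cand) >= ll - 1e-10:
                break
            lam /= 2.0
        beta = beta + lam * step
        ll = loglik(beta)
    else:
        raise ConvergenceError(
            f"Poisson Newton–Raphson did not converge in {max_iter} iterations; "
            f"score trace tail {trace[-5:]}"
        )

    eta = np.clip(X @ beta, -30, 30)
    mu = np.exp(eta)
    H = X.T @ (X * (w * mu)[:, None])
    bread = np.linalg.inv(H)
    scores = X * (w * (y - mu))[:, None]
    cov, g = cluster_covariance(X, scores, bread, design.clusters)
    return FitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        n_obs=n,
        n_clusters=g,
        family="poisson",
        estimator=spec.estimator if spec else "cre",
        residuals=y - mu,
        loglik=ll,
        spec=spec,
        dropped={"rows": design.dropped_rows, "columns": design.dropped_columns},
    )


# ----------------------------------------------------------------------
# Post-estimation
# ----------------------------------------------------------------------


def marginal_effects(
    fit: FitResult,
    focal: str,
    interaction: str | None = None,
    at: Sequence[float] = (),
) -> pd.DataFrame:
    """Marginal effect of the focal regressor over a moderator grid.

    For a linear interaction model, effect(d) = β_focal + β_int·d and
    SE(d) = sqrt(v11 + d²·v22 + 2d·v12) — the delta method, exact here.
    """
    if interaction is None:
        interaction = next(
            (n for n in fit.params.index if n.startswith(f"{focal}_x_")), None
        )
        if interaction is None:
            raise ValueError(f"no interaction term found for {focal!r}")
    if interaction not in fit.params.index:
        raise ValueError(f"missing interaction term {interaction!r}")
    b1 = float(fit.params[focal])
    b2 = float(fit.params[interaction])
    v11 = float(fit.cov.loc[focal, focal])
    v22 = float(fit.cov.loc[interaction, interaction])
    v12 = float(fit.cov.loc[focal, interaction])
    d = np.asarray(list(at), dtype=float)
    effect = b1 + b2 * d
    se = np.sqrt(np.maximum(v11 + d**2 * v22 + 2 * d * v12, 0.0))
    return pd.DataFrame(
        {
            "at": d,
            "effect": effect,
            "se": se,
            "ci_low": effect - Z975 * se,
            "ci_high": effect + Z975 * se,
        }
    )


def group_comparison(
    scores: pd.DataFrame, variable: str, group: str = "subsistence"
) -> dict:
    """Welch two-sample comparison of ``variable`` between the two levels
    of a binary grouping column (default: subsistence class)."""
    d = scores[[variable, group]].dropna()
    g1 = d.loc[d[group] == 1, variable].to_numpy(dtype=float)
    g0 = d.loc[d[group] == 0, variable].to_numpy(dtype=float)
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError(
            f"both groups need at least 2 observations (got {len(g1)}, {len(g0)})"
        )
    stat, p = stats.ttest_ind(g1, g0, equal_var=False)
    return {
        "variable": variable,
        "mean_group1": float(g1.mean()),
        "mean_group0": float(g0.mean()),
        "difference": float(g1.mean() - g0.mean()),
        "statistic": float(stat),
        "p_value": float(p),
        "n_group1": int(len(g1)),
        "n_group0": int(len(g0)),
    }


# ----------------------------------------------------------------------
# Attrition: inverse-probability weights
# ----------------------------------------------------------------------


def _fit_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 200
) -> np.ndarray:
    """Newton–Raphson logistic regression with step halving.

    Raises :class:`ConvergenceError` on (quasi-)separation, signalled by
    diverging linear predictors, or on failure to converge.
    """
    n, k = X.shape
    beta = np.zeros(k)

    def loglik(b: np.ndarray) -> float:
        eta = X @ b
        # log(1 + e^eta) computed stably
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    ll = loglik(beta)
    for _ in range(max_iter):
        eta = X @ beta
        if np.abs(eta).max() > 100:
            raise ConvergenceError("separation suspected in retention model")
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        score = X.T @ (y - p)
        if np.abs(score).max() < tol * max(1.0, n / 100):
            return beta
        W = np.maximum(p * (1 - p), 1e-10)
        H = X.T @ (X * W[:, None]) + 1e-10 * np.eye(k)
        step = np.linalg.solve(H, score)
        lam = 1.0
        for _ in range(40):
            cand = beta + lam * step
            if loglik(cand) >= ll - 1e-12:
                break
            lam /= 2.0
        beta = beta + lam * step
        ll = loglik(beta)
    raise ConvergenceError("retention logistic model did not converge")


def ipw_attrition_weights(
    panel, baseline_covariates: Sequence[str]
) -> pd.DataFrame:
    """Inverse-probability-of-retention weights against attrition bias.

    For each country and wave t ≥ 2, a logistic model of being retained at
    t (among households retained at t−1) on first-wave covariates is
    fitted; the weight of an observed household-wave is the inverse of the
    cumulative predicted retention probability up to its wave, normalized
    to mean 1 within country-wave.  Returns (household_id, wave, weight).
    """
    if panel.retention is None:
        raise ValueError("panel carries no retention indicators")
    hh = panel.households
    ret = panel.retention

    # baseline covariates from each household's first observed wave
    base = hh.sort_values(["household_id", "wave"]).drop_duplicates("household_id")
    base = base.set_index("household_id")
    missing = [c for c in baseline_covariates if c not in base.columns]
    if missing:
        raise ValueError(f"baseline covariates missing from households: {missing}")

    country_of = base["country"]
    ret = ret.merge(
        country_of.rename("country").reset_index(), on="household_id", how="left"
    )

    weights = []
    for country, cal in panel.wave_calendar.items():
        cal = sorted(cal)
        ids = country_of.index[country_of == country]
        cum = pd.Series(1.0, index=ids)  # cumulative retention probability
        rc = ret[ret["country"] == country].pivot_table(
            index="household_id", columns="wave", values="retained", aggfunc="first"
        )
        first = cal[0]
        weights.append(
            pd.DataFrame(
                {"household_id": ids, "wave": first, "weight_raw": 1.0}
            )
        )
        for prev, wave in zip(cal[:-1], cal[1:]):
            at_risk = rc.index[rc.get(prev, pd.Series(0, index=rc.index)) == 1]
            at_risk = at_risk.intersection(base.index)
            if not len(at_risk):
                continue
            y = rc.loc[at_risk, wave].fillna(0).to_numpy(dtype=float)
            Xb = base.loc[at_risk, list(baseline_covariates)].to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(at_risk)), Xb])
            if y.min() == y.max():  # no attrition (or total) this wave
                p = np.full(len(at_risk), max(y.mean(), 1e-12))
            else:
                beta = _fit_logistic(X, y)
                p = 1.0 / (1.0 + np.exp(-(X @ beta)))
            cum.loc[at_risk] *= p
            retained_now = at_risk[y == 1]
            weights.append(
                pd.DataFrame(
                    {
                        "household_id": retained_now,
                        "wave": wave,
                        "weight_raw": 1.0 / cum.loc[retained_now].to_numpy(),
                    }
                )
            )
    w = pd.concat(weights, ignore_index=True)
    # keep only observed household-waves, normalize to mean 1 within country-wave
    obs = hh[["household_id", "wave", "country"]]
    w = obs.merge(w, on=["household_id", "wave"], how="left")
    w["weight_raw"] = w["weight_raw"].fillna(1.0)
    w["weight"] = w["weight_raw"] / w.groupby(["country", "wave"], sort=False)[
        "weight_raw"
    ].transform("mean")
    return w[["household_id", "wave", "weight"]]
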