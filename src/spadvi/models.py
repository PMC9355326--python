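"""SPAD estimators: ordinary least squares (with optional shade dummy
variables), a random-intercept linear mixed model fitted by REML, random
forest, and RBF-kernel support vector regression.

Shade enters in two ways. The dummy-variable model

    SPAD = b·x + sum_i a_i z_i + eps

codes the four shade levels one-hot *without* a separate global intercept,
so each a_i is directly the level-specific intercept. The mixed model

    SPAD = b·x + u_g + eps,   u_g ~ N(0, sigma²_r),  eps ~ N(0, sigma²_e)

treats shade-level deviations as random intercepts; variance components are
estimated by restricted maximum likelihood (profiled over the variance
ratio with a bounded 1-D search) and predictions for known levels use BLUPs.

OLS and the REML fit are implemented here; random forest and SVR delegate
to scikit-learn with seeded, reproducible configurations.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConfigError, DegenerateInputError, DesignError

log = logging.getLogger(__name__)


def one_hot(levels: Sequence[float]) -> tuple[np.ndarray, list[float]]:
    """One-hot shade coding (no intercept column); returns (Z, level order)."""
    uniq = sorted(set(float(v) for v in levels))
    Z = np.zeros((len(levels), len(uniq)))
    pos = {v: j for j, v in enumerate(uniq)}
    for i, v in enumerate(levels):
        Z[i, pos[float(v)]] = 1.0
    return Z, uniq


@dataclass
class ModelFitReport:
    """Fitted estimator plus everything needed to audit or reuse it."""

    family: str
    feature_names: list[str]
    hyperparameters: dict = field(default_factory=dict)
    coefficients: dict | None = None
    predict: Callable[..., np.ndarray] | None = None
    metrics: dict = field(default_factory=dict)  # split name -> (R2, RMSE, MAPE)

    def to_json_dict(self) -> dict:
        return {"family": self.family, "features": self.feature_names,
                "hyperparameters": _jsonable(self.hyperparameters),
                "coefficients": _jsonable(self.coefficients),
                "metrics": {k: list(v) for k, v in self.metrics.items()}}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    M = np.asarray(X, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    return M, [f"x{j}" for j in range(M.shape[1])]


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise DesignError(
            f"rank-deficient design (rank {rank} < {design.shape[1]} columns: "
            f"{names})")


def fit_olr(X, y, shade: Sequence[float] | None = None) -> ModelFitReport:
    """Least-squares regression, optionally with shade dummy intercepts.

    Without shade a global intercept is included; with shade the one-hot
    level columns replace it, so their coefficients are the level-specific
    intercepts a_i.
    """
    M, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    if shade is not None:
        Z, levels = one_hot(shade)
        design = np.hstack([M, Z])
        dnames = names + [f"shade_{v:g}" for v in levels]
    else:
        design = np.hstack([M, np.ones((len(yv), 1))])
        dnames = names + ["intercept"]
        levels = None
    _check_rank(design, dnames)
    coef, *_ = np.linalg.lstsq(design, yv, rcond=None)
    coefs = dict(zip(dnames, coef.tolist()))

    def predict(Xn, shade_n: Sequence[float] | None = None) -> np.ndarray:
        Mn, _ = _as_matrix(Xn)
        if levels is not None:
            if shade_n is None:
                raise ConfigError("model was fitted with shade dummies; "
                                  "pass shade levels at prediction time")
            Zn = np.zeros((len(Mn), len(levels)))
            pos = {v: j for j, v in enumerate(levels)}
            for i, v in enumerate(shade_n):
                if float(v) not in pos:
                    raise ConfigError(f"unseen shade level {v}")
                Zn[i, pos[float(v)]] = 1.0
            Dn = np.hstack([Mn, Zn])
        else:
            Dn = np.hstack([Mn, np.ones((len(Mn), 1))])
        return Dn @ coef

    return ModelFitReport(family="olr_dummy" if shade is not None else "olr",
                          feature_names=names, coefficients=coefs,
                          predict=predict)


# ---------------------------------------------------------------------------
# random-intercept LMM by REML

@dataclass
class LMMFit:
    beta: np.ndarray
    sigma2_random: float
    sigma2_residual: float
    blups: dict[float, float]
    reml_neg2ll: float


def _reml_profile(theta: float, M: np.ndarray, yv: np.ndarray,
                  groups: list[np.ndarray]) -> tuple[float, np.ndarray, float]:
    """Profiled REML criterion at variance ratio theta = s2_r / s2_e.

    Block structure V_g = I + theta·J allows closed-form inverses:
    V_g^{-1} = I − (c_g/n_g)·J with c_g = theta·n_g/(1 + theta·n_g).
    Returns (−2 restricted log-likelihood up to a constant, beta, s2_e).
    """
    n, p = M.shape
    XtVX = M.T @ M
    XtVy = M.T @ yv
    logdet_v = 0.0
    cs = []
    for g in groups:
        ng = len(g)
        c = theta * ng / (1.0 + theta * ng)
        cs.append(c)
        xbar = M[g].mean(axis=0)
        ybar = yv[g].mean()
        XtVX -= c * ng * np.outer(xbar, xbar)
        XtVy -= c * ng * xbar * ybar
        logdet_v += math.log1p(theta * ng)
    beta = np.linalg.solve(XtVX, XtVy)
    r = yv - M @ beta
    quad = float(r @ r)
    for g, c in zip(groups, cs):
        rbar = r[g].mean()
        quad -= c * len(g) * rbar ** 2
    quad = max(quad, 1e-12)
    s2e = quad / (n - p)
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise DesignError("singular X'V^{-1}X in mixed-model fit")
    neg2ll = (n - p) * math.log(s2e) + logdet_v + logdet_x
    return neg2ll, beta, s2e


def fit_lmm(X, shade: Sequence[float], y,
            tol: float = 1e-8) -> ModelFitReport:
    """Random-intercept mixed model grouped by shade level, fitted by REML.

    The variance ratio sigma²_r/sigma²_e is profiled out and maximized by a
    bounded 1-D search; fixed effects include a global intercept. With a
    single group the model degenerates to OLS (a warning is logged).
    """
    M, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    design = np.hstack([M, np.ones((len(yv), 1))])
    dnames = names + ["intercept"]
    _check_rank(design, dnames)
    labels = [float(v) for v in shade]
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        log.warning("single shade group: mixed model degenerates to OLS")
        rep = fit_olr(X, y)
        rep.family = "lmm"
        rep.hyperparameters = {"sigma2_random": 0.0}
        return rep
    groups = [np.flatnonzero(np.asarray(labels) == u) for u in uniq]
    if min(len(g) for g in groups) < 2:
        raise DegenerateInputError("each shade group needs >= 2 records")

    obj = lambda th: _reml_profile(th, design, yv, groups)[0]
    res = optimize.minimize_scalar(obj, bounds=(0.0, 1e4), method="bounded",
                                   options={"xatol": tol})
    theta = float(res.x)
    if obj(0.0) <= res.fun:  # boundary check: no between-group variance
        theta = 0.0
    neg2ll, beta, s2e = _reml_profile(theta, design, yv, groups)
    s2r = theta * s2e

    r = yv - design @ beta
    blups = {}
    for u, g in zip(uniq, groups):
        ng = len(g)
        shrink = theta * ng / (1.0 + theta * ng)
        blups[u] = float(shrink * r[g].mean())

    coefs = dict(zip(dnames, beta.tolist()))

    def predict(Xn, shade_n: Sequence[float] | None = None) -> np.ndarray:
        Mn, _ = _as_matrix(Xn)
        Dn = np.hstack([Mn, np.ones((len(Mn), 1))])
        out = Dn @ beta
        if shade_n is not None:
            out = out + np.array([blups.get(float(v), 0.0) for v in shade_n])
        return out

    return ModelFitReport(
        family="lmm", feature_names=names, coefficients=coefs,
        hyperparameters={"sigma2_random": s2r, "sigma2_residual": s2e,
                         "theta": theta, "reml_neg2ll": neg2ll,
                         "blups": blups},
        predict=predict)


# ---------------------------------------------------------------------------
# machine-learning estimators (delegated, seeded)

def _with_dummies(M: np.ndarray, shade, levels=None):
    if shade is None:
        return M, levels
    labels = [float(v) for v in shade]
    if levels is None:
        levels = sorted(set(labels))
    Z = np.zeros((len(labels), len(levels)))
    pos = {v: j for j, v in enumerate(levels)}
    for i, v in enumerate(labels):
        Z[i, pos[v]] = 1.0
    return np.hstack([M, Z]), levels


def fit_rf(X, y, shade: Sequence[float] | None = None, n_trees: int = 500,
           seed: int = 0) -> ModelFitReport:
    """Bootstrap-aggregated regression trees (mean over trees).

    Defaults: 500 trees, ceil(p/3) features per split, unlimited depth,
    minimum leaf size 2; deterministic for a fixed seed.
    """
    from sklearn.ensemble import RandomForestRegressor

    M, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    if len(yv) < 10:
        raise ConfigError("random forest needs at least 10 rows")
    D, levels = _with_dummies(M, shade)
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, math.ceil(D.shape[1] / 3)),
        min_samples_leaf=2, random_state=seed, n_jobs=1)
    rf.fit(D, yv)

    def predict(Xn, shade_n=None):
        Mn, _ = _as_matrix(Xn)
        Dn, _ = _with_dummies(Mn, shade_n, levels)
        if Dn.shape[1] != D.shape[1]:
            raise ConfigError("prediction design width mismatch "
                              "(shade supplied at fit but not predict?)")
        return rf.predict(Dn)

    return ModelFitReport(
        family="rf_dummy" if shade is not None else "rf",
        feature_names=names,
        hyperparameters={"n_trees": n_trees, "min_samples_leaf": 2,
                         "max_features": int(rf.max_features),
                         "seed": seed},
        predict=predict)


DEFAULT_SVR_C = tuple(2.0 ** k for k in range(-3, 11))
DEFAULT_SVR_GAMMA = tuple(2.0 ** k for k in range(-10, 4))
DEFAULT_SVR_EPSILON = (0.01, 0.1, 0.5, 1.0)


def fit_svr(X, y, shade: Sequence[float] | None = None,
            c_grid: Sequence[float] = DEFAULT_SVR_C,
            gamma_grid: Sequence[float] = DEFAULT_SVR_GAMMA,
            epsilon_grid: Sequence[float] = DEFAULT_SVR_EPSILON,
            k_folds: int = 10, seed: int = 0) -> ModelFitReport:
    """RBF-kernel epsilon-SVR with (C, gamma, epsilon) chosen by k-fold CV.

    Features are standardized inside the estimator; the CV criterion is
    mean squared error and fold assignment is seeded, so the chosen triple
    is reproducible.
    """
    from sklearn.model_selection import GridSearchCV, KFold
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVR

    M, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    if np.std(yv) == 0:
        raise DegenerateInputError("response has zero variance")
    D, levels = _with_dummies(M, shade)
    pipe = make_pipeline(StandardScaler(), SVR(kernel="rbf"))
    grid = {"svr__C": list(c_grid), "svr__gamma": list(gamma_grid),
            "svr__epsilon": list(epsilon_grid)}
    cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, cv=cv,
                          scoring="neg_mean_squared_error", n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(D, yv)
    best = search.best_estimator_
    chosen = {k.split("__")[1]: v for k, v in search.best_params_.items()}

    def predict(Xn, shade_n=None):
        Mn, _ = _as_matrix(Xn)
        Dn, _ = _with_dummies(Mn, shade_n, levels)
        if Dn.shape[1] != D.shape[1]:
            raise ConfigError("prediction design width mismatch")
        return best.predict(Dn)

    return ModelFitReport(
        family="svr_dummy" if shade is not None else "svr",
        feature_names=names,
        hyperparameters={**chosen, "k_folds": k_folds, "seed": seed},
        predict=predict)
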