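"""Statistical screening of index features.

Three stages mirror the selection workflow: (i) per-index Pearson
correlation with SPAD and its two-sided t-based p-value; (ii) variance
inflation factors (VIF = 1/(1 - R²) from regressing each index on the
others) with the conventional bands — <10 no multicollinearity, 10–20 some,
>20 serious; (iii) a significance pre-filter followed by Lasso selection,

    beta_hat = argmin ||y - X beta||² + lambda * sum_j |beta_j|,

solved by cyclic coordinate descent with soft-thresholding on standardized
columns, lambda chosen by k-fold cross-validated MSE over a log-spaced grid.
The penalty enters once (not scaled by n); the CV minimum is used, not the
one-standard-error rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import numba
from scipy import stats

from .errors import DegenerateInputError, ScreeningError

log = logging.getLogger(__name__)

VIF_CAP = 1e6


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation and two-sided p-value (Student t, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError("need two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance input to correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def vif(X: pd.DataFrame | np.ndarray,
        columns: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per column.

    Each column is regressed (with intercept) on all the others; VIF_j is
    1/(1 - R²_j), capped at 1e6 when the auxiliary fit is numerically
    perfect (exactly collinear columns).
    """
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        columns = columns or [f"x{j}" for j in range(M.shape[1])]
    n, p = M.shape
    if p < 2:
        raise DegenerateInputError("VIF needs at least two columns")
    if n <= p:
        raise DegenerateInputError(f"need n > p for VIF diagnostics (n={n}, p={p})")
    out = {}
    ones = np.ones((n, 1))
    for j in range(p):
        target = M[:, j]
        tss = np.sum((target - target.mean()) ** 2)
        if tss == 0:
            raise DegenerateInputError(f"constant column {columns[j]!r}")
        others = np.hstack([ones, np.delete(M, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        rss = np.sum((target - others @ coef) ** 2)
        r2 = 1.0 - rss / tss
        out[columns[j]] = VIF_CAP if r2 >= 1.0 - 1e-6 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def vif_band(value: float) -> str:
    """Multicollinearity class for one VIF value."""
    if value < 10:
        return "none"
    if value <= 20:
        return "some"
    return "serious"


def prefilter(pvalues: pd.Series, alpha: float = 0.05) -> list[str]:
    """Keep columns whose correlation with the response is significant.

    Columns with p >= alpha are dropped (and logged); dropping everything is
    an error, not an empty result.
    """
    keep = [c for c, p in pvalues.items() if p < alpha]
    dropped = [c for c in pvalues.index if c not in keep]
    if dropped:
        log.info("prefilter dropped %d column(s): %s", len(dropped), dropped)
    if not keep:
        raise ScreeningError(f"significance pre-filter (alpha={alpha}) dropped "
                             "every column")
    return keep


def soft_threshold(z: float, gamma: float) -> float:
    """sign(z) * max(|z| - gamma, 0)."""
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


@numba.njit(cache=False)
def _cd_kernel(gram, xty, col_ss, beta, q, lam, tol, max_sweeps,
               kkt_tol):  # pragma: no cover - exercised via wrapper
    p = beta.shape[0]
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            bj = beta[j]
            rho = xty[j] - q[j] + col_ss[j] * bj
            if rho > lam / 2.0:
                bj_new = (rho - lam / 2.0) / col_ss[j]
            elif rho < -lam / 2.0:
                bj_new = (rho + lam / 2.0) / col_ss[j]
            else:
                bj_new = 0.0
            if bj_new != bj:
                d = bj_new - bj
                for k in range(p):
                    q[k] += gram[k, j] * d
                beta[j] = bj_new
                if abs(d) > delta:
                    delta = abs(d)
        if delta < tol:
            break
        viol = 0.0
        for j in range(p):
            g = 2.0 * (xty[j] - q[j])
            if beta[j] == 0.0:
                v = abs(g) - lam
                if v < 0.0:
                    v = 0.0
            elif beta[j] > 0.0:
                v = abs(g - lam)
            else:
                v = abs(g + lam)
            if v > viol:
                viol = v
        if viol < kkt_tol:
            break
    return beta


def lasso_coordinate_descent(X: np.ndarray, y: np.ndarray, lam: float,
                             beta0: np.ndarray | None = None,
                             tol: float = 1e-8,
                             max_sweeps: int = 100_000) -> np.ndarray:
    """Minimize ||y - X beta||² + lam * ||beta||_1 by cyclic coordinate descent.

    Stationarity per coordinate gives beta_j = S(x_jᵀ r_j, lam/2) / x_jᵀx_j
    with r_j the partial residual; sweeps stop when no coefficient moves by
    more than ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    # covariance (Gram) updates: each coordinate costs O(p), which keeps
    # slowly-converging near-collinear designs tractable
    gram = X.T @ X
    col_ss = np.diag(gram).copy()
    if np.any(col_ss == 0):
        raise DegenerateInputError("zero-norm column in Lasso design")
    xty = np.array([float(X[:, j] @ y) for j in range(p)])
    q = gram @ beta  # running X'X beta
    # secondary stop: first-order (KKT) optimality — on near-collinear
    # designs coefficients drift along a flat valley long after the fit
    # itself has converged
    kkt_tol = tol * max(1.0, float(np.abs(xty).max()))
    return _cd_kernel(np.ascontiguousarray(gram), xty, col_ss, beta, q,
                      float(lam), float(tol), int(max_sweeps), kkt_tol)


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that zeroes every coefficient: max_j |2 x_jᵀ y|.

    Uses the same per-column dot product as the coordinate-descent loop so
    the kill condition holds bit-exactly at this penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return max(abs(2.0 * float(X[:, j] @ y)) for j in range(X.shape[1]))


def kkt_violation(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                  lam: float) -> float:
    """Largest KKT violation at ``beta`` for the Lasso objective.

    Zero coefficients require |2 x_jᵀ r| <= lam; active ones require
    2 x_jᵀ r = lam * sign(beta_j). Returns the max absolute slack excess.
    """
    grad = 2.0 * X.T @ (y - X @ beta)
    viol = 0.0
    for j, b in enumerate(beta):
        if b == 0.0:
            viol = max(viol, abs(grad[j]) - lam)
        else:
            viol = max(viol, abs(grad[j] - lam * np.sign(b)))
    return float(viol)


@dataclass
class ScreenReport:
    """Everything the screening stage decided, with its evidence."""

    columns: list[str]
    pearson_r: pd.Series | None = None
    pearson_p: pd.Series | None = None
    vif_before: pd.Series | None = None
    vif_after: pd.Series | None = None
    prefilter_survivors: list[str] = field(default_factory=list)
    lam_grid: np.ndarray | None = None
    coef_path: np.ndarray | None = None  # len(grid) x p, standardized scale
    cv_mse: np.ndarray | None = None
    lam_star: float | None = None
    retained: list[str] = field(default_factory=list)
    multiple_r: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "columns": self.columns,
            "pearson_r": None if self.pearson_r is None else self.pearson_r.to_dict(),
            "pearson_p": None if self.pearson_p is None else self.pearson_p.to_dict(),
            "vif_before": None if self.vif_before is None else self.vif_before.to_dict(),
            "vif_after": None if self.vif_after is None else self.vif_after.to_dict(),
            "prefilter_survivors": self.prefilter_survivors,
            "lam_star": self.lam_star,
            "retained": self.retained,
            "multiple_r": self.multiple_r,
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def path_frame(self) -> pd.DataFrame:
        """Lasso path as a tidy frame (one row per lambda)."""
        df = pd.DataFrame(self.coef_path, columns=self.prefilter_survivors)
        df.insert(0, "lambda", self.lam_grid)
        if self.cv_mse is not None:
            df["cv_mse"] = self.cv_mse
        return df


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateInputError("constant column cannot be standardized")
    return (X - mu) / sd, mu, sd


def lasso_select(X: pd.DataFrame, y: np.ndarray,
                 lam_grid: np.ndarray | None = None, k_folds: int = 10,
                 seed: int = 0, tol: float = 1e-8) -> ScreenReport:
    """Lasso variable selection with cross-validated penalty.

    Columns are standardized to mean 0 / variance 1 and y is centered; the
    default grid is 100 log-spaced penalties from lambda_max down to
    1e-4 * lambda_max. The retained set is the support at the CV-MSE
    minimizer; if it is empty, the smallest grid penalty is used instead and
    a warning is recorded. ``multiple_r`` is the multiple correlation
    coefficient of an OLS refit of y on the retained columns.
    """
    cols = list(X.columns)
    M = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    Z, _, _ = _standardize(M)
    yc = yv - yv.mean()

    if lam_grid is None:
        lmax = lambda_max(Z, yc)
        lam_grid = np.geomspace(lmax, 1e-4 * lmax, 100)
    lam_grid = np.sort(np.asarray(lam_grid, dtype=float))[::-1]

    # full-data path with warm starts down the grid
    path = np.zeros((lam_grid.size, Z.shape[1]))
    beta = np.zeros(Z.shape[1])
    for i, lam in enumerate(lam_grid):
        beta = lasso_coordinate_descent(Z, yc, lam, beta0=beta, tol=tol)
        path[i] = beta

    # k-fold CV over the same grid (same standardization, per-fold fits)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(yc))
    folds = np.array_split(idx, k_folds)
    cv_sse = np.zeros(lam_grid.size)
    for f in folds:
        train = np.setdiff1d(idx, f, assume_unique=False)
        bw = np.zeros(Z.shape[1])
        for i, lam in enumerate(lam_grid):
            bw = lasso_coordinate_descent(Z[train], yc[train], lam, beta0=bw,
                                          tol=tol)
            resid = yc[f] - Z[f] @ bw
            cv_sse[i] += float(resid @ resid)
    cv_mse = cv_sse / len(yc)

    best = int(np.argmin(cv_mse))
    lam_star = float(lam_grid[best])
    # support tolerance guards against numerical leakage into exactly
    # collinear duplicates, which sit on the soft-threshold boundary
    support = np.flatnonzero(np.abs(path[best]) > 1e-8)
    warnings = []
    if support.size == 0:
        warnings.append("empty retained set at lambda*; falling back to the "
                        "smallest grid penalty")
        support = np.flatnonzero(np.abs(path[-1]) > 1e-8)
        lam_star = float(lam_grid[-1])
    # the L1 solution is non-unique across exactly collinear columns (any
    # same-sign split has equal objective); collapse such duplicates onto
    # the first member so the retained set is well-posed for OLS refits
    deduped: list[int] = []
    for j in support:
        if any(abs(float(Z[:, j] @ Z[:, k])) / len(yc) > 1.0 - 1e-10
               for k in deduped):
            warnings.append(f"dropped {cols[j]!r}: exactly collinear with an "
                            "already-retained column")
            continue
        deduped.append(j)
    support = np.asarray(deduped, dtype=int)
    retained = [cols[j] for j in support]

    multiple_r = None
    if retained:
        design = np.column_stack([np.ones(len(yv)), M[:, support]])
        coef, *_ = np.linalg.lstsq(design, yv, rcond=None)
        resid = yv - design @ coef
        tss = float(np.sum((yv - yv.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / tss
        multiple_r = float(np.sqrt(max(r2, 0.0)))

    return ScreenReport(columns=cols, prefilter_survivors=cols,
                        lam_grid=lam_grid, coef_path=path, cv_mse=cv_mse,
                        lam_star=lam_star, retained=retained,
                        multiple_r=multiple_r, warnings=warnings)


def screen_features(table: pd.DataFrame, feature_cols: list[str],
                    y_col: str = "spad_measured", alpha: float = 0.05,
                    k_folds: int = 10, seed: int = 0,
                    holm: bool = False) -> ScreenReport:
    """Full screening pass: Pearson + VIF diagnostics, pre-filter, Lasso.

    Rows with any missing (invalid-index) value among ``feature_cols`` are
    dropped with a logged count. p-values are uncorrected by default,
    matching common practice in this workflow; ``holm=True`` applies a Holm
    step-down correction before the pre-filter.
    """
    sub = table[feature_cols + [y_col]]
    n_before = len(sub)
    sub = sub.dropna()
    if len(sub) < n_before:
        log.info("dropped %d record(s) with invalid index values",
                 n_before - len(sub))
    y = sub[y_col].to_numpy(dtype=float)

    r_vals, p_vals = {}, {}
    for c in feature_cols:
        r_vals[c], p_vals[c] = pearson_with_p(sub[c].to_numpy(dtype=float), y)
    r_ser = pd.Series(r_vals, name="r")
    p_ser = pd.Series(p_vals, name="p")
    if holm:
        order = np.argsort(p_ser.values)
        m = len(p_ser)
        adj = p_ser.values.copy()
        running = 0.0
        for rank, j in enumerate(order):
            running = max(running, (m - rank) * p_ser.values[j])
            adj[j] = min(running, 1.0)
        p_for_filter = pd.Series(adj, index=p_ser.index)
    else:
        p_for_filter = p_ser

    vif_before = vif(sub[feature_cols])
    survivors = prefilter(p_for_filter, alpha)

    report = lasso_select(sub[survivors], y, k_folds=k_folds, seed=seed)
    report.columns = feature_cols
    report.pearson_r = r_ser
    report.pearson_p = p_ser
    report.vif_before = vif_before
    report.prefilter_survivors = survivors
    if len(report.retained) >= 2:
        report.vif_after = vif(sub[report.retained])
    return report
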