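"""Evaluation protocol: 3:1 modeling/test split, R²/RMSE/MAPE metrics,
one-way ANOVA across shade levels, and percent-comparison arithmetic.

Test-set R² uses the test-set mean in its denominator and may be negative
for models worse than the constant predictor. Reported percentages follow
half-up rounding to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateInputError

__all__ = ["metrics", "split", "SplitPlan", "anova_oneway",
           "relative_change", "percent_lower", "round_half_up"]


def metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(R², RMSE, MAPE%) of predictions against observations.

    R² = 1 − SS_res/SS_tot (mean of ``y_true``); RMSE in the units of y;
    MAPE = 100·mean(|y−ŷ|/|y|) percent, undefined if any y is zero.
    """
    y = np.asarray(y_true, dtype=float)
    f = np.asarray(y_pred, dtype=float)
    if y.shape != f.shape or y.size < 2:
        raise DegenerateInputError("need two equal-length vectors, n >= 2")
    if np.any(y == 0):
        raise ConfigError("MAPE undefined: zero entries in y_true")
    resid = y - f
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateInputError("constant y_true: R² undefined")
    r2 = 1.0 - float(resid @ resid) / ss_tot
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mape = float(100.0 * np.mean(np.abs(resid) / np.abs(y)))
    return r2, rmse, mape


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint modeling/test id partition (default 3:1)."""

    modeling_ids: tuple
    test_ids: tuple
    seed: int
    stratified: bool = False

    def __post_init__(self) -> None:
        if set(self.modeling_ids) & set(self.test_ids):
            raise ConfigError("modeling and test ids overlap")


def split(ids, ratio: tuple[int, int] = (3, 1), seed: int = 0,
          stratify_by=None) -> SplitPlan:
    """Random modeling/test partition of ids at ``ratio`` (modeling:test).

    With ``stratify_by`` (e.g. shade labels, aligned with ids) the test
    fraction is applied within each stratum, largest-remainder rounded.
    """
    ids = list(ids)
    if len(ids) < 4:
        raise ConfigError("need at least 4 ids to split")
    m, t = ratio
    if m <= 0 or t <= 0:
        raise ConfigError("ratio parts must be positive")
    test_frac = t / (m + t)
    rng = np.random.default_rng(seed)

    if stratify_by is None:
        n_test = int(round(len(ids) * test_frac))
        if n_test == 0 or n_test == len(ids):
            raise ConfigError(f"ratio {ratio} infeasible for n={len(ids)}")
        perm = rng.permutation(len(ids))
        test = {ids[i] for i in perm[:n_test]}
    else:
        labels = list(stratify_by)
        if len(labels) != len(ids):
            raise ConfigError("stratify_by must align with ids")
        test = set()
        for lvl in sorted(set(labels), key=str):
            members = [i for i, l in zip(ids, labels) if l == lvl]
            n_test_g = int(round(len(members) * test_frac))
            perm = rng.permutation(len(members))
            test.update(members[i] for i in perm[:n_test_g])
        if not test or len(test) == len(ids):
            raise ConfigError(f"ratio {ratio} infeasible under stratification")
    modeling = tuple(i for i in ids if i not in test)
    testing = tuple(i for i in ids if i in test)
    return SplitPlan(modeling_ids=modeling, test_ids=testing, seed=seed,
                     stratified=stratify_by is not None)


def anova_oneway(groups) -> tuple[float, float]:
    """Classic one-way ANOVA F and p across groups of values."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise DegenerateInputError("need >= 2 groups with >= 2 values each")
    if all(np.var(a) == 0 for a in arrs):
        raise DegenerateInputError("zero within-group variance in every group")
    res = stats.f_oneway(*arrs)
    return float(res.statistic), float(res.pvalue)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def relative_change(reference: float, value: float,
                    decimals: int = 2) -> float:
    """Signed percent change of ``value`` relative to ``reference``.

    100·(value − reference)/reference, half-up rounded; positive means
    "X% higher than the reference".
    """
    if reference == 0:
        raise ConfigError("zero reference in relative change")
    return round_half_up(100.0 * (value - reference) / reference, decimals)


def percent_lower(reference: float, value: float, decimals: int = 2) -> float:
    """How many percent ``value`` is *lower* than ``reference``."""
    if reference == 0:
        raise ConfigError("zero reference in relative change")
    return round_half_up(100.0 * (reference - value) / reference, decimals)
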