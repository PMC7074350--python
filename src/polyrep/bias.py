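"""Parental-bias regressions and the slope-equality F-test.

Cluster sizes (read numbers) are natural-log transformed and the tetraploid
size is regressed on each parent's size separately:

    ln t = b0 + b1 ln m        (maternal)
    ln t = b0' + b1' ln p      (paternal)

Under the nuclear-cytoplasmic interaction hypothesis the paternal subgenome
should be preferentially degraded, which would make the two regressions
differ. The slope comparison is the standard interaction-term F-test on the
stacked model

    ln t = b0 + b1 ln x + b2 I + b3 (ln x * I),   I = 1 for paternal rows,

with H0: b3 = 0. The statistic is

    SS   = SSE_restricted - SSE_full
    F    = SS / (SSE_full / (n_total - 4)),    df = (1, n_total - 4)

where n_total = 2 x n_clusters stacked observations. A joint two-predictor
plane fit (ln t on ln m and ln p) is provided as the 3D visualisation
companion. All fits use closed-form normal-equation OLS.

Note that the tetraploid observation appears in both stacked groups, so the
two groups' errors are not independent; the F-test is the field's standard
recipe but its nominal calibration is approximate (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .additivity import DeviationRecord
from .filtering import CrossDesign, DEFAULT_MIN_READS


@dataclass
class RegressionFit:
    """Simple OLS fit of ln(t) on one parent's ln(count)."""

    parent: str
    slope: float
    intercept: float
    residual_sum_squares: float
    n: int
    r_squared: float
    se_intercept: float
    se_slope: float

    def to_dict(self) -> dict:
        return {
            "parent": self.parent,
            "slope": self.slope,
            "intercept": self.intercept,
            "residual_sum_squares": self.residual_sum_squares,
            "n": self.n,
            "r_squared": self.r_squared,
            "se_intercept": self.se_intercept,
            "se_slope": self.se_slope,
        }


@dataclass
class SlopeTest:
    """Slope-equality test on the stacked two-parent model."""

    sum_of_squares: float
    f_stat: float
    p_value: float
    df: tuple[int, int]
    n_clusters: int

    def to_dict(self) -> dict:
        return {
            "sum_of_squares": self.sum_of_squares,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "df_num": self.df[0],
            "df_den": self.df[1],
            "n_clusters": self.n_clusters,
        }


@dataclass
class PlaneFit:
    """Joint OLS of ln(t) on ln(m) and ln(p)."""

    intercept: float
    slope_maternal: float
    slope_paternal: float
    residual_sum_squares: float
    n: int
    r_squared: float
    se: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope_maternal": self.slope_maternal,
            "slope_paternal": self.slope_paternal,
            "residual_sum_squares": self.residual_sum_squares,
            "n": self.n,
            "r_squared": self.r_squared,
            "se_intercept": self.se[0],
            "se_slope_maternal": self.se[1],
            "se_slope_paternal": self.se[2],
        }


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Closed-form OLS via the normal equations; returns (beta, SSE, cov)."""
    xtx = X.T @ X
    try:
        beta = np.linalg.solve(xtx, X.T @ y)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"collinear design matrix: {exc}") from exc
    resid = y - X @ beta
    sse = float(resid @ resid)
    df = X.shape[0] - X.shape[1]
    cov = (sse / df) * np.linalg.inv(xtx) if df > 0 else np.full_like(xtx, np.nan)
    return beta, sse, cov


def _r_squared(y: np.ndarray, sse: float) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - sse / sst if sst > 0 else 1.0


def fit_parent_regression(
    records: list[DeviationRecord],
    parent: str,
    min_count: int = DEFAULT_MIN_READS,
    min_n: int = 3,
) -> RegressionFit:
    """OLS of ln(t) on one parent's ln(count).

    Only records with both the parent count and the tetraploid count at or
    above ``min_count`` enter (log positivity; matches the presence filter).
    """
    if parent not in {"maternal", "paternal"}:
        raise ValueError("parent must be 'maternal' or 'paternal'")
    pairs = [
        (r.m if parent == "maternal" else r.p, r.t)
        for r in records
        if (r.m if parent == "maternal" else r.p) >= max(min_count, 1)
        and r.t >= max(min_count, 1)
    ]
    n = len(pairs)
    if n < min_n:
        raise ValueError(f"{parent} regression needs >= {min_n} records, got {n}")
    x = np.log([c for c, _ in pairs])
    y = np.log([t for _, t in pairs])
    if np.ptp(x) == 0:
        raise ValueError(f"{parent} regression: zero variance in predictor")
    X = np.column_stack([np.ones(n), x])
    beta, sse, cov = _ols(X, y)
    return RegressionFit(
        parent=parent,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        residual_sum_squares=sse,
        n=n,
        r_squared=_r_squared(y, sse),
        se_intercept=float(np.sqrt(cov[0, 0])),
        se_slope=float(np.sqrt(cov[1, 1])),
    )


def slope_equality_test(
    records: list[DeviationRecord],
    design: CrossDesign | None = None,
    min_count: int = DEFAULT_MIN_READS,
) -> SlopeTest:
    """Test whether the maternal and paternal regression slopes are equal.

    Uses only records positive (>= ``min_count``) in all three species, each
    contributing one maternal and one paternal stacked observation.
    """
    del design  # roles are already encoded in the records
    usable = [
        r
        for r in records
        if min(r.m, r.p, r.t) >= max(min_count, 1)
    ]
    n = len(usable)
    if 2 * n - 4 < 1:
        raise ValueError(f"slope test needs >= 3 usable clusters, got {n}")
    ln_m = np.log([r.m for r in usable])
    ln_p = np.log([r.p for r in usable])
    ln_t = np.log([r.t for r in usable])
    y = np.concatenate([ln_t, ln_t])
    x = np.concatenate([ln_m, ln_p])
    ind = np.concatenate([np.zeros(n), np.ones(n)])
    X_full = np.column_stack([np.ones(2 * n), x, ind, x * ind])
    X_restr = X_full[:, :3]
    _, sse_full, _ = _ols(X_full, y)
    _, sse_restr, _ = _ols(X_restr, y)
    ss = max(0.0, sse_restr - sse_full)  # clip numerical negatives
    df_den = 2 * n - 4
    f_stat = ss / (sse_full / df_den) if sse_full > 0 else 0.0
    p_value = float(stats.f.sf(f_stat, 1, df_den))
    return SlopeTest(
        sum_of_squares=ss,
        f_stat=f_stat,
        p_value=p_value,
        df=(1, df_den),
        n_clusters=n,
    )


def fit_joint_plane(
    records: list[DeviationRecord],
    min_count: int = DEFAULT_MIN_READS,
    min_n: int = 4,
) -> PlaneFit:
    """Joint OLS of ln(t) on ln(m) and ln(p) (the 3D regression plane)."""
    usable = [r for r in records if min(r.m, r.p, r.t) >= max(min_count, 1)]
    n = len(usable)
    if n < min_n:
        raise ValueError(f"plane fit needs >= {min_n} usable clusters, got {n}")
    ln_m = np.log([r.m for r in usable])
    ln_p = np.log([r.p for r in usable])
    ln_t = np.log([r.t for r in usable])
    if np.ptp(ln_m) == 0 or np.ptp(ln_p) == 0:
        raise ValueError("plane fit: zero variance in a predictor")
    corr = float(np.corrcoef(ln_m, ln_p)[0, 1])
    if abs(corr) >= 1.0 - 1e-12:
        raise ValueError("plane fit: ln(m) and ln(p) are perfectly collinear")
    X = np.column_stack([np.ones(n), ln_m, ln_p])
    beta, sse, cov = _ols(X, ln_t)
    return PlaneFit(
        intercept=float(beta[0]),
        slope_maternal=float(beta[1]),
        slope_paternal=float(beta[2]),
        residual_sum_squares=sse,
        n=n,
        r_squared=_r_squared(ln_t, sse),
        se=tuple(float(np.sqrt(cov[i, i])) for i in range(3)),
    )
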