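"""Statistical summaries for the in-silico harness.

Two-way fixed-effects ANOVA with interaction (Type II sums of squares,
which reduce to the classical decomposition for balanced designs and
behave sensibly for the mildly unbalanced tables that arise when a few
trials are excluded), effect sizes as eta squared = SS_effect / SS_total,
Tukey-fence outlier removal, and ordinary least-squares regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class EffectResult:
    ss: float
    df: int
    F: float
    p: float
    eta_squared: float


@dataclass(frozen=True)
class AnovaResult:
    """Per-effect statistics plus the residual and total sums of squares."""

    effects: dict[str, EffectResult]
    ss_residual: float
    df_residual: int
    ss_total: float

    def to_dict(self) -> dict:
        out = {
            name: {
                "SS": e.ss, "df": e.df, "F": e.F, "p": e.p,
                "eta_squared": e.eta_squared,
            }
            for name, e in self.effects.items()
        }
        out["residual"] = {"SS": self.ss_residual, "df": self.df_residual}
        out["total"] = {"SS": self.ss_total}
        return out


def _dummy(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero (effects) coding; returns (n, levels-1) matrix."""
    levels = sorted(set(labels.tolist()))
    k = len(levels)
    cols = np.zeros((labels.size, k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[labels == lev, j] = 1.0
    cols[labels == levels[-1], :] = -1.0
    return cols, levels


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    factor_names: tuple[str, str] = ("A", "B"),
) -> AnovaResult:
    """Two-way ANOVA with interaction, Type II sums of squares.

    Each effect's SS is the increase in residual SS when that effect is
    dropped from the model that contains it and every other effect not
    marginal to it (main effects are tested against the two-main-effects
    model; the interaction against the full model). eta squared is
    SS_effect over SS_total. Every cell of the design must be observed.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (y.size == a.size == b.size):
        raise ValueError("values and factor labels must have equal length")

    da, levels_a = _dummy(a)
    db, levels_b = _dummy(b)
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    for la, lb in product(levels_a, levels_b):
        if not np.any((a == la) & (b == lb)):
            raise ValueError(f"empty design cell: ({la!r}, {lb!r})")

    inter = np.einsum("ij,ik->ijk", da, db).reshape(y.size, -1)
    ones = np.ones((y.size, 1))

    X_full = np.hstack([ones, da, db, inter])
    X_ab = np.hstack([ones, da, db])
    rss_full = _rss(X_full, y)
    rss_ab = _rss(X_ab, y)
    df_a = da.shape[1]
    df_b = db.shape[1]
    df_int = inter.shape[1]
    df_res = y.size - 1 - df_a - df_b - df_int
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    ss = {
        factor_names[0]: _rss(np.hstack([ones, db]), y) - rss_ab,
        factor_names[1]: _rss(np.hstack([ones, da]), y) - rss_ab,
        f"{factor_names[0]}:{factor_names[1]}": rss_ab - rss_full,
    }
    dfs = {
        factor_names[0]: df_a,
        factor_names[1]: df_b,
        f"{factor_names[0]}:{factor_names[1]}": df_int,
    }
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ms_res = rss_full / df_res

    effects = {}
    for name in ss:
        ss_eff = max(ss[name], 0.0)
        if ms_res > 0:
            F = (ss_eff / dfs[name]) / ms_res
            p = float(sps.f.sf(F, dfs[name], df_res))
        else:
            F = np.inf if ss_eff > 0 else 0.0
            p = 0.0 if ss_eff > 0 else 1.0
        effects[name] = EffectResult(
            ss=ss_eff,
            df=dfs[name],
            F=float(F),
            p=p,
            eta_squared=ss_eff / ss_total if ss_total > 0 else 0.0,
        )
    return AnovaResult(
        effects=effects,
        ss_residual=rss_full,
        df_residual=df_res,
        ss_total=ss_total,
    )


def iqr_outlier_filter(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, removed) by the interquartile-range rule.

    Fences are Q1 - 1.5 IQR and Q3 + 1.5 IQR with linear-interpolation
    quantiles. With fewer than 4 values the rule is not meaningful, so
    everything is kept (with a warning).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        warnings.warn(
            "fewer than 4 values: IQR outlier rule skipped", stacklevel=2
        )
        return v, np.array([])
    q1, q3 = np.quantile(v, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (v >= lo) & (v <= hi)
    return v[mask], v[~mask]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    p: float
    stderr: float


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least-squares line with Pearson R and the slope t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
        stderr=float(res.stderr),
    )
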