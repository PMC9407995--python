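"""Effect analysis: importance ranking, partial dependence, OLS baseline.

Given a fitted boosted-tree model, this module answers the questions
planners actually ask of it: which predictors matter (relative
importance and a key-variable cut at a contribution threshold, 7% by
default), how each key predictor acts on the response (smoothed
partial-dependence curves, which expose nonlinear thresholds a linear
coefficient cannot), and whether the nonlinear model beats a global
ordinary-least-squares fit on the same table.

Partial dependence of feature s at value v is the average prediction
with that feature clamped: PD(v) = mean_i f(x_i with x_is := v).  The
grid is confined to an interior quantile range (1st-99th percentile by
default) and the raw curve is smoothed with a locally weighted linear
regression that down-weights sparsely populated bins, because tails
and low-density intervals of the feature support unreliable estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from greenaccess.gbdt import CVReport, GBDTResults


@dataclass
class PartialDependenceCurve:
    """A feature's partial-dependence profile over an interior grid."""

    feature: str
    grid: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    density: np.ndarray  # sample share per grid bin

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.raw) == len(self.smoothed) == len(self.density)):
            raise ValueError("grid, raw, smoothed, density must share a length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature,
                "grid": self.grid,
                "raw": self.raw,
                "smoothed": self.smoothed,
                "density": self.density,
            }
        )


def smooth_curve(
    values: Sequence[float],
    grid: Sequence[float] | None = None,
    span: float = 0.5,
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Locally weighted linear smoothing of a curve.

    At each grid point a linear fit is computed over the ``span``
    fraction of nearest points with tricube distance weights,
    multiplied by the optional per-point ``weights`` (used to
    down-weight low-density bins).  A linear input is reproduced
    exactly; isolated spikes are attenuated.  Output length equals
    input length and the endpoints are estimated, not dropped.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 points to smooth")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    x = np.arange(n, dtype=float) if grid is None else np.asarray(grid, dtype=float)
    if len(x) != n:
        raise ValueError("grid and values must share a length")
    w_extra = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if len(w_extra) != n or np.any(w_extra < 0):
        raise ValueError("weights must be non-negative and match the curve length")
    k = max(3, int(np.ceil(span * n)))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.sort(d)[min(k - 1, n - 1)]
        h = h if h > 0 else 1.0
        tri = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        w = tri * w_extra
        if w.sum() <= 0 or np.count_nonzero(w) < 2:
            out[i] = y[i]
            continue
        xm = np.average(x, weights=w)
        ym = np.average(y, weights=w)
        sxx = np.sum(w * (x - xm) ** 2)
        if sxx <= 0:
            out[i] = ym
            continue
        slope = np.sum(w * (x - xm) * (y - ym)) / sxx
        out[i] = ym + slope * (x[i] - xm)
    return out


def partial_dependence(
    results: GBDTResults,
    X: pd.DataFrame,
    feature: str,
    n_grid: int = 50,
    quantile_range: tuple[float, float] = (0.01, 0.99),
    span: float = 0.5,
) -> PartialDependenceCurve:
    """Partial dependence of the fitted model on one feature.

    The grid spans the feature's ``quantile_range`` interior (clipping
    away unreliable tails); the raw curve is the clamped-average
    prediction and the smoothed curve applies :func:`smooth_curve` with
    the per-bin sample density as weights.
    """
    if feature not in X.columns:
        raise KeyError(f"feature {feature!r} not in the table")
    lo, hi = np.quantile(X[feature].to_numpy(), quantile_range)
    if hi <= lo:
        warnings.warn(f"feature {feature!r} is (near-)constant; single-point curve",
                      stacklevel=2)
        grid = np.array([lo])
        raw = np.array([float(np.mean(_clamped_predict(results, X, feature, lo)))])
        return PartialDependenceCurve(feature, grid, raw, raw.copy(), np.array([1.0]))
    grid = np.linspace(lo, hi, n_grid)
    raw = np.array(
        [float(np.mean(_clamped_predict(results, X, feature, v))) for v in grid]
    )
    # sample density per grid bin (bins centred on grid points)
    edges = np.concatenate([[-np.inf], (grid[1:] + grid[:-1]) / 2, [np.inf]])
    counts, _ = np.histogram(X[feature].to_numpy(), bins=edges)
    density = counts / counts.sum()
    smoothed = smooth_curve(raw, grid=grid, span=span, weights=density + 1e-3)
    return PartialDependenceCurve(feature, grid, raw, smoothed, density)


def _clamped_predict(results: GBDTResults, X: pd.DataFrame, feature: str, v: float):
    Xc = X.copy()
    Xc[feature] = v
    return results.predict(Xc)


def select_key_variables(
    importance: Mapping[str, float] | pd.Series,
    threshold_pct: float = 7.0,
) -> list[str]:
    """Variables contributing strictly more than ``threshold_pct`` percent.

    Input must be a relative-importance table summing to 100; the
    result is ordered by descending importance (ties by name for
    determinism).
    """
    imp = pd.Series(importance, dtype=float)
    if abs(imp.sum() - 100.0) > 1e-6 and imp.sum() != 0:
        raise ValueError(f"importance must sum to 100%, got {imp.sum():.6f}")
    key = imp[imp > threshold_pct]
    key = key.sort_index().sort_values(ascending=False, kind="stable")
    return list(key.index)


@dataclass
class OLSResult:
    """Ordinary-least-squares baseline fit."""

    coefficients: pd.Series
    intercept: float
    r_squared: float
    n_obs: int


def ols_fit(X: pd.DataFrame, y: Sequence[float]) -> OLSResult:
    """Global OLS fit of the response on all predictors.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if len(X) <= X.shape[1]:
        raise ValueError(f"need more rows ({len(X)}) than predictors ({X.shape[1]})")
    design = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify dependent columns via the QR diagonal
        _, r = np.linalg.qr(design.to_numpy())
        diag = np.abs(np.diag(r))
        bad = [design.columns[j] for j in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    coefs = pd.Series(fit.params, index=design.columns)
    return OLSResult(
        coefficients=coefs.drop("const"),
        intercept=float(coefs["const"]),
        r_squared=float(fit.rsquared),
        n_obs=len(y),
    )


@dataclass
class ModelComparison:
    """OLS vs. boosted-tree explanatory power on the same table."""

    ols_r2: float
    gbdt_r2: float
    difference: float

    def to_dict(self) -> dict:
        return {"ols_r2": self.ols_r2, "gbdt_r2": self.gbdt_r2,
                "difference": self.difference}


def compare_models(ols: OLSResult, gbdt_cv: CVReport | float) -> ModelComparison:
    """Report OLS R^2 against GBDT cross-validated R^2 and their gap."""
    g = gbdt_cv.mean_r2 if isinstance(gbdt_cv, CVReport) else float(gbdt_cv)
    return ModelComparison(ols_r2=ols.r_squared, gbdt_r2=g, difference=g - ols.r_squared)


def plot_partial_dependence(curve: PartialDependenceCurve, ax=None):
    """Line plot of raw and smoothed partial dependence."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.grid, curve.raw, color="0.6", lw=0.8, label="raw")
    ax.plot(curve.grid, curve.smoothed, color="tab:blue", lw=2, label="smoothed")
    ax.set_xlabel(curve.feature)
    ax.set_ylabel("partial dependence")
    ax.legend(frameon=False)
    return ax
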