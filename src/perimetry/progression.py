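"""Longitudinal progression analysis: pointwise regression and PoPLR.

Per location, sensitivity (or total deviation) is regressed on time
since baseline; the one-sided t-test against the alternative of a
negative slope gives a per-location p-value, and the median absolute
deviation (MAD, unscaled) of the residuals flags highly variable series.

PoPLR — permutation of pointwise linear regression — combines the
per-location p-values into the Fisher-type statistic
``S = sum_i -ln(max(p_i, eps))`` and calibrates it by re-running all
regressions after randomly permuting the visit order (dates fixed,
fields shuffled jointly across locations, preserving spatial
correlation).  The combined p-value uses the add-one rule
``(1 + #{S_perm >= S_obs}) / (n_perm + 1)``, which is super-uniform
under the null by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fields import VisualField
from .grids import GridRegistry, default_registry
from .norms import NormativeModel, total_deviation

__all__ = ["LocationTrend", "PoPLRResult", "ProgressionError",
           "pointwise_linear_regression", "poplr", "P_FLOOR"]

#: Floor applied to per-location p-values inside S (keeps -ln p finite
#: for numerically zero p on perfect trends).
P_FLOOR = 1e-6


class ProgressionError(ValueError):
    pass


@dataclass(frozen=True)
class LocationTrend:
    """Per-location regression summary over a series of visits."""

    slope: float  # dB / year
    intercept: float  # dB at baseline
    se: float  # dB / year
    t_stat: float
    p: float  # one-sided, alternative slope < 0
    residual_mad: float  # dB, unscaled MAD of the residuals
    flagged: bool  # residual_mad > mad_threshold
    n_visits: int


@dataclass
class PoPLRResult:
    """The combined permutation test over one eye's series."""

    s_observed: float
    n_locations: int
    permutation_s: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    trends: list  #: per-grid-location LocationTrend (None at blind spots)

    @property
    def s_over_n(self) -> float:
        return self.s_observed / self.n_locations


def _ols_trend(t: np.ndarray, Y: np.ndarray):
    """Vectorized OLS of Y (..., m, L) on time t (m,).

    Returns slopes, intercepts, se, t-stats and lower-tail p-values of
    the t(m-2) distribution.  Degenerate zero-residual series get
    ``t = 0`` (p = 0.5) when flat and ``t = +/-inf`` (p = 1 or 0) on a
    perfect trend.
    """
    m = len(t)
    tc = t - t.mean()
    sxx = float(np.sum(tc**2))
    ym = Y.mean(axis=-2, keepdims=True)
    # centering Y keeps a constant series at slope exactly 0
    slope = np.einsum("m,...ml->...l", tc, Y - ym) / sxx
    intercept = (ym - slope[..., None, :] * t.mean()).squeeze(-2)
    fitted = intercept[..., None, :] + slope[..., None, :] * t[:, None]
    resid = Y - fitted
    sse = np.sum(resid**2, axis=-2)
    dof = m - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / dof / sxx)
        tstat = slope / se
    tstat = np.where(se == 0.0,
                     np.where(slope == 0.0, 0.0,
                              np.where(slope < 0, -np.inf, np.inf)),
                     tstat)
    p = stats.t.cdf(tstat, dof)
    return slope, intercept, se, tstat, p, resid


def _series_matrix(series, use: str, model: NormativeModel | None,
                   registry: GridRegistry):
    if len(series) < 4:
        raise ProgressionError(f"need >= 4 visits, got {len(series)}")
    grids = {f.grid_name for f in series}
    if len(grids) != 1:
        raise ProgressionError(f"series mixes grids: {sorted(grids)}")
    dates = [f.date for f in series]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ProgressionError("visit dates must be strictly increasing")
    grid = registry[series[0].grid_name]
    t = np.array([(d - dates[0]).days / 365.25 for d in dates])
    if use == "td":
        if model is None:
            raise ProgressionError("td mode requires a normative model")
        Y = np.stack([total_deviation(f, model) for f in series])
    elif use == "sensitivity":
        Y = np.stack([f.sensitivities for f in series])
    else:
        raise ProgressionError(f"use must be 'td' or 'sensitivity', got "
                               f"{use!r}")
    bs = grid.blind_spot_mask
    analyzed = ~bs & np.all(np.isfinite(Y), axis=0)
    return t, Y, grid, analyzed


def pointwise_linear_regression(
    series,
    use: str = "td",
    model: NormativeModel | None = None,
    mad_threshold: float = 2.0,
    registry: GridRegistry | None = None,
) -> list:
    """Per-location trends over an ordered series of fields of one eye.

    Returns one :class:`LocationTrend` per grid location, with ``None``
    at blind-spot (or all-missing) locations.
    """
    reg = registry if registry is not None else default_registry
    t, Y, grid, analyzed = _series_matrix(series, use, model, reg)
    slope, intercept, se, tstat, p, resid = _ols_trend(t, Y)
    med = np.median(resid, axis=0)
    mad = np.median(np.abs(resid - med), axis=0)
    trends: list = []
    for i in range(len(grid)):
        if not analyzed[i]:
            trends.append(None)
            continue
        trends.append(LocationTrend(
            slope=float(slope[i]), intercept=float(intercept[i]),
            se=float(se[i]), t_stat=float(tstat[i]),
            p=float(min(max(p[i], 5e-324), 1.0)),
            residual_mad=float(mad[i]),
            flagged=bool(mad[i] > mad_threshold),
            n_visits=len(series),
        ))
    return trends


def _combine_s(p: np.ndarray, axis=-1) -> np.ndarray:
    return np.sum(-np.log(np.maximum(p, P_FLOOR)), axis=axis)


def poplr(
    series,
    use: str = "td",
    model: NormativeModel | None = None,
    n_permutations: int = 5000,
    seed: int = 0,
    mad_threshold: float = 2.0,
    registry: GridRegistry | None = None,
) -> PoPLRResult:
    """PoPLR combined permutation test for visual-field deterioration.

    Visit order is permuted jointly across locations with the dates held
    fixed; each draw recomputes all per-location one-sided p-values and
    their combined ``S``.  Requires >= 100 permutations; draws exceeding
    the size of the permutation group are capped with a warning.
    """
    reg = registry if registry is not None else default_registry
    if n_permutations < 100:
        raise ProgressionError("need n_permutations >= 100")
    t, Y, grid, analyzed = _series_matrix(series, use, model, reg)
    m = len(series)
    n_distinct = math.factorial(m)
    if n_permutations > n_distinct:
        warnings.warn(
            f"{n_permutations} permutations requested but only "
            f"{n_distinct} distinct orderings of {m} visits exist; "
            f"capping", stacklevel=2,
        )
        n_permutations = n_distinct
    trends = pointwise_linear_regression(
        series, use=use, model=model, mad_threshold=mad_threshold,
        registry=reg,
    )
    p_obs = np.array([tr.p for tr in trends if tr is not None])
    s_obs = float(_combine_s(p_obs))
    Ya = Y[:, analyzed]
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_permutations, m)), axis=1)
    Yp = Ya[order]  # (B, m, L)
    *_, p_perm, _ = _ols_trend(t, Yp)
    s_perm = _combine_s(p_perm, axis=-1)
    p_value = float((1 + np.sum(s_perm >= s_obs)) / (n_permutations + 1))
    return PoPLRResult(
        s_observed=s_obs, n_locations=int(analyzed.sum()),
        permutation_s=s_perm, p_value=p_value,
        n_permutations=int(n_permutations), seed=int(seed), trends=trends,
    )
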