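"""Normative models and deviation analysis of visual fields.

A normative model is fitted from a healthy cohort: per location, an
ordinary least-squares regression of sensitivity on age gives the
age-expected normal value; the empirical quantiles of the cohort's total
deviation (TD) residuals at {0.5, 1, 2, 5}% give the probability-map
cutoffs.  Pattern deviation (PD) subtracts the general height (the 85th
percentile of TD), isolating localized from diffuse loss; its cutoffs
are fitted from general-height-corrected cohort residuals.  The
``smooth`` method shrinks each location's dispersion estimates toward
its Voronoi neighbors before the cutoffs are used.

Mean deviation (MD) is a weighted mean of TD over non-blind-spot
locations, weighted by inverse residual variance by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .fields import VisualField
from .grids import GridRegistry, default_registry, mirror_to_right_eye_format
from .tessellation import (
    adjacency_from_tessellation,
    neighbors_map,
    voronoi_tessellate,
)

__all__ = [
    "PROBABILITY_LEVELS", "CATEGORY_LABELS", "NormativeModel",
    "DeviationMap", "NormativeError", "fit_normative_model",
    "total_deviation", "deviation_probability", "pattern_deviation",
    "mean_deviation", "analyze_field",
]

#: Probability-map levels, in percent, from most to least extreme.
PROBABILITY_LEVELS = (0.5, 1.0, 2.0, 5.0)
CATEGORY_LABELS = ("<0.5%", "<1%", "<2%", "<5%", "normal")


class NormativeError(ValueError):
    pass


@dataclass
class NormativeModel:
    """Per-location age regressions, deviation cutoffs and index weights."""

    grid_name: str
    intercepts: np.ndarray  #: dB at age 0
    slopes: np.ndarray  #: dB / year
    residual_sd: np.ndarray  #: dB
    td_cutoffs: np.ndarray  #: (4, n) dB at the probability levels
    pd_cutoffs: np.ndarray  #: (4, n) dB
    md_weights: np.ndarray  #: non-negative, sum 1 over analyzed locations
    blind_spot_mask: np.ndarray
    gh_percentile: float = 85.0
    method: str = "pointwise"
    probability_levels: tuple = PROBABILITY_LEVELS

    def __post_init__(self) -> None:
        diffs = np.diff(self.td_cutoffs, axis=0)
        if np.any(diffs[:, ~self.blind_spot_mask] < -1e-9):
            raise NormativeError("TD cutoffs must be monotone in the level")
        w = self.md_weights[~self.blind_spot_mask]
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise NormativeError("MD weights must be non-negative, sum 1")

    def expected(self, age: float) -> np.ndarray:
        """Age-expected normal sensitivity per location."""
        return self.intercepts + self.slopes * age

    # -- JSON round trip -------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "grid_name": self.grid_name,
            "intercepts": self.intercepts.tolist(),
            "slopes": self.slopes.tolist(),
            "residual_sd": self.residual_sd.tolist(),
            "td_cutoffs": self.td_cutoffs.tolist(),
            "pd_cutoffs": self.pd_cutoffs.tolist(),
            "md_weights": self.md_weights.tolist(),
            "blind_spot_mask": self.blind_spot_mask.astype(int).tolist(),
            "gh_percentile": self.gh_percentile,
            "method": self.method,
            "probability_levels": list(self.probability_levels),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "NormativeModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            grid_name=payload["grid_name"],
            intercepts=np.asarray(payload["intercepts"], float),
            slopes=np.asarray(payload["slopes"], float),
            residual_sd=np.asarray(payload["residual_sd"], float),
            td_cutoffs=np.asarray(payload["td_cutoffs"], float),
            pd_cutoffs=np.asarray(payload["pd_cutoffs"], float),
            md_weights=np.asarray(payload["md_weights"], float),
            blind_spot_mask=np.asarray(payload["blind_spot_mask"],
                                       bool),
            gh_percentile=float(payload["gh_percentile"]),
            method=payload["method"],
            probability_levels=tuple(payload["probability_levels"]),
        )


@dataclass
class DeviationMap:
    """TD/PD values, probability categories and global indices for one
    field.  Blind-spot entries are nan / None."""

    td: np.ndarray
    pd: np.ndarray
    td_category: list
    pd_category: list
    md: float
    general_height: float


def _general_height(td: np.ndarray, mask: np.ndarray,
                    percentile: float) -> float:
    vals = td[~mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) < 5:
        raise NormativeError(
            "general height needs >= 5 valid analyzed locations"
        )
    return float(np.percentile(vals, percentile))


def fit_normative_model(
    cohort,
    method: str = "pointwise",
    registry: GridRegistry | None = None,
    gh_percentile: float = 85.0,
    uniform_weights: bool = False,
) -> NormativeModel:
    """Fit a normative model from a healthy cohort (one field per
    subject-eye, >= 20 fields, ages spanning >= 20 years, one grid).

    ``method="smooth"`` additionally replaces each location's residual sd
    and cutoffs by a weighted mean over itself (weight 0.5) and its
    Voronoi neighbors (sharing the other 0.5).
    """
    reg = registry if registry is not None else default_registry
    if method not in ("pointwise", "smooth"):
        raise NormativeError(f"unknown method {method!r}")
    cohort = [mirror_to_right_eye_format(f, f.eye, reg) for f in cohort]
    if len(cohort) < 20:
        raise NormativeError(f"need >= 20 fields, got {len(cohort)}")
    grids = {f.grid_name for f in cohort}
    if len(grids) != 1:
        raise NormativeError(f"cohort mixes grids: {sorted(grids)}")
    keys = [(f.subject_id, f.eye) for f in cohort]
    if len(set(keys)) != len(keys):
        raise NormativeError("duplicated subject-eye in cohort")
    grid_name = cohort[0].grid_name
    grid = reg[grid_name]
    ages = np.array([f.age for f in cohort])
    if ages.max() - ages.min() < 20:
        raise NormativeError(
            f"cohort ages span {ages.max() - ages.min():.1f} years; "
            "need >= 20"
        )
    Y = np.stack([f.sensitivities for f in cohort])  # (n_subj, n_loc)
    bs = grid.blind_spot_mask
    n_loc = len(grid)
    m = len(cohort)

    # per-location OLS of sensitivity on age (shared design matrix)
    X = np.column_stack([np.ones(m), ages])
    Yf = np.where(np.isnan(Y), 0.0, Y)  # blind-spot columns only
    beta, *_ = np.linalg.lstsq(X, Yf, rcond=None)
    intercepts, slopes = beta[0].copy(), beta[1].copy()
    resid = Yf - X @ beta
    dof = m - 2
    residual_sd = np.sqrt(np.sum(resid**2, axis=0) / dof)
    intercepts[bs] = np.nan
    slopes[bs] = np.nan
    residual_sd[bs] = np.nan
    resid[:, bs] = np.nan

    q = np.array(PROBABILITY_LEVELS) / 100.0
    td_cutoffs = np.full((4, n_loc), np.nan)
    td_cutoffs[:, ~bs] = np.quantile(resid[:, ~bs], q, axis=0)

    # general-height-correct each cohort field's TD before PD quantiles
    gh = np.array([
        _general_height(resid[k], bs, gh_percentile) for k in range(m)
    ])
    pd_resid = resid - gh[:, None]
    pd_cutoffs = np.full((4, n_loc), np.nan)
    pd_cutoffs[:, ~bs] = np.quantile(pd_resid[:, ~bs], q, axis=0)

    if method == "smooth":
        tess = voronoi_tessellate(grid)
        nbrs = neighbors_map(adjacency_from_tessellation(tess), n_loc)
        residual_sd = _neighbor_shrink(residual_sd, nbrs, bs)
        td_cutoffs = np.stack([
            _neighbor_shrink(td_cutoffs[k], nbrs, bs) for k in range(4)
        ])
        pd_cutoffs = np.stack([
            _neighbor_shrink(pd_cutoffs[k], nbrs, bs) for k in range(4)
        ])
        # shrinkage can only jitter the ordering at the 1e-16 scale
        td_cutoffs = np.sort(td_cutoffs, axis=0)
        pd_cutoffs = np.sort(pd_cutoffs, axis=0)

    if uniform_weights:
        w = (~bs).astype(float)
    else:
        var = np.where(bs, np.nan, residual_sd**2)
        if np.nanmax(var) <= 0:
            w = (~bs).astype(float)
        else:
            floor = max(np.nanmax(var) * 1e-12, 1e-12)
            w = np.where(bs, 0.0, 1.0 / np.maximum(var, floor))
    w = np.where(bs, 0.0, w)
    w = w / w.sum()

    return NormativeModel(
        grid_name=grid_name, intercepts=intercepts, slopes=slopes,
        residual_sd=residual_sd, td_cutoffs=td_cutoffs,
        pd_cutoffs=pd_cutoffs, md_weights=w, blind_spot_mask=bs,
        gh_percentile=gh_percentile, method=method,
    )


def _neighbor_shrink(values: np.ndarray, nbrs: list[set[int]],
                     bs: np.ndarray) -> np.ndarray:
    """Self keeps weight 0.5; non-blind-spot neighbors share 0.5."""
    out = values.copy()
    for i in range(len(values)):
        if bs[i]:
            continue
        others = [j for j in nbrs[i] if not bs[j]]
        if not others:
            continue
        out[i] = 0.5 * values[i] + 0.5 * np.mean([values[j] for j in others])
    return out


def total_deviation(field: VisualField, model: NormativeModel) -> np.ndarray:
    """Sensitivity minus the age-expected normal, per location (dB)."""
    if field.grid_name != model.grid_name:
        raise NormativeError(
            f"field grid {field.grid_name!r} does not match model grid "
            f"{model.grid_name!r}"
        )
    td = field.sensitivities - model.expected(field.age)
    td[model.blind_spot_mask] = np.nan
    return td


def deviation_probability(values: np.ndarray, cutoffs: np.ndarray) -> list:
    """Probability category per location: the smallest level whose cutoff
    strictly exceeds the value; ``"normal"`` otherwise, None if missing."""
    cats = []
    for i, v in enumerate(values):
        if not np.isfinite(v):
            cats.append(None)
            continue
        label = "normal"
        for k in range(len(PROBABILITY_LEVELS)):
            if v < cutoffs[k, i]:
                label = CATEGORY_LABELS[k]
                break
        cats.append(label)
    return cats


def pattern_deviation(
    td: np.ndarray, model: NormativeModel
) -> tuple[np.ndarray, float]:
    """PD = TD minus the general height (the model's GH percentile of TD
    over analyzed locations)."""
    gh = _general_height(td, model.blind_spot_mask, model.gh_percentile)
    pd = td - gh
    pd[model.blind_spot_mask] = np.nan
    return pd, gh


def mean_deviation(td: np.ndarray, model: NormativeModel) -> float:
    """Weighted mean of TD over analyzed locations (weights renormalized
    over the non-missing ones)."""
    mask = ~model.blind_spot_mask & np.isfinite(td)
    w = model.md_weights[mask]
    if w.sum() <= 0:
        raise NormativeError("no analyzed locations with TD values")
    return float(np.sum(w * td[mask]) / w.sum())


def analyze_field(field: VisualField, model: NormativeModel) -> DeviationMap:
    """TD/PD maps with probability categories, MD and general height."""
    td = total_deviation(field, model)
    pd, gh = pattern_deviation(td, model)
    return DeviationMap(
        td=td,
        pd=pd,
        td_category=deviation_probability(td, model.td_cutoffs),
        pd_category=deviation_probability(pd, model.pd_cutoffs),
        md=mean_deviation(td, model),
        general_height=gh,
    )
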