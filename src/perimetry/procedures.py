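"""Threshold-estimation procedures: ZEST, 4-2 staircase, FT, MOCS.

ZEST maintains a discrete probability mass function (PMF) over candidate
thresholds on the machine's dB grid.  Each presentation is placed at the
posterior mean; the response multiplies the PMF by the psychometric
likelihood and renormalizes.  The prior is bimodal: one peak at 0 dB for
damaged locations and one at the expected normal sensitivity (seeded
from neighboring estimates during a whole-field test).

The 4-2 staircase steps 4 dB until the first response reversal and 2 dB
afterwards (the step halves on the move following the reversal),
terminating at the second reversal with the midpoint of the bracketing
levels, or pinned at a dynamic-range bound.  Full Threshold (FT) runs a
4-2 staircase and retests from the first estimate when it lands 4 dB or
more from the start.  MOCS presents a fixed level set repeatedly in
shuffled order and fits the frequency-of-seeing curve by maximum
likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .machine import prob_seen

__all__ = [
    "PMF", "ZestState", "StaircaseState", "FosRecord", "FosFit", "FTResult",
    "ProcedureError", "ProcedureStateError", "ProcedureConfigError",
    "make_zest_prior", "zest_create", "zest_next_level", "zest_update",
    "zest_estimate", "staircase_create", "staircase_update",
    "staircase_estimate", "full_threshold_run", "mocs_run", "fit_fos",
]


class ProcedureError(Exception):
    pass


class ProcedureStateError(ProcedureError, RuntimeError):
    pass


class ProcedureConfigError(ProcedureError, ValueError):
    pass


class FosFitError(ProcedureError, RuntimeError):
    pass


# ---------------------------------------------------------------------------
# PMF
# ---------------------------------------------------------------------------

@dataclass
class PMF:
    """Discrete probability mass function over a uniform dB grid."""

    domain: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.domain = np.asarray(self.domain, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.domain.ndim != 1 or self.domain.shape != self.masses.shape:
            raise ProcedureConfigError("domain and masses must match in shape")
        if len(self.domain) < 2:
            raise ProcedureConfigError("PMF domain needs >= 2 points")
        steps = np.diff(self.domain)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ProcedureConfigError(
                "PMF domain must be increasing and uniform"
            )
        if np.any(self.masses < 0):
            raise ProcedureConfigError("PMF masses must be non-negative")
        s = self.masses.sum()
        if abs(s - 1.0) > 1e-12:
            raise ProcedureConfigError(f"PMF masses sum to {s}, not 1")

    @classmethod
    def from_weights(cls, domain, weights) -> "PMF":
        w = np.asarray(weights, dtype=float)
        s = w.sum()
        if not np.isfinite(s) or s <= 0:
            raise ProcedureConfigError("weights must have positive finite sum")
        return cls(np.asarray(domain, dtype=float), w / s)

    def mean(self) -> float:
        return float(np.dot(self.domain, self.masses))

    def sd(self) -> float:
        m = self.mean()
        return float(math.sqrt(np.dot((self.domain - m) ** 2, self.masses)))

    def mode(self) -> float:
        return float(self.domain[int(np.argmax(self.masses))])


def make_zest_prior(
    domain,
    peak_normal: float,
    w_abn: float = 0.3,
    sd_abn: float = 5.0,
    sd_norm: float = 5.0,
) -> PMF:
    """Bimodal ZEST prior on the dB grid.

    Mixture of a Gaussian kernel at 0 dB (weight ``w_abn``, modeling
    damaged locations) and one at ``peak_normal`` (expected normal
    sensitivity, typically seeded from neighboring estimates).
    """
    domain = np.asarray(domain, dtype=float)
    if not (0.0 <= w_abn <= 1.0):
        raise ProcedureConfigError(f"w_abn={w_abn} outside [0, 1]")
    if sd_abn <= 0 or sd_norm <= 0:
        raise ProcedureConfigError("prior peak spreads must be > 0")
    if not (domain[0] <= peak_normal <= domain[-1]):
        raise ProcedureConfigError(
            f"peak_normal={peak_normal} outside domain "
            f"[{domain[0]}, {domain[-1]}]"
        )
    g_abn = np.exp(-0.5 * (domain / sd_abn) ** 2)
    g_norm = np.exp(-0.5 * ((domain - peak_normal) / sd_norm) ** 2)
    w = w_abn * g_abn / g_abn.sum() + (1.0 - w_abn) * g_norm / g_norm.sum()
    return PMF.from_weights(domain, w)


# ---------------------------------------------------------------------------
# ZEST
# ---------------------------------------------------------------------------

@dataclass
class ZestState:
    """Mutable state of one ZEST run."""

    pmf: PMF
    likelihood_sd: float = 1.5
    fp_l: float = 0.03  # false-positive rate baked into the likelihood
    fn_l: float = 0.03
    stop_sd: float = 1.5
    min_presentations: int = 4
    max_presentations: int = 25
    use_mode: bool = False  # QUEST-style mode instead of the ZEST mean
    history: list[tuple[float, bool]] = field(default_factory=list)
    finished: bool = False


def zest_create(
    prior: PMF,
    likelihood_sd: float = 1.5,
    stop_sd: float = 1.5,
    min_presentations: int = 4,
    max_presentations: int = 25,
    fp_l: float = 0.03,
    fn_l: float = 0.03,
    use_mode: bool = False,
) -> ZestState:
    if likelihood_sd <= 0 or stop_sd < 0:
        raise ProcedureConfigError("likelihood_sd must be > 0, stop_sd >= 0")
    if not (1 <= min_presentations <= max_presentations):
        raise ProcedureConfigError(
            "need 1 <= min_presentations <= max_presentations"
        )
    return ZestState(
        pmf=prior, likelihood_sd=likelihood_sd, stop_sd=stop_sd,
        min_presentations=min_presentations,
        max_presentations=max_presentations, fp_l=fp_l, fn_l=fn_l,
        use_mode=use_mode,
    )


def _snap_to_domain(domain: np.ndarray, value: float) -> float:
    return float(domain[int(np.argmin(np.abs(domain - value)))])


def zest_next_level(state: ZestState) -> float | None:
    """Next presentation level (posterior mean snapped to the dB grid),
    or None once the procedure has finished."""
    if state.finished:
        return None
    target = state.pmf.mode() if state.use_mode else state.pmf.mean()
    return _snap_to_domain(state.pmf.domain, target)


def zest_update(state: ZestState, level: float, seen: bool) -> ZestState:
    """Fold one response into the posterior; returns the mutated state."""
    if state.finished:
        raise ProcedureStateError("zest procedure already finished")
    like = prob_seen(level, state.pmf.domain, state.likelihood_sd,
                     state.fp_l, state.fn_l)
    if not seen:
        like = 1.0 - like
    w = state.pmf.masses * like
    s = w.sum()
    if not np.isfinite(s) or s <= 0.0:
        raise ProcedureError(
            "posterior vanished numerically "
            f"(level={level}, seen={seen}, history={state.history}); the "
            "likelihood false-response rates guard against this unless "
            "both are zero"
        )
    state.pmf = PMF(state.pmf.domain, w / s)
    state.history.append((float(level), bool(seen)))
    n = len(state.history)
    if n >= state.max_presentations or (
        n >= state.min_presentations and state.pmf.sd() < state.stop_sd
    ):
        state.finished = True
    return state


def zest_estimate(state: ZestState) -> float:
    """Current threshold estimate (posterior mean, or mode for QUEST)."""
    return state.pmf.mode() if state.use_mode else state.pmf.mean()


# ---------------------------------------------------------------------------
# 4-2 staircase and Full Threshold
# ---------------------------------------------------------------------------

@dataclass
class StaircaseState:
    """Mutable state of a 4-2 dB staircase."""

    current_level: float
    floor_db: float = 0.0
    ceiling_db: float = 40.0
    step_sizes: tuple[float, float] = (4.0, 2.0)
    reversals: int = 0
    last_response: bool | None = None
    last_seen_level: float | None = None
    last_not_seen_level: float | None = None
    history: list[tuple[float, bool]] = field(default_factory=list)
    finished: bool = False
    estimate: float | None = None
    pinned: bool = False


def staircase_create(
    start: float, floor_db: float = 0.0, ceiling_db: float = 40.0
) -> StaircaseState:
    if not (floor_db <= start <= ceiling_db):
        raise ProcedureConfigError(
            f"start level {start} outside [{floor_db}, {ceiling_db}]"
        )
    return StaircaseState(current_level=float(start), floor_db=floor_db,
                          ceiling_db=ceiling_db)


def staircase_update(state: StaircaseState, seen: bool) -> StaircaseState:
    """Process the response to the current level and move the staircase.

    The step for the move is chosen by the reversal count *before* this
    response: 4 dB while no reversal has completed, 2 dB afterwards.
    Terminates at the second reversal (estimate = midpoint of the last
    seen and last not-seen levels) or when the staircase pins at a
    dynamic-range bound.
    """
    if state.finished:
        raise ProcedureStateError("staircase already finished")
    level = state.current_level
    state.history.append((level, bool(seen)))
    if seen:
        state.last_seen_level = level
    else:
        state.last_not_seen_level = level
    step = state.step_sizes[0] if state.reversals == 0 else state.step_sizes[1]
    if state.last_response is not None and seen != state.last_response:
        state.reversals += 1
    state.last_response = bool(seen)
    if state.reversals >= 2:
        state.finished = True
        state.estimate = (state.last_seen_level + state.last_not_seen_level) / 2.0
        return state
    nxt = level + step if seen else level - step
    nxt = min(max(nxt, state.floor_db), state.ceiling_db)
    if nxt == level and level in (state.floor_db, state.ceiling_db):
        state.finished = True
        state.pinned = True
        state.estimate = level
        return state
    state.current_level = nxt
    return state


def staircase_estimate(state: StaircaseState) -> float:
    if not state.finished or state.estimate is None:
        raise ProcedureStateError("staircase has not terminated yet")
    return state.estimate


@dataclass
class FTResult:
    estimate: float
    trials: list[tuple[float, bool]]
    retested: bool
    first_estimate: float
    second_estimate: float | None = None


def _run_staircase(
    start: float, responder: Callable[[float], bool],
    floor_db: float, ceiling_db: float,
) -> StaircaseState:
    st = staircase_create(start, floor_db, ceiling_db)
    while not st.finished:
        staircase_update(st, bool(responder(st.current_level)))
    return st


def full_threshold_run(
    start: float,
    responder: Callable[[float], bool],
    floor_db: float = 0.0,
    ceiling_db: float = 40.0,
    retest_delta: float = 4.0,
) -> FTResult:
    """Full Threshold: a 4-2 staircase with a conditional retest.

    If the first staircase's estimate lands ``retest_delta`` dB or more
    from the start, a second staircase starts at that estimate and its
    result is returned.  All trials from both staircases are logged.
    """
    first = _run_staircase(start, responder, floor_db, ceiling_db)
    trials = list(first.history)
    if abs(first.estimate - start) >= retest_delta:
        second = _run_staircase(first.estimate, responder, floor_db,
                                ceiling_db)
        trials += second.history
        return FTResult(second.estimate, trials, True, first.estimate,
                        second.estimate)
    return FTResult(first.estimate, trials, False, first.estimate)


# ---------------------------------------------------------------------------
# MOCS
# ---------------------------------------------------------------------------

@dataclass
class FosRecord:
    """Presentation counts per level from a method-of-constant-stimuli run."""

    levels: np.ndarray
    n_presented: np.ndarray
    n_seen: np.ndarray
    trials: list[tuple[float, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.n_presented = np.asarray(self.n_presented, dtype=int)
        self.n_seen = np.asarray(self.n_seen, dtype=int)
        if np.any(self.n_seen < 0) or np.any(self.n_seen > self.n_presented):
            raise ProcedureConfigError("need 0 <= n_seen <= n_presented")


@dataclass
class FosFit:
    threshold: float
    fos_sd: float
    converged: bool
    fallback: bool  # linear interpolation of the 50% crossing was used


def mocs_run(
    levels: Sequence[float],
    reps: int,
    responder: Callable[[float], bool],
    rng: np.random.Generator,
) -> FosRecord:
    """Present each level ``reps`` times in a seeded shuffled order."""
    levels = np.asarray(sorted(set(float(l) for l in levels)))
    if len(levels) < 2:
        raise ProcedureConfigError("MOCS needs >= 2 distinct levels")
    if reps < 1:
        raise ProcedureConfigError("MOCS needs reps >= 1")
    order = np.repeat(levels, reps)
    rng.shuffle(order)
    counts = {l: [0, 0] for l in levels}
    trials = []
    for level in order:
        seen = bool(responder(float(level)))
        counts[level][0] += 1
        counts[level][1] += seen
        trials.append((float(level), seen))
    n_pres = np.array([counts[l][0] for l in levels])
    n_seen = np.array([counts[l][1] for l in levels])
    return FosRecord(levels, n_pres, n_seen, trials)


def _interp_crossing(levels: np.ndarray, frac: np.ndarray) -> float:
    """Level at which the (decreasing) seen fraction crosses 0.5."""
    for k in range(len(levels) - 1):
        f0, f1 = frac[k], frac[k + 1]
        if f0 >= 0.5 >= f1 and f0 != f1:
            return float(
                levels[k] + (f0 - 0.5) / (f0 - f1) * (levels[k + 1] - levels[k])
            )
    # no bracketing pair: nearest level to 50%
    return float(levels[int(np.argmin(np.abs(frac - 0.5)))])


def fit_fos(
    record: FosRecord, fp: float = 0.0, fn: float = 0.0
) -> FosFit:
    """Maximum-likelihood fit of (threshold, fos_sd) to a FoS record.

    The Bernoulli likelihood of ``prob_seen(level, t, sd, fp, fn)`` is
    maximized over t and sd (sd bounded to [0.1, 20]).  Perfectly
    separated records and failed optimizations fall back to linear
    interpolation of the 50% crossing, flagged on the result.
    """
    lv, np_, ns = record.levels, record.n_presented, record.n_seen
    if np.all(ns == np_) or np.all(ns == 0):
        raise FosFitError(
            "all responses seen (or none): widen the level range"
        )
    frac = ns / np_
    t0 = _interp_crossing(lv, frac)
    separated = np.all((ns == 0) | (ns == np_))
    if separated:
        return FosFit(t0, 0.1, converged=False, fallback=True)

    def nll(params: np.ndarray) -> float:
        t, sd = params
        p = prob_seen(lv, t, sd, fp, fn)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(ns * np.log(p) + (np_ - ns) * np.log(1 - p)))

    span = lv[-1] - lv[0]
    res = minimize(
        nll, x0=np.array([t0, 2.0]), method="L-BFGS-B",
        bounds=[(lv[0] - span, lv[-1] + span), (0.1, 20.0)],
    )
    if res.success and np.isfinite(res.fun):
        return FosFit(float(res.x[0]), float(res.x[1]), converged=True,
                      fallback=False)
    return FosFit(t0, 2.0, converged=False, fallback=True)
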