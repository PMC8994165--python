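"""Whole-field test execution with a growth pattern.

Seed locations (one per quadrant on the 24-2) are tested first; as they
finish, neighboring locations open with ZEST priors whose normal peak is
conditioned on the finished neighbors' estimates (inverse-distance
weighted).  The growth order is a breadth-first wave labeling over the
Voronoi adjacency of the grid, which works identically for regular and
irregular grids.  Trials interleave uniformly at random among open
locations using a scheduler RNG that is seeded independently of the
machine's response RNG, so schedules and responses reproduce separately.
"""

from __future__ import annotations

import datetime as dt
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .fields import VisualField
from .grids import Grid
from .machine import MachineHandle, Stimulus
from .procedures import (
    ProcedureConfigError,
    make_zest_prior,
    staircase_create,
    staircase_update,
    zest_create,
    zest_next_level,
    zest_update,
)
from .tessellation import (
    adjacency_from_tessellation,
    neighbors_map,
    voronoi_tessellate,
)

__all__ = [
    "GrowthPlan", "TrialLog", "TrialRecord", "OrchestrationError",
    "assign_growth_waves", "neighbor_prediction", "default_seeds",
    "build_growth_plan", "run_static_test",
]


class OrchestrationError(RuntimeError):
    pass


@dataclass
class GrowthPlan:
    """Wave labels and adjacency driving the growth pattern."""

    grid: Grid
    waves: np.ndarray  #: wave index per location, seeds have wave 1
    seeds: frozenset[int]
    adjacency: set[tuple[int, int]]
    neighbors: list[set[int]]


@dataclass(frozen=True)
class TrialRecord:
    presentation: int  # strictly increasing per session
    location: int
    level: float
    seen: bool
    time: float | None


@dataclass
class TrialLog:
    records: list[TrialRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def for_location(self, index: int) -> list[TrialRecord]:
        return [r for r in self.records if r.location == index]

    def to_rows(self) -> list[dict]:
        return [
            {
                "presentation": r.presentation,
                "location": r.location,
                "level": r.level,
                "seen": int(r.seen),
                "time_ms": "" if r.time is None else r.time,
            }
            for r in self.records
        ]


def assign_growth_waves(
    grid: Grid, seeds, adjacency: set[tuple[int, int]]
) -> GrowthPlan:
    """Breadth-first wave labeling from the seed locations.

    Every seed gets wave 1; every other location gets one more than the
    smallest wave among its neighbors.  A location unreachable from the
    seeds is an error.
    """
    seeds = frozenset(int(s) for s in seeds)
    if not seeds:
        raise OrchestrationError("growth pattern needs >= 1 seed location")
    n = len(grid)
    for s in seeds:
        if not (0 <= s < n):
            raise OrchestrationError(f"seed index {s} outside grid of size {n}")
    nbrs = neighbors_map(adjacency, n)
    waves = np.zeros(n, dtype=int)
    queue: deque[int] = deque()
    for s in seeds:
        waves[s] = 1
        queue.append(s)
    while queue:
        i = queue.popleft()
        for j in nbrs[i]:
            if waves[j] == 0:
                waves[j] = waves[i] + 1
                queue.append(j)
    if np.any(waves == 0):
        missing = int(np.argmax(waves == 0))
        loc = grid.locations[missing]
        raise OrchestrationError(
            f"location {missing} at ({loc.x}, {loc.y}) is unreachable from "
            "the seed locations"
        )
    return GrowthPlan(grid=grid, waves=waves, seeds=seeds,
                      adjacency=adjacency, neighbors=nbrs)


def build_growth_plan(grid: Grid, seeds=None) -> GrowthPlan:
    """Voronoi-adjacency growth plan with default or explicit seeds."""
    if len(grid) == 1:
        return assign_growth_waves(grid, [0], set())
    tess = voronoi_tessellate(grid)
    adjacency = adjacency_from_tessellation(tess)
    if seeds is None:
        seeds = default_seeds(grid)
    return assign_growth_waves(grid, seeds, adjacency)


def default_seeds(grid: Grid) -> list[int]:
    """One seed per quadrant: the non-blind-spot location nearest each of
    (+/-9, +/-9), the conventional primary points."""
    coords = grid.coords()
    bs = grid.blind_spot_mask
    seeds: list[int] = []
    for qx, qy in ((9, 9), (-9, 9), (-9, -9), (9, -9)):
        d = np.hypot(coords[:, 0] - qx, coords[:, 1] - qy)
        d[bs] = np.inf
        k = int(np.argmin(d))
        if k not in seeds:
            seeds.append(k)
    return seeds


def neighbor_prediction(
    plan: GrowthPlan, completed: dict[int, float], target: int
) -> float | None:
    """Inverse-distance-weighted mean of finished neighbors' estimates,
    or None when no adjacent location has finished."""
    coords = plan.grid.coords()
    num = 0.0
    den = 0.0
    for j in plan.neighbors[target]:
        if j in completed:
            d = float(np.hypot(*(coords[target] - coords[j])))
            w = 1.0 / d if d > 0 else 1e12
            num += w * completed[j]
            den += w
    if den == 0.0:
        return None
    return num / den


def _make_state(procedure: str, cfg: dict, machine: MachineHandle,
                start: float):
    domain = np.arange(machine.floor_db, machine.ceiling_db + 1e-9,
                       float(cfg.get("domain_step", 1.0)))
    if procedure == "zest":
        prior = make_zest_prior(
            domain, peak_normal=start,
            w_abn=float(cfg.get("w_abn", 0.3)),
            sd_abn=float(cfg.get("sd_abn", 5.0)),
            sd_norm=float(cfg.get("sd_norm", 5.0)),
        )
        return zest_create(
            prior,
            likelihood_sd=float(cfg.get("likelihood_sd", 1.5)),
            stop_sd=float(cfg.get("stop_sd", 1.5)),
            min_presentations=int(cfg.get("min_presentations", 4)),
            max_presentations=int(cfg.get("max_presentations", 25)),
            fp_l=float(cfg.get("fp_l", 0.03)),
            fn_l=float(cfg.get("fn_l", 0.03)),
            use_mode=bool(cfg.get("use_mode", False)),
        )
    if procedure == "fourTwo":
        return staircase_create(start, machine.floor_db, machine.ceiling_db)
    raise ProcedureConfigError(
        f"unsupported whole-field procedure {procedure!r} (use 'zest' or "
        "'fourTwo')"
    )


def run_static_test(
    grid: Grid,
    procedure_config: dict,
    machine: MachineHandle,
    seeds=None,
    rng: np.random.Generator | int | None = None,
    plan: GrowthPlan | None = None,
    subject_id: str = "simulated",
    eye: str = "OD",
    age: float = 45.0,
    date: dt.date = dt.date(2000, 1, 1),
) -> tuple[VisualField, TrialLog]:
    """Run a whole-field static test against the attached observer.

    Wave-1 locations open immediately; any other location opens as soon
    as one adjacent lower-wave location finishes, with its prior peak (or
    staircase start) set by :func:`neighbor_prediction`, falling back to
    ``procedure_config["fallback_normal"]`` (default: the dynamic-range
    midpoint).  Blind-spot locations are never presented.  Returns the
    assembled :class:`~perimetry.fields.VisualField` (estimates rounded
    to 2 decimals, blind spots missing) and the full trial log.
    """
    cfg = dict(procedure_config)
    procedure = cfg.get("procedure", "zest")
    if plan is None:
        plan = build_growth_plan(grid, seeds)
    if machine.state == "initialized":
        machine.set_background({"luminance_cdm2": 10.0, "fixation": "cross"})
    sched = (rng if isinstance(rng, np.random.Generator)
             else np.random.default_rng(rng))
    n = len(grid)
    bs = grid.blind_spot_mask
    fallback = float(cfg.get(
        "fallback_normal", (machine.floor_db + machine.ceiling_db) / 2.0
    ))
    coords = grid.coords()
    waves = plan.waves

    states: dict[int, object] = {}
    estimates: dict[int, float] = {}
    # blind spots count as finished (with no estimate) so they do not
    # block the growth wavefront
    finished: set[int] = {i for i in range(n) if bs[i]}
    opened: set[int] = set()

    def try_open(i: int) -> None:
        if i in opened or i in finished or bs[i]:
            return
        if waves[i] == 1:
            ok = True
        else:
            ok = any(
                j in finished and waves[j] < waves[i]
                for j in plan.neighbors[i]
            )
        if ok:
            start = neighbor_prediction(plan, estimates, i)
            if start is None:
                start = fallback
            start = min(max(start, machine.floor_db), machine.ceiling_db)
            states[i] = _make_state(procedure, cfg, machine, start)
            opened.add(i)

    for i in range(n):
        try_open(i)

    log = TrialLog()
    presentation = 0
    while opened:
        active = sorted(opened)
        i = int(active[sched.integers(len(active))])
        st = states[i]
        if procedure == "zest":
            level = zest_next_level(st)
        else:
            level = st.current_level
        stim = Stimulus(x=coords[i, 0], y=coords[i, 1], level=level)
        resp = machine.present(stim, i)
        if procedure == "zest":
            zest_update(st, level, resp.seen)
            done = st.finished
            est = st.pmf.mean() if done else None
        else:
            staircase_update(st, resp.seen)
            done = st.finished
            est = st.estimate if done else None
        presentation += 1
        log.records.append(TrialRecord(presentation, i, float(level),
                                       resp.seen, resp.time))
        if done:
            opened.discard(i)
            finished.add(i)
            estimates[i] = float(est)
            for j in plan.neighbors[i]:
                try_open(j)
            # a finished location may unlock locations further away too
            for j in range(n):
                try_open(j)

    sens = np.full(n, np.nan)
    for i, e in estimates.items():
        sens[i] = round(e, 2)
    obs = machine.observer
    fieldrec = VisualField(
        subject_id=subject_id, eye=eye, date=date, age=age,
        duration=machine.elapsed_ms / 1000.0,
        fpr=float(obs.fp) if obs is not None else 0.0,
        fnr=float(obs.fn) if obs is not None else 0.0,
        fl=0.0, grid_name=grid.name, sensitivities=sens,
    )
    return fieldrec, log
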