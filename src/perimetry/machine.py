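"""The machine contract with a simulated-observer backend.

The five commands every perimetric backend supports — initialize, query,
set background, present, close — are modeled as a small state machine.
The only backend shipped here is a simulation: responses are drawn from a
frequency-of-seeing (FoS) model, the cumulative-Gaussian probability of
reporting a stimulus of a given dB level seen, given the observer's true
threshold, FoS spread and false-response rates.  With a fixed seed a full
session is bit-reproducible, which is what makes new procedures testable
before they touch hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import ndtr

__all__ = [
    "GOLDMANN_SIZES", "Stimulus", "Response", "SimulatedObserver",
    "MachineHandle", "MachineError", "MachineConfigError",
    "MachineStateError", "UnsupportedStimulusError", "prob_seen",
    "open_machine",
]

#: Goldmann stimulus sizes I-V as diameters in degrees of visual angle.
GOLDMANN_SIZES = {"I": 0.108, "II": 0.216, "III": 0.431, "IV": 0.862,
                  "V": 1.724}


class MachineError(Exception):
    """Base class for machine-contract violations."""


class MachineConfigError(MachineError, ValueError):
    pass


class MachineStateError(MachineError, RuntimeError):
    pass


class UnsupportedStimulusError(MachineError, ValueError):
    pass


@dataclass(frozen=True)
class Stimulus:
    """One stimulus presentation request.

    ``level`` is dB attenuation (0 dB = brightest the device can show).
    ``size`` may be a diameter in degrees or a Goldmann size name.
    """

    x: float
    y: float
    level: float
    kind: str = "static"
    size: float | str = "III"
    duration: float = 200.0  # ms
    response_window: float = 1500.0  # ms
    eye: str = "right"
    color: str = "white"

    def __post_init__(self) -> None:
        if self.kind not in ("static", "temporal", "kinetic"):
            raise MachineConfigError(f"unknown stimulus kind {self.kind!r}")
        if self.duration <= 0:
            raise MachineConfigError("stimulus duration must be > 0")
        if self.response_window < self.duration:
            raise MachineConfigError(
                "response window must be >= stimulus duration"
            )
        if self.eye not in ("left", "right", "both"):
            raise MachineConfigError(f"unknown eye {self.eye!r}")

    @property
    def size_deg(self) -> float:
        if isinstance(self.size, str):
            try:
                return GOLDMANN_SIZES[self.size]
            except KeyError:
                raise MachineConfigError(
                    f"unknown Goldmann size {self.size!r}"
                ) from None
        return float(self.size)


@dataclass(frozen=True)
class Response:
    """Observer response: whether seen and, if so, the reaction time."""

    seen: bool
    time: float | None = None  # ms, present iff seen
    clamped: bool = False  # stimulus level was clamped into dynamic range


@dataclass
class SimulatedObserver:
    """Ground truth for simulation mode.

    ``thresholds`` is one true sensitivity (dB) per grid location;
    ``fos_sd`` the spread of the frequency-of-seeing curve; ``fp``/``fn``
    the false-positive/negative response rates; ``rt_mean``/``rt_sd`` a
    Gaussian response-time model truncated to the response window.
    ``fos_sd_fn`` may map a threshold to a per-location spread (defaults
    to the constant ``fos_sd``).
    """

    thresholds: np.ndarray
    fos_sd: float = 1.0
    fp: float = 0.0
    fn: float = 0.0
    rt_mean: float = 400.0
    rt_sd: float = 60.0
    fos_sd_fn: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.fos_sd <= 0:
            raise MachineConfigError("fos_sd must be > 0")
        if not (0 <= self.fp < 1 and 0 <= self.fn < 1):
            raise MachineConfigError("fp and fn must be in [0, 1)")
        if self.fp + self.fn >= 1:
            raise MachineConfigError("fp + fn must be < 1")

    def spread_at(self, threshold: float) -> float:
        if self.fos_sd_fn is not None:
            return float(self.fos_sd_fn(threshold))
        return self.fos_sd


def prob_seen(level, threshold, fos_sd, fp: float = 0.0, fn: float = 0.0):
    """Probability of a "seen" response under the FoS model.

    ``fp + (1 - fp - fn) * Phi((threshold - level) / fos_sd)`` with Phi
    the standard normal CDF: non-increasing in level (dimmer stimuli are
    seen less often), asymptotes fp and 1 - fn.  Vectorized over level
    and threshold.
    """
    if np.any(np.asarray(fos_sd) <= 0):
        raise ValueError("fos_sd must be > 0")
    fp = float(fp)
    fn = float(fn)
    if not (0 <= fp < 1 and 0 <= fn < 1 and fp + fn < 1):
        raise ValueError("need 0 <= fp, fn < 1 and fp + fn < 1")
    z = (np.asarray(threshold, float) - np.asarray(level, float)) / fos_sd
    return fp + (1.0 - fp - fn) * ndtr(z)


@dataclass
class MachineHandle:
    """A connection to the simulated perimeter.

    States advance closed -> initialized -> background_set -> closed;
    presentation is legal only once a background has been set.
    """

    floor_db: float
    ceiling_db: float
    seed: int
    observer: SimulatedObserver | None
    state: str = "initialized"
    background: dict = field(default_factory=dict)
    rng: np.random.Generator = field(init=False, repr=False)
    n_presentations: int = 0
    elapsed_ms: float = 0.0

    def __post_init__(self) -> None:
        self.rng = np.random.default_rng(self.seed)

    # -- query -----------------------------------------------------------
    def query(self) -> dict:
        """Device description: backend, dynamic range, state, background."""
        return {
            "backend": "simulation",
            "dynamic_range": (self.floor_db, self.ceiling_db),
            "state": self.state,
            "background": dict(self.background),
            "stimulus_kinds": ["static"],
            "n_presentations": self.n_presentations,
        }

    # -- background ------------------------------------------------------
    def set_background(self, descriptor: dict) -> dict:
        if self.state == "closed":
            raise MachineStateError("machine is closed")
        if self.state not in ("initialized", "background_set"):
            raise MachineStateError(f"cannot set background in {self.state}")
        eye = descriptor.get("eye", "both")
        if eye not in ("left", "right", "both"):
            raise MachineConfigError(f"unknown background eye {eye!r}")
        self.background = dict(descriptor)
        self.state = "background_set"
        return {"acknowledged": True, "background": dict(self.background)}

    # -- present ---------------------------------------------------------
    def present(self, stimulus: Stimulus, location_index: int) -> Response:
        if self.state != "background_set":
            raise MachineStateError(
                f"present() requires background_set state, machine is "
                f"{self.state}"
            )
        if stimulus.kind != "static":
            raise UnsupportedStimulusError(
                f"{stimulus.kind} stimuli are unsupported by the "
                "simulation backend"
            )
        obs = self.observer
        if obs is None:
            raise MachineConfigError("no observer attached to the machine")
        if not (0 <= location_index < len(obs.thresholds)):
            raise MachineConfigError(
                f"location index {location_index} outside the observer's "
                f"threshold map of size {len(obs.thresholds)}"
            )
        level = float(stimulus.level)
        clamped = False
        if level < self.floor_db or level > self.ceiling_db:
            level = min(max(level, self.floor_db), self.ceiling_db)
            clamped = True
        t = float(obs.thresholds[location_index])
        p = prob_seen(level, t, obs.spread_at(t), obs.fp, obs.fn)
        seen = bool(self.rng.random() < p)
        time = None
        if seen:
            time = self._draw_rt(stimulus.response_window)
        self.n_presentations += 1
        self.elapsed_ms += stimulus.duration + (
            time if seen else stimulus.response_window
        )
        return Response(seen=seen, time=time, clamped=clamped)

    def _draw_rt(self, window: float) -> float:
        obs = self.observer
        for _ in range(100):
            t = self.rng.normal(obs.rt_mean, obs.rt_sd)
            if 0.0 < t <= window:
                return float(t)
        return float(min(max(obs.rt_mean, 1.0), window))

    # -- close -----------------------------------------------------------
    def close(self) -> dict:
        if self.state == "closed":
            raise MachineStateError("machine already closed")
        self.state = "closed"
        return {
            "presentations": self.n_presentations,
            "elapsed_ms": self.elapsed_ms,
        }


def open_machine(
    config: dict | None = None,
    observer: SimulatedObserver | None = None,
) -> MachineHandle:
    """Open a simulated perimeter.

    ``config`` keys: ``floor_db`` (default 0), ``ceiling_db`` (default
    40), ``seed`` (default 0), optional ``background`` applied
    immediately.
    """
    cfg = dict(config or {})
    floor_db = float(cfg.get("floor_db", 0.0))
    ceiling_db = float(cfg.get("ceiling_db", 40.0))
    if floor_db >= ceiling_db:
        raise MachineConfigError(
            f"floor_db ({floor_db}) must be < ceiling_db ({ceiling_db})"
        )
    handle = MachineHandle(
        floor_db=floor_db,
        ceiling_db=ceiling_db,
        seed=int(cfg.get("seed", 0)),
        observer=observer,
    )
    if "background" in cfg:
        handle.set_background(cfg["background"])
    return handle
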