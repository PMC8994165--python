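"""Test-location grids for static automated perimetry.

All coordinates are degrees of visual angle in *right-eye format*:
positive x is temporal, positive y is superior.  Left-eye (OS) data are
mirrored into this frame at import so that a single normative model can
serve both eyes.

The standard 24-2 grid (54 locations, 6-degree spacing, two blind-spot
locations at (15, +/-3)) is built in; arbitrary regular and irregular
grids can be generated from a cartesian, polar or explicit specification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GridLocation",
    "Grid",
    "GridError",
    "GridRegistryError",
    "GridSpecError",
    "GridRegistry",
    "default_registry",
    "build_standard_grid",
    "generate_custom_grid",
    "mirror_to_right_eye_format",
]


class GridError(ValueError):
    """Invalid grid or grid location."""


class GridRegistryError(GridError):
    """Unknown grid name."""


class GridSpecError(GridError):
    """Invalid custom-grid specification."""


@dataclass(frozen=True)
class GridLocation:
    """A single test location.

    Parameters
    ----------
    x, y : float
        Degrees of visual angle, right-eye format (positive x temporal,
        positive y superior).
    is_blind_spot : bool
        Whether the location falls on the physiological blind spot and is
        excluded from statistical analysis.
    wave : int or None
        Growth-pattern wave index (1 = tested first), if assigned.
    """

    x: float
    y: float
    is_blind_spot: bool = False
    wave: int | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GridError(f"non-finite coordinates ({self.x}, {self.y})")
        if abs(self.x) > 90 or abs(self.y) > 90:
            raise GridError(
                f"location ({self.x}, {self.y}) outside +/-90 degrees"
            )
        if self.wave is not None and self.wave < 1:
            raise GridError(f"wave must be a positive integer, got {self.wave}")


def _coord_key(x: float, y: float) -> tuple[float, float]:
    return (round(float(x), 9), round(float(y), 9))


@dataclass(frozen=True)
class Grid:
    """A named, ordered set of test locations.

    The location order is stable and defines the column order of field
    CSV files.
    """

    name: str
    locations: tuple[GridLocation, ...]

    def __post_init__(self) -> None:
        if len(self.locations) < 1:
            raise GridError("a grid needs at least one location")
        keys = [_coord_key(l.x, l.y) for l in self.locations]
        if len(set(keys)) != len(keys):
            raise GridError(f"grid {self.name!r} has duplicate coordinates")

    def __len__(self) -> int:
        return len(self.locations)

    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) coordinates in grid order."""
        return np.array([(l.x, l.y) for l in self.locations], dtype=float)

    @property
    def blind_spot_mask(self) -> np.ndarray:
        return np.array([l.is_blind_spot for l in self.locations], dtype=bool)

    @property
    def n_analyzed(self) -> int:
        """Number of locations entering statistical analysis."""
        return int((~self.blind_spot_mask).sum())

    def index_of(self, x: float, y: float) -> int:
        key = _coord_key(x, y)
        for i, l in enumerate(self.locations):
            if _coord_key(l.x, l.y) == key:
                return i
        raise GridError(f"no location ({x}, {y}) in grid {self.name!r}")


def _build_24_2() -> Grid:
    """The 54-location 24-2 grid in right-eye format.

    Rows at y = +/-3 carry the nasal extension column at x = -27; the two
    temporal locations (15, +/-3) sit on the blind spot.
    """
    locs: list[GridLocation] = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        if abs(y) == 21:
            xs: Sequence[int] = range(-9, 10, 6)
        elif abs(y) == 15:
            xs = range(-15, 16, 6)
        elif abs(y) == 9:
            xs = range(-21, 22, 6)
        else:  # |y| == 3, nasal step to -27
            xs = range(-27, 22, 6)
        for x in xs:
            blind = x == 15 and abs(y) == 3
            locs.append(GridLocation(float(x), float(y), is_blind_spot=blind))
    return Grid("24-2", tuple(locs))


_MIRROR_SUFFIX = "-mirrored"


def _mirror_name(name: str) -> str:
    if name.endswith(_MIRROR_SUFFIX):
        return name[: -len(_MIRROR_SUFFIX)]
    return name + _MIRROR_SUFFIX


def _mirror_grid(grid: Grid) -> Grid:
    locs = tuple(
        replace(l, x=(-l.x if l.x != 0 else 0.0)) for l in grid.locations
    )
    return Grid(_mirror_name(grid.name), locs)


_STANDARD_BUILDERS = {
    "24-2": _build_24_2,
    "24-2-mirrored": lambda: _mirror_grid(_build_24_2()),
}


def build_standard_grid(name: str) -> Grid:
    """Build a registered standard grid by name ("24-2" and its mirror)."""
    try:
        return _STANDARD_BUILDERS[name]()
    except KeyError:
        known = ", ".join(sorted(_STANDARD_BUILDERS))
        raise GridRegistryError(
            f"unknown grid {name!r}; known standard grids: {known}"
        ) from None


class GridRegistry:
    """Name -> Grid lookup; standard grids resolve lazily."""

    def __init__(self) -> None:
        self._grids: dict[str, Grid] = {}

    def register(self, grid: Grid, overwrite: bool = False) -> None:
        if grid.name in self._grids and not overwrite:
            existing = self._grids[grid.name]
            if existing != grid:
                raise GridRegistryError(
                    f"grid {grid.name!r} already registered with different "
                    "locations"
                )
            return
        self._grids[grid.name] = grid

    def __contains__(self, name: str) -> bool:
        return name in self._grids or name in _STANDARD_BUILDERS

    def __getitem__(self, name: str) -> Grid:
        if name in self._grids:
            return self._grids[name]
        if name in _STANDARD_BUILDERS:
            grid = _STANDARD_BUILDERS[name]()
            self._grids[name] = grid
            return grid
        known = sorted(set(self._grids) | set(_STANDARD_BUILDERS))
        raise GridRegistryError(
            f"unknown grid {name!r}; known grids: {', '.join(known)}"
        )

    def names(self) -> list[str]:
        return sorted(set(self._grids) | set(_STANDARD_BUILDERS))


#: Process-wide default registry used when no registry is passed explicitly.
default_registry = GridRegistry()


def _unique_locations(
    pts: Iterable[tuple[float, float]], name: str
) -> Grid:
    locs = []
    seen: set[tuple[float, float]] = set()
    for x, y in pts:
        key = _coord_key(x, y)
        if key in seen:
            raise GridSpecError(f"duplicate location ({x}, {y}) in grid spec")
        seen.add(key)
        locs.append(GridLocation(float(x), float(y)))
    if not locs:
        raise GridSpecError("grid spec yields no locations")
    return Grid(name, tuple(locs))


def generate_custom_grid(spec: dict) -> Grid:
    """Generate a grid from a declarative specification.

    ``spec["mode"]`` selects the generator:

    - ``"cartesian"``: lattice over ``x_range``/``y_range`` (inclusive)
      with ``x_step``/``y_step`` spacing in degrees;
    - ``"polar"``: all combinations of ``rings`` (eccentricities, degrees)
      and ``meridians`` (degrees, 0 = temporal, 90 = superior);
    - ``"explicit"``: pass-through ``points`` list ``[[x, y], ...]``.

    Duplicate coordinates and empty results are rejected.
    """
    if "mode" not in spec:
        raise GridSpecError("grid spec needs a 'mode' key")
    mode = spec["mode"]
    name = spec.get("name", f"custom-{mode}")
    if mode == "cartesian":
        try:
            x0, x1 = spec["x_range"]
            y0, y1 = spec["y_range"]
            dx = float(spec["x_step"])
            dy = float(spec["y_step"])
        except KeyError as exc:
            raise GridSpecError(f"cartesian spec missing {exc}") from None
        if dx <= 0 or dy <= 0:
            raise GridSpecError("grid steps must be positive")
        xs = np.arange(x0, x1 + dx / 2, dx)
        ys = np.arange(y0, y1 + dy / 2, dy)
        pts = [(x, y) for y in ys[::-1] for x in xs]
    elif mode == "polar":
        try:
            rings = spec["rings"]
            meridians = spec["meridians"]
        except KeyError as exc:
            raise GridSpecError(f"polar spec missing {exc}") from None
        pts = []
        for r in rings:
            for m in meridians:
                a = math.radians(float(m))
                pts.append(
                    (
                        round(r * math.cos(a), 9),
                        round(r * math.sin(a), 9),
                    )
                )
    elif mode == "explicit":
        try:
            pts = [(float(x), float(y)) for x, y in spec["points"]]
        except KeyError:
            raise GridSpecError("explicit spec missing 'points'") from None
    else:
        raise GridSpecError(f"unknown grid mode {mode!r}")
    try:
        return _unique_locations(pts, name)
    except GridError as exc:  # coordinate out of range etc.
        raise GridSpecError(str(exc)) from None


def mirror_to_right_eye_format(obj, eye: str, registry: GridRegistry | None = None):
    """Mirror a grid or a field into right-eye format.

    OD input is returned unchanged.  For OS, every location's x coordinate
    is negated.  For fields, sensitivities are re-matched onto the original
    grid when its coordinate set is mirror-symmetric; otherwise the field
    is moved onto the mirrored grid (registered as ``<name>-mirrored``).
    Applying the operation twice with OS restores the input.
    """
    from .fields import VisualField  # local import to avoid a cycle

    if eye not in ("OD", "OS"):
        raise GridError(f"eye must be 'OD' or 'OS', got {eye!r}")
    if eye == "OD":
        return obj
    if isinstance(obj, Grid):
        return _mirror_grid(obj)
    if isinstance(obj, VisualField):
        reg = registry if registry is not None else default_registry
        grid = reg[obj.grid_name]
        keys = {_coord_key(l.x, l.y): i for i, l in enumerate(grid.locations)}
        mirrored_keys = [_coord_key(-l.x, l.y) for l in grid.locations]
        if all(k in keys for k in mirrored_keys):
            # symmetric grid: value at (x, y) comes from the old (-x, y)
            perm = [keys[k] for k in mirrored_keys]
            sens = np.asarray(obj.sensitivities, dtype=float)[perm]
            return replace(obj, sensitivities=sens)
        mgrid = _mirror_grid(grid)
        reg.register(mgrid)
        return replace(obj, grid_name=mgrid.name)
    raise TypeError(f"cannot mirror object of type {type(obj).__name__}")
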