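"""Geometric model of the circular escape arenas and their analysis zones.

Two variants are supported: the 85 cm "clockmaze" (12 wall holes laid out
like the hours of a clock face, one of which is the true exit on any given
trial) and the 160 cm "watermaze" (no holes, a hidden platform instead).

Coordinate convention: origin at the arena centre, +x toward 3 o'clock,
+y toward 12 o'clock, units cm.  Angles are degrees, counterclockwise
positive, measured from +x.  Hole ``k`` (1-based, clockwise like a clock)
sits on the wall circle at ``90 - 30*k`` degrees, so hole 12 is at the top
and hole 3 at the right.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence, Tuple, Union

from .errors import ConfigurationError, UnsupportedVariantError

Point = Tuple[float, float]


class Variant(str, Enum):
    CLOCKMAZE = "clockmaze"
    WATERMAZE = "watermaze"


class ZoneKind(str, Enum):
    HOLE = "hole"
    DECOY = "decoy"
    EXIT = "exit"
    PERIPHERY = "periphery"
    QUADRANT = "quadrant"
    PLATFORM = "platform"
    TARGET = "target"
    NONTARGET = "nontarget"


# --------------------------------------------------------------------------
# zone geometries


@dataclass(frozen=True)
class Circle:
    center: Point
    radius: float


@dataclass(frozen=True)
class Annulus:
    """Ring centred on the origin; ``inner <= r <= outer`` is inside."""

    inner: float
    outer: float


@dataclass(frozen=True)
class Sector:
    """Circular sector centred on the origin, spanning ``[start_deg, end_deg]``
    counterclockwise (closed on both boundaries), out to ``radius``."""

    start_deg: float
    end_deg: float
    radius: float


Geometry = Union[Circle, Annulus, Sector]


@dataclass(frozen=True)
class Zone:
    name: str
    kind: ZoneKind
    geometry: Geometry


# --------------------------------------------------------------------------
# configuration


_DEFAULT_RADII = {Variant.CLOCKMAZE: 42.5, Variant.WATERMAZE: 80.0}


@dataclass(frozen=True)
class ArenaConfig:
    """Validated arena parameters.

    ``quadrant_offset_deg`` rotates the four quadrant sector boundaries;
    the clockmaze default of 45 places boundaries between holes so each
    quadrant holds exactly three holes, while the watermaze default of 0
    yields axis-aligned NE/NW/SW/SE quadrants.
    """

    variant: Variant = Variant.CLOCKMAZE
    radius_cm: Optional[float] = None
    n_holes: Optional[int] = None
    hole_diameter_cm: float = 4.0
    hole_zone_radius_cm: float = 2.0
    probe_zone_radius_cm: float = 6.0
    periphery_band_cm: float = 8.0
    platform_center: Optional[Point] = None
    platform_radius_cm: float = 8.0
    quadrant_offset_deg: Optional[float] = None

    def __post_init__(self) -> None:
        variant = Variant(self.variant)
        object.__setattr__(self, "variant", variant)
        if self.radius_cm is None:
            object.__setattr__(self, "radius_cm", _DEFAULT_RADII[variant])
        if self.n_holes is None:
            object.__setattr__(
                self, "n_holes", 12 if variant is Variant.CLOCKMAZE else 0
            )
        if self.quadrant_offset_deg is None:
            object.__setattr__(
                self,
                "quadrant_offset_deg",
                45.0 if variant is Variant.CLOCKMAZE else 0.0,
            )
        if variant is Variant.WATERMAZE and self.platform_center is None:
            # centre of the SE quadrant, halfway to the wall
            r = self.radius_cm / 2.0
            c = (r * math.cos(math.radians(-45.0)), r * math.sin(math.radians(-45.0)))
            object.__setattr__(self, "platform_center", (c[0], c[1]))
        if self.platform_center is not None:
            object.__setattr__(
                self, "platform_center", tuple(float(v) for v in self.platform_center)
            )
        self._validate()

    def _validate(self) -> None:
        if not self.radius_cm > 0:
            raise ConfigurationError("radius_cm must be > 0")
        for name in (
            "hole_diameter_cm",
            "hole_zone_radius_cm",
            "probe_zone_radius_cm",
            "periphery_band_cm",
            "platform_radius_cm",
        ):
            v = getattr(self, name)
            if not 0 < v < self.radius_cm:
                raise ConfigurationError(
                    f"{name} must be > 0 and < radius_cm ({self.radius_cm}); got {v}"
                )
        if self.n_holes < 0:
            raise ConfigurationError("n_holes must be >= 0")
        if self.variant is Variant.CLOCKMAZE and self.n_holes < 2:
            raise ConfigurationError("clockmaze requires n_holes >= 2")
        if self.variant is Variant.WATERMAZE:
            x, y = self.platform_center
            if math.hypot(x, y) >= self.radius_cm:
                raise ConfigurationError(
                    "watermaze platform_center must lie inside the arena"
                )


def load_arena_config(path) -> ArenaConfig:
    """Read an :class:`ArenaConfig` from a flat JSON or YAML mapping."""
    with open(path) as fh:
        text = fh.read()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"arena config {path!r} is not a mapping")
    if "platform_center" in raw and raw["platform_center"] is not None:
        raw["platform_center"] = tuple(raw["platform_center"])
    try:
        return ArenaConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


# --------------------------------------------------------------------------
# arena


def hole_angle_deg(k: int, n_holes: int = 12) -> float:
    """Angle of hole ``k`` (1-based, clockwise clock numbering)."""
    return 90.0 - k * (360.0 / n_holes)


@dataclass(frozen=True)
class Arena:
    config: ArenaConfig
    hole_centers: Tuple[Point, ...]
    zones: Tuple[Zone, ...]

    @property
    def radius_cm(self) -> float:
        return self.config.radius_cm

    def zones_of_kind(self, kind: ZoneKind) -> Tuple[Zone, ...]:
        return tuple(z for z in self.zones if z.kind is kind)

    def zone(self, name: str) -> Zone:
        for z in self.zones:
            if z.name == name:
                return z
        raise KeyError(name)

    def hole_center(self, k: int) -> Point:
        if not 1 <= k <= len(self.hole_centers):
            raise ConfigurationError(
                f"hole index {k} out of range 1..{len(self.hole_centers)}"
            )
        return self.hole_centers[k - 1]

    def hole_zone(self, k: int, radius: Optional[float] = None) -> Zone:
        r = self.config.hole_zone_radius_cm if radius is None else radius
        return Zone(f"hole_{k}", ZoneKind.HOLE, Circle(self.hole_center(k), r))


_QUADRANT_NAMES = ("NE", "NW", "SW", "SE")


def build_arena(config: ArenaConfig) -> Arena:
    """Construct the arena with its hole, periphery, quadrant (and platform)
    zones.  Raises :class:`ConfigurationError` on an invalid config."""
    R = config.radius_cm
    centers = []
    zones = []
    for k in range(1, config.n_holes + 1):
        a = math.radians(hole_angle_deg(k, config.n_holes))
        c = (R * math.cos(a), R * math.sin(a))
        centers.append(c)
        zones.append(Zone(f"hole_{k}", ZoneKind.HOLE, Circle(c, config.hole_zone_radius_cm)))
    zones.append(
        Zone("periphery", ZoneKind.PERIPHERY, Annulus(R - config.periphery_band_cm, R))
    )
    off = config.quadrant_offset_deg
    for i, name in enumerate(_QUADRANT_NAMES):
        start = i * 90.0 + off
        zones.append(
            Zone(f"quadrant_{name}", ZoneKind.QUADRANT, Sector(start, start + 90.0, R))
        )
    if config.variant is Variant.WATERMAZE:
        zones.append(
            Zone(
                "platform",
                ZoneKind.PLATFORM,
                Circle(config.platform_center, config.platform_radius_cm),
            )
        )
    return Arena(config=config, hole_centers=tuple(centers), zones=tuple(zones))


def hole_positions(arena: Arena) -> Tuple[Point, ...]:
    """Hole centres on the wall circle, ordered by clock index 1..n."""
    if arena.config.variant is not Variant.CLOCKMAZE:
        raise UnsupportedVariantError("hole_positions is only defined for the clockmaze")
    return arena.hole_centers


def trial_zones(arena: Arena, true_exit: int) -> Tuple[Zone, ...]:
    """Hole zones relabelled for a trial: the true exit keeps its geometry but
    gets kind ``exit``; the other holes become ``decoy`` zones."""
    if arena.config.variant is not Variant.CLOCKMAZE:
        raise UnsupportedVariantError("trial_zones is only defined for the clockmaze")
    if not 1 <= true_exit <= arena.config.n_holes:
        raise ConfigurationError(
            f"true_exit {true_exit} out of range 1..{arena.config.n_holes}"
        )
    out = []
    for k in range(1, arena.config.n_holes + 1):
        geom = Circle(arena.hole_center(k), arena.config.hole_zone_radius_cm)
        if k == true_exit:
            out.append(Zone(f"exit_{k}", ZoneKind.EXIT, geom))
        else:
            out.append(Zone(f"decoy_{k}", ZoneKind.DECOY, geom))
    return tuple(out)


def probe_zones(arena: Arena, former_exit: int, radius: Optional[float] = None) -> Tuple[Zone, ...]:
    """Probe-test zones: a target zone at the former exit and non-target zones
    at the 11 decoys, all with the (larger) probe radius."""
    if arena.config.variant is not Variant.CLOCKMAZE:
        raise UnsupportedVariantError("probe_zones is only defined for the clockmaze")
    r = arena.config.probe_zone_radius_cm if radius is None else radius
    out = []
    for k in range(1, arena.config.n_holes + 1):
        geom = Circle(arena.hole_center(k), r)
        if k == former_exit:
            out.append(Zone(f"target_{k}", ZoneKind.TARGET, geom))
        else:
            out.append(Zone(f"nontarget_{k}", ZoneKind.NONTARGET, geom))
    return tuple(out)


def _wrap_deg(a: float) -> float:
    return a % 360.0


def point_in_zone(p: Point, zone: Zone) -> bool:
    """Closed-region membership test: boundary points belong to the zone."""
    x, y = float(p[0]), float(p[1])
    g = zone.geometry
    if isinstance(g, Circle):
        return math.hypot(x - g.center[0], y - g.center[1]) <= g.radius
    if isinstance(g, Annulus):
        r = math.hypot(x, y)
        return g.inner <= r <= g.outer
    if isinstance(g, Sector):
        r = math.hypot(x, y)
        if r > g.radius:
            return False
        if r == 0.0:
            return True
        ang = _wrap_deg(math.degrees(math.atan2(y, x)))
        span = g.end_deg - g.start_deg
        rel = _wrap_deg(ang - g.start_deg)
        return rel <= span or math.isclose(rel, 360.0, abs_tol=1e-12)
    raise TypeError(f"unknown geometry {type(g)!r}")
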