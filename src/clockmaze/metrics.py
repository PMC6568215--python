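"""Per-trial trajectory metrics: latency, inspection errors, distance, speed,
rotations, meander, heading to exit, zone dwell times and occupancy maps.

Inspection (error) events are nose-based: an event opens once the nose has
stayed inside a 2 cm hole zone for a debounce interval, and the zone only
re-arms after the nose leaves the zone dilated by ``rearm_factor``.  A track
that ends before the cutoff must end with the nose inside the true-exit zone
(the animal left through the pipe); otherwise the trial is malformed.  Tracks
that reach the cutoff are censored at ``latency = cutoff``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .arena import Arena, Annulus, Circle, Sector, Zone, ZoneKind, trial_zones
from .errors import CapabilityError, MalformedTrialError, ValidationError
from .trackio import Track, TrialRecord

_NOSE_KINDS = frozenset(
    {ZoneKind.HOLE, ZoneKind.DECOY, ZoneKind.EXIT, ZoneKind.TARGET, ZoneKind.NONTARGET}
)


# --------------------------------------------------------------------------
# vectorized zone membership


def points_in_zone(points: np.ndarray, zone: Zone) -> np.ndarray:
    """Boolean mask of closed-region membership for an ``(n, 2)`` array."""
    pts = np.asarray(points, dtype=float)
    g = zone.geometry
    if isinstance(g, Circle):
        d = np.hypot(pts[:, 0] - g.center[0], pts[:, 1] - g.center[1])
        return d <= g.radius
    if isinstance(g, Annulus):
        r = np.hypot(pts[:, 0], pts[:, 1])
        return (r >= g.inner) & (r <= g.outer)
    if isinstance(g, Sector):
        r = np.hypot(pts[:, 0], pts[:, 1])
        ang = np.degrees(np.arctan2(pts[:, 1], pts[:, 0])) % 360.0
        rel = (ang - g.start_deg) % 360.0
        span = g.end_deg - g.start_deg
        inside = (rel <= span) | np.isclose(rel, 360.0, atol=1e-12)
        return (r <= g.radius) & (inside | (r == 0.0))
    raise TypeError(f"unknown geometry {type(g)!r}")


# --------------------------------------------------------------------------
# inspection events


@dataclass(frozen=True)
class InspectionEvent:
    zone_name: str
    t_on: float
    t_off: float
    is_true_exit: bool


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal [start, stop] index runs of True in a boolean array."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), stops.tolist()))


def detect_inspections(
    track: Track,
    arena: Arena,
    true_exit: int,
    debounce_s: float = 0.1,
    rearm_factor: float = 1.5,
) -> List[InspectionEvent]:
    """Detect hole-inspection events from the nose trajectory.

    For each hole zone: a maximal run of in-zone nose samples spanning at
    least ``debounce_s`` opens an event at the run's first timestamp; the
    event closes (and the zone re-arms) only once the nose has left the zone
    dilated by ``rearm_factor``.  Events are returned ordered by onset.
    """
    if track.nose is None:
        raise CapabilityError("inspection detection requires nose coordinates")
    zones = trial_zones(arena, true_exit)
    t = track.t
    n = len(t)
    events: List[InspectionEvent] = []
    for zone in zones:
        g: Circle = zone.geometry  # hole zones are circles
        d = np.hypot(track.nose[:, 0] - g.center[0], track.nose[:, 1] - g.center[1])
        inside = d <= g.radius
        if not inside.any():
            continue
        outside_dil = d > g.radius * rearm_factor
        out_idx = np.nonzero(outside_dil)[0]
        blocked_until = -1
        for i0, i1 in _runs(inside):
            if i0 <= blocked_until:
                continue  # still within the dilated zone of the previous event
            if t[i1] - t[i0] < debounce_s:
                continue  # graze shorter than the debounce
            pos = np.searchsorted(out_idx, i1 + 1)
            j = int(out_idx[pos]) if pos < out_idx.size else n
            close_idx = j - 1 if j < n else n - 1
            events.append(
                InspectionEvent(
                    zone_name=zone.name,
                    t_on=float(t[i0]),
                    t_off=float(t[close_idx]),
                    is_true_exit=zone.kind is ZoneKind.EXIT,
                )
            )
            blocked_until = close_idx
    events.sort(key=lambda e: (e.t_on, e.zone_name))
    return events


# --------------------------------------------------------------------------
# scalar path metrics


def path_length(track: Track, jitter_cm: float = 0.05) -> float:
    """Total centre-point path length, ignoring sub-jitter steps."""
    c = track.center
    if len(c) < 2:
        raise ValidationError("path_length needs at least 2 samples")
    step = np.hypot(np.diff(c[:, 0]), np.diff(c[:, 1]))
    return float(step[step >= jitter_cm].sum())


def count_rotations(track: Track, hysteresis_deg: float = 45.0) -> int:
    """Completed 360-degree body-axis excursions (clockwise + counter).

    The body-axis heading (nose minus tail) is unwrapped; an excursion counts
    once its cumulative magnitude reaches 360 degrees.  A reversal larger
    than ``hysteresis_deg`` before completion cancels the running excursion.
    """
    if track.nose is None or track.tail is None:
        raise CapabilityError("rotation counting requires nose and tail coordinates")
    axis = track.nose - track.tail
    theta = np.degrees(np.unwrap(np.arctan2(axis[:, 1], axis[:, 0])))
    ref = theta[0]
    emax = emin = 0.0
    count = 0
    eps = 1e-9  # unwrap rounding can leave an excursion a hair short of 360
    for a in theta[1:]:
        e = a - ref
        while e >= 360.0 - eps:
            count += 1
            ref += 360.0
            e -= 360.0
            emax = emin = 0.0
        while e <= -360.0 + eps:
            count += 1
            ref -= 360.0
            e += 360.0
            emax = emin = 0.0
        emax = max(emax, e)
        emin = min(emin, e)
        if emax > 0.0 and emax - e > hysteresis_deg:
            ref, emax, emin = a, 0.0, 0.0
        elif emin < 0.0 and e - emin > hysteresis_deg:
            ref, emax, emin = a, 0.0, 0.0
    return count


def _wrap180(a: np.ndarray) -> np.ndarray:
    return (a + 180.0) % 360.0 - 180.0


def meander_count(
    track: Track,
    smooth_window: int = 5,
    turn_threshold_deg: float = 20.0,
    speed_floor_cm_s: float = 2.0,
) -> int:
    """Direction changes along the (smoothed) centre path.

    Turning angles are computed between consecutive moving steps; a meander
    is a sign reversal whose flanking turns both exceed the threshold.
    """
    c = track.center
    if len(c) < max(2, smooth_window):
        raise ValidationError("track shorter than the smoothing window")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        x = np.convolve(c[:, 0], kernel, mode="valid")
        y = np.convolve(c[:, 1], kernel, mode="valid")
        off = (smooth_window - 1) // 2
        t = track.t[off : off + len(x)]
    else:
        x, y, t = c[:, 0], c[:, 1], track.t
    if len(x) < 3:
        return 0
    dx, dy, dt = np.diff(x), np.diff(y), np.diff(t)
    speed = np.hypot(dx, dy) / dt
    moving = speed >= speed_floor_cm_s
    ang = np.degrees(np.arctan2(dy, dx))[moving]
    if len(ang) < 3:
        return 0
    turns = _wrap180(np.diff(ang))
    count = 0
    for j in range(1, len(turns)):
        a, b = turns[j - 1], turns[j]
        if a * b < 0 and abs(a) > turn_threshold_deg and abs(b) > turn_threshold_deg:
            count += 1
    return count


def heading_to_exit(
    track: Track,
    exit_center: Tuple[float, float],
    speed_floor_cm_s: float = 2.0,
) -> Optional[float]:
    """Mean absolute angle between the movement direction and the bearing to
    the exit, over moving steps; ``None`` when the animal never moves."""
    c = track.center
    if len(c) < 2:
        raise ValidationError("heading_to_exit needs at least 2 samples")
    d = np.diff(c, axis=0)
    dt = np.diff(track.t)
    speed = np.hypot(d[:, 0], d[:, 1]) / dt
    to_exit = np.asarray(exit_center, dtype=float) - c[:-1]
    norm_e = np.hypot(to_exit[:, 0], to_exit[:, 1])
    ok = (speed >= speed_floor_cm_s) & (norm_e > 1e-12)
    if not ok.any():
        return None
    mv = np.degrees(np.arctan2(d[ok, 1], d[ok, 0]))
    be = np.degrees(np.arctan2(to_exit[ok, 1], to_exit[ok, 0]))
    diff = np.abs(_wrap180(mv - be))
    return float(diff.mean())


# --------------------------------------------------------------------------
# dwell and occupancy


def zone_dwell_times(track: Track, zones: Sequence[Zone]) -> Dict[str, float]:
    """Seconds spent in each zone.  Each sample contributes its inter-sample
    interval; hole-type zones are evaluated on the nose (when present), all
    other zones on the centre point."""
    dt = np.diff(track.t)
    out: Dict[str, float] = {}
    for zone in zones:
        if zone.kind in _NOSE_KINDS and track.nose is not None:
            pts = track.nose
        else:
            pts = track.center
        mask = points_in_zone(pts, zone)
        out[zone.name] = float(dt[mask[:-1]].sum())
    return out


@dataclass
class OccupancyMap:
    bin_cm: float
    grid: np.ndarray  # dwell seconds, shape (nx, ny), index [ix, iy]
    x_edges: np.ndarray
    y_edges: np.ndarray
    duration_s: float

    @property
    def origin(self) -> Tuple[float, float]:
        return (float(self.x_edges[0]), float(self.y_edges[0]))

    def total(self) -> float:
        return float(self.grid.sum())

    def __add__(self, other: "OccupancyMap") -> "OccupancyMap":
        if self.grid.shape != other.grid.shape or not np.allclose(
            self.x_edges, other.x_edges
        ):
            raise ValidationError("occupancy maps have incompatible grids")
        return OccupancyMap(
            bin_cm=self.bin_cm,
            grid=self.grid + other.grid,
            x_edges=self.x_edges,
            y_edges=self.y_edges,
            duration_s=self.duration_s + other.duration_s,
        )


def occupancy_map(
    track: Track, bin_cm: float = 1.0, radius_cm: Optional[float] = None
) -> OccupancyMap:
    """Dwell-time histogram of the centre point over ``[-R, R]^2``.

    The grid total equals the trial duration exactly (the final sample has no
    following interval and contributes nothing).
    """
    if bin_cm <= 0:
        raise ValidationError("bin_cm must be > 0")
    c = track.center
    if radius_cm is None:
        radius_cm = float(np.ceil(np.abs(c).max() + 1e-9))
    n_bins = max(1, int(math.ceil(2 * radius_cm / bin_cm)))
    edges = -radius_cm + bin_cm * np.arange(n_bins + 1)
    dt = np.diff(track.t)
    x = np.clip(c[:-1, 0], edges[0], edges[-1] - 1e-9)
    y = np.clip(c[:-1, 1], edges[0], edges[-1] - 1e-9)
    grid, _, _ = np.histogram2d(x, y, bins=[edges, edges], weights=dt)
    return OccupancyMap(
        bin_cm=bin_cm,
        grid=grid,
        x_edges=edges,
        y_edges=edges.copy(),
        duration_s=float(track.t[-1] - track.t[0]),
    )


def write_occupancy_map(omap: OccupancyMap, sink) -> None:
    """Delimited numeric grid with a 3-line header (bin size, origin, duration)."""
    header = (
        f"bin_cm={omap.bin_cm}\n"
        f"origin={omap.origin[0]},{omap.origin[1]}\n"
        f"duration_s={omap.duration_s}"
    )
    np.savetxt(sink, omap.grid, delimiter=",", header=header, fmt="%.6f")


# --------------------------------------------------------------------------
# the per-trial feature vector


@dataclass
class MetricsParams:
    debounce_s: float = 0.1
    rearm_factor: float = 1.5
    jitter_cm: float = 0.05
    hysteresis_deg: float = 45.0
    smooth_window: int = 5
    turn_threshold_deg: float = 20.0
    speed_floor_cm_s: float = 2.0
    exit_zone_tol_cm: float = 1e-6


@dataclass
class TrialMetrics:
    escaped: bool
    latency_s: float
    n_errors: Optional[int]
    distance_cm: float
    mean_speed_cm_s: float
    rotations: Optional[int]
    meander_turns: int
    heading_to_exit_deg: Optional[float]
    periphery_s: float
    zone_dwell: Dict[str, float] = field(default_factory=dict)
    inspections: List[InspectionEvent] = field(default_factory=list)


def _truncate(track: Track, cutoff_s: float) -> Track:
    """Drop samples after the cutoff (guided portion of a failed trial)."""
    rel = track.t - track.t[0]
    keep = rel <= cutoff_s + 1e-9
    if keep.all():
        return track
    n = int(keep.sum())
    if n < 2:
        raise ValidationError("track has fewer than 2 samples before the cutoff")
    return Track(
        t=track.t[:n],
        center=track.center[:n],
        nose=None if track.nose is None else track.nose[:n],
        tail=None if track.tail is None else track.tail[:n],
        rate_hz=track.rate_hz,
    )


def compute_trial_metrics(
    track: Track,
    trial: TrialRecord,
    arena: Arena,
    params: Optional[MetricsParams] = None,
) -> TrialMetrics:
    """All per-trial metrics for one track.

    Escape rule: a (truncated) track ending before the cutoff must end with
    the nose inside the true-exit zone, giving ``latency = final timestamp``;
    a track reaching the cutoff is censored at ``latency = cutoff``.  Probe
    trials are always censored and carry no error count.
    """
    params = params or MetricsParams()
    track = _truncate(track, trial.cutoff_s)
    t_rel_end = float(track.t[-1] - track.t[0])
    cutoff = trial.cutoff_s

    if trial.probe:
        escaped = False
        latency = cutoff
    elif t_rel_end >= cutoff - 1e-9:
        escaped = False
        latency = cutoff
    else:
        exit_zone = arena.hole_zone(trial.true_exit_hole)
        end_pt = track.nose[-1] if track.nose is not None else track.center[-1]
        d = math.hypot(
            end_pt[0] - exit_zone.geometry.center[0],
            end_pt[1] - exit_zone.geometry.center[1],
        )
        if d > exit_zone.geometry.radius + params.exit_zone_tol_cm:
            raise MalformedTrialError(
                f"track ends at t={t_rel_end:.2f}s (< cutoff {cutoff}s) with the "
                f"nose {d:.2f} cm from the exit centre (zone radius "
                f"{exit_zone.geometry.radius} cm)"
            )
        escaped = True
        latency = t_rel_end

    inspections: List[InspectionEvent] = []
    n_errors: Optional[int] = None
    if not trial.probe and track.nose is not None:
        inspections = detect_inspections(
            track,
            arena,
            trial.true_exit_hole,
            debounce_s=params.debounce_s,
            rearm_factor=params.rearm_factor,
        )
        t0 = float(track.t[0])
        n_errors = sum(
            1
            for e in inspections
            if not e.is_true_exit and (e.t_on - t0) < latency - 1e-12
        )

    distance = path_length(track, jitter_cm=params.jitter_cm)
    mean_speed = distance / latency if latency > 0 else 0.0

    rotations: Optional[int] = None
    if track.nose is not None and track.tail is not None:
        rotations = count_rotations(track, hysteresis_deg=params.hysteresis_deg)

    meander = meander_count(
        track,
        smooth_window=params.smooth_window,
        turn_threshold_deg=params.turn_threshold_deg,
        speed_floor_cm_s=params.speed_floor_cm_s,
    )

    heading: Optional[float] = None
    if not trial.probe and trial.true_exit_hole is not None:
        heading = heading_to_exit(
            track,
            arena.hole_center(trial.true_exit_hole),
            speed_floor_cm_s=params.speed_floor_cm_s,
        )

    dwell_zones = [z for z in arena.zones if z.kind in (ZoneKind.PERIPHERY, ZoneKind.QUADRANT)]
    dwell = zone_dwell_times(track, dwell_zones)
    periphery = dwell.get("periphery", 0.0)

    return TrialMetrics(
        escaped=escaped,
        latency_s=float(latency),
        n_errors=n_errors,
        distance_cm=distance,
        mean_speed_cm_s=float(mean_speed),
        rotations=rotations,
        meander_turns=meander,
        heading_to_exit_deg=heading,
        periphery_s=periphery,
        zone_dwell=dwell,
        inspections=inspections,
    )
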