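"""Agent-based synthetic cohort generator.

Paddling mice are simulated at the tracking rate (default 30 Hz) with a
constant-speed step and rate-limited heading relaxation toward a policy
target, plus Gaussian heading noise and per-coordinate tracking jitter.
Three movement policies mirror the observed escape strategies:

* ``spatial`` — steer from the centre toward the true exit, optionally
  inspecting up to three decoys adjacent to it;
* ``chain`` — reach the wall several holes away from the exit, then
  wall-follow in one direction, dwelling 0.5-1.5 s at each hole passed,
  until the exit is reached;
* ``futile`` — wall-follow with dwells and occasional direction reversals,
  detouring inward around the exit so the nose never satisfies the
  escape rule, until the cutoff.

Per-trial policies are drawn from a learning-curve mixture whose spatial
probability rises logistically with the trial index.  All randomness flows
from per-trial substreams derived from (seed, subject, trial), so results
are independent of iteration order.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .arena import Arena, ArenaConfig, Variant, build_arena
from .errors import ValidationError
from .strategy import Strategy
from .trackio import (
    Protocol,
    Schedule,
    Sex,
    Strain,
    Track,
    TrialRecord,
    make_schedule,
    schedule_trials,
)

TWO_PI = 2.0 * math.pi


class Task(str, Enum):
    PPT = "PPT"
    MWM = "MWM"


@dataclass
class SimConfig:
    seed: int = 0
    dt: float = 1.0 / 30.0
    speed_mean: float = 10.0
    speed_sd: float = 2.0
    body_length_mean: float = 8.0
    body_length_sd: float = 0.5
    heading_noise_kappa: float = 8.0
    p_inspect_near: float = 0.15
    chain_dwell_min_s: float = 0.5
    chain_dwell_max_s: float = 1.5
    spatial_dwell_s: float = 0.3
    learning_a: float = -1.5
    learning_b: float = 0.35
    futile_weight0: float = 0.5
    futile_weight_decay: float = 0.7
    jitter_sd: float = 0.1
    temp_rate_ppt: float = 2.0
    temp_rate_mwm: float = 5.0
    temp_noise_sd: float = 0.3
    turn_rate_deg_s: float = 540.0
    p_reverse: float = 0.2

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")
        if self.speed_mean <= 0:
            raise ValidationError("speed_mean must be > 0")
        for name in ("speed_sd", "body_length_sd", "jitter_sd", "temp_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("p_inspect_near", "futile_weight0", "futile_weight_decay", "p_reverse"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.chain_dwell_max_s < self.chain_dwell_min_s:
            raise ValidationError("chain dwell range inverted")


@dataclass(frozen=True)
class GroundTruth:
    policy: Strategy
    escape_time_s: Optional[float]  # None when censored at the cutoff
    planned_inspections: Tuple[int, ...]
    delta_t_c: Optional[float] = None

    @property
    def escaped(self) -> bool:
        return self.escape_time_s is not None


def trial_rng(seed: int, subject_id: str, trial_index: int) -> np.random.Generator:
    """Substream derived from (seed, subject, trial) via a stable hash."""
    digest = hashlib.blake2b(
        f"{seed}|{subject_id}|{trial_index}".encode(), digest_size=8
    ).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest, "big")])
    )


def _wrap_pi(a: float) -> float:
    return (a + math.pi) % TWO_PI - math.pi


# --------------------------------------------------------------------------
# single trial


def simulate_trial(
    policy: Union[Strategy, str],
    arena: Arena,
    trial: TrialRecord,
    config: SimConfig,
    rng: np.random.Generator,
) -> Tuple[Track, GroundTruth]:
    """One synthetic trial under the given movement policy."""
    policy = Strategy(policy)
    if arena.config.variant is Variant.WATERMAZE:
        return _simulate_watermaze_trial(policy, arena, trial, config, rng)
    return _simulate_clockmaze_trial(policy, arena, trial, config, rng)


def _hole_bearing(arena: Arena, k: int) -> float:
    c = arena.hole_center(k)
    return math.atan2(c[1], c[0])


def _mod_hole(k: int) -> int:
    return (k - 1) % 12 + 1


def _simulate_clockmaze_trial(
    policy: Strategy,
    arena: Arena,
    trial: TrialRecord,
    config: SimConfig,
    rng: np.random.Generator,
) -> Tuple[Track, GroundTruth]:
    R = arena.radius_cm
    dt = config.dt
    cutoff = trial.cutoff_s
    exit_hole = trial.true_exit_hole
    probe = trial.probe or exit_hole is None
    n_max = int(round(cutoff / dt))

    speed = max(3.0, float(rng.normal(config.speed_mean, config.speed_sd)))
    half_len = max(2.0, float(rng.normal(config.body_length_mean, config.body_length_sd))) / 2.0
    turn_rate = math.radians(config.turn_rate_deg_s)
    noise_sd = math.sqrt(dt) / math.sqrt(config.heading_noise_kappa)
    heading_noise = rng.normal(0.0, noise_sd, size=n_max + 1)
    jitter = rng.normal(0.0, config.jitter_sd, size=(n_max + 1, 6))

    exit_center = arena.hole_center(exit_hole) if exit_hole else None
    exit_zone_r = arena.config.hole_zone_radius_cm
    r_dwell = R - half_len + 0.2  # nose pokes ~0.2 cm into the hole when radial
    zone_r = arena.config.hole_zone_radius_cm

    # ---- policy plan -----------------------------------------------------
    plan_holes: List[int] = []
    if probe:
        # wander futile-style, starting (and so dwelling first) at the
        # former exit to express the learned spatial bias
        d = int(rng.choice([-1, 1]))
        base = exit_hole if exit_hole else int(rng.integers(1, 13))
        visit_seq = [base]
        policy_eff = Strategy.FUTILE
    else:
        policy_eff = policy
        if policy is Strategy.SPATIAL:
            n_ins = int(rng.binomial(3, config.p_inspect_near))
            near = [_mod_hole(exit_hole + j) for j in (-2, -1, 1, 2)]
            plan_holes = sorted(
                rng.choice(near, size=n_ins, replace=False).tolist() if n_ins else []
            )
            visit_seq = plan_holes + [exit_hole]
            d = 0
        elif policy is Strategy.CHAIN:
            k = int(rng.integers(4, 12))
            d = int(rng.choice([-1, 1]))
            visit_seq = [_mod_hole(exit_hole + d * j) for j in range(k, 0, -1)] + [exit_hole]
            plan_holes = visit_seq[:-1]
        elif policy is Strategy.FUTILE:
            k = int(rng.integers(3, 10))
            d = int(rng.choice([-1, 1]))
            visit_seq = [_mod_hole(exit_hole + d * k)]
        else:
            raise ValidationError(f"unknown policy {policy!r}")

    # ---- state -----------------------------------------------------------
    px = float(rng.normal(0.0, 0.5))
    py = float(rng.normal(0.0, 0.5))
    heading = float(rng.uniform(0.0, TWO_PI))

    ts = np.empty(n_max + 1)
    noses = np.empty((n_max + 1, 2))
    centers = np.empty((n_max + 1, 2))
    tails = np.empty((n_max + 1, 2))

    phase = "goto"  # goto | dwell
    seq_pos = 0
    dwell_left = 0.0
    futile_dir = d
    escape_idx: Optional[int] = None
    never_escape = probe or policy_eff is Strategy.FUTILE
    # only a non-probe futile agent must avoid the (open) exit
    guard_exit = (not probe) and policy_eff is Strategy.FUTILE

    def target_point(hole: int) -> Tuple[float, float]:
        c = arena.hole_center(hole)
        s = r_dwell / R
        return (c[0] * s, c[1] * s)

    def record(i: int) -> None:
        t = i * dt
        ux, uy = math.cos(heading), math.sin(heading)
        nx, ny = px + half_len * ux, py + half_len * uy
        tx, tyy = px - half_len * ux, py - half_len * uy
        jx = jitter[i]
        nx, ny = nx + jx[0], ny + jx[1]
        if guard_exit and exit_center is not None:
            # keep the recorded nose out of the exit zone by construction
            dx, dy = nx - exit_center[0], ny - exit_center[1]
            dist = math.hypot(dx, dy)
            guard = exit_zone_r + 0.3
            if dist <= guard:
                if dist < 1e-9:
                    dx, dy, dist = 1.0, 0.0, 1.0
                scale = (guard + 0.1) / dist
                nx = exit_center[0] + dx * scale
                ny = exit_center[1] + dy * scale
        ts[i] = t
        noses[i] = (nx, ny)
        centers[i] = (px + jx[2], py + jx[3])
        tails[i] = (tx + jx[4], tyy + jx[5])

    record(0)
    i = 0
    current_hole = visit_seq[seq_pos] if visit_seq else None
    while i < n_max:
        i += 1
        # ---- steering target
        if phase == "dwell" and current_hole is not None:
            tgt = math.atan2(
                arena.hole_center(current_hole)[1] - py,
                arena.hole_center(current_hole)[0] - px,
            )
            move = False
        else:
            if current_hole is None:
                tx_, ty_ = 0.0, 0.0
            else:
                tx_, ty_ = target_point(current_hole)
                if guard_exit and exit_hole is not None:
                    # detour inward when the leg would brush the exit
                    eb = _hole_bearing(arena, exit_hole)
                    pb = math.atan2(py, px)
                    if abs(_wrap_pi(pb - eb)) < math.radians(25.0) and math.hypot(px, py) > R - 12.0:
                        s = (R - 14.0) / R
                        c = arena.hole_center(exit_hole)
                        tx_, ty_ = c[0] * s, c[1] * s
            tgt = math.atan2(ty_ - py, tx_ - px)
            move = True
        dh = _wrap_pi(tgt - heading)
        max_turn = turn_rate * dt
        heading += max(-max_turn, min(max_turn, dh)) + heading_noise[i]
        if move:
            px += speed * dt * math.cos(heading)
            py += speed * dt * math.sin(heading)
            r = math.hypot(px, py)
            if r > R - 1.0:  # radial reflection at the wall standoff
                rr = max(2.0 * (R - 1.0) - r, 0.0)
                px *= rr / r
                py *= rr / r

        record(i)

        # ---- escape check on the recorded (jittered) nose
        if not never_escape and exit_center is not None:
            if (
                math.hypot(noses[i, 0] - exit_center[0], noses[i, 1] - exit_center[1])
                <= exit_zone_r
            ):
                escape_idx = i
                break

        # ---- phase transitions
        if current_hole is not None and phase == "goto":
            hx, hy = target_point(current_hole)
            if math.hypot(px - hx, py - hy) < 0.8:
                phase = "dwell"
                if policy_eff is Strategy.SPATIAL:
                    dwell_left = config.spatial_dwell_s
                else:
                    dwell_left = float(
                        rng.uniform(config.chain_dwell_min_s, config.chain_dwell_max_s)
                    )
        elif phase == "dwell":
            dwell_left -= dt
            if dwell_left <= 0.0:
                phase = "goto"
                if never_escape:
                    if rng.uniform() < config.p_reverse:
                        futile_dir = -futile_dir
                    nxt = _mod_hole(current_hole + futile_dir)
                    if guard_exit and nxt == exit_hole:
                        nxt = _mod_hole(nxt + futile_dir)
                    current_hole = nxt
                else:
                    seq_pos += 1
                    if seq_pos < len(visit_seq):
                        current_hole = visit_seq[seq_pos]
                    # at the exit the dwell never ends until escape triggers
                    if seq_pos >= len(visit_seq):
                        seq_pos = len(visit_seq) - 1
                        current_hole = visit_seq[-1]

    end = escape_idx if escape_idx is not None else n_max
    track = Track(
        t=ts[: end + 1].copy(),
        center=centers[: end + 1].copy(),
        nose=noses[: end + 1].copy(),
        tail=tails[: end + 1].copy(),
        rate_hz=1.0 / dt,
    )
    truth = GroundTruth(
        policy=policy,
        escape_time_s=float(ts[end]) if escape_idx is not None else None,
        planned_inspections=tuple(plan_holes),
    )
    return track, truth


def _simulate_watermaze_trial(
    policy: Strategy,
    arena: Arena,
    trial: TrialRecord,
    config: SimConfig,
    rng: np.random.Generator,
) -> Tuple[Track, GroundTruth]:
    """Swimming variant: goal-directed (spatial) vs periphery-biased
    (chain/futile) modes; escape = centre inside the platform zone."""
    R = arena.radius_cm
    dt = config.dt
    cutoff = trial.cutoff_s
    n_max = int(round(cutoff / dt))
    platform = arena.config.platform_center
    platform_r = arena.config.platform_radius_cm

    speed = max(5.0, float(rng.normal(config.speed_mean * 1.8, config.speed_sd)))
    half_len = max(2.0, float(rng.normal(config.body_length_mean, config.body_length_sd))) / 2.0
    turn_rate = math.radians(config.turn_rate_deg_s)
    noise_sd = math.sqrt(dt) / math.sqrt(config.heading_noise_kappa)
    heading_noise = rng.normal(0.0, noise_sd, size=n_max + 1)
    jitter = rng.normal(0.0, config.jitter_sd, size=(n_max + 1, 6))

    start_angle = float(rng.choice([0.25, 0.75, 1.25, 1.75])) * math.pi
    px = (R - 5.0) * math.cos(start_angle)
    py = (R - 5.0) * math.sin(start_angle)
    heading = math.atan2(-py, -px)
    goal_directed = policy is Strategy.SPATIAL

    ts = np.empty(n_max + 1)
    noses = np.empty((n_max + 1, 2))
    centers = np.empty((n_max + 1, 2))
    tails = np.empty((n_max + 1, 2))

    def record(i: int) -> None:
        ux, uy = math.cos(heading), math.sin(heading)
        jx = jitter[i]
        ts[i] = i * dt
        noses[i] = (px + half_len * ux + jx[0], py + half_len * uy + jx[1])
        centers[i] = (px + jx[2], py + jx[3])
        tails[i] = (px - half_len * ux + jx[4], py - half_len * uy + jx[5])

    record(0)
    escape_idx: Optional[int] = None
    i = 0
    while i < n_max:
        i += 1
        if goal_directed:
            tgt = math.atan2(platform[1] - py, platform[0] - px)
        else:
            # thigmotaxis: follow the wall tangentially
            pb = math.atan2(py, px)
            tgt = pb + math.pi / 2.0
            if math.hypot(px, py) < R - 12.0:
                tgt = pb  # head back out to the periphery band
        dh = _wrap_pi(tgt - heading)
        max_turn = turn_rate * dt
        heading += max(-max_turn, min(max_turn, dh)) + heading_noise[i]
        px += speed * dt * math.cos(heading)
        py += speed * dt * math.sin(heading)
        r = math.hypot(px, py)
        if r > R - 1.0:
            rr = max(2.0 * (R - 1.0) - r, 0.0)
            px *= rr / r
            py *= rr / r
        record(i)
        if goal_directed and math.hypot(px - platform[0], py - platform[1]) <= platform_r:
            escape_idx = i
            break

    end = escape_idx if escape_idx is not None else n_max
    track = Track(
        t=ts[: end + 1].copy(),
        center=centers[: end + 1].copy(),
        nose=noses[: end + 1].copy(),
        tail=tails[: end + 1].copy(),
        rate_hz=1.0 / dt,
    )
    truth = GroundTruth(
        policy=policy,
        escape_time_s=float(ts[end]) if escape_idx is not None else None,
        planned_inspections=(),
    )
    return track, truth


# --------------------------------------------------------------------------
# learning-curve mixture


def policy_probabilities(trial_index: int, config: SimConfig) -> Dict[Strategy, float]:
    """P(spatial) rises logistically with the trial index; the remainder is
    split between futile (decaying geometrically) and chain."""
    p_sp = 1.0 / (1.0 + math.exp(-(config.learning_a + config.learning_b * trial_index)))
    rem = 1.0 - p_sp
    w_f = min(1.0, config.futile_weight0 * config.futile_weight_decay ** (trial_index - 1))
    p_fu = rem * w_f
    return {
        Strategy.SPATIAL: p_sp,
        Strategy.CHAIN: rem - p_fu,
        Strategy.FUTILE: p_fu,
    }


def draw_policy(trial_index: int, config: SimConfig, rng: np.random.Generator) -> Strategy:
    probs = policy_probabilities(trial_index, config)
    labels = [Strategy.SPATIAL, Strategy.CHAIN, Strategy.FUTILE]
    p = np.array([probs[l] for l in labels])
    return labels[int(rng.choice(3, p=p / p.sum()))]


# --------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    schedule: Schedule
    strain: Strain = Strain.OTHER
    sex: Sex = Sex.F
    forced_futile_trials: frozenset = frozenset()  # e.g. drug-infusion trials


@dataclass
class TrialData:
    record: TrialRecord
    track: Optional[Track]
    truth: GroundTruth


@dataclass
class CohortDataset:
    trials: List[TrialData]

    def __len__(self) -> int:
        return len(self.trials)


def make_roster(
    n_subjects: int,
    protocol: Union[Protocol, str] = Protocol.ONE_EXIT,
    strain: Union[Strain, str] = Strain.OTHER,
    sex: Union[Sex, str] = Sex.F,
    prefix: str = "m",
    seed: Optional[int] = None,
) -> List[SubjectSpec]:
    schedule = make_schedule(protocol, seed=seed)
    return [
        SubjectSpec(
            subject_id=f"{prefix}{i + 1:03d}",
            schedule=schedule,
            strain=Strain(strain),
            sex=Sex(sex),
        )
        for i in range(n_subjects)
    ]


def strategy_analysis_roster(seed: Optional[int] = None) -> List[SubjectSpec]:
    """The 290-subject design used for strategy-cluster analyses: four
    one-exit cohorts (C57 50M/20F, BALB/c 20M/60F) and four three-exit
    cohorts (C57 70M/20F, BALB/c 20M/30F), 12 trials per subject."""
    groups = [
        ("one_exit", Strain.C57, Sex.M, 50),
        ("one_exit", Strain.C57, Sex.F, 20),
        ("one_exit", Strain.BALBC, Sex.M, 20),
        ("one_exit", Strain.BALBC, Sex.F, 60),
        ("three_exits", Strain.C57, Sex.M, 70),
        ("three_exits", Strain.C57, Sex.F, 20),
        ("three_exits", Strain.BALBC, Sex.M, 20),
        ("three_exits", Strain.BALBC, Sex.F, 30),
    ]
    roster: List[SubjectSpec] = []
    for gi, (protocol, strain, sex, n) in enumerate(groups):
        roster.extend(
            make_roster(
                n,
                protocol=protocol,
                strain=strain,
                sex=sex,
                prefix=f"g{gi}_",
                seed=seed,
            )
        )
    return roster


def simulate_cohort(
    roster: Sequence[SubjectSpec],
    config: Optional[SimConfig] = None,
    seed: Optional[int] = None,
    arena: Optional[Arena] = None,
    with_tracks: bool = True,
) -> CohortDataset:
    """Simulate every (subject, trial) of the roster.

    Identical (seed, roster, config) inputs give byte-identical output;
    per-trial substreams make the result independent of iteration order.
    With ``with_tracks=False`` only policies and outcome-level ground truth
    are generated (fast path for statistical property checks).
    """
    config = config or SimConfig()
    root_seed = config.seed if seed is None else seed
    arena = arena or build_arena(ArenaConfig())
    out: List[TrialData] = []
    for spec in roster:
        for record in schedule_trials(
            spec.schedule, spec.subject_id, strain=spec.strain, sex=spec.sex
        ):
            rng = trial_rng(root_seed, spec.subject_id, record.trial_index)
            if record.trial_index in spec.forced_futile_trials:
                policy = Strategy.FUTILE
            else:
                policy = draw_policy(record.trial_index, config, rng)
            if with_tracks:
                track, truth = simulate_trial(policy, arena, record, config, rng)
            else:
                track = None
                truth = _cheap_outcome(policy, record, config, rng)
            out.append(TrialData(record=record, track=track, truth=truth))
    return CohortDataset(trials=out)


def _cheap_outcome(
    policy: Strategy, record: TrialRecord, config: SimConfig, rng: np.random.Generator
) -> GroundTruth:
    """Outcome-level generative model consistent with the classifier:
    spatial escapes fast with <=3 errors, chain escapes slower with >3,
    futile is censored."""
    cutoff = record.cutoff_s
    if policy is Strategy.FUTILE:
        return GroundTruth(policy=policy, escape_time_s=None, planned_inspections=())
    if policy is Strategy.SPATIAL:
        n_err = int(rng.binomial(3, config.p_inspect_near))
        lat = min(cutoff - 1.0, float(rng.lognormal(math.log(6.0), 0.4)) + n_err)
    else:
        n_err = int(rng.integers(4, 12))
        lat = min(cutoff - 1.0, 5.0 + 2.5 * n_err + float(rng.normal(0.0, 3.0)))
    holes = tuple(int(h) for h in rng.choice(12, size=n_err, replace=False) + 1)
    return GroundTruth(policy=policy, escape_time_s=max(lat, 0.5), planned_inspections=holes)


# --------------------------------------------------------------------------
# temperature model


def temperature_model(
    latency_s: float,
    task: Union[Task, str],
    config: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Body-temperature change for one trial: a linear drop with trial
    duration (about -2 C over 60 s paddling, -5 C over 60 s swimming) plus
    Gaussian noise when an RNG is supplied."""
    config = config or SimConfig()
    task = Task(task)
    if not 0 < latency_s:
        raise ValidationError("latency must be positive")
    rate = config.temp_rate_ppt if task is Task.PPT else config.temp_rate_mwm
    dT = -rate * latency_s / 60.0
    if rng is not None and config.temp_noise_sd > 0:
        dT += float(rng.normal(0.0, config.temp_noise_sd))
    return dT
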