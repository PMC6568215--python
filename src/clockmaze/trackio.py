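"""Reading and writing tracks, trial metadata, metric tables and schedules.

The canonical track format is a delimited text file (comma or tab, auto
detected) with header::

    time_s,nose_x,nose_y,center_x,center_y,tail_x,tail_y

modelled on raw 3-point tracker exports.  Files missing the nose and/or
tail columns are accepted but flagged as degraded; downstream operations
that require those points refuse to run on degraded tracks.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError


# --------------------------------------------------------------------------
# track


@dataclass(frozen=True)
class TrackSample:
    t: float
    nose: Optional[Tuple[float, float]]
    center: Tuple[float, float]
    tail: Optional[Tuple[float, float]]


@dataclass
class Track:
    """Time-ordered 3-point samples for one trial.

    Coordinates are stored as float arrays of shape ``(n, 2)``; ``nose`` and
    ``tail`` are ``None`` on degraded tracks.
    """

    t: np.ndarray
    center: np.ndarray
    nose: Optional[np.ndarray] = None
    tail: Optional[np.ndarray] = None
    rate_hz: float = 30.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if self.nose is not None:
            self.nose = np.asarray(self.nose, dtype=float)
        if self.tail is not None:
            self.tail = np.asarray(self.tail, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValidationError("track needs at least 2 samples")
        if not np.all(np.isfinite(self.t)) or self.t[0] < 0:
            raise ValidationError("timestamps must be finite and non-negative")
        dt = np.diff(self.t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise FormatError(f"non-increasing timestamp at row {int(bad[0]) + 1}")
        for name in ("center", "nose", "tail"):
            arr = getattr(self, name)
            if arr is None:
                continue
            if arr.shape != (len(self.t), 2):
                raise ValidationError(f"{name} must have shape (n, 2)")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite coordinates")

    @property
    def has_nose(self) -> bool:
        return self.nose is not None

    @property
    def has_tail(self) -> bool:
        return self.tail is not None

    @property
    def degraded(self) -> bool:
        return not (self.has_nose and self.has_tail)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def samples(self) -> List[TrackSample]:
        out = []
        for i in range(len(self.t)):
            out.append(
                TrackSample(
                    t=float(self.t[i]),
                    nose=tuple(self.nose[i]) if self.nose is not None else None,
                    center=tuple(self.center[i]),
                    tail=tuple(self.tail[i]) if self.tail is not None else None,
                )
            )
        return out

    def check_in_arena(self, radius_cm: float, tolerance_cm: float = 1.0) -> None:
        """Every centre point must lie within ``radius_cm + tolerance_cm``."""
        r = np.hypot(self.center[:, 0], self.center[:, 1])
        bad = np.nonzero(r > radius_cm + tolerance_cm)[0]
        if bad.size:
            raise ValidationError(
                f"{bad.size} centre samples outside the arena "
                f"(radius {radius_cm} + {tolerance_cm} cm tolerance); "
                f"sample indices {bad[:10].tolist()}"
            )


_TRACK_COLUMNS = ["time_s", "nose_x", "nose_y", "center_x", "center_y", "tail_x", "tail_y"]


def _sniff_sep(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_track(
    source: Union[str, os.PathLike, IO],
    rate_hz: float = 30.0,
    arena_radius_cm: Optional[float] = None,
) -> Track:
    """Parse a delimited track file (comma or tab auto-detected).

    ``arena_radius_cm``, when given, enables the out-of-arena check with a
    1 cm tolerance.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    first = text.splitlines()[0] if text else ""
    sep = _sniff_sep(first)
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message is opaque
        raise FormatError(f"cannot parse track: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    if "time_s" not in df.columns:
        raise FormatError("missing required column 'time_s'")
    for c in ("center_x", "center_y"):
        if c not in df.columns:
            raise FormatError(f"missing required column '{c}'")
    has_nose = {"nose_x", "nose_y"} <= set(df.columns)
    has_tail = {"tail_x", "tail_y"} <= set(df.columns)
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        # +2: 1 for the header line, 1 because the offender is the later row
        raise FormatError(
            f"non-monotone time at data row {int(bad[0]) + 2} (t={t[bad[0] + 1]!r})"
        )
    track = Track(
        t=t,
        center=df[["center_x", "center_y"]].to_numpy(dtype=float),
        nose=df[["nose_x", "nose_y"]].to_numpy(dtype=float) if has_nose else None,
        tail=df[["tail_x", "tail_y"]].to_numpy(dtype=float) if has_tail else None,
        rate_hz=rate_hz,
    )
    if arena_radius_cm is not None:
        track.check_in_arena(arena_radius_cm)
    return track


def write_track(track: Track, sink: Union[str, os.PathLike, IO], sep: str = ",") -> None:
    """Write a track with 6-decimal precision (lossless at 1e-6 cm)."""
    cols = {"time_s": track.t}
    if track.nose is not None:
        cols["nose_x"], cols["nose_y"] = track.nose[:, 0], track.nose[:, 1]
    cols["center_x"], cols["center_y"] = track.center[:, 0], track.center[:, 1]
    if track.tail is not None:
        cols["tail_x"], cols["tail_y"] = track.tail[:, 0], track.tail[:, 1]
    df = pd.DataFrame(cols)
    df.to_csv(sink, sep=sep, index=False, float_format="%.6f")


# --------------------------------------------------------------------------
# trial metadata


class Strain(str, Enum):
    C57 = "C57"
    BALBC = "BALBc"
    OTHER = "other"


class Sex(str, Enum):
    M = "M"
    F = "F"


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    strain: Strain = Strain.OTHER
    sex: Sex = Sex.F
    day: int = 1
    trial_index: int = 1
    true_exit_hole: Optional[int] = None
    cutoff_s: float = 60.0
    probe: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "strain", Strain(self.strain))
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.trial_index < 1:
            raise ValidationError("trial_index must be >= 1")
        if not self.cutoff_s > 0:
            raise ValidationError("cutoff_s must be > 0")
        if not self.probe and self.true_exit_hole is None:
            raise ValidationError("non-probe trials need a true_exit_hole")


TRIAL_COLUMNS = [
    "subject_id",
    "strain",
    "sex",
    "day",
    "trial_index",
    "true_exit_hole",
    "cutoff_s",
    "probe",
]


def write_trials_table(records: Sequence[TrialRecord], sink) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "strain": r.strain.value,
                "sex": r.sex.value,
                "day": r.day,
                "trial_index": r.trial_index,
                "true_exit_hole": "" if r.true_exit_hole is None else r.true_exit_hole,
                "cutoff_s": r.cutoff_s,
                "probe": r.probe,
            }
        )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(sink, index=False)


def read_trials_table(source) -> List[TrialRecord]:
    df = pd.read_csv(source)
    out = []
    for _, row in df.iterrows():
        exit_hole = row.get("true_exit_hole")
        if pd.isna(exit_hole) or exit_hole == "":
            exit_hole = None
        else:
            exit_hole = int(exit_hole)
        out.append(
            TrialRecord(
                subject_id=str(row["subject_id"]),
                strain=Strain(row["strain"]),
                sex=Sex(row["sex"]),
                day=int(row["day"]),
                trial_index=int(row["trial_index"]),
                true_exit_hole=exit_hole,
                cutoff_s=float(row.get("cutoff_s", 60.0)),
                probe=bool(row.get("probe", False)),
            )
        )
    return out


# --------------------------------------------------------------------------
# metrics table

METRICS_COLUMNS = [
    "subject_id",
    "strain",
    "sex",
    "day",
    "trial_index",
    "true_exit_hole",
    "escaped",
    "latency_s",
    "n_errors",
    "distance_cm",
    "mean_speed_cm_s",
    "rotations",
    "meander_turns",
    "heading_to_exit_deg",
    "periphery_s",
    "strategy",
]


def write_metrics_table(records: Iterable[tuple], sink) -> None:
    """Write one row per (TrialRecord, TrialMetrics, strategy-label) triple
    with the stable column order of :data:`METRICS_COLUMNS`."""
    rows = []
    for trial, m, strat in records:
        label = getattr(strat, "value", strat)
        rows.append(
            {
                "subject_id": trial.subject_id,
                "strain": trial.strain.value,
                "sex": trial.sex.value,
                "day": trial.day,
                "trial_index": trial.trial_index,
                "true_exit_hole": "" if trial.true_exit_hole is None else trial.true_exit_hole,
                "escaped": m.escaped,
                "latency_s": m.latency_s,
                "n_errors": "" if m.n_errors is None else m.n_errors,
                "distance_cm": m.distance_cm,
                "mean_speed_cm_s": m.mean_speed_cm_s,
                "rotations": m.rotations,
                "meander_turns": m.meander_turns,
                "heading_to_exit_deg": ""
                if m.heading_to_exit_deg is None
                else m.heading_to_exit_deg,
                "periphery_s": m.periphery_s,
                "strategy": "" if label is None else label,
            }
        )
    pd.DataFrame(rows, columns=METRICS_COLUMNS).to_csv(sink, index=False)


def read_metrics_table(source) -> pd.DataFrame:
    return pd.read_csv(source)


# --------------------------------------------------------------------------
# schedules


class Protocol(str, Enum):
    ONE_EXIT = "one_exit"
    THREE_EXITS = "three_exits"
    EIGHT_EXITS = "eight_exits"
    CUSTOM = "custom"


_DEFAULT_EXITS = {
    Protocol.ONE_EXIT: [9],
    Protocol.THREE_EXITS: [4, 10, 2],
    Protocol.EIGHT_EXITS: [7, 11, 4, 9, 3, 5, 1, 6],
}

_TRIALS_PER_DAY = {
    Protocol.ONE_EXIT: [4, 4, 4],
    Protocol.THREE_EXITS: [4, 4, 4],
    Protocol.EIGHT_EXITS: [5, 5, 5, 5, 4, 4, 4, 4],
}


@dataclass(frozen=True)
class Schedule:
    protocol: Protocol
    trials_per_day: Tuple[int, ...]
    exits_per_day: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.trials_per_day) != len(self.exits_per_day):
            raise ValidationError("trials_per_day and exits_per_day length mismatch")
        for e in self.exits_per_day:
            if not 1 <= e <= 12:
                raise ValidationError(f"exit {e} outside 1..12")

    @property
    def n_trials(self) -> int:
        return sum(self.trials_per_day)

    @property
    def n_days(self) -> int:
        return len(self.trials_per_day)

    def entries(self) -> List[Tuple[int, int, int]]:
        """Flattened (day, trial_index, exit) entries, trial_index 1-based
        and global across days."""
        out = []
        idx = 0
        for d, (count, exit_hole) in enumerate(
            zip(self.trials_per_day, self.exits_per_day), start=1
        ):
            for _ in range(count):
                idx += 1
                out.append((d, idx, exit_hole))
        return out

    def novel_trial_indices(self) -> List[int]:
        """First global trial index of each day that introduces a new exit."""
        out = []
        idx = 1
        prev = None
        for count, exit_hole in zip(self.trials_per_day, self.exits_per_day):
            if exit_hole != prev:
                out.append(idx)
            prev = exit_hole
            idx += count
        return out


def make_schedule(
    protocol: Union[Protocol, str],
    exits: Optional[Sequence[int]] = None,
    seed: Optional[int] = None,
) -> Schedule:
    """Build a trial schedule for one subject.

    Without ``exits`` and ``seed`` the documented default exit sequences are
    used; with a ``seed`` (and no explicit exits) a pseudo-random sequence is
    drawn uniformly without replacement so no exit repeats across days.
    """
    protocol = Protocol(protocol)
    if protocol is Protocol.CUSTOM:
        if exits is None:
            raise ValidationError("custom protocol requires an explicit exit list")
        exits = list(exits)
        tpd = [4] * len(exits)
    else:
        tpd = list(_TRIALS_PER_DAY[protocol])
        if exits is None:
            if seed is None:
                exits = list(_DEFAULT_EXITS[protocol])
            else:
                rng = np.random.default_rng(seed)
                n_days_distinct = {
                    Protocol.ONE_EXIT: 1,
                    Protocol.THREE_EXITS: 3,
                    Protocol.EIGHT_EXITS: 8,
                }[protocol]
                exits = (rng.permutation(12)[:n_days_distinct] + 1).tolist()
        else:
            exits = list(exits)
    for e in exits:
        if not 1 <= int(e) <= 12:
            raise ValidationError(f"exit {e} outside 1..12")
    if protocol is Protocol.ONE_EXIT:
        if len(exits) == 1:
            exits = exits * 3
        if len(exits) != 3 or len(set(exits)) != 1:
            raise ValidationError("one_exit uses a single exit across 3 days")
    elif protocol is not Protocol.CUSTOM and len(exits) != len(tpd):
        raise ValidationError(
            f"{protocol.value} needs {len(tpd)} daily exits, got {len(exits)}"
        )
    return Schedule(
        protocol=protocol,
        trials_per_day=tuple(tpd),
        exits_per_day=tuple(int(e) for e in exits),
    )


def schedule_trials(
    schedule: Schedule,
    subject_id: str,
    strain: Union[Strain, str] = Strain.OTHER,
    sex: Union[Sex, str] = Sex.F,
    cutoff_s: float = 60.0,
) -> List[TrialRecord]:
    """Materialize a schedule into TrialRecords for one subject."""
    return [
        TrialRecord(
            subject_id=subject_id,
            strain=Strain(strain),
            sex=Sex(sex),
            day=day,
            trial_index=idx,
            true_exit_hole=exit_hole,
            cutoff_s=cutoff_s,
        )
        for day, idx, exit_hole in schedule.entries()
    ]
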