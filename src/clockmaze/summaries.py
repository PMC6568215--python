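"""Group-level derived measures: learning scores, novelty differences,
probe-zone preference, ensemble bands, EPM ratio, rank correlation and the
temperature-latency relation."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .arena import Arena, probe_zones
from .errors import ValidationError
from .metrics import zone_dwell_times
from .trackio import Track


# --------------------------------------------------------------------------
# learning scores


@dataclass(frozen=True)
class LearningScore:
    subject_id: str
    score: float  # mean of per-trial inverse latencies, 1/s


def learning_scores(
    trials: Dict[str, Sequence[float]],
    cutoff: float = 60.0,
    exclude_trials: frozenset = frozenset(),
    mode: str = "reciprocal",
) -> List[LearningScore]:
    """Per-subject learning score from ordered latency lists.

    ``mode='reciprocal'`` (default) scores each trial as ``1/latency`` with
    failed trials contributing ``1/cutoff``; ``mode='complement'`` uses
    ``(cutoff - latency) / cutoff`` instead.  ``exclude_trials`` holds 1-based
    trial indices to drop (e.g. the novel trials of the many-exits test).
    """
    if mode not in ("reciprocal", "complement"):
        raise ValidationError(f"unknown learning-score mode {mode!r}")
    out = []
    for subject, lats in trials.items():
        vals = []
        for i, lat in enumerate(lats, start=1):
            if i in exclude_trials:
                continue
            if not 0 < lat <= cutoff + 1e-9:
                raise ValidationError(
                    f"latency {lat} for {subject} trial {i} outside (0, {cutoff}]"
                )
            lat = min(lat, cutoff)
            vals.append(1.0 / lat if mode == "reciprocal" else (cutoff - lat) / cutoff)
        if not vals:
            raise ValidationError(f"no trials left for {subject} after exclusion")
        out.append(LearningScore(subject_id=subject, score=float(np.mean(vals))))
    return out


def novelty_differences(
    latencies: Sequence[float], novel_indices: Sequence[int]
) -> List[float]:
    """Signed latency differences between each novel trial and the trial
    immediately before it (1-based indices)."""
    out = []
    for i in novel_indices:
        if i < 2 or i > len(latencies):
            raise ValidationError(f"novel index {i} out of range 2..{len(latencies)}")
        out.append(float(latencies[i - 1] - latencies[i - 2]))
    return out


# --------------------------------------------------------------------------
# probe preference


@dataclass(frozen=True)
class ProbeResult:
    tz_pct: float
    nt_pct: float  # mean over the 11 non-target zones
    zone_pct: Dict[str, float]


def probe_zone_preference(
    track: Track,
    arena: Arena,
    former_exit: int,
    probe_zone_radius: Optional[float] = None,
) -> ProbeResult:
    """Dwell in the target zone (former exit) and non-target zones as a
    percentage of the probe duration."""
    if former_exit is None:
        raise ValidationError("probe analysis requires the former exit hole")
    zones = probe_zones(arena, former_exit, radius=probe_zone_radius)
    dwell = zone_dwell_times(track, zones)
    duration = float(track.t[-1] - track.t[0])
    if duration <= 0:
        raise ValidationError("probe track has no duration")
    pct = {name: 100.0 * s / duration for name, s in dwell.items()}
    tz = pct[f"target_{former_exit}"]
    nts = [v for name, v in pct.items() if name.startswith("nontarget_")]
    return ProbeResult(tz_pct=tz, nt_pct=float(np.mean(nts)) if nts else 0.0, zone_pct=pct)


# --------------------------------------------------------------------------
# scalar summaries


def epm_ratio(t_closed: float, t_open: float) -> float:
    """Anxiety index ``(T_C - T_O) / (T_C + T_O)`` in [-1, 1]."""
    if t_closed < 0 or t_open < 0:
        raise ValidationError("arm times must be non-negative")
    total = t_closed + t_open
    if total <= 0:
        raise ValidationError("total arm time must be positive")
    return (t_closed - t_open) / total


def _midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mid-rank."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Returns ``None`` for constant input (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("inputs must have equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 pairs")
    rx, ry = _midranks(x), _midranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return None
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


# --------------------------------------------------------------------------
# ensemble band


@dataclass(frozen=True)
class EnsembleBand:
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    lower_pct: float
    upper_pct: float


def ensemble_band(
    table: np.ndarray, lower_pct: float = 5.0, upper_pct: float = 95.0
) -> EnsembleBand:
    """Per-trial mean and percentile envelope of a subjects-by-trials table
    (linear interpolation between order statistics)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValidationError("need a 2-D subjects x trials table")
    return EnsembleBand(
        mean=arr.mean(axis=0),
        lower=np.percentile(arr, lower_pct, axis=0),
        upper=np.percentile(arr, upper_pct, axis=0),
        lower_pct=lower_pct,
        upper_pct=upper_pct,
    )


# --------------------------------------------------------------------------
# temperature vs latency


@dataclass(frozen=True)
class TempModelFit:
    rho: Optional[float]
    coefficients: Tuple[float, ...]  # highest degree first


def temp_latency_fit(
    latencies: Sequence[float],
    delta_temps: Sequence[float],
    degree: int = 1,
) -> TempModelFit:
    """Rank correlation plus a least-squares polynomial of the temperature
    drop against escape latency (successful trials only)."""
    lat = np.asarray(latencies, dtype=float)
    dT = np.asarray(delta_temps, dtype=float)
    if len(lat) != len(dT):
        raise ValidationError("inputs must have equal length")
    if len(lat) < 3:
        raise ValidationError("need at least 3 pairs")
    rho = spearman_rho(lat, dT)
    coeffs = np.polyfit(lat, dT, degree)
    return TempModelFit(rho=rho, coefficients=tuple(float(c) for c in coeffs))
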