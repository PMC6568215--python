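"""Escape-strategy classification and strategy-use trend analysis.

A trial is classified from its escape latency and error count alone:
censoring takes precedence (a trial that reached the cutoff is futile no
matter how few errors it made), then the error threshold splits spatial
(errors <= 3) from chain (errors > 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .summaries import spearman_rho


class Strategy(str, Enum):
    SPATIAL = "spatial"
    CHAIN = "chain"
    FUTILE = "futile"


def classify_trial(
    latency_s: float,
    n_errors: Optional[int],
    cutoff_s: float = 60.0,
    error_threshold: int = 3,
) -> Strategy:
    """Label one completed trial.

    ``latency_s >= cutoff_s`` is futile regardless of errors; otherwise
    ``n_errors <= error_threshold`` is spatial, more is chain.  An absent
    error count on a sub-cutoff trial is unclassifiable.
    """
    if latency_s <= 0:
        raise ValidationError(f"latency must be positive, got {latency_s}")
    if latency_s >= cutoff_s:
        return Strategy.FUTILE
    if n_errors is None:
        raise ValidationError(
            "trial below cutoff has no error count (degraded track); unclassifiable"
        )
    if n_errors < 0:
        raise ValidationError(f"n_errors must be >= 0, got {n_errors}")
    return Strategy.SPATIAL if n_errors <= error_threshold else Strategy.CHAIN


# --------------------------------------------------------------------------
# strategy matrix and trend


@dataclass
class StrategyMatrix:
    """Subjects x trials table of strategy labels (pandas DataFrame of
    'spatial'/'chain'/'futile' strings; NaN marks unclassifiable trials)."""

    table: pd.DataFrame

    @classmethod
    def from_records(
        cls, records: Sequence[tuple]
    ) -> "StrategyMatrix":
        """Build from (subject_id, trial_index, Strategy) triples."""
        rows: Dict[str, Dict[int, str]] = {}
        for subject, trial_index, label in records:
            rows.setdefault(subject, {})[int(trial_index)] = getattr(
                label, "value", label
            )
        df = pd.DataFrame.from_dict(rows, orient="index")
        df = df.reindex(sorted(df.columns), axis=1)
        df = df.reindex(sorted(df.index))
        return cls(table=df)

    @property
    def n_subjects(self) -> int:
        return self.table.shape[0]

    @property
    def n_trials(self) -> int:
        return self.table.shape[1]

    def label_counts(self) -> Dict[str, int]:
        counts = self.table.stack().value_counts().to_dict()
        return {str(k): int(v) for k, v in counts.items()}

    def write(self, sink) -> None:
        self.table.to_csv(sink, index_label="subject_id")


@dataclass(frozen=True)
class TrendResult:
    trial_indices: np.ndarray
    spatial_fraction: np.ndarray
    slope: float
    intercept: float
    rho: Optional[float]


def spatial_use_trend(matrix: StrategyMatrix) -> TrendResult:
    """Fraction of subjects using the spatial strategy at each trial, with an
    OLS linear fit and the Spearman correlation of (trial, fraction) pairs."""
    df = matrix.table
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise ValidationError("need at least 2 trials and 1 subject")
    trials = np.asarray(sorted(df.columns), dtype=float)
    frac = np.array(
        [
            (df[c] == Strategy.SPATIAL.value).sum() / df[c].notna().sum()
            if df[c].notna().sum()
            else np.nan
            for c in sorted(df.columns)
        ]
    )
    ok = ~np.isnan(frac)
    t, f = trials[ok], frac[ok]
    if len(t) < 2:
        raise ValidationError("fewer than 2 trials with classifiable labels")
    if np.allclose(f, f[0]):
        slope, intercept, rho = 0.0, float(f[0]), None
    else:
        slope, intercept = np.polyfit(t, f, 1)
        rho = spearman_rho(t, f)
    return TrendResult(
        trial_indices=trials,
        spatial_fraction=frac,
        slope=float(slope),
        intercept=float(intercept),
        rho=rho,
    )
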