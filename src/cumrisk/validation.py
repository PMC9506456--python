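"""Analytical-method validation statistics.

Covers the numbers a residue-method validation reports: the matrix effect
(relative change of the calibration slope measured in crop matrix versus pure
solvent; negative values mean signal suppression), and recovery mean and
relative standard deviation (RSD) from spiked-sample experiments.  RSD uses
the n−1 sample standard deviation, the convention in residue-method work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CalibrationCurve",
    "RecoverySet",
    "matrix_effect",
    "recovery_stats",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """A linear calibration curve (response vs concentration, mg/L)."""

    analyte: str
    medium: str  # "solvent" or "matrix"
    slope: float
    intercept: float = 0.0
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.medium not in ("solvent", "matrix"):
            raise ValueError(f"medium must be 'solvent' or 'matrix', got {self.medium!r}")
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")


@dataclass(frozen=True)
class RecoverySet:
    """Replicate recoveries (%) at one spike level for one analyte."""

    analyte: str
    spike_level: float
    recoveries: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.recoveries:
            raise ValueError("empty recovery set")
        if any(r <= 0 for r in self.recoveries):
            raise ValueError("recoveries must be positive percentages")


def matrix_effect(matrix_curve: CalibrationCurve, solvent_curve: CalibrationCurve) -> float:
    """Matrix effect in percent: 100·(slope_matrix − slope_solvent)/slope_solvent."""
    if matrix_curve.analyte != solvent_curve.analyte:
        raise ValueError(
            f"analyte mismatch: {matrix_curve.analyte!r} vs {solvent_curve.analyte!r}"
        )
    if solvent_curve.slope == 0:
        raise ZeroDivisionError("solvent calibration slope is zero")
    return 100.0 * (matrix_curve.slope - solvent_curve.slope) / solvent_curve.slope


def recovery_stats(recovery_set: RecoverySet) -> tuple[float, float]:
    """Mean recovery and RSD (both %) for one spike level.

    RSD = 100·sd/mean with the sample (n−1) standard deviation; with a single
    replicate the RSD is undefined and returned as NaN.
    """
    r = np.asarray(recovery_set.recoveries, dtype=float)
    mean = float(r.mean())
    if r.size < 2:
        return mean, float("nan")
    sd = float(r.std(ddof=1))
    return mean, 100.0 * sd / mean


def validate_recoveries(
    sets: Sequence[RecoverySet], mean_range: tuple[float, float] = (70.0, 120.0)
) -> list[dict]:
    """Tabulate recovery statistics with a pass flag against an accepted range."""
    lo, hi = mean_range
    rows = []
    for s in sets:
        mean, rsd = recovery_stats(s)
        rows.append(
            {
                "analyte": s.analyte,
                "spike_level": s.spike_level,
                "n": len(s.recoveries),
                "mean_recovery": mean,
                "rsd": rsd,
                "acceptable": lo <= mean <= hi and (math.isnan(rsd) or rsd <= 20.0),
            }
        )
    return rows
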