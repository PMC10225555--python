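"""Control statistics, percent activity, and the Z'-factor per plate.

Percent activity places each well between the negative (0) and positive
(100) control means:

    activity(x) = 100 * (x - mu_n) / (mu_p - mu_n)

and the screening-window statistic is

    Z' = 1 - 3 * (delta_p + delta_n) / |mu_p - mu_n|

with sample standard deviations (n - 1 denominator) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import DegenerateControlsError, InsufficientControlsError

__all__ = [
    "ControlStats",
    "ActivityResult",
    "PlateQC",
    "control_stats",
    "controls_by_plate",
    "percent_activity",
    "z_prime",
    "plate_qc",
    "activity_table",
]


@dataclass(frozen=True)
class ControlStats:
    """Means/SDs of control-well GFP plus negative-control cell counts."""

    mu_p: float
    delta_p: float
    mu_n: float
    delta_n: float
    n_pos: int
    n_neg: int
    cell_mu_n: float
    cell_delta_n: float

    def __post_init__(self):
        if self.n_pos < 2 or self.n_neg < 2:
            raise InsufficientControlsError(
                f"need >= 2 wells per control role, got pos={self.n_pos}, neg={self.n_neg}"
            )
        if min(self.delta_p, self.delta_n, self.cell_delta_n) < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class ActivityResult:
    """Percent activity of one extract well, with viability context."""

    extract_id: str
    well: str
    percent_activity: Optional[float]
    cell_count: int
    gfp_missing: bool
    plate_id: str = ""


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    z_prime: float
    passed: bool
    z_min: float
    controls: ControlStats

    def as_dict(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "z_prime": self.z_prime,
            "passed": self.passed,
            "z_min": self.z_min,
            "mu_p": self.controls.mu_p,
            "delta_p": self.controls.delta_p,
            "mu_n": self.controls.mu_n,
            "delta_n": self.controls.delta_n,
            "n_pos": self.controls.n_pos,
            "n_neg": self.controls.n_neg,
            "cell_mu_n": self.controls.cell_mu_n,
            "cell_delta_n": self.controls.cell_delta_n,
        }


def _merged(measurements: pd.DataFrame, plate_map: pd.DataFrame) -> pd.DataFrame:
    return measurements.merge(
        plate_map[["plate_id", "well", "role"] + (["extract_id"] if "extract_id" in plate_map else [])],
        on=["plate_id", "well"],
        how="left",
        validate="one_to_one",
    )


def control_stats(measurements: pd.DataFrame, plate_map: pd.DataFrame) -> ControlStats:
    """Sample mean/SD of control avg_gfp and of negative-control cell counts.

    Wells with missing avg_gfp are excluded from the GFP statistics but still
    contribute their cell counts.  Raises
    :class:`~hcscreen.errors.InsufficientControlsError` below two usable
    wells of either role.
    """
    df = _merged(measurements, plate_map)
    pos = df[(df["role"] == "POS") & df["avg_gfp"].notna()]
    neg = df[(df["role"] == "NEG") & df["avg_gfp"].notna()]
    if len(pos) < 2 or len(neg) < 2:
        raise InsufficientControlsError(
            f"need >= 2 control wells with GFP per role, got pos={len(pos)}, neg={len(neg)}"
        )
    neg_counts = df.loc[df["role"] == "NEG", "cell_count"].astype(float)
    return ControlStats(
        mu_p=float(pos["avg_gfp"].mean()),
        delta_p=float(pos["avg_gfp"].std(ddof=1)),
        mu_n=float(neg["avg_gfp"].mean()),
        delta_n=float(neg["avg_gfp"].std(ddof=1)),
        n_pos=int(len(pos)),
        n_neg=int(len(neg)),
        cell_mu_n=float(neg_counts.mean()),
        cell_delta_n=float(neg_counts.std(ddof=1)),
    )


def controls_by_plate(measurements: pd.DataFrame, plate_map: pd.DataFrame) -> dict[str, ControlStats]:
    """Per-plate control statistics (controls are not pooled across plates)."""
    out: dict[str, ControlStats] = {}
    for plate_id in plate_map["plate_id"].drop_duplicates():
        out[str(plate_id)] = control_stats(
            measurements[measurements["plate_id"] == plate_id],
            plate_map[plate_map["plate_id"] == plate_id],
        )
    return out


def _check_window(controls: ControlStats) -> float:
    window = controls.mu_p - controls.mu_n
    if window == 0:
        raise DegenerateControlsError("positive and negative control means coincide")
    return window


def percent_activity(x, controls: ControlStats):
    """100 * (x - mu_n) / (mu_p - mu_n); unclamped, vectorised over ``x``."""
    window = _check_window(controls)
    result = 100.0 * (np.asarray(x, dtype=float) - controls.mu_n) / window
    return float(result) if result.ndim == 0 else result


def z_prime(controls: ControlStats) -> float:
    window = _check_window(controls)
    return 1.0 - 3.0 * (controls.delta_p + controls.delta_n) / abs(window)


def plate_qc(controls: ControlStats, z_min: float = 0.4, plate_id: str = "") -> PlateQC:
    """Pass iff Z' >= z_min."""
    z = z_prime(controls)
    return PlateQC(plate_id=plate_id, z_prime=z, passed=z >= z_min, z_min=z_min, controls=controls)


def activity_table(
    measurements: pd.DataFrame,
    plate_map: pd.DataFrame,
    controls: Union[ControlStats, dict],
) -> pd.DataFrame:
    """Percent activity of every extract well.

    ``controls`` may be a single :class:`ControlStats` or a per-plate dict as
    returned by :func:`controls_by_plate`.  Wells with missing GFP get NaN
    activity and ``gfp_missing=True``.
    """
    df = _merged(measurements, plate_map)
    df = df[df["role"] == "EXTRACT"].copy()
    activities = np.full(len(df), np.nan)
    for i, row in enumerate(df.itertuples(index=False)):
        stats = controls[row.plate_id] if isinstance(controls, dict) else controls
        if pd.notna(row.avg_gfp):
            activities[i] = percent_activity(row.avg_gfp, stats)
    df["percent_activity"] = activities
    df["gfp_missing"] = df["avg_gfp"].isna()
    cols = ["plate_id", "well", "extract_id", "percent_activity", "cell_count", "gfp_missing"]
    return df[cols].reset_index(drop=True)
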