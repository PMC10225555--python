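"""Dual-criterion hit calling: activity above threshold AND viable cell counts.

A well is a hit iff its percent activity strictly exceeds the threshold, its
cell count lies inside the negative-control viability band, and its GFP
readout is present.  Boundary counts (exactly at the floor or ceiling) are
kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .plate_stats import ActivityResult, ControlStats

__all__ = [
    "ViabilityBand",
    "HitCall",
    "ScreenReport",
    "viability_band",
    "call_hits",
    "hit_table",
    "screen_report",
]

FAIL_LOW_ACTIVITY = "LOW_ACTIVITY"
FAIL_CYTOTOXIC = "CYTOTOXIC"
FAIL_HIGH_COUNT = "HIGH_COUNT"
FAIL_MISSING_GFP = "MISSING_GFP"


@dataclass(frozen=True)
class ViabilityBand:
    """Acceptable cell-count range around the negative-control mean."""

    floor: float
    ceiling: Optional[float]
    k: float
    sided: str

    def contains(self, cell_count: float) -> bool:
        if cell_count < self.floor:
            return False
        return self.ceiling is None or cell_count <= self.ceiling


def viability_band(controls: ControlStats, k: float = 1.0, sided: str = "both") -> ViabilityBand:
    """Band [cell_mu_n - k*sd, cell_mu_n + k*sd]; lower-only drops the ceiling."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if sided not in ("lower", "both"):
        raise ValueError(f"sided must be 'lower' or 'both', got {sided!r}")
    floor = controls.cell_mu_n - k * controls.cell_delta_n
    ceiling = controls.cell_mu_n + k * controls.cell_delta_n if sided == "both" else None
    return ViabilityBand(floor=floor, ceiling=ceiling, k=k, sided=sided)


@dataclass(frozen=True)
class HitCall:
    extract_id: str
    well: str
    is_hit: bool
    percent_activity: Optional[float]
    cell_count: int
    fail_reasons: frozenset[str]
    plate_id: str = ""


def call_hits(
    activities: Iterable[ActivityResult],
    band: ViabilityBand,
    activity_threshold: float = 40.0,
) -> list[HitCall]:
    """Apply the dual criterion to each activity result, preserving order.

    ``is_hit`` iff percent_activity > activity_threshold (strict) and the
    cell count lies in the band and the GFP readout is present; otherwise all
    applicable fail reasons are recorded.
    """
    calls = []
    for a in activities:
        reasons = set()
        if a.gfp_missing or a.percent_activity is None or np.isnan(a.percent_activity):
            reasons.add(FAIL_MISSING_GFP)
        elif not a.percent_activity > activity_threshold:
            reasons.add(FAIL_LOW_ACTIVITY)
        if a.cell_count < band.floor:
            reasons.add(FAIL_CYTOTOXIC)
        elif band.ceiling is not None and a.cell_count > band.ceiling:
            reasons.add(FAIL_HIGH_COUNT)
        activity = None
        if a.percent_activity is not None and not np.isnan(a.percent_activity):
            activity = float(a.percent_activity)
        calls.append(
            HitCall(
                extract_id=a.extract_id,
                well=a.well,
                is_hit=not reasons,
                percent_activity=activity,
                cell_count=a.cell_count,
                fail_reasons=frozenset(reasons),
                plate_id=a.plate_id,
            )
        )
    return calls


def activities_from_frame(df: pd.DataFrame) -> list[ActivityResult]:
    """Adapter from an activity table (see plate_stats.activity_table)."""
    out = []
    for row in df.itertuples(index=False):
        missing = bool(getattr(row, "gfp_missing", pd.isna(row.percent_activity)))
        out.append(
            ActivityResult(
                extract_id=str(row.extract_id),
                well=str(row.well),
                percent_activity=None if pd.isna(row.percent_activity) else float(row.percent_activity),
                cell_count=int(row.cell_count),
                gfp_missing=missing,
                plate_id=str(getattr(row, "plate_id", "")),
            )
        )
    return out


def hit_table(calls: Sequence[HitCall]) -> pd.DataFrame:
    """Tidy frame of hit calls; fail reasons joined with '|' for CSV round-trips."""
    return pd.DataFrame(
        [
            {
                "plate_id": c.plate_id,
                "well": c.well,
                "extract_id": c.extract_id,
                "cell_count": c.cell_count,
                "percent_activity": np.nan if c.percent_activity is None else c.percent_activity,
                "is_hit": c.is_hit,
                "fail_reasons": "|".join(sorted(c.fail_reasons)),
            }
            for c in calls
        ],
        columns=[
            "plate_id", "well", "extract_id", "cell_count",
            "percent_activity", "is_hit", "fail_reasons",
        ],
    )


@dataclass(frozen=True)
class ScreenReport:
    """Primary-screen summary: hit listing plus truth-based confusion counts."""

    hits: pd.DataFrame
    all_calls: pd.DataFrame
    decoys: pd.DataFrame
    confusion: Optional[dict]

    @property
    def n_hits(self) -> int:
        return len(self.hits)


def screen_report(
    calls: Sequence[HitCall],
    truth=None,
    activity_threshold: float = 40.0,
) -> ScreenReport:
    """Tabulate hits; with planted ground truth, count TP/FP/FN/TN.

    The decoy section lists wells whose activity cleared the threshold (or was
    withheld) but that failed viability — extracts suppressed by cytotoxicity.
    """
    table = hit_table(calls)
    hits = table[table["is_hit"]].reset_index(drop=True)
    toxic_fail = table["fail_reasons"].str.contains(FAIL_CYTOTOXIC, regex=False)
    cleared = table["percent_activity"] > activity_threshold
    withheld = table["fail_reasons"].str.contains(FAIL_MISSING_GFP, regex=False)
    decoys = table[~table["is_hit"] & toxic_fail & (cleared | withheld)].reset_index(drop=True)

    confusion = None
    if truth is not None:
        true_ids = set(truth.true_hits(activity_threshold))
        called_ids = set(hits["extract_id"])
        all_ids = {c.extract_id for c in calls}
        tp = len(called_ids & true_ids)
        fp = len(called_ids - true_ids)
        fn = len(true_ids & all_ids - called_ids)
        tn = len(all_ids - called_ids - true_ids)
        confusion = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
    return ScreenReport(hits=hits, all_calls=table, decoys=decoys, confusion=confusion)
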