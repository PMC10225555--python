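"""Seeded generators for every input the screen pipeline consumes.

Everything here produces data with planted ground truth: plate maps and
per-well measurement tables for a primary screen, two-channel field images
with known cell placements, serial-dilution responses driven by a known 4PL,
flow-cytometry-like event samples, and qPCR Ct quadruples.  All randomness
flows from explicit integer seeds via ``numpy.random.default_rng``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dose_response import four_param_logistic
from .errors import LayoutError, PlacementError

__all__ = [
    "ScreenScenario",
    "PlateLayout",
    "GroundTruthEntry",
    "GroundTruth",
    "FieldImageSpec",
    "FieldImage",
    "PlantedCell",
    "CtQuadruple",
    "SimulatedScreen",
    "simulate_screen",
    "render_field",
    "write_field_tiffs",
    "field_tiff_paths",
    "simulate_dose_series",
    "simulate_flow",
    "simulate_qpcr",
    "apply_reporting_floor",
]

PRIMARY_SCREEN_CONC_MG_PER_ML = 0.175


@dataclass(frozen=True)
class PlateLayout:
    """96-well plate geometry with configurable control columns."""

    rows: str = "ABCDEFGH"
    n_cols: int = 12
    neg_columns: tuple[int, ...] = (1,)
    pos_columns: tuple[int, ...] = (12,)
    max_plates: Optional[int] = None

    def __post_init__(self):
        cols = set(range(1, self.n_cols + 1))
        if not set(self.neg_columns) <= cols or not set(self.pos_columns) <= cols:
            raise LayoutError("control columns fall outside the plate")
        if set(self.neg_columns) & set(self.pos_columns):
            raise LayoutError("a column cannot hold both control roles")

    @property
    def extract_wells_per_plate(self) -> int:
        n_control_cols = len(self.neg_columns) + len(self.pos_columns)
        return len(self.rows) * (self.n_cols - n_control_cols)

    def wells(self):
        """Yield (well_name, role) in row-major order for one plate."""
        for row in self.rows:
            for col in range(1, self.n_cols + 1):
                if col in self.neg_columns:
                    role = "NEG"
                elif col in self.pos_columns:
                    role = "POS"
                else:
                    role = "EXTRACT"
                yield f"{row}{col}", role


@dataclass(frozen=True)
class ScreenScenario:
    """Generative description of a primary screen with planted ground truth.

    ``hit_effect`` is on the percent-activity scale anchored by
    ``(neg_mean, pos_mean)``; a scalar applies to every planted hit, a
    sequence gives one value per hit.  ``hit_cell_sd_factor`` shrinks the
    cell-count jitter of planted hit wells so that "well-separated" hits stay
    inside the viability band of the negative controls (set to 1 for fully
    realistic counts).
    """

    n_extracts: int = 480
    n_true_hits: int = 7
    hit_effect: float | tuple[float, ...] = 55.0
    n_cytotoxic: int = 20
    cytotoxic_kill_fraction: float = 0.7
    neg_mean: float = 200.0
    neg_sd: float = 15.0
    pos_mean: float = 1000.0
    pos_sd: float = 25.0
    cells_per_well_mean: float = 3500.0
    cells_per_well_sd: float = 250.0
    extract_sd: float = 15.0
    hit_cell_sd_factor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_extracts < 0 or self.n_true_hits < 0 or self.n_cytotoxic < 0:
            raise ValueError("counts must be non-negative")
        if self.n_true_hits + self.n_cytotoxic > self.n_extracts:
            raise ValueError("n_true_hits + n_cytotoxic exceeds n_extracts")
        if self.pos_mean < self.neg_mean:
            raise ValueError("pos_mean must be >= neg_mean")
        for name in ("neg_sd", "pos_sd", "extract_sd", "cells_per_well_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.cytotoxic_kill_fraction <= 1.0:
            raise ValueError("cytotoxic_kill_fraction must lie in [0, 1]")
        if not 0.0 <= self.hit_cell_sd_factor:
            raise ValueError("hit_cell_sd_factor must be >= 0")
        effects = self.hit_effects()
        if len(effects) != self.n_true_hits:
            raise ValueError("hit_effect sequence length must equal n_true_hits")
        if any(e <= 40.0 for e in effects):
            raise ValueError("planted hit effects must exceed 40 percent activity")
        if isinstance(self.hit_effect, (list, np.ndarray)):
            object.__setattr__(self, "hit_effect", tuple(float(e) for e in self.hit_effect))

    def hit_effects(self) -> tuple[float, ...]:
        if isinstance(self.hit_effect, (int, float)):
            return tuple(float(self.hit_effect) for _ in range(self.n_true_hits))
        return tuple(float(e) for e in self.hit_effect)

    def to_json(self) -> str:
        d = self.__dict__.copy()
        if isinstance(d["hit_effect"], tuple):
            d["hit_effect"] = list(d["hit_effect"])
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScreenScenario":
        d = json.loads(text)
        if isinstance(d.get("hit_effect"), list):
            d["hit_effect"] = tuple(d["hit_effect"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruthEntry:
    extract_id: str
    true_activity: float
    is_cytotoxic: bool
    true_ec50: Optional[float] = None
    true_hill: Optional[float] = None


class GroundTruth(Mapping[str, GroundTruthEntry]):
    """Planted per-extract truth; the oracle for every simulation-based test."""

    def __init__(self, entries: Sequence[GroundTruthEntry] = ()):
        self._entries = {e.extract_id: e for e in entries}

    def __getitem__(self, key: str) -> GroundTruthEntry:
        return self._entries[key]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def true_hits(self, activity_threshold: float = 40.0) -> list[str]:
        """Extracts planted active (above threshold) and not cytotoxic."""
        return [
            e.extract_id
            for e in self._entries.values()
            if e.true_activity > activity_threshold and not e.is_cytotoxic
        ]

    def cytotoxic(self) -> list[str]:
        return [e.extract_id for e in self._entries.values() if e.is_cytotoxic]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "extract_id": e.extract_id,
                    "true_activity": e.true_activity,
                    "is_cytotoxic": e.is_cytotoxic,
                    "true_ec50": e.true_ec50,
                    "true_hill": e.true_hill,
                }
                for e in self._entries.values()
            ],
            columns=["extract_id", "true_activity", "is_cytotoxic", "true_ec50", "true_hill"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruth":
        entries = []
        for row in df.itertuples(index=False):
            ec50 = getattr(row, "true_ec50", None)
            hill = getattr(row, "true_hill", None)
            entries.append(
                GroundTruthEntry(
                    extract_id=str(row.extract_id),
                    true_activity=float(row.true_activity),
                    is_cytotoxic=bool(row.is_cytotoxic),
                    true_ec50=None if ec50 is None or pd.isna(ec50) else float(ec50),
                    true_hill=None if hill is None or pd.isna(hill) else float(hill),
                )
            )
        return cls(entries)


@dataclass(frozen=True)
class SimulatedScreen:
    plate_map: pd.DataFrame
    measurements: pd.DataFrame
    truth: GroundTruth

    def __iter__(self):  # tuple-unpacking convenience
        return iter((self.plate_map, self.measurements, self.truth))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One Normal draw clipped at zero (well-average intensities cannot be negative)."""
    return max(0.0, float(rng.normal(mean, sd)))


def simulate_screen(
    scenario: ScreenScenario,
    layout: PlateLayout | None = None,
    reporting_floor_fraction: float = 0.25,
) -> SimulatedScreen:
    """Simulate a primary screen: plate map, per-well measurements, ground truth.

    Extract wells draw their well-average GFP from a Normal centred at
    ``neg_mean + true_activity/100 * (pos_mean - neg_mean)`` so that the
    expected percent activity equals the planted value.  Cytotoxic extracts
    have their cell count multiplied by ``1 - cytotoxic_kill_fraction``.
    Wells whose count falls below ``reporting_floor_fraction *
    cells_per_well_mean`` get a missing (NaN) GFP value, mirroring
    instruments that withhold intensity in highly cytotoxic wells; pass 0 to
    disable.
    """
    layout = layout or PlateLayout()
    if scenario.n_extracts > 0 and layout.extract_wells_per_plate == 0:
        raise LayoutError("layout has no extract wells but extracts were requested")
    n_plates = (
        1
        if scenario.n_extracts == 0
        else -(-scenario.n_extracts // layout.extract_wells_per_plate)
    )
    if layout.max_plates is not None and n_plates > layout.max_plates:
        raise LayoutError(
            f"{scenario.n_extracts} extracts need {n_plates} plates, "
            f"but layout allows {layout.max_plates}"
        )

    rng = np.random.default_rng(scenario.seed)
    id_width = max(4, len(str(scenario.n_extracts)))
    extract_ids = [f"EXT{i + 1:0{id_width}d}" for i in range(scenario.n_extracts)]

    n_special = scenario.n_true_hits + scenario.n_cytotoxic
    special = (
        rng.choice(scenario.n_extracts, size=n_special, replace=False)
        if n_special
        else np.array([], dtype=int)
    )
    hit_idx = set(special[: scenario.n_true_hits].tolist())
    tox_idx = set(special[scenario.n_true_hits :].tolist())
    effects = dict(zip(sorted(hit_idx), scenario.hit_effects()))

    truth_entries = [
        GroundTruthEntry(
            extract_id=extract_ids[i],
            true_activity=effects.get(i, 0.0),
            is_cytotoxic=i in tox_idx,
        )
        for i in range(scenario.n_extracts)
    ]
    truth = GroundTruth(truth_entries)

    window = scenario.pos_mean - scenario.neg_mean
    floor = reporting_floor_fraction * scenario.cells_per_well_mean

    map_rows, meas_rows = [], []
    extract_cursor = 0
    for plate_i in range(n_plates):
        plate_id = f"PLATE{plate_i + 1:02d}"
        for well, role in layout.wells():
            extract_id = ""
            conc = np.nan
            if role == "EXTRACT":
                if extract_cursor >= scenario.n_extracts:
                    role = "EMPTY"
                else:
                    idx = extract_cursor
                    extract_id = extract_ids[idx]
                    conc = PRIMARY_SCREEN_CONC_MG_PER_ML
                    extract_cursor += 1
            map_rows.append(
                {
                    "plate_id": plate_id,
                    "well": well,
                    "role": role,
                    "extract_id": extract_id,
                    "concentration_mg_per_ml": conc,
                }
            )
            if role == "EMPTY":
                continue

            if role == "NEG":
                gfp_mean, gfp_sd = scenario.neg_mean, scenario.neg_sd
                count_sd = scenario.cells_per_well_sd
                kill = 0.0
            elif role == "POS":
                gfp_mean, gfp_sd = scenario.pos_mean, scenario.pos_sd
                count_sd = scenario.cells_per_well_sd
                kill = 0.0
            else:
                entry = truth[extract_id]
                gfp_mean = scenario.neg_mean + entry.true_activity / 100.0 * window
                gfp_sd = scenario.extract_sd
                is_hit = entry.true_activity > 0.0
                count_sd = scenario.cells_per_well_sd * (
                    scenario.hit_cell_sd_factor if is_hit else 1.0
                )
                kill = scenario.cytotoxic_kill_fraction if entry.is_cytotoxic else 0.0

            count = rng.normal(scenario.cells_per_well_mean, count_sd) * (1.0 - kill)
            count = max(0, int(round(count)))
            avg_gfp = _truncated_normal(rng, gfp_mean, gfp_sd)
            if count < floor:
                avg_gfp = np.nan
            meas_rows.append(
                {
                    "plate_id": plate_id,
                    "well": well,
                    "cell_count": count,
                    "avg_gfp": avg_gfp,
                    "n_fields": 12,
                }
            )

    plate_map = pd.DataFrame(
        map_rows,
        columns=["plate_id", "well", "role", "extract_id", "concentration_mg_per_ml"],
    )
    measurements = pd.DataFrame(
        meas_rows, columns=["plate_id", "well", "cell_count", "avg_gfp", "n_fields"]
    )
    return SimulatedScreen(plate_map=plate_map, measurements=measurements, truth=truth)


def apply_reporting_floor(
    measurements: pd.DataFrame, floor_cells: float
) -> pd.DataFrame:
    """Blank avg_gfp in wells whose cell count falls below ``floor_cells``."""
    out = measurements.copy()
    out.loc[out["cell_count"] < floor_cells, "avg_gfp"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Field-image phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldImageSpec:
    """Geometric phantom for one microscope field.

    The DNA channel holds disk nuclei of ``nucleus_radius_px``; the GFP
    channel holds a cytoplasmic band of constant mean around each nucleus.
    The band is rendered from ``nucleus_radius - inner_pad_px`` out to
    ``nucleus_radius + ring_width_px + outer_pad_px`` so that a measurement
    ring of ``ring_width_px`` built on a segmented nucleus (whose boundary may
    differ from the drawn disk by a pixel) still samples only cytoplasm.
    Cell centres are placed at least ``2 * (nucleus_radius + ring_width +
    outer_pad)`` apart, so planted counts are unambiguous.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 50
    nucleus_radius_px: int = 5
    ring_width_px: int = 5
    cytoplasm_gfp_mean: float = 300.0
    noise_sd: float = 0.0
    dna_mean: float = 4000.0
    background: float = 100.0
    inner_pad_px: int = 1
    outer_pad_px: int = 2
    seed: int = 0
    max_placement_tries: int = 20000

    def __post_init__(self):
        if len(self.image_shape) != 2 or min(self.image_shape) < 1:
            raise ValueError("image_shape must be a positive (rows, cols) pair")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.nucleus_radius_px < 1 or self.ring_width_px < 0:
            raise ValueError("nucleus_radius_px >= 1 and ring_width_px >= 0 required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for v in (self.cytoplasm_gfp_mean, self.dna_mean, self.background):
            if not 0 <= v <= 65535:
                raise ValueError("intensities must fit the unsigned 16-bit range")

    @property
    def outer_radius_px(self) -> int:
        return self.nucleus_radius_px + self.ring_width_px + self.outer_pad_px

    @property
    def min_center_distance_px(self) -> int:
        return 2 * self.outer_radius_px


@dataclass(frozen=True)
class PlantedCell:
    centroid: tuple[int, int]
    true_mean_gfp: float


@dataclass(frozen=True)
class FieldImage:
    dna: np.ndarray
    gfp: np.ndarray
    cells: tuple[PlantedCell, ...]
    spec: FieldImageSpec

    def cytoplasm_band_mask(self, cell: PlantedCell) -> np.ndarray:
        """Boolean mask of the rendered cytoplasm band of one planted cell."""
        spec = self.spec
        yy, xx = np.ogrid[: self.dna.shape[0], : self.dna.shape[1]]
        d2 = (yy - cell.centroid[0]) ** 2 + (xx - cell.centroid[1]) ** 2
        inner = max(0, spec.nucleus_radius_px - spec.inner_pad_px)
        return (d2 > inner**2) & (d2 <= spec.outer_radius_px**2)


def _place_centers(spec: FieldImageSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    margin = spec.outer_radius_px + 1
    n_rows, n_cols = spec.image_shape
    if spec.n_cells == 0:
        return []
    if n_rows - 2 * margin < 0 or n_cols - 2 * margin < 0:
        raise PlacementError("image too small for a single cell at this geometry")
    centers: list[tuple[int, int]] = []
    min_d2 = spec.min_center_distance_px**2
    tries = 0
    while len(centers) < spec.n_cells:
        if tries >= spec.max_placement_tries:
            raise PlacementError(
                f"placed {len(centers)}/{spec.n_cells} cells "
                f"in {tries} tries; relax spacing or enlarge the field"
            )
        tries += 1
        r = int(rng.integers(margin, n_rows - margin))
        c = int(rng.integers(margin, n_cols - margin))
        if all((r - cr) ** 2 + (c - cc) ** 2 >= min_d2 for cr, cc in centers):
            centers.append((r, c))
    return centers


def render_field(spec: FieldImageSpec) -> FieldImage:
    """Render a two-channel uint16 phantom field with planted cell records."""
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)

    n_rows, n_cols = spec.image_shape
    dna = np.full((n_rows, n_cols), spec.background, dtype=float)
    gfp = np.full((n_rows, n_cols), spec.background, dtype=float)
    r_nuc = spec.nucleus_radius_px
    inner = max(0, r_nuc - spec.inner_pad_px)
    outer = spec.outer_radius_px
    for cr, cc in centers:
        y0, y1 = cr - outer, cr + outer + 1
        x0, x1 = cc - outer, cc + outer + 1
        yy, xx = np.ogrid[y0:y1, x0:x1]
        d2 = (yy - cr) ** 2 + (xx - cc) ** 2
        dna[y0:y1, x0:x1][d2 <= r_nuc**2] = spec.dna_mean
        gfp[y0:y1, x0:x1][(d2 > inner**2) & (d2 <= outer**2)] = spec.cytoplasm_gfp_mean

    if spec.noise_sd > 0:
        dna += rng.normal(0.0, spec.noise_sd, size=dna.shape)
        gfp += rng.normal(0.0, spec.noise_sd, size=gfp.shape)
    dna = np.clip(np.rint(dna), 0, 65535).astype(np.uint16)
    gfp = np.clip(np.rint(gfp), 0, 65535).astype(np.uint16)

    cells = tuple(
        PlantedCell(centroid=(cr, cc), true_mean_gfp=spec.cytoplasm_gfp_mean)
        for cr, cc in centers
    )
    return FieldImage(dna=dna, gfp=gfp, cells=cells, spec=spec)


def field_tiff_paths(directory, plate_id: str, well: str, field: int) -> dict[str, str]:
    """Filenames follow {plate}_{well}_f{field}_{channel}.tif."""
    import os

    return {
        channel: os.path.join(directory, f"{plate_id}_{well}_f{field}_{channel}.tif")
        for channel in ("dna", "gfp")
    }


def write_field_tiffs(image: FieldImage, directory, plate_id: str, well: str, field: int) -> dict[str, str]:
    import tifffile

    paths = field_tiff_paths(directory, plate_id, well, field)
    tifffile.imwrite(paths["dna"], image.dna)
    tifffile.imwrite(paths["gfp"], image.gfp)
    return paths


# ---------------------------------------------------------------------------
# Dose series, flow events, qPCR
# ---------------------------------------------------------------------------

def simulate_dose_series(
    true_fit: Sequence[float],
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    cytotoxic_above: Optional[float] = None,
    seed: int = 0,
    cell_count_mean: float = 3500.0,
    cell_count_sd: float = 50.0,
    kill_fraction: float = 0.7,
) -> pd.DataFrame:
    """Per-dilution (activity, cell_count) rows from a known 4PL.

    ``true_fit`` is (bottom, top, ec50, hill).  Dilutions above
    ``cytotoxic_above`` get depressed cell counts and a missing activity.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0 or np.any(conc <= 0):
        raise ValueError("concentrations must be positive and non-empty")
    if np.any(np.diff(conc) >= 0):
        raise ValueError("concentrations must be strictly decreasing")
    bottom, top, ec50, hill = (float(v) for v in true_fit)
    rng = np.random.default_rng(seed)

    rows = []
    for c in conc:
        toxic = cytotoxic_above is not None and c > cytotoxic_above
        count = rng.normal(cell_count_mean, cell_count_sd)
        if toxic:
            count *= 1.0 - kill_fraction
        count = max(0, int(round(count)))
        if toxic:
            activity = np.nan
        else:
            activity = four_param_logistic(c, bottom, top, ec50, hill)
            if noise_sd > 0:
                activity += rng.normal(0.0, noise_sd)
        rows.append({"concentration": c, "activity": activity, "cell_count": count})
    return pd.DataFrame(rows, columns=["concentration", "activity", "cell_count"])


def simulate_flow(n_events: int, mean: float, sd: float, seed: int = 0) -> np.ndarray:
    """Flow-cytometry-like event intensities: ``n_events`` Normal draws."""
    if n_events < 1:
        raise ValueError(f"n_events must be >= 1, got {n_events}")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return np.full(n_events, float(mean))
    return rng.normal(mean, sd, size=n_events)


@dataclass(frozen=True)
class CtQuadruple:
    """Ct values for target/housekeeping genes under treated/reference conditions."""

    ct_target_treated: float
    ct_hk_treated: float
    ct_target_ref: float
    ct_hk_ref: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (
            self.ct_target_treated,
            self.ct_hk_treated,
            self.ct_target_ref,
            self.ct_hk_ref,
        )


def simulate_qpcr(
    true_rq: float,
    ct_housekeeping: float = 20.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    target_offset: float = 3.0,
) -> CtQuadruple:
    """Ct quadruple whose noiseless double-delta equals -log2(true_rq) exactly.

    ``target_offset`` is the reference-condition Ct gap between target and
    housekeeping genes; it cancels in the double delta.
    """
    if true_rq <= 0:
        raise ValueError(f"true_rq must be > 0, got {true_rq}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    ct_hk = float(ct_housekeeping)
    ct_target_ref = ct_hk + target_offset
    ct_target_treated = ct_target_ref - float(np.log2(true_rq))
    cts = np.array([ct_target_treated, ct_hk, ct_target_ref, ct_hk])
    if noise_sd > 0:
        cts = cts + rng.normal(0.0, noise_sd, size=4)
    return CtQuadruple(*(float(v) for v in cts))
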