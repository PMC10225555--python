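"""Seeded end-to-end runs: simulate -> (render/quantify) -> normalize -> call hits -> validate.

Two entry modes share all downstream code: "table" starts from the simulated
per-well measurement table; "image" renders phantom fields per well (cell
counts scaled down to a renderable number) and re-derives the table through
the imaging module.  Every stochastic stage receives a child seed spawned
deterministically from the run seed, so identical configs give byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import imaging
from .dose_response import (
    DoseResponseFit,
    ValidationCall,
    classify_validated,
    fit_sigmoid,
    serial_dilution,
)
from .errors import PipelineStageError, ScreenError
from .hit_calling import (
    ScreenReport,
    activities_from_frame,
    call_hits,
    screen_report,
    viability_band,
)
from .plate_stats import activity_table, controls_by_plate, plate_qc
from .synthetic_data import (
    FieldImageSpec,
    GroundTruth,
    PlateLayout,
    ScreenScenario,
    apply_reporting_floor,
    render_field,
    simulate_dose_series,
    simulate_screen,
)

__all__ = [
    "ImagingParams",
    "RenderParams",
    "ValidationParams",
    "RunConfig",
    "ScreenRunResult",
    "ValidationRunResult",
    "run_screen_pipeline",
    "run_validation_pipeline",
]


@dataclass(frozen=True)
class ImagingParams:
    smoothing_sigma: float = 1.0
    min_area: int = 8
    ring_width_px: float = 3
    border_policy: str = "exclude"


@dataclass(frozen=True)
class RenderParams:
    """How image mode turns a well row into phantom fields.

    ``cells_scale`` maps simulated cell counts (thousands) to a renderable
    per-field number; all wells are scaled identically so viability logic is
    unaffected.
    """

    image_shape: tuple[int, int] = (192, 192)
    fields_per_well: int = 1
    cells_scale: float = 0.006
    nucleus_radius_px: int = 4
    dna_mean: float = 4000.0
    background: float = 100.0
    noise_sd: float = 5.0


@dataclass(frozen=True)
class ValidationParams:
    """Planted dose-response design for the validation stage."""

    start_mg_per_ml: float = 0.5
    dilution_factor: float = 3.0
    n_points: int = 7
    noise_sd: float = 1.0
    n_validated: int = 4
    active_top_range: tuple[float, float] = (48.0, 70.0)
    inactive_top_range: tuple[float, float] = (5.0, 30.0)
    ec50: float = 0.005
    hill: float = 2.0
    cytotoxic_above: Optional[float] = 0.1
    kill_fraction: float = 0.7
    cell_count_mean: float = 3500.0
    cell_count_sd: float = 50.0


@dataclass(frozen=True)
class RunConfig:
    scenario: ScreenScenario = field(default_factory=ScreenScenario)
    layout: PlateLayout = field(default_factory=PlateLayout)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    render: RenderParams = field(default_factory=RenderParams)
    validation: ValidationParams = field(default_factory=ValidationParams)
    mode: str = "table"
    activity_threshold: float = 40.0
    k: float = 1.0
    sided: str = "both"
    z_min: float = 0.4
    reporting_floor_fraction: float = 0.25
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.mode not in ("table", "image"):
            raise ValueError(f"mode must be 'table' or 'image', got {self.mode!r}")

    def to_json(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return json.dumps(encode(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)

        def tup(d, key):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])

        scenario = raw.pop("scenario", {})
        tup(scenario, "hit_effect")
        layout = raw.pop("layout", {})
        tup(layout, "neg_columns")
        tup(layout, "pos_columns")
        render = raw.pop("render", {})
        tup(render, "image_shape")
        validation = raw.pop("validation", {})
        tup(validation, "active_top_range")
        tup(validation, "inactive_top_range")
        imaging_params = raw.pop("imaging", {})
        return cls(
            scenario=ScreenScenario(**scenario),
            layout=PlateLayout(**layout),
            imaging=ImagingParams(**imaging_params),
            render=RenderParams(**render),
            validation=ValidationParams(**validation),
            **raw,
        )


@dataclass(frozen=True)
class ScreenRunResult:
    config: RunConfig
    plate_map: pd.DataFrame
    measurements: pd.DataFrame
    truth: GroundTruth
    qc: dict
    activities: pd.DataFrame
    report: ScreenReport
    log: list


@dataclass(frozen=True)
class ValidationRunResult:
    series: pd.DataFrame
    fits: dict[str, DoseResponseFit]
    calls: dict[str, ValidationCall]
    planted_active: list[str]
    summary: dict


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage label attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Ctx()


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def _render_measurements(
    plate_map: pd.DataFrame,
    raw_measurements: pd.DataFrame,
    config: RunConfig,
    seed: int,
) -> pd.DataFrame:
    """Image mode: re-derive the measurement table through phantom rendering."""
    rp, ip = config.render, config.imaging
    seeds = iter(_child_seeds(seed, len(raw_measurements) * rp.fields_per_well))
    rows = []
    for row in raw_measurements.itertuples(index=False):
        per_field = row.cell_count * rp.cells_scale / rp.fields_per_well
        gfp_mean = row.avg_gfp
        fields = []
        for _ in range(rp.fields_per_well):
            spec = FieldImageSpec(
                image_shape=rp.image_shape,
                n_cells=max(0, int(round(per_field))),
                nucleus_radius_px=rp.nucleus_radius_px,
                ring_width_px=int(round(ip.ring_width_px)),
                cytoplasm_gfp_mean=float(np.round(gfp_mean)),
                noise_sd=rp.noise_sd,
                dna_mean=rp.dna_mean,
                background=rp.background,
                seed=next(seeds),
            )
            image = render_field(spec)
            fields.append(
                imaging.process_field(
                    image.dna,
                    image.gfp,
                    smoothing_sigma=ip.smoothing_sigma,
                    min_area=ip.min_area,
                    border_policy=ip.border_policy,
                    ring_width_px=ip.ring_width_px,
                )
            )
        well = imaging.aggregate_well(fields, plate_id=row.plate_id, well=row.well)
        rows.append(well)
    return imaging.wells_to_frame(rows)


def run_screen_pipeline(config: RunConfig) -> ScreenRunResult:
    """Execute the primary screen end to end; see module docstring."""
    log: list[dict] = []
    sim_seed, render_seed = _child_seeds(config.seed, 2)

    with _stage("simulate"):
        scenario = replace(config.scenario, seed=sim_seed)
        # In image mode missingness is applied after quantification, against
        # the rendered negative-control counts.
        floor_frac = config.reporting_floor_fraction if config.mode == "table" else 0.0
        sim = simulate_screen(scenario, layout=config.layout, reporting_floor_fraction=floor_frac)
        plate_map, measurements = sim.plate_map, sim.measurements
        log.append({"stage": "simulate", "seed": sim_seed, "digest": _digest(measurements)})

    if config.mode == "image":
        with _stage("imaging"):
            measurements = _render_measurements(plate_map, measurements, config, render_seed)
            neg_wells = plate_map.loc[plate_map["role"] == "NEG", ["plate_id", "well"]]
            neg_counts = measurements.merge(neg_wells, on=["plate_id", "well"])["cell_count"]
            floor = config.reporting_floor_fraction * float(neg_counts.mean())
            measurements = apply_reporting_floor(measurements, floor)
            log.append({"stage": "imaging", "seed": render_seed, "digest": _digest(measurements)})

    with _stage("plate_stats"):
        controls = controls_by_plate(measurements, plate_map)
        qc = {
            plate: plate_qc(stats, z_min=config.z_min, plate_id=plate)
            for plate, stats in controls.items()
        }
        activities = activity_table(measurements, plate_map, controls)
        log.append({"stage": "plate_stats", "plates": len(controls)})

    with _stage("hit_calling"):
        calls = []
        for plate_id, stats in controls.items():
            band = viability_band(stats, k=config.k, sided=config.sided)
            plate_acts = activities_from_frame(activities[activities["plate_id"] == plate_id])
            calls.extend(call_hits(plate_acts, band, activity_threshold=config.activity_threshold))
        report = screen_report(calls, truth=sim.truth, activity_threshold=config.activity_threshold)
        log.append({"stage": "hit_calling", "n_hits": report.n_hits})

    result = ScreenRunResult(
        config=config,
        plate_map=plate_map,
        measurements=measurements,
        truth=sim.truth,
        qc=qc,
        activities=activities,
        report=report,
        log=log,
    )
    if config.out_dir:
        write_screen_outputs(result, config.out_dir)
    return result


def write_screen_outputs(result: ScreenRunResult, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    result.plate_map.to_csv(os.path.join(out_dir, "plate_map.csv"), index=False)
    result.measurements.to_csv(os.path.join(out_dir, "measurements.csv"), index=False)
    result.truth.to_frame().to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
    result.activities.to_csv(os.path.join(out_dir, "activity.csv"), index=False)
    result.report.all_calls.to_csv(os.path.join(out_dir, "calls.csv"), index=False)
    result.report.hits.to_csv(os.path.join(out_dir, "hits.csv"), index=False)
    qc = {plate: q.as_dict() for plate, q in result.qc.items()}
    with open(os.path.join(out_dir, "qc.json"), "w") as fh:
        json.dump(qc, fh, sort_keys=True, indent=2)
    report = {
        "n_hits": result.report.n_hits,
        "hit_extracts": sorted(result.report.hits["extract_id"].tolist()),
        "confusion": result.report.confusion,
        "z_prime": {plate: q.z_prime for plate, q in sorted(result.qc.items())},
    }
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
    with open(os.path.join(out_dir, "log.jsonl"), "w") as fh:
        for entry in result.log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def run_validation_pipeline(
    config: RunConfig,
    hit_extracts: Sequence[str],
) -> ValidationRunResult:
    """Serial-dilution validation of the given hit extracts.

    The first ``validation.n_validated`` hits (in the given order) are planted
    with supra-threshold 4PL plateaus reachable at non-cytotoxic dilutions;
    the rest get marginal plateaus.  Each series is fitted and classified with
    the lower-sided viability rule.
    """
    vp = config.validation
    hit_extracts = list(hit_extracts)
    if not hit_extracts:
        return ValidationRunResult(
            series=pd.DataFrame(columns=["extract_id", "concentration", "activity", "cell_count"]),
            fits={},
            calls={},
            planted_active=[],
            summary={"n_extracts": 0, "n_validated": 0},
        )

    series_def = serial_dilution(vp.start_mg_per_ml, vp.dilution_factor, vp.n_points)
    seeds = _child_seeds(hash_seed(config.seed, "validation"), len(hit_extracts) + 1)
    rng = np.random.default_rng(seeds[-1])

    # Viability band from simulated DMSO control wells of the validation run.
    control_counts = rng.normal(vp.cell_count_mean, 250.0, size=16)
    cell_mu = float(control_counts.mean())
    cell_sd = float(control_counts.std(ddof=1))
    band = _validation_band(cell_mu, cell_sd, k=config.k)

    planted_active = hit_extracts[: vp.n_validated]
    frames, fits, calls = [], {}, {}
    for extract_id, seed in zip(hit_extracts, seeds):
        active = extract_id in planted_active
        lo, hi = vp.active_top_range if active else vp.inactive_top_range
        top = float(rng.uniform(lo, hi))
        points = simulate_dose_series(
            (0.0, top, vp.ec50, vp.hill),
            series_def.concentrations,
            noise_sd=vp.noise_sd,
            cytotoxic_above=vp.cytotoxic_above,
            seed=seed,
            cell_count_mean=vp.cell_count_mean,
            cell_count_sd=vp.cell_count_sd,
            kill_fraction=vp.kill_fraction,
        )
        frames.append(points.assign(extract_id=extract_id))
        try:
            fits[extract_id] = fit_sigmoid(series_def.as_array(), points["activity"].to_numpy())
        except ScreenError as err:
            fits[extract_id] = DoseResponseFit(
                bottom=np.nan, top=np.nan, ec50=np.nan, hill=np.nan,
                converged=False, rss=np.nan, n_points=0, message=str(err),
            )
        calls[extract_id] = classify_validated(points, band, config.activity_threshold)

    series = pd.concat(frames, ignore_index=True)[
        ["extract_id", "concentration", "activity", "cell_count"]
    ]
    n_validated = sum(1 for c in calls.values() if c.is_active)
    summary = {
        "n_extracts": len(hit_extracts),
        "n_validated": n_validated,
        "validated_extracts": sorted(e for e, c in calls.items() if c.is_active),
        "planted_active": sorted(planted_active),
        "band_floor": band.floor,
    }
    return ValidationRunResult(
        series=series, fits=fits, calls=calls, planted_active=planted_active, summary=summary
    )


def _validation_band(cell_mu: float, cell_sd: float, k: float):
    from .hit_calling import ViabilityBand

    return ViabilityBand(floor=cell_mu - k * cell_sd, ceiling=None, k=k, sided="lower")


def hash_seed(seed: int, label: str) -> int:
    """Deterministic child seed for a named sub-stream."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**63)
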