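"""Per-cell reporter quantification from two-channel field images.

Workflow: segment nuclei on the DNA channel (Gaussian smoothing + Otsu),
grow a fixed-width cytoplasmic ring around each nucleus (exact Euclidean
dilation, contested pixels to the nearest nucleus centre), measure the mean
GFP per cell inside its ring, and aggregate fields into per-well
measurements.
"""

from __future__ import annotations

import glob
import math
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import clear_border, relabel_sequential

__all__ = [
    "CellRecord",
    "WellMeasurement",
    "segment_nuclei",
    "cytoplasmic_masks",
    "quantify_cells",
    "aggregate_well",
    "process_field",
    "quantify_well_images",
    "cells_to_frame",
    "wells_to_frame",
]


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: nucleus geometry plus cytoplasmic GFP."""

    label: int
    centroid: tuple[float, float]
    nuclear_area: int
    cytoplasm_area: int
    mean_gfp: float


@dataclass(frozen=True)
class WellMeasurement:
    """Field-aggregated readout for one well.

    ``avg_gfp`` is the unweighted mean over cells of per-cell mean GFP
    (intensity per cell per pixel); it is None when the well has no cells or
    was flagged unreported.
    """

    plate_id: str
    well: str
    cell_count: int
    avg_gfp: Optional[float]
    n_fields: int


def _check_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    return arr


def segment_nuclei(
    dna_channel: np.ndarray,
    smoothing_sigma: float = 1.0,
    min_area: int = 20,
    border_policy: str = "exclude",
) -> np.ndarray:
    """Label nuclei in the DNA channel.

    Gaussian smoothing followed by Otsu thresholding; connected components
    below ``min_area`` pixels are dropped, components touching the image
    border are dropped when ``border_policy == "exclude"``.  Returned labels
    are consecutive positive integers; a uniform image yields zero labels.
    """
    arr = _check_image(dna_channel).astype(float)
    if border_policy not in ("exclude", "include"):
        raise ValueError(f"unknown border_policy {border_policy!r}")
    if np.ptp(arr) == 0.0:
        return np.zeros(arr.shape, dtype=np.int32)
    smoothed = gaussian(arr, sigma=smoothing_sigma, preserve_range=True) if smoothing_sigma > 0 else arr
    mask = smoothed > threshold_otsu(smoothed)
    labels = sk_label(mask)
    if border_policy == "exclude":
        labels = clear_border(labels)
    if min_area > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area)
        labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def cytoplasmic_masks(nucleus_labels: np.ndarray, ring_width_px: float = 5) -> np.ndarray:
    """Grow a cytoplasmic ring of Euclidean width ``ring_width_px`` per nucleus.

    A pixel belongs to cell i's ring iff its distance to nucleus i's region is
    in (0, ring_width] and it is not nuclear; pixels reachable from several
    nuclei go to the nucleus with the nearest centroid (ties to the smaller
    label).  Rings of distinct cells are therefore pairwise disjoint.
    """
    labels = np.asarray(nucleus_labels)
    if labels.ndim != 2:
        raise ValueError("nucleus_labels must be 2-D")
    if ring_width_px < 0:
        raise ValueError(f"ring_width_px must be >= 0, got {ring_width_px}")
    out = np.zeros(labels.shape, dtype=np.int32)
    if ring_width_px == 0 or labels.max() == 0:
        return out

    nuclear = labels > 0
    best_dist = np.full(labels.shape, np.inf)
    pad = int(math.ceil(ring_width_px)) + 1
    n_rows, n_cols = labels.shape
    for region in regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        r0, c0 = max(0, r0 - pad), max(0, c0 - pad)
        r1, c1 = min(n_rows, r1 + pad), min(n_cols, c1 + pad)
        window = (slice(r0, r1), slice(c0, c1))
        own = labels[window] == region.label
        dist_to_nucleus = distance_transform_edt(~own)
        candidate = (dist_to_nucleus > 0) & (dist_to_nucleus <= ring_width_px) & ~nuclear[window]
        if not candidate.any():
            continue
        cy, cx = region.centroid
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dist_to_center = np.hypot(yy - cy, xx - cx)
        take = candidate & (dist_to_center < best_dist[window])
        out[window][take] = region.label
        best_dist[window][take] = dist_to_center[take]
    return out


def quantify_cells(
    gfp_channel: np.ndarray,
    cytoplasm_labels: np.ndarray,
    nucleus_labels: Optional[np.ndarray] = None,
) -> list[CellRecord]:
    """One :class:`CellRecord` per cytoplasm label, mean GFP over its ring.

    When ``nucleus_labels`` is supplied (same labelling), centroid and
    nuclear area come from the nucleus; otherwise from the ring itself.
    """
    gfp = _check_image(gfp_channel).astype(float)
    cyto = np.asarray(cytoplasm_labels)
    if cyto.shape != gfp.shape:
        raise ValueError(f"shape mismatch: gfp {gfp.shape} vs labels {cyto.shape}")
    nuc_info: dict[int, tuple[tuple[float, float], int]] = {}
    if nucleus_labels is not None:
        nuc = np.asarray(nucleus_labels)
        if nuc.shape != gfp.shape:
            raise ValueError("nucleus_labels shape mismatch")
        for region in regionprops(nuc):
            nuc_info[region.label] = (tuple(region.centroid), int(region.area))

    records = []
    for region in regionprops(cyto, intensity_image=gfp):
        centroid, nuclear_area = nuc_info.get(
            region.label, (tuple(region.centroid), 0)
        )
        records.append(
            CellRecord(
                label=int(region.label),
                centroid=(float(centroid[0]), float(centroid[1])),
                nuclear_area=nuclear_area,
                cytoplasm_area=int(region.area),
                mean_gfp=float(region.intensity_mean),
            )
        )
    records.sort(key=lambda r: r.label)
    return records


def aggregate_well(
    fields: Sequence[Sequence[CellRecord]],
    plate_id: str = "",
    well: str = "",
) -> WellMeasurement:
    """Pool per-field cell records into one per-well measurement."""
    if len(fields) == 0:
        raise ValueError("aggregate_well requires at least one field")
    all_cells = [cell for field_cells in fields for cell in field_cells]
    count = len(all_cells)
    avg = float(np.mean([c.mean_gfp for c in all_cells])) if count else None
    return WellMeasurement(
        plate_id=plate_id, well=well, cell_count=count, avg_gfp=avg, n_fields=len(fields)
    )


def process_field(
    dna_channel: np.ndarray,
    gfp_channel: np.ndarray,
    smoothing_sigma: float = 1.0,
    min_area: int = 20,
    border_policy: str = "exclude",
    ring_width_px: float = 5,
) -> list[CellRecord]:
    """Segment + ring + quantify for one field."""
    nuclei = segment_nuclei(
        dna_channel,
        smoothing_sigma=smoothing_sigma,
        min_area=min_area,
        border_policy=border_policy,
    )
    rings = cytoplasmic_masks(nuclei, ring_width_px=ring_width_px)
    return quantify_cells(gfp_channel, rings, nucleus_labels=nuclei)


def quantify_well_images(
    directory,
    plate_id: str,
    well: str,
    **field_params,
) -> WellMeasurement:
    """Process every stored field of one well (``{plate}_{well}_f*_dna.tif``)."""
    import tifffile

    pattern = os.path.join(directory, f"{plate_id}_{well}_f*_dna.tif")
    dna_paths = sorted(glob.glob(pattern))
    if not dna_paths:
        raise FileNotFoundError(f"no fields match {pattern}")
    fields = []
    for dna_path in dna_paths:
        gfp_path = dna_path[: -len("dna.tif")] + "gfp.tif"
        dna = tifffile.imread(dna_path)
        gfp = tifffile.imread(gfp_path)
        fields.append(process_field(dna, gfp, **field_params))
    return aggregate_well(fields, plate_id=plate_id, well=well)


def cells_to_frame(records: Sequence[CellRecord], plate_id: str = "", well: str = "", field: int = 0) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plate_id": plate_id,
                "well": well,
                "field": field,
                "label": r.label,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "nuclear_area": r.nuclear_area,
                "cytoplasm_area": r.cytoplasm_area,
                "mean_gfp": r.mean_gfp,
            }
            for r in records
        ],
        columns=[
            "plate_id", "well", "field", "label", "centroid_row", "centroid_col",
            "nuclear_area", "cytoplasm_area", "mean_gfp",
        ],
    )


def wells_to_frame(measurements: Sequence[WellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plate_id": m.plate_id,
                "well": m.well,
                "cell_count": m.cell_count,
                "avg_gfp": np.nan if m.avg_gfp is None else m.avg_gfp,
                "n_fields": m.n_fields,
            }
            for m in measurements
        ],
        columns=["plate_id", "well", "cell_count", "avg_gfp", "n_fields"],
    )
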