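"""TIFF ingestion and CSV/JSON/PNG emission.

Reads single-plane multichannel TIFFs (channel-first or channel-last),
taking the pixel size from the file's resolution tags when present and from
an explicit override otherwise; anisotropic pixels are rejected. The declared
bit depth comes from configuration (12-bit data ships in 16-bit containers
and cannot be inferred from the file).

Measurement rows are emitted as CSV with the fixed column order
``label, area_um2, mean, std_dev, min, max, intden, rawintden, median, mode,
skew, kurt, perim_um``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio
from scipy import ndimage

from .autophagoquant import AutophagoquantResult, dot_distance_to_boundary
from .exoquant import ExoquantResult
from .imagecore import (
    Calibration,
    CalibrationError,
    ChannelImage,
    RegionMask,
    RegionStats,
    TwoChannelStack,
)
from .synth import GroundTruth

__all__ = [
    "STATS_COLUMNS",
    "load_stack",
    "save_stack",
    "exo_result_to_frame",
    "auto_result_to_frame",
    "dots_to_frame",
    "ground_truth_to_json",
    "save_overlay",
]

STATS_COLUMNS = (
    "label",
    "area_um2",
    "mean",
    "std_dev",
    "min",
    "max",
    "intden",
    "rawintden",
    "median",
    "mode",
    "skew",
    "kurt",
    "perim_um",
)

_UNIT_UM = {2: 25400.0, 3: 10000.0}  # ResolutionUnit: inch, centimetre


def _pixel_size_from_tags(page: "tifffile.TiffPage") -> Optional[float]:
    tags = page.tags
    unit = tags.get("ResolutionUnit")
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    if unit is None or xres is None or unit.value not in (2, 3):
        return None
    unit_um = _UNIT_UM[int(unit.value)]

    def _per_px(value) -> float:
        num, den = value
        return unit_um * den / num

    px = _per_px(xres.value)
    py = _per_px(yres.value) if yres is not None else px
    if abs(px - py) > 1e-6 * max(px, py):
        raise CalibrationError(f"anisotropic pixels: {px} x {py} um")
    return px


def load_stack(
    path: Union[str, Path],
    channel_order: Tuple[int, int] = (1, 2),
    pixel_size_um: Optional[float] = None,
    bit_depth: int = 12,
) -> TwoChannelStack:
    """Read a ≥2-channel TIFF into a :class:`TwoChannelStack`.

    ``channel_order`` gives the 1-based indices of (protein, mask). Pixel size
    comes from the resolution tags, overridden by ``pixel_size_um`` when
    given; a file without usable tags requires the override. A saturation
    warning is emitted if any pixel sits at the declared bit-depth maximum.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        tag_ps = _pixel_size_from_tags(tf.pages[0])
    if arr.ndim == 2:
        raise ValueError(f"{path.name}: requires two channels, found one plane")
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: expected a 2-D multichannel image, shape {arr.shape}")
    if arr.shape[-1] <= 4 < arr.shape[0]:  # channel-last layout
        arr = np.moveaxis(arr, -1, 0)
    if arr.shape[0] < 2:
        raise ValueError(f"{path.name}: requires two channels, found {arr.shape[0]}")

    ps = pixel_size_um if pixel_size_um is not None else tag_ps
    if ps is None:
        raise CalibrationError(
            f"{path.name}: no resolution tags and no pixel-size override given"
        )
    cal = Calibration(ps, bit_depth)

    pi, mi = channel_order[0] - 1, channel_order[1] - 1
    if not (0 <= pi < arr.shape[0] and 0 <= mi < arr.shape[0]):
        raise ValueError(f"{path.name}: channel order {channel_order} out of range")
    protein = ChannelImage(np.asarray(arr[pi]), cal)
    mask = ChannelImage(np.asarray(arr[mi]), cal)
    stack = TwoChannelStack(protein=protein, mask=mask)
    if protein.is_saturated() or mask.is_saturated():
        warnings.warn(f"{path.name}: saturated pixels present", stacklevel=2)
    return stack


def save_stack(stack: TwoChannelStack, path: Union[str, Path]) -> None:
    """Write (protein, mask) as a 2-page TIFF with centimetre resolution tags
    encoding the pixel size, so a round-trip restores both pixels and
    calibration."""
    cal = stack.calibration
    dtype = np.uint8 if cal.bit_depth == 8 else np.uint16
    data = np.stack([stack.protein.pixels, stack.mask.pixels]).astype(dtype)
    ppcm = 1e4 / cal.pixel_size_um  # pixels per centimetre
    tifffile.imwrite(
        str(path),
        data,
        resolution=(ppcm, ppcm),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )


def _stats_record(label: str, s: RegionStats) -> dict:
    return {
        "label": label,
        "area_um2": s.area_um2,
        "mean": s.mean,
        "std_dev": s.std_dev,
        "min": s.min,
        "max": s.max,
        "intden": s.integrated_density,
        "rawintden": s.raw_integrated_density,
        "median": s.median,
        "mode": s.mode,
        "skew": s.skewness,
        "kurt": s.kurtosis,
        "perim_um": s.perimeter_um,
    }


def exo_result_to_frame(
    res: ExoquantResult, filename: Optional[str] = None
) -> pd.DataFrame:
    """8 labeled rows plus a summary row carrying the Otsu threshold and the
    release index."""
    records = [
        _stats_record(f"{i}_{label}", s)
        for i, (label, s) in enumerate(zip(res.labels, res.rows), start=1)
    ]
    summary = {c: np.nan for c in STATS_COLUMNS}
    summary["label"] = "summary"
    records.append(summary)
    frame = pd.DataFrame.from_records(records, columns=STATS_COLUMNS)
    frame["otsu_threshold"] = [np.nan] * 8 + [res.otsu_threshold_value]
    frame["release_index"] = [np.nan] * 8 + [res.release_index]
    if filename is not None:
        frame.insert(0, "filename", filename)
    return frame


def auto_result_to_frame(
    res: AutophagoquantResult, filename: Optional[str] = None
) -> pd.DataFrame:
    """4 labeled rows plus the summary row of the merged-dot table."""
    records = [
        _stats_record(f"{i}_{label}", s)
        for i, (label, s) in enumerate(zip(res.labels, res.rows), start=1)
    ]
    summ = res.summary
    records.append(
        {
            "label": "summary",
            "area_um2": summ.total_area_um2,
            "mean": summ.mean,
            "std_dev": np.nan,
            "min": np.nan,
            "max": np.nan,
            "intden": summ.integrated_density,
            "rawintden": np.nan,
            "median": summ.median,
            "mode": summ.mode,
            "skew": summ.skewness,
            "kurt": summ.kurtosis,
            "perim_um": summ.perimeter_um,
        }
    )
    frame = pd.DataFrame.from_records(records, columns=STATS_COLUMNS)
    frame["count"] = [np.nan] * 4 + [summ.count]
    frame["average_size_um2"] = [np.nan] * 4 + [summ.average_size_um2]
    frame["percent_area"] = [np.nan] * 4 + [summ.percent_area]
    frame["detection_threshold"] = [np.nan] * 4 + [res.detection_threshold]
    frame["otsu_threshold"] = [np.nan] * 4 + [res.mask_otsu_threshold]
    if filename is not None:
        frame.insert(0, "filename", filename)
    return frame


def dots_to_frame(res: AutophagoquantResult, cal: Calibration) -> pd.DataFrame:
    """One row per post-merge dot, including the centroid distance to the
    ROI boundary."""
    records = []
    for i, dot in enumerate(res.dots, start=1):
        try:
            dist = dot_distance_to_boundary(dot, res.roi_mask, cal)
        except ValueError:
            dist = np.nan
        records.append(
            {
                "id": i,
                "centroid_x_um": dot.centroid_um[0],
                "centroid_y_um": dot.centroid_um[1],
                "area_um2": dot.area_um2,
                "perim_um": dot.perimeter_um,
                "circularity": dot.circularity,
                "mean": dot.mean,
                "intden": dot.integrated_density,
                "dist_to_boundary_um": dist,
            }
        )
    columns = [
        "id",
        "centroid_x_um",
        "centroid_y_um",
        "area_um2",
        "perim_um",
        "circularity",
        "mean",
        "intden",
        "dist_to_boundary_um",
    ]
    return pd.DataFrame.from_records(records, columns=columns)


def ground_truth_to_json(truth: GroundTruth, path: Union[str, Path]) -> None:
    """Serialize the planted-object record (schema version 1).

    Pixel sets and masks are stored as counts/positions, not full grids:
    enough to re-derive every planted compartment sum.
    """
    payload = {
        "schema_version": truth.schema_version,
        "bouton_area_px": truth.bouton_mask.area_px,
        "shell_area_px": truth.shell_mask.area_px,
        "shell_protein_sum": truth.shell_protein_sum,
        "shell_membrane_sum": truth.shell_membrane_sum,
        "shell_protein_plants": [
            {"row": r, "col": c, "amplitude": a}
            for (r, c), a in truth.shell_protein_plants
        ],
        "shell_membrane_plants": [
            {"row": r, "col": c, "amplitude": a}
            for (r, c), a in truth.shell_membrane_plants
        ],
        "spot_count": truth.spot_count,
        "spot_centers": [{"row": r, "col": c} for r, c in truth.spot_centers],
        "spot_areas_um2": list(truth.spot_areas_um2),
        "spot_pixel_counts": [len(p) for p in truth.spot_pixel_sets],
        "expected_count_after_merge": truth.expected_count_after_merge,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _outline(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))


def save_overlay(
    stack: TwoChannelStack,
    outlines: Sequence[Tuple[RegionMask, Tuple[int, int, int]]],
    path: Union[str, Path],
) -> None:
    """Write a PNG of the protein channel with coloured region outlines
    (ROI, shell, dots) for visual review before quantification."""
    cal = stack.calibration
    base = (stack.protein.pixels.astype(np.float64) / cal.max_value * 255).astype(
        np.uint8
    )
    rgb = np.stack([base] * 3, axis=-1)
    for region, color in outlines:
        edge = _outline(region.mask)
        rgb[edge] = color
    iio.imwrite(str(path), rgb)
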