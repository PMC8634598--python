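"""Detection, filtering, merging and counting of fluorescent protein clusters
(autophagosomes, Atg8/LC3-positive puncta) inside a segmented synaptic region.

The protein channel is converted to 8 bits, median-filtered (radius 1 px by
default), and candidate pixels are those strictly above mean + k·SD of the
filtered ROI (k = 4 by default). 8-connected candidate components are kept if
their area falls in a calibrated window (0.09–0.5 µm² by default) and their
circularity 4π·area/perimeter² lies in the configured band (floor 0 by
default, since puncta circularity is inconsistent in practice). Dots closer
than a merge limit (0.5 µm centroid-to-centroid by default) are iteratively
collapsed into single objects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .imagecore import (
    Calibration,
    ChannelImage,
    EmptyRegionError,
    DegenerateHistogramError,
    RegionMask,
    RegionStats,
    TwoChannelStack,
    chain_code_perimeter,
    convert_to_8bit,
    otsu_threshold,
    region_stats,
    select_component,
)

__all__ = [
    "AutophagoquantConfig",
    "Dot",
    "DotSummary",
    "AutophagoquantResult",
    "AUTOPHAGOQUANT_ROW_LABELS",
    "median_filter",
    "detection_threshold",
    "detect_dots",
    "merge_dots",
    "run_autophagoquant",
    "dot_distance_to_boundary",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)

AUTOPHAGOQUANT_ROW_LABELS: Tuple[str, ...] = (
    "mask_channel_otsu_binarized",
    "roi_protein_median_filtered",
    "roi_protein_unfiltered",
    "roi_protein_above_otsu",
)


@dataclass(frozen=True)
class AutophagoquantConfig:
    """Parameters of a cluster-counting run (defaults match the validated
    autophagosome settings).

    k_sd
        Detection threshold is ROI mean + k_sd·SD of the filtered channel
        (default 4).
    median_radius_px
        Radius of the Euclidean-disk median filter (default 1: a pixel and
        its four edge neighbours).
    size_min_um2, size_max_um2
        Particle area window in µm² (defaults 0.09, 0.5). With
        ``size_unit="um-diameter"`` the same two numbers are read as a
        diameter window and converted to areas via π(d/2)².
    circ_min, circ_max
        Circularity window in [0, 1]; floor 0 by default.
    merge_distance_um
        Centroid-to-centroid merge limit (default 0.5 µm); ``merge_metric``
        may be ``"centroid"`` or ``"edge"`` (minimum pixel-to-pixel distance).
    threshold_source
        ``"filtered"`` (ROI stats of the median-filtered channel, default) or
        ``"unfiltered"``.
    row4_mode
        ``"otsu"`` (ROI pixels above the Otsu threshold of the 8-bit protein
        channel, default) or ``"detection"`` (ROI pixels above mean + k·SD).
    """

    k_sd: float = 4.0
    median_radius_px: int = 1
    size_min_um2: float = 0.09
    size_max_um2: float = 0.5
    circ_min: float = 0.0
    circ_max: float = 1.0
    merge_distance_um: float = 0.5
    roi_selection: Union[str, Tuple[int, int]] = "largest"
    size_unit: str = "um2"
    merge_metric: str = "centroid"
    threshold_source: str = "filtered"
    row4_mode: str = "otsu"

    def __post_init__(self) -> None:
        if not (0 <= self.circ_min <= self.circ_max <= 1):
            raise ValueError("need 0 <= circ_min <= circ_max <= 1")
        if not self.size_min_um2 < self.size_max_um2:
            raise ValueError("need size_min_um2 < size_max_um2")
        if self.k_sd < 0 or self.merge_distance_um < 0 or self.median_radius_px < 0:
            raise ValueError("k_sd, merge_distance_um, median_radius_px must be >= 0")
        if self.size_unit not in ("um2", "um-diameter"):
            raise ValueError(f"unknown size_unit {self.size_unit!r}")
        if self.merge_metric not in ("centroid", "edge"):
            raise ValueError(f"unknown merge_metric {self.merge_metric!r}")
        if self.threshold_source not in ("filtered", "unfiltered"):
            raise ValueError(f"unknown threshold_source {self.threshold_source!r}")
        if self.row4_mode not in ("otsu", "detection"):
            raise ValueError(f"unknown row4_mode {self.row4_mode!r}")

    def area_window_um2(self) -> Tuple[float, float]:
        """The effective area window, converting a diameter window if asked."""
        if self.size_unit == "um2":
            return self.size_min_um2, self.size_max_um2
        return (
            math.pi * (self.size_min_um2 / 2) ** 2,
            math.pi * (self.size_max_um2 / 2) ** 2,
        )


@dataclass(frozen=True)
class Dot:
    """One detected cluster.

    ``pixels`` are (row, col) grid coordinates; ``values`` the matching source
    8-bit intensities. The centroid is in µm with pixel centres at
    (index + 0.5)·pixel_size, x along columns. Circularity is
    4π·area/perimeter², capped at 1 (chain-code perimeters of few-pixel
    particles can push the raw formula above 1).
    """

    pixels: np.ndarray
    values: np.ndarray
    grid_shape: Tuple[int, int]
    calibration: Calibration
    centroid_um: Tuple[float, float]  # (x, y)
    area_um2: float
    perimeter_um: float
    circularity: float

    @classmethod
    def from_pixels(
        cls,
        pixels: np.ndarray,
        values: np.ndarray,
        grid_shape: Tuple[int, int],
        cal: Calibration,
    ) -> "Dot":
        pixels = np.asarray(pixels, dtype=np.intp).reshape(-1, 2)
        values = np.asarray(values).reshape(-1)
        if len(pixels) == 0:
            raise ValueError("a dot needs at least one pixel")
        mask = np.zeros(grid_shape, dtype=bool)
        mask[pixels[:, 0], pixels[:, 1]] = True
        perim = chain_code_perimeter(RegionMask(mask), cal)
        area = len(pixels) * cal.pixel_area_um2
        circ = min(1.0, 4 * math.pi * area / perim ** 2) if perim > 0 else 1.0
        cy = (pixels[:, 0].mean() + 0.5) * cal.pixel_size_um
        cx = (pixels[:, 1].mean() + 0.5) * cal.pixel_size_um
        return cls(
            pixels=pixels,
            values=values,
            grid_shape=grid_shape,
            calibration=cal,
            centroid_um=(float(cx), float(cy)),
            area_um2=area,
            perimeter_um=perim,
            circularity=circ,
        )

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def min(self) -> int:
        return int(self.values.min())

    @property
    def max(self) -> int:
        return int(self.values.max())

    @property
    def raw_integrated_density(self) -> int:
        return int(self.values.sum(dtype=np.int64))

    @property
    def integrated_density(self) -> float:
        return self.area_um2 * self.mean

    def as_mask(self) -> RegionMask:
        m = np.zeros(self.grid_shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return RegionMask(m)


@dataclass(frozen=True)
class DotSummary:
    """Summary-table row over the 0/255 binarized detection image restricted
    to dot pixels (the macro's summary window; mode is 255 whenever any dot
    exists)."""

    count: int
    total_area_um2: float
    average_size_um2: float
    percent_area: float
    mean: float
    mode: int
    perimeter_um: float
    integrated_density: float
    median: int
    skewness: float
    kurtosis: float


@dataclass(frozen=True)
class AutophagoquantResult:
    """The 4-row results table, the post-merge dot list and the summary."""

    rows: Tuple[RegionStats, ...]
    labels: Tuple[str, ...]
    dots: Tuple[Dot, ...]
    pre_merge_dots: Tuple[Dot, ...]
    summary: DotSummary
    detection_threshold: float
    mask_otsu_threshold: int
    roi_mask: RegionMask
    warnings: Tuple[str, ...] = ()

    def row(self, number: int) -> RegionStats:
        if not 1 <= number <= 4:
            raise IndexError("row number must be in 1..4")
        return self.rows[number - 1]


def _disk_footprint(radius_px: int) -> np.ndarray:
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy ** 2 + xx ** 2) <= r ** 2


def median_filter(img: ChannelImage, radius_px: int = 1) -> ChannelImage:
    """Median filter over a Euclidean-disk neighbourhood.

    Radius 1 covers a pixel and its four edge neighbours (diagonals sit at
    distance √2 > 1). Image borders use the in-bounds part of the
    neighbourhood only; when that truncated neighbourhood has an even count
    the lower middle value is taken.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    if radius_px == 0:
        return img
    fp = _disk_footprint(radius_px)
    px = img.pixels
    out = ndimage.median_filter(px, footprint=fp, mode="nearest")
    # redo the border ring with shrinking neighbourhoods
    h, w = px.shape
    r = radius_px
    offsets = np.argwhere(fp) - r
    border = np.zeros((h, w), dtype=bool)
    border[:r, :] = border[h - r :, :] = True
    border[:, :r] = border[:, w - r :] = True
    for y, x in np.argwhere(border):
        ys = y + offsets[:, 0]
        xs = x + offsets[:, 1]
        ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        vals = np.sort(px[ys[ok], xs[ok]])
        out[y, x] = vals[(len(vals) - 1) // 2]
    return img.with_pixels(out)


def detection_threshold(roi_stats: RegionStats, k_sd: float) -> float:
    """mean + k·SD of the ROI; not clamped (may exceed 255, yielding no dots)."""
    return roi_stats.mean + k_sd * roi_stats.std_dev


def detect_dots(
    filtered: ChannelImage,
    roi: RegionMask,
    threshold: float,
    cfg: AutophagoquantConfig,
    intensity_image: Optional[ChannelImage] = None,
) -> List[Dot]:
    """Find size/circularity-filtered 8-connected clusters above threshold.

    Candidate pixels are ROI pixels of ``filtered`` strictly above
    ``threshold``; components outside the area or circularity window are
    discarded. Intensity statistics are read from ``intensity_image`` (the
    unfiltered 8-bit source) when given, else from ``filtered``.
    """
    if roi.area_px == 0:
        raise EmptyRegionError("empty region")
    src = intensity_image if intensity_image is not None else filtered
    cal = filtered.calibration
    cand = roi.mask & (filtered.pixels > threshold)
    labels, n_comp = ndimage.label(cand, structure=_STRUCT8)
    lo, hi = cfg.area_window_um2()
    dots: List[Dot] = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n_comp + 1)):
        comp = labels[sl] == lab
        n = int(comp.sum())
        area = n * cal.pixel_area_um2
        if not (lo <= area <= hi):
            continue
        local = np.argwhere(comp)
        pixels = local + np.array([sl[0].start, sl[1].start])
        dot = Dot.from_pixels(
            pixels, src.pixels[pixels[:, 0], pixels[:, 1]], filtered.shape, cal
        )
        if not (cfg.circ_min <= dot.circularity <= cfg.circ_max):
            continue
        dots.append(dot)
    return dots


def _pair_distance_um(a: Dot, b: Dot, metric: str) -> float:
    if metric == "centroid":
        return math.hypot(
            a.centroid_um[0] - b.centroid_um[0], a.centroid_um[1] - b.centroid_um[1]
        )
    # edge-to-edge: minimum pixel-centre distance
    tree = cKDTree(a.pixels)
    d, _ = tree.query(b.pixels)
    return float(d.min()) * a.calibration.pixel_size_um


def _merge_key(d: Dot) -> Tuple[float, float]:
    """Row-major (y, x) centroid sort key used for deterministic tie-breaks."""
    return (d.centroid_um[1], d.centroid_um[0])


def merge_dots(
    dots: Sequence[Dot],
    merge_distance_um: float,
    cal: Calibration,
    metric: str = "centroid",
) -> List[Dot]:
    """Iteratively collapse dots closer than the merge limit into single dots.

    The closest qualifying pair is merged first (ties broken toward the pair
    with the smaller row-major centroid); the merged dot's centroid, area,
    perimeter and circularity are recomputed and it re-enters the pool, so
    chains closer than the limit collapse transitively. Terminates at the
    fixed point where all pairwise distances exceed the limit. Merged dots
    are exempt from re-applying the size filter (filtering precedes merging).
    """
    pool = list(dots)
    while len(pool) > 1:
        best = None
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                d = _pair_distance_um(pool[i], pool[j], metric)
                if d > merge_distance_um:
                    continue
                a, b = sorted((pool[i], pool[j]), key=_merge_key)
                key = (d, _merge_key(a), _merge_key(b))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        a, b = pool[i], pool[j]
        merged = Dot.from_pixels(
            np.vstack([a.pixels, b.pixels]),
            np.concatenate([a.values, b.values]),
            a.grid_shape,
            cal,
        )
        pool = [d for k, d in enumerate(pool) if k not in (i, j)]
        pool.append(merged)
    pool.sort(key=_merge_key)
    return pool


def _dot_summary(
    dots: Sequence[Dot], roi: RegionMask, cal: Calibration
) -> DotSummary:
    """Summary over the binarized (0/255) detection image within dot pixels."""
    count = len(dots)
    if count == 0:
        return DotSummary(0, 0.0, 0.0, 0.0, 0.0, 0, 0.0, 0.0, 0, 0.0, 0.0)
    total_area = sum(d.area_um2 for d in dots)
    roi_area = roi.area_px * cal.pixel_area_um2
    return DotSummary(
        count=count,
        total_area_um2=total_area,
        average_size_um2=total_area / count,
        percent_area=100.0 * total_area / roi_area,
        mean=255.0,
        mode=255,
        perimeter_um=sum(d.perimeter_um for d in dots),
        integrated_density=255.0 * total_area,
        median=255,
        skewness=0.0,  # constant 255 values: SD 0 → moments 0 by convention
        kurtosis=0.0,
    )


def run_autophagoquant(
    stack: TwoChannelStack, cfg: AutophagoquantConfig = AutophagoquantConfig()
) -> AutophagoquantResult:
    """Run the full cluster-counting pipeline on a two-channel stack.

    Order: 8-bit conversion of both channels → Otsu on the surround (DLG)
    channel, measured binarized over the full frame (row 1) → ROI component
    selection → median filter on the protein channel → filtered/unfiltered ROI
    measurements (rows 2–3) → detection threshold mean + k·SD → dot detection,
    filtering and merging → above-Otsu ROI measurement of the protein channel
    (row 4) → summary over the binarized detection image.
    """
    warns: List[str] = []
    protein8 = convert_to_8bit(stack.protein)
    mask8 = convert_to_8bit(stack.mask)

    mask_thr, thresh_mask = otsu_threshold(mask8)
    binarized = mask8.with_pixels(
        np.where(thresh_mask.mask, 255, 0).astype(np.uint8)
    )
    row1 = region_stats(binarized, RegionMask.full(stack.shape))

    roi = select_component(thresh_mask, cfg.roi_selection)

    if protein8.pixels[roi.mask].max(initial=0) >= 255:
        msg = "saturated pixels inside the ROI of the protein channel"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)

    filtered = median_filter(protein8, cfg.median_radius_px)
    row2 = region_stats(filtered, roi)
    row3 = region_stats(protein8, roi)

    thr_stats = row2 if cfg.threshold_source == "filtered" else row3
    thr = detection_threshold(thr_stats, cfg.k_sd)

    pre_merge = detect_dots(filtered, roi, thr, cfg, intensity_image=protein8)
    dots = merge_dots(pre_merge, cfg.merge_distance_um, stack.calibration, cfg.merge_metric)

    row4 = _row4(protein8, filtered, roi, thr, cfg, warns)
    summary = _dot_summary(dots, roi, stack.calibration)

    return AutophagoquantResult(
        rows=(row1, row2, row3, row4),
        labels=AUTOPHAGOQUANT_ROW_LABELS,
        dots=tuple(dots),
        pre_merge_dots=tuple(pre_merge),
        summary=summary,
        detection_threshold=thr,
        mask_otsu_threshold=mask_thr,
        roi_mask=roi,
        warnings=tuple(warns),
    )


def _row4(
    protein8: ChannelImage,
    filtered: ChannelImage,
    roi: RegionMask,
    thr: float,
    cfg: AutophagoquantConfig,
    warns: List[str],
) -> RegionStats:
    """Row 4: protein channel over its above-threshold ROI pixels.

    Default region is the ROI intersected with the protein channel's own Otsu
    foreground; ``row4_mode="detection"`` uses the mean + k·SD detection
    region instead. A degenerate histogram or empty region yields an all-zero
    row with a warning instead of aborting the run.
    """
    try:
        if cfg.row4_mode == "otsu":
            _, pmask = otsu_threshold(protein8)
            region = roi & pmask
        else:
            region = RegionMask(roi.mask & (filtered.pixels > thr))
        return region_stats(protein8, region)
    except (DegenerateHistogramError, EmptyRegionError) as exc:
        msg = f"row 4 region degenerate ({exc}); reporting zeros"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)
        return RegionStats.zeros()


def dot_distance_to_boundary(dot: Dot, roi: RegionMask, cal: Calibration) -> float:
    """Euclidean distance (µm) from the dot centroid to the nearest pixel
    outside the ROI — e.g. the distance of an autophagosome to the plasma
    membrane."""
    outside = np.argwhere(~roi.mask)
    if len(outside) == 0:
        raise ValueError("no boundary: roi covers the full grid")
    cx, cy = dot.centroid_um
    centroid_px = np.array([cy / cal.pixel_size_um - 0.5, cx / cal.pixel_size_um - 0.5])
    tree = cKDTree(outside)
    d, _ = tree.query(centroid_px)
    return float(d) * cal.pixel_size_um
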