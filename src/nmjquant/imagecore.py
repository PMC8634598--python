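"""Calibrated image model and the measurement/segmentation primitives shared
by both quantification pipelines.

The conventions here deliberately mirror ImageJ's measurement semantics on
thresholded confocal data, because downstream defaults (mean + k·SD detection
thresholds, 0.09–0.5 µm² particle windows) were calibrated against them:

* foreground connectivity is 8-connected (wand-tool behaviour);
* Otsu thresholding uses a 256-bin histogram spanning the full nominal
  bit-depth range (0..2^bits−1), independent of the data range, so that a
  12-bit and an 8-bit acquisition of the same scene threshold identically;
* the histogram mode breaks ties toward the smaller value, the median of an
  even-count region is the lower middle, and skewness/kurtosis are population
  (÷n) moments with excess kurtosis, all reported as 0 when the SD is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy import ndimage

__all__ = [
    "Calibration",
    "ChannelImage",
    "TwoChannelStack",
    "RegionMask",
    "RegionStats",
    "DegenerateHistogramError",
    "EmptyRegionError",
    "EmptyMaskError",
    "SeedNotInForegroundError",
    "CalibrationError",
    "otsu_threshold",
    "select_component",
    "enlarge_region",
    "clear_region",
    "region_stats",
    "convert_to_8bit",
    "chain_code_perimeter",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)

# Euclidean slack when comparing a distance map against a calibrated radius:
# both sides are correctly-rounded square roots of integers, so the slack only
# absorbs the division distance_um / pixel_size_um.
_DIST_EPS = 1e-9


class DegenerateHistogramError(ValueError):
    """All pixels fall into a single histogram bin; no threshold exists."""


class EmptyRegionError(ValueError):
    """A measurement was requested over a region with no pixels."""


class EmptyMaskError(ValueError):
    """Component selection was requested on an empty mask."""


class SeedNotInForegroundError(ValueError):
    """The seed coordinate lies on background."""


class CalibrationError(ValueError):
    """Missing, non-positive, or anisotropic pixel calibration."""


@dataclass(frozen=True)
class Calibration:
    """Isotropic spatial calibration of an acquisition.

    Parameters
    ----------
    pixel_size_um : float
        Edge length of one pixel in micrometres; must be positive.
    bit_depth : int
        Bits per sample of the source data (8, 12 or 16). 12-bit data is
        assumed to arrive in 16-bit containers; the depth is declared, not
        inferred.
    """

    pixel_size_um: float
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise CalibrationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.bit_depth not in (8, 12, 16):
            raise CalibrationError(f"bit_depth must be 8, 12 or 16, got {self.bit_depth}")

    @property
    def max_value(self) -> int:
        """Largest representable intensity, 2^bit_depth − 1."""
        return (1 << self.bit_depth) - 1

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2


@dataclass(frozen=True)
class ChannelImage:
    """A single-plane grayscale channel with its calibration.

    Pixels are stored as a read-only 2-D integer array; values must lie in
    [0, 2^bit_depth − 1].
    """

    pixels: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"pixels must be integer-valued, got dtype {px.dtype}")
        if px.size and (px.min() < 0 or int(px.max()) > self.calibration.max_value):
            raise ValueError(
                f"pixel values outside [0, {self.calibration.max_value}] "
                f"for declared bit depth {self.calibration.bit_depth}"
            )
        px = px.copy()
        px.setflags(write=False)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        return ChannelImage(pixels=pixels, calibration=self.calibration)

    def is_saturated(self) -> bool:
        """True if any pixel sits at the bit-depth maximum."""
        return bool((self.pixels == self.calibration.max_value).any())


@dataclass(frozen=True)
class TwoChannelStack:
    """A calibrated (protein, mask) channel pair on a shared grid.

    Channel 1 carries the protein of interest (Evi-GFP or Atg8-mCherry);
    channel 2 the membrane/surround marker (HRP or DLG) used for segmentation.
    """

    protein: ChannelImage
    mask: ChannelImage

    def __post_init__(self) -> None:
        if self.protein.shape != self.mask.shape:
            raise ValueError(
                f"channel shapes differ: {self.protein.shape} vs {self.mask.shape}"
            )
        if self.protein.calibration != self.mask.calibration:
            raise ValueError("channels must share one calibration")

    @property
    def calibration(self) -> Calibration:
        return self.protein.calibration

    @property
    def shape(self) -> Tuple[int, int]:
        return self.protein.shape


@dataclass(frozen=True)
class RegionMask:
    """A binary pixel set on an image grid (8-connected foreground convention)."""

    mask: np.ndarray
    connectivity: int = 8

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool).copy()
        if m.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {m.shape}")
        m.setflags(write=False)
        object.__setattr__(self, "mask", m)

    @classmethod
    def full(cls, shape: Tuple[int, int]) -> "RegionMask":
        return cls(np.ones(shape, dtype=bool))

    @classmethod
    def empty(cls, shape: Tuple[int, int]) -> "RegionMask":
        return cls(np.zeros(shape, dtype=bool))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.mask.shape

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def __and__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.mask & other.mask)

    def __or__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.mask | other.mask)

    def __sub__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.mask & ~other.mask)

    def __invert__(self) -> "RegionMask":
        return RegionMask(~self.mask)


@dataclass(frozen=True)
class RegionStats:
    """Per-region measurement vector (one results-table row).

    ``integrated_density`` is area_um2 × mean; ``raw_integrated_density`` is
    the exact integer sum of pixel values. Skewness and kurtosis are population
    moments; kurtosis is excess (normal distribution → 0). ``perimeter_um`` is
    filled only for dot regions where a boundary is meaningful.
    """

    n_pixels: int
    area_um2: float
    mean: float
    std_dev: float
    min: int
    max: int
    integrated_density: float
    raw_integrated_density: int
    median: int
    mode: int
    skewness: float
    kurtosis: float
    perimeter_um: Optional[float] = None

    @classmethod
    def zeros(cls) -> "RegionStats":
        """All-zero stats used for degenerate rows (e.g. empty row-4 region)."""
        return cls(0, 0.0, 0.0, 0.0, 0, 0, 0.0, 0, 0, 0, 0.0, 0.0, None)


def region_stats(
    img: ChannelImage, roi: RegionMask, *, perimeter: bool = False
) -> RegionStats:
    """Measure all :class:`RegionStats` fields of ``img`` over ``roi``.

    Raises :class:`EmptyRegionError` on an empty region. When the SD is zero
    the standardized moments are undefined and reported as 0 by convention.
    """
    if roi.shape != img.shape:
        raise ValueError(f"roi shape {roi.shape} does not match image {img.shape}")
    values = img.pixels[roi.mask]
    n = values.size
    if n == 0:
        raise EmptyRegionError("empty region")
    cal = img.calibration
    values64 = values.astype(np.float64)
    mean = float(values64.mean())
    raw = int(values.sum(dtype=np.int64))
    area = n * cal.pixel_area_um2
    centered = values64 - mean
    var = float((centered ** 2).mean())
    sd = float(np.sqrt(var))
    if sd > 0:
        skew = float((centered ** 3).mean()) / sd ** 3
        kurt = float((centered ** 4).mean()) / sd ** 4 - 3.0
    else:
        skew = 0.0
        kurt = 0.0
    sorted_vals = np.sort(values)
    median = int(sorted_vals[(n - 1) // 2])  # lower middle for even n
    counts = np.bincount(values.ravel())
    mode = int(np.argmax(counts))  # first maximum → smallest value on ties
    perim = chain_code_perimeter(roi, cal) if perimeter else None
    return RegionStats(
        n_pixels=n,
        area_um2=area,
        mean=mean,
        std_dev=sd,
        min=int(sorted_vals[0]),
        max=int(sorted_vals[-1]),
        integrated_density=area * mean,
        raw_integrated_density=raw,
        median=median,
        mode=mode,
        skewness=skew,
        kurtosis=kurt,
        perimeter_um=perim,
    )


def otsu_threshold(img: ChannelImage) -> Tuple[int, RegionMask]:
    """Otsu auto-threshold on a 256-bin histogram of the nominal value range.

    The histogram spans [0, 2^bit_depth − 1] in 256 equal bins regardless of
    the data range (ImageJ's behaviour on display-scaled data), so thresholds
    are comparable across acquisitions. Returns the threshold as an intensity
    value (the top of the last background bin) and the mask of pixels strictly
    above it; ties in the between-class variance break toward the smallest
    threshold.
    """
    cal = img.calibration
    bin_width = (cal.max_value + 1) // 256  # 1, 16 or 256
    binned = img.pixels // bin_width
    hist = np.bincount(binned.ravel(), minlength=256)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "degenerate histogram: all pixels in a single intensity bin"
        )
    # Exact integer arithmetic: with integer counts h_b and bin values b, the
    # between-class variance at threshold t is (M0·N − M·W0)² / (W0·W1) up to
    # a constant factor; comparing these rationals by cross-multiplication
    # makes the argmax (and its smallest-threshold tie-break) exact, so an
    # image with an empty gap between its classes thresholds reproducibly.
    counts = [int(c) for c in hist]
    n_total = sum(counts)
    m_total = sum(b * c for b, c in enumerate(counts))
    w0 = 0
    m0 = 0
    best_num = -1
    best_den = 1
    t_bin = 0
    for t in range(255):
        w0 += counts[t]
        m0 += t * counts[t]
        w1 = n_total - w0
        if w0 == 0 or w1 == 0:
            continue
        num = (m0 * n_total - m_total * w0) ** 2
        den = w0 * w1
        if num * best_den > best_num * den:
            best_num, best_den, t_bin = num, den, t
    threshold = (t_bin + 1) * bin_width - 1
    return threshold, RegionMask(img.pixels > threshold)


def select_component(
    mask: RegionMask, seed: Union[str, Tuple[int, int]] = "largest"
) -> RegionMask:
    """Pick one 8-connected component of ``mask``.

    ``seed`` is either a ``(row, col)`` coordinate that must lie on foreground,
    or the string ``"largest"`` (ties broken by the smallest row-major member
    coordinate). This replaces the macro's interactive wand click, which only
    ever picks a connected component.
    """
    if mask.area_px == 0:
        raise EmptyMaskError("empty mask")
    labels, n_comp = ndimage.label(mask.mask, structure=_STRUCT8)
    if seed == "largest":
        areas = np.bincount(labels.ravel())[1:]  # skip background
        best = areas.max()
        candidates = np.flatnonzero(areas == best) + 1
        if len(candidates) == 1:
            lab = int(candidates[0])
        else:
            flat = labels.ravel()
            # smallest row-major index of any member, per candidate
            firsts = {int(l): int(np.flatnonzero(flat == l)[0]) for l in candidates}
            lab = min(firsts, key=firsts.get)
    else:
        r, c = int(seed[0]), int(seed[1])
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or labels[r, c] == 0:
            raise SeedNotInForegroundError(f"seed not in foreground: {(r, c)}")
        lab = int(labels[r, c])
    return RegionMask(labels == lab)


def enlarge_region(
    roi: RegionMask, distance_um: float, cal: Calibration
) -> RegionMask:
    """Grow ``roi`` by a calibrated Euclidean distance.

    Returns roi ∪ {p : dist(p, roi) ≤ distance_um / pixel_size_um}, clipped to
    the grid — the exact Euclidean distance transform, not an iterated square
    or diamond dilation, so a 1 µm enlargement at 1 µm pixels adds the four
    edge neighbours of an isolated pixel but not its √2-distant diagonals.
    """
    if distance_um < 0:
        raise ValueError(f"distance_um must be >= 0, got {distance_um}")
    if roi.area_px == 0:
        return roi
    d_px = distance_um / cal.pixel_size_um
    dist = ndimage.distance_transform_edt(~roi.mask)
    return RegionMask(dist <= d_px + _DIST_EPS)


def clear_region(img: ChannelImage, roi: RegionMask) -> ChannelImage:
    """Return a copy of ``img`` with all roi pixels set to 0."""
    if roi.shape != img.shape:
        raise ValueError(f"roi shape {roi.shape} does not match image {img.shape}")
    out = img.pixels.copy()
    out[roi.mask] = 0
    return img.with_pixels(out)


def convert_to_8bit(img: ChannelImage) -> ChannelImage:
    """Linearly map the full nominal range [0, 2^bits−1] onto [0, 255].

    Rounding is half-up. The mapping is fixed by the declared bit depth, never
    by the per-image min/max, so images acquired with identical settings stay
    comparable after conversion. 8-bit input is returned unchanged.
    """
    cal = img.calibration
    if cal.bit_depth == 8:
        return img
    scaled = np.floor(img.pixels.astype(np.float64) * (255.0 / cal.max_value) + 0.5)
    out = scaled.astype(np.uint8)
    return ChannelImage(out, Calibration(cal.pixel_size_um, 8))


# ---------------------------------------------------------------------------
# chain-code perimeter

# clockwise Moore neighbourhood starting north
_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_STEP = tuple(np.hypot(dr, dc) for dr, dc in _MOORE)


def chain_code_perimeter(roi: RegionMask, cal: Calibration) -> float:
    """Outer-boundary chain-code perimeter in µm.

    Each 8-connected component contributes the length of the closed Moore
    trace over its boundary pixel centres (edge step 1·pixel, diagonal step
    √2·pixel); a single-pixel component contributes its pixel outline, 4·pixel.
    Multi-component masks (e.g. a merged dot) sum component perimeters.
    """
    if roi.area_px == 0:
        return 0.0
    labels, n_comp = ndimage.label(roi.mask, structure=_STRUCT8)
    total = 0.0
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        comp = labels[sl] == lab
        total += _trace_component(comp)
    return total * cal.pixel_size_um


def _trace_component(comp: np.ndarray) -> float:
    """Chain-code length of one 8-connected component (in pixels)."""
    n = int(comp.sum())
    if n == 1:
        return 4.0
    h, w = comp.shape
    rows, cols = np.nonzero(comp)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    # came "from the west": nothing above start, nothing left of it in its row
    cur = start
    backtrack = (start[0], start[1] - 1)
    # The clockwise Moore walk is a deterministic map on (cur, backtrack)
    # states, so it eventually cycles; the cycle is the closed boundary tour
    # and its length is the perimeter (any pre-cycle tail is discarded).
    seen = {(cur, backtrack): 0.0}
    length = 0.0
    while True:
        dr, dc = backtrack[0] - cur[0], backtrack[1] - cur[1]
        i = _MOORE.index((dr, dc))
        for k in range(1, 9):
            j = (i + k) % 8
            nr, nc = cur[0] + _MOORE[j][0], cur[1] + _MOORE[j][1]
            if 0 <= nr < h and 0 <= nc < w and comp[nr, nc]:
                length += _STEP[j]
                backtrack = (
                    cur[0] + _MOORE[(i + k - 1) % 8][0],
                    cur[1] + _MOORE[(i + k - 1) % 8][1],
                )
                cur = (nr, nc)
                break
        else:  # pragma: no cover - unreachable for n > 1 components
            return length
        state = (cur, backtrack)
        if state in seen:
            return length - seen[state]
        seen[state] = length
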