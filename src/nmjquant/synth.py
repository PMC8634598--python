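"""Synthetic two-channel NMJ-like images with exhaustive ground truth.

The generator emulates the geometry the pipelines were designed for: a
rounded bouton (2–5 µm diameter) rendered in the membrane/surround channel
over a dark background, a diffuse protein signal inside it, and either
single-pixel intensity plants in the ≤1 µm perisynaptic shell (exosome-release
fixtures) or compact super-threshold spots inside the region (autophagosome
fixtures). Single-pixel plants and flat levels keep every planted compartment
sum exact in the noise-free default, so pipeline outputs can be asserted to
machine precision; Gaussian noise, Poisson noise and Gaussian blur are
opt-in for robustness tests.

All randomness flows from ``SynthParams.seed`` through one
``numpy.random.default_rng`` stream: identical parameters give bit-identical
images and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .imagecore import Calibration, ChannelImage, RegionMask, TwoChannelStack, enlarge_region

__all__ = ["SynthParams", "GroundTruth", "make_exo_stack", "make_auto_stack"]


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic acquisition.

    Defaults render a 256×256 frame at 0.1 µm/px, 12 bits, with a 2 µm-radius
    bouton — inside the 2–5 µm bouton-diameter range while keeping fixtures
    sub-second. Exosome fixtures plant ``n_shell_plants`` single protein
    pixels and ``n_membrane_plants`` single membrane pixels in the shell
    annulus of width ``shell_width_um``; autophagosome fixtures plant
    ``n_spots`` compact spots of radius ``spot_radius_um`` (optionally
    elongated up to ``spot_axis_ratio``) inside a surround region of radius
    ``region_radius_um``. Intensities are on the nominal bit-depth scale.
    """

    shape: Tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    bit_depth: int = 12
    seed: int = 0

    # geometry
    bouton_center: Optional[Tuple[int, int]] = None  # (row, col); None → frame centre
    bouton_radius_um: float = 2.0
    region_radius_um: float = 4.0  # DLG-like surround region (auto mode)

    # intensity levels (nominal bit-depth scale)
    membrane_level: int = 3000
    protein_interior_level: int = 300
    protein_background_level: int = 320
    spot_peak_level: int = 3200

    # exo-mode plants
    shell_width_um: float = 1.0
    n_shell_plants: int = 6
    n_membrane_plants: int = 6
    plant_amplitude_range: Tuple[int, int] = (800, 2400)
    shell_plants: Optional[Sequence[Tuple[Tuple[int, int], int]]] = None
    membrane_plants: Optional[Sequence[Tuple[Tuple[int, int], int]]] = None

    # auto-mode spots
    n_spots: int = 5
    spot_radius_um: float = 0.2
    spot_axis_ratio: float = 1.0  # >1 → random elongation up to this ratio
    min_spot_separation_um: float = 1.0
    spot_centers: Optional[Sequence[Tuple[int, int]]] = None
    require_non_overlapping: bool = True
    merge_distance_um: float = 0.5  # used only for the ground-truth merge count

    # degradation
    noise_sd: float = 0.0
    poisson_noise: bool = False
    blur_sd_px: float = 0.0

    def __post_init__(self) -> None:
        cal = self.calibration  # validates pixel size / bit depth
        for name in ("membrane_level", "protein_interior_level",
                     "protein_background_level", "spot_peak_level"):
            v = getattr(self, name)
            if not 0 <= v <= cal.max_value:
                raise ValueError(f"{name}={v} outside [0, {cal.max_value}]")
        if self.plant_amplitude_range[1] > cal.max_value:
            raise ValueError("plant amplitudes exceed the bit-depth maximum")

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.pixel_size_um, self.bit_depth)

    @property
    def center_px(self) -> Tuple[int, int]:
        if self.bouton_center is not None:
            return self.bouton_center
        return (self.shape[0] // 2, self.shape[1] // 2)


@dataclass(frozen=True)
class GroundTruth:
    """Planted-object record for one synthetic stack (schema version 1).

    Noise-free channel sums over any recorded compartment equal the recorded
    planted sums exactly.
    """

    bouton_mask: RegionMask
    shell_mask: RegionMask
    shell_protein_sum: int  # S
    shell_membrane_sum: int  # M
    shell_protein_plants: Tuple[Tuple[Tuple[int, int], int], ...]
    shell_membrane_plants: Tuple[Tuple[Tuple[int, int], int], ...]
    spot_count: int
    spot_centers: Tuple[Tuple[int, int], ...]
    spot_pixel_sets: Tuple[np.ndarray, ...]  # (n, 2) row/col arrays
    spot_areas_um2: Tuple[float, ...]
    expected_count_after_merge: int
    schema_version: int = 1


def _disk_mask(shape: Tuple[int, int], center: Tuple[int, int], radius_px: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px ** 2


def _finalize_channel(
    raw: np.ndarray, params: SynthParams, rng: np.random.Generator
) -> ChannelImage:
    """Apply blur/noise, clip to the nominal range and quantize."""
    cal = params.calibration
    out = raw.astype(np.float64)
    if params.blur_sd_px > 0:
        out = ndimage.gaussian_filter(out, params.blur_sd_px)
    if params.poisson_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, size=out.shape)
    out = np.clip(np.rint(out), 0, cal.max_value)
    dtype = np.uint8 if cal.bit_depth == 8 else np.uint16
    return ChannelImage(out.astype(dtype), cal)


def _sample_positions(
    candidates: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    if k > len(candidates):
        raise ValueError(f"cannot place {k} plants in {len(candidates)} candidate pixels")
    idx = rng.choice(len(candidates), size=k, replace=False)
    return candidates[np.sort(idx)]


def make_exo_stack(params: SynthParams) -> Tuple[TwoChannelStack, GroundTruth]:
    """Exosome-release fixture: bouton disk + single-pixel shell plants.

    The membrane channel renders the bouton as a filled disk well above
    background (a clean Otsu gap); membrane plants are restricted to shell
    pixels farther than 1.5 px from the bouton so no plant can 8-connect to
    the bouton component. Explicit plant positions outside the shell annulus
    raise an error. Ground truth records the bouton and shell pixel sets and
    the exact planted sums S (protein) and M (membrane).
    """
    rng = np.random.default_rng(params.seed)
    cal = params.calibration
    shape = params.shape
    r_px = params.bouton_radius_um / cal.pixel_size_um
    bouton = RegionMask(_disk_mask(shape, params.center_px, r_px))
    enlarged = enlarge_region(bouton, params.shell_width_um, cal)
    shell = enlarged - bouton

    shell_set = shell.mask
    # shell pixels not 8-adjacent to the bouton (EDT distance > 1.5 px)
    dist = ndimage.distance_transform_edt(~bouton.mask)
    detached_shell = shell_set & (dist > 1.5)

    lo, hi = params.plant_amplitude_range

    def _plants(explicit, n, candidates_mask):
        if explicit is not None:
            out = []
            for (r, c), amp in explicit:
                if not shell_set[r, c]:
                    raise ValueError(f"plant outside annulus: {(r, c)}")
                out.append(((int(r), int(c)), int(amp)))
            return tuple(out)
        pos = _sample_positions(np.argwhere(candidates_mask), n, rng)
        amps = rng.integers(lo, hi + 1, size=n)
        return tuple(((int(p[0]), int(p[1])), int(a)) for p, a in zip(pos, amps))

    protein_plants = _plants(params.shell_plants, params.n_shell_plants, shell_set)
    membrane_plants = _plants(
        params.membrane_plants, params.n_membrane_plants, detached_shell
    )

    mask_raw = np.zeros(shape, dtype=np.float64)
    mask_raw[bouton.mask] = params.membrane_level
    for (r, c), amp in membrane_plants:
        mask_raw[r, c] = amp

    protein_raw = np.zeros(shape, dtype=np.float64)
    protein_raw[bouton.mask] = params.protein_interior_level
    for (r, c), amp in protein_plants:
        protein_raw[r, c] = amp

    stack = TwoChannelStack(
        protein=_finalize_channel(protein_raw, params, rng),
        mask=_finalize_channel(mask_raw, params, rng),
    )
    truth = GroundTruth(
        bouton_mask=bouton,
        shell_mask=shell,
        shell_protein_sum=sum(a for _, a in protein_plants),
        shell_membrane_sum=sum(a for _, a in membrane_plants),
        shell_protein_plants=protein_plants,
        shell_membrane_plants=membrane_plants,
        spot_count=0,
        spot_centers=(),
        spot_pixel_sets=(),
        spot_areas_um2=(),
        expected_count_after_merge=0,
    )
    return stack, truth


def _spot_pixels(
    shape: Tuple[int, int],
    center: Tuple[int, int],
    radius_px: float,
    axis_ratio: float,
    angle: float,
) -> np.ndarray:
    """Pixel set of an elliptical spot with axes radius_px·√ratio and
    radius_px/√ratio (area-preserving elongation)."""
    a = radius_px * math.sqrt(axis_ratio)
    b = radius_px / math.sqrt(axis_ratio)
    rmax = int(math.ceil(a)) + 1
    yy, xx = np.mgrid[-rmax : rmax + 1, -rmax : rmax + 1]
    u = xx * math.cos(angle) + yy * math.sin(angle)
    v = -xx * math.sin(angle) + yy * math.cos(angle)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    local = np.argwhere(inside) - rmax
    pixels = local + np.array(center)
    ok = (
        (pixels[:, 0] >= 0)
        & (pixels[:, 0] < shape[0])
        & (pixels[:, 1] >= 0)
        & (pixels[:, 1] < shape[1])
    )
    return pixels[ok]


def _expected_merge_count(
    centers_px: Sequence[Tuple[float, float]], merge_um: float, ps: float
) -> int:
    """Iterated closest-pair merging on point masses (mirrors the pipeline's
    merge rule on centroids) to record the expected post-merge count."""
    pts = [(np.array(c, dtype=float), 1) for c in centers_px]
    while len(pts) > 1:
        best = None
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = float(np.hypot(*(pts[i][0] - pts[j][0]))) * ps
                if d <= merge_um and (best is None or d < best[0]):
                    best = (d, i, j)
        if best is None:
            break
        _, i, j = best
        (ca, na), (cb, nb) = pts[i], pts[j]
        merged = ((ca * na + cb * nb) / (na + nb), na + nb)
        pts = [p for k, p in enumerate(pts) if k not in (i, j)] + [merged]
    return len(pts)


def make_auto_stack(params: SynthParams) -> Tuple[TwoChannelStack, GroundTruth]:
    """Autophagosome fixture: DLG-like surround region + compact protein spots.

    The mask channel renders a filled surround disk; the protein channel a
    flat background plus uniform-intensity spots whose pixel sets, centres and
    areas are recorded. Explicit spot centres that overlap (when non-overlap
    is requested) raise an error; sampled centres keep a minimum pairwise
    separation and stay inside the region.
    """
    rng = np.random.default_rng(params.seed)
    cal = params.calibration
    shape = params.shape
    ps = cal.pixel_size_um
    region = RegionMask(
        _disk_mask(shape, params.center_px, params.region_radius_um / ps)
    )

    r_spot_px = params.spot_radius_um / ps
    margin_px = r_spot_px * math.sqrt(max(1.0, params.spot_axis_ratio)) + 2
    inner = RegionMask(
        _disk_mask(
            shape, params.center_px, params.region_radius_um / ps - margin_px
        )
    )

    if params.spot_centers is not None:
        centers = [tuple(map(int, c)) for c in params.spot_centers]
    else:
        centers = _sample_spot_centers(params, inner, rng)

    spot_sets: List[np.ndarray] = []
    occupied = np.zeros(shape, dtype=bool)
    for c in centers:
        ratio = (
            1.0
            if params.spot_axis_ratio <= 1.0
            else float(rng.uniform(1.0, params.spot_axis_ratio))
        )
        angle = float(rng.uniform(0, math.pi)) if ratio > 1.0 else 0.0
        pix = _spot_pixels(shape, c, r_spot_px, ratio, angle)
        if params.require_non_overlapping and occupied[pix[:, 0], pix[:, 1]].any():
            raise ValueError(f"spot at {c} overlaps a previously planted spot")
        occupied[pix[:, 0], pix[:, 1]] = True
        spot_sets.append(pix)

    mask_raw = np.zeros(shape, dtype=np.float64)
    mask_raw[region.mask] = params.membrane_level

    protein_raw = np.full(shape, float(params.protein_background_level))
    for pix in spot_sets:
        protein_raw[pix[:, 0], pix[:, 1]] = params.spot_peak_level

    stack = TwoChannelStack(
        protein=_finalize_channel(protein_raw, params, rng),
        mask=_finalize_channel(mask_raw, params, rng),
    )
    centroids = [tuple(pix.mean(axis=0)) for pix in spot_sets] if spot_sets else []
    truth = GroundTruth(
        bouton_mask=region,
        shell_mask=RegionMask.empty(shape),
        shell_protein_sum=0,
        shell_membrane_sum=0,
        shell_protein_plants=(),
        shell_membrane_plants=(),
        spot_count=len(spot_sets),
        spot_centers=tuple(tuple(map(int, c)) for c in centers),
        spot_pixel_sets=tuple(spot_sets),
        spot_areas_um2=tuple(len(pix) * cal.pixel_area_um2 for pix in spot_sets),
        expected_count_after_merge=_expected_merge_count(
            centroids, params.merge_distance_um, ps
        ),
    )
    return stack, truth


def _sample_spot_centers(
    params: SynthParams, inner: RegionMask, rng: np.random.Generator
) -> List[Tuple[int, int]]:
    """Rejection-sample spot centres inside ``inner`` with a minimum pairwise
    separation."""
    if params.n_spots == 0:
        return []
    candidates = np.argwhere(inner.mask)
    if len(candidates) == 0:
        raise ValueError("region too small for the requested spot radius")
    min_sep_px = params.min_spot_separation_um / params.pixel_size_um
    centers: List[Tuple[int, int]] = []
    for _ in range(10000):
        c = candidates[int(rng.integers(len(candidates)))]
        if all(np.hypot(c[0] - r, c[1] - q) >= min_sep_px for r, q in centers):
            centers.append((int(c[0]), int(c[1])))
            if len(centers) == params.n_spots:
                return centers
    raise ValueError(
        f"could not place {params.n_spots} spots with separation "
        f"{params.min_spot_separation_um} um"
    )
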