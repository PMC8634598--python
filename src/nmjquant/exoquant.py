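"""Extrasynaptic (shell) fluorescence quantification around a segmented bouton.

Pipeline: measure both raw channels → Otsu-segment the membrane channel →
pick the bouton component → measure its interior in both channels → zero the
interior → enlarge the bouton selection by a calibrated shell distance
(default 1 µm, the subsynaptic-reticulum width exosomes travel through) →
measure the enlarged region and the full cleared frames. The release index is
the shell protein signal divided by the shell membrane (HRP) signal, which
normalizes away shell-area differences between boutons.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .imagecore import (
    RegionMask,
    RegionStats,
    TwoChannelStack,
    clear_region,
    enlarge_region,
    otsu_threshold,
    region_stats,
    select_component,
)

__all__ = [
    "ExoquantConfig",
    "ExoquantResult",
    "EXOQUANT_ROW_LABELS",
    "run_exoquant",
    "release_index",
    "normalize_to_control",
]

EXOQUANT_ROW_LABELS: Tuple[str, ...] = (
    "full_image_mask_channel",
    "full_image_protein_channel",
    "bouton_interior_mask_channel",
    "bouton_interior_protein_channel",
    "enlarged_cleared_mask_channel",
    "enlarged_cleared_protein_channel",
    "full_cleared_mask_channel",
    "full_cleared_protein_channel",
)


@dataclass(frozen=True)
class ExoquantConfig:
    """Parameters of a shell-quantification run.

    shell_distance_um
        Extracellular distance from the bouton membrane to quantify;
        default 1.0 µm (the SSR diameter).
    roi_selection
        ``"largest"`` or an explicit ``(row, col)`` seed inside the bouton.
    index_mode
        ``"shell-ratio"`` (shell protein ÷ shell membrane, the default) or
        ``"inside-outside"`` (shell protein ÷ bouton-interior protein).
    annulus_stats
        Also measure the shell annulus only (enlarged minus bouton), excluding
        the zeroed interior from the mean; off by default to stay
        macro-faithful.
    """

    shell_distance_um: float = 1.0
    roi_selection: Union[str, Tuple[int, int]] = "largest"
    index_mode: str = "shell-ratio"
    annulus_stats: bool = False

    def __post_init__(self) -> None:
        if self.shell_distance_um < 0:
            raise ValueError("shell_distance_um must be >= 0")
        if self.index_mode not in ("shell-ratio", "inside-outside"):
            raise ValueError(f"unknown index_mode {self.index_mode!r}")


@dataclass(frozen=True)
class ExoquantResult:
    """The 8-row results table plus derived masks and the release index.

    Rows (1-based, matching the macro's results window):
      1/2 full frame, mask/protein channel;
      3/4 bouton interior, mask/protein;
      5/6 enlarged region after clearing the interior, mask/protein;
      7/8 full frame after clearing, mask/protein.
    """

    rows: Tuple[RegionStats, ...]
    labels: Tuple[str, ...]
    otsu_threshold_value: int
    bouton_mask: RegionMask
    enlarged_mask: RegionMask
    shell_mask: RegionMask
    release_index: float
    annulus_rows: Optional[Tuple[RegionStats, RegionStats]] = None
    warnings: Tuple[str, ...] = ()

    def row(self, number: int) -> RegionStats:
        """1-based row access matching the macro's results window."""
        if not 1 <= number <= 8:
            raise IndexError("row number must be in 1..8")
        return self.rows[number - 1]


def run_exoquant(stack: TwoChannelStack, cfg: ExoquantConfig = ExoquantConfig()) -> ExoquantResult:
    """Run the full shell-quantification pipeline on a two-channel stack."""
    warns: List[str] = []
    full = RegionMask.full(stack.shape)
    row1 = region_stats(stack.mask, full)
    row2 = region_stats(stack.protein, full)

    threshold, thresh_mask = otsu_threshold(stack.mask)
    bouton = select_component(thresh_mask, cfg.roi_selection)
    enlarged = enlarge_region(bouton, cfg.shell_distance_um, stack.calibration)

    for name, ch in (("mask", stack.mask), ("protein", stack.protein)):
        if ch.pixels[enlarged.mask].max(initial=0) >= ch.calibration.max_value:
            msg = f"saturated pixels in measured region of {name} channel"
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)

    row3 = region_stats(stack.mask, bouton)
    row4 = region_stats(stack.protein, bouton)

    cleared_mask_ch = clear_region(stack.mask, bouton)
    cleared_protein_ch = clear_region(stack.protein, bouton)

    row5 = region_stats(cleared_mask_ch, enlarged)
    row6 = region_stats(cleared_protein_ch, enlarged)

    row7 = region_stats(cleared_mask_ch, full)
    row8 = region_stats(cleared_protein_ch, full)

    shell = enlarged - bouton
    annulus = None
    if cfg.annulus_stats and shell.area_px > 0:
        annulus = (
            region_stats(cleared_mask_ch, shell),
            region_stats(cleared_protein_ch, shell),
        )

    result = ExoquantResult(
        rows=(row1, row2, row3, row4, row5, row6, row7, row8),
        labels=EXOQUANT_ROW_LABELS,
        otsu_threshold_value=threshold,
        bouton_mask=bouton,
        enlarged_mask=enlarged,
        shell_mask=shell,
        release_index=np.nan,
        annulus_rows=annulus,
        warnings=tuple(warns),
    )
    idx = release_index(result, mode=cfg.index_mode)
    return dataclasses.replace(result, release_index=idx)


def release_index(res: ExoquantResult, mode: str = "shell-ratio") -> float:
    """Exosome-release readout from an 8-row result.

    ``"shell-ratio"``: shell protein raw integrated density ÷ shell membrane
    raw integrated density (rows 6/5) — area-normalized and robust to bouton
    size. ``"inside-outside"``: shell protein ÷ bouton-interior protein
    (rows 6/4). A zero denominator yields NaN with a warning.
    """
    num = res.row(6).raw_integrated_density
    den = (
        res.row(5).raw_integrated_density
        if mode == "shell-ratio"
        else res.row(4).raw_integrated_density
    )
    if den == 0:
        warnings.warn("release index undefined: zero denominator signal", stacklevel=2)
        return float("nan")
    return num / den


def normalize_to_control(
    indices: Sequence[float], control_indices: Sequence[float]
) -> np.ndarray:
    """Divide each index by the mean of the control group."""
    control = np.asarray(control_indices, dtype=float)
    if control.size == 0:
        raise ValueError("control set is empty")
    cmean = control.mean()
    if not cmean > 0:
        raise ValueError(f"control mean must be > 0, got {cmean}")
    return np.asarray(indices, dtype=float) / cmean
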