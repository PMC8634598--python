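"""Batch driver: process many images with one configuration.

Each image is processed independently and deterministically (sorted input
order, no hidden randomness); one failure is recorded and does not abort the
batch, matching the recommended study design of ≥15 images per condition.
A SHA-256 hash of the canonical configuration is recorded in every report so
re-runs with changed parameters are distinguishable.
"""

from __future__ import annotations

import dataclasses
import glob as globmod
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .autophagoquant import AutophagoquantConfig, run_autophagoquant
from .exoquant import ExoquantConfig, run_exoquant
from .io import auto_result_to_frame, dots_to_frame, exo_result_to_frame, load_stack

__all__ = ["RunConfig", "BatchReport", "run_batch"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one batch run (CLI flags and YAML keys map 1:1)."""

    mode: str  # "exo" | "auto"
    inputs: Tuple[str, ...]
    channel_order: Tuple[int, int] = (1, 2)
    pixel_size_um: Optional[float] = None
    bit_depth: int = 12
    exo: ExoquantConfig = field(default_factory=ExoquantConfig)
    auto: AutophagoquantConfig = field(default_factory=AutophagoquantConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("exo", "auto"):
            raise ValueError(f"mode must be 'exo' or 'auto', got {self.mode!r}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class BatchReport:
    """Per-image result blocks plus failure records and run metadata.

    ``started_at`` is kept on the in-memory object only; serialized outputs
    carry version and config hash but no wall-clock fields, so identical
    inputs and configuration produce byte-identical files.
    """

    blocks: List[dict]
    failures: List[dict]
    version: str
    config_hash: str
    started_at: float = field(default_factory=time.time, compare=False)

    def results_frame(self) -> pd.DataFrame:
        frames = [b["frame"] for b in self.blocks]
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "config_hash": self.config_hash,
            "n_processed": len(self.blocks),
            "n_failed": len(self.failures),
            "images": [
                {"path": b["path"], "warnings": b["warnings"]} for b in self.blocks
            ],
            "failures": self.failures,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def _resolve_inputs(patterns: Sequence[str]) -> List[str]:
    paths: List[str] = []
    for pat in patterns:
        hits = sorted(globmod.glob(pat))
        paths.extend(hits if hits else ([pat] if Path(pat).exists() else []))
    return sorted(dict.fromkeys(paths))


def run_batch(cfg: RunConfig) -> BatchReport:
    """Process every input image with the shared configuration.

    Inputs are resolved from paths/globs and processed in sorted order; a
    per-image exception becomes a failure record. Raises if no input
    resolves.
    """
    paths = _resolve_inputs(cfg.inputs)
    if not paths:
        raise ValueError(f"no inputs resolve from {list(cfg.inputs)}")
    blocks: List[dict] = []
    failures: List[dict] = []
    for path in paths:
        try:
            stack = load_stack(
                path,
                channel_order=cfg.channel_order,
                pixel_size_um=cfg.pixel_size_um,
                bit_depth=cfg.bit_depth,
            )
            if cfg.mode == "exo":
                res = run_exoquant(stack, cfg.exo)
                frame = exo_result_to_frame(res, filename=path)
                dots = None
            else:
                res = run_autophagoquant(stack, cfg.auto)
                frame = auto_result_to_frame(res, filename=path)
                dots = dots_to_frame(res, stack.calibration)
                dots.insert(0, "filename", path)
            blocks.append(
                {
                    "path": path,
                    "frame": frame,
                    "dots": dots,
                    "result": res,
                    "warnings": list(res.warnings),
                }
            )
        except Exception as exc:  # noqa: BLE001 - a batch must survive bad images
            failures.append({"path": path, "error": f"{type(exc).__name__}: {exc}"})
    return BatchReport(
        blocks=blocks,
        failures=failures,
        version=__version__,
        config_hash=cfg.config_hash(),
    )
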