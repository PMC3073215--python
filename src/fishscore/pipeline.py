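"""Case-level orchestration: images in, per-nucleus table and case call out.

A clinical "case" may span several images; nuclei found in each image are
pooled until the cell budget (default 60) is reached.  In ``both`` mode
the morphology (MM) and inverse-multifractal (IMF) detectors run on the
same nucleus label map, so their case scores are a paired comparison of
the dot detectors, not of the segmentations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .image_io import RgbImage, read_rgb, split_channels
from .morphology import MMDetectParams, detect_dots_mm
from .multifractal import MFParams, detect_dots_imf
from .nuclei import NucleusLabelMap, SegmentationParams, qc_dapi, segment_nuclei
from .scoring import (
    CaseScore,
    DotRecord,
    NucleusScore,
    case_score,
    estimate_count,
    nucleus_scores,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "score_images", "write_report"]

_METHODS = ("mm", "imf", "both")


@dataclass
class PipelineConfig:
    """Full pipeline configuration with flat, namespaced config-file keys.

    File keys are ``section.field`` (e.g. ``segmentation.min_area``,
    ``mm.se_radius``, ``imf.alpha_percentile``); unknown keys are
    rejected so typos cannot silently fall back to defaults.
    """

    method: str = "both"
    max_cells: int = 60
    estimate_overlaps: bool = False
    ratio_of_sums: bool = False
    qc_area_floor: float = 0.01
    qc_intensity_floor: float = 0.05
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    mm: MMDetectParams = field(default_factory=MMDetectParams)
    imf: MFParams = field(default_factory=MFParams)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")

    @property
    def methods(self) -> tuple[str, ...]:
        return ("mm", "imf") if self.method == "both" else (self.method,)

    _TOP_KEYS = {
        "method": str,
        "max_cells": int,
        "estimate_overlaps": bool,
        "ratio_of_sums": bool,
        "qc.area_floor": ("qc_area_floor", float),
        "qc.intensity_floor": ("qc_intensity_floor", float),
    }

    @classmethod
    def from_mapping(cls, flat: Mapping[str, object]) -> "PipelineConfig":
        """Build a config from a flat ``section.field`` mapping."""
        sections = {
            "segmentation": (SegmentationParams, {}),
            "mm": (MMDetectParams, {}),
            "imf": (MFParams, {}),
        }
        top: dict[str, object] = {}
        for key, value in flat.items():
            if key in cls._TOP_KEYS:
                spec = cls._TOP_KEYS[key]
                if isinstance(spec, tuple):
                    attr, typ = spec
                else:
                    attr, typ = key, spec
                top[attr] = typ(value)
                continue
            if "." in key:
                section, _, fname = key.partition(".")
                if section in sections:
                    klass, kwargs = sections[section]
                    valid = {f.name for f in dataclasses.fields(klass)}
                    if fname not in valid:
                        raise KeyError(f"unknown config key {key!r}")
                    if isinstance(value, list):
                        value = tuple(value)
                    kwargs[fname] = value
                    continue
            raise KeyError(f"unknown config key {key!r}")
        return cls(
            segmentation=SegmentationParams(**sections["segmentation"][1]),
            mm=MMDetectParams(**sections["mm"][1]),
            imf=MFParams(**sections["imf"][1]),
            **top,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        return cls.from_mapping(data)

    def reference_text(self) -> str:
        """Flat key = default listing, for a generated reference file."""
        lines = ["# fishscore pipeline configuration reference", ""]
        lines.append(f"method: {self.method}")
        lines.append(f"max_cells: {self.max_cells}")
        lines.append(f"estimate_overlaps: {self.estimate_overlaps}")
        lines.append(f"ratio_of_sums: {self.ratio_of_sums}")
        lines.append(f"qc.area_floor: {self.qc_area_floor}")
        lines.append(f"qc.intensity_floor: {self.qc_intensity_floor}")
        for section, obj in (("segmentation", self.segmentation), ("mm", self.mm), ("imf", self.imf)):
            for f in dataclasses.fields(obj):
                lines.append(f"{section}.{f.name}: {getattr(obj, f.name)}")
        return "\n".join(lines) + "\n"


@dataclass
class PipelineResult:
    """Scores per method plus the pooled per-nucleus tables behind them."""

    cases: dict[str, CaseScore]
    nucleus_tables: dict[str, list[NucleusScore]]
    qc_warnings: list[str]
    n_nuclei_total: int


def _apply_overlap_estimator(dots: list[DotRecord]) -> None:
    """Area-based copy estimate for red dots, referenced to green dot areas."""
    green_areas = [d.area for d in dots if d.channel == "green"]
    if not green_areas:
        return
    reference = float(np.median(green_areas))
    for d in dots:
        if d.channel == "red":
            d.est_count = estimate_count(d.area, reference)


def score_images(
    images: Sequence[RgbImage], config: PipelineConfig | None = None
) -> PipelineResult:
    """Score one case from in-memory RGB images.

    Per image: split channels, segment nuclei from blue, run DAPI QC, then
    detect red and green dots with each configured engine.  Nuclei are
    pooled across images (ids offset per image) and each engine's pooled
    table is averaged into one :class:`CaseScore`.

    Raises :class:`fishscore.scoring.UnscorableCaseError` (with the QC
    context attached) when no nucleus has a defined ratio.
    """
    if config is None:
        config = PipelineConfig()
    qc_warnings: list[str] = []
    pooled: dict[str, list[NucleusScore]] = {m: [] for m in config.methods}
    offset = 0
    for i, img in enumerate(images):
        red, green, blue = split_channels(img)
        nmap = segment_nuclei(blue, config.segmentation)
        qc = qc_dapi(
            blue,
            nmap,
            area_floor=config.qc_area_floor,
            intensity_floor=config.qc_intensity_floor,
        )
        if qc.no_dapi_suspected:
            qc_warnings.append(
                f"image {i}: no_dapi_suspected "
                f"(nuclear area fraction {qc.nuclear_area_fraction:.4f})"
            )
        logger.info(
            "image %d: %d nuclei, nuclear area fraction %.4f",
            i,
            nmap.n_nuclei,
            qc.nuclear_area_fraction,
        )
        for method in config.methods:
            if method == "mm":
                dots = detect_dots_mm(red, nmap, config.mm, channel_name="red")
                dots += detect_dots_mm(green, nmap, config.mm, channel_name="green")
            else:
                dots = detect_dots_imf(
                    red,
                    nmap,
                    config.imf,
                    min_dot_area=config.mm.min_dot_area,
                    max_dot_area=config.mm.resolved_max_dot_area,
                    channel_name="red",
                )
                dots += detect_dots_imf(
                    green,
                    nmap,
                    config.imf,
                    min_dot_area=config.mm.min_dot_area,
                    max_dot_area=config.mm.resolved_max_dot_area,
                    channel_name="green",
                )
            if config.estimate_overlaps:
                _apply_overlap_estimator(dots)
            logger.info(
                "image %d, %s: %d red dots, %d green dots",
                i,
                method.upper(),
                sum(d.est_count for d in dots if d.channel == "red"),
                sum(d.est_count for d in dots if d.channel == "green"),
            )
            for score in nucleus_scores(dots, nmap):
                pooled[method].append(
                    NucleusScore(
                        nucleus_id=score.nucleus_id + offset,
                        red_count=score.red_count,
                        green_count=score.green_count,
                        ratio=score.ratio,
                    )
                )
        offset += nmap.n_nuclei
    cases: dict[str, CaseScore] = {}
    for method in config.methods:
        cases[method] = case_score(
            pooled[method],
            max_cells=config.max_cells,
            method=method.upper(),
            qc_warnings=qc_warnings,
            ratio_of_sums=config.ratio_of_sums,
        )
    return PipelineResult(
        cases=cases,
        nucleus_tables=pooled,
        qc_warnings=qc_warnings,
        n_nuclei_total=offset,
    )


def run_pipeline(
    image_paths: Sequence[str | Path], config: PipelineConfig | None = None
) -> PipelineResult:
    """Read image files and score the case they jointly constitute."""
    if not image_paths:
        raise ValueError("at least one image path is required")
    images = [read_rgb(p) for p in image_paths]
    return score_images(images, config)


def write_report(
    case: CaseScore,
    scores: Sequence[NucleusScore],
    outdir: str | Path,
    case_id: str = "case",
) -> tuple[Path, Path]:
    """Write the per-nucleus CSV and the case-level JSON (overwriting)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    method = (case.method or "NA").lower()
    csv_path = outdir / f"{case_id}_{method}_nuclei.csv"
    json_path = outdir / f"{case_id}_{method}_score.json"
    frame = pd.DataFrame(
        {
            "case_id": case_id,
            "nucleus_id": [s.nucleus_id for s in scores],
            "red_count": [s.red_count for s in scores],
            "green_count": [s.green_count for s in scores],
            "ratio": [s.ratio if s.ratio is not None else np.nan for s in scores],
            "excluded_flag": [s.excluded for s in scores],
        }
    )
    frame.to_csv(csv_path, index=False)
    payload = {
        "case_id": case_id,
        "mean_ratio": case.mean_ratio,
        "n_nuclei_used": case.n_nuclei_used,
        "status": case.status,
        "method": case.method,
        "qc_warnings": case.qc_warnings,
    }
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    return csv_path, json_path
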