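"""End-to-end orchestration of the attention and tile-by-tile pipelines.

The attention pipeline runs: sparse initial allocation → classification →
FP correction → one or two rounds of tumour-triggered densification →
DBSCAN clustering of tumour points → convex-hull ROI prediction → uniform
in-ROI fill → TSR estimation → metrics. The tile-by-tile reference covers
the slide with contiguous 224 px tiles in a single pass and shares the ROI
and TSR stages, so the two modes differ only in how patches are allocated.

Everything is deterministic given (slide, config, seed): independent random
streams for sampling, classification and TSR are spawned from the config
seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

from . import roi as roi_mod
from . import slide_model, tsr as tsr_mod
from .classify import (
    ClassifierBundle,
    FpStageSpec,
    fp_correct,
    make_confusion,
    simulate_classify,
    tumour_inside_fraction,
)
from .errors import InputError, ParameterError, UndefinedMetricError
from .sampling import (
    Patch,
    allocate_initial,
    allocate_resample,
    allocate_roi_fill,
    build_grid,
    patches_to_records,
)
from .slide_model import AnnotationSet, TissueClass, VirtualSlide

logger = logging.getLogger(__name__)

GRID_SIZES = (640, 768, 1024)
TILE_MODE_BOX = 224
TSR_METHODS = ("uniform_roi", "box_max_density", "sliding_mean", "gt_locations")

#: JSON schema of the YAML pipeline configuration.
CONFIG_SCHEMA: dict = {
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "wsisampler pipeline configuration",
    "type": "object",
    "properties": {
        "box_px": {"enum": [224, 640, 768, 1024]},
        "resample_iterations": {"enum": [1, 2]},
        "per_box_cap": {"type": "integer", "minimum": 1},
        "per_tumour": {"type": "integer", "minimum": 1},
        "eps_px": {"type": "number", "exclusiveMinimum": 0},
        "min_samples": {"type": "integer", "minimum": 2},
        "classifier_accuracy": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
        "normal_epi_to_tumour_rate": {"type": "number", "minimum": 0, "maximum": 1},
        "fp_sensitivity": {"type": "number", "minimum": 0, "maximum": 1},
        "fp_specificity": {"type": "number", "minimum": 0, "maximum": 1},
        "tsr_methods": {"type": "array", "items": {"enum": list(TSR_METHODS)}},
        "seed": {"type": "integer", "minimum": 0},
    },
    "additionalProperties": False,
}


@dataclass
class PipelineConfig:
    """Tunable parameters of one pipeline run.

    ``box_px`` of 224 selects tile-by-tile mode. Classifier parameters feed
    the confusion-matrix simulator; plug in a real model by constructing the
    :class:`~wsisampler.classify.ClassifierBundle` yourself.
    """

    box_px: int = 640
    resample_iterations: int = 1
    per_box_cap: int = 5
    per_tumour: int = 4
    eps_px: float = 2000.0
    min_samples: int = 3
    classifier_accuracy: float = 0.79
    normal_epi_to_tumour_rate: float = 0.3
    fp_sensitivity: float = 0.927
    fp_specificity: float = 0.927
    tsr_methods: tuple[str, ...] = TSR_METHODS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_px not in (TILE_MODE_BOX, *GRID_SIZES):
            raise ParameterError(
                f"box_px must be one of {(TILE_MODE_BOX, *GRID_SIZES)}, got {self.box_px}"
            )
        if self.resample_iterations not in (1, 2):
            raise ParameterError("resample_iterations must be 1 or 2")
        unknown = set(self.tsr_methods) - set(TSR_METHODS)
        if unknown:
            raise ParameterError(f"unknown TSR methods {sorted(unknown)}")

    def bundle(self) -> ClassifierBundle:
        return ClassifierBundle(
            confusion=make_confusion(
                self.classifier_accuracy, self.normal_epi_to_tumour_rate
            ),
            fp_stage=FpStageSpec(
                sensitivity=self.fp_sensitivity, specificity=self.fp_specificity
            ),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tsr_methods"] = list(self.tsr_methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "tsr_methods" in d:
            d["tsr_methods"] = tuple(d["tsr_methods"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


@dataclass
class RunReport:
    """Everything one pipeline run produced, recomputable from its patch table."""

    slide_id: str
    mode: str  # "attention" | "tiled"
    config: PipelineConfig
    stage_counts: dict[int, int]
    total_patches: int
    hulls: list[Polygon]
    dice: float | None
    tumour_inside_pre: float | None
    tumour_inside_post: float | None
    tsr: dict[str, tsr_mod.TsrResult]
    tsr_skipped: dict[str, str]
    gt_point_tsr: float | None
    gt_area_tsr: float | None
    patches: list[Patch] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "mode": self.mode,
            "config": self.config.to_dict(),
            "stage_counts": {str(k): v for k, v in self.stage_counts.items()},
            "total_patches": self.total_patches,
            "n_predicted_roi_polygons": len(self.hulls),
            "dice": self.dice,
            "tumour_inside_pre_fpc_pct": self.tumour_inside_pre,
            "tumour_inside_post_fpc_pct": self.tumour_inside_post,
            "tsr": {
                m: {"T": r.T, "S": r.S, "value": r.value, "n_locations": len(r.locations)}
                for m, r in self.tsr.items()
            },
            "tsr_skipped": dict(self.tsr_skipped),
            "gt_point_tsr": self.gt_point_tsr,
            "gt_area_tsr": self.gt_area_tsr,
        }

    def save(self, out_dir: str | Path) -> None:
        """Write patches.csv, predicted_roi.geojson and report.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(patches_to_records(self.patches)).to_csv(
            out / "patches.csv", index=False
        )
        (out / "predicted_roi.geojson").write_text(
            json.dumps(roi_mod.hulls_to_geojson(self.hulls))
        )
        (out / "report.json").write_text(json.dumps(self.to_dict(), indent=2))


def _slide_id(slide: VirtualSlide) -> str:
    return f"{slide.seed}:{slide.width_px}x{slide.height_px}"


def _classify_stage(
    new_patches: list[Patch],
    slide: VirtualSlide,
    bundle: ClassifierBundle,
    rng: np.random.Generator,
) -> None:
    simulate_classify(new_patches, slide, bundle.confusion, rng)
    fp_correct(new_patches, bundle.fp_stage, slide, rng)


def _tumour_patches(patches: list[Patch]) -> list[Patch]:
    return [p for p in patches if p.pred_class == TissueClass.TUMOUR]


def _inside_fraction_pct(centres: list[tuple[float, float]], gt_roi) -> float | None:
    """Percentage of points inside the ground-truth ROI; None when empty."""
    if not centres:
        return None
    import shapely

    pts = np.asarray(centres, dtype=float)
    inside = shapely.intersects_xy(gt_roi, pts[:, 0], pts[:, 1])
    return 100.0 * float(inside.sum()) / len(centres)


def _run_tsr_methods(
    slide: VirtualSlide,
    patches: list[Patch],
    est: roi_mod.RoiEstimate,
    annotations: AnnotationSet | None,
    config: PipelineConfig,
    bundle: ClassifierBundle,
    rng: np.random.Generator,
) -> tuple[dict, dict]:
    results: dict[str, tsr_mod.TsrResult] = {}
    skipped: dict[str, str] = {}
    tumour_pts = np.array(
        [p.centre for p in _tumour_patches(patches)], dtype=float
    ).reshape(-1, 2)
    for method in config.tsr_methods:
        try:
            if method == "uniform_roi":
                results[method] = tsr_mod.tsr_uniform_roi(slide, est.hulls, bundle, rng)
            elif method == "box_max_density":
                results[method] = tsr_mod.tsr_box_max_density(
                    slide, tumour_pts, bundle, rng
                )
            elif method == "sliding_mean":
                results[method] = tsr_mod.tsr_sliding_mean(
                    patches, est.hulls, slide.dims
                )
            elif method == "gt_locations":
                if annotations is not None and annotations.sample_points:
                    pts = np.array(
                        [(x, y) for x, y, _ in annotations.sample_points], dtype=float
                    )
                else:
                    pts = np.array(
                        [
                            (x, y)
                            for x, y, _ in tsr_mod.gt_annotation_points(
                                slide
                            ).sample_points
                        ],
                        dtype=float,
                    )
                results[method] = tsr_mod.tsr_gt_locations(slide, pts, bundle, rng)
        except UndefinedMetricError as exc:
            skipped[method] = str(exc)
    return results, skipped


def _finish_report(
    slide: VirtualSlide,
    patches: list[Patch],
    est: roi_mod.RoiEstimate,
    annotations: AnnotationSet | None,
    config: PipelineConfig,
    bundle: ClassifierBundle,
    rng_tsr: np.random.Generator,
    mode: str,
) -> RunReport:
    """Metrics + TSR stages shared by both pipeline modes."""
    dice = roi_mod.dice_roi(est.hulls, slide.gt_roi, slide.dims, slide.raster_step)
    # pre-FPC tumour set = current tumour predictions plus those the FP
    # stage relabelled away; post-FPC = current tumour predictions only
    pre = _inside_fraction_pct(
        [
            p.centre
            for p in patches
            if p.pred_class == TissueClass.TUMOUR or p.fp_corrected
        ],
        slide.gt_roi,
    )
    try:
        post = tumour_inside_fraction(patches, slide.gt_roi)
    except UndefinedMetricError:
        post = None
    tsr_results, tsr_skipped = _run_tsr_methods(
        slide, patches, est, annotations, config, bundle, rng_tsr
    )
    if annotations is not None and annotations.sample_points:
        gt_tsr_points: AnnotationSet | None = annotations
    else:
        try:
            gt_tsr_points = tsr_mod.gt_annotation_points(slide)
        except UndefinedMetricError:
            gt_tsr_points = None
    try:
        gt_point = tsr_mod.gt_point_tsr(gt_tsr_points) if gt_tsr_points else None
    except UndefinedMetricError:
        gt_point = None
    try:
        gt_area = slide_model.gt_area_tsr(slide)
    except Exception:
        gt_area = None
    stage_counts: dict[int, int] = {}
    for p in patches:
        stage_counts[p.iteration] = stage_counts.get(p.iteration, 0) + 1
    return RunReport(
        slide_id=_slide_id(slide),
        mode=mode,
        config=config,
        stage_counts=dict(sorted(stage_counts.items())),
        total_patches=len(patches),
        hulls=est.hulls,
        dice=dice,
        tumour_inside_pre=pre,
        tumour_inside_post=post,
        tsr=tsr_results,
        tsr_skipped=tsr_skipped,
        gt_point_tsr=gt_point,
        gt_area_tsr=gt_area,
        patches=patches,
    )


def run_attention_pipeline(
    slide: VirtualSlide,
    config: PipelineConfig,
    annotations: AnnotationSet | None = None,
) -> RunReport:
    """Run the full attention-guided sampling pipeline on one slide."""
    if config.box_px == TILE_MODE_BOX:
        return run_tiled_reference(slide, config, annotations)
    ss = np.random.SeedSequence(config.seed)
    rng_sample, rng_classify, rng_tsr = (np.random.default_rng(s) for s in ss.spawn(3))
    bundle = config.bundle()

    grid = build_grid(slide.dims, config.box_px)
    patches = allocate_initial(grid, slide, rng_sample)
    _classify_stage(patches, slide, bundle, rng_classify)

    for it in range(1, config.resample_iterations + 1):
        new = allocate_resample(
            _tumour_patches(patches),
            patches,
            grid,
            slide,
            rng_sample,
            iteration=it,
            per_tumour=config.per_tumour,
            cap=config.per_box_cap,
        )
        _classify_stage(new, slide, bundle, rng_classify)
        patches.extend(new)

    tumour_pts = np.array(
        [p.centre for p in _tumour_patches(patches)], dtype=float
    ).reshape(-1, 2)
    est = roi_mod.estimate_roi(tumour_pts, config.eps_px, config.min_samples)

    fill = allocate_roi_fill(
        grid,
        est.hulls,
        patches,
        slide,
        rng_sample,
        iteration=config.resample_iterations + 1,
        cap=config.per_box_cap,
    )
    _classify_stage(fill, slide, bundle, rng_classify)
    patches.extend(fill)

    return _finish_report(
        slide, patches, est, annotations, config, bundle, rng_tsr, "attention"
    )


def run_tiled_reference(
    slide: VirtualSlide,
    config: PipelineConfig,
    annotations: AnnotationSet | None = None,
) -> RunReport:
    """Tile-by-tile reference: contiguous 224 px tiles, single iteration.

    Tiles that would extend past the slide edge are dropped; tiles centred
    on background are excluded, as in the attention mode.
    """
    ss = np.random.SeedSequence(config.seed)
    _, rng_classify, rng_tsr = (np.random.default_rng(s) for s in ss.spawn(3))
    bundle = config.bundle()
    tile = TILE_MODE_BOX
    width, height = slide.dims
    patches: list[Patch] = []
    d = slide.raster_step
    bg = slide_model.CLASS_CODES[TissueClass.BACKGROUND]
    for row in range(height // tile):
        for col in range(width // tile):
            x, y = col * tile, row * tile
            if slide.label_raster[(y + tile // 2) // d, (x + tile // 2) // d] == bg:
                continue
            patches.append(Patch(x=x, y=y, box_idx=(col, row), iteration=0))
    _classify_stage(patches, slide, bundle, rng_classify)
    tumour_pts = np.array(
        [p.centre for p in _tumour_patches(patches)], dtype=float
    ).reshape(-1, 2)
    est = roi_mod.estimate_roi(tumour_pts, config.eps_px, config.min_samples)
    tiled_config = dataclasses.replace(config, box_px=TILE_MODE_BOX)
    return _finish_report(
        slide, patches, est, annotations, tiled_config, bundle, rng_tsr, "tiled"
    )


def compare_runs(attention_report: RunReport, tiled_report: RunReport) -> dict:
    """Hardware-independent comparison of the two pipeline modes.

    The headline quantity is ``patch_count_ratio`` (tiled / attention): how
    many times fewer patches the attention pipeline needed to classify.
    """
    if attention_report.slide_id != tiled_report.slide_id:
        raise InputError(
            f"reports are for different slides: {attention_report.slide_id} "
            f"vs {tiled_report.slide_id}"
        )
    if attention_report.total_patches == 0:
        raise InputError("attention report holds zero patches")
    out = {
        "slide_id": attention_report.slide_id,
        "patch_count_ratio": tiled_report.total_patches
        / attention_report.total_patches,
        "dice_delta": None,
        "tsr_abs_error_delta": {},
    }
    if attention_report.dice is not None and tiled_report.dice is not None:
        out["dice_delta"] = attention_report.dice - tiled_report.dice
    gt = attention_report.gt_point_tsr
    if gt is not None:
        for m in set(attention_report.tsr) & set(tiled_report.tsr):
            out["tsr_abs_error_delta"][m] = abs(
                gt - attention_report.tsr[m].value
            ) - abs(gt - tiled_report.tsr[m].value)
    return out


def run_evaluation_set(
    slides: list[VirtualSlide | tuple[VirtualSlide, AnnotationSet | None]],
    config: PipelineConfig,
) -> dict:
    """Run the pipeline over a slide set and aggregate Dice and TSR errors.

    Per-slide seeds are spawned deterministically from ``config.seed``.
    Returns per-slide reports plus the mean Dice and, per TSR method, an
    RMSE / mean-error report against each slide's point-sampled ground
    truth.
    """
    if not slides:
        raise InputError("evaluation set is empty")
    reports: list[RunReport] = []
    child_seeds = np.random.SeedSequence(config.seed).generate_state(len(slides))
    for item, child in zip(slides, child_seeds):
        slide, ann = item if isinstance(item, tuple) else (item, None)
        cfg = dataclasses.replace(config, seed=int(child) % (2**31))
        reports.append(run_attention_pipeline(slide, cfg, ann))
    dices = [r.dice for r in reports if r.dice is not None]
    tsr_reports: dict[str, tsr_mod.TsrErrorReport] = {}
    for method in config.tsr_methods:
        pairs = [
            (r.gt_point_tsr, r.tsr[method].value)
            for r in reports
            if r.gt_point_tsr is not None and method in r.tsr
        ]
        if pairs:
            tsr_reports[method] = tsr_mod.error_report(pairs)
    return {
        "n_slides": len(reports),
        "reports": reports,
        "mean_dice": float(np.mean(dices)) if dices else None,
        "mean_total_patches": float(np.mean([r.total_patches for r in reports])),
        "tsr_error_reports": tsr_reports,
    }
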