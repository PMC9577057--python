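"""Coarse-grid construction and the three generations of sample patches.

The attention pipeline samples a slide in stages: one quasi-random 224 px
patch per coarse grid box, then densification of boxes where tumour was
detected (4 extra patches per tumour hit, capped at 5 per box), then a
uniform top-up of every box inside the predicted ROI to the same cap.
Throughout, the patch *top-left corner* is drawn uniformly over its grid
box — the patch itself may extend past the box's right/bottom edge (but
never past the slide edge). This reading is forced by the 5-patch cap: five
non-overlapping 224 px squares cannot fit wholly inside a 640 px box, but
their top-left corners can.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .errors import ParameterError
from .slide_model import CLASS_CODES, TissueClass, VirtualSlide

logger = logging.getLogger(__name__)

PATCH_PX = 224
_BACKGROUND = CLASS_CODES[TissueClass.BACKGROUND]


@dataclass(frozen=True)
class GridSpec:
    """Coarse square grid covering a slide with half-open boxes."""

    box_px: int
    n_cols: int
    n_rows: int
    slide_dims: tuple[int, int]

    def box_centre(self, col: int, row: int) -> tuple[float, float]:
        return ((col + 0.5) * self.box_px, (row + 0.5) * self.box_px)


@dataclass
class Patch:
    """One 224 px square sample patch.

    ``iteration`` is the sampling generation: 0 for the initial quasi-random
    allocation, 1..k for tumour-triggered resampling rounds, and the final
    index for the whole-ROI fill.
    """

    x: int
    y: int
    box_idx: tuple[int, int]
    iteration: int
    size_px: int = PATCH_PX
    gt_class: TissueClass | None = None
    pred_class: TissueClass | None = None
    fp_corrected: bool = False

    @property
    def centre(self) -> tuple[int, int]:
        return (self.x + self.size_px // 2, self.y + self.size_px // 2)


def overlaps(a: Patch, b: Patch) -> bool:
    """True iff two half-open 224 px squares intersect with positive area."""
    return (
        a.x < b.x + b.size_px
        and b.x < a.x + a.size_px
        and a.y < b.y + b.size_px
        and b.y < a.y + a.size_px
    )


def build_grid(slide_dims: tuple[int, int], box_px: int) -> GridSpec:
    """Divide a slide into a coarse square grid of half-open boxes.

    The grid fully covers the slide; last-row/column boxes may be clipped
    by the slide bounds for patch placement purposes.
    """
    width, height = slide_dims
    if box_px < PATCH_PX:
        raise ParameterError(f"box_px {box_px} smaller than patch size {PATCH_PX}")
    if width <= 0 or height <= 0:
        raise ParameterError(f"invalid slide dims {slide_dims}")
    return GridSpec(
        box_px=box_px,
        n_cols=math.ceil(width / box_px),
        n_rows=math.ceil(height / box_px),
        slide_dims=(width, height),
    )


def _draw_top_left(
    grid: GridSpec, col: int, row: int, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Uniform top-left corner over the box, clamped so the patch stays
    fully inside the slide. None when the box (clipped by the slide edge)
    admits no in-box placement."""
    width, height = grid.slide_dims
    x0 = col * grid.box_px
    y0 = row * grid.box_px
    x_hi = min((col + 1) * grid.box_px, width - PATCH_PX + 1)
    y_hi = min((row + 1) * grid.box_px, height - PATCH_PX + 1)
    if x_hi <= x0 or y_hi <= y0:
        return None
    return int(rng.integers(x0, x_hi)), int(rng.integers(y0, y_hi))


def _centre_is_background(slide: VirtualSlide, x: int, y: int) -> bool:
    d = slide.raster_step
    cx = x + PATCH_PX // 2
    cy = y + PATCH_PX // 2
    return slide.label_raster[cy // d, cx // d] == _BACKGROUND


def _by_box(patches: list[Patch]) -> dict[tuple[int, int], list[Patch]]:
    out: dict[tuple[int, int], list[Patch]] = {}
    for p in patches:
        out.setdefault(p.box_idx, []).append(p)
    return out


def allocate_initial(
    grid: GridSpec, slide: VirtualSlide, rng: np.random.Generator
) -> list[Patch]:
    """Allocate at most one patch per grid box, uniformly at random.

    A patch is retained only if the slide label at its centre is not
    background, so empty areas of the slide contribute no patches.
    """
    patches: list[Patch] = []
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            pos = _draw_top_left(grid, col, row, rng)
            if pos is None or _centre_is_background(slide, *pos):
                continue
            patches.append(Patch(x=pos[0], y=pos[1], box_idx=(col, row), iteration=0))
    return patches


def _free_position(
    grid: GridSpec,
    slide: VirtualSlide,
    box: tuple[int, int],
    occupants: list[Patch],
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Uniform draw over the exact set of clear top-left positions in a box.

    Equivalent in distribution to redrawing uniformly until a clear,
    non-background-centred spot is found — but terminates, and proves a
    dead-end when the free set is empty.
    """
    col, row = box
    width, height = grid.slide_dims
    x0, y0 = col * grid.box_px, row * grid.box_px
    x_hi = min((col + 1) * grid.box_px, width - PATCH_PX + 1)
    y_hi = min((row + 1) * grid.box_px, height - PATCH_PX + 1)
    if x_hi <= x0 or y_hi <= y0:
        return None
    xs = np.arange(x0, x_hi)
    ys = np.arange(y0, y_hi)
    d = slide.raster_step
    free = (
        slide.label_raster[np.ix_((ys + PATCH_PX // 2) // d, (xs + PATCH_PX // 2) // d)]
        != _BACKGROUND
    )
    for p in occupants:
        free[
            max(p.y - PATCH_PX + 1 - y0, 0) : p.y + PATCH_PX - y0,
            max(p.x - PATCH_PX + 1 - x0, 0) : p.x + PATCH_PX - x0,
        ] = False
    flat = np.flatnonzero(free)
    if flat.size == 0:
        return None
    pick = int(flat[rng.integers(flat.size)])
    return (x0 + pick % xs.size, y0 + pick // xs.size)


def _fill_box(
    grid: GridSpec,
    slide: VirtualSlide,
    box: tuple[int, int],
    existing: list[Patch],
    n_new: int,
    iteration: int,
    rng: np.random.Generator,
    max_retries: int,
) -> list[Patch]:
    """Place up to ``n_new`` patches in a box, re-drawing locations that
    overlap an existing same-box patch or land centre-on-background. After
    ``max_retries`` failed draws the free region is enumerated exactly and
    a position drawn uniformly from it; a slot is skipped (with a logged
    warning) only when no clear position exists at all."""
    added: list[Patch] = []
    col, row = box
    width, height = grid.slide_dims
    if (
        min((col + 1) * grid.box_px, width - PATCH_PX + 1) <= col * grid.box_px
        or min((row + 1) * grid.box_px, height - PATCH_PX + 1) <= row * grid.box_px
    ):
        return added  # edge box too thin for any in-box placement
    occupants = list(existing)
    for _ in range(n_new):
        placed = False
        for _attempt in range(max_retries):
            pos = _draw_top_left(grid, col, row, rng)
            if pos is None:
                break
            if _centre_is_background(slide, *pos):
                continue
            cand = Patch(x=pos[0], y=pos[1], box_idx=box, iteration=iteration)
            if any(overlaps(cand, other) for other in occupants):
                continue
            occupants.append(cand)
            added.append(cand)
            placed = True
            break
        if not placed:
            pos = _free_position(grid, slide, box, occupants, rng)
            if pos is None:
                logger.warning(
                    "box %s is fully blocked; patch slot skipped", box
                )
                continue
            cand = Patch(x=pos[0], y=pos[1], box_idx=box, iteration=iteration)
            occupants.append(cand)
            added.append(cand)
    return added


def allocate_resample(
    tumour_patches: list[Patch],
    all_patches: list[Patch],
    grid: GridSpec,
    slide: VirtualSlide,
    rng: np.random.Generator,
    *,
    iteration: int,
    per_tumour: int = 4,
    cap: int = 5,
    max_retries: int = 100,
) -> list[Patch]:
    """Densify sampling around detected tumour.

    For each grid box holding at least one tumour-predicted patch, up to
    ``per_tumour`` new patches per tumour hit are added, never exceeding
    ``cap`` total patches in the box. New placements are re-drawn until they
    overlap no existing patch of the same box (and are not centred on
    background); a slot is dropped, with a logged warning, only when the box
    holds no clear position at all.
    """
    by_box = _by_box(all_patches)
    tumour_boxes: dict[tuple[int, int], int] = {}
    for p in tumour_patches:
        tumour_boxes[p.box_idx] = tumour_boxes.get(p.box_idx, 0) + 1
    added: list[Patch] = []
    for box in sorted(tumour_boxes):
        existing = by_box.get(box, [])
        n_new = min(per_tumour * tumour_boxes[box], cap - len(existing))
        if n_new <= 0:
            continue
        added.extend(
            _fill_box(grid, slide, box, existing, n_new, iteration, rng, max_retries)
        )
    return added


def allocate_roi_fill(
    grid: GridSpec,
    hull_polygons: list[Polygon],
    all_patches: list[Patch],
    slide: VirtualSlide,
    rng: np.random.Generator,
    *,
    iteration: int,
    cap: int = 5,
    max_retries: int = 100,
) -> list[Patch]:
    """Top up every grid box whose centre lies inside the predicted ROI.

    Boxes inside the convex-hull union are filled to ``cap`` patches with
    the usual placement rules; boxes outside retain their original density.
    """
    if not hull_polygons:
        return []
    hull_union = unary_union(hull_polygons)
    by_box = _by_box(all_patches)
    centres_x = np.array(
        [(c + 0.5) * grid.box_px for r in range(grid.n_rows) for c in range(grid.n_cols)]
    )
    centres_y = np.array(
        [(r + 0.5) * grid.box_px for r in range(grid.n_rows) for c in range(grid.n_cols)]
    )
    inside = shapely.intersects_xy(hull_union, centres_x, centres_y)
    added: list[Patch] = []
    i = 0
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            if inside[i]:
                box = (col, row)
                existing = by_box.get(box, [])
                n_new = cap - len(existing)
                if n_new > 0:
                    added.extend(
                        _fill_box(
                            grid, slide, box, existing, n_new, iteration, rng,
                            max_retries,
                        )
                    )
            i += 1
    return added


def patches_to_records(patches: list[Patch]) -> list[dict]:
    """Rows for the CSV patch table."""
    return [
        {
            "x": p.x,
            "y": p.y,
            "size_px": p.size_px,
            "box_col": p.box_idx[0],
            "box_row": p.box_idx[1],
            "iteration": p.iteration,
            "gt_class": p.gt_class.value if p.gt_class else "",
            "pred_class": p.pred_class.value if p.pred_class else "",
            "fp_corrected": p.fp_corrected,
        }
        for p in patches
    ]
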