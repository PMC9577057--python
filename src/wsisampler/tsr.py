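"""Tumour–stroma-ratio (TSR) estimation and its sampling strategies.

TSR = T / (T + S), where T and S are the numbers of sampled patches
classified as tumour and as stroma/fibrosis. The ratio is prognostic in
colorectal cancer, and its accuracy depends heavily on *where* the patches
are sampled. Four strategies are implemented:

- ``uniform_roi``: 100 patches uniformly distributed over the predicted ROI;
- ``box_max_density``: 120 patches on a systematic-random triangular
  ("RandomSpot") lattice inside a 3 mm square box centred on the point of
  highest tumour-patch density — emulating how pathologists place their
  scoring field in point-annotation workflows;
- ``sliding_mean``: the unweighted mean of per-window TSRs over a sliding
  3 mm window across the predicted ROI;
- ``gt_locations``: classification at the pathologist's own ground-truth
  sampling points, bounding the achievable accuracy.

Accuracy across a slide set is summarised by RMSE and signed mean error
(ground truth minus estimate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .classify import ClassifierBundle, fp_correct, simulate_classify
from .errors import ParameterError, UndefinedMetricError
from .sampling import PATCH_PX, Patch
from .slide_model import CLASS_CODES, AnnotationSet, TissueClass, VirtualSlide

#: 3 mm square scoring box expressed in pixels at 0.49 um/px.
BOX_3MM_PX = 6122
#: Patch count of the in-box systematic-random layout.
RANDOMSPOT_N = 120
#: Minimum lattice pitch; adjacent spots closer than one patch width would
#: produce near-duplicate samples.
MIN_PITCH_PX = 224.0

_TUM = CLASS_CODES[TissueClass.TUMOUR]
_STR = CLASS_CODES[TissueClass.STROMA_FIBROSIS]


@dataclass
class TsrResult:
    """One TSR estimate with its supporting counts and sample locations."""

    method_id: str
    T: int
    S: int
    value: float
    locations: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


@dataclass
class TsrErrorReport:
    """RMSE and signed mean error of TSR estimates over a slide set."""

    n_slides: int
    rmse: float
    me: float
    pairs: list[tuple[float, float]] = field(default_factory=list)


def tsr_from_counts(T: int, S: int) -> float:
    """TSR = T / (T + S)."""
    if T < 0 or S < 0:
        raise ParameterError("counts must be non-negative")
    if T + S == 0:
        raise UndefinedMetricError("TSR undefined: no tumour or stroma patches")
    return T / (T + S)


def _largest_pitch(box_side_px: float, n_points: int) -> float:
    """Largest triangular-lattice pitch guaranteeing >= n points in the box
    for every random offset."""

    def guaranteed(p: float) -> int:
        row_h = p * math.sqrt(3.0) / 2.0
        return math.floor(box_side_px / row_h) * math.floor(box_side_px / p)

    # counts only change where box_side/p or box_side/row_h crosses an
    # integer; enumerate those candidate pitches and take the largest valid
    k_max = int(box_side_px / MIN_PITCH_PX) + 2
    cands = set()
    for k in range(1, k_max + 1):
        cands.add(box_side_px / k)  # floor(L/p) boundary
        cands.add(2.0 * box_side_px / (math.sqrt(3.0) * k))  # row-count boundary
    best = 0.0
    for p in cands:
        if p > best and guaranteed(p) >= n_points:
            best = p
    return best


def randomspot_layout(
    box_centre: tuple[float, float],
    box_side_px: float,
    n_points: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Systematic-random sampling points on a triangular lattice.

    Points lie on an equilateral-triangular (hexagonal-packing) lattice with
    a uniformly random offset and fixed orientation. The pitch is the
    largest value for which at least ``n_points`` lattice points fall inside
    the box for every offset; the first ``n_points`` in row-major order are
    returned.
    """
    if n_points < 1:
        raise ParameterError("n_points must be >= 1")
    pitch = _largest_pitch(box_side_px, n_points)
    if pitch < MIN_PITCH_PX:
        raise ParameterError(
            f"box of {box_side_px} px too small for {n_points} points at "
            f"minimum pitch {MIN_PITCH_PX} px"
        )
    row_h = pitch * math.sqrt(3.0) / 2.0
    ox = rng.uniform(0.0, pitch)
    oy = rng.uniform(0.0, row_h)
    x0 = box_centre[0] - box_side_px / 2.0
    y0 = box_centre[1] - box_side_px / 2.0
    pts: list[tuple[float, float]] = []
    j = 0
    while True:
        y = oy + j * row_h
        if y >= box_side_px:
            break
        shift = (ox + (pitch / 2.0 if j % 2 else 0.0)) % pitch
        n_in_row = math.floor((box_side_px - shift) / pitch) + 1 if shift < box_side_px else 0
        for i in range(n_in_row):
            pts.append((x0 + shift + i * pitch, y0 + y))
        j += 1
    if len(pts) < n_points:  # the pitch guarantee makes this unreachable
        raise ParameterError("lattice produced fewer points than guaranteed")
    return np.array(pts[:n_points])


def max_density_centre(
    tumour_points: np.ndarray,
    slide_dims: tuple[int, int],
    window_px: float = BOX_3MM_PX,
    stride_px: float | None = None,
) -> tuple[float, float]:
    """Centre of the axis-aligned window holding the most tumour points.

    Candidate centres lie on a ``stride_px`` lattice (default window/4),
    clamped so the window stays inside the slide; ties are broken by the
    smallest (y, x).
    """
    tumour_points = np.asarray(tumour_points, dtype=float).reshape(-1, 2)
    if tumour_points.shape[0] == 0:
        raise UndefinedMetricError("no tumour points to centre a window on")
    if stride_px is None:
        stride_px = window_px / 4.0
    width, height = slide_dims
    half = window_px / 2.0

    def axis_candidates(extent: float) -> np.ndarray:
        lo, hi = min(half, extent / 2.0), max(extent - half, extent / 2.0)
        n = int(math.floor((hi - lo) / stride_px)) + 1
        return lo + stride_px * np.arange(n)

    cxs = axis_candidates(width)
    cys = axis_candidates(height)
    px = tumour_points[:, 0]
    py = tumour_points[:, 1]
    in_x = (px[None, :] >= cxs[:, None] - half) & (px[None, :] < cxs[:, None] + half)
    in_y = (py[None, :] >= cys[:, None] - half) & (py[None, :] < cys[:, None] + half)
    counts = in_y.astype(np.int64) @ in_x.T.astype(np.int64)  # (n_cy, n_cx)
    iy, ix = np.unravel_index(np.argmax(counts), counts.shape)  # first max = smallest (y, x)
    return (float(cxs[ix]), float(cys[iy]))


def classify_at_points(
    slide: VirtualSlide,
    points: np.ndarray,
    bundle: ClassifierBundle,
    rng: np.random.Generator,
    iteration: int = -1,
) -> list[Patch]:
    """Classify fresh 224 px patches centred on the given points.

    Patch corners are clamped into the slide so every patch is fully
    readable; the FP-correction stage is applied.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    width, height = slide.dims
    patches = []
    for x, y in points:
        tlx = int(np.clip(round(x) - PATCH_PX // 2, 0, width - PATCH_PX))
        tly = int(np.clip(round(y) - PATCH_PX // 2, 0, height - PATCH_PX))
        patches.append(Patch(x=tlx, y=tly, box_idx=(-1, -1), iteration=iteration))
    simulate_classify(patches, slide, bundle.confusion, rng)
    fp_correct(patches, bundle.fp_stage, slide, rng)
    return patches


def _counts(patches: list[Patch]) -> tuple[int, int]:
    t = sum(1 for p in patches if p.pred_class == TissueClass.TUMOUR)
    s = sum(1 for p in patches if p.pred_class == TissueClass.STROMA_FIBROSIS)
    return t, s


def tsr_uniform_roi(
    slide: VirtualSlide,
    hulls: list[Polygon],
    bundle: ClassifierBundle,
    rng: np.random.Generator,
    n: int = 100,
) -> TsrResult:
    """TSR from ``n`` patches uniformly distributed over the predicted ROI.

    Centres are drawn by rejection sampling over the hull union, at least
    half a patch away from the slide edges.
    """
    union = unary_union([h for h in hulls if not h.is_empty]) if hulls else Polygon()
    if union.is_empty:
        raise UndefinedMetricError("predicted ROI is empty")
    width, height = slide.dims
    margin = PATCH_PX / 2.0
    minx, miny, maxx, maxy = union.bounds
    minx, maxx = max(minx, margin), min(maxx, width - margin)
    miny, maxy = max(miny, margin), min(maxy, height - margin)
    if not (maxx > minx and maxy > miny):
        raise UndefinedMetricError("predicted ROI has no valid sampling area")
    pts: list[tuple[float, float]] = []
    for _ in range(10_000):
        need = n - len(pts)
        if need <= 0:
            break
        xs = rng.uniform(minx, maxx, size=4 * need)
        ys = rng.uniform(miny, maxy, size=4 * need)
        keep = shapely.contains_xy(union, xs, ys)
        pts.extend(zip(xs[keep], ys[keep]))
    if len(pts) < n:
        raise UndefinedMetricError("rejection sampling failed to cover the ROI")
    locations = np.array(pts[:n])
    patches = classify_at_points(slide, locations, bundle, rng)
    t, s = _counts(patches)
    return TsrResult("uniform_roi", t, s, tsr_from_counts(t, s), locations)


def tsr_box_max_density(
    slide: VirtualSlide,
    tumour_points: np.ndarray,
    bundle: ClassifierBundle,
    rng: np.random.Generator,
    window_px: float = BOX_3MM_PX,
    n_points: int = RANDOMSPOT_N,
) -> TsrResult:
    """TSR from a RandomSpot layout in the 3 mm box of peak tumour density."""
    centre = max_density_centre(tumour_points, slide.dims, window_px)
    locations = randomspot_layout(centre, window_px, n_points, rng)
    patches = classify_at_points(slide, locations, bundle, rng)
    t, s = _counts(patches)
    return TsrResult("box_max_density", t, s, tsr_from_counts(t, s), locations)


def tsr_sliding_mean(
    classified_patches: list[Patch],
    hulls: list[Polygon],
    slide_dims: tuple[int, int],
    window_px: float = BOX_3MM_PX,
    stride_px: float | None = None,
    min_counts: int = 10,
) -> TsrResult:
    """Mean of per-window TSRs over a sliding 3 mm window across the ROI.

    A window participates iff its centre is inside the hull union and it
    holds at least ``min_counts`` tumour+stroma patches; the value is the
    unweighted mean of participating windows' TSRs.
    """
    if not classified_patches:
        raise UndefinedMetricError("no classified patches")
    if stride_px is None:
        stride_px = window_px / 2.0
    union = unary_union([h for h in hulls if not h.is_empty]) if hulls else Polygon()
    if union.is_empty:
        raise UndefinedMetricError("predicted ROI is empty")
    half = window_px / 2.0
    centres = np.array(
        [p.centre for p in classified_patches], dtype=float
    )
    codes = np.array(
        [
            0 if p.pred_class == TissueClass.TUMOUR
            else 1 if p.pred_class == TissueClass.STROMA_FIBROSIS
            else -1
            for p in classified_patches
        ]
    )
    width, height = slide_dims
    gx = np.arange(0.0, width + stride_px, stride_px)
    gy = np.arange(0.0, height + stride_px, stride_px)
    wxs, wys = np.meshgrid(gx, gy)
    inside = shapely.intersects_xy(union, wxs.ravel(), wys.ravel())
    values = []
    t_total = s_total = 0
    used_centres = []
    for cx, cy in zip(wxs.ravel()[inside], wys.ravel()[inside]):
        in_win = (
            (centres[:, 0] >= cx - half)
            & (centres[:, 0] < cx + half)
            & (centres[:, 1] >= cy - half)
            & (centres[:, 1] < cy + half)
        )
        t = int(np.sum(in_win & (codes == 0)))
        s = int(np.sum(in_win & (codes == 1)))
        if t + s >= min_counts:
            values.append(t / (t + s))
            t_total += t
            s_total += s
            used_centres.append((cx, cy))
    if not values:
        raise UndefinedMetricError("no sliding window met the minimum patch count")
    return TsrResult(
        "sliding_mean",
        t_total,
        s_total,
        float(np.mean(values)),
        np.array(used_centres),
    )


def tsr_gt_locations(
    slide: VirtualSlide,
    gt_points: np.ndarray,
    bundle: ClassifierBundle,
    rng: np.random.Generator,
) -> TsrResult:
    """TSR from classification at the pathologist's own sampling points."""
    gt_points = np.asarray(gt_points, dtype=float).reshape(-1, 2)
    if gt_points.shape[0] == 0:
        raise ParameterError("gt_points must be non-empty")
    patches = classify_at_points(slide, gt_points, bundle, rng)
    t, s = _counts(patches)
    return TsrResult("gt_locations", t, s, tsr_from_counts(t, s), gt_points)


def gt_annotation_points(
    slide: VirtualSlide, n_points: int = 50, seed: int | None = None
) -> AnnotationSet:
    """Emulate the pathologist's ground-truth point annotation of a slide.

    A 3 mm box is placed at the point of maximum ground-truth tumour-cell
    density and ``n_points`` locations are laid out on a RandomSpot lattice
    inside it; each point carries the true tissue class at its location.
    The layout is derived from the slide's own seed by default, making it a
    fixed property of the slide.
    """
    rng = np.random.default_rng(slide.seed if seed is None else seed)
    d = slide.raster_step
    rows, cols = np.nonzero(slide.label_raster == _TUM)
    if rows.size == 0:
        raise UndefinedMetricError("slide contains no tumour cells")
    cell_pts = np.column_stack([(cols + 0.5) * d, (rows + 0.5) * d])
    centre = max_density_centre(cell_pts, slide.dims, BOX_3MM_PX)
    pts = randomspot_layout(centre, BOX_3MM_PX, n_points, rng)
    codes = slide.label_codes_at(
        np.clip(pts[:, 0], 0, slide.width_px - 1),
        np.clip(pts[:, 1], 0, slide.height_px - 1),
    )
    from .slide_model import CODE_TO_CLASS

    samples = [
        (float(x), float(y), CODE_TO_CLASS[int(c)])
        for (x, y), c in zip(pts, codes)
    ]
    return AnnotationSet(roi_polygons=[slide.gt_roi], sample_points=samples)


def gt_point_tsr(ann: AnnotationSet) -> float:
    """Ground-truth TSR from annotated sample points (TSR_GT)."""
    t = sum(1 for *_xy, c in ann.sample_points if c == TissueClass.TUMOUR)
    s = sum(1 for *_xy, c in ann.sample_points if c == TissueClass.STROMA_FIBROSIS)
    return tsr_from_counts(t, s)


def error_report(pairs: list[tuple[float, float]]) -> TsrErrorReport:
    """RMSE and mean error of (TSR_GT, TSR_est) pairs across slides.

    The signed convention is ground truth minus estimate, so a positive
    mean error means the pipeline underestimates TSR.
    """
    if not pairs:
        raise UndefinedMetricError("error report requires at least one slide")
    arr = np.asarray(pairs, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ParameterError("TSR values must lie in [0, 1]")
    diff = arr[:, 0] - arr[:, 1]
    return TsrErrorReport(
        n_slides=len(pairs),
        rmse=float(np.sqrt(np.mean(diff**2))),
        me=float(np.mean(diff)),
        pairs=[tuple(p) for p in arr.tolist()],
    )
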