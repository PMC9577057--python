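"""Virtual-slide model: tissue classes, synthetic slide generation and I/O.

A :class:`VirtualSlide` stands in for a gigapixel whole-slide image (WSI).
Instead of pixels it carries a coarse label raster (one tissue class per
``raster_step`` × ``raster_step`` pixel cell) together with a ground-truth
tumour region-of-interest (ROI) polygon. A patch's ground-truth class is the
raster label at its centre pixel, mirroring the central-pixel convention used
when pathologists annotate point locations on real slides. This lets the
sampling and ROI-prediction machinery be exercised end-to-end, with exact
ground truth, without rendering any histology.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import shapely
from PIL import Image
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, mapping, shape

from .errors import (
    BoundsError,
    DegenerateSlideError,
    DimensionError,
    FormatError,
    ParameterError,
)


class TissueClass(str, Enum):
    """Tissue classes used for annotation and classification.

    The first nine labels form the output space of the patch classifier.
    ``BACKGROUND`` (no tissue) and ``NORMAL_EPITHELIUM`` (epithelium outside
    the tumour ROI that mimics tumour epithelium — the false-positive source)
    are ground-truth-only labels: a nine-class classifier never emits them.
    """

    NON_INFORMATIVE = "non_informative"
    TUMOUR = "tumour"
    STROMA_FIBROSIS = "stroma_fibrosis"
    NECROSIS = "necrosis"
    VESSELS = "vessels"
    INFLAMMATION = "inflammation"
    LUMEN = "lumen"
    MUCIN = "mucin"
    MUSCLE = "muscle"
    BACKGROUND = "background"
    NORMAL_EPITHELIUM = "normal_epithelium"


#: The nine classes a patch classifier can emit.
CLASSIFIER_CLASSES: tuple[TissueClass, ...] = (
    TissueClass.NON_INFORMATIVE,
    TissueClass.TUMOUR,
    TissueClass.STROMA_FIBROSIS,
    TissueClass.NECROSIS,
    TissueClass.VESSELS,
    TissueClass.INFLAMMATION,
    TissueClass.LUMEN,
    TissueClass.MUCIN,
    TissueClass.MUSCLE,
)

#: Stable integer codes used in the raster PNG. Background is 0 so an empty
#: (zero-initialised) raster is all background.
CLASS_CODES: dict[TissueClass, int] = {
    TissueClass.BACKGROUND: 0,
    TissueClass.NON_INFORMATIVE: 1,
    TissueClass.TUMOUR: 2,
    TissueClass.STROMA_FIBROSIS: 3,
    TissueClass.NECROSIS: 4,
    TissueClass.VESSELS: 5,
    TissueClass.INFLAMMATION: 6,
    TissueClass.LUMEN: 7,
    TissueClass.MUCIN: 8,
    TissueClass.MUSCLE: 9,
    TissueClass.NORMAL_EPITHELIUM: 10,
}

CODE_TO_CLASS: dict[int, TissueClass] = {v: k for k, v in CLASS_CODES.items()}

#: Default class mix of non-ROI tissue (the normal-epithelium band is
#: assigned separately, along the tissue border).
DEFAULT_OUTSIDE_COMPOSITION: dict[TissueClass, float] = {
    TissueClass.STROMA_FIBROSIS: 0.55,
    TissueClass.MUSCLE: 0.20,
    TissueClass.INFLAMMATION: 0.15,
    TissueClass.LUMEN: 0.10,
}

#: Default class mix inside the tumour ROI.
DEFAULT_INSIDE_COMPOSITION: dict[TissueClass, float] = {
    TissueClass.TUMOUR: 0.50,
    TissueClass.STROMA_FIBROSIS: 0.30,
    TissueClass.LUMEN: 0.05,
    TissueClass.NECROSIS: 0.05,
    TissueClass.INFLAMMATION: 0.04,
    TissueClass.MUCIN: 0.03,
    TissueClass.VESSELS: 0.03,
}

_FORMAT_VERSION = 1


@dataclass
class VirtualSlide:
    """Downsampled class-label raster standing in for a gigapixel WSI.

    Coordinates are 0-based level-0 pixels, x rightward, y downward, with
    half-open bounds ``[0, width_px) × [0, height_px)``.
    """

    width_px: int
    height_px: int
    microns_per_px: float
    raster_step: int
    label_raster: np.ndarray  # uint8 codes, shape (n_rows, n_cols)
    gt_roi: Polygon
    composition: dict[TissueClass, float]
    seed: int

    def __post_init__(self) -> None:
        d = self.raster_step
        expect = (math.ceil(self.height_px / d), math.ceil(self.width_px / d))
        if self.label_raster.shape != expect:
            raise DimensionError(
                f"label raster shape {self.label_raster.shape} does not match "
                f"slide dims {self.width_px}x{self.height_px} at step {d} "
                f"(expected {expect})"
            )

    @property
    def dims(self) -> tuple[int, int]:
        """(width_px, height_px)."""
        return (self.width_px, self.height_px)

    def label_codes_at(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Vectorised raster lookup for arrays of level-0 pixel coordinates."""
        xs = np.asarray(xs)
        ys = np.asarray(ys)
        if np.any((xs < 0) | (xs >= self.width_px) | (ys < 0) | (ys >= self.height_px)):
            raise BoundsError("coordinate outside slide bounds")
        d = self.raster_step
        return self.label_raster[
            (ys // d).astype(np.int64), (xs // d).astype(np.int64)
        ]

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Level-0 pixel coordinates of every raster cell centre (xs, ys grids)."""
        d = self.raster_step
        n_rows, n_cols = self.label_raster.shape
        cx = (np.arange(n_cols) + 0.5) * d
        cy = (np.arange(n_rows) + 0.5) * d
        return np.meshgrid(cx, cy)

    def roi_mask(self) -> np.ndarray:
        """Boolean raster mask of cells whose centre lies inside ``gt_roi``."""
        xs, ys = self.cell_centres()
        return shapely.contains_xy(self.gt_roi, xs, ys)


@dataclass
class AnnotationSet:
    """ROI polygons plus ground-truth classification points (level-0 pixels)."""

    roi_polygons: list[Polygon] = field(default_factory=list)
    sample_points: list[tuple[float, float, TissueClass]] = field(default_factory=list)
    coordinate_space: str = "level0_pixels"


def _validate_composition(composition: dict[TissueClass, float]) -> None:
    if not composition:
        raise ParameterError("composition must be non-empty")
    total = 0.0
    for cls, frac in composition.items():
        cls = TissueClass(cls)
        if cls in (TissueClass.BACKGROUND, TissueClass.NORMAL_EPITHELIUM):
            raise ParameterError(f"{cls.value} is not a valid in-ROI composition class")
        if frac < 0:
            raise ParameterError("composition fractions must be non-negative")
        total += frac
    if abs(total - 1.0) > 1e-9:
        raise ParameterError(f"composition fractions sum to {total}, expected 1")


def _star_convex_blob(
    target_area_px2: float,
    centre_bound_px: float,
    rng: np.random.Generator,
    n_theta: int = 1024,
) -> tuple[np.ndarray, float]:
    """Radii of a radial-noise-perturbed ellipse with the requested area.

    Returns ``(r, r_max)`` with ``r`` sampled on a uniform angle grid. The
    perturbation amplitude is progressively damped (down to a plain circle)
    until the blob fits inside a disc of radius ``centre_bound_px``.
    """
    n_harm = int(rng.integers(8, 17))
    ks = np.arange(2, 2 + n_harm)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_harm)
    raw = rng.uniform(0.3, 1.0, n_harm) / ks
    amp_total = rng.uniform(0.06, 0.12)
    amps = raw / raw.sum() * amp_total
    axis_ratio = rng.uniform(0.75, 1.0)

    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    for damp in (1.0, 0.5, 0.25, 0.0):
        a = amps * damp
        q = 1.0 - (1.0 - axis_ratio) * damp
        s = 1.0 + np.sum(
            a[:, None] * np.cos(ks[:, None] * theta[None, :] + phases[:, None]), axis=0
        )
        r_ell = 1.0 / np.sqrt(np.cos(theta) ** 2 + (np.sin(theta) / q) ** 2)
        rho = r_ell * s
        # polygon area of the radial curve via the shoelace formula on the
        # fine angle grid; scale radii so the area matches the target exactly
        unit_area = 0.5 * np.abs(
            np.sum(rho * np.roll(rho, -1) * np.sin(2.0 * np.pi / n_theta))
        )
        scale = math.sqrt(target_area_px2 / unit_area)
        r = rho * scale
        if r.max() <= centre_bound_px:
            return r, float(r.max())
    raise DimensionError(
        "requested ROI area cannot fit inside the tissue region of this slide"
    )


def _mask_to_polygon(mask: np.ndarray, step: int) -> Polygon:
    """Boundary polygon of the union of raster cells in ``mask``.

    Built from per-row run rectangles so the polygon covers exactly the
    masked cells; if the mask is disconnected the largest component is
    returned.
    """
    rects = []
    for r in np.flatnonzero(mask.any(axis=1)):
        row = mask[r]
        edges = np.diff(np.concatenate([[0], row.view(np.int8), [0]]))
        for c0, c1 in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
            rects.append(shapely.box(c0 * step, r * step, c1 * step, (r + 1) * step))
    merged = shapely.union_all(rects)
    if merged.is_empty:
        raise DimensionError("ROI rasterizes to no cells at this raster_step")
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    return merged


def _quantile_assign(
    raster: np.ndarray,
    mask: np.ndarray,
    fractions: dict[TissueClass, float],
    noise_field: np.ndarray,
) -> None:
    """Assign classes to ``mask`` cells by splitting a smooth noise field
    at the composition quantiles; realised fractions are exact to ±1 cell."""
    idx_rows, idx_cols = np.nonzero(mask)
    n = idx_rows.size
    if n == 0:
        return
    order = np.argsort(noise_field[mask], kind="stable")
    bounds = np.round(np.cumsum(list(fractions.values())) * n).astype(int)
    start = 0
    for cls, stop in zip(fractions, bounds):
        sel = order[start:stop]
        raster[idx_rows[sel], idx_cols[sel]] = CLASS_CODES[TissueClass(cls)]
        start = stop


def generate_slide(
    width_px: int,
    height_px: int,
    roi_area_fraction: float,
    composition: dict[TissueClass, float] | None = None,
    seed: int = 0,
    *,
    raster_step: int = 32,
    microns_per_px: float = 0.49,
    margin_fraction: float = 0.05,
    outside_composition: dict[TissueClass, float] | None = None,
    epithelium_band_px: float = 256.0,
    noise_sigma_cells: float = 4.0,
) -> VirtualSlide:
    """Generate a synthetic virtual slide with known ground truth.

    The slide consists of a background margin, a rectangular tissue region,
    a star-convex tumour ROI blob occupying ``roi_area_fraction`` of the
    tissue area, and — outside the ROI — normal tissue including a contiguous
    band of normal epithelium along the tissue border (the false-positive
    source for tumour classification). Classes inside and outside the ROI
    are laid down by thresholding low-frequency Gaussian noise fields at the
    composition quantiles, so realised class fractions match the request
    almost exactly while remaining spatially clumped at a sub-millimetre
    scale, as in real tissue.

    Parameters
    ----------
    width_px, height_px
        Level-0 pixel dimensions; must be at least ``50 * raster_step``.
    roi_area_fraction
        Fraction of the tissue area covered by the tumour ROI, in (0.01, 0.6).
    composition
        Target area fractions of the classes inside the ROI; must sum to 1.
        Defaults to :data:`DEFAULT_INSIDE_COMPOSITION`.
    seed
        Generation seed; identical parameters and seed give a bit-identical
        slide.
    """
    if composition is None:
        composition = dict(DEFAULT_INSIDE_COMPOSITION)
    composition = {TissueClass(k): float(v) for k, v in composition.items()}
    _validate_composition(composition)
    if outside_composition is None:
        outside_composition = dict(DEFAULT_OUTSIDE_COMPOSITION)
    _validate_composition(outside_composition)
    if not (0.01 < roi_area_fraction < 0.6):
        raise ParameterError(
            f"roi_area_fraction {roi_area_fraction} outside (0.01, 0.6)"
        )
    if min(width_px, height_px) < 50 * raster_step:
        raise DimensionError(
            f"slide dims {width_px}x{height_px} below 50x raster_step {raster_step}"
        )

    rng = np.random.default_rng(seed)
    d = raster_step
    n_rows = math.ceil(height_px / d)
    n_cols = math.ceil(width_px / d)

    cx = (np.arange(n_cols) + 0.5) * d
    cy = (np.arange(n_rows) + 0.5) * d
    xs, ys = np.meshgrid(cx, cy)

    mx = margin_fraction * width_px
    my = margin_fraction * height_px
    tissue = (xs >= mx) & (xs < width_px - mx) & (ys >= my) & (ys < height_px - my)
    tissue_area = float(tissue.sum()) * d * d

    # ROI blob: centred near the tissue centre, clamped to stay >= 2 cells
    # away from the tissue border so the normal-epithelium band never touches it
    half_w = (width_px - 2 * mx) / 2.0
    half_h = (height_px - 2 * my) / 2.0
    bound = min(half_w, half_h) - 2 * d
    radii, r_max = _star_convex_blob(roi_area_fraction * tissue_area, bound, rng)
    jitter_cap_x = min(half_w - r_max - 2 * d, 0.04 * width_px)
    jitter_cap_y = min(half_h - r_max - 2 * d, 0.04 * height_px)
    centre = np.array(
        [
            width_px / 2.0 + rng.uniform(-1, 1) * max(jitter_cap_x, 0.0),
            height_px / 2.0 + rng.uniform(-1, 1) * max(jitter_cap_y, 0.0),
        ]
    )
    rot = rng.uniform(0.0, np.pi)
    theta = np.linspace(0.0, 2.0 * np.pi, radii.size, endpoint=False)
    vx = centre[0] + radii * np.cos(theta + rot)
    vy = centre[1] + radii * np.sin(theta + rot)
    blob = Polygon(np.column_stack([vx, vy]))

    # snap the ROI outline to the boundary of its raster cells so polygon
    # containment and raster labels agree exactly everywhere
    inside = shapely.contains_xy(blob, xs, ys) & tissue
    gt_roi = _mask_to_polygon(inside, d)
    inside = shapely.contains_xy(gt_roi, xs, ys) & tissue

    raster = np.zeros((n_rows, n_cols), dtype=np.uint8)  # background
    outside = tissue & ~inside

    field_in = gaussian_filter(rng.standard_normal((n_rows, n_cols)), noise_sigma_cells)
    field_out = gaussian_filter(rng.standard_normal((n_rows, n_cols)), noise_sigma_cells)

    _quantile_assign(raster, inside, composition, field_in)

    edge_dist = np.minimum.reduce(
        [xs - mx, width_px - mx - xs, ys - my, height_px - my - ys]
    )
    epi_band = outside & (edge_dist < epithelium_band_px)
    bulk = outside & ~epi_band
    _quantile_assign(raster, bulk, outside_composition, field_out)
    raster[epi_band] = CLASS_CODES[TissueClass.NORMAL_EPITHELIUM]

    return VirtualSlide(
        width_px=width_px,
        height_px=height_px,
        microns_per_px=microns_per_px,
        raster_step=raster_step,
        label_raster=raster,
        gt_roi=gt_roi,
        composition=composition,
        seed=seed,
    )


def label_at(slide: VirtualSlide, x: float, y: float) -> TissueClass:
    """Ground-truth tissue class at a level-0 pixel coordinate.

    Pure raster lookup (no interpolation): returns
    ``label_raster[floor(y/D)][floor(x/D)]``. Bounds are half-open.
    """
    if not (0 <= x < slide.width_px and 0 <= y < slide.height_px):
        raise BoundsError(
            f"({x}, {y}) outside slide bounds {slide.width_px}x{slide.height_px}"
        )
    d = slide.raster_step
    code = slide.label_raster[int(y) // d, int(x) // d]
    return CODE_TO_CLASS[int(code)]


def gt_area_tsr(slide: VirtualSlide) -> float:
    """Ground-truth area-level tumour–stroma ratio inside the ROI.

    TSR = tumour cells / (tumour + stroma cells), counted over raster cells
    whose centre lies inside ``gt_roi``.
    """
    mask = slide.roi_mask()
    codes = slide.label_raster[mask]
    t = int(np.sum(codes == CLASS_CODES[TissueClass.TUMOUR]))
    s = int(np.sum(codes == CLASS_CODES[TissueClass.STROMA_FIBROSIS]))
    if t + s == 0:
        raise DegenerateSlideError("no tumour or stroma cells inside the ROI")
    return t / (t + s)


def write_slide(slide: VirtualSlide, path: str | Path) -> None:
    """Serialize a slide as an 8-bit label-raster PNG plus a JSON sidecar.

    ``path`` is the PNG path; the sidecar is written next to it with a
    ``.json`` suffix and records dimensions, resolution, the ROI polygon,
    composition, seed and the class-code table.
    """
    path = Path(path)
    Image.fromarray(slide.label_raster, mode="L").save(path, format="PNG")
    meta = {
        "format_version": _FORMAT_VERSION,
        "width_px": slide.width_px,
        "height_px": slide.height_px,
        "microns_per_px": slide.microns_per_px,
        "raster_step": slide.raster_step,
        "seed": slide.seed,
        "composition": {c.value: f for c, f in slide.composition.items()},
        "gt_roi": [[float(x), float(y)] for x, y in slide.gt_roi.exterior.coords],
        "class_codes": {c.value: code for c, code in CLASS_CODES.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_slide(path: str | Path) -> VirtualSlide:
    """Read a slide written by :func:`write_slide`; exact round-trip."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed sidecar {sidecar}: {exc}") from exc
    for key in ("width_px", "height_px", "raster_step", "gt_roi", "class_codes"):
        if key not in meta:
            raise FormatError(f"sidecar missing field {key!r}")
    raster = np.asarray(Image.open(path), dtype=np.uint8)
    file_codes = {k: int(v) for k, v in meta["class_codes"].items()}
    known = {c.value: code for c, code in CLASS_CODES.items()}
    if file_codes != known:
        raise FormatError("class-code table in sidecar does not match this package")
    valid = np.array(sorted(CODE_TO_CLASS), dtype=np.uint8)
    if not np.isin(raster, valid).all():
        bad = sorted(set(np.unique(raster)) - set(valid.tolist()))
        raise FormatError(f"raster contains unknown class codes {bad}")
    return VirtualSlide(
        width_px=int(meta["width_px"]),
        height_px=int(meta["height_px"]),
        microns_per_px=float(meta.get("microns_per_px", 0.49)),
        raster_step=int(meta["raster_step"]),
        label_raster=raster,
        gt_roi=Polygon(meta["gt_roi"]),
        composition={
            TissueClass(k): float(v) for k, v in meta.get("composition", {}).items()
        },
        seed=int(meta.get("seed", 0)),
    )


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    """Write ROI polygons and sample points as GeoJSON (level-0 pixel coords)."""
    features = []
    for poly in ann.roi_polygons:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {"role": "roi"},
            }
        )
    for x, y, cls in ann.sample_points:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                "properties": {"role": "sample", "tissue_class": TissueClass(cls).value},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs": "pixel:level0",
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a GeoJSON annotation file written by :func:`write_annotations`."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed GeoJSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise FormatError("annotation file is not a GeoJSON FeatureCollection")
    ann = AnnotationSet()
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        role = props.get("role")
        geom = feat.get("geometry") or {}
        if role == "roi":
            if geom.get("type") != "Polygon":
                raise FormatError(
                    f"ROI feature has geometry type {geom.get('type')!r}, "
                    "expected Polygon"
                )
            ann.roi_polygons.append(shape(geom))
        elif role == "sample":
            if geom.get("type") != "Point":
                raise FormatError("sample feature must have Point geometry")
            label = props.get("tissue_class")
            try:
                cls = TissueClass(label)
            except ValueError as exc:
                raise FormatError(f"unknown tissue_class {label!r}") from exc
            x, y = geom["coordinates"]
            ann.sample_points.append((float(x), float(y), cls))
        else:
            raise FormatError(f"feature with unknown role {role!r}")
    return ann
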