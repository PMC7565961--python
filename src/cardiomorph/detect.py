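"""Cardiomyocyte detection and morphological characterization.

From a binary cell mask, each 8-connected foreground component contributes
one external contour (holes are ignored).  Contours are filtered for
plausibility (area > 100 um^2, perimeter > 40 um), enclosed in a rotated
rectangle of minimum area, padded outward along the box diagonals, and
measured:

* L — cell length (um): mean of the long sides of the fitted and the padded
  rectangle,
* W — cell width (um): short side of the fitted rectangle,
* R = L / W, A = L * W,
* angle — orientation of the long axis, degrees in (-90, 90], measured from
  the +x (column) axis with y (rows) pointing down.

A second plausibility filter keeps cells with 20 < L < 200 um and
5 < W < 50 um (strict bounds).

Geometry conventions: continuous coordinates put the centre of pixel
``(row, col)`` at ``(col + 0.5, row + 0.5)``.  Contour vertices are traced at
the 0.5-intensity level around pixel centres (marching squares), which cuts
object corners at 45 degrees; contour area/perimeter are the shoelace area
and the Euclidean edge length of that polygon.  Rotated boxes are rasterized
with the pixel-centre-inside-or-on-boundary rule; the same rasterization is
shared with CX43 compartment counting and mask-agreement evaluation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Polygon
from skimage import measure as skmeasure

from .config import PipelineConfig
from .images import ChannelSet
from .masks import BinaryMask, build_masks

__all__ = [
    "DegenerateGeometryError",
    "SelectionError",
    "Contour",
    "RotatedBox",
    "CMRecord",
    "find_external_contours",
    "filter_contours",
    "fit_min_area_box",
    "expand_box",
    "measure_cm",
    "filter_boxes",
    "rasterize_box",
    "box_pixel_coords",
    "detect_from_mask",
    "detect_myocytes",
    "apply_selection",
]


class DegenerateGeometryError(ValueError):
    """Contour or box geometry is degenerate (collinear / zero-size)."""


class SelectionError(KeyError):
    """A selection manifest references an unknown cell id."""


# --------------------------------------------------------------------------
# contours


@dataclasses.dataclass
class Contour:
    """A closed boundary polygon of a foreground component.

    ``vertices`` is an (N, 2) array of (x, y) continuous coordinates without
    the closing duplicate; the polygon closes from the last vertex back to
    the first.
    """

    vertices: np.ndarray
    area_px2: float
    perim_px: float

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise DegenerateGeometryError("contour needs >= 3 (x, y) vertices")
        self.vertices = v


def _polygon_area_perim(verts: np.ndarray) -> tuple[float, float]:
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * yn - xn * y))
    perim = float(np.sum(np.hypot(xn - x, yn - y)))
    return float(area), perim


def find_external_contours(mask: BinaryMask) -> list[Contour]:
    """External boundary of every 8-connected foreground component.

    Holes are suppressed (components are filled before tracing) and the
    component discovery order is top-to-bottom, left-to-right by first pixel.
    """
    labels, n = ndimage.label(mask.pixels, structure=np.ones((3, 3), int))
    contours: list[Contour] = []
    for idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        comp = labels[sl] == idx
        filled = ndimage.binary_fill_holes(comp)
        padded = np.pad(filled, 1).astype(np.float64)
        traced = skmeasure.find_contours(padded, 0.5)
        if not traced:  # pragma: no cover - a component always has a boundary
            continue
        best = None
        best_area = -1.0
        r0 = sl[0].start
        c0 = sl[1].start
        for tr in traced:
            closed = np.allclose(tr[0], tr[-1])
            pts = tr[:-1] if closed else tr
            # (row, col) in the padded frame -> (x, y) continuous coordinates
            xy = np.column_stack([pts[:, 1] + c0 - 1 + 0.5, pts[:, 0] + r0 - 1 + 0.5])
            area, perim = _polygon_area_perim(xy)
            if area > best_area:
                best_area = area
                best = (xy, area, perim)
        assert best is not None
        contours.append(Contour(vertices=best[0], area_px2=best[1], perim_px=best[2]))
    return contours


def filter_contours(
    contours: Iterable[Contour],
    scale: float,
    min_area_um2: float = 100.0,
    min_perim_um: float = 40.0,
) -> list[Contour]:
    """Keep contours with area > min_area_um2 and perimeter > min_perim_um."""
    if not scale > 0:
        raise ValueError("scale must be positive")
    s2 = scale * scale
    return [
        c
        for c in contours
        if c.area_px2 * s2 > min_area_um2 and c.perim_px * scale > min_perim_um
    ]


# --------------------------------------------------------------------------
# rotated boxes


def _normalize_angle(deg: float) -> float:
    a = deg % 180.0
    if a > 90.0:
        a -= 180.0
    if a <= -90.0:
        a += 180.0
    return a


@dataclasses.dataclass
class RotatedBox:
    """A rotated rectangle: centre, long-axis angle, side lengths, corners.

    Corners are stored in ring order, so diagonal pairs are (0, 2) and
    (1, 3).  ``angle_deg`` is the direction of the long axis in (-90, 90].
    For square boxes the designated "long" axis follows the edge used at
    construction (first hull edge achieving the minimum area when fitted).
    """

    center: tuple[float, float]
    angle_deg: float
    long_px: float
    short_px: float
    vertices: np.ndarray

    def __post_init__(self) -> None:
        if not (self.long_px >= self.short_px > 0):
            raise DegenerateGeometryError(
                f"need long >= short > 0, got {self.long_px}, {self.short_px}"
            )
        self.vertices = np.asarray(self.vertices, float)
        if self.vertices.shape != (4, 2):
            raise DegenerateGeometryError("a box has exactly 4 (x, y) vertices")

    @classmethod
    def from_params(
        cls,
        center: tuple[float, float],
        angle_deg: float,
        long_px: float,
        short_px: float,
    ) -> "RotatedBox":
        t = np.deg2rad(angle_deg)
        u = np.array([np.cos(t), np.sin(t)]) * (long_px / 2.0)
        v = np.array([-np.sin(t), np.cos(t)]) * (short_px / 2.0)
        c = np.asarray(center, float)
        verts = np.array([c - u - v, c + u - v, c + u + v, c - u + v])
        return cls(
            center=(float(c[0]), float(c[1])),
            angle_deg=_normalize_angle(angle_deg),
            long_px=float(long_px),
            short_px=float(short_px),
            vertices=verts,
        )

    @classmethod
    def from_vertices(cls, verts: np.ndarray) -> "RotatedBox":
        verts = np.asarray(verts, float)
        if verts.shape != (4, 2):
            raise DegenerateGeometryError("expected 4 corner vertices")
        e0 = verts[1] - verts[0]
        e1 = verts[2] - verts[1]
        l0, l1 = float(np.hypot(*e0)), float(np.hypot(*e1))
        if min(l0, l1) <= 0:
            raise DegenerateGeometryError("zero-length box side")
        if l0 >= l1:
            long_px, short_px, axis = l0, l1, e0
        else:
            long_px, short_px, axis = l1, l0, e1
        angle = _normalize_angle(np.rad2deg(np.arctan2(axis[1], axis[0])))
        center = verts.mean(axis=0)
        return cls(
            center=(float(center[0]), float(center[1])),
            angle_deg=angle,
            long_px=long_px,
            short_px=short_px,
            vertices=verts,
        )

    @property
    def area_px2(self) -> float:
        return self.long_px * self.short_px

    @property
    def diagonal_px(self) -> float:
        return float(np.hypot(self.long_px, self.short_px))


def fit_min_area_box(contour: Contour | np.ndarray) -> RotatedBox:
    """Smallest-area rotated rectangle enclosing the contour vertices."""
    pts = contour.vertices if isinstance(contour, Contour) else np.asarray(contour, float)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points")
    rect = MultiPoint([tuple(p) for p in pts]).minimum_rotated_rectangle
    if not isinstance(rect, Polygon) or rect.area <= 0:
        raise DegenerateGeometryError("point set is collinear or degenerate")
    verts = np.asarray(rect.exterior.coords)[:4]
    return RotatedBox.from_vertices(verts)


def expand_box(box: RotatedBox, h: float) -> RotatedBox:
    """Pad a box by projecting each vertex outward along its diagonal.

    Vertex ``i`` moves a distance ``h`` away from its diagonal partner
    ``i + 2``; the result is a rectangle similar to the input with diagonal
    ``d + 2h``.
    """
    if h < 0:
        raise ValueError("padding distance h must be >= 0")
    if h == 0:
        return box
    v = box.vertices
    out = np.empty_like(v)
    for i in range(4):
        j = (i + 2) % 4
        diff = v[i] - v[j]
        d = float(np.hypot(*diff))
        if d <= 0:
            raise DegenerateGeometryError("zero diagonal")
        out[i] = v[i] + h * diff / d
    return RotatedBox.from_vertices(out)


def measure_cm(
    box: RotatedBox, box_expanded: RotatedBox, scale: float
) -> tuple[float, float, float, float]:
    """Morphometry (L, W, R, A) in um / um^2 from fitted and padded boxes."""
    if not scale > 0:
        raise ValueError("scale must be positive")
    L = scale * (box.long_px + box_expanded.long_px) / 2.0
    W = scale * box.short_px
    if W <= 0:
        raise DegenerateGeometryError("zero width")
    return L, W, L / W, L * W


# --------------------------------------------------------------------------
# rasterization (shared with CX43 quantification and mask evaluation)


def box_pixel_coords(
    box: RotatedBox, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pixels whose centres lie inside or on the box, clipped to the image.

    Returns ``(rows, cols, u, v)`` where ``u``/``v`` are the pixel-centre
    coordinates along the box long/short axes, measured from the box centre.
    """
    eps = 1e-9
    verts = box.vertices
    r_lo = max(int(np.floor(verts[:, 1].min())), 0)
    r_hi = min(int(np.ceil(verts[:, 1].max())), shape[0])
    c_lo = max(int(np.floor(verts[:, 0].min())), 0)
    c_hi = min(int(np.ceil(verts[:, 0].max())), shape[1])
    if r_hi <= r_lo or c_hi <= c_lo:
        empty = np.empty(0)
        return empty.astype(int), empty.astype(int), empty, empty
    rr, cc = np.meshgrid(
        np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij"
    )
    px = cc + 0.5 - box.center[0]
    py = rr + 0.5 - box.center[1]
    t = np.deg2rad(box.angle_deg)
    ux, uy = np.cos(t), np.sin(t)
    u = px * ux + py * uy
    v = -px * uy + py * ux
    inside = (np.abs(u) <= box.long_px / 2.0 + eps) & (
        np.abs(v) <= box.short_px / 2.0 + eps
    )
    return rr[inside], cc[inside], u[inside], v[inside]


def rasterize_box(box: RotatedBox, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the pixels covered by a box within an image."""
    rows, cols, _, _ = box_pixel_coords(box, shape)
    return rows, cols


# --------------------------------------------------------------------------
# records and the detection pipeline


@dataclasses.dataclass
class CMRecord:
    """Per-cell detection result: geometry, morphometry, CX43 quantities."""

    id: int
    box: RotatedBox
    box_expanded: RotatedBox
    L: float
    W: float
    R: float
    A: float
    angle_deg: float
    contour: Contour | None = None
    F: tuple[float, float, float, float] | None = None
    clat: float | None = None
    no_signal: bool = False

    @property
    def Fp(self) -> float | None:
        return None if self.F is None else self.F[0] + self.F[3]

    @property
    def Fl(self) -> float | None:
        return None if self.F is None else self.F[1] + self.F[2]


def filter_boxes(
    records: Iterable[CMRecord],
    length_um: tuple[float, float] = (20.0, 200.0),
    width_um: tuple[float, float] = (5.0, 50.0),
) -> list[CMRecord]:
    """Keep cells with strictly in-range length and width."""
    lo_l, hi_l = length_um
    lo_w, hi_w = width_um
    if not (lo_l < hi_l and lo_w < hi_w):
        raise ValueError("filter bounds must be ordered")
    return [
        r
        for r in records
        if lo_l < r.L < hi_l and lo_w < r.W < hi_w
    ]


def detect_from_mask(
    mask: BinaryMask, config: PipelineConfig, h: float | None = None
) -> list[CMRecord]:
    """Geometry pipeline on an existing CM mask (automatic or manual).

    Contour extraction -> plausibility filter -> min-area boxes -> padding ->
    morphometry -> size filter.  Ids are assigned sequentially in contour
    discovery order after filtering.
    """
    if h is None:
        h = config.resolved_h()
    contours = find_external_contours(mask)
    contours = filter_contours(
        contours, mask.scale, config.min_area_um2, config.min_perim_um
    )
    records: list[CMRecord] = []
    for c in contours:
        try:
            box = fit_min_area_box(c)
        except DegenerateGeometryError:
            continue
        box_exp = expand_box(box, h)
        L, W, R, A = measure_cm(box, box_exp, mask.scale)
        records.append(
            CMRecord(
                id=-1,
                box=box,
                box_expanded=box_exp,
                L=L,
                W=W,
                R=R,
                A=A,
                angle_deg=box.angle_deg,
                contour=c,
            )
        )
    records = filter_boxes(records, config.length_um, config.width_um)
    for i, r in enumerate(records):
        r.id = i
    return records


def detect_myocytes(channels: ChannelSet, config: PipelineConfig) -> list[CMRecord]:
    """Full unsupervised detection on a channel set.

    Builds the channel masks and the automatic CM mask, runs the geometry
    pipeline, and — when a CX43 channel is present — fills in the per-cell
    compartment fractions and lateralization.  A supervised-selection
    manifest in the config restricts the output to the listed ids.
    """
    all_masks = build_masks(channels, config)
    h = config.resolved_h(c2_present=channels.c2 is not None)
    records = detect_from_mask(all_masks["Ma"], config, h=h)
    if "Mc4" in all_masks:
        from .cx43 import annotate_records

        annotate_records(records, all_masks["Mc4"])
    if config.supervised_manifest is not None:
        records = apply_selection(records, config.supervised_manifest)
    return records


def apply_selection(records: Sequence[CMRecord], manifest: Iterable[int]) -> list[CMRecord]:
    """Non-interactive supervised mode: keep the listed ids, original order."""
    wanted = set(manifest)
    known = {r.id for r in records}
    unknown = wanted - known
    if unknown:
        raise SelectionError(f"manifest references unknown ids: {sorted(unknown)}")
    return [r for r in records if r.id in wanted]
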