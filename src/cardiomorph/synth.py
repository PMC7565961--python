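"""Synthetic fluorescence-like scenes with exact vector ground truth.

The generator emulates the image features the pipeline operates on, at
realistic tissue geometry: rectangular cell bodies 20-200 um long and
5-50 um wide at arbitrary orientations (channel c1), thin CX43 bands at the
cell poles — about 4 px thick at the 0.21 um/px human-image resolution —
plus a controllable lateral CX43 fraction along the long sides (channel c2),
a thin interstitial halo delimiting each cell (channel c3, WGA-like), and
optional salt noise and a brightness ramp.  CX43 is rendered at the channel
maximum (255) so that the fixed 254 threshold on the equalized channel
captures it; cell bodies are rendered mid-range.

Each rendered cell carries exact ground truth: its bounding box in pixel
coordinates and the actually planted lateral fraction of CX43 pixels, so a
pipeline-recovered lateralization can be compared against
``100 * lateral / (lateral + polar)`` without any manual annotation.

Lateral CX43 pixels are planted only in the middle half of the cell length,
so that under the four-quarter compartment rule they fall entirely in the
lateral compartments and the planted fraction is the expected Clat.  When a
requested lateral fraction exceeds what the lateral strips can host, polar
and lateral pixel counts are scaled down jointly to preserve the fraction.

All randomness (pixel sampling, noise, scene layout) is driven by a single
seed; rendering is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .detect import RotatedBox, box_pixel_coords
from .images import ChannelSet, GrayImage
from .masks import BinaryMask

__all__ = [
    "SceneError",
    "CellSpec",
    "SyntheticScene",
    "GroundTruthCell",
    "render_scene",
    "ground_truth_manual_mask",
    "sample_clat_population",
    "random_scene",
]

CELL_BODY_INTENSITY = 200
HALO_INTENSITY = 180
CX43_INTENSITY = 255


class SceneError(ValueError):
    """Invalid synthetic scene (out-of-bounds or overlapping cells)."""


@dataclasses.dataclass
class CellSpec:
    """One synthetic cell: centre (x, y) in px, orientation, size, phi.

    ``phi`` is the lateral fraction of the cell's CX43 pixel budget in
    [0, 1]: 0 plants polar-only signal, 1 lateral-only.
    """

    center: tuple[float, float]
    angle_deg: float
    L_um: float
    W_um: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise SceneError(f"phi must be in [0, 1], got {self.phi}")
        if self.L_um <= 0 or self.W_um <= 0:
            raise SceneError("cell dimensions must be positive")

    def box_px(self, scale: float) -> RotatedBox:
        L_px = self.L_um / scale
        W_px = self.W_um / scale
        long_px, short_px = max(L_px, W_px), min(L_px, W_px)
        return RotatedBox.from_params(self.center, self.angle_deg, long_px, short_px)


@dataclasses.dataclass
class SyntheticScene:
    """A full scene description; rendering is deterministic given the seed."""

    image_size: tuple[int, int] = (768, 768)
    scale: float = 0.21
    cells: list[CellSpec] = dataclasses.field(default_factory=list)
    cx43_band_px: int = 4
    lateral_band_px: int = 4
    noise_density: float = 0.0
    brightness_gradient: float | None = None
    seed: int = 0
    min_gap_px: int = 2
    allow_overlap: bool = False


@dataclasses.dataclass
class GroundTruthCell:
    """Exact per-cell ground truth of a rendered scene."""

    id: int
    box: RotatedBox
    L_um: float
    W_um: float
    angle_deg: float
    phi: float
    planted_clat: float | None
    n_polar_px: int
    n_lateral_px: int


def _check_in_bounds(box: RotatedBox, shape: tuple[int, int]) -> None:
    v = box.vertices
    if (
        v[:, 0].min() < 0
        or v[:, 1].min() < 0
        or v[:, 0].max() > shape[1]
        or v[:, 1].max() > shape[0]
    ):
        raise SceneError("cell box extends beyond the image bounds")


def _plant_cx43(
    rng: np.random.Generator,
    box: RotatedBox,
    rows: np.ndarray,
    cols: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    phi: float,
    band_px: int,
    lateral_band_px: int,
) -> tuple[tuple[np.ndarray, np.ndarray], int, int]:
    """Choose the CX43 pixel set of one cell.

    Polar candidates are the body pixels within ``band_px`` of either pole;
    lateral candidates hug the two long sides (within ``lateral_band_px`` of
    them) restricted to the middle half of the length.  Counts are chosen so
    that lateral/(lateral+polar) equals ``phi`` as closely as the candidate
    pools allow, scaling the total down when one pool is the bottleneck.
    """
    t = u + box.long_px / 2.0
    polar = (t < band_px) | (t > box.long_px - band_px)
    lateral = (
        (np.abs(v) > box.short_px / 2.0 - lateral_band_px)
        & (t >= box.long_px / 4.0)
        & (t <= 3.0 * box.long_px / 4.0)
        & ~polar
    )
    cap_pol = int(polar.sum())
    cap_lat = int(lateral.sum())
    if phi <= 0.0:
        n_pol, n_lat = cap_pol, 0
    elif phi >= 1.0:
        n_pol, n_lat = 0, cap_lat
    else:
        total = min(cap_pol / (1.0 - phi), cap_lat / phi)
        n_lat = int(round(total * phi))
        n_pol = int(round(total * (1.0 - phi)))
        n_lat = min(n_lat, cap_lat)
        n_pol = min(n_pol, cap_pol)
    sel = np.zeros(rows.size, bool)
    pol_idx = np.flatnonzero(polar)
    lat_idx = np.flatnonzero(lateral)
    if n_pol > 0:
        sel[rng.choice(pol_idx, size=n_pol, replace=False)] = True
    if n_lat > 0:
        sel[rng.choice(lat_idx, size=n_lat, replace=False)] = True
    return (rows[sel], cols[sel]), n_pol, n_lat


def render_scene(
    scene: SyntheticScene,
) -> tuple[ChannelSet, list[GroundTruthCell]]:
    """Render a scene into channels c1-c3 (c4 mirrors c2) plus ground truth."""
    shape = scene.image_size
    rng = np.random.default_rng(scene.seed)
    c1 = np.zeros(shape, np.uint8)
    c2 = np.zeros(shape, np.uint8)
    c3 = np.zeros(shape, np.uint8)
    occupancy = np.zeros(shape, bool)
    truth: list[GroundTruthCell] = []

    for i, cell in enumerate(scene.cells):
        box = cell.box_px(scene.scale)
        _check_in_bounds(box, shape)
        rows, cols, u, v = box_pixel_coords(box, shape)
        if rows.size == 0:
            raise SceneError(f"cell {i} rasterizes to an empty pixel set")
        body = np.zeros(shape, bool)
        body[rows, cols] = True
        footprint = ndimage.binary_dilation(
            body, np.ones((2 * scene.min_gap_px + 1,) * 2, bool)
        )
        if not scene.allow_overlap and (occupancy & footprint).any():
            raise SceneError(f"cell {i} violates the minimum inter-cell gap")
        occupancy |= footprint

        c1[rows, cols] = CELL_BODY_INTENSITY
        halo = ndimage.binary_dilation(body, np.ones((3, 3), bool)) & ~body
        c3[halo] = HALO_INTENSITY

        (cx_rows, cx_cols), n_pol, n_lat = _plant_cx43(
            rng, box, rows, cols, u, v, cell.phi,
            scene.cx43_band_px, scene.lateral_band_px,
        )
        c2[cx_rows, cx_cols] = CX43_INTENSITY
        planted = (
            None if n_pol + n_lat == 0 else 100.0 * n_lat / (n_pol + n_lat)
        )
        truth.append(
            GroundTruthCell(
                id=i,
                box=box,
                L_um=cell.L_um,
                W_um=cell.W_um,
                angle_deg=box.angle_deg,
                phi=cell.phi,
                planted_clat=planted,
                n_polar_px=n_pol,
                n_lateral_px=n_lat,
            )
        )

    for plane in (c1, c2, c3):
        if scene.noise_density > 0:
            salt = rng.random(shape) < scene.noise_density
            plane[salt] = 255
        if scene.brightness_gradient is not None:
            ramp = 1.0 - scene.brightness_gradient * (
                np.arange(shape[1]) / max(shape[1] - 1, 1)
            )
            np.multiply(plane, ramp[np.newaxis, :], out=plane, casting="unsafe")

    return (
        ChannelSet(
            c1=GrayImage(c1, scene.scale),
            c2=GrayImage(c2, scene.scale),
            c3=GrayImage(c3, scene.scale),
        ),
        truth,
    )


def ground_truth_manual_mask(scene: SyntheticScene) -> BinaryMask:
    """Union of the rasterized ground-truth cell boxes (stands in for a
    manually delineated CM mask; synthetic, not expert-drawn)."""
    shape = scene.image_size
    px = np.zeros(shape, bool)
    for cell in scene.cells:
        box = cell.box_px(scene.scale)
        _check_in_bounds(box, shape)
        rows, cols, _, _ = box_pixel_coords(box, shape)
        px[rows, cols] = True
    return BinaryMask(px, role="Mm", scale=scene.scale)


def sample_clat_population(
    n: int, rate: float, hi: float = 100.0, seed: int = 0
) -> np.ndarray:
    """Draws from an exponential(rate) truncated to [0, hi], via inverse CDF."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rate <= 0 or hi <= 0:
        raise ValueError("rate and truncation bound must be positive")
    rng = np.random.default_rng(seed)
    uu = rng.random(n)
    tail = 1.0 - np.exp(-rate * hi)
    return -np.log1p(-uu * tail) / rate


def random_scene(
    n_cells: int = 5,
    seed: int = 0,
    image_size: tuple[int, int] = (1024, 1024),
    scale: float = 0.21,
    length_um: tuple[float, float] = (30.0, 70.0),
    width_um: tuple[float, float] = (10.0, 30.0),
    phis: Sequence[float] = (0.0, 0.2, 0.5, 0.8, 1.0),
    noise_density: float = 0.0,
    max_tries: int = 500,
) -> SyntheticScene:
    """A reproducible scene of non-overlapping random cells.

    Cells are placed by rejection sampling: candidate centre/orientation
    pairs are drawn until the cell footprint (dilated by the minimum gap)
    avoids all previously placed cells and stays inside the image.
    """
    rng = np.random.default_rng(seed)
    shape = image_size
    occupancy = np.zeros(shape, bool)
    cells: list[CellSpec] = []
    gap = 2
    for i in range(n_cells):
        L = float(rng.uniform(*length_um))
        W = float(rng.uniform(*width_um))
        phi = float(phis[i % len(phis)])
        placed = False
        for _ in range(max_tries):
            angle = float(rng.uniform(-90.0, 90.0))
            half_diag = 0.5 * np.hypot(L / scale, W / scale) + gap + 2
            cx = float(rng.uniform(half_diag, shape[1] - half_diag))
            cy = float(rng.uniform(half_diag, shape[0] - half_diag))
            cand = CellSpec(center=(cx, cy), angle_deg=angle, L_um=L, W_um=W, phi=phi)
            box = cand.box_px(scale)
            v = box.vertices
            if (
                v[:, 0].min() < 0
                or v[:, 1].min() < 0
                or v[:, 0].max() > shape[1]
                or v[:, 1].max() > shape[0]
            ):
                continue
            rows, cols, _, _ = box_pixel_coords(box, shape)
            body = np.zeros(shape, bool)
            body[rows, cols] = True
            footprint = ndimage.binary_dilation(
                body, np.ones((2 * gap + 1,) * 2, bool)
            )
            if (occupancy & footprint).any():
                continue
            occupancy |= footprint
            cells.append(cand)
            placed = True
            break
        if not placed:
            raise SceneError(
                f"could not place cell {i} after {max_tries} attempts; "
                "reduce cell sizes or count"
            )
    return SyntheticScene(
        image_size=image_size,
        scale=scale,
        cells=cells,
        noise_density=noise_density,
        seed=seed,
        min_gap_px=gap,
    )
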