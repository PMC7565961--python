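"""Raster I/O and calibrated grayscale channels.

Fluorescence channels are handled as 8-bit grayscale rasters with a physical
calibration (micrometres per pixel).  Channel roles follow the convention of
the downstream pipeline:

* ``c1`` — cardiomyocyte body marker (SERCA2 or F-actin),
* ``c2`` — connexin-43 (CX43),
* ``c3`` — interstitium (e.g. WGA), optional,
* ``c4`` — duplicate of ``c2`` reserved for CX43 quantification.

Coordinate convention used throughout the package: row-major arrays, origin
at the top-left, 0-based indices.  In continuous coordinates pixel
``(row, col)`` spans ``[col, col+1) x [row, row+1)`` so its centre is at
``(col + 0.5, row + 0.5)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "DimensionError",
    "ConfigurationError",
    "GrayImage",
    "ChannelSet",
    "to_grayscale",
    "equalize_histogram",
    "split_merged",
    "load_channels",
    "read_raster",
    "save_gray",
    "px_to_um",
    "area_px_to_um2",
]


class DimensionError(ValueError):
    """Raster dimensions are inconsistent."""


class ConfigurationError(ValueError):
    """Invalid channel/role configuration."""


@dataclasses.dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale raster with a micrometre-per-pixel calibration."""

    pixels: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise DimensionError(f"expected a 2-D raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass
class ChannelSet:
    """Calibrated channels sharing dimensions and scale.

    ``c4`` is materialised automatically as a copy of ``c2`` when ``c2`` is
    present; it is the channel CX43 quantification operates on.
    """

    c1: GrayImage
    c2: GrayImage | None = None
    c3: GrayImage | None = None
    c4: GrayImage | None = None

    def __post_init__(self) -> None:
        if self.c2 is not None and self.c4 is None:
            self.c4 = GrayImage(self.c2.pixels.copy(), self.c2.scale)
        for name in ("c2", "c3", "c4"):
            ch = getattr(self, name)
            if ch is None:
                continue
            if ch.shape != self.c1.shape:
                raise DimensionError(
                    f"channel {name} shape {ch.shape} != c1 shape {self.c1.shape}"
                )
            if ch.scale != self.c1.scale:
                raise ValueError(f"channel {name} scale differs from c1")

    @property
    def scale(self) -> float:
        return self.c1.scale

    @property
    def shape(self) -> tuple[int, int]:
        return self.c1.shape

    @property
    def n_channels(self) -> int:
        return 1 + (self.c2 is not None) + (self.c3 is not None)


def to_grayscale(rgb: np.ndarray, scale: float = 1.0) -> GrayImage:
    """Average the R, G and B planes into an 8-bit grayscale image.

    Rounding is half-up on the arithmetic mean, so e.g. (10, 20, 40) -> 23.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise DimensionError(f"expected an (H, W, 3) raster, got shape {rgb.shape}")
    mean = rgb[..., :3].astype(np.float64).mean(axis=2)
    out = np.clip(np.floor(mean + 0.5), 0, 255).astype(np.uint8)
    return GrayImage(out, scale)


def _equalization_lut(pixels: np.ndarray) -> np.ndarray:
    hist = np.bincount(pixels.ravel(), minlength=256)
    present = np.nonzero(hist)[0]
    if present.size <= 1:
        # Degenerate histogram (a single gray level): the remapping is the
        # identity, so a constant image stays at its original level.
        return np.arange(256, dtype=np.uint8)
    cdf = np.cumsum(hist)
    cdf_min = cdf[present[0]]
    n = pixels.size
    lut = np.floor((cdf - cdf_min) / (n - cdf_min) * 255.0 + 0.5)
    return np.clip(lut, 0, 255).astype(np.uint8)


def equalize_histogram(img: GrayImage) -> GrayImage:
    """Global 8-bit histogram equalization.

    The remapping is the cumulative-distribution transfer function
    ``lut[v] = round(255 * (cdf[v] - cdf_min) / (N - cdf_min))`` where
    ``cdf_min`` is the cumulative count at the lowest occupied level.  It is
    monotone non-decreasing, maps the lowest occupied level to 0 and the
    highest to 255.  Single-level images are returned unchanged.
    """
    lut = _equalization_lut(img.pixels)
    return GrayImage(lut[img.pixels], img.scale)


_PLANE_INDEX = {"red": 0, "green": 1, "blue": 2}


def _extract_plane(rgb: np.ndarray, plane: str) -> np.ndarray:
    if plane in _PLANE_INDEX:
        return rgb[..., _PLANE_INDEX[plane]]
    if plane == "white":
        # White signal is high in all three planes; the pixelwise minimum
        # recovers it without leaking pure-colour regions.
        return rgb[..., :3].min(axis=2)
    if plane == "gray":
        return np.clip(
            np.floor(rgb[..., :3].astype(np.float64).mean(axis=2) + 0.5), 0, 255
        )
    raise ConfigurationError(f"unknown plane spec {plane!r}")


def split_merged(
    rgb: np.ndarray, role_assignment: Mapping[str, str], scale: float = 1.0
) -> ChannelSet:
    """Split a merged RGB image into channel roles.

    ``role_assignment`` maps channel roles (``c1``..``c3``) to plane specs:
    ``red``/``green``/``blue`` select a single plane, ``white`` takes the
    pixelwise minimum of the three planes (white staining is high in all of
    them), ``gray`` averages them.  ``c1`` must be assigned; ``c4`` is copied
    from ``c2`` when present.
    """
    rgb = np.asarray(rgb)
    if "c1" not in role_assignment:
        raise ConfigurationError("role assignment must include c1")
    if rgb.ndim == 2:
        # Single-plane input: only a c1-only assignment makes sense.
        extra = set(role_assignment) - {"c1"}
        if extra:
            raise ConfigurationError(
                f"single-plane image cannot provide roles {sorted(extra)}"
            )
        return ChannelSet(c1=GrayImage(rgb.astype(np.uint8), scale))
    channels: dict[str, GrayImage] = {}
    for role in ("c1", "c2", "c3"):
        if role in role_assignment:
            plane = _extract_plane(rgb, role_assignment[role])
            channels[role] = GrayImage(plane.astype(np.uint8), scale)
    return ChannelSet(c1=channels["c1"], c2=channels.get("c2"), c3=channels.get("c3"))


def read_raster(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG raster as an 8-bit array (gray or RGB).

    Higher bit depths are linearly rescaled to the 8-bit range, since all
    pipeline thresholds are defined on [0, 255].
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer):
        top = np.iinfo(arr.dtype).max
        return np.floor(arr.astype(np.float64) * (255.0 / top) + 0.5).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(np.floor(arr * 255.0 + 0.5), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported raster dtype {arr.dtype}")


def save_gray(pixels: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit single-channel raster as TIFF or PNG."""
    path = Path(path)
    pixels = np.ascontiguousarray(pixels, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), pixels)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), pixels)


def _load_one(path: str | Path, scale: float) -> GrayImage:
    arr = read_raster(path)
    if arr.ndim == 3:
        return to_grayscale(arr, scale)
    return GrayImage(arr, scale)


def load_channels(
    paths: Mapping[str, str | Path] | None = None,
    *,
    merged: str | Path | None = None,
    role_assignment: Mapping[str, str] | None = None,
    scale: float,
    equalize: bool | Mapping[str, bool] = False,
) -> ChannelSet:
    """Load a :class:`ChannelSet` from per-channel files or a merged image.

    Exactly one of ``paths`` (mapping roles ``c1``..``c3`` to files) or
    ``merged`` (an RGB file split through ``role_assignment``) must be given.
    ``equalize`` applies per-channel histogram equalization, either globally
    (bool) or per role (mapping).
    """
    if (paths is None) == (merged is None):
        raise ConfigurationError("provide either per-channel paths or a merged image")
    if merged is not None:
        if role_assignment is None:
            raise ConfigurationError("a merged image requires a role assignment")
        rgb = read_raster(merged)
        cs = split_merged(rgb, role_assignment, scale)
    else:
        assert paths is not None
        if "c1" not in paths:
            raise ConfigurationError("channel paths must include c1")
        loaded = {role: _load_one(p, scale) for role, p in paths.items()}
        shapes = {im.shape for im in loaded.values()}
        if len(shapes) > 1:
            raise DimensionError(f"channel files have mismatched shapes: {shapes}")
        cs = ChannelSet(c1=loaded["c1"], c2=loaded.get("c2"), c3=loaded.get("c3"))

    def wants(role: str) -> bool:
        if isinstance(equalize, Mapping):
            return bool(equalize.get(role, False))
        return bool(equalize)

    out = {}
    for role in ("c1", "c2", "c3"):
        ch = getattr(cs, role)
        if ch is not None and wants(role):
            ch = equalize_histogram(ch)
        out[role] = ch
    # c4 mirrors c2 before any equalization choice for c2: it is re-derived
    # from the (possibly equalized) c2 and equalized again later inside the
    # CX43 mask builder, which always equalizes.
    return ChannelSet(c1=out["c1"], c2=out["c2"], c3=out["c3"])


def px_to_um(value_px: float, scale: float) -> float:
    """Convert a length in pixels to micrometres (``value * scale``)."""
    if not scale > 0:
        raise ValueError("scale must be positive")
    return value_px * scale


def area_px_to_um2(value_px2: float, scale: float) -> float:
    """Convert an area in squared pixels to squared micrometres."""
    if not scale > 0:
        raise ValueError("scale must be positive")
    return value_px2 * scale * scale
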