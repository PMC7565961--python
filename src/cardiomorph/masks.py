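"""Binary mask construction.

Grayscale channels become binary masks through thresholding followed by
morphological cleanup (opening to delete small isolated noise objects, then
repeated dilation to re-grow object boundaries).  The cleaned channel masks
are combined into:

* ``Ma`` — the automatic cardiomyocyte mask: a ``Mc1`` pixel survives unless
  it is active in *both* ``Mc2`` and ``Mc3``,
* ``Mt`` — the tissue mask: the union of ``Mc1``, ``Mc2`` and ``Mc3``,
* ``Mc4`` — the CX43 quantification mask: ``c2`` equalized and thresholded at
  the fixed value 254 (~the top 1% of the equalized intensity range), with no
  noise removal and no growth.

Morphology conventions: square windows of rank ``n`` (side length ``n``),
centred for odd ``n``; for even ``n`` the anchor sits at the top-left pixel of
the central 2x2 block.  Out-of-image pixels are background (zero padding).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .config import ChannelParams, PipelineConfig
from .images import ChannelSet, DimensionError, GrayImage, equalize_histogram

__all__ = [
    "BinaryMask",
    "binarize",
    "denoise_open",
    "grow",
    "build_channel_mask",
    "combine_automatic_mask",
    "build_cx43_mask",
    "build_tissue_mask",
    "build_masks",
]


@dataclasses.dataclass
class BinaryMask:
    """A boolean raster with a role tag and physical calibration."""

    pixels: np.ndarray
    role: str = "M"
    scale: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise DimensionError(f"expected a 2-D mask, got shape {px.shape}")
        self.pixels = px.astype(bool)
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.pixels.sum())


def binarize(img: GrayImage, thr: int, role: str = "M") -> BinaryMask:
    """Threshold an 8-bit channel: pixel active iff intensity > thr."""
    if not 0 <= thr <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {thr}")
    return BinaryMask(img.pixels > thr, role=role, scale=img.scale)


def _dilate(px: np.ndarray, n: int) -> np.ndarray:
    if n == 1:
        return px.copy()
    return ndimage.maximum_filter(px, size=n, mode="constant", cval=False)


def _erode(px: np.ndarray, n: int) -> np.ndarray:
    if n == 1:
        return px.copy()
    return ndimage.minimum_filter(px, size=n, mode="constant", cval=False)


def denoise_open(mask: BinaryMask, nr: int) -> BinaryMask:
    """Morphological opening (erosion then dilation) with an nr x nr window.

    Rank 1 is the identity.  Objects smaller than the window are deleted;
    larger objects are preserved up to boundary re-growth.
    """
    if nr < 1:
        raise ValueError("nr must be >= 1")
    return BinaryMask(
        _dilate(_erode(mask.pixels, nr), nr), role=mask.role, scale=mask.scale
    )


def grow(mask: BinaryMask, ng: int, ng_it: int = 1) -> BinaryMask:
    """ng_it successive dilations with an ng x ng window (rank 1 = identity)."""
    if ng < 1 or ng_it < 1:
        raise ValueError("ng and ng_it must be >= 1")
    px = mask.pixels
    if ng > 1:
        for _ in range(ng_it):
            px = _dilate(px, ng)
    return BinaryMask(px.copy() if px is mask.pixels else px,
                      role=mask.role, scale=mask.scale)


def build_channel_mask(img: GrayImage, p: ChannelParams, role: str = "M") -> BinaryMask:
    """Full per-channel pipeline: (equalize) -> binarize -> open -> grow."""
    if p.equalize:
        img = equalize_histogram(img)
    m = binarize(img, p.thr, role=role)
    m = denoise_open(m, p.nr)
    return grow(m, p.ng, p.ng_it)


def _as_pixels(m: BinaryMask | None, like: BinaryMask) -> np.ndarray:
    if m is None:
        return np.zeros(like.shape, bool)
    if m.shape != like.shape:
        raise DimensionError(f"mask shape {m.shape} != {like.shape}")
    return m.pixels


def combine_automatic_mask(
    mc1: BinaryMask, mc2: BinaryMask | None = None, mc3: BinaryMask | None = None
) -> BinaryMask:
    """Automatic CM mask: Ma = Mc1 AND (NOT Mc2 OR NOT Mc3).

    A cell-marker pixel is kept unless it is active in both the CX43 mask and
    the interstitium mask.  Absent channels count as all-zero, so with a
    single channel Ma degenerates to Mc1.
    """
    p2 = _as_pixels(mc2, mc1)
    p3 = _as_pixels(mc3, mc1)
    ma = mc1.pixels & (~p2 | ~p3)
    return BinaryMask(ma, role="Ma", scale=mc1.scale)


def build_cx43_mask(c2: GrayImage) -> BinaryMask:
    """CX43 quantification mask: equalize c2, threshold at 254, no morphology."""
    if c2 is None:
        raise ValueError("CX43 channel (c2) is absent")
    m = binarize(equalize_histogram(c2), 254)
    return BinaryMask(m.pixels, role="Mc4", scale=c2.scale)


def build_tissue_mask(
    mc1: BinaryMask, mc2: BinaryMask | None = None, mc3: BinaryMask | None = None
) -> BinaryMask:
    """Tissue mask: pixelwise OR of the binarized channels."""
    mt = mc1.pixels | _as_pixels(mc2, mc1) | _as_pixels(mc3, mc1)
    return BinaryMask(mt, role="Mt", scale=mc1.scale)


def build_masks(channels: ChannelSet, config: PipelineConfig) -> dict[str, BinaryMask]:
    """Build every mask the pipeline needs from a channel set.

    Returns a dict with keys ``Mc1`` and ``Ma``/``Mt`` always, plus ``Mc2``,
    ``Mc3`` and ``Mc4`` when the corresponding channels are available.  With
    ``config.invert_c3`` set and no c3 channel, the interstitium mask is
    approximated as the complement of ``Mc1``.
    """
    out: dict[str, BinaryMask] = {}
    mc1 = build_channel_mask(channels.c1, config.c1, role="Mc1")
    out["Mc1"] = mc1
    mc2 = mc3 = None
    if channels.c2 is not None and config.c2 is not None:
        mc2 = build_channel_mask(channels.c2, config.c2, role="Mc2")
        out["Mc2"] = mc2
    if channels.c3 is not None and config.c3 is not None:
        mc3 = build_channel_mask(channels.c3, config.c3, role="Mc3")
        out["Mc3"] = mc3
    elif config.invert_c3:
        mc3 = BinaryMask(~mc1.pixels, role="Mc3", scale=mc1.scale)
        out["Mc3"] = mc3
    out["Ma"] = combine_automatic_mask(mc1, mc2, mc3)
    out["Mt"] = build_tissue_mask(mc1, mc2, mc3)
    if channels.c4 is not None:
        out["Mc4"] = build_cx43_mask(channels.c4)
    return out
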