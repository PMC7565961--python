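"""Connexin-43 expression and lateralization quantification.

Global expression ``Cex`` is the percentage of tissue pixels that carry CX43
signal; the noise level ``r`` is the percentage of off-tissue pixels that do.
Per cell, the padded bounding box is cut by three lines perpendicular to its
long axis into four equal compartments: P0 and P3 at the cell poles (where
intercalated discs normally concentrate gap junctions) and P1, P2 along the
lateral middle.  With ``F_i`` the fraction of compartment pixels carrying
CX43 signal, the polar and lateral amounts are ``Fp = F0 + F3`` and
``Fl = F1 + F2``, and the lateralization percentage is

    Clat = 100 * Fl / (Fl + Fp).

Cells without any CX43 signal in their box (``Fl + Fp = 0``) are flagged
``no_signal`` and excluded from Clat distributions rather than coded as 0.

The population-level Clat frequency distribution is summarised by fitting
``f(x) = a * exp(-b x)`` to the density histogram; the closed-form integral
``(a/b) (exp(-b lo) - exp(-b hi))`` then gives the fraction of cells with
Clat in ``[lo, hi]``.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .detect import CMRecord, RotatedBox, box_pixel_coords, find_external_contours
from .images import DimensionError
from .masks import BinaryMask

__all__ = [
    "UndefinedRatioError",
    "InsufficientDataError",
    "CompartmentPartition",
    "ExpressionStats",
    "ExpFitModel",
    "compute_cex",
    "compute_noise",
    "tissue_area",
    "partition_box",
    "compartment_fractions",
    "compute_clat",
    "annotate_records",
    "fit_exponential",
    "fit_exponential_histogram",
    "integrate_fraction",
]


class UndefinedRatioError(ZeroDivisionError):
    """A percentage with an empty denominator (e.g. empty tissue mask)."""


class InsufficientDataError(ValueError):
    """Too little data to fit the lateralization distribution."""


# --------------------------------------------------------------------------
# global expression


def _check_same_shape(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise DimensionError(f"mask shapes differ: {a.shape} vs {b.shape}")


def compute_cex(mc4: BinaryMask, mt: BinaryMask) -> float:
    """CX43 expression: % of tissue-mask pixels active in the CX43 mask."""
    _check_same_shape(mc4, mt)
    denom = int(mt.pixels.sum())
    if denom == 0:
        raise UndefinedRatioError("tissue mask is empty")
    num = int((mt.pixels & mc4.pixels).sum())
    return 100.0 * num / denom


def compute_noise(mc4: BinaryMask, mt: BinaryMask) -> float:
    """Noise level: % of off-tissue pixels active in the CX43 mask."""
    _check_same_shape(mc4, mt)
    off = ~mt.pixels
    denom = int(off.sum())
    if denom == 0:
        raise UndefinedRatioError("tissue mask covers the whole image")
    num = int((off & mc4.pixels).sum())
    return 100.0 * num / denom


def tissue_area(mt: BinaryMask, scale: float, method: str = "pixel_count") -> float:
    """Tissue area in mm^2.

    ``pixel_count`` counts activated pixels; ``max_contour`` takes the area
    of the largest external contour of the tissue mask, which can be more
    faithful when tissue regions contain unstained pixels.
    """
    if not scale > 0:
        raise ValueError("scale must be positive")
    if method == "pixel_count":
        area_px2 = float(mt.pixels.sum())
    elif method == "max_contour":
        contours = find_external_contours(mt)
        area_px2 = max((c.area_px2 for c in contours), default=0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return area_px2 * scale * scale * 1e-6


# --------------------------------------------------------------------------
# per-cell compartments


@dataclasses.dataclass
class CompartmentPartition:
    """Pixel-index sets of the four box compartments.

    ``compartments[i]`` holds (rows, cols) for compartment ``P_i``; P0/P3 are
    the polar end quarters, P1/P2 the lateral middle quarters.  Pixels
    falling outside the image are dropped; a cut-line boundary pixel goes to
    the lower-index quarter.
    """

    compartments: tuple[tuple[np.ndarray, np.ndarray], ...]

    @property
    def sizes(self) -> tuple[int, int, int, int]:
        return tuple(len(r) for r, _ in self.compartments)  # type: ignore[return-value]


def partition_box(box: RotatedBox, shape: tuple[int, int]) -> CompartmentPartition:
    """Cut the rasterized box into four equal quarters along its long axis."""
    rows, cols, u, _ = box_pixel_coords(box, shape)
    if rows.size == 0:
        raise DimensionError("box does not cover any pixel of the image")
    # position along the long axis, from 0 at one pole to long_px at the other
    t = u + box.long_px / 2.0
    quarter = box.long_px / 4.0
    # boundary pixels (t exactly on a cut) belong to the lower-index quarter
    idx = np.clip(np.ceil(t / quarter).astype(int) - 1, 0, 3)
    comps = []
    for i in range(4):
        m = idx == i
        comps.append((rows[m], cols[m]))
    return CompartmentPartition(compartments=tuple(comps))


def compartment_fractions(
    partition: CompartmentPartition, mc4: BinaryMask
) -> tuple[float, float, float, float]:
    """F_i: fraction of compartment-i pixels active in the CX43 mask."""
    out = []
    for rows, cols in partition.compartments:
        n = len(rows)
        if n == 0:
            raise UndefinedRatioError("empty compartment")
        out.append(float(mc4.pixels[rows, cols].sum()) / n)
    return tuple(out)  # type: ignore[return-value]


def compute_clat(F: Sequence[float]) -> float | None:
    """Lateralization percentage 100*Fl/(Fl+Fp); None when there is no signal."""
    f0, f1, f2, f3 = F
    if min(F) < 0:
        raise ValueError("fractions must be non-negative")
    fp = f0 + f3
    fl = f1 + f2
    if fp + fl == 0:
        return None
    return 100.0 * fl / (fl + fp)


def annotate_records(records: Iterable[CMRecord], mc4: BinaryMask) -> None:
    """Fill CX43 compartment fractions and Clat into detection records."""
    for rec in records:
        part = partition_box(rec.box_expanded, mc4.shape)
        F = compartment_fractions(part, mc4)
        clat = compute_clat(F)
        rec.F = F
        rec.clat = clat
        rec.no_signal = clat is None


@dataclasses.dataclass
class ExpressionStats:
    """Image-level CX43 summary."""

    cex: float
    noise_r: float
    tissue_area_mm2: float
    tissue_area_max_contour_mm2: float
    n_pixels: int


# --------------------------------------------------------------------------
# lateralization distribution model


@dataclasses.dataclass
class ExpFitModel:
    """Exponential frequency model f(x) = a * exp(-b x) of the Clat histogram."""

    a: float
    b: float
    bin_width: float = 5.0
    rss: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("amplitude and rate must be positive")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.exp(-self.b * np.asarray(x, float))


def fit_exponential_histogram(
    centers: np.ndarray, density: np.ndarray, bin_width: float = 5.0
) -> ExpFitModel:
    """Nonlinear least-squares fit of a*exp(-b x) to histogram densities."""
    centers = np.asarray(centers, float)
    density = np.asarray(density, float)
    pos = density > 0
    if pos.sum() < 2:
        raise InsufficientDataError("need at least two non-empty bins")
    # log-linear regression on the positive bins seeds the nonlinear fit
    slope, intercept = np.polyfit(centers[pos], np.log(density[pos]), 1)
    p0 = (float(np.exp(intercept)), max(-float(slope), 1e-6))
    popt, _ = curve_fit(
        lambda x, a, b: a * np.exp(-b * x),
        centers,
        density,
        p0=p0,
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=10000,
    )
    resid = density - popt[0] * np.exp(-popt[1] * centers)
    return ExpFitModel(
        a=float(popt[0]), b=float(popt[1]), bin_width=bin_width,
        rss=float(np.sum(resid**2)),
    )


def fit_exponential(
    clat_values: Sequence[float], bin_width: float = 5.0
) -> ExpFitModel:
    """Fit the exponential model to the density histogram of Clat values.

    Values are binned on [0, 100] with the given bin width; the model is fit
    to (bin centre, density) pairs.
    """
    values = np.asarray(list(clat_values), float)
    if values.size == 0:
        raise InsufficientDataError("no Clat values")
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    density, edges = np.histogram(values, bins=edges, density=True)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return fit_exponential_histogram(centers, density, bin_width)


def integrate_fraction(model: ExpFitModel, lo: float, hi: float) -> float:
    """Closed-form integral of the fitted model over [lo, hi].

    Returns (a/b) * (exp(-b*lo) - exp(-b*hi)): the model-predicted fraction
    of cells with Clat in the interval.
    """
    if lo > hi:
        raise ValueError("lo must be <= hi")
    return (model.a / model.b) * (np.exp(-model.b * lo) - np.exp(-model.b * hi))
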