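"""Pipeline configuration.

All thresholds are expressed on the 8-bit intensity range [0, 255].  Square
morphology windows are given by their rank ``n`` (side length in pixels);
rank 1 is the identity.  The default parameter set is the one used for
three-channel human left-ventricle images at 0.21 um/pixel:

===========  ====  ====  ====
parameter     c1    c2    c3
===========  ====  ====  ====
thr            8    15     2
nr             3     3     3
ng             3     3     3
ng_it          3     5     3
equalize       no    no    no
===========  ====  ====  ====

with the CX43 quantification threshold fixed at ``thr_c4 = 254``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

__all__ = ["ChannelParams", "PipelineConfig", "default_config", "threshold_only_config"]


@dataclasses.dataclass
class ChannelParams:
    """Per-channel binarization and morphology parameters.

    thr:     binarization threshold (mask pixel active iff intensity > thr)
    nr:      rank of the square noise-removal (opening) window
    ng:      rank of the square growth (dilation) window
    ng_it:   number of growth iterations
    equalize: apply histogram equalization before binarization
    """

    thr: int
    nr: int = 1
    ng: int = 1
    ng_it: int = 1
    equalize: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.thr <= 255:
            raise ValueError(f"thr must be in [0, 255], got {self.thr}")
        for name in ("nr", "ng", "ng_it"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclasses.dataclass
class PipelineConfig:
    """Full parameterization of the detection/quantification pipeline.

    ``h_px`` is the box-padding distance in pixels.  When left ``None`` it is
    derived as ``2 * ng(c2) * ng_it(c2)`` — the padding compensating the
    cell-mask erosion caused by growth of the CX43 mask — and is 0 when no
    CX43 channel is present.
    """

    c1: ChannelParams
    c2: ChannelParams | None = None
    c3: ChannelParams | None = None
    thr_c4: int = 254
    scale: float = 0.21
    min_area_um2: float = 100.0
    min_perim_um: float = 40.0
    length_um: tuple[float, float] = (20.0, 200.0)
    width_um: tuple[float, float] = (5.0, 50.0)
    h_px: float | None = None
    invert_c3: bool = False
    bin_width: float = 5.0
    supervised_manifest: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if not (0 < self.length_um[0] < self.length_um[1]):
            raise ValueError("length bounds must be positive and ordered")
        if not (0 < self.width_um[0] < self.width_um[1]):
            raise ValueError("width bounds must be positive and ordered")
        if self.h_px is not None and self.h_px < 0:
            raise ValueError("h_px must be >= 0")

    def resolved_h(self, c2_present: bool = True) -> float:
        """Box-padding distance in pixels (explicit value or derived)."""
        if self.h_px is not None:
            return float(self.h_px)
        if not c2_present or self.c2 is None:
            return 0.0
        return float(2 * self.c2.ng * self.c2.ng_it)

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "scale": self.scale,
            "thr_c4": self.thr_c4,
            "channels": {},
            "filters": {
                "min_area_um2": self.min_area_um2,
                "min_perim_um": self.min_perim_um,
                "length_um": list(self.length_um),
                "width_um": list(self.width_um),
            },
            "h_px": self.h_px,
            "invert_c3": self.invert_c3,
            "bin_width": self.bin_width,
            "supervised_manifest": self.supervised_manifest,
        }
        for role in ("c1", "c2", "c3"):
            p = getattr(self, role)
            if p is not None:
                d["channels"][role] = dataclasses.asdict(p)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        chans = {
            role: ChannelParams(**params)
            for role, params in d.get("channels", {}).items()
        }
        if "c1" not in chans:
            raise ValueError("configuration must define channel c1")
        filters = d.get("filters", {})
        kwargs: dict[str, Any] = {}
        for key in ("thr_c4", "scale", "h_px", "invert_c3", "bin_width",
                    "supervised_manifest"):
            if key in d and d[key] is not None:
                kwargs[key] = d[key]
        for key in ("min_area_um2", "min_perim_um"):
            if key in filters:
                kwargs[key] = filters[key]
        for key in ("length_um", "width_um"):
            if key in filters:
                kwargs[key] = tuple(filters[key])
        return cls(c1=chans["c1"], c2=chans.get("c2"), c3=chans.get("c3"), **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(scale: float = 0.21) -> PipelineConfig:
    """Default parameter set for three-channel human ventricular images."""
    return PipelineConfig(
        c1=ChannelParams(thr=8, nr=3, ng=3, ng_it=3),
        c2=ChannelParams(thr=15, nr=3, ng=3, ng_it=5),
        c3=ChannelParams(thr=2, nr=3, ng=3, ng_it=3),
        scale=scale,
    )


def threshold_only_config(
    scale: float = 0.21,
    thr_c1: int = 8,
    thr_c2: int = 15,
    thr_c3: int = 2,
    h_px: float = 0.0,
) -> PipelineConfig:
    """Pure-thresholding configuration (all morphology ranks 1, no padding).

    Appropriate for noise-free inputs where no opening/growth compensation is
    needed; with ranks at 1 the channel pipeline reduces to binarization.
    """
    return PipelineConfig(
        c1=ChannelParams(thr=thr_c1),
        c2=ChannelParams(thr=thr_c2),
        c3=ChannelParams(thr=thr_c3),
        scale=scale,
        h_px=h_px,
    )
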