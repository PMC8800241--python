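"""Image containers, projection, preprocessing and local thresholding.

The pipeline works on single-channel 2-D immunofluorescence planes
(max-intensity projections of confocal z-stacks, one stain per channel:
IBA1 for microglia, GFAP + S100B for astrocytes).  A pixel scale in
pixels/µm converts all derived measurements to physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ImagePlane",
    "ThresholdConfig",
    "project_max",
    "preprocess_plane",
    "local_threshold",
]

#: Default pixel scale of the imaging setup (20x magnification), px per µm.
DEFAULT_SCALE = 1.5


@dataclass
class ImagePlane:
    """A single-channel grayscale plane with physical scale.

    Parameters
    ----------
    pixels
        2-D nonnegative intensity grid (any numeric dtype; converted to
        float64 internally by most operations).
    scale
        Pixels per micrometre; strictly positive.
    channel
        Stain label, e.g. ``"IBA1"``, ``"GFAP"``, ``"S100B"``.
    tissue_mask
        Optional boolean grid of the same shape; True marks tissue.  Pixels
        outside the mask are cleared during preprocessing and excluded from
        analysis.
    """

    pixels: np.ndarray
    scale: float = DEFAULT_SCALE
    channel: str = ""
    tissue_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not self.scale > 0:
            raise ValueError("scale must be > 0 (pixels per µm)")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be nonnegative")
        if self.tissue_mask is not None:
            self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
            if self.tissue_mask.shape != self.pixels.shape:
                raise ValueError("tissue_mask shape must match pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def size_um(self) -> tuple[float, float]:
        """(height, width) in µm."""
        h, w = self.pixels.shape
        return h / self.scale, w / self.scale


@dataclass(frozen=True)
class ThresholdConfig:
    """Parameters of the Phansalkar local threshold.

    The classical formula for low-contrast stained images: a pixel with
    normalised intensity ``v`` is foreground iff

        v > m * (1 + p * exp(-q * m) + k * (s / r - 1))

    with ``m``, ``s`` the local mean and standard deviation, ``p = 2``,
    ``q = 10``.  ``k`` and ``r`` are the two tunable parameters; the
    defaults below are the conventional ones.
    """

    method: Literal["phansalkar"] = "phansalkar"
    radius: int = 60
    k: float = 0.25
    r: float = 0.5

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")


PHANSALKAR_P = 2.0
PHANSALKAR_Q = 10.0


def project_max(zstack: Sequence[ImagePlane]) -> ImagePlane:
    """Maximum-intensity projection of a z-stack.

    All planes must share shape and scale; the result takes the per-pixel
    maximum and inherits metadata from the first plane.
    """
    if len(zstack) == 0:
        raise ValueError("z-stack must contain at least one plane")
    first = zstack[0]
    for p in zstack[1:]:
        if p.shape != first.shape:
            raise ValueError("all planes must share the same shape")
        if p.scale != first.scale:
            raise ValueError("all planes must share the same scale")
    stacked = np.stack([np.asarray(p.pixels, dtype=np.float64) for p in zstack])
    return replace(first, pixels=stacked.max(axis=0))


def _square_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Grey opening with a flat square element of side 2*radius+1.

    Used as the background estimate for background subtraction; the flat
    square is separable, so this stays fast at the radii used here.
    """
    size = 2 * radius + 1
    eroded = ndimage.grey_erosion(img, size=(size, size), mode="reflect")
    return ndimage.grey_dilation(eroded, size=(size, size), mode="reflect")


def subtract_background(img: np.ndarray, radius: int = 50) -> np.ndarray:
    """Background subtraction via a square-element grey opening.

    Removes smooth large-scale illumination while preserving structures
    smaller than the element (cells, processes).  A constant image maps to
    all zeros.
    """
    img = np.asarray(img, dtype=np.float64)
    return np.clip(img - _square_opening(img, radius), 0.0, None)


def despeckle(img: np.ndarray) -> np.ndarray:
    """3x3 median filter; removes single-pixel shot noise."""
    return ndimage.median_filter(np.asarray(img, dtype=np.float64), size=3, mode="reflect")


def contrast_stretch(img: np.ndarray, saturated: float = 0.35) -> np.ndarray:
    """Saturated-percentile contrast enhancement.

    Linearly rescales so that ``saturated`` percent of pixels at each tail
    are clipped; applied to GFAP planes so faint distal arborisation
    survives thresholding.
    """
    img = np.asarray(img, dtype=np.float64)
    lo, hi = np.percentile(img, [saturated, 100.0 - saturated])
    if hi <= lo:
        return img.copy()
    out = (img - lo) / (hi - lo)
    np.clip(out, 0.0, 1.0, out=out)
    return out * max(img.max(), 1.0)


Protocol = Literal["microglia", "astrocyte_branching", "soma"]


def preprocess_plane(plane: ImagePlane, protocol: Protocol = "microglia") -> ImagePlane:
    """Standard preprocessing: background subtraction, despeckle, masking.

    ``astrocyte_branching`` additionally contrast-stretches the plane so
    the full arborisation is detectable.  Pixels outside ``tissue_mask``
    are cleared in every protocol.
    """
    if protocol not in ("microglia", "astrocyte_branching", "soma"):
        raise ValueError(f"unknown protocol {protocol!r}")
    img = subtract_background(plane.pixels, radius=50)
    img = despeckle(img)
    if protocol == "astrocyte_branching":
        img = contrast_stretch(img)
    if plane.tissue_mask is not None:
        img = np.where(plane.tissue_mask, img, 0.0)
    return replace(plane, pixels=img)


def _local_mean_std(img: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Local mean and standard deviation in a (2r+1) square neighbourhood."""
    size = 2 * radius + 1
    mean = ndimage.uniform_filter(img, size=size, mode="reflect")
    mean_sq = ndimage.uniform_filter(img * img, size=size, mode="reflect")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    return mean, np.sqrt(var)


def phansalkar_threshold_surface(img: np.ndarray, cfg: ThresholdConfig) -> np.ndarray:
    """Per-pixel Phansalkar threshold surface on the normalised image."""
    m, s = _local_mean_std(img, cfg.radius)
    return m * (1.0 + PHANSALKAR_P * np.exp(-PHANSALKAR_Q * m) + cfg.k * (s / cfg.r - 1.0))


def local_threshold(plane: ImagePlane, cfg: ThresholdConfig | None = None) -> np.ndarray:
    """Binarise a plane with the Phansalkar local threshold.

    Intensities are normalised to [0, 1] by the plane maximum before the
    formula is applied (the formula's constants assume unit range).  Returns
    a boolean foreground mask; an all-zero plane yields all background.
    Foreground requires a strictly greater intensity than the local
    threshold.
    """
    cfg = cfg or ThresholdConfig()
    if cfg.method != "phansalkar":
        raise ValueError(f"unsupported threshold method {cfg.method!r}")
    img = np.asarray(plane.pixels, dtype=np.float64)
    vmax = img.max()
    if vmax <= 0:
        return np.zeros(img.shape, dtype=bool)
    norm = img / vmax
    mask = norm > phansalkar_threshold_surface(norm, cfg)
    if plane.tissue_mask is not None:
        mask &= plane.tissue_mask
    return mask
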