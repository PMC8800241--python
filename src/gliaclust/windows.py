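"""Sliding-window enumeration and per-window intensity features.

A square window (default 100 µm) is translated across the section with a
fractional overlap (default 50%), and the window centres become the spatial
coordinates attached to every downstream feature row.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .image import ImagePlane

__all__ = ["WindowSpec", "Window", "enumerate_windows", "intensity_features"]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.

    side
        Window side length in µm (default 100).
    overlap
        Fractional overlap between successive windows in each axis; the
        stride is ``side * (1 - overlap)``.
    min_tissue_fraction
        Windows whose tissue-mask coverage falls below this fraction are
        dropped.  The default 0 keeps every window (off-tissue pixels are
        already cleared during preprocessing).
    """

    side: float = 100.0
    overlap: float = 0.5
    min_tissue_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.side > 0:
            raise ValueError("window side must be > 0")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if not 0.0 <= self.min_tissue_fraction <= 1.0:
            raise ValueError("min_tissue_fraction must be in [0, 1]")

    @property
    def stride(self) -> float:
        return self.side * (1.0 - self.overlap)


@dataclass(frozen=True)
class Window:
    """An axis-aligned window rectangle in µm coordinates."""

    x0: float
    y0: float
    side: float

    @property
    def center(self) -> tuple[float, float]:
        return self.x0 + self.side / 2.0, self.y0 + self.side / 2.0

    def pixel_slice(self, scale: float) -> tuple[slice, slice]:
        """(row, col) slice of this window at a given px/µm scale."""
        r0 = int(round(self.y0 * scale))
        c0 = int(round(self.x0 * scale))
        n = int(round(self.side * scale))
        return slice(r0, r0 + n), slice(c0, c0 + n)


def enumerate_windows(plane: ImagePlane, spec: WindowSpec) -> list[Window]:
    """Enumerate sliding windows over a plane.

    The grid is anchored at the image origin with stride
    ``side * (1 - overlap)``; windows that would extend past the image edge
    are dropped, as are windows with insufficient tissue coverage.  Per
    axis the count follows the closed form ``floor((L - w) / stride) + 1``.
    """
    h_um, w_um = plane.size_um
    side, stride = spec.side, spec.stride
    if h_um < side or w_um < side:
        warnings.warn("image smaller than the window; no windows enumerated")
        return []
    eps = 1e-9  # guards float stride accumulation at exact-fit edges
    nx = int(math.floor((w_um - side) / stride + eps)) + 1
    ny = int(math.floor((h_um - side) / stride + eps)) + 1
    windows = []
    for j in range(ny):
        for i in range(nx):
            win = Window(x0=i * stride, y0=j * stride, side=side)
            if spec.min_tissue_fraction > 0 and plane.tissue_mask is not None:
                rs, cs = win.pixel_slice(plane.scale)
                cov = float(plane.tissue_mask[rs, cs].mean())
                if cov < spec.min_tissue_fraction:
                    continue
            windows.append(win)
    return windows


def intensity_features(
    plane: ImagePlane, mask: np.ndarray, window: Window
) -> tuple[float, float, float]:
    """Mean, integrated density and area of foreground within a window.

    Returns ``(mean, integrated_density, area_um2)`` with
    ``mean`` the mean intensity over foreground pixels, ``area`` the
    foreground pixel count converted to µm², and
    ``integrated_density = mean * foreground_pixel_count``.  All three are
    0 when the window contains no foreground.
    """
    rs, cs = window.pixel_slice(plane.scale)
    sub = np.asarray(plane.pixels, dtype=np.float64)[rs, cs]
    fg = np.asarray(mask, dtype=bool)[rs, cs]
    n = int(fg.sum())
    if n == 0:
        return 0.0, 0.0, 0.0
    mean = float(sub[fg].mean())
    area = n / plane.scale**2
    return mean, mean * n, area
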