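"""Synthetic tissue with known ground truth.

Two decoupled generators:

* a *feature-level* generator that draws per-window feature tables
  directly (control sections, plus test sections carrying an implanted
  activation region with optional brighter focal core) — the fast vehicle
  for testing the statistical pipeline end to end; and
* an *image-level* renderer that paints ramified and ameboid cells into a
  grayscale plane — exercising the feature-extraction and soma-counting
  stages against per-cell ground truth.

Effect-size defaults encode the canonical activation phenotype: brighter,
larger-area staining, enlarged rounder somata, fewer and shorter branches,
and densified cell spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .features import ALL_FEATURES, CSV_COLUMNS, FeatureTable
from .image import ImagePlane
from .windows import WindowSpec

__all__ = [
    "SyntheticFeatureSpec",
    "SyntheticTissueSpec",
    "SyntheticGroundTruth",
    "generate_feature_table",
    "render_section",
]

#: Control (ramified) per-window feature distributions: (mean, sd).
#: Magnitudes mimic a 100 µm window of quiescent microglia at 1.5 px/µm.
CONTROL_FEATURE_STATS: dict[str, tuple[float, float]] = {
    "Area": (1600.0, 250.0),
    "Mean": (40.0, 5.0),
    "FracDim": (1.45, 0.06),
    "NumCells": (5.0, 1.2),
    "MeanNND": (35.0, 5.0),
    "MeanSomaArea": (40.0, 6.0),
    "MeanSomaCirc": (0.75, 0.05),
    "NumBranches": (110.0, 15.0),
    "BranchLength": (900.0, 120.0),
    "NumJunctions": (45.0, 8.0),
    "NumTriplePoints": (38.0, 7.0),
    "NumEndPoints": (70.0, 10.0),
    "NumSlabPixels": (1300.0, 180.0),
    "Perimeter": (2500.0, 300.0),
}

#: Mean fold changes inside the activation region (proximal phenotype):
#: hyperintensity and hypertrophy with deramification.
PROXIMAL_MULTIPLIERS: dict[str, float] = {
    "Mean": 1.4,
    "Area": 1.4,
    "MeanSomaArea": 1.2,
    "NumBranches": 0.7,
    "BranchLength": 0.75,
    "MeanNND": 0.85,
    "NumCells": 1.38,
    "MeanSomaCirc": 1.1,
    "FracDim": 0.95,
    "NumJunctions": 0.7,
    "NumTriplePoints": 0.7,
    "NumEndPoints": 0.7,
    "NumSlabPixels": 0.7,
    "Perimeter": 1.2,
}

#: Fold changes inside the focal core (strongest activation).
FOCAL_MULTIPLIERS: dict[str, float] = {
    "Mean": 1.8,
    "Area": 2.0,
    "MeanSomaArea": 1.4,
    "NumBranches": 0.55,
    "BranchLength": 0.6,
    "MeanNND": 0.65,
    "NumCells": 2.3,
    "MeanSomaCirc": 1.2,
    "FracDim": 0.9,
    "NumJunctions": 0.55,
    "NumTriplePoints": 0.55,
    "NumEndPoints": 0.55,
    "NumSlabPixels": 0.55,
    "Perimeter": 1.3,
}


@dataclass(frozen=True)
class SyntheticFeatureSpec:
    """Study conditions for the feature-level generator.

    The activation region and focal core are inclusive rectangles in
    window-grid indices (col0, row0, col1, row1); all test sections carry
    the same implant.  ``section_noise_sd`` scales each feature's sd to
    give a per-section additive random effect (staining variability).
    """

    n_sections_control: int = 4
    n_sections_test: int = 4
    grid_shape: tuple[int, int] = (28, 28)  # (n_cols, n_rows) of windows
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    control_stats: dict = field(default_factory=lambda: dict(CONTROL_FEATURE_STATS))
    proximal_multipliers: dict = field(default_factory=lambda: dict(PROXIMAL_MULTIPLIERS))
    focal_multipliers: dict = field(default_factory=lambda: dict(FOCAL_MULTIPLIERS))
    activation_rect: tuple[int, int, int, int] = (8, 8, 19, 19)
    focal_rect: tuple[int, int, int, int] | None = (12, 12, 15, 15)
    section_noise_sd: float = 0.1
    latent_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for mult in (self.proximal_multipliers, self.focal_multipliers):
            if any(v <= 0 for v in mult.values()):
                raise ValueError("effect multipliers must be > 0")
        c0, r0, c1, r1 = self.activation_rect
        nc, nr = self.grid_shape
        if not (0 <= c0 <= c1 < nc and 0 <= r0 <= r1 < nr):
            raise ValueError("activation region must lie within the grid")
        if self.focal_rect is not None:
            f0, g0, f1, g1 = self.focal_rect
            if not (c0 <= f0 <= f1 <= c1 and r0 <= g0 <= g1 <= r1):
                raise ValueError("focal core must lie within the activation region")


@dataclass
class SyntheticGroundTruth:
    """True per-window labels and implant geometry."""

    windows: pd.DataFrame  # section_id, x_um, y_um, true_region
    region_polygons: dict  # {"proximal": geom, "focal": geom or None}
    cells: pd.DataFrame | None = None  # image-level: x_um, y_um, type

    def implant_polygon(self):
        return self.region_polygons.get("proximal")

    def focal_polygon(self):
        return self.region_polygons.get("focal")


def _window_centers(spec: SyntheticFeatureSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nc, nr = spec.grid_shape
    side = spec.window_spec.side
    stride = spec.window_spec.stride
    cols, rows = np.meshgrid(np.arange(nc), np.arange(nr))
    xs = side / 2.0 + cols.ravel() * stride
    ys = side / 2.0 + rows.ravel() * stride
    return xs, ys, np.stack([cols.ravel(), rows.ravel()], axis=1)


def _in_rect(ij: np.ndarray, rect: tuple[int, int, int, int]) -> np.ndarray:
    c0, r0, c1, r1 = rect
    return (ij[:, 0] >= c0) & (ij[:, 0] <= c1) & (ij[:, 1] >= r0) & (ij[:, 1] <= r1)


def _rect_polygon(rect, spec: SyntheticFeatureSpec):
    side, stride = spec.window_spec.side, spec.window_spec.stride
    c0, r0, c1, r1 = rect
    boxes = [
        box(side / 2 + c * stride - side / 2, side / 2 + r * stride - side / 2,
            side / 2 + c * stride + side / 2, side / 2 + r * stride + side / 2)
        for c in range(c0, c1 + 1) for r in range(r0, r1 + 1)
    ]
    return unary_union(boxes)


def generate_feature_table(
    spec: SyntheticFeatureSpec | None = None,
) -> tuple[FeatureTable, FeatureTable, SyntheticGroundTruth]:
    """Draw control and test feature tables with an implanted activation
    region.

    Control windows are per-feature Gaussians plus a per-section random
    effect.  Inside the implant, feature means are multiplied by the
    proximal (or focal) fold changes, modulated by a per-window latent
    activation intensity shared across features — this latent couples the
    features so the PCA has genuine low-rank structure.  Integrated
    density is derived as Mean × foreground pixel count so its coupling to
    Mean and Area matches extracted tables.  Fully seeded.
    """
    spec = spec or SyntheticFeatureSpec()
    rng = np.random.default_rng(spec.seed)
    xs, ys, ij = _window_centers(spec)
    n_win = len(xs)
    scale = 1.5  # px/µm, converts Area µm² to a pixel count for IntDen
    feats = list(CONTROL_FEATURE_STATS)

    def draw_section(section_id: str, group: str, implant: bool) -> pd.DataFrame:
        sec_effect = {
            f: rng.normal(0.0, spec.section_noise_sd * sd)
            for f, (mu, sd) in spec.control_stats.items()
        }
        in_prox = _in_rect(ij, spec.activation_rect) if implant else np.zeros(n_win, bool)
        in_focal = (
            _in_rect(ij, spec.focal_rect)
            if implant and spec.focal_rect is not None
            else np.zeros(n_win, bool)
        )
        latent = np.clip(rng.normal(1.0, spec.latent_sd, n_win), 0.4, 1.6)
        cols = {}
        for f in feats:
            mu, sd = spec.control_stats[f]
            mult = np.ones(n_win)
            mp = spec.proximal_multipliers.get(f, 1.0)
            mf = spec.focal_multipliers.get(f, mp)
            mult[in_prox] = 1.0 + (mp - 1.0) * latent[in_prox]
            mult[in_focal] = 1.0 + (mf - 1.0) * latent[in_focal]
            vals = rng.normal((mu + sec_effect[f]) * mult, sd)
            cols[f] = np.clip(vals, 0.0, None)
        cols["IntDen"] = cols["Mean"] * cols["Area"] * scale**2
        d = pd.DataFrame({"section_id": section_id, "group": group,
                          "x_um": xs, "y_um": ys, **cols})
        return d[CSV_COLUMNS]

    def concat(frames):
        if not frames:
            return pd.DataFrame(columns=CSV_COLUMNS)
        return pd.concat(frames, ignore_index=True)

    control = concat([draw_section(f"C{i + 1}", "control", False)
                      for i in range(spec.n_sections_control)])
    test = concat([draw_section(f"T{i + 1}", "test", True)
                   for i in range(spec.n_sections_test)])

    in_prox = _in_rect(ij, spec.activation_rect)
    in_focal = (_in_rect(ij, spec.focal_rect)
                if spec.focal_rect is not None else np.zeros(n_win, bool))
    true_region = np.where(in_focal, "focal", np.where(in_prox, "proximal", "control"))
    gt_rows = []
    for i in range(spec.n_sections_test):
        gt_rows.append(pd.DataFrame({
            "section_id": f"T{i + 1}", "x_um": xs, "y_um": ys,
            "true_region": true_region,
        }))
    truth = SyntheticGroundTruth(
        windows=(pd.concat(gt_rows, ignore_index=True) if gt_rows else
                 pd.DataFrame(columns=["section_id", "x_um", "y_um", "true_region"])),
        region_polygons={
            "proximal": _rect_polygon(spec.activation_rect, spec),
            "focal": (_rect_polygon(spec.focal_rect, spec)
                      if spec.focal_rect is not None else None),
        },
    )
    wspec = spec.window_spec
    return (
        FeatureTable(control, "microglia", wspec),
        FeatureTable(test, "microglia", wspec),
        truth,
    )


# --------------------------------------------------------------------------
# image-level renderer
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTissueSpec:
    """Study conditions for the image renderer.

    Cells are placed by a hard-core Poisson process (minimum separation
    ~1.5 soma diameters, as tiling microglia keep exclusion zones); inside
    the optional activation disk the density is raised by the square of
    the inverse NND fold change and cells are rendered ameboid (enlarged,
    brighter soma; drastically pruned branches).
    """

    section_size_um: tuple[float, float] = (200.0, 200.0)
    cell_density_per_mm2: float = 300.0
    scale: float = 1.5  # px per µm
    soma_radius_um: float = 3.5
    soma_intensity: float = 160.0
    branch_intensity: float = 70.0
    n_primary_branches: tuple[int, int] = (4, 6)
    branch_depth: int = 3
    branch_segment_um: tuple[float, float] = (8.0, 16.0)
    ameboid_soma_factor: float = 1.5
    ameboid_intensity_factor: float = 1.8
    ameboid_branch_depth: int = 1
    nnd_fold: float = 0.85  # activation-region NND fold change (density x 1/f²)
    activation_center_um: tuple[float, float] | None = None
    activation_radius_um: float = 0.0
    background_noise_sd: float = 6.0
    background_level: float = 12.0
    seed: int = 0


def _draw_cell(img, rng, cx, cy, spec: SyntheticTissueSpec, ameboid: bool) -> None:
    h, w = img.shape
    r_px = spec.soma_radius_um * spec.scale * (spec.ameboid_soma_factor if ameboid else 1.0)
    inten = spec.soma_intensity * (spec.ameboid_intensity_factor if ameboid else 1.0)
    rr, cc = draw_disk((cy, cx), max(r_px, 1.5), shape=img.shape)
    img[rr, cc] = np.maximum(img[rr, cc], inten * rng.uniform(0.9, 1.1))
    depth = spec.ameboid_branch_depth if ameboid else spec.branch_depth
    if depth < 1:
        return
    n_primary = rng.integers(spec.n_primary_branches[0], spec.n_primary_branches[1] + 1)
    if ameboid:
        n_primary = max(2, n_primary // 2)
    binten = spec.branch_intensity * (spec.ameboid_intensity_factor if ameboid else 1.0)

    def grow(x, y, angle, level):
        if level > depth:
            return
        seg = rng.uniform(*spec.branch_segment_um) * spec.scale
        if ameboid:
            seg *= 0.4
        x1 = x + seg * np.cos(angle)
        y1 = y + seg * np.sin(angle)
        rr, cc = draw_line(int(round(y)), int(round(x)), int(round(y1)), int(round(x1)))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        img[rr[keep], cc[keep]] = np.maximum(
            img[rr[keep], cc[keep]], binten * rng.uniform(0.8, 1.0) / level
        )
        for _ in range(2 if level < depth else 0):
            grow(x1, y1, angle + rng.normal(0.0, 0.6), level + 1)

    for i in range(n_primary):
        angle = 2 * np.pi * i / n_primary + rng.normal(0.0, 0.3)
        grow(cx + r_px * np.cos(angle), cy + r_px * np.sin(angle), angle, 1)


def _place_cells(rng, spec: SyntheticTissueSpec) -> pd.DataFrame:
    h_um, w_um = spec.section_size_um
    margin = spec.soma_radius_um * 2.5
    min_sep = spec.soma_radius_um * 3.0
    base = spec.cell_density_per_mm2 / 1e6  # per µm²

    def in_activation(x, y):
        if spec.activation_center_um is None or spec.activation_radius_um <= 0:
            return False
        ax, ay = spec.activation_center_um
        return (x - ax) ** 2 + (y - ay) ** 2 <= spec.activation_radius_um**2

    boost = 1.0 / spec.nnd_fold**2
    n_target = rng.poisson(base * h_um * w_um * max(boost, 1.0))
    placed: list[tuple[float, float, bool]] = []
    attempts = 0
    while len(placed) < n_target and attempts < n_target * 60:
        attempts += 1
        x = rng.uniform(margin, w_um - margin)
        y = rng.uniform(margin, h_um - margin)
        act = in_activation(x, y)
        # thin non-activation candidates back to the base density
        if not act and boost > 1.0 and rng.uniform() > 1.0 / boost:
            continue
        if any((x - px) ** 2 + (y - py) ** 2 < min_sep**2 for px, py, _ in placed):
            continue
        placed.append((x, y, act))
    return pd.DataFrame(placed, columns=["x_um", "y_um", "activated"])


def render_section(
    spec: SyntheticTissueSpec | None = None,
) -> tuple[dict[str, ImagePlane], SyntheticGroundTruth]:
    """Render one synthetic section.

    Returns planes ``{"IBA1": ..., "S100B": ...}`` — the branching channel
    with full cells, and a paired soma-only channel (disks) for
    astrocyte-mode tests — plus ground truth listing every cell's position
    and type and the activation geometry.
    """
    spec = spec or SyntheticTissueSpec()
    rng = np.random.default_rng(spec.seed)
    h_um, w_um = spec.section_size_um
    h_px = int(round(h_um * spec.scale))
    w_px = int(round(w_um * spec.scale))
    img = np.zeros((h_px, w_px), dtype=np.float64)
    soma_img = np.zeros_like(img)
    cells = _place_cells(rng, spec)
    for _, c in cells.iterrows():
        cx, cy = c.x_um * spec.scale, c.y_um * spec.scale
        _draw_cell(img, rng, cx, cy, spec, bool(c.activated))
        r_px = spec.soma_radius_um * spec.scale * (
            spec.ameboid_soma_factor if c.activated else 1.0
        )
        inten = spec.soma_intensity * (
            spec.ameboid_intensity_factor if c.activated else 1.0
        )
        rr, cc = draw_disk((cy, cx), max(r_px, 1.5), shape=soma_img.shape)
        soma_img[rr, cc] = np.maximum(soma_img[rr, cc], inten)
    for plane in (img, soma_img):
        plane += spec.background_level
        plane += rng.normal(0.0, spec.background_noise_sd, plane.shape)
        np.clip(plane, 0.0, None, out=plane)

    from shapely.geometry import Point

    act_poly = None
    if spec.activation_center_um is not None and spec.activation_radius_um > 0:
        act_poly = Point(*spec.activation_center_um).buffer(spec.activation_radius_um)
    truth = SyntheticGroundTruth(
        windows=pd.DataFrame(columns=["section_id", "x_um", "y_um", "true_region"]),
        region_polygons={"proximal": act_poly, "focal": None},
        cells=cells,
    )
    planes = {
        "IBA1": ImagePlane(img, scale=spec.scale, channel="IBA1"),
        "S100B": ImagePlane(soma_img, scale=spec.scale, channel="S100B"),
    }
    return planes, truth
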