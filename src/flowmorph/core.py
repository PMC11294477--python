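"""Quantitative morphometrics for endothelial flow-response imaging.

Endothelial cells remodel when exposed to fluid shear stress: nuclei and
cell bodies elongate and align with the flow axis, adherens junctions
straighten, and the Golgi apparatus repositions upstream of the nucleus.
This module implements the image quantifications used to score those
responses, together with a ground-truthed synthetic scene generator so
every measurement can be validated without microscopy data.

The file is organised in the order a pipeline runs:

1.  angle helpers and shared conventions
2.  domain types
3.  synthetic scene generation (monolayers, vessel phantoms, stained
    tissue, sprouting stacks, tube stacks)
4.  scene I/O (multipage TIFF + CSV truth + JSON config sidecar)
5.  segmentation (nuclei, cells, area masks)
6.  morphometrics (ellipse fits, orientation histograms, junctional
    linearization, Golgi polarization, circular statistics, colour
    fractions, vessel geometry, depth profiles)
7.  config-driven pipeline orchestration

Coordinate conventions
----------------------
Rasters are indexed ``(row, col)``, 0-based.  All angles are measured in
the mathematical frame ``x = col, y = -row`` so that counter-clockwise is
positive on screen.  Nucleus/cell orientations are *axial* (θ and θ+180°
are the same orientation) and are folded to [0°, 90°] relative to the
flow axis.  Golgi polarization is a *directed* angle in [0°, 360°) with
0° defined as pointing against the flow (upstream).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage import color as skcolor
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage import segmentation as skseg
from skimage.filters import threshold_otsu

__all__ = [
    "AngularLaw",
    "CellShapeRecord",
    "CircularSummary",
    "DepthProfile",
    "EllipseFit",
    "FlowField",
    "LabelImage",
    "OrientationSummary",
    "RunConfig",
    "SceneConfig",
    "SegmentCounts",
    "SyntheticScene",
    "VesselGeometry",
    "area_fraction",
    "binary_area_mask",
    "cell_shape_table",
    "circular_summary",
    "depth_profile",
    "eccentricity",
    "ellipse_fit",
    "fold_axial_deg",
    "golgi_angle",
    "hsv_blue_fraction",
    "junction_linearization_index",
    "load_scene",
    "make_monolayer",
    "make_sprout_stack",
    "make_stained_tissue",
    "make_tube_stack",
    "make_vessel",
    "object_density",
    "orientation_summary",
    "rose_histogram",
    "run",
    "save_rose_plot",
    "save_scene",
    "segment_cells",
    "segment_counts_by_diameter",
    "segment_nuclei",
    "vessel_diameter",
]

logger = logging.getLogger("flowmorph")

# --- shared numerical constants -------------------------------------------
#: Gaussian sigma (in contour-vertex units) applied to iso-contours before
#: perimeter measurement.  Balances staircase inflation on curved outlines
#: (pushes convex rasterised shapes to JLI ~ 1) against corner rounding on
#: genuinely angular outlines.
CONTOUR_SMOOTH_SIGMA = 0.75

#: Relative semi-axis gap (a - b) / a below which the fitted orientation is
#: flagged unstable (near-isotropic object).
ISOTROPY_TOL = 0.02

#: Resultant lengths below this leave the circular mean undefined.
RBAR_EPS = 1e-9

#: Cells whose centroid lies within this band below the gel surface count as
#: non-invading for the mean sprout length.
SURFACE_EXCLUSION_UM = 5.0


# ==========================================================================
# 1. angle helpers
# ==========================================================================

def fold_axial_deg(delta_deg: np.ndarray | float) -> np.ndarray | float:
    """Fold an axial angle difference into [0, 90] degrees.

    Axial data identify θ with θ+180°, so the angle between two axes is at
    most 90°.
    """
    return np.abs(((np.asarray(delta_deg, dtype=float) + 90.0) % 180.0) - 90.0)


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.hypot(v[0], v[1]))
    if n < 1e-12:
        raise ValueError("direction vector must be non-zero")
    return v / n


# ==========================================================================
# 2. domain types
# ==========================================================================

@dataclass(frozen=True)
class FlowField:
    """Flow direction as a unit vector in the math frame (x=col, y=-row).

    ``direction=(1, 0)`` is flow to the right.  For the Golgi polarization
    metric, 0° is the *upstream* direction ``-direction``.
    """

    direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        u = _unit(self.direction)
        object.__setattr__(self, "direction", (float(u[0]), float(u[1])))

    @property
    def angle_deg(self) -> float:
        """Axis angle of the flow direction in [0, 180)."""
        return float(np.degrees(np.arctan2(self.direction[1], self.direction[0])) % 180.0)

    def rotated(self, by_deg: float) -> "FlowField":
        t = np.radians(by_deg)
        c, s = np.cos(t), np.sin(t)
        x, y = self.direction
        return FlowField((c * x - s * y, s * x + c * y))


@dataclass(frozen=True)
class AngularLaw:
    """Sampling law for angles.

    ``kind='uniform'`` ignores the parameters.  ``kind='von_mises'`` uses
    ``mean_deg`` and concentration ``kappa >= 0`` (kappa 0 degenerates to
    uniform).  Axial use (nucleus axes) samples on the doubled circle and
    halves; directed use (Golgi offsets) samples the full circle.
    """

    kind: str = "uniform"
    mean_deg: float = 0.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "von_mises"):
            raise ValueError(f"unknown angular law kind {self.kind!r}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    def sample_axial_deg(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n axial angles in [0, 180) degrees."""
        if self.kind == "uniform" or self.kappa == 0:
            return rng.uniform(0.0, 180.0, size=n)
        # von Mises on the doubled angle, then halve: the standard device
        # for axial (undirected) orientations.
        phi = rng.vonmises(np.radians(2.0 * self.mean_deg), self.kappa, size=n)
        return (np.degrees(phi) / 2.0) % 180.0

    def sample_full_deg(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n directed angles in [0, 360) degrees."""
        if self.kind == "uniform" or self.kappa == 0:
            return rng.uniform(0.0, 360.0, size=n)
        phi = rng.vonmises(np.radians(self.mean_deg), self.kappa, size=n)
        return np.degrees(phi) % 360.0


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic endothelial monolayer scene.

    Defaults emulate a confluent HUVEC field imaged at 20x: ~50 nuclei in a
    512 px field, strongly flow-aligned (von Mises kappa 50 about the flow
    axis) and elongated (eccentricity 0.8), with a Golgi positioned a few
    pixels upstream of each nucleus.  Flow is along +x.
    """

    width: int = 512
    height: int = 512
    pixel_size: float = 1.0
    n_cells: int = 50
    orientation_law: AngularLaw = field(default_factory=lambda: AngularLaw("von_mises", 0.0, 50.0))
    ecc_target: float = 0.8
    junction_irregularity: float = 0.0
    golgi_offset_law: AngularLaw | None = None
    nucleus_semi_major_px: float = 11.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ecc_target < 1.0):
            raise ValueError("ecc_target must be in [0, 1)")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.junction_irregularity < 0:
            raise ValueError("junction_irregularity must be >= 0")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class SyntheticScene:
    """A generated scene: named channels, a ground-truth table, the config.

    Channels (present depending on scene kind):
      ``nuclei`` uint8, ``cells`` int32 label image, ``junction`` uint8,
      ``golgi`` uint8, ``mask`` bool (vessel), ``rgb`` (H,W,3) uint8,
      ``roi`` bool, ``stack`` int32 (Z,Y,X) label stack.
    """

    kind: str
    channels: dict[str, np.ndarray]
    truth: pd.DataFrame
    config: dict
    pixel_size: float = 1.0
    z_step_um: float | None = None


@dataclass(frozen=True)
class LabelImage:
    """Integer label raster: 0 = background, k > 0 = object k.

    Labels are consecutive positive integers.  ``border_labels`` flags
    objects touching the image border (their clipped shapes are excluded
    from shape metrics by default, but kept for counting).
    """

    labels: np.ndarray
    pixel_size: float = 1.0
    border_labels: frozenset = frozenset()

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a labelled object.

    ``a >= b`` are the semi-axes (2 sqrt of the covariance eigenvalues, the
    semi-axes of the ellipse with the same normalized second central
    moments).  ``theta_deg`` is the axial angle of the major axis in
    [0, 180), math frame.  ``theta_stable`` is False for near-isotropic
    objects whose orientation is numerically meaningless.
    """

    centroid_rc: tuple[float, float]
    a: float
    b: float
    theta_deg: float
    theta_stable: bool = True

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("ellipse requires a >= b > 0")


@dataclass(frozen=True)
class OrientationSummary:
    """Folded nucleus-to-flow angles with the standard 10-degree histogram.

    ``histogram_pct`` has 9 bins [0,10), ..., [80,90]; it sums to 100.
    ``aligned_fraction_pct`` is the percentage of cells strictly within
    0-30 degrees of the flow axis.
    """

    angles_deg: np.ndarray
    histogram_pct: np.ndarray
    bin_edges_deg: np.ndarray
    aligned_fraction_pct: float
    n: int


@dataclass(frozen=True)
class CellShapeRecord:
    """Per-cell shape metrics from its outline."""

    cell_id: int
    area_px: float
    area_um2: float
    perimeter_px: float
    convex_perimeter_px: float
    jli: float
    eccentricity: float


@dataclass(frozen=True)
class CircularSummary:
    """Circular mean / SD / resultant length of a set of angles.

    ``sd_deg`` defaults to the circular standard deviation
    sqrt(-2 ln Rbar); the angular deviation sqrt(2 (1 - Rbar)) is available
    via ``circular_summary(..., sd_kind='angular')``.  ``mean_defined`` is
    False when the resultant length vanishes.
    """

    mean_deg: float
    sd_deg: float
    resultant_length: float
    n: int
    mean_defined: bool = True


@dataclass(frozen=True)
class VesselGeometry:
    """Chord-width profile of a tubular mask."""

    widths_px: np.ndarray
    mean_diameter_px: float
    mean_diameter_um: float
    axis: str


@dataclass(frozen=True)
class SegmentCounts:
    """Vessel cross-section counts per z-slice, binned by equivalent diameter."""

    bin_edges_um: np.ndarray
    per_slice: np.ndarray  # (n_slices, n_bins)
    totals: np.ndarray  # (n_bins,)


@dataclass(frozen=True)
class DepthProfile:
    """Foreground area vs depth below the gel surface, plus sprout lengths."""

    depth_bin_edges_um: np.ndarray
    area_um2: np.ndarray
    sprout_lengths_um: np.ndarray
    mean_sprout_length_um: float
    n_invading: int


# ==========================================================================
# 3. synthetic scene generation
# ==========================================================================

def _place_centers(
    n: int,
    height: int,
    width: int,
    margin: float,
    min_sep: float,
    rng: np.random.Generator,
    max_tries_per_cell: int = 2000,
) -> np.ndarray:
    """Rejection-sample n non-overlapping centres; error if too dense."""
    centers: list[tuple[float, float]] = []
    tries = 0
    budget = max(1, n) * max_tries_per_cell
    while len(centers) < n:
        if tries >= budget:
            raise ValueError(
                f"could not place {n} objects with separation {min_sep:.1f} px in a "
                f"{height}x{width} field after {budget} attempts; reduce the density"
            )
        tries += 1
        r = rng.uniform(margin, height - margin)
        c = rng.uniform(margin, width - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers):
            centers.append((r, c))
    return np.asarray(centers, dtype=float).reshape(n, 2)


def _smooth_periodic_noise(n: int, sigma_samples: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-std periodic noise (circularly smoothed white noise)."""
    w = rng.standard_normal(n)
    s = ndimage.gaussian_filter1d(w, sigma_samples, mode="wrap")
    s -= s.mean()
    sd = s.std()
    return s / sd if sd > 0 else s


def _jitter_cell_boundaries(
    labels: np.ndarray,
    centers_rc: np.ndarray,
    amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturb each cell's boundary radially and re-rasterize.

    Each cell polygon (contour of its nearest-nucleus region) has its
    vertices displaced along the ray from the nucleus centre by smooth
    periodic Gaussian noise of the given amplitude (px).  Earlier cells
    win contested pixels; pixels left unclaimed stay 0 and read as
    junction-gap background.
    """
    out = np.zeros_like(labels)
    h, w = labels.shape
    for k in range(1, int(labels.max()) + 1):
        mask = labels == k
        if not mask.any():
            continue
        padded = np.pad(mask.astype(float), 1)
        contours = skmeasure.find_contours(padded, 0.5)
        if not contours:
            continue
        cont = max(contours, key=len) - 1.0  # undo pad
        cr, cc = centers_rc[k - 1]
        dr = cont[:, 0] - cr
        dc = cont[:, 1] - cc
        rad = np.hypot(dr, dc)
        rad_safe = np.where(rad < 1e-9, 1e-9, rad)
        noise = amplitude * _smooth_periodic_noise(len(cont), max(2.0, len(cont) / 24.0), rng)
        scale = np.clip((rad + noise) / rad_safe, 0.05, None)
        rows = cr + dr * scale
        cols = cc + dc * scale
        rr, cc2 = skdraw.polygon(rows, cols, shape=(h, w))
        claim = out[rr, cc2] == 0
        out[rr[claim], cc2[claim]] = k
    return out


def make_monolayer(cfg: SceneConfig) -> SyntheticScene:
    """Generate a confluent monolayer scene with known per-cell truth.

    Produces a nuclei channel (filled ellipses with the configured
    orientation law and eccentricity), a cell label image (nearest-nucleus
    partition, boundaries optionally roughened by ``junction_irregularity``),
    a junction channel (bright cell boundaries), and, when a
    ``golgi_offset_law`` is set, a Golgi channel of small blobs offset from
    each nucleus at a controlled angle from the upstream direction.

    The truth table has one row per cell: nucleus centroid, axial angle to
    flow (folded to [0, 90]), eccentricity, areas, Golgi position/angle and
    a border flag.  Flow is along +x.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    nuclei = np.zeros((h, w), dtype=np.uint8)
    cells = np.zeros((h, w), dtype=np.int32)
    junction = np.zeros((h, w), dtype=np.uint8)
    golgi_img = np.zeros((h, w), dtype=np.uint8)

    cols = [
        "id", "row", "col", "theta_deg", "angle_to_flow_deg", "eccentricity",
        "nucleus_area_px", "cell_area_px", "border",
        "golgi_row", "golgi_col", "golgi_angle_deg",
    ]
    if cfg.n_cells == 0:
        truth = pd.DataFrame(columns=cols)
        channels = {"nuclei": nuclei, "cells": cells, "junction": junction}
        if cfg.golgi_offset_law is not None:
            channels["golgi"] = golgi_img
        return SyntheticScene("monolayer", channels, truth, cfg.to_dict(), cfg.pixel_size)

    a = float(cfg.nucleus_semi_major_px)
    b = a * np.sqrt(1.0 - cfg.ecc_target**2)
    margin = a + 3.0
    if 2 * margin >= min(h, w):
        raise ValueError("field too small for the configured nucleus size")
    centers = _place_centers(cfg.n_cells, h, w, margin, 2.0 * a + 2.0, rng)
    thetas = cfg.orientation_law.sample_axial_deg(cfg.n_cells, rng)

    nucleus_areas = np.zeros(cfg.n_cells)
    for i, ((cr, cc), th) in enumerate(zip(centers, thetas)):
        rr, cc2 = skdraw.ellipse(cr, cc, b, a, rotation=np.radians(th), shape=(h, w))
        nuclei[rr, cc2] = 255
        nucleus_areas[i] = len(rr)

    # nearest-nucleus partition of the field
    grid_r, grid_c = np.mgrid[0:h, 0:w]
    tree = cKDTree(centers)
    _, nearest = tree.query(np.column_stack([grid_r.ravel(), grid_c.ravel()]))
    cells = (nearest.reshape(h, w) + 1).astype(np.int32)

    if cfg.junction_irregularity > 0:
        cells = _jitter_cell_boundaries(cells, centers, cfg.junction_irregularity, rng)
        # nuclei must remain inside their own cell
        for i, (cr, cc) in enumerate(centers):
            rr, cc2 = skdraw.ellipse(cr, cc, b, a, rotation=np.radians(thetas[i]), shape=(h, w))
            cells[rr, cc2] = i + 1

    boundaries = skseg.find_boundaries(cells, mode="thick") | (cells == 0)
    junction[boundaries] = 255

    border = np.zeros(cfg.n_cells, dtype=bool)
    edge_labels = np.unique(
        np.concatenate([cells[0, :], cells[-1, :], cells[:, 0], cells[:, -1]])
    )
    border[[lab - 1 for lab in edge_labels if lab > 0]] = True
    cell_areas = np.bincount(cells.ravel(), minlength=cfg.n_cells + 1)[1:].astype(float)

    golgi_rc = np.full((cfg.n_cells, 2), np.nan)
    golgi_psi = np.full(cfg.n_cells, np.nan)
    if cfg.golgi_offset_law is not None:
        psi = cfg.golgi_offset_law.sample_full_deg(cfg.n_cells, rng)
        dist = a + 4.0
        for i, ((cr, cc), p) in enumerate(zip(centers, psi)):
            # 0 deg = upstream (-x); rotating (-1, 0) CCW by psi gives
            # (-cos psi, -sin psi) in the math frame; row = -y.
            ang = np.radians(p)
            gc = cc - dist * np.cos(ang)
            gr = cr + dist * np.sin(ang)
            rr, cc2 = skdraw.disk((gr, gc), 2.5, shape=(h, w))
            golgi_img[rr, cc2] = 255
            golgi_rc[i] = (gr, gc)
            golgi_psi[i] = p

    truth = pd.DataFrame(
        {
            "id": np.arange(1, cfg.n_cells + 1),
            "row": centers[:, 0],
            "col": centers[:, 1],
            "theta_deg": thetas,
            "angle_to_flow_deg": fold_axial_deg(thetas),
            "eccentricity": np.full(cfg.n_cells, cfg.ecc_target),
            "nucleus_area_px": nucleus_areas,
            "cell_area_px": cell_areas,
            "border": border,
            "golgi_row": golgi_rc[:, 0],
            "golgi_col": golgi_rc[:, 1],
            "golgi_angle_deg": golgi_psi,
        }
    )
    channels = {"nuclei": nuclei, "cells": cells, "junction": junction}
    if cfg.golgi_offset_law is not None:
        channels["golgi"] = golgi_img
    return SyntheticScene("monolayer", channels, truth, cfg.to_dict(), cfg.pixel_size)


def make_vessel(
    diameter_px: float,
    length_px: int = 400,
    noise: float = 0.0,
    seed: int = 0,
    height: int | None = None,
    pixel_size: float = 1.0,
) -> SyntheticScene:
    """Binary tube phantom of known mean width, horizontal axis.

    ``noise`` is the standard deviation (px) of smooth zero-mean
    displacements applied independently to the top and bottom edges; the
    offsets are re-centred so the mean width equals ``diameter_px`` by
    construction (up to rasterization).
    """
    if diameter_px <= 0:
        raise ValueError("diameter_px must be > 0")
    if height is None:
        height = int(np.ceil(diameter_px * 3 + 6 * max(noise, 1.0) + 10))
    if diameter_px > height:
        raise ValueError(f"diameter {diameter_px} px exceeds image height {height} px")
    rng = np.random.default_rng(seed)
    cy = height / 2.0
    if noise > 0:
        top_off = noise * _smooth_periodic_noise(length_px, 5.0, rng)
        bot_off = noise * _smooth_periodic_noise(length_px, 5.0, rng)
    else:
        top_off = np.zeros(length_px)
        bot_off = np.zeros(length_px)
    top = cy - diameter_px / 2.0 + top_off
    bot = cy + diameter_px / 2.0 + bot_off
    rows = np.arange(height)[:, None] + 0.5
    mask = (rows > top[None, :]) & (rows <= bot[None, :])
    widths = mask.sum(axis=0)
    truth = pd.DataFrame(
        {
            "diameter_px": [diameter_px],
            "noise_px": [noise],
            "realized_mean_width_px": [float(widths.mean())],
        }
    )
    cfgd = {
        "kind": "vessel",
        "diameter_px": diameter_px,
        "length_px": length_px,
        "noise": noise,
        "seed": seed,
        "height": height,
        "pixel_size": pixel_size,
    }
    return SyntheticScene("vessel", {"mask": mask}, truth, cfgd, pixel_size)


def make_stained_tissue(
    blue_fraction: float,
    shape: tuple[int, int] = (256, 256),
    roi: str | np.ndarray = "ellipse",
    seed: int = 0,
) -> SyntheticScene:
    """RGB tissue phantom with a known blue-pixel fraction inside an ROI.

    ROI pixels are pure blue (hue 240°) with probability ``blue_fraction``
    and pure red (hue 0°) otherwise; pixels outside the ROI are black.  The
    truth table records the exactly realized fraction.
    """
    if not (0.0 <= blue_fraction <= 1.0):
        raise ValueError("blue_fraction must be in [0, 1]")
    h, w = shape
    if isinstance(roi, np.ndarray):
        roi_mask = roi.astype(bool)
        if roi_mask.shape != (h, w):
            raise ValueError("roi mask shape mismatch")
    elif roi == "full":
        roi_mask = np.ones((h, w), dtype=bool)
    elif roi == "ellipse":
        roi_mask = np.zeros((h, w), dtype=bool)
        rr, cc = skdraw.ellipse(h / 2.0, w / 2.0, h * 0.42, w * 0.42, shape=(h, w))
        roi_mask[rr, cc] = True
    else:
        raise ValueError(f"unknown roi spec {roi!r}")
    rng = np.random.default_rng(seed)
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    n_roi = int(roi_mask.sum())
    is_blue = rng.random(n_roi) < blue_fraction
    rs, cs = np.nonzero(roi_mask)
    rgb[rs[is_blue], cs[is_blue], 2] = 255
    rgb[rs[~is_blue], cs[~is_blue], 0] = 255
    realized = float(is_blue.sum()) / n_roi if n_roi else 0.0
    truth = pd.DataFrame(
        {
            "blue_fraction_target": [blue_fraction],
            "blue_fraction_realized": [realized],
            "n_roi_px": [n_roi],
        }
    )
    cfgd = {"kind": "tissue", "blue_fraction": blue_fraction, "shape": list(shape), "seed": seed}
    return SyntheticScene("tissue", {"rgb": rgb, "roi": roi_mask}, truth, cfgd)


def make_sprout_stack(
    n_cells: int,
    depth_law: Mapping[str, Any],
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 128, 128),
    pixel_size: float = 1.0,
    z_step_um: float = 2.0,
    radius_px: float = 4.0,
    radius_z: float = 2.0,
) -> SyntheticScene:
    """3D label stack of sprouting cells at known depths below the surface.

    ``depth_law`` is one of ``{'kind': 'point', 'value': d}``,
    ``{'kind': 'uniform', 'low': a, 'high': b}`` or
    ``{'kind': 'exponential', 'scale': s}`` (depths in µm; 0 = gel
    surface, z index 0).  Each cell is an ellipsoidal blob centred at its
    drawn depth (clipped at the surface for near-zero depths, as a cell
    body resting on the gel would be).
    """
    nz, h, w = shape
    rng = np.random.default_rng(seed)
    stack = np.zeros(shape, dtype=np.int32)
    if n_cells == 0:
        truth = pd.DataFrame(columns=["id", "depth_um", "row", "col"])
        cfgd = {"kind": "sprout", "n_cells": 0, "depth_law": dict(depth_law), "seed": seed,
                "shape": list(shape), "pixel_size": pixel_size, "z_step_um": z_step_um}
        return SyntheticScene("sprout", {"stack": stack}, truth, cfgd, pixel_size, z_step_um)

    kind = depth_law.get("kind")
    if kind == "point":
        depths = np.full(n_cells, float(depth_law["value"]))
    elif kind == "uniform":
        depths = rng.uniform(float(depth_law["low"]), float(depth_law["high"]), n_cells)
    elif kind == "exponential":
        depths = rng.exponential(float(depth_law["scale"]), n_cells)
    else:
        raise ValueError(f"unknown depth law {kind!r}")
    if np.any(depths < 0):
        raise ValueError("depths must be >= 0")
    max_depth = (nz - 1) * z_step_um
    if np.any(depths > max_depth):
        raise ValueError(
            f"drawn depth {depths.max():.1f} µm exceeds the stack extent {max_depth:.1f} µm"
        )
    margin = radius_px + 2.0
    centers = _place_centers(n_cells, h, w, margin, 2 * radius_px + 2.0, rng)
    zz, yy, xx = np.mgrid[0:nz, 0:h, 0:w]
    for i, ((cr, cc), d) in enumerate(zip(centers, depths)):
        zc = d / z_step_um
        blob = (
            ((zz - zc) / radius_z) ** 2
            + ((yy - cr) / radius_px) ** 2
            + ((xx - cc) / radius_px) ** 2
        ) <= 1.0
        stack[blob] = i + 1
    truth = pd.DataFrame(
        {"id": np.arange(1, n_cells + 1), "depth_um": depths,
         "row": centers[:, 0], "col": centers[:, 1]}
    )
    cfgd = {"kind": "sprout", "n_cells": n_cells, "depth_law": dict(depth_law), "seed": seed,
            "shape": list(shape), "pixel_size": pixel_size, "z_step_um": z_step_um}
    return SyntheticScene("sprout", {"stack": stack}, truth, cfgd, pixel_size, z_step_um)


def make_tube_stack(
    diameters_px: Sequence[float],
    n_slices: int = 200,
    shape_xy: tuple[int, int] | None = None,
    pixel_size: float = 1.0,
) -> SyntheticScene:
    """Label stack of straight tubes along z with known circular diameters.

    Emulates a vascular cast volume re-sliced into z-sections for segment
    counting: each tube contributes one cross-section of known diameter to
    every slice.
    """
    diameters = [float(d) for d in diameters_px]
    if any(d <= 0 for d in diameters):
        raise ValueError("diameters must be > 0")
    dmax = max(diameters)
    pitch = int(np.ceil(dmax + 10))
    if shape_xy is None:
        shape_xy = (pitch + 10, pitch * len(diameters) + 10)
    h, w = shape_xy
    plane = np.zeros((h, w), dtype=np.int32)
    for i, d in enumerate(diameters):
        cy = h / 2.0
        cx = pitch * (i + 0.5) + 5
        rr, cc = skdraw.disk((cy, cx), d / 2.0, shape=(h, w))
        plane[rr, cc] = i + 1
    stack = np.repeat(plane[None, :, :], n_slices, axis=0)
    areas = np.bincount(plane.ravel(), minlength=len(diameters) + 1)[1:]
    truth = pd.DataFrame(
        {
            "id": np.arange(1, len(diameters) + 1),
            "diameter_px": diameters,
            "cross_section_area_px": areas,
            "equivalent_diameter_px": 2.0 * np.sqrt(areas / np.pi),
        }
    )
    cfgd = {"kind": "tubes", "diameters_px": diameters, "n_slices": n_slices,
            "pixel_size": pixel_size}
    return SyntheticScene("tubes", {"stack": stack}, truth, cfgd, pixel_size)


# ==========================================================================
# 4. scene I/O
# ==========================================================================

def save_scene(scene: SyntheticScene, out_dir: str | Path) -> Path:
    """Write a scene as per-channel TIFFs + truth CSV + JSON config sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, arr in scene.channels.items():
        a = arr
        if a.dtype == bool:
            a = a.astype(np.uint8) * 255 if name != "roi" else a.astype(np.uint8)
        tifffile.imwrite(out / f"{name}.tif", a)
    scene.truth.to_csv(out / "truth.csv", index=False)
    meta = {"kind": scene.kind, "pixel_size": scene.pixel_size,
            "z_step_um": scene.z_step_um, "config": scene.config,
            "channels": sorted(scene.channels)}
    (out / "scene.json").write_text(json.dumps(meta, indent=2, default=str))
    return out


def load_scene(scene_dir: str | Path) -> SyntheticScene:
    """Read a scene written by :func:`save_scene`."""
    d = Path(scene_dir)
    meta = json.loads((d / "scene.json").read_text())
    channels = {}
    for name in meta["channels"]:
        arr = tifffile.imread(d / f"{name}.tif")
        if name in ("mask", "roi"):
            arr = arr.astype(bool)
        channels[name] = arr
    truth = pd.read_csv(d / "truth.csv")
    return SyntheticScene(
        meta["kind"], channels, truth, meta["config"],
        float(meta["pixel_size"]), meta.get("z_step_um"),
    )


# ==========================================================================
# 5. segmentation
# ==========================================================================

def segment_nuclei(gray: np.ndarray, min_area_px: int = 20, pixel_size: float = 1.0) -> LabelImage:
    """Threshold (Otsu) and label nuclei; drop specks below ``min_area_px``.

    Connected components use 8-connectivity; surviving labels are
    renumbered consecutively.  A uniform image yields an empty label image
    with a warning rather than an error.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("segment_nuclei expects a single-channel image")
    if gray.max() == gray.min():
        warnings.warn("uniform image: no threshold separates foreground", stacklevel=2)
        return LabelImage(np.zeros(gray.shape, dtype=np.int32), pixel_size)
    thr = threshold_otsu(gray)
    bw = gray > thr
    lab = skmeasure.label(bw, connectivity=2)
    if min_area_px > 0 and lab.max() > 0:
        sizes = np.bincount(lab.ravel())
        too_small = np.nonzero(sizes < min_area_px)[0]
        lab[np.isin(lab, too_small[too_small > 0])] = 0
    lab, _, _ = skseg.relabel_sequential(lab)
    return LabelImage(lab.astype(np.int32), pixel_size)


def segment_cells(junction: np.ndarray, seeds: LabelImage) -> LabelImage:
    """Seeded watershed on the junction channel; one region per seed.

    Regions climb towards bright junction lines, so boundaries land on the
    stained junctions.  Regions touching the image border are flagged in
    ``border_labels`` (shape metrics skip them by default).
    """
    junction = np.asarray(junction, dtype=float)
    if seeds.n_objects == 0:
        return LabelImage(np.zeros(junction.shape, dtype=np.int32), seeds.pixel_size)
    lab = skseg.watershed(junction, markers=seeds.labels)
    edge = np.unique(np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]))
    border = frozenset(int(v) for v in edge if v > 0)
    return LabelImage(lab.astype(np.int32), seeds.pixel_size, border)


def binary_area_mask(
    gray: np.ndarray, method: str = "otsu", level: float | None = None
) -> np.ndarray:
    """Foreground mask for area-fraction readouts (permeability, density).

    ``method='otsu'`` picks the threshold automatically; ``method='fixed'``
    requires ``level`` and keeps pixels strictly above it.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("binary_area_mask expects a single-channel image")
    if method == "fixed":
        if level is None:
            raise ValueError("fixed thresholding requires a level")
        return gray > level
    if method == "otsu":
        if gray.max() == gray.min():
            warnings.warn("uniform image: empty mask returned", stacklevel=2)
            return np.zeros(gray.shape, dtype=bool)
        return gray > threshold_otsu(gray)
    raise ValueError(f"unknown method {method!r}")


# ==========================================================================
# 6. morphometrics
# ==========================================================================

def ellipse_fit(mask: np.ndarray) -> EllipseFit:
    """Moment-equivalent ellipse of a single-object binary mask.

    Semi-axes are ``2 sqrt(eigenvalues)`` of the pixel covariance (with the
    1/12 px² continuous-pixel correction), i.e. the ellipse with the same
    normalized second central moments as the object.  The axial angle of
    the major axis is reported in [0, 180) in the math frame.
    """
    mask = np.asarray(mask).astype(bool)
    ys, xs = np.nonzero(mask)
    n = len(ys)
    if n < 5:
        raise ValueError(f"ellipse fit needs >= 5 foreground pixels, got {n}")
    x = xs - xs.mean()
    y = -(ys - ys.mean())  # math frame
    mxx = (x * x).mean() + 1.0 / 12.0
    myy = (y * y).mean() + 1.0 / 12.0
    mxy = (x * y).mean()
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 0:
        raise ValueError("degenerate mask: zero variance along one axis")
    a = 2.0 * np.sqrt(evals[1])
    b = 2.0 * np.sqrt(evals[0])
    v = evecs[:, 1]
    theta = float(np.degrees(np.arctan2(v[1], v[0])) % 180.0)
    stable = (a - b) / a >= ISOTROPY_TOL
    return EllipseFit((float(ys.mean()), float(xs.mean())), float(a), float(b), theta, stable)


def eccentricity(fit: EllipseFit | tuple[float, float]) -> float:
    """First eccentricity e = sqrt(a² − b²) / a of an ellipse with a ≥ b.

    0 for a circle, approaching 1 as the ellipse degenerates to a line.
    """
    if isinstance(fit, EllipseFit):
        a, b = fit.a, fit.b
    else:
        a, b = fit
    if b > a:
        raise ValueError("requires a >= b")
    if b <= 0:
        raise ValueError("requires b > 0")
    return float(np.sqrt(a * a - b * b) / a)


def orientation_summary(fits: Sequence[EllipseFit], flow: FlowField) -> OrientationSummary:
    """Fold major-axis angles against the flow axis and histogram them.

    Angles fold to [0°, 90°]; the histogram uses the nine 10° bins
    [0,10), ..., [80,90] in percent of cells; the aligned fraction is the
    percentage of cells strictly below 30°.
    """
    if len(fits) == 0:
        raise ValueError("orientation_summary requires at least one fit")
    thetas = np.array([f.theta_deg for f in fits])
    angles = np.asarray(fold_axial_deg(thetas - flow.angle_deg), dtype=float)
    edges = np.arange(0.0, 100.0, 10.0)
    counts, _ = np.histogram(angles, bins=edges)  # 90 lands in the last bin
    pct = counts / len(angles) * 100.0
    aligned = float((angles < 30.0).mean() * 100.0)
    return OrientationSummary(angles, pct, edges, aligned, len(angles))


def _measured_contour(mask: np.ndarray) -> np.ndarray:
    """Sub-pixel iso-contour (level 0.5) of a mask, lightly smoothed.

    Smoothing is periodic Gaussian on the vertex chain
    (sigma = CONTOUR_SMOOTH_SIGMA vertices): it removes marching-squares
    staircase inflation so convex rasterized shapes measure JLI ~ 1.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = skmeasure.find_contours(padded, 0.5)
    cont = max(contours, key=len)
    if CONTOUR_SMOOTH_SIGMA > 0 and len(cont) > 8:
        cont = np.column_stack(
            [
                ndimage.gaussian_filter1d(cont[:, 0], CONTOUR_SMOOTH_SIGMA, mode="wrap"),
                ndimage.gaussian_filter1d(cont[:, 1], CONTOUR_SMOOTH_SIGMA, mode="wrap"),
            ]
        )
    return cont - 1.0  # undo padding offset


def _polyline_length(points: np.ndarray, closed: bool = True) -> float:
    pts = np.vstack([points, points[:1]]) if closed else points
    return float(np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1)).sum())


def junction_linearization_index(
    mask: np.ndarray, pixel_size: float = 1.0, cell_id: int = 0
) -> CellShapeRecord:
    """Cell contour perimeter divided by its convex-hull perimeter.

    A cell with linear junctions is convex and scores ~1; irregular,
    wiggly junctions push the index above 1.  The contour is the sub-pixel
    iso-contour of the mask; the convex perimeter comes from the convex
    hull of its vertices.  Holes are filled (with a warning); masks with
    multiple components are rejected.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    ncomp = int(skmeasure.label(mask, connectivity=2).max())
    if ncomp > 1:
        raise ValueError(f"mask has {ncomp} components; expected a single cell")
    filled = ndimage.binary_fill_holes(mask)
    if filled.sum() != mask.sum():
        warnings.warn("cell mask had holes; filled before measuring", stacklevel=2)
        mask = filled
    cont = _measured_contour(mask)
    perim = _polyline_length(cont)
    hull = Polygon(cont).convex_hull
    convex_perim = float(hull.length)
    jli = perim / convex_perim
    fit = ellipse_fit(mask)
    area = float(mask.sum())
    return CellShapeRecord(
        cell_id, area, area * pixel_size**2, perim, convex_perim, jli, eccentricity(fit)
    )


def golgi_angle(
    nucleus_rc: Sequence[float], golgi_rc: Sequence[float], flow: FlowField
) -> float:
    """Directed angle of the nucleus→Golgi vector, 0° = against the flow.

    Counter-clockwise positive in the math frame, result in [0, 360).
    Coincident centroids mean the cell is unpolarized: returns NaN (with a
    warning) so the caller can exclude it from circular statistics.
    """
    v = np.array(
        [float(golgi_rc[1]) - float(nucleus_rc[1]), -(float(golgi_rc[0]) - float(nucleus_rc[0]))]
    )
    if np.hypot(v[0], v[1]) < 1e-12:
        warnings.warn("coincident nucleus/Golgi centroids: unpolarized cell", stacklevel=2)
        return float("nan")
    u = -np.asarray(flow.direction)  # upstream
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return float(np.degrees(np.arctan2(cross, dot)) % 360.0)


def circular_summary(
    angles_deg: Sequence[float], axial: bool = False, sd_kind: str = "circular"
) -> CircularSummary:
    """Circular mean and spread of a set of angles in degrees.

    The mean is the direction of the resultant of the unit vectors; the
    default spread is the circular standard deviation sqrt(−2 ln R̄)
    (``sd_kind='circular'``), with the angular deviation sqrt(2 (1 − R̄))
    available as ``sd_kind='angular'``.  Axial data are doubled before
    averaging and the mean/SD halved after.  A vanishing resultant leaves
    the mean undefined (``mean_defined=False``).
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular_summary requires at least one angle")
    if sd_kind not in ("circular", "angular"):
        raise ValueError(f"unknown sd_kind {sd_kind!r}")
    if axial:
        a = 2.0 * a
    C = np.cos(a).mean()
    S = np.sin(a).mean()
    rbar = float(np.hypot(C, S))
    defined = rbar >= RBAR_EPS
    mean = float(np.degrees(np.arctan2(S, C)) % 360.0) if defined else float("nan")
    if mean >= 360.0:  # float wrap: (-eps) % 360 == 360.0
        mean = 0.0
    if rbar >= 1.0:
        sd = 0.0
    elif not defined:
        sd = float("inf") if sd_kind == "circular" else float(np.degrees(np.sqrt(2.0)))
    elif sd_kind == "circular":
        sd = float(np.degrees(np.sqrt(-2.0 * np.log(rbar))))
    else:
        sd = float(np.degrees(np.sqrt(2.0 * (1.0 - rbar))))
    if axial:
        if defined:
            mean = mean / 2.0
        sd = sd / 2.0
    return CircularSummary(mean, sd, rbar, int(a.size), defined)


def rose_histogram(angles_deg: Sequence[float], bin_deg: int = 20) -> np.ndarray:
    """Sector counts for a rose plot: [k·bin, (k+1)·bin) over [0°, 360°)."""
    if bin_deg <= 0 or 360 % bin_deg != 0:
        raise ValueError("bin width must divide 360")
    a = np.asarray(angles_deg, dtype=float) % 360.0
    edges = np.arange(0.0, 360.0 + bin_deg, bin_deg)
    counts, _ = np.histogram(a, bins=edges)
    return counts


def save_rose_plot(angles_deg: Sequence[float], path: str | Path, bin_deg: int = 20) -> None:
    """Render a polar rose plot of the angle distribution to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = rose_histogram(angles_deg, bin_deg)
    centers = np.radians(np.arange(0, 360, bin_deg) + bin_deg / 2.0)
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.bar(centers, counts, width=np.radians(bin_deg), edgecolor="k", alpha=0.75)
    ax.set_theta_zero_location("W")  # 0° = against flow, flow along +x
    fig.savefig(path, dpi=120)
    plt.close(fig)


def hsv_blue_fraction(
    rgb: np.ndarray, roi: np.ndarray | None = None, min_saturation: float = 0.0
) -> float:
    """Fraction of ROI pixels whose HSV hue falls in the blue window.

    The image is converted to HSV (hexcone model); pixels with hue in the
    inclusive window [120°, 240°] count as blue.  Gray pixels have
    undefined hue, which the conversion reports as 0° — they count as
    non-blue.  ``min_saturation`` (0–1) optionally gates out washed-out
    pixels.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if roi is None:
        roi = np.ones(rgb.shape[:2], dtype=bool)
    roi = np.asarray(roi).astype(bool)
    if not roi.any():
        raise ValueError("empty ROI")
    hsv = skcolor.rgb2hsv(rgb)
    hue_deg = hsv[..., 0] * 360.0
    blue = (hue_deg >= 120.0) & (hue_deg <= 240.0)
    if min_saturation > 0:
        blue &= hsv[..., 1] >= min_saturation
    return float(blue[roi].mean())


def area_fraction(mask: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Foreground-pixel fraction of the ROI (whole field if roi is None)."""
    mask = np.asarray(mask).astype(bool)
    if roi is None:
        roi = np.ones(mask.shape, dtype=bool)
    roi = np.asarray(roi).astype(bool)
    if not roi.any():
        raise ValueError("empty ROI")
    return float(mask[roi].mean())


def object_density(labels: LabelImage, pixel_size: float | None = None) -> float:
    """Labelled-object count per mm² of field."""
    ps = labels.pixel_size if pixel_size is None else pixel_size
    h, w = labels.labels.shape
    area_mm2 = h * w * ps**2 / 1e6
    if area_mm2 <= 0:
        raise ValueError("zero field area")
    return labels.n_objects / area_mm2


def vessel_diameter(
    mask: np.ndarray,
    axis: str = "auto",
    pixel_size: float = 1.0,
    trim_frac: float = 0.05,
    mode: str = "chord",
) -> VesselGeometry:
    """Diameter profile of a tube-like binary mask.

    ``mode='chord'`` measures the foreground chord perpendicular to the
    tube axis at every position along the measured span, with ``trim_frac``
    of the span dropped at each end (partially drawn vessel ends).  The
    axis is auto-chosen as the longer principal direction.  For curved
    vessels ``mode='skeleton'`` returns twice the medial-axis distance
    along the skeleton instead.  Masks with aspect ratio < 2 trigger a
    non-tubular warning.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty vessel mask")
    fit = ellipse_fit(mask)
    if fit.a / fit.b < 2.0:
        warnings.warn(
            f"mask aspect ratio {fit.a / fit.b:.2f} < 2: not clearly tubular", stacklevel=2
        )
    if axis == "auto":
        axis = "x" if fold_axial_deg(fit.theta_deg) < 45.0 else "y"
    if axis not in ("x", "y"):
        raise ValueError(f"unknown axis {axis!r}")
    if mode == "skeleton":
        skel, dist = skmorph.medial_axis(mask, return_distance=True)
        widths = 2.0 * dist[skel]
        widths = widths[widths > 0]
    elif mode == "chord":
        chords = mask.sum(axis=0) if axis == "x" else mask.sum(axis=1)
        occ = np.nonzero(chords > 0)[0]
        lo, hi = occ[0], occ[-1]
        span = hi - lo + 1
        t = int(np.floor(span * trim_frac))
        widths = chords[lo + t : hi + 1 - t].astype(float)
        widths = widths[widths > 0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mean_px = float(widths.mean())
    return VesselGeometry(widths, mean_px, mean_px * pixel_size, axis)


def segment_counts_by_diameter(
    stack: np.ndarray, bin_edges_um: Sequence[float], pixel_size: float = 1.0
) -> SegmentCounts:
    """Count vessel cross-sections per z-slice, binned by equivalent diameter.

    Each slice is labelled independently (8-connectivity on its foreground)
    and every cross-section contributes its equivalent diameter
    2·sqrt(area/π)·pixel_size to the histogram; totals sum over slices.
    """
    edges = np.asarray(bin_edges_um, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be a sorted 1-D sequence")
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3-D (Z, Y, X) stack")
    nz = stack.shape[0]
    per_slice = np.zeros((nz, len(edges) - 1), dtype=int)
    for z in range(nz):
        lab = skmeasure.label(stack[z] > 0, connectivity=2)
        if lab.max() == 0:
            continue
        areas = np.bincount(lab.ravel())[1:]
        eqd = 2.0 * np.sqrt(areas / np.pi) * pixel_size
        per_slice[z], _ = np.histogram(eqd, bins=edges)
    return SegmentCounts(edges, per_slice, per_slice.sum(axis=0))


def depth_profile(
    stack: np.ndarray,
    pixel_size: float = 1.0,
    z_step_um: float = 1.0,
    surface_exclusion_um: float = SURFACE_EXCLUSION_UM,
) -> DepthProfile:
    """Foreground area vs depth and mean sprout length of a 3-D label stack.

    Slice z lies at depth z·z_step below the gel surface (z = 0).  The
    profile sums foreground area (µm²) per slice.  Each object's sprout
    length is the depth of its centroid; the mean is taken over objects
    deeper than ``surface_exclusion_um`` (cells still sitting on the
    surface are not sprouts).  With no invading object the mean is
    reported as 0 with ``n_invading = 0``.
    """
    if z_step_um <= 0:
        raise ValueError("z_step_um must be > 0")
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3-D (Z, Y, X) stack")
    if stack.dtype == bool or stack.max() <= 1:
        lab = skmeasure.label(stack > 0)
    else:
        lab = stack.astype(np.int32)
    nz = stack.shape[0]
    areas = (stack > 0).reshape(nz, -1).sum(axis=1) * pixel_size**2
    edges = np.arange(nz + 1) * z_step_um
    n_obj = int(lab.max())
    lengths = np.empty(0)
    if n_obj > 0:
        coms = ndimage.center_of_mass(lab > 0, lab, index=np.arange(1, n_obj + 1))
        lengths = np.array([c[0] for c in coms]) * z_step_um
    invading = lengths[lengths > surface_exclusion_um]
    mean_len = float(invading.mean()) if invading.size else 0.0
    return DepthProfile(edges, areas.astype(float), lengths, mean_len, int(invading.size))


def cell_shape_table(cells: LabelImage, include_border: bool = False) -> pd.DataFrame:
    """Per-cell shape metrics for every (by default non-border) cell.

    Cells clipped by the field of view have meaningless perimeters and are
    skipped unless ``include_border``.  Labels whose mask splits into
    several components (rare raster artefacts of jittered boundaries) are
    measured on their largest component.
    """
    rows = []
    for k in range(1, cells.n_objects + 1):
        if not include_border and k in cells.border_labels:
            continue
        mask = cells.labels == k
        if not mask.any():
            continue
        comp = skmeasure.label(mask, connectivity=2)
        if comp.max() > 1:
            sizes = np.bincount(comp.ravel())[1:]
            mask = comp == (int(np.argmax(sizes)) + 1)
        if mask.sum() < 5:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = junction_linearization_index(mask, cells.pixel_size, cell_id=k)
        rows.append(dataclasses.asdict(rec))
    return pd.DataFrame(rows)


# ==========================================================================
# 7. pipeline orchestration
# ==========================================================================

_KNOWN_METRICS = ("orientation", "jli", "golgi", "blue", "permeability", "density",
                  "vessel", "segments", "depth")

_METRIC_CHANNELS = {
    "orientation": ("nuclei",),
    "jli": ("cells",),
    "golgi": ("nuclei", "golgi"),
    "blue": ("rgb",),
    "permeability": ("stain",),
    "density": ("stain",),
    "vessel": ("mask",),
    "segments": ("stack",),
    "depth": ("stack",),
}


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run.

    Built from a flat YAML/JSON mapping; every default is materialised so
    the snapshot written next to the outputs fully determines the run.
    """

    out_dir: str
    metrics: list[str] = field(default_factory=lambda: ["orientation"])
    flow_dir: tuple[float, float] = (1.0, 0.0)
    pixel_size: float = 1.0
    seed: int = 0
    min_area_px: int = 20
    threshold_method: str = "otsu"
    threshold_level: float | None = None
    z_step_um: float = 1.0
    diameter_bins_um: list[float] = field(default_factory=lambda: [0.0, 6.0, 12.0, 24.0, 48.0])
    sd_kind: str = "circular"
    simulate: dict | None = None
    inputs: dict | None = None

    @classmethod
    def from_mapping(cls, m: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(m) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in m:
            raise ValueError("config requires out_dir")
        cfg = cls(**{k: v for k, v in m.items()})
        cfg.flow_dir = tuple(float(v) for v in cfg.flow_dir)  # type: ignore[assignment]
        for metric in cfg.metrics:
            if metric not in _KNOWN_METRICS:
                raise ValueError(f"unknown metric {metric!r}; known: {_KNOWN_METRICS}")
        if cfg.simulate is None and cfg.inputs is None:
            raise ValueError("config needs either a 'simulate' spec or 'inputs' paths")
        if cfg.threshold_method == "fixed" and cfg.threshold_level is None:
            raise ValueError("fixed thresholding requires threshold_level")
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, Mapping):
            raise ValueError("config file must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _simulate_from_spec(spec: Mapping[str, Any], seed: int, pixel_size: float) -> SyntheticScene:
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind == "monolayer":
        law = spec.pop("orientation_law", None)
        glaw = spec.pop("golgi_offset_law", None)
        kw: dict[str, Any] = dict(spec)
        if law is not None:
            kw["orientation_law"] = AngularLaw(**law) if isinstance(law, Mapping) else law
        if glaw is not None:
            kw["golgi_offset_law"] = AngularLaw(**glaw) if isinstance(glaw, Mapping) else glaw
        cfg = SceneConfig(seed=seed, pixel_size=pixel_size, **kw)
        return make_monolayer(cfg)
    if kind == "vessel":
        return make_vessel(seed=seed, pixel_size=pixel_size, **spec)
    if kind == "tissue":
        spec.pop("pixel_size", None)
        if "shape" in spec:
            spec["shape"] = tuple(spec["shape"])
        return make_stained_tissue(seed=seed, **spec)
    if kind == "sprout":
        if "shape" in spec:
            spec["shape"] = tuple(spec["shape"])
        return make_sprout_stack(seed=seed, pixel_size=pixel_size, **spec)
    if kind == "tubes":
        return make_tube_stack(pixel_size=pixel_size, **spec)
    raise ValueError(f"unknown simulate kind {kind!r}")


def _load_inputs(inputs: Mapping[str, str], pixel_size: float) -> SyntheticScene:
    channels = {}
    for name, path in inputs.items():
        arr = _read_image(path)
        if name in ("mask", "roi"):
            arr = arr > 0
        channels[name] = arr
    return SyntheticScene("loaded", channels, pd.DataFrame(), {"inputs": dict(inputs)}, pixel_size)


def _read_image(path: str | Path) -> np.ndarray:
    p = str(path)
    if p.endswith((".tif", ".tiff")):
        return tifffile.imread(p)
    import imageio.v3 as iio

    return iio.imread(p)


def _require_channel(scene: SyntheticScene, metric: str, names: tuple[str, ...]) -> None:
    for name in names:
        ok = name in scene.channels or (name == "stain" and (
            "stain" in scene.channels or "nuclei" in scene.channels))
        if not ok:
            raise ValueError(
                f"metric '{metric}' requires channel '{name}', which is not present"
            )


def run(config: RunConfig, scene: SyntheticScene | None = None) -> dict:
    """Execute simulate → segment → measure and write a report bundle.

    Writes, under ``config.out_dir``: ``per_object.csv`` (one row per
    measured object), ``summary.csv`` (scalar metrics and histograms in
    long form), ``config_snapshot.json`` (every resolved default) and
    ``run.log`` (stage timings and object counts).  Returns the summary as
    a dict.  Identical config + seed reproduce the CSVs byte-for-byte.
    An already loaded/generated ``scene`` may be passed directly, skipping
    the simulate/load stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_stages(config, out, scene)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, out: Path, scene: SyntheticScene | None = None) -> dict:
    (out / "config_snapshot.json").write_text(json.dumps(config.to_dict(), indent=2))
    flow = FlowField(config.flow_dir)
    t0 = time.perf_counter()
    if scene is not None:
        logger.info("scene provided: kind=%s", scene.kind)
    elif config.simulate is not None:
        scene = _simulate_from_spec(config.simulate, config.seed, config.pixel_size)
        logger.info("simulate: kind=%s in %.2fs", scene.kind, time.perf_counter() - t0)
    else:
        scene = _load_inputs(config.inputs or {}, config.pixel_size)
        logger.info("load: channels=%s", sorted(scene.channels))

    for metric in config.metrics:
        _require_channel(scene, metric, _METRIC_CHANNELS[metric])

    summary_rows: list[dict] = []
    per_object: list[pd.DataFrame] = []

    def add(metric: str, quantity: str, value: float, unit: str = "") -> None:
        summary_rows.append(
            {"metric": metric, "quantity": quantity, "value": value, "unit": unit}
        )

    nuclei_labels: LabelImage | None = None
    if any(m in config.metrics for m in ("orientation", "golgi")):
        t = time.perf_counter()
        nuclei_labels = segment_nuclei(
            scene.channels["nuclei"], config.min_area_px, config.pixel_size
        )
        logger.info(
            "segment nuclei: %d objects in %.2fs",
            nuclei_labels.n_objects, time.perf_counter() - t,
        )

    if "orientation" in config.metrics:
        assert nuclei_labels is not None
        fits = []
        rows = []
        for k in range(1, nuclei_labels.n_objects + 1):
            fit = ellipse_fit(nuclei_labels.labels == k)
            fits.append(fit)
            rows.append(
                {
                    "object": "nucleus", "id": k,
                    "row": fit.centroid_rc[0], "col": fit.centroid_rc[1],
                    "angle_to_flow_deg": float(fold_axial_deg(fit.theta_deg - flow.angle_deg)),
                    "eccentricity": eccentricity(fit),
                }
            )
        if not fits:
            raise ValueError("orientation metric: no nuclei segmented")
        summ = orientation_summary(fits, flow)
        per_object.append(pd.DataFrame(rows))
        add("orientation", "n_cells", summ.n)
        add("orientation", "aligned_fraction", summ.aligned_fraction_pct, "%")
        for i, pct in enumerate(summ.histogram_pct):
            add("orientation", f"hist_{10 * i}_{10 * (i + 1)}", float(pct), "%")
        add("orientation", "mean_eccentricity",
            float(np.mean([eccentricity(f) for f in fits])))
        logger.info("orientation: n=%d aligned=%.1f%%", summ.n, summ.aligned_fraction_pct)

    if "jli" in config.metrics:
        t = time.perf_counter()
        if "cells" in scene.channels and scene.channels["cells"].max() > 0:
            lab = scene.channels["cells"].astype(np.int32)
            edge = np.unique(np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
            cells = LabelImage(lab, config.pixel_size,
                               frozenset(int(v) for v in edge if v > 0))
        else:
            if nuclei_labels is None:
                nuclei_labels = segment_nuclei(
                    scene.channels["nuclei"], config.min_area_px, config.pixel_size
                )
            cells = segment_cells(scene.channels["junction"], nuclei_labels)
        shapes = cell_shape_table(cells)
        if shapes.empty:
            raise ValueError("jli metric: no interior cells to measure")
        shapes.insert(0, "object", "cell")
        per_object.append(shapes.rename(columns={"cell_id": "id"}))
        add("jli", "n_cells", len(shapes))
        add("jli", "mean_jli", float(shapes["jli"].mean()))
        add("jli", "mean_cell_eccentricity", float(shapes["eccentricity"].mean()))
        add("jli", "mean_cell_area", float(shapes["area_um2"].mean()), "um2")
        logger.info("jli: %d cells, mean %.3f in %.2fs",
                    len(shapes), shapes["jli"].mean(), time.perf_counter() - t)

    if "golgi" in config.metrics:
        assert nuclei_labels is not None
        golgi_labels = segment_nuclei(scene.channels["golgi"], min_area_px=3,
                                      pixel_size=config.pixel_size)
        n_centroids = np.array(ndimage.center_of_mass(
            nuclei_labels.labels > 0, nuclei_labels.labels,
            index=np.arange(1, nuclei_labels.n_objects + 1)))
        g_centroids = np.array(ndimage.center_of_mass(
            golgi_labels.labels > 0, golgi_labels.labels,
            index=np.arange(1, golgi_labels.n_objects + 1)))
        angles = []
        rows = []
        if len(g_centroids):
            tree = cKDTree(n_centroids)
            _, owner = tree.query(g_centroids)
            for gi, ni in enumerate(owner):
                ang = golgi_angle(n_centroids[ni], g_centroids[gi], flow)
                if np.isfinite(ang):
                    angles.append(ang)
                    rows.append({"object": "golgi", "id": gi + 1,
                                 "nucleus_id": int(ni + 1), "golgi_angle_deg": ang})
        if not angles:
            raise ValueError("golgi metric: no polarized nucleus/Golgi pairs found")
        summ = circular_summary(angles, axial=False, sd_kind=config.sd_kind)
        per_object.append(pd.DataFrame(rows))
        add("golgi", "n_pairs", summ.n)
        add("golgi", "circular_mean", summ.mean_deg, "deg")
        add("golgi", "circular_sd", summ.sd_deg, "deg")
        add("golgi", "resultant_length", summ.resultant_length)
        for i, cnt in enumerate(rose_histogram(angles, 20)):
            add("golgi", f"rose_{20 * i}_{20 * (i + 1)}", int(cnt))
        logger.info("golgi: n=%d mean=%.1f sd=%.1f", summ.n, summ.mean_deg, summ.sd_deg)

    if "blue" in config.metrics:
        roi = scene.channels.get("roi")
        if roi is None:
            roi = scene.channels["rgb"].sum(axis=-1) > 0
        frac = hsv_blue_fraction(scene.channels["rgb"], roi)
        add("blue", "blue_fraction", frac)
        logger.info("blue fraction: %.4f", frac)

    if "permeability" in config.metrics or "density" in config.metrics:
        stain = scene.channels.get("stain", scene.channels.get("nuclei"))
        mask = binary_area_mask(stain, config.threshold_method, config.threshold_level)
        if "permeability" in config.metrics:
            frac = area_fraction(mask)
            add("permeability", "area_fraction", frac)
            add("permeability", "area_um2", float(mask.sum()) * config.pixel_size**2, "um2")
        if "density" in config.metrics:
            lab = skmeasure.label(mask, connectivity=2)
            li = LabelImage(lab.astype(np.int32), config.pixel_size)
            add("density", "objects_per_mm2", object_density(li), "1/mm2")
            add("density", "n_objects", li.n_objects)

    if "vessel" in config.metrics:
        geom = vessel_diameter(scene.channels["mask"], pixel_size=config.pixel_size)
        add("vessel", "mean_diameter_px", geom.mean_diameter_px, "px")
        add("vessel", "mean_diameter_um", geom.mean_diameter_um, "um")
        add("vessel", "n_chords", len(geom.widths_px))
        logger.info("vessel: mean diameter %.2f px", geom.mean_diameter_px)

    if "segments" in config.metrics:
        counts = segment_counts_by_diameter(
            scene.channels["stack"], config.diameter_bins_um, config.pixel_size
        )
        for i in range(len(counts.totals)):
            add("segments",
                f"count_{counts.bin_edges_um[i]:g}_{counts.bin_edges_um[i + 1]:g}um",
                int(counts.totals[i]))

    if "depth" in config.metrics:
        z_step = scene.z_step_um or config.z_step_um
        prof = depth_profile(scene.channels["stack"], config.pixel_size, z_step)
        add("depth", "mean_sprout_length_um", prof.mean_sprout_length_um, "um")
        add("depth", "n_invading", prof.n_invading)
        add("depth", "total_area_um2", float(prof.area_um2.sum()), "um2")

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.csv", index=False, float_format="%.10g")
    if per_object:
        per_obj = pd.concat(per_object, ignore_index=True)
    else:
        per_obj = pd.DataFrame()
    per_obj.to_csv(out / "per_object.csv", index=False, float_format="%.10g")
    logger.info("wrote %s and %s", out / "summary.csv", out / "per_object.csv")
    return {f"{r['metric']}/{r['quantity']}": r["value"] for r in summary_rows}
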