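"""Synthetic femoral-anatomy sampling and B-mode phantom rendering.

The generator draws ground-truth descriptions of the common femoral vessels
from population priors (skin-to-anterior-wall depth, lumen diameter, wall
thickness, the 65% prevalence of anteroposterior artery-over-vein overlap)
and renders transverse B-mode frames: hypoechoic elliptical lumens, a
hyperechoic wall ring that is thicker and brighter for the artery than for
the vein, a textured tissue background, and multiplicative speckle.  Every
frame carries exact per-lumen ground truth (class, bounding box, centroid,
boundary polyline) for downstream evaluation.

Coordinate conventions
----------------------
* Pixels: row 0 at the skin, depth increasing downward; 0-based indices;
  bounding boxes are half-open ``[r0, r1) x [c0, c1)``.
* Physical frame: millimetres; depth positive downward from the skin;
  lateral coordinate measured from the probe's centre element, positive
  toward image right.  A pixel ``(r, c)`` is centred at depth
  ``(r + 0.5) * pixel_spacing`` and lateral ``(c + 0.5 - n_cols/2) *
  pixel_spacing``.
* Cranio-caudal (out-of-plane) position is tracked only through the probe
  pose and the bifurcation coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely import affinity
from shapely.geometry import Point
from shapely.ops import unary_union

__all__ = [
    "AnatomyPriors",
    "VesselGeometry",
    "AnatomyInstance",
    "ImagingConfig",
    "BModeFrame",
    "GroundTruthRecord",
    "sample_anatomy",
    "apply_hypotension",
    "render_frame",
    "render_sweep",
]

NORMOTENSIVE = "normotensive"
HYPOTENSIVE = "hypotensive"
_STATES = (NORMOTENSIVE, HYPOTENSIVE)

ARTERY = "artery"
VEIN = "vein"
BIFURCATION = "bifurcation"


@dataclass(frozen=True)
class AnatomyPriors:
    """Population priors for common femoral vessel geometry (mm).

    Defaults encode the anatomical statistics of adult femoral vessels:
    vein depth 22 +/- 6 mm, vein diameter 9 +/- 3 mm, artery depth
    18 +/- 6 mm, artery diameter 8 +/- 2 mm, a 65% prevalence of partial
    anteroposterior artery-over-vein overlap, and a mean safe access
    length of 80 mm cranial of the bifurcation.
    """

    vein_depth_mean_mm: float = 22.0
    vein_depth_sd_mm: float = 6.0
    vein_diameter_mean_mm: float = 9.0
    vein_diameter_sd_mm: float = 3.0
    artery_depth_mean_mm: float = 18.0
    artery_depth_sd_mm: float = 6.0
    artery_diameter_mean_mm: float = 8.0
    artery_diameter_sd_mm: float = 2.0
    overlap_prevalence: float = 0.65
    access_length_mean_mm: float = 80.0
    # cranio-caudal coordinate of the bifurcation (device cc frame, mm);
    # probe cc=0 sits mid access window by default
    bifurcation_cc_mean_mm: float = -40.0
    bifurcation_cc_sd_mm: float = 10.0
    artery_wall_mean_mm: float = 1.2
    artery_wall_sd_mm: float = 0.15
    vein_wall_mean_mm: float = 0.6
    vein_wall_sd_mm: float = 0.1
    # lumen aspect (depth axis / lateral axis); arteries near-circular,
    # veins more variable
    artery_aspect_mean: float = 0.95
    artery_aspect_sd: float = 0.03
    vein_aspect_mean: float = 0.85
    vein_aspect_sd: float = 0.08
    # anterior-wall deflection a needle can impose before puncture
    tenting_capacity_mean_mm: float = 4.5
    tenting_capacity_sd_mm: float = 1.5
    hypotension_diameter_factor: float = 0.6
    hypotension_artery_factor: float = 0.9
    hypotension_flattening_factor: float = 0.8
    hypotension_tenting_multiplier: float = 2.0
    max_depth_extent_mm: float = 40.0

    def __post_init__(self) -> None:
        for name in (
            "vein_depth_mean_mm", "vein_diameter_mean_mm",
            "artery_depth_mean_mm", "artery_diameter_mean_mm",
            "access_length_mean_mm", "artery_wall_mean_mm",
            "vein_wall_mean_mm", "tenting_capacity_mean_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in (
            "vein_depth_sd_mm", "vein_diameter_sd_mm",
            "artery_depth_sd_mm", "artery_diameter_sd_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.overlap_prevalence <= 1.0:
            raise ValueError("overlap_prevalence must be in [0, 1]")
        if not 0.0 < self.hypotension_diameter_factor < 1.0:
            raise ValueError("hypotension_diameter_factor must be in (0, 1)")
        if self.hypotension_tenting_multiplier <= 1.0:
            raise ValueError("hypotension_tenting_multiplier must exceed 1")


@dataclass(frozen=True)
class VesselGeometry:
    """One vessel lumen cross-section: ellipse in the lateral-depth plane."""

    lateral_center_mm: float
    depth_mm: float              # skin to anterior wall
    diameter_mm: float           # lateral lumen diameter
    wall_thickness_mm: float
    eccentricity: float          # depth axis / lateral axis of the lumen

    @property
    def semi_lateral_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def semi_depth_mm(self) -> float:
        return self.diameter_mm * self.eccentricity / 2.0

    @property
    def centroid_depth_mm(self) -> float:
        return self.depth_mm + self.semi_depth_mm

    @property
    def posterior_depth_mm(self) -> float:
        return self.depth_mm + 2.0 * self.semi_depth_mm

    @property
    def effective_diameter_mm(self) -> float:
        return 2.0 * math.sqrt(self.semi_lateral_mm * self.semi_depth_mm)

    def lateral_interval(self) -> tuple[float, float]:
        return (self.lateral_center_mm - self.semi_lateral_mm,
                self.lateral_center_mm + self.semi_lateral_mm)


@dataclass(frozen=True)
class AnatomyInstance:
    """Ground-truth femoral anatomy for one subject (device frame, mm)."""

    artery: VesselGeometry
    vein: VesselGeometry
    bifurcation_cc_mm: float
    state: str
    tenting_capacity_mm: float
    rng_seed: int
    mirror: bool = False  # False = right leg (artery on image left of vein)

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown physiologic state {self.state!r}")
        if self.tenting_capacity_mm < 0:
            raise ValueError("tenting_capacity_mm must be non-negative")

    @property
    def has_ap_overlap(self) -> bool:
        """True when the artery's lateral extent overlaps the vein's."""
        a0, a1 = self.artery.lateral_interval()
        v0, v1 = self.vein.lateral_interval()
        return a0 < v1 and v0 < a1

    @property
    def access_window_cc_mm(self) -> tuple[float, float]:
        return (self.bifurcation_cc_mm,
                self.bifurcation_cc_mm + 80.0)


@dataclass(frozen=True)
class ImagingConfig:
    """Rendering parameters for synthetic transverse B-mode frames."""

    n_rows: int = 400
    n_cols: int = 384
    pixel_spacing_mm: float = 0.1
    frame_rate_hz: float = 30.0
    background_mean: float = 110.0
    background_texture_amplitude: float = 12.0
    background_texture_sigma_px: float = 12.0
    lumen_intensity: float = 18.0
    artery_wall_intensity: float = 225.0
    vein_wall_intensity: float = 175.0
    edge_blur_sigma_px: float = 0.8
    speckle_sigma: float = 0.35
    speckle_corr_sigma_px: float = 1.0
    # cc half-width around the bifurcation within which the target vessel
    # renders as two merging lumens
    bifurcation_halfwidth_mm: float = 5.0
    skin_lateral_extent_mm: float = 60.0
    skin_cc_extent_mm: float = 120.0
    boundary_points: int = 64

    @property
    def depth_extent_mm(self) -> float:
        return self.n_rows * self.pixel_spacing_mm

    @property
    def lateral_extent_mm(self) -> float:
        return self.n_cols * self.pixel_spacing_mm


@dataclass(frozen=True)
class BModeFrame:
    """One grayscale transverse B-mode frame with probe pose metadata."""

    pixels: np.ndarray  # uint8, (n_rows, n_cols)
    pixel_spacing_mm: float
    probe_lateral_mm: float
    probe_cc_mm: float
    frame_index: int = 0
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8 (intensities 0-255)")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def depth_extent_mm(self) -> float:
        return self.n_rows * self.pixel_spacing_mm

    def col_to_lateral_mm(self, col: float) -> float:
        return (col + 0.5 - self.n_cols / 2.0) * self.pixel_spacing_mm

    def row_to_depth_mm(self, row: float) -> float:
        return (row + 0.5) * self.pixel_spacing_mm

    def lateral_mm_to_col(self, lateral_mm: float) -> float:
        return lateral_mm / self.pixel_spacing_mm + self.n_cols / 2.0 - 0.5

    def depth_mm_to_row(self, depth_mm: float) -> float:
        return depth_mm / self.pixel_spacing_mm - 0.5


@dataclass(frozen=True)
class GroundTruthRecord:
    """Per-lumen annotation: class, half-open pixel bbox, centroid, boundary."""

    frame_index: int
    cls: str
    bbox: tuple[int, int, int, int]       # (r0, c0, r1, c1), half-open
    centroid_mm: tuple[float, float]      # (lateral, depth), frame coords
    boundary_mm: np.ndarray               # (N, 2) columns (lateral, depth)

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bbox
        if not (r0 < r1 and c0 < c1):
            raise ValueError("bbox must be non-empty and half-open")

    def to_dict(self) -> dict:
        return {
            "frame": self.frame_index,
            "class": self.cls,
            "bbox": [int(v) for v in self.bbox],
            "centroid_mm": [float(self.centroid_mm[0]), float(self.centroid_mm[1])],
            "boundary_mm": np.asarray(self.boundary_mm).round(4).tolist(),
        }


# ---------------------------------------------------------------------------
# anatomy sampling
# ---------------------------------------------------------------------------

def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float | None = None, hi: float | None = None) -> float:
    """Normal draw truncated to [mean - 3 sd, mean + 3 sd] (and [lo, hi])."""
    if sd == 0.0:
        return mean
    lo = mean - 3.0 * sd if lo is None else max(lo, mean - 3.0 * sd)
    hi = mean + 3.0 * sd if hi is None else min(hi, mean + 3.0 * sd)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def sample_anatomy(priors: AnatomyPriors, state: str = NORMOTENSIVE,
                   seed: int = 0, mirror: bool = False) -> AnatomyInstance:
    """Draw one ground-truth anatomy from truncated-normal priors.

    Artery-over-vein anteroposterior overlap occurs with probability
    ``priors.overlap_prevalence``: the artery's lateral offset from the
    vein is drawn either inside (partial overlap) or outside the sum of
    the two lateral semi-diameters.  Hypotensive instances are produced
    by sampling a normotensive instance and applying
    :func:`apply_hypotension`, so the hypotension monotonicity contract
    holds by construction.  Deterministic given ``seed``.
    """
    if state not in _STATES:
        raise ValueError(f"unknown physiologic state {state!r}")
    rng = np.random.default_rng(seed)

    max_extent = priors.max_depth_extent_mm
    margin = 0.5

    def _vessel(depth_mean, depth_sd, diam_mean, diam_sd, wall_mean, wall_sd,
                aspect_mean, aspect_sd, lateral) -> VesselGeometry:
        if depth_mean - 3 * depth_sd >= max_extent:
            raise ValueError("priors place vessels outside the field of view")
        depth = _trunc_normal(rng, depth_mean, depth_sd, lo=3.0)
        diam = _trunc_normal(rng, diam_mean, diam_sd, lo=1.0)
        wall = _trunc_normal(rng, wall_mean, wall_sd, lo=0.1)
        aspect = _trunc_normal(rng, aspect_mean, aspect_sd, lo=0.5, hi=1.0)
        # keep the lumen inside the imaged depth without distorting the
        # depth/diameter marginals: deep-tail vessels flatten first, and
        # only then shrink
        depth = min(depth, max_extent - margin - 0.5)
        budget = max_extent - margin - depth
        if diam * aspect > budget:
            aspect = max(0.5, budget / diam)
            if diam * aspect > budget:
                diam = max(1.0, budget / aspect)
        return VesselGeometry(lateral, depth, diam, wall, aspect)

    vein_lateral = _trunc_normal(rng, 0.0, 2.0, lo=-4.0, hi=4.0)
    vein = _vessel(priors.vein_depth_mean_mm, priors.vein_depth_sd_mm,
                   priors.vein_diameter_mean_mm, priors.vein_diameter_sd_mm,
                   priors.vein_wall_mean_mm, priors.vein_wall_sd_mm,
                   priors.vein_aspect_mean, priors.vein_aspect_sd,
                   vein_lateral)
    artery = _vessel(priors.artery_depth_mean_mm, priors.artery_depth_sd_mm,
                     priors.artery_diameter_mean_mm, priors.artery_diameter_sd_mm,
                     priors.artery_wall_mean_mm, priors.artery_wall_sd_mm,
                     priors.artery_aspect_mean, priors.artery_aspect_sd,
                     0.0)

    overlap = rng.random() < priors.overlap_prevalence
    half_sum = artery.semi_lateral_mm + vein.semi_lateral_mm
    if overlap:
        separation = half_sum * rng.uniform(0.35, 0.90)
    else:
        separation = half_sum * rng.uniform(1.10, 1.40)
    side = 1.0 if mirror else -1.0  # right leg: artery toward image left
    artery = replace(artery,
                     lateral_center_mm=vein.lateral_center_mm + side * separation)

    # vessels may overlap in the anteroposterior projection but never
    # interpenetrate: when the outer walls would intersect, the artery is
    # pulled anteriorly (it passes over the vein) until clear
    clearance = 0.5
    r_a = artery.semi_lateral_mm + artery.wall_thickness_mm
    r_v = vein.semi_lateral_mm + vein.wall_thickness_mm
    needed = r_a + r_v + clearance
    d_lat = abs(artery.lateral_center_mm - vein.lateral_center_mm)
    if d_lat < needed:
        d_depth_needed = math.sqrt(needed ** 2 - d_lat ** 2)
        max_artery_centroid = vein.centroid_depth_mm - d_depth_needed
        shift = artery.centroid_depth_mm - max_artery_centroid
        if shift > 0:
            raise_artery = min(shift, artery.depth_mm - 2.0)
            if raise_artery > 0:
                artery = replace(artery,
                                 depth_mm=artery.depth_mm - raise_artery)
            sink_vein = shift - max(raise_artery, 0.0)
            if sink_vein > 0:  # rare: very shallow vein under a large artery
                vein = replace(vein, depth_mm=vein.depth_mm + sink_vein)

    bif_cc = rng.normal(priors.bifurcation_cc_mean_mm, priors.bifurcation_cc_sd_mm)
    tenting = _trunc_normal(rng, priors.tenting_capacity_mean_mm,
                            priors.tenting_capacity_sd_mm, lo=0.5)

    instance = AnatomyInstance(artery=artery, vein=vein,
                               bifurcation_cc_mm=bif_cc, state=NORMOTENSIVE,
                               tenting_capacity_mm=tenting, rng_seed=seed,
                               mirror=mirror)
    if state == HYPOTENSIVE:
        instance = apply_hypotension(instance, priors)
    return instance


def apply_hypotension(instance: AnatomyInstance,
                      priors: AnatomyPriors) -> AnatomyInstance:
    """Return the hypotensive counterpart of a normotensive anatomy.

    The vein shrinks by ``hypotension_diameter_factor`` and flattens
    (aspect scaled by ``hypotension_flattening_factor``), the artery is
    mildly reduced, and the tenting capacity grows by
    ``hypotension_tenting_multiplier``.  The input is left unchanged.
    """
    if instance.state != NORMOTENSIVE:
        raise ValueError("instance is already hypotensive")
    vein = replace(
        instance.vein,
        diameter_mm=instance.vein.diameter_mm * priors.hypotension_diameter_factor,
        eccentricity=max(0.3, instance.vein.eccentricity
                         * priors.hypotension_flattening_factor),
    )
    artery = replace(
        instance.artery,
        diameter_mm=instance.artery.diameter_mm * priors.hypotension_artery_factor,
    )
    return replace(
        instance, artery=artery, vein=vein, state=HYPOTENSIVE,
        tenting_capacity_mm=(instance.tenting_capacity_mm
                             * priors.hypotension_tenting_multiplier),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _ellipse_polygon(cx: float, cy: float, a: float, b: float, n: int = 64):
    circle = Point(0.0, 0.0).buffer(1.0, quad_segs=max(8, n // 4))
    return affinity.translate(affinity.scale(circle, a, b), cx, cy)


def _lumen_shapes(instance: AnatomyInstance, probe_lateral: float,
                  probe_cc: float, config: ImagingConfig):
    """Lumen/wall geometry in frame coordinates.

    Returns a list of dicts with keys cls, lumen (shapely polygon in frame
    mm), wall polygon, wall intensity.  Near the bifurcation the vein is
    replaced by two merging lobes labelled ``bifurcation``.
    """
    shapes = []
    near_bif = abs(probe_cc - instance.bifurcation_cc_mm) \
        < config.bifurcation_halfwidth_mm

    for cls, vessel, wall_int in (
        (ARTERY, instance.artery, config.artery_wall_intensity),
        (VEIN, instance.vein, config.vein_wall_intensity),
    ):
        cx = vessel.lateral_center_mm - probe_lateral
        a, b = vessel.semi_lateral_mm, vessel.semi_depth_mm
        w = vessel.wall_thickness_mm
        if cls == VEIN and near_bif:
            # two merging daughter lumens straddling the parent centre
            la, lb = 0.72 * a, 0.80 * b
            off = 0.62 * a
            cy = vessel.depth_mm + lb
            lum = unary_union([
                _ellipse_polygon(cx - off, cy, la, lb, config.boundary_points),
                _ellipse_polygon(cx + off, cy, la, lb, config.boundary_points),
            ])
            outer = unary_union([
                _ellipse_polygon(cx - off, cy, la + w, lb + w),
                _ellipse_polygon(cx + off, cy, la + w, lb + w),
            ])
            shapes.append({"cls": BIFURCATION, "lumen": lum, "outer": outer,
                           "wall_intensity": wall_int})
        else:
            cy = vessel.centroid_depth_mm
            lum = _ellipse_polygon(cx, cy, a, b, config.boundary_points)
            outer = _ellipse_polygon(cx, cy, a + w, b + w)
            shapes.append({"cls": cls, "lumen": lum, "outer": outer,
                           "wall_intensity": wall_int})
    return shapes


def _polygon_mask(poly, config: ImagingConfig,
                  lat_grid: np.ndarray, depth_grid: np.ndarray) -> np.ndarray:
    """Boolean raster of a shapely polygon on the pixel-centre grid."""
    minx, miny, maxx, maxy = poly.bounds
    # cheap analytic path for single ellipses would be possible, but the
    # vectorised point-in-polygon below is fast enough at 400x384
    from shapely import contains_xy
    mask = np.zeros(lat_grid.shape, dtype=bool)
    r0 = max(0, int((miny) / config.pixel_spacing_mm) - 1)
    r1 = min(config.n_rows, int(maxy / config.pixel_spacing_mm) + 2)
    c0 = max(0, int(minx / config.pixel_spacing_mm + config.n_cols / 2.0) - 1)
    c1 = min(config.n_cols, int(maxx / config.pixel_spacing_mm + config.n_cols / 2.0) + 2)
    if r0 >= r1 or c0 >= c1:
        return mask
    sub = contains_xy(poly, lat_grid[r0:r1, c0:c1], depth_grid[r0:r1, c0:c1])
    mask[r0:r1, c0:c1] = sub
    return mask


def render_frame(instance: AnatomyInstance,
                 probe_pose: tuple[float, float] = (0.0, 0.0),
                 config: ImagingConfig | None = None,
                 seed: int = 0,
                 frame_index: int = 0,
                 ) -> tuple[BModeFrame, list[GroundTruthRecord]]:
    """Render one transverse B-mode frame plus its ground truth.

    ``probe_pose`` is ``(lateral_mm, cc_mm)`` of the probe centre on the
    skin.  Rendering is deterministic given the instance, pose, config and
    seed.  Raises ``ValueError`` when the pose leaves the skin extent.
    """
    config = config or ImagingConfig()
    probe_lateral, probe_cc = probe_pose
    if abs(probe_lateral) > config.skin_lateral_extent_mm \
            or abs(probe_cc) > config.skin_cc_extent_mm:
        raise ValueError("probe pose outside skin extent")

    rng = np.random.default_rng(seed)
    rows = np.arange(config.n_rows)
    cols = np.arange(config.n_cols)
    depth_grid, lat_grid = np.meshgrid(
        (rows + 0.5) * config.pixel_spacing_mm,
        (cols + 0.5 - config.n_cols / 2.0) * config.pixel_spacing_mm,
        indexing="ij")

    # smooth tissue texture
    texture = gaussian_filter(rng.standard_normal(depth_grid.shape),
                              config.background_texture_sigma_px)
    sd = texture.std()
    if sd > 0:
        texture /= sd
    img = config.background_mean + config.background_texture_amplitude * texture

    shapes = _lumen_shapes(instance, probe_lateral, probe_cc, config)
    records: list[GroundTruthRecord] = []
    for shp in shapes:
        wall_mask = _polygon_mask(shp["outer"], config, lat_grid, depth_grid)
        lumen_mask = _polygon_mask(shp["lumen"], config, lat_grid, depth_grid)
        img[wall_mask] = shp["wall_intensity"]
        img[lumen_mask] = config.lumen_intensity

        if not lumen_mask.any():
            continue  # lumen does not intersect the frame
        minx, miny, maxx, maxy = shp["lumen"].bounds
        r0 = max(0, math.floor(miny / config.pixel_spacing_mm))
        r1 = min(config.n_rows, math.ceil(maxy / config.pixel_spacing_mm))
        c0 = max(0, math.floor(minx / config.pixel_spacing_mm + config.n_cols / 2.0))
        c1 = min(config.n_cols, math.ceil(maxx / config.pixel_spacing_mm + config.n_cols / 2.0))
        centroid = shp["lumen"].centroid
        boundary = np.asarray(shp["lumen"].exterior.coords)
        records.append(GroundTruthRecord(
            frame_index=frame_index, cls=shp["cls"],
            bbox=(r0, c0, r1, c1),
            centroid_mm=(centroid.x, centroid.y),
            boundary_mm=boundary))

    if config.edge_blur_sigma_px > 0:
        img = gaussian_filter(img, config.edge_blur_sigma_px)
    if config.speckle_sigma > 0:
        noise = rng.standard_normal(img.shape)
        if config.speckle_corr_sigma_px > 0:
            noise = gaussian_filter(noise, config.speckle_corr_sigma_px)
            nsd = noise.std()
            if nsd > 0:
                noise /= nsd
        img = img * (1.0 + config.speckle_sigma * noise)

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    frame = BModeFrame(pixels=pixels, pixel_spacing_mm=config.pixel_spacing_mm,
                       probe_lateral_mm=probe_lateral, probe_cc_mm=probe_cc,
                       frame_index=frame_index,
                       frame_rate_hz=config.frame_rate_hz)
    return frame, records


def render_sweep(instance: AnatomyInstance,
                 probe_path: Sequence[tuple[float, float]],
                 config: ImagingConfig | None = None,
                 seed: int = 0,
                 ) -> list[tuple[BModeFrame, list[GroundTruthRecord]]]:
    """Render one frame per probe pose with consecutive frame indices.

    Frame ``i`` uses seed ``seed + i``, so a single-pose sweep is
    bit-identical to :func:`render_frame` with the same seed.
    """
    if len(probe_path) == 0:
        raise ValueError("probe_path must contain at least one pose")
    out = []
    for i, pose in enumerate(probe_path):
        out.append(render_frame(instance, pose, config, seed=seed + i,
                                frame_index=i))
    return out
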