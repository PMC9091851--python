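"""Sector and quadrant geometry on labelled cross-section rasters.

A measurement sector spans the posthatching cortex between two roughly radial
sides and two borders following the inner and outer cortical surfaces.  Each
sector is split into four quadrants (a innermost .. d outermost) by dividing
each radial side into four sections of equal arc length and joining the
corresponding division points with curves that follow the section
circumference.  Class areas are then integrated over raster pixels whose
centres fall inside each quadrant polygon.

Coordinate convention: images are indexed ``raster[row, col]`` with the origin
at the top-left; polygons live in continuous ``(x=col, y=row)`` coordinates
with the centre of pixel ``[r, c]`` at ``(c, r)``.  All reported areas are in
physical units (``pixel_size**2`` per pixel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon

from .core import (
    InvalidInputError,
    LayerThickness,
    QuadrantMeasure,
    SectorProfile,
    QUADRANTS,
    quadrant_porosity,
    relative_layer_thickness,
)

__all__ = [
    "CLASS_BACKGROUND",
    "CLASS_PRIMARY",
    "CLASS_VASCULAR",
    "CLASS_CAVITY",
    "CLASS_REMODELLED",
    "CLASS_OCL",
    "CLASS_EL",
    "CORTEX_CLASSES",
    "LabelImage",
    "SectorSpec",
    "QuadrantGeometry",
    "GeometryError",
    "build_quadrants",
    "measure_quadrant",
    "measure_section",
    "place_sectors_auto",
]

# Tissue class codes of a LabelImage raster.
CLASS_BACKGROUND = 0
CLASS_PRIMARY = 1  # primary (woven/parallel-fibred) bone matrix
CLASS_VASCULAR = 2  # primary vascular spaces, incl. secondarily enlarged canals
CLASS_CAVITY = 3  # medullary cavity
CLASS_REMODELLED = 4  # secondary osteons / CCCB
CLASS_OCL = 5  # outer circumferential layer
CLASS_EL = 6  # endosteal lamellar layer

ALL_CLASSES = (0, 1, 2, 3, 4, 5, 6)
#: Classes that belong to the cortex ring (everything except background/cavity).
CORTEX_CLASSES = (1, 2, 4, 5, 6)
#: Classes excluded from porosity denominators (secondary + lamellar layers).
DEFAULT_EXCLUDED_CLASSES = (CLASS_REMODELLED, CLASS_OCL, CLASS_EL)


class GeometryError(ValueError):
    """Raised for invalid or out-of-bounds measurement geometry."""


@dataclass(frozen=True)
class LabelImage:
    """Class-coded cross-section raster with a physical pixel size."""

    raster: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        r = np.asarray(self.raster)
        if r.ndim != 2:
            raise InvalidInputError("raster must be 2-D")
        if self.pixel_size <= 0:
            raise InvalidInputError("pixel_size must be positive")
        if not np.isin(np.unique(r), ALL_CLASSES).all():
            raise InvalidInputError(f"raster values must be in {ALL_CLASSES}")
        object.__setattr__(self, "raster", r.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape


def _as_polyline(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
        raise InvalidInputError("polyline must be an (n>=2, 2) array of (x, y)")
    return a


def _arc_lengths(poly: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise InvalidInputError("degenerate (zero-length) polyline")
    return s / total


def _point_at(poly: np.ndarray, fracs: np.ndarray) -> np.ndarray:
    """Points at arc-length fractions of a polyline (vectorized interp)."""
    s = _arc_lengths(poly)
    fx = np.interp(fracs, s, poly[:, 0])
    fy = np.interp(fracs, s, poly[:, 1])
    return np.column_stack([fx, fy])


def _sub_polyline(poly: np.ndarray, f0: float, f1: float) -> np.ndarray:
    """Portion of a polyline between arc-length fractions f0 < f1."""
    s = _arc_lengths(poly)
    inner = poly[(s > f0 + 1e-12) & (s < f1 - 1e-12)]
    p0 = _point_at(poly, np.array([f0]))
    p1 = _point_at(poly, np.array([f1]))
    return np.vstack([p0, inner, p1])


@dataclass(frozen=True)
class SectorSpec:
    """Polygonal measurement sector on the posthatching cortex.

    ``inner_boundary`` and ``outer_boundary`` follow the inner and outer
    cortical surfaces, both ordered from the side-1 corner to the side-2
    corner; ``radial_side_1``/``radial_side_2`` run inner -> outer.  The four
    curves must close into a simple polygon (corners coincide within
    ``tol``).  Corner mismatches from flipped input polylines are repaired
    automatically.
    """

    sector_index: int
    inner_boundary: np.ndarray
    outer_boundary: np.ndarray
    radial_side_1: np.ndarray
    radial_side_2: np.ndarray
    tol: float = 1e-6

    def __post_init__(self) -> None:
        inner = _as_polyline(self.inner_boundary)
        outer = _as_polyline(self.outer_boundary)
        s1 = _as_polyline(self.radial_side_1)
        s2 = _as_polyline(self.radial_side_2)
        # Canonical orientation: s1 inner->outer; inner/outer run s1->s2.
        # Try flips to close the four corners.
        best = None
        for fi in (False, True):
            for fo in (False, True):
                for f1 in (False, True):
                    for f2 in (False, True):
                        a = inner[::-1] if fi else inner
                        b = outer[::-1] if fo else outer
                        c = s1[::-1] if f1 else s1
                        d = s2[::-1] if f2 else s2
                        err = (
                            np.linalg.norm(a[0] - c[0])
                            + np.linalg.norm(b[0] - c[-1])
                            + np.linalg.norm(a[-1] - d[0])
                            + np.linalg.norm(b[-1] - d[-1])
                        )
                        if best is None or err < best[0]:
                            best = (err, a, b, c, d)
        err, a, b, c, d = best
        scale = max(1.0, float(np.abs(np.vstack([a, b])).max()))
        if err > 1e-3 * scale:
            raise GeometryError(
                f"sector {self.sector_index}: boundary polylines do not close "
                f"into a quadrilateral patch (corner mismatch {err:.3g})"
            )
        object.__setattr__(self, "inner_boundary", a)
        object.__setattr__(self, "outer_boundary", b)
        object.__setattr__(self, "radial_side_1", c)
        object.__setattr__(self, "radial_side_2", d)
        if not self.polygon().is_valid:
            raise GeometryError(
                f"sector {self.sector_index}: self-intersecting sector polygon"
            )

    def _ring(self, n_samples: int = 129) -> np.ndarray:
        s = np.linspace(0.0, 1.0, n_samples)
        inner = _point_at(self.inner_boundary, s)
        outer = _point_at(self.outer_boundary, s)
        return np.vstack(
            [
                inner,
                self.radial_side_2,
                outer[::-1],
                self.radial_side_1[::-1],
            ]
        )

    def polygon(self) -> Polygon:
        """Closed sector polygon (inner, side 2, reversed outer, reversed side 1)."""
        return Polygon(self._ring()).buffer(0)


@dataclass(frozen=True)
class QuadrantGeometry:
    """One radial quadrant of a sector as a simple polygon."""

    sector_index: int
    quadrant_index: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.quadrant_index not in QUADRANTS:
            raise InvalidInputError(f"quadrant_index must be in {QUADRANTS}")

    @property
    def area(self) -> float:
        return self.polygon.area


def _separator(
    sector: SectorSpec, t: float, s_grid: np.ndarray
) -> np.ndarray:
    """Circumference-following separator curve at radial fraction ``t``.

    Blends the arc-length-parameterized inner and outer boundaries at fraction
    ``t`` and warps the blend linearly so its endpoints coincide with the
    points at arc fraction ``t`` of the two radial sides.  At t=0 and t=1 the
    curve reduces exactly to the inner/outer boundary.
    """
    inner = _point_at(sector.inner_boundary, s_grid)
    outer = _point_at(sector.outer_boundary, s_grid)
    blend = (1.0 - t) * inner + t * outer
    p1 = _point_at(sector.radial_side_1, np.array([t]))[0]
    p2 = _point_at(sector.radial_side_2, np.array([t]))[0]
    s = s_grid[:, None]
    return blend + (1.0 - s) * (p1 - blend[0]) + s * (p2 - blend[-1])


def build_quadrants(
    sector: SectorSpec, n_boundary_samples: int = 129, straight_separators: bool = False
) -> list[QuadrantGeometry]:
    """Split a sector into four radial quadrants of equal radial-side arc length.

    Each radial side is divided at arc-length fractions 1/4, 1/2, 3/4 and the
    corresponding division points are joined by circumference-following
    blended curves (``straight_separators=True`` joins them with chords
    instead).  Quadrants are returned ordered a (adjacent to the inner
    boundary) to d (adjacent to the outer boundary).
    """
    s_grid = np.linspace(0.0, 1.0, n_boundary_samples)
    fractions = [0.0, 0.25, 0.5, 0.75, 1.0]
    if straight_separators:
        seps = []
        for t in fractions:
            p1 = _point_at(sector.radial_side_1, np.array([t]))[0]
            p2 = _point_at(sector.radial_side_2, np.array([t]))[0]
            seps.append(np.vstack([p1, p2]))
    else:
        seps = [_separator(sector, t, s_grid) for t in fractions]

    quads: list[QuadrantGeometry] = []
    for i, q in enumerate(QUADRANTS):
        lo, hi = fractions[i], fractions[i + 1]
        side1 = _sub_polyline(sector.radial_side_1, lo, hi)
        side2 = _sub_polyline(sector.radial_side_2, lo, hi)
        ring = np.vstack([seps[i], side2, seps[i + 1][::-1], side1[::-1]])
        poly = Polygon(ring).buffer(0)
        if poly.is_empty or not poly.is_valid:
            raise GeometryError(
                f"sector {sector.sector_index}: degenerate quadrant {q!r}"
            )
        quads.append(
            QuadrantGeometry(
                sector_index=sector.sector_index, quadrant_index=q, polygon=poly
            )
        )
    return quads


def _pixel_mask(image: LabelImage, polygon: Polygon) -> tuple[np.ndarray, slice, slice]:
    """Boolean mask of pixels whose centres fall inside the polygon.

    Returns the mask restricted to the polygon's bounding box plus the row and
    column slices locating it in the full raster.
    """
    minx, miny, maxx, maxy = polygon.bounds
    h, w = image.shape
    c0 = max(int(np.floor(minx)), 0)
    c1 = min(int(np.ceil(maxx)) + 1, w)
    r0 = max(int(np.floor(miny)), 0)
    r1 = min(int(np.ceil(maxy)) + 1, h)
    if minx < -0.5 or miny < -0.5 or maxx > w - 0.5 or maxy > h - 0.5:
        raise GeometryError("polygon extends outside the raster")
    if c1 <= c0 or r1 <= r0:
        return np.zeros((0, 0), dtype=bool), slice(r0, r0), slice(c0, c0)
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    if polygon.geom_type == "MultiPolygon":
        inside = np.zeros(len(pts), dtype=bool)
        for part in polygon.geoms:
            path = MplPath(np.asarray(part.exterior.coords))
            inside |= path.contains_points(pts)
    else:
        path = MplPath(np.asarray(polygon.exterior.coords))
        inside = path.contains_points(pts)
    return inside.reshape(rows.shape), slice(r0, r1), slice(c0, c1)


def _class_areas(image: LabelImage, polygon: Polygon) -> dict[int, float]:
    mask, rs, cs = _pixel_mask(image, polygon)
    sub = image.raster[rs, cs]
    px2 = image.pixel_size**2
    counts = np.bincount(sub[mask].ravel(), minlength=7)
    return {k: counts[k] * px2 for k in ALL_CLASSES}


def measure_quadrant(
    image: LabelImage,
    quadrant: QuadrantGeometry,
    missing_threshold: float = 0.5,
    excluded_classes: Sequence[int] = DEFAULT_EXCLUDED_CLASSES,
) -> QuadrantMeasure:
    """Integrate class areas over a quadrant and derive its porosity.

    The quadrant area is the pixel-counted polygon area; the porosity
    denominator removes excluded classes (remodelled bone and, by default,
    OCL and EL) and any non-cortex pixels.  The porosity is reported missing
    when the excluded fraction exceeds ``missing_threshold`` — the quadrant's
    primary record is mostly or wholly obliterated — or when no usable
    primary area remains.
    """
    areas = _class_areas(image, quadrant.polygon)
    quadrant_area = sum(areas.values())
    vascular = areas[CLASS_VASCULAR]
    excluded = sum(areas[k] for k in excluded_classes)
    non_cortex = areas[CLASS_BACKGROUND] + areas[CLASS_CAVITY]
    present = tuple(
        name
        for k, name in ((CLASS_REMODELLED, "remodelled"), (CLASS_OCL, "OCL"), (CLASS_EL, "EL"))
        if k in excluded_classes and areas[k] > 0
    )
    if quadrant_area <= 0:
        return QuadrantMeasure(
            quadrant_index=quadrant.quadrant_index,
            quadrant_area=0.0,
            vascular_area=0.0,
            excluded_area=0.0,
            porosity=None,
            exclusion_classes=present,
        )
    porosity = None
    if excluded / quadrant_area <= missing_threshold:
        porosity = quadrant_porosity(vascular, quadrant_area, excluded + non_cortex)
    return QuadrantMeasure(
        quadrant_index=quadrant.quadrant_index,
        quadrant_area=quadrant_area,
        vascular_area=vascular,
        excluded_area=excluded,
        porosity=porosity,
        exclusion_classes=present,
    )


def measure_section(
    image: LabelImage,
    sectors: Sequence[SectorSpec],
    missing_threshold: float = 0.5,
    excluded_classes: Sequence[int] = DEFAULT_EXCLUDED_CLASSES,
) -> tuple[list[SectorProfile], list[LayerThickness]]:
    """Measure all sectors of a section.

    Returns one four-point porosity profile per sector plus the OCL and EL
    relative areal thicknesses pooled over all sector polygons (layer area as
    a percentage of the total cortex area sampled by the sectors).
    """
    if not sectors:
        raise InvalidInputError("measure_section needs at least one sector")
    profiles: list[SectorProfile] = []
    pooled = {k: 0.0 for k in ALL_CLASSES}
    for sector in sectors:
        quads = build_quadrants(sector)
        values = []
        for quad in quads:
            m = measure_quadrant(image, quad, missing_threshold, excluded_classes)
            values.append(np.nan if m.porosity is None else m.porosity)
        profiles.append(
            SectorProfile(sector_index=sector.sector_index, values=tuple(values))
        )
        for k, v in _class_areas(image, sector.polygon()).items():
            pooled[k] += v
    cortex_area = sum(pooled[k] for k in CORTEX_CLASSES)
    if cortex_area > 0:
        ocl = relative_layer_thickness(pooled[CLASS_OCL], cortex_area)
        el = relative_layer_thickness(pooled[CLASS_EL], cortex_area)
    else:
        ocl = el = 0.0
    layers = [
        LayerThickness(layer="OCL", relative_area_percent=ocl),
        LayerThickness(layer="EL", relative_area_percent=el),
    ]
    return profiles, layers


def _ray_cortex_span(
    image: LabelImage, center: np.ndarray, angle_rad: float
) -> tuple[float, float]:
    """Innermost and outermost cortex radius along a ray from the centre."""
    h, w = image.shape
    rmax = float(np.hypot(h, w))
    radii = np.arange(1.0, rmax, 0.5)
    xs = center[0] + radii * np.cos(angle_rad)
    ys = center[1] + radii * np.sin(angle_rad)
    ok = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    radii, xs, ys = radii[ok], xs[ok], ys[ok]
    vals = image.raster[np.round(ys).astype(int), np.round(xs).astype(int)]
    cortex = np.isin(vals, CORTEX_CLASSES)
    if not cortex.any():
        raise GeometryError(
            f"no cortex found along ray at {np.degrees(angle_rad):.1f} deg; "
            "cortex ring not closed around the requested centre"
        )
    idx = np.flatnonzero(cortex)
    return float(radii[idx[0]]), float(radii[idx[-1]])


def place_sectors_auto(
    image: LabelImage,
    n_sectors: int = 3,
    angular_positions: Sequence[float] | None = None,
    angular_width_deg: float = 60.0,
    n_arc_samples: int = 33,
) -> list[SectorSpec]:
    """Place measurement sectors automatically around the cortex ring.

    Sectors are centred at the requested angles (degrees, measured from the
    +x axis around the medullary-cavity centroid); radial sides follow rays
    from the centroid and the inner/outer borders trace the cortex-class
    boundary sampled along ``n_arc_samples`` intermediate rays.
    """
    if angular_positions is None:
        angular_positions = [360.0 * i / n_sectors for i in range(n_sectors)]
    if len(angular_positions) != n_sectors:
        raise InvalidInputError("need one angular position per sector")
    cavity = np.argwhere(image.raster == CLASS_CAVITY)
    if len(cavity) == 0:
        cavity = np.argwhere(np.isin(image.raster, CORTEX_CLASSES))
    if len(cavity) == 0:
        raise GeometryError("image contains no cortex")
    center = np.array([cavity[:, 1].mean(), cavity[:, 0].mean()])  # (x, y)

    sectors: list[SectorSpec] = []
    half = np.radians(angular_width_deg) / 2.0
    for i, theta_deg in enumerate(angular_positions):
        theta = np.radians(theta_deg)
        angles = np.linspace(theta - half, theta + half, n_arc_samples)
        inner_pts, outer_pts = [], []
        for phi in angles:
            r_in, r_out = _ray_cortex_span(image, center, phi)
            d = np.array([np.cos(phi), np.sin(phi)])
            inner_pts.append(center + r_in * d)
            outer_pts.append(center + r_out * d)
        inner = np.asarray(inner_pts)
        outer = np.asarray(outer_pts)
        side1 = np.vstack([inner[0], outer[0]])
        side2 = np.vstack([inner[-1], outer[-1]])
        sectors.append(
            SectorSpec(
                sector_index=i + 1,
                inner_boundary=inner,
                outer_boundary=outer,
                radial_side_1=side1,
                radial_side_2=side2,
            )
        )
    return sectors
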