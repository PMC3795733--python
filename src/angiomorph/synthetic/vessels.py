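"""Continuum vessel archetypes and their exact geometry.

Each synthetic microvessel profile is defined as a continuum shape
(a shapely polygon, built from densely sampled generating curves):

* ``annulus`` -- a circular profile; with a lumen it is a ring, without it
  a solid disc.
* ``elliptical_ring`` -- an elongated profile of uniform wall thickness.
* ``ribbon`` -- a buffered wavy centre line (a sectioned vessel running in
  the cut plane); with a lumen it becomes a closed elongated tube.
* ``branched`` -- a buffered union of strokes radiating from the centre,
  emulating branching/sprouting profiles (always concave, low solidity).

Ground-truth areas, perimeters, solidity, centroid and largest-inscribed-
circle width come straight from the continuum geometry, so rasterized
measurements can be validated against analytic truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import LineString, Point, Polygon

__all__ = ["VesselSpec", "build_geometry", "vessel_truth", "rasterize_vessel"]

#: arc resolution of buffered curves: 64 segments per quarter circle keeps
#: the polygonal approximation error of a 40 px radius below 0.01 px
_QUAD_SEGS = 64

_FAMILIES = ("annulus", "elliptical_ring", "ribbon", "branched")


@dataclass
class VesselSpec:
    """Construction parameters of one synthetic vessel profile.

    ``centre_px`` is (col, row) == (x, y) in pixel units.  Depending on the
    family, size is carried by ``outer_radius_px`` (annulus: outer radius;
    branched: arm length) or ``axis_lengths_px`` (elliptical_ring: semi-axes;
    ribbon: (half_length, half_width)).  ``wall_thickness_px`` is the stain
    band width (for branched vessels, the stroke width).
    """

    shape_family: str
    centre_px: tuple[float, float]
    outer_radius_px: float | None = None
    axis_lengths_px: tuple[float, float] | None = None
    wall_thickness_px: float = 3.0
    has_lumen: bool = False
    orientation_deg: float = 0.0
    waviness_amplitude_px: float = 0.0
    n_branches: int = 0
    intended_vessel: bool = True

    def __post_init__(self) -> None:
        if self.shape_family not in _FAMILIES:
            raise ValueError(f"unknown shape family {self.shape_family!r}")
        if self.wall_thickness_px < 1:
            raise ValueError("wall thickness must be at least 1 px")


def _ribbon_centreline(spec: VesselSpec) -> LineString:
    half_len, _ = spec.axis_lengths_px
    t = np.linspace(-half_len, half_len, 200)
    y = spec.waviness_amplitude_px * np.sin(1.5 * math.pi * t / half_len)
    line = LineString(np.column_stack([t, y]))
    line = affinity.rotate(line, spec.orientation_deg, origin=(0, 0))
    return affinity.translate(line, xoff=spec.centre_px[0], yoff=spec.centre_px[1])


def build_geometry(spec: VesselSpec) -> tuple[Polygon, list[Polygon]]:
    """Continuum (outer polygon, lumen polygons) of a vessel spec."""
    cx, cy = spec.centre_px
    lumens: list[Polygon] = []
    if spec.shape_family == "annulus":
        r = float(spec.outer_radius_px)
        outer = Point(cx, cy).buffer(r, quad_segs=_QUAD_SEGS)
        if spec.has_lumen:
            r_in = r - spec.wall_thickness_px
            if r_in > 0.5:
                lumens = [Point(cx, cy).buffer(r_in, quad_segs=_QUAD_SEGS)]
    elif spec.shape_family == "elliptical_ring":
        a, b = spec.axis_lengths_px
        outer = affinity.scale(Point(0, 0).buffer(1.0, quad_segs=_QUAD_SEGS), a, b)
        outer = affinity.rotate(outer, spec.orientation_deg, origin=(0, 0))
        outer = affinity.translate(outer, xoff=cx, yoff=cy)
        if spec.has_lumen:
            inner = outer.buffer(-spec.wall_thickness_px, quad_segs=_QUAD_SEGS)
            if not inner.is_empty and inner.geom_type == "Polygon" and inner.area > 1.0:
                lumens = [inner]
    elif spec.shape_family == "ribbon":
        _, half_width = spec.axis_lengths_px
        line = _ribbon_centreline(spec)
        outer = line.buffer(half_width, quad_segs=_QUAD_SEGS)
        if spec.has_lumen:
            inner_r = half_width - spec.wall_thickness_px
            if inner_r > 0.5:
                lumens = [line.buffer(inner_r, quad_segs=_QUAD_SEGS)]
    else:  # branched
        n = max(int(spec.n_branches), 3)
        length = float(spec.outer_radius_px)
        arms = []
        for k in range(n):
            ang = math.radians(spec.orientation_deg + 360.0 * k / n)
            arms.append(
                LineString(
                    [(cx, cy), (cx + length * math.cos(ang), cy + length * math.sin(ang))]
                )
            )
        outer = shapely.union_all(arms).buffer(
            spec.wall_thickness_px / 2.0, quad_segs=_QUAD_SEGS
        )
    return outer, lumens


def vessel_truth(spec: VesselSpec, pitch: float) -> dict:
    """Continuum ground-truth descriptors of one vessel, in physical units."""
    outer, lumens = build_geometry(spec)
    lum_area = sum(l.area for l in lumens)
    circ = shapely.maximum_inscribed_circle(outer, tolerance=0.02)
    c = outer.centroid
    return {
        "shape_family": spec.shape_family,
        "centre_col_px": c.x,
        "centre_row_px": c.y,
        "has_lumen": len(lumens) > 0,
        "vascular_area_um2": outer.area * pitch**2,
        "endothelial_area_um2": (outer.area - lum_area) * pitch**2,
        "luminal_area_um2": lum_area * pitch**2,
        "perimeter_um": outer.exterior.length * pitch,
        "solidity": outer.area / outer.convex_hull.area,
        "width_um": 2.0 * circ.length * pitch,
    }


def bounding_radius(spec: VesselSpec) -> float:
    """Radius of a disc around the centre guaranteed to contain the vessel."""
    outer, _ = build_geometry(spec)
    minx, miny, maxx, maxy = outer.bounds
    cx, cy = spec.centre_px
    return max(
        math.hypot(x - cx, y - cy)
        for x in (minx, maxx)
        for y in (miny, maxy)
    )


def rasterize_vessel(
    spec: VesselSpec, image_shape: tuple[int, int]
) -> tuple[tuple[int, int], np.ndarray, np.ndarray]:
    """Pixel masks of one vessel on the field grid.

    Returns ``(offset, wall_mask, lumen_mask)`` where the boolean crops share
    one bounding box with top-left corner ``offset`` (row, col).  A pixel
    belongs to a mask iff its centre lies inside the continuum polygon.
    """
    h, w = image_shape
    outer, lumens = build_geometry(spec)
    minx, miny, maxx, maxy = outer.bounds
    c0 = max(0, int(math.floor(minx)) - 1)
    r0 = max(0, int(math.floor(miny)) - 1)
    c1 = min(w, int(math.ceil(maxx)) + 2)
    r1 = min(h, int(math.ceil(maxy)) + 2)
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    xx, yy = np.meshgrid(cols.astype(float), rows.astype(float))
    filled = shapely.contains_xy(outer, xx.ravel(), yy.ravel()).reshape(xx.shape)
    lumen_mask = np.zeros_like(filled)
    for lum in lumens:
        lumen_mask |= shapely.contains_xy(lum, xx.ravel(), yy.ravel()).reshape(xx.shape)
    wall = filled & ~lumen_mask
    return (r0, c0), wall, lumen_mask
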