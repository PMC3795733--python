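"""Field-level angiogenesis markers aggregated from vessel profiles.

The marker vector of one hot-spot field covers:

* the density/size family -- MVD (vessels per mm^2), total and mean
  vascular area (MVA_sum, MVA_mean), the coefficient of variation of the
  vessel areas (MVA_cv), mean and total outer perimeter (MVP_mean,
  MVP_sum), mean endothelial area (MVE_mean) and mean skeleton length
  (MVL_mean);
* shape -- mean solidity (MVS_mean) and the fraction of profiles with at
  least one lumen (MV_luminal);
* context -- MVA_rx4, the ratio of the field's total vascular area to that
  of the highest-scoring subfield at four times higher magnification
  (1 = concentrated, 16 = uniform); MV_scale, the slope of mean skeleton
  content versus window size in a double-logarithmic plot over randomly
  placed square subfields (a mass-scaling descriptor); and ICD, the mean
  intercapillary centre-to-centre distance between Gabriel-graph
  neighbours.

Markers that are undefined for the number of vessels present (e.g. MVA_cv
and ICD need at least two) are reported as missing (NaN), never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .morphometry import VesselProfile

__all__ = [
    "FieldMarkers",
    "ScaleConfig",
    "size_summary",
    "shape_summary",
    "mva_rx4",
    "mv_scale",
    "gabriel_edges",
    "icd_mean",
    "compute_field_markers",
    "profiles_to_masks",
]


@dataclass
class ScaleConfig:
    """Sampling scheme of the mass-scaling (MV_scale) estimate.

    Fifty window sizes are geometrically spaced from 3 px to the image
    height; at each size, windows are placed uniformly at random fully
    inside the field and the skeleton content is averaged over the
    non-empty windows.
    """

    n_sizes: int = 50
    min_size_px: int = 3
    max_size_px: int | None = None  # None -> image height
    placements_per_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sizes < 2:
            raise ValueError("need at least two window sizes")
        if self.max_size_px is not None and self.max_size_px <= self.min_size_px:
            raise ValueError("max_size_px must exceed min_size_px")


@dataclass
class FieldMarkers:
    """The per-field marker vector; missing markers are NaN."""

    n_vessels: int = 0
    mvd: float = math.nan  # vessels / mm^2
    mva_sum_um2: float = math.nan
    mva_field_fraction: float = math.nan
    mva_mean_um2: float = math.nan
    mva_cv: float = math.nan
    mvp_mean_um: float = math.nan
    mvp_sum_um: float = math.nan
    mve_mean_um2: float = math.nan
    mvl_mean_um: float = math.nan
    mvs_mean: float = math.nan
    mv_luminal: float = math.nan
    mva_rx4: float = math.nan
    mv_scale: float = math.nan
    icd_um: float = math.nan

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @staticmethod
    def columns() -> list[str]:
        return [f.name for f in dc_fields(FieldMarkers)]


def size_summary(profiles: list[VesselProfile], field_area_mm2: float) -> dict:
    """Density and size markers of the vessel population."""
    n = len(profiles)
    out = {
        "n_vessels": n,
        "mvd": n / field_area_mm2,
        "mva_sum_um2": math.nan,
        "mva_mean_um2": math.nan,
        "mva_cv": math.nan,
        "mvp_mean_um": math.nan,
        "mvp_sum_um": math.nan,
        "mve_mean_um2": math.nan,
        "mvl_mean_um": math.nan,
        "mva_field_fraction": math.nan,
    }
    if n == 0:
        out["mvd"] = 0.0
        return out
    areas = np.array([p.vascular_area_um2 for p in profiles])
    perims = np.array([p.perimeter_um for p in profiles])
    out["mva_sum_um2"] = float(areas.sum())
    out["mva_mean_um2"] = float(areas.mean())
    out["mvp_sum_um"] = float(perims.sum())
    out["mvp_mean_um"] = float(perims.mean())
    out["mve_mean_um2"] = float(np.mean([p.endothelial_area_um2 for p in profiles]))
    out["mvl_mean_um"] = float(np.mean([p.skeleton_length_um for p in profiles]))
    out["mva_field_fraction"] = float(areas.sum()) / (field_area_mm2 * 1e6)
    if n >= 2:
        out["mva_cv"] = float(areas.std(ddof=1) / areas.mean())
    return out


def shape_summary(profiles: list[VesselProfile]) -> dict:
    """Mean solidity and luminal fraction; missing on an empty field."""
    if not profiles:
        return {"mvs_mean": math.nan, "mv_luminal": math.nan}
    return {
        "mvs_mean": float(np.mean([p.solidity for p in profiles])),
        "mv_luminal": float(np.mean([p.has_lumen for p in profiles])),
    }


def _integral_image(mask: np.ndarray) -> np.ndarray:
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=ii[1:, 1:])
    return ii


def _window_sums(ii: np.ndarray, r: np.ndarray, c: np.ndarray, hr: int, wc: int) -> np.ndarray:
    return ii[r + hr, c + wc] - ii[r, c + wc] - ii[r + hr, c] + ii[r, c]


def mva_rx4(vascular_mask: np.ndarray, stride_divisor: int = 8) -> float:
    """Ratio of total vascular area to the best subfield at 4x magnification.

    The subfield is an axis-aligned window with linear dimensions one
    quarter of the field's, slid across the field with stride window/8.
    """
    mask = np.asarray(vascular_mask, dtype=bool)
    total = int(mask.sum())
    if total == 0:
        return math.nan
    h, w = mask.shape
    win_h = max(1, h // 4)
    win_w = max(1, w // 4)
    ii = _integral_image(mask)
    stride_r = max(1, win_h // stride_divisor)
    stride_c = max(1, win_w // stride_divisor)
    rows = np.unique(np.append(np.arange(0, h - win_h + 1, stride_r), h - win_h))
    cols = np.unique(np.append(np.arange(0, w - win_w + 1, stride_c), w - win_w))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    best = int(_window_sums(ii, rr, cc, win_h, win_w).max())
    return total / best


def mv_scale(skeleton_mask: np.ndarray, cfg: ScaleConfig | None = None) -> float:
    """Mass-scaling slope of mean skeleton content vs. window size (log-log).

    At each of the geometrically spaced sizes, square windows are dropped
    uniformly at random fully inside the image; the skeleton pixel content
    is averaged over non-empty windows only (unconditional averaging would
    make every pattern scale with exponent two).  The slope is the ordinary
    least-squares fit of log mean content against log size.  Low values
    accompany uniform distributions of small, simple vessels; high values,
    concentrated or space-filling patterns.
    """
    cfg = cfg or ScaleConfig()
    mask = np.asarray(skeleton_mask, dtype=bool)
    if not np.any(mask):
        return math.nan
    h, w = mask.shape
    max_size = cfg.max_size_px if cfg.max_size_px is not None else h
    max_size = min(max_size, h, w)
    sizes = np.unique(
        np.round(np.geomspace(cfg.min_size_px, max_size, cfg.n_sizes)).astype(int)
    )
    sizes = sizes[(sizes >= 1) & (sizes <= min(h, w))]
    rng = np.random.default_rng(cfg.seed)
    ii = _integral_image(mask)
    log_s, log_m = [], []
    for s in sizes:
        r = rng.integers(0, h - s + 1, size=cfg.placements_per_size)
        c = rng.integers(0, w - s + 1, size=cfg.placements_per_size)
        sums = _window_sums(ii, r, c, int(s), int(s))
        hit = sums > 0
        if not np.any(hit):
            continue  # all windows empty at this size: size dropped
        log_s.append(math.log(s))
        log_m.append(math.log(sums[hit].mean()))
    if len(log_s) < 2:
        return math.nan
    slope = np.polyfit(log_s, log_m, 1)[0]
    return float(slope)


def gabriel_edges(points: np.ndarray, jitter_seed: int = 0) -> list[tuple[int, int]]:
    """Gabriel-graph edges of a 2-D point set.

    Two points are neighbours iff no third point lies inside or on the
    circle whose diameter is their connecting segment (closed-disc rule, so
    a point exactly on the circle blocks the edge).  Exact coordinate
    duplicates are jittered by 1e-6 px with a seeded RNG.  Candidate edges
    come from the Delaunay triangulation (the Gabriel graph is one of its
    subgraphs); degenerate inputs fall back to checking all pairs.
    """
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    if n < 2:
        return []
    # jitter exact duplicates for a well-defined graph
    _, first_idx = np.unique(pts, axis=0, return_index=True)
    if len(first_idx) < n:
        rng = np.random.default_rng(jitter_seed)
        dup = np.setdiff1d(np.arange(n), first_idx)
        pts = pts.copy()
        pts[dup] += rng.uniform(-1e-6, 1e-6, size=(len(dup), 2))

    if n <= 4:
        candidates = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        try:
            tri = Delaunay(pts)
            edge_set = set()
            for simplex in tri.simplices:
                for a in range(3):
                    i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
                    edge_set.add((int(i), int(j)))
            candidates = sorted(edge_set)
        except QhullError:  # collinear or otherwise degenerate point sets
            candidates = [(i, j) for i in range(n) for j in range(i + 1, n)]

    edges = []
    for i, j in candidates:
        mid = (pts[i] + pts[j]) / 2.0
        r2 = np.sum((pts[i] - pts[j]) ** 2) / 4.0
        d2 = np.sum((pts - mid) ** 2, axis=1)
        d2[[i, j]] = np.inf
        if d2.min() > r2 + 1e-12 * max(r2, 1.0):
            edges.append((i, j))
    return edges


def icd_mean(profiles_or_points, pitch: float) -> float:
    """Mean Gabriel-edge length between vessel centre points, in um.

    Accepts vessel profiles (their centroids are used -- centre points, not
    boundary-to-boundary distances) or an (n, 2) coordinate array.
    Undefined (NaN) for fewer than two vessels.
    """
    if len(profiles_or_points) < 2:
        return math.nan
    if isinstance(profiles_or_points[0], VesselProfile):
        pts = np.array([p.centroid_px for p in profiles_or_points], dtype=float)
    else:
        pts = np.asarray(profiles_or_points, dtype=float)
    edges = gabriel_edges(pts)
    if not edges:
        return math.nan
    lengths = [math.dist(pts[i], pts[j]) for i, j in edges]
    return float(np.mean(lengths)) * pitch


def profiles_to_masks(
    profiles: list[VesselProfile], image_dims: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Union vascular (filled) mask and union skeleton mask on the field grid."""
    vascular = np.zeros(image_dims, dtype=bool)
    skeleton = np.zeros(image_dims, dtype=bool)
    for p in profiles:
        r0, c0 = p.offset
        h, w = p.filled.shape
        vascular[r0 : r0 + h, c0 : c0 + w] |= p.filled
        if p.skeleton is not None:
            skeleton[r0 : r0 + h, c0 : c0 + w] |= p.skeleton
    return vascular, skeleton


def compute_field_markers(
    profiles: list[VesselProfile],
    image_dims: tuple[int, int],
    pitch: float,
    scale_cfg: ScaleConfig | None = None,
) -> FieldMarkers:
    """The full marker vector of one field; deterministic given the seed."""
    h, w = image_dims
    field_area_mm2 = h * w * pitch**2 / 1e6
    markers = FieldMarkers()
    for key, val in size_summary(profiles, field_area_mm2).items():
        setattr(markers, key, val)
    for key, val in shape_summary(profiles).items():
        setattr(markers, key, val)
    if profiles:
        vascular, skeleton = profiles_to_masks(profiles, image_dims)
        markers.mva_rx4 = mva_rx4(vascular)
        markers.mv_scale = mv_scale(skeleton, scale_cfg)
        markers.icd_um = icd_mean(profiles, pitch)
    return markers
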