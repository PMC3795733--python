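"""Synthetic hot-spot field rendering with exact continuum ground truth.

The generator emulates a photographed CD34-immunostained hot-spot field:
DAB-brown vessel walls on a near-white background with haematoxylin-blue
nuclei and sub-threshold DAB specks (dust/noise that segmentation must
discard).  Defaults reproduce the acquisition conditions of the measurement
protocol: 1813 x 1813 px at 0.34 um/px (a 0.38 mm^2 field).

Every rendered field carries a :class:`GroundTruth` with per-vessel pixel
masks and continuum (analytic) descriptors, so the segmentation and
morphometry stages can be validated without any external data.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from skimage.color import hsv2rgb

from ..markers import (
    FieldMarkers,
    ScaleConfig,
    icd_mean,
    mv_scale,
    mva_rx4,
)
from ..segmentation import ImageField
from .vessels import VesselSpec, bounding_radius, rasterize_vessel, vessel_truth

__all__ = [
    "StainColourModel",
    "FieldSpec",
    "GroundTruth",
    "GeneratorParams",
    "PlacementError",
    "render_field",
    "sample_field_spec",
    "true_markers",
]


class PlacementError(RuntimeError):
    """Raised when vessels or specks cannot be placed within bounded retries."""


@dataclass
class StainColourModel:
    """HSV stain colours (hue in degrees) and background/noise model.

    DAB chromogen renders brown (hue ~27 deg, mid saturation, low-mid
    value); haematoxylin renders blue (hue ~230 deg); the background is
    near-white.  The choice exercises both the darkness and the hue test of
    stain detection.  Stain intensity is uniform within a vessel (real DAB
    is heterogeneous; see the methods note), with small additive Gaussian
    pixel noise on the whole image.
    """

    dab_hsv: tuple[float, float, float] = (27.0, 0.70, 0.42)
    haematoxylin_hsv: tuple[float, float, float] = (230.0, 0.55, 0.45)
    background_rgb: tuple[float, float, float] = (0.96, 0.95, 0.97)
    value_noise_sd: float = 0.008


@dataclass
class FieldSpec:
    """Deterministic construction recipe of one synthetic field."""

    height_px: int = 1813
    width_px: int = 1813
    pixel_pitch_um: float = 0.34
    vessels: list[VesselSpec] = field(default_factory=list)
    colours: StainColourModel = field(default_factory=StainColourModel)
    n_specks: int = 40
    speck_radius_px: tuple[float, float] = (0.8, 2.2)
    n_nuclei: int = 250
    nucleus_radius_px: tuple[float, float] = (4.0, 9.0)
    seed: int = 0
    field_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FieldSpec":
        raw = yaml.safe_load(text)
        vessels = [VesselSpec(**{**v, "centre_px": tuple(v["centre_px"]),
                                  "axis_lengths_px": tuple(v["axis_lengths_px"])
                                  if v.get("axis_lengths_px") else None})
                   for v in raw.pop("vessels", [])]
        colours = StainColourModel(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("colours", {}).items()
        })
        for key in ("speck_radius_px", "nucleus_radius_px"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(vessels=vessels, colours=colours, **raw)


@dataclass
class GroundTruth:
    """Pixel-level and continuum truth of one rendered field.

    ``vessels`` holds one row per vessel with continuum areas/perimeter/
    solidity/width; ``label_map`` marks each vessel's filled pixels with its
    1-based id; ``stain_mask`` marks every DAB-coloured pixel (walls and
    noise specks).
    """

    vessels: pd.DataFrame
    label_map: np.ndarray
    stain_mask: np.ndarray
    lumen_mask: np.ndarray
    pixel_pitch_um: float

    @property
    def n_vessels(self) -> int:
        return len(self.vessels)

    @property
    def vascular_mask(self) -> np.ndarray:
        return self.label_map > 0


def _paint_disc(canvas: np.ndarray, centre: tuple[float, float], radius: float,
                colour: np.ndarray) -> np.ndarray | None:
    h, w = canvas.shape[:2]
    r0 = max(0, int(centre[0] - radius) - 1)
    r1 = min(h, int(centre[0] + radius) + 2)
    c0 = max(0, int(centre[1] - radius) - 1)
    c1 = min(w, int(centre[1] + radius) + 2)
    if r0 >= r1 or c0 >= c1:
        return None
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask = (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2
    canvas[r0:r1, c0:c1][mask] = colour
    full = np.zeros((h, w), dtype=bool)
    full[r0:r1, c0:c1] = mask
    return full


def _hsv_colour(hsv: tuple[float, float, float]) -> np.ndarray:
    h, s, v = hsv
    return hsv2rgb(np.array([[[h / 360.0, s, v]]]))[0, 0]


def render_field(spec: FieldSpec) -> tuple[ImageField, GroundTruth]:
    """Render a field spec to an 8-bit RGB image plus aligned ground truth.

    The same spec (same seed) renders bit-identically.  Vessel walls carry
    DAB colours; lumens and background carry background colour; nuclei carry
    haematoxylin colour and never overwrite vessels.
    """
    h, w = spec.height_px, spec.width_px
    rng = np.random.default_rng(spec.seed)
    colours = spec.colours
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = colours.background_rgb

    # haematoxylin nuclei (blue blobs): painted first so vessels overwrite
    nuc_colour = _hsv_colour(colours.haematoxylin_hsv)
    for _ in range(spec.n_nuclei):
        centre = rng.uniform([0, 0], [h, w])
        radius = rng.uniform(*spec.nucleus_radius_px)
        _paint_disc(canvas, tuple(centre), radius, nuc_colour)

    dab_colour = _hsv_colour(colours.dab_hsv)
    bg_colour = np.asarray(colours.background_rgb)
    label_map = np.zeros((h, w), dtype=np.int32)
    stain_mask = np.zeros((h, w), dtype=bool)
    lumen_mask_field = np.zeros((h, w), dtype=bool)
    records = []
    for vid, vspec in enumerate(spec.vessels, start=1):
        (r0, c0), wall, lum = rasterize_vessel(vspec, (h, w))
        hh, ww = wall.shape
        view = canvas[r0 : r0 + hh, c0 : c0 + ww]
        view[wall] = dab_colour
        view[lum] = bg_colour
        label_map[r0 : r0 + hh, c0 : c0 + ww][wall | lum] = vid
        stain_mask[r0 : r0 + hh, c0 : c0 + ww][wall] = True
        lumen_mask_field[r0 : r0 + hh, c0 : c0 + ww][lum] = True
        rec = vessel_truth(vspec, spec.pixel_pitch_um)
        rec["vessel_id"] = vid
        rec["intended_vessel"] = vspec.intended_vessel
        records.append(rec)

    # sub-threshold DAB specks: noise the segmentation must remove
    vessel_centres = np.array(
        [v.centre_px[::-1] for v in spec.vessels], dtype=float
    ).reshape(-1, 2)  # (row, col)
    vessel_brad = np.array([bounding_radius(v) for v in spec.vessels])
    speck_centres: list[np.ndarray] = []
    placed = 0
    tries = 0
    max_tries = 200 * max(spec.n_specks, 1)
    while placed < spec.n_specks and tries < max_tries:
        tries += 1
        centre = rng.uniform([2, 2], [h - 2, w - 2])
        radius = rng.uniform(*spec.speck_radius_px)
        if len(vessel_centres):
            if np.min(
                np.hypot(*(vessel_centres - centre).T) - vessel_brad
            ) < radius + 8.0:
                continue
        if speck_centres and np.min(
            np.hypot(*(np.array(speck_centres) - centre).T)
        ) < 2 * radius + 6.0:
            continue
        mask = _paint_disc(canvas, tuple(centre), radius, dab_colour)
        if mask is not None:
            stain_mask |= mask
            speck_centres.append(centre)
            placed += 1
    if placed < spec.n_specks:
        raise PlacementError(
            f"placed only {placed}/{spec.n_specks} noise specks"
        )

    if colours.value_noise_sd > 0:
        canvas += rng.normal(0.0, colours.value_noise_sd, size=canvas.shape)
    rgb = (np.clip(canvas, 0.0, 1.0) * 255.0).round().astype(np.uint8)

    truth_columns = [
        "shape_family", "centre_col_px", "centre_row_px", "has_lumen",
        "vascular_area_um2", "endothelial_area_um2", "luminal_area_um2",
        "perimeter_um", "solidity", "width_um", "vessel_id", "intended_vessel",
    ]
    image = ImageField(rgb=rgb, pixel_pitch_um=spec.pixel_pitch_um,
                       field_id=spec.field_id)
    truth = GroundTruth(
        vessels=pd.DataFrame(records, columns=truth_columns),
        label_map=label_map,
        stain_mask=stain_mask,
        lumen_mask=lumen_mask_field,
        pixel_pitch_um=spec.pixel_pitch_um,
    )
    return image, truth


@dataclass
class GeneratorParams:
    """Distributional parameters of random field sampling.

    Defaults model a moderately vascular hot-spot: 25 vessel profiles per
    0.38 mm^2 field (about 66 vessels/mm^2), mean outer radius 25 px --
    about a 17 um vessel diameter, i.e. a mean outer perimeter near 53 um,
    matching the marker scale of the default synthetic cohort -- half of
    the profiles with an open lumen, and 40 sub-threshold noise specks.
    """

    n_vessels: int = 25
    mean_outer_radius_px: float = 25.0
    sd_outer_radius_px: float = 7.0
    min_outer_radius_px: float = 6.5
    family_probs: dict = field(
        default_factory=lambda: {
            "annulus": 0.45,
            "elliptical_ring": 0.25,
            "ribbon": 0.20,
            "branched": 0.10,
        }
    )
    lumen_prob: float = 0.5
    waviness_px: tuple[float, float] = (0.0, 6.0)
    clustering: tuple[int, float] | None = None  # (n_parents, spread_px)
    height_px: int = 1813
    width_px: int = 1813
    pixel_pitch_um: float = 0.34
    n_specks: int = 40
    max_placement_tries: int = 400


def _sample_vessel(rng: np.random.Generator, params: GeneratorParams,
                   pitch: float) -> VesselSpec:
    """Draw one vessel spec (without a centre) from the generator model."""
    min_width_px = 3.5 / pitch  # intended vessels must pass the width filter
    family = rng.choice(list(params.family_probs), p=list(params.family_probs.values()))
    r = float(np.clip(
        rng.normal(params.mean_outer_radius_px, params.sd_outer_radius_px),
        params.min_outer_radius_px, 3.0 * params.mean_outer_radius_px,
    ))
    r = max(r, min_width_px / 2.0 + 0.5)
    has_lumen = bool(rng.random() < params.lumen_prob)
    orientation = float(rng.uniform(0, 360))
    if family == "annulus":
        wall = max(2.5, r * rng.uniform(0.30, 0.55))
        if has_lumen:
            wall = min(wall, r - 2.0)  # keep the lumen opening > 1 um wide
        else:
            wall = r  # solid disc
        return VesselSpec("annulus", (0, 0), outer_radius_px=r,
                          wall_thickness_px=wall, has_lumen=has_lumen,
                          orientation_deg=orientation)
    if family == "elliptical_ring":
        a = r * rng.uniform(1.2, 1.8)
        b = max(r * rng.uniform(0.6, 0.95), min_width_px / 2.0 + 0.5)
        wall = max(2.5, b * rng.uniform(0.35, 0.6))
        if has_lumen:
            wall = min(wall, b - 2.0)
        else:
            wall = b
        return VesselSpec("elliptical_ring", (0, 0), axis_lengths_px=(a, b),
                          wall_thickness_px=wall, has_lumen=has_lumen,
                          orientation_deg=orientation)
    if family == "ribbon":
        half_len = r * rng.uniform(2.0, 4.0)
        half_width = max(min_width_px / 2.0 + 0.7, r * rng.uniform(0.35, 0.6))
        wall = max(2.5, half_width * rng.uniform(0.4, 0.7))
        if has_lumen:
            wall = min(wall, half_width - 2.0)
        else:
            wall = half_width
        waviness = float(rng.uniform(*params.waviness_px))
        return VesselSpec("ribbon", (0, 0), axis_lengths_px=(half_len, half_width),
                          wall_thickness_px=wall, has_lumen=has_lumen,
                          orientation_deg=orientation,
                          waviness_amplitude_px=waviness)
    # branched profiles carry no lumen; stroke width must itself pass the
    # vessel-width rule
    return VesselSpec("branched", (0, 0), outer_radius_px=r * rng.uniform(1.2, 2.0),
                      wall_thickness_px=max(min_width_px + 0.7, 11.0),
                      has_lumen=False, orientation_deg=orientation,
                      n_branches=int(rng.integers(3, 5)))


def sample_field_spec(params: GeneratorParams | None = None, seed: int = 0) -> FieldSpec:
    """Draw a reproducible random field spec with non-overlapping vessels.

    Vessel placements are rejection-sampled so that bounding discs stay
    inside the field and at least 4 px apart (per-vessel ground truth stays
    unambiguous).  Raises :class:`PlacementError` if the requested density
    is infeasible within the bounded retries.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    h, w, pitch = params.height_px, params.width_px, params.pixel_pitch_um

    parents = None
    if params.clustering is not None:
        n_parents, spread = params.clustering
        parents = rng.uniform([0, 0], [w, h], size=(n_parents, 2))

    placed: list[VesselSpec] = []
    radii: list[float] = []
    centres: list[tuple[float, float]] = []
    for _ in range(params.n_vessels):
        vspec = _sample_vessel(rng, params, pitch)
        brad = bounding_radius(vspec)
        margin = brad + 3.0
        if 2 * margin >= min(h, w):
            raise PlacementError("vessel larger than the field")
        for attempt in range(params.max_placement_tries):
            if parents is not None:
                px, py = parents[rng.integers(len(parents))]
                cx = float(np.clip(rng.normal(px, params.clustering[1]), margin, w - margin))
                cy = float(np.clip(rng.normal(py, params.clustering[1]), margin, h - margin))
            else:
                cx = float(rng.uniform(margin, w - margin))
                cy = float(rng.uniform(margin, h - margin))
            ok = all(
                math.hypot(cx - ox, cy - oy) > brad + orad + 4.0
                for (ox, oy), orad in zip(centres, radii)
            )
            if ok:
                break
        else:
            raise PlacementError(
                f"could not place vessel {len(placed) + 1} of {params.n_vessels}"
            )
        vspec.centre_px = (cx, cy)
        placed.append(vspec)
        centres.append((cx, cy))
        radii.append(brad)

    return FieldSpec(
        height_px=h, width_px=w, pixel_pitch_um=pitch, vessels=placed,
        n_specks=params.n_specks, seed=int(rng.integers(2**31)),
        field_id=f"synthetic-{seed}",
    )


def true_markers(gt: GroundTruth, pitch: float | None = None,
                 scale_cfg: ScaleConfig | None = None) -> FieldMarkers:
    """Continuum-geometry field markers of a ground truth.

    Size and shape markers come from the analytic per-vessel descriptors;
    MVA_rx4 and MV_scale are computed from the ground-truth masks by the
    same definitions as the measurement module; ICD uses the continuum
    centroids.  Markers undefined for the vessel count are NaN.
    """
    pitch = pitch if pitch is not None else gt.pixel_pitch_um
    h, w = gt.label_map.shape
    area_mm2 = h * w * pitch**2 / 1e6
    m = FieldMarkers(n_vessels=gt.n_vessels, mvd=gt.n_vessels / area_mm2)
    if gt.n_vessels == 0:
        m.mvd = 0.0
        return m
    df = gt.vessels
    areas = df["vascular_area_um2"].to_numpy()
    m.mva_sum_um2 = float(areas.sum())
    m.mva_mean_um2 = float(areas.mean())
    m.mva_field_fraction = m.mva_sum_um2 / (area_mm2 * 1e6)
    m.mvp_sum_um = float(df["perimeter_um"].sum())
    m.mvp_mean_um = float(df["perimeter_um"].mean())
    m.mve_mean_um2 = float(df["endothelial_area_um2"].mean())
    m.mvs_mean = float(df["solidity"].mean())
    m.mv_luminal = float(df["has_lumen"].mean())
    if gt.n_vessels >= 2:
        m.mva_cv = float(areas.std(ddof=1) / areas.mean())
        centres = df[["centre_row_px", "centre_col_px"]].to_numpy()
        m.icd_um = icd_mean(centres, pitch)
    # skeletons per vessel (cropped for speed); the union feeds MV_scale
    from scipy import ndimage

    from ..morphometry import skeleton_metrics  # local import avoids a cycle

    skeleton = np.zeros_like(gt.vascular_mask)
    lengths = []
    for vid, sl in zip(range(1, gt.n_vessels + 1), ndimage.find_objects(gt.label_map)):
        if sl is None:
            continue
        length, _, skel = skeleton_metrics(gt.label_map[sl] == vid, pitch)
        lengths.append(length)
        skeleton[sl] |= skel
    m.mvl_mean_um = float(np.mean(lengths))
    m.mva_rx4 = mva_rx4(gt.vascular_mask)
    m.mv_scale = mv_scale(skeleton, scale_cfg)
    return m
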