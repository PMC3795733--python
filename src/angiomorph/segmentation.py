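"""Microvessel segmentation of calibrated RGB immunostain photomicrographs.

The pipeline converts one hot-spot field into vessel profiles in four
deterministic steps:

1. ``detect_stain`` -- CD34/DAB-positive pixels are all pixels that are both
   dark (below a dynamically computed intensity threshold, Otsu by default)
   and outside the haematoxylin (blue counterstain) hue band.
2. connected components -- stained objects are 8-connected components.
3. ``classify_gaps`` -- fully enclosed background gaps wider than the lumen
   threshold (1.0 um) are lumens; narrower gaps are noise and are filled
   into the stain.  Background touching the image border is never a gap.
4. ``filter_candidates`` -- only objects whose filled set (lumens included)
   is at least the minimum vessel width (3.5 um) wide are microvessels; the
   rest are discarded as noise or artefacts.

Width is always the diameter of the largest inscribable circle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import label

from .morphometry import VesselProfile, measure_profile, object_width

__all__ = [
    "ImageField",
    "SegmentationConfig",
    "CandidateObject",
    "detect_stain",
    "classify_gaps",
    "filter_candidates",
    "segment_field",
]

logger = logging.getLogger(__name__)


@dataclass
class ImageField:
    """A calibrated RGB raster of one hot-spot field."""

    rgb: np.ndarray  # (H, W, 3) uint8
    pixel_pitch_um: float
    field_id: str = ""

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3 or self.rgb.size == 0:
            raise ValueError("ImageField requires a nonempty (H, W, 3) raster")
        if not self.pixel_pitch_um > 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    @property
    def area_mm2(self) -> float:
        h, w = self.shape
        return h * w * self.pixel_pitch_um**2 / 1e6


@dataclass
class SegmentationConfig:
    min_lumen_width_um: float = 1.0
    min_vessel_width_um: float = 3.5
    haematoxylin_hue_deg: tuple[float, float] = (180.0, 280.0)
    darkness_method: str = "otsu"  # "otsu" | "percentile"
    darkness_percentile: float = 25.0
    object_connectivity: int = 2  # skimage connectivity: 2 == 8-neighbour
    gap_connectivity: int = 1  # 1 == 4-neighbour
    keep_border_vessels: bool = True
    perimeter_method: str = "corrected"

    def __post_init__(self) -> None:
        if not 0 < self.min_lumen_width_um < self.min_vessel_width_um:
            raise ValueError(
                "require 0 < min_lumen_width_um < min_vessel_width_um"
            )
        if self.darkness_method not in ("otsu", "percentile"):
            raise ValueError(f"unknown darkness method {self.darkness_method!r}")


@dataclass
class CandidateObject:
    """A stained connected component with its gap classification."""

    endothelium: np.ndarray  # stain pixels plus filled sub-threshold gaps
    lumens: list[np.ndarray] = field(default_factory=list)
    offset: tuple[int, int] = (0, 0)

    @property
    def filled(self) -> np.ndarray:
        out = self.endothelium.copy()
        for lum in self.lumens:
            out |= lum
        return out


def detect_stain(image: ImageField, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Binary mask of chromogen-positive (DAB) pixels.

    A pixel is stain iff its intensity (mean of the RGB channels) falls
    below the per-image dark threshold AND its hue lies outside the
    haematoxylin band, so dark blue counterstain is rejected.
    """
    cfg = cfg or SegmentationConfig()
    rgb = image.rgb.astype(np.float64) / 255.0
    intensity = rgb.mean(axis=2)
    if intensity.max() - intensity.min() < 1e-3:
        warnings.warn(
            "image intensity is (near-)uniform; no dynamic threshold exists "
            "-- returning an empty stain mask",
            stacklevel=2,
        )
        return np.zeros(image.shape, dtype=bool)
    if cfg.darkness_method == "otsu":
        thresh = threshold_otsu(intensity)
    else:
        thresh = np.percentile(intensity, cfg.darkness_percentile)
    dark = intensity < thresh

    hue_deg = rgb2hsv(rgb)[..., 0] * 360.0
    lo, hi = cfg.haematoxylin_hue_deg
    haematoxylin = (hue_deg >= lo) & (hue_deg <= hi)
    return dark & ~haematoxylin


def classify_gaps(
    obj_mask: np.ndarray,
    cfg: SegmentationConfig,
    pitch: float,
    offset: tuple[int, int] = (0, 0),
) -> CandidateObject:
    """Split the enclosed background of a stained object into lumens and noise.

    ``obj_mask`` is a boolean crop of one 8-connected stain component.  Gaps
    are 4-connected background components fully enclosed by the object (the
    crop is padded, so anything reaching the crop border is open background,
    never a gap).  A gap at least ``min_lumen_width_um`` wide (largest
    inscribed circle) is a lumen; narrower gaps are filled into the stain.
    """
    padded = np.pad(obj_mask, 1)
    holes = ndimage.binary_fill_holes(padded) & ~padded
    endothelium = obj_mask.copy()
    lumens: list[np.ndarray] = []
    if np.any(holes):
        labelled, n = ndimage.label(holes, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for k in range(1, n + 1):
            gap = labelled == k
            gap_crop = gap[1:-1, 1:-1]
            if object_width(gap_crop, pitch) >= cfg.min_lumen_width_um:
                lumens.append(gap_crop)
            else:
                endothelium |= gap_crop  # noise/artefact gap: treated as stain
    return CandidateObject(endothelium=endothelium, lumens=lumens, offset=offset)


def filter_candidates(
    objects: list[CandidateObject],
    cfg: SegmentationConfig,
    pitch: float,
) -> list[VesselProfile]:
    """Keep gap-classified objects whose filled width meets the vessel rule."""
    profiles: list[VesselProfile] = []
    n_noise = 0
    for obj in objects:
        filled = obj.filled
        if object_width(filled, pitch) >= cfg.min_vessel_width_um:
            profiles.append(
                measure_profile(
                    vessel_id=len(profiles) + 1,
                    endothelium=obj.endothelium,
                    lumens=obj.lumens,
                    offset=obj.offset,
                    pitch=pitch,
                    perimeter_method=cfg.perimeter_method,
                )
            )
        else:
            n_noise += 1
    logger.info(
        "filter_candidates: kept %d vessel(s), discarded %d sub-width object(s)",
        len(profiles),
        n_noise,
    )
    return profiles


def segment_field(
    image: ImageField, cfg: SegmentationConfig | None = None
) -> list[VesselProfile]:
    """Full deterministic segmentation of one field into vessel profiles."""
    cfg = cfg or SegmentationConfig()
    pitch = image.pixel_pitch_um
    stain = detect_stain(image, cfg)
    labelled = label(stain, connectivity=cfg.object_connectivity)
    candidates: list[CandidateObject] = []
    for k, sl in enumerate(ndimage.find_objects(labelled), start=1):
        if sl is None:
            continue
        comp = labelled[sl] == k
        candidates.append(
            classify_gaps(comp, cfg, pitch, offset=(sl[0].start, sl[1].start))
        )
    if not cfg.keep_border_vessels:
        h, w = image.shape
        kept = []
        for obj in candidates:
            r0, c0 = obj.offset
            r1 = r0 + obj.endothelium.shape[0]
            c1 = c0 + obj.endothelium.shape[1]
            if r0 > 0 and c0 > 0 and r1 < h and c1 < w:
                kept.append(obj)
        candidates = kept
    profiles = filter_candidates(candidates, cfg, pitch)
    logger.info(
        "segment_field %s: %d stained object(s) -> %d vessel profile(s)",
        image.field_id,
        len(candidates),
        len(profiles),
    )
    return profiles
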