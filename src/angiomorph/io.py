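"""File plumbing: images, label maps, provenance-stamped tables, configs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .segmentation import ImageField

__all__ = [
    "save_image",
    "load_image_field",
    "save_label_map",
    "load_label_map",
    "write_table",
    "read_table",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of a (nested) config dataclass or mapping."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_image(path, image: ImageField, provenance: dict | None = None) -> None:
    """8-bit RGB PNG/TIFF plus a JSON sidecar carrying pitch and provenance."""
    path = Path(path)
    Image.fromarray(image.rgb, mode="RGB").save(path)
    meta = {
        "pixel_pitch_um": image.pixel_pitch_um,
        "field_id": image.field_id,
        "tool": f"angiomorph {__version__}",
    }
    meta.update(provenance or {})
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_image_field(path, pixel_pitch_um: float | None = None) -> ImageField:
    """Read a PNG/TIFF field; pitch comes from the sidecar unless given."""
    path = Path(path)
    rgb = np.asarray(Image.open(path).convert("RGB"))
    field_id = path.stem
    sidecar = _sidecar_path(path)
    if pixel_pitch_um is None:
        if not sidecar.exists():
            raise ValueError(
                f"no pixel pitch given and no sidecar {sidecar.name} found"
            )
        meta = json.loads(sidecar.read_text())
        pixel_pitch_um = float(meta["pixel_pitch_um"])
        field_id = meta.get("field_id", field_id)
    return ImageField(rgb=rgb, pixel_pitch_um=pixel_pitch_um, field_id=field_id)


def save_label_map(path, label_map: np.ndarray) -> None:
    """16-bit single-channel PNG: 0 = background, k = vessel k."""
    arr = np.asarray(label_map)
    if arr.max() > 65535:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit PNG")
    Image.fromarray(arr.astype(np.uint16)).save(Path(path))


def load_label_map(path) -> np.ndarray:
    return np.asarray(Image.open(Path(path))).astype(np.int32)


def write_table(path, df: pd.DataFrame, provenance: dict | None = None) -> None:
    """CSV with '# key=value' provenance header lines."""
    path = Path(path)
    lines = [f"# tool=angiomorph {__version__}"]
    for key, val in (provenance or {}).items():
        lines.append(f"# {key}={val}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")
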