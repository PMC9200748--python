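"""Image and manifest I/O, preprocessing and run configuration.

Raw microscopy is exchanged as one single-channel 16-bit TIFF per channel
per field, with a delimited manifest binding paths to metadata.  Model-space
images (normalized inputs, predictions) are 32-bit float TIFFs since they
are signed and standardized.

Preprocessing is the two-step pipeline applied to every field before
training or inference: bilinear ×0.5 downscale (1996×1996 → 998×998 in the
original acquisition geometry; skipped when the field is already at working
size) followed by per-image, per-channel standardization to mean 0 / sd 1.
Per-image standardization is what removes batch-level intensity shifts:
every image is individually mapped to the same intensity scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.transform import resize

from .constants import ALL_CHANNELS, BRIGHTFIELD_PLANES, FLUOR_CHANNELS

#: raw synthetic intensities are written as 16-bit integers scaled by this
#: factor, using roughly [0, 20000] of the 16-bit range — real microscopy
#: rarely approaches the theoretical maximum.
UINT16_SCALE = 16000.0


@dataclass
class PairedField:
    """One field of view: brightfield z-stack, fluorescent target, metadata.

    brightfield: (3, H, W) in plane order (z−4 µm, in focus, z+4 µm)
    fluorescent: (5, H, W) in channel order (DNA, ER, RNA, AGP, Mito)
    """

    brightfield: np.ndarray
    fluorescent: np.ndarray
    batch_id: str = "A"
    well_id: str = "A01"
    field_id: str = "f0"
    role: str = "treatment"

    def __post_init__(self):
        self.brightfield = np.asarray(self.brightfield)
        self.fluorescent = np.asarray(self.fluorescent)
        if self.brightfield.ndim != 3 or self.brightfield.shape[0] != 3:
            raise ValueError(f"brightfield must be (3, H, W), got {self.brightfield.shape}")
        if self.fluorescent.ndim != 3 or self.fluorescent.shape[0] != 5:
            raise ValueError(f"fluorescent must be (5, H, W), got {self.fluorescent.shape}")
        if self.brightfield.shape[1:] != self.fluorescent.shape[1:]:
            raise ValueError("brightfield and fluorescent stacks must share H, W")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fluorescent.shape[1:]

    @property
    def metadata(self) -> dict:
        return {"batch_id": self.batch_id, "well_id": self.well_id,
                "field_id": self.field_id, "role": self.role}


def save_field(field: PairedField, out_dir: Path) -> dict[str, str]:
    """Write one 16-bit TIFF per channel; returns channel → path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    stacks = {**dict(zip(BRIGHTFIELD_PLANES, field.brightfield)),
              **dict(zip(FLUOR_CHANNELS, field.fluorescent))}
    for channel, img in stacks.items():
        data = np.round(np.clip(img * UINT16_SCALE, 0, 65535)).astype(np.uint16)
        path = out_dir / f"{field.field_id}_{channel}.tif"
        tifffile.imwrite(path, data)
        paths[channel] = str(path)
    return paths


def load_field(manifest_row: pd.Series | dict) -> PairedField:
    """Assemble a PairedField from one manifest row (wide format, path_<channel> columns)."""
    row = dict(manifest_row)
    channels = {}
    for channel in ALL_CHANNELS:
        key = f"path_{channel}"
        if key not in row or not isinstance(row[key], str) or not Path(row[key]).exists():
            raise FileNotFoundError(
                f"field {row.get('field_id', '?')}: missing file for channel {channel}")
        img = tifffile.imread(row[key])
        if img.ndim != 2:
            raise ValueError(f"{row[key]}: expected a single-channel image, got shape {img.shape}")
        channels[channel] = img.astype(np.float32) / UINT16_SCALE
    return PairedField(
        brightfield=np.stack([channels[c] for c in BRIGHTFIELD_PLANES]),
        fluorescent=np.stack([channels[c] for c in FLUOR_CHANNELS]),
        batch_id=str(row.get("batch", "A")),
        well_id=str(row.get("well", "A01")),
        field_id=str(row.get("field_id", "f0")),
        role=str(row.get("role", "treatment")),
    )


def save_prediction(field_id: str, channels: np.ndarray, out_dir: Path) -> list[str]:
    """Write a (5, H, W) float prediction as 32-bit float TIFFs, one per channel."""
    channels = np.asarray(channels, dtype=np.float32)
    if channels.ndim != 3 or channels.shape[0] != 5:
        raise ValueError(f"prediction must be (5, H, W), got {channels.shape}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, img in zip(FLUOR_CHANNELS, channels):
        path = out_dir / f"{field_id}_pred_{name}.tif"
        tifffile.imwrite(path, img)
        paths.append(str(path))
    return paths


def load_prediction(field_id: str, out_dir: Path) -> np.ndarray:
    out_dir = Path(out_dir)
    return np.stack([tifffile.imread(out_dir / f"{field_id}_pred_{name}.tif")
                     for name in FLUOR_CHANNELS])


def _downscale_half(stack: np.ndarray) -> np.ndarray:
    """Bilinear ×0.5 downscale of a (C, H, W) stack."""
    C, H, W = stack.shape
    out_shape = (C, H // 2, W // 2)
    return resize(stack, out_shape, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True).astype(stack.dtype)


def standardize(stack: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Per-channel z-normalization of a (C, H, W) stack to mean 0, sd 1."""
    stack = np.asarray(stack, dtype=np.float32)
    mu = stack.mean(axis=(1, 2), keepdims=True)
    sd = stack.std(axis=(1, 2), keepdims=True)
    if eps <= 0 and np.any(sd == 0):
        ch = int(np.argwhere(sd.reshape(-1) == 0)[0][0])
        raise ValueError(f"channel {ch} is constant; cannot standardize without an eps floor")
    return (stack - mu) / (sd + eps)


def preprocess(field: PairedField, working_size: int | None = None,
               eps: float = 0.0) -> PairedField:
    """Downscale ×0.5 (if larger than the working size) then standardize.

    ``working_size``: target spatial side; when None, a single ×0.5
    downscale is applied whenever the field side is even and > 256, which
    maps the acquisition size 1996 to the working size 998.
    """
    bf, fl = field.brightfield, field.fluorescent
    h = bf.shape[1]
    needs_downscale = (working_size is not None and h > working_size) or \
                      (working_size is None and h > 256 and h % 2 == 0)
    if needs_downscale:
        bf, fl = _downscale_half(bf), _downscale_half(fl)
    return PairedField(standardize(bf, eps), standardize(fl, eps),
                       field.batch_id, field.well_id, field.field_id, field.role)


@dataclass
class RunConfig:
    """Snapshot of everything a run needs to be reproduced."""

    data_root: str = "runs/data"
    output_root: str = "runs/out"
    master_seed: int = 0
    working_size: int = 128
    n_fields: int = 40
    n_cells: int = 14
    noise_sd: float = 0.02
    batch_intensity_shift: float = 1.3
    training: dict = dc_field(default_factory=dict)
    tiling: dict = dc_field(default_factory=lambda: {"patch": 256, "stride": 128})
    profiling: dict = dc_field(default_factory=dict)
    toxicity: dict = dc_field(default_factory=dict)
    verbosity: str = "info"

    def to_yaml(self, path: Path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
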