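"""Image and manifest I/O plus run configuration.

Conventions: raw channels are 16-bit TIFF (float-valued DOPU and
retardation maps are linearly scaled to the 16-bit range; the scale
window is recorded in the manifest), 8-bit tiles and overlays are PNG,
manifests are CSV, reports are JSON, run configs are YAML.  Axis 0 is
depth, axis 1 is lateral.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .errors import ConfigurationError
from .phantom import PhantomConfig

__all__ = [
    "read_image",
    "write_image",
    "scale_to_uint16",
    "unscale_from_uint16",
    "CHANNEL_SCALES",
    "RunConfig",
    "derive_seed",
]

# fixed physical display windows per channel (vmin, vmax)
CHANNEL_SCALES = {
    "intensity": (0.0, 65535.0),
    "dopu": (0.0, 1.0),
    "retardation": (0.0, float(np.pi / 2)),
}


def write_image(path, image: np.ndarray, bit_depth: int = 16) -> Path:
    """Write a grayscale (or RGB uint8) image; format follows bit depth."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if bit_depth == 16:
        if image.dtype != np.uint16:
            raise ValueError("16-bit output requires a uint16 array")
        tifffile.imwrite(path, image)
    elif bit_depth == 8:
        if image.dtype != np.uint8:
            raise ValueError("8-bit output requires a uint8 array")
        Image.fromarray(image).save(path)
    else:
        raise ConfigurationError("bit_depth must be 8 or 16")
    return path


def read_image(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return tifffile.imread(path)
    if suffix == ".png":
        return np.asarray(Image.open(path))
    raise ConfigurationError(f"unsupported image format: {path}")


def scale_to_uint16(values: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    """Linear map of [vmin, vmax] onto the 16-bit range (round to nearest)."""
    scaled = (np.asarray(values, dtype=np.float64) - vmin) / (vmax - vmin)
    return np.round(np.clip(scaled, 0.0, 1.0) * 65535).astype(np.uint16)


def unscale_from_uint16(counts: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    return counts.astype(np.float64) / 65535.0 * (vmax - vmin) + vmin


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def _desk_scale_phantom() -> PhantomConfig:
    return PhantomConfig(image_height=36, image_width=72,
                         n_layers_range=(2, 3), dopu_kernel=3)


@dataclass
class PhantomStageConfig:
    """Defaults are desk scale (32x32 tiles) so `run-all` finishes in
    minutes on one CPU; set the full-scale geometry (256x512 frames,
    202-px tiles, depth-5/base-64 GAN, lr 2e-5, 50 epochs) explicitly
    for a study-sized run."""

    n_frames_per_class: int = 60
    n_cases_per_class: int = 3
    phantom: PhantomConfig = field(default_factory=_desk_scale_phantom)


@dataclass
class PreprocessStageConfig:
    tile_side: int = 32
    margin_threshold: float = 0.02
    split_strategy: str = "image_based"


@dataclass
class GanStageConfig:
    depth: int = 3
    base_channels: int = 16
    disc_base_channels: int = 16
    epochs: int = 8
    learning_rate: float = 2e-4
    lambda_adv: float = 1.0
    lambda_l1: float = 100.0
    lambda_ssim: float = 10.0


@dataclass
class EvaluateStageConfig:
    threshold: int = 10


@dataclass
class ValidateStageConfig:
    epochs: int = 24
    contrasts: tuple = ("dopu", "retardation")
    tsne_perplexity: float = 30.0


@dataclass
class RunConfig:
    """Full pipeline configuration; YAML round trip is lossless."""

    global_seed: int = 0
    output_root: str = "polsynth_run"
    log_level: str = "INFO"
    phantom: PhantomStageConfig = field(default_factory=PhantomStageConfig)
    preprocess: PreprocessStageConfig = field(default_factory=PreprocessStageConfig)
    gan: GanStageConfig = field(default_factory=GanStageConfig)
    evaluate: EvaluateStageConfig = field(default_factory=EvaluateStageConfig)
    validate: ValidateStageConfig = field(default_factory=ValidateStageConfig)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, d):
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name not in d:
                    continue
                v = d[f.name]
                if dataclasses.is_dataclass(f.type) or f.name in (
                        "phantom",) and isinstance(v, dict):
                    continue  # handled below
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
            return kwargs

        phantom_d = dict(raw.get("phantom", {}))
        inner = phantom_d.pop("phantom", {})
        inner = {k: (tuple(v) if isinstance(v, list) else v)
                 for k, v in inner.items()}
        stage_phantom = PhantomStageConfig(
            **{k: v for k, v in phantom_d.items()},
            phantom=PhantomConfig(**inner),
        ) if (phantom_d or inner) else PhantomStageConfig()
        return cls(
            global_seed=raw.get("global_seed", 0),
            output_root=raw.get("output_root", "polsynth_run"),
            log_level=raw.get("log_level", "INFO"),
            phantom=stage_phantom,
            preprocess=PreprocessStageConfig(**build(PreprocessStageConfig,
                                                     raw.get("preprocess", {}))),
            gan=GanStageConfig(**build(GanStageConfig, raw.get("gan", {}))),
            evaluate=EvaluateStageConfig(**build(EvaluateStageConfig,
                                                 raw.get("evaluate", {}))),
            validate=ValidateStageConfig(**build(ValidateStageConfig,
                                                 raw.get("validate", {}))),
        )


_STAGE_IDS = {
    "phantom": 1,
    "preprocess": 2,
    "gan_dopu": 3,
    "gan_retardation": 4,
    "evaluate": 5,
    "validate": 6,
    "tsne": 7,
}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the run seed."""
    if stage not in _STAGE_IDS:
        raise ConfigurationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def save_json(path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_manifest(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
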