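"""Masked-SSIM evaluation of synthetic contrasts and jet overlay rendering.

The masked SSIM mirrors the evaluation used for synthetic PS-OCT
contrasts: the local SSIM map is computed on the full real/synthetic
pair, and only map entries whose OCT intensity is at or above a
threshold (the signal region) enter the average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps

from .errors import EmptyMaskError, EmptyResultError
from .ssim import effective_win, ssim_map

__all__ = ["EvalReport", "masked_ssim", "evaluate_dataset", "render_overlay",
           "DEFAULT_INTENSITY_THRESHOLD"]

DEFAULT_INTENSITY_THRESHOLD = 10  # 8-bit counts


@dataclass
class EvalReport:
    per_tile_ssim: list[float]
    mean: float
    std: float
    contrast: str
    threshold: float
    n_tiles: int
    n_excluded: int = 0

    def validate(self) -> None:
        if self.n_tiles != len(self.per_tile_ssim):
            raise ValueError("n_tiles inconsistent with per-tile list")
        if abs(self.mean - float(np.mean(self.per_tile_ssim))) > 1e-9:
            raise ValueError("mean inconsistent with per-tile list")

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "threshold": self.threshold,
            "n_tiles": self.n_tiles,
            "n_excluded": self.n_excluded,
            "mean": self.mean,
            "std": self.std,
            "per_tile_ssim": list(map(float, self.per_tile_ssim)),
        }


def masked_ssim(real: np.ndarray, synthetic: np.ndarray,
                intensity: np.ndarray, threshold: float,
                mask_first: bool = False) -> float:
    """Mean of the local SSIM map over pixels with intensity >= threshold.

    The map is computed over valid 11-px windows; the mask is the
    intensity image cropped to the same valid region, so raising the
    threshold changes which entries are averaged, never their values.
    With ``mask_first=True`` sub-threshold pixels are zeroed in both
    contrast images *before* the map is computed (changes the window
    statistics; off by default).
    """
    if not (real.shape == synthetic.shape == intensity.shape):
        raise ValueError("real, synthetic and intensity tiles must be co-shaped")
    if mask_first:
        keep = intensity >= threshold
        real = np.where(keep, real, 0)
        synthetic = np.where(keep, synthetic, 0)
    smap = ssim_map(real, synthetic)
    r = (effective_win(real.shape) - 1) // 2
    sl = slice(r, -r) if r else slice(None)
    mask = np.asarray(intensity)[sl, sl] >= threshold
    if not mask.any():
        raise EmptyMaskError(
            f"no pixel at or above intensity threshold {threshold}"
        )
    return float(smap[mask].mean())


def evaluate_dataset(real_tiles, synthetic_tiles, intensity_tiles,
                     threshold: float = DEFAULT_INTENSITY_THRESHOLD,
                     contrast: str = "dopu") -> EvalReport:
    """Per-tile masked SSIM, aggregated as mean and std over the set.

    Tiles whose mask is empty are excluded and counted in
    ``n_excluded``.
    """
    if not (len(real_tiles) == len(synthetic_tiles) == len(intensity_tiles)):
        raise ValueError("tile lists must be aligned")
    values: list[float] = []
    excluded = 0
    for r, s, i in zip(real_tiles, synthetic_tiles, intensity_tiles):
        try:
            values.append(masked_ssim(r, s, i, threshold))
        except EmptyMaskError:
            excluded += 1
    if not values:
        raise EmptyResultError("no evaluable tiles (all masks empty)")
    report = EvalReport(
        per_tile_ssim=values,
        mean=float(np.mean(values)),
        std=float(np.std(values)),
        contrast=contrast,
        threshold=threshold,
        n_tiles=len(values),
        n_excluded=excluded,
    )
    report.validate()
    return report


def render_overlay(intensity: np.ndarray, contrast: np.ndarray,
                   threshold: float, colormap: str = "jet",
                   alpha: float = 0.6) -> np.ndarray:
    """Jet-colormap contrast overlay on the intensity image (both 8-bit).

    Pixels below the intensity threshold show pure grayscale intensity;
    pixels at or above it show the jet-mapped contrast alpha-blended
    over the intensity.  Returns an (H, W, 3) uint8 RGB image.
    """
    if intensity.shape != contrast.shape:
        raise ValueError("intensity and contrast tiles must be co-shaped")
    inten = np.asarray(intensity, dtype=np.float64)
    gray = np.repeat(inten[..., None], 3, axis=-1)
    cmap = colormaps[colormap]
    colored = cmap(np.asarray(contrast, dtype=np.float64) / 255.0)[..., :3] * 255.0
    blended = (1.0 - alpha) * gray + alpha * colored
    keep = (inten >= threshold)[..., None]
    out = np.where(keep, np.round(blended), np.round(gray))
    return out.astype(np.uint8)
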