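"""Scaled-down translation tasks used for training-loop verification.

The recovery task pairs small phantom intensity tiles with a target
that is a smooth, invertible (logistic) function of the Gaussian-blurred
intensity.  Because the mapping is deterministic, a working training
loop must reach high masked SSIM on held-out tiles; failure indicates a
training defect rather than a hard dataset.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantom import PhantomConfig, generate_frame
from .preprocess import convert_to_8bit, split_into_tiles

__all__ = ["small_phantom_config", "smooth_mapping_target",
           "make_recovery_pairs", "make_phantom_tile_set"]


def small_phantom_config(tile_side: int = 32, seed: int = 0) -> PhantomConfig:
    """Phantom configuration producing frames that tile into two
    ``tile_side`` x ``tile_side`` tiles with no margin cropping."""
    return PhantomConfig(
        image_height=tile_side,
        image_width=2 * tile_side,
        n_layers_range=(2, 4),
        dopu_kernel=3,
        rng_seed=seed,
    )


def smooth_mapping_target(intensity8: np.ndarray, blur_sigma: float = 1.5,
                          gain: float = 40.0) -> np.ndarray:
    """Logistic map of the blurred intensity onto the 8-bit scale.

    ``y = 255 / (1 + exp(-(blur(x) - 127.5) / gain))`` — smooth and
    strictly monotone (hence invertible) in the blurred intensity.
    """
    blurred = gaussian_filter(np.asarray(intensity8, dtype=np.float64),
                              blur_sigma, mode="nearest")
    return 255.0 / (1.0 + np.exp(-(blurred - 127.5) / gain))


def _intensity_tiles(config: PhantomConfig, n_tiles: int, label_cycle,
                     rng: np.random.Generator):
    """Yield (intensity8 tile, label) pairs from freshly drawn frames."""
    out = []
    i = 0
    while len(out) < n_tiles:
        label = label_cycle[i % len(label_cycle)]
        frame = generate_frame(config, label, rng, frame_id=f"tile_src_{i}")
        for tile in split_into_tiles(frame.intensity,
                                     tile_side=config.image_height,
                                     frame_id=frame.frame_id):
            if len(out) < n_tiles:
                out.append((convert_to_8bit(tile.image), label, frame))
        i += 1
    return out


def make_recovery_pairs(n_tiles: int = 200, tile_side: int = 32,
                        seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """(intensity8, target8) pairs for the smooth-mapping recovery task."""
    config = small_phantom_config(tile_side, seed)
    rng = config.rng()
    tiles = _intensity_tiles(config, n_tiles, ("normal", "cancer"), rng)
    return [(x8, smooth_mapping_target(x8)) for x8, _, _ in tiles]


def make_phantom_tile_set(n_frames_per_class: int, tile_side: int = 32,
                          seed: int = 0):
    """Labeled 8-bit tile triples from small phantom frames.

    Returns a list of dicts with ``intensity``, ``dopu``,
    ``retardation`` (all 8-bit), ``label`` and ``frame_id`` — two tiles
    per frame.
    """
    config = small_phantom_config(tile_side, seed)
    rng = config.rng()
    records = []
    for label in ("cancer", "normal"):
        for i in range(n_frames_per_class):
            frame = generate_frame(config, label, rng,
                                   frame_id=f"{label}_{i:04d}")
            chans = {
                "intensity": frame.intensity,
                "dopu": np.round(frame.dopu * 65535).astype(np.uint16),
                "retardation": np.round(
                    frame.retardation / (np.pi / 2) * 65535).astype(np.uint16),
            }
            tiles = {
                name: split_into_tiles(img, tile_side=tile_side,
                                       frame_id=frame.frame_id, channel=name)
                for name, img in chans.items()
            }
            for k, half in enumerate(("left", "right")):
                records.append({
                    "intensity": convert_to_8bit(tiles["intensity"][k].image),
                    "dopu": convert_to_8bit(tiles["dopu"][k].image),
                    "retardation": convert_to_8bit(tiles["retardation"][k].image),
                    "label": label,
                    "frame_id": frame.frame_id,
                    "tile_id": f"{frame.frame_id}_{half}",
                })
    return records
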