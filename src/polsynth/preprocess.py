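"""Image conditioning and dataset partitioning ahead of GAN training.

Raw frames are margin-cropped, split into two square tiles per frame,
converted from 16-bit to 8-bit, and partitioned 8:1:1 into train /
validation / test sets, either per image or per case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyResultError

__all__ = [
    "Tile",
    "SplitAssignment",
    "crop_dark_margins",
    "split_into_tiles",
    "tile_offsets",
    "convert_to_8bit",
    "plan_tiles",
    "assign_splits",
]

DEFAULT_TILE_SIDE = 202
DEFAULT_MARGIN_THRESHOLD = 0.02

PARTITIONS = ("train", "test", "validation")


@dataclass
class Tile:
    image: np.ndarray
    parent_frame_id: str
    half: str              # "left" | "right"
    channel: str           # "intensity" | "dopu" | "retardation"
    bit_depth: int = 16

    def validate(self) -> None:
        h, w = self.image.shape
        if h != w:
            raise ValueError("tile is not square")
        if self.half not in ("left", "right"):
            raise ValueError(f"bad half {self.half!r}")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit depth must be 8 or 16")


@dataclass
class SplitAssignment:
    """Partition label per tile row, with the strategy that produced it."""

    partition: pd.Series   # indexed like the tile manifest
    strategy: str          # "image_based" | "case_based"
    ratio: tuple[int, int, int]
    seed: int

    def counts(self) -> dict[str, int]:
        c = self.partition.value_counts().to_dict()
        return {p: int(c.get(p, 0)) for p in PARTITIONS}


def crop_dark_margins(image: np.ndarray,
                      margin_threshold: float = DEFAULT_MARGIN_THRESHOLD,
                      ) -> np.ndarray:
    """Strip leading/trailing rows and columns darker than the threshold.

    A row/column is dark when its mean is below ``margin_threshold``
    times the global maximum.  Only contiguous margins are removed;
    interior content is never touched.
    """
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    peak = float(image.max())
    if peak <= 0:
        raise EmptyResultError("image has no signal above zero")
    thr = margin_threshold * peak
    row_ok = image.mean(axis=1) >= thr
    col_ok = image.mean(axis=0) >= thr
    if not row_ok.any() or not col_ok.any():
        raise EmptyResultError("image is entirely below the margin threshold")
    r = np.flatnonzero(row_ok)
    c = np.flatnonzero(col_ok)
    return image[r[0]: r[-1] + 1, c[0]: c[-1] + 1]


def tile_offsets(shape: tuple[int, int], tile_side: int = DEFAULT_TILE_SIDE,
                 ) -> dict[str, tuple[int, int]]:
    """(row, col) origin of the left and right tile inside the cropped frame."""
    h, w = shape
    if h < tile_side or w < 2 * tile_side:
        raise ValueError(
            f"image {h}x{w} too small for two {tile_side}x{tile_side} tiles"
        )
    top = (h - tile_side) // 2
    half_w = w // 2
    off = (half_w - tile_side) // 2
    return {"left": (top, off), "right": (top, half_w + off)}


def split_into_tiles(image: np.ndarray, tile_side: int = DEFAULT_TILE_SIDE,
                     frame_id: str = "", channel: str = "intensity",
                     bit_depth: int = 16) -> tuple[Tile, Tile]:
    """Center-crop the depth axis and split laterally into two square tiles.

    The lateral axis is halved and each half is center-cropped to the
    tile side, so the two tiles never overlap.
    """
    offs = tile_offsets(image.shape, tile_side)
    tiles = []
    for half in ("left", "right"):
        top, left = offs[half]
        tiles.append(Tile(
            image=image[top: top + tile_side, left: left + tile_side],
            parent_frame_id=frame_id, half=half, channel=channel,
            bit_depth=bit_depth,
        ))
    return tiles[0], tiles[1]


def convert_to_8bit(image: np.ndarray, mode: str = "global-linear") -> np.ndarray:
    """16-bit to 8-bit conversion.

    ``global-linear`` (default) maps [0, 65535] -> [0, 255] with
    round-half-up, i.e. ``floor(v / 257 + 0.5)``.  ``per-image``
    min-max rescales each image to the full 8-bit range first.
    """
    v = np.asarray(image, dtype=np.float64)
    if mode == "per-image":
        lo, hi = v.min(), v.max()
        v = (v - lo) / (hi - lo) * 65535.0 if hi > lo else np.zeros_like(v)
    elif mode != "global-linear":
        raise ConfigurationError(f"unknown conversion mode {mode!r}")
    return np.floor(v / 257.0 + 0.5).astype(np.uint8)


def plan_tiles(frame_manifest: pd.DataFrame) -> pd.DataFrame:
    """Expand a frame manifest into a tile manifest (two tiles per frame).

    Pure bookkeeping: one row per (frame, half); each row stands for the
    co-registered intensity/DOPU/retardation tile triple at that
    position, so channel counts are always equal.
    """
    if frame_manifest.empty:
        raise ConfigurationError("empty frame manifest")
    rows = []
    for _, fr in frame_manifest.iterrows():
        for half in ("left", "right"):
            rows.append({
                "tile_id": f"{fr.frame_id}_{half}",
                "frame_id": fr.frame_id,
                "case_id": fr.case_id,
                "label": fr.label,
                "half": half,
            })
    return pd.DataFrame(rows)


def _floor_split_sizes(n: int, ratio: tuple[int, int, int]) -> tuple[int, int, int]:
    if tuple(ratio) != (8, 1, 1):
        raise ConfigurationError("only the 8:1:1 split family is supported")
    n_test = n // 10
    n_val = n // 10
    return n - n_test - n_val, n_test, n_val


def assign_splits(tile_manifest: pd.DataFrame,
                  ratio: tuple[int, int, int] = (8, 1, 1),
                  strategy: str = "image_based",
                  seed: int = 0) -> SplitAssignment:
    """Partition tiles into train/test/validation.

    * ``image_based``: one global seeded shuffle; test and validation
      each receive ``floor(N / 10)`` tiles and train the remainder.
    * ``case_based``: all but one case per class go to train; the two
      held-out cases are each split half/half between test and
      validation (frame order shuffled with the seed).
    """
    if tile_manifest.empty:
        raise ConfigurationError("empty tile manifest")
    rng = np.random.default_rng(seed)
    n = len(tile_manifest)
    part = pd.Series(index=tile_manifest.index, dtype=object)

    if strategy == "image_based":
        _, n_test, n_val = _floor_split_sizes(n, ratio)
        order = rng.permutation(n)
        part.iloc[order[:n_test]] = "test"
        part.iloc[order[n_test: n_test + n_val]] = "validation"
        part.iloc[order[n_test + n_val:]] = "train"
    elif strategy == "case_based":
        if tuple(ratio) != (8, 1, 1):
            raise ConfigurationError("only the 8:1:1 split family is supported")
        part[:] = "train"
        for label in sorted(tile_manifest["label"].unique()):
            cases = sorted(tile_manifest.loc[tile_manifest["label"] == label,
                                             "case_id"].unique())
            if len(cases) < 2:
                raise ConfigurationError(
                    f"case_based split needs >= 2 cases for label {label!r}"
                )
            held_out = cases[int(rng.integers(len(cases)))]
            idx = tile_manifest.index[tile_manifest["case_id"] == held_out]
            shuffled = rng.permutation(len(idx))
            half = len(idx) // 2
            part.loc[idx[shuffled[:half]]] = "test"
            part.loc[idx[shuffled[half:]]] = "validation"
    else:
        raise ConfigurationError(f"unknown split strategy {strategy!r}")

    return SplitAssignment(partition=part, strategy=strategy,
                           ratio=tuple(ratio), seed=seed)
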