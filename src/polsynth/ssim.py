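"""Structural similarity (SSIM) with an 11x11 Gaussian window, sigma 1.5.

Two code paths share the same definition:

* :func:`ssim_map` / :func:`ssim_term` on numpy arrays — used for
  evaluation (the masked variant averages the same local map over a
  signal mask);
* :func:`ssim_term` on :class:`~polsynth.nn.Tensor` inputs — a
  differentiable twin built from the autodiff primitives, used inside
  the generator loss.

The local map is computed over *valid* window positions only (the
window never leaves the image), with stabilizers C1 = (0.01 L)^2 and
C2 = (0.03 L)^2 and weighted (not sample) covariance, matching the
standard Wang et al. formulation.  SSIM is invariant to a joint affine
rescaling of both images together with ``data_range``, so computing it
on [-1, 1]-normalized tiles with ``data_range=2`` equals the 8-bit
result with ``data_range=255``.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["gaussian_window", "ssim_map", "ssim_term", "WIN_SIZE", "WIN_SIGMA"]

WIN_SIZE = 11
WIN_SIGMA = 1.5


def gaussian_window(win_size: int = WIN_SIZE, sigma: float = WIN_SIGMA) -> np.ndarray:
    """Normalized 2-D Gaussian window (outer product of normalized 1-D)."""
    r = (win_size - 1) // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    return np.outer(k1, k1)


def _filt(a: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    win = np.lib.stride_tricks.sliding_window_view(a, kernel.shape)
    return np.einsum("ijkl,kl->ij", win, kernel)


def _stabilizers(data_range: float) -> tuple[float, float]:
    return (0.01 * data_range) ** 2, (0.03 * data_range) ** 2


def effective_win(shape: tuple, win_size: int = WIN_SIZE) -> int:
    """Window size actually used: shrunk to the largest odd size that
    fits the image (a 1x1 window reduces SSIM to its luminance term)."""
    m = min(shape)
    if m < 1:
        raise ValueError("empty image")
    w = min(win_size, m)
    return w if w % 2 == 1 else w - 1


def ssim_map(x: np.ndarray, y: np.ndarray, data_range: float = 255.0,
             win_size: int = WIN_SIZE, sigma: float = WIN_SIGMA) -> np.ndarray:
    """Local SSIM map over valid window positions.

    For an H x W pair the map has shape (H - win + 1, W - win + 1); its
    entry (i, j) corresponds to the window centered at input pixel
    (i + r, j + r) with r = (win - 1) // 2.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    win_size = effective_win(x.shape, win_size)
    k = gaussian_window(win_size, sigma)
    c1, c2 = _stabilizers(data_range)
    mx = _filt(x, k)
    my = _filt(y, k)
    sxx = _filt(x * x, k) - mx * mx
    syy = _filt(y * y, k) - my * my
    sxy = _filt(x * y, k) - mx * my
    num = (2 * mx * my + c1) * (2 * sxy + c2)
    den = (mx * mx + my * my + c1) * (sxx + syy + c2)
    return num / den


def ssim_term(pred, target, data_range: float = 255.0,
              win_size: int = WIN_SIZE, sigma: float = WIN_SIGMA):
    """Mean SSIM between two images; scalar float or scalar Tensor.

    Symmetric in its arguments and equal to 1 iff the images are
    identical.  Accepts 2-D numpy arrays (returns float) or NCHW
    single-channel Tensors (returns a differentiable scalar Tensor).
    """
    if isinstance(pred, Tensor) or isinstance(target, Tensor):
        return _ssim_term_tensor(nn.as_tensor(pred), nn.as_tensor(target),
                                 data_range, win_size, sigma)
    return float(ssim_map(pred, target, data_range, win_size, sigma).mean())


def _ssim_term_tensor(x: Tensor, y: Tensor, data_range: float,
                      win_size: int, sigma: float) -> Tensor:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.ndim == 2:
        x = x.reshape((1, 1) + tuple(x.shape))
        y = y.reshape((1, 1) + tuple(y.shape))
    if x.ndim != 4 or x.shape[1] != 1:
        raise ValueError("expected 2-D images or NCHW single-channel tensors")
    win_size = effective_win(x.shape[2:], win_size)
    k = gaussian_window(win_size, sigma).astype(x.dtype)
    w = Tensor(k[None, None])  # fixed window, no gradient
    c1, c2 = _stabilizers(data_range)

    def filt(a):
        return nn.conv2d(a, w)

    mx = filt(x)
    my = filt(y)
    sxx = filt(x * x) - mx * mx
    syy = filt(y * y) - my * my
    sxy = filt(x * y) - mx * my
    num = (2.0 * mx * my + c1) * (2.0 * sxy + c2)
    den = (mx * mx + my * my + c1) * (sxx + syy + c2)
    return (num / den).mean()
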