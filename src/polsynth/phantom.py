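"""Layered birefringent tissue phantom for polarization-sensitive OCT.

Generates co-registered triplets of OCT intensity, DOPU (degree of
polarization uniformity) and phase retardation B-scans with a
cancer-vs-normal class structure:

* **normal** tissue is modeled as a stack of organized birefringent
  layers (high :math:`\\Delta n`, e.g. collagen/stroma), so the
  round-trip retardation ramps up with depth;
* **cancer** tissue has near-zero :math:`\\Delta n` (disorganized
  fibers) plus depolarizing lesion blobs that scramble the local
  polarization state.

The retardation channel is derived from a noisier Stokes perturbation
than the DOPU channel, so retardation maps are intrinsically the noisier
contrast.  Axis convention: axis 0 is depth (axial), axis 1 is lateral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "PhantomConfig",
    "Layer",
    "LesionBlob",
    "LayerStack",
    "TissueFrame",
    "StokesField",
    "simulate_layer_stack",
    "cumulative_retardation",
    "fold_retardation",
    "render_speckled_intensity",
    "expected_intensity",
    "stokes_from_retardation",
    "apply_lesion_depolarization",
    "compute_dopu",
    "generate_frame",
    "generate_dataset",
]

LABELS = ("cancer", "normal")

# fixed log-compression window for 16-bit quantization (natural-log units)
_LOG_LO = float(np.log(1e-5))
_LOG_HI = float(np.log(10.0))


@dataclass
class PhantomConfig:
    """Physical and sampling parameters of the phantom generator."""

    image_height: int = 256          # depth pixels
    image_width: int = 512           # lateral pixels
    pixel_depth_um: float = 5.0      # axial sampling, micrometers/pixel
    wavelength_um: float = 1.3       # center wavelength, micrometers
    n_layers_range: tuple[int, int] = (3, 6)
    birefringence_range_normal: tuple[float, float] = (5e-4, 2e-3)
    birefringence_range_cancer: tuple[float, float] = (0.0, 1e-4)
    attenuation_coeff_range: tuple[float, float] = (0.002, 0.010)  # per pixel
    speckle_looks: int = 4
    depol_noise_sigma_dopu: float = 0.10
    depol_noise_sigma_ret: float = 0.25
    dopu_kernel: int = 5
    lesion_density_cancer: float = 6.0  # mean blobs per frame
    rng_seed: int = 0

    def validate(self) -> None:
        if self.depol_noise_sigma_ret <= self.depol_noise_sigma_dopu:
            raise ConfigurationError(
                "retardation channel must be noisier: "
                "depol_noise_sigma_ret > depol_noise_sigma_dopu"
            )
        if self.birefringence_range_cancer[1] >= self.birefringence_range_normal[0]:
            raise ConfigurationError(
                "cancer birefringence range must lie below the normal range"
            )
        if self.dopu_kernel < 3 or self.dopu_kernel % 2 == 0:
            raise ConfigurationError("dopu_kernel must be odd and >= 3")
        lo, hi = self.n_layers_range
        if lo > hi or lo < 1:
            raise ConfigurationError("n_layers_range is empty or non-positive")
        if self.image_height < hi:
            raise ConfigurationError("image_height smaller than maximum layer count")
        for name in ("birefringence_range_normal", "birefringence_range_cancer",
                     "attenuation_coeff_range"):
            a, b = getattr(self, name)
            if a > b or a < 0:
                raise ConfigurationError(f"{name} is not a valid interval")
        if self.speckle_looks < 1:
            raise ConfigurationError("speckle_looks must be a positive integer")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class Layer:
    thickness: int          # pixels
    delta_n: float          # birefringence
    scatter_amp: float      # backscatter amplitude (linear units)
    attenuation: float      # exponential decay per pixel


@dataclass
class LesionBlob:
    row: float
    col: float
    radius: float
    depol_strength: float   # extra Stokes perturbation scale inside the blob
    amp_boost: float        # multiplicative backscatter boost


@dataclass
class LayerStack:
    layers: list[Layer]
    lesions: list[LesionBlob] = field(default_factory=list)


@dataclass
class StokesField:
    """Per-pixel Stokes parameters (I, Q, U, V), arbitrary intensity units."""

    i_comp: np.ndarray
    q_comp: np.ndarray
    u_comp: np.ndarray
    v_comp: np.ndarray

    def validate(self) -> None:
        if not (self.i_comp > 0).all():
            raise ValueError("Stokes I must be positive everywhere")
        pol = np.sqrt(self.q_comp**2 + self.u_comp**2 + self.v_comp**2)
        if (pol > self.i_comp * (1 + 1e-9)).any():
            raise ValueError("polarized fraction exceeds total intensity")


@dataclass
class TissueFrame:
    intensity: np.ndarray   # uint16, log-compressed backscatter
    dopu: np.ndarray        # float in [0, 1]
    retardation: np.ndarray  # float radians in [0, pi/2]
    label: str              # "cancer" | "normal"
    case_id: str
    frame_id: str

    def validate(self) -> None:
        if not (self.intensity.shape == self.dopu.shape == self.retardation.shape):
            raise ValueError("channel shapes differ")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.intensity.dtype != np.uint16:
            raise ValueError("intensity must be uint16")
        if self.dopu.min() < 0 or self.dopu.max() > 1:
            raise ValueError("DOPU out of [0, 1]")
        if self.retardation.min() < 0 or self.retardation.max() > np.pi / 2 + 1e-12:
            raise ValueError("retardation out of [0, pi/2]")


# ---------------------------------------------------------------------------
# layer geometry and optics
# ---------------------------------------------------------------------------

def simulate_layer_stack(config: PhantomConfig, label: str,
                         rng: np.random.Generator) -> LayerStack:
    """Draw a stack of horizontal tissue slabs (plus lesions for cancer).

    Layer thicknesses are drawn by cutting the depth axis at ``n - 1``
    distinct interior positions, so every layer is at least one pixel
    thick and thicknesses sum exactly to ``image_height``.
    """
    config.validate()
    if label not in LABELS:
        raise ConfigurationError(f"unknown label {label!r}")
    lo, hi = config.n_layers_range
    n = int(rng.integers(lo, hi + 1))
    h = config.image_height
    if n > 1:
        cuts = np.sort(rng.choice(np.arange(1, h), size=n - 1, replace=False))
        bounds = np.concatenate([[0], cuts, [h]])
    else:
        bounds = np.array([0, h])
    thicknesses = np.diff(bounds)
    if label == "normal":
        dn_lo, dn_hi = config.birefringence_range_normal
    else:
        dn_lo, dn_hi = config.birefringence_range_cancer
    layers = [
        Layer(
            thickness=int(t),
            delta_n=float(rng.uniform(dn_lo, dn_hi)),
            scatter_amp=float(rng.uniform(0.2, 1.0)),
            attenuation=float(rng.uniform(*config.attenuation_coeff_range)),
        )
        for t in thicknesses
    ]
    lesions: list[LesionBlob] = []
    if label == "cancer":
        n_les = int(rng.poisson(config.lesion_density_cancer))
        for _ in range(n_les):
            lesions.append(LesionBlob(
                row=float(rng.uniform(0, h)),
                col=float(rng.uniform(0, config.image_width)),
                radius=float(rng.uniform(h / 8, h / 3)),
                depol_strength=float(rng.uniform(0.3, 0.7)),
                amp_boost=float(rng.uniform(1.5, 2.5)),
            ))
    return LayerStack(layers=layers, lesions=lesions)


def fold_retardation(delta: np.ndarray) -> np.ndarray:
    """Triangular fold of an unbounded retardation into [0, pi/2]."""
    half = np.pi / 2
    return half - np.abs(np.mod(delta, np.pi) - half)


def _per_pixel(stack: LayerStack, attr: str) -> np.ndarray:
    return np.concatenate([
        np.full(layer.thickness, getattr(layer, attr)) for layer in stack.layers
    ])


def cumulative_retardation(stack: LayerStack, config: PhantomConfig) -> np.ndarray:
    """Depth-cumulative round-trip phase retardation, folded to [0, pi/2].

    Single-pass retardation accumulates as
    ``delta(z) = (2 pi / lambda) * sum_{z' <= z} dn(z') * dz``; the
    round trip doubles it, and the displayed value is the triangular
    fold into [0, pi/2].  Layers are laterally uniform, so the map is
    constant along axis 1.
    """
    dn = _per_pixel(stack, "delta_n")
    if (dn < 0).any():
        raise ConfigurationError("negative birefringence in layer stack")
    single_pass = (2 * np.pi / config.wavelength_um) * np.cumsum(
        dn * config.pixel_depth_um
    )
    folded = fold_retardation(2.0 * single_pass)
    return np.tile(folded[:, None], (1, config.image_width))


def _lesion_mask(stack: LayerStack, shape: tuple[int, int]) -> np.ndarray:
    """Maximum lesion depolarization strength per pixel (0 outside blobs)."""
    strength = np.zeros(shape)
    if not stack.lesions:
        return strength
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    for blob in stack.lesions:
        inside = (rows - blob.row) ** 2 + (cols - blob.col) ** 2 <= blob.radius**2
        strength = np.where(inside, np.maximum(strength, blob.depol_strength),
                            strength)
    return strength


def _amplitude_map(stack: LayerStack, config: PhantomConfig) -> np.ndarray:
    """Noiseless linear backscatter amplitude with depth attenuation."""
    amp = _per_pixel(stack, "scatter_amp")
    mu = _per_pixel(stack, "attenuation")
    decay = np.exp(-np.cumsum(mu))
    a = np.tile((amp * decay)[:, None], (1, config.image_width))
    if stack.lesions:
        rows = np.arange(config.image_height)[:, None]
        cols = np.arange(config.image_width)[None, :]
        for blob in stack.lesions:
            inside = (rows - blob.row) ** 2 + (cols - blob.col) ** 2 <= blob.radius**2
            a = np.where(inside, a * blob.amp_boost, a)
    return a


def _quantize_log(linear: np.ndarray) -> np.ndarray:
    logim = np.log(linear + 1e-12)
    scaled = np.clip((logim - _LOG_LO) / (_LOG_HI - _LOG_LO), 0.0, 1.0)
    return np.round(scaled * 65535).astype(np.uint16)


def render_speckled_intensity(stack: LayerStack, config: PhantomConfig,
                              rng: np.random.Generator) -> np.ndarray:
    """Speckled, attenuated, log-compressed 16-bit OCT intensity image.

    Speckle is modeled as multi-look averaging of unit-mean exponential
    intensity draws, i.e. a Gamma(k, 1/k) multiplicative factor with
    ``k = speckle_looks``.
    """
    if any(layer.attenuation <= 0 for layer in stack.layers):
        raise ConfigurationError("attenuation coefficients must be positive")
    a = _amplitude_map(stack, config)
    k = config.speckle_looks
    factor = rng.gamma(shape=k, scale=1.0 / k, size=a.shape)
    return _quantize_log(a * factor)


def expected_intensity(stack: LayerStack, config: PhantomConfig) -> np.ndarray:
    """Noiseless (speckle-free) counterpart of render_speckled_intensity."""
    return _quantize_log(_amplitude_map(stack, config))


# ---------------------------------------------------------------------------
# polarization channels
# ---------------------------------------------------------------------------

def stokes_from_retardation(retardation: np.ndarray, config: PhantomConfig,
                            rng: np.random.Generator,
                            sigma: float) -> StokesField:
    """Map retardation to a perturbed unit Stokes field.

    The noise-free state is the incident (Q, U, V) = (1, 0, 0) rotated
    by ``2 * delta`` about the V axis: ``(cos 2d, sin 2d, 0)``.  A
    Gaussian perturbation of scale ``sigma`` is added to (Q, U, V) and
    the vector is re-clipped to the physical bound |(Q,U,V)| <= I.
    """
    if sigma < 0:
        raise ConfigurationError("noise sigma must be non-negative")
    if retardation.min() < 0 or retardation.max() > np.pi / 2 + 1e-12:
        raise ValueError("retardation must lie in [0, pi/2]")
    two_d = 2.0 * retardation
    i = np.ones_like(retardation)
    q = np.cos(two_d)
    u = np.sin(two_d)
    v = np.zeros_like(retardation)
    if sigma > 0:
        q = q + rng.normal(0.0, sigma, q.shape)
        u = u + rng.normal(0.0, sigma, u.shape)
        v = v + rng.normal(0.0, sigma, v.shape)
    return _clip_to_physical(i, q, u, v)


def _clip_to_physical(i, q, u, v) -> StokesField:
    pol = np.sqrt(q * q + u * u + v * v)
    scale = np.where(pol > i, i / np.maximum(pol, 1e-300), 1.0)
    return StokesField(i_comp=i, q_comp=q * scale, u_comp=u * scale,
                       v_comp=v * scale)


def apply_lesion_depolarization(field: StokesField, stack: LayerStack,
                                rng: np.random.Generator) -> StokesField:
    """Scramble the polarization state inside lesion blobs.

    Models the loss of organized structure in tumors: inside each blob
    an extra Gaussian perturbation of the blob's ``depol_strength`` is
    applied to (Q, U, V).
    """
    strength = _lesion_mask(stack, field.i_comp.shape)
    if not strength.any():
        return field
    q = field.q_comp + strength * rng.normal(0.0, 1.0, strength.shape)
    u = field.u_comp + strength * rng.normal(0.0, 1.0, strength.shape)
    v = field.v_comp + strength * rng.normal(0.0, 1.0, strength.shape)
    return _clip_to_physical(field.i_comp, q, u, v)


def compute_dopu(field: StokesField, kernel: int) -> np.ndarray:
    """Degree of polarization uniformity via kernel-averaged Stokes vectors.

    Each (Q, U, V) is normalized by I, averaged over a ``kernel`` x
    ``kernel`` window (windows are clipped at the image borders), and
    DOPU is the norm of the averaged vector, clipped to [0, 1].
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ConfigurationError("DOPU kernel must be odd and >= 1")
    i = field.i_comp
    comps = [field.q_comp / i, field.u_comp / i, field.v_comp / i]
    means = [_clipped_window_mean(c, kernel) for c in comps]
    dopu = np.sqrt(sum(m * m for m in means))
    return np.clip(dopu, 0.0, 1.0)


def _clipped_window_mean(x: np.ndarray, kernel: int) -> np.ndarray:
    """Mean over k x k windows, shrunk (not padded) at the borders."""
    r = (kernel - 1) // 2
    xp = np.pad(x.astype(np.float64), r)
    ones = np.pad(np.ones_like(x, dtype=np.float64), r)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel))
    cnt = np.lib.stride_tricks.sliding_window_view(ones, (kernel, kernel))
    return win.sum(axis=(-2, -1)) / cnt.sum(axis=(-2, -1))


# ---------------------------------------------------------------------------
# frame and dataset assembly
# ---------------------------------------------------------------------------

def generate_frame(config: PhantomConfig, label: str, rng: np.random.Generator,
                   case_id: str = "case_0", frame_id: str = "frame_0") -> TissueFrame:
    """Generate one co-registered intensity/DOPU/retardation triplet."""
    stack = simulate_layer_stack(config, label, rng)
    ret_clean = cumulative_retardation(stack, config)
    intensity = render_speckled_intensity(stack, config, rng)

    field_d = stokes_from_retardation(ret_clean, config, rng,
                                      config.depol_noise_sigma_dopu)
    field_d = apply_lesion_depolarization(field_d, stack, rng)
    dopu = compute_dopu(field_d, config.dopu_kernel)

    field_r = stokes_from_retardation(ret_clean, config, rng,
                                      config.depol_noise_sigma_ret)
    field_r = apply_lesion_depolarization(field_r, stack, rng)
    # measured retardation from the (noisy) Stokes state; abs folds the
    # atan2 branch back into [0, pi/2]
    ret = 0.5 * np.abs(np.arctan2(field_r.u_comp, field_r.q_comp))

    frame = TissueFrame(intensity=intensity, dopu=dopu, retardation=ret,
                        label=label, case_id=case_id, frame_id=frame_id)
    frame.validate()
    return frame


def generate_dataset(config: PhantomConfig, n_frames_per_class: int,
                     n_cases_per_class: int,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[list[TissueFrame], pd.DataFrame]:
    """Generate a labeled dataset; frames are assigned round-robin to cases.

    Returns the frames plus a manifest DataFrame with one row per frame
    (``frame_id``, ``case_id``, ``label``).
    """
    if n_frames_per_class < 1:
        raise ConfigurationError("need at least one frame per class")
    if n_cases_per_class < 1 or n_frames_per_class < n_cases_per_class:
        raise ConfigurationError("need n_frames >= n_cases >= 1 per class")
    if rng is None:
        rng = config.rng()
    frames: list[TissueFrame] = []
    rows = []
    for label in LABELS:
        for i in range(n_frames_per_class):
            case_id = f"{label}_case_{i % n_cases_per_class:02d}"
            frame_id = f"{label}_{i:05d}"
            frames.append(generate_frame(config, label, rng,
                                         case_id=case_id, frame_id=frame_id))
            rows.append({"frame_id": frame_id, "case_id": case_id, "label": label})
    return frames, pd.DataFrame(rows)
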