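"""SSIM-augmented conditional GAN for intensity-to-contrast translation.

A pix2pix-style setup: a U-Net generator maps an 8-bit OCT intensity
tile to a DOPU or phase-retardation tile, and a three-layer patch
discriminator scores (intensity, contrast) pairs.  The generator loss
adds a structural-similarity term to the usual adversarial + L1
objective:

    L_G = lambda_adv * L_adv + lambda_l1 * mean|G(x) - y|
          + lambda_ssim * (1 - SSIM(G(x), y))

One model is trained per contrast.  Tiles are normalized to [-1, 1]
internally; the SSIM term is evaluated with ``data_range=2`` there,
which is numerically identical to the 8-bit convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError
from .evaluation import DEFAULT_INTENSITY_THRESHOLD, masked_ssim
from .nn import Tensor
from .ssim import ssim_term

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "LossWeights",
    "TrainConfig",
    "UNetGenerator",
    "PatchDiscriminator",
    "GanBundle",
    "generator_loss",
    "discriminator_loss",
    "train_gan",
    "synthesize",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    """U-Net encoder-decoder with skip connections.

    Inputs whose side is not a multiple of ``2**depth`` are
    reflect-padded up to the next multiple and the output is cropped
    back, so output shape always equals input shape.
    """

    depth: int = 5
    base_channels: int = 64
    normalization: str = "instance"

    def validate(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ConfigurationError("depth and base_channels must be positive")
        if self.normalization != "instance":
            raise ConfigurationError("only instance normalization is supported")


@dataclass
class DiscriminatorSpec:
    """Patch discriminator with exactly three conv feature layers."""

    n_conv_layers: int = 3
    base_channels: int = 64

    def validate(self) -> None:
        if self.n_conv_layers != 3:
            raise ConfigurationError("the discriminator uses three conv layers")
        if self.base_channels < 1:
            raise ConfigurationError("base_channels must be positive")


@dataclass
class LossWeights:
    lambda_adv: float = 1.0
    lambda_l1: float = 100.0
    lambda_ssim: float = 10.0

    def validate(self) -> None:
        if min(self.lambda_adv, self.lambda_l1, self.lambda_ssim) < 0:
            raise ConfigurationError("loss weights must be non-negative")


@dataclass
class TrainConfig:
    learning_rate: float = 2e-5
    batch_size: int = 1
    beta1: float = 0.5
    beta2: float = 0.999
    epochs: int = 50
    seed: int = 0
    contrast_target: str = "dopu"        # "dopu" | "retardation"
    adversarial: str = "bce"             # "bce" | "lsgan"
    val_mask_threshold: float = DEFAULT_INTENSITY_THRESHOLD

    def validate(self) -> None:
        if self.batch_size != 1:
            # instance normalization computes per-sample statistics
            raise ConfigurationError(
                "batch_size must be 1 under instance normalization"
            )
        if self.contrast_target not in ("dopu", "retardation"):
            raise ConfigurationError(
                f"unknown contrast target {self.contrast_target!r}"
            )
        if self.adversarial not in ("bce", "lsgan"):
            raise ConfigurationError("adversarial must be 'bce' or 'lsgan'")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ConfigurationError("epochs and learning rate must be positive")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _enc_channels(spec: GeneratorSpec) -> list[int]:
    return [min(spec.base_channels * 2**i, spec.base_channels * 8)
            for i in range(spec.depth)]


class UNetGenerator(nn.Module):
    """U-Net: stride-2 conv encoder, nearest-upsample + conv decoder."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator,
                 in_ch: int = 1, out_ch: int = 1):
        spec.validate()
        self.spec = spec
        chans = _enc_channels(spec)
        self.enc_convs = []
        self.enc_norms = []
        prev = in_ch
        for i, c in enumerate(chans):
            self.enc_convs.append(nn.Conv2d(prev, c, 4, stride=2, padding=1,
                                            rng=rng))
            self.enc_norms.append(nn.InstanceNorm2d(c) if i > 0 else None)
            prev = c
        self.dec_convs = []
        self.dec_norms = []
        for j in range(spec.depth - 1):
            skip = chans[spec.depth - 2 - j]
            self.dec_convs.append(nn.Conv2d(prev + skip, skip, 3, stride=1,
                                            padding=1, rng=rng))
            self.dec_norms.append(nn.InstanceNorm2d(skip))
            prev = skip
        self.final_conv = nn.Conv2d(prev, out_ch, 3, stride=1, padding=1,
                                    rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        feats = []
        h = x
        for i, conv in enumerate(self.enc_convs):
            h = conv(h)
            if self.enc_norms[i] is not None:
                h = self.enc_norms[i](h)
            h = nn.ops.leaky_relu(h, 0.2)
            feats.append(h)
        for j, conv in enumerate(self.dec_convs):
            h = nn.upsample2(h)
            h = nn.concat([h, feats[self.spec.depth - 2 - j]], axis=1)
            h = conv(h)
            h = self.dec_norms[j](h)
            h = nn.ops.relu(h)
        h = nn.upsample2(h)
        h = self.final_conv(h)
        return nn.ops.tanh(h)


class PatchDiscriminator(nn.Module):
    """Three stride-2 conv layers then a 1-channel patch score head.

    Input is the 2-channel concatenation of the conditioning intensity
    tile and the (real or synthetic) contrast tile; the output is a map
    of patch logits.
    """

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator,
                 in_ch: int = 2):
        spec.validate()
        self.spec = spec
        chans = [spec.base_channels * 2**i for i in range(spec.n_conv_layers)]
        self.convs = []
        self.norms = []
        prev = in_ch
        for i, c in enumerate(chans):
            self.convs.append(nn.Conv2d(prev, c, 4, stride=2, padding=1,
                                        rng=rng))
            self.norms.append(nn.InstanceNorm2d(c) if i > 0 else None)
            prev = c
        self.score = nn.Conv2d(prev, 1, 4, stride=1, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for i, conv in enumerate(self.convs):
            h = conv(h)
            if self.norms[i] is not None:
                h = self.norms[i](h)
            h = nn.ops.leaky_relu(h, 0.2)
        return self.score(h)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _adv_loss(scores, target: float, kind: str = "bce"):
    if kind == "lsgan":
        diff = nn.as_tensor(scores) - target
        return (diff * diff).mean()
    return nn.bce_with_logits(scores, target)


def discriminator_loss(scores_real, scores_fake, kind: str = "bce"):
    """Mean BCE-with-logits pushing real patches to 1 and fake to 0."""
    real = _adv_loss(nn.as_tensor(scores_real), 1.0, kind)
    fake = _adv_loss(nn.as_tensor(scores_fake), 0.0, kind)
    out = 0.5 * (real + fake)
    if not isinstance(scores_real, Tensor) and not isinstance(scores_fake, Tensor):
        return float(out.data)
    return out


def generator_loss(scores_fake, pred, target, weights: LossWeights,
                   data_range: float = 255.0, adversarial: str = "bce"):
    """Weighted adversarial + L1 + (1 - SSIM) objective.

    Returns ``(total, components)`` where components holds the three
    unweighted terms as floats (``ssim`` is None when its weight is
    zero; the term is then skipped entirely, recovering the plain
    pix2pix objective bit-for-bit).
    """
    weights.validate()
    pred_t = nn.as_tensor(pred)
    target_t = nn.as_tensor(target)
    if pred_t.shape != target_t.shape:
        raise ValueError("pred and target shapes differ")
    if scores_fake is None:
        adv = nn.Tensor(np.zeros(()))
    else:
        adv = _adv_loss(nn.as_tensor(scores_fake), 1.0, adversarial)
    l1 = nn.ops.absolute(pred_t - target_t).mean()
    total = weights.lambda_adv * adv + weights.lambda_l1 * l1
    components = {"adv": float(adv.data), "l1": float(l1.data), "ssim": None}
    if weights.lambda_ssim != 0:
        ssim = ssim_term(pred_t, target_t, data_range=data_range)
        total = total + weights.lambda_ssim * (1.0 - ssim)
        components["ssim"] = float(ssim.data)
    if not any(isinstance(v, Tensor) for v in (scores_fake, pred, target)):
        return float(total.data), components
    return total, components


# ---------------------------------------------------------------------------
# padding policy and inference
# ---------------------------------------------------------------------------

def _pad_amounts(side: int, depth: int) -> tuple[int, int]:
    m = 2**depth
    total = (-side) % m
    return total // 2, total - total // 2


def _pad_input(img: np.ndarray, depth: int) -> tuple[np.ndarray, tuple]:
    t, b = _pad_amounts(img.shape[0], depth)
    l, r = _pad_amounts(img.shape[1], depth)
    return np.pad(img, ((t, b), (l, r)), mode="reflect"), (t, l)


def _normalize(img8: np.ndarray) -> np.ndarray:
    return (np.asarray(img8, dtype=np.float32) / 127.5) - 1.0


def _denormalize(x: np.ndarray) -> np.ndarray:
    return np.clip((x + 1.0) * 127.5, 0.0, 255.0)


def _forward_generator(gen: UNetGenerator, img8: np.ndarray,
                       for_training: bool = False) -> Tensor:
    h, w = img8.shape
    padded, (t, l) = _pad_input(_normalize(img8), gen.spec.depth)
    x = Tensor(padded[None, None])
    out = gen(x)
    return nn.crop2d(out, t, l, h, w)


def synthesize(model, intensity8: np.ndarray) -> np.ndarray:
    """Run the generator on an 8-bit intensity tile or frame.

    Returns a float array on the [0, 255] scale, co-shaped with the
    input; deterministic (inference has no stochastic elements).
    """
    gen = model.generator if isinstance(model, GanBundle) else model
    if gen is None:
        raise ValueError("uninitialized model")
    if intensity8.ndim != 2:
        raise ValueError("expected a single 2-D image")
    out = _forward_generator(gen, intensity8)
    return _denormalize(out.data[0, 0].astype(np.float64))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class GanBundle:
    """Trained generator plus everything needed to reproduce it."""

    generator: UNetGenerator
    generator_spec: GeneratorSpec
    discriminator_spec: DiscriminatorSpec
    weights: LossWeights
    train_config: TrainConfig
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_ssim: float = float("nan")
    best_state: list | None = None
    n_generator_steps: int = 0

    def best_generator(self) -> UNetGenerator:
        """Generator restored to the epoch with best validation masked-SSIM."""
        if self.best_state is None:
            return self.generator
        gen = UNetGenerator(self.generator_spec, np.random.default_rng(0))
        gen.load_state_arrays(self.best_state)
        return gen

    def save(self, path) -> None:
        meta = {
            "generator_spec": asdict(self.generator_spec),
            "discriminator_spec": asdict(self.discriminator_spec),
            "weights": asdict(self.weights),
            "train_config": asdict(self.train_config),
            "history": self.history,
            "best_epoch": self.best_epoch,
            "best_val_ssim": self.best_val_ssim,
            "n_generator_steps": self.n_generator_steps,
        }
        arrays = {f"final_{i}": a for i, a in
                  enumerate(self.generator.state_arrays())}
        if self.best_state is not None:
            arrays.update({f"best_{i}": a for i, a in
                           enumerate(self.best_state)})
        np.savez(path, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "GanBundle":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            finals = [data[f"final_{i}"] for i in
                      range(sum(1 for k in data.files if k.startswith("final_")))]
            bests = [data[f"best_{i}"] for i in
                     range(sum(1 for k in data.files if k.startswith("best_")))]
        gspec = GeneratorSpec(**meta["generator_spec"])
        gen = UNetGenerator(gspec, np.random.default_rng(0))
        gen.load_state_arrays(finals)
        return cls(
            generator=gen,
            generator_spec=gspec,
            discriminator_spec=DiscriminatorSpec(**meta["discriminator_spec"]),
            weights=LossWeights(**meta["weights"]),
            train_config=TrainConfig(**meta["train_config"]),
            history=meta["history"],
            best_epoch=meta["best_epoch"],
            best_val_ssim=meta["best_val_ssim"],
            best_state=bests or None,
            n_generator_steps=meta["n_generator_steps"],
        )


def _copy_state(module: nn.Module) -> list[np.ndarray]:
    return [a.copy() for a in module.state_arrays()]


def train_gan(train_pairs, val_pairs, generator_spec: GeneratorSpec,
              discriminator_spec: DiscriminatorSpec, weights: LossWeights,
              config: TrainConfig) -> GanBundle:
    """Alternating generator/discriminator training at batch size 1.

    ``train_pairs`` / ``val_pairs`` are sequences of ``(intensity8,
    contrast8)`` tile pairs on the 8-bit scale.  Per epoch the history
    records the mean loss components and the validation masked-SSIM of
    the current generator; the parameters of the epoch with the best
    validation masked-SSIM are retained alongside the final ones.
    """
    generator_spec.validate()
    discriminator_spec.validate()
    weights.validate()
    config.validate()
    if len(train_pairs) == 0:
        raise ConfigurationError("empty training set")
    rng = np.random.default_rng(config.seed)
    gen = UNetGenerator(generator_spec, np.random.default_rng(rng.integers(2**31)))
    disc = PatchDiscriminator(discriminator_spec,
                              np.random.default_rng(rng.integers(2**31)))
    opt_g = nn.Adam(gen.parameters(), lr=config.learning_rate,
                    beta1=config.beta1, beta2=config.beta2)
    opt_d = nn.Adam(disc.parameters(), lr=config.learning_rate,
                    beta1=config.beta1, beta2=config.beta2)

    bundle = GanBundle(gen, generator_spec, discriminator_spec, weights, config)
    norm_pairs = [(np.asarray(x), _normalize(y)) for x, y in train_pairs]

    for epoch in range(config.epochs):
        order = rng.permutation(len(norm_pairs))
        sums = {"d_loss": 0.0, "adv": 0.0, "l1": 0.0, "ssim": 0.0}
        for idx in order:
            x8, y_norm = norm_pairs[idx]
            fake = _forward_generator(gen, x8)
            x_norm = _normalize(x8)[None, None]
            y_t = Tensor(y_norm[None, None])
            x_t = Tensor(x_norm)

            # discriminator update
            d_real = disc(nn.concat([x_t, y_t], axis=1))
            d_fake = disc(nn.concat([x_t, fake.detach()], axis=1))
            d_loss = discriminator_loss(d_real, d_fake, config.adversarial)
            disc.zero_grad()
            d_loss.backward()
            opt_d.step()

            # generator update (discriminator grads are discarded)
            scores = disc(nn.concat([x_t, fake], axis=1))
            g_total, comps = generator_loss(
                scores, fake, y_t, weights, data_range=2.0,
                adversarial=config.adversarial,
            )
            if not np.isfinite(g_total.data) or not np.isfinite(d_loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: "
                    f"G={float(g_total.data)}, D={float(d_loss.data)}"
                )
            gen.zero_grad()
            disc.zero_grad()
            g_total.backward()
            opt_g.step()
            disc.zero_grad()
            bundle.n_generator_steps += 1

            sums["d_loss"] += float(d_loss.data)
            sums["adv"] += comps["adv"]
            sums["l1"] += comps["l1"]
            sums["ssim"] += comps["ssim"] if comps["ssim"] is not None else 0.0

        record = {k: v / len(norm_pairs) for k, v in sums.items()}
        record["epoch"] = epoch
        record["val_masked_ssim"] = _validation_masked_ssim(
            gen, val_pairs, config.val_mask_threshold
        )
        bundle.history.append(record)
        val = record["val_masked_ssim"]
        if val is not None and (
            np.isnan(bundle.best_val_ssim) or val > bundle.best_val_ssim
        ):
            bundle.best_val_ssim = val
            bundle.best_epoch = epoch
            bundle.best_state = _copy_state(gen)
    return bundle


def _validation_masked_ssim(gen: UNetGenerator, val_pairs,
                            threshold: float) -> float | None:
    if val_pairs is None or len(val_pairs) == 0:
        return None
    vals = []
    for x8, y8 in val_pairs:
        synth = synthesize(gen, np.asarray(x8))
        vals.append(masked_ssim(np.asarray(y8, dtype=np.float64), synth,
                                np.asarray(x8), threshold))
    return float(np.mean(vals))
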