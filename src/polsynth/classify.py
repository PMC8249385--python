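"""Cancer/normal classification of contrast tiles and t-SNE visualization.

A residual convolutional backbone with a 512-wide penultimate layer
feeds a 512 -> 2 fully connected head.  In the default transfer-style
regime the backbone is frozen and only the head is trained (24 epochs,
best-validation-accuracy checkpoint).  Classifiers trained on real and
on synthetic contrast tiles are compared via ROC/AUC and per-item
agreement, and penultimate activations are embedded in 2-D with t-SNE.

Class convention: ``cancer`` is the positive class (index 1); ROC
scores are the softmax probability of cancer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from . import nn
from .errors import ConfigurationError
from .nn import Tensor

__all__ = [
    "ClassifierSpec",
    "ValidationReport",
    "ResidualBackbone",
    "TrainedClassifier",
    "split_for_classifier",
    "train_classifier",
    "roc_and_auc",
    "extract_activations",
    "conditional_probabilities",
    "tsne_embed",
    "compare_real_vs_synthetic",
]

POSITIVE_LABEL = "cancer"
LABEL_TO_INDEX = {"normal": 0, "cancer": 1}
FEATURE_WIDTH = 512


@dataclass
class ClassifierSpec:
    backbone: str = "reduced_resnet"     # "reduced_resnet" | "resnet18"
    trainable_scope: str = "head_only"   # "head_only" | "all"
    init: str = "random"                 # "random" | "pretrained"
    epochs: int = 24
    head_learning_rate: float = 1e-3
    batch_size: int = 32

    def validate(self) -> None:
        if self.backbone not in ("reduced_resnet", "resnet18"):
            raise ConfigurationError(f"unknown backbone {self.backbone!r}")
        if self.trainable_scope not in ("head_only", "all"):
            raise ConfigurationError("trainable_scope must be head_only or all")
        if self.init == "pretrained":
            raise ConfigurationError(
                "pretrained initialization requires downloaded weights, "
                "which are not bundled; use init='random'"
            )
        if self.init != "random":
            raise ConfigurationError(f"unknown init {self.init!r}")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be positive")


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

class _ResidualBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                               rng=rng, init_std=0.05)
        self.norm1 = nn.InstanceNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, stride=1, padding=1,
                               rng=rng, init_std=0.05)
        self.norm2 = nn.InstanceNorm2d(out_ch)
        self.proj = (nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng,
                               init_std=0.05)
                     if (stride != 1 or in_ch != out_ch) else None)

    def forward(self, x):
        h = nn.ops.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        shortcut = self.proj(x) if self.proj is not None else x
        return nn.ops.relu(h + shortcut)


class ResidualBackbone(nn.Module):
    """Residual feature extractor ending in a 512-d global-average vector.

    ``reduced_resnet`` uses one residual block per stage (4 blocks
    total); ``resnet18`` uses the classic two blocks per stage.  Both
    keep the 512-channel penultimate width.
    """

    STAGES = (64, 128, 256, 512)

    def __init__(self, spec: ClassifierSpec, rng: np.random.Generator,
                 in_ch: int = 1):
        spec.validate()
        blocks_per_stage = 1 if spec.backbone == "reduced_resnet" else 2
        self.stem = nn.Conv2d(in_ch, 64, 3, stride=1, padding=1, rng=rng,
                              init_std=0.05)
        self.stem_norm = nn.InstanceNorm2d(64)
        self.blocks = []
        prev = 64
        for s, ch in enumerate(self.STAGES):
            for b in range(blocks_per_stage):
                stride = 2 if (s > 0 and b == 0) else 1
                self.blocks.append(_ResidualBlock(prev, ch, stride, rng))
                prev = ch

    def forward(self, x):
        h = nn.ops.relu(self.stem_norm(self.stem(x)))
        for block in self.blocks:
            h = block(h)
        return h.mean(axis=(2, 3))  # (N, 512)


@dataclass
class TrainedClassifier:
    backbone: ResidualBackbone
    head: nn.Linear
    spec: ClassifierSpec
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = float("nan")

    def features(self, tiles) -> np.ndarray:
        return extract_activations(self, tiles)

    def logits(self, tiles) -> np.ndarray:
        feats = self.features(tiles)
        return feats @ self.head.weight.data + self.head.bias.data

    def predict_scores(self, tiles) -> np.ndarray:
        """Softmax probability of the cancer class per tile."""
        z = self.logits(tiles).astype(np.float64)
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e[:, 1] / e.sum(axis=1)


def _stack_tiles(tiles) -> np.ndarray:
    arr = np.stack([np.asarray(t, dtype=np.float32) for t in tiles])
    return (arr / 127.5 - 1.0)[:, None]  # NCHW in [-1, 1]


def extract_activations(classifier: TrainedClassifier, tiles) -> np.ndarray:
    """Penultimate 512-d activation per tile (deterministic inference)."""
    backbone = (classifier.backbone
                if isinstance(classifier, TrainedClassifier) else classifier)
    x = _stack_tiles(tiles)
    feats = []
    for lo in range(0, len(x), 16):
        feats.append(backbone(Tensor(x[lo:lo + 16])).data)
    return np.concatenate(feats, axis=0)


def _labels_to_indices(labels) -> np.ndarray:
    try:
        return np.array([LABEL_TO_INDEX[l] for l in labels])
    except KeyError as err:
        raise ValueError(f"unknown class label {err.args[0]!r}") from None


def _cross_entropy(logits: Tensor, y_idx: np.ndarray) -> Tensor:
    shift = logits.data.max(axis=1, keepdims=True)  # constant for stability
    z = logits - shift
    expz = nn.ops.tsum(nn.ops.exp(z), axis=1, keepdims=True)
    onehot = np.zeros(logits.shape, dtype=logits.dtype)
    onehot[np.arange(len(y_idx)), y_idx] = 1.0
    picked = nn.ops.tsum(z * onehot, axis=1, keepdims=True)
    return (nn.ops.log(expz) - picked).mean()


def train_classifier(train_tiles, train_labels, val_tiles, val_labels,
                     spec: ClassifierSpec | None = None,
                     seed: int = 0) -> TrainedClassifier:
    """Train the tile classifier; returns the best-validation checkpoint.

    With ``trainable_scope='head_only'`` backbone features are computed
    once and only the 512 -> 2 head is optimized, so the backbone
    parameters are bitwise unchanged.  The head of the epoch with the
    best validation accuracy is restored before returning.
    """
    spec = spec or ClassifierSpec()
    spec.validate()
    y_train = _labels_to_indices(train_labels)
    y_val = _labels_to_indices(val_labels)
    for name, y in (("training", y_train), ("validation", y_val)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} set must contain both classes")
    rng = np.random.default_rng(seed)
    backbone = ResidualBackbone(spec, np.random.default_rng(rng.integers(2**31)))
    head = nn.Linear(FEATURE_WIDTH, 2,
                     rng=np.random.default_rng(rng.integers(2**31)))
    clf = TrainedClassifier(backbone=backbone, head=head, spec=spec)

    if spec.trainable_scope == "head_only":
        backbone.set_trainable(False)
        f_train = extract_activations(clf, train_tiles)
        f_val = extract_activations(clf, val_tiles)
        _fit_head(clf, f_train, y_train, f_val, y_val, rng)
    else:
        _fit_all(clf, train_tiles, y_train, val_tiles, y_val, rng)
    return clf


def _fit_head(clf, f_train, y_train, f_val, y_val, rng) -> None:
    spec = clf.spec
    opt = nn.Adam(clf.head.parameters(), lr=spec.head_learning_rate,
                  beta1=0.9, beta2=0.999)
    best_state = None
    for epoch in range(spec.epochs):
        order = rng.permutation(len(f_train))
        losses = []
        for lo in range(0, len(order), spec.batch_size):
            sel = order[lo:lo + spec.batch_size]
            logits = clf.head(Tensor(f_train[sel].astype(np.float32)))
            loss = _cross_entropy(logits, y_train[sel])
            clf.head.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_logits = f_val @ clf.head.weight.data + clf.head.bias.data
        val_acc = float((val_logits.argmax(axis=1) == y_val).mean())
        clf.history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                            "val_accuracy": val_acc})
        if np.isnan(clf.best_val_accuracy) or val_acc > clf.best_val_accuracy:
            clf.best_val_accuracy = val_acc
            clf.best_epoch = epoch
            best_state = [a.copy() for a in clf.head.state_arrays()]
    if best_state is not None:
        clf.head.load_state_arrays(best_state)


def _fit_all(clf, train_tiles, y_train, val_tiles, y_val, rng) -> None:
    spec = clf.spec
    x_train = _stack_tiles(train_tiles)
    params = clf.backbone.parameters() + clf.head.parameters()
    opt = nn.Adam(params, lr=1e-4, beta1=0.9, beta2=0.999)
    best_state = None
    for epoch in range(spec.epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for lo in range(0, len(order), 8):
            sel = order[lo:lo + 8]
            feats = clf.backbone(Tensor(x_train[sel]))
            logits = clf.head(feats)
            loss = _cross_entropy(logits, y_train[sel])
            clf.backbone.zero_grad()
            clf.head.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_acc = float(
            (clf.logits(val_tiles).argmax(axis=1) == y_val).mean()
        )
        clf.history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                            "val_accuracy": val_acc})
        if np.isnan(clf.best_val_accuracy) or val_acc > clf.best_val_accuracy:
            clf.best_val_accuracy = val_acc
            clf.best_epoch = epoch
            best_state = [a.copy() for a in
                          clf.backbone.state_arrays() + clf.head.state_arrays()]
    if best_state is not None:
        nb = len(clf.backbone.state_arrays())
        clf.backbone.load_state_arrays(best_state[:nb])
        clf.head.load_state_arrays(best_state[nb:])


# ---------------------------------------------------------------------------
# splits, ROC, reports
# ---------------------------------------------------------------------------

def split_for_classifier(tile_manifest: pd.DataFrame,
                         ratio: tuple[int, int, int] = (6, 3, 1),
                         seed: int = 0) -> pd.Series:
    """6:3:1 train/test/validation split of the classifier tiles.

    Floor-based sizes: test = floor(0.3 N), validation = floor(0.1 N),
    train = remainder; one seeded global shuffle.
    """
    if len(tile_manifest) == 0:
        raise ConfigurationError("empty tile manifest")
    if tuple(ratio) != (6, 3, 1):
        raise ConfigurationError("only the 6:3:1 split is supported")
    n = len(tile_manifest)
    n_test = (3 * n) // 10
    n_val = n // 10
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    part = pd.Series(index=tile_manifest.index, dtype=object)
    part.iloc[order[:n_test]] = "test"
    part.iloc[order[n_test:n_test + n_val]] = "validation"
    part.iloc[order[n_test + n_val:]] = "train"
    return part


def roc_and_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points over all score thresholds plus trapezoidal AUC.

    Equal scores are grouped into a single threshold step; the curve is
    anchored at (0, 0) and (1, 1).  ``labels`` may be class names or
    already-binarized 0/1 values with cancer = 1.
    """
    labels = list(labels)
    if labels and isinstance(labels[0], str):
        y = _labels_to_indices(labels)
    else:
        y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, _ = skmetrics.roc_curve(y, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(skmetrics.auc(fpr, tpr))


@dataclass
class ValidationReport:
    roc_points: list[tuple[float, float]]
    auc: float
    activations: np.ndarray          # N x 512
    tsne_embedding: np.ndarray | None  # N x 2
    per_item: pd.DataFrame           # tile_id, score, label, predicted, correct
    contrast: str = ""
    trained_on: str = ""             # "real" | "synthetic"

    def validate(self) -> None:
        pts = np.asarray(self.roc_points)
        if (np.diff(pts[:, 0]) < -1e-12).any() or (np.diff(pts[:, 1]) < -1e-12).any():
            raise ValueError("ROC points must be monotone non-decreasing")
        if not (np.allclose(pts[0], (0, 0)) and np.allclose(pts[-1], (1, 1))):
            raise ValueError("ROC curve must be anchored at (0,0) and (1,1)")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC out of [0, 1]")

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "trained_on": self.trained_on,
            "auc": self.auc,
            "roc_points": [list(p) for p in self.roc_points],
            "n_items": int(len(self.per_item)),
            "accuracy": float(self.per_item["correct"].mean()),
        }


def build_validation_report(classifier: TrainedClassifier, tiles, labels,
                            tile_ids=None, contrast: str = "",
                            trained_on: str = "",
                            with_tsne: bool = False,
                            tsne_seed: int = 0) -> ValidationReport:
    """Score a test set and assemble the downstream-validation report."""
    scores = classifier.predict_scores(tiles)
    y = _labels_to_indices(labels)
    roc_points, auc = roc_and_auc(scores, list(labels))
    acts = extract_activations(classifier, tiles)
    predicted = (scores >= 0.5).astype(int)
    per_item = pd.DataFrame({
        "tile_id": tile_ids if tile_ids is not None else np.arange(len(scores)),
        "score": scores,
        "label": list(labels),
        "predicted": predicted,
        "correct": predicted == y,
    })
    emb = tsne_embed(acts, seed=tsne_seed) if with_tsne else None
    report = ValidationReport(roc_points=roc_points, auc=auc, activations=acts,
                              tsne_embedding=emb, per_item=per_item,
                              contrast=contrast, trained_on=trained_on)
    report.validate()
    return report


def compare_real_vs_synthetic(report_real: ValidationReport,
                              report_synthetic: ValidationReport) -> dict:
    """|AUC difference| and per-item agreement of two classifiers.

    Both reports must score the same test items (same ids and labels);
    agreement is the fraction of items assigned the same predicted
    class.
    """
    a, b = report_real.per_item, report_synthetic.per_item
    if len(a) != len(b) or not (a["tile_id"].values == b["tile_id"].values).all() \
            or not (a["label"].values == b["label"].values).all():
        raise ValueError("reports must share an identical test set")
    return {
        "auc_real": report_real.auc,
        "auc_synthetic": report_synthetic.auc,
        "delta_auc": abs(report_real.auc - report_synthetic.auc),
        "agreement": float((a["predicted"].values == b["predicted"].values).mean()),
    }


# ---------------------------------------------------------------------------
# t-SNE
# ---------------------------------------------------------------------------

def conditional_probabilities(x: np.ndarray, perplexity: float,
                              tol: float = 1e-6, max_iter: int = 64,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-point Gaussian conditional distributions at a fixed perplexity.

    For each point the kernel bandwidth (precision ``beta``) is found by
    binary search so that the Shannon entropy of the conditional
    distribution equals ``log(perplexity)`` (natural log).  Returns the
    row-conditional matrix P (rows sum to 1, zero diagonal) and betas.
    """
    n = len(x)
    d2 = skmetrics.pairwise_distances(x, metric="sqeuclidean")
    target = np.log(perplexity)
    p = np.zeros((n, n))
    betas = np.ones(n)
    for i in range(n):
        lo, hi = 0.0, np.inf
        beta = 1.0
        di = np.delete(d2[i], i)
        for _ in range(max_iter):
            w = np.exp(-di * beta)
            sw = w.sum()
            if sw <= 0:
                h = 0.0
                pi = np.zeros_like(w)
            else:
                pi = w / sw
                nz = pi > 0
                h = float(-(pi[nz] * np.log(pi[nz])).sum())
            if abs(h - target) < tol:
                break
            if h > target:      # too flat -> narrow the kernel
                lo = beta
                beta = beta * 2 if not np.isfinite(hi) else (lo + hi) / 2
            else:
                hi = beta
                beta = (lo + hi) / 2
        betas[i] = beta
        p[i, np.arange(n) != i] = pi
    return p, betas


def tsne_embed(activations: np.ndarray, perplexity: float = 30.0,
               seed: int = 0, n_iter: int = 600,
               learning_rate: float | str = "auto",
               return_details: bool = False):
    """Exact t-SNE embedding to 2-D (Euclidean metric, random init).

    Standard formulation: binary-search perplexity calibration,
    symmetrized affinities, early exaggeration (factor 12 for the first
    100 iterations), gradient descent with momentum 0.5 -> 0.8 (switch
    at iteration 250) and adaptive per-coordinate gains.  The default
    ``learning_rate="auto"`` is ``max(N / 12, 50)`` (large fixed rates
    overshoot on small point sets).  The KL divergence is recorded
    every 25 iterations once exaggeration ends.
    """
    x = np.asarray(activations, dtype=np.float64)
    n = len(x)
    if n < 5:
        raise ValueError("t-SNE needs at least 5 points")
    if n - 1 < 3 * perplexity:
        new_perp = max((n - 1) / 3.0, 2.0)
        warnings.warn(
            f"perplexity {perplexity} too large for {n} points; "
            f"reduced to {new_perp:.1f}"
        )
        perplexity = new_perp
    if learning_rate == "auto":
        learning_rate = max(n / 12.0, 50.0)
    rng = np.random.default_rng(seed)
    p_cond, _ = conditional_probabilities(x, perplexity)
    p = (p_cond + p_cond.T) / (2.0 * n)
    p = np.maximum(p, 1e-12)

    y = rng.normal(0.0, 1e-4, size=(n, 2))
    dy = np.zeros_like(y)
    gains = np.ones_like(y)
    exaggeration_until = 100
    kl_history: list[tuple[int, float]] = []

    for it in range(n_iter):
        pe = p * 12.0 if it < exaggeration_until else p
        num = 1.0 / (1.0 + skmetrics.pairwise_distances(y, metric="sqeuclidean"))
        np.fill_diagonal(num, 0.0)
        q = np.maximum(num / num.sum(), 1e-12)
        pq = (pe - q) * num
        grad = 4.0 * ((np.diag(pq.sum(axis=1)) - pq) @ y)
        momentum = 0.5 if it < 250 else 0.8
        gains = np.where(np.sign(grad) != np.sign(dy), gains + 0.2, gains * 0.8)
        gains = np.maximum(gains, 0.01)
        dy = momentum * dy - learning_rate * gains * grad
        y = y + dy
        y = y - y.mean(axis=0)
        if it >= exaggeration_until and (it - exaggeration_until) % 25 == 0:
            kl = float((p * np.log(p / q)).sum())
            kl_history.append((it, kl))
    if return_details:
        return y, {"kl_history": kl_history, "perplexity": perplexity}
    return y
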