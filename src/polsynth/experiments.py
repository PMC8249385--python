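"""Desk-scale experiments exercising the full method.

These runners reproduce, at reduced problem sizes, the study design:
dataset bookkeeping arithmetic, simulator noise properties, GAN
recovery of a known smooth mapping, the SSIM-loss ablation, the full
phantom -> GAN -> classifier chain with masked-SSIM evaluation and
ROC/AUC comparison, and t-SNE diagnostics.  Problem sizes are
parameters with defaults chosen so each experiment runs in minutes on
one CPU; every stochastic element is driven by the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from . import classify, evaluation, gan, phantom, preprocess, tasks

__all__ = [
    "dataset_arithmetic",
    "noise_asymmetry",
    "recovery_experiment",
    "ablation_experiment",
    "end_to_end_experiment",
    "tsne_diagnostics",
]


def dataset_arithmetic(n_frames: int = 22072, n_cancer_cases: int = 7,
                       n_normal_cases: int = 4, seed: int = 0) -> dict:
    """Tiling and split arithmetic at the full study scale.

    Pure manifest bookkeeping (no pixels are generated): ``n_frames``
    frames are assigned round-robin to cases, expanded to two tiles per
    frame, and split 8:1:1 image-based.
    """
    n_cancer = n_frames // 2 + n_frames % 2
    n_normal = n_frames // 2
    rows = []
    for label, count, n_cases in (("cancer", n_cancer, n_cancer_cases),
                                  ("normal", n_normal, n_normal_cases)):
        for i in range(count):
            rows.append({"frame_id": f"{label}_{i:06d}",
                         "case_id": f"{label}_case_{i % n_cases}",
                         "label": label})
    frame_manifest = pd.DataFrame(rows)
    tile_manifest = preprocess.plan_tiles(frame_manifest)
    split = preprocess.assign_splits(tile_manifest, strategy="image_based",
                                     seed=seed)
    counts = split.counts()
    return {
        "n_frames": len(frame_manifest),
        "n_tiles_per_channel": len(tile_manifest),
        "n_test_tiles": counts["test"],
        "n_validation_tiles": counts["validation"],
        "n_train_tiles": counts["train"],
    }


def noise_asymmetry(n_frames: int = 100, seed: int = 0,
                    config: phantom.PhantomConfig | None = None) -> dict:
    """Fraction of frames whose retardation map is noisier than DOPU.

    Spatial noise is the standard deviation of the high-pass residual
    (image minus its 3x3 clipped-window mean), with both channels on
    their natural [0, 1] scales (retardation divided by pi/2).
    """
    config = config or phantom.PhantomConfig()
    rng = np.random.default_rng(seed)
    noisier = 0
    for i in range(n_frames):
        label = "cancer" if i % 2 == 0 else "normal"
        frame = phantom.generate_frame(config, label, rng,
                                       frame_id=f"noise_{i}")
        n_ret = _highpass_std(frame.retardation / (np.pi / 2))
        n_dopu = _highpass_std(frame.dopu)
        noisier += n_ret > n_dopu
    return {"n_frames": n_frames,
            "fraction_retardation_noisier": noisier / n_frames}


def _highpass_std(img: np.ndarray) -> float:
    smooth = phantom._clipped_window_mean(img, 3)
    return float(np.std(img - smooth))


def _scaled_specs(base_channels: int = 16):
    return (gan.GeneratorSpec(depth=3, base_channels=base_channels),
            gan.DiscriminatorSpec(base_channels=base_channels))


def recovery_experiment(n_tiles: int = 200, n_val: int = 20, epochs: int = 8,
                        tile_side: int = 32, seed: int = 0,
                        lambda_ssim: float = 10.0) -> dict:
    """Train the GAN on the smooth-mapping task and report validation SSIM."""
    pairs = tasks.make_recovery_pairs(n_tiles=n_tiles, tile_side=tile_side,
                                      seed=seed)
    train, val = pairs[:-n_val], pairs[-n_val:]
    gspec, dspec = _scaled_specs()
    cfg = gan.TrainConfig(learning_rate=2e-4, epochs=epochs, seed=seed)
    bundle = gan.train_gan(train, val, gspec, dspec,
                           gan.LossWeights(lambda_ssim=lambda_ssim), cfg)
    return {
        "best_val_masked_ssim": bundle.best_val_ssim,
        "best_epoch": bundle.best_epoch,
        "n_train": len(train),
        "n_val": len(val),
        "epochs": epochs,
        "history": bundle.history,
    }


def ablation_experiment(n_tiles: int = 140, n_val: int = 20, epochs: int = 6,
                        seeds: tuple = (0, 1, 2), seed: int = 0) -> dict:
    """Paired SSIM-loss ablation: lambda_ssim = 10 vs 0 at matched seeds.

    Returns the per-seed best-validation-SSIM gain of the augmented
    objective over the plain adversarial + L1 objective, and its median.
    """
    pairs = tasks.make_recovery_pairs(n_tiles=n_tiles, seed=seed)
    train, val = pairs[:-n_val], pairs[-n_val:]
    gspec, dspec = _scaled_specs()
    gains = []
    for s in seeds:
        run_seed = (seed * 1000 + s) % (2**31)
        best = {}
        for lam in (10.0, 0.0):
            cfg = gan.TrainConfig(learning_rate=2e-4, epochs=epochs,
                                  seed=run_seed)
            bundle = gan.train_gan(train, val, gspec, dspec,
                                   gan.LossWeights(lambda_ssim=lam), cfg)
            best[lam] = bundle.best_val_ssim
        gains.append(best[10.0] - best[0.0])
    return {"gains": gains, "median_gain": float(np.median(gains)),
            "epochs": epochs, "n_train": len(train)}


def end_to_end_experiment(n_frames_per_class: int = 160,
                          n_gan_tiles: int = 166, n_gan_val: int = 16,
                          gan_epochs: int = 12, classifier_epochs: int = 24,
                          tile_side: int = 32, seed: int = 0,
                          contrasts: tuple = ("dopu", "retardation")) -> dict:
    """Phantom -> GAN -> classifiers, mirroring the full study design.

    Disjoint frame sets feed GAN training and the classifier stage.
    Per contrast: a GAN is trained on (intensity, contrast) pairs, the
    classifier tiles are synthesized from intensity alone, masked SSIM
    compares real and synthetic tiles, and two classifiers (trained on
    real and on synthetic tiles) are compared on the same test
    positions — the real-trained one tested on real tiles, the
    synthetic-trained one on synthetic tiles of the same frames.
    """
    records = tasks.make_phantom_tile_set(n_frames_per_class,
                                          tile_side=tile_side, seed=seed)
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(len(records))
    gan_idx = order[:n_gan_tiles]
    clf_idx = order[n_gan_tiles:]
    clf_records = [records[i] for i in clf_idx]
    clf_manifest = pd.DataFrame({"tile_id": [r["tile_id"] for r in clf_records],
                                 "label": [r["label"] for r in clf_records]})
    part = classify.split_for_classifier(clf_manifest, seed=seed)
    sel = {p: [r for r, q in zip(clf_records, part) if q == p]
           for p in ("train", "validation", "test")}

    out: dict = {"n_classifier_tiles": len(clf_records),
                 "n_gan_train": n_gan_tiles - n_gan_val}
    for contrast in contrasts:
        pairs = [(records[i]["intensity"], records[i][contrast])
                 for i in gan_idx]
        gspec, dspec = _scaled_specs()
        cfg = gan.TrainConfig(learning_rate=2e-4, epochs=gan_epochs,
                              seed=seed, contrast_target=contrast)
        bundle = gan.train_gan(pairs[:-n_gan_val], pairs[-n_gan_val:],
                               gspec, dspec, gan.LossWeights(), cfg)
        # synthesize with the final generator: with noisy targets the
        # masked-SSIM-selected checkpoint favors oversmoothed early epochs
        # that carry little class information
        gen = bundle.generator
        synth = {r["tile_id"]: gan.synthesize(gen, r["intensity"])
                 for r in clf_records}

        test_recs = sel["test"]
        eval_report = evaluation.evaluate_dataset(
            [r[contrast].astype(np.float64) for r in test_recs],
            [synth[r["tile_id"]] for r in test_recs],
            [r["intensity"] for r in test_recs],
            threshold=evaluation.DEFAULT_INTENSITY_THRESHOLD,
            contrast=contrast,
        )

        reports = {}
        for source in ("real", "synthetic"):
            def tile_of(r):
                return (r[contrast] if source == "real"
                        else synth[r["tile_id"]])
            clf = classify.train_classifier(
                [tile_of(r) for r in sel["train"]],
                [r["label"] for r in sel["train"]],
                [tile_of(r) for r in sel["validation"]],
                [r["label"] for r in sel["validation"]],
                classify.ClassifierSpec(epochs=classifier_epochs),
                seed=seed,
            )
            reports[source] = classify.build_validation_report(
                clf, [tile_of(r) for r in test_recs],
                [r["label"] for r in test_recs],
                tile_ids=[r["tile_id"] for r in test_recs],
                contrast=contrast, trained_on=source,
            )
        comparison = classify.compare_real_vs_synthetic(reports["real"],
                                                        reports["synthetic"])
        emb = classify.tsne_embed(reports["real"].activations, seed=seed)
        labels01 = [1 if r["label"] == "cancer" else 0 for r in test_recs]
        out[contrast] = {
            "masked_ssim_mean": eval_report.mean,
            "masked_ssim_std": eval_report.std,
            "auc_real": comparison["auc_real"],
            "auc_synthetic": comparison["auc_synthetic"],
            "delta_auc": comparison["delta_auc"],
            "agreement": comparison["agreement"],
            "tsne_silhouette": float(silhouette_score(emb, labels01)),
            "n_test": len(test_recs),
        }
    return out


def tsne_diagnostics(n_per_cluster: int = 50, dim: int = 512,
                     separation: float = 12.0, perplexity: float = 30.0,
                     seed: int = 0) -> dict:
    """Perplexity calibration and cluster preservation on synthetic data.

    Two far-separated Gaussian clusters in ``dim`` dimensions; reports
    the worst per-point deviation of the conditional-distribution
    entropy from log(perplexity) and the silhouette score of the 2-D
    embedding against the true cluster labels.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_cluster, dim))
    b = rng.normal(0.0, 1.0, size=(n_per_cluster, dim))
    b[:, 0] += separation
    x = np.vstack([a, b])
    labels = np.array([0] * n_per_cluster + [1] * n_per_cluster)
    eff_perp = min(perplexity, max((len(x) - 1) / 3.0, 2.0))
    p_cond, _ = classify.conditional_probabilities(x, eff_perp)
    entropies = np.array([
        -np.sum(row[row > 0] * np.log(row[row > 0])) for row in p_cond
    ])
    emb, details = classify.tsne_embed(x, perplexity=perplexity, seed=seed,
                                       return_details=True)
    kls = [kl for _, kl in details["kl_history"]]
    return {
        "max_entropy_error": float(np.abs(entropies - np.log(eff_perp)).max()),
        "silhouette": float(silhouette_score(emb, labels)),
        "kl_history": kls,
        # momentum descent oscillates at the 1e-4 level near convergence
        "kl_monotone": bool(np.all(np.diff(kls) <= 1e-3)),
        "effective_perplexity": eff_perp,
    }
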