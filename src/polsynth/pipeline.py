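"""End-to-end orchestration: simulate -> preprocess -> GANs -> evaluate
-> downstream classification -> t-SNE.

Each stage writes its artifacts (plus the config and derived seed)
under ``output_root`` and is skipped on rerun when its completion
marker exists, so a run is resumable per stage.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, evaluation, gan, phantom, preprocess
from .io import (CHANNEL_SCALES, RunConfig, derive_seed, load_manifest,
                 read_image, save_json, save_manifest, scale_to_uint16,
                 write_image)

__all__ = ["run_pipeline"]

log = logging.getLogger("polsynth")

CHANNELS = ("intensity", "dopu", "retardation")
CONTRASTS = ("dopu", "retardation")


def _done(stage_dir: Path) -> bool:
    return (stage_dir / ".done").exists()


def _mark_done(stage_dir: Path) -> None:
    (stage_dir / ".done").touch()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the artifact directory."""
    root = Path(config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    config.to_yaml(root / "config.yaml")
    try:
        stage_simulate(config, root)
        stage_preprocess(config, root)
        for contrast in config.validate.contrasts:
            stage_train_gan(config, root, contrast)
        stage_evaluate(config, root)
        stage_validate(config, root)
    except Exception as err:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed: {err}") from err
    return root


def stage_simulate(config: RunConfig, root: Path) -> Path:
    out = root / "phantom"
    if _done(out):
        log.info("simulate: reusing existing artifacts")
        return out
    seed = derive_seed(config.global_seed, "phantom")
    pconf = dataclasses.replace(config.phantom.phantom, rng_seed=seed)
    frames, manifest = phantom.generate_dataset(
        pconf, config.phantom.n_frames_per_class,
        config.phantom.n_cases_per_class)
    rows = []
    for frame in frames:
        paths = {}
        for channel in CHANNELS:
            vmin, vmax = CHANNEL_SCALES[channel]
            arr = getattr(frame, channel)
            img16 = arr if channel == "intensity" else scale_to_uint16(
                arr, vmin, vmax)
            p = out / channel / f"{frame.frame_id}.tiff"
            write_image(p, img16, bit_depth=16)
            paths[f"path_{channel}"] = str(p.relative_to(root))
        rows.append({"frame_id": frame.frame_id, "case_id": frame.case_id,
                     "label": frame.label, **paths,
                     "scale_dopu_min": 0.0, "scale_dopu_max": 1.0,
                     "scale_retardation_min": 0.0,
                     "scale_retardation_max": float(np.pi / 2)})
    save_manifest(pd.DataFrame(rows), out / "manifest.csv")
    _mark_done(out)
    log.info("simulate: wrote %d frames", len(frames))
    return out


def stage_preprocess(config: RunConfig, root: Path) -> Path:
    out = root / "tiles"
    if _done(out):
        log.info("preprocess: reusing existing artifacts")
        return out
    seed = derive_seed(config.global_seed, "preprocess")
    frame_manifest = load_manifest(root / "phantom" / "manifest.csv")
    tile_manifest = preprocess.plan_tiles(frame_manifest)
    side = config.preprocess.tile_side
    paths: dict[str, dict[str, str]] = {}
    for _, fr in frame_manifest.iterrows():
        ref = read_image(root / fr["path_intensity"])
        # the margin window is found on intensity and applied to all three
        # co-registered channels
        for channel in CHANNELS:
            img = read_image(root / fr[f"path_{channel}"])
            cropped = _apply_same_crop(ref, img, config.preprocess.margin_threshold)
            tiles = preprocess.split_into_tiles(cropped, tile_side=side,
                                                frame_id=fr["frame_id"],
                                                channel=channel)
            for tile in tiles:
                img8 = preprocess.convert_to_8bit(tile.image)
                p = out / channel / f"{tile.parent_frame_id}_{tile.half}.png"
                write_image(p, img8, bit_depth=8)
                paths.setdefault(f"{tile.parent_frame_id}_{tile.half}", {})[
                    f"path_{channel}"] = str(p.relative_to(root))
    for channel in CHANNELS:
        tile_manifest[f"path_{channel}"] = [
            paths[t][f"path_{channel}"] for t in tile_manifest["tile_id"]]
    split = preprocess.assign_splits(tile_manifest,
                                     strategy=config.preprocess.split_strategy,
                                     seed=seed)
    tile_manifest["partition"] = split.partition.values
    save_manifest(tile_manifest, out / "tile_manifest.csv")
    _mark_done(out)
    log.info("preprocess: wrote %d tile triples", len(tile_manifest))
    return out


def _apply_same_crop(ref: np.ndarray, img: np.ndarray,
                     margin_threshold: float) -> np.ndarray:
    thr = margin_threshold * float(ref.max())
    rows = np.flatnonzero(ref.mean(axis=1) >= thr)
    cols = np.flatnonzero(ref.mean(axis=0) >= thr)
    return img[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]


def _load_pairs(root: Path, manifest: pd.DataFrame, contrast: str):
    return [
        (read_image(root / r["path_intensity"]),
         read_image(root / r[f"path_{contrast}"]))
        for _, r in manifest.iterrows()
    ]


def stage_train_gan(config: RunConfig, root: Path, contrast: str) -> Path:
    out = root / f"gan_{contrast}"
    if _done(out):
        log.info("train-gan[%s]: reusing existing artifacts", contrast)
        return out
    seed = derive_seed(config.global_seed, f"gan_{contrast}")
    manifest = load_manifest(root / "tiles" / "tile_manifest.csv")
    train = _load_pairs(root, manifest[manifest.partition == "train"], contrast)
    val = _load_pairs(root, manifest[manifest.partition == "validation"],
                      contrast)
    g = config.gan
    bundle = gan.train_gan(
        train, val,
        gan.GeneratorSpec(depth=g.depth, base_channels=g.base_channels),
        gan.DiscriminatorSpec(base_channels=g.disc_base_channels),
        gan.LossWeights(g.lambda_adv, g.lambda_l1, g.lambda_ssim),
        gan.TrainConfig(learning_rate=g.learning_rate, epochs=g.epochs,
                        seed=seed, contrast_target=contrast,
                        val_mask_threshold=config.evaluate.threshold),
    )
    out.mkdir(parents=True, exist_ok=True)
    bundle.save(out / "model.npz")
    save_json(out / "history.json", bundle.history)
    # synthesize the GAN test partition with the final generator (the
    # best-masked-SSIM checkpoint stays available inside the bundle)
    gen = bundle.generator
    for _, r in manifest[manifest.partition == "test"].iterrows():
        synth = gan.synthesize(gen, read_image(root / r["path_intensity"]))
        write_image(out / "synthetic" / f"{r['tile_id']}.png",
                    np.round(synth).astype(np.uint8), bit_depth=8)
    _mark_done(out)
    return out


def stage_evaluate(config: RunConfig, root: Path) -> Path:
    out = root / "evaluation"
    if _done(out):
        log.info("evaluate: reusing existing artifacts")
        return out
    manifest = load_manifest(root / "tiles" / "tile_manifest.csv")
    test = manifest[manifest.partition == "test"]
    results = {}
    for contrast in config.validate.contrasts:
        reals, synths, intens = [], [], []
        for _, r in test.iterrows():
            reals.append(read_image(root / r[f"path_{contrast}"]))
            synths.append(read_image(
                root / f"gan_{contrast}" / "synthetic" / f"{r['tile_id']}.png"))
            intens.append(read_image(root / r["path_intensity"]))
        report = evaluation.evaluate_dataset(
            reals, synths, intens, threshold=config.evaluate.threshold,
            contrast=contrast)
        results[contrast] = report.to_dict()
        overlay = evaluation.render_overlay(intens[0], synths[0],
                                            config.evaluate.threshold)
        write_image(out / f"overlay_{contrast}.png", overlay, bit_depth=8)
    save_json(out / "eval_report.json", results)
    _mark_done(out)
    return out


def stage_validate(config: RunConfig, root: Path) -> Path:
    out = root / "validation"
    if _done(out):
        log.info("validate: reusing existing artifacts")
        return out
    seed = derive_seed(config.global_seed, "validate")
    tsne_seed = derive_seed(config.global_seed, "tsne")
    manifest = load_manifest(root / "tiles" / "tile_manifest.csv")
    test = manifest[manifest.partition == "test"].reset_index(drop=True)
    part = classify.split_for_classifier(test, seed=seed)
    summary = {}
    for contrast in config.validate.contrasts:
        real = {r["tile_id"]: read_image(root / r[f"path_{contrast}"])
                for _, r in test.iterrows()}
        synth = {r["tile_id"]: read_image(
            root / f"gan_{contrast}" / "synthetic" / f"{r['tile_id']}.png")
            for _, r in test.iterrows()}
        reports = {}
        for source, images in (("real", real), ("synthetic", synth)):
            sel = {p: test[part == p] for p in ("train", "validation", "test")}
            clf = classify.train_classifier(
                [images[t] for t in sel["train"].tile_id],
                list(sel["train"].label),
                [images[t] for t in sel["validation"].tile_id],
                list(sel["validation"].label),
                classify.ClassifierSpec(epochs=config.validate.epochs),
                seed=seed,
            )
            reports[source] = classify.build_validation_report(
                clf, [images[t] for t in sel["test"].tile_id],
                list(sel["test"].label), tile_ids=list(sel["test"].tile_id),
                contrast=contrast, trained_on=source, with_tsne=True,
                tsne_seed=tsne_seed,
            )
        comparison = classify.compare_real_vs_synthetic(reports["real"],
                                                        reports["synthetic"])
        summary[contrast] = {
            "real": reports["real"].to_dict(),
            "synthetic": reports["synthetic"].to_dict(),
            "comparison": comparison,
        }
        _plot_validation(out, contrast, reports)
    save_json(out / "validation_report.json", summary)
    _mark_done(out)
    return out


def _plot_validation(out: Path, contrast: str, reports: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 4))
    for source, report in reports.items():
        pts = np.asarray(report.roc_points)
        ax.plot(pts[:, 0], pts[:, 1],
                label=f"{source} (AUC={report.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.5)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.set_title(f"{contrast} classifiers")
    ax.legend()
    fig.savefig(out / f"roc_{contrast}.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, (source, report) in zip(axes, reports.items()):
        emb = report.tsne_embedding
        labels = np.asarray(report.per_item["label"])
        for lab, color in (("normal", "tab:blue"), ("cancer", "tab:red")):
            m = labels == lab
            ax.scatter(emb[m, 0], emb[m, 1], s=8, c=color, label=lab)
        ax.set_title(f"{contrast} / {source}")
        ax.legend()
    fig.savefig(out / f"tsne_{contrast}.png", dpi=120)
    plt.close(fig)
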