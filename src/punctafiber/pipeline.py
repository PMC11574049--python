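"""End-to-end orchestration: simulate -> train -> segment -> quantify -> compare.

Each stage reads only the artifacts of its upstream stages from the working
directory, so any stage can be re-run in isolation. Every artifact gets a
``.prov.json`` sidecar recording the config hash, seed, and stage, and the
whole run is deterministic for a fixed (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import binary_erosion

from . import __version__
from .config import config_hash, validate_config
from .imaging_io import BinaryMask, ChannelImage, read_mask, write_mask
from .quantify import quantify_batch
from .segmentation import load_classifier, save_classifier, segment, train_classifier
from .stats import build_report
from .synthetic import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "train", "segment", "quantify", "compare")

__all__ = ["STAGES", "run", "StageError"]


class StageError(RuntimeError):
    """A stage could not run; the message names the stage to run first."""


def _sidecar(path: Path, config: dict, stage: str) -> None:
    prov = {
        "artifact": path.name,
        "stage": stage,
        "config_sha256": config_hash(config),
        "seed": config["seed"],
        "punctafiber_version": __version__,
    }
    with open(path.with_suffix(path.suffix + ".prov.json"), "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageError(
            f"missing artifact {path.name}: run the '{producer}' stage first"
        )
    return path


def _training_strokes(mask: np.ndarray, rng: np.random.Generator, n_per_class: int = 400):
    """Sparse stroke labels sampled from an eroded truth mask and its eroded
    complement (keeps strokes off the ambiguous boundary)."""
    fiber_core = binary_erosion(mask, iterations=1) if mask.any() else mask
    bg_core = binary_erosion(~mask, iterations=2)
    fiber_stroke = np.zeros_like(mask)
    bg_stroke = np.zeros_like(mask)
    for core, stroke in ((fiber_core, fiber_stroke), (bg_core, bg_stroke)):
        idx = np.argwhere(core)
        if len(idx):
            pick = idx[rng.choice(len(idx), size=min(n_per_class, len(idx)), replace=False)]
            stroke[pick[:, 0], pick[:, 1]] = True
    return fiber_stroke, bg_stroke


def run(config: dict, stages: list[str] | None = None, workdir: str | Path | None = None) -> dict:
    """Execute the requested stages in dependency order; returns a map of
    stage name -> primary artifact path."""
    config = validate_config(config)
    stages = list(stages) if stages else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}; valid stages: {STAGES}")
    stages = [s for s in STAGES if s in stages]

    workdir = Path(workdir or config["workdir"])
    workdir.mkdir(parents=True, exist_ok=True)
    data_dir = workdir / "data"
    seg_dir = workdir / "segmentation"
    artifacts: dict[str, Path] = {}
    px = config["pixel_size_um"]
    sim = config["simulate"]
    seg_cfg = config["segmentation"]

    if "simulate" in stages:
        spec = SyntheticSpec(
            image_shape=tuple(sim["image_shape"]),
            n_fibers=sim["n_fibers"],
            fiber_thickness_px=sim["fiber_thickness_px"],
            fiber_amplitude=sim["fiber_amplitude"],
            n_puncta_on=sim["n_puncta_on"],
            n_puncta_off=sim["n_puncta_off"],
            punctum_sigma_px=sim["punctum_sigma_px"],
            punctum_amplitude=sim["punctum_amplitude"],
            background_level=sim["background_level"],
            noise_sd=sim["noise_sd"],
            pixel_size_um=px,
        )
        specs = [spec] * sim["n_images"]
        generate_dataset(specs, data_dir, master_seed=config["seed"])
        artifacts["simulate"] = data_dir / "manifest.json"
        _sidecar(artifacts["simulate"], config, "simulate")
        logger.info("simulate: wrote %d image(s) to %s", sim["n_images"], data_dir)

    manifest_path = data_dir / "manifest.json"
    model_path = workdir / "classifier.joblib"

    if "train" in stages:
        _require(manifest_path, "simulate")
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        n_train = min(seg_cfg["n_train_images"], len(manifest["images"]))
        if n_train == 0:
            raise StageError("no images available for training: run 'simulate' first")
        rng = np.random.default_rng(config["seed"])
        images, labels = [], []
        for rec in manifest["images"][:n_train]:
            img = ChannelImage(
                tifffile.imread(data_dir / rec["files"]["pgp95"]),
                channel_name="PGP9.5",
                pixel_size_um=px,
            )
            truth = read_mask(data_dir / rec["files"]["truth_mask"], pixel_size_um=px)
            fiber_stroke, bg_stroke = _training_strokes(truth.pixels, rng)
            images.append(img)
            labels.append((BinaryMask(fiber_stroke, px), BinaryMask(bg_stroke, px)))
        clf = train_classifier(
            images,
            labels,
            scales=tuple(seg_cfg["scales"]),
            n_trees=seg_cfg["n_trees"],
            seed=config["seed"],
        )
        save_classifier(clf, model_path)
        artifacts["train"] = model_path
        _sidecar(model_path, config, "train")
        logger.info("train: fitted classifier on %d image(s)", n_train)

    if "segment" in stages:
        _require(manifest_path, "simulate")
        _require(model_path, "train")
        clf = load_classifier(model_path)
        seg_dir.mkdir(exist_ok=True)
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        for rec in manifest["images"]:
            img = ChannelImage(
                tifffile.imread(data_dir / rec["files"]["pgp95"]),
                channel_name="PGP9.5",
                pixel_size_um=px,
            )
            result = segment(
                img,
                clf,
                threshold=seg_cfg["prob_threshold"],
                min_object_px=seg_cfg["min_object_px"],
            )
            write_mask(result.mask, seg_dir / f"{rec['image_id']}_rf_mask.tif")
        artifacts["segment"] = seg_dir
        _sidecar(seg_dir / "masks", config, "segment")
        logger.info("segment: wrote %d mask(s)", len(manifest["images"]))

    quant_path = workdir / "quantification.csv"
    if "quantify" in stages:
        _require(manifest_path, "simulate")
        backends: dict[str, object] = {"truth": "truth"}
        if seg_cfg["backend"] == "rf":
            _require(seg_dir, "segment")

            def _rf_mask(image_id: str) -> BinaryMask:
                return read_mask(seg_dir / f"{image_id}_rf_mask.tif", pixel_size_um=px)

            backends["rf"] = _rf_mask
        table = quantify_batch(
            manifest_path,
            backends,
            threshold=config["threshold"],
            out_csv=quant_path,
        )
        artifacts["quantify"] = quant_path
        _sidecar(quant_path, config, "quantify")
        logger.info(
            "quantify: %d row(s), %d failure(s)", len(table), len(table.attrs["failures"])
        )

    if "compare" in stages:
        _require(quant_path, "quantify")
        table = pd.read_csv(quant_path)
        report = build_report(table)
        report_path = workdir / "report.json"
        report.to_json(report_path)
        artifacts["compare"] = report_path
        _sidecar(report_path, config, "compare")
        logger.info("compare: report for %d image(s)", report.n_images)

    return {k: str(v) for k, v in artifacts.items()}
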