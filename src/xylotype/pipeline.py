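"""End-to-end orchestration: generate -> split -> patch -> train -> evaluate.

One :class:`~xylotype.config.RunConfig` drives every stage; the run
directory is named by the config hash so semantically identical configs
reuse (or reproduce) the same outputs. Stages are resumable: a stage whose
outputs already exist under the run directory is loaded instead of rerun.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from xylotype.config import RunConfig
from xylotype.dataset import (
    PatchManifest,
    PatchSpec,
    SplitSpec,
    build_patch_manifest,
    genus_subset_from_species_patches,
    load_patch_arrays,
    split_images,
)
from xylotype.estimator import WoodPatchCNN
from xylotype.evaluation import club_to_genus, evaluate_model, render_report
from xylotype.synthetic import (
    build_synthetic_dataset,
    meliaceae10_specs,
    meliaceae10_split_fractions,
    three_class_demo_specs,
)

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger("xylotype")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _dataset_specs(config: RunConfig):
    ds = config.dataset
    if ds.preset == "meliaceae10":
        specs, imaging, taxonomy = meliaceae10_specs(
            scale=ds.scale, image_size=ds.image_size
        )
        fractions = meliaceae10_split_fractions()
    else:
        twins = ds.preset == "three_class_twins"
        n = max(2, round(12 * ds.scale / 0.1))
        specs, imaging, taxonomy = three_class_demo_specs(
            twins=twins, n_images=n, image_size=ds.image_size
        )
        fractions = None
    return specs, imaging, taxonomy, fractions


def _patch_spec(config: RunConfig) -> PatchSpec:
    p = config.patch
    return PatchSpec(
        patch_height=p.patch_height,
        patch_width=p.patch_width,
        resized_height=p.resized_height,
        resized_width=p.resized_width,
        train_quota_per_class=p.train_quota_per_class,
        test_quota_per_class=p.test_quota_per_class,
    )


def _stage(name):
    """Decorator: wrap stage failures with the stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("generate")
def _generate(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    manifest_path = run_dir / "images" / "manifest.csv"
    if config.dataset.image_dir:
        external = Path(config.dataset.image_dir) / "manifest.csv"
        logger.info("generate: using external image dir %s", external.parent)
        return pd.read_csv(external)
    if manifest_path.exists():
        logger.info("generate: resuming from %s", manifest_path)
        return pd.read_csv(manifest_path)
    specs, imaging, _, _ = _dataset_specs(config)
    logger.info(
        "generate: preset=%s scale=%s image_size=%d n_images=%d",
        config.dataset.preset,
        config.dataset.scale,
        config.dataset.image_size,
        sum(s.n_images for s in specs),
    )
    build_synthetic_dataset(
        specs, imaging, config.stage_seed("generate"), run_dir / "images"
    )
    return pd.read_csv(manifest_path)


@_stage("split")
def _split(config: RunConfig, run_dir: Path, images: pd.DataFrame) -> pd.DataFrame:
    out = run_dir / "images_split.csv"
    if out.exists():
        logger.info("split: resuming from %s", out)
        return pd.read_csv(out)
    _, _, _, fractions = _dataset_specs(config)
    fraction = (
        fractions
        if config.split.train_fraction == "preset" and fractions is not None
        else (
            0.6
            if config.split.train_fraction == "preset"
            else float(config.split.train_fraction)
        )
    )
    spec = SplitSpec(
        train_fraction=fraction,
        stratify_by=config.split.stratify_by,
        unit=config.split.unit,
        seed=config.stage_seed("split"),
    )
    tagged = split_images(images, spec)
    counts = tagged.groupby("split").size().to_dict()
    logger.info("split: unit=%s counts=%s", config.split.unit, counts)
    tagged.to_csv(out, index=False)
    return tagged


@_stage("patch")
def _patch(
    config: RunConfig, run_dir: Path, tagged: pd.DataFrame, taxonomy
) -> dict[str, PatchManifest]:
    spec = _patch_spec(config)
    paths = {
        "species": run_dir / "patch_manifest_species.csv",
        "genus": run_dir / "patch_manifest_genus.csv",
    }
    if all(p.exists() for p in paths.values()):
        logger.info("patch: resuming from existing manifests")
        return {
            level: PatchManifest.from_csv(path, spec, level)
            for level, path in paths.items()
        }
    species = build_patch_manifest(
        tagged, taxonomy, spec, "species", seed=config.stage_seed("patch")
    )
    genus = genus_subset_from_species_patches(
        species, taxonomy, seed=config.stage_seed("patch_genus")
    )
    species.to_csv(paths["species"])
    genus.to_csv(paths["genus"])
    logger.info(
        "patch: species rows=%d genus rows=%d quotas=%d/%d",
        len(species.rows),
        len(genus.rows),
        spec.train_quota_per_class,
        spec.test_quota_per_class,
    )
    return {"species": species, "genus": genus}


@_stage("train")
def _train(
    config: RunConfig,
    run_dir: Path,
    manifest: PatchManifest,
    level: str,
) -> WoodPatchCNN:
    tr = config.training
    clf = WoodPatchCNN(
        backbone=config.model.backbone,
        pooling=config.model.pooling,
        dropout=config.model.dropout,
        batch_size=tr.batch_size,
        phase1_epochs=tr.phase1.max_epochs,
        phase1_lr=tr.phase1.learning_rate,
        phase1_momentum=tr.phase1.momentum,
        phase2_epochs=tr.phase2.max_epochs,
        phase2_lr=tr.phase2.learning_rate,
        phase2_decay=tr.phase2.decay,
        decay_mode=tr.phase2.decay_mode,
        patience=tr.phase2.early_stop_patience,
        monitor="val" if tr.monitor == "val" else "none",
        val_fraction=tr.val_fraction,
        pretrained=config.model.pretrained,
        random_state=config.stage_seed(f"train_{level}"),
    )
    logger.info(
        "train[%s]: backbone=%s pooling=%s dropout=%.2f batch_size=%d "
        "phase1(sgd lr=%g momentum=%g epochs=%d) "
        "phase2(adam lr=%g decay=%g mode=%s epochs=%d patience=%s) monitor=%s",
        level,
        config.model.backbone,
        config.model.pooling,
        config.model.dropout,
        tr.batch_size,
        tr.phase1.learning_rate,
        tr.phase1.momentum,
        tr.phase1.max_epochs,
        tr.phase2.learning_rate,
        tr.phase2.decay,
        tr.phase2.decay_mode,
        tr.phase2.max_epochs,
        tr.phase2.early_stop_patience,
        tr.monitor,
    )
    train_rows = manifest.subset("train")
    x_train = load_patch_arrays(train_rows, manifest.patch_spec)
    y_train = train_rows["class_label"].to_numpy()
    monitor_set = None
    if tr.monitor == "test":
        test_rows = manifest.subset("test")
        monitor_set = (
            load_patch_arrays(test_rows, manifest.patch_spec),
            test_rows["class_label"].to_numpy(),
        )
    clf.fit(x_train, y_train, monitor_set=monitor_set)
    clf.history_.to_csv(run_dir / f"history_{level}.csv")
    clf.history_.plot_curves(run_dir / f"curves_{level}.png")
    clf.model_.save(run_dir / f"weights_{level}.npz")
    return clf


@_stage("evaluate")
def _evaluate(
    config: RunConfig,
    run_dir: Path,
    tagged: pd.DataFrame,
    manifests: dict[str, PatchManifest],
    models: dict[str, WoodPatchCNN],
    taxonomy,
) -> dict:
    test_records = tagged[tagged["split"] == "test"].reset_index(drop=True)
    levels = config.evaluation.levels
    metrics: dict = {}
    species_report = None
    if "species" in levels or "genus_clubbed" in levels:
        species_report = evaluate_model(
            models["species"],
            test_records,
            manifests["species"],
            taxonomy,
            "species",
        )
    if "species" in levels:
        render_report(species_report, run_dir / "reports" / "species")
        metrics["species"] = species_report.to_metrics_dict()
    if "genus_clubbed" in levels:
        rows = manifests["species"].subset("test")
        patches = load_patch_arrays(rows, manifests["species"].patch_spec)
        patch_pairs = list(
            zip(rows["class_label"], models["species"].predict(patches))
        )
        clubbed = club_to_genus(
            species_report.image_predictions, taxonomy, patch_pairs=patch_pairs
        )
        render_report(clubbed, run_dir / "reports" / "genus_clubbed")
        metrics["genus_clubbed"] = clubbed.to_metrics_dict()
    if "genus" in levels:
        genus_report = evaluate_model(
            models["genus"], test_records, manifests["genus"], taxonomy, "genus"
        )
        render_report(genus_report, run_dir / "reports" / "genus")
        metrics["genus"] = genus_report.to_metrics_dict()
    return metrics


def run_pipeline(config: RunConfig, out_root: str | Path) -> Path:
    """Execute every stage; returns the run directory.

    The run directory is ``<out_root>/run_<config hash>`` and receives the
    image set and its manifest, the split table, patch manifests, training
    histories/curves/weights per label level, rendered evaluation reports
    and a ``metrics.json`` summary.
    """
    config.validate()
    run_dir = Path(out_root) / f"run_{config.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)

    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        with open(run_dir / "config.json", "w") as fh:
            json.dump(config.to_canonical_dict(), fh, indent=2, sort_keys=True)

        _, _, taxonomy, _ = _dataset_specs(config)
        images = _generate(config, run_dir)
        tagged = _split(config, run_dir, images)
        manifests = _patch(config, run_dir, tagged, taxonomy)

        levels = config.evaluation.levels
        models: dict[str, WoodPatchCNN] = {}
        if "species" in levels or "genus_clubbed" in levels:
            models["species"] = _train(config, run_dir, manifests["species"], "species")
        if "genus" in levels:
            models["genus"] = _train(config, run_dir, manifests["genus"], "genus")

        metrics = _evaluate(config, run_dir, tagged, manifests, models, taxonomy)
        with open(run_dir / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete: %s", run_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return run_dir
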