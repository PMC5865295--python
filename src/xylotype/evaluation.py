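"""Patch-, image- and genus-level evaluation with score-sum aggregation.

An image is classified by extracting five equally spaced full-height
patches, summing their five softmax score vectors and taking the argmax of
the summed vector (lowest index on ties). Summation is deliberately not a
majority vote: a single confident patch can outvote several lukewarm ones.

Species-level predictions can be "clubbed" to the genus level — a wrong
species but correct genus counts as correct — which can only raise
accuracy. Confusion matrices are reported as row proportions, rows ordered
by the taxonomy; rows without test support are flagged NaN rather than
renormalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from xylotype.dataset import (
    PatchManifest,
    PatchSpec,
    enumerate_offsets,
    extract_patch_array,
    load_patch_arrays,
)
from xylotype.taxonomy import LabelTaxonomy

__all__ = [
    "ImagePrediction",
    "EvaluationReport",
    "predict_image",
    "predict_images",
    "evaluate_model",
    "club_to_genus",
    "render_report",
]

N_EVAL_PATCHES = 5


@dataclass(frozen=True)
class ImagePrediction:
    """Score-sum prediction for one image."""

    image_id: str
    scores: np.ndarray  # summed softmax vector, length = n classes
    predicted_label: str
    true_label: str
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.class_order):
            raise ValueError("score vector length must equal the class count")


@dataclass
class EvaluationReport:
    """Accuracies and row-proportion confusion at one label level."""

    label_level: str
    labels: tuple[str, ...]
    patch_accuracy: float
    image_accuracy: float
    confusion: pd.DataFrame  # rows: true labels, columns: predicted
    per_class_counts: np.ndarray
    image_predictions: list[ImagePrediction] = field(default_factory=list)

    def to_metrics_dict(self) -> dict:
        return {
            "label_level": self.label_level,
            "patch_accuracy": self.patch_accuracy,
            "image_accuracy": self.image_accuracy,
            "per_class_counts": {
                label: int(n) for label, n in zip(self.labels, self.per_class_counts)
            },
        }


def _aggregate_scores(patch_scores: np.ndarray) -> tuple[np.ndarray, int]:
    """Sum patch score vectors; argmax with lowest-index tie-break."""
    scores = np.asarray(patch_scores, dtype=np.float64).sum(axis=0)
    return scores, int(scores.argmax())


def predict_image(
    estimator,
    image: np.ndarray,
    patch_spec: PatchSpec,
    true_label: str,
    image_id: str = "",
    n_patches: int = N_EVAL_PATCHES,
) -> ImagePrediction:
    """Classify one image from its equally spaced patches.

    ``estimator`` must expose ``predict_proba`` over (n, H, W, 3) patches
    and ``classes_``; the five patch probability vectors are summed and the
    maximum-score class returned.
    """
    offsets = enumerate_offsets(
        image.shape[:2],
        (patch_spec.patch_height, patch_spec.patch_width),
        n_patches,
        mode="equally_spaced",
    )
    patches = np.stack(
        [extract_patch_array(image, x, y, patch_spec) for x, y in offsets]
    )
    probs = estimator.predict_proba(patches)
    scores, pred_idx = _aggregate_scores(probs)
    class_order = tuple(estimator.classes_)
    return ImagePrediction(
        image_id=image_id,
        scores=scores,
        predicted_label=class_order[pred_idx],
        true_label=true_label,
        class_order=class_order,
    )


def predict_images(
    estimator,
    records: pd.DataFrame,
    patch_spec: PatchSpec,
    label_column: str,
) -> list[ImagePrediction]:
    """Score-sum predictions for every image row of a split table."""
    from PIL import Image as PILImage

    preds = []
    for row in records.itertuples(index=False):
        image = np.asarray(PILImage.open(row.image_path).convert("RGB"))
        preds.append(
            predict_image(
                estimator,
                image,
                patch_spec,
                true_label=getattr(row, label_column),
                image_id=str(row.image_path),
            )
        )
    return preds


def _confusion_from_pairs(
    pairs: Sequence[tuple[str, str]], labels: tuple[str, ...]
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Row-proportion confusion, per-class support and overall accuracy."""
    index = {label: i for i, label in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=float)
    for true, pred in pairs:
        counts[index[true], index[pred]] += 1
    support = counts.sum(axis=1)
    props = np.full_like(counts, np.nan)
    nonzero = support > 0
    props[nonzero] = counts[nonzero] / support[nonzero, None]
    accuracy = counts.trace() / support.sum() if support.sum() else np.nan
    frame = pd.DataFrame(props, index=list(labels), columns=list(labels))
    return frame, support.astype(int), float(accuracy)


def evaluate_model(
    estimator,
    test_records: pd.DataFrame,
    test_manifest: PatchManifest,
    taxonomy: LabelTaxonomy,
    label_level: str = "species",
) -> EvaluationReport:
    """Patch and image accuracy plus confusion on the test split.

    ``test_records`` are image rows (with ``image_path`` and ``species``);
    ``test_manifest`` supplies the fixed-quota test patches for the
    patch-level accuracy.
    """
    labels = taxonomy.labels(label_level)
    rows = test_manifest.subset("test")
    patches = load_patch_arrays(rows, test_manifest.patch_spec)
    patch_pred = estimator.predict(patches)
    patch_acc = float(np.mean(patch_pred == rows["class_label"].to_numpy()))

    records = test_records.copy()
    if label_level == "genus":
        records["label"] = records["species"].map(taxonomy.genus_of)
    else:
        records["label"] = records["species"]
    missing = records["label"].isna()
    if missing.any():
        raise ValueError("every test image must be labelled at the requested level")
    preds = predict_images(
        estimator, records, test_manifest.patch_spec, label_column="label"
    )
    pairs = [(p.true_label, p.predicted_label) for p in preds]
    confusion, support, image_acc = _confusion_from_pairs(pairs, labels)
    return EvaluationReport(
        label_level=label_level,
        labels=labels,
        patch_accuracy=patch_acc,
        image_accuracy=image_acc,
        confusion=confusion,
        per_class_counts=support,
        image_predictions=preds,
    )


def club_to_genus(
    predictions: Sequence[ImagePrediction],
    taxonomy: LabelTaxonomy,
    patch_pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> EvaluationReport:
    """Re-score species-level predictions at the genus level.

    Each prediction's species labels are mapped through the taxonomy's
    species -> genus map; a wrong species in the right genus becomes
    correct. ``patch_pairs`` optionally supplies species-level
    (true, predicted) patch pairs to club for the patch-level accuracy.
    """
    genera = taxonomy.genera
    pairs = []
    for p in predictions:
        for lbl in (p.true_label, p.predicted_label):
            if lbl not in taxonomy.genus_of:
                raise ValueError(f"species {lbl!r} absent from the taxonomy")
        pairs.append(
            (taxonomy.genus_of[p.true_label], taxonomy.genus_of[p.predicted_label])
        )
    confusion, support, image_acc = _confusion_from_pairs(pairs, genera)
    patch_acc = np.nan
    if patch_pairs is not None:
        clubbed = [
            (taxonomy.genus_of[t], taxonomy.genus_of[p]) for t, p in patch_pairs
        ]
        patch_acc = float(
            np.mean([t == p for t, p in clubbed]) if clubbed else np.nan
        )
    return EvaluationReport(
        label_level="genus",
        labels=genera,
        patch_accuracy=patch_acc,
        image_accuracy=image_acc,
        confusion=confusion,
        per_class_counts=support,
        image_predictions=list(predictions),
    )


def render_report(report: EvaluationReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the confusion CSV, a metrics JSON and a confusion heatmap PNG.

    Heatmap convention: correct (diagonal) proportions in blues, errors
    (off-diagonal) in reds, zeros and unsupported rows left blank.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "confusion_csv": out_dir / f"confusion_{report.label_level}.csv",
        "metrics_json": out_dir / f"metrics_{report.label_level}.json",
        "heatmap_png": out_dir / f"confusion_{report.label_level}.png",
    }
    report.confusion.to_csv(paths["confusion_csv"])
    with open(paths["metrics_json"], "w") as fh:
        json.dump(report.to_metrics_dict(), fh, indent=2)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = report.confusion.to_numpy()
    k = matrix.shape[0]
    diag_mask = np.eye(k, dtype=bool)
    blank = np.isnan(matrix) | (matrix == 0)
    diag = np.where(diag_mask & ~blank, matrix, np.nan)
    off = np.where(~diag_mask & ~blank, matrix, np.nan)

    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * k, 1.0 + 0.6 * k))
    ax.imshow(diag, cmap="Blues", vmin=0, vmax=1)
    ax.imshow(off, cmap="Reds", vmin=0, vmax=1)
    for i in range(k):
        for j in range(k):
            if not blank[i, j]:
                ax.text(
                    j,
                    i,
                    f"{matrix[i, j]:.2f}",
                    ha="center",
                    va="center",
                    fontsize=7,
                    fontweight="bold" if i == j else "normal",
                )
    ax.set_xticks(range(k), report.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(k), report.labels, fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.tight_layout()
    fig.savefig(paths["heatmap_png"], dpi=120)
    plt.close(fig)
    return paths
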