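"""Shared fixtures: a small rendered three-class dataset with patch arrays.

Everything is generated at test time from the synthetic-texture module; no
image fixtures live in the repository.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from xylotype.dataset import (
    PatchSpec,
    SplitSpec,
    build_patch_manifest,
    load_patch_arrays,
    split_images,
)
from xylotype.synthetic import build_synthetic_dataset, three_class_demo_specs

TINY_PATCH_SPEC = PatchSpec(
    patch_height=128,
    patch_width=48,
    resized_height=64,
    resized_width=24,
    train_quota_per_class=12,
    test_quota_per_class=6,
)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """24 rendered 64-px images of 3 well-separated classes, split-tagged."""
    out = tmp_path_factory.mktemp("tiny_images")
    specs, imaging, taxonomy = three_class_demo_specs(n_images=8, image_size=128)
    build_synthetic_dataset(specs, imaging, seed=1234, out_dir=out)
    frame = pd.read_csv(out / "manifest.csv")
    tagged = split_images(frame, SplitSpec(train_fraction=0.6, seed=5))
    return {"records": tagged, "taxonomy": taxonomy, "dir": out}


@pytest.fixture(scope="session")
def tiny_patches(tiny_dataset):
    """Patch manifest plus loaded train/test arrays for the tiny dataset."""
    manifest = build_patch_manifest(
        tiny_dataset["records"],
        tiny_dataset["taxonomy"],
        TINY_PATCH_SPEC,
        label_level="species",
        seed=9,
    )
    train_rows = manifest.subset("train")
    test_rows = manifest.subset("test")
    return {
        "manifest": manifest,
        "x_train": load_patch_arrays(train_rows, TINY_PATCH_SPEC),
        "y_train": train_rows["class_label"].to_numpy(),
        "x_test": load_patch_arrays(test_rows, TINY_PATCH_SPEC),
        "y_test": test_rows["class_label"].to_numpy(),
    }


class ScriptedEstimator:
    """Estimator stub returning pre-scripted probability rows in order."""

    def __init__(self, rows: np.ndarray, classes: tuple[str, ...]):
        self.rows = np.asarray(rows, dtype=float)
        self.classes_ = np.asarray(classes)
        self._cursor = 0

    def predict_proba(self, X) -> np.ndarray:
        n = len(X)
        out = self.rows[self._cursor : self._cursor + n]
        self._cursor += n
        return out

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
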