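"""Image splitting and quota-based patch-dataset construction.

Patches are full-height vertical strips cut from each source image and
downscaled 2x before being fed to the classifier (reference geometry:
2048 x 768 strips resized to 1024 x 384 from 2048 x 2048 images). Each
class contributes a fixed quota of training and testing patches regardless
of how many images it has; classes with few images are oversampled by
allowing patch overlap, which counters class imbalance without reweighting.

The genus-level patch dataset is a relabelled subset of the species-level
one, composed per genus in proportion to each member species' image count
(largest-remainder rounding), so genus classes inherit the species mix of
the underlying collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from xylotype.synthetic import _stable_seed
from xylotype.taxonomy import LabelTaxonomy

__all__ = [
    "SplitSpec",
    "PatchSpec",
    "PatchManifest",
    "split_images",
    "enumerate_offsets",
    "build_patch_manifest",
    "genus_subset_from_species_patches",
    "materialize_patches",
    "extract_patch_array",
    "load_patch_arrays",
]

PATCH_MANIFEST_COLUMNS = [
    "image_path",
    "x_offset",
    "y_offset",
    "split",
    "class_label",
]


class GeometryError(ValueError):
    """A patch does not fit the image geometry."""


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split policy for source images.

    ``train_fraction`` may be a single proportion or a per-class mapping
    (class -> proportion), which allows reproducing collections whose
    per-class splits deviate from one global ratio. ``unit`` chooses the
    leakage boundary: by image, or by specimen (all images of a physical
    block stay on one side).
    """

    train_fraction: float | dict[str, float] = 0.6
    stratify_by: str = "species"  # {"species", "none"}
    unit: str = "image"  # {"image", "specimen"}
    seed: int = 0

    def validate(self) -> None:
        fractions = (
            self.train_fraction.values()
            if isinstance(self.train_fraction, dict)
            else [self.train_fraction]
        )
        for f in fractions:
            if not 0 < f < 1:
                raise ValueError("train_fraction must lie in (0, 1)")
        if self.stratify_by not in ("species", "none"):
            raise ValueError("stratify_by must be 'species' or 'none'")
        if self.unit not in ("image", "specimen"):
            raise ValueError("unit must be 'image' or 'specimen'")


@dataclass(frozen=True)
class PatchSpec:
    """Geometry and per-class quotas of a patch dataset."""

    patch_height: int = 2048
    patch_width: int = 768
    resized_height: int = 1024
    resized_width: int = 384
    train_quota_per_class: int = 500
    test_quota_per_class: int = 200

    def validate(self) -> None:
        for name in (
            "patch_height",
            "patch_width",
            "resized_height",
            "resized_width",
            "train_quota_per_class",
            "test_quota_per_class",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def quota(self, split: str) -> int:
        return (
            self.train_quota_per_class
            if split == "train"
            else self.test_quota_per_class
        )


@dataclass
class PatchManifest:
    """Rows of (image_path, x_offset, y_offset, split, class_label)."""

    rows: pd.DataFrame
    patch_spec: PatchSpec
    label_level: str = "species"

    def __post_init__(self) -> None:
        missing = [c for c in PATCH_MANIFEST_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")

    def subset(self, split: str) -> pd.DataFrame:
        return self.rows[self.rows["split"] == split].reset_index(drop=True)

    def counts(self) -> pd.DataFrame:
        return self.rows.groupby(["class_label", "split"]).size().unstack(fill_value=0)

    def to_csv(self, path: str | Path) -> None:
        self.rows[PATCH_MANIFEST_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, patch_spec: PatchSpec, label_level: str = "species"
    ) -> "PatchManifest":
        return cls(pd.read_csv(path), patch_spec, label_level)


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    import dataclasses as _dc

    return pd.DataFrame([_dc.asdict(r) for r in records])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_images(records, spec: SplitSpec) -> pd.DataFrame:
    """Assign each image to the train or test side.

    Returns a copy of the image table with a ``split`` column. Stratified
    splitting keeps each class's train share within one image of its target
    fraction; ``unit='specimen'`` keeps every specimen whole, cutting the
    shuffled specimen sequence at the point closest to the target share.
    """
    spec.validate()
    frame = _records_frame(records)
    rng = np.random.default_rng(spec.seed)

    def fraction_for(stratum: str) -> float:
        if isinstance(spec.train_fraction, dict):
            if stratum not in spec.train_fraction:
                raise ValueError(f"no train_fraction given for class {stratum!r}")
            return spec.train_fraction[stratum]
        return spec.train_fraction

    if spec.stratify_by == "species":
        groups = [(name, g) for name, g in frame.groupby("species", sort=True)]
    else:
        groups = [("all", frame)]

    split_col = pd.Series(index=frame.index, dtype=object)
    for name, group in groups:
        frac = fraction_for(name)
        if spec.unit == "specimen":
            specimens = sorted(group["specimen_id"].unique())
            order = rng.permutation(len(specimens))
            counts = group["specimen_id"].value_counts()
            target = frac * len(group)
            cum = 0
            best_cut, best_err = 0, abs(target)
            cumulative = []
            for idx in order:
                cum += counts[specimens[idx]]
                cumulative.append(cum)
            for k, c in enumerate(cumulative, start=1):
                if abs(c - target) < best_err:
                    best_err, best_cut = abs(c - target), k
            train_specimens = {specimens[i] for i in order[:best_cut]}
            split_col.loc[group.index] = np.where(
                group["specimen_id"].isin(train_specimens), "train", "test"
            )
        else:
            n = len(group)
            if n == 1:
                warnings.warn(
                    f"stratum {name!r} has a single image; assigned to train",
                    stacklevel=2,
                )
                split_col.loc[group.index] = "train"
                continue
            n_train = min(max(_round_half_up(frac * n), 1), n - 1)
            order = rng.permutation(n)
            idx = group.index.to_numpy()[order]
            split_col.loc[idx[:n_train]] = "train"
            split_col.loc[idx[n_train:]] = "test"

    frame["split"] = split_col
    return frame


def enumerate_offsets(
    image_dims: tuple[int, int],
    patch_dims: tuple[int, int],
    n: int,
    mode: str = "equally_spaced",
    seed: int | None = None,
) -> list[tuple[int, int]]:
    """Top-left (x, y) offsets for ``n`` patches within an image.

    Dimensions are (height, width). ``equally_spaced`` places patches at
    x_i = round(i * (W - w) / (n - 1)) across the width (centred for n=1),
    with y centred (0 for full-height patches); ``uniform_random`` draws
    i.i.d. offsets uniformly over all valid positions.
    """
    H, W = image_dims
    h, w = patch_dims
    if h > H or w > W:
        raise GeometryError(
            f"patch {h}x{w} does not fit image {H}x{W} (height x width)"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    y_center = _round_half_up((H - h) / 2)
    if mode == "equally_spaced":
        if n == 1:
            return [(_round_half_up((W - w) / 2), y_center)]
        return [
            (_round_half_up(i * (W - w) / (n - 1)), y_center) for i in range(n)
        ]
    if mode == "uniform_random":
        rng = np.random.default_rng(seed)
        xs = rng.integers(0, W - w + 1, size=n)
        ys = rng.integers(0, H - h + 1, size=n)
        return [(int(x), int(y)) for x, y in zip(xs, ys)]
    raise ValueError(f"unknown offset mode: {mode!r}")


def build_patch_manifest(
    records,
    taxonomy: LabelTaxonomy,
    patch_spec: PatchSpec,
    label_level: str = "species",
    seed: int = 0,
) -> PatchManifest:
    """Carve a fixed-quota patch dataset from split-tagged images.

    For every class and split, exactly the quota of patches is listed.
    Patches are assigned round-robin over the class's images (per-image
    counts differ by at most one) at uniform-random x/y offsets, so classes
    with few images are oversampled through overlapping patches.
    """
    patch_spec.validate()
    frame = _records_frame(records)
    if "split" not in frame.columns:
        raise ValueError("records must carry a 'split' column (run split_images)")
    labels = taxonomy.labels(label_level)
    class_col = (
        frame["species"]
        if label_level == "species"
        else frame["species"].map(taxonomy.genus_of)
    )
    frame = frame.assign(class_label=class_col)

    all_rows: list[pd.DataFrame] = []
    for cls in labels:
        for split in ("train", "test"):
            group = frame[(frame["class_label"] == cls) & (frame["split"] == split)]
            if group.empty:
                raise ValueError(
                    f"class {cls!r} has no images in the {split!r} split"
                )
            group = group.sort_values("image_path").reset_index(drop=True)
            quota = patch_spec.quota(split)
            k = len(group)
            base, extra = divmod(quota, k)
            order = np.random.default_rng(
                _stable_seed(seed, label_level, cls, split, "order")
            ).permutation(k)
            per_image = np.full(k, base, dtype=int)
            per_image[order[:extra]] += 1
            for img_idx in range(k):
                row = group.iloc[img_idx]
                n_patches = int(per_image[img_idx])
                if n_patches == 0:
                    continue
                offsets = enumerate_offsets(
                    (int(row["height"]), int(row["width"])),
                    (patch_spec.patch_height, patch_spec.patch_width),
                    n_patches,
                    mode="uniform_random",
                    # seed from the basename so manifests do not depend on
                    # where the image directory happens to live
                    seed=_stable_seed(
                        seed, label_level, cls, split, Path(row["image_path"]).name
                    ),
                )
                all_rows.append(
                    pd.DataFrame(
                        {
                            "image_path": row["image_path"],
                            "x_offset": [x for x, _ in offsets],
                            "y_offset": [y for _, y in offsets],
                            "split": split,
                            "class_label": cls,
                        }
                    )
                )
    rows = pd.concat(all_rows, ignore_index=True)
    return PatchManifest(rows=rows, patch_spec=patch_spec, label_level=label_level)


def largest_remainder_apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``.

    Floors the exact shares, then hands the remaining units to the largest
    fractional remainders (ties broken by lower index).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    exact = total * weights / weights.sum()
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = total - base.sum()
    # argsort is stable: ties go to the lower index after negating remainders
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        base[idx] += 1
    return base


def genus_subset_from_species_patches(
    species_manifest: PatchManifest,
    taxonomy: LabelTaxonomy,
    seed: int = 0,
) -> PatchManifest:
    """Derive the genus-level patch dataset from the species-level one.

    Per genus and split, the genus quota is filled by sampling rows from
    each member species in proportion to that species' image count within
    the genus (largest-remainder rounding), then relabelling them to the
    genus. Every returned row is a row of the species manifest.
    """
    spec = species_manifest.patch_spec
    if species_manifest.label_level != "species":
        raise ValueError("input manifest must be species-level")
    rows = species_manifest.rows
    out: list[pd.DataFrame] = []
    for genus in taxonomy.genera:
        members = taxonomy.species_in_genus(genus)
        for split in ("train", "test"):
            quota = spec.quota(split)
            image_counts = np.array(
                [
                    rows[(rows["class_label"] == s) & (rows["split"] == split)][
                        "image_path"
                    ].nunique()
                    for s in members
                ]
            )
            takes = largest_remainder_apportion(image_counts, quota)
            for species, take in zip(members, takes):
                pool = rows[
                    (rows["class_label"] == species) & (rows["split"] == split)
                ]
                if take > len(pool):
                    raise ValueError(
                        f"species {species!r} has only {len(pool)} {split} patches, "
                        f"need {take} for genus {genus!r}"
                    )
                rng = np.random.default_rng(
                    _stable_seed(seed, "genus_subset", genus, species, split)
                )
                chosen = pool.iloc[
                    np.sort(rng.choice(len(pool), size=int(take), replace=False))
                ].copy()
                chosen["class_label"] = genus
                out.append(chosen)
    subset = pd.concat(out, ignore_index=True)
    return PatchManifest(rows=subset, patch_spec=spec, label_level="genus")


def extract_patch_array(
    image: np.ndarray, x: int, y: int, patch_spec: PatchSpec
) -> np.ndarray:
    """Crop one patch from an image array and resize it (bilinear, uint8)."""
    h, w = patch_spec.patch_height, patch_spec.patch_width
    if y + h > image.shape[0] or x + w > image.shape[1]:
        raise GeometryError(
            f"patch at ({x}, {y}) of size {h}x{w} exceeds image {image.shape[:2]}"
        )
    crop = Image.fromarray(image[y : y + h, x : x + w])
    resized = crop.resize(
        (patch_spec.resized_width, patch_spec.resized_height), Image.BILINEAR
    )
    return np.asarray(resized, dtype=np.uint8)


def load_patch_arrays(
    manifest_rows: pd.DataFrame, patch_spec: PatchSpec
) -> np.ndarray:
    """Load all patches of a manifest into one (N, H, W, 3) uint8 array.

    Source images are opened once each; rows are processed in manifest order.
    """
    out = np.empty(
        (
            len(manifest_rows),
            patch_spec.resized_height,
            patch_spec.resized_width,
            3,
        ),
        dtype=np.uint8,
    )
    cache: dict[str, np.ndarray] = {}
    for i, row in enumerate(manifest_rows.itertuples(index=False)):
        path = row.image_path
        if path not in cache:
            try:
                cache[path] = np.asarray(Image.open(path).convert("RGB"))
            except FileNotFoundError as exc:
                raise FileNotFoundError(f"missing source image: {path}") from exc
        out[i] = extract_patch_array(
            cache[path], int(row.x_offset), int(row.y_offset), patch_spec
        )
    return out


def materialize_patches(
    manifest: PatchManifest, out_dir: str | Path
) -> list[Path]:
    """Write every manifest row as a resized PNG patch file.

    Filenames encode the source image and offsets, so re-running produces
    byte-identical files at the same paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = manifest.patch_spec
    paths: list[Path] = []
    cache: dict[str, np.ndarray] = {}
    for row in manifest.rows.itertuples(index=False):
        src = Path(row.image_path)
        if str(src) not in cache:
            try:
                cache[str(src)] = np.asarray(Image.open(src).convert("RGB"))
            except FileNotFoundError as exc:
                raise FileNotFoundError(f"missing source image: {src}") from exc
        patch = extract_patch_array(
            cache[str(src)], int(row.x_offset), int(row.y_offset), spec
        )
        dest = out_dir / f"{src.stem}_x{int(row.x_offset)}_y{int(row.y_offset)}.png"
        Image.fromarray(patch).save(dest)
        paths.append(dest)
    return paths
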