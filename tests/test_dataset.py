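"""Splitting, offsets, quota manifests, genus subset, materialization."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from xylotype.dataset import (
    GeometryError,
    PatchSpec,
    SplitSpec,
    build_patch_manifest,
    enumerate_offsets,
    extract_patch_array,
    genus_subset_from_species_patches,
    largest_remainder_apportion,
    materialize_patches,
    split_images,
)
from xylotype.taxonomy import (
    MELIACEAE10_TABLE,
    LabelTaxonomy,
    meliaceae10_taxonomy,
)


def records_frame(counts: dict[str, int], genus_of=None, height=2048, width=2048):
    """Image table without actual files (splitting/manifesting never reads pixels)."""
    rows = []
    for species, n in counts.items():
        genus = (genus_of or {}).get(species, species.split()[0])
        for i in range(n):
            rows.append(
                dict(
                    image_path=f"/img/{species.replace(' ', '_')}_{i:04d}.png",
                    specimen_id=f"{species}_s{i // 2}",
                    species=species,
                    genus=genus,
                    width=width,
                    height=height,
                    seed=i,
                )
            )
    return pd.DataFrame(rows)


class TestSplitImages:
    def test_exact_division(self):
        frame = records_frame({"a sp": 10, "b sp": 10})
        tagged = split_images(frame, SplitSpec(train_fraction=0.6, seed=0))
        counts = tagged.groupby(["species", "split"]).size()
        assert counts["a sp", "train"] == 6 and counts["a sp", "test"] == 4

    def test_reference_per_class_fractions_reproduce_totals(self):
        # Per-class fractions of the emulated collection recover its exact
        # 1596/707 split at full scale (within the +-1 rounding guarantee).
        counts = {s: tr + te for s, (_, tr, te) in MELIACEAE10_TABLE.items()}
        fractions = {
            s: tr / (tr + te) for s, (_, tr, te) in MELIACEAE10_TABLE.items()
        }
        tagged = split_images(
            records_frame(counts), SplitSpec(train_fraction=fractions, seed=1)
        )
        by = tagged.groupby(["species", "split"]).size()
        assert by["Carapa guianensis", "train"] == 305
        assert by["Carapa guianensis", "test"] == 134
        totals = tagged.groupby("split").size()
        assert totals["train"] == 1596 and totals["test"] == 707

    def test_deterministic_for_fixed_seed(self):
        frame = records_frame({"a sp": 7, "b sp": 9})
        one = split_images(frame, SplitSpec(seed=3))["split"]
        two = split_images(frame, SplitSpec(seed=3))["split"]
        assert one.equals(two)
        other = split_images(frame, SplitSpec(seed=4))["split"]
        assert not one.equals(other)

    def test_single_image_stratum_warns_and_goes_to_train(self):
        frame = records_frame({"a sp": 1, "b sp": 4})
        with pytest.warns(UserWarning, match="single image"):
            tagged = split_images(frame, SplitSpec(seed=0))
        assert (tagged.loc[tagged["species"] == "a sp", "split"] == "train").all()

    def test_specimen_unit_prevents_leakage(self):
        frame = records_frame({"a sp": 10})  # 5 specimens x 2 images
        tagged = split_images(
            frame, SplitSpec(train_fraction=0.6, unit="specimen", seed=2)
        )
        sides = tagged.groupby("specimen_id")["split"].nunique()
        assert (sides == 1).all()
        assert set(tagged["split"]) == {"train", "test"}


class TestEnumerateOffsets:
    def test_equally_spaced_reference_geometry(self):
        offsets = enumerate_offsets((2048, 2048), (2048, 768), 5)
        assert offsets == [(0, 0), (320, 0), (640, 0), (960, 0), (1280, 0)]

    def test_single_patch_is_centered(self):
        assert enumerate_offsets((2048, 2048), (2048, 768), 1) == [(640, 0)]

    def test_uniform_random_bounds_and_mean(self):
        offsets = enumerate_offsets(
            (2048, 2048), (2048, 768), 1000, mode="uniform_random", seed=8
        )
        xs = np.array([x for x, _ in offsets])
        ys = np.array([y for _, y in offsets])
        assert xs.min() >= 0 and xs.max() <= 1280 and (ys == 0).all()
        assert abs(xs.mean() - 640) <= 0.03 * 1280

    def test_oversized_patch_rejected(self):
        with pytest.raises(GeometryError):
            enumerate_offsets((100, 100), (128, 64), 1)


@pytest.mark.parametrize(
    "counts,quotas",
    [
        ({"a sp": 6, "b sp": 20}, (50, 20)),
        ({"a sp": 2, "b sp": 3, "c sp": 11}, (37, 13)),
    ],
)
def test_quota_exactness_and_offset_validity(counts, quotas):
    taxonomy = LabelTaxonomy(
        species=tuple(counts), genus_of={s: s.split()[0] for s in counts}
    )
    spec = PatchSpec(
        patch_height=2048,
        patch_width=768,
        resized_height=1024,
        resized_width=384,
        train_quota_per_class=quotas[0],
        test_quota_per_class=quotas[1],
    )
    tagged = split_images(records_frame(counts), SplitSpec(seed=1))
    manifest = build_patch_manifest(tagged, taxonomy, spec, "species", seed=2)
    table = manifest.counts()
    for species in counts:
        assert table.loc[species, "train"] == quotas[0]
        assert table.loc[species, "test"] == quotas[1]
    rows = manifest.rows
    assert rows["x_offset"].between(0, 2048 - 768).all()
    assert rows["y_offset"].eq(0).all()
    # round-robin balance: per-image patch counts within a class differ by <= 1
    per_image = rows.groupby(["class_label", "split", "image_path"]).size()
    spread = per_image.groupby(["class_label", "split"]).agg(lambda s: s.max() - s.min())
    assert (spread <= 1).all()
    # no image appears on both sides
    sides = rows.groupby("image_path")["split"].nunique()
    assert (sides == 1).all()


def test_oversampling_floor_single_image_class():
    counts = {"a sp": 5, "b sp": 5}
    taxonomy = LabelTaxonomy(
        species=("a sp", "b sp"), genus_of={"a sp": "A", "b sp": "B"}
    )
    tagged = records_frame(counts)
    # force class a to one train image
    tagged["split"] = "test"
    tagged.loc[tagged.index[:1], "split"] = "train"
    tagged.loc[tagged["species"] == "b sp", "split"] = ["train"] * 3 + ["test"] * 2
    spec = PatchSpec(train_quota_per_class=500, test_quota_per_class=10)
    manifest = build_patch_manifest(tagged, taxonomy, spec, "species", seed=0)
    a_train = manifest.rows.query("class_label == 'a sp' and split == 'train'")
    assert len(a_train) == 500
    assert a_train["image_path"].nunique() == 1
    assert len(a_train[["x_offset", "y_offset"]].drop_duplicates()) >= 2


def test_missing_class_in_split_is_an_error():
    counts = {"a sp": 4, "b sp": 4}
    taxonomy = LabelTaxonomy(
        species=("a sp", "b sp"), genus_of={"a sp": "A", "b sp": "B"}
    )
    tagged = records_frame(counts)
    tagged["split"] = "train"
    tagged.loc[tagged["species"] == "b sp", "split"] = ["train", "train", "test", "test"]
    with pytest.raises(ValueError, match="'a sp'.*'test'"):
        build_patch_manifest(tagged, taxonomy, PatchSpec(), "species", seed=0)


class TestGenusSubset:
    def test_largest_remainder_two_to_one(self):
        assert list(largest_remainder_apportion(np.array([2, 1]), 500)) == [333, 167]

    def test_subset_respects_image_proportions(self):
        counts = {"x one": 8, "x two": 4, "y one": 6}
        taxonomy = LabelTaxonomy(
            species=tuple(counts),
            genus_of={"x one": "X", "x two": "X", "y one": "Y"},
        )
        tagged = split_images(records_frame(counts), SplitSpec(seed=0))
        spec = PatchSpec(train_quota_per_class=500, test_quota_per_class=200)
        species_manifest = build_patch_manifest(tagged, taxonomy, spec, "species", 1)
        genus_manifest = genus_subset_from_species_patches(species_manifest, taxonomy, 2)
        table = genus_manifest.counts()
        assert table.loc["X", "train"] == 500 and table.loc["X", "test"] == 200
        assert table.loc["Y", "train"] == 500
        # image counts within X are ~2:1 (exact split rounding decides), so the
        # per-species composition follows the largest-remainder apportionment
        x_train = genus_manifest.rows.query("class_label == 'X' and split == 'train'")
        tr = tagged.query("split == 'train'")
        n1 = len(tr[tr["species"] == "x one"])
        n2 = len(tr[tr["species"] == "x two"])
        expected = largest_remainder_apportion(np.array([n1, n2]), 500)
        got_one = x_train["image_path"].str.contains("x_one").sum()
        assert got_one == expected[0]

    def test_rows_are_subset_of_species_manifest(self):
        counts = {"x one": 4, "x two": 3, "y one": 5}
        taxonomy = LabelTaxonomy(
            species=tuple(counts),
            genus_of={"x one": "X", "x two": "X", "y one": "Y"},
        )
        tagged = split_images(records_frame(counts), SplitSpec(seed=0))
        spec = PatchSpec(train_quota_per_class=40, test_quota_per_class=10)
        species_manifest = build_patch_manifest(tagged, taxonomy, spec, "species", 1)
        genus_manifest = genus_subset_from_species_patches(species_manifest, taxonomy, 2)
        key = ["image_path", "x_offset", "y_offset", "split"]
        species_keys = set(map(tuple, species_manifest.rows[key].to_numpy()))
        genus_keys = set(map(tuple, genus_manifest.rows[key].to_numpy()))
        assert genus_keys <= species_keys

    def test_monotypic_genus_draws_from_single_species(self):
        taxonomy = meliaceae10_taxonomy()
        counts = {s: 6 for s in taxonomy.species}
        tagged = split_images(records_frame(counts), SplitSpec(seed=3))
        spec = PatchSpec(train_quota_per_class=30, test_quota_per_class=10)
        species_manifest = build_patch_manifest(tagged, taxonomy, spec, "species", 1)
        genus_manifest = genus_subset_from_species_patches(species_manifest, taxonomy, 2)
        carapa = genus_manifest.rows.query("class_label == 'Carapa'")
        assert carapa["image_path"].str.contains("Carapa_guianensis").all()
        assert len(carapa.query("split == 'train'")) == 30


class TestMaterializePatches:
    @pytest.fixture()
    def constant_image_manifest(self, tmp_path):
        from xylotype.dataset import PatchManifest

        img = np.full((64, 64, 3), 77, dtype=np.uint8)
        path = tmp_path / "const.png"
        Image.fromarray(img).save(path)
        spec = PatchSpec(
            patch_height=64,
            patch_width=24,
            resized_height=32,
            resized_width=12,
            train_quota_per_class=1,
            test_quota_per_class=1,
        )
        rows = pd.DataFrame(
            {
                "image_path": [str(path)] * 2,
                "x_offset": [0, 40],
                "y_offset": [0, 0],
                "split": ["train", "test"],
                "class_label": ["c", "c"],
            }
        )
        return PatchManifest(rows, spec)

    def test_resized_constant_patches(self, tmp_path, constant_image_manifest):
        paths = materialize_patches(constant_image_manifest, tmp_path / "out")
        assert len(paths) == 2
        for p in paths:
            arr = np.asarray(Image.open(p))
            assert arr.shape == (32, 12, 3)
            assert np.all(arr == 77)

    def test_rerun_is_byte_identical(self, tmp_path, constant_image_manifest):
        first = materialize_patches(constant_image_manifest, tmp_path / "o1")
        second = materialize_patches(constant_image_manifest, tmp_path / "o1")
        assert [p.read_bytes() for p in first] == [p.read_bytes() for p in second]

    def test_missing_source_lists_path(self, constant_image_manifest, tmp_path):
        manifest = constant_image_manifest
        manifest.rows.loc[0, "image_path"] = "/nope/gone.png"
        with pytest.raises(FileNotFoundError, match="gone.png"):
            materialize_patches(manifest, tmp_path / "out")


def test_extract_patch_geometry_error():
    img = np.zeros((64, 64, 3), dtype=np.uint8)
    spec = PatchSpec(patch_height=64, patch_width=24, resized_height=32, resized_width=12)
    with pytest.raises(GeometryError):
        extract_patch_array(img, 60, 0, spec)
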