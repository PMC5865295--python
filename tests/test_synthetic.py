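"""Texture generator: determinism, rendered content, class separability."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from skimage.measure import label, regionprops

from xylotype.synthetic import (
    ImagingSpec,
    ParameterValidationError,
    SyntheticClassSpec,
    TextureParams,
    build_synthetic_dataset,
    meliaceae10_specs,
    render_image,
    sample_class_instance,
    three_class_demo_specs,
)


def count_pores(rgb: np.ndarray, min_area: int = 4) -> int:
    """Flood-fill oracle: connected dark blobs in the green (untinted) channel."""
    dark = rgb[..., 1] < 98
    regions = regionprops(label(dark))
    return sum(1 for r in regions if r.area >= min_area)


class TestRenderImage:
    def test_same_seed_bit_identical(self):
        params = TextureParams()
        imaging = ImagingSpec(image_height=128, image_width=128)
        a = render_image(params, imaging, seed=7)
        b = render_image(params, imaging, seed=7)
        assert a.dtype == np.uint8 and a.shape == (128, 128, 3)
        np.testing.assert_array_equal(a, b)
        c = render_image(params, imaging, seed=8)
        assert not np.array_equal(a, c)

    def test_degenerate_texture_is_constant_midgrey(self):
        params = TextureParams(
            pore_density=0.0,
            ray_width=0.0,
            parenchyma_band_period=0.0,
            ring_boundary_period=0.0,
            background_tone=128.0,
            tone_jitter_sd=0.0,
        )
        img = render_image(
            params, ImagingSpec(image_height=64, image_width=64), seed=3
        )
        assert np.all(img == 128)

    def test_pore_count_matches_density(self):
        # 4 pores/mm^2 over a 6.35 mm field -> ~161 expected blobs.
        params = TextureParams(
            pore_density=4.0,
            pore_radius_mean=10.0,
            pore_radius_sd=1.5,
            ray_width=0.0,
            parenchyma_band_period=0.0,
            tone_jitter_sd=3.0,
        )
        img = render_image(params, ImagingSpec(), seed=11)
        expected = 4.0 * 6.35**2
        assert abs(count_pores(img) - expected) <= 0.2 * expected

    @pytest.mark.parametrize("species_idx", [0, 2, 6, 8])
    def test_histogram_centering(self, species_idx):
        specs, imaging, _ = meliaceae10_specs(scale=0.1, image_size=256)
        img = render_image(specs[species_idx].base_params, imaging, seed=5)
        assert abs(img.mean() - imaging.target_mean_intensity) <= 10

    def test_invalid_params_name_the_field(self):
        with pytest.raises(ParameterValidationError, match="pore_radius_mean"):
            render_image(
                TextureParams(pore_radius_mean=1.0, pore_radius_sd=0.6),
                ImagingSpec(image_height=32, image_width=32),
                seed=0,
            )


class TestSampleClassInstance:
    def _spec(self, scale: float) -> SyntheticClassSpec:
        base = dataclasses.replace(
            TextureParams(), intra_class_sd_scale=scale
        )
        return SyntheticClassSpec("sp", "ge", base, n_images=1)

    def test_zero_dispersion_returns_base_exactly(self):
        spec = self._spec(0.0)
        assert sample_class_instance(spec, seed=42) == spec.base_params

    def test_nonzero_dispersion_varies_fields(self):
        spec = self._spec(1.0)
        a = sample_class_instance(spec, seed=1)
        b = sample_class_instance(spec, seed=2)
        assert a != b
        assert a != spec.base_params

    def test_sd_scales_linearly(self):
        draws = {
            s: np.array(
                [
                    sample_class_instance(self._spec(s), seed=i).pore_radius_mean
                    for i in range(500)
                ]
            )
            for s in (1.0, 2.0)
        }
        ratio = draws[2.0].std() / draws[1.0].std()
        assert 1.6 <= ratio <= 2.4

    def test_sampled_params_stay_valid(self):
        spec = self._spec(3.0)
        for i in range(50):
            sample_class_instance(spec, seed=i).validate()


class TestBuildDataset:
    def _specs(self, counts):
        base = TextureParams()
        return [
            SyntheticClassSpec(f"sp{i}", f"ge{i}", base, n_images=n)
            for i, n in enumerate(counts)
        ]

    def test_count_conservation_and_manifest(self, tmp_path):
        imaging = ImagingSpec(image_height=32, image_width=32)
        records = build_synthetic_dataset(
            self._specs([3, 2]), imaging, seed=1, out_dir=tmp_path
        )
        assert len(records) == 5
        manifest = pd.read_csv(tmp_path / "manifest.csv")
        assert len(manifest) == 5
        assert all((tmp_path / p).name for p in manifest["image_path"])

    def test_specimen_grouping(self, tmp_path):
        imaging = ImagingSpec(image_height=32, image_width=32)
        specs = [
            SyntheticClassSpec(
                "a", "A", TextureParams(), n_images=5, images_per_specimen=2
            ),
            SyntheticClassSpec("b", "B", TextureParams(), n_images=2),
        ]
        records = build_synthetic_dataset(specs, imaging, seed=0, out_dir=tmp_path)
        a_specimens = [r.specimen_id for r in records if r.species == "a"]
        assert a_specimens[0] == a_specimens[1]
        assert a_specimens[2] == a_specimens[3]
        assert a_specimens[4] != a_specimens[0]

    def test_same_seed_identical_manifest(self, tmp_path):
        imaging = ImagingSpec(image_height=32, image_width=32)
        for sub in ("one", "two"):
            build_synthetic_dataset(
                self._specs([2, 2]), imaging, seed=9, out_dir=tmp_path / sub
            )
        a = (tmp_path / "one" / "manifest.csv").read_text()
        b = (tmp_path / "two" / "manifest.csv").read_text()
        assert a.replace("one", "x") == b.replace("two", "x")

    def test_preset_counts_follow_reference_proportions(self):
        specs, _, _ = meliaceae10_specs(scale=0.1)
        by_name = {s.species_name: s.n_images for s in specs}
        assert by_name["Cedrela odorata"] == 51  # 514 total images / 10
        assert by_name["Guarea grandifolia"] == 5  # 47 total images / 10
        assert by_name["Carapa guianensis"] == 44

    def test_rejects_duplicate_species(self, tmp_path):
        imaging = ImagingSpec(image_height=32, image_width=32)
        specs = self._specs([1, 1])
        specs[1] = dataclasses.replace(specs[1], species_name="sp0")
        with pytest.raises(ParameterValidationError, match="disjoint"):
            build_synthetic_dataset(specs, imaging, seed=0, out_dir=tmp_path)


class TestSeparabilityLadder:
    """A trivial classifier separates distant classes but not identical twins."""

    @staticmethod
    def _features(specs, imaging, n_per_class, seed0):
        feats, labels = [], []
        for ci, spec in enumerate(specs):
            for i in range(n_per_class):
                params = sample_class_instance(spec, seed=seed0 + 97 * ci + i)
                img = render_image(params, imaging, seed=seed0 + 1000 + 31 * ci + i)
                feats.append([img.mean(), count_pores(img)])
                labels.append(ci)
        return np.array(feats), np.array(labels)

    def _confusion(self, twins: bool):
        from sklearn.neighbors import NearestCentroid
        from sklearn.preprocessing import StandardScaler

        specs, imaging, _ = three_class_demo_specs(twins=twins, image_size=256)
        x, y = self._features(specs, imaging, n_per_class=24, seed0=50)
        train = np.arange(len(y)) % 2 == 0
        scaler = StandardScaler().fit(x[train])
        clf = NearestCentroid().fit(scaler.transform(x[train]), y[train])
        pred = clf.predict(scaler.transform(x[~train]))
        return y[~train], pred

    def test_distant_classes_are_separable(self):
        truth, pred = self._confusion(twins=False)
        assert (truth == pred).mean() > 0.9

    def test_identical_twins_confuse(self):
        truth, pred = self._confusion(twins=True)
        twin_mask = truth < 2
        cross = ((pred != truth) & (pred < 2))[twin_mask].mean()
        assert cross > 0.3
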