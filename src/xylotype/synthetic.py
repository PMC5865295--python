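"""Procedural transverse-surface wood textures with controllable class structure.

Real macroscopic images of wood cross-sections show a small set of
anatomical primitives: pores (vessels) as dark, roughly circular openings;
rays as fine radial lines; parenchyma as lighter periodic bands; and growth
rings as broad tonal gradients. The generator renders these primitives onto
a noisy background so that classifiers see class-specific texture "energy"
without any photographic input. Per-class parameter distributions let class
pairs range from trivially separable to nearly identical (twin species), and
per-class image counts reproduce a realistic imbalance.

Axes convention: rays run vertically (narrow column ranges of the array),
while parenchyma bands and growth-ring gradients run horizontally (periodic
along the row axis).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse

from xylotype.taxonomy import MELIACEAE10_TABLE, LabelTaxonomy, meliaceae10_taxonomy

__all__ = [
    "TextureParams",
    "SyntheticClassSpec",
    "ImagingSpec",
    "ImageRecord",
    "render_image",
    "sample_class_instance",
    "build_synthetic_dataset",
    "meliaceae10_specs",
    "three_class_demo_specs",
]

#: Tonal depth (8-bit units) by which a pore darkens the background field.
PORE_DEPTH = 55.0
#: Tonal depth of a ray line.
RAY_DEPTH = 14.0
#: Tonal lift of a parenchyma band.
BAND_LIFT = 16.0
#: Amplitude of the growth-ring tonal gradient.
RING_AMPLITUDE = 7.0
#: Warm-tint strength used to produce RGB from the grey field. The tint
#: pivots at the target mean so that mid-tone pixels stay neutral and the
#: channel-averaged intensity is unchanged.
TINT_STRENGTH = 0.25


class ParameterValidationError(ValueError):
    """A texture parameter violates its invariant; names the field."""


@dataclass(frozen=True)
class TextureParams:
    """Parameters of one rendered transverse-surface texture.

    Lengths and periods are in pixels of the rendered image; pore density is
    in pores per mm^2 of imaged tissue (converted through the imaging
    field of view).
    """

    pore_density: float = 4.0
    pore_radius_mean: float = 4.0
    pore_radius_sd: float = 0.6
    pore_arrangement: str = "diffuse"  # {"diffuse", "ring-banded"}
    ray_spacing_mean: float = 10.0
    ray_spacing_sd: float = 2.0
    ray_width: float = 1.0
    parenchyma_band_period: float = 0.0  # 0 = absent
    ring_boundary_period: float = 0.0  # 0 = absent
    background_tone: float = 128.0
    tone_jitter_sd: float = 5.0
    intra_class_sd_scale: float = 1.0

    def validate(self) -> None:
        if self.pore_density < 0:
            raise ParameterValidationError("pore_density must be >= 0")
        if self.pore_density > 0:
            if self.pore_radius_mean <= 0:
                raise ParameterValidationError("pore_radius_mean must be > 0")
            if self.pore_radius_mean <= 2.0 * self.pore_radius_sd:
                raise ParameterValidationError(
                    "pore_radius_mean must exceed 2 * pore_radius_sd"
                )
        if self.pore_radius_sd < 0:
            raise ParameterValidationError("pore_radius_sd must be >= 0")
        if self.pore_arrangement not in ("diffuse", "ring-banded"):
            raise ParameterValidationError(
                f"pore_arrangement must be 'diffuse' or 'ring-banded', "
                f"got {self.pore_arrangement!r}"
            )
        if self.pore_arrangement == "ring-banded" and self.ring_boundary_period <= 0:
            raise ParameterValidationError(
                "ring_boundary_period must be > 0 for ring-banded arrangement"
            )
        if self.ray_width > 0 and self.ray_spacing_mean <= 0:
            raise ParameterValidationError("ray_spacing_mean must be > 0")
        if self.ray_spacing_sd < 0:
            raise ParameterValidationError("ray_spacing_sd must be >= 0")
        for name in ("parenchyma_band_period", "ring_boundary_period", "ray_width"):
            if getattr(self, name) < 0:
                raise ParameterValidationError(f"{name} must be >= 0")
        if not 0 <= self.background_tone <= 255:
            raise ParameterValidationError("background_tone must be in [0, 255]")
        if self.tone_jitter_sd < 0:
            raise ParameterValidationError("tone_jitter_sd must be >= 0")
        if self.intra_class_sd_scale < 0:
            raise ParameterValidationError("intra_class_sd_scale must be >= 0")


@dataclass(frozen=True)
class ImagingSpec:
    """Geometry and tonal target of the emulated imaging setup.

    The reference capture geometry is a 2048 x 2048, 8-bit RGB image of a
    6.35 mm x 6.35 mm field of view, exposure-adjusted so the intensity
    histogram centres around 128. Desk-scale work uses the same field of
    view at a smaller pixel count.
    """

    image_height: int = 2048
    image_width: int = 2048
    bit_depth: int = 8
    field_of_view: float = 6.35  # mm
    target_mean_intensity: float = 128.0

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ParameterValidationError("image dimensions must be positive")
        if self.bit_depth != 8:
            raise ParameterValidationError("only 8-bit rendering is supported")
        if self.field_of_view <= 0:
            raise ParameterValidationError("field_of_view must be > 0")
        if not 0 <= self.target_mean_intensity <= 255:
            raise ParameterValidationError(
                "target_mean_intensity must be in [0, 255]"
            )


@dataclass(frozen=True)
class SyntheticClassSpec:
    """One synthetic class: a species with base texture parameters and counts."""

    species_name: str
    genus_name: str
    base_params: TextureParams
    n_images: int = 1
    images_per_specimen: int = 2

    def validate(self) -> None:
        if self.n_images < 1:
            raise ParameterValidationError("n_images must be >= 1")
        if self.images_per_specimen < 1:
            raise ParameterValidationError("images_per_specimen must be >= 1")
        self.base_params.validate()


@dataclass(frozen=True)
class ImageRecord:
    """One synthetic image on disk with its labels and provenance."""

    image_path: str
    specimen_id: str
    species: str
    genus: str
    width: int
    height: int
    seed: int
    flags: str = ""


def _stable_seed(*parts) -> int:
    """Deterministic 31-bit seed derived from arbitrary string-able parts."""
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def render_image(
    params: TextureParams, imaging: ImagingSpec, seed: int
) -> np.ndarray:
    """Render one transverse-surface texture as an 8-bit RGB array.

    The same (params, imaging, seed) always yields bit-identical pixels.

    Returns
    -------
    ndarray of uint8, shape (image_height, image_width, 3)
    """
    params.validate()
    imaging.validate()
    rng = np.random.default_rng(seed)
    h, w = imaging.image_height, imaging.image_width
    field = np.full((h, w), float(params.background_tone), dtype=np.float64)

    # Low-frequency mottle plus per-pixel grain, both scaled by tone jitter.
    if params.tone_jitter_sd > 0:
        mottle = gaussian_filter(rng.standard_normal((h, w)), sigma=max(h, w) / 32)
        sd = mottle.std()
        if sd > 0:
            field += mottle * (params.tone_jitter_sd / sd)
        field += rng.standard_normal((h, w)) * params.tone_jitter_sd

    # Growth-ring tonal gradient: smooth sinusoid along y.
    if params.ring_boundary_period > 0:
        phase = rng.uniform(0, 2 * np.pi)
        y = np.arange(h)[:, None]
        field += RING_AMPLITUDE * np.sin(
            2 * np.pi * y / params.ring_boundary_period + phase
        )

    # Parenchyma bands: light narrow horizontal rows, periodic along y.
    if params.parenchyma_band_period > 0:
        period = params.parenchyma_band_period
        offset = rng.uniform(0, period)
        band_half_width = max(1.0, period / 12.0)
        y = np.arange(h)[:, None]
        dist = np.abs((y - offset + period / 2) % period - period / 2)
        field += BAND_LIFT * np.exp(-0.5 * (dist / band_half_width) ** 2)

    # Rays: dark vertical lines at jittered spacing.
    if params.ray_width > 0 and params.ray_spacing_mean > 0:
        width = max(1, int(round(params.ray_width)))
        x = rng.uniform(0, params.ray_spacing_mean)
        while x < w:
            x0 = int(round(x))
            field[:, x0 : x0 + width] -= RAY_DEPTH
            gap = rng.normal(params.ray_spacing_mean, params.ray_spacing_sd)
            x += max(1.0, gap)

    # Pores: dark near-circular openings; count follows a Poisson law with
    # the requested areal density over the imaged field of view.
    if params.pore_density > 0:
        n_pores = int(rng.poisson(params.pore_density * imaging.field_of_view**2))
        if params.pore_arrangement == "ring-banded":
            period = params.ring_boundary_period
            band_offset = rng.uniform(0, period)
            n_bands = max(1, int(np.ceil(h / period)))
            band_idx = rng.integers(0, n_bands, size=n_pores)
            cy = band_idx * period + band_offset + rng.normal(
                0, period / 10.0, size=n_pores
            )
            cy = np.mod(cy, h)
        else:
            cy = rng.uniform(0, h, size=n_pores)
        cx = rng.uniform(0, w, size=n_pores)
        radii = rng.normal(
            params.pore_radius_mean, params.pore_radius_sd, size=n_pores
        )
        radii = np.clip(radii, 1.0, None)
        ecc = rng.uniform(0.75, 1.0, size=n_pores)  # mild ellipticity
        for i in range(n_pores):
            rr, cc = ellipse(
                cy[i], cx[i], radii[i], radii[i] * ecc[i], shape=(h, w)
            )
            field[rr, cc] = params.background_tone - PORE_DEPTH

    # Exposure emulation: shift so the histogram centres on the target mean.
    field += imaging.target_mean_intensity - field.mean()
    field = np.clip(field, 0.0, 255.0)

    # Warm (brown) tint pivoted at the target mean: R lifted, B lowered in
    # proportion to the distance from the pivot, so a flat field at the
    # target renders neutral grey and the channel-mean intensity is kept.
    pivot = imaging.target_mean_intensity
    delta = field - pivot
    rgb = np.stack(
        [
            np.clip(field + TINT_STRENGTH * delta, 0, 255),
            field,
            np.clip(field - TINT_STRENGTH * delta, 0, 255),
        ],
        axis=-1,
    )
    return rgb.astype(np.uint8)


# Relative per-field dispersion (fraction of the base value at scale 1) used
# when sampling an instance of a class around its base parameters.
_FIELD_REL_SD: dict[str, float] = {
    "pore_density": 0.10,
    "pore_radius_mean": 0.06,
    "pore_radius_sd": 0.10,
    "ray_spacing_mean": 0.08,
    "ray_spacing_sd": 0.10,
    "ray_width": 0.0,  # kept integral; varied only through spacing
    "parenchyma_band_period": 0.06,
    "ring_boundary_period": 0.06,
    "background_tone": 0.04,
    "tone_jitter_sd": 0.10,
}


def sample_class_instance(spec: SyntheticClassSpec, seed: int) -> TextureParams:
    """Draw texture parameters for one specimen of a class.

    Each continuous field is drawn from a normal law centred on the base
    value with standard deviation ``rel_sd * base * intra_class_sd_scale``,
    then clipped into its valid range; zero-valued base fields (absent
    features) stay zero. A zero ``intra_class_sd_scale`` returns the base
    parameters exactly.
    """
    spec.validate()
    base = spec.base_params
    scale = base.intra_class_sd_scale
    if scale == 0:
        return base
    rng = np.random.default_rng(seed)
    updates: dict[str, float] = {}
    for name, rel in _FIELD_REL_SD.items():
        value = getattr(base, name)
        if value == 0 or rel == 0:
            continue
        drawn = rng.normal(value, rel * abs(value) * scale)
        # clip into a broad valid band around the base; invariants re-checked below
        drawn = float(np.clip(drawn, 0.25 * value, 4.0 * value))
        updates[name] = drawn
    params = replace(base, **updates)
    # Keep the pore-radius non-degeneracy invariant under independent draws.
    if params.pore_density > 0 and params.pore_radius_mean <= 2 * params.pore_radius_sd:
        params = replace(params, pore_radius_sd=params.pore_radius_mean / 2.5)
    params = replace(
        params, background_tone=float(np.clip(params.background_tone, 0, 255))
    )
    params.validate()
    return params


MANIFEST_COLUMNS = [
    "image_path",
    "specimen_id",
    "species",
    "genus",
    "width",
    "height",
    "seed",
]


def build_synthetic_dataset(
    specs: list[SyntheticClassSpec],
    imaging: ImagingSpec,
    seed: int,
    out_dir: str | Path,
) -> list[ImageRecord]:
    """Render every class's images to ``out_dir`` and write a CSV manifest.

    Images of one specimen share texture parameters (drawn once per
    specimen) but differ in rendering noise, emulating repeated captures of
    one physical block. The whole dataset is a pure function of
    (specs, imaging, seed).
    """
    if len(specs) < 2:
        raise ParameterValidationError("need at least two class specs")
    names = [s.species_name for s in specs]
    if len(set(names)) != len(names):
        raise ParameterValidationError("species names must be disjoint")
    for spec in specs:
        spec.validate()
    imaging.validate()

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    from PIL import Image

    records: list[ImageRecord] = []
    for spec in specs:
        slug = spec.species_name.replace(" ", "_")
        for i in range(spec.n_images):
            specimen_idx = i // spec.images_per_specimen
            specimen_id = f"{slug}_s{specimen_idx:03d}"
            params = sample_class_instance(
                spec, _stable_seed(seed, spec.species_name, "specimen", specimen_idx)
            )
            img_seed = _stable_seed(seed, spec.species_name, "image", i)
            pixels = render_image(params, imaging, img_seed)
            path = out_dir / f"{slug}_{i:04d}.png"
            Image.fromarray(pixels).save(path)
            records.append(
                ImageRecord(
                    image_path=str(path),
                    specimen_id=specimen_id,
                    species=spec.species_name,
                    genus=spec.genus_name,
                    width=imaging.image_width,
                    height=imaging.image_height,
                    seed=img_seed,
                )
            )

    manifest = pd.DataFrame([dataclasses.asdict(r) for r in records])
    manifest[MANIFEST_COLUMNS].to_csv(out_dir / "manifest.csv", index=False)
    return records


def _px(value_at_256: float, image_size: int) -> float:
    """Scale a pixel-valued parameter calibrated at 256 px to another size."""
    return value_at_256 * image_size / 256.0


# Per-species base texture parameters calibrated for a 256-px image of the
# 6.35 mm field of view. Genera carry distinct macro-signatures (pore size
# and density, ray spacing, band structure); congeneric species differ only
# slightly, and the two Cedrela species are deliberately identical twins.
# Carapa carries a high intra-class dispersion (its hallmark variability).
_MELIACEAE10_BASE: dict[str, dict] = {
    "Cabralea canjerana": dict(
        pore_density=6.0, pore_radius_mean=3.2, pore_radius_sd=0.5,
        ray_spacing_mean=9.0, ray_spacing_sd=1.8, ray_width=1.0,
        parenchyma_band_period=22.0, ring_boundary_period=0.0,
        pore_arrangement="diffuse", background_tone=120.0,
        tone_jitter_sd=5.0, intra_class_sd_scale=1.0,
    ),
    "Carapa guianensis": dict(
        pore_density=3.0, pore_radius_mean=4.5, pore_radius_sd=0.7,
        ray_spacing_mean=14.0, ray_spacing_sd=2.8, ray_width=1.0,
        parenchyma_band_period=0.0, ring_boundary_period=0.0,
        pore_arrangement="diffuse", background_tone=135.0,
        tone_jitter_sd=6.0, intra_class_sd_scale=2.5,
    ),
    "Cedrela fissilis": dict(
        pore_density=3.0, pore_radius_mean=5.5, pore_radius_sd=0.8,
        ray_spacing_mean=12.0, ray_spacing_sd=2.4, ray_width=1.0,
        parenchyma_band_period=0.0, ring_boundary_period=48.0,
        pore_arrangement="ring-banded", background_tone=140.0,
        tone_jitter_sd=6.0, intra_class_sd_scale=1.5,
    ),
    # Twin of Cedrela fissilis: identical base parameters by construction.
    "Cedrela odorata": dict(
        pore_density=3.0, pore_radius_mean=5.5, pore_radius_sd=0.8,
        ray_spacing_mean=12.0, ray_spacing_sd=2.4, ray_width=1.0,
        parenchyma_band_period=0.0, ring_boundary_period=48.0,
        pore_arrangement="ring-banded", background_tone=140.0,
        tone_jitter_sd=6.0, intra_class_sd_scale=1.5,
    ),
    "Guarea glabra": dict(
        pore_density=5.5, pore_radius_mean=3.4, pore_radius_sd=0.5,
        ray_spacing_mean=10.0, ray_spacing_sd=2.0, ray_width=1.0,
        parenchyma_band_period=25.0, ring_boundary_period=0.0,
        pore_arrangement="diffuse", background_tone=122.0,
        tone_jitter_sd=5.0, intra_class_sd_scale=1.0,
    ),
    "Guarea grandifolia": dict(
        pore_density=5.0, pore_radius_mean=3.6, pore_radius_sd=0.5,
        ray_spacing_mean=11.0, ray_spacing_sd=2.2, ray_width=1.0,
        parenchyma_band_period=28.0, ring_boundary_period=0.0,
        pore_arrangement="diffuse", background_tone=124.0,
        tone_jitter_sd=5.0, intra_class_sd_scale=1.0,
    ),
    "Khaya ivorensis": dict(
        pore_density=1.2, pore_radius_mean=6.5, pore_radius_sd=0.9,
        ray_spacing_mean=18.0, ray_spacing_sd=3.6, ray_width=2.0,
        parenchyma_band_period=0.0, ring_boundary_period=0.0,
        pore_arrangement="diffuse", background_tone=132.0,
        tone_jitter_sd=6.0, intra_class_sd_scale=1.0,
    ),
    "Khaya senegalensis": dict(
        pore_density=1.6, pore_radius_mean=6.0, pore_radius_sd=0.9,
        ray_spacing_mean=16.0, ray_spacing_sd=3.2, ray_width=2.0,
        parenchyma_band_period=0.0, ring_boundary_period=0.0,
        pore_arrangement="diffuse", background_tone=130.0,
        tone_jitter_sd=6.0, intra_class_sd_scale=1.0,
    ),
    "Swietenia macrophylla": dict(
        pore_density=8.0, pore_radius_mean=2.6, pore_radius_sd=0.4,
        ray_spacing_mean=7.0, ray_spacing_sd=1.4, ray_width=1.0,
        parenchyma_band_period=40.0, ring_boundary_period=32.0,
        pore_arrangement="diffuse", background_tone=112.0,
        tone_jitter_sd=5.0, intra_class_sd_scale=1.0,
    ),
    "Swietenia mahagoni": dict(
        pore_density=9.0, pore_radius_mean=2.4, pore_radius_sd=0.4,
        ray_spacing_mean=6.0, ray_spacing_sd=1.2, ray_width=1.0,
        parenchyma_band_period=36.0, ring_boundary_period=30.0,
        pore_arrangement="diffuse", background_tone=110.0,
        tone_jitter_sd=5.0, intra_class_sd_scale=1.0,
    ),
}

_PIXEL_FIELDS = (
    "pore_radius_mean",
    "pore_radius_sd",
    "ray_spacing_mean",
    "ray_spacing_sd",
    "ray_width",
    "parenchyma_band_period",
    "ring_boundary_period",
)


def meliaceae10_specs(
    scale: float = 0.1, image_size: int = 256
) -> tuple[list[SyntheticClassSpec], ImagingSpec, LabelTaxonomy]:
    """The 10-species Meliaceae preset at a configurable scale.

    ``scale`` multiplies each species' reference image count (train + test
    totals of the emulated collection, 2303 images at scale 1); pixel-valued
    texture parameters are calibrated at 256 px and scale with
    ``image_size`` so the rendered anatomy keeps its physical size.
    """
    if scale <= 0:
        raise ParameterValidationError("scale must be > 0")
    taxonomy = meliaceae10_taxonomy()
    specs = []
    for species, (genus, n_train, n_test) in MELIACEAE10_TABLE.items():
        base_kwargs = dict(_MELIACEAE10_BASE[species])
        for f in _PIXEL_FIELDS:
            base_kwargs[f] = _px(base_kwargs[f], image_size)
        n_images = max(1, round((n_train + n_test) * scale))
        specs.append(
            SyntheticClassSpec(
                species_name=species,
                genus_name=genus,
                base_params=TextureParams(**base_kwargs),
                n_images=n_images,
                images_per_specimen=2,
            )
        )
    imaging = ImagingSpec(image_height=image_size, image_width=image_size)
    return specs, imaging, taxonomy


def meliaceae10_split_fractions() -> dict[str, float]:
    """Per-species train fractions of the emulated collection's split."""
    return {
        s: n_train / (n_train + n_test)
        for s, (_, n_train, n_test) in MELIACEAE10_TABLE.items()
    }


def three_class_demo_specs(
    twins: bool = False, n_images: int = 12, image_size: int = 256
) -> tuple[list[SyntheticClassSpec], ImagingSpec, LabelTaxonomy]:
    """A 3-class toy preset with widely separated base parameters.

    With ``twins=True`` the first two classes share identical parameters,
    making them deliberately confusable while the third stays distinct.
    """
    sparse = TextureParams(
        pore_density=1.0,
        pore_radius_mean=_px(6.0, image_size),
        pore_radius_sd=_px(0.8, image_size),
        ray_spacing_mean=_px(18.0, image_size),
        ray_spacing_sd=_px(3.0, image_size),
        parenchyma_band_period=0.0,
        background_tone=140.0,
    )
    medium = TextureParams(
        pore_density=5.0,
        pore_radius_mean=_px(4.0, image_size),
        pore_radius_sd=_px(0.6, image_size),
        ray_spacing_mean=_px(10.0, image_size),
        ray_spacing_sd=_px(2.0, image_size),
        parenchyma_band_period=_px(30.0, image_size),
        background_tone=125.0,
    )
    dense = TextureParams(
        pore_density=12.0,
        pore_radius_mean=_px(2.5, image_size),
        pore_radius_sd=_px(0.35, image_size),
        ray_spacing_mean=_px(6.0, image_size),
        ray_spacing_sd=_px(1.2, image_size),
        parenchyma_band_period=0.0,
        background_tone=112.0,
    )
    params = [sparse, sparse if twins else medium, dense]
    genera = ["Alpha", "Alpha" if twins else "Beta", "Gamma"]
    species = ["Alpha one", "Alpha two" if twins else "Beta one", "Gamma one"]
    specs = [
        SyntheticClassSpec(
            species_name=s, genus_name=g, base_params=p, n_images=n_images
        )
        for s, g, p in zip(species, genera, params)
    ]
    taxonomy = LabelTaxonomy(
        species=tuple(species), genus_of=dict(zip(species, genera))
    )
    imaging = ImagingSpec(image_height=image_size, image_width=image_size)
    return specs, imaging, taxonomy
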