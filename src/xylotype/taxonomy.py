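"""Label taxonomy: an ordered species list with a species-to-genus map.

Classification is evaluated at two granularities: the fine species level and
the coarser genus level obtained by "clubbing" congeneric species into one
class. The taxonomy fixes the class ordering used everywhere downstream
(softmax output order, confusion-matrix rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LabelTaxonomy:
    """Ordered species labels plus the species -> genus mapping.

    Parameters
    ----------
    species : tuple of str
        Ordered species names; this order defines class indices.
    genus_of : dict
        Maps every species name to exactly one genus name.
    """

    species: tuple[str, ...]
    genus_of: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        missing = [s for s in self.species if s not in self.genus_of]
        if missing:
            raise ValueError(f"species without a genus mapping: {missing}")

    @property
    def genera(self) -> tuple[str, ...]:
        """Ordered distinct genera, in order of first appearance."""
        seen: list[str] = []
        for s in self.species:
            g = self.genus_of[s]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def labels(self, level: str) -> tuple[str, ...]:
        if level == "species":
            return self.species
        if level == "genus":
            return self.genera
        raise ValueError(f"unknown label level: {level!r}")

    def species_in_genus(self, genus: str) -> tuple[str, ...]:
        return tuple(s for s in self.species if self.genus_of[s] == genus)

    def index_of(self, label: str, level: str) -> int:
        return self.labels(level).index(label)


# Per-species (genus, train images, test images) of the 10-species /
# 6-genus neotropical Meliaceae image collection the pipeline emulates.
MELIACEAE10_TABLE: dict[str, tuple[str, int, int]] = {
    "Cabralea canjerana": ("Cabralea", 41, 18),
    "Carapa guianensis": ("Carapa", 305, 134),
    "Cedrela fissilis": ("Cedrela", 133, 59),
    "Cedrela odorata": ("Cedrela", 354, 160),
    "Guarea glabra": ("Guarea", 45, 20),
    "Guarea grandifolia": ("Guarea", 33, 14),
    "Khaya ivorensis": ("Khaya", 240, 105),
    "Khaya senegalensis": ("Khaya", 36, 16),
    "Swietenia macrophylla": ("Swietenia", 372, 165),
    "Swietenia mahagoni": ("Swietenia", 37, 16),
}


def meliaceae10_taxonomy() -> LabelTaxonomy:
    """The 10-species / 6-genus Meliaceae taxonomy."""
    species = tuple(MELIACEAE10_TABLE)
    genus_of = {s: MELIACEAE10_TABLE[s][0] for s in species}
    return LabelTaxonomy(species=species, genus_of=genus_of)
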