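"""Shared fixtures: tiny deterministic worlds and curated label sets."""

import pytest
from hypothesis import settings

import sdmfuse as sf

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_world():
    """A 30x30-cell world with 12 species used across module tests."""
    return sf.generate_world(7, R=30, C=30, S=12, B=8, m=4, n_active_env=3)


@pytest.fixture(scope="session")
def tiny_labels(tiny_world):
    """Curated, imputed, rank-expanded labels from the tiny world."""
    occ = sf.simulate_occurrences(tiny_world, 900, detectability=0.5, seed=3)
    occs = [sf.Occurrence(r.record_id, r.species, r.x, r.y)
            for r in occ.itertuples(index=False)]
    occs = sf.dedup_within_radius(occs, 150)
    occs = sf.drop_confined_species(occs, 256)
    labels, names = sf.neighbor_impute(occs, 256)
    labels, names = sf.filter_min_count(labels, names, 5)
    taxonomy = sf.TaxonomyTable.from_frame(sf.taxonomy_frame(tiny_world))
    labels, index = sf.expand_ranks(labels, names, taxonomy)
    return labels, index


def make_occurrences(points, species="sp1"):
    """Occurrence list helper: points is [(x, y), ...] in meters."""
    if isinstance(species, str):
        species = [species] * len(points)
    return [sf.Occurrence(f"r{i}", sp, float(x), float(y))
            for i, ((x, y), sp) in enumerate(zip(points, species))]
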