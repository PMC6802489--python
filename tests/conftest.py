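import numpy as np
import pytest

from herbnet.simulate import StudyConfig, generate_study


def small_config(seed: int = 0, **overrides) -> StudyConfig:
    """A scaled-down study: fast to generate but structurally complete."""
    fields = dict(
        n_herbs=3,
        compounds_per_herb=(20, 15, 10),
        cross_herb_overlap_rate=0.1,
        reference_library_size=300,
        n_descriptors=6,
        active_fraction=0.2,
        n_targets=30,
        mean_targets_per_active=5.0,
        hub_compound_count=1,
        hub_degree=20,
        disease_rates={"obesity": 0.3, "diabetes": 0.2, "inflammation": 0.15},
        n_pathways=8,
        pathway_size_range=(5, 12),
        planted_enriched_pathways=1,
        planted_overlap_strength=0.75,
        pathway_universe_size=120,
        n_decoy_predictions=40,
        curated_fraction=0.25,
        seed=seed,
    )
    fields.update(overrides)
    return StudyConfig(**fields)


@pytest.fixture
def small_study():
    return generate_study(small_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
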