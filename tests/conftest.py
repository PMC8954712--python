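import numpy as np
import pytest

from fragminer.synthetic_data import (
    GeneratorConfig,
    generate_fingerprint_dataset,
    study_config,
    study_enrichment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def study_dataset():
    """One full-shape synthetic dataset: 117 compounds, 89 P, 881 bits."""
    return generate_fingerprint_dataset(study_config(seed=7))


@pytest.fixture(scope="session")
def train_shaped_dataset():
    """A training-set-shaped dataset: 88 compounds, 69 P / 19 N, 300 bits."""
    from fragminer.synthetic_data import EnrichmentSpec

    enriched = tuple(
        EnrichmentSpec(f"PubchemFP{10 + i}", s.p_present_in_P, s.p_present_in_N)
        for i, s in enumerate(study_enrichment())
    )
    cfg = GeneratorConfig(
        n_compounds=88,
        n_potent=69,
        n_bits=300,
        enriched=enriched,
        background_p=0.15,
        n_constant_bits=4,
        n_correlated_pairs=5,
        seed=11,
    )
    return generate_fingerprint_dataset(cfg)
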