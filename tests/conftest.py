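import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from codonpause.codon_stats import classify_codons, compute_rscu, count_codons
from codonpause.genetic_code import standard_code
from codonpause.synthetic_data import (
    default_family_config,
    default_usage_model,
    generate_family,
    generate_heg_set,
)


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def usage_model():
    return default_usage_model(seed=0)


@pytest.fixture(scope="session")
def classification(usage_model):
    """Classification estimated from a synthetic HEG set (study conditions)."""
    heg = generate_heg_set(usage_model, n_genes=200, mean_length=300, seed=1)
    return classify_codons(compute_rscu(count_codons(heg, gene_set_label="synthetic HEGs")))


@pytest.fixture(scope="session")
def default_bundle(usage_model):
    """The canonical planted fixture: 8 species, TM [26,46], CAA/GGG at 24-25."""
    return generate_family(default_family_config(seed=7), usage_model)
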