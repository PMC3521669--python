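import numpy as np
import pytest

from te_spread import CLASS_BOTH, CLASS_H3K9, CLASS_NONE
from te_spread import synthetic_data as sd


def small_config(seed=11, **overrides):
    """A reduced bundle config for fast unit tests."""
    families = [
        sd.FamilyConfig(family_id="famB0", superfamily="RLG",
                        true_class=CLASS_BOTH, effect_a_meth=0.8,
                        effect_a_h3k9=0.8, lambda_bp=600.0,
                        copy_number=10, element_length_bp=800,
                        polymorphism_rate=0.4),
        sd.FamilyConfig(family_id="famK0", superfamily="RLC",
                        true_class=CLASS_H3K9, effect_a_meth=0.8,
                        effect_a_h3k9=0.8, lambda_bp=600.0,
                        lambda_meth_bp=120.0, copy_number=10,
                        element_length_bp=800, polymorphism_rate=0.4),
        sd.FamilyConfig(family_id="famN0", superfamily="RLX",
                        true_class=CLASS_NONE, copy_number=10,
                        element_length_bp=800, polymorphism_rate=0.3),
        sd.FamilyConfig(family_id="famN1", superfamily="LINE",
                        true_class=CLASS_NONE, copy_number=10,
                        element_length_bp=800),
    ]
    config = sd.SyntheticConfig(
        chromosomes={"chr1": 150_000, "chr2": 150_000},
        families=families, seed=seed, reserve_bp=25_000)
    config.genes.n_genes = 60
    for key, value in overrides.items():
        setattr(config, key, value)
    return config


@pytest.fixture(scope="session")
def small_bundle():
    return sd.simulate(small_config())


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    sd.simulate(small_config(), outdir=outdir)
    return outdir


@pytest.fixture
def rng():
    return np.random.default_rng(123)
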