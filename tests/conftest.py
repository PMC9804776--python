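import numpy as np
import pytest

from phylometa import phylo, synthetic_data
from phylometa.effects_io import EffectSizeRecord


def make_record(estimate_id="e1", study_id="s1", species="species_01", h2=0.5,
                se=0.1, n=100, publication_year=2010, **overrides):
    defaults = dict(
        environmental_setting="natural",
        age_at_measurement="adult",
        laboratory_method="qPCR",
        statistical_method="pedigree",
        parental_sex="nonspecific",
        repeated_measurement="no",
    )
    defaults.update(overrides)
    return EffectSizeRecord(
        estimate_id=estimate_id, study_id=study_id, species=species,
        h2=h2, se=se, n=n, publication_year=publication_year, **defaults,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def paper_scale_dataset():
    """One synthetic dataset at the design size of the real literature."""
    cfg = synthetic_data.SimulationConfig(seed=42)
    tree = synthetic_data.simulate_tree(cfg.n_species, cfg.seed)
    records, truth = synthetic_data.simulate_dataset(cfg, tree=tree)
    A = phylo.phylo_correlation(tree)
    return records, truth, A, tree


@pytest.fixture(scope="session")
def small_dataset():
    """Compact dataset (20 records, 8 studies, 5 species) for fast fits."""
    cfg = synthetic_data.SimulationConfig(
        n_species=5, n_studies=8, n_estimates=20, seed=11
    )
    tree = synthetic_data.simulate_tree(5, 11)
    records, truth = synthetic_data.simulate_dataset(cfg, tree=tree)
    A = phylo.phylo_correlation(tree)
    return records, truth, A
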