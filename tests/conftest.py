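import numpy as np
import pytest

from armsurvey import pipeline, simgen


@pytest.fixture(scope="session")
def small_cfg():
    return simgen.SimConfig(
        seed=1, arm_size=300_000, n_genes=60, repeat_fraction=0.5,
        coverage_fold=2.0, purity=0.92, artifact_rate=0.02,
        n_nonsyntenic_pool=30, n_nonsyntenic_insertions=6,
        n_contaminant_genes=10, marker_fraction=0.5, n_bins=6)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """One modest arm survey shared by the unit tests."""
    return pipeline.simulate_all(small_cfg)


@pytest.fixture(scope="session")
def small_filtered(small_sim):
    lib = sorted(small_sim["arm"].te_families.items())
    return pipeline.run_repeat_filter(small_sim["reads"], lib)


@pytest.fixture(scope="session")
def small_hom(small_sim, small_filtered):
    return pipeline.run_homology(
        small_filtered["reads"], small_sim["panel"],
        organelle_genome=small_sim["arm"].organelle_genome)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
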