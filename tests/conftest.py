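import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from divshift.io import Dataset
from divshift.synthetic import SyntheticConfig, generate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


SMALL_CONFIG = SyntheticConfig(
    n_genomes=60,
    n_phyla=10,
    depth_per_sample=50_000,
    function_pool_size=20,
    seed=11,
)


@pytest.fixture(scope="session")
def small_null_dataset():
    """Small watershed with no runoff effect."""
    import dataclasses

    return generate_dataset(dataclasses.replace(SMALL_CONFIG, runoff_tilt=0.0))


@pytest.fixture(scope="session")
def small_tilted_dataset():
    """Small watershed with a strong evenness loss in the H class."""
    import dataclasses

    return generate_dataset(dataclasses.replace(SMALL_CONFIG, runoff_tilt=0.6))


@pytest.fixture(scope="session")
def default_dataset():
    """Full-scale watershed (300 genomes, 25 phyla) with a moderate tilt."""
    return generate_dataset(SyntheticConfig(seed=2, runoff_tilt=0.3))


@pytest.fixture()
def as_bundle():
    def _bundle(ds) -> Dataset:
        return Dataset(
            counts=ds.counts,
            taxonomy=ds.taxonomy,
            quality=ds.quality,
            design=ds.design,
            annotations=ds.annotations,
            pathways=ds.pathways,
            geochem=ds.geochem,
        )

    return _bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_profile(rng, n_taxa=6, classes=("L", "C", "H", "S")):
    """Random taxon x class proportion profile."""
    X = rng.dirichlet(np.ones(n_taxa), size=len(classes)).T
    return pd.DataFrame(X, index=[f"t{i}" for i in range(n_taxa)], columns=list(classes))
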