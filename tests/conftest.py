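import numpy as np
import pytest

from silkatlas.assembly import assemble_loci
from silkatlas.pipeline import discover
from silkatlas.synthetic import (SyntheticConfig, grouped_config,
                                 load_terminal_library, make_bundle)

BUNDLE_SEED = 1


@pytest.fixture(scope="session")
def refs():
    return load_terminal_library()


@pytest.fixture(scope="session")
def bundle():
    """Default study-condition bundle: 10 spidroins (1 frameshifted,
    1 C-truncated) + 50 decoys on 3 chromosomes."""
    return make_bundle(SyntheticConfig(), seed=BUNDLE_SEED)


@pytest.fixture(scope="session")
def discovery(bundle, refs):
    return discover(bundle.proteome, refs)


@pytest.fixture(scope="session")
def models(bundle, refs):
    return assemble_loci(refs, bundle.chromosomes)


@pytest.fixture(scope="session")
def grouped_bundle():
    """Bundle with three chromosome groups of sizes 4 / 4 / 5."""
    return make_bundle(grouped_config(), seed=BUNDLE_SEED)


@pytest.fixture(scope="session")
def grouped_discovery(grouped_bundle, refs):
    return discover(grouped_bundle.proteome, refs)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
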