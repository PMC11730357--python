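import numpy as np
import pytest

import nanotherm as nt


@pytest.fixture(scope="session")
def syn_small():
    """Small synthetic labeled dataset shared across tests (n=120)."""
    return nt.generate_labeled_dataset(nt.SyntheticSpec(n=120, seed=42))


@pytest.fixture(scope="session")
def syn_small_onehot(syn_small):
    ds = syn_small.dataset
    return nt.encode_sequences(ds.aligned, "onehot", ids=ds.ids)


@pytest.fixture(scope="session")
def syn_small_strata(syn_small):
    ds = syn_small.dataset
    return nt.make_strata(ds.methods, syn_small.template_labels,
                          min_class_size=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
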