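import numpy as np
import pytest

from keystone.abundance_data import Cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_cohort():
    """4-sample, 3-taxon cohort with taxon 0 present in samples 0 and 2.

    Reduced profiles (excluding taxon 0) are [0.5, 0.5] for the present
    group and [0.25, 0.75] for the absent group, giving hand-computable
    D1 = D2 = 0.25 under Bray-Curtis.
    """
    abund = np.array([
        [0.2, 0.0, 0.2, 0.0],
        [0.4, 0.25, 0.4, 0.25],
        [0.4, 0.75, 0.4, 0.75],
    ])
    return Cohort(abund, ["t0", "t1", "t2"], ["s0", "s1", "s2", "s3"])


def random_cohort(rng, n_taxa=20, n_samples=30, sparsity=0.3):
    """I.i.d. random compositional cohort with independent presence."""
    raw = rng.uniform(0.0, 1.0, (n_taxa, n_samples))
    raw *= rng.random((n_taxa, n_samples)) > sparsity
    # ensure no zero-sum columns
    dead = raw.sum(axis=0) == 0
    raw[0, dead] = 1.0
    return Cohort.from_counts(raw, [f"t{i}" for i in range(n_taxa)],
                              [f"s{k}" for k in range(n_samples)])
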