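import numpy as np
import pandas as pd
import pytest

from sibriver import GenotypeTable


def make_table(calls, pops=None, fragments=None, locus_ids=None, ids=None):
    """Small genotype table from a nested list/array of calls (rows = individuals)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_loci = calls.shape
    ids = ids or [f"i{k}" for k in range(n_ind)]
    pops = np.array(pops if pops is not None else ["pop1"] * n_ind, dtype=object)
    locus_ids = locus_ids or [f"L{k}" for k in range(n_loci)]
    fragments = fragments or [f"frag{k}" for k in range(n_loci)]
    loci = pd.DataFrame(
        {"locus_id": locus_ids, "fragment_id": fragments, "ref": "A", "alt": "B"}
    )
    return GenotypeTable(ids, pops, loci, calls)


@pytest.fixture
def table_factory():
    return make_table


def hwe_table(rng, n, freqs, pops=None, ids=None):
    """n individuals drawn in HWE at per-locus frequencies."""
    calls = rng.binomial(2, np.broadcast_to(freqs, (n, len(freqs))))
    return make_table(calls.astype(np.int8), pops=pops, ids=ids)


@pytest.fixture
def hwe_factory():
    return hwe_table
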