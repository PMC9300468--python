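import numpy as np
import pytest

from fcabseq import (
    SimulationConfig,
    TRNAGene,
    toy_mt_trna_set,
    wt_default_truth,
)


@pytest.fixture(scope="session")
def toy_refset():
    return toy_mt_trna_set()


@pytest.fixture(scope="session")
def amplicon_refset(toy_refset):
    """The two genes the targeted amplicon assay sequences."""
    return {k: toy_refset[k] for k in ("MT-TM", "MT-TS2")}


@pytest.fixture(scope="session")
def tiny_refset():
    """Two short, dissimilar genes for exhaustive-oracle alignment tests."""
    return {
        "GENE1": TRNAGene("GENE1", "ACGTACCGGTTACGATCCGATACGGATCTTAGCCGTAACG"),
        "GENE2": TRNAGene("GENE2", "TTGCAACTGGCATCAACGGCCTTGAGATCACGTGCTATGC"),
    }


@pytest.fixture
def wt_truth():
    return wt_default_truth()


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_reads_per_chemistry=400, n_replicates=2, read_length=40, rng_seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(13)
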