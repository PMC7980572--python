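import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ncrpi import (
    IPTable,
    PairSample,
    ProteinRecord,
    RnaRecord,
    SynthConfig,
    generate_dataset,
    make_ip_table_fixture,
)


@pytest.fixture
def ip_table():
    return make_ip_table_fixture(seed=11)


@pytest.fixture
def uniform_ip():
    return IPTable.uniform()


def _tert(rng, n):
    return pd.DataFrame({
        "asa": rng.lognormal(np.log(50), 0.5, n),
        "cn": rng.lognormal(np.log(15), 0.4, n),
        "hse_up": rng.lognormal(np.log(10), 0.5, n),
        "hse_down": rng.lognormal(np.log(10), 0.5, n),
    })


@pytest.fixture
def small_records():
    """Two fully annotated RNAs and proteins plus two labeled pairs."""
    rng = np.random.default_rng(5)
    rna = [
        RnaRecord("r1", "GCAUGCAUGCAUGCAUGCAU", ss="EESSSHHHHSSSXXSSHHSS"[:20]),
        RnaRecord("r2", "AUGCUAGCUAGCAUGG", ss="EESSHHHHSSEEEEEE"),
    ]
    prot = [
        ProteinRecord(
            "p1",
            "MKVLAWREYDSTGHNQCIFP" "MKVLA",
            ss="HHHHHEEEEECCCCCHHHHH" "CCCCC",
            tert=_tert(rng, 25),
        ),
        ProteinRecord(
            "p2",
            "ARNDCQEGHILKMFPSTWYV" "GGGGG",
            ss="CCCCCCCCCCHHHHHHHHHH" "EEEEE",
            tert=_tert(rng, 25),
        ),
    ]
    pairs = [PairSample("r1", "p1", 1), PairSample("r2", "p2", 0)]
    return rna, prot, pairs


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small synthetic dataset with a strong planted signal, for fast tests."""
    cfg = SynthConfig(
        n_pos=12, n_neg=12,
        rna_len_range=(15, 60), prot_len_range=(25, 60),
        motif_prob_pos=1.0, motif_prob_neg=0.0, seed=3,
    )
    return generate_dataset(cfg)
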