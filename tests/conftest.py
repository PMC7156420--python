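import numpy as np
import pandas as pd
import pytest

from mdseq import load_amplicons
from mdseq.frequency import compute_frequencies
from mdseq.pipeline import parse_mutation_label


@pytest.fixture(scope="session")
def amplicons():
    return load_amplicons()


@pytest.fixture(scope="session")
def kras_ex2_nt(amplicons):
    return amplicons["kras_ex2_nt"]


@pytest.fixture(scope="session")
def kras_ex2_t(amplicons):
    return amplicons["kras_ex2_t"]


@pytest.fixture(scope="session")
def kras_ex1_nt(amplicons):
    return amplicons["kras_ex1_nt"]


@pytest.fixture(scope="session")
def kras_ex1_t(amplicons):
    return amplicons["kras_ex1_t"]


@pytest.fixture(scope="session")
def q61l_key(kras_ex2_nt):
    return parse_mutation_label("A182>T", kras_ex2_nt)


@pytest.fixture()
def empty_calls():
    return pd.DataFrame(columns=["status", "cdna_pos", "ref", "alt", "aa_change"])


@pytest.fixture()
def zero_table(kras_ex2_nt, empty_calls):
    """Frequency table of an all-wild-type sample at the QC floor."""

    def make(sample_id="s", amplicon=kras_ex2_nt, total=150_000, meta=None):
        return compute_frequencies(empty_calls, total, amplicon, sample_id=sample_id, meta=meta)

    return make
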