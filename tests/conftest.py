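import numpy as np
import pytest

from ggscan.proteolysis import ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_protein(rng, length, accession="P00001", start_met=True):
    seq = "".join(rng.choice(list(AA20), size=length))
    if start_met:
        seq = "M" + seq[1:]
    return ProteinRecord(accession, seq)


@pytest.fixture
def mini_proteome():
    """Hand-built proteome exercising every classification branch."""
    return [
        # starts with the S11IP-like N-terminal peptide
        ProteinRecord("S11IP", "MFGSAPQRPVAMTTAQRLKWDEF"),
        # contains an encoded internal GGX motif ...K GG MLTNAR...
        ProteinRecord("MOTIF1", "MAEWVKGGMLTNARDDFHW"),
        # ubiquitin-like stretch holding LIFAGKQLEDGR
        ProteinRecord("UBIQ", "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQK"),
        # Met-clipped candidate: second residue Ala
        ProteinRecord("CLIP1", "MAVLKTNDEWQRFHS"),
        # unreviewed fragment with variable first residue
        ProteinRecord("FRAG1", "XMAAKWDNQLTRVEY", source_db="unreviewed"),
    ]
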