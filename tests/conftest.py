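import numpy as np
import pytest

from archseek.io_formats import Orf, OrfSet
from archseek.similarity import AlignParams
from archseek.synthetic_data import SimConfig, simulate_clade

GENBANK_FIXTURE = """\
LOCUS       testrec                   34 bp    DNA     linear   UNK 01-JAN-1980
DEFINITION  synthetic three-CDS test record.
ACCESSION   testrec
VERSION     testrec.1
KEYWORDS    .
SOURCE      .
  ORGANISM  .
FEATURES             Location/Qualifiers
     CDS             1..9
                     /locus_tag="t1"
                     /product="toy protein 1"
                     /translation="MKT"
     CDS             complement(26..34)
                     /locus_tag="t2"
                     /translation="MCE"
     CDS             13..24
                     /locus_tag="t3"
ORIGIN
        1 atgaaaactt ttatgggtgg ataaattcgc acat
//
"""


@pytest.fixture
def genbank_file(tmp_path):
    p = tmp_path / "toy.gbk"
    p.write_text(GENBANK_FIXTURE)
    return p


@pytest.fixture(scope="session")
def default_params():
    return AlignParams()


@pytest.fixture(scope="session")
def small_sim():
    """A small, loss-free clade: clean family correspondence across leaves."""
    return simulate_clade(
        SimConfig(
            seed=7,
            n_core_families=12,
            n_clade_specific=4,
            n_hgt=3,
            gene_len_mean=120,
            gene_len_sd=20,
            loss_prob=0.0,
        )
    )


def random_orfset(rng: np.random.Generator, genome_id: str, n: int, length: int = 40) -> OrfSet:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    orfs = [
        Orf(
            f"{genome_id}_o{i}",
            "".join(aas[k] for k in rng.integers(0, 20, size=length)),
        )
        for i in range(n)
    ]
    return OrfSet(genome_id, orfs)
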