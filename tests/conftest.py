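import numpy as np
import pytest
from hypothesis import settings

import pcrfidelity as pf

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def homolog_set():
    """1100-bp homolog pair with 9 markers (recombination-assay geometry)."""
    seq_a, seq_b, table = pf.make_artificial_template(1100, 9, seed=101)
    return pf.TemplateSet(
        entries=[pf.TemplateEntry("DNA-A", seq_a, "homolog-A"),
                 pf.TemplateEntry("DNA-B", seq_b, "homolog-B")],
        marker_table=table)


@pytest.fixture(scope="session")
def structured_set():
    """1353-bp amplicon carrying an inverted repeat at 45..183.

    Stem 10 / loop 119, the geometry whose 5'-anchored single-switch
    fold-back product is 227 nt.
    """
    rng = np.random.default_rng(202)
    from pcrfidelity.dna import random_sequence
    seq = random_sequence(1353, rng)
    seq, element = pf.insert_inverted_repeat(seq, 45, 10, 119, rng)
    return pf.TemplateSet(
        entries=[pf.TemplateEntry("structured-1", seq, "structured")],
        elements=[element])


@pytest.fixture(scope="session")
def plain_amplicon():
    from pcrfidelity.dna import random_sequence
    seq = random_sequence(1100, np.random.default_rng(303))
    return pf.TemplateSet(entries=[pf.TemplateEntry("amp", seq, "amplicon")])


def make_read(sequence="ACGTACGTAC", read_id="r0", strand="+", n_passes=20,
              mapq=254, qualities=None, reference_name="ref", ref_start=0,
              cigar=None, is_chimeric=False):
    return pf.ConsensusRead(
        read_id=read_id, sequence=sequence, strand=strand, n_passes=n_passes,
        mapq=mapq, qualities=qualities, reference_name=reference_name,
        ref_start=ref_start, cigar=cigar, is_chimeric=is_chimeric)
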