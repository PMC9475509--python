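import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_corpus(tmp_path):
    """A 6-record FASTA exercising the common CDS defects."""
    fasta = tmp_path / "corpus.fa"
    fasta.write_text(
        ">g1|t1 gene:geneA\n"
        "ATGAAACAAGAATAA\n"          # clean: ATG AAA CAA GAA + stop
        ">g2|t1\n"
        "ATGAAAT\n"                   # trailing partial codon
        ">g3|t1\n"
        "atgtttugg\n"                 # lowercase + RNA U, no stop
        ">g4|t1\n"
        "ATGTAACCCTAA\n"              # internal stop
        ">g5|t1\n"
        "ATGANATAA\n"                 # ambiguous codon
        ">bad|t1\n"
        "AT\n"                        # too short -> rejected
    )
    return fasta
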