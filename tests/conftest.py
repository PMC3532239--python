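import numpy as np
import pytest

from enu_spectra.core_models_io import GenomeSequence, TranscriptModel
from enu_spectra.synthetic_data import ToyGenomeSpec, make_toy_transcriptome


@pytest.fixture
def mini_gene():
    """Single-exon plus-strand gene: CDS ATGAAATGA (M K *)."""
    genome = GenomeSequence({"chrT": "ATGAAATGA"})
    model = TranscriptModel(
        gene_id="g1", transcript_id="t1", contig="chrT", strand="+",
        exons=[(1, 9)], cds=[(1, 9)],
    )
    return genome, model


@pytest.fixture
def two_exon_gene():
    """Plus-strand gene with exon 1-6, intron 7-106 (GT..AG), exon 107-112.

    Sense CDS: ATGAAA + AAATGA = M K K * .
    """
    intron = "GT" + "C" * 96 + "AG"
    seq = "ATGAAA" + intron + "AAATGA" + "TTTT"
    genome = GenomeSequence({"chrT": seq})
    model = TranscriptModel(
        gene_id="g2", transcript_id="t2", contig="chrT", strand="+",
        exons=[(1, 6), (107, 112)], cds=[(1, 6), (107, 112)],
    )
    return genome, model


@pytest.fixture
def toy_transcriptome():
    """Deterministic 5-gene toy genome with both strands represented."""
    return make_toy_transcriptome(ToyGenomeSpec(n_genes=5, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
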