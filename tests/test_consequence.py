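"""Consequence classification: coding calls, splice geometry, strand handling."""

import numpy as np
import pytest

from enu_spectra.consequence import (
    OVERT_NULL_CATEGORIES,
    classify,
    classify_batch,
    splice_distance,
    summarize_calls,
)
from enu_spectra.core_models_io import (
    GenomeSequence,
    MutationRecord,
    SubstitutionType,
    TranscriptModel,
    revcomp,
)
from enu_spectra.synthetic_data import make_mutation_set


def _mut(pos, ref, alt, contig="chrT", dataset="unlabeled"):
    return MutationRecord("m", contig, pos, ref, alt, dataset)


class TestCodingCalls:
    def test_nonsense_K2stop(self, mini_gene):
        genome, model = mini_gene
        call = classify(_mut(4, "A", "T"), model, genome)
        assert call.category == "nonsense"
        assert (call.codon_from, call.codon_to) == ("AAA", "TAA")
        assert call.aa_change == "K2*"
        assert call.overt_null

    def test_make_sense_stop3W(self, mini_gene):
        genome, model = mini_gene
        call = classify(_mut(9, "A", "G"), model, genome)
        assert call.category == "make_sense"
        assert (call.codon_from, call.codon_to) == ("TGA", "TGG")
        assert call.aa_change == "*3W"
        assert not call.overt_null

    def test_missense_and_synonymous(self, mini_gene):
        genome, model = mini_gene
        assert classify(_mut(5, "A", "G"), model, genome).category == "missense"  # AAA->AGA K->R
        assert classify(_mut(6, "A", "G"), model, genome).category == "synonymous"  # AAA->AAG K

    def test_start_loss(self, mini_gene):
        genome, model = mini_gene
        call = classify(_mut(2, "T", "C"), model, genome)
        assert call.category == "start_loss"
        assert call.aa_change == "M1T"
        assert not call.overt_null

    def test_minus_strand_sense_substitution(self):
        # gene is the reverse complement of ATGAAATGA (M K *)
        genome = GenomeSequence({"c": revcomp("ATGAAATGA")})
        model = TranscriptModel("g", "t", "c", "-", [(1, 9)], [(1, 9)])
        assert model.cds_sequence(genome) == "ATGAAATGA"
        # genomic C->T at pos 2 is sense G->A at sense position 8: TGA->TAA,
        # a stop-to-stop change, i.e. synonymous
        call = classify(_mut(2, "C", "T", contig="c"), model, genome)
        assert call.sense_substitution == SubstitutionType("G", "A")
        assert call.category == "synonymous"
        # genomic T->C at pos 6 is sense A->G at sense position 4, the first
        # base of codon 2: AAA->GAA, K2E
        call = classify(_mut(6, "T", "C", contig="c"), model, genome)
        assert call.sense_substitution == SubstitutionType("A", "G")
        assert call.category == "missense"
        assert call.aa_change == "K2E"

    def test_single_base_deletion_is_frameshift(self, mini_gene):
        genome, model = mini_gene
        call = classify(_mut(5, "A", ""), model, genome)
        assert call.category == "frameshift"
        assert call.overt_null

    def test_ref_mismatch_raises(self, mini_gene):
        genome, model = mini_gene
        with pytest.raises(ValueError, match="does not match genome"):
            classify(_mut(4, "C", "T"), model, genome)

    def test_outside_span_is_intergenic(self, two_exon_gene):
        genome, model = two_exon_gene
        call = classify(_mut(115, "T", "A"), model, genome)
        assert call.category == "intergenic"


class TestSpliceCalls:
    def test_critical_donor_distance_2(self, two_exon_gene):
        genome, model = two_exon_gene
        call = classify(_mut(8, "T", "A"), model, genome)
        assert call.category == "critical_splice_donor"
        assert call.splice_distance == 2
        assert call.overt_null

    def test_noncritical_donor_distance_5(self, two_exon_gene):
        genome, model = two_exon_gene
        call = classify(_mut(11, "C", "T"), model, genome)
        assert call.category == "noncritical_splice_donor"
        assert call.splice_distance == 5
        assert not call.overt_null

    def test_critical_acceptor(self, two_exon_gene):
        genome, model = two_exon_gene
        call = classify(_mut(105, "A", "C"), model, genome)
        assert call.category == "critical_splice_acceptor"
        assert call.splice_distance == 2
        assert call.overt_null

    def test_deep_intronic_beyond_window(self, two_exon_gene):
        genome, model = two_exon_gene
        assert classify(_mut(50, "C", "T"), model, genome).category == "deep_intronic"

    def test_window_is_configurable(self, two_exon_gene):
        genome, model = two_exon_gene
        call = classify(_mut(18, "C", "T"), model, genome, window=15)
        assert call.category == "noncritical_splice_donor"
        assert call.splice_distance == 12
        assert classify(_mut(18, "C", "T"), model, genome, window=10).category == "deep_intronic"

    def test_splice_distance_boundaries(self, two_exon_gene):
        _, model = two_exon_gene
        assert splice_distance(7, model) == (1, "donor")
        assert splice_distance(106, model) == (1, "acceptor")
        with pytest.raises(ValueError, match="not intronic"):
            splice_distance(4, model)

    def test_minus_strand_donor_is_genomically_rightmost(self):
        # mirrored two-exon gene: the gene body is the revcomp of the plus
        # strand version, so the donor side of the intron sits at the
        # genomic right end
        intron = "GT" + "C" * 96 + "AG"
        plus = "ATGAAA" + intron + "AAATGA"
        genome = GenomeSequence({"c": revcomp(plus)})
        L = len(plus)
        flip = lambda s, e: (L - e + 1, L - s + 1)
        model = TranscriptModel(
            "g", "t", "c", "-",
            exons=sorted([flip(1, 6), flip(107, 112)]),
            cds=sorted([flip(1, 6), flip(107, 112)]),
        )
        assert model.cds_sequence(genome) == "ATGAAAAAATGA"
        # genomically-rightmost intron base adjacent to an exon = donor 1
        intron_start, intron_end = model.introns()[0]
        assert splice_distance(intron_end, model) == (1, "donor")
        assert splice_distance(intron_start, model) == (1, "acceptor")


class TestInvariants:
    def test_partition_over_gene_span(self, two_exon_gene):
        """Every single-base substitution in the span gets exactly one category."""
        genome, model = two_exon_gene
        for pos in range(1, 113):
            ref = genome.base("chrT", pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                call = classify(_mut(pos, ref, alt), model, genome)
                assert call.category in {
                    "missense", "synonymous", "nonsense", "make_sense", "start_loss",
                    "critical_splice_donor", "critical_splice_acceptor",
                    "noncritical_splice_donor", "noncritical_splice_acceptor",
                    "deep_intronic",
                }
                assert call.overt_null == (call.category in OVERT_NULL_CATEGORIES)

    def test_strand_equivariance(self, toy_transcriptome):
        """Mirroring the genome and all gene coordinates preserves category
        and sense-strand substitution type for every mutation."""
        genome, models = toy_transcriptome
        L = genome.lengths()["toy1"]
        mirrored = GenomeSequence({"toy1": revcomp(genome.contigs["toy1"])})

        def flip_model(m):
            flip = lambda s, e: (L - e + 1, L - s + 1)
            return TranscriptModel(
                m.gene_id, m.transcript_id, m.contig,
                "+" if m.strand == "-" else "-",
                sorted(flip(s, e) for s, e in m.exons),
                sorted(flip(s, e) for s, e in m.cds),
            )

        rng = np.random.default_rng(0)
        for m in models:
            fm = flip_model(m)
            s, e = m.span
            for _ in range(40):
                pos = int(rng.integers(s, e + 1))
                ref = genome.base("toy1", pos)
                alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
                call = classify(_mut(pos, ref, alt, contig="toy1"), m, genome)
                mpos = L - pos + 1
                mref = revcomp(ref)
                malt = revcomp(alt)
                mcall = classify(_mut(mpos, mref, malt, contig="toy1"), fm, mirrored)
                assert mcall.category == call.category
                assert mcall.sense_substitution == call.sense_substitution


class TestBatch:
    def test_summary_one_per_category(self, toy_transcriptome):
        genome, models = toy_transcriptome
        requests = {
            "phenotypic": {
                "missense": 1, "synonymous": 1, "nonsense": 1,
                "critical_splice_donor": 1, "noncritical_splice_acceptor": 1,
                "frameshift": 1,
            }
        }
        muts = make_mutation_set(models, genome, requests, seed=8)
        batch = classify_batch(muts, models, genome)
        assert not batch.errors
        assert len(batch.summary) == 6
        assert batch.summary["phenotypic"].sum() == 6

    def test_empty_batch(self, toy_transcriptome):
        genome, models = toy_transcriptome
        batch = classify_batch([], models, genome)
        assert batch.summary.empty

    def test_overt_ratio_rendering(self):
        """59 overt nulls against 122 other calls renders as 1 : 2.07."""
        from enu_spectra.consequence import ConsequenceCall

        calls = [
            ConsequenceCall(f"n{i}", "g", "nonsense", dataset="phenotypic")
            for i in range(59)
        ] + [
            ConsequenceCall(f"m{i}", "g", "missense", dataset="phenotypic")
            for i in range(122)
        ]
        summary = summarize_calls(calls)
        assert summary.attrs["overt_ratio"]["phenotypic"] == "1 : 2.07"
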