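"""Substitution-opportunity enumeration and binomial null probabilities.

For a transcript set, count every possible sense-strand single-base
substitution that would (a) change coding sense — missense, nonsense,
make-sense or start-loss, but not synonymous — or (b) hit one of the four
critical splice-junction bases of an intron.  The per-type totals define the
null probability of observing a substitution on the sense rather than the
antisense strand:

    p(s) = N_total(s) / (N_total(s) + N_total(complement(s)))

since a substitution of type s on the antisense strand reads as complement(s)
on the sense strand, and under the null both strands are equally mutable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .consequence import translate_codon
from .core_models_io import (
    ALL_SUBSTITUTIONS,
    COMPLEMENT,
    GenomeSequence,
    SubstitutionType,
    TranscriptModel,
)


@dataclass
class OpportunityTable:
    """Per-substitution-type counts of possible coding-change and
    critical-splice-change events, with derived null probabilities."""

    coding: dict[SubstitutionType, int] = field(
        default_factory=lambda: {s: 0 for s in ALL_SUBSTITUTIONS}
    )
    splice: dict[SubstitutionType, int] = field(
        default_factory=lambda: {s: 0 for s in ALL_SUBSTITUTIONS}
    )

    def n_coding(self, s: SubstitutionType) -> int:
        return self.coding.get(s, 0)

    def n_splice(self, s: SubstitutionType) -> int:
        return self.splice.get(s, 0)

    def n_total(self, s: SubstitutionType) -> int:
        return self.n_coding(s) + self.n_splice(s)

    @property
    def grand_total(self) -> int:
        return sum(self.n_total(s) for s in ALL_SUBSTITUTIONS)

    def add(self, other: "OpportunityTable") -> "OpportunityTable":
        out = OpportunityTable()
        for s in ALL_SUBSTITUTIONS:
            out.coding[s] = self.n_coding(s) + other.n_coding(s)
            out.splice[s] = self.n_splice(s) + other.n_splice(s)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "substitution": str(s),
                "coding": self.n_coding(s),
                "splice": self.n_splice(s),
                "total": self.n_total(s),
            }
            for s in sorted(ALL_SUBSTITUTIONS, key=str)
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OpportunityTable":
        table = cls()
        for _, row in df.iterrows():
            s = SubstitutionType.parse(str(row["substitution"]))
            table.coding[s] = int(row["coding"])
            table.splice[s] = int(row["splice"])
        return table

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OpportunityTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def enumerate_gene_opportunities(
    model: TranscriptModel, genome: GenomeSequence
) -> OpportunityTable:
    """Opportunity counts contributed by a single transcript model.

    Every CDS position is tested against its three alternative bases in
    sense-strand space: the substitution counts toward the coding total iff
    the encoded residue or stop status changes.  Codons containing N are
    skipped.  Each intron contributes its four critical bases (donor 1-2,
    acceptor 1-2) times three alternates to the splice total, keyed by the
    sense-strand identity of the reference base with no coding filter.
    """
    table = OpportunityTable()
    cds = model.cds_sequence(genome)
    n_codons = len(cds) // 3
    for ci in range(n_codons):
        codon = cds[3 * ci : 3 * ci + 3]
        if "N" in codon:
            continue
        aa = translate_codon(codon)
        for within in range(3):
            ref = codon[within]
            for alt in "ACGT":
                if alt == ref:
                    continue
                mutated = codon[:within] + alt + codon[within + 1 :]
                if translate_codon(mutated) != aa:
                    table.coding[SubstitutionType(ref, alt)] += 1
    for start, end in model.introns():
        for pos in (start, start + 1, end - 1, end):
            if not (start <= pos <= end):
                continue  # degenerate short intron
            base = genome.base(model.contig, pos)
            if model.strand == "-":
                base = base.translate(COMPLEMENT)
            if base == "N":
                continue
            for alt in "ACGT":
                if alt != base:
                    table.splice[SubstitutionType(base, alt)] += 1
    return table


def enumerate_opportunities(
    models: Sequence[TranscriptModel], genome: GenomeSequence
) -> OpportunityTable:
    """Aggregate opportunity counts over one chosen transcript per gene.

    Overlapping transcripts are counted independently per model; a warning
    reports how many genomic positions are claimed by more than one model so
    users can assess double-counting.
    """
    _warn_on_overlaps(models)
    total = OpportunityTable()
    for model in models:
        total = total.add(enumerate_gene_opportunities(model, genome))
    return total


def _warn_on_overlaps(models: Sequence[TranscriptModel]) -> None:
    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for m in models:
        s, e = m.span
        by_contig.setdefault(m.contig, []).append((s, e, m.gene_id))
    overlap = 0
    for spans in by_contig.values():
        spans.sort()
        for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                overlap += min(e1, e2) - s2 + 1
    if overlap:
        warnings.warn(f"{overlap} genomic positions shared by more than one chosen transcript")


def null_probabilities(table: OpportunityTable) -> dict[SubstitutionType, float]:
    """Sense-strand null probability for each substitution type.

    p(s) + p(complement(s)) = 1 for every complementary pair.  Pairs with a
    zero denominator are omitted from the result.
    """
    probs: dict[SubstitutionType, float] = {}
    for s in ALL_SUBSTITUTIONS:
        denom = table.n_total(s) + table.n_total(s.complement())
        if denom == 0:
            continue
        probs[s] = table.n_total(s) / denom
    return probs
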