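"""Classify mutations against transcript models.

Categories follow the forward-genetics allele taxonomy: coding substitutions
(missense / synonymous / nonsense / make-sense / start-loss), splice-junction
substitutions split into critical (the GT/AG dinucleotides at intron positions
1-2) and non-critical (positions 3..W, default window W=10), structural indel
classes, and the residual deep-intronic / intergenic / unresolvable bins.

An *overt null* is a frameshift, nonsense, or critical-splice allele — the
classes assumed to abolish protein function outright.

Decision ladder when a position could be read two ways: critical splice >
non-critical splice > coding change > deep intronic.  The splice dichotomy
takes precedence because a junction hit disrupts the transcript regardless of
what the base would encode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .core_models_io import (
    COMPLEMENT,
    GenomeSequence,
    MutationRecord,
    SubstitutionType,
    TranscriptModel,
)

STANDARD_TABLE = unambiguous_dna_by_id[1]

CATEGORIES = (
    "missense",
    "synonymous",
    "nonsense",
    "make_sense",
    "start_loss",
    "critical_splice_donor",
    "critical_splice_acceptor",
    "noncritical_splice_donor",
    "noncritical_splice_acceptor",
    "frameshift",
    "inframe_indel",
    "deep_intronic",
    "intergenic",
    "unresolvable",
)

OVERT_NULL_CATEGORIES = frozenset(
    {"frameshift", "nonsense", "critical_splice_donor", "critical_splice_acceptor"}
)

#: Categories carrying an amino-acid change annotation.
AA_CATEGORIES = frozenset({"missense", "synonymous", "nonsense", "make_sense", "start_loss"})

#: Categories that qualify for the substitution-spectrum tallies: single-base
#: changes altering coding sense or hitting a critical splice junction.
SPECTRUM_CATEGORIES = frozenset(
    {"missense", "nonsense", "make_sense", "start_loss",
     "critical_splice_donor", "critical_splice_acceptor"}
)


def translate_codon(codon: str, table=STANDARD_TABLE) -> str:
    """One-letter residue for a codon, '*' for stop, 'X' if ambiguous."""
    if any(b not in "ACGT" for b in codon) or len(codon) != 3:
        return "X"
    return table.forward_table.get(codon, "*")


@dataclass
class ConsequenceCall:
    """The classified effect of one mutation on one transcript."""

    mutation_id: str
    gene_id: str
    category: str
    dataset: str = "unlabeled"
    sense_substitution: SubstitutionType | None = None
    codon_from: str | None = None
    codon_to: str | None = None
    aa_from: str | None = None
    aa_to: str | None = None
    residue_index: int | None = None
    splice_distance: int | None = None
    score: float | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def overt_null(self) -> bool:
        return self.category in OVERT_NULL_CATEGORIES

    @property
    def aa_change(self) -> str | None:
        if self.aa_from is None:
            return None
        return f"{self.aa_from}{self.residue_index}{self.aa_to}"


def splice_distance(position: int, model: TranscriptModel) -> tuple[int, str]:
    """Distance (>=1) of an intronic position from the nearest exon boundary,
    plus the side in transcript orientation: donor = 5' end of the intron,
    acceptor = 3' end.

    Raises ``ValueError`` for non-intronic positions.
    """
    for start, end in model.introns():
        if start <= position <= end:
            d_left = position - start + 1
            d_right = end - position + 1
            if model.strand == "+":
                d_donor, d_acceptor = d_left, d_right
            else:
                d_donor, d_acceptor = d_right, d_left
            if d_donor <= d_acceptor:
                return d_donor, "donor"
            return d_acceptor, "acceptor"
    raise ValueError(f"position {position} is not intronic for {model.transcript_id}")


def classify(
    mutation: MutationRecord,
    model: TranscriptModel,
    genome: GenomeSequence,
    window: int = 10,
) -> ConsequenceCall:
    """Classify one mutation against one transcript model.

    ``window`` is the non-critical splice window: intronic positions 1-2 are
    critical, 3..window are non-critical, deeper ones deep_intronic.
    """
    mutation.check_reference(genome)

    def call(category: str, **kw) -> ConsequenceCall:
        return ConsequenceCall(
            mutation_id=mutation.id,
            gene_id=model.gene_id,
            category=category,
            dataset=mutation.dataset,
            score=mutation.score,
            **kw,
        )

    pos = mutation.position
    if not model.contains(pos):
        return call("intergenic")

    # Intronic positions: the splice ladder outranks everything else.
    for start, end in model.introns():
        if start <= pos <= end:
            dist, side = splice_distance(pos, model)
            sense_sub = None
            if mutation.is_snv:
                sense_sub = _sense_substitution(mutation, model)
            if dist <= 2:
                category = f"critical_splice_{side}"
            elif dist <= window:
                category = f"noncritical_splice_{side}"
            else:
                return call("deep_intronic", splice_distance=dist)
            return call(category, splice_distance=dist, sense_substitution=sense_sub)

    # Indels and multi-nucleotide substitutions within exons: structural call.
    if not mutation.is_snv:
        if model.in_cds(pos):
            if mutation.length_change % 3 != 0:
                return call("frameshift")
            return call("inframe_indel")
        return call("unresolvable")

    if not model.in_cds(pos):
        # Exonic but non-coding (UTR); outside the scope of the coding taxonomy.
        return call("unresolvable")

    return _classify_coding_snv(mutation, model, genome, call)


def _sense_substitution(mutation: MutationRecord, model: TranscriptModel) -> SubstitutionType:
    ref, alt = mutation.ref, mutation.alt
    if model.strand == "-":
        ref = ref.translate(COMPLEMENT)
        alt = alt.translate(COMPLEMENT)
    return SubstitutionType(ref, alt)


def _classify_coding_snv(mutation, model, genome, call) -> ConsequenceCall:
    cds = model.cds_sequence(genome)
    idx = model.cds_coordinate(mutation.position)
    codon_index = idx // 3
    within = idx % 3
    codon_start = codon_index * 3
    codon_from = cds[codon_start : codon_start + 3]
    if len(codon_from) < 3:
        return call("unresolvable")
    sense_sub = _sense_substitution(mutation, model)
    assert codon_from[within] == sense_sub.from_base, (
        f"{mutation.id}: CDS base {codon_from[within]} != sense ref {sense_sub.from_base}"
    )
    codon_to = codon_from[:within] + sense_sub.to_base + codon_from[within + 1 :]
    aa_from = translate_codon(codon_from)
    aa_to = translate_codon(codon_to)
    if "X" in (aa_from, aa_to) or "N" in codon_from:
        return call("unresolvable", sense_substitution=sense_sub)
    common = dict(
        sense_substitution=sense_sub,
        codon_from=codon_from,
        codon_to=codon_to,
        aa_from=aa_from,
        aa_to=aa_to,
        residue_index=codon_index + 1,
    )
    if aa_from == aa_to:
        return call("synonymous", **common)
    if codon_index == 0 and codon_from == "ATG" and model.complete:
        return call("start_loss", **common)
    if aa_to == "*" and aa_from != "*":
        return call("nonsense", **common)
    if aa_from == "*" and aa_to != "*":
        return call("make_sense", **common)
    return call("missense", **common)


# ----------------------------------------------------------------------
# Batch classification
# ----------------------------------------------------------------------

@dataclass
class BatchResult:
    calls: list[ConsequenceCall]
    errors: list[tuple[str, str]]
    summary: pd.DataFrame


def _find_model(mutation: MutationRecord, models: Sequence[TranscriptModel]):
    candidates = [
        m for m in models
        if m.contig == mutation.contig and m.contains(mutation.position)
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda m: m.gene_id)


def classify_batch(
    mutations: Iterable[MutationRecord],
    models: Sequence[TranscriptModel],
    genome: GenomeSequence,
    window: int = 10,
) -> BatchResult:
    """Classify every mutation; per-record errors are collected, not fatal.

    The summary counts category x dataset with percent-of-total columns;
    start-loss calls are folded into missense there (they are reported as
    their own category on each call).  When overt nulls are present, an
    ``overt_ratio`` attribute on the summary records "1 : R" per dataset.
    """
    calls: list[ConsequenceCall] = []
    errors: list[tuple[str, str]] = []
    for mut in mutations:
        model = _find_model(mut, models)
        if model is None:
            calls.append(
                ConsequenceCall(mutation_id=mut.id, gene_id="", category="intergenic",
                                dataset=mut.dataset, score=mut.score)
            )
            continue
        try:
            calls.append(classify(mut, model, genome, window=window))
        except (ValueError, KeyError, IndexError) as exc:
            errors.append((mut.id, str(exc)))
    summary = summarize_calls(calls)
    return BatchResult(calls=calls, errors=errors, summary=summary)


def summarize_calls(calls: Sequence[ConsequenceCall]) -> pd.DataFrame:
    """Category x dataset count table with percent-of-total columns."""
    if not calls:
        return pd.DataFrame(columns=["category"])
    rows = []
    for c in calls:
        category = "missense" if c.category == "start_loss" else c.category
        rows.append({"category": category, "dataset": c.dataset})
    df = pd.DataFrame(rows)
    table = df.groupby(["category", "dataset"]).size().unstack(fill_value=0)
    for ds in table.columns:
        total = table[ds].sum()
        table[f"{ds}_pct"] = 100.0 * table[ds] / total if total else 0.0
    table = table.reset_index().rename_axis(None, axis=1)
    ratios = {}
    for ds in {c.dataset for c in calls}:
        overt = sum(1 for c in calls if c.dataset == ds and c.overt_null)
        other = sum(1 for c in calls if c.dataset == ds and not c.overt_null)
        if overt:
            ratios[ds] = f"1 : {other / overt:.3g}"
    table.attrs["overt_ratio"] = ratios
    return table


def calls_to_frame(calls: Sequence[ConsequenceCall]) -> pd.DataFrame:
    """Flatten calls into the classify-output table."""
    rows = []
    for c in calls:
        rows.append(
            {
                "id": c.mutation_id,
                "gene": c.gene_id,
                "category": c.category,
                "dataset": c.dataset,
                "sense_sub": str(c.sense_substitution) if c.sense_substitution else "NA",
                "codon_change": f"{c.codon_from}>{c.codon_to}" if c.codon_from else "NA",
                "aa_change": c.aa_change or "NA",
                "splice_distance": c.splice_distance if c.splice_distance is not None else "NA",
                "overt_null": c.overt_null,
                "score": c.score if c.score is not None else "NA",
            }
        )
    return pd.DataFrame(rows)
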