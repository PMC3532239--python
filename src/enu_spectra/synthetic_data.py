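"""Toy genomes, ground-truth mutation sets, and packaged count-table fixtures.

The toy transcriptome generator emulates just enough gene structure for every
pipeline stage to be exercised end to end: multi-exon genes on both strands,
ATG...stop coding sequences free of internal stops, GT/AG intron ends, and
introns long enough (>= 20 bp) that the critical (1-2) and non-critical
(3-10) splice windows never collide across an intron.  It makes no attempt at
realistic chromosome structure, repeat content, or CpG context.

Mutation sets are generated with known ground truth: candidate positions are
rejection-sampled until the consequence classifier itself confirms the
requested category, so generation-time intent is never trusted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consequence import classify
from .core_models_io import (
    GenomeSequence,
    MutationRecord,
    TranscriptModel,
    revcomp,
    write_mutation_table,
    write_transcript_table,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

FIXTURE_CHECKSUMS = {
    "table2": "3f2cfa6bcddce500c3fb510c951e73bfc53267e9cdb3c3c24d9b07795092153c",
    "table3": "9e8d83e0880f1d39b8bddcd085930039a8f5ff741eab5f49564eb18f0b84a474",
    "table5": "edd91ddd88fcb9909dd5c76cb94cd7595acf998a02ed7c3188d80f2ba589cf60",
    "table7": "a7e87a506075ba3b381f24f8c6e71dc20946724156d55d19b4590bea7d4a5b3d",
}


@dataclass
class ToyGenomeSpec:
    """Parameters of a generated toy transcriptome."""

    n_genes: int = 5
    exons_per_gene: tuple[int, int] = (1, 3)
    codons_per_gene: tuple[int, int] = (30, 80)
    intron_length: tuple[int, int] = (20, 60)
    minus_strand_prob: float = 0.5
    gc_content: float = 0.45
    intergenic_length: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.intron_length[0] < 20:
            raise ValueError("minimum intron length is 20 bp (keeps splice windows disjoint)")
        if self.codons_per_gene[0] < 4:
            raise ValueError("genes need at least 4 codons (start, 2 interior, stop)")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")


def make_toy_transcriptome(
    spec: ToyGenomeSpec, out_dir: str | Path | None = None
) -> tuple[GenomeSequence, list[TranscriptModel]]:
    """Generate a deterministic toy genome + transcript models.

    When ``out_dir`` is given, genome.fa and transcripts.tsv (the simplified
    dialect) plus annotation.gff3 are written there.
    """
    rng = np.random.default_rng(spec.seed)
    chunks: list[str] = []
    genome_len = 0
    models: list[TranscriptModel] = []

    def random_bases(n: int) -> str:
        gc = spec.gc_content
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(rng.choice(list("ACGT"), size=n, p=probs))

    for g in range(spec.n_genes):
        chunks.append(random_bases(spec.intergenic_length))
        genome_len += spec.intergenic_length

        n_codons = int(rng.integers(spec.codons_per_gene[0], spec.codons_per_gene[1] + 1))
        interior = rng.choice(NONSTOP_CODONS, size=n_codons - 2)
        cds = "ATG" + "".join(interior) + str(rng.choice(STOP_CODONS))
        n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        n_exons = min(n_exons, len(cds) // 10)  # keep exons >= ~10 bp
        n_exons = max(n_exons, 1)
        cut_points = sorted(
            rng.choice(np.arange(10, len(cds) - 9), size=n_exons - 1, replace=False)
        ) if n_exons > 1 else []
        exon_seqs = []
        prev = 0
        for cp in list(cut_points) + [len(cds)]:
            exon_seqs.append(cds[prev:cp])
            prev = cp

        # region: exon1 intron1 exon2 ... ; introns begin GT, end AG
        region_parts: list[str] = []
        exon_bounds: list[tuple[int, int]] = []
        cursor = 0
        for i, es in enumerate(exon_seqs):
            exon_bounds.append((cursor + 1, cursor + len(es)))
            region_parts.append(es)
            cursor += len(es)
            if i < len(exon_seqs) - 1:
                ilen = int(rng.integers(spec.intron_length[0], spec.intron_length[1] + 1))
                intron = "GT" + random_bases(ilen - 4) + "AG"
                region_parts.append(intron)
                cursor += ilen
        region = "".join(region_parts)
        strand = "-" if rng.random() < spec.minus_strand_prob else "+"
        gene_start = genome_len + 1
        L = len(region)
        if strand == "+":
            chunks.append(region)
            genomic = [(gene_start + s - 1, gene_start + e - 1) for s, e in exon_bounds]
        else:
            chunks.append(revcomp(region))
            genomic = sorted(
                (gene_start + (L - e), gene_start + (L - s)) for s, e in exon_bounds
            )
        genome_len += L
        models.append(
            TranscriptModel(
                gene_id=f"gene{g + 1}",
                transcript_id=f"tx{g + 1}",
                contig="toy1",
                strand=strand,
                exons=genomic,
                cds=list(genomic),
            )
        )
    chunks.append(random_bases(spec.intergenic_length))
    genome = GenomeSequence({"toy1": "".join(chunks)})
    for m in models:
        msgs = m.validate(genome)
        if msgs:
            raise AssertionError(f"generated model failed validation: {msgs}")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_fasta(genome, out_dir / "genome.fa")
        write_transcript_table(models, out_dir / "transcripts.tsv")
        _write_gff3(models, out_dir / "annotation.gff3")
    return genome, models


def _write_fasta(genome: GenomeSequence, path: Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_gff3(models: Sequence[TranscriptModel], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            fh.write(f"{m.contig}\ttoy\tgene\t{s}\t{e}\t.\t{m.strand}\t.\tID={m.gene_id}\n")
            fh.write(
                f"{m.contig}\ttoy\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for i, (es, ee) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.contig}\ttoy\texon\t{es}\t{ee}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                )
            for i, (cs, ce) in enumerate(m.cds, 1):
                fh.write(
                    f"{m.contig}\ttoy\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t0\t"
                    f"ID={m.transcript_id}.cds{i};Parent={m.transcript_id}\n"
                )


# ----------------------------------------------------------------------
# Ground-truth mutation sets
# ----------------------------------------------------------------------

class CategoryUnreachable(ValueError):
    """Requested category cannot be produced on the given toy transcriptome."""


def make_mutation_set(
    models: Sequence[TranscriptModel],
    genome: GenomeSequence,
    requests: Mapping[str, Mapping[str, int]],
    seed: int = 0,
    window: int = 10,
    out_path: str | Path | None = None,
    max_attempts: int = 20000,
) -> list[MutationRecord]:
    """Draw mutations whose classified category matches the request exactly.

    ``requests`` maps dataset label -> {category: count}.  Positions and
    alternate alleles are rejection-sampled until ``classify`` confirms the
    requested category, so re-classifying the output reproduces the request
    verbatim.  Repeated draws of the same site are allowed (independent
    mutation events may recur).
    """
    rng = np.random.default_rng(seed)
    records: list[MutationRecord] = []
    counter = 0
    for dataset, cats in requests.items():
        for category, count in cats.items():
            for _ in range(int(count)):
                counter += 1
                rec = _sample_one(
                    models, genome, category, dataset, f"m{counter:05d}",
                    rng, window, max_attempts,
                )
                records.append(rec)
    if out_path is not None:
        write_mutation_table(records, out_path)
    return records


def _sample_one(models, genome, category, dataset, mut_id, rng, window, max_attempts):
    for _ in range(max_attempts):
        model = models[int(rng.integers(len(models)))]
        if category in (
            "critical_splice_donor", "critical_splice_acceptor",
            "noncritical_splice_donor", "noncritical_splice_acceptor",
            "deep_intronic",
        ):
            pos = _splice_candidate(model, category, rng, window)
            if pos is None:
                continue
            ref = genome.base(model.contig, pos)
            alt = _random_alt(ref, rng)
        elif category == "frameshift":
            pos = _random_cds_position(model, rng)
            ref, alt = genome.base(model.contig, pos), ""
        else:
            pos = _random_cds_position(model, rng)
            ref = genome.base(model.contig, pos)
            alt = _random_alt(ref, rng)
        rec = MutationRecord(
            id=mut_id, contig=model.contig, position=pos, ref=ref, alt=alt, dataset=dataset
        )
        call = classify(rec, model, genome, window=window)
        if call.category == category:
            return rec
    raise CategoryUnreachable(
        f"could not generate category {category!r} on this transcriptome "
        f"after {max_attempts} attempts"
    )


def _random_alt(ref: str, rng) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(3))]


def _random_cds_position(model: TranscriptModel, rng) -> int:
    s, e = model.cds[int(rng.integers(len(model.cds)))]
    return int(rng.integers(s, e + 1))


def _splice_candidate(model, category, rng, window):
    introns = model.introns()
    if not introns:
        return None
    start, end = introns[int(rng.integers(len(introns)))]
    length = end - start + 1
    if category == "critical_splice_donor":
        offset = int(rng.integers(1, 3))
    elif category == "critical_splice_acceptor":
        offset = -int(rng.integers(1, 3))
    elif category == "noncritical_splice_donor":
        offset = int(rng.integers(3, window + 1))
    elif category == "noncritical_splice_acceptor":
        offset = -int(rng.integers(3, window + 1))
    else:  # deep_intronic
        if length <= 2 * window + 2:
            return None
        offset = int(rng.integers(window + 1, length - window))
    if model.strand == "+":
        return start + offset - 1 if offset > 0 else end + offset + 1
    return end - offset + 1 if offset > 0 else start - offset - 1


def sample_detectability_counts(
    f_d: float,
    n_phenotypic: int,
    n_incidental: int,
    incidental_overt_fraction: float = 28 / 402,
    rng: np.random.Generator | int | None = None,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Draw overt-null counts for a phenotypic/incidental pair with known
    detectable-missense fraction.

    The phenotypic class is the incidental class re-weighted by detectability,
    which multiplies its overt-null *fraction* by 1/f_d (the structure the
    fraction-ratio estimator inverts): f_p = f_i / f_d, clipped to 1.  Counts
    are then independent binomial draws.
    """
    if not 0.0 < f_d <= 1.0:
        raise ValueError("f_d must be in (0, 1]")
    rng = np.random.default_rng(rng)
    f_i = incidental_overt_fraction
    f_p = min(1.0, f_i / f_d)
    k_p = int(rng.binomial(n_phenotypic, f_p))
    k_i = int(rng.binomial(n_incidental, f_i))
    return (k_p, n_phenotypic), (k_i, n_incidental)


# ----------------------------------------------------------------------
# Packaged fixtures
# ----------------------------------------------------------------------

def load_published_tables() -> dict[str, pd.DataFrame]:
    """Load the packaged count tables, verifying embedded checksums.

    Keys: table2 (allele-type tallies by dataset), table3 (splice distances),
    table5 (sense-strand substitution counts and test statistics), table7
    (genome-wide substitution opportunities).
    """
    out: dict[str, pd.DataFrame] = {}
    for name, digest in FIXTURE_CHECKSUMS.items():
        ref = resources.files("enu_spectra") / "fixtures" / f"{name}.tsv"
        data = ref.read_bytes()
        observed = hashlib.sha256(data).hexdigest()
        if observed != digest:
            raise ValueError(f"fixture {name}.tsv is corrupted (sha256 {observed})")
        out[name] = pd.read_csv(ref, sep="\t")
    return out


def table7_opportunities():
    """The packaged genome-wide opportunity counts as an OpportunityTable."""
    from .opportunity import OpportunityTable

    return OpportunityTable.from_frame(load_published_tables()["table7"])


def table5_tallies():
    """The packaged observed sense-strand tallies as SpectrumTally objects."""
    from .core_models_io import SubstitutionType
    from .spectrum_stats import SpectrumTally

    df = load_published_tables()["table5"]
    phen = SpectrumTally(dataset="phenotypic")
    inc = SpectrumTally(dataset="incidental")
    for _, row in df.iterrows():
        s = SubstitutionType.parse(str(row["substitution"]))
        phen.counts[s] = int(row["phenotypic_k"])
        inc.counts[s] = int(row["incidental_k"])
    return phen, inc
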