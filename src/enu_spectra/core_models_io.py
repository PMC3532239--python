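"""Domain types and readers for genomes, transcript models and mutation tables.

Coordinates are 1-based inclusive throughout (GFF3 convention).  Mutation
positions are genomic; strand handling (complementing alleles for genes coded
on the minus strand) happens at classification time, so stored records are
strand-agnostic.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase, N-aware)."""
    return seq.translate(COMPLEMENT)[::-1]


def _open_text(path: str | Path):
    """Open a possibly gzip-compressed text file for reading."""
    path = Path(path)
    raw = open(path, "rb")
    if raw.read(2) == b"\x1f\x8b":
        raw.seek(0)
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    raw.seek(0)
    return io.TextIOWrapper(raw, encoding="utf-8")


class MutationTableError(ValueError):
    """Raised for malformed rows in a mutation table (carries line number)."""


@dataclass(frozen=True)
class SubstitutionType:
    """A single-base substitution expressed on a transcript's sense strand.

    Exactly 12 values exist (4 reference bases x 3 alternates).  The
    ``complement`` of a type is the same physical DNA change read on the
    opposite strand: complement(A→G) = T→C.
    """

    from_base: str
    to_base: str

    def __post_init__(self):
        if self.from_base not in VALID_BASES or self.to_base not in VALID_BASES:
            raise ValueError(f"invalid substitution bases {self.from_base}->{self.to_base}")
        if self.from_base == self.to_base:
            raise ValueError("substitution must change the base")

    def complement(self) -> "SubstitutionType":
        return SubstitutionType(
            self.from_base.translate(COMPLEMENT), self.to_base.translate(COMPLEMENT)
        )

    def __str__(self) -> str:
        return f"{self.from_base}>{self.to_base}"

    @classmethod
    def parse(cls, text: str) -> "SubstitutionType":
        for sep in (">", "->", "→"):
            if sep in text:
                a, b = text.split(sep)
                return cls(a.strip().upper(), b.strip().upper())
        raise ValueError(f"cannot parse substitution type {text!r}")


#: The 12 substitution types in a fixed display order (purine references first
#: within each complementary pair, matching the usual strand-asymmetry layout).
ALL_SUBSTITUTIONS: tuple[SubstitutionType, ...] = tuple(
    SubstitutionType(a, b) for a in "ACGT" for b in "ACGT" if a != b
)

#: The six purine-reference focal types used for strand-asymmetry testing.
PURINE_FOCAL: tuple[SubstitutionType, ...] = tuple(
    s for s in ALL_SUBSTITUTIONS if s.from_base in "AG"
)


class GenomeSequence:
    """In-memory genome: contig name -> uppercase nucleotide string."""

    def __init__(self, contigs: dict[str, str]):
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}

    @property
    def contigs(self) -> dict[str, str]:
        return self._contigs

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._contigs.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self._contigs

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the sequence of ``contig`` from ``start`` to ``end``, 1-based inclusive."""
        try:
            seq = self._contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(f"interval {start}..{end} outside contig {contig} (len {len(seq)})")
        return seq[start - 1 : end]

    def base(self, contig: str, position: int) -> str:
        return self.fetch(contig, position, position)


def load_genome(path: str | Path) -> GenomeSequence:
    """Load a (possibly gzipped) FASTA file into memory.

    Lookups are case-insensitive on sequence content: everything is stored
    uppercase.  Duplicate contig names and empty files are errors.
    """
    contigs: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in contigs:
                raise ValueError(f"duplicate contig name {record.id!r} in {path}")
            contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


@dataclass
class TranscriptModel:
    """One gene's coding transcript: exons, CDS intervals, strand.

    ``exons`` and ``cds`` are sorted lists of 1-based inclusive genomic
    intervals.  ``phase`` is the number of bases to trim from the 5' end of
    the concatenated sense-strand CDS before the first complete codon.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    phase: int = 0
    complete: bool = True
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(tuple(iv) for iv in self.exons)
        self.cds = sorted(tuple(iv) for iv in self.cds)

    # --- geometry -----------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals in genomic order (1-based inclusive)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, position: int) -> bool:
        s, e = self.span
        return s <= position <= e

    def in_cds(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.cds)

    def in_exon(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.exons)

    # --- sequence access ---------------------------------------------

    def cds_sequence(self, genome: GenomeSequence) -> str:
        """Sense-strand CDS sequence with the phase trim applied.

        Cached per genome object; transcript models are treated as immutable
        once built.
        """
        cache = getattr(self, "_cds_cache", None)
        if cache is not None and cache[0] is genome:
            return cache[1]
        parts = [genome.fetch(self.contig, s, e) for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = revcomp(seq)
        seq = seq[self.phase :]
        object.__setattr__(self, "_cds_cache", (genome, seq))
        return seq

    def cds_coordinate(self, position: int) -> int:
        """0-based offset of a genomic position within the sense-strand CDS.

        Raises ``ValueError`` if the position is not inside a CDS interval or
        falls within the phase trim.
        """
        offset = 0
        if self.strand == "+":
            for s, e in self.cds:
                if s <= position <= e:
                    idx = offset + (position - s)
                    break
                offset += e - s + 1
            else:
                raise ValueError(f"position {position} not in CDS of {self.transcript_id}")
        else:
            for s, e in reversed(self.cds):
                if s <= position <= e:
                    idx = offset + (e - position)
                    break
                offset += e - s + 1
            else:
                raise ValueError(f"position {position} not in CDS of {self.transcript_id}")
        idx -= self.phase
        if idx < 0:
            raise ValueError(f"position {position} lies within the phase trim")
        return idx

    # --- validation ---------------------------------------------------

    def validate(self, genome: GenomeSequence | None = None) -> list[str]:
        """Check structural invariants; returns (and stores) warning strings.

        Hard violations (overlapping exons, CDS outside exons) raise;
        soft ones (CDS length not a multiple of 3, missing start/stop) are
        returned as warnings.
        """
        msgs: list[str] = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons {s1}-{e1}, {s2}-{e2}")
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(f"{self.transcript_id}: CDS {s}-{e} outside exons")
        if genome is not None and self.contig not in genome:
            raise ValueError(f"{self.transcript_id}: unknown contig {self.contig!r}")
        n = self.cds_length() - self.phase
        if self.complete and n % 3 != 0:
            msgs.append(f"{self.transcript_id}: CDS length {n} not a multiple of 3")
        if genome is not None and self.complete and n % 3 == 0 and n >= 6:
            seq = self.cds_sequence(genome)
            if not seq.startswith("ATG"):
                msgs.append(f"{self.transcript_id}: CDS does not begin with ATG")
            if seq[-3:] not in ("TAA", "TAG", "TGA"):
                msgs.append(f"{self.transcript_id}: CDS does not end with a stop codon")
        self.warnings = msgs
        return msgs


@dataclass
class MutationRecord:
    """One mutation: a SNV by default, small indels allowed.

    ``ref``/``alt`` are plus-strand genomic alleles; ``dataset`` labels the
    record as phenotypic (proven causal), incidental (found by sequencing) or
    unlabeled.  ``score`` optionally carries an external damage score in [0,1]
    such as a PolyPhen-2 value.
    """

    id: str
    contig: str
    position: int
    ref: str
    alt: str
    dataset: str = "unlabeled"
    zygosity: str = "unknown"
    score: float | None = None

    DATASETS = ("phenotypic", "incidental", "unlabeled")
    ZYGOSITIES = ("hom", "het", "hemi", "unknown")

    def __post_init__(self):
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if not self.ref or any(b not in VALID_BASES for b in self.ref):
            raise ValueError(f"{self.id}: invalid ref allele {self.ref!r}")
        if any(b not in VALID_BASES for b in self.alt):
            raise ValueError(f"{self.id}: invalid alt allele {self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref equals alt ({self.ref})")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"{self.id}: damage score {self.score} outside [0,1]")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    def check_reference(self, genome: GenomeSequence) -> None:
        observed = genome.fetch(self.contig, self.position, self.position + len(self.ref) - 1)
        if observed != self.ref:
            raise ValueError(
                f"{self.id}: ref allele {self.ref} does not match genome "
                f"({observed}) at {self.contig}:{self.position}"
            )


# ----------------------------------------------------------------------
# Transcript loading
# ----------------------------------------------------------------------

def load_transcripts(
    path: str | Path, genome: GenomeSequence | None = None
) -> list[TranscriptModel]:
    """Load transcript models from GFF3 or the simplified transcript TSV.

    The TSV dialect has columns gene, transcript, contig, strand, exons, cds
    with interval lists as "start-end;start-end".  Validation warnings are
    attached to each model; hard invariant violations raise with the
    offending transcript id.
    """
    path = Path(path)
    with _open_text(path) as handle:
        head = handle.readline()
    if head.startswith("gene\t") or head.startswith("gene,"):
        models = _load_transcripts_tsv(path)
    else:
        models = _load_transcripts_gff3(path)
    for m in models:
        msgs = m.validate(genome)
        for msg in msgs:
            warnings.warn(msg)
    return models


def _load_transcripts_tsv(path: Path) -> list[TranscriptModel]:
    models = []
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = {"gene", "transcript", "contig", "strand", "exons", "cds"}
        missing = required - set(idx)
        if missing:
            raise ValueError(f"transcript TSV missing columns: {sorted(missing)}")
        for line in handle:
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")
            exons = _parse_intervals(row[idx["exons"]])
            cds = _parse_intervals(row[idx["cds"]])
            phase = int(row[idx["phase"]]) if "phase" in idx else 0
            models.append(
                TranscriptModel(
                    gene_id=row[idx["gene"]],
                    transcript_id=row[idx["transcript"]],
                    contig=row[idx["contig"]],
                    strand=row[idx["strand"]],
                    exons=exons,
                    cds=cds,
                    phase=phase,
                )
            )
    return models


def _parse_intervals(text: str) -> list[tuple[int, int]]:
    out = []
    for part in text.strip().split(";"):
        if not part:
            continue
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


def _load_transcripts_gff3(path: Path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        cds = [(f.start, f.end) for f in cds_feats]
        if not exons:
            exons = list(cds)
        if cds_feats:
            first = cds_feats[0] if mrna.strand == "+" else cds_feats[-1]
            phase = int(first.frame) if first.frame not in (None, ".") else 0
        else:
            phase = 0
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                contig=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
                phase=phase,
            )
        )
    return models


def select_longest_cds(models: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Keep one transcript per gene: the one with the longest total CDS.

    Ties break to the lexicographically smallest transcript id, so the choice
    is independent of input order.
    """
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None:
            best[m.gene_id] = m
            continue
        key_new = (-m.cds_length(), m.transcript_id)
        key_cur = (-cur.cds_length(), cur.transcript_id)
        if key_new < key_cur:
            best[m.gene_id] = m
    return [best[g] for g in sorted(best)]


def write_transcript_table(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write the simplified transcript TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\ttranscript\tcontig\tstrand\texons\tcds\tphase\n")
        for m in models:
            exons = ";".join(f"{s}-{e}" for s, e in m.exons)
            cds = ";".join(f"{s}-{e}" for s, e in m.cds)
            fh.write(
                f"{m.gene_id}\t{m.transcript_id}\t{m.contig}\t{m.strand}\t{exons}\t{cds}\t{m.phase}\n"
            )


# ----------------------------------------------------------------------
# Mutation tables
# ----------------------------------------------------------------------

MUTATION_COLUMNS = ("id", "contig", "pos", "ref", "alt", "dataset", "zygosity", "score")


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read the tab-separated mutation table.

    Columns: id, contig, pos, ref, alt, dataset, zygosity, score ("NA" for a
    missing damage score).  Unknown dataset strings map to "unlabeled" with a
    warning; malformed rows raise with their line number.
    """
    records = []
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[: len(MUTATION_COLUMNS)] != list(MUTATION_COLUMNS):
            raise MutationTableError(
                f"unexpected header {header}; expected {list(MUTATION_COLUMNS)}"
            )
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")
            if len(row) != len(MUTATION_COLUMNS):
                raise MutationTableError(f"line {lineno}: expected 8 columns, got {len(row)}")
            try:
                pos = int(row[2])
            except ValueError:
                raise MutationTableError(f"line {lineno}: non-integer position {row[2]!r}") from None
            dataset = row[5]
            if dataset not in MutationRecord.DATASETS:
                warnings.warn(f"line {lineno}: unknown dataset {dataset!r}, using 'unlabeled'")
                dataset = "unlabeled"
            score = None if row[7] in ("NA", "", ".") else float(row[7])
            try:
                rec = MutationRecord(
                    id=row[0], contig=row[1], position=pos,
                    ref=row[3], alt="" if row[4] in ("-", "") else row[4],
                    dataset=dataset, zygosity=row[6], score=score,
                )
            except ValueError as exc:
                raise MutationTableError(f"line {lineno}: {exc}") from None
            records.append(rec)
    return records


def write_mutation_table(records: Sequence[MutationRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(MUTATION_COLUMNS) + "\n")
        for r in records:
            score = "NA" if r.score is None else repr(r.score)
            alt = r.alt if r.alt else "-"
            fh.write(
                f"{r.id}\t{r.contig}\t{r.position}\t{r.ref}\t{alt}\t{r.dataset}\t{r.zygosity}\t{score}\n"
            )
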