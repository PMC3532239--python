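"""In-silico germline mutagenesis and screen-saturation estimation.

The simulator draws random single-base substitutions over a genome at an
ENU-like rate (default one mutation per Mbp of the G1 genome), assigns each a
substitution type from configurable sense-strand weights, classifies every
hit with the consequence module, and flags phenotype-causing mutations per
category (overt nulls always; missense with the detectable fraction).  On top
of that it estimates screen saturation — the fraction of genes driven to a
detectable, homozygous phenovariant state in a screened G3 population — and
validates the detectability estimator against known truth.

Strand asymmetry enters through the sense-strand weights applied per gene
orientation; no mechanistic transcription-coupled-repair model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .consequence import ConsequenceCall, classify
from .core_models_io import (
    ALL_SUBSTITUTIONS,
    COMPLEMENT,
    GenomeSequence,
    MutationRecord,
    SubstitutionType,
    TranscriptModel,
)
from .detectability import estimate_detectability
from .synthetic_data import sample_detectability_counts

#: Default substitution-type weights, proportional to the combined observed
#: sense-strand totals of the phenotypic + incidental sets (A>T 62, T>A 103,
#: A>G 90, T>C 102, A>C 10, T>G 16, G>T 24, C>A 23, G>A 44, C>T 50, G>C 1,
#: C>G 0).
DEFAULT_WEIGHTS: dict[SubstitutionType, float] = {
    SubstitutionType("A", "T"): 62,
    SubstitutionType("T", "A"): 103,
    SubstitutionType("A", "G"): 90,
    SubstitutionType("T", "C"): 102,
    SubstitutionType("A", "C"): 10,
    SubstitutionType("T", "G"): 16,
    SubstitutionType("G", "T"): 24,
    SubstitutionType("C", "A"): 23,
    SubstitutionType("G", "A"): 44,
    SubstitutionType("C", "T"): 50,
    SubstitutionType("G", "C"): 1,
    SubstitutionType("C", "G"): 0,
}

#: Per-category probability that a mutation causes a detectable phenotype.
DEFAULT_DETECTABILITY: dict[str, float] = {
    "frameshift": 1.0,
    "nonsense": 1.0,
    "critical_splice_donor": 1.0,
    "critical_splice_acceptor": 1.0,
    "missense": 0.213,
    "start_loss": 0.213,
    "make_sense": 0.213,
    "noncritical_splice_donor": 0.0,
    "noncritical_splice_acceptor": 0.0,
    "synonymous": 0.0,
}


@dataclass
class SimulationConfig:
    """Knobs of the in-silico mutagenesis run.

    ``rate_per_mbp`` is the per-gamete genomic mutation rate (1/Mbp is the
    standard ENU figure; each mutagenized gamete of a real-sized genome then
    carries ~3000 mutations, ~30 of them coding).  ``homozygosity_prob`` is
    the chance a given G1 mutation is homozygous in a given G3 mouse; 1/8
    reflects the backcross scheme (a G2 daughter inherits the mutation w.p.
    1/2, her G3 offspring is homozygous w.p. 1/4 given that).
    """

    seed: int = 0
    rate_per_mbp: float = 1.0
    weights: dict[SubstitutionType, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )
    detectability: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECTABILITY)
    )
    n_pedigrees: int = 50
    g3_per_pedigree: int = 12
    homozygosity_prob: float = 1.0 / 8.0
    splice_window: int = 10

    def __post_init__(self):
        total = sum(self.weights.values())
        if total <= 0 or any(w < 0 for w in self.weights.values()):
            raise ValueError("substitution weights must be non-negative with positive sum")
        self.weights = {s: w / total for s, w in self.weights.items()}
        for cat, p in self.detectability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"detectability[{cat}] = {p} outside [0,1]")


@dataclass
class SimulatedMutation:
    record: MutationRecord
    call: ConsequenceCall | None
    phenotype: bool

    @property
    def category(self) -> str:
        return self.call.category if self.call else "intergenic"


def _gene_index(models: Sequence[TranscriptModel]):
    index: dict[str, list[tuple[int, int, TranscriptModel]]] = {}
    for m in models:
        s, e = m.span
        index.setdefault(m.contig, []).append((s, e, m))
    for spans in index.values():
        spans.sort(key=lambda t: t[:2])
    return index


def _lookup(index, contig: str, pos: int) -> TranscriptModel | None:
    for s, e, m in index.get(contig, ()):
        if s <= pos <= e:
            return m
        if s > pos:
            break
    return None


def simulate_g1_genome(
    config: SimulationConfig,
    models: Sequence[TranscriptModel],
    genome: GenomeSequence,
    rng: np.random.Generator,
    tag: str = "g1",
) -> list[SimulatedMutation]:
    """Mutations carried by one G1 genome.

    The mutation count is Poisson with mean rate x genome size; positions are
    uniform.  The substitution type is drawn from the configured sense-strand
    weights conditioned on the reference base (sense-strand identity for
    positions inside a gene, plus strand elsewhere), then mapped back to
    genomic alleles.  Every hit is classified; the phenotype flag is a
    Bernoulli draw from the per-category detectability.
    """
    if not models:
        raise ValueError("transcript set is empty")
    index = _gene_index(models)
    contigs = list(genome.contigs)
    lengths = np.array([len(genome.contigs[c]) for c in contigs], dtype=float)
    genome_size = lengths.sum()
    n = rng.poisson(config.rate_per_mbp * genome_size / 1e6)
    out: list[SimulatedMutation] = []
    if n == 0:
        return out
    contig_idx = rng.choice(len(contigs), size=n, p=lengths / genome_size)
    for i in range(n):
        contig = contigs[contig_idx[i]]
        pos = int(rng.integers(1, len(genome.contigs[contig]) + 1))
        ref = genome.base(contig, pos)
        if ref == "N":
            continue
        model = _lookup(index, contig, pos)
        sense_ref = ref
        if model is not None and model.strand == "-":
            sense_ref = ref.translate(COMPLEMENT)
        candidates = [s for s in ALL_SUBSTITUTIONS if s.from_base == sense_ref]
        w = np.array([config.weights.get(s, 0.0) for s in candidates])
        if w.sum() == 0:
            continue
        sense_sub = candidates[int(rng.choice(3, p=w / w.sum()))]
        alt = sense_sub.to_base
        if model is not None and model.strand == "-":
            alt = alt.translate(COMPLEMENT)
        rec = MutationRecord(
            id=f"{tag}_{i}", contig=contig, position=pos, ref=ref, alt=alt
        )
        call = None
        if model is not None:
            call = classify(rec, model, genome, window=config.splice_window)
        p_detect = config.detectability.get(call.category, 0.0) if call else 0.0
        phenotype = bool(rng.random() < p_detect)
        out.append(SimulatedMutation(record=rec, call=call, phenotype=phenotype))
    return out


def simulate_g1_genomes(
    config: SimulationConfig,
    models: Sequence[TranscriptModel],
    genome: GenomeSequence,
) -> list[SimulatedMutation]:
    """Mutations pooled over ``config.n_pedigrees`` independent G1 genomes."""
    rng = np.random.default_rng(config.seed)
    out: list[SimulatedMutation] = []
    for ped in range(config.n_pedigrees):
        out.extend(simulate_g1_genome(config, models, genome, rng, tag=f"p{ped}"))
    return out


@dataclass
class SaturationResult:
    mean: float
    std_error: float
    per_replicate: list[float]
    n_genes: int


def saturation_estimate(
    config: SimulationConfig,
    models: Sequence[TranscriptModel],
    genome: GenomeSequence,
    replicates: int = 20,
) -> SaturationResult:
    """Fraction of genes with >= 1 phenotype-detectable mutation rendered
    homozygous in >= 1 screened G3 mouse, by Monte Carlo over replicates.

    A G1 mutation reaches homozygosity in at least one of the m screened G3
    mice with probability 1 - (1 - homozygosity_prob)^m.
    """
    rng = np.random.default_rng(config.seed)
    p_seen = 1.0 - (1.0 - config.homozygosity_prob) ** config.g3_per_pedigree
    fractions: list[float] = []
    gene_ids = [m.gene_id for m in models]
    for rep in range(replicates):
        saturated: set[str] = set()
        for ped in range(config.n_pedigrees):
            for sim in simulate_g1_genome(config, models, genome, rng, tag=f"r{rep}p{ped}"):
                if not sim.phenotype or sim.call is None:
                    continue
                if rng.random() < p_seen:
                    saturated.add(sim.call.gene_id)
        fractions.append(len(saturated) / len(gene_ids))
    arr = np.asarray(fractions)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return SaturationResult(
        mean=float(arr.mean()), std_error=se, per_replicate=fractions, n_genes=len(gene_ids)
    )


def expected_detectable_rate_per_gene(
    config: SimulationConfig,
    models: Sequence[TranscriptModel],
    genome: GenomeSequence,
) -> dict[str, float]:
    """Expected number of phenotype-detectable mutations per gene per G1
    genome, by deterministic enumeration.

    Every position in each gene span is weighted by the per-base mutation
    expectation, the conditional substitution-type weights given its sense
    reference base, and the per-category detectability of the resulting
    consequence call.  This is the rate entering the Poisson closed form
    against which Monte-Carlo saturation can be checked.
    """
    per_base = config.rate_per_mbp / 1e6
    rates: dict[str, float] = {}
    for m in models:
        lam = 0.0
        s, e = m.span
        for pos in range(s, e + 1):
            ref = genome.base(m.contig, pos)
            if ref == "N":
                continue
            sense_ref = ref.translate(COMPLEMENT) if m.strand == "-" else ref
            candidates = [t for t in ALL_SUBSTITUTIONS if t.from_base == sense_ref]
            total_w = sum(config.weights.get(t, 0.0) for t in candidates)
            if total_w == 0:
                continue
            for t in candidates:
                w = config.weights.get(t, 0.0)
                if w == 0:
                    continue
                alt = t.to_base
                if m.strand == "-":
                    alt = alt.translate(COMPLEMENT)
                rec = MutationRecord(id="enum", contig=m.contig, position=pos, ref=ref, alt=alt)
                call = classify(rec, m, genome, window=config.splice_window)
                lam += per_base * (w / total_w) * config.detectability.get(call.category, 0.0)
        rates[m.gene_id] = lam
    return rates


def closed_form_saturation(
    lambda_detectable_per_gene: dict[str, float],
    p_homozygous_seen: float,
) -> float:
    """Poisson-thinning limit: each gene is saturated with probability
    1 - exp(-lambda_g * p_seen); the expected saturation is their mean."""
    probs = [1.0 - np.exp(-lam * p_homozygous_seen) for lam in lambda_detectable_per_gene.values()]
    return float(np.mean(probs))


# ----------------------------------------------------------------------
# Estimator validation
# ----------------------------------------------------------------------

@dataclass
class RecoveryReport:
    true_f_d: float
    mean_estimate: float
    bias: float
    coverage: float | None
    estimates: list[float]


def recover_detectability(
    true_f_d: float,
    n_phenotypic: int = 181,
    n_incidental: int = 402,
    incidental_overt_fraction: float = 28 / 402,
    replicates: int = 200,
    bootstrap: int = 0,
    seed: int = 0,
) -> RecoveryReport:
    """Simulate phenotypic/incidental splits with known detectable-missense
    fraction and report how the enrichment estimator recovers it.

    Sets are drawn in the fraction-enrichment structure the estimator
    inverts (phenotypic overt fraction = incidental fraction / f_d), so the
    mean estimate is consistent; ``bootstrap`` > 0 additionally tracks 95%
    interval coverage of the truth.
    """
    rng = np.random.default_rng(seed)
    estimates: list[float] = []
    covered = 0
    for _ in range(replicates):
        phen, inc = sample_detectability_counts(
            true_f_d, n_phenotypic, n_incidental, incidental_overt_fraction, rng
        )
        if phen[0] == 0 or inc[0] == 0:
            estimates.append(float("nan"))
            continue
        est = estimate_detectability(phen, inc, bootstrap=bootstrap, rng=rng)
        estimates.append(est.detectable_missense_fraction)
        if bootstrap and est.bootstrap_interval is not None:
            lo, hi = est.bootstrap_interval
            covered += int(lo <= true_f_d <= hi)
    arr = np.asarray([e for e in estimates if not np.isnan(e)])
    mean = float(arr.mean())
    return RecoveryReport(
        true_f_d=true_f_d,
        mean_estimate=mean,
        bias=mean - true_f_d,
        coverage=covered / replicates if bootstrap else None,
        estimates=estimates,
    )


def mechanistic_bias(true_f_d: float, overt_mix: float) -> float:
    """Predicted asymptotic bias of the fraction-ratio estimator when the
    phenotypic class arises from conditional detection (overt nulls detected
    with probability 1, missense with f_d) while the incidental class is an
    unconditional reference sample.

    The estimator then converges to overt_mix + (1 - overt_mix) * f_d, i.e.
    the overall detectable fraction rather than the missense-specific one —
    an upward bias of overt_mix * (1 - f_d).
    """
    return overt_mix * (1.0 - true_f_d)
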