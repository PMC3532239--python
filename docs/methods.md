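# Methods

## Mutation classification

Transcript models carry 1-based inclusive genomic intervals (GFF3
convention); mutation records are stored on the genomic plus strand and
complemented at classification time for genes coded on the minus strand, so
stored tables stay strand-agnostic. Classification follows a fixed decision
ladder: critical splice (intron positions 1–2 from either end, in transcript
orientation: donor = 5′ end of the intron, acceptor = 3′ end) outranks
non-critical splice (positions 3..W), which outranks coding interpretation,
which outranks deep-intronic. The non-critical window W defaults to 10 bp
but is a parameter, because documented splicing-defect alleles occur out to
17 bp from the exon boundary; positions beyond W are deep-intronic.
Creation of novel splice sites is not predicted — such alleles are known
only from experiment, and records carrying that knowledge can be imported
with a manual category override rather than inferred.

Coding single-base substitutions are typed by their sense-strand codon
change: missense, synonymous (including stop→stop), nonsense (residue→stop),
make-sense (stop→residue), and start-loss (any non-synonymous hit in the
initiator ATG of a complete model). Start-loss is reported as its own
category but folded into missense in allele-type summaries, matching how
initiator-codon alleles are listed in published inventories. Codons
containing N are unresolvable and excluded from enumeration. Indels are
classified structurally (frameshift / in-frame), as are multi-nucleotide
substitutions, and are excluded from substitution-spectrum tallies. The
*overt null* flag is exactly membership in {frameshift, nonsense, critical
splice donor, critical splice acceptor}.

## Opportunity counts and the strand-asymmetry null

For one chosen transcript per gene (the longest CDS; ties break to the
lexicographically smallest transcript id so the choice is input-order
independent), every CDS position is tested against its three alternate bases
in sense-strand space; an event counts iff the encoded residue or stop
status changes (missense, nonsense, make-sense, start-loss — not
synonymous). Stop codons of complete models are included, so make-sense
opportunities are counted. Each intron contributes its four critical bases
times three alternates, keyed by the sense-strand reference base with no
coding filter. Overlapping chosen transcripts are counted independently per
model, with a logged overlap size so double-counting is visible.

The null probability for a complementary pair {s, s̄} is
p(s) = N(s) / (N(s) + N(s̄)): under strand-symmetric mutagenesis, a physical
DNA change appears as s or s̄ on the sense strand in proportion to
opportunity. The test statistic is the exact lower tail Pr[X ≤ k] for
X ~ Binomial(n, p(s)), k the observed count of the purine-reference focal
type and n the pair total, computed by direct pmf summation with the stable
multiplicative recurrence (log-space fallback via lgamma when (1−p)^n
underflows; agreement with rational-arithmetic summation is enforced in
tests for n ≤ 30, and with an independent library implementation at larger
n). The upper tail and a doubled-smaller-tail two-sided value are also
emitted. The lower-tail convention reproduces the published values for
every pair except two cells of the incidental/combined A→G row, which
follow the upper tail and a doubled tail respectively; those two are
documented rather than matched.

## Codon-change-type combinatorics

All single-base codon substitutions of the standard genetic code are
enumerated and grouped into four classes: residue→residue, residue→stop,
stop→residue, and start-codon elimination (the six residue targets reachable
from ATG, counted as their own class since initiator loss is mechanistically
distinct from an internal M→X). Residues are typed by one-letter symbol.
Stop codons are typed, by default, by their codon-table cell: TAA/TAG share
a single two-codon box (as CAA/CAG do for Gln) while TGA sits apart, so a
change to or from the TAA/TAG box is a different type than one involving
TGA. Under this "cell" convention the totals are 150 + 13 + 13 + 6 = 182;
under the coarser "symbol" convention (all stops '*') they are
150 + 10 + 10 + 6 = 176. Both conventions are exposed and the per-class
breakdown is always printed, so the convention in use is never implicit.

Observed amino-acid change spectra are compared per type with a two-sided
Fisher exact test on the 2×2 table (type count vs all other changes, by
dataset), unadjusted at α = 0.05 — a deliberate choice to keep the flags
descriptive rather than inferential; no multiple-testing machinery is
layered on top.

## Detectability estimation

With overt-null fractions f_p (phenotypic) and f_i (incidental), the
enrichment is E = f_p / f_i and the detectable-missense fraction is
f_d = 1/E (capped at 1 with a warning if E < 1). The package reports direct
unrounded values alongside 3-significant-figure renderings; small
discrepancies with published roundings (e.g. 4.68 vs 4.70, 21.4% vs 21.3%)
arise from rounding intermediate percentages before dividing. Ratio
renderings are other:overt as "1 : R" at three significant figures.
Bootstrap intervals resample mutations with replacement within each dataset
(equivalently, binomial resampling of the overt count), 1000 replicates by
default, percentile method, seeded.

Damage-score summaries consume externally computed per-mutation scores in
[0, 1] (e.g. PolyPhen-2 output; the scoring model itself is never run here)
and report counts, mean, and the fraction at or above a threshold (default
0.95) under both the assignable-scores-only and the all-mutations
denominator, since published summaries use each. The specificity bound
multiplies f_d by the number of score-assignable mutations to get the
expected count of truly phenotype-causing ones; because the product falls
between integers, both floor and round renderings are printed (floor feeds
the headline specificity = expected / called-damaging).

### A known limitation of the fraction-ratio estimator

The estimator f_d = 1/E is exactly consistent when the phenotypic class is
an enrichment of the incidental class in *fraction* space (f_p = f_i / f_d).
Under a mechanistic detection model — overt nulls detected with probability
1, missense with probability f_d, phenotypic = detected, incidental = an
unconditional reference sample — the fraction ratio instead converges to
f_d + m_o(1 − f_d), where m_o is the overt-null share of all mutations:
an upward bias equal to the overt base rate times (1 − f_d). In that model
it is the *odds* ratio, not the fraction ratio, whose inverse equals f_d
exactly. The package implements the fraction-ratio estimator as the primary
method, exposes the predicted mechanistic bias
(`enu_simulator.mechanistic_bias`), and validates both claims by
simulation. The synthetic detectability generator therefore draws sets in
the fraction-enrichment structure, which is what parameter-recovery tests
exercise.

## The simulator

Per G1 genome, the mutation count is Poisson with mean rate × genome size
(default 1 per Mbp — the standard ENU figure, under which a real-sized
mutagenized gamete carries ~3000 mutations, ~30 of them coding); positions
are uniform. The substitution type is drawn from the 12 sense-strand weights
conditioned on the reference base (sense-strand identity inside genes, plus
strand elsewhere); defaults are proportional to the combined observed
sense-strand totals, so strand asymmetry enters through per-gene orientation
rather than a mechanistic transcription-coupled-repair model. Every genic
hit is classified with the consequence module and flagged phenotype-causing
per category: overt nulls 1.0, missense (and start-loss/make-sense) 0.213,
non-critical splice 0.0 by default (their real detectability is unknown;
it is a knob), synonymous 0.

Saturation: a G1 mutation is homozygous in a given screened G3 mouse with
probability 1/8 (backcross scheme: a G2 daughter carries it w.p. 1/2; her
G3 offspring is homozygous w.p. 1/4 given that), hence seen in at least one
of m G3 mice w.p. 1 − (1 − 1/8)^m. A gene is saturated when ≥ 1
phenotype-detectable mutation is rendered homozygous in ≥ 1 screened mouse;
the Monte-Carlo estimate over replicates is validated against the
per-gene Poisson-thinning closed form 1 − exp(−λ_g · p_seen), with λ_g
computed by deterministic enumeration over the gene span. No pedigree-level
Mendelian bookkeeping, dominance model, or assay-noise model is attempted.

## Synthetic data

The toy-transcriptome generator emits deterministic (seeded) multi-exon
genes on both strands: ATG start, interior codons free of stops, in-frame
terminal stop, GT/AG intron dinucleotides, intron length ≥ 20 bp so the
critical (1–2) and non-critical (3–10) windows of the two intron ends never
collide. All exons are coding (no UTRs), genes do not overlap, and base
composition outside CDS follows a configurable GC content. What passing
tests on these toys demonstrate is the correctness of coordinate handling,
strand logic, and counting — not robustness to real-genome features
(overlapping genes, UTRs, alternative isoform structure, repeats, CpG
context), which the generator deliberately omits.

Ground-truth mutation sets are made by rejection sampling: a candidate
position/alternate is drawn and kept only when the consequence classifier
itself returns the requested category, so labels are verified, never
assumed. Packaged fixtures carry published count tables verbatim behind
sha256 checksums; one printed grand-total row is internally inconsistent
with its own column (it counts positions rather than position × alternate
events) and is therefore not asserted.

## Numerical and scale choices

Exact binomial tails switch to log-space summation only when the direct
recurrence underflows; probabilities are clipped to [0, 1] at machine
precision. Property sweeps use toy transcriptomes of ≤ 10 genes with CDS of
15–80 codons, 50 random genomes for the enumeration-vs-oracle sweep, 200
replicates × 1000 bootstrap resamples for parameter recovery, and ~10⁵
simulated mutations for spectrum goodness-of-fit — sizes chosen so the full
suite runs in well under a minute of CPU while keeping Monte-Carlo standard
errors far below the tolerances being asserted. Report-bundle numbers are
serialised at full precision; all display rounding happens in rendering
only.
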