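"""Observed substitution spectra, exact binomial strand-asymmetry tests, and
amino-acid change-type combinatorics.

The strand-asymmetry test asks whether a substitution type s and its
complement occur at the rates predicted by mutational opportunity alone.
With k observed sense-strand events of the purine-reference focal type s out
of n = k(s) + k(complement(s)) events in the pair, and null probability p(s)
from the opportunity table, the reported statistic is the exact lower tail
Pr[X <= k] for X ~ Binomial(n, p), computed by direct summation of the
probability mass (never a normal approximation).  The upper tail and a
two-sided value (doubled smaller tail, capped at 1) are also carried for
transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .consequence import ConsequenceCall, SPECTRUM_CATEGORIES
from .core_models_io import ALL_SUBSTITUTIONS, PURINE_FOCAL, SubstitutionType


# ----------------------------------------------------------------------
# Exact binomial tail
# ----------------------------------------------------------------------

def binomial_lower_tail(k: int, n: int, p: float) -> float:
    """Pr[X <= k] for X ~ Binomial(n, p), by exact summation of the pmf.

    The mass is accumulated with the stable multiplicative recurrence
    pmf(j+1) = pmf(j) * (n-j)/(j+1) * p/(1-p); when (1-p)^n underflows the
    sum is redone in log space via lgamma.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p={p} outside (0,1)")
    if n == 0:
        return 1.0
    pmf = (1.0 - p) ** n
    if pmf == 0.0:
        return _lower_tail_logspace(k, n, p)
    total = pmf
    ratio = p / (1.0 - p)
    for j in range(k):
        pmf *= (n - j) / (j + 1) * ratio
        total += pmf
    return min(total, 1.0)


def _lower_tail_logspace(k: int, n: int, p: float) -> float:
    logs = []
    lp, lq = math.log(p), math.log1p(-p)
    lgn = math.lgamma(n + 1)
    for j in range(k + 1):
        logs.append(lgn - math.lgamma(j + 1) - math.lgamma(n - j + 1) + j * lp + (n - j) * lq)
    m = max(logs)
    return min(math.exp(m) * sum(math.exp(x - m) for x in logs), 1.0)


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """Pr[X >= k] = 1 - Pr[X <= k-1], via the complementary exact sum."""
    if k <= 0:
        return 1.0
    return max(1.0 - binomial_lower_tail(k - 1, n, p), 0.0)


# ----------------------------------------------------------------------
# Spectrum tallies and strand tests
# ----------------------------------------------------------------------

@dataclass
class SpectrumTally:
    """Observed sense-strand counts of qualifying single-base mutations."""

    dataset: str
    counts: dict[SubstitutionType, int] = field(
        default_factory=lambda: {s: 0 for s in ALL_SUBSTITUTIONS}
    )

    def k(self, s: SubstitutionType) -> int:
        return self.counts.get(s, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, other: "SpectrumTally", dataset: str = "combined") -> "SpectrumTally":
        merged = SpectrumTally(dataset=dataset)
        for s in ALL_SUBSTITUTIONS:
            merged.counts[s] = self.k(s) + other.k(s)
        return merged


def tally_spectrum(calls: Iterable[ConsequenceCall], dataset: str | None = None) -> SpectrumTally:
    """Tally sense-strand substitution types over qualifying calls.

    Qualifying categories are the coding-sense changers (missense, nonsense,
    make-sense, start-loss) plus critical splice hits; synonymous and all
    other categories are excluded.
    """
    tally = SpectrumTally(dataset=dataset or "all")
    for call in calls:
        if dataset is not None and call.dataset != dataset:
            continue
        if call.category not in SPECTRUM_CATEGORIES:
            continue
        if call.sense_substitution is None:
            continue
        tally.counts[call.sense_substitution] += 1
    return tally


@dataclass
class StrandTestResult:
    """One strand-asymmetry test: focal purine-reference type vs its complement."""

    substitution: SubstitutionType
    k: int
    n: int
    p: float | None
    lower_tail: float | None = None
    upper_tail: float | None = None
    two_sided: float | None = None

    @property
    def testable(self) -> bool:
        return self.n > 0 and self.p is not None


def strand_asymmetry_test(
    tally: SpectrumTally, null_p: Mapping[SubstitutionType, float]
) -> list[StrandTestResult]:
    """Run the exact binomial test for each of the six complementary pairs.

    Each focal type is the purine-reference member (A→N or G→N); k counts the
    focal type, n the pair total.  Pairs with n = 0 or no available null
    probability are returned untestable.
    """
    results = []
    for s in PURINE_FOCAL:
        k = tally.k(s)
        n = k + tally.k(s.complement())
        p = null_p.get(s)
        if n == 0 or p is None or not (0.0 < p < 1.0):
            results.append(StrandTestResult(substitution=s, k=k, n=n, p=p))
            continue
        lower = binomial_lower_tail(k, n, p)
        upper = binomial_upper_tail(k, n, p)
        results.append(
            StrandTestResult(
                substitution=s, k=k, n=n, p=p,
                lower_tail=lower, upper_tail=upper,
                two_sided=min(1.0, 2.0 * min(lower, upper)),
            )
        )
    return results


def strand_table(
    tallies: Sequence[SpectrumTally], null_p: Mapping[SubstitutionType, float]
) -> pd.DataFrame:
    """Strand-asymmetry report over several datasets plus their combination."""
    combined = tallies[0]
    for t in tallies[1:]:
        combined = combined.add(t)
    rows = []
    for s in PURINE_FOCAL:
        row = {"substitution": str(s), "complement": str(s.complement()),
               "p": null_p.get(s)}
        for t in list(tallies) + [combined]:
            res = next(r for r in strand_asymmetry_test(t, null_p) if r.substitution == s)
            row[f"{t.dataset}_k"] = res.k
            row[f"{t.dataset}_n"] = res.n
            row[f"{t.dataset}_P"] = res.lower_tail
        rows.append(row)
    return pd.DataFrame(rows)


def sense_antisense_ratio(tally: SpectrumTally, s: SubstitutionType) -> float | None:
    """k(s) / k(complement(s)); None when the denominator is zero."""
    denom = tally.k(s.complement())
    if denom == 0:
        return None
    return tally.k(s) / denom


# ----------------------------------------------------------------------
# Amino-acid change-type combinatorics
# ----------------------------------------------------------------------

#: How stop codons are typed when counting change types.  "symbol" collapses
#: all three stops to '*'; "cell" distinguishes the TAA/TAG codon-table cell
#: (a single two-codon box, like Gln's CAA/CAG) from the TGA cell, which sits
#: apart in the table next to Trp.
STOP_RESOLUTIONS = ("symbol", "cell")

_STOP_CELL = {"TAA": "*TAR", "TAG": "*TAR", "TGA": "*TGA"}


@dataclass
class AAChangeTypes:
    """Distinct coding-change types reachable by single-base substitutions."""

    missense: set[tuple[str, str]]
    nonsense: set[tuple[str, str]]
    make_sense: set[tuple[str, str]]
    start_loss: set[tuple[str, str]]
    stop_resolution: str = "cell"

    @property
    def breakdown(self) -> dict[str, int]:
        return {
            "missense": len(self.missense),
            "nonsense": len(self.nonsense),
            "make_sense": len(self.make_sense),
            "start_loss": len(self.start_loss),
        }

    @property
    def total(self) -> int:
        return sum(self.breakdown.values())


def enumerate_aa_change_types(
    forward_table: Mapping[str, str] | None = None,
    stop_codons: Iterable[str] | None = None,
    stop_resolution: str = "cell",
) -> AAChangeTypes:
    """Enumerate the coding-change types achievable by single-base codon
    substitutions, across four classes: residue→residue, residue→stop,
    stop→residue, and start-codon elimination.

    ``forward_table`` maps codons to one-letter residues and ``stop_codons``
    lists the stops; the standard genetic code (with its three stops) is used
    by default.  Codons in neither collection are absent from the code and
    contribute nothing.  Residues are typed by symbol; stop codons by
    ``stop_resolution`` — under "cell" the TAA/TAG box and TGA are distinct
    stop identities (the counting that treats each cell of the codon table as
    one entity), under "symbol" all stops are '*'.  With the standard code
    "cell" yields 182 types (150 + 13 + 13 + 6) and "symbol" 176
    (150 + 10 + 10 + 6).
    """
    if stop_resolution not in STOP_RESOLUTIONS:
        raise ValueError(f"stop_resolution must be one of {STOP_RESOLUTIONS}")
    if forward_table is None:
        from .consequence import STANDARD_TABLE

        forward_table = STANDARD_TABLE.forward_table
        if stop_codons is None:
            stop_codons = STANDARD_TABLE.stop_codons
    stops = set(stop_codons or ())
    codons = {"".join(t) for t in product("ACGT", repeat=3)}
    for c in list(forward_table) + sorted(stops):
        if c not in codons:
            raise ValueError(f"malformed codon {c!r} in codon table")

    def symbol(codon: str) -> str:
        aa = forward_table.get(codon)
        if aa is not None:
            return aa
        if stop_resolution == "cell":
            return _STOP_CELL.get(codon, f"*{codon}")
        return "*"

    universe = set(forward_table) | stops

    missense, nonsense, make_sense = set(), set(), set()
    for codon in universe:
        for i in range(3):
            for b in "ACGT":
                if b == codon[i]:
                    continue
                other = codon[:i] + b + codon[i + 1 :]
                if other not in universe:
                    continue  # neighbour absent from a degenerate code
                a1, a2 = symbol(codon), symbol(other)
                if a1 == a2:
                    continue
                from_stop, to_stop = codon in stops, other in stops
                if from_stop and to_stop:
                    continue  # stop-to-stop: no coding-sense change
                if from_stop:
                    make_sense.add((a1, a2))
                elif to_stop:
                    nonsense.add((a1, a2))
                else:
                    missense.add((a1, a2))
    start_loss = set()
    if forward_table.get("ATG") == "M":
        for i in range(3):
            for b in "ACGT":
                if b == "ATG"[i]:
                    continue
                other = "ATG"[:i] + b + "ATG"[i + 1 :]
                if other in universe and symbol(other) != "M":
                    start_loss.add(("Mstart", symbol(other)))
    return AAChangeTypes(
        missense=missense, nonsense=nonsense, make_sense=make_sense,
        start_loss=start_loss, stop_resolution=stop_resolution,
    )


# ----------------------------------------------------------------------
# Observed amino-acid change matrices and their comparison
# ----------------------------------------------------------------------

@dataclass
class AAChangeMatrix:
    """Observed (from residue, to residue) change counts for one dataset.

    Stops appear as '*'; start-loss changes are entered as plain M→X types,
    matching the convention that start-codon hits are listed among missense
    changes in allele inventories.
    """

    dataset: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_types(self) -> int:
        return len([t for t, c in self.counts.items() if c > 0])


def aa_change_matrix(calls: Iterable[ConsequenceCall], dataset: str | None = None) -> AAChangeMatrix:
    matrix = AAChangeMatrix(dataset=dataset or "all")
    for call in calls:
        if dataset is not None and call.dataset != dataset:
            continue
        if call.aa_from is None or call.aa_from == call.aa_to:
            continue
        if call.category == "synonymous":
            continue
        key = (call.aa_from, call.aa_to)
        matrix.counts[key] = matrix.counts.get(key, 0) + 1
    return matrix


def compare_aa_spectra(
    phenotypic: AAChangeMatrix, incidental: AAChangeMatrix, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-type relative frequencies with a two-sided exact 2x2 test.

    For each change type observed in either set, the 2x2 table (type count vs
    all other changes, by dataset) is tested with Fisher's exact test
    (hypergeometric summation).  The direction flag marks phenotypic- or
    incidental-enrichment; ``significant`` applies the unadjusted ``alpha``.
    """
    if phenotypic.total == 0 or incidental.total == 0:
        raise ValueError("both change matrices must be non-empty")
    types = sorted(set(phenotypic.counts) | set(incidental.counts))
    n_p, n_i = phenotypic.total, incidental.total
    rows = []
    for t in types:
        k_p = phenotypic.counts.get(t, 0)
        k_i = incidental.counts.get(t, 0)
        _, pval = fisher_exact([[k_p, n_p - k_p], [k_i, n_i - k_i]], alternative="two-sided")
        f_p, f_i = k_p / n_p, k_i / n_i
        direction = "phenotypic" if f_p > f_i else ("incidental" if f_i > f_p else "equal")
        rows.append(
            {
                "change": f"{t[0]}>{t[1]}",
                "phenotypic_count": k_p,
                "incidental_count": k_i,
                "phenotypic_freq": f_p,
                "incidental_freq": f_i,
                "p_value": pval,
                "direction": direction,
                "significant": pval < alpha,
            }
        )
    return pd.DataFrame(rows)
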