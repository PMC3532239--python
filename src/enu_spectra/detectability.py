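"""Overt-null enrichment and the detectable-missense-fraction estimate.

The phenotypic mutation class is selected for causing phenotype, which
enriches overt null alleles (frameshift, nonsense, critical splice) relative
to the incidental class.  Assuming the same selection enriches deleterious
missense alleles by the same factor, the enrichment

    E = f_p / f_i        (overt-null fractions in each class)

implies that a fraction f_d = 1/E of missense alleles observed among
incidental mutations would be phenotypically detectable.  Damage-score
summaries (external PolyPhen-2-style scores consumed as plain numbers) and
the derived specificity bound round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .consequence import ConsequenceCall


@dataclass
class OvertNullRatio:
    dataset: str
    overt: int
    other: int

    @property
    def total(self) -> int:
        return self.overt + self.other

    @property
    def fraction(self) -> float:
        return self.overt / self.total if self.total else 0.0

    @property
    def ratio(self) -> float | None:
        """other/overt — rendered as "1 : R"; None when no overt nulls."""
        if self.overt == 0:
            return None
        return self.other / self.overt

    def render(self) -> str:
        if self.ratio is None:
            return "undefined"
        return f"1 : {self.ratio:.3g}"


def overt_null_ratios(calls: Iterable[ConsequenceCall]) -> dict[str, OvertNullRatio]:
    """Per-dataset overt-null vs other counts over single-base calls."""
    acc: dict[str, list[int]] = {}
    for c in calls:
        bucket = acc.setdefault(c.dataset, [0, 0])
        bucket[0 if c.overt_null else 1] += 1
    return {
        ds: OvertNullRatio(dataset=ds, overt=overt, other=other)
        for ds, (overt, other) in acc.items()
    }


@dataclass
class DetectabilityEstimate:
    phenotypic_overt: int
    phenotypic_total: int
    incidental_overt: int
    incidental_total: int
    bootstrap_interval: tuple[float, float] | None = None
    capped: bool = False

    @property
    def f_p(self) -> float:
        return self.phenotypic_overt / self.phenotypic_total

    @property
    def f_i(self) -> float:
        return self.incidental_overt / self.incidental_total

    @property
    def enrichment(self) -> float:
        return self.f_p / self.f_i

    @property
    def detectable_missense_fraction(self) -> float:
        return min(1.0, 1.0 / self.enrichment)


def estimate_detectability(
    phenotypic: tuple[int, int],
    incidental: tuple[int, int],
    bootstrap: int = 0,
    rng: np.random.Generator | int | None = None,
) -> DetectabilityEstimate:
    """Estimate overt-null enrichment E and detectable missense fraction 1/E.

    ``phenotypic`` and ``incidental`` are (overt-null count, total count)
    pairs.  With ``bootstrap`` > 0, mutations are resampled with replacement
    within each dataset to attach a 95% percentile interval for f_d.
    """
    (k_p, n_p), (k_i, n_i) = phenotypic, incidental
    if n_p <= 0 or n_i <= 0:
        raise ValueError("dataset totals must be positive")
    if k_i == 0:
        raise ValueError("incidental overt-null count is zero; enrichment undefined")
    est = DetectabilityEstimate(k_p, n_p, k_i, n_i)
    if est.f_p < est.f_i:
        warnings.warn("phenotypic overt fraction below incidental; f_d capped at 1")
        est.capped = True
    if bootstrap > 0:
        est.bootstrap_interval = bootstrap_interval(
            k_p, n_p, k_i, n_i, replicates=bootstrap, rng=rng
        )
    return est


def bootstrap_interval(
    k_p: int, n_p: int, k_i: int, n_i: int,
    replicates: int = 1000,
    rng: np.random.Generator | int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval for f_d = 1/E.

    Resampling n mutations with replacement within a dataset and counting
    overt nulls is equivalent to a Binomial(n, k/n) draw, which keeps the
    procedure vectorised.  Degenerate resamples (zero overt nulls on either
    side) are redrawn as f_d -> the capped boundary values.
    """
    rng = np.random.default_rng(rng)
    bp = rng.binomial(n_p, k_p / n_p, size=replicates)
    bi = rng.binomial(n_i, k_i / n_i, size=replicates)
    with np.errstate(divide="ignore", invalid="ignore"):
        fd = (bp / n_p) ** -1 * (bi / n_i)
    fd = np.where(bp == 0, 1.0, fd)  # no phenotypic overt nulls: no enrichment signal
    fd = np.minimum(fd, 1.0)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(fd, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ----------------------------------------------------------------------
# Damage-score summaries
# ----------------------------------------------------------------------

@dataclass
class ScoreSummary:
    dataset: str
    n_scored: int
    n_unscored: int
    mean_score: float | None
    n_above: int
    threshold: float

    @property
    def n_total(self) -> int:
        return self.n_scored + self.n_unscored

    @property
    def fraction_above_scored(self) -> float | None:
        """Fraction >= threshold among scored entries (assignable scores)."""
        return self.n_above / self.n_scored if self.n_scored else None

    @property
    def fraction_above_total(self) -> float | None:
        """Fraction >= threshold with scored+unscored as denominator."""
        return self.n_above / self.n_total if self.n_total else None


def summarize_scores(
    calls: Iterable[ConsequenceCall], threshold: float = 0.95, dataset: str | None = None
) -> ScoreSummary:
    """Summarise damage scores: counts, mean, and fraction >= threshold.

    Both denominators are reported: assignable-scores-only and the full
    total including unscored mutations, since published summaries use each
    in different places.  Scores outside [0,1] raise.
    """
    scores, unscored = [], 0
    for c in calls:
        if dataset is not None and c.dataset != dataset:
            continue
        if c.score is None:
            unscored += 1
            continue
        if not (0.0 <= c.score <= 1.0):
            raise ValueError(f"{c.mutation_id}: score {c.score} outside [0,1]")
        scores.append(c.score)
    n_above = sum(1 for s in scores if s >= threshold)
    return ScoreSummary(
        dataset=dataset or "all",
        n_scored=len(scores),
        n_unscored=unscored,
        mean_score=float(np.mean(scores)) if scores else None,
        n_above=n_above,
        threshold=threshold,
    )


@dataclass
class SpecificityBound:
    expected_floor: int
    expected_round: int
    n_called_damaging: int
    capped: bool

    @property
    def specificity(self) -> float:
        """Upper bound on specificity, using the floor rendering of the
        expected count (the more conservative of the two)."""
        return min(1.0, self.expected_floor / self.n_called_damaging)


def specificity_bound(
    f_d: float, n_assignable: int, n_called_damaging: int
) -> SpecificityBound:
    """Expected truly-damaging count f_d * n_assignable vs calls made.

    If only f_d of mutations are phenotypically detectable, at most
    expected/n_called of the "damaging" calls can be correct.  The expected
    count is printed in both floor and round-half-even renderings because the
    product typically falls between integers.
    """
    if n_called_damaging <= 0:
        raise ValueError("n_called_damaging must be positive")
    exact = f_d * n_assignable
    floor = int(np.floor(exact))
    rounded = int(np.round(exact))
    capped = floor > n_called_damaging
    if capped:
        warnings.warn("expected damaging exceeds calls made; specificity capped at 100%")
    return SpecificityBound(
        expected_floor=floor,
        expected_round=rounded,
        n_called_damaging=n_called_damaging,
        capped=capped,
    )
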