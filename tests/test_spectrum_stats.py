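"""Exact binomial machinery, spectrum tallies, and codon-change combinatorics."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import binom, hypergeom

from enu_spectra.consequence import ConsequenceCall
from enu_spectra.core_models_io import PURINE_FOCAL, SubstitutionType
from enu_spectra.spectrum_stats import (
    AAChangeMatrix,
    SpectrumTally,
    binomial_lower_tail,
    binomial_upper_tail,
    compare_aa_spectra,
    enumerate_aa_change_types,
    sense_antisense_ratio,
    strand_asymmetry_test,
    tally_spectrum,
)

S = SubstitutionType.parse


def rational_lower_tail(k, n, p_num, p_den):
    """Oracle: exact rational-arithmetic summation of the binomial mass."""
    p = Fraction(p_num, p_den)
    return float(sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k + 1)))


class TestBinomialTail:
    def test_rational_oracle_sweep(self):
        """Agreement with exact rational summation for all n <= 30."""
        for n in range(0, 31, 3):
            for k in range(0, n + 1, max(1, n // 4)):
                for p_num, p_den in [(1, 2), (547, 1000), (1, 10), (9, 10)]:
                    expected = rational_lower_tail(k, n, p_num, p_den)
                    got = binomial_lower_tail(k, n, p_num / p_den)
                    assert got == pytest.approx(expected, rel=1e-12)

    def test_scipy_cross_check_large_n(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(50, 5000))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.05, 0.95))
            assert binomial_lower_tail(k, n, p) == pytest.approx(
                float(binom.cdf(k, n, p)), rel=1e-9, abs=1e-300
            )

    def test_known_small_values(self):
        # C(10,0)+C(10,1)+C(10,2) = 1+10+45 = 56 of 1024
        assert binomial_lower_tail(2, 10, 0.5) == pytest.approx(56 / 1024, rel=1e-12)
        assert binomial_lower_tail(10, 10, 0.5) == 1.0

    def test_monotone_in_k(self):
        vals = [binomial_lower_tail(k, 40, 0.547) for k in range(41)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_mirrored_tails(self):
        """Pr[X' <= n-k] with p' = 1-p equals Pr[X >= k]; the two tails of
        the same test sum to 1 + Pr[X = k]."""
        k, n, p = 23, 62, 0.547
        assert binomial_lower_tail(n - k, n, 1 - p) == pytest.approx(
            binomial_upper_tail(k, n, p), rel=1e-10
        )
        pmf_k = float(binom.pmf(k, n, p))
        assert binomial_lower_tail(k, n, p) + binomial_upper_tail(k, n, p) == pytest.approx(
            1.0 + pmf_k, rel=1e-10
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binomial_lower_tail(5, 4, 0.5)
        with pytest.raises(ValueError):
            binomial_lower_tail(1, 4, 0.0)


class TestTally:
    def _call(self, category, sub, dataset="phenotypic"):
        return ConsequenceCall(
            "m", "g", category, dataset=dataset, sense_substitution=S(sub)
        )

    def test_qualifying_categories(self):
        calls = [
            self._call("missense", "A>T"),
            self._call("nonsense", "T>A"),
            self._call("critical_splice_donor", "T>A"),
        ]
        tally = tally_spectrum(calls, "phenotypic")
        assert tally.k(S("A>T")) == 1
        assert tally.k(S("T>A")) == 2
        assert tally.total == 3

    def test_synonymous_and_noncritical_excluded(self):
        calls = [
            self._call("synonymous", "A>G"),
            self._call("noncritical_splice_donor", "A>G"),
            self._call("deep_intronic", "A>G"),
        ]
        assert tally_spectrum(calls, "phenotypic").total == 0

    def test_dataset_filter(self):
        calls = [
            self._call("missense", "A>T", dataset="phenotypic"),
            self._call("missense", "A>T", dataset="incidental"),
        ]
        assert tally_spectrum(calls, "phenotypic").total == 1
        assert tally_spectrum(calls).total == 2


class TestStrandTest:
    def test_untestable_pair_flagged(self):
        tally = SpectrumTally(dataset="x")
        results = strand_asymmetry_test(tally, {s: 0.5 for s in PURINE_FOCAL})
        assert all(not r.testable for r in results)

    def test_two_sided_capped_at_one(self):
        tally = SpectrumTally(dataset="x")
        tally.counts[S("A>T")] = 5
        tally.counts[S("T>A")] = 5
        (res,) = [r for r in strand_asymmetry_test(tally, {S("A>T"): 0.5}) if r.n]
        assert res.two_sided <= 1.0
        assert res.lower_tail == pytest.approx(binomial_lower_tail(5, 10, 0.5))

    def test_sense_antisense_ratio(self):
        tally = SpectrumTally(dataset="combined")
        tally.counts[S("T>A")] = 103
        tally.counts[S("A>T")] = 62
        assert round(sense_antisense_ratio(tally, S("T>A")), 1) == 1.7
        tally.counts[S("G>A")] = 4
        tally.counts[S("C>T")] = 4
        assert sense_antisense_ratio(tally, S("G>A")) == 1.0
        tally.counts[S("G>C")] = 0
        tally.counts[S("C>G")] = 3
        assert sense_antisense_ratio(tally, S("G>C")) == 0.0
        assert sense_antisense_ratio(tally, S("C>G")) is None


class TestAAChangeTypes:
    def test_standard_code_cell_convention(self):
        """Typing stop changes by codon-table cell (TAA/TAG box vs TGA)
        yields 182 distinct coding-change types."""
        result = enumerate_aa_change_types()
        assert result.breakdown == {
            "missense": 150, "nonsense": 13, "make_sense": 13, "start_loss": 6
        }
        assert result.total == 182

    def test_standard_code_symbol_convention(self):
        """Collapsing all stops to '*' gives the coarser 176-type count."""
        result = enumerate_aa_change_types(stop_resolution="symbol")
        assert result.breakdown == {
            "missense": 150, "nonsense": 10, "make_sense": 10, "start_loss": 6
        }
        assert result.total == 176

    def test_tryptophan_nonsense_reachable(self):
        result = enumerate_aa_change_types(stop_resolution="symbol")
        assert ("W", "*") in result.nonsense

    def test_start_codon_elimination_targets(self):
        """Single-base neighbours of ATG encode I, L, V, K, T, R."""
        result = enumerate_aa_change_types(stop_resolution="symbol")
        assert {t for _, t in result.start_loss} == set("ILVKTR")

    def test_degenerate_single_codon_code(self):
        result = enumerate_aa_change_types({"TTT": "F"}, stop_codons=())
        assert result.total == 0

    def test_invariant_under_table_order(self):
        from enu_spectra.consequence import STANDARD_TABLE

        fwd = dict(STANDARD_TABLE.forward_table)
        reordered = dict(reversed(list(fwd.items())))
        a = enumerate_aa_change_types(fwd, STANDARD_TABLE.stop_codons)
        b = enumerate_aa_change_types(reordered, tuple(reversed(STANDARD_TABLE.stop_codons)))
        assert a.breakdown == b.breakdown

    def test_malformed_codon_rejected(self):
        with pytest.raises(ValueError, match="malformed codon"):
            enumerate_aa_change_types({"TTTT": "F"}, stop_codons=())


class TestCompareAASpectra:
    def test_identical_matrices_nonsignificant(self):
        counts = {("S", "P"): 10, ("L", "P"): 5, ("T", "I"): 8}
        a = AAChangeMatrix("phenotypic", dict(counts))
        b = AAChangeMatrix("incidental", dict(counts))
        df = compare_aa_spectra(a, b)
        assert not df["significant"].any()
        assert (df["phenotypic_freq"] == df["incidental_freq"]).all()

    def test_hypergeometric_oracle(self):
        """Fisher's exact p for (10 of 100) vs (1 of 100) matches a direct
        hypergeometric tail summation."""
        a = AAChangeMatrix("phenotypic", {("S", "P"): 10, ("X", "Y"): 90})
        b = AAChangeMatrix("incidental", {("S", "P"): 1, ("X", "Y"): 99})
        df = compare_aa_spectra(a, b)
        row = df[df["change"] == "S>P"].iloc[0]
        # two-sided Fisher: sum of all tables with probability <= observed
        rv = hypergeom(200, 11, 100)
        p_obs = rv.pmf(10)
        expected = sum(rv.pmf(x) for x in range(0, 12) if rv.pmf(x) <= p_obs + 1e-12)
        assert row["p_value"] == pytest.approx(expected, rel=1e-8)
        assert row["direction"] == "phenotypic"
        assert row["significant"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_aa_spectra(AAChangeMatrix("p"), AAChangeMatrix("i", {("A", "B"): 1}))
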