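"""End-to-end orchestration: classify -> tally -> opportunities -> strand
tests -> amino-acid comparison -> detectability, bundled into one report.

Numbers are serialised at full precision; display rounding belongs to the
rendering layer so downstream comparisons never depend on formatting.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .consequence import classify_batch
from .core_models_io import load_genome, load_transcripts, read_mutation_table, select_longest_cds
from .detectability import estimate_detectability, overt_null_ratios, summarize_scores
from .opportunity import enumerate_opportunities, null_probabilities
from .spectrum_stats import aa_change_matrix, compare_aa_spectra, strand_table, tally_spectrum
from .synthetic_data import table7_opportunities


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ReportBundle:
    category_summary: pd.DataFrame
    strand_tests: pd.DataFrame
    aa_comparison: pd.DataFrame | None
    detectability: dict
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.category_summary.to_csv(out / "category_summary.tsv", sep="\t", index=False)
        self.strand_tests.to_csv(out / "strand_tests.tsv", sep="\t", index=False)
        if self.aa_comparison is not None:
            self.aa_comparison.to_csv(out / "aa_comparison.tsv", sep="\t", index=False)
        (out / "detectability.json").write_text(json.dumps(self.detectability, indent=2))
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    genome_path: str | Path,
    transcripts_path: str | Path,
    mutations_path: str | Path,
    window: int = 10,
    use_table7_fixture: bool = False,
    bootstrap: int = 1000,
    seed: int = 0,
    log=sys.stderr,
) -> ReportBundle:
    """Run the full analysis over one genome/annotation/mutation-table trio.

    With ``use_table7_fixture`` the packaged genome-wide opportunity counts
    stand in for enumeration over the supplied transcript set (the choice is
    recorded in provenance).  Stage failures raise ``StageError`` naming the
    stage.
    """

    def stage(name, fn, *args, **kw):
        print(f"pipeline: {name}", file=log)
        try:
            return fn(*args, **kw)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    def _load_inputs():
        genome = load_genome(genome_path)
        models = select_longest_cds(load_transcripts(transcripts_path, genome))
        mutations = read_mutation_table(mutations_path)
        return genome, models, mutations

    genome, models, mutations = stage("load", _load_inputs)
    batch = stage("classify", classify_batch, mutations, models, genome, window)
    if batch.errors:
        for mid, msg in batch.errors:
            print(f"pipeline: classify error {mid}: {msg}", file=log)

    if use_table7_fixture:
        opp = stage("opportunities", table7_opportunities)
    else:
        opp = stage("opportunities", enumerate_opportunities, models, genome)
    probs = stage("null-probabilities", null_probabilities, opp)

    datasets = sorted({c.dataset for c in batch.calls})
    tallies = [tally_spectrum(batch.calls, ds) for ds in datasets]
    tests = stage("strand-tests", strand_table, tallies, probs)

    aa_cmp = None
    if {"phenotypic", "incidental"} <= set(datasets):
        phen = aa_change_matrix(batch.calls, "phenotypic")
        inc = aa_change_matrix(batch.calls, "incidental")
        if phen.total and inc.total:
            aa_cmp = stage("aa-comparison", compare_aa_spectra, phen, inc)

    detect: dict = {"ratios": {}, "scores": {}}
    ratios = overt_null_ratios(batch.calls)
    for ds, r in ratios.items():
        detect["ratios"][ds] = {
            "overt": r.overt, "other": r.other,
            "fraction": r.fraction, "ratio": r.render(),
        }
        summary = summarize_scores(batch.calls, dataset=ds)
        detect["scores"][ds] = {
            "n_scored": summary.n_scored,
            "n_unscored": summary.n_unscored,
            "mean": summary.mean_score,
            "n_at_or_above_0.95": summary.n_above,
        }
    if {"phenotypic", "incidental"} <= set(ratios):
        rp, ri = ratios["phenotypic"], ratios["incidental"]
        if rp.overt and ri.overt:
            est = stage(
                "detectability", estimate_detectability,
                (rp.overt, rp.total), (ri.overt, ri.total),
                bootstrap, seed,
            )
            detect["estimate"] = {
                "enrichment": est.enrichment,
                "detectable_missense_fraction": est.detectable_missense_fraction,
                "bootstrap_interval": est.bootstrap_interval,
            }

    provenance = {
        "package": "enu-spectra",
        "version": __version__,
        "seed": seed,
        "window": window,
        "opportunity_source": "table7_fixture" if use_table7_fixture else "enumerated",
        "inputs": {
            "genome": {"path": str(genome_path), "sha256": _checksum(genome_path)},
            "transcripts": {"path": str(transcripts_path), "sha256": _checksum(transcripts_path)},
            "mutations": {"path": str(mutations_path), "sha256": _checksum(mutations_path)},
        },
    }
    return ReportBundle(
        category_summary=batch.summary,
        strand_tests=tests,
        aa_comparison=aa_cmp,
        detectability=detect,
        provenance=provenance,
    )
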