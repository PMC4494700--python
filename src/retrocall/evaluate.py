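"""Concordance scoring of pipeline calls against a simulated truth set.

The simulated cohort truth plays the role that individual site-specific
PCR + gel electrophoresis played for the real assay: an independent
per-sample, per-locus genotype oracle.  Reaction-level concordance
compares presence/absence calls per library (E or G) against the
product-presence state implied by the true genotypes; genotype-level
concordance compares combined diallelic calls at loci that passed QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genotype import ABSENT, PRESENT
from .pipeline import PipelineResult
from .simulate import CohortTruth, SimConfig, expected_reaction_states


@dataclass
class ConcordanceSummary:
    reaction: str
    n_match: int
    n_total: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_match / self.n_total if self.n_total else float("nan")


def reaction_concordance(
    result: PipelineResult,
    truth: CohortTruth,
    sim_config: SimConfig,
    reaction: str,
) -> ConcordanceSummary:
    """Count per-sample presence/absence calls agreeing with truth for one library.

    Every (sample, locus) cell is scored — reaction-level calls exist for
    all loci regardless of combined-call QC, mirroring per-library
    validation against site-specific PCR.
    """
    expected = expected_reaction_states(truth, sim_config)[reaction]
    n_match = 0
    n_total = 0
    for l, lid in enumerate(truth.locus_ids):
        cs = result.callsets[(lid, reaction)]
        for i, sid in enumerate(cs.sample_ids):
            s = truth.sample_ids.index(sid)
            want = PRESENT if expected[s, l] else ABSENT
            n_total += 1
            if cs.calls[i] == want:
                n_match += 1
    return ConcordanceSummary(reaction, n_match, n_total)


def genotype_concordance(result: PipelineResult, truth: CohortTruth) -> ConcordanceSummary:
    """Combined diallelic genotype concordance over loci that passed both QCs."""
    want = {
        (sid, lid): truth.genotype_str(s, l)
        for s, sid in enumerate(truth.sample_ids)
        for l, lid in enumerate(truth.locus_ids)
    }
    n_match = sum(c.genotype == want[(c.sample_id, c.locus_id)] for c in result.combined)
    return ConcordanceSummary("combined", n_match, len(result.combined))


def phase_concordance(phase_table: pd.DataFrame, truth: CohortTruth) -> ConcordanceSummary:
    """Fraction of phased heterozygotes assigned to the true insertion-bearing allele."""
    want = {}
    for s, sid in enumerate(truth.sample_ids):
        for l, lid in enumerate(truth.locus_ids):
            if truth.genotypes[s, l] == 1:
                want[(sid, lid)] = int(truth.insertion_hap[s, l])
    phased = phase_table[phase_table["phased"] == True]  # noqa: E712
    n_match = sum(
        int(row.insertion_allele) == want.get((row.sample_id, row.locus_id), -1)
        for row in phased.itertuples()
    )
    return ConcordanceSummary("phase", n_match, len(phased))


def summarize_run(
    result: PipelineResult,
    truth: CohortTruth,
    sim_config: SimConfig,
    phase_table: pd.DataFrame | None = None,
) -> dict:
    """Full concordance report as a plain dict (JSON-serializable)."""
    e = reaction_concordance(result, truth, sim_config, "E")
    g = reaction_concordance(result, truth, sim_config, "G")
    gt = genotype_concordance(result, truth)
    out = {
        "e_calls_match": e.n_match,
        "e_calls_total": e.n_total,
        "e_concordance_pct": round(e.percent, 1),
        "g_calls_match": g.n_match,
        "g_calls_total": g.n_total,
        "g_concordance_pct": round(g.percent, 1),
        "genotype_match": gt.n_match,
        "genotype_total": gt.n_total,
        "genotype_concordance_pct": round(gt.percent, 1) if gt.n_total else None,
        "n_loci_dropped": sum(1 for q in result.qc.values() if not q.passed),
    }
    if phase_table is not None and len(phase_table):
        ph = phase_concordance(phase_table, truth)
        out["phase_match"] = ph.n_match
        out["phase_total"] = ph.n_total
    return out
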