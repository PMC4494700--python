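"""Phase heterozygous insertions using known SNPs in the 3' flank.

For a heterozygous sample, reads of the E and G reactions originate from
the allele without and with the insertion, respectively.  Known
heterozygous SNPs in the flank covered by read 1 therefore admit
*monoploid* base calls per reaction; matching the G-library base to the
first or second allele recorded in the external SNP resource assigns the
insertion to haplotype 1 or 2.  Multiple SNPs vote independently and the
majority wins; the phase quality is the fraction of informative SNPs
supporting the call.

Reads are anchored gaplessly: the amplicon start is known from the assay
design, so the read-1 offset of a reference position is pure arithmetic.
Samples carrying indels in the flank will miscall downstream SNP
positions; the informativeness filter and the majority vote mitigate
this (a documented limitation, not handled by realignment).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .panel import Panel, PanelLocus

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class FlankSNP:
    """A known biallelic SNP in a locus's 3' flank, with per-sample phased alleles.

    ``pos`` is 1-based (VCF convention); ``alleles[sample] = (a1, a2)``
    are the two recorded haplotype bases, order as in the source VCF.
    """

    locus_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alleles: dict  # sample_id -> (base1, base2)

    @property
    def pos0(self) -> int:
        return self.pos - 1

    def is_het(self, sample_id: str) -> bool:
        a1, a2 = self.alleles[sample_id]
        return a1 != a2


class SnpVcfError(ValueError):
    pass


def load_snp_vcf(path: str | Path) -> tuple[dict, list[str]]:
    """Parse the external SNP VCF once; returns ({chrom: [records]}, sample_ids).

    Each record is (pos0, ref, alt, {sample: (base1, base2)}).  Biallelic
    SNVs only — multi-allelic and indel records are skipped and counted.
    """
    import pysam

    by_chrom: dict[str, list] = {}
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                n_skipped += 1
                continue
            alleles = {}
            for sid in samples:
                gt = rec.samples[sid]["GT"]
                if gt is None or None in gt:
                    alleles[sid] = ("N", "N")
                else:
                    pair = (ref, alt)
                    alleles[sid] = (pair[gt[0]], pair[gt[1]])
            by_chrom.setdefault(rec.chrom, []).append((rec.start, ref, alt, alleles))
    for recs in by_chrom.values():
        recs.sort(key=lambda r: r[0])
    return by_chrom, samples


def collect_flank_snps(locus: PanelLocus, snp_records: dict) -> list[FlankSNP]:
    """Biallelic SNVs inside the locus's flank interval (junction -> 3'-flank primer).

    ``snp_records`` is the mapping from :func:`load_snp_vcf`.  The flank
    interval is derived from the manifest tag targets.
    """
    if locus.chrom not in snp_records:
        raise SnpVcfError(f"chrom {locus.chrom!r} absent from SNP VCF")
    lo, hi = locus.flank_interval
    out = []
    for pos0, ref, alt, alleles in snp_records[locus.chrom]:
        if lo <= pos0 < hi:
            out.append(
                FlankSNP(
                    locus_id=locus.locus_id,
                    chrom=locus.chrom,
                    pos=pos0 + 1,
                    ref=ref,
                    alt=alt,
                    alleles=alleles,
                )
            )
    return out


def pileup_read1(
    read1s: list[str],
    anchor_end: int,
    positions: list[int],
) -> list[Counter]:
    """Pile up bases over 0-based reference ``positions`` from read-1 sequences.

    Read 1 starts at the 3'-flank primer and proceeds leftward along the
    reference, so reference position ``p`` sits at read offset
    ``anchor_end - 1 - p`` and appears complemented.  ``anchor_end`` is the
    3'-flank primer site end (G tag target end + primer length).
    """
    counters = [Counter() for _ in positions]
    by_len: dict[int, list[str]] = {}
    for r in read1s:
        by_len.setdefault(len(r), []).append(r)
    for length, reads in by_len.items():
        arr = np.frombuffer("".join(reads).encode(), dtype=np.uint8).reshape(
            len(reads), length
        )
        for k, p in enumerate(positions):
            off = anchor_end - 1 - p
            if 0 <= off < length:
                vals, cnts = np.unique(arr[:, off], return_counts=True)
                for v, c in zip(vals, cnts):
                    counters[k][_COMP.get(chr(v), "N")] += int(c)
    return counters


def monoploid_call(
    pileup: Counter,
    config: PipelineConfig | None = None,
) -> str | None:
    """Majority base of a single-allele pileup, or None (no call).

    Requires depth >= ``min_phase_depth`` and a majority fraction >=
    ``min_phase_fraction``; valid because each reaction of a heterozygote
    amplifies exactly one allele.
    """
    config = config or PipelineConfig()
    depth = sum(pileup.values())
    if depth < config.min_phase_depth:
        return None
    base, n = pileup.most_common(1)[0]
    if base == "N" or n / depth < config.min_phase_fraction:
        return None
    return base


@dataclass
class PhaseResult:
    sample_id: str
    locus_id: str
    phased: bool
    insertion_allele: int | None  # 1 or 2 (index into the recorded allele pair)
    n_het_snps: int               # informative heterozygous SNPs
    n_supporting: int
    phase_quality: float | None


def phase_locus_sample(
    sample_id: str,
    locus_id: str,
    e_calls: list[str | None],
    g_calls: list[str | None],
    snps: list[FlankSNP],
) -> PhaseResult:
    """Vote the insertion-bearing allele for one heterozygous (sample, locus).

    Per SNP: informative iff both reactions yielded a call and
    {E base, G base} equals the recorded allele pair as a set; the G base
    matching the first or second recorded allele votes haplotype 1 or 2.
    Majority over informative SNPs; exact ties and zero informative SNPs
    leave the sample unphased.
    """
    if not (len(e_calls) == len(g_calls) == len(snps)):
        raise ValueError("per-SNP call lists must align with the SNP list")
    votes: list[int] = []
    for e_base, g_base, snp in zip(e_calls, g_calls, snps):
        if e_base is None or g_base is None:
            continue
        a1, a2 = snp.alleles[sample_id]
        if a1 == a2:
            raise ValueError(
                f"{snp.locus_id}:{snp.pos}: sample {sample_id} is not heterozygous"
            )
        if {e_base, g_base} != {a1, a2}:
            continue  # allele mismatch: uninformative
        votes.append(1 if g_base == a1 else 2)
    if not votes:
        return PhaseResult(sample_id, locus_id, False, None, 0, 0, None)
    n1 = votes.count(1)
    n2 = votes.count(2)
    if n1 == n2:
        return PhaseResult(sample_id, locus_id, False, None, len(votes), 0, None)
    winner = 1 if n1 > n2 else 2
    support = max(n1, n2)
    return PhaseResult(
        sample_id,
        locus_id,
        True,
        winner,
        len(votes),
        support,
        support / len(votes),
    )


def phase_cohort(
    genotypes: dict,
    pileups: dict,
    panel: Panel,
    snp_records: dict,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Phase every heterozygous (sample, locus); returns the phase table.

    ``genotypes`` maps (sample_id, locus_id) -> genotype string;
    ``pileups`` maps (sample_id, locus_id, reaction) -> list of Counters
    aligned with the locus's flank SNPs (as produced by the pipeline's
    streaming pileup).  Homozygous entries are skipped.
    """
    config = config or PipelineConfig()
    rows = []
    for locus in panel.loci:
        snps = collect_flank_snps(locus, snp_records)
        for (sid, lid), gt in genotypes.items():
            if lid != locus.locus_id or gt != "0/1":
                continue
            het_snps = [s for s in snps if s.alleles.get(sid) and s.is_het(sid)]
            if not het_snps:
                result = PhaseResult(sid, lid, False, None, 0, 0, None)
            else:
                idx = [snps.index(s) for s in het_snps]
                e_pile = pileups.get((sid, lid, "E"))
                g_pile = pileups.get((sid, lid, "G"))
                e_calls = [
                    monoploid_call(e_pile[i], config) if e_pile else None for i in idx
                ]
                g_calls = [
                    monoploid_call(g_pile[i], config) if g_pile else None for i in idx
                ]
                result = phase_locus_sample(sid, lid, e_calls, g_calls, het_snps)
            rows.append(
                {
                    "sample_id": result.sample_id,
                    "locus_id": result.locus_id,
                    "phased": result.phased,
                    "insertion_allele": result.insertion_allele or ".",
                    "phase_quality": (
                        round(result.phase_quality, 4) if result.phase_quality else "."
                    ),
                    "n_het_snps": result.n_het_snps,
                    "n_supporting": result.n_supporting,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "locus_id",
            "phased",
            "insertion_allele",
            "phase_quality",
            "n_het_snps",
            "n_supporting",
        ],
    )
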