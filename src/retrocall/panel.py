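"""Assay panel model: loci, primers, diagnostic motifs and their manifest.

A panel describes the breakpoint-PCR design for a set of insertion loci.
Each locus is assayed by two reactions: E (empty site — both flank primers,
amplifies the allele *without* the insertion) and G (junction — the shared
TE-internal primer plus the 3'-flank primer, amplifies the allele *with*
the insertion).  Reads are later checked for specificity by aligning a
fixed-length tag to the expected genomic target interval recorded here.

Coordinates are 0-based, half-open throughout; primer strings are given in
read orientation (as they appear at the start of their read) and exclude
the universal PCR tails.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from .config import PipelineConfig
from .seq import is_dna, revcomp

# Family-specific diagnostic 3'-end motifs whose reverse complement in an
# E-reaction read reveals read-through across a short insertion.
DEFAULT_TE_MOTIFS = {
    "L1Hs": "TGCACATGTACCCTAAAACTTAG",
    "AluYb8": "ACTGCAGTCCGCAGTCCG",
}

PRIMER_MIN_LEN = 15
PRIMER_MAX_LEN = 35

MANIFEST_COLUMNS = [
    "locus_id",
    "chrom",
    "te_family",
    "primer_5flank",
    "primer_3flank",
    "e_tag_chrom",
    "e_tag_start",
    "e_tag_end",
    "e_tag_strand",
    "g_tag_chrom",
    "g_tag_start",
    "g_tag_end",
    "g_tag_strand",
    "e_product_len",
    "g_product_len",
    "library_group",
]


class PanelError(ValueError):
    """Raised for malformed panels or manifests."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise PanelError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise PanelError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PanelLocus:
    locus_id: str
    chrom: str
    te_family: str
    primer_5flank: str
    primer_3flank: str
    e_tag_target: GenomicInterval
    g_tag_target: GenomicInterval
    e_product_len: int
    g_product_len: int
    library_group: str

    def __post_init__(self) -> None:
        for name in ("primer_5flank", "primer_3flank"):
            p = getattr(self, name)
            if not is_dna(p):
                raise PanelError(f"locus {self.locus_id}: {name} is not ACGT: {p!r}")
            if not PRIMER_MIN_LEN <= len(p) <= PRIMER_MAX_LEN:
                raise PanelError(
                    f"locus {self.locus_id}: {name} length {len(p)} outside "
                    f"[{PRIMER_MIN_LEN}, {PRIMER_MAX_LEN}]"
                )
        if self.e_product_len <= 0 or self.g_product_len <= 0:
            raise PanelError(f"locus {self.locus_id}: product lengths must be positive")

    @property
    def flank_interval(self) -> tuple[int, int]:
        """0-based half-open interval between the two tag targets.

        This is the 3'-flank window (insertion junction → 3'-flank primer)
        that read 1 covers; known SNPs inside it are usable for phasing.
        Derived from the manifest as (e_tag end, g_tag end).
        """
        lo = self.e_tag_target.end
        hi = max(self.g_tag_target.start, self.g_tag_target.end)
        return (lo, hi)


@dataclass
class Panel:
    loci: list[PanelLocus]
    te_primers: dict[str, str]
    te_motifs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TE_MOTIFS))

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes: list[str] = []
        for locus in self.loci:
            if locus.locus_id in seen:
                dupes.append(locus.locus_id)
            seen.add(locus.locus_id)
        if dupes:
            raise PanelError(f"duplicate locus_id(s): {sorted(set(dupes))}")
        for locus in self.loci:
            if locus.te_family not in self.te_primers:
                raise PanelError(
                    f"locus {locus.locus_id}: no te_primer for family {locus.te_family!r}"
                )
            if locus.te_family not in self.te_motifs:
                raise PanelError(
                    f"locus {locus.locus_id}: no te_motif for family {locus.te_family!r}"
                )
        for fam, primer in self.te_primers.items():
            if not is_dna(primer):
                raise PanelError(f"te_primer for {fam!r} is not ACGT")

    def __len__(self) -> int:
        return len(self.loci)

    def locus(self, locus_id: str) -> PanelLocus:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(locus_id)

    def validate_tag_lengths(self, tag_length: int) -> None:
        for loc in self.loci:
            for name, iv in (("e_tag_target", loc.e_tag_target), ("g_tag_target", loc.g_tag_target)):
                if len(iv) != tag_length:
                    raise PanelError(
                        f"locus {loc.locus_id}: {name} length {len(iv)} != tag_length {tag_length}"
                    )


def read_panel(manifest_path: str | Path, te_primers_path: str | Path | None = None) -> Panel:
    """Read a panel manifest TSV (documented columns, '#' comments ignored).

    The shared TE-internal primers are read from ``te_primers_path`` — a
    2/3-column TSV (te_family, primer[, motif]) — or, by default, from
    ``<manifest>.te_primers.tsv`` next to the manifest.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise PanelError(f"manifest not found: {manifest_path}")
    with open(manifest_path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows:
        raise PanelError(f"{manifest_path}: empty manifest (no header)")
    header = rows[0]
    if header != MANIFEST_COLUMNS:
        raise PanelError(
            f"{manifest_path}: bad header; expected columns {MANIFEST_COLUMNS}, got {header}"
        )
    loci: list[PanelLocus] = []
    seen: set[str] = set()
    for row in rows[1:]:
        if len(row) != len(MANIFEST_COLUMNS):
            raise PanelError(f"{manifest_path}: row has {len(row)} fields: {row}")
        rec = dict(zip(MANIFEST_COLUMNS, row))
        if rec["locus_id"] in seen:
            raise PanelError(f"duplicate locus_id(s): ['{rec['locus_id']}']")
        seen.add(rec["locus_id"])
        loci.append(
            PanelLocus(
                locus_id=rec["locus_id"],
                chrom=rec["chrom"],
                te_family=rec["te_family"],
                primer_5flank=rec["primer_5flank"],
                primer_3flank=rec["primer_3flank"],
                e_tag_target=GenomicInterval(
                    rec["e_tag_chrom"], int(rec["e_tag_start"]), int(rec["e_tag_end"]), rec["e_tag_strand"]
                ),
                g_tag_target=GenomicInterval(
                    rec["g_tag_chrom"], int(rec["g_tag_start"]), int(rec["g_tag_end"]), rec["g_tag_strand"]
                ),
                e_product_len=int(rec["e_product_len"]),
                g_product_len=int(rec["g_product_len"]),
                library_group=rec["library_group"],
            )
        )
    te_primers: dict[str, str] = {}
    te_motifs: dict[str, str] = dict(DEFAULT_TE_MOTIFS)
    primers_path = (
        Path(te_primers_path)
        if te_primers_path is not None
        else manifest_path.with_suffix(manifest_path.suffix + ".te_primers.tsv")
    )
    if primers_path.exists():
        with open(primers_path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                fam, primer = row[0], row[1]
                te_primers[fam] = primer
                if len(row) > 2 and row[2]:
                    te_motifs[fam] = row[2]
    missing = {l.te_family for l in loci} - set(te_primers)
    if missing:
        raise PanelError(f"missing te_primer for family(ies): {sorted(missing)}")
    return Panel(loci=loci, te_primers=te_primers, te_motifs=te_motifs)


def write_panel(panel: Panel, manifest_path: str | Path) -> None:
    """Write manifest TSV plus the companion te-primers TSV (round-trips with read_panel)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MANIFEST_COLUMNS)
        for loc in panel.loci:
            w.writerow(
                [
                    loc.locus_id,
                    loc.chrom,
                    loc.te_family,
                    loc.primer_5flank,
                    loc.primer_3flank,
                    loc.e_tag_target.chrom,
                    loc.e_tag_target.start,
                    loc.e_tag_target.end,
                    loc.e_tag_target.strand,
                    loc.g_tag_target.chrom,
                    loc.g_tag_target.start,
                    loc.g_tag_target.end,
                    loc.g_tag_target.strand,
                    loc.e_product_len,
                    loc.g_product_len,
                    loc.library_group,
                ]
            )
    primers_path = manifest_path.with_suffix(manifest_path.suffix + ".te_primers.tsv")
    with open(primers_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for fam in sorted(panel.te_primers):
            w.writerow([fam, panel.te_primers[fam], panel.te_motifs.get(fam, "")])


@dataclass
class LocusValidation:
    locus_id: str
    passed: bool
    reasons: list[str]


def validate_panel(
    panel: Panel, reference, config: PipelineConfig | None = None
) -> list[LocusValidation]:
    """Validate a panel against an indexed reference (pyfaidx.Fasta or dict-like).

    Flags loci whose expected tag-target sequence occurs more than once in
    the reference (either strand) and library groups whose expected E
    product lengths spread more than ``max_amplicon_spread``.  Pure
    function of its inputs: never mutates the panel.
    """
    config = config or PipelineConfig()
    panel.validate_tag_lengths(config.tag_length)

    chrom_seqs: dict[str, str] = {}
    names = set(reference.keys()) if hasattr(reference, "keys") else set()
    for loc in panel.loci:
        for iv in (loc.e_tag_target, loc.g_tag_target):
            if iv.chrom not in chrom_seqs:
                if names and iv.chrom not in names:
                    raise PanelError(f"chrom {iv.chrom!r} absent from reference")
                try:
                    chrom_seqs[iv.chrom] = str(reference[iv.chrom][:]).upper()
                except KeyError as exc:
                    raise PanelError(f"chrom {iv.chrom!r} absent from reference") from exc
            if iv.end > len(chrom_seqs[iv.chrom]):
                raise PanelError(
                    f"locus {loc.locus_id}: tag target {iv} beyond end of {iv.chrom}"
                )

    def occurrences(kmer: str) -> int:
        n = 0
        rc = revcomp(kmer)
        for seq in chrom_seqs.values():
            for probe in {kmer, rc}:
                start = 0
                while True:
                    i = seq.find(probe, start)
                    if i < 0:
                        break
                    n += 1
                    start = i + 1
        return n

    group_spread_fail: set[str] = set()
    by_group: dict[str, list[int]] = {}
    for loc in panel.loci:
        by_group.setdefault(loc.library_group, []).append(loc.e_product_len)
    for group, lens in by_group.items():
        if max(lens) - min(lens) > config.max_amplicon_spread:
            group_spread_fail.add(group)

    report: list[LocusValidation] = []
    for loc in panel.loci:
        reasons: list[str] = []
        for name, iv in (("e_tag", loc.e_tag_target), ("g_tag", loc.g_tag_target)):
            tag_seq = chrom_seqs[iv.chrom][iv.start : iv.end]
            if iv.strand == "-":
                tag_seq = revcomp(tag_seq)
            if occurrences(tag_seq) > 1:
                reasons.append(f"multi-mapping:{name}")
        if loc.library_group in group_spread_fail:
            reasons.append("amplicon_spread")
        report.append(LocusValidation(loc.locus_id, passed=not reasons, reasons=reasons))
    return report
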