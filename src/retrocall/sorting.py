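"""Assign read pairs to targeted (locus, reaction) amplicons.

Sorting rules (read orientation, position 0 prefix matching only — the
universal tails are the sequencing primers, so every read begins at its
locus-specific primer):

* G reaction: read 1 begins with an exact match to some locus's 3'-flank
  primer AND read 2 begins with the family TE-internal primer within
  ``te_primer_max_mm`` mismatches (default 1).
* E reaction: read 1 begins with an exact 3'-flank primer match AND read 2
  begins with an exact match to the SAME locus's 5'-flank primer.
* Anything else is unassigned (a value, not an error).  If a read 2
  satisfies both conditions, G wins and a warning is counted.

Specificity tags are the ``tag_length`` bases immediately after the matched
primer: read 2 after the 5'-flank primer (E), read 1 after the 3'-flank
primer (G).  E-reaction reads are additionally scanned for the reverse
complement of the family diagnostic motif (Hamming distance <=
``motif_max_mm`` at any offset), which flags read-through across short
truncated insertions.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from numba import njit

from .config import PipelineConfig
from .panel import Panel
from .seq import revcomp


@dataclass(frozen=True)
class AmpliconAssignment:
    locus_id: str
    reaction: str  # 'E' or 'G'
    tag: str | None  # None when the read is too short to yield a full tag


@njit(cache=True)
def _motif_scan(read: np.ndarray, motif: np.ndarray, max_mm: int) -> bool:
    n, m = read.size, motif.size
    for off in range(n - m + 1):
        mm = 0
        for j in range(m):
            if read[off + j] != motif[j]:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            return True
    return False


def detect_te_motif(read: str, motif: str, max_mm: int) -> bool:
    """True iff some offset of ``read`` matches revcomp(motif) within ``max_mm`` mismatches.

    The scan is exhaustive over all offsets; reads shorter than the motif
    are never positive.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    rc = np.frombuffer(revcomp(motif).encode(), dtype=np.uint8)
    arr = np.frombuffer(read.encode(), dtype=np.uint8)
    if arr.size < rc.size:
        return False
    return bool(_motif_scan(arr, rc, max_mm))


class _MotifScanner:
    """Cached motif detector for one family (reads repeat heavily within an amplicon)."""

    def __init__(self, motif: str, max_mm: int):
        self._rc = np.frombuffer(revcomp(motif).encode(), dtype=np.uint8)
        self._max_mm = max_mm
        self._cache: dict[str, bool] = {}

    def __call__(self, read: str) -> bool:
        hit = self._cache.get(read)
        if hit is None:
            arr = np.frombuffer(read.encode(), dtype=np.uint8)
            hit = arr.size >= self._rc.size and bool(_motif_scan(arr, self._rc, self._max_mm))
            self._cache[read] = hit
        return hit


def _hamming_leq(a: str, b: str, max_mm: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > max_mm:
                return False
    return True


class ReadSorter:
    """Pure-function read-pair classifier for one panel + config."""

    def __init__(self, panel: Panel, config: PipelineConfig | None = None):
        self.panel = panel
        self.config = config or PipelineConfig()
        self.collision_warnings = 0
        self.dual_match_warnings = 0

        # 3'-flank primer lookup, one dict per primer length, longest first.
        by_len: dict[int, dict[str, int]] = {}
        collided: dict[int, set[str]] = {}
        for i, locus in enumerate(panel.loci):
            p3 = locus.primer_3flank
            d = by_len.setdefault(len(p3), {})
            if p3 in d:
                collided.setdefault(len(p3), set()).add(p3)
            else:
                d[p3] = i
        for length, primers in collided.items():
            for p in primers:
                del by_len[length][p]  # exact tie -> unassigned
        self._p3_by_len = sorted(by_len.items(), key=lambda kv: -kv[0])
        self._collided = collided

    def _match_locus(self, read1: str) -> int | None:
        for length, table in self._p3_by_len:
            idx = table.get(read1[:length])
            if idx is not None:
                return idx
        for length, primers in self._collided.items():
            if read1[:length] in primers:
                self.collision_warnings += 1
                break
        return None

    def assign_read_pair(self, read1: str, read2: str) -> AmpliconAssignment | None:
        """Assign one pair, or return None (unassigned)."""
        if not read1 or not read2:
            raise ValueError("reads must be non-empty")
        idx = self._match_locus(read1)
        if idx is None:
            return None
        locus = self.panel.loci[idx]
        te_primer = self.panel.te_primers[locus.te_family]
        is_g = len(read2) >= len(te_primer) and _hamming_leq(
            read2, te_primer, self.config.te_primer_max_mm
        )
        is_e = read2.startswith(locus.primer_5flank)
        if is_g and is_e:
            self.dual_match_warnings += 1
        if is_g:
            tag = self._extract(read1, len(locus.primer_3flank))
            return AmpliconAssignment(locus.locus_id, "G", tag)
        if is_e:
            tag = self._extract(read2, len(locus.primer_5flank))
            return AmpliconAssignment(locus.locus_id, "E", tag)
        return None

    def _extract(self, read: str, primer_len: int) -> str | None:
        end = primer_len + self.config.tag_length
        if len(read) < end:
            return None
        return read[primer_len:end]


def extract_tag(reaction: str, read1: str, read2: str, primer_len: int, config: PipelineConfig) -> str | None:
    """Tag of a pre-assigned pair: read 2 after the 5'-flank primer (E), read 1 after the 3'-flank primer (G)."""
    read = read2 if reaction == "E" else read1
    end = primer_len + config.tag_length
    if len(read) < end:
        return None
    return read[primer_len:end]


@dataclass
class AmpliconReads:
    """All reads of one sample assigned to one (locus, reaction) amplicon."""

    locus_id: str
    reaction: str
    n_assigned: int = 0
    tags: list = field(default_factory=list)        # str | None per read
    motif_positive: list = field(default_factory=list)  # bool per read (E only)
    read1s: list = field(default_factory=list)      # retained for phasing pileups


@dataclass
class SampleSortResult:
    sample_id: str
    amplicons: dict  # (locus_id, reaction) -> AmpliconReads
    n_total: int
    n_unassigned: int

    @property
    def n_assigned(self) -> int:
        return sum(a.n_assigned for a in self.amplicons.values())


class FastqFormatError(ValueError):
    pass


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_read_pairs(fastq1: str | Path, fastq2: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, read1, read2); hard error on ill-formed or unpaired FASTQ."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_maybe_gz(fastq1) as fh1, _open_maybe_gz(fastq2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        n = 0
        while True:
            try:
                rec1 = next(it1, None)
                rec2 = next(it2, None)
            except ValueError as exc:  # Biopython raises on truncated/ill-formed records
                raise FastqFormatError(f"ill-formed FASTQ near record {n + 1}: {exc}") from exc
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise FastqFormatError(
                    f"unpaired FASTQ files: one ended at record {n + 1}"
                )
            n += 1
            name1 = rec1[0].split()[0]
            name2 = rec2[0].split()[0]
            if name1 != name2:
                raise FastqFormatError(
                    f"read name mismatch at record {n}: {name1!r} vs {name2!r}"
                )
            yield name1, rec1[1], rec2[1]


def sort_sample(
    sample_id: str,
    fastq1: str | Path,
    fastq2: str | Path,
    panel: Panel,
    config: PipelineConfig | None = None,
    keep_read1: bool = True,
) -> SampleSortResult:
    """Sort one sample's read pairs into per-amplicon collections.

    Every pair lands in exactly one bucket (an amplicon or unassigned):
    ``n_total == sum(n_assigned) + n_unassigned`` holds on every run.
    Read 1 sequences are retained per amplicon for downstream SNP pileups
    unless ``keep_read1=False``.
    """
    config = config or PipelineConfig()
    sorter = ReadSorter(panel, config)
    scanners = {
        fam: _MotifScanner(motif, config.motif_max_mm)
        for fam, motif in panel.te_motifs.items()
    }
    scanners2 = (
        {fam: _MotifScanner(motif, config.motif_max_mm) for fam, motif in panel.te_motifs.items()}
        if config.scan_read2_for_motif
        else None
    )
    family = {loc.locus_id: loc.te_family for loc in panel.loci}

    amplicons: dict[tuple[str, str], AmpliconReads] = {
        (loc.locus_id, reaction): AmpliconReads(loc.locus_id, reaction)
        for loc in panel.loci
        for reaction in ("E", "G")
    }
    n_total = 0
    n_unassigned = 0
    for _name, read1, read2 in iter_read_pairs(fastq1, fastq2):
        n_total += 1
        assignment = sorter.assign_read_pair(read1, read2)
        if assignment is None:
            n_unassigned += 1
            continue
        bucket = amplicons[(assignment.locus_id, assignment.reaction)]
        bucket.n_assigned += 1
        bucket.tags.append(assignment.tag)
        if assignment.reaction == "E":
            fam = family[assignment.locus_id]
            hit = scanners[fam](read1)
            if not hit and scanners2 is not None:
                hit = scanners2[fam](read2)
            bucket.motif_positive.append(hit)
        else:
            bucket.motif_positive.append(False)
        if keep_read1:
            bucket.read1s.append(read1)
    return SampleSortResult(
        sample_id=sample_id,
        amplicons=amplicons,
        n_total=n_total,
        n_unassigned=n_unassigned,
    )


def write_tag_table(result: SampleSortResult, path: str | Path) -> None:
    """Long-format per-read tag table (sample, locus, reaction, tag, motif_positive)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tlocus_id\treaction\ttag\tmotif_positive\n")
        for (locus_id, reaction), bucket in sorted(result.amplicons.items()):
            for tag, motif in zip(bucket.tags, bucket.motif_positive):
                fh.write(
                    f"{result.sample_id}\t{locus_id}\t{reaction}\t{tag or '.'}\t{int(motif)}\n"
                )
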