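"""Align specificity tags to the reference and tabulate specific read counts.

A tag is *specific* when it has exactly one alignment in the whole
reference (both strands, within the reporting cap) and that alignment
starts at the expected target position on the expected strand (within
``tag_slack_bp``).  Default matching is exact (0 mismatches, 0 slack),
replicating the primary analysis; the relaxed mode
(``tag_max_mm``/``tag_slack_bp`` > 0) exists because exact matching is
blind to small variants in the tag region.

The index is a k-mer-seed (k=16) + Hamming-verification scheme: with
three disjoint seeds in a 50-bp tag, any alignment with at most 2
mismatches is guaranteed to be found (pigeonhole), which covers the
supported relaxation range.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

from .config import ConfigError, PipelineConfig
from .panel import GenomicInterval, Panel
from .seq import revcomp
from .sorting import SampleSortResult

SEED_K = 16
REPORT_CAP = 10  # uniqueness is defined within this many reported locations


class TagClass(str, Enum):
    UNALIGNED = "unaligned"
    MULTI = "multi"
    UNIQUE_OFFTARGET = "unique_offtarget"
    SPECIFIC = "specific"


@dataclass(frozen=True)
class Alignment:
    chrom: str
    start: int
    strand: str


class ReferenceIndex:
    """Exact/near-exact query index over both strands of a reference.

    ``reference`` may be a dict {chrom: sequence} or a pyfaidx.Fasta.
    Supports queries with up to ``(number of disjoint seeds) - 1``
    mismatches; results capped at ``REPORT_CAP`` locations.
    """

    def __init__(self, reference, tag_length: int = 50):
        if hasattr(reference, "keys"):
            self._seqs = {c: str(reference[c][:]).upper() for c in reference.keys()}
        else:
            raise TypeError("reference must be dict-like (chrom -> sequence)")
        if not self._seqs or all(len(s) == 0 for s in self._seqs.values()):
            raise ConfigError("empty reference")
        self.tag_length = tag_length
        self.max_supported_mm = tag_length // SEED_K - 1
        self._seed_offsets = [i * (SEED_K + 1) for i in range(tag_length // SEED_K)]
        self._seed_offsets = [o for o in self._seed_offsets if o + SEED_K <= tag_length]
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self._seqs.items():
            for i in range(len(seq) - SEED_K + 1):
                self._index.setdefault(seq[i : i + SEED_K], []).append((chrom, i))
        self._cache: dict[tuple[str, int], tuple[Alignment, ...]] = {}

    def _forward_hits(self, query: str, max_mm: int) -> set[tuple[str, int]]:
        hits: set[tuple[str, int]] = set()
        n = len(query)
        for off in self._seed_offsets:
            for chrom, pos in self._index.get(query[off : off + SEED_K], ()):
                start = pos - off
                seq = self._seqs[chrom]
                if start < 0 or start + n > len(seq):
                    continue
                if (chrom, start) in hits:
                    continue
                window = seq[start : start + n]
                mm = 0
                for a, b in zip(query, window):
                    if a != b:
                        mm += 1
                        if mm > max_mm:
                            break
                else:
                    hits.add((chrom, start))
                if len(hits) > REPORT_CAP:
                    return hits
        return hits

    def query(self, tag: str, max_mm: int = 0) -> tuple[Alignment, ...]:
        """All alignments of ``tag`` with <= ``max_mm`` mismatches, both strands, capped."""
        if max_mm > self.max_supported_mm:
            raise ConfigError(
                f"tag_max_mm={max_mm} exceeds the guaranteed-sensitivity limit "
                f"{self.max_supported_mm} for {self.tag_length}-bp tags"
            )
        key = (tag, max_mm)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        hits = [
            Alignment(c, p, "+") for c, p in sorted(self._forward_hits(tag, max_mm))
        ]
        hits += [
            Alignment(c, p, "-")
            for c, p in sorted(self._forward_hits(revcomp(tag), max_mm))
        ]
        result = tuple(hits[: REPORT_CAP + 1])
        self._cache[key] = result
        return result


def build_reference_index(reference, config: PipelineConfig | None = None) -> ReferenceIndex:
    """Build the searchable both-strand index (accepts pyfaidx.Fasta or dict)."""
    config = config or PipelineConfig()
    return ReferenceIndex(reference, tag_length=config.tag_length)


def classify_tag(
    tag: str,
    target: GenomicInterval,
    index: ReferenceIndex,
    config: PipelineConfig | None = None,
) -> TagClass:
    """Classify one tag against its expected target interval."""
    config = config or PipelineConfig()
    if len(target) != config.tag_length:
        raise ConfigError(
            f"target interval length {len(target)} != tag_length {config.tag_length}"
        )
    hits = index.query(tag, config.tag_max_mm)
    if not hits:
        return TagClass.UNALIGNED
    if len(hits) > 1:
        return TagClass.MULTI
    hit = hits[0]
    if (
        hit.chrom == target.chrom
        and hit.strand == target.strand
        and abs(hit.start - target.start) <= config.tag_slack_bp
    ):
        return TagClass.SPECIFIC
    return TagClass.UNIQUE_OFFTARGET


@dataclass
class AmpliconCountRecord:
    """Per (sample, locus, reaction) read accounting."""

    sample_id: str
    locus_id: str
    reaction: str
    n_assigned: int
    n_tags: int
    n_aligned: int
    n_unique: int
    n_specific: int
    n_motif_specific: int

    def __post_init__(self) -> None:
        ok = 0 <= self.n_specific <= self.n_unique <= self.n_aligned <= self.n_tags <= self.n_assigned
        if not ok:
            raise ValueError(f"count identities violated: {self}")

    @property
    def unique_fraction(self) -> float:
        return self.n_unique / self.n_tags if self.n_tags else 0.0

    @property
    def motif_fraction(self) -> float:
        return self.n_motif_specific / self.n_specific if self.n_specific else 0.0


@dataclass
class CountMatrix:
    """loci x samples matrices of specific counts and QC fractions for one reaction."""

    reaction: str
    n_specific: pd.DataFrame
    unique_fraction: pd.DataFrame
    motif_fraction: pd.DataFrame


def tabulate_counts(
    sort_results: list[SampleSortResult],
    panel: Panel,
    index: ReferenceIndex,
    config: PipelineConfig | None = None,
) -> tuple[dict[str, CountMatrix], list[AmpliconCountRecord]]:
    """Classify every tag and build per-reaction count matrices.

    Deterministic; the AmpliconCountRecord count identities hold for every
    cell by construction.
    """
    config = config or PipelineConfig()
    targets = {
        (loc.locus_id, "E"): loc.e_tag_target for loc in panel.loci
    } | {(loc.locus_id, "G"): loc.g_tag_target for loc in panel.loci}

    records: list[AmpliconCountRecord] = []
    sample_ids = [r.sample_id for r in sort_results]
    locus_ids = [loc.locus_id for loc in panel.loci]
    mats = {
        reaction: {
            name: pd.DataFrame(0.0, index=locus_ids, columns=sample_ids)
            for name in ("n_specific", "unique_fraction", "motif_fraction")
        }
        for reaction in ("E", "G")
    }

    for result in sort_results:
        for (locus_id, reaction), bucket in result.amplicons.items():
            target = targets[(locus_id, reaction)]
            n_tags = n_aligned = n_unique = n_specific = n_motif_specific = 0
            cls_cache: dict[str, TagClass] = {}
            for tag, motif in zip(bucket.tags, bucket.motif_positive):
                if tag is None:
                    continue
                n_tags += 1
                cls = cls_cache.get(tag)
                if cls is None:
                    cls = classify_tag(tag, target, index, config)
                    cls_cache[tag] = cls
                if cls is TagClass.UNALIGNED:
                    continue
                n_aligned += 1
                if cls is TagClass.MULTI:
                    continue
                n_unique += 1
                if cls is TagClass.SPECIFIC:
                    n_specific += 1
                    if motif:
                        n_motif_specific += 1
            rec = AmpliconCountRecord(
                sample_id=result.sample_id,
                locus_id=locus_id,
                reaction=reaction,
                n_assigned=bucket.n_assigned,
                n_tags=n_tags,
                n_aligned=n_aligned,
                n_unique=n_unique,
                n_specific=n_specific,
                n_motif_specific=n_motif_specific,
            )
            records.append(rec)
            m = mats[reaction]
            m["n_specific"].loc[locus_id, result.sample_id] = n_specific
            m["unique_fraction"].loc[locus_id, result.sample_id] = rec.unique_fraction
            m["motif_fraction"].loc[locus_id, result.sample_id] = rec.motif_fraction

    matrices = {
        reaction: CountMatrix(
            reaction=reaction,
            n_specific=mats[reaction]["n_specific"].astype(int),
            unique_fraction=mats[reaction]["unique_fraction"],
            motif_fraction=mats[reaction]["motif_fraction"],
        )
        for reaction in ("E", "G")
    }
    return matrices, records


def matrices_from_records(
    records: list[AmpliconCountRecord],
    locus_ids: list[str],
    sample_ids: list[str],
) -> dict[str, CountMatrix]:
    """Assemble per-reaction CountMatrix objects from flat count records."""
    out = {}
    for reaction in ("E", "G"):
        frames = {}
        for name, attr in (
            ("n_specific", "n_specific"),
            ("unique_fraction", "unique_fraction"),
            ("motif_fraction", "motif_fraction"),
        ):
            df = pd.DataFrame(0.0, index=locus_ids, columns=sample_ids)
            for r in records:
                if r.reaction == reaction:
                    df.loc[r.locus_id, r.sample_id] = getattr(r, attr)
            frames[name] = df
        out[reaction] = CountMatrix(
            reaction=reaction,
            n_specific=frames["n_specific"].astype(int),
            unique_fraction=frames["unique_fraction"],
            motif_fraction=frames["motif_fraction"],
        )
    return out


def write_count_tables(
    matrices: dict[str, CountMatrix],
    records: list[AmpliconCountRecord],
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    for reaction, mat in matrices.items():
        mat.n_specific.to_csv(outdir / f"counts_{reaction}.tsv", sep="\t")
    rows = [
        {
            "sample_id": r.sample_id,
            "locus_id": r.locus_id,
            "reaction": r.reaction,
            "n_assigned": r.n_assigned,
            "n_tags": r.n_tags,
            "n_aligned": r.n_aligned,
            "n_unique": r.n_unique,
            "n_specific": r.n_specific,
            "unique_fraction": round(r.unique_fraction, 6),
            "motif_fraction": round(r.motif_fraction, 6),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(outdir / "amplicon_qc.tsv", sep="\t", index=False)
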