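"""Synthetic experiment generator.

Produces a fully self-contained genotyping experiment with the statistical
structure the genotyper assumes: a random reference, a breakpoint-PCR panel,
a cohort of diploid insertion genotypes drawn under Hardy-Weinberg, known
flank SNPs with phased per-sample genotypes (the external-SNP-resource
role), and per-sample paired-end amplicon reads whose specific read counts
form well-separated high (amplicon present) and low (cross-contamination)
clusters on the log10 scale.

Injectable failure modes mirror what real assays exhibit:

* short, 3'-anchored truncated insertions that let the empty-site (E)
  reaction read through the element (diagnosed downstream via the family
  motif);
* a primer-overlapping variant that abolishes amplification of the
  empty-site allele in one sample (the affected genotype is forced to a
  heterozygote so the dropout is consequential);
* a 1-bp deletion at the start of the E tag window that breaks exact tag
  alignment;
* an E tag 50-mer duplicated elsewhere in the reference (multi-mapping).

All randomness flows from ``SimConfig.seed`` through fixed, named
substreams, so every output file is byte-identical across reruns.

Amplicon geometry (one block per locus, all on the '+' strand)::

    [pad][P5 primer][E tag][gap] | junction | [flank, SNPs][G tag][P3 site][pad]

Read 1 starts at the 3'-flank primer and reads leftward (reverse strand)
across the flank toward the junction; read 2 starts at the 5'-flank primer
(E) or the TE-internal primer (G).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ConfigError
from .panel import DEFAULT_TE_MOTIFS, GenomicInterval, Panel, PanelLocus, write_panel
from .seq import revcomp

# Fixed assay geometry (bp).  The 5'-flank primer is 19 bp so that a 50-bp
# tag fits exactly in the 69-bp read 2 (19 + 50 = 69); the 3' flank is
# 175 bp so that read 1 (250 bp) covers every flank SNP and, for short
# insertions, the reverse-complement diagnostic motif; the TE-internal
# primer sits 120 bp from the TE 3' end so a 150-bp truncated element
# still amplifies in the G reaction.
PAD = 30
P5_LEN = 19
P3_LEN = 22
E_TAG_GAP = 10
FLANK_LEN = 175
TE_TAIL_LEN = 120
TE_PRIMER_LEN = 20
TE_CONSENSUS_LEN = 1000
POLYA_LEN = 20
SPACER = 64
SNP_EDGE = 5  # keep SNPs clear of the junction and of the G tag window

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_QUAL_CHAR = "?"  # constant Q30 (Phred+33)


@dataclass
class SimConfig:
    """Study conditions for a simulated experiment."""

    n_samples: int
    n_loci: int
    seed: int = 0
    insertion_allele_freq_range: tuple[float, float] = (0.1, 0.9)
    present_log10_mean_range: tuple[float, float] = (3.5, 4.5)
    present_log10_sd: float = 0.15
    absent_count_lambda: float = 2.0
    per_base_error: float = 0.002
    read1_len: int = 250
    read2_len: int = 69
    flank_snps_per_locus: tuple[int, int] = (1, 11)
    short_insertion_loci: list[tuple[int, int]] = field(default_factory=list)
    primer_snp_failures: list[tuple[int, int]] = field(default_factory=list)
    tag_indel_samples: list[tuple[int, int, int]] = field(default_factory=list)
    multimap_loci: list[int] = field(default_factory=list)
    te_family: str = "L1Hs"
    tag_length: int = 50

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_loci < 1:
            raise ConfigError("n_samples and n_loci must be >= 1")
        for name in (
            "insertion_allele_freq_range",
            "present_log10_mean_range",
            "flank_snps_per_locus",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} is not well-ordered: ({lo}, {hi})")
        lo, hi = self.insertion_allele_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("insertion_allele_freq_range must lie in [0, 1]")
        if not (0.0 <= self.per_base_error < 1.0):
            raise ConfigError("per_base_error must be in [0, 1)")
        if self.read2_len < P5_LEN:
            raise ConfigError(
                f"read2_len {self.read2_len} shorter than the 5'-flank primer ({P5_LEN} bp)"
            )
        if self.tag_length + 2 * SNP_EDGE >= FLANK_LEN:
            raise ConfigError(
                f"tag_length {self.tag_length} does not fit the {FLANK_LEN}-bp flank"
            )
        for locus, trunc in self.short_insertion_loci:
            self._check_locus(locus)
            if not 1 <= trunc < 200:
                raise ConfigError(f"truncated length must be in [1, 200), got {trunc}")
        for locus, sample in self.primer_snp_failures:
            self._check_locus(locus)
            self._check_sample(sample)
        for locus, sample, indel in self.tag_indel_samples:
            self._check_locus(locus)
            self._check_sample(sample)
            if indel != 1:
                raise ConfigError(f"only 1-bp tag indels are modelled, got {indel}")
        for locus in self.multimap_loci:
            self._check_locus(locus)

    def _check_locus(self, i: int) -> None:
        if not 0 <= i < self.n_loci:
            raise ConfigError(f"locus index {i} out of range [0, {self.n_loci})")

    def _check_sample(self, i: int) -> None:
        if not 0 <= i < self.n_samples:
            raise ConfigError(f"sample index {i} out of range [0, {self.n_samples})")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


@dataclass(frozen=True)
class LocusGeometry:
    """Absolute 0-based coordinates of one locus block on the reference."""

    p5_start: int   # 5'-flank primer start
    p5_end: int     # = E tag start
    junction: int   # insertion point
    p3_site_start: int  # 3'-flank primer binding site (plus strand)
    p3_site_end: int


@dataclass
class SimulatedReference:
    """Reference, panel and SNP catalogue of a simulated experiment."""

    config: SimConfig
    reference: dict[str, str]
    panel: Panel
    geometry: list[LocusGeometry]
    te_consensus: str
    # per locus: SNP absolute positions (0-based), ref bases, alt bases, alt freqs
    snp_positions: list[np.ndarray]
    snp_ref: list[list[str]]
    snp_alt: list[list[str]]
    snp_freq: list[np.ndarray]

    @property
    def chrom(self) -> str:
        return "chr1"


def simulate_reference_and_panel(config: SimConfig) -> SimulatedReference:
    """Build the reference sequence, the assay panel and the flank SNP catalogue.

    The reference carries the empty-site haplotype of every locus; the TE
    consensus (family motif + poly-A at its 3' end) is returned separately
    for constructing insertion-allele amplicons.  Loci listed in
    ``multimap_loci`` get their E tag duplicated in a tail region.
    """
    rng = _rng(config, 0)
    tag = config.tag_length
    block = PAD + P5_LEN + tag + E_TAG_GAP + FLANK_LEN + P3_LEN + PAD + SPACER

    chrom_seq = _random_dna(rng, config.n_loci * block)
    geometry: list[LocusGeometry] = []
    for i in range(config.n_loci):
        b = i * block
        p5s = b + PAD
        p5e = p5s + P5_LEN
        junction = p5e + tag + E_TAG_GAP
        p3ss = junction + FLANK_LEN
        p3se = p3ss + P3_LEN
        geometry.append(LocusGeometry(p5s, p5e, junction, p3ss, p3se))

    # TE consensus: body ... motif ... poly-A tail at the 3' end.
    motif = DEFAULT_TE_MOTIFS.get(config.te_family)
    if motif is None:
        raise ConfigError(f"no diagnostic motif for family {config.te_family!r}")
    te_body = _random_dna(rng, TE_CONSENSUS_LEN - len(motif) - POLYA_LEN)
    te_consensus = te_body + motif + "A" * POLYA_LEN
    te_primer = te_consensus[-TE_TAIL_LEN : -TE_TAIL_LEN + TE_PRIMER_LEN]

    # Multi-mapping pathology: duplicate the E tag 50-mer into a tail region.
    tail_parts: list[str] = []
    for locus in config.multimap_loci:
        g = geometry[locus]
        tail_parts.append(_random_dna(rng, PAD))
        tail_parts.append(chrom_seq[g.p5_end : g.p5_end + tag])
    tail_parts.append(_random_dna(rng, PAD))
    chrom_seq = chrom_seq + "".join(tail_parts)

    loci: list[PanelLocus] = []
    snp_positions: list[np.ndarray] = []
    snp_ref: list[list[str]] = []
    snp_alt: list[list[str]] = []
    snp_freq: list[np.ndarray] = []
    lo_snp, hi_snp = config.flank_snps_per_locus
    for i, g in enumerate(geometry):
        primer5 = chrom_seq[g.p5_start : g.p5_end]
        primer3 = revcomp(chrom_seq[g.p3_site_start : g.p3_site_end])
        e_product = g.p3_site_end - g.p5_start
        g_product = TE_TAIL_LEN + (g.p3_site_end - g.junction)
        loci.append(
            PanelLocus(
                locus_id=f"L{i:03d}",
                chrom="chr1",
                te_family=config.te_family,
                primer_5flank=primer5,
                primer_3flank=primer3,
                e_tag_target=GenomicInterval("chr1", g.p5_end, g.p5_end + tag, "+"),
                g_tag_target=GenomicInterval(
                    "chr1", g.p3_site_start - tag, g.p3_site_start, "-"
                ),
                e_product_len=e_product,
                g_product_len=g_product,
                library_group="lib1",
            )
        )
        # SNPs between the junction and the G tag window, clear of both.
        n_snps = int(rng.integers(lo_snp, hi_snp + 1))
        window = np.arange(g.junction + SNP_EDGE, g.p3_site_start - tag - SNP_EDGE)
        pos = np.sort(rng.choice(window, size=n_snps, replace=False))
        refs, alts = [], []
        for p in pos:
            ref_base = chrom_seq[p]
            alt_base = "ACGT"[(("ACGT".index(ref_base)) + int(rng.integers(1, 4))) % 4]
            refs.append(ref_base)
            alts.append(alt_base)
        snp_positions.append(pos)
        snp_ref.append(refs)
        snp_alt.append(alts)
        snp_freq.append(rng.uniform(0.2, 0.8, size=n_snps))

    panel = Panel(loci=loci, te_primers={config.te_family: te_primer})
    return SimulatedReference(
        config=config,
        reference={"chr1": chrom_seq},
        panel=panel,
        geometry=geometry,
        te_consensus=te_consensus,
        snp_positions=snp_positions,
        snp_ref=snp_ref,
        snp_alt=snp_alt,
        snp_freq=snp_freq,
    )


@dataclass
class CohortTruth:
    """Per-sample ground truth: the oracle that stands in for locus-specific PCR.

    ``genotypes[s, l]`` counts insertion alleles (0, 1, 2); for
    heterozygotes ``insertion_hap[s, l]`` in {1, 2} names the carrying
    haplotype (0 elsewhere).  ``snp_haps[l][s, h, k]`` is the allele
    (0=ref, 1=alt) of haplotype ``h`` at flank SNP ``k`` of locus ``l``.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray
    insertion_hap: np.ndarray
    snp_haps: list[np.ndarray]
    allele_freqs: np.ndarray
    trunc_len: np.ndarray  # per locus, 0 = full-length element
    seed: int

    def genotype_str(self, s: int, l: int) -> str:
        return {0: "0/0", 1: "0/1", 2: "1/1"}[int(self.genotypes[s, l])]


def simulate_cohort(ref: SimulatedReference, config: SimConfig | None = None) -> CohortTruth:
    """Draw diploid insertion genotypes (Hardy-Weinberg) and flank SNP haplotypes.

    Loci named in ``primer_snp_failures`` have the affected sample forced
    to a heterozygote so that the empty-allele amplification failure is
    consequential downstream.
    """
    config = config or ref.config
    rng = _rng(config, 1)
    n_s, n_l = config.n_samples, config.n_loci

    freqs = rng.uniform(*config.insertion_allele_freq_range, size=n_l)
    # haplotype-level insertion indicators: HW by construction
    hap_ins = rng.random(size=(n_s, 2, n_l)) < freqs[None, None, :]

    snp_haps: list[np.ndarray] = []
    for l in range(n_l):
        f = ref.snp_freq[l]
        snp_haps.append((rng.random(size=(n_s, 2, len(f))) < f[None, None, :]).astype(np.int8))

    for locus, sample in config.primer_snp_failures:
        which = int(rng.integers(0, 2))
        hap_ins[sample, :, locus] = False
        hap_ins[sample, which, locus] = True

    genotypes = hap_ins.sum(axis=1).astype(np.int8)  # (n_s, n_l)
    insertion_hap = np.zeros((n_s, n_l), dtype=np.int8)
    het = genotypes == 1
    # for hets: 1-based index of the carrying haplotype
    insertion_hap[het] = np.argmax(hap_ins, axis=1).astype(np.int8)[het] + 1

    trunc = np.zeros(n_l, dtype=np.int64)
    for locus, tlen in config.short_insertion_loci:
        trunc[locus] = tlen

    return CohortTruth(
        sample_ids=[f"S{i:03d}" for i in range(n_s)],
        locus_ids=[loc.locus_id for loc in ref.panel.loci],
        genotypes=genotypes,
        insertion_hap=insertion_hap,
        snp_haps=snp_haps,
        allele_freqs=freqs,
        trunc_len=trunc,
        seed=config.seed,
    )


def _hap_has_insertion(truth: CohortTruth, s: int, l: int, hap: int) -> bool:
    g = int(truth.genotypes[s, l])
    if g == 2:
        return True
    if g == 0:
        return False
    return int(truth.insertion_hap[s, l]) == hap


def carried_haps(
    truth: CohortTruth,
    config: SimConfig,
    s: int,
    l: int,
    reaction: str,
    apply_failures: bool = True,
) -> list[int]:
    """Haplotypes (1/2) of sample ``s`` that yield a product for ``reaction`` at locus ``l``.

    With ``apply_failures=False`` the primer-overlap failure mode is
    ignored, giving the biological truth used for concordance scoring.
    """
    trunc = int(truth.trunc_len[l])
    failed = apply_failures and (l, s) in set(config.primer_snp_failures)
    haps: list[int] = []
    for hap in (1, 2):
        ins = _hap_has_insertion(truth, s, l, hap)
        if reaction == "E":
            if not ins:
                if not failed:
                    haps.append(hap)
            elif trunc:  # short insertion: E reads through
                haps.append(hap)
        elif reaction == "G":
            if ins and (trunc == 0 or trunc >= TE_TAIL_LEN):
                haps.append(hap)
        else:
            raise ValueError(f"reaction must be 'E' or 'G', got {reaction!r}")
    return haps


def expected_reaction_states(truth: CohortTruth, config: SimConfig) -> dict[str, np.ndarray]:
    """Biological truth of per-reaction product presence, (n_samples, n_loci) booleans."""
    out = {}
    for reaction in ("E", "G"):
        mat = np.zeros((config.n_samples, config.n_loci), dtype=bool)
        for s in range(config.n_samples):
            for l in range(config.n_loci):
                mat[s, l] = bool(
                    carried_haps(truth, config, s, l, reaction, apply_failures=False)
                )
        out[reaction] = mat
    return out


def simulate_counts(ref: SimulatedReference, truth: CohortTruth, config: SimConfig | None = None):
    """Draw per (sample, locus, reaction) read-pair counts.

    Present amplicons: ``round(10**N(mu_lr, sd))`` with ``mu_lr`` drawn
    uniformly per amplicon from ``present_log10_mean_range``.  Absent
    amplicons: Poisson cross-contamination; emitted reads are zero when no
    other sample carries the amplicon (there is nothing to contaminate
    with).  Returns a pandas DataFrame; deterministic given the seed.
    """
    import pandas as pd

    config = config or ref.config
    rng = _rng(config, 2)
    n_s, n_l = config.n_samples, config.n_loci

    mu = rng.uniform(*config.present_log10_mean_range, size=(n_l, 2))
    normals = rng.normal(mu[None, :, :], config.present_log10_sd, size=(n_s, n_l, 2))
    poissons = rng.poisson(config.absent_count_lambda, size=(n_s, n_l, 2))

    rows = []
    for l in range(n_l):
        for r_i, reaction in enumerate(("E", "G")):
            carriers = [
                s
                for s in range(n_s)
                if carried_haps(truth, config, s, l, reaction)
            ]
            carrier_set = set(carriers)
            for s in range(n_s):
                if s in carrier_set:
                    drawn = int(round(10.0 ** normals[s, l, r_i]))
                    drawn = max(drawn, 1)
                    emitted = drawn
                    present = True
                else:
                    drawn = int(poissons[s, l, r_i])
                    donors = [d for d in carriers if d != s]
                    emitted = drawn if donors else 0
                    present = False
                rows.append(
                    {
                        "sample_id": truth.sample_ids[s],
                        "locus_id": truth.locus_ids[l],
                        "reaction": reaction,
                        "carried": present,
                        "count_drawn": drawn,
                        "count_emitted": emitted,
                    }
                )
    return pd.DataFrame(rows)


def _apply_snps(ref: SimulatedReference, truth: CohortTruth, seq: str, start: int, l: int, s: int, hap: int) -> str:
    """Substitute haplotype ``hap`` SNP alleles into ``seq`` (which begins at ref position ``start``)."""
    pos = ref.snp_positions[l]
    if len(pos) == 0:
        return seq
    chars = list(seq)
    alleles = truth.snp_haps[l][s, hap - 1]
    for k, p in enumerate(pos):
        off = int(p) - start
        if 0 <= off < len(chars) and alleles[k] == 1:
            chars[off] = ref.snp_alt[l][k]
    return "".join(chars)


def _template(
    ref: SimulatedReference,
    truth: CohortTruth,
    config: SimConfig,
    s: int,
    l: int,
    reaction: str,
    hap: int,
) -> tuple[str, str]:
    """Error-free (read1, read2) for one haplotype of one amplicon.

    Templates are written on the '+' strand from the 5' primer (E) or the
    TE-internal primer (G) to the end of the 3'-flank primer site; read 1
    is the reverse complement (it starts at the 3'-flank primer).
    """
    chrom = ref.reference["chr1"]
    g = ref.geometry[l]
    trunc = int(truth.trunc_len[l])
    ins = _hap_has_insertion(truth, s, l, hap)

    if reaction == "E":
        left = chrom[g.p5_start : g.junction]
        if (l, s, 1) in {(a, b, c) for a, b, c in config.tag_indel_samples}:
            # 1-bp deletion at the first base of the E tag window, both alleles
            cut = g.p5_end - g.p5_start
            left = left[:cut] + left[cut + 1 :]
        right = _apply_snps(
            ref, truth, chrom[g.junction : g.p3_site_end], g.junction, l, s, hap
        )
        if ins:
            if not trunc:
                raise ValueError("E template requested for a full-length insertion allele")
            insert = ref.te_consensus[-trunc:]
            template = left + insert + right
        else:
            template = left + right
    else:
        te_tail = ref.te_consensus[-TE_TAIL_LEN:]
        right = _apply_snps(
            ref, truth, chrom[g.junction : g.p3_site_end], g.junction, l, s, hap
        )
        template = te_tail + right

    read1 = revcomp(template)[: config.read1_len]
    read2 = template[: config.read2_len]
    return read1, read2


_CODE_LUT = np.zeros(256, dtype=np.uint8)
_CODE_LUT[_BASES] = np.arange(4)


def _emit_block(
    out1: list[str],
    out2: list[str],
    read1: str,
    read2: str,
    n: int,
    rng: np.random.Generator,
    per_base_error: float,
) -> None:
    """Append ``n`` error-bearing copies of a read pair to the output buffers."""
    if n <= 0:
        return
    for read, out in ((read1, out1), (read2, out2)):
        L = len(read)
        total = n * L
        n_err = rng.binomial(total, per_base_error) if per_base_error > 0 else 0
        if n_err == 0:
            out.extend([read] * n)
            continue
        arr = np.tile(np.frombuffer(read.encode(), dtype=np.uint8), (n, 1))
        idx = rng.integers(0, total, size=n_err)
        flat = arr.reshape(-1)
        shifted = (_CODE_LUT[flat[idx]] + rng.integers(1, 4, size=n_err)) % 4
        flat[idx] = _BASES[shifted]
        data = arr.tobytes().decode()
        out.extend(data[i * L : (i + 1) * L] for i in range(n))


def _write_fastq(path: Path, names: list[str], seqs: list[str]) -> None:
    with open(path, "w") as fh:
        parts = []
        for name, seq in zip(names, seqs):
            parts.append(f"@{name}\n{seq}\n+\n{_QUAL_CHAR * len(seq)}\n")
            if len(parts) >= 20000:
                fh.write("".join(parts))
                parts = []
        fh.write("".join(parts))


def simulate_reads(
    ref: SimulatedReference,
    truth: CohortTruth,
    outdir: str | Path,
    config: SimConfig | None = None,
):
    """Write per-sample paired FASTQ files plus the truth count table.

    Read names encode ``sample:locus:reaction:source:index`` purely as a
    debugging channel — the pipeline never reads them.  Returns the counts
    DataFrame (same draws as :func:`simulate_counts`).
    """
    config = config or ref.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = simulate_counts(ref, truth, config)
    rng = _rng(config, 3)
    n_s, n_l = config.n_samples, config.n_loci

    emitted = {
        (r.sample_id, r.locus_id, r.reaction): (r.carried, r.count_emitted)
        for r in counts.itertuples()
    }

    fastq_paths: list[tuple[str, Path, Path]] = []
    for s in range(n_s):
        sid = truth.sample_ids[s]
        names: list[str] = []
        seqs1: list[str] = []
        seqs2: list[str] = []
        for l in range(n_l):
            lid = truth.locus_ids[l]
            for reaction in ("E", "G"):
                carried, n_reads = emitted[(sid, lid, reaction)]
                if n_reads <= 0:
                    continue
                if carried:
                    haps = carried_haps(truth, config, s, l, reaction)
                    if len(haps) == 2:
                        n_first = int(rng.binomial(n_reads, 0.5))
                        split = [(haps[0], n_first), (haps[1], n_reads - n_first)]
                    else:
                        split = [(haps[0], n_reads)]
                    for hap, n in split:
                        if n <= 0:
                            continue
                        r1, r2 = _template(ref, truth, config, s, l, reaction, hap)
                        start = len(names)
                        names.extend(
                            f"{sid}:{lid}:{reaction}:h{hap}:{start + i}" for i in range(n)
                        )
                        _emit_block(seqs1, seqs2, r1, r2, n, rng, config.per_base_error)
                else:
                    # cross-contamination: templates from other carrying samples
                    donors = [
                        d
                        for d in range(n_s)
                        if d != s and carried_haps(truth, config, d, l, reaction)
                    ]
                    for i in range(n_reads):
                        d = int(donors[rng.integers(0, len(donors))])
                        d_haps = carried_haps(truth, config, d, l, reaction)
                        hap = int(d_haps[rng.integers(0, len(d_haps))])
                        r1, r2 = _template(ref, truth, config, d, l, reaction, hap)
                        names.append(f"{sid}:{lid}:{reaction}:c{truth.sample_ids[d]}:{i}")
                        _emit_block(seqs1, seqs2, r1, r2, 1, rng, config.per_base_error)
        p1 = outdir / f"{sid}_R1.fastq"
        p2 = outdir / f"{sid}_R2.fastq"
        _write_fastq(p1, names, seqs1)
        _write_fastq(p2, names, seqs2)
        fastq_paths.append((sid, p1, p2))

    counts.to_csv(outdir / "truth_counts.tsv", sep="\t", index=False)
    return counts, fastq_paths


def write_reference_fasta(ref: SimulatedReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in ref.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_snp_vcf(ref: SimulatedReference, truth: CohortTruth, path: str | Path) -> None:
    """Write the known flank SNPs with phased per-sample diploid genotypes.

    Plays the role of the external population SNP resource used for
    phasing.  Plain VCF 4.2 text via pysam.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##source=retrocall-simulate')
    header.contigs.add("chr1", length=len(ref.reference["chr1"]))
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sid in truth.sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for l, lid in enumerate(truth.locus_ids):
            for k, pos in enumerate(ref.snp_positions[l]):
                rec = vcf.new_record(
                    contig="chr1",
                    start=int(pos),
                    stop=int(pos) + 1,
                    alleles=(ref.snp_ref[l][k], ref.snp_alt[l][k]),
                    id=f"sim_{lid}_snp{k}",
                )
                for s, sid in enumerate(truth.sample_ids):
                    a1, a2 = truth.snp_haps[l][s, :, k]
                    rec.samples[sid]["GT"] = (int(a1), int(a2))
                    rec.samples[sid].phased = True
                vcf.write(rec)


def write_truth_tables(truth: CohortTruth, outdir: str | Path) -> None:
    """Write genotype and phase truth TSVs (the gel-electrophoresis stand-in)."""
    outdir = Path(outdir)
    with open(outdir / "truth_genotypes.tsv", "w") as fh:
        fh.write("sample_id\tlocus_id\tgenotype\tinsertion_allele\n")
        for s, sid in enumerate(truth.sample_ids):
            for l, lid in enumerate(truth.locus_ids):
                hap = int(truth.insertion_hap[s, l])
                fh.write(
                    f"{sid}\t{lid}\t{truth.genotype_str(s, l)}\t{hap if hap else '.'}\n"
                )
    with open(outdir / "truth_phase.tsv", "w") as fh:
        fh.write("sample_id\tlocus_id\tinsertion_allele\n")
        for s, sid in enumerate(truth.sample_ids):
            for l, lid in enumerate(truth.locus_ids):
                if truth.genotypes[s, l] == 1:
                    fh.write(f"{sid}\t{lid}\t{int(truth.insertion_hap[s, l])}\n")


def simulate_dataset(config: SimConfig, outdir: str | Path):
    """Generate a complete experiment directory.

    Writes ``reference.fa``, ``panel.tsv`` (+ te-primers companion),
    ``snps.vcf``, ``samples.tsv``, per-sample FASTQ pairs and the truth
    tables.  Returns ``(ref, truth, counts)``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = simulate_reference_and_panel(config)
    truth = simulate_cohort(ref, config)
    write_reference_fasta(ref, outdir / "reference.fa")
    write_panel(ref.panel, outdir / "panel.tsv")
    write_snp_vcf(ref, truth, outdir / "snps.vcf")
    write_truth_tables(truth, outdir)
    counts, fastq_paths = simulate_reads(ref, truth, outdir, config)
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("sample_id\tfastq1\tfastq2\n")
        for sid, p1, p2 in fastq_paths:
            fh.write(f"{sid}\t{p1.name}\t{p2.name}\n")
    with open(outdir / "sim_config.json", "w") as fh:
        import json

        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    return ref, truth, counts
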