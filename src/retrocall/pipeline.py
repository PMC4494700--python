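"""End-to-end orchestration: sort -> map -> fit -> QC -> override -> combine -> write.

The pipeline is a pure function of its inputs and config: fixed inputs
produce byte-identical outputs (the EM initialization is deterministic and
no stage holds random state).  Memory stays bounded by processing one
sample at a time: reads are sorted, tags classified and SNP pileups taken
per sample, after which the raw reads are dropped.
"""

from __future__ import annotations

import hashlib
import json
import time
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .genotype import (
    AllelicGenotype,
    apply_post_hoc_rules,
    apply_short_insertion_override,
    combine_calls,
    fit_clusters,
    label_and_call,
    log_transform,
    qc_amplicon,
    write_genotypes,
)
from .panel import Panel, read_panel
from .phase import collect_flank_snps, load_snp_vcf, phase_cohort, pileup_read1
from .sorting import sort_sample
from .tagmap import (
    AmpliconCountRecord,
    CountMatrix,
    build_reference_index,
    matrices_from_records,
    tabulate_counts,
    write_count_tables,
)


class InputError(ValueError):
    """Missing or inconsistent pipeline inputs."""


@dataclass
class SampleSheetEntry:
    sample_id: str
    fastq1: Path
    fastq2: Path


def read_sample_sheet(path: str | Path, fastq_dir: str | Path | None = None) -> list[SampleSheetEntry]:
    """Read the sample sheet TSV (sample_id, fastq1, fastq2); paths resolved against fastq_dir."""
    path = Path(path)
    base = Path(fastq_dir) if fastq_dir else path.parent
    entries = []
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t")[:3] != ["sample_id", "fastq1", "fastq2"]:
        raise InputError(f"{path}: expected header 'sample_id\\tfastq1\\tfastq2'")
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        sid, f1, f2 = line.split("\t")[:3]
        entries.append(SampleSheetEntry(sid, base / f1, base / f2))
    seen = set()
    for e in entries:
        if e.sample_id in seen:
            raise InputError(f"duplicate sample_id {e.sample_id!r} in sample sheet")
        seen.add(e.sample_id)
        for fq in (e.fastq1, e.fastq2):
            if not fq.exists():
                raise InputError(f"missing FASTQ for sample {e.sample_id!r}: {fq}")
    return entries


@dataclass
class PipelineResult:
    panel: Panel
    config: PipelineConfig
    sample_ids: list[str]
    matrices: dict[str, CountMatrix]
    records: list[AmpliconCountRecord]
    fits: dict
    callsets: dict          # (locus_id, reaction) -> ReactionCallSet
    qc: dict                # (locus_id, reaction) -> AmpliconQCResult
    combined: list[AllelicGenotype]
    pileups: dict           # (sample_id, locus_id, reaction) -> [Counter per flank SNP]
    snp_records: dict | None
    sort_stats: pd.DataFrame

    def reaction_calls_frame(self) -> pd.DataFrame:
        rows = []
        for (lid, rxn), cs in sorted(self.callsets.items()):
            qc = self.qc[(lid, rxn)]
            for i, sid in enumerate(cs.sample_ids):
                rows.append(
                    {
                        "sample_id": sid,
                        "locus_id": lid,
                        "reaction": rxn,
                        "call": cs.calls[i],
                        "quality": round(float(cs.quality[i]), 4),
                        "low_quality": int(bool(cs.low_quality[i])),
                        "override": int(bool(cs.override[i])),
                        "fit_status": cs.fit_status,
                        "qc_pass": int(qc.passed),
                        "qc_reasons": ",".join(qc.reasons) or ".",
                    }
                )
        return pd.DataFrame(rows)

    def cluster_fits_frame(self) -> pd.DataFrame:
        rows = []
        for (lid, rxn), fit in sorted(self.fits.items()):
            for k in range(fit.n_components):
                rows.append(
                    {
                        "locus_id": lid,
                        "reaction": rxn,
                        "component": k,
                        "mean": round(float(fit.means[k]), 4),
                        "sd": round(float(fit.sds[k]), 4),
                        "weight": round(float(fit.weights[k]), 4),
                        "n_components": fit.n_components,
                        "fit_status": fit.fit_status,
                        "converged": int(fit.converged),
                        "n_iter": fit.n_iter,
                    }
                )
        return pd.DataFrame(rows)


def run_pipeline(
    panel: Panel,
    reference,
    samples: list[SampleSheetEntry],
    config: PipelineConfig | None = None,
    snp_records: dict | None = None,
) -> PipelineResult:
    """Run the full genotyping pipeline in memory.

    ``reference`` is dict-like (chrom -> sequence; pyfaidx.Fasta works).
    When ``snp_records`` (from :func:`retrocall.phase.load_snp_vcf`) is
    given, per-SNP pileups are taken during the per-sample pass so phasing
    needs no second pass over the reads.
    """
    config = config or PipelineConfig()
    panel.validate_tag_lengths(config.tag_length)
    index = build_reference_index(reference, config)

    flank_snps = {}
    if snp_records is not None:
        for loc in panel.loci:
            flank_snps[loc.locus_id] = collect_flank_snps(loc, snp_records)

    sample_ids = [s.sample_id for s in samples]
    records: list[AmpliconCountRecord] = []
    pileups: dict = {}
    stats_rows = []
    for entry in samples:
        result = sort_sample(
            entry.sample_id,
            entry.fastq1,
            entry.fastq2,
            panel,
            config,
            keep_read1=snp_records is not None,
        )
        if snp_records is not None:
            for loc in panel.loci:
                snps = flank_snps[loc.locus_id]
                if not snps:
                    continue
                anchor_end = loc.g_tag_target.end + len(loc.primer_3flank)
                positions = [s.pos0 for s in snps]
                for rxn in ("E", "G"):
                    bucket = result.amplicons[(loc.locus_id, rxn)]
                    pileups[(entry.sample_id, loc.locus_id, rxn)] = pileup_read1(
                        bucket.read1s, anchor_end, positions
                    )
        for bucket in result.amplicons.values():
            bucket.read1s = []
        _, sample_records = tabulate_counts([result], panel, index, config)
        records.extend(sample_records)
        stats_rows.append(
            {
                "sample_id": entry.sample_id,
                "n_total": result.n_total,
                "n_assigned": result.n_assigned,
                "n_unassigned": result.n_unassigned,
            }
        )
        del result

    locus_ids = [loc.locus_id for loc in panel.loci]
    matrices = matrices_from_records(records, locus_ids, sample_ids)
    rec_by_amp: dict = {}
    for r in records:
        rec_by_amp.setdefault((r.locus_id, r.reaction), []).append(r)

    fits: dict = {}
    callsets: dict = {}
    qc: dict = {}
    combined: list[AllelicGenotype] = []
    for loc in panel.loci:
        lid = loc.locus_id
        for rxn in ("E", "G"):
            counts_vec = matrices[rxn].n_specific.loc[lid].to_numpy()
            fit = fit_clusters(log_transform(counts_vec), config, lid, rxn)
            fit = apply_post_hoc_rules(fit, counts_vec, config)
            callset = label_and_call(fit, config, sample_ids)
            amp_qc = qc_amplicon(fit, rec_by_amp.get((lid, rxn), []), config)
            if rxn == "E" and amp_qc.passed:
                motif_row = matrices["E"].motif_fraction.loc[lid].to_numpy()
                callset = apply_short_insertion_override(callset, motif_row, config)
            fits[(lid, rxn)] = fit
            callsets[(lid, rxn)] = callset
            qc[(lid, rxn)] = amp_qc
        if qc[(lid, "E")].passed and qc[(lid, "G")].passed:
            combined.extend(
                combine_calls(
                    callsets[(lid, "E")], callsets[(lid, "G")], qc[(lid, "E")], qc[(lid, "G")]
                )
            )

    return PipelineResult(
        panel=panel,
        config=config,
        sample_ids=sample_ids,
        matrices=matrices,
        records=records,
        fits=fits,
        callsets=callsets,
        qc=qc,
        combined=combined,
        pileups=pileups,
        snp_records=snp_records,
        sort_stats=pd.DataFrame(stats_rows),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(
    outdir: Path,
    config: PipelineConfig,
    inputs: dict[str, Path],
    timings: dict[str, float],
    seed: int | None = None,
) -> None:
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": seed,
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in inputs.items()},
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_genotyping(
    panel_path: str | Path,
    reference_path: str | Path,
    sample_sheet: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    fastq_dir: str | Path | None = None,
    snp_vcf: str | Path | None = None,
) -> PipelineResult:
    """File-level wrapper: read inputs, run the pipeline, write all outputs."""
    import pyfaidx

    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    panel = read_panel(panel_path)
    reference = pyfaidx.Fasta(str(reference_path))
    samples = read_sample_sheet(sample_sheet, fastq_dir)
    snp_records = None
    if snp_vcf is not None:
        snp_records, _vcf_samples = load_snp_vcf(snp_vcf)
    t_load = time.perf_counter()

    result = run_pipeline(panel, reference, samples, config, snp_records)
    t_run = time.perf_counter()

    write_count_tables(result.matrices, result.records, outdir)
    result.reaction_calls_frame().to_csv(outdir / "reaction_calls.tsv", sep="\t", index=False)
    result.cluster_fits_frame().to_csv(outdir / "cluster_fits.tsv", sep="\t", index=False)
    qc_rows = [
        {
            "locus_id": lid,
            "reaction": rxn,
            "qc_pass": int(q.passed),
            "reasons": ",".join(q.reasons) or ".",
        }
        for (lid, rxn), q in sorted(result.qc.items())
    ]
    pd.DataFrame(qc_rows).to_csv(outdir / "locus_qc.tsv", sep="\t", index=False)
    result.sort_stats.to_csv(outdir / "sort_stats.tsv", sep="\t", index=False)
    counts_lookup = {
        (r.sample_id, r.locus_id, r.reaction): r.n_specific for r in result.records
    }
    write_genotypes(result.combined, panel, result.sample_ids, counts_lookup, outdir)
    if result.pileups:
        _write_pileups(result, outdir / "snp_pileups.tsv")
    t_write = time.perf_counter()

    inputs = {
        "panel": Path(panel_path),
        "reference": Path(reference_path),
        "sample_sheet": Path(sample_sheet),
    }
    if snp_vcf is not None:
        inputs["snp_vcf"] = Path(snp_vcf)
    write_run_manifest(
        outdir,
        config,
        inputs,
        {"load": t_load - t0, "pipeline": t_run - t_load, "write": t_write - t_run},
    )
    return result


def _write_pileups(result: PipelineResult, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlocus_id\treaction\tsnp_index\tbase\tcount\n")
        for (sid, lid, rxn), counters in sorted(result.pileups.items()):
            for k, counter in enumerate(counters):
                for base, n in sorted(counter.items()):
                    fh.write(f"{sid}\t{lid}\t{rxn}\t{k}\t{base}\t{n}\n")


def load_pileups(path: str | Path) -> dict:
    """Inverse of the pileup writer: (sample, locus, reaction) -> [Counter per SNP]."""
    pileups: dict = {}
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples():
        key = (row.sample_id, row.locus_id, row.reaction)
        counters = pileups.setdefault(key, [])
        while len(counters) <= row.snp_index:
            counters.append(Counter())
        counters[row.snp_index][row.base] += int(row.count)
    return pileups


def run_phasing(
    result: PipelineResult,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Phase all heterozygous combined calls of a pipeline run."""
    if result.snp_records is None:
        raise InputError("pipeline was run without a SNP VCF; nothing to phase")
    config = config or result.config
    genotypes = {(c.sample_id, c.locus_id): c.genotype for c in result.combined}
    return phase_cohort(genotypes, result.pileups, result.panel, result.snp_records, config)
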