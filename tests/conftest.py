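"""Shared fixtures: simulated datasets at several scales.

The heavyweight cohorts (paper-scale read counts, ~10^4 pairs per present
amplicon) are session-scoped and shared between the acceptance twins and
the property tests that must run on the clean default simulation.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from retrocall.config import PipelineConfig
from retrocall.pipeline import run_genotyping, run_phasing
from retrocall.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def clean12(tmp_path_factory):
    """Clean default cohort, 25 loci x 12 samples, seed 1, full pipeline + phasing."""
    simdir = tmp_path_factory.mktemp("clean12_sim")
    rundir = tmp_path_factory.mktemp("clean12_run")
    cfg = SimConfig(n_samples=12, n_loci=25, seed=1)
    ref, truth, counts = simulate_dataset(cfg, simdir)
    result = run_genotyping(
        simdir / "panel.tsv",
        simdir / "reference.fa",
        simdir / "samples.tsv",
        rundir,
        snp_vcf=simdir / "snps.vcf",
    )
    phase_table = run_phasing(result)
    return {
        "sim_config": cfg,
        "ref": ref,
        "truth": truth,
        "counts": counts,
        "result": result,
        "phase_table": phase_table,
        "simdir": Path(simdir),
        "rundir": Path(rundir),
    }


@pytest.fixture(scope="session")
def validation24(tmp_path_factory):
    """Validation-style cohort, 18 loci x 24 samples, one primer-overlap failure."""
    simdir = tmp_path_factory.mktemp("val24_sim")
    rundir = tmp_path_factory.mktemp("val24_run")
    cfg = SimConfig(n_samples=24, n_loci=18, seed=1, primer_snp_failures=[(0, 0)])
    ref, truth, counts = simulate_dataset(cfg, simdir)
    result = run_genotyping(
        simdir / "panel.tsv", simdir / "reference.fa", simdir / "samples.tsv", rundir
    )
    return {"sim_config": cfg, "ref": ref, "truth": truth, "result": result}


@pytest.fixture(scope="session")
def small_default(tmp_path_factory):
    """Small cohort (5 loci x 6 samples) at default read-count scale, with phasing."""
    simdir = tmp_path_factory.mktemp("small_sim")
    rundir = tmp_path_factory.mktemp("small_run")
    cfg = SimConfig(n_samples=6, n_loci=5, seed=7)
    ref, truth, counts = simulate_dataset(cfg, simdir)
    result = run_genotyping(
        simdir / "panel.tsv",
        simdir / "reference.fa",
        simdir / "samples.tsv",
        rundir,
        snp_vcf=simdir / "snps.vcf",
    )
    return {
        "sim_config": cfg,
        "ref": ref,
        "truth": truth,
        "counts": counts,
        "result": result,
        "simdir": Path(simdir),
        "rundir": Path(rundir),
    }


@pytest.fixture(scope="session")
def tiny_sim(tmp_path_factory):
    """4x4 cohort at reduced count scale: cheap I/O-level fixture (no pipeline run)."""
    simdir = tmp_path_factory.mktemp("tiny_sim")
    cfg = SimConfig(
        n_samples=4, n_loci=4, seed=3, present_log10_mean_range=(2.0, 2.4)
    )
    ref, truth, counts = simulate_dataset(cfg, simdir)
    return {
        "sim_config": cfg,
        "ref": ref,
        "truth": truth,
        "counts": counts,
        "simdir": Path(simdir),
    }


@pytest.fixture()
def config():
    return PipelineConfig()
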