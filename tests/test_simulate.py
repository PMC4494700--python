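"""Synthetic-data generator: determinism, truth consistency, count structure."""

import numpy as np
import pytest

from retrocall.config import ConfigError
from retrocall.seq import revcomp
from retrocall.simulate import (
    SimConfig,
    carried_haps,
    simulate_cohort,
    simulate_counts,
    simulate_dataset,
    simulate_reference_and_panel,
)
from retrocall.sorting import detect_te_motif


class TestSimConfigValidation:
    def test_reversed_range_rejected(self):
        with pytest.raises(ConfigError, match="well-ordered"):
            SimConfig(n_samples=2, n_loci=2, insertion_allele_freq_range=(0.9, 0.1))

    def test_out_of_bounds_locus_index_rejected(self):
        with pytest.raises(ConfigError, match="out of range"):
            SimConfig(n_samples=2, n_loci=2, multimap_loci=[5])

    def test_out_of_bounds_sample_index_rejected(self):
        with pytest.raises(ConfigError, match="out of range"):
            SimConfig(n_samples=2, n_loci=2, primer_snp_failures=[(0, 7)])

    def test_truncation_length_bounds(self):
        with pytest.raises(ConfigError, match="truncated"):
            SimConfig(n_samples=2, n_loci=2, short_insertion_loci=[(0, 250)])


class TestReferenceAndPanel:
    def test_panel_geometry(self):
        cfg = SimConfig(n_samples=2, n_loci=10, seed=7)
        ref = simulate_reference_and_panel(cfg)
        assert len(ref.panel) == 10
        for loc in ref.panel.loci:
            assert len(loc.e_tag_target) == 50
            assert len(loc.g_tag_target) == 50
        # tag targets carry the primer-adjacent reference sequence
        g = ref.geometry[0]
        chrom = ref.reference["chr1"]
        loc = ref.panel.loci[0]
        assert loc.primer_5flank == chrom[g.p5_start : g.p5_end]
        assert loc.primer_3flank == revcomp(chrom[g.p3_site_start : g.p3_site_end])

    def test_exact_snp_count_when_range_degenerate(self):
        cfg = SimConfig(n_samples=2, n_loci=6, seed=5, flank_snps_per_locus=(5, 5))
        ref = simulate_reference_and_panel(cfg)
        assert all(len(p) == 5 for p in ref.snp_positions)

    def test_snps_lie_in_flank_outside_g_tag(self):
        cfg = SimConfig(n_samples=2, n_loci=6, seed=5)
        ref = simulate_reference_and_panel(cfg)
        for loc, g, pos in zip(ref.panel.loci, ref.geometry, ref.snp_positions):
            lo, hi = loc.flank_interval
            assert all(lo <= p < hi for p in pos)
            assert all(not (loc.g_tag_target.start <= p < loc.g_tag_target.end) for p in pos)

    def test_multimap_duplicates_e_tag(self):
        cfg = SimConfig(n_samples=2, n_loci=3, seed=5, multimap_loci=[1])
        ref = simulate_reference_and_panel(cfg)
        loc = ref.panel.loci[1]
        seq = ref.reference["chr1"]
        tag = seq[loc.e_tag_target.start : loc.e_tag_target.end]
        assert seq.count(tag) == 2


class TestCohort:
    @pytest.mark.parametrize("freq,expect", [(0.0, 0), (1.0, 2)])
    def test_boundary_allele_frequencies(self, freq, expect):
        cfg = SimConfig(
            n_samples=20, n_loci=3, seed=2, insertion_allele_freq_range=(freq, freq)
        )
        truth = simulate_cohort(simulate_reference_and_panel(cfg), cfg)
        assert np.all(truth.genotypes == expect)

    def test_het_fraction_matches_binomial_oracle(self):
        # At p=0.5 the het fraction is Binomial(n, 1/2)/n per locus:
        # across 1000 samples it must fall within 3 standard errors of 0.5.
        cfg = SimConfig(
            n_samples=1000, n_loci=1, seed=11, insertion_allele_freq_range=(0.5, 0.5)
        )
        truth = simulate_cohort(simulate_reference_and_panel(cfg), cfg)
        het = float(np.mean(truth.genotypes == 1))
        se = np.sqrt(0.25 / 1000)
        assert abs(het - 0.5) < 3 * se

    def test_phase_defined_iff_heterozygous(self):
        cfg = SimConfig(n_samples=50, n_loci=4, seed=9)
        truth = simulate_cohort(simulate_reference_and_panel(cfg), cfg)
        het = truth.genotypes == 1
        assert np.all(truth.insertion_hap[het] > 0)
        assert np.all(truth.insertion_hap[~het] == 0)


class TestCounts:
    def test_separation_exceeds_two_log_units(self):
        # Aggregate separation property at default parameters over >= 20 loci.
        cfg = SimConfig(n_samples=12, n_loci=25, seed=13)
        ref = simulate_reference_and_panel(cfg)
        truth = simulate_cohort(ref, cfg)
        counts = simulate_counts(ref, truth, cfg)
        checked = 0
        for (lid, rxn), grp in counts.groupby(["locus_id", "reaction"]):
            present = grp[grp.carried]["count_drawn"].to_numpy(float)
            absent = grp[~grp.carried]["count_drawn"].to_numpy(float)
            if len(present) == 0 or len(absent) == 0:
                continue
            sep = np.mean(np.log10(np.maximum(present, 1))) - np.mean(
                np.log10(np.maximum(absent, 1))
            )
            assert sep > 2.0, (lid, rxn, sep)
            checked += 1
        assert checked >= 20

    def test_counts_deterministic_given_seed(self):
        cfg = SimConfig(n_samples=5, n_loci=4, seed=21)
        ref = simulate_reference_and_panel(cfg)
        truth = simulate_cohort(ref, cfg)
        c1 = simulate_counts(ref, truth, cfg)
        c2 = simulate_counts(ref, truth, cfg)
        assert c1.equals(c2)


class TestReads:
    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = SimConfig(
            n_samples=3, n_loci=3, seed=17, present_log10_mean_range=(2.0, 2.4)
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(cfg, d1)
        simulate_dataset(cfg, d2)
        for p1 in sorted(d1.iterdir()):
            p2 = d2 / p1.name
            assert p2.exists()
            assert p1.read_bytes() == p2.read_bytes(), p1.name

    def test_fastq_headers_reproduce_drawn_counts(self, tiny_sim):
        # The debugging channel in read names must agree with the truth table.
        from collections import Counter

        tallies = Counter()
        for fq in tiny_sim["simdir"].glob("*_R1.fastq"):
            with open(fq) as fh:
                for i, line in enumerate(fh):
                    if i % 4 == 0:
                        sid, lid, rxn, _src, _n = line[1:].strip().split(":")
                        tallies[(sid, lid, rxn)] += 1
        for row in tiny_sim["counts"].itertuples():
            assert tallies.get((row.sample_id, row.locus_id, row.reaction), 0) == row.count_emitted

    def test_noise_free_reads_are_exact_template_slices(self, tmp_path):
        cfg = SimConfig(
            n_samples=2,
            n_loci=2,
            seed=23,
            per_base_error=0.0,
            absent_count_lambda=0.0,
            present_log10_mean_range=(1.5, 1.8),
        )
        ref, truth, counts = simulate_dataset(cfg, tmp_path)
        chrom = ref.reference["chr1"]
        g = ref.geometry
        for fq in sorted(tmp_path.glob("*_R2.fastq")):
            lines = fq.read_text().splitlines()
            for name, seq in zip(lines[0::4], lines[1::4]):
                sid, lid, rxn, src, _ = name[1:].split(":")
                l = int(lid[1:])
                loc = ref.panel.loci[l]
                if rxn == "E":
                    assert seq.startswith(loc.primer_5flank)
                    # noise-free E read 2 = 5' primer + tag, verbatim reference
                    start = g[l].p5_start
                    assert seq == chrom[start : start + cfg.read2_len]
                else:
                    assert seq.startswith(ref.panel.te_primers["L1Hs"])

    def test_short_insertion_reads_carry_reverse_complement_motif(self, tmp_path):
        cfg = SimConfig(
            n_samples=4,
            n_loci=2,
            seed=29,
            short_insertion_loci=[(1, 150)],
            insertion_allele_freq_range=(1.0, 1.0),
            present_log10_mean_range=(1.7, 1.9),
        )
        ref, truth, counts = simulate_dataset(cfg, tmp_path)
        motif = ref.panel.te_motifs["L1Hs"]
        n_pos = n_tot = 0
        for fq in tmp_path.glob("*_R1.fastq"):
            lines = fq.read_text().splitlines()
            for name, seq in zip(lines[0::4], lines[1::4]):
                _sid, lid, rxn, _src, _n = name[1:].split(":")
                if lid == "L001" and rxn == "E":
                    n_tot += 1
                    n_pos += detect_te_motif(seq, motif, 6)
        assert n_tot > 0
        assert n_pos / n_tot > 0.8

    def test_primer_failure_cell_emits_no_real_e_pairs(self, tmp_path):
        cfg = SimConfig(
            n_samples=4,
            n_loci=2,
            seed=31,
            primer_snp_failures=[(0, 1)],
            present_log10_mean_range=(1.7, 1.9),
        )
        ref, truth, counts = simulate_dataset(cfg, tmp_path)
        # forced heterozygote at the failure cell
        assert truth.genotypes[1, 0] == 1
        assert carried_haps(truth, cfg, 1, 0, "E") == []
        assert carried_haps(truth, cfg, 1, 0, "E", apply_failures=False) != []
        cell = counts[
            (counts.sample_id == "S001")
            & (counts.locus_id == "L000")
            & (counts.reaction == "E")
        ].iloc[0]
        assert not cell.carried
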