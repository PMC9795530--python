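"""Gamete-pool simulator: genome, reads, error model and evaluation."""

import re
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import pytest

from gametecross import simulator as sim
from gametecross.hpc import compress_sequence


BASE_CFG = sim.SimConfig(genome_length=200_000, depth=5.0, seed=13)


class TestSimulateGenome:
    def test_snv_count_near_poisson_expectation(self):
        cfg = replace(BASE_CFG, genome_length=1_000_000, snv_spacing=100.0)
        g = sim.simulate_genome(cfg, np.random.default_rng(1))
        n = len(g.site_positions["chr1"])
        lam = 1_000_000 / 100.0
        assert abs(n - lam) < 3 * np.sqrt(lam) + 0.02 * lam

    def test_deterministic_given_seed(self, tmp_path):
        outs = []
        for d in ("a", "b"):
            g = sim.simulate_genome(BASE_CFG, np.random.default_rng(BASE_CFG.seed))
            ref = tmp_path / d / "ref.fa"
            ref.parent.mkdir()
            g.write_reference(str(ref))
            vcf = tmp_path / d / "p.vcf"
            g.write_phased_vcf(str(vcf), rng=np.random.default_rng(3))
            outs.append((ref.read_bytes(), vcf.read_bytes()))
        assert outs[0] == outs[1]

    def test_vcf_all_heterozygous_and_phased(self, tmp_path):
        cfg = replace(BASE_CFG, decoy_variant_fraction=0.0)
        g = sim.simulate_genome(cfg, np.random.default_rng(2))
        vcf = tmp_path / "p.vcf"
        g.write_phased_vcf(str(vcf))
        n = 0
        for rec in pysam.VariantFile(str(vcf)):
            s = rec.samples[0]
            assert s.phased and sorted(s["GT"]) == [0, 1]
            assert len(rec.ref) == 1 and len(rec.alts[0]) == 1
            n += 1
        assert n == len(g.site_positions["chr1"])

    def test_haplotypes_share_compression_coordinates(self):
        g = sim.simulate_genome(BASE_CFG, np.random.default_rng(4))
        cs = g.compressed["chr1"]
        for hap in (g.hap_a_seq["chr1"], g.hap_b_seq["chr1"]):
            s = hap.tobytes().decode()
            # substituting alleles must not create adjacent duplicates
            assert compress_sequence(s).seq == s

    def test_reference_compression_matches_map(self):
        g = sim.simulate_genome(BASE_CFG, np.random.default_rng(5))
        cs = g.compressed["chr1"]
        assert cs.original_length == len(g.references["chr1"])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sim.SimConfig(snv_spacing=-1)
        with pytest.raises(ValueError):
            sim.SimConfig(sub_rate=1.5)
        with pytest.raises(ValueError):
            sim.SimConfig(genome_length=100, snv_spacing=200.0)


class TestSimulateReads:
    def _reads(self, tmp_path, cfg, name="r.bam"):
        g = sim.simulate_genome(cfg, np.random.default_rng(cfg.seed))
        bam = str(tmp_path / name)
        truth = sim.simulate_reads(
            cfg, g, bam, rng=np.random.default_rng(cfg.seed + 1)
        )
        return g, bam, truth

    def test_zero_recomb_fraction_has_no_breakpoints(self, tmp_path):
        cfg = replace(BASE_CFG, recomb_fraction=0.0)
        _, _, truth = self._reads(tmp_path, cfg)
        assert not truth["recombinant"].any()
        assert (truth["breakpoint_comp"] == -1).all()

    def test_noiseless_reads_substring_of_source_haplotype(self, tmp_path):
        cfg = replace(
            BASE_CFG, sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
            recomb_fraction=0.0, depth=2.0,
        )
        g, bam, truth = self._reads(tmp_path, cfg)
        haps = {"A": g.hap_a_seq["chr1"], "B": g.hap_b_seq["chr1"]}
        src = dict(zip(truth["read_id"], truth["source"]))
        n = 0
        for read in pysam.AlignmentFile(bam):
            tpl = haps[src[read.query_name]]
            expect = tpl[read.reference_start : read.reference_end].tobytes().decode()
            assert read.query_sequence == expect
            n += 1
        assert n > 0

    def test_truthful_cigars_consume_read_and_reference(self, tmp_path):
        g, bam, truth = self._reads(tmp_path, BASE_CFG)
        spans = dict(zip(truth["read_id"], zip(truth["comp_start"], truth["comp_end"])))
        for read in pysam.AlignmentFile(bam):
            stats = read.get_cigar_stats()[0]
            read_consumed = stats[0] + stats[1] + stats[4]  # M + I + S
            assert read_consumed == len(read.query_sequence)
            s, e = spans[read.query_name]
            assert s <= read.reference_start <= read.reference_end <= e

    def test_empirical_error_rate_matches_configuration(self, tmp_path):
        cfg = replace(
            BASE_CFG, genome_length=500_000, depth=8.0, recomb_fraction=0.0,
            ins_rate=0.0, del_rate=0.0, sub_rate=0.02,
            homopolymer_indel_mult=1.0, seed=3,
        )
        g, bam, truth = self._reads(tmp_path, cfg)
        haps = {"A": g.hap_a_seq["chr1"], "B": g.hap_b_seq["chr1"]}
        src = dict(zip(truth["read_id"], truth["source"]))
        mism = total = 0
        for read in pysam.AlignmentFile(bam):
            tpl = haps[src[read.query_name]][read.reference_start : read.reference_end]
            obs = np.frombuffer(read.query_sequence.encode(), dtype=np.uint8)
            mism += int((obs != tpl).sum())
            total += len(obs)
        p_hat = mism / total
        # substitutions hit one of three other bases, all counted as mismatch
        sigma = np.sqrt(0.02 * 0.98 / total)
        assert abs(p_hat - 0.02) < 4 * sigma + 1e-4

    def test_homopolymer_multiplier_raises_indel_rate_in_runs(self, tmp_path):
        cfg = replace(
            BASE_CFG, genome_length=400_000, depth=6.0, sub_rate=0.0,
            ins_rate=0.0, del_rate=0.02, homopolymer_indel_mult=3.0,
            recomb_fraction=0.0, seed=9,
        )
        g, bam, _ = self._reads(tmp_path, cfg)
        run_len = g.compressed["chr1"].run_lengths
        del_in_run = del_out_run = n_in = n_out = 0
        for read in pysam.AlignmentFile(bam):
            ref_pos = read.reference_start
            for op, ln in read.cigartuples:
                if op == 2:
                    for p in range(ref_pos, ref_pos + ln):
                        if run_len[p] > 1:
                            del_in_run += 1
                        else:
                            del_out_run += 1
                if op in (0, 2):
                    for p in range(ref_pos, ref_pos + ln):
                        if run_len[p] > 1:
                            n_in += 1
                        else:
                            n_out += 1
                    ref_pos += ln
        rate_in = del_in_run / n_in
        rate_out = del_out_run / n_out
        assert rate_in > 2.0 * rate_out  # configured x3, generous slack


class TestEvaluate:
    def _truth(self):
        rows = []
        for i in range(3):
            rows.append((f"rec{i}", "chr1", "AB", True, 100, 100, 0, 500, True))
        for i in range(7):
            rows.append((f"non{i}", "chr1", "A", False, -1, -1, 0, 500, True))
        return pd.DataFrame(
            rows,
            columns=[
                "read_id", "chrom", "source", "recombinant", "breakpoint_comp",
                "breakpoint_orig", "comp_start", "comp_end", "aligned",
            ],
        )

    def _calls(self, ids):
        return pd.DataFrame(
            {
                "read_id": ids,
                "chrom": "chr1",
                "orig_start": 90,
                "orig_end": 120,
            }
        )

    def test_hand_counted_fixture(self):
        # 2 TP, 1 FN, 1 FP among 3 recombinant / 7 non-recombinant
        m = sim.evaluate(self._calls(["rec0", "rec1", "non0"]), self._truth())
        assert m.accuracy == pytest.approx(2 / 3)
        assert m.error_rate == pytest.approx(1 / 7)
        assert m.mean_breakpoint_error == 0.0  # 100 lies in [90, 120)

    def test_perfect_and_degenerate_callers(self):
        truth = self._truth()
        perfect = sim.evaluate(self._calls(["rec0", "rec1", "rec2"]), truth)
        assert perfect.accuracy == 1.0 and perfect.error_rate == 0.0
        allcall = sim.evaluate(self._calls(list(truth["read_id"])), truth)
        assert allcall.accuracy == 1.0 and allcall.error_rate == 1.0

    def test_unknown_read_id_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            sim.evaluate(self._calls(["ghost"]), self._truth())

    def test_breakpoint_localisation_distance(self):
        calls = self._calls(["rec0"])
        calls.loc[:, ["orig_start", "orig_end"]] = [150, 200]
        m = sim.evaluate(calls, self._truth())
        assert m.mean_breakpoint_error == 50.0  # |150 - 100|


class TestGrid:
    def test_small_grid_runs_and_is_deterministic(self, tmp_path):
        base = replace(
            BASE_CFG, genome_length=150_000, read_length_mean=10_000.0,
            read_length_sd=2_000.0,
        )
        kwargs = dict(
            spacings=[100.0], depths=[5.0], reps=2, seed=5, base_config=base,
        )
        fig = tmp_path / "grid.png"
        r1 = sim.run_grid(**kwargs, figure_out=str(fig))
        assert fig.exists() and fig.stat().st_size > 0
        r2 = sim.run_grid(**kwargs)
        pd.testing.assert_frame_equal(r1, r2)
        assert len(r1) == 2
        assert r1["accuracy"].between(0, 1).all()
        summary = sim.summarize_grid(r1)
        assert len(summary) == 1 and "accuracy_se" in summary
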