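"""Haplotype scoring, sliding-window phasing and switch calling."""

import itertools

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from gametecross.crossover import (
    HAP_A,
    HAP_B,
    NA,
    DetectOptions,
    PhaseVector,
    ScoreVector,
    call_crossover,
    detect_segments,
    extract_genotypes,
    phase_windows,
    score_read,
)
from gametecross.haplotypes import HaplotypeTable
from gametecross import simulator as sim

from conftest import make_sam


def _table(positions, hap_a, hap_b, chrom="chr1"):
    return HaplotypeTable(
        chrom,
        np.asarray(positions),
        np.asarray(list(hap_a)),
        np.asarray(list(hap_b)),
        np.zeros(len(positions), dtype=np.int64),
    )


def _read(seq, pos, cigar, name="r1"):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "chr1", "LN": 10_000}]}
    )
    a = pysam.AlignedSegment(header=header)
    a.query_name = name
    a.query_sequence = seq
    a.reference_id = 0
    a.reference_start = pos
    a.mapping_quality = 60
    a.cigartuples = cigar
    return a


class TestExtractGenotypes:
    def test_all_match_cigar(self):
        table = _table([110, 120], "AC", "CA")
        seq = "G" * 30
        seq = seq[:10] + "A" + seq[11:20] + "C" + seq[21:]
        read = _read(seq, 100, [(0, 30)])
        pos, bases = extract_genotypes(read, table)
        assert pos.tolist() == [110, 120]
        assert bases.tolist() == ["A", "C"]

    def test_deletion_spanning_site_is_unknown(self):
        table = _table([115], "A", "C")
        read = _read("G" * 20, 100, [(0, 10), (2, 10), (0, 10)])
        pos, bases = extract_genotypes(read, table)
        assert bases.tolist() == ["."]

    def test_cigar_length_mismatch_rejected(self):
        table = _table([5], "A", "C")
        read = _read("ACGT", 0, [(0, 10)])
        with pytest.raises(ValueError, match="CIGAR"):
            extract_genotypes(read, table)

    def test_random_cigars_match_aligned_pairs_oracle(self):
        rng = np.random.default_rng(17)
        sites = np.arange(5, 500, 7)
        table = _table(sites, "A" * len(sites), "C" * len(sites))
        for trial in range(50):
            # random CIGAR of M/I/D/S pieces
            cig = []
            if rng.random() < 0.3:
                cig.append((4, int(rng.integers(1, 10))))
            for _ in range(int(rng.integers(1, 12))):
                op = int(rng.choice([0, 1, 2]))
                cig.append((op, int(rng.integers(1, 30))))
            if cig[-1][0] != 0:
                cig.append((0, 5))
            if rng.random() < 0.3:
                cig.append((4, int(rng.integers(1, 10))))
            read_len = sum(l for op, l in cig if op in (0, 1, 4))
            seq = "".join(rng.choice(list("ACGT"), read_len))
            read = _read(seq, int(rng.integers(0, 50)), cig, name=f"t{trial}")
            pos, bases = extract_genotypes(read, table)
            # oracle: pysam's aligned-pairs expansion
            expect = {}
            for qpos, rpos in read.get_aligned_pairs():
                if rpos is not None and rpos in set(sites.tolist()):
                    expect[rpos] = seq[qpos] if qpos is not None else "."
            span = set(range(read.reference_start, read.reference_end))
            expected_sites = sorted(p for p in sites.tolist() if p in span)
            assert pos.tolist() == expected_sites
            assert bases.tolist() == [expect[p] for p in expected_sites]


class TestScoreRead:
    def test_scores_follow_allele_match(self):
        table = _table([10, 20, 30], "ACG", "CAT")
        sv = score_read(
            "r", "chr1", np.array([10, 20, 30]), np.array(["A", "A", "C"]), table
        )
        # A==hapA -> +1; A==hapB -> -1; C matches neither (hapA=G, hapB=T) -> 0
        assert sv.scores.tolist() == [1, -1, 0]

    def test_random_reads_match_direct_comparison(self):
        rng = np.random.default_rng(23)
        n = 200
        positions = np.sort(rng.choice(10_000, n, replace=False))
        hap_a = rng.choice(list("ACGT"), n)
        hap_b = np.array(
            [rng.choice([b for b in "ACGT" if b != a]) for a in hap_a]
        )
        table = _table(positions, hap_a, hap_b)
        observed = rng.choice(list("ACGT."), n)
        sv = score_read("r", "chr1", positions, observed, table)
        expect = [
            1 if o == a else (-1 if o == b else 0)
            for o, a, b in zip(observed, hap_a, hap_b)
        ]
        assert sv.scores.tolist() == expect


def brute_force_phase(scores, flank=3, min_represented=5, num=4, den=6):
    """Independent per-window recomputation with plain Python arithmetic."""
    from fractions import Fraction

    n = len(scores)
    w = 2 * flank + 1
    if n < w:
        return []
    out = []
    for i in range(flank, n - flank):
        window = scores[i - flank : i + flank + 1]
        ln = sum(1 for s in window if s != 0)
        if ln < min_represented:
            out.append(NA)
            continue
        ratio = Fraction(sum(window), ln)
        if ratio >= Fraction(num, den):
            out.append(HAP_A)
        elif ratio <= Fraction(-num, den):
            out.append(HAP_B)
        else:
            out.append(NA)
    return out


def _pv(scores):
    sv = ScoreVector(
        "r", "chr1", np.arange(len(scores)) * 10, np.asarray(scores, dtype=np.int8),
        np.array(["A"] * len(scores)),
    )
    return phase_windows(sv)


class TestPhaseWindows:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([1] * 7, [HAP_A]),                      # sum/Ln = 1
            ([1, 1, 1, -1, 1, 1, 1], [HAP_A]),       # 5/7 >= 4/6
            ([1, 1, 1, 1, -1, -1, 0], [NA]),         # 2/6 between thresholds
            ([-1] * 7, [HAP_B]),
            ([1, 1, 0, 0, 0, 1, 1], [NA]),           # Ln = 4 < 5
            ([1] * 6, []),                            # shorter than window
        ],
    )
    def test_forced_arithmetic_cases(self, scores, expected):
        assert _pv(scores).calls.tolist() == expected

    def test_evaluated_positions_are_fourth_to_fourth_from_last(self):
        pv = _pv([1] * 10)
        assert len(pv) == 10 - 6
        assert pv.site_positions.tolist() == [30, 40, 50, 60]
        assert (pv.window_ln <= 7).all() and (pv.window_ln >= 0).all()

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=0, max_size=40))
    def test_matches_brute_force_oracle(self, scores):
        assert _pv(scores).calls.tolist() == brute_force_phase(scores)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=7, max_size=30))
    def test_negation_swaps_haplotypes(self, scores):
        fwd = _pv(scores).calls
        rev = _pv([-s for s in scores]).calls
        assert (rev == -fwd).all()

    def test_inclusive_threshold_boundary(self):
        # sum/Ln exactly 4/6: six informative, sum 4
        scores = [1, 1, 1, 1, 1, -1, 0]
        assert sum(s for s in scores) == 4
        assert _pv(scores).calls.tolist() == [HAP_A]


class TestCallCrossover:
    def _phase_vector(self, calls, positions=None):
        calls = np.asarray(calls, dtype=np.int8)
        if positions is None:
            positions = np.arange(len(calls)) * 10
        return PhaseVector("r", "chr1", positions, calls, np.full(len(calls), 7))

    def test_uniform_phase_no_call(self):
        assert call_crossover(self._phase_vector([HAP_A] * 8)) == []

    def test_na_positions_dropped_before_transition(self):
        pv = self._phase_vector([HAP_A] * 5 + [NA] * 2 + [HAP_B] * 5)
        calls = call_crossover(pv)
        assert len(calls) == 1
        c = calls[0]
        # between the 5th HapA site (pos 40) and the 1st HapB site (pos 70)
        assert c.switch_interval_compressed == (40, 70)
        assert c.n_switches == 1 and not c.multi_switch
        assert (c.flank_a, c.flank_b) == (5, 5)

    def test_double_switch_flagged(self):
        pv = self._phase_vector([HAP_A, HAP_B, HAP_A])
        calls = call_crossover(pv)
        assert [c.n_switches for c in calls] == [2, 2]
        assert all(c.multi_switch for c in calls)


class TestDetectSegments:
    def _simulate(self, tmp_path, **overrides):
        cfg = sim.SimConfig(
            genome_length=300_000, depth=6.0, recomb_fraction=0.4,
            sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
            decoy_variant_fraction=0.0, breakpoint_min_flank_sites=7, seed=29,
        )
        from dataclasses import replace

        cfg = replace(cfg, **overrides)
        genome = sim.simulate_genome(cfg, np.random.default_rng(cfg.seed))
        bam = str(tmp_path / "r.bam")
        truth = sim.simulate_reads(
            cfg, genome, bam, rng=np.random.default_rng(cfg.seed + 1)
        )
        return cfg, genome, bam, truth

    def test_clean_pool_without_recombinants_yields_no_calls(self, tmp_path):
        _, genome, bam, truth = self._simulate(tmp_path, recomb_fraction=0.0)
        tables = sim.haplotype_tables_from_genome(genome)
        calls, summary = detect_segments(
            pysam.AlignmentFile(bam), tables, position_map=genome.position_map
        )
        assert len(calls) == 0
        assert not summary["recombinant"].any()

    def test_error_free_recombinants_all_found_with_breakpoint_inside(self, tmp_path):
        _, genome, bam, truth = self._simulate(tmp_path)
        tables = sim.haplotype_tables_from_genome(genome)
        calls, _ = detect_segments(
            pysam.AlignmentFile(bam), tables, position_map=genome.position_map
        )
        rec = truth[truth["recombinant"]]
        assert set(calls["read_id"]) == set(rec["read_id"])
        merged = calls.merge(rec, on="read_id", suffixes=("", "_t"))
        inside = (merged["comp_start"] < merged["breakpoint_comp"]) & (
            merged["breakpoint_comp"] <= merged["comp_end"]
        )
        assert inside.all()

    def test_haplotype_label_swap_symmetry(self, tmp_path):
        _, genome, bam, _ = self._simulate(tmp_path)
        tables = sim.haplotype_tables_from_genome(genome)
        swapped = {c: t.swap_labels() for c, t in tables.items()}
        calls1, _ = detect_segments(pysam.AlignmentFile(bam), tables)
        calls2, _ = detect_segments(pysam.AlignmentFile(bam), swapped)
        # identical recombinant set and intervals, flank labels exchanged
        cols = ["read_id", "chrom", "comp_start", "comp_end", "n_switches"]
        assert calls1[cols].equals(calls2[cols])
        assert calls1["flank_A"].tolist() == calls2["flank_B"].tolist()
        assert calls1["flank_B"].tolist() == calls2["flank_A"].tolist()

    def test_read_order_invariance(self, tmp_path):
        _, genome, bam, _ = self._simulate(tmp_path)
        tables = sim.haplotype_tables_from_genome(genome)
        reads = list(pysam.AlignmentFile(bam))
        calls1, _ = detect_segments(iter(reads), tables)
        rng = np.random.default_rng(0)
        shuffled = [reads[i] for i in rng.permutation(len(reads))]
        calls2, _ = detect_segments(iter(shuffled), tables)
        assert calls1.equals(calls2)

    def test_contig_without_haplotypes_skipped(self, tmp_path):
        bam = make_sam(
            tmp_path / "b.bam",
            [{"name": "r0", "pos": 10, "seq": "ACGTACGTAC", "chrom": "chrUn"}],
            {"chrUn": 1000},
        )
        tables = {"chr1": _table([5], "A", "C")}
        calls, summary = detect_segments(pysam.AlignmentFile(bam), tables)
        assert len(calls) == 0 and len(summary) == 0


class TestShortReads:
    def test_fewer_than_seven_sites_never_recombinant(self):
        # forced by the traversal bounds: no evaluated position exists
        for n in range(7):
            scores = ([1, -1] * 4)[:n]
            assert len(_pv(scores)) == 0
            assert call_crossover(_pv(scores)) == []
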