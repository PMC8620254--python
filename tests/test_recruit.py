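"""Recruiter correctness against an exhaustive sliding-window oracle."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import mutate, random_seq
from phylopop import synthdata as sd
from phylopop.assembly import ReferenceAssembly, revcomp
from phylopop.recruit import (
    merge_profiles,
    pileup,
    read_alignments_sam,
    recruit_reads,
    write_sam,
)

ORD_N = ord("N")


def oracle_recruit(reads, ref, minid=0.95):
    """Exhaustive ungapped placement: all offsets, both strands.

    Best identity wins; ties resolve to the lowest contig rank, then the
    lowest reference start, then the forward strand — the recruiter's
    stated contract.
    """
    contig_arrays = [
        np.frombuffer(ref.contigs[c].encode(), dtype=np.uint8) for c in ref.contig_ids
    ]
    placements = {}
    for rid, seq in reads:
        length = len(seq)
        best_key = None
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            for ci, carr in enumerate(contig_arrays):
                if carr.size < length:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(carr, length)
                mism = (
                    (windows != arr) | (windows == ORD_N) | (arr == ORD_N)
                ).sum(axis=1)
                identities = (length - mism) / length
                start = int(np.argmax(identities))
                identity = float(identities[start])
                key = (-identity, ci, start, strand)
                if best_key is None or key < best_key:
                    best_key = key
        if best_key is not None and -best_key[0] >= minid:
            placements[rid] = (
                ref.contig_ids[best_key[1]],
                best_key[2],
                best_key[3],
                -best_key[0],
            )
    return placements


def _sample_reads(ref, n, length, seed, error_rate=0.0):
    design = sd.SampleDesign("s", "AL", "summer", "f", 1.0, {"a": 1.0})
    design.mean_depth = n * length / len(ref)
    return sd.simulate_reads(
        ref,
        [sd.PhylotypeSpec("a")],
        design,
        seed=seed,
        read_length=length,
        error_rate=error_rate,
        revcomp_fraction=0.3,
    )


class TestRecruitReads:
    def test_exact_read_accepted_at_identity_one(self, tiny_ref):
        read = tiny_ref.contigs["A2"][300:400]
        [aln] = recruit_reads([("r", read)], tiny_ref)
        assert (aln.contig_id, aln.ref_start, aln.identity) == ("A2", 300, 1.0)

    def test_six_mismatches_in_hundred_rejected(self, tiny_ref):
        read = mutate(tiny_ref.contigs["A1"][100:200], range(10, 70, 10))
        assert recruit_reads([("r", read)], tiny_ref) == []

    def test_five_mismatches_in_hundred_accepted(self, tiny_ref):
        read = mutate(tiny_ref.contigs["A1"][100:200], range(10, 60, 10))
        [aln] = recruit_reads([("r", read)], tiny_ref)
        assert aln.identity == pytest.approx(0.95)
        assert sorted(p for p, _ in aln.mismatches) == [110, 120, 130, 140, 150]

    def test_reverse_complement_read_recovered(self, tiny_ref):
        read = revcomp(tiny_ref.contigs["B1"][200:320])
        [aln] = recruit_reads([("r", read)], tiny_ref)
        assert (aln.contig_id, aln.ref_start, aln.strand) == ("B1", 200, "-")

    def test_multi_mapping_resolves_to_lowest_rank(self):
        shared = random_seq(400, 21, "shared")
        ref = ReferenceAssembly(
            contigs={
                "X": random_seq(500, 22) + shared,
                "Y": shared + random_seq(500, 23),
            }
        )
        [aln] = recruit_reads([("r", shared[50:150])], ref)
        assert (aln.contig_id, aln.ref_start) == ("X", 550)

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="empty reference"):
            recruit_reads([("r", "ACGT" * 30)], ReferenceAssembly(contigs={}))

    def test_minid_monotonicity(self, tiny_ref):
        reads = _sample_reads(tiny_ref, 300, 100, seed=9, error_rate=0.03)
        accepted = [len(recruit_reads(reads, tiny_ref, minid=m)) for m in (0.98, 0.95, 0.90)]
        assert accepted == sorted(accepted)

    def test_oracle_equivalence_error_free(self):
        # exhaustive check on small references, error-free reads
        for seed in (0, 1, 2):
            cfg = sd.SimulationConfig(
                seed=seed, genome_length=6000, n_contigs=3, n_scaffolds=2
            )
            ref = sd.make_reference(cfg)
            reads = _sample_reads(ref, 400, 120, seed=seed)
            expected = oracle_recruit(reads, ref)
            got = {
                a.read_id: (a.contig_id, a.ref_start, a.strand, a.identity)
                for a in recruit_reads(reads, ref)
            }
            assert got == expected

    def test_oracle_equivalence_with_errors(self):
        # erroneous reads: every oracle-accepted read gets the oracle's
        # placement; anything extra can only be a gap-rescued read
        cfg = sd.SimulationConfig(seed=5, genome_length=5000, n_contigs=2, n_scaffolds=1)
        ref = sd.make_reference(cfg)
        reads = _sample_reads(ref, 300, 100, seed=5, error_rate=0.02)
        expected = oracle_recruit(reads, ref)
        got = {
            a.read_id: (a.contig_id, a.ref_start, a.strand, a.identity)
            for a in recruit_reads(reads, ref)
        }
        for rid, placement in expected.items():
            assert got[rid] == placement
        for rid in set(got) - set(expected):
            assert got[rid][3] >= 0.95  # gap rescue still honours minid


class TestPileup:
    def test_overlapping_alignments_depth(self, tiny_ref):
        reads = [
            ("r1", tiny_ref.contigs["A1"][100:150]),
            ("r2", tiny_ref.contigs["A1"][140:190]),
        ]
        profile, _ = pileup(recruit_reads(reads, tiny_ref), tiny_ref)
        d = profile.depth["A1"]
        assert d[140:150].tolist() == [2] * 10
        assert d[100:140].tolist() == [1] * 40
        assert d[150:190].tolist() == [1] * 40

    def test_mismatch_recorded_in_allele_counts(self, tiny_ref):
        pos = 250
        read = mutate(tiny_ref.contigs["A1"][200:300], [pos - 200])
        alt = read[pos - 200]
        _, counts = pileup(recruit_reads([("r", read)], tiny_ref), tiny_ref)
        col = counts.at("A1", pos)
        assert col[alt] == 1
        assert sum(col.values()) == 1

    def test_depth_conservation(self, tiny_ref):
        reads = _sample_reads(tiny_ref, 500, 100, seed=3, error_rate=0.01)
        alignments = recruit_reads(reads, tiny_ref)
        profile, counts = pileup(alignments, tiny_ref)
        assert profile.total_depth() == sum(a.span for a in alignments)
        # allele counts reconcile with depth at every position (no N reads)
        for cid in tiny_ref.contig_ids:
            assert np.array_equal(counts.counts[cid].sum(axis=0), profile.depth[cid])

    def test_brute_force_recount(self, tiny_ref):
        reads = _sample_reads(tiny_ref, 400, 80, seed=4)
        alignments = recruit_reads(reads, tiny_ref)
        profile, _ = pileup(alignments, tiny_ref)
        manual = {c: np.zeros(len(s), dtype=int) for c, s in tiny_ref.contigs.items()}
        for a in alignments:
            manual[a.contig_id][a.ref_start : a.ref_end] += 1
        for cid in tiny_ref.contig_ids:
            assert np.array_equal(profile.depth[cid], manual[cid])

    def test_empty_input_zero_profile(self, tiny_ref):
        profile, counts = pileup([], tiny_ref)
        assert profile.total_depth() == 0
        assert profile.aligned_read_count == 0


class TestSamInterop:
    def test_round_trip_preserves_profile(self, tiny_ref, tmp_path):
        reads = _sample_reads(tiny_ref, 400, 100, seed=6, error_rate=0.01)
        alignments = recruit_reads(reads, tiny_ref)
        sam = tmp_path / "out.sam"
        write_sam(alignments, tiny_ref, sam)
        recovered = read_alignments_sam(sam, tiny_ref)
        p1, c1 = pileup(alignments, tiny_ref)
        p2, c2 = pileup(recovered, tiny_ref)
        for cid in tiny_ref.contig_ids:
            assert np.array_equal(p1.depth[cid], p2.depth[cid])
            assert np.array_equal(c1.counts[cid], c2.counts[cid])

    def test_identity_recomputed_not_trusted(self, tiny_ref, tmp_path):
        read = mutate(tiny_ref.contigs["A1"][0:100], [10, 20])
        [aln] = recruit_reads([("r", read)], tiny_ref)
        sam = tmp_path / "one.sam"
        write_sam([aln], tiny_ref, sam)
        [rec] = read_alignments_sam(sam, tiny_ref)
        assert rec.identity == pytest.approx(0.98)
        assert sorted(p for p, _ in rec.mismatches) == [10, 20]

    def test_unmapped_records_ignored(self, tiny_ref, tmp_path):
        sam = tmp_path / "u.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:A1\tLN:2000\n"
            "u1\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\t*\n"
        )
        ref = ReferenceAssembly(contigs={"A1": tiny_ref.contigs["A1"]})
        assert read_alignments_sam(sam, ref) == []

    def test_unknown_contig_errors(self, tiny_ref, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ZZ\tLN:100\n"
            "r\t0\tZZ\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n"
        )
        with pytest.raises(ValueError, match="ZZ"):
            read_alignments_sam(sam, tiny_ref)


class TestMergeProfiles:
    def test_elementwise_sum_and_read_count(self, tiny_ref):
        r1 = _sample_reads(tiny_ref, 200, 100, seed=1)
        r2 = _sample_reads(tiny_ref, 150, 100, seed=2)
        p1, _ = pileup(recruit_reads(r1, tiny_ref), tiny_ref)
        p2, _ = pileup(recruit_reads(r2, tiny_ref), tiny_ref)
        merged = merge_profiles([p1, p2])
        for cid in tiny_ref.contig_ids:
            assert np.array_equal(merged.depth[cid], p1.depth[cid] + p2.depth[cid])
        assert merged.aligned_read_count == p1.aligned_read_count + p2.aligned_read_count

    def test_merge_with_empty_is_identity(self, tiny_ref):
        p1, _ = pileup(recruit_reads(_sample_reads(tiny_ref, 100, 100, 1), tiny_ref), tiny_ref)
        empty, _ = pileup([], tiny_ref)
        merged = merge_profiles([p1, empty])
        for cid in tiny_ref.contig_ids:
            assert np.array_equal(merged.depth[cid], p1.depth[cid])

    def test_mismatched_reference_rejected(self, tiny_ref):
        other = ReferenceAssembly(contigs={"Q": random_seq(1200, 40)})
        p1, _ = pileup([], tiny_ref)
        p2, _ = pileup([], other)
        with pytest.raises(ValueError, match="different references"):
            merge_profiles([p1, p2])
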