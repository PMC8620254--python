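"""SNP classification, depth formulas, LCRs, aggregation, diversity."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylopop import popstruct as ps
from phylopop.assembly import ReferenceAssembly
from phylopop.recruit import ALLELES, AlleleCounts, DepthProfile
from conftest import random_seq


def _ref_and_profile(depths: dict[str, list[int]], seed: int = 17):
    ref = ReferenceAssembly(
        contigs={cid: random_seq(len(d), seed, cid) for cid, d in depths.items()}
    )
    profile = DepthProfile(ref)
    for cid, d in depths.items():
        profile.depth[cid] = np.asarray(d, dtype=np.int64)
    return ref, profile


def _counts_for(ref: ReferenceAssembly, spec: dict) -> AlleleCounts:
    """spec: contig -> {pos: {allele: count}}; rest of depth goes to ref base."""
    counts = AlleleCounts(ref)
    for cid, positions in spec.items():
        for pos, alleles in positions.items():
            for allele, n in alleles.items():
                counts.counts[cid][ALLELES.index(allele), pos] = n
    return counts


class TestCallSnps:
    def test_one_percent_boundary_reported_with_low_depth_flag(self, tiny_ref):
        pos, refb = 10, tiny_ref.contigs["A1"][10]
        alt = "A" if refb != "A" else "C"
        counts = _counts_for(tiny_ref, {"A1": {pos: {refb: 99, alt: 1}}})
        [call] = ps.call_snps(counts, tiny_ref)
        assert call.variant_frequency == pytest.approx(0.01)
        assert call.klass == "reported"
        assert call.low_depth_flag  # a single supporting read
        assert (call.contig, call.pos, call.alt_base) == ("A1", pos, alt)

    def test_fixed_classification(self, tiny_ref):
        pos, refb = 20, tiny_ref.contigs["A1"][20]
        alt = "G" if refb != "G" else "T"
        counts = _counts_for(tiny_ref, {"A1": {pos: {refb: 5, alt: 95}}})
        [call] = ps.call_snps(counts, tiny_ref)
        assert call.variant_frequency == pytest.approx(0.95)
        assert call.klass == "fixed"
        assert not call.low_depth_flag

    def test_exact_fixed_threshold_included(self, tiny_ref):
        pos, refb = 30, tiny_ref.contigs["A1"][30]
        alt = "G" if refb != "G" else "T"
        counts = _counts_for(tiny_ref, {"A1": {pos: {refb: 10, alt: 90}}})
        [call] = ps.call_snps(counts, tiny_ref)
        assert call.klass == "fixed"  # vf exactly 0.9 is fixed (>= semantics)

    def test_below_report_threshold_silent(self, tiny_ref):
        pos, refb = 40, tiny_ref.contigs["A1"][40]
        alt = "G" if refb != "G" else "T"
        counts = _counts_for(tiny_ref, {"A1": {pos: {refb: 200, alt: 1}}})
        assert ps.call_snps(counts, tiny_ref) == []

    def test_no_alt_no_calls(self, tiny_ref):
        counts = _counts_for(
            tiny_ref, {"A1": {i: {tiny_ref.contigs["A1"][i]: 50} for i in range(100)}}
        )
        assert ps.call_snps(counts, tiny_ref) == []

    def test_deletion_allele_called_and_dilutes_frequency(self, tiny_ref):
        pos, refb = 55, tiny_ref.contigs["A1"][55]
        alt = "A" if refb != "A" else "C"
        counts = _counts_for(tiny_ref, {"A1": {pos: {refb: 50, alt: 30, "DEL": 20}}})
        calls = ps.call_snps(counts, tiny_ref)
        by_alt = {c.alt_base: c for c in calls}
        assert by_alt[alt].variant_frequency == pytest.approx(0.30)
        assert by_alt["DEL"].variant_frequency == pytest.approx(0.20)

    def test_invalid_thresholds(self, tiny_ref):
        counts = AlleleCounts(tiny_ref)
        with pytest.raises(ValueError):
            ps.call_snps(counts, tiny_ref, report_threshold=0.5, fixed_threshold=0.1)


class TestDepthFormulas:
    def test_mean_depth_arithmetic(self):
        _, profile = _ref_and_profile({"c": [4, 6] + [0] * 998})
        ref, _ = _ref_and_profile({"c": [4, 6] + [0] * 998})
        assert ps.mean_depth(profile, ("c", 0, 2)) == pytest.approx(5.0)

    def test_uniform_region_equals_depth(self):
        _, profile = _ref_and_profile({"c": [7] * 1000})
        assert ps.mean_depth(profile, ("c", 100, 900)) == pytest.approx(7.0)

    def test_zero_length_region_errors(self):
        _, profile = _ref_and_profile({"c": [1] * 1000})
        with pytest.raises(ValueError, match="zero-length"):
            ps.mean_depth(profile, ("c", 5, 5))

    def test_relative_coverage_examples(self):
        _, profile = _ref_and_profile({"c": [30] * 500 + [90] * 500})
        # region mean 30, genome mean 60 -> 50%
        assert ps.relative_coverage(profile, ("c", 0, 500)) == pytest.approx(50.0)
        assert ps.relative_coverage(profile, ("c", 0, 1000)) == pytest.approx(100.0)

    def test_zero_genome_depth_errors(self):
        _, profile = _ref_and_profile({"c": [0] * 1000})
        with pytest.raises(ValueError, match="zero"):
            ps.relative_coverage(profile, ("c", 0, 10))

    def test_formula_fidelity_random_profiles(self):
        # exact match against direct summation on 100 randomized profiles
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(1000, 3000))
            depths = rng.integers(0, 500, size=n)
            _, profile = _ref_and_profile({"c": depths.tolist()})
            s = int(rng.integers(0, n - 2))
            e = int(rng.integers(s + 1, n))
            expected = depths[s:e].sum() / (e - s)
            assert ps.mean_depth(profile, ("c", s, e)) == expected
            if depths.sum() > 0:
                expected_rc = 100.0 * expected / (depths.sum() / n)
                assert ps.relative_coverage(profile, ("c", s, e)) == pytest.approx(
                    expected_rc, abs=0, rel=0
                )


class TestDetectLcrs:
    def test_uniform_profile_no_lcrs(self, tiny_ref):
        profile = DepthProfile(tiny_ref)
        for cid in tiny_ref.contig_ids:
            profile.depth[cid][:] = 100
        assert ps.detect_lcrs(profile, tiny_ref) == []

    def test_planted_low_stretch_found_with_tight_boundaries(self):
        ref, profile = _ref_and_profile({"c": [100] * 3000 + [40] * 5000 + [100] * 2000})
        ref.scaffolds = {"S": ["c"]}
        [lcr] = ps.detect_lcrs(profile, ref)
        (cid, s, e) = lcr.segments[0]
        assert cid == "c"
        assert abs(s - 3000) <= 500 and abs(e - 8000) <= 500

    def test_straddling_contigs_merge_into_one(self):
        ref, profile = _ref_and_profile(
            {"a": [100] * 4000 + [20] * 2000, "b": [20] * 3000 + [100] * 4000}
        )
        ref.scaffolds = {"S": ["a", "b"]}
        [lcr] = ps.detect_lcrs(profile, ref)
        assert lcr.first_contig == "a" and lcr.last_contig == "b"
        assert lcr.length >= 4500

    def test_never_merges_across_scaffolds(self):
        ref, profile = _ref_and_profile(
            {"a": [100] * 4000 + [20] * 2000, "b": [20] * 3000 + [100] * 4000}
        )
        ref.scaffolds = {"S1": ["a"], "S2": ["b"]}
        lcrs = ps.detect_lcrs(profile, ref)
        assert len(lcrs) == 2
        assert {l.scaffold for l in lcrs} == {"S1", "S2"}

    def test_disjoint_and_sorted_within_scaffold(self):
        ref, profile = _ref_and_profile(
            {"c": [100] * 2000 + [10] * 2500 + [100] * 3000 + [10] * 2500 + [100] * 2000}
        )
        ref.scaffolds = {"S": ["c"]}
        lcrs = ps.detect_lcrs(profile, ref)
        assert len(lcrs) == 2
        spans = [seg for l in lcrs for seg in l.segments]
        assert spans == sorted(spans)
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestAggregation:
    @pytest.fixture
    def cov_meta(self):
        cov = pd.DataFrame(
            [
                {"region_id": "r1", "sample_id": "s1", "relative_coverage": 60.0},
                {"region_id": "r1", "sample_id": "s2", "relative_coverage": 80.0},
                {"region_id": "r1", "sample_id": "w1", "relative_coverage": 35.0},
                {"region_id": "r1", "sample_id": "w2", "relative_coverage": 35.0},
            ]
        )
        meta = pd.DataFrame(
            [
                {"sample_id": "s1", "system": "AL", "season": "summer"},
                {"sample_id": "s2", "system": "AL", "season": "summer"},
                {"sample_id": "w1", "system": "AL", "season": "winter"},
                {"sample_id": "w2", "system": "AL", "season": "winter"},
            ]
        )
        return cov, meta

    def test_group_mean_and_minimum(self, cov_meta):
        out = ps.aggregate_groups(*cov_meta, group_key="season")
        summer = out[out["season"] == "summer"].iloc[0]
        assert summer["mean"] == pytest.approx(70.0)
        assert summer["minimum"] == pytest.approx(60.0)

    def test_summer_winter_fold_change(self, cov_meta):
        out = ps.aggregate_groups(*cov_meta, group_key="season")
        assert out["summer_winter_fold_change"].iloc[0] == pytest.approx(2.0)

    def test_identical_groups_give_unit_fold(self, cov_meta):
        cov, meta = cov_meta
        cov["relative_coverage"] = 42.0
        out = ps.aggregate_groups(cov, meta, group_key="season")
        assert out["summer_winter_fold_change"].iloc[0] == pytest.approx(1.0)

    def test_unknown_sample_errors(self, cov_meta):
        cov, meta = cov_meta
        cov.loc[0, "sample_id"] = "ghost"
        with pytest.raises(KeyError, match="ghost"):
            ps.aggregate_groups(cov, meta, group_key="season")


class TestDifferential:
    def test_bh_textbook_example(self):
        adjusted = ps.benjamini_hochberg([0.01, 0.02, 0.03])
        assert np.allclose(adjusted, [0.03, 0.03, 0.03])

    def test_identical_groups_null(self):
        table = pd.DataFrame(
            {s: [1.0, 2.0, 0.5] for s in ("a1", "a2", "b1", "b2")},
            index=["r1", "r2", "r3"],
        )
        res = ps.differential_regions(table, ["a1", "a2"], ["b1", "b2"], seed=0)
        for r in res:
            assert r.log2_fold_change == pytest.approx(0.0)
            assert r.p_value == pytest.approx(1.0)

    def test_min_permutations_enforced(self):
        table = pd.DataFrame({s: [1.0] for s in ("a1", "a2", "b1", "b2")}, index=["r"])
        with pytest.raises(ValueError, match="n_perm"):
            ps.differential_regions(table, ["a1", "a2"], ["b1", "b2"], n_perm=10)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        data = {s: 1.0 + 0.01 * rng.standard_normal(20) for s in samples}
        for s in samples[:4]:
            data[s][0] *= 2.0  # region 0 doubled in group A
        table = pd.DataFrame(data, index=[f"r{i}" for i in range(20)])
        res = ps.differential_regions(table, samples[:4], samples[4:], seed=1)
        best = min(res, key=lambda r: r.p_adjusted)
        assert best.region_id == "r0"
        assert best.log2_fold_change == pytest.approx(1.0, abs=0.1)


class TestSimpson:
    def test_single_taxon_zero(self):
        assert ps.simpson_diversity([10]) == pytest.approx(0.0)

    def test_two_even_taxa(self):
        assert ps.simpson_diversity([5, 5]) == pytest.approx(1 - 40 / 90)

    def test_all_singletons_maximal(self):
        assert ps.simpson_diversity([1] * 12) == pytest.approx(1.0)

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            ps.simpson_diversity([1])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(min_value=0, max_value=200), min_size=1, max_size=15))
    def test_matches_direct_formula_and_bounds(self, counts):
        n = sum(counts)
        if n < 2:
            with pytest.raises(ValueError):
                ps.simpson_diversity(counts)
            return
        value = ps.simpson_diversity(counts)
        direct = 1 - sum(c * (c - 1) for c in counts) / (n * (n - 1))
        assert value == pytest.approx(direct)
        assert 0.0 <= value <= 1.0


class TestConsistencyReport:
    def test_lcr_membership_and_sample_sets(self):
        lcr = ps.LCR(
            id="LCR1",
            scaffold="S",
            segments=[("c", 100, 400)],
            length=300,
            mean_depth=10.0,
            relative_coverage_percent=20.0,
        )
        call_in = ps.SNPCall("c", 200, "A", "G", 0.2, 50, 10, "reported", False)
        call_out = ps.SNPCall("c", 900, "A", "T", 0.3, 50, 15, "reported", False)
        meta = pd.DataFrame(
            [
                {"sample_id": "al1", "system": "AL"},
                {"sample_id": "tb1", "system": "TB"},
            ]
        )
        report = ps.snp_consistency_report(
            {"al1": [call_in, call_out], "tb1": [call_out]}, [lcr], meta
        )
        by_pos = report.set_index("pos")
        assert bool(by_pos.loc[200, "in_lcr"]) is True
        assert bool(by_pos.loc[900, "in_lcr"]) is False
        assert by_pos.loc[900, "systems"] == "AL,TB"
        assert by_pos.loc[200, "systems"] == "AL"
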