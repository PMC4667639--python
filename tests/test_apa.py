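"""Poly(A)-site merging, the U statistic and expression-aware site filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mti.apa import (
    AnnotationError,
    CoverageTrack,
    MergedPolyASite,
    PolyASite,
    TranscriptAnnot,
    assign_and_order,
    compare_usage_by_group,
    compare_usage_paired,
    compute_usage,
    filter_sites_by_expression,
    merge_polya_sites,
    passes_coverage_filter,
    site_genomic_interval,
)
from mti.seedscan import SeedSite


def site(pos, chrom="chr1", strand="+"):
    return PolyASite(chrom=chrom, position=pos, strand=strand)


def merged_at(pos, chrom="chr1", strand="+"):
    return MergedPolyASite(chrom, strand, pos, pos + 1, pos, 1)


def oracle_merge(sites, max_gap=20):
    """O(n^2) union-find transitive closure, independent of the sweep."""
    groups = {}
    for s in sites:
        groups.setdefault((s.chrom, s.strand), []).append(s.position)
    out = set()
    for (chrom, strand), pos in groups.items():
        parent = list(range(len(pos)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if abs(pos[i] - pos[j]) < max_gap:
                    parent[find(i)] = find(j)
        clusters = {}
        for i in range(len(pos)):
            clusters.setdefault(find(i), []).append(pos[i])
        for members in clusters.values():
            out.add((chrom, strand, min(members), max(members) + 1,
                     len(members)))
    return out


class TestMerge:
    def test_within_gap_merges(self):
        m = merge_polya_sites([site(100), site(115)])
        assert len(m) == 1
        assert (m[0].start, m[0].end, m[0].n_merged) == (100, 116, 2)
        assert m[0].representative == 107

    def test_distance_exactly_gap_does_not_merge(self):
        m = merge_polya_sites([site(100), site(120)])
        assert len(m) == 2

    def test_strands_never_merge(self):
        m = merge_polya_sites([site(100, strand="+"), site(105, strand="-")])
        assert len(m) == 2

    def test_transitive_chain(self):
        m = merge_polya_sites([site(100), site(115), site(130)])
        assert len(m) == 1
        assert m[0].n_merged == 3

    def test_random_instances_match_union_find_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 120))
            sites = [
                site(
                    int(rng.integers(0, 2000)),
                    chrom=str(rng.choice(["c1", "c2"])),
                    strand=str(rng.choice(["+", "-"])),
                )
                for _ in range(n)
            ]
            got = {
                (m.chrom, m.strand, m.start, m.end, m.n_merged)
                for m in merge_polya_sites(sites)
            }
            assert got == oracle_merge(sites)

    def test_idempotent_and_order_independent(self, rng):
        sites = [site(int(p)) for p in rng.integers(0, 500, size=40)]
        once = merge_polya_sites(sites)
        again = merge_polya_sites(
            [PolyASite("chr1", m.representative, m.strand) for m in once]
        )
        assert [(m.start, m.end) for m in again] == [
            (m.representative, m.representative + 1) for m in once
        ]
        perm = list(sites)
        rng.shuffle(perm)
        assert merge_polya_sites(perm) == merge_polya_sites(sites)


class TestAssignOrder:
    def test_plus_strand_order(self):
        tx = TranscriptAnnot("t", "chr1", 0, 3000, "+")
        out = assign_and_order([merged_at(1000), merged_at(2000)], [tx])
        assert [m.representative for m in out["t"]] == [1000, 2000]

    def test_minus_strand_flips(self):
        tx = TranscriptAnnot("t", "chr1", 0, 3000, "-")
        out = assign_and_order(
            [merged_at(1000, strand="-"), merged_at(2000, strand="-")], [tx]
        )
        assert [m.representative for m in out["t"]] == [2000, 1000]

    def test_site_outside_interval_excluded(self):
        tx = TranscriptAnnot("t", "chr1", 500, 1500, "+")
        out = assign_and_order([merged_at(1000), merged_at(2000)], [tx])
        assert [m.representative for m in out["t"]] == [1000]

    def test_missing_strand_is_error(self):
        with pytest.raises(AnnotationError):
            TranscriptAnnot("t", "chr1", 0, 100, ".")


def step_track(lp, ld, depth, w, strand="+", sample="s"):
    v = np.where(np.arange(ld) < lp, depth, depth * (1.0 - w))
    if strand == "-":
        v = v[::-1].copy()
    return CoverageTrack(chrom="chr1", values=v, start=0, sample=sample)


def two_sites(lp, ld, strand="+"):
    if strand == "+":
        prox, dist = lp - 1, ld - 1
    else:
        prox, dist = ld - lp, 0
    return [merged_at(prox, strand=strand), merged_at(dist, strand=strand)]


class TestUStatistic:
    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("w", [0.0, 0.5, 0.75, 1.0])
    def test_two_isoform_mixture_recovers_w_exactly(self, w, strand):
        """Noise-free step coverage with proximal weight w gives U == w."""
        lp, ld, depth = 300, 800, 64.0
        annot = TranscriptAnnot("t", "chr1", 0, ld, strand)
        track = step_track(lp, ld, depth, w, strand)
        rec = compute_usage(track, two_sites(lp, ld, strand), annot)
        assert rec.passed
        assert rec.u == w

    def test_scaling_invariance(self):
        lp, ld = 300, 800
        annot = TranscriptAnnot("t", "chr1", 0, ld, "+")
        rng = np.random.default_rng(3)
        base = np.abs(rng.normal(20, 5, size=ld))
        u0 = compute_usage(
            CoverageTrack("chr1", base), two_sites(lp, ld), annot
        ).u
        u1 = compute_usage(
            CoverageTrack("chr1", base * 7.3), two_sites(lp, ld), annot
        ).u
        assert u1 == pytest.approx(u0, abs=1e-12)

    def test_af_al_arithmetic(self):
        # A_f = 20, A_l = 5 -> U = 0.75
        v = np.concatenate([np.full(300, 20.0), np.full(500, 5.0)])
        annot = TranscriptAnnot("t", "chr1", 0, 800, "+")
        rec = compute_usage(CoverageTrack("chr1", v), two_sites(300, 800), annot)
        assert (rec.a_f, rec.a_l, rec.u) == (20.0, 5.0, 0.75)

    def test_single_site_filtered(self):
        annot = TranscriptAnnot("t", "chr1", 0, 800, "+")
        rec = compute_usage(step_track(300, 800, 10, 0.5),
                            [merged_at(299)], annot)
        assert not rec.passed and rec.reason == "too_few_sites"

    def test_short_window_filtered(self):
        annot = TranscriptAnnot("t", "chr1", 0, 400, "+")
        sites = [merged_at(10), merged_at(399)]  # only 10 bp before proximal
        rec = compute_usage(step_track(11, 400, 30, 0.5), sites, annot)
        assert not rec.passed and rec.reason == "short_window"

    def test_zero_af_excluded(self):
        v = np.zeros(800)
        v[400:] = 10.0
        annot = TranscriptAnnot("t", "chr1", 0, 800, "+")
        rec = compute_usage(CoverageTrack("chr1", v), two_sites(300, 800), annot)
        assert not rec.passed and rec.reason == "undefined_u_zero_af"

    def test_coverage_filter_needs_one_sample_above_threshold(self):
        annot = TranscriptAnnot("t", "chr1", 0, 800, "+")
        low = compute_usage(step_track(300, 800, 8, 0.0), two_sites(300, 800),
                            annot)
        high = compute_usage(step_track(300, 800, 30, 0.0),
                             two_sites(300, 800), annot)
        assert passes_coverage_filter({"a": {"t": low}}) == set()
        assert passes_coverage_filter({"a": {"t": low}, "b": {"t": high}}) == {"t"}


class TestPairedComparison:
    def test_identical_usage_degenerate(self):
        annot = TranscriptAnnot("t", "chr1", 0, 800, "+")
        rec = compute_usage(step_track(300, 800, 30, 0.5),
                            two_sites(300, 800), annot)
        res = compare_usage_paired({"t": rec}, {"t": rec})
        assert res.p_value == 1.0

    def test_no_common_transcripts_is_error(self):
        annot = TranscriptAnnot("t", "chr1", 0, 800, "+")
        rec = compute_usage(step_track(300, 800, 30, 0.5),
                            two_sites(300, 800), annot)
        with pytest.raises(ValueError):
            compare_usage_paired({"t1": rec}, {"t2": rec})


class TestGroupComparison:
    def test_identical_groups(self):
        res, box = compare_usage_by_group([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.p_value == 1.0
        assert box["group_a"]["median"] == 0.2

    def test_shifted_groups_detected(self, rng):
        a = rng.uniform(0.2, 0.5, 40)
        b = rng.uniform(0.5, 0.8, 40)
        res, _ = compare_usage_by_group(a, b)
        assert res.p_value < 1e-6


class TestSiteVerdicts:
    def make_setup(self, w=0.75):
        lp, ld = 300, 800
        annot = TranscriptAnnot("t.2", "chr1", 0, ld, "+")
        track = step_track(lp, ld, 40.0, w)
        rec = compute_usage(track, two_sites(lp, ld), annot)
        return annot, track, rec

    def test_expressed_site_yes(self):
        annot, track, rec = self.make_setup()
        s = SeedSite("t.2", "g", "f", "8mer", 100, 108)
        out = filter_sites_by_expression([s], rec, track, annot)
        assert out[0].expression_verdict == "YES"

    def test_abandoned_distal_site_no(self):
        """The shortening-escape pattern: a site downstream of a heavily
        used proximal poly(A) site sits in near-zero coverage."""
        annot, track, rec = self.make_setup(w=0.9)
        s = SeedSite("t.2", "g", "f", "8mer", 500, 508)
        out = filter_sites_by_expression([s], rec, track, annot)
        assert out[0].expression_verdict == "NO"

    def test_intermediate_coverage_weak_yes(self):
        annot, track, rec = self.make_setup(w=0.7)  # distal r = 0.3
        s = SeedSite("t.2", "g", "f", "8mer", 500, 508)
        out = filter_sites_by_expression([s], rec, track, annot)
        assert out[0].expression_verdict == "YES*"

    def test_site_beyond_transcript_bounds_nd(self):
        annot, track, rec = self.make_setup()
        s = SeedSite("t.2", "g", "f", "8mer", 795, 803)
        out = filter_sites_by_expression([s], rec, track, annot)
        assert out[0].expression_verdict == "ND"

    def test_zero_af_gives_nd(self):
        annot, track, _ = self.make_setup()
        s = SeedSite("t.2", "g", "f", "8mer", 100, 108)
        out = filter_sites_by_expression([s], None, track, annot)
        assert out[0].expression_verdict == "ND"

    def test_raising_theta_hi_never_promotes(self):
        annot, track, rec = self.make_setup(w=0.7)
        s = SeedSite("t.2", "g", "f", "8mer", 500, 508)
        rank = {"YES": 0, "YES*": 1, "NO": 2, "ND": 3}
        verdicts = [
            filter_sites_by_expression([s], rec, track, annot,
                                       theta_hi=th)[0].expression_verdict
            for th in (0.25, 0.4, 0.6, 0.9)
        ]
        assert all(rank[a] <= rank[b] for a, b in zip(verdicts, verdicts[1:]))

    def test_minus_strand_genomic_mapping(self):
        annot = TranscriptAnnot("t.2", "chr1", 0, 800, "-")
        s = SeedSite("t.2", "g", "f", "8mer", 0, 8)
        assert site_genomic_interval(s, annot) == (792, 800)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=500), min_size=1,
                max_size=60))
def test_merge_is_idempotent_for_arbitrary_positions(positions):
    """Property: re-merging merged representatives changes nothing, and
    n_merged totals are conserved."""
    sites = [site(p) for p in positions]
    once = merge_polya_sites(sites)
    assert sum(m.n_merged for m in once) == len(positions)
    again = merge_polya_sites(
        [PolyASite("chr1", m.representative, m.strand) for m in once]
    )
    assert [m.representative for m in again] == [m.representative for m in once]
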