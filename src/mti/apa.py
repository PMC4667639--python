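"""Alternative polyadenylation (APA): poly(A)-site usage and 3' UTR shortening.

Strand-specific poly(A) sites (e.g. a multi-tissue poly(A)-Seq atlas) are
merged when closer than 20 bp, assigned to transcripts, and for each
transcript with >= 2 sites the differential usage index

    U = (A_f - A_l) / A_f

is computed, where ``A_f`` and ``A_l`` are the mean read coverages in
100-bp windows immediately upstream (in transcription direction) of the
first (proximal) and last (distal) poly(A) site.  U near 1 indicates
preferential use of the proximal site (a shortened 3' UTR); U near 0
indicates distal preference.

The same coverage evidence grades predicted seed sites: a site whose
local coverage is high relative to ``A_f`` lies in an expressed isoform
(verdict YES / YES*), a site in an abandoned distal region gets NO (the
shortening-escape pattern), and a site outside annotated transcript
bounds gets ND.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seedscan import SeedSite
from .stats import TestResult, mann_whitney, wilcoxon_signed_rank

__all__ = [
    "PolyASite",
    "MergedPolyASite",
    "TranscriptAnnot",
    "CoverageTrack",
    "UsageRecord",
    "AnnotationError",
    "merge_polya_sites",
    "assign_and_order",
    "compute_usage",
    "passes_coverage_filter",
    "compare_usage_paired",
    "compare_usage_by_group",
    "filter_sites_by_expression",
    "site_genomic_interval",
]


class AnnotationError(ValueError):
    """Missing or inconsistent transcript annotation."""


@dataclass(frozen=True)
class PolyASite:
    """One reported poly(A) cleavage position (0-based, strand-specific)."""

    chrom: str
    position: int
    strand: str
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("poly(A) position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class MergedPolyASite:
    """A cluster of nearby same-strand sites; representative = midpoint."""

    chrom: str
    strand: str
    start: int
    end: int
    representative: int
    n_merged: int


@dataclass(frozen=True)
class TranscriptAnnot:
    """Genomic interval of a transcript's 3' UTR (0-based half-open)."""

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )


@dataclass
class CoverageTrack:
    """Per-base coverage over one contig/transcript interval, one sample."""

    chrom: str
    values: np.ndarray
    start: int = 0
    sample: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    def window_mean(self, a: int, b: int) -> tuple[float, int]:
        """Mean over genomic [a, b) clipped to the track; (mean, n_bases)."""
        lo = max(a, self.start)
        hi = min(b, self.start + self.values.size)
        if hi <= lo:
            return 0.0, 0
        seg = self.values[lo - self.start : hi - self.start]
        return float(seg.mean()), int(seg.size)


@dataclass
class UsageRecord:
    """Per-transcript poly(A) usage summary in one sample."""

    transcript_id: str
    n_sites: int
    a_f: float | None = None
    a_l: float | None = None
    u: float | None = None
    mean_coverage: float = 0.0
    sample: str = ""
    passed: bool = True
    reason: str | None = None


def merge_polya_sites(
    sites: Iterable[PolyASite], max_gap: int = 20
) -> list[MergedPolyASite]:
    """Merge same-strand sites transitively when adjacent distance < max_gap.

    Distance is the difference of positions; the boundary is strict, so
    two sites exactly ``max_gap`` apart stay separate.  Strands never
    merge.  Output sorted by (chrom, strand, start).
    """
    by_key: dict[tuple[str, str], list[int]] = {}
    for s in sites:
        by_key.setdefault((s.chrom, s.strand), []).append(s.position)
    merged: list[MergedPolyASite] = []
    for (chrom, strand), positions in by_key.items():
        positions.sort()
        cluster = [positions[0]]
        for p in positions[1:]:
            if p - cluster[-1] < max_gap:
                cluster.append(p)
            else:
                merged.append(_finish_cluster(chrom, strand, cluster))
                cluster = [p]
        merged.append(_finish_cluster(chrom, strand, cluster))
    merged.sort(key=lambda m: (m.chrom, m.strand, m.start))
    return merged


def _finish_cluster(chrom: str, strand: str, cluster: list[int]) -> MergedPolyASite:
    lo, hi = cluster[0], cluster[-1]
    return MergedPolyASite(
        chrom=chrom,
        strand=strand,
        start=lo,
        end=hi + 1,
        representative=(lo + hi) // 2,
        n_merged=len(cluster),
    )


def assign_and_order(
    merged_sites: Iterable[MergedPolyASite],
    transcripts: Iterable[TranscriptAnnot],
) -> dict[str, list[MergedPolyASite]]:
    """Assign merged sites to transcripts and order them 5'->3'.

    A site belongs to a transcript when its representative falls inside
    the transcript interval on the same chrom and strand.  Ordering is in
    transcription direction: minus-strand transcripts are ordered by
    decreasing genomic coordinate, so the first element is always the
    proximal (most upstream) site and the last the distal one.
    """
    by_chrom: dict[tuple[str, str], list[MergedPolyASite]] = {}
    for m in merged_sites:
        by_chrom.setdefault((m.chrom, m.strand), []).append(m)
    out: dict[str, list[MergedPolyASite]] = {}
    for tx in transcripts:
        hits = [
            m
            for m in by_chrom.get((tx.chrom, tx.strand), [])
            if tx.start <= m.representative < tx.end
        ]
        hits.sort(key=lambda m: m.representative, reverse=(tx.strand == "-"))
        out[tx.transcript_id] = hits
    return out


def _upstream_window(pos: int, strand: str, window: int) -> tuple[int, int]:
    """Genomic [a, b) of the window immediately upstream of ``pos`` in
    transcription direction (excluding the site base itself)."""
    if strand == "+":
        return pos - window, pos
    return pos + 1, pos + 1 + window


def compute_usage(
    track: CoverageTrack,
    ordered_sites: Sequence[MergedPolyASite],
    annot: TranscriptAnnot,
    window: int = 100,
    min_sites: int = 2,
    min_window_bases: int = 20,
) -> UsageRecord:
    """Compute the U statistic for one transcript in one sample.

    ``ordered_sites`` must already be in transcription order (see
    :func:`assign_and_order`).  Windows are truncated at the transcript
    boundary; fewer than ``min_window_bases`` evaluable bases in either
    window filters the transcript out rather than producing an unstable
    mean.  ``A_f == 0`` leaves U undefined and the record excluded.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_sites = len(ordered_sites)
    mean_cov, _ = track.window_mean(annot.start, annot.end)
    rec = UsageRecord(
        transcript_id=annot.transcript_id,
        n_sites=n_sites,
        mean_coverage=mean_cov,
        sample=track.sample,
    )
    if n_sites < min_sites:
        rec.passed = False
        rec.reason = "too_few_sites"
        return rec
    means = []
    for site in (ordered_sites[0], ordered_sites[-1]):
        a, b = _upstream_window(site.representative, annot.strand, window)
        a, b = max(a, annot.start), min(b, annot.end)
        mean, nbases = track.window_mean(a, b)
        if nbases < min_window_bases:
            rec.passed = False
            rec.reason = "short_window"
            return rec
        means.append(mean)
    rec.a_f, rec.a_l = means
    if rec.a_f == 0:
        rec.passed = False
        rec.reason = "undefined_u_zero_af"
        return rec
    rec.u = (rec.a_f - rec.a_l) / rec.a_f
    return rec


def passes_coverage_filter(
    records_by_sample: Mapping[str, Mapping[str, UsageRecord]],
    min_mean_cov: float = 10.0,
) -> set[str]:
    """Transcripts whose mean coverage is strictly greater than
    ``min_mean_cov`` in at least one sample and whose U is defined in
    every sample where they were evaluated."""
    keep: set[str] = set()
    all_tx = set()
    for recs in records_by_sample.values():
        all_tx.update(recs)
    for tx in all_tx:
        recs = [r[tx] for r in records_by_sample.values() if tx in r]
        if any(r.mean_coverage > min_mean_cov for r in recs) and all(
            r.passed for r in recs
        ):
            keep.add(tx)
    return keep


def compare_usage_paired(
    usage_a: Mapping[str, UsageRecord],
    usage_b: Mapping[str, UsageRecord],
) -> TestResult:
    """Two-sided Wilcoxon signed-rank on paired per-transcript U values.

    Transcripts present with a defined U in both samples are paired by
    transcript id; zero differences are dropped inside the test.
    """
    common = sorted(
        tx
        for tx in usage_a
        if tx in usage_b
        and usage_a[tx].u is not None
        and usage_b[tx].u is not None
    )
    if not common:
        raise ValueError("no transcripts with defined U in both samples")
    a = [usage_a[tx].u for tx in common]
    b = [usage_b[tx].u for tx in common]
    return wilcoxon_signed_rank(a, b)


def compare_usage_by_group(
    u_group_a,
    u_group_b,
) -> tuple[TestResult, dict[str, dict[str, float]]]:
    """Two-sided Mann-Whitney on two groups of U values plus five-number
    summaries (boxplot coordinates) per group."""
    result = mann_whitney(u_group_a, u_group_b)
    summaries = {
        name: _five_number(vals)
        for name, vals in (("group_a", u_group_a), ("group_b", u_group_b))
    }
    return result, summaries


def _five_number(values) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return {
        "min": float(q[0]),
        "q1": float(q[1]),
        "median": float(q[2]),
        "q3": float(q[3]),
        "max": float(q[4]),
    }


def site_genomic_interval(
    site: SeedSite, annot: TranscriptAnnot
) -> tuple[int, int]:
    """Map a transcript-local site interval to genomic coordinates."""
    if annot.strand == "+":
        return annot.start + site.start, annot.start + site.end
    return annot.end - site.end, annot.end - site.start


def filter_sites_by_expression(
    sites: Iterable[SeedSite],
    usage: UsageRecord | None,
    track: CoverageTrack,
    annot: TranscriptAnnot,
    theta_hi: float = 0.5,
    theta_lo: float = 0.2,
) -> list[SeedSite]:
    """Grade predicted sites by expression of the isoform containing them.

    An automated surrogate for manual curation of 3' UTR expression: with
    ``r`` the mean coverage over the (genomic) site interval divided by
    the proximal reference coverage ``A_f``,

    * ``r >= theta_hi``           -> YES  (site clearly expressed)
    * ``theta_lo <= r < theta_hi``-> YES* (weak evidence)
    * ``r <  theta_lo``           -> NO   (expressed isoforms exclude it)
    * outside transcript bounds, or ``A_f`` unavailable/zero -> ND.

    Sites are given in transcript-local coordinates; returns copies with
    ``expression_verdict`` set.
    """
    if not 0 < theta_lo <= theta_hi:
        raise ValueError("require 0 < theta_lo <= theta_hi")
    out: list[SeedSite] = []
    a_f = usage.a_f if usage is not None else None
    for s in sites:
        a, b = site_genomic_interval(s, annot)
        graded = SeedSite(
            s.transcript_id, s.gene_id, s.family, s.site_type, s.start, s.end
        )
        if a < annot.start or b > annot.end:
            graded.expression_verdict = "ND"
        elif a_f is None or a_f == 0:
            graded.expression_verdict = "ND"
        else:
            mean, nbases = track.window_mean(a, b)
            r = mean / a_f if nbases else 0.0
            if r >= theta_hi:
                graded.expression_verdict = "YES"
            elif r >= theta_lo:
                graded.expression_verdict = "YES*"
            else:
                graded.expression_verdict = "NO"
        out.append(graded)
    return out
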