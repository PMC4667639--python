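"""miRNA seed families and unbiased seed-match scanning of 3' UTR sequences.

A miRNA *seed* is nucleotides 2-8 of the mature sequence.  On the target
(mRNA) side two canonical site classes are searched:

* ``7mer-m8`` -- the 7-nt reverse complement of the seed;
* ``8mer``    -- the 7mer-m8 match followed by an adenosine (the base
  opposite miRNA position 1).

The scan is *unbiased*: every occurrence of either pattern in a 3' UTR
isoform is reported, with no conservation or context scoring.  A position
matching the 8mer pattern is reported once, as an 8mer only; the 7mer-m8
contained in it is suppressed so the two site classes stay disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "MiRNAFamily",
    "UTRIsoform",
    "SeedSite",
    "SITE_TYPES",
    "VERDICTS",
    "SeedscanError",
    "InvalidMiRNAError",
    "FamilyConflictError",
    "AlphabetError",
    "site_patterns",
    "build_family_seeds",
    "scan_utr",
    "scan_utrs",
    "genes_by_site_type",
]

SITE_TYPES = ("8mer", "7mer-m8")
#: Expression-filter verdict vocabulary for a predicted site.  YES / YES*
#: mean strong / weak evidence that the site lies in an expressed isoform,
#: NO means the expressed 3' UTR excludes it, ND means the site falls
#: outside annotated transcript bounds, UNSET means no filtering was run.
VERDICTS = ("YES", "YES*", "NO", "ND", "UNSET")

_DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SeedscanError(ValueError):
    """Base class for seed-scanning input errors."""


class InvalidMiRNAError(SeedscanError):
    """Mature miRNA sequence too short to contain a seed."""


class FamilyConflictError(SeedscanError):
    """Members grouped under one family label disagree in seed."""


class AlphabetError(SeedscanError):
    """Non-nucleotide character where A/C/G/T/U was required."""


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    """DNA reverse complement; accepts RNA input (U treated as T)."""
    s = _to_dna(seq)
    bad = set(s) - set(_DNA)
    if bad:
        raise AlphabetError(f"non-ACGTU characters in sequence: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def site_patterns(seed: str) -> tuple[str, str]:
    """Target-side match patterns for a 7-nt seed.

    Returns ``(pattern_7mer_m8, pattern_8mer)``: the DNA reverse complement
    of the seed, and the same followed by ``"A"``.
    """
    if len(seed) != 7:
        raise SeedscanError(f"seed must be 7 nt, got {len(seed)}")
    p7 = reverse_complement(seed)
    return p7, p7 + "A"


@dataclass(frozen=True)
class MiRNAFamily:
    """A seed family: miRNAs sharing an identical seed (positions 2-8)."""

    name: str
    members: tuple[str, ...]
    seed: str
    pattern_7mer_m8: str = field(default="", compare=False)
    pattern_8mer: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        p7, p8 = site_patterns(self.seed)
        object.__setattr__(self, "pattern_7mer_m8", p7)
        object.__setattr__(self, "pattern_8mer", p8)


@dataclass(frozen=True)
class UTRIsoform:
    """One 3' UTR isoform sequence (5'->3', mRNA sense strand)."""

    transcript_id: str
    gene_id: str
    sequence: str
    chrom: str | None = None
    strand: str | None = None
    start: int | None = None
    end: int | None = None


@dataclass
class SeedSite:
    """One predicted seed-match site, 0-based half-open within the UTR."""

    transcript_id: str
    gene_id: str
    family: str
    site_type: str
    start: int
    end: int
    expression_verdict: str = "UNSET"

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise SeedscanError(f"unknown site type {self.site_type!r}")
        width = 8 if self.site_type == "8mer" else 7
        if self.end - self.start != width:
            raise SeedscanError(
                f"{self.site_type} site must span {width} nt, "
                f"got [{self.start},{self.end})"
            )


def build_family_seeds(
    mirna_records: Iterable[tuple[str, str, str]],
) -> list[MiRNAFamily]:
    """Group ``(name, mature_sequence, family_label)`` records into families.

    The seed is characters 2-8 (1-based) of the mature sequence.  All
    members of one label must share an identical seed; conflict is an
    error, because a family is *defined* by its seed.
    """
    order: list[str] = []
    members: dict[str, list[str]] = {}
    seeds: dict[str, str] = {}
    for name, seq, label in mirna_records:
        if not label:
            raise SeedscanError(f"miRNA {name!r} has an empty family label")
        if len(seq) < 8:
            raise InvalidMiRNAError(
                f"miRNA {name!r}: mature sequence must be >= 8 nt, got {len(seq)}"
            )
        seed = seq[1:8].upper()
        if label not in seeds:
            order.append(label)
            seeds[label] = seed
            members[label] = []
        elif seeds[label] != seed:
            raise FamilyConflictError(
                f"family {label!r}: member {name!r} has seed {seed}, "
                f"expected {seeds[label]}"
            )
        members[label].append(name)
    return [
        MiRNAFamily(name=lab, members=tuple(members[lab]), seed=seeds[lab])
        for lab in order
    ]


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) occurrence offsets of needle."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def scan_utr(
    isoform: UTRIsoform, families: Sequence[MiRNAFamily]
) -> list[SeedSite]:
    """Report every 8mer and 7mer-m8 occurrence for each family.

    Overlapping occurrences are all reported.  A 7mer-m8 occurrence whose
    following base is A is an 8mer occurrence and is reported only as such.
    ``N`` never matches.  Output is sorted by ``(start, family)``.
    """
    if not families:
        raise SeedscanError("no miRNA families supplied")
    seq = _to_dna(isoform.sequence)
    sites: list[SeedSite] = []
    for fam in families:
        for i in _find_all(seq, fam.pattern_8mer):
            sites.append(
                SeedSite(isoform.transcript_id, isoform.gene_id, fam.name,
                         "8mer", i, i + 8)
            )
        for i in _find_all(seq, fam.pattern_7mer_m8):
            if seq[i : i + 8] == fam.pattern_8mer:
                continue  # counted as the 8mer above
            sites.append(
                SeedSite(isoform.transcript_id, isoform.gene_id, fam.name,
                         "7mer-m8", i, i + 7)
            )
    sites.sort(key=lambda s: (s.start, s.family))
    return sites


def scan_utrs(
    isoforms: Iterable[UTRIsoform], families: Sequence[MiRNAFamily]
) -> list[SeedSite]:
    """Scan many isoforms; concatenated per-isoform results."""
    out: list[SeedSite] = []
    for iso in isoforms:
        out.extend(scan_utr(iso, families))
    return out


def genes_by_site_type(sites: Iterable[SeedSite]) -> dict[str, set[str]]:
    """Gene sets per site class.

    A gene with sites of several types belongs to every matching class
    (the classes are plotted as separate ECDF curves downstream).
    """
    out: dict[str, set[str]] = {t: set() for t in SITE_TYPES}
    for s in sites:
        out[s.site_type].add(s.gene_id)
    return out
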