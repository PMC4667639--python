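"""Readers and writers for the pipeline's standard formats.

FASTA via Biopython, tabular formats via pandas.  All intervals are
0-based half-open (BED convention); bedGraph intervals must be
non-overlapping per contig.  Parse errors name the offending record or
line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .apa import CoverageTrack, MergedPolyASite, PolyASite, TranscriptAnnot
from .expression import ProteinQuant, TranscriptQuant
from .seedscan import SeedSite, UTRIsoform

__all__ = [
    "ParseError",
    "ValidationError",
    "read_utr_fasta",
    "write_utr_fasta",
    "read_mirna_table",
    "write_mirna_table",
    "write_sites_bed",
    "read_sites_bed",
    "read_polya_bed",
    "write_polya_bed",
    "read_transcripts_bed",
    "write_transcripts_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_protein_table",
    "write_protein_table",
    "read_transcript_table",
    "write_transcript_table",
    "read_gene_list",
    "write_gene_list",
    "write_json",
]


class ParseError(ValueError):
    """Malformed record in an input file."""


class ValidationError(ValueError):
    """Well-formed input violating a pipeline contract."""


# ---------------------------------------------------------------- FASTA

def read_utr_fasta(path) -> list[UTRIsoform]:
    """Read 3' UTR isoforms; headers are ``transcript_id|gene_id``."""
    isoforms = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ParseError(
                f"{path}: FASTA header {rec.id!r} lacks the "
                "'transcript_id|gene_id' separator"
            )
        tx, gene = rec.id.split("|", 1)
        isoforms.append(UTRIsoform(tx, gene, str(rec.seq).upper()))
    return isoforms


def write_utr_fasta(isoforms: Iterable[UTRIsoform], path) -> None:
    records = [
        SeqRecord(Seq(iso.sequence), id=f"{iso.transcript_id}|{iso.gene_id}",
                  description="")
        for iso in isoforms
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- miRNAs

def read_mirna_table(path) -> list[tuple[str, str, str]]:
    """TSV with columns name, sequence, family."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("name", "sequence", "family"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return list(df[["name", "sequence", "family"]].itertuples(index=False, name=None))


def write_mirna_table(records: Iterable[tuple[str, str, str]], path) -> None:
    pd.DataFrame(records, columns=["name", "sequence", "family"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------- BED

def write_sites_bed(sites: Iterable[SeedSite], path) -> None:
    """BED6 of seed sites: chrom=transcript_id, name=family:site_type,
    score field reused for the expression verdict (0 when unset)."""
    rows = [
        (
            s.transcript_id, s.start, s.end, f"{s.family}:{s.site_type}",
            s.expression_verdict if s.expression_verdict != "UNSET" else "0",
            "+",
        )
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_sites_bed(path, gene_by_transcript: Mapping[str, str] | None = None) -> list[SeedSite]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "score": str},
    )
    sites = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if ":" not in row.name:
            raise ParseError(f"{path}:{i}: site name {row.name!r} lacks family:type")
        fam, stype = row.name.rsplit(":", 1)
        gene = (gene_by_transcript or {}).get(row.chrom, "")
        verdict = row.score if row.score in ("YES", "YES*", "NO", "ND") else "UNSET"
        sites.append(
            SeedSite(row.chrom, gene, fam, stype, int(row.start), int(row.end),
                     expression_verdict=verdict)
        )
    return sites


def read_polya_bed(path) -> list[PolyASite]:
    """BED6: one poly(A) site per line, name = source/tissue label."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    sites = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.strand not in ("+", "-"):
            raise ParseError(f"{path}:{i}: bad strand {row.strand!r}")
        sites.append(
            PolyASite(chrom=row.chrom, position=int(row.start),
                      strand=row.strand, sources=(str(row.name),))
        )
    return sites


def write_polya_bed(sites: Iterable[PolyASite], path) -> None:
    rows = [
        (s.chrom, s.position, s.position + 1,
         ",".join(s.sources) or ".", 0, s.strand)
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_merged_bed(merged: Iterable[MergedPolyASite], path) -> None:
    rows = [
        (m.chrom, m.start, m.end, f"n={m.n_merged}", m.representative, m.strand)
        for m in merged
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_transcripts_bed(path) -> list[TranscriptAnnot]:
    """BED6 transcript models: name = transcript_id."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.strand not in ("+", "-"):
            raise ParseError(f"{path}:{i}: transcript {row.name!r} lacks a strand")
        out.append(
            TranscriptAnnot(row.name, row.chrom, int(row.start), int(row.end),
                            row.strand)
        )
    return out


def write_transcripts_bed(annots: Iterable[TranscriptAnnot], path) -> None:
    rows = [(a.chrom, a.start, a.end, a.transcript_id, 0, a.strand) for a in annots]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------- bedGraph

def read_bedgraph(path, sample: str = "") -> dict[str, CoverageTrack]:
    """Per-chrom coverage arrays from a bedGraph (0-based half-open).

    Intervals must be non-overlapping within a chrom; uncovered positions
    are zero.  Arrays start at position 0 and extend to the last covered
    base of each chrom.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    tracks: dict[str, CoverageTrack] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(dtype=int)
        ends = sub["end"].to_numpy(dtype=int)
        if (starts[1:] < ends[:-1]).any():
            raise ValidationError(
                f"{path}: overlapping bedGraph intervals on {chrom}"
            )
        values = np.zeros(int(ends[-1]), dtype=float)
        for a, b, v in zip(starts, ends, sub["value"].to_numpy(dtype=float)):
            values[a:b] = v
        tracks[chrom] = CoverageTrack(chrom=chrom, values=values, start=0,
                                      sample=sample)
    return tracks


def write_bedgraph(tracks: Mapping[str, CoverageTrack], path) -> None:
    """Run-length-encoded bedGraph; zero runs are omitted."""
    frames = []
    for chrom in sorted(tracks):
        t = tracks[chrom]
        v = t.values
        if v.size == 0:
            continue
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [v.size]])
        vals = v[starts]
        keep = vals != 0
        if not keep.any():
            continue
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts[keep] + t.start,
                    "end": ends[keep] + t.start,
                    "value": vals[keep],
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "start", "end", "value"])
    )
    df.to_csv(path, sep="\t", index=False, header=False,
              float_format="%.10g")


# ---------------------------------------------------------------- quant TSVs

def write_protein_table(quants: Sequence[ProteinQuant], path) -> None:
    """Wide TSV: ratio_<rep>, intensity_<rep>, ratio_count_<rep> columns."""
    reps: list[str] = []
    for q in quants:
        for rep in list(q.ratio) + list(q.intensity) + list(q.ratio_count):
            if rep not in reps:
                reps.append(rep)
    rows = []
    for q in quants:
        row: dict = {
            "protein_id": q.protein_id,
            "gene_id": q.gene_id,
            "peptides": q.peptide_count,
            "unique_peptides": q.unique_peptide_count,
        }
        for rep in reps:
            row[f"ratio_{rep}"] = q.ratio.get(rep, np.nan)
            row[f"intensity_{rep}"] = q.intensity.get(rep, np.nan)
            row[f"ratio_count_{rep}"] = q.ratio_count.get(rep, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_protein_table(path) -> list[ProteinQuant]:
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "gene_id", "peptides", "unique_peptides"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    reps = [c[len("ratio_"):] for c in df.columns
            if c.startswith("ratio_") and not c.startswith("ratio_count_")]
    if not reps:
        raise ParseError(f"{path}: no ratio_<replicate> columns found")
    quants = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        ratio, intensity, rc = {}, {}, {}
        for rep in reps:
            r = d.get(f"ratio_{rep}")
            if r is not None and np.isfinite(r):
                ratio[rep] = float(r)
            v = d.get(f"intensity_{rep}")
            if v is not None and np.isfinite(v):
                intensity[rep] = float(v)
            rc[rep] = int(d.get(f"ratio_count_{rep}", 0) or 0)
        quants.append(
            ProteinQuant(
                protein_id=str(d["protein_id"]),
                gene_id=str(d["gene_id"]),
                ratio=ratio,
                intensity=intensity,
                ratio_count=rc,
                peptide_count=int(d["peptides"]),
                unique_peptide_count=int(d["unique_peptides"]),
            )
        )
    return quants


def write_transcript_table(tquants: Iterable[TranscriptQuant], path) -> None:
    pd.DataFrame(
        [(t.gene_id, t.log2_fc) for t in tquants],
        columns=["gene_id", "log2_fc"],
    ).to_csv(path, sep="\t", index=False)


def read_transcript_table(path) -> list[TranscriptQuant]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "log2_fc"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene row {dup!r}")
    return [
        TranscriptQuant(str(g), float(fc))
        for g, fc in zip(df["gene_id"], df["log2_fc"])
    ]


# ---------------------------------------------------------------- misc

def read_gene_list(path) -> set[str]:
    """One gene id per line; blank lines ignored."""
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
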