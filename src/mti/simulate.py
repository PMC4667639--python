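"""Ground-truthed synthetic inputs for the whole pipeline.

The generator emulates the study design end to end: a quantified
proteome of ~4,500 genes, a handful of miRNA seed families with planted
8mer/7mer-m8 sites in two-isoform 3' UTRs, SILAC-style H/L ratios with a
planted protein-level effect on *effective* targets, a null
control-vs-control proteome for cut-off calibration, transcript fold
changes, per-base coverage tracks for a "normal" and a "tumour" sample
with configurable proximal-usage shift, a jittered multi-tissue poly(A)
site list, and a TF (MYC) target list overlapping the miRNA targets.

Special gene roles planted in the truth:

* ``effective``          -- seed sites upstream of the proximal poly(A) site,
  protein ratio shifted down by ``protein_effect`` log2 units;
* ``escape``             -- seed sites *only* downstream of the proximal site
  with high proximal usage, protein unshifted: the 3' UTR-shortening
  escape pattern;
* ``transcriptome_only`` -- sites upstream, strong mRNA downregulation, but
  absent from the quantified proteome;
* ``background``         -- no sites, null everywhere.

Noise models are deliberately simple and stated: Normal log2 ratios,
Poisson per-base coverage, log-uniform intensities, Poisson ratio
counts.  Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .apa import CoverageTrack, PolyASite, TranscriptAnnot
from .expression import ProteinQuant, TranscriptQuant
from .seedscan import (
    MiRNAFamily,
    SeedSite,
    UTRIsoform,
    build_family_seeds,
    scan_utr,
)

__all__ = [
    "SimConfig",
    "GeneTruth",
    "GroundTruth",
    "ConfigError",
    "GenerationError",
    "default_mirna_records",
    "generate_truth",
    "emit_utrs",
    "emit_quant_tables",
    "emit_coverage_and_polya",
    "transcript_annotations",
    "coverage_array",
]


class ConfigError(ValueError):
    """Simulation parameter outside its documented range."""


class GenerationError(RuntimeError):
    """Rejection sampling exhausted its retry budget."""


#: Mature sequences of the miR-17-92 cluster members grouped into the four
#: seed families used throughout (members of a family share positions 2-8).
_DEFAULT_MIRNAS = (
    ("miR-17-5p", "CAAAGUGCUUACAGUGCAGGUAG", "miR-17"),
    ("miR-20a-5p", "UAAAGUGCUUAUAGUGCAGGUAG", "miR-17"),
    ("miR-18a-5p", "UAAGGUGCAUCUAGUGCAGAUAG", "miR-18"),
    ("miR-19a-3p", "UGUGCAAAUCUAUGCAAAACUGA", "miR-19"),
    ("miR-19b-3p", "UGUGCAAAUCCAUGCAAAACUGA", "miR-19"),
    ("miR-92a-3p", "UAUUGCACUUGUCCCGGCCUGU", "miR-92"),
)


def default_mirna_records() -> list[tuple[str, str, str]]:
    """(name, mature sequence, family) records for the default families."""
    return [tuple(r) for r in _DEFAULT_MIRNAS]


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: a ~4,500-gene quantified proteome with 148
    effective targets, a 40% TF-joint fraction among them, and a
    Normal(0, 0.1) log2-ratio null matching the calibration design."""

    n_genes: int = 4500
    n_effective_targets: int = 148
    n_escape_targets: int = 16
    n_transcriptome_only: int = 15
    joint_fraction: float = 0.4
    myc_background_fraction: float = 0.10

    protein_effect: float = 0.5     # delta, log2 units
    protein_noise: float = 0.1      # sigma of log2 ratios
    mrna_effect: float = 0.0        # delta_m, log2 units
    mrna_noise: float = 0.2
    mrna_strong_effect: float = 0.8  # transcriptome-only genes
    detection_probability: float = 0.93
    ratio_count_mean: float = 8.0
    peptide_count_mean: float = 7.0
    n_replicates: int = 2
    n_control_replicates: int = 3

    utr_proximal_range: tuple[int, int] = (300, 800)
    utr_extension_range: tuple[int, int] = (400, 1200)
    w_background: tuple[float, float] = (0.2, 0.6)
    w_joint: tuple[float, float] = (0.2, 0.5)
    w_nonjoint: tuple[float, float] = (0.4, 0.7)
    w_escape: tuple[float, float] = (0.85, 0.95)
    tumour_shift: float = 0.2
    tumour_shift_fraction: float = 0.5
    read_depth: float = 50.0
    coverage_noise: bool = True
    polya_jitter: int = 5
    n_tissues: int = 5

    def __post_init__(self) -> None:
        n_special = (
            self.n_effective_targets
            + self.n_escape_targets
            + self.n_transcriptome_only
        )
        if self.n_genes <= 0 or n_special > self.n_genes:
            raise ConfigError("special-role genes exceed n_genes")
        for name in ("joint_fraction", "myc_background_fraction",
                     "detection_probability", "tumour_shift_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("protein_noise", "mrna_noise", "protein_effect",
                     "mrna_effect", "mrna_strong_effect", "tumour_shift"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.read_depth <= 0:
            raise ConfigError("read_depth must be positive")
        for name in ("w_background", "w_joint", "w_nonjoint", "w_escape"):
            lo, hi = getattr(self, name)
            if not 0.0 <= lo <= hi <= 1.0:
                raise ConfigError(f"{name} range must satisfy 0<=lo<=hi<=1")
        if self.polya_jitter < 0 or self.polya_jitter * 2 >= 20:
            raise ConfigError("polya_jitter must keep clusters mergeable")

    def noise_free(self) -> "SimConfig":
        """Deterministic limit: no measurement noise, no dropout, no
        ratio-count masking -- planted truth should be recovered exactly."""
        return dataclasses.replace(
            self,
            protein_noise=0.0,
            mrna_noise=0.0,
            detection_probability=1.0,
            ratio_count_mean=30.0,
            coverage_noise=False,
        )


@dataclass
class GeneTruth:
    """Planted attributes of one gene."""

    gene_id: str
    role: str                   # background / effective / escape / transcriptome_only
    strand: str
    proximal_len: int           # local offset of the proximal poly(A) boundary
    distal_len: int             # total 3' UTR length (distal isoform)
    w_normal: float             # proximal-usage weight, normal sample
    w_tumour: float
    tumour_shifted: bool
    is_myc_target: bool
    detected_in_proteome: bool
    sites: tuple[tuple[int, str, str], ...] = ()  # (offset, site_type, family)

    @property
    def chrom(self) -> str:
        return self.gene_id

    @property
    def is_target(self) -> bool:
        return self.role != "background"


@dataclass
class GroundTruth:
    """Full planted truth: per-gene records plus the generating config."""

    config: SimConfig
    seed: int
    genes: list[GeneTruth]
    families: list[MiRNAFamily] = field(default_factory=list)

    def genes_with_role(self, role: str) -> list[GeneTruth]:
        return [g for g in self.genes if g.role == role]

    @property
    def myc_targets(self) -> set[str]:
        return {g.gene_id for g in self.genes if g.is_myc_target}

    def as_dict(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        return {
            "config": cfg,
            "seed": self.seed,
            "genes": [dataclasses.asdict(g) for g in self.genes],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), sort_keys=True))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def generate_truth(config: SimConfig, seed: int) -> GroundTruth:
    """Draw the planted truth (roles, geometry, usage weights, sites)."""
    rng = _rng(seed, 0)
    cfg = config
    families = build_family_seeds(default_mirna_records())
    fam_names = [f.name for f in families]

    perm = rng.permutation(cfg.n_genes)
    roles = np.full(cfg.n_genes, "background", dtype=object)
    k = 0
    for role, count in (
        ("effective", cfg.n_effective_targets),
        ("escape", cfg.n_escape_targets),
        ("transcriptome_only", cfg.n_transcriptome_only),
    ):
        roles[perm[k : k + count]] = role
        k += count

    effective_idx = perm[: cfg.n_effective_targets]
    n_joint = int(round(cfg.joint_fraction * cfg.n_effective_targets))
    joint_idx = set(effective_idx[:n_joint].tolist())

    genes: list[GeneTruth] = []
    for i in range(cfg.n_genes):
        gid = f"g{i:05d}"
        role = str(roles[i])
        lp = int(rng.integers(cfg.utr_proximal_range[0],
                              cfg.utr_proximal_range[1] + 1))
        ld = lp + int(rng.integers(cfg.utr_extension_range[0],
                                   cfg.utr_extension_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        is_joint = i in joint_idx
        if role == "escape":
            w_range = cfg.w_escape
        elif role == "effective":
            w_range = cfg.w_joint if is_joint else cfg.w_nonjoint
        else:
            w_range = cfg.w_background
        w = float(rng.uniform(*w_range))
        shifted = bool(rng.random() < cfg.tumour_shift_fraction)
        w_t = min(w + cfg.tumour_shift, 0.97) if shifted else w

        if is_joint:
            myc = True
        elif role == "effective":
            myc = False  # keeps the joint/non-joint usage groups clean
        else:
            myc = bool(rng.random() < cfg.myc_background_fraction)

        detected = role != "transcriptome_only" and bool(
            rng.random() < cfg.detection_probability
        )

        sites: tuple[tuple[int, str, str], ...] = ()
        if role != "background":
            region = (20, lp - 40) if role != "escape" else (lp + 20, ld - 40)
            sites = _plant_site_layout(rng, fam_names, region)

        genes.append(
            GeneTruth(
                gene_id=gid,
                role=role,
                strand=strand,
                proximal_len=lp,
                distal_len=ld,
                w_normal=w,
                w_tumour=w_t,
                tumour_shifted=shifted,
                is_myc_target=myc,
                detected_in_proteome=detected,
                sites=sites,
            )
        )
    return GroundTruth(config=cfg, seed=seed, genes=genes, families=families)


def _plant_site_layout(
    rng: np.random.Generator,
    fam_names: list[str],
    region: tuple[int, int],
) -> tuple[tuple[int, str, str], ...]:
    """Choose families, site types and non-overlapping offsets in region."""
    n_fams = int(rng.integers(1, 3))
    fams = list(rng.choice(fam_names, size=n_fams, replace=False))
    wanted = []
    for fam in fams:
        for _ in range(int(rng.integers(1, 3))):
            stype = "8mer" if rng.random() < 0.5 else "7mer-m8"
            wanted.append((stype, fam))
    lo, hi = region
    for _ in range(200):
        offs = sorted(int(rng.integers(lo, hi)) for _ in wanted)
        if all(b - a >= 12 for a, b in zip(offs, offs[1:])):
            return tuple(
                (o, stype, fam) for o, (stype, fam) in zip(offs, wanted)
            )
    raise GenerationError("could not place non-overlapping sites")


_BASES = np.array(list("ACGT"))


def emit_utrs(
    truth: GroundTruth, max_retries: int = 200
) -> tuple[list[UTRIsoform], list[SeedSite]]:
    """Emit two 3' UTR isoforms per gene plus the planted-site records.

    Background sequence is uniform ACGT, rejection-sampled so that it
    contains *no* seed match for any configured family; planted patterns
    are then written at the recorded offsets and the whole sequence is
    re-scanned -- the emitted scan result must equal the planted layout
    exactly, otherwise the gene is re-drawn.  Isoforms share the prefix
    up to the proximal poly(A) boundary.
    """
    rng = _rng(truth.seed, 1)
    fams = truth.families
    patterns = [f.pattern_7mer_m8 for f in fams]  # 8mer contains the 7mer
    isoforms: list[UTRIsoform] = []
    planted: list[SeedSite] = []
    for g in truth.genes:
        seq = _emit_gene_sequence(rng, g, fams, patterns, max_retries)
        iso_ids = (f"{g.gene_id}.1", f"{g.gene_id}.2")
        lp, ld = g.proximal_len, g.distal_len
        if g.strand == "+":
            spans = ((0, lp), (0, ld))
        else:
            spans = ((ld - lp, ld), (0, ld))
        isoforms.append(
            UTRIsoform(iso_ids[0], g.gene_id, seq[:lp], chrom=g.chrom,
                       strand=g.strand, start=spans[0][0], end=spans[0][1])
        )
        isoforms.append(
            UTRIsoform(iso_ids[1], g.gene_id, seq, chrom=g.chrom,
                       strand=g.strand, start=spans[1][0], end=spans[1][1])
        )
        for off, stype, fam in g.sites:
            width = 8 if stype == "8mer" else 7
            planted.append(
                SeedSite(iso_ids[1], g.gene_id, fam, stype, off, off + width)
            )
    return isoforms, planted


def _emit_gene_sequence(
    rng: np.random.Generator,
    g: GeneTruth,
    fams,
    patterns: list[str],
    max_retries: int,
) -> str:
    want = {(off, stype, fam) for off, stype, fam in g.sites}
    for _ in range(max_retries):
        arr = rng.choice(_BASES, size=g.distal_len)
        seq = "".join(arr)
        if any(p in seq for p in patterns):
            continue
        chars = list(seq)

        for off, stype, fam in g.sites:
            pat = next(f for f in fams if f.name == fam)
            pattern = pat.pattern_8mer if stype == "8mer" else pat.pattern_7mer_m8
            chars[off : off + len(pattern)] = pattern
            if stype == "7mer-m8":
                j = off + 7
                if j < g.distal_len and chars[j] == "A":
                    chars[j] = str(rng.choice(np.array(list("CGT"))))
        seq = "".join(chars)
        iso = UTRIsoform(f"{g.gene_id}.2", g.gene_id, seq)
        found = {(s.start, s.site_type, s.family) for s in scan_utr(iso, fams)}
        if found == want:
            return seq

    raise GenerationError(
        f"{g.gene_id}: could not emit a clean sequence in {max_retries} tries"
    )


def emit_quant_tables(
    truth: GroundTruth,
) -> tuple[list[ProteinQuant], list[ProteinQuant], list[TranscriptQuant]]:
    """Emit (functional proteome, control null proteome, transcript table).

    Functional replicates: log2 H/L ~ Normal(-delta * 1[effective], sigma).
    Control replicates:    log2 H/L ~ Normal(0, sigma) -- the WT:WT null.
    Escape genes are sequence-level targets but draw from the null.
    Transcript log2 FC ~ Normal(-delta_m * 1[effective], sigma_m), with a
    strong planted effect for transcriptome-only genes.
    """
    cfg = truth.config
    rng = _rng(truth.seed, 2)
    quants: list[ProteinQuant] = []
    controls: list[ProteinQuant] = []
    mrna: list[TranscriptQuant] = []
    reps = [f"rep{i+1}" for i in range(cfg.n_replicates)]
    creps = [f"ctrl{i+1}" for i in range(cfg.n_control_replicates)]
    for g in truth.genes:
        if g.detected_in_proteome:
            shift = cfg.protein_effect if g.role == "effective" else 0.0
            quants.append(
                _protein_row(rng, g.gene_id, reps, -shift, cfg)
            )
            controls.append(
                _protein_row(rng, g.gene_id, creps, 0.0, cfg)
            )
        if g.role == "transcriptome_only":
            mu = -cfg.mrna_strong_effect
        elif g.role == "effective":
            mu = -cfg.mrna_effect
        else:
            mu = 0.0
        mrna.append(
            TranscriptQuant(g.gene_id, float(rng.normal(mu, cfg.mrna_noise)))
        )
    return quants, controls, mrna


def _protein_row(
    rng: np.random.Generator,
    gene_id: str,
    reps: list[str],
    mu_log2: float,
    cfg: SimConfig,
) -> ProteinQuant:
    ratio, intensity, rc = {}, {}, {}
    for rep in reps:
        ratio[rep] = float(2.0 ** rng.normal(mu_log2, cfg.protein_noise))
        intensity[rep] = float(10.0 ** rng.uniform(6.0, 10.0))
        rc[rep] = int(rng.poisson(cfg.ratio_count_mean))
    peptides = 2 + int(rng.poisson(max(cfg.peptide_count_mean - 2.0, 0.0)))
    unique = 1 + int(rng.binomial(peptides - 1, 0.7))
    return ProteinQuant(
        protein_id=f"P_{gene_id}",
        gene_id=gene_id,
        ratio=ratio,
        intensity=intensity,
        ratio_count=rc,
        peptide_count=peptides,
        unique_peptide_count=unique,
    )


def coverage_array(
    g: GeneTruth,
    w: float,
    depth: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Genomic per-base coverage of one gene's 3' UTR locus.

    Local (transcription-direction) model: full depth up to the proximal
    poly(A) boundary, ``(1 - w) * depth`` between proximal and distal
    boundaries, zero beyond; optional Poisson noise per base.  Minus-strand
    genes are flipped into genomic orientation.
    """
    local = np.where(
        np.arange(g.distal_len) < g.proximal_len, depth, (1.0 - w) * depth
    )
    if rng is not None:
        local = rng.poisson(local).astype(float)
    return local[::-1].copy() if g.strand == "-" else local


def emit_coverage_and_polya(
    truth: GroundTruth,
    samples: tuple[str, ...] = ("normal", "tumour"),
) -> tuple[dict[str, dict[str, CoverageTrack]], list[PolyASite]]:
    """Emit per-sample coverage tracks and the jittered poly(A) site list.

    Each pseudo-tissue re-reports both true poly(A) positions with small
    (< 20 bp) positional jitter, exercising the merge step.
    """
    cfg = truth.config
    rng_cov = _rng(truth.seed, 3)
    rng_pa = _rng(truth.seed, 4)
    tracks: dict[str, dict[str, CoverageTrack]] = {s: {} for s in samples}
    for g in truth.genes:
        for sample in samples:
            w = g.w_tumour if sample == "tumour" else g.w_normal
            values = coverage_array(
                g, w, cfg.read_depth, rng_cov if cfg.coverage_noise else None
            )
            tracks[sample][g.chrom] = CoverageTrack(
                chrom=g.chrom, values=values, start=0, sample=sample
            )
    sites: list[PolyASite] = []
    tissues = [f"tissue{i+1}" for i in range(cfg.n_tissues)]
    for g in truth.genes:
        for local_pos in (g.proximal_len - 1, g.distal_len - 1):
            for tissue in tissues:
                j = int(rng_pa.integers(-cfg.polya_jitter, cfg.polya_jitter + 1))
                lp = int(np.clip(local_pos + j, 0, g.distal_len - 1))
                pos = lp if g.strand == "+" else g.distal_len - 1 - lp
                sites.append(
                    PolyASite(chrom=g.chrom, position=pos, strand=g.strand,
                              sources=(tissue,))
                )
    return tracks, sites


def transcript_annotations(truth: GroundTruth) -> list[TranscriptAnnot]:
    """Gene-level transcript models: the distal isoform spans the locus."""
    return [
        TranscriptAnnot(f"{g.gene_id}.2", g.chrom, 0, g.distal_len, g.strand)
        for g in truth.genes
    ]


def simulate_to_dir(config: SimConfig, seed: int, outdir) -> "GroundTruth":
    """Generate one full synthetic study and write every pipeline input.

    Writes utrs.fa, mirnas.tsv, sites_truth.bed, quant.tsv, control.tsv,
    mrna.tsv, coverage_<sample>.bedGraph, polya.bed, transcripts.bed,
    tf_myc.txt, truth.json and a ready-to-run pipeline.yaml.
    """
    from . import io
    from .config import PipelineConfig

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(config, seed)
    isoforms, planted = emit_utrs(truth)
    io.write_utr_fasta(isoforms, out / "utrs.fa")
    io.write_mirna_table(default_mirna_records(), out / "mirnas.tsv")
    io.write_sites_bed(planted, out / "sites_truth.bed")
    quants, controls, mrna = emit_quant_tables(truth)
    io.write_protein_table(quants, out / "quant.tsv")
    io.write_protein_table(controls, out / "control.tsv")
    io.write_transcript_table(mrna, out / "mrna.tsv")
    tracks, polya = emit_coverage_and_polya(truth)
    coverage_paths = {}
    for sample, per_chrom in tracks.items():
        p = out / f"coverage_{sample}.bedGraph"
        io.write_bedgraph(per_chrom, p)
        coverage_paths[sample] = str(p)
    io.write_polya_bed(polya, out / "polya.bed")
    io.write_transcripts_bed(transcript_annotations(truth), out / "transcripts.bed")
    io.write_gene_list(truth.myc_targets, out / "tf_myc.txt")
    truth.to_json(out / "truth.json")
    cfg = PipelineConfig(
        utrs=str(out / "utrs.fa"),
        mirnas=str(out / "mirnas.tsv"),
        quant=str(out / "quant.tsv"),
        control=str(out / "control.tsv"),
        mrna=str(out / "mrna.tsv"),
        polya=str(out / "polya.bed"),
        transcripts=str(out / "transcripts.bed"),
        coverage=coverage_paths,
        verdict_sample="tumour",
        tf_lists={"MYC": str(out / "tf_myc.txt")},
        outdir=str(out / "run"),
        seed=seed,
    )
    cfg.to_yaml(out / "pipeline.yaml")
    return truth
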