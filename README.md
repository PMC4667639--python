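# mti — integrated miRNA target identification in tumour cells

`mti` is a Python package for calling the direct targets of a miRNA
cluster in a cellular system by integrating four lines of evidence, the
way this is done in SILAC-proteomics studies of miRNA function:

1. **Unbiased seed scanning.** Every 3′ UTR isoform is searched for
   canonical seed-match sites of each miRNA seed family: **8mer** sites
   (reverse complement of miRNA positions 2–8 followed by an A) and
   **7mer-m8** sites (the 7-nt match alone). No conservation or context
   scoring — presence of a site is the hypothesis, not the verdict.
2. **Calibrated proteome response.** Protein H/L SILAC ratios from a
   miRNA-induction experiment are compared against a cut-off calibrated
   on a control-vs-control (null) proteome: proteins are ordered by MS
   intensity, split into equal-count bins of 300, the 0.5% and 99.5%
   empirical quantiles are taken per bin, and the responder cut-off is
   the **median of the per-bin quantiles**. A gene *responds* in a
   replicate when its ratio (supported by ≥3 ratio counts) falls
   strictly below the cut-off. Population-level repression of predicted
   targets vs non-targets is tested with a one-sided Kolmogorov–Smirnov
   comparison of ECDFs, at both the protein and the transcript level.
3. **3′ UTR shortening (alternative polyadenylation).** Strand-specific
   poly(A) sites are merged when closer than 20 bp, assigned to
   transcripts, and per-transcript proximal-site usage is summarized by

   *U* = (*A*_f − *A*_l) / *A*_f,

   where *A*_f and *A*_l are mean read coverages in 100-bp windows
   upstream of the first (proximal) and last (distal) poly(A) site.
   *U* ≈ 1 means the short-UTR isoform dominates. The same coverage
   grades each predicted site (YES / YES\* / NO / ND): a site in an
   abandoned distal region is **not** in the expressed transcript, so a
   gene can escape miRNA regulation by 3′ UTR shortening even though its
   genomic sequence carries a perfect seed match.
4. **Feed-forward loops.** Called targets are intersected with
   transcription-factor target lists (e.g. MYC ChIP targets) and tested
   for enrichment with a two-sided Fisher exact test; joint targets are
   compared with non-joint targets for proximal poly(A) usage
   (Mann–Whitney U test).

A gene's final class is the conjunction of evidence:
`high_confidence` (responder in ≥2 replicates + retained site),
`low_confidence` (responder in ≥1 replicate + retained site),
`transcriptome_only` (transcript responder with a retained site, absent
from the quantified proteome), or `non_target`. Responder rules never
fire without a retained site.

Because all of this is statistical machinery that can silently go wrong,
the package ships a first-class **synthetic-data generator**
(`mti.simulate`) that plants known targets, shortening-escape genes,
transcriptome-only targets and TF-joint structure into generated
FASTA/TSV/BED/bedGraph inputs, so every stage — and the full pipeline —
can be validated against ground truth with no external downloads.

## Worked example

Generate a 300-gene synthetic study (30 planted protein-level targets,
6 shortening-escape genes, 5 transcriptome-only targets) and run the
pipeline on it:

```bash
mti simulate --config sim300.yaml --seed 7 --outdir demo
mti run --config demo/pipeline.yaml
```

where `sim300.yaml` contains:

```yaml
n_genes: 300
n_effective_targets: 30
n_escape_targets: 6
n_transcriptome_only: 5
```

The run prints the class counts and writes `demo/run/summary.json`:

```text
{"high_confidence": 29, "low_confidence": 1, "transcriptome_only": 5, "non_target": 244}
cutoff_low 0.8301
ks 8mer protein p 1.38e-17   mrna p 0.406
paired wilcoxon (normal vs tumour U) p 1.36e-34
MYC ffl p 1.73e-05  table [[12, 18], [20, 224]]
joint vs non-joint usage MW p 2.53e-05
```

Reading this: the calibrated responder cut-off is H/L < 0.830 (a null
proteome with σ(log2) = 0.1 has its 0.5% quantile at 0.836); all 30
planted protein-level targets are recovered (29 in both replicates, 1 in
one), while all 6 escape genes are excluded because their sites grade
NO; predicted targets are repressed at the protein level (KS p ≈ 1e−17)
but not at the mRNA level (p ≈ 0.4); the tumour sample shows a global
shift toward proximal poly(A) usage; and the planted 40% MYC overlap is
recovered as a significant feed-forward-loop enrichment, with MYC-joint
targets showing longer expressed 3′ UTRs (lower *U*).

Each stage is also available separately (`mti scan`, `mti calibrate`,
`mti respond`, `mti apa`, `mti integrate`) and as library functions
(`mti.seedscan`, `mti.expression`, `mti.apa`, `mti.integration`).

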