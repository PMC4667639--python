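# Methods

This note documents the models, rules and numerical choices behind
`mti`, and what the synthetic-data generator does and does not emulate.

## Seed-site model

A miRNA *seed family* is a set of miRNAs sharing positions 2–8 of the
mature sequence (e.g. the miR-17 family comprising miR-17 and miR-20a;
the miR-19 family comprising miR-19a/b). For each family two
target-side patterns are derived: the 7mer-m8 (DNA reverse complement
of the seed) and the 8mer (7mer-m8 followed by `A`, the adenosine
opposite miRNA position 1). The scan reports **every** occurrence of
either pattern in a 3′ UTR isoform, including overlapping occurrences;
gene-level logic downstream only needs site presence, so collapsing is
deferred. Precedence: a location matching the 8mer is reported once, as
an 8mer only — otherwise the contained 7mer-m8 would be double-counted
and bias the per-class ECDF comparisons. `N` never matches
(conservative and deterministic). Coordinates are 0-based half-open
within the UTR sense strand; genome anchoring is optional metadata.
7mer-A1 and 6mer sites, conservation and context scores are explicitly
out of scope: the site classes analysed are 8mer and 7mer-m8 only.

## Responder cut-off calibration

The null model for technical variation is a control-vs-control SILAC
proteome. Each (protein, replicate) ratio with ≥3 ratio counts is one
observation; observations are ordered by MS intensity (ties broken by
protein id, then replicate, for determinism), cut into consecutive
equal-count bins of `bin_size = 300` (a trailing bin shorter than
`bin_size/2` merges into its predecessor), and the `q_low = 0.5%` /
`q_high = 99.5%` empirical quantiles are computed per bin. The
responder cut-offs are the medians of the per-bin quantiles. Equal-count
binning was chosen over equal-intensity-width binning because the
latter yields wildly unequal bins on log-uniform intensity data and
leaves extreme bins too small for a 0.5% quantile.

**Quantile estimator.** At p = 0.005 with n = 300, the quantile falls
between the 1st and 2nd order statistics, where interpolation rules
differ materially. Plain linear interpolation (the R/NumPy default) is
biased toward the distribution centre here, which would inflate the
realized null responder rate to ≈0.7% at a nominal 0.5%. The per-bin
quantiles therefore use the *normal-unbiased* (Hyndman–Fan type 9)
plotting position, the estimator designed to be approximately unbiased
for order statistics of Gaussian samples — matching the package's noise
model of Gaussian log-ratios. An analytic calibration study (expected
flag probability Φ(log₂ c / σ) over 3,000 simulated binned proteomes)
gives realized null rates of 0.0070 (type 7), 0.0048 (type 8), 0.0036
(type 6) and 0.0050 (type 9).

Only the lower cut-off defines responders; the upper one is computed
for symmetry and reported. Cut-offs are computed and applied on the
linear ratio scale. Replicates are kept separate — per-replicate calls
plus "either replicate" (union) and "both replicates" (intersection)
views — rather than averaging ratios. The boundary is strict: a ratio
exactly equal to the cut-off does not respond. Transcript responders
use log₂ FC strictly below −0.5; |log₂ FC| ≥ 1.5 is additionally
flagged as a transcriptome outlier.

## ECDF response testing

Repression of a target class is tested one-sidedly: D⁺ = sup_x
(F_target − F_nontarget), large when targets are shifted down. The p
value is the standard asymptotic bound exp(−2mnD²/(m+n)); when
min(n, m) ≤ 10 (and the label space is enumerable) the exact
permutation distribution over all label assignments is used instead.
No multiple-testing correction is applied across families or site
classes; raw p values are reported.

## Poly(A)-site usage

Sites are merged per (chrom, strand) transitively while adjacent
distance < 20 bp (strict inequality; 20 bp apart stays separate). The
merged representative is the interval midpoint — the input data are
silent on a canonical position, and the midpoint keeps the 100-bp
windows centred on the cluster. Windows are the 100 bp immediately
upstream of the representative in transcription direction, truncated at
the transcript boundary; a window with fewer than 20 evaluable bases
filters the transcript out rather than producing an unstable mean.
Transcripts need ≥2 assigned sites and mean coverage strictly >10 in at
least one sample. U = (A_f − A_l)/A_f; A_f = 0 leaves U undefined and
the transcript excluded (logged). For an ideal two-isoform mixture with
proximal weight w, U = w exactly; U is invariant to uniform coverage
scaling. Between-sample comparison is a two-sided Wilcoxon signed-rank
on paired U values (zero differences dropped; all-zero pairs are
degenerate with p = 1); group comparisons use a two-sided Mann–Whitney
with tie correction.

**Exact small-sample tests.** The signed-rank null is computed exactly
for n ≤ 25 informative pairs by dynamic-programming convolution over
doubled midranks (ties allowed); beyond that, the normal approximation
with continuity correction. Mann–Whitney is enumerated exactly over
label assignments while C(n+m, n) ≤ 20,000, otherwise asymptotic with
tie and continuity corrections.

## Expression verdicts for predicted sites

An automated surrogate for manual curation of site expression: with
r = (mean coverage over the site)/A_f, a site grades YES if r ≥ θ_hi
(default 0.5), YES\* if θ_lo ≤ r < θ_hi (default θ_lo = 0.2), NO if
r < θ_lo, and ND if it lies outside annotated transcript bounds or A_f
is unavailable. The defaults reproduce noise-free synthetic truth
exactly and are configurable. Sites on transcripts that fail the
coverage filters keep the verdict UNSET — absence of evidence, treated
as retained downstream, exactly as when no coverage data are supplied
at all ("unfiltered" mode).

## Target classes

Classes form a partition; the precedence is
high_confidence → low_confidence → transcriptome_only → non_target.
"Reproducibility across replicates" is implemented as responder-in-≥2-
replicates for the high-confidence class. YES\* counts as retained:
weak positive evidence keeps a site in play. Genes whose only sites
grade NO/ND are excluded from every target class regardless of
responder status — the 3′ UTR-shortening escape rule.

## Feed-forward loops

Enrichment of TF targets among miRNA targets uses a two-sided Fisher
exact test on the 2×2 table over a gene universe; the universe defaults
to the quantified proteome (the measurable set) and is configurable.
The odds ratio is reported uncorrected; when a cell is zero a
Haldane-corrected (+0.5) odds ratio is reported separately. The
MYC-joint / non-joint partition of called targets feeds the usage
comparison above.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* **Scale.** 4,500 genes (a quantified-proteome scale) with 148
  *effective* targets (protein log₂ ratio shifted by δ = 0.5), 16
  *escape* genes (sites only downstream of the proximal poly(A) site,
  proximal usage w ∈ [0.85, 0.95], protein unshifted), 15
  *transcriptome-only* targets (strong mRNA effect −0.8 log₂, absent
  from the proteome), and background genes.
* **Noise.** Log₂ ratios are Gaussian with σ = 0.1 (functional and
  control replicates alike); mRNA log₂ FC Gaussian with σ = 0.2 and
  zero mean effect by default — the protein-shift-without-mRNA-shift
  contrast; intensities log-uniform over 10⁶–10¹⁰; ratio counts
  Poisson(8), occasionally <3 to exercise masking; per-base coverage
  Poisson around an ideal two-isoform step profile at depth 50.
* **Geometry.** Two 3′ UTR isoforms per gene sharing a prefix up to the
  proximal poly(A) boundary (proximal length 300–800 bp, distal
  extension 400–1,200 bp), on a per-gene pseudo-contig with random
  strand. Background sequence is uniform ACGT rejection-sampled to
  contain no seed match for any configured family; planted patterns are
  written at recorded offsets and the sequence is re-scanned to verify
  the emitted layout equals the plan exactly.
* **Structure.** 40% of effective targets are MYC-joint and receive
  lower proximal usage (w ∈ [0.2, 0.5] vs [0.4, 0.7]); 10% of
  non-effective genes enter the MYC list as background. A "tumour"
  sample shifts w up by 0.2 for half the genes. Poly(A) sites are
  re-reported by five pseudo-tissues with ±5 bp jitter to exercise
  merging. Peptide counts are drawn so the ≥2-peptides/≥1-unique QC
  rule always passes (2 + Poisson, 1 + binomial): QC dropping is
  covered by unit tests on crafted rows, and keeping it out of the
  generator makes the zero-noise limit exactly recoverable.

Everything is deterministic given (config, seed); emitters draw from
independent, stream-indexed generators so each output file is
reproducible in isolation. `SimConfig.noise_free()` gives the
deterministic limit (σ = 0, no dropout, no masking, no coverage noise)
in which pipeline output must equal planted truth exactly.

**What passing tests do not show.** The generator uses uniform base
composition, independent Gaussian ratio noise, a clean two-isoform APA
model and exact identifier joins. Real data add conserved non-seed
matches, intensity-dependent ratio variance, multi-isoform UTR
structure, mapping biases and identifier ambiguity; recovery rates on
synthetic data are therefore upper bounds, not estimates, of
performance on a real study.

## Problem sizes used in validation

The test suite runs the scanner oracle on 1,000 random UTRs × 4
families, cut-off calibration and the KS contrast over 100 simulations
at the 4,500-gene scale, the merge oracle on 500 random instances,
exact-test oracles on 100 small instances each, and the full pipeline
end to end at the default scale plus its noise-free limit; power checks
of the feed-forward-loop and joint-target usage comparisons run the
generator across 100 seeds. Unit tests use a 250-gene scaled-down
configuration of the same structure.

## Known limitations

* The responder classes are gene-level; protein-group ambiguity
  (shared peptides) is not modelled — one protein id maps to one gene.
* The U statistic summarizes only the first and last poly(A) site;
  internal sites contribute to merging and counting but not to U.
* The one-sided KS asymptotic bound is conservative for very small
  samples; the exact path covers min(n, m) ≤ 10 only.
* The expression-verdict thresholds (θ_hi, θ_lo) are a stated surrogate
  for manual curation; they are exact on noise-free synthetic data but
  have no claim of matching any particular curator on real coverage.
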