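"""Integrated target calling and TF/miRNA feed-forward-loop enrichment.

A gene becomes a miRNA target only through the conjunction of evidence:
at least one seed-match site retained by the expression filter *and* a
responder call in the quantitative data.  Genes whose only sites are
graded NO/ND are excluded from every target class regardless of how far
their protein drops -- the shortening-escape pattern, where the repressed
isoform is simply not expressed.

Class vocabulary:

* ``high_confidence``   -- protein responder in >= 2 replicates, retained site;
* ``low_confidence``    -- protein responder in >= 1 replicate, retained site;
* ``transcriptome_only``-- transcript responder with a retained site but the
  gene was not quantified in the proteome;
* ``non_target``        -- everything else.

Feed-forward loops: a transcription factor that activates both the miRNA
cluster and the miRNA's targets.  Candidate loops are scored by the
overlap between the miRNA target set and a TF's target list over a gene
universe, with a two-sided Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seedscan import SeedSite
from .stats import fisher_exact_2x2

__all__ = [
    "TargetCall",
    "FFLResult",
    "UniverseError",
    "CLASS_LABELS",
    "RETAINED_VERDICTS",
    "best_verdicts_by_gene",
    "call_targets",
    "ffl_enrichment",
    "joint_target_report",
]

logger = logging.getLogger(__name__)

CLASS_LABELS = (
    "high_confidence",
    "low_confidence",
    "transcriptome_only",
    "non_target",
)

#: Verdicts that keep a site in play.  YES* counts as retained (weak but
#: positive evidence); UNSET is retained because it means the expression
#: filter was never run, not that it failed.
RETAINED_VERDICTS = frozenset({"YES", "YES*", "UNSET"})

_VERDICT_RANK = {"YES": 0, "YES*": 1, "UNSET": 2, "NO": 3, "ND": 4}


class UniverseError(ValueError):
    """A gene set is not contained in the stated universe."""


@dataclass
class TargetCall:
    """One gene's integrated verdict with the provenance of each rule."""

    gene_id: str
    families_with_sites: frozenset[str]
    best_verdict_by_family: dict[str, str]
    protein_responder_reps: frozenset[str]
    transcript_responder: bool
    class_label: str
    rules_fired: tuple[str, ...] = ()


@dataclass
class FFLResult:
    """Fisher-exact enrichment of one TF's targets among miRNA targets."""

    tf_name: str
    contingency: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    odds_ratio_haldane: float | None
    p_value: float
    significant: bool

    def as_dict(self) -> dict:
        return {
            "tf_name": self.tf_name,
            "contingency": [list(r) for r in self.contingency],
            "odds_ratio": self.odds_ratio,
            "odds_ratio_haldane": self.odds_ratio_haldane,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def best_verdicts_by_gene(
    sites: Iterable[SeedSite],
) -> dict[str, dict[str, str]]:
    """Best expression verdict per (gene, family) over all isoform sites."""
    best: dict[str, dict[str, str]] = {}
    for s in sites:
        fam = best.setdefault(s.gene_id, {})
        cur = fam.get(s.family)
        if cur is None or _VERDICT_RANK[s.expression_verdict] < _VERDICT_RANK[cur]:
            fam[s.family] = s.expression_verdict
    return best


def call_targets(
    sites: Iterable[SeedSite],
    protein_responders: Mapping[str, set[str]],
    transcript_responders: set[str],
    proteome_genes: set[str],
    min_reps_high: int = 2,
) -> list[TargetCall]:
    """Assign every gene exactly one target class.

    The gene universe is the union of genes with sites, genes in the
    quantified proteome and transcript responders.  Responder rules never
    fire without a retained site.
    """
    verdicts = best_verdicts_by_gene(sites)
    genes = sorted(
        set(verdicts) | set(proteome_genes) | set(transcript_responders)
    )
    calls: list[TargetCall] = []
    for g in genes:
        fam_verdicts = verdicts.get(g, {})
        retained = {
            f for f, v in fam_verdicts.items() if v in RETAINED_VERDICTS
        }
        reps = frozenset(protein_responders.get(g, set()))
        t_resp = g in transcript_responders
        rules: list[str] = []
        if fam_verdicts and not retained:
            rules.append("all_sites_filtered_out")
        if retained:
            rules.append("retained_site")
        if reps:
            rules.append(f"protein_responder_{len(reps)}_reps")
        if t_resp:
            rules.append("transcript_responder")

        if retained and len(reps) >= min_reps_high:
            label = "high_confidence"
        elif retained and len(reps) >= 1:
            label = "low_confidence"
        elif retained and t_resp and g not in proteome_genes:
            label = "transcriptome_only"
            rules.append("absent_from_proteome")
        else:
            label = "non_target"
        calls.append(
            TargetCall(
                gene_id=g,
                families_with_sites=frozenset(fam_verdicts),
                best_verdict_by_family=dict(fam_verdicts),
                protein_responder_reps=reps,
                transcript_responder=t_resp,
                class_label=label,
                rules_fired=tuple(rules),
            )
        )
    return calls


def ffl_enrichment(
    mirna_targets: set[str],
    tf_targets: set[str],
    universe: set[str],
    tf_name: str = "TF",
    alpha: float = 0.05,
) -> FFLResult:
    """Two-sided Fisher exact test on the miRNA-target x TF-target table.

    The 2x2 table over the universe is [[joint, miR-only], [TF-only,
    neither]].  The odds ratio is reported uncorrected; when any cell is
    zero a Haldane-corrected (+0.5 per cell) odds ratio is reported
    alongside, never inside, the table.
    """
    if not mirna_targets <= universe:
        raise UniverseError("miRNA target set not contained in universe")
    if not tf_targets <= universe:
        raise UniverseError("TF target set not contained in universe")
    a = len(mirna_targets & tf_targets)
    b = len(mirna_targets - tf_targets)
    c = len(tf_targets - mirna_targets)
    d = len(universe) - a - b - c
    table = ((a, b), (c, d))
    odds, p = fisher_exact_2x2(table)
    haldane = None
    if min(a, b, c, d) == 0:
        haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return FFLResult(
        tf_name=tf_name,
        contingency=table,
        odds_ratio=odds,
        odds_ratio_haldane=haldane,
        p_value=p,
        significant=p < alpha,
    )


def joint_target_report(
    target_calls: Sequence[TargetCall],
    tf_lists: Mapping[str, set[str]],
    universe: set[str],
    partition_tf: str = "MYC",
    target_classes: tuple[str, ...] = ("high_confidence", "low_confidence"),
    alpha: float = 0.05,
) -> tuple[dict[str, FFLResult], set[str], set[str]]:
    """Per-TF feed-forward-loop enrichment plus the joint/non-joint split.

    Returns ``(results_by_tf, joint, non_joint)`` where the partition
    divides the called miRNA targets into those also on ``partition_tf``'s
    list ("co-regulated") and those with no such evidence; downstream the
    partition feeds the usage comparison of 3' UTR lengths.
    """
    targets = {
        c.gene_id for c in target_calls if c.class_label in target_classes
    } & universe
    results: dict[str, FFLResult] = {}
    for name, tf_set in tf_lists.items():
        if not tf_set:
            logger.warning("TF list %r is empty; skipped", name)
            continue
        results[name] = ffl_enrichment(
            targets, tf_set & universe, universe, tf_name=name, alpha=alpha
        )
    joint: set[str] = set()
    non_joint = set(targets)
    if partition_tf in tf_lists:
        joint = targets & tf_lists[partition_tf]
        non_joint = targets - joint
    return results, joint, non_joint
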