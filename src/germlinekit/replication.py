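"""Cross-cohort replication and novel predisposition-gene calling.

Replication intersects the deleterious gene and variant sets of a discovery
and a validation cohort.  Novel-gene calling pools the significantly enriched
variants of both cohorts and reports genes that (i) harbor at least one
variant with q <= 0.05 and OR >= 1 in either cohort (optionally both),
(ii) are not DNA-damage-repair genes, and (iii) are absent from the supplied
list of previously reported predisposition genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set

from .enrichment import EnrichmentResult
from .summary import percent

__all__ = ["ReplicationReport", "intersect_cohorts", "call_novel_genes"]


@dataclass
class ReplicationReport:
    shared_genes: Set[str]
    shared_variants: Set
    discovery_fraction: float  # percent, 1 dp
    validation_fraction: float
    novel_genes: Dict[str, List[EnrichmentResult]] = field(default_factory=dict)


def intersect_cohorts(
    genes_a: Set[str],
    genes_b: Set[str],
    variants_a: Set,
    variants_b: Set,
) -> ReplicationReport:
    """Exact set intersections with one-decimal percent fractions.

    Fractions are shared genes over each cohort's deleterious gene count
    (7 of 25 -> 28.0, 7 of 28 -> 25.0).
    """
    shared_genes = set(genes_a) & set(genes_b)
    shared_variants = set(variants_a) & set(variants_b)
    return ReplicationReport(
        shared_genes=shared_genes,
        shared_variants=shared_variants,
        discovery_fraction=percent(len(shared_genes), len(genes_a)) if genes_a else 0.0,
        validation_fraction=percent(len(shared_genes), len(genes_b)) if genes_b else 0.0,
    )


def call_novel_genes(
    sig_a: Sequence[EnrichmentResult],
    sig_b: Sequence[EnrichmentResult],
    known_predisposition: Set[str],
    ddr_flags: Dict[str, bool],
    *,
    q_cutoff: float = 0.05,
    require_both: bool = False,
) -> Dict[str, List[EnrichmentResult]]:
    """Genes with enriched variants that are non-DDR and not previously reported.

    ``ddr_flags`` must cover every gene appearing in the enrichment results
    (missing flags are an error: silently assuming non-DDR would inflate the
    novel list).  With ``require_both`` a gene must reach significance in
    both cohorts rather than either.
    """

    def qualifying(results: Sequence[EnrichmentResult]) -> Dict[str, List[EnrichmentResult]]:
        out: Dict[str, List[EnrichmentResult]] = {}
        for r in results:
            if r.gene is None:
                continue
            if r.q <= q_cutoff and r.or_point >= 1.0:
                out.setdefault(r.gene, []).append(r)
        return out

    hits_a = qualifying(sig_a)
    hits_b = qualifying(sig_b)
    if require_both:
        candidate_genes = set(hits_a) & set(hits_b)
    else:
        candidate_genes = set(hits_a) | set(hits_b)

    novel: Dict[str, List[EnrichmentResult]] = {}
    for gene in sorted(candidate_genes):
        if gene not in ddr_flags:
            raise ValueError(f"gene {gene} has no DDR flag")
        if ddr_flags[gene]:
            continue
        if gene in known_predisposition:
            continue
        novel[gene] = hits_a.get(gene, []) + hits_b.get(gene, [])
    return novel
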