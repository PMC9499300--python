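"""End-to-end orchestration: filter -> panel -> classify -> enrich -> summarize.

`run_cohort` executes the single-cohort pipeline on in-memory objects;
`run_study` runs both cohorts of a paired study and adds replication,
novel-gene calling and the cross-cohort metastasis model.  The CLI and the
synthetic end-to-end tests are thin layers over these two functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from . import acmg
from .enrichment import EnrichmentResult, run_enrichment
from .filtering import FilterConfig, FilterReport, apply_qc_filters, intersect_panel
from .io_formats import ReferenceTable
from .models import ModelEval, cross_cohort_evaluate, make_feature_table
from .replication import ReplicationReport, call_novel_genes, intersect_cohorts
from .summary import CohortReport, build_cohort_report
from .types import ClinicalRecord, PanelGene, VariantRecord

__all__ = ["CohortResult", "StudyResult", "run_cohort", "run_study"]

logger = logging.getLogger(__name__)


@dataclass
class CohortResult:
    roster: List[str]
    filter_report: FilterReport
    panel_variants: List[VariantRecord]
    classifications: Dict[tuple, acmg.Classification]
    deleterious: List[VariantRecord]
    vus: List[VariantRecord]
    enrichment: List[EnrichmentResult] = field(default_factory=list)
    significant: List[EnrichmentResult] = field(default_factory=list)
    report: Optional[CohortReport] = None

    @property
    def deleterious_genes(self) -> Set[str]:
        return {v.gene for v in self.deleterious if v.gene}

    @property
    def deleterious_variant_keys(self) -> Set[tuple]:
        return {v.key for v in self.deleterious}


def run_cohort(
    variants: Sequence[VariantRecord],
    roster: Sequence[str],
    panel: Sequence[PanelGene],
    reference: ReferenceTable,
    *,
    filter_config: FilterConfig = FilterConfig(),
    fdr_cutoff: float = 0.05,
    adjust_method: str = "fdr_bh",
) -> CohortResult:
    """Run the full single-cohort pipeline.

    Classification uses evidence codes from the annotation when present,
    otherwise the minimal default assigner (loss-of-function consequences are
    treated as acting through a LoF mechanism for panel genes).  Enrichment
    is computed over the deleterious variants.
    """
    qc_passed, report = apply_qc_filters(variants, filter_config)
    panel_variants = intersect_panel(qc_passed, panel, report)

    panel_by_symbol = {g.symbol: g for g in panel}
    classifications: Dict[tuple, acmg.Classification] = {}
    deleterious: List[VariantRecord] = []
    vus: List[VariantRecord] = []
    for v in panel_variants:
        evidence = tuple(code for code in v.evidence if code in acmg.ALL_CODES)
        if not evidence:
            evidence = acmg.assign_default_evidence(
                v, panel_by_symbol.get(v.gene), reference.lookup(v.key),
                lof_mechanism=True,
            )
        cls = acmg.classify(evidence)
        classifications[v.key] = cls
        if cls.tier3 == "deleterious":
            deleterious.append(v)
        elif cls.tier3 == "VUS":
            vus.append(v)

    enrichment: List[EnrichmentResult] = []
    significant: List[EnrichmentResult] = []
    if deleterious:
        enrichment, significant = run_enrichment(
            deleterious, len(roster), reference,
            fdr_cutoff=fdr_cutoff, method=adjust_method,
        )
    report_summary = build_cohort_report(deleterious, roster)
    return CohortResult(
        roster=list(roster),
        filter_report=report,
        panel_variants=panel_variants,
        classifications=classifications,
        deleterious=deleterious,
        vus=vus,
        enrichment=enrichment,
        significant=significant,
        report=report_summary,
    )


@dataclass
class StudyResult:
    discovery: CohortResult
    validation: CohortResult
    replication: ReplicationReport
    novel_genes: Dict[str, List[EnrichmentResult]]
    model_eval: Optional[Tuple[ModelEval, ModelEval]] = None


def run_study(
    discovery: CohortResult,
    validation: CohortResult,
    panel: Sequence[PanelGene],
    known_predisposition: Set[str],
    *,
    clinical_discovery: Optional[Sequence[ClinicalRecord]] = None,
    clinical_validation: Optional[Sequence[ClinicalRecord]] = None,
    model_genes: Sequence[str] = (),
    require_both: bool = False,
) -> StudyResult:
    """Replication, novel-gene calling and (optionally) the metastasis model."""
    replication = intersect_cohorts(
        discovery.deleterious_genes, validation.deleterious_genes,
        discovery.deleterious_variant_keys, validation.deleterious_variant_keys,
    )
    ddr_flags = {g.symbol: g.is_ddr for g in panel}
    novel = call_novel_genes(
        discovery.enrichment, validation.enrichment,
        known_predisposition, ddr_flags, require_both=require_both,
    )
    replication.novel_genes = novel

    model_eval = None
    if model_genes and clinical_discovery is not None and clinical_validation is not None:
        def vus_carriers(result: CohortResult) -> Dict[str, set]:
            carriers: Dict[str, set] = {}
            for v in result.vus:
                if v.gene:
                    carriers.setdefault(v.gene, set()).update(v.carriers)
            return carriers

        train = make_feature_table(clinical_discovery, vus_carriers(discovery), model_genes)
        test = make_feature_table(clinical_validation, vus_carriers(validation), model_genes)
        features = ["psa", "isup"] + list(model_genes)
        model_eval = cross_cohort_evaluate(train, test, features, ["psa", "isup"])

    return StudyResult(
        discovery=discovery,
        validation=validation,
        replication=replication,
        novel_genes=novel,
        model_eval=model_eval,
    )
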