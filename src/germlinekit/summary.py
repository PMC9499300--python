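"""Cohort-level summaries of deleterious variants and clinical associations.

Covers carrier statistics (including patients carrying two variants),
mutation-type spectrum, pathway burden at the variant and the patient level,
recurrent variants, and carrier-vs-non-carrier association tests (Fisher
exact for dichotomous traits, Wilcoxon rank-sum for continuous/ordinal
traits).  Percentages are rounded half-up to one decimal, matching the usual
reporting style (33.3%, 30.6%, 25.1%).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from scipy import stats

from .enrichment import ContingencyTable, odds_ratio_ci
from .types import ClinicalRecord, VariantRecord

__all__ = [
    "percent",
    "CarrierStats",
    "CohortReport",
    "summarize_carriers",
    "mutation_spectrum",
    "tier_shares",
    "pathway_burden",
    "find_recurrent",
    "associate_clinical",
    "build_cohort_report",
    "oncoprint_matrix",
]


def percent(count: float, total: float, digits: int = 1) -> float:
    """Percentage rounded half-up to ``digits`` decimals (2475/4205 -> 58.9)."""
    if total == 0:
        return 0.0
    quantum = Decimal(1).scaleb(-digits)
    return float(
        (Decimal(count) / Decimal(total) * 100).quantize(quantum, rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class CarrierStats:
    n_patients: int
    n_variants: int
    n_carriers: int
    n_dual_carriers: int
    per_patient: Mapping[str, int]

    @property
    def carrier_percent(self) -> float:
        return percent(self.n_carriers, self.n_patients)


def summarize_carriers(
    deleterious: Sequence[VariantRecord], roster: Sequence[str]
) -> CarrierStats:
    """Distinct carriers and multi-variant carriers among the roster.

    ``n_dual_carriers`` counts patients carrying two or more deleterious
    variants.  A carrier absent from the roster is an error.
    """
    roster_set = set(roster)
    per_patient: Counter = Counter()
    for v in deleterious:
        stray = v.carriers - roster_set
        if stray:
            raise ValueError(f"carrier(s) {sorted(stray)} of {v.label} not in roster")
        for sample in v.carriers:
            per_patient[sample] += 1
    n_carriers = len(per_patient)
    n_dual = sum(1 for n in per_patient.values() if n >= 2)
    return CarrierStats(
        n_patients=len(roster_set),
        n_variants=len(deleterious),
        n_carriers=n_carriers,
        n_dual_carriers=n_dual,
        per_patient=dict(per_patient),
    )


def mutation_spectrum(
    deleterious: Sequence[VariantRecord],
) -> Dict[str, Tuple[int, float]]:
    """Consequence-class counts and one-decimal percentages of the input."""
    total = len(deleterious)
    counts = Counter(v.consequence or "other" for v in deleterious)
    return {
        consequence: (count, percent(count, total))
        for consequence, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }


def tier_shares(tier3_labels: Sequence[str]) -> Dict[str, Tuple[int, float]]:
    """Counts and percentages of deleterious / VUS / benign labels."""
    total = len(tier3_labels)
    counts = Counter(tier3_labels)
    return {label: (counts.get(label, 0), percent(counts.get(label, 0), total))
            for label in ("deleterious", "VUS", "benign")}


def pathway_burden(
    deleterious: Sequence[VariantRecord], n_patients: int
) -> Tuple[Dict[str, Tuple[int, float]], Dict[str, Tuple[int, float]]]:
    """Pathway fractions over variants and over patients.

    Variant-level fractions are out of the number of deleterious variants;
    patient-level fractions count the union of carriers of the pathway's
    variants out of the cohort size (a patient carrying variants in two
    pathways counts once per pathway).  Unlabeled genes fall into "other".
    """
    n_variants = len(deleterious)
    variant_counts: Counter = Counter()
    pathway_carriers: Dict[str, Set[str]] = {}
    for v in deleterious:
        pathway = v.pathway or "other"
        variant_counts[pathway] += 1
        pathway_carriers.setdefault(pathway, set()).update(v.carriers)
    variant_fractions = {
        pw: (n, percent(n, n_variants))
        for pw, n in sorted(variant_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }
    patient_fractions = {
        pw: (len(carriers), percent(len(carriers), n_patients))
        for pw, carriers in sorted(
            pathway_carriers.items(), key=lambda kv: (-len(kv[1]), kv[0])
        )
    }
    return variant_fractions, patient_fractions


def find_recurrent(deleterious: Sequence[VariantRecord]) -> Dict[str, int]:
    """Variants carried by two or more distinct patients (rsid or key label)."""
    out = {}
    for v in deleterious:
        n = len(v.carriers)  # carriers is a set: one patient counts once
        if n >= 2:
            out[v.rsid or v.label] = n
    return dict(sorted(out.items(), key=lambda kv: (-kv[1], kv[0])))


@dataclass(frozen=True)
class AssociationResult:
    trait: str
    kind: str  # "fisher" or "wilcoxon"
    p: float
    or_point: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def _wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum p: exact for small untied samples, normal
    approximation with tie correction otherwise."""
    n = len(x) + len(y)
    has_ties = len(set(list(x) + list(y))) < n
    method = "exact" if (n <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.pvalue)


def associate_clinical(
    carrier_flags: Mapping[str, bool], clinical: Sequence[ClinicalRecord]
) -> List[AssociationResult]:
    """Carrier vs non-carrier association for each clinical characteristic.

    Dichotomous traits (metastasis, castration resistance within one year)
    get a Fisher exact p and a continuity-corrected OR; continuous/ordinal
    traits (age, PSA, ISUP grade) get a Wilcoxon rank-sum p.
    """
    carriers = [c for c in clinical if carrier_flags.get(c.sample_id, False)]
    non_carriers = [c for c in clinical if not carrier_flags.get(c.sample_id, False)]
    if not carriers or not non_carriers:
        raise ValueError("need at least one carrier and one non-carrier")

    results: List[AssociationResult] = []
    for trait, getter in (("age", lambda c: c.age), ("psa", lambda c: c.psa),
                          ("isup", lambda c: c.isup)):
        p = _wilcoxon_rank_sum([getter(c) for c in carriers],
                               [getter(c) for c in non_carriers])
        results.append(AssociationResult(trait=trait, kind="wilcoxon", p=p))

    def dichotomous(trait: str, flag) -> Optional[AssociationResult]:
        car = [flag(c) for c in carriers if flag(c) is not None]
        non = [flag(c) for c in non_carriers if flag(c) is not None]
        if not car or not non:
            return None
        table = ContingencyTable(
            a=sum(car), b=len(car) - sum(car), c=sum(non), d=len(non) - sum(non)
        )
        _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]])
        or_point, lo, hi, _ = odds_ratio_ci(table)
        return AssociationResult(trait=trait, kind="fisher", p=float(p),
                                 or_point=or_point, ci_low=lo, ci_high=hi)

    for trait, flag in (
        ("metastasis", lambda c: c.metastasis == "M1"),
        ("crpc_within_1yr", lambda c: c.crpc_within_1yr),
    ):
        res = dichotomous(trait, flag)
        if res is not None:
            results.append(res)
    return results


@dataclass
class CohortReport:
    """Bundle of per-cohort summaries."""

    n_patients: int
    n_deleterious_variants: int
    n_carriers: int
    n_dual_carriers: int
    spectrum: Dict[str, Tuple[int, float]]
    pathway_variant_fractions: Dict[str, Tuple[int, float]]
    pathway_patient_fractions: Dict[str, Tuple[int, float]]
    recurrent_variants: Dict[str, int]
    deleterious_genes: Set[str] = field(default_factory=set)

    @property
    def carrier_percent(self) -> float:
        return percent(self.n_carriers, self.n_patients)

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_deleterious_variants": self.n_deleterious_variants,
            "n_carriers": self.n_carriers,
            "carrier_percent": self.carrier_percent,
            "n_dual_carriers": self.n_dual_carriers,
            "spectrum": {k: list(v) for k, v in self.spectrum.items()},
            "pathway_variant_fractions": {k: list(v) for k, v in self.pathway_variant_fractions.items()},
            "pathway_patient_fractions": {k: list(v) for k, v in self.pathway_patient_fractions.items()},
            "recurrent_variants": self.recurrent_variants,
            "deleterious_genes": sorted(self.deleterious_genes),
        }


def build_cohort_report(
    deleterious: Sequence[VariantRecord], roster: Sequence[str]
) -> CohortReport:
    stats_ = summarize_carriers(deleterious, roster)
    variant_fr, patient_fr = pathway_burden(deleterious, stats_.n_patients)
    return CohortReport(
        n_patients=stats_.n_patients,
        n_deleterious_variants=stats_.n_variants,
        n_carriers=stats_.n_carriers,
        n_dual_carriers=stats_.n_dual_carriers,
        spectrum=mutation_spectrum(deleterious),
        pathway_variant_fractions=variant_fr,
        pathway_patient_fractions=patient_fr,
        recurrent_variants=find_recurrent(deleterious),
        deleterious_genes={v.gene for v in deleterious if v.gene},
    )


def oncoprint_matrix(deleterious: Sequence[VariantRecord], roster: Sequence[str]):
    """Patients x genes mutation matrix (consequence class, or "" if none)."""
    import pandas as pd

    genes = sorted({v.gene for v in deleterious if v.gene})
    matrix = pd.DataFrame("", index=list(roster), columns=genes)
    for v in deleterious:
        if not v.gene:
            continue
        for sample in v.carriers:
            existing = matrix.at[sample, v.gene]
            label = v.consequence or "other"
            matrix.at[sample, v.gene] = f"{existing};{label}" if existing else label
    matrix.index.name = "sample_id"
    return matrix
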