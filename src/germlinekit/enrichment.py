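"""Per-variant case-vs-reference enrichment statistics.

For each variant a 2x2 table of alternate versus non-alternate allele counts
(cohort vs population reference) is tested with the two-sided Fisher exact
test; p-values are adjusted across the variants of one run with the
Benjamini-Hochberg step-up (Bonferroni optional); odds ratios use the
Haldane-Anscombe continuity correction (0.5 added to every cell when any
cell is zero) with Woolf logit 95% confidence intervals.  The correction
applies to the OR/CI only -- p-values always come from the raw integer table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ReferenceCount, VariantRecord
from .io_formats import ReferenceTable

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "build_contingency",
    "fisher_exact_two_sided",
    "odds_ratio_ci",
    "adjust_fdr",
    "run_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a/b = case alt / non-alt, c/d = reference alt / non-alt."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {value!r}")

    @property
    def cells(self) -> Tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def case_freq(self) -> float:
        return self.a / (self.a + self.b) if (self.a + self.b) else 0.0

    @property
    def ref_freq(self) -> float:
        return self.c / (self.c + self.d) if (self.c + self.d) else 0.0


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-variant enrichment statistics."""

    key: tuple
    gene: Optional[str]
    table: ContingencyTable
    p: float
    q: float
    or_point: float
    ci_low: float
    ci_high: float
    corrected: bool
    significant: bool = False
    is_ddr: Optional[bool] = None


def build_contingency(
    v: VariantRecord,
    n_cases: int,
    ref: ReferenceCount,
    mode: str = "allele",
) -> ContingencyTable:
    """Build the case-vs-reference 2x2 table.

    Allele mode counts alternate alleles against 2*n_cases chromosomes and
    uses the reference AC/AN directly.  Carrier mode counts carrier
    individuals against n_cases, treating the reference AC as a carrier
    estimate out of AN/2 individuals.
    """
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    if mode == "allele":
        a = v.n_alt_alleles if v.n_alt_alleles is not None else len(v.carriers)
        total = 2 * n_cases
        if a > total:
            raise ValueError(f"alt allele count {a} exceeds 2*n_cases={total}")
        return ContingencyTable(a=int(a), b=total - int(a), c=ref.ac, d=ref.an - ref.ac)
    if mode == "carrier":
        a = len(v.carriers)
        if a > n_cases:
            raise ValueError(f"carrier count {a} exceeds n_cases={n_cases}")
        n_ref = ref.an // 2
        c = min(ref.ac, n_ref)
        return ContingencyTable(a=a, b=n_cases - a, c=c, d=n_ref - c)
    raise ValueError(f"unknown mode {mode!r}")


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    same-margin tables no more probable than the observed one."""
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(min(p, 1.0))


def odds_ratio_ci(
    t: ContingencyTable, alpha: float = 0.05
) -> Tuple[float, float, float, bool]:
    """Odds ratio with Woolf logit CI; Haldane-Anscombe corrected when needed.

    When any cell is zero, 0.5 is added to every cell before computing both
    the point estimate and the interval.  Returns
    ``(or_point, ci_low, ci_high, corrected)``.
    """
    a, b, c, d = t.cells
    if a + b + c + d == 0:
        raise ValueError("all-zero table has no odds ratio")
    corrected = 0 in t.cells
    if corrected:
        a, b, c, d = (x + 0.5 for x in t.cells)
    or_point = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    ci_low = math.exp(math.log(or_point) - z * se)
    ci_high = math.exp(math.log(or_point) + z * se)
    return or_point, ci_low, ci_high, corrected


def adjust_fdr(pvalues: Sequence[float], method: str = "fdr_bh") -> List[float]:
    """Benjamini-Hochberg step-up q-values (or Bonferroni) in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown adjustment method {method!r}")
    _, q, _, _ = multipletests(p, method=method)
    return [float(x) for x in q]


def run_enrichment(
    variants: Sequence[VariantRecord],
    n_cases: int,
    reference: ReferenceTable,
    *,
    fdr_cutoff: float = 0.05,
    mode: str = "allele",
    method: str = "fdr_bh",
    use_raw_p: bool = False,
) -> Tuple[List[EnrichmentResult], List[EnrichmentResult]]:
    """Test every variant against the reference; flag the significant subset.

    A variant is significant when its adjusted q (or raw p when
    ``use_raw_p``, the convention used for VUS-level screens) is at or below
    the cutoff AND its case allele frequency exceeds the reference frequency.
    The adjustment spans exactly the variants tested in this run.
    """
    if not variants:
        logger.warning("run_enrichment called with no variants")
        return [], []
    tables = []
    for v in variants:
        ref = reference.lookup(v.key)
        tables.append(build_contingency(v, n_cases, ref, mode=mode))
    pvals = [fisher_exact_two_sided(t) for t in tables]
    qvals = adjust_fdr(pvals, method=method)
    results: List[EnrichmentResult] = []
    for v, t, p, q in zip(variants, tables, pvals, qvals):
        or_point, lo, hi, corrected = odds_ratio_ci(t)
        stat = p if use_raw_p else q
        significant = stat <= fdr_cutoff and t.case_freq > t.ref_freq
        results.append(
            EnrichmentResult(
                key=v.key, gene=v.gene, table=t, p=p, q=q,
                or_point=or_point, ci_low=lo, ci_high=hi,
                corrected=corrected, significant=significant, is_ddr=v.is_ddr,
            )
        )
    significant = [r for r in results if r.significant]
    logger.info("enrichment: %d variants tested, %d significant", len(results), len(significant))
    return results, significant
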