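"""Five-criterion QC cascade and predisposition-panel intersection.

Variants are retained when they are (i) rare in every available East Asian
population source (MAF below the threshold, absent sources counted as 0),
(ii) exonic, (iii) covered above the depth threshold, (iv) free of strand
bias under the selected convention, and (v) supported by at least one carrier
allele fraction above the VAF threshold.  The cascade is applied in that
order for reporting; the final retained set is order-independent because each
criterion is per-variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .types import PanelGene, VariantRecord

__all__ = ["FilterConfig", "FilterReport", "apply_qc_filters", "intersect_panel"]

logger = logging.getLogger(__name__)

STAGES = ("maf", "exonic", "depth", "strand", "vaf")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the QC cascade.

    ``strand_bias_mode`` selects between the conventional reading in which a
    Phred-scaled strand-bias score above the threshold indicates bias and the
    variant is excluded (``retain_le``), and the literal reading that keeps
    scores above the threshold (``retain_gt_literal``).  ``maf_combine``
    selects whether rarity is required in every source (``max`` of available
    frequencies below threshold, the default) or in at least one (``min``).
    """

    maf_max: float = 0.01
    require_exonic: bool = True
    depth_min: float = 20.0  # strict >
    strand_bias_threshold: float = 60.0
    strand_bias_mode: str = "retain_le"
    vaf_min: float = 0.25  # inclusive >=
    maf_combine: str = "max"

    def __post_init__(self):
        if not 0 < self.maf_max < 1:
            raise ValueError("maf_max must lie in (0, 1)")
        if self.depth_min < 0:
            raise ValueError("depth_min must be >= 0")
        if not 0 <= self.vaf_min <= 1:
            raise ValueError("vaf_min must lie in [0, 1]")
        if self.strand_bias_mode not in ("retain_le", "retain_gt_literal"):
            raise ValueError(f"unknown strand_bias_mode {self.strand_bias_mode!r}")
        if self.maf_combine not in ("max", "min"):
            raise ValueError(f"unknown maf_combine {self.maf_combine!r}")


@dataclass
class FilterReport:
    """Stage-wise funnel counts and the variants dropped at each stage."""

    input: int = 0
    counts: Dict[str, int] = field(default_factory=dict)
    dropped: Dict[str, List[VariantRecord]] = field(default_factory=dict)
    pass_panel: int = 0
    dropped_panel: List[VariantRecord] = field(default_factory=list)

    def funnel(self) -> List[Tuple[str, int]]:
        out = [("input", self.input)]
        out += [(f"pass_{stage}", self.counts.get(stage, 0)) for stage in STAGES]
        out.append(("pass_panel", self.pass_panel))
        return out

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            **{f"pass_{stage}": self.counts.get(stage, 0) for stage in STAGES},
            "pass_panel": self.pass_panel,
            "dropped": {stage: [v.label for v in lst] for stage, lst in self.dropped.items()},
            "dropped_panel": [v.label for v in self.dropped_panel],
        }


def _passes(v: VariantRecord, stage: str, cfg: FilterConfig) -> bool:
    if stage == "maf":
        freqs = list(v.eas_af.values())
        maf = (max(freqs, default=0.0) if cfg.maf_combine == "max"
               else min(freqs, default=0.0))
        return maf < cfg.maf_max
    if stage == "exonic":
        if not cfg.require_exonic:
            return True
        return v.exonic is True
    if stage == "depth":
        return v.depth is not None and v.depth > cfg.depth_min
    if stage == "strand":
        if v.strand_bias is None:
            return False
        if cfg.strand_bias_mode == "retain_le":
            return v.strand_bias <= cfg.strand_bias_threshold
        return v.strand_bias > cfg.strand_bias_threshold
    if stage == "vaf":
        vaf = v.max_vaf
        return vaf is not None and vaf >= cfg.vaf_min
    raise ValueError(f"unknown stage {stage!r}")  # pragma: no cover


def apply_qc_filters(
    variants: Sequence[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> Tuple[List[VariantRecord], FilterReport]:
    """Apply the QC cascade; returns the retained variants and a funnel report.

    Records missing a field required by a stage (no depth, no strand-bias
    score, no usable VAF) are dropped at that stage and logged.
    """
    report = FilterReport(input=len(variants))
    current = list(variants)
    for stage in STAGES:
        kept, dropped = [], []
        for v in current:
            (kept if _passes(v, stage, cfg) else dropped).append(v)
        report.counts[stage] = len(kept)
        report.dropped[stage] = dropped
        logger.info("filter stage %-6s: %d -> %d", stage, len(current), len(kept))
        current = kept
    return current, report


def intersect_panel(
    variants: Sequence[VariantRecord],
    panel: Sequence[PanelGene],
    report: FilterReport | None = None,
) -> List[VariantRecord]:
    """Keep variants whose gene is in the panel; attach pathway and DDR flag.

    Matching is case-sensitive on whitespace-stripped symbols.  Variants with
    an empty gene symbol are dropped and logged.
    """
    by_symbol = {g.symbol: g for g in panel}
    kept: List[VariantRecord] = []
    dropped: List[VariantRecord] = []
    for v in variants:
        symbol = (v.gene or "").strip()
        if not symbol:
            logger.warning("variant %s has no gene symbol; dropped", v.label)
            dropped.append(v)
            continue
        gene = by_symbol.get(symbol)
        if gene is None:
            dropped.append(v)
            continue
        kept.append(v.with_panel_info(gene.pathway, gene.is_ddr))
    if report is not None:
        report.pass_panel = len(kept)
        report.dropped_panel = dropped
    logger.info("panel intersection: %d -> %d", len(variants), len(kept))
    return kept
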