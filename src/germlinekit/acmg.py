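"""ACMG/AMP evidence combination into five pathogenicity tiers.

The combiner implements the published evidence-combining rule table over the
28 standard codes (PVS1; PS1-4; PM1-6; PP1-5; BA1; BS1-4; BP1-7) and the
package's reading of the "contradictory criteria" clause: whenever a
benign-direction classification fires while pathogenic-direction evidence is
present (or the reverse), the variant is a VUS.

The default evidence assigner is deliberately minimal -- rarity (PM2), high
population frequency (BA1), and loss-of-function in a gene where LoF is the
known disease mechanism (PVS1), plus computational codes (PP3/BP4) passed
through from the annotation table.  It is pluggable: any callable with the
same signature may replace it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Optional

from .types import LOF_CONSEQUENCES, PanelGene, ReferenceCount, VariantRecord

__all__ = [
    "ALL_CODES",
    "EvidenceSet",
    "Classification",
    "assign_default_evidence",
    "combine_evidence",
    "triage",
    "classify",
]

PVS_CODES = frozenset({"PVS1"})
PS_CODES = frozenset({f"PS{i}" for i in range(1, 5)})
PM_CODES = frozenset({f"PM{i}" for i in range(1, 7)})
PP_CODES = frozenset({f"PP{i}" for i in range(1, 6)})
BA_CODES = frozenset({"BA1"})
BS_CODES = frozenset({f"BS{i}" for i in range(1, 5)})
BP_CODES = frozenset({f"BP{i}" for i in range(1, 8)})

PATHOGENIC_DIRECTION = PVS_CODES | PS_CODES | PM_CODES | PP_CODES
BENIGN_DIRECTION = BA_CODES | BS_CODES | BP_CODES
ALL_CODES = PATHOGENIC_DIRECTION | BENIGN_DIRECTION

TIER5 = ("Pathogenic", "LikelyPathogenic", "VUS", "LikelyBenign", "Benign")


def EvidenceSet(codes: Iterable[str]) -> FrozenSet[str]:
    """Validate and normalize a collection of ACMG evidence codes."""
    codes = frozenset(codes)
    unknown = codes - ALL_CODES
    if unknown:
        raise ValueError(f"unknown ACMG evidence code(s): {sorted(unknown)}")
    return codes


@dataclass(frozen=True)
class Classification:
    """Five-tier ACMG label with its three-bin triage."""

    tier5: str
    tier3: str

    def __post_init__(self):
        if self.tier5 not in TIER5:
            raise ValueError(f"unknown tier5 label {self.tier5!r}")
        expected = _TRIAGE[self.tier5]
        if self.tier3 != expected:
            raise ValueError(f"tier3 {self.tier3!r} inconsistent with tier5 {self.tier5!r}")


_TRIAGE = {
    "Pathogenic": "deleterious",
    "LikelyPathogenic": "deleterious",
    "VUS": "VUS",
    "LikelyBenign": "benign",
    "Benign": "benign",
}


def assign_default_evidence(
    v: VariantRecord,
    gene_meta: Optional[PanelGene],
    ref: Optional[ReferenceCount],
    *,
    lof_mechanism: bool = False,
) -> FrozenSet[str]:
    """Minimal deterministic evidence assignment.

    PVS1 for null variants (stopgain, frameshift, splicing) in genes where
    loss of function is the known mechanism; PM2 when the variant is absent
    or ultra-rare (< 1e-4) in both the reference table and every EAS source;
    BA1 when any EAS source exceeds 5%; PP3/BP4 accepted from the annotation
    table when present.
    """
    codes = set()
    if lof_mechanism and v.consequence in LOF_CONSEQUENCES:
        codes.add("PVS1")
    ref_af = ref.af if ref is not None else 0.0
    if ref_af < 1e-4 and all(af < 1e-4 for af in v.eas_af.values()):
        codes.add("PM2")
    if any(af > 0.05 for af in v.eas_af.values()):
        codes.add("BA1")
    for code in ("PP3", "BP4"):
        if code in v.evidence:
            codes.add(code)
    return EvidenceSet(codes)


def combine_evidence(evidence: Iterable[str]) -> str:
    """Combine evidence codes into one of the five tiers.

    Contradictory evidence (a benign-direction classification firing in the
    presence of any pathogenic-direction code, or vice versa) yields VUS.
    """
    codes = EvidenceSet(evidence)
    pvs = len(codes & PVS_CODES)
    ps = len(codes & PS_CODES)
    pm = len(codes & PM_CODES)
    pp = len(codes & PP_CODES)
    ba = len(codes & BA_CODES)
    bs = len(codes & BS_CODES)
    bp = len(codes & BP_CODES)

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_fires = pathogenic or likely_pathogenic
    benign_fires = benign or likely_benign
    any_path_code = (pvs + ps + pm + pp) > 0
    any_benign_code = (ba + bs + bp) > 0

    if path_fires and benign_fires:
        return "VUS"
    if path_fires and any_benign_code:
        return "VUS"
    if benign_fires and any_path_code:
        return "VUS"
    if pathogenic:
        return "Pathogenic"
    if likely_pathogenic:
        return "LikelyPathogenic"
    if benign:
        return "Benign"
    if likely_benign:
        return "LikelyBenign"
    return "VUS"


def triage(tier5: str) -> Classification:
    """Map a five-tier label onto the deleterious / VUS / benign triage."""
    if tier5 not in TIER5:
        raise ValueError(f"unknown tier5 label {tier5!r}")
    return Classification(tier5=tier5, tier3=_TRIAGE[tier5])


def classify(evidence: Iterable[str]) -> Classification:
    """Convenience: combine evidence and triage in one call."""
    return triage(combine_evidence(evidence))
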