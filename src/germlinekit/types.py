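"""Core domain containers shared across the pipeline.

A :class:`VariantRecord` is one normalized biallelic germline variant with the
QC metrics the filter cascade needs (depth, Phred-scaled strand-bias score,
per-carrier allele fractions), its functional annotation (gene symbol,
consequence class, exonic flag), East Asian population allele frequencies from
up to three sources, and the set of cohort samples carrying at least one
alternate allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

__all__ = [
    "CONSEQUENCES",
    "PATHWAYS",
    "PANEL_CATEGORIES",
    "EAS_SOURCES",
    "VariantRecord",
    "PanelGene",
    "ReferenceCount",
    "ClinicalRecord",
]

#: Controlled vocabulary of consequence classes.
CONSEQUENCES = frozenset(
    {
        "nonsynonymous_SNV",
        "stopgain",
        "frameshift_deletion",
        "frameshift_insertion",
        "splicing",
        "synonymous",
        "nonframeshift",
        "other",
    }
)

#: Loss-of-function consequence classes (used by the default evidence assigner).
LOF_CONSEQUENCES = frozenset(
    {"stopgain", "frameshift_deletion", "frameshift_insertion", "splicing"}
)

#: Controlled vocabulary of pathway labels for panel genes.
PATHWAYS = frozenset(
    {
        "DNA_methylation",
        "DDR",
        "tyrosine_protein_kinase",
        "GPCR_signaling",
        "peroxisome",
        "MAPK_ERK",
        "ErbB",
        "cell_cycle",
        "PI3K_Akt",
        "other",
    }
)

#: Panel membership source categories.
PANEL_CATEGORIES = frozenset({"hereditary_cancer", "cosmic_driver", "pca_predisposition"})

#: Recognized East Asian population frequency sources.
EAS_SOURCES = ("ExAC_EAS", "KG_EAS", "gnomAD_EAS")


def _check_allele(name: str, allele: str) -> None:
    if not allele or not set(allele) <= set("ACGTN*"):
        raise ValueError(f"{name} allele {allele!r} is not a valid sequence")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant (after multiallelic splitting) with QC and annotation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    consequence: Optional[str] = None
    exonic: Optional[bool] = None
    depth: Optional[float] = None
    strand_bias: Optional[float] = None
    vafs: Mapping[str, float] = field(default_factory=dict)
    eas_af: Mapping[str, float] = field(default_factory=dict)
    carriers: frozenset = field(default_factory=frozenset)
    n_alt_alleles: Optional[int] = None
    rsid: Optional[str] = None
    evidence: tuple = ()
    pathway: Optional[str] = None
    is_ddr: Optional[bool] = None
    annotated: bool = True

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        _check_allele("ref", self.ref)
        _check_allele("alt", self.alt)
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence class {self.consequence!r}")
        for sample, vaf in self.vafs.items():
            if not 0.0 <= vaf <= 1.0:
                raise ValueError(f"VAF for {sample} out of [0,1]: {vaf}")
        for source, af in self.eas_af.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency for {source} out of [0,1]: {af}")
        object.__setattr__(self, "carriers", frozenset(self.carriers))
        object.__setattr__(self, "vafs", dict(self.vafs))
        object.__setattr__(self, "eas_af", dict(self.eas_af))
        object.__setattr__(self, "evidence", tuple(self.evidence))

    @property
    def key(self) -> tuple:
        """Exact-match identity: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def max_eas_af(self) -> float:
        """Maximum frequency across available EAS sources; 0 when none present."""
        return max(self.eas_af.values(), default=0.0)

    @property
    def max_vaf(self) -> Optional[float]:
        return max(self.vafs.values(), default=None)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def with_panel_info(self, pathway: str, is_ddr: bool) -> "VariantRecord":
        return replace(self, pathway=pathway, is_ddr=is_ddr)


def is_parsimonious(ref: str, alt: str) -> bool:
    """True when the allele pair is minimal (left-aligned inputs assumed).

    A pair is non-parsimonious when both alleles are longer than one base and
    share either a leading or trailing base that could be trimmed.
    """
    if ref == alt:
        return False
    if len(ref) > 1 and len(alt) > 1:
        if ref[-1] == alt[-1] or ref[0] == alt[0]:
            return False
    return True


@dataclass(frozen=True)
class PanelGene:
    """One predisposition-panel gene with its source categories and pathway label."""

    symbol: str
    categories: frozenset = field(default_factory=frozenset)
    pathway: str = "other"
    is_ddr: bool = False

    def __post_init__(self):
        if not self.symbol or not self.symbol.strip():
            raise ValueError("panel gene symbol must be non-empty")
        object.__setattr__(self, "symbol", self.symbol.strip())
        object.__setattr__(self, "categories", frozenset(self.categories))
        unknown = self.categories - PANEL_CATEGORIES
        if unknown:
            raise ValueError(f"unknown panel categories: {sorted(unknown)}")
        if self.pathway not in PATHWAYS:
            raise ValueError(f"pathway {self.pathway!r} not in controlled vocabulary")


@dataclass(frozen=True)
class ReferenceCount:
    """Population reference allele counts for one variant (AC/AN convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    ac: int
    an: int

    def __post_init__(self):
        if self.an <= 0:
            raise ValueError(f"AN must be positive, got {self.an}")
        if not 0 <= self.ac <= self.an:
            raise ValueError(f"require 0 <= AC <= AN, got AC={self.ac} AN={self.an}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def af(self) -> float:
        return self.ac / self.an


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical covariates."""

    sample_id: str
    age: float
    psa: float
    isup: int
    metastasis: str
    crpc_within_1yr: Optional[bool] = None

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.psa < 0:
            raise ValueError(f"PSA must be non-negative, got {self.psa}")
        if self.isup not in (1, 2, 3, 4, 5):
            raise ValueError(f"ISUP grade must be 1..5, got {self.isup}")
        if self.metastasis not in ("M0", "M1"):
            raise ValueError(f"metastasis must be M0 or M1, got {self.metastasis!r}")
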