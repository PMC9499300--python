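"""Readers and writers for every external artifact.

Formats handled: VCF 4.x (via pysam) joined with a tab-separated annotation
table on exact (chrom, pos, ref, alt); panel, reference-count and clinical
TSVs; GMT gene sets; and generic result tables written so that a round trip
reproduces identical values (integers bit-exact, reals at 12 significant
digits).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd
import pysam

from .types import (
    EAS_SOURCES,
    ClinicalRecord,
    PanelGene,
    ReferenceCount,
    VariantRecord,
    is_parsimonious,
)

__all__ = [
    "ParseError",
    "read_cohort",
    "ReferenceTable",
    "read_reference",
    "read_panel",
    "read_clinical",
    "read_gene_sets",
    "write_table",
    "read_table",
]

#: Default total allele number assumed for variants absent from the reference
#: table (two alleles for each of the 9,197 reference individuals).
DEFAULT_REFERENCE_AN = 18394


class ParseError(ValueError):
    """Raised when an input artifact cannot be parsed."""


def _annotation_frame(annotation_path) -> Dict[tuple, dict]:
    df = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence", "exonic"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"annotation table missing columns: {sorted(missing)}")
    rows: Dict[tuple, dict] = {}
    for idx, row in enumerate(df.to_dict("records"), start=2):
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        if key in rows:
            raise ParseError(
                f"duplicate annotation for {key[0]}:{key[1]}:{key[2]}>{key[3]} at line {idx}"
            )
        rows[key] = row
    return rows


def _truthy(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    return bool(value)


def _float_or_none(value) -> Optional[float]:
    if value is None:
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(out) else out


def read_cohort(
    vcf_path, annotation_path=None, *, validate_parsimony: bool = True
) -> Tuple[List[VariantRecord], List[str]]:
    """Read a cohort VCF (+ optional annotation TSV) into VariantRecords.

    Multiallelic sites are split into one record per alternate allele; a
    sample is a carrier of an allele when its genotype contains that allele
    at least once.  Per-carrier VAF comes from the sample AD field
    (alt / (ref + alt)); when AD is absent a site-level AF is used for every
    carrier.  Records without an annotation row are retained with
    ``annotated=False`` and ``exonic=None``.

    Returns ``(records, roster)`` where roster is the VCF sample list.
    """
    annotations = _annotation_frame(annotation_path) if annotation_path else {}
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:  # pragma: no cover - pysam message passthrough
        raise ParseError(f"cannot open VCF {vcf_path}: {exc}") from exc

    roster = list(vcf.header.samples)
    records: List[VariantRecord] = []
    rec_no = 0
    iterator = iter(vcf)
    while True:
        try:
            rec = next(iterator)
        except StopIteration:
            break
        except Exception as exc:
            raise ParseError(
                f"malformed VCF record #{rec_no + 1} in {vcf_path}: {exc}"
            ) from exc
        rec_no += 1
        alts = rec.alts or ()
        for alt_index, alt in enumerate(alts, start=1):
            if validate_parsimony and not is_parsimonious(rec.ref, alt):
                raise ParseError(
                    f"non-parsimonious alleles {rec.ref}>{alt} at "
                    f"{rec.chrom}:{rec.pos} (record #{rec_no}); normalize the VCF first"
                )
            carriers: Set[str] = set()
            vafs: Dict[str, float] = {}
            n_alt = 0
            for sample in roster:
                call = rec.samples[sample]
                gt = call.get("GT") or ()
                count = sum(1 for a in gt if a == alt_index)
                if count == 0:
                    continue
                carriers.add(sample)
                n_alt += count
                ad = call.get("AD")
                if ad is not None and len(ad) > alt_index and ad[alt_index] is not None:
                    total = sum(x for x in ad if x is not None)
                    if total > 0:
                        vafs[sample] = ad[alt_index] / total
            if not vafs and carriers:
                site_af = rec.info.get("AF")
                if site_af is not None:
                    af = site_af[alt_index - 1] if isinstance(site_af, tuple) else site_af
                    if af is not None:
                        vafs = {s: float(af) for s in carriers}

            depth = rec.info.get("DP")
            if depth is None:
                depths = [rec.samples[s].get("DP") for s in roster]
                depths = [d for d in depths if d is not None]
                depth = sum(depths) if depths else None
            strand_bias = rec.info.get("FS")

            key = (str(rec.chrom), int(rec.pos), str(rec.ref), str(alt))
            ann = annotations.get(key)
            if ann is not None:
                eas = {}
                for source in EAS_SOURCES:
                    af = _float_or_none(ann.get(source))
                    if af is not None:
                        eas[source] = af
                evidence = ann.get("evidence")
                evidence = (
                    tuple(code for code in str(evidence).split(",") if code)
                    if isinstance(evidence, str) and evidence
                    else ()
                )
                record = VariantRecord(
                    chrom=key[0],
                    pos=key[1],
                    ref=key[2],
                    alt=key[3],
                    gene=str(ann["gene"]) if not pd.isna(ann["gene"]) else None,
                    consequence=str(ann["consequence"]),
                    exonic=_truthy(ann["exonic"]),
                    depth=float(depth) if depth is not None else None,
                    strand_bias=float(strand_bias) if strand_bias is not None else None,
                    vafs=vafs,
                    eas_af=eas,
                    carriers=frozenset(carriers),
                    n_alt_alleles=n_alt,
                    rsid=str(ann["rsid"]) if "rsid" in ann and not pd.isna(ann["rsid"]) else None,
                    evidence=evidence,
                )
            else:
                record = VariantRecord(
                    chrom=key[0],
                    pos=key[1],
                    ref=key[2],
                    alt=key[3],
                    depth=float(depth) if depth is not None else None,
                    strand_bias=float(strand_bias) if strand_bias is not None else None,
                    vafs=vafs,
                    carriers=frozenset(carriers),
                    n_alt_alleles=n_alt,
                    annotated=False,
                )
            records.append(record)
    vcf.close()
    return records, roster


class ReferenceTable:
    """Exact-match (chrom, pos, ref, alt) -> ReferenceCount lookup.

    Variants absent from the table resolve to AC=0 with a configured default
    AN, mirroring the convention that population databases omit unobserved
    variants rather than listing them with zero counts.
    """

    def __init__(self, counts: Sequence[ReferenceCount], default_an: int = DEFAULT_REFERENCE_AN):
        if default_an <= 0:
            raise ValueError("default AN must be positive")
        self.default_an = default_an
        self._table: Dict[tuple, ReferenceCount] = {}
        for count in counts:
            if count.key in self._table:
                raise ValueError(f"duplicate reference row for {count.key}")
            self._table[count.key] = count

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, key: tuple) -> bool:
        return tuple(key) in self._table

    def lookup(self, key: tuple) -> ReferenceCount:
        key = (str(key[0]), int(key[1]), str(key[2]), str(key[3]))
        found = self._table.get(key)
        if found is not None:
            return found
        return ReferenceCount(*key, ac=0, an=self.default_an)


def read_reference(path, default_an: int = DEFAULT_REFERENCE_AN) -> ReferenceTable:
    """Read a reference allele-count TSV (chrom, pos, ref, alt, ac, an)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "ac", "an"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"reference table missing columns: {sorted(missing)}")
    counts = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        if row.ac > row.an:
            raise ParseError(f"reference row at line {idx}: AC={row.ac} exceeds AN={row.an}")
        try:
            counts.append(
                ReferenceCount(str(row.chrom), int(row.pos), str(row.ref), str(row.alt),
                               ac=int(row.ac), an=int(row.an))
            )
        except ValueError as exc:
            raise ParseError(f"reference row at line {idx}: {exc}") from exc
    return ReferenceTable(counts, default_an=default_an)


def read_panel(path) -> List[PanelGene]:
    """Read a predisposition gene panel TSV (symbol, categories, pathway, is_ddr)."""
    df = pd.read_csv(path, sep="\t")
    if "symbol" not in df.columns:
        raise ParseError("panel table must have a 'symbol' column")
    genes: List[PanelGene] = []
    seen = set()
    for row in df.to_dict("records"):
        symbol = str(row["symbol"]).strip()
        if symbol in seen:
            raise ParseError(f"duplicate panel symbol {symbol}")
        seen.add(symbol)
        raw_cat = row.get("categories", "")
        categories = frozenset(
            c.strip() for c in str(raw_cat).split(",") if c.strip()
        ) if not pd.isna(raw_cat) else frozenset()
        genes.append(
            PanelGene(
                symbol=symbol,
                categories=categories,
                pathway=str(row.get("pathway", "other")),
                is_ddr=_truthy(row.get("is_ddr", False)),
            )
        )
    return genes


def read_clinical(path) -> List[ClinicalRecord]:
    """Read clinical covariates TSV (sample_id, age, psa, isup, metastasis[, crpc_within_1yr])."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "age", "psa", "isup", "metastasis"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"clinical table missing columns: {sorted(missing)}")
    records = []
    for row in df.to_dict("records"):
        crpc = row.get("crpc_within_1yr")
        crpc = None if crpc is None or (isinstance(crpc, float) and math.isnan(crpc)) else _truthy(crpc)
        records.append(
            ClinicalRecord(
                sample_id=str(row["sample_id"]),
                age=float(row["age"]),
                psa=float(row["psa"]),
                isup=int(row["isup"]),
                metastasis=str(row["metastasis"]),
                crpc_within_1yr=crpc,
            )
        )
    return records


def read_gene_sets(gmt_path) -> Dict[str, Set[str]]:
    """Read GMT gene sets: name, description, then members; empty sets rejected."""
    sets: Dict[str, Set[str]] = {}
    with open(gmt_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ParseError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise ParseError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = members
    return sets


def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table as TSV with 12-significant-digit reals."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
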