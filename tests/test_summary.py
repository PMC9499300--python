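"""Carrier arithmetic, spectrum/pathway percentages and clinical associations."""

import numpy as np
import pytest

from germlinekit.summary import (
    associate_clinical,
    build_cohort_report,
    find_recurrent,
    mutation_spectrum,
    pathway_burden,
    percent,
    summarize_carriers,
    tier_shares,
)
from germlinekit.types import ClinicalRecord, VariantRecord

from oracles import rank_sum_exact_oracle


def make_variant(pos, carriers, consequence="stopgain", pathway="DDR", gene="FANCI",
                 rsid=None):
    return VariantRecord(
        chrom="1", pos=pos, ref="A", alt="G", gene=gene, consequence=consequence,
        exonic=True, carriers=frozenset(carriers), n_alt_alleles=len(carriers),
        pathway=pathway, rsid=rsid,
    )


def spread_variants(n_variants, n_carriers, n_dual):
    """n_variants distributed over n_carriers patients, n_dual carrying two."""
    assert n_variants == n_carriers + n_dual
    variants = []
    pos = 1
    for i in range(n_carriers):
        variants.append(make_variant(pos, {f"P{i}"}))
        pos += 1
    for i in range(n_dual):
        variants.append(make_variant(pos, {f"P{i}"}))
        pos += 1
    return variants


class TestCarriers:
    def test_discovery_cohort_arithmetic(self):
        variants = spread_variants(36, 29, 7)
        stats = summarize_carriers(variants, [f"P{i}" for i in range(100)])
        assert (stats.n_variants, stats.n_carriers, stats.n_dual_carriers) == (36, 29, 7)
        assert stats.carrier_percent == 29.0

    def test_validation_cohort_arithmetic(self):
        variants = spread_variants(45, 42, 3)
        stats = summarize_carriers(variants, [f"P{i}" for i in range(167)])
        assert (stats.n_carriers, stats.n_dual_carriers) == (42, 3)
        assert stats.carrier_percent == 25.1

    def test_no_variants(self):
        stats = summarize_carriers([], ["P0", "P1"])
        assert (stats.n_carriers, stats.n_dual_carriers) == (0, 0)

    def test_carrier_outside_roster_is_an_error(self):
        with pytest.raises(ValueError, match="not in roster"):
            summarize_carriers([make_variant(1, {"ghost"})], ["P0"])


class TestSpectrum:
    def test_printed_spectrum(self):
        variants = []
        pos = 1
        for consequence, n in [("nonsynonymous_SNV", 12), ("stopgain", 11),
                               ("frameshift_deletion", 7), ("frameshift_insertion", 6)]:
            for _ in range(n):
                variants.append(make_variant(pos, {f"P{pos}"}, consequence=consequence))
                pos += 1
        spectrum = mutation_spectrum(variants)
        assert spectrum["nonsynonymous_SNV"] == (12, 33.3)
        assert spectrum["stopgain"] == (11, 30.6)
        assert spectrum["frameshift_deletion"] == (7, 19.4)
        assert spectrum["frameshift_insertion"] == (6, 16.7)

    def test_single_variant_is_100_percent(self):
        assert mutation_spectrum([make_variant(1, {"P1"})])["stopgain"] == (1, 100.0)

    def test_percents_sum_to_100(self):
        rng = np.random.default_rng(3)
        kinds = ["nonsynonymous_SNV", "stopgain", "splicing", "synonymous"]
        variants = [make_variant(i + 1, {f"P{i}"}, consequence=str(rng.choice(kinds)))
                    for i in range(57)]
        total = sum(pct for _, pct in mutation_spectrum(variants).values())
        assert total == pytest.approx(100.0, abs=0.1)


def test_percent_rounds_half_up():
    assert percent(2475, 4205) == 58.9
    assert percent(1694, 4205) == 40.3
    assert percent(1, 16) == 6.3   # 6.25 rounds up, not to even
    assert percent(0, 10) == 0.0


def test_tier_shares_match_printed_proportions():
    labels = ["deleterious"] * 36 + ["VUS"] * 2475 + ["benign"] * 1694
    shares = tier_shares(labels)
    assert shares["deleterious"] == (36, 0.9)
    assert shares["VUS"] == (2475, 58.9)
    assert shares["benign"] == (1694, 40.3)


class TestPathwayBurden:
    def test_variant_and_patient_level_fractions(self):
        variants = []
        # 12 DNA-methylation variants spread over 10 distinct patients
        carriers = [f"P{i}" for i in range(10)] + ["P0", "P1"]
        for i, c in enumerate(carriers):
            variants.append(make_variant(i + 1, {c}, pathway="DNA_methylation"))
        for i in range(24):
            variants.append(make_variant(100 + i, {f"Q{i}"}, pathway="DDR"))
        variant_fr, patient_fr = pathway_burden(variants, n_patients=100)
        assert variant_fr["DNA_methylation"] == (12, 33.3)
        assert patient_fr["DNA_methylation"] == (10, 10.0)

    def test_unlabeled_gene_goes_to_other(self):
        v = make_variant(1, {"P1"}, pathway=None)
        variant_fr, _ = pathway_burden([v], n_patients=10)
        assert variant_fr == {"other": (1, 100.0)}

    def test_absent_pathway_not_reported(self):
        variant_fr, _ = pathway_burden([make_variant(1, {"P1"})], 10)
        assert "peroxisome" not in variant_fr


class TestRecurrence:
    def test_recurrent_map(self):
        variants = [
            make_variant(1, {f"P{i}" for i in range(4)}, rsid="rs752118948"),
            make_variant(2, {"P8", "P9"}, rsid="rs200662726"),
            make_variant(3, {"P5"}),
        ]
        assert find_recurrent(variants) == {"rs752118948": 4, "rs200662726": 2}

    def test_all_singletons_empty(self):
        assert find_recurrent([make_variant(1, {"P1"})]) == {}


def make_clinical(n, rng, prevalence=0.3):
    records = []
    for i in range(n):
        records.append(ClinicalRecord(
            sample_id=f"P{i}", age=float(rng.integers(50, 85)),
            psa=float(rng.lognormal(3, 1)), isup=int(rng.integers(1, 6)),
            metastasis="M1" if rng.random() < prevalence else "M0",
            crpc_within_1yr=bool(rng.random() < 0.3),
        ))
    return records


class TestClinicalAssociation:
    def test_identical_dichotomous_distributions_give_p_one(self):
        records = []
        for i in range(20):
            records.append(ClinicalRecord(
                sample_id=f"P{i}", age=60 + i, psa=10.0, isup=3,
                metastasis="M1" if i % 2 else "M0"))
        flags = {f"P{i}": i < 10 for i in range(20)}  # 5 M1 in each group
        results = {r.trait: r for r in associate_clinical(flags, records)}
        assert results["metastasis"].p == pytest.approx(1.0)

    def test_small_sample_rank_sum_is_exact(self):
        records = [
            ClinicalRecord(sample_id=f"P{i}", age=float(a), psa=1.0, isup=1,
                           metastasis="M0")
            for i, a in enumerate([1, 2, 3, 4, 5, 6])
        ]
        flags = {f"P{i}": i < 3 for i in range(6)}
        results = {r.trait: r for r in associate_clinical(flags, records)}
        assert results["age"].p == pytest.approx(0.1)
        assert float(rank_sum_exact_oracle([1, 2, 3], [4, 5, 6])) == pytest.approx(0.1)

    def test_single_group_is_an_error(self):
        rng = np.random.default_rng(1)
        records = make_clinical(10, rng)
        with pytest.raises(ValueError):
            associate_clinical({r.sample_id: True for r in records}, records)


def test_cohort_report_internal_consistency(study):
    from germlinekit import pipeline, synthetic
    ref = synthetic.reference_table_from_frame(
        study["reference"], study["discovery"].config.reference_an)
    cohort = study["discovery"]
    result = pipeline.run_cohort(cohort.variants, cohort.roster, study["panel"], ref)
    report = result.report
    assert sum(n for n, _ in report.spectrum.values()) == report.n_deleterious_variants
    assert sum(n for n, _ in report.pathway_variant_fractions.values()) \
        == report.n_deleterious_variants
    assert report.n_dual_carriers <= report.n_carriers
    per_patient = summarize_carriers(result.deleterious, cohort.roster).per_patient
    # per-patient counts sum to carrier slots: one per (variant, carrier) pair,
    # so recurrent variants contribute once per carrier
    assert sum(per_patient.values()) == sum(len(v.carriers) for v in result.deleterious)
    assert sum(per_patient.values()) >= report.n_deleterious_variants
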