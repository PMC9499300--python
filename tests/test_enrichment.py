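"""Enrichment statistics against exact enumeration oracles."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from germlinekit.enrichment import (
    ContingencyTable,
    adjust_fdr,
    build_contingency,
    fisher_exact_two_sided,
    odds_ratio_ci,
    run_enrichment,
)
from germlinekit.io_formats import ReferenceTable
from germlinekit.types import ReferenceCount, VariantRecord

from oracles import bh_oracle, fisher_two_sided_oracle, odds_ratio_corrected_oracle


def make_variant(carriers, n_alt=None, pos=100, gene="SUGCT"):
    return VariantRecord(
        chrom="1", pos=pos, ref="AG", alt="A", gene=gene,
        consequence="frameshift_deletion", exonic=True, depth=60.0,
        strand_bias=5.0, vafs={s: 0.5 for s in carriers},
        carriers=frozenset(carriers),
        n_alt_alleles=len(carriers) if n_alt is None else n_alt,
    )


class TestBuildContingency:
    def test_recurrent_variant_in_allele_mode(self):
        # four heterozygous carriers among 100 patients vs a singleton in the reference
        v = make_variant({f"P{i}" for i in range(4)})
        ref = ReferenceCount("1", 100, "AG", "A", ac=1, an=18394)
        t = build_contingency(v, 100, ref, mode="allele")
        assert t.cells == (4, 196, 1, 18393)

    def test_zero_carriers(self):
        t = build_contingency(make_variant(set()), 100,
                              ReferenceCount("1", 100, "AG", "A", ac=5, an=18394))
        assert (t.a, t.b) == (0, 200)

    def test_homozygous_carrier_counts_two_alleles(self):
        v = make_variant({"P1"}, n_alt=2)
        t = build_contingency(v, 100, ReferenceCount("1", 100, "AG", "A", ac=0, an=18394))
        assert t.a == 2

    def test_carrier_mode_uses_individual_counts(self):
        v = make_variant({"P1", "P2"})
        t = build_contingency(v, 100, ReferenceCount("1", 100, "AG", "A", ac=3, an=18394),
                              mode="carrier")
        assert t.cells == (2, 98, 3, 9197 - 3)


class TestFisher:
    @pytest.mark.parametrize("cells,expected", [
        ((2, 8, 2, 8), 1.0),
        ((0, 10, 0, 10), 1.0),
        ((3, 7, 1, 9), 188 / 323),
    ])
    def test_worked_examples(self, cells, expected):
        assert fisher_exact_two_sided(ContingencyTable(*cells)) == pytest.approx(expected, rel=1e-9)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 5, 2, 3)

    def test_matches_enumeration_oracle_on_random_small_tables(self):
        rng = random.Random(7)
        for _ in range(400):
            r1, r2 = rng.randint(1, 30), rng.randint(1, 30)
            a, c = rng.randint(0, r1), rng.randint(0, r2)
            t = ContingencyTable(a, r1 - a, c, r2 - c)
            expected = float(fisher_two_sided_oracle(*t.cells))
            assert fisher_exact_two_sided(t) == pytest.approx(expected, rel=1e-7)


class TestOddsRatio:
    def test_symmetric_table_is_one_without_correction(self):
        or_point, lo, hi, corrected = odds_ratio_ci(ContingencyTable(5, 95, 5, 95))
        assert or_point == pytest.approx(1.0)
        assert not corrected
        assert lo <= 1.0 <= hi

    def test_singleton_case_gets_haldane_anscombe_correction(self):
        or_point, lo, hi, corrected = odds_ratio_ci(ContingencyTable(1, 199, 0, 18394))
        assert corrected
        assert or_point == pytest.approx((1.5 / 199.5) / (0.5 / 18394.5), rel=1e-12)
        assert or_point == pytest.approx(276.6, abs=0.1)
        assert lo <= or_point <= hi

    def test_proportional_table_is_exactly_one(self):
        or_point, *_ = odds_ratio_ci(ContingencyTable(2, 98, 20, 980))
        assert or_point == 1.0

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_ci(ContingencyTable(0, 0, 0, 0))

    def test_double_row_swap_and_transposition_invariance(self):
        t = ContingencyTable(3, 17, 5, 45)
        base = odds_ratio_ci(t)[0]
        swapped = odds_ratio_ci(ContingencyTable(5, 45, 3, 17))[0]
        transposed = odds_ratio_ci(ContingencyTable(3, 5, 17, 45))[0]
        assert swapped == pytest.approx(1 / base, rel=1e-12)
        assert transposed == pytest.approx(base, rel=1e-12)

    def test_matches_closed_form_oracle_on_random_tables(self):
        rng = random.Random(13)
        for _ in range(200):
            cells = tuple(rng.randint(0, 50) for _ in range(4))
            if sum(cells) == 0:
                continue
            assert odds_ratio_ci(ContingencyTable(*cells))[0] == pytest.approx(
                odds_ratio_corrected_oracle(*cells), rel=1e-12)


class TestFdr:
    def test_single_p_is_identity(self):
        assert adjust_fdr([0.5]) == [0.5]

    def test_stepup_worked_example(self):
        assert adjust_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_literal_stepup_oracle_and_preserves_order(self, pvals):
        q = adjust_fdr(pvals)
        assert q == pytest.approx(bh_oracle(pvals), rel=1e-12)
        ranked = sorted(zip(pvals, q))
        assert all(q1 <= q2 + 1e-12 for (_, q1), (_, q2) in zip(ranked, ranked[1:]))

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20),
           st.data())
    def test_increasing_one_p_never_grows_the_significant_set(self, pvals, data):
        idx = data.draw(st.integers(0, len(pvals) - 1))
        bumped = list(pvals)
        bumped[idx] = min(1.0, bumped[idx] + data.draw(st.floats(0.0, 1.0)))
        sig_before = {i for i, q in enumerate(adjust_fdr(pvals)) if q <= 0.05}
        sig_after = {i for i, q in enumerate(adjust_fdr(bumped)) if q <= 0.05}
        assert sig_after <= sig_before


class TestRunEnrichment:
    def reference(self, rows, default_an=18394):
        return ReferenceTable(
            [ReferenceCount(*k, ac=ac, an=an) for k, ac, an in rows],
            default_an=default_an)

    def test_strongly_recurrent_variant_is_flagged(self):
        v = make_variant({f"P{i}" for i in range(4)})
        ref = self.reference([(("1", 100, "AG", "A"), 1, 18394)])
        results, significant = run_enrichment([v], 100, ref)
        assert len(significant) == 1
        assert results[0].q <= 0.05

    def test_frequency_matched_variant_is_not_flagged(self):
        v = make_variant({"P1"})  # 1/200 alleles
        ref = self.reference([(("1", 100, "AG", "A"), 92, 18394)])  # ~same frequency
        _, significant = run_enrichment([v], 100, ref)
        assert significant == []

    def test_every_significant_or_is_at_least_one(self):
        rng = np.random.default_rng(5)
        variants, rows = [], []
        for i in range(30):
            carriers = {f"P{j}" for j in range(int(rng.integers(0, 6)))}
            v = make_variant(carriers, pos=100 + i)
            variants.append(v)
            rows.append(((v.chrom, v.pos, v.ref, v.alt), int(rng.integers(0, 40)), 18394))
        _, significant = run_enrichment(variants, 100, self.reference(rows))
        assert all(r.or_point >= 1.0 for r in significant)

    def test_empty_input_warns_and_returns_empty(self):
        ref = self.reference([])
        assert run_enrichment([], 100, ref) == ([], [])

    def test_bonferroni_mode_is_no_less_conservative(self):
        variants = [make_variant({f"P{i}"}, pos=100 + i) for i in range(10)]
        ref = self.reference([])
        _, sig_bh = run_enrichment(variants, 100, ref)
        _, sig_bonf = run_enrichment(variants, 100, ref, method="bonferroni")
        assert {r.key for r in sig_bonf} <= {r.key for r in sig_bh}
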