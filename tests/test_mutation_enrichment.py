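"""Mutation frequency statistics, the binomial domain test and impact scores."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import binomial_tail_oracle
from famscore import mutation_enrichment as me
from famscore.synthetic_data import SimulationConfig, simulate_mutations


def muts(rows):
    return pd.DataFrame(rows, columns=["sample", "cancer", "gene", "protein_pos"])


class TestSubtypeFrequency:
    def test_direct_formula(self, tiny_annotation):
        # S1 has 2 members {GA, GB}; craft m=2 mutated samples of 10 total,
        # n=1 member mutated -> freq = (2/10) * (1/2) = 0.1
        rows = [("P1", "C", "GA", 10), ("P2", "C", "GA", 20)]
        rows += [(f"X{i}", "C", "OTHER", 1) for i in range(8)]
        res = {r.subtype: r for r in
               me.subtype_mutation_frequency(muts(rows), tiny_annotation, "C")}
        assert res["S1"].m == 2 and res["S1"].M == 10
        assert res["S1"].n == 1 and res["S1"].N_members == 2
        assert res["S1"].mut_freq == pytest.approx(0.1)

    def test_fully_mutated_subtype_reaches_one(self, tiny_annotation):
        rows = [("P1", "C", "GA", 10), ("P1", "C", "GB", 10),
                ("P2", "C", "GA", 5), ("P2", "C", "GB", 6)]
        res = {r.subtype: r for r in
               me.subtype_mutation_frequency(muts(rows), tiny_annotation, "C")}
        assert res["S1"].mut_freq == pytest.approx(1.0)

    def test_unmutated_subtype_is_zero(self, tiny_annotation):
        rows = [("P1", "C", "GA", 10)]
        res = {r.subtype: r for r in
               me.subtype_mutation_frequency(muts(rows), tiny_annotation, "C")}
        assert res["S2"].mut_freq == 0.0

    def test_row_order_permutation_invariance(self, tiny_annotation):
        rng = np.random.default_rng(3)
        rows = [(f"P{rng.integers(5)}", "C", g, int(rng.integers(1, 200)))
                for g in ["GA", "GB", "GC", "OTHER"] * 5]
        a = me.subtype_mutation_frequency(muts(rows), tiny_annotation, "C")
        shuffled = muts(rows).sample(frac=1.0, random_state=0).reset_index(drop=True)
        b = me.subtype_mutation_frequency(shuffled, tiny_annotation, "C")
        assert a == b
        assert all(0 <= r.mut_freq <= 1 for r in a)

    def test_no_mutated_samples_errors(self, tiny_annotation):
        with pytest.raises(ValueError, match="no mutated samples"):
            me.subtype_mutation_frequency(muts([("P", "X", "GA", 1)]),
                                          tiny_annotation, "C")


class TestDomainFrequency:
    def test_fraction_of_mutated_samples(self, tiny_annotation):
        # 5 of 50 samples hit GA's SPRY (301-420)
        rows = [(f"H{i}", "C", "GA", 350) for i in range(5)]
        rows += [(f"X{i}", "C", "OTHER", 1) for i in range(45)]
        res = {r.domain: r for r in
               me.domain_mutation_frequency(muts(rows), tiny_annotation, "C")}
        assert res["SPRY"].d == 5 and res["SPRY"].N_j == 50
        assert res["SPRY"].f == pytest.approx(0.1)

    def test_sample_with_two_hits_counts_once(self, tiny_annotation):
        rows = [("P1", "C", "GA", 310), ("P1", "C", "GA", 400)]
        res = {r.domain: r for r in
               me.domain_mutation_frequency(muts(rows), tiny_annotation, "C")}
        assert res["SPRY"].d == 1

    def test_unhit_domain_reports_zero_with_warning(self, tiny_annotation, caplog):
        rows = [("P1", "C", "GA", 350)]
        with caplog.at_level(logging.WARNING):
            res = {r.domain: r for r in
                   me.domain_mutation_frequency(muts(rows), tiny_annotation, "C")}
        assert res["CC"].f == 0.0
        assert any("CC" in r.message for r in caplog.records)


class TestBinomialDomainTest:
    def test_worked_example(self):
        p, E = me.domain_binomial_test(6, 10, 20, 100)
        assert E == pytest.approx(3.0, abs=0)
        assert p == pytest.approx(binomial_tail_oracle(6, 10, 20, 100), rel=1e-12)
        assert p == pytest.approx(6.37e-3, rel=1e-2)

    def test_degenerate_full_length_domain(self):
        for k in (0, 3, 10):
            p, E = me.domain_binomial_test(k, 10, 100, 100)
            assert p == pytest.approx(1.0)
        assert me.domain_binomial_test(4, 10, 100, 100)[1] == pytest.approx(0.4)

    def test_zero_hits(self):
        assert me.domain_binomial_test(0, 10, 20, 100) == (1.0, 0.0)

    def test_n_zero_errors(self):
        with pytest.raises(ValueError):
            me.domain_binomial_test(0, 0, 20, 100)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_exact_rational_oracle(self, data):
        N = data.draw(st.integers(1, 500))
        k = data.draw(st.integers(0, N))
        L_g = data.draw(st.integers(2, 2000))
        L_d = data.draw(st.integers(1, L_g))
        p, E = me.domain_binomial_test(k, N, L_d, L_g)
        expected = binomial_tail_oracle(k, N, L_d, L_g)
        assert p == pytest.approx(expected, rel=1e-12, abs=1e-300)
        assert E == pytest.approx(k / (N * L_d / L_g))

    def test_E_scale_invariance_and_p_monotonicity(self):
        p1, E1 = me.domain_binomial_test(6, 10, 20, 100)
        _, E2 = me.domain_binomial_test(18, 30, 20, 100)   # k, N scaled by 3
        assert E1 == pytest.approx(E2)
        ps = [me.domain_binomial_test(k, 20, 20, 100)[0] for k in range(1, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestPrioritization:
    def test_planted_hotspot_recovered(self, hotspot_annotation):
        config = SimulationConfig.from_dict({
            "seed": 11, "samples_per_cancer": 40,
            "mutation": {"per_gene_rate": 1.0,
                         "enriched": [["HOTG", "HOT", 5.0]]}})
        table, truth = simulate_mutations(hotspot_annotation, config)
        results = me.prioritize_enriched_domains(table, hotspot_annotation)
        planted = [r for r in results if (r.gene, r.domain) == ("HOTG", "HOT")]
        assert planted and planted[0].significant

    def test_low_count_domains_excluded_from_bh_family(self, tiny_annotation):
        # GA: 5 events, 4 in SPRY (tested); GB: 2 events in RING (k < 3, skipped)
        rows = [("P1", "C", "GA", 310), ("P2", "C", "GA", 320),
                ("P3", "C", "GA", 350), ("P4", "C", "GA", 400),
                ("P5", "C", "GA", 10),
                ("P6", "C", "GB", 10), ("P7", "C", "GB", 20)]
        results = me.prioritize_enriched_domains(muts(rows), tiny_annotation)
        keys = {(r.gene, r.domain) for r in results}
        assert ("GA", "SPRY") in keys
        assert ("GB", "RING") not in keys
        spry = next(r for r in results if r.domain == "SPRY")
        assert (spry.k, spry.N) == (4, 5)

    def test_exact_E_of_two_is_not_significant(self, tiny_annotation):
        # 12 of 30 events in a domain covering 20% of GA -> E = 2 exactly
        from famscore.core_io import DomainRecord, FamilyAnnotation, FamilyGene

        ann = FamilyAnnotation([
            FamilyGene("G", "S1", 100, (DomainRecord("D", 1, 20),))
        ])
        rows = [(f"P{i}", "C", "G", 10) for i in range(12)]
        rows += [(f"Q{i}", "C", "G", 50) for i in range(18)]
        (res,) = me.prioritize_enriched_domains(muts(rows), ann)
        assert res.E == pytest.approx(2.0)
        assert res.padj < 0.05
        assert not res.significant  # strict E > 2 rule

    def test_per_cancer_pooling_splits_tests(self, tiny_annotation):
        rows = [(f"P{i}", "C1", "GA", 310 + i) for i in range(4)]
        rows += [(f"Q{i}", "C2", "GA", 310 + i) for i in range(4)]
        pan = me.prioritize_enriched_domains(muts(rows), tiny_annotation)
        per = me.prioritize_enriched_domains(muts(rows), tiny_annotation,
                                             pooling="per-cancer")
        assert {r.cancer for r in pan} == {me.PAN_CANCER}
        assert {r.cancer for r in per} == {"C1", "C2"}


class TestImpactComparison:
    @staticmethod
    def _table(rng, n=200, shift=1.0):
        # GA of tiny_annotation: SPRY 301-420 (in-domain), 150 (outside CC/RING? no:
        # use 200 which is outside all GA domains)
        rows = []
        for i in range(n):
            rows.append((f"I{i}", "C", "GA", 350, "A", "T",
                         rng.normal(shift), np.nan))
        for i in range(n):
            rows.append((f"O{i}", "C", "GA", 200, "A", "T",
                         rng.normal(0.0), np.nan))
        return pd.DataFrame(rows, columns=["sample", "cancer", "gene",
                                           "protein_pos", "ref_aa", "alt_aa",
                                           "conservation", "cadd"])

    def test_planted_shift_detected(self, tiny_annotation):
        table = self._table(np.random.default_rng(0))
        results = {r.score_name: r for r in
                   me.compare_impact_scores(table, tiny_annotation)}
        r = results["conservation"]
        assert r.p_value < 1e-6 and r.direction > 0
        assert r.n_in == 200 and r.n_out == 200

    def test_all_missing_score_skipped(self, tiny_annotation, caplog):
        table = self._table(np.random.default_rng(0))
        with caplog.at_level(logging.WARNING):
            results = me.compare_impact_scores(table, tiny_annotation)
        assert {r.score_name for r in results} == {"conservation"}
        assert any("cadd" in r.message for r in caplog.records)

    def test_sift_damaging_transform_flips_direction(self, tiny_annotation):
        rng = np.random.default_rng(1)
        table = self._table(rng).rename(columns={"conservation": "sift"})
        # in-domain sift values are *larger* here; with the 1 - SIFT transform
        # the reported direction must flip relative to the raw comparison
        raw = me.compare_impact_scores(table, tiny_annotation,
                                       damaging_orient_sift=False)[0]
        oriented = me.compare_impact_scores(table, tiny_annotation)[0]
        assert raw.direction == -oriented.direction
        assert raw.p_value == pytest.approx(oriented.p_value)

    def test_null_scores_give_large_p_on_average(self, tiny_annotation):
        ps = []
        for seed in range(20):
            table = self._table(np.random.default_rng(seed), n=50, shift=0.0)
            (r,) = me.compare_impact_scores(table, tiny_annotation)
            ps.append(r.p_value)
        assert np.mean(ps) > 0.2  # roughly uniform p under the null


def test_residue_tally_counts_events_and_samples(tiny_annotation):
    rows = [("P1", "C", "GA", 456, "R", "C"), ("P2", "C", "GA", 456, "R", "C"),
            ("P1", "C", "GA", 10, "A", "T")]
    table = pd.DataFrame(rows, columns=["sample", "cancer", "gene",
                                        "protein_pos", "ref_aa", "alt_aa"])
    tally = me.residue_mutation_tally(table, tiny_annotation)
    hot = tally.loc[tally["protein_pos"] == 456].iloc[0]
    assert hot.n_events == 2 and hot.n_samples == 2
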