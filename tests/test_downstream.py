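"""SNP-to-gene aggregation, QC filters, trajectory classification, exact
Fisher testing and chromatin-state association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from daesc.downstream import (ChromatinStateTrack, DASEClassInput,
                              _matching_rules, aggregate_phased,
                              aggregate_unphased, allelic_ratio,
                              chromatin_assoc, classify_dase, classify_table,
                              filter_coverage, filter_monoallelic,
                              fisher_2x3_bruteforce, fisher_exact_2x3,
                              recode_chromatin)


def _snp_row(snp, donor, cell, ref, alt, hap=1, gene="G1"):
    return {"snp": snp, "gene": gene, "donor": donor, "cell": cell,
            "ref_count": ref, "alt_count": alt, "hap_of_alt": hap}


class TestAggregatePhased:
    def test_two_snp_manual_sum(self):
        # SNP-A alt on hap1 (alt=3, ref=1); SNP-B alt on hap2 (alt=2,
        # ref=4): hap1 = 3 + 4 = 7, hap2 = 1 + 2 = 3
        recs = pd.DataFrame([_snp_row("A", "d1", "c1", 1, 3, hap=1),
                             _snp_row("B", "d1", "c1", 4, 2, hap=2)])
        out = aggregate_phased(recs)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["total_count"] == 10
        # top tSNP is B (6 reads > 4); its alt is on hap2, so the gene's
        # alternative haplotype count is hap2 = 3
        assert row["alt_count"] == 3

    def test_single_snp_passthrough(self):
        recs = pd.DataFrame([_snp_row("A", "d1", "c1", 2, 5, hap=1)])
        out = aggregate_phased(recs)
        assert out.iloc[0]["alt_count"] == 5
        assert out.iloc[0]["total_count"] == 7

    def test_read_conservation(self):
        rng = np.random.default_rng(0)
        rows = []
        for snp in "ABC":
            for cell in range(4):
                rows.append(_snp_row(snp, "d1", f"c{cell}",
                                     int(rng.integers(0, 9)),
                                     int(rng.integers(0, 9)),
                                     hap=1 + (snp == "B")))
        recs = pd.DataFrame(rows)
        out = aggregate_phased(recs)
        assert out["total_count"].sum() == \
            (recs["ref_count"] + recs["alt_count"]).sum()

    def test_homozygous_top_tsnp_random_anchor_is_seeded(self):
        rows = [_snp_row("A", "d1", "c1", 1, 9, hap=1),
                _snp_row("B", "d1", "c1", 2, 3, hap=2),
                # donor d2 has no record at the top tSNP (A) -> random
                _snp_row("B", "d2", "c1", 4, 4, hap=1)]
        recs = pd.DataFrame(rows)
        out1 = aggregate_phased(recs, seed=5)
        out2 = aggregate_phased(recs, seed=5)
        pd.testing.assert_frame_equal(out1, out2)

    def test_mixed_phase_rejected(self):
        recs = pd.DataFrame([_snp_row("A", "d1", "c1", 1, 3, hap=1),
                             _snp_row("B", "d1", "c1", 4, 2,
                                      hap="unknown")])
        with pytest.raises(ValueError, match="unphased"):
            aggregate_phased(recs)


class TestAggregateUnphased:
    def test_minor_allele_rule_single_snp(self):
        recs = pd.DataFrame([_snp_row("A", "d1", "c1", 30, 10)])
        out = aggregate_unphased(recs)
        assert out.iloc[0]["alt_count"] == 10
        assert out.iloc[0]["total_count"] == 40

    def test_two_snp_manual_rule(self):
        # pooled (alt, ref): A = (10, 30) minor=alt=10; B = (25, 5)
        # minor=ref=5 -> gene alt = 15, total = 70
        recs = pd.DataFrame([_snp_row("A", "d1", "c1", 30, 10),
                             _snp_row("B", "d1", "c1", 5, 25)])
        out = aggregate_unphased(recs)
        assert out.iloc[0]["alt_count"] == 15
        assert out.iloc[0]["total_count"] == 70

    def test_tie_broken_toward_alternative(self):
        recs = pd.DataFrame([_snp_row("A", "d1", "c1", 7, 7)])
        out = aggregate_unphased(recs)
        assert out.iloc[0]["alt_count"] == 7

    def test_minor_allele_determined_from_pooled_cells(self):
        # per-cell counts disagree; pooled (alt=6, ref=9) -> minor is alt
        recs = pd.DataFrame([_snp_row("A", "d1", "c1", 1, 5),
                             _snp_row("A", "d1", "c2", 8, 1)])
        out = aggregate_unphased(recs)
        assert list(out["alt_count"]) == [5, 1]


class TestFilters:
    def test_monoallelic_thresholds(self):
        rows = [_snp_row("A", "d1", f"c{i}", 99, 1) for i in range(2)]
        rows += [_snp_row("B", "d1", f"c{i}", 50, 50) for i in range(2)]
        rows += [_snp_row("C", "d1", "c0", 98, 2)]  # exactly 0.02: kept
        recs = pd.DataFrame(rows)
        out = filter_monoallelic(recs, low=0.02, high=0.98)
        assert set(out["snp"]) == {"B", "C"}

    def test_monoallelic_idempotent(self):
        rows = [_snp_row(s, d, "c0", int(r), int(a))
                for s, d, r, a in [("A", "d1", 99, 1), ("B", "d1", 6, 4),
                                   ("B", "d2", 3, 5)]]
        recs = pd.DataFrame(rows)
        once = filter_monoallelic(recs)
        twice = filter_monoallelic(once)
        pd.testing.assert_frame_equal(once, twice)

    def _gene_table(self, gene, donors_cells, nonzero=True):
        rows = []
        for donor, n_cells, reads in donors_cells:
            for c in range(n_cells):
                tot = reads if nonzero else 0
                rows.append({"gene": gene, "donor": donor, "cell":
                             f"{donor}c{c}", "alt_count": tot // 2,
                             "total_count": tot})
        return pd.DataFrame(rows)

    def test_endoderm_sparse_gene_removed(self):
        sparse = self._gene_table("G1", [("d1", 20, 5)])
        sparse.loc[3:, "total_count"] = 0  # 3/20 = 15% non-zero
        sparse.loc[3:, "alt_count"] = 0
        dense = self._gene_table("G2", [("d1", 20, 5)])
        table = pd.concat([sparse, dense], ignore_index=True)
        out, tally = filter_coverage(table, preset="endoderm")
        assert set(out["gene"]) == {"G2"}
        assert tally["nonzero<=20%-of-cells"] == 1

    def test_pancreatic_donor_and_gene_rules(self):
        keep = self._gene_table("G1", [("d1", 20, 6), ("d2", 20, 6),
                                       ("d3", 20, 6), ("d4", 20, 6)])
        # donor with 2 cells is pruned before gene-level checks
        drop_donor = self._gene_table("G1", [("d5", 2, 6)])
        small = self._gene_table("G2", [("d1", 10, 6), ("d2", 10, 6),
                                        ("d3", 10, 6), ("d4", 10, 6)])
        table = pd.concat([keep, drop_donor, small], ignore_index=True)
        cond = {"d1": 1, "d2": 1, "d3": 0, "d4": 0, "d5": 1}
        out, tally = filter_coverage(table, preset="pancreatic",
                                     condition=cond)
        assert set(out["gene"]) == {"G1"}
        assert "d5" not in set(out["donor"])
        assert tally["gene<50cells"] == 1

    def test_pancreatic_requires_labels(self):
        table = self._gene_table("G1", [("d1", 5, 6)])
        with pytest.raises(ValueError, match="label"):
            filter_coverage(table, preset="pancreatic")


class TestClassification:
    def test_allelic_ratio_values(self):
        assert allelic_ratio(0.0, 0.0, 0.3) == 0.5
        assert allelic_ratio(0.0, 2.0, 1.0) == pytest.approx(0.8808, abs=1e-4)
        # sign flip reflects around 0.5
        assert allelic_ratio(0.4, -1.0, 0.7) == pytest.approx(
            1.0 - allelic_ratio(-0.4, 1.0, 0.7))

    @pytest.mark.parametrize("p_start,p_end,want", [
        (0.50, 0.62, "late"),
        (0.40, 0.35, "increasing"),
        (0.40, 0.60, "switching"),
        (0.49, 0.51, "unspecified"),
        (0.35, 0.42, "decreasing"),
        (0.58, 0.505, "early"),
    ])
    def test_rule_examples(self, p_start, p_end, want):
        matches = _matching_rules(p_start, p_end)
        got = matches[0] if matches else "unspecified"
        assert got == want

    @given(st.floats(0.001, 0.999), st.floats(0.001, 0.999))
    @settings(max_examples=400, deadline=None)
    def test_rules_mutually_exclusive(self, p_start, p_end):
        assert len(_matching_rules(p_start, p_end)) <= 1

    def test_classify_from_coefficients(self):
        inp = DASEClassInput(beta0=0.0, beta1=2.0, t_start=0.0, t_end=1.0)
        assert classify_dase(inp) == "late"

    def test_classify_table_sorted_by_gene(self):
        df = pd.DataFrame({"gene": ["b", "a"], "beta0": [0.0, 1.0],
                           "beta1": [2.0, 0.0]})
        out = classify_table(df, t_start=0.0, t_end=1.0)
        assert list(out["gene"]) == ["a", "b"]


class TestFisher2x3:
    def test_reduces_to_two_by_two(self):
        # the zero column collapses; classical 2x2 answer 34/70
        p, exact = fisher_exact_2x3([[3, 1, 0], [1, 3, 0]])
        assert exact
        assert p == pytest.approx(34 / 70, abs=1e-10)
        assert p == pytest.approx(
            fisher_exact([[3, 1], [1, 3]]).pvalue, abs=1e-10)

    def test_identical_rows_p_one(self):
        p, _ = fisher_exact_2x3([[2, 3, 4], [2, 3, 4]])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_strong_association_small_p(self):
        p, _ = fisher_exact_2x3([[5, 0, 0], [0, 5, 0]])
        assert p < 0.01

    def test_matches_bruteforce_oracle_small_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(150):
            t = rng.integers(0, 6, size=(2, 3))
            if t.sum() == 0:
                continue
            p, exact = fisher_exact_2x3(t)
            assert exact
            assert p == pytest.approx(fisher_2x3_bruteforce(t), abs=1e-9)

    def test_matches_scipy_on_2x2_margins(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            t = rng.integers(0, 10, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            t3 = np.column_stack([t, [0, 0]])
            p, _ = fisher_exact_2x3(t3)
            assert p == pytest.approx(fisher_exact(t).pvalue, abs=1e-9)

    def test_monte_carlo_branch_close_to_exact_rule(self):
        t = np.array([[120, 90, 100], [80, 110, 105]])  # total > 500
        p_mc, exact = fisher_exact_2x3(t, seed=1, n_mc=60_000)
        assert not exact
        from scipy.stats import chi2_contingency
        p_chi = chi2_contingency(t).pvalue
        assert p_mc == pytest.approx(p_chi, abs=0.05)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x3([[1, -2, 3], [1, 1, 1]])


class TestChromatin:
    def test_active_state_recoding(self):
        t = ChromatinStateTrack("g", [5], 9)
        assert recode_chromatin(t) == 1.0
        t2 = ChromatinStateTrack("g", [9], 9)
        assert recode_chromatin(t2) == 0.0

    def test_average_over_start_epigenomes(self):
        t = ChromatinStateTrack("g", [1, 1, 9, 1, 1], 9)
        assert recode_chromatin(t) == pytest.approx(0.8)

    def test_no_change_when_activity_equal(self):
        t = ChromatinStateTrack("g", [3, 4], 6)
        assert recode_chromatin(t) == 0.0

    def test_state_code_bounds(self):
        with pytest.raises(ValueError):
            ChromatinStateTrack("g", [0], 5)
        with pytest.raises(ValueError):
            ChromatinStateTrack("g", [1], 16)

    def test_assoc_recovers_planted_group_shift(self):
        rng = np.random.default_rng(10)
        n = 2000
        flag = rng.integers(0, 2, n)
        depth = rng.gamma(4, 200, n)
        change = 0.1 * flag + rng.normal(0, 0.25, n)
        D, p, means = chromatin_assoc(change, flag, depth)
        assert 0.07 <= D <= 0.13
        assert p < 0.01

    def test_assoc_adjusts_for_depth_confounding(self):
        rng = np.random.default_rng(11)
        ds = []
        for _ in range(20):
            n = 600
            flag = rng.integers(0, 2, n)
            depth = rng.gamma(4, 100, n)
            change = 0.0005 * depth + rng.normal(0, 0.2, n)
            D, p, _ = chromatin_assoc(change, flag, depth)
            ds.append(D)
        assert abs(np.mean(ds)) < 0.02

    def test_constant_change_degenerate(self):
        D, p, _ = chromatin_assoc([0.3] * 10, [1] * 5 + [0] * 5,
                                  range(10))
        assert D == 0.0 and p == 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            chromatin_assoc([0.1, 0.2, 0.3], [1, 0, 0], [1, 2, 3])
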