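"""ORA statistics: GMT parsing, hypergeometric p, BH FDR, enrichment ratios.

The hypergeometric upper tail is checked against an exhaustive enumeration
oracle: for tiny universes every possible draw of the input list is
enumerated with exact rational arithmetic and the tail probability counted
directly.
"""

import io
import itertools
from fractions import Fraction

import numpy as np
import pytest

from addscreen.enrichment import (
    GeneSet,
    adjust_fdr,
    build_er_matrix,
    enrich_chemical,
    filter_gene_sets,
    ora_test,
    parse_gmt,
)


def enumeration_tail_p(background_size, set_size, input_size, min_overlap):
    """P(overlap >= min_overlap) by enumerating all C(M, N) draws exactly."""
    population = range(background_size)
    successes = set(range(set_size))
    hits = total = 0
    for draw in itertools.combinations(population, input_size):
        total += 1
        if len(successes.intersection(draw)) >= min_overlap:
            hits += 1
    return Fraction(hits, total)


class TestParseGmt:
    def test_basic_line(self):
        sets = parse_gmt(io.StringIO("WP530\tcytokines\tIL6\tCXCL8\n"))
        assert len(sets) == 1
        assert sets[0].genes == {"IL6", "CXCL8"}

    def test_duplicate_members_collapsed(self):
        sets = parse_gmt(io.StringIO("S\tdesc\t1\t2\t2\t3\n"))
        assert sets[0].genes == {1, 2, 3}

    def test_malformed_line_names_line_number(self):
        with pytest.raises(ValueError, match="line 3"):
            parse_gmt(io.StringIO("S\tdesc\t1\n\nS2\tonly-two-fields\n"))

    def test_empty_lines_skipped(self):
        sets = parse_gmt(io.StringIO("\nS\td\t5\t6\n\n"))
        assert len(sets) == 1


class TestFilterGeneSets:
    BG = frozenset(range(1, 101))

    def gs(self, n, start=1):
        return GeneSet("S", "s", frozenset(range(start, start + n)))

    def test_too_small_removed(self):
        assert filter_gene_sets([self.gs(9)], self.BG) == []

    def test_intersection_first(self):
        # 15 members but only 8 inside the background -> effective size 8
        gs = GeneSet("S", "s", frozenset(range(94, 109)))
        assert filter_gene_sets([gs], self.BG) == []

    def test_boundary_inclusive(self):
        kept = filter_gene_sets([self.gs(10)], self.BG)
        assert len(kept) == 1 and len(kept[0].genes) == 10

    def test_max_boundary(self):
        assert filter_gene_sets([self.gs(11)], self.BG, max_size=10) == []


class TestOraTest:
    def test_printed_formula(self):
        # input 5, set 10, background 100, overlap 2 -> expect 0.5, ER 4
        bg = frozenset(range(100))
        gs = GeneSet("S", "s", frozenset(range(10)))
        res = ora_test({0, 1, 90, 91, 92}, gs, bg)
        assert res.overlap == 2
        assert res.expect == pytest.approx(0.5)
        assert res.er == pytest.approx(4.0)

    def test_enumeration_small_case(self):
        # drawing 4 from 10 with 5 successes, all 4 hits: 5 of C(10,4)=210 draws
        bg = frozenset(range(10))
        gs = GeneSet("S", "s", frozenset(range(5)))
        res = ora_test({0, 1, 2, 3}, gs, bg)
        assert res.p == pytest.approx(5 / 210, abs=1e-15)

    def test_zero_overlap(self):
        bg = frozenset(range(20))
        gs = GeneSet("S", "s", frozenset(range(5)))
        res = ora_test({10, 11}, gs, bg)
        assert res.p == 1.0 and res.er == 0.0

    def test_matches_enumeration_oracle(self):
        """Exact agreement with full enumeration for backgrounds up to 15."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            M = int(rng.integers(4, 16))
            s = int(rng.integers(1, M))
            n = int(rng.integers(1, M - 1))
            bg = frozenset(range(M))
            gs = GeneSet("S", "s", frozenset(range(s)))
            inp = set(int(x) for x in rng.choice(M, size=n, replace=False))
            res = ora_test(inp, gs, bg)
            expected = enumeration_tail_p(M, s, n, res.overlap)
            assert abs(res.p - float(expected)) < 1e-12

    def test_p_nonincreasing_in_overlap(self):
        bg = frozenset(range(40))
        ps = []
        for overlap in range(0, 6):
            gs = GeneSet("S", "s", frozenset(range(10)))
            inp = set(range(overlap)) | set(range(30, 40 - overlap))
            res = ora_test(inp, gs, bg)
            assert res.overlap == overlap and res.input_size == 10
            ps.append(res.p)
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_er_scale_invariance(self):
        bg1 = frozenset(range(50))
        gs1 = GeneSet("S", "s", frozenset(range(10)))
        r1 = ora_test(set(range(5)) | {40}, gs1, bg1)
        bg2 = frozenset(range(100))
        gs2 = GeneSet("S", "s", frozenset(range(20)))
        r2 = ora_test(set(range(10)) | {80, 81}, gs2, bg2)
        assert r1.er == pytest.approx(r2.er)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            ora_test(set(), GeneSet("S", "s", frozenset({1})), frozenset(range(5)))


class TestAdjustFdr:
    def test_stepup_hand_example(self):
        got = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_identity(self):
        assert adjust_fdr([0.5]) == pytest.approx([0.5])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, size=30)
        assert np.all(adjust_fdr(p) >= p - 1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(200):
            m = int(rng.integers(1, 51))
            p = rng.uniform(1e-9, 1, size=m)
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.max(np.abs(adjust_fdr(p) - q_ref)) < 1e-12

    def test_rejection_set_equals_classic_stepup(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            m = int(rng.integers(2, 40))
            p = rng.uniform(1e-9, 1, size=m)
            alpha = float(rng.uniform(0.01, 0.5))
            q = adjust_fdr(p)
            # classic step-up: largest i with p_(i) <= i*alpha/m rejects 1..i
            order = np.argsort(p)
            thresh = (np.arange(1, m + 1) * alpha) / m
            passing = np.nonzero(p[order] <= thresh)[0]
            classic = set(order[: passing.max() + 1]) if passing.size else set()
            assert set(np.nonzero(q <= alpha)[0]) == classic

    def test_invalid_p_rejected(self):
        for bad in ([0.0], [1.5], [-0.1], [float("nan")]):
            with pytest.raises(ValueError):
                adjust_fdr(bad)


class TestEnrichChemical:
    BG = frozenset(range(1, 1001))

    def decoys(self, n, size=10):
        """Gene sets disjoint from 1..10 (drawn from 500..)."""
        out = []
        for i in range(n):
            start = 500 + i * size
            out.append(GeneSet(f"D{i:03d}", f"decoy {i}", frozenset(range(start, start + size))))
        return out

    def test_perfect_overlap_significant(self):
        target = GeneSet("T", "target", frozenset(range(1, 11)))
        res = enrich_chemical("x", set(range(1, 11)), [target] + self.decoys(40), self.BG)
        assert [r.set_id for r in res] == ["T"]

    def test_disjoint_input_empty_result(self):
        res = enrich_chemical("x", {900, 901, 902}, self.decoys(10), self.BG)
        assert res == []

    def test_phentin_style_six_sets_pass(self):
        """5 input genes planted in 6 pathway sets -> exactly those 6 pass."""
        input_genes = set(range(1, 6))
        planted = [
            GeneSet(f"P{i}", f"prostate signaling {i}",
                    frozenset(input_genes | set(range(100 + 10 * i, 105 + 10 * i))))
            for i in range(6)
        ]
        res = enrich_chemical("900-95-8", input_genes, planted + self.decoys(30), self.BG)
        assert sorted(r.set_id for r in res) == [f"P{i}" for i in range(6)]

    def test_collection_order_invariant(self):
        target = GeneSet("T", "t", frozenset(range(1, 11)))
        coll = [target] + self.decoys(20)
        a = enrich_chemical("x", set(range(1, 9)), coll, self.BG)
        b = enrich_chemical("x", set(range(1, 9)), list(reversed(coll)), self.BG)
        assert a == b

    def test_fdr_at_least_p(self):
        target = GeneSet("T", "t", frozenset(range(1, 11)))
        res = enrich_chemical("x", set(range(1, 11)), [target] + self.decoys(20), self.BG)
        assert all(r.fdr >= r.p for r in res)


class TestErMatrix:
    def test_single_significant_cell(self):
        from addscreen.enrichment import OraResult

        res = {
            "a": [OraResult("a", "S1", 2, 5, 10, 100, 0.5, 4.0, 0.01, 0.02)],
            "b": [],
        }
        mat = build_er_matrix(res, chemicals=["a", "b"], set_ids=["S1", "S2", "S3"])
        assert mat.shape == (2, 3)
        assert mat.loc["a", "S1"] == 4.0
        assert (mat.to_numpy() != 0).sum() == 1

    def test_default_rows_require_results(self):
        from addscreen.enrichment import OraResult

        res = {
            "a": [OraResult("a", "S1", 2, 5, 10, 100, 0.5, 4.0, 0.01, 0.02)],
            "b": [],
        }
        mat = build_er_matrix(res)
        assert list(mat.index) == ["a"]

    def test_row_sums_equal_significant_er_sums(self, strong_results, strong_er):
        for cas in strong_er.index[:10]:
            assert strong_er.loc[cas].sum() == pytest.approx(
                sum(r.er for r in strong_results[cas])
            )

    def test_all_zero_when_no_significant(self):
        mat = build_er_matrix({"a": []}, chemicals=["a"], set_ids=["S1"])
        assert mat.shape == (1, 1) and (mat.to_numpy() == 0).all()
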