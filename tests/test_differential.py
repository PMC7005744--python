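"""Fisher exact test, BH-FDR, contrast calling, and the bidirectional join."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sicall.differential import (
    ContrastResult,
    Thresholds,
    bh_fdr,
    call_contrast,
    fisher_exact_2x2,
    join_bidirectional,
    passes_filters,
    read_contrast_results,
    write_contrast_results,
)
from sicall.quantify import EventQuantification


def fisher_oracle(a, b, c, d):
    """Independent enumeration over all tables with the observed margins,
    using scipy's hypergeometric pmf."""
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2
    lo, hi = max(0, k - n2), min(k, n1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, n1, k)
    obs = pmf[a - lo]
    return float(pmf[pmf <= obs * (1 + 1e-9)].sum())


class TestFisherExact:
    def test_disjoint_table_enumerates_to_2_over_252(self):
        # margins (5,5,5,5): 6 admissible tables; only the two extreme
        # ones have probability <= 1/252
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(
            2 / 252, rel=1e-12
        )

    def test_balanced_table_p_is_one(self):
        assert fisher_exact_2x2([[3, 3], [3, 3]]) == 1.0

    def test_matches_enumeration_oracle_on_asymmetric_table(self):
        assert fisher_exact_2x2([[12, 3], [4, 11]]) == pytest.approx(
            fisher_oracle(12, 3, 4, 11), rel=1e-9
        )

    @settings(max_examples=150, deadline=None)
    @given(
        a=st.integers(0, 30),
        b=st.integers(0, 30),
        c=st.integers(0, 30),
        d=st.integers(0, 30),
    )
    def test_matches_scipy_cross_check(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        ours = fisher_exact_2x2([[a, b], [c, d]])
        scipys = stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(scipys, rel=1e-9, abs=1e-12)

    def test_row_swap_leaves_p_unchanged(self):
        assert fisher_exact_2x2([[12, 3], [4, 11]]) == pytest.approx(
            fisher_exact_2x2([[4, 11], [12, 3]]), rel=1e-12
        )

    @pytest.mark.parametrize("bad", [[[1, -1], [0, 2]], [[0.5, 1], [2, 2]]])
    def test_invalid_cells_rejected(self, bad):
        with pytest.raises(ValueError):
            fisher_exact_2x2(bad)


def bh_reference(pvals):
    """Quadratic-time BH step-up: q_i = min over j with p_j >= p_i of
    p_j * m / rank(p_j), capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, pvals[i] * m / (rank_from_top + 1))
        adjusted[i] = running_min
    return adjusted


class TestBhFdr:
    def test_uniform_grid_collapses_to_largest(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_is_identity(self):
        assert bh_fdr([0.5]) == [0.5]

    def test_empty_list(self):
        assert bh_fdr([]) == []

    @settings(max_examples=100, deadline=None)
    @given(
        pvals=st.lists(
            st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=60
        )
    )
    def test_matches_quadratic_reference_and_preserves_order(self, pvals):
        ours = bh_fdr(pvals)
        ref = bh_reference(pvals)
        assert ours == pytest.approx(ref, rel=1e-10)
        # monotone transform: order of distinct p-values is preserved
        for i in range(len(pvals)):
            for j in range(len(pvals)):
                if pvals[i] < pvals[j]:
                    assert ours[i] <= ours[j] + 1e-12


def quant(eid, inc, skip):
    return {eid: EventQuantification(eid, "s", inc, skip)}


class TestCallContrast:
    def test_low_total_fails_regardless_of_significance(self):
        res = call_contrast(
            [quant("e", 9, 0)], [quant("e", 0, 30)], "c"
        )
        (r,) = res
        assert r.total_junction_reads == 9
        assert not r.passes_filters

    def test_small_delta_si_fails(self):
        res = call_contrast(
            [quant("e", 599, 401)], [quant("e", 500, 500)], "c"
        )
        (r,) = res
        assert r.delta_si == pytest.approx(0.099)
        assert not r.passes_filters

    def test_passing_event(self):
        res = call_contrast(
            [quant("e", 50, 150)], [quant("e", 90, 90)], "c"
        )
        (r,) = res
        assert r.delta_si == pytest.approx(-0.25)
        assert r.passes_filters

    def test_event_absent_from_one_arm_flagged_untested(self):
        res = call_contrast([quant("e", 10, 10)], [{}], "c")
        (r,) = res
        assert not r.tested and not r.passes_filters

    def test_replicates_pooled_by_count_summation(self):
        res = call_contrast(
            [quant("e", 30, 10), quant("e", 30, 10)],
            [quant("e", 20, 20)],
            "c",
        )
        (r,) = res
        assert r.si_treatment == pytest.approx(60 / 80)

    def test_treatment_control_swap_negates_delta_and_keeps_p(self):
        fwd = call_contrast([quant("e", 50, 150)], [quant("e", 90, 90)], "c")[0]
        rev = call_contrast([quant("e", 90, 90)], [quant("e", 50, 150)], "c")[0]
        assert rev.delta_si == pytest.approx(-fwd.delta_si)
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-12)

    def test_fdr_pooled_across_events_of_contrast(self):
        t = [{**quant("e1", 100, 100), **quant("e2", 195, 5)}]
        c = [{**quant("e1", 100, 100), **quant("e2", 100, 100)}]
        res = {r.event_id: r for r in call_contrast(t, c, "c")}
        # two tests: BH multiplies the smaller p by 2 (then caps/min)
        assert res["e2"].fdr == pytest.approx(min(res["e2"].p_value * 2, 1.0))


def result(eid, dsi, passing=True, cid="c"):
    return ContrastResult(
        eid, cid, None, None, dsi, 1e-4, fdr=1e-3,
        total_junction_reads=100, passes_filters=passing,
    )


class TestJoinBidirectional:
    def test_opposite_signs_called_strict(self):
        calls = join_bidirectional(
            [[result("e", +0.12)]], [[result("e", -0.15)]], "strict"
        )
        assert len(calls) == 1 and calls[0].direction_consistent

    def test_same_sign_not_called(self):
        assert (
            join_bidirectional(
                [[result("e", +0.12)]], [[result("e", +0.20)]], "strict"
            )
            == []
        )

    def test_zero_delta_never_called(self):
        for mode in ("strict", "relaxed"):
            assert (
                join_bidirectional(
                    [[result("e", 0.0)]], [[result("e", -0.2)]], mode
                )
                == []
            )

    def test_strict_requires_all_contrasts_pass(self):
        kd = [[result("e", +0.12, cid="kd1")], [result("e", +0.2, passing=False, cid="kd2")]]
        oe = [[result("e", -0.15, cid="oe1")]]
        assert join_bidirectional(kd, oe, "strict") == []
        calls = join_bidirectional(kd, oe, "relaxed")
        assert len(calls) == 1
        assert calls[0].satisfying_pairs == [("kd1", "oe1")]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            join_bidirectional([[result("e", 0.1)]], [[result("e", -0.1)]], "odd")


def test_passes_filters_inequalities():
    th = Thresholds()
    assert passes_filters(15, 0.10, 0.199, th)
    assert not passes_filters(14, 0.30, 0.01, th)
    assert not passes_filters(100, 0.099, 0.01, th)
    assert not passes_filters(100, 0.30, 0.2, th)


def test_contrast_results_tsv_round_trip(tmp_path):
    res = call_contrast(
        [quant("e1", 50, 150)], [quant("e1", 90, 90)], "c"
    ) + [ContrastResult("e2", "c", None, None, None, None, tested=False)]
    p = tmp_path / "res.tsv"
    write_contrast_results(res, p)
    back = read_contrast_results(p)
    assert [r.event_id for r in back] == ["e1", "e2"]
    assert back[0].delta_si == pytest.approx(res[0].delta_si)
    assert back[0].passes_filters == res[0].passes_filters
    assert back[1].tested is False
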