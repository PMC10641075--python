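"""Allelic LRT, BH, signed-rank and enrichment against enumeration oracles."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from utrmpra.differential import (
    FilterThresholds,
    bh_adjust,
    direction_enrichment,
    grid_search_filter,
    lrt_pair_test,
    paired_signed_rank,
    compare_pairs,
)
from utrmpra.quantify import barcode_activity


class TestLrtPairTest:
    def test_identical_sides_null(self):
        y = np.tile([0.1, 0.2, 0.3], 4)
        bc = np.repeat(np.arange(4), 3)
        side = np.repeat([0, 1], 6)
        res = lrt_pair_test(y, bc, side)
        assert abs(res.log2fc) < 1e-8
        assert res.p_value > 0.9
        assert res.n_barcodes_a == res.n_barcodes_b == 2

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(5)
        bc = np.repeat(np.arange(12), 6)
        side = np.repeat([0, 1], 36)
        y = rng.normal(0, 0.1, 72) + side
        res = lrt_pair_test(y, bc, side)
        assert 0.8 < res.log2fc < 1.2
        assert res.p_value < 1e-6

    def test_null_rejection_rate_calibrated(self):
        # sigma_b = 0: LRT should reject at ~alpha
        rng = np.random.default_rng(1234)
        bc = np.repeat(np.arange(12), 6)
        side = np.repeat([0, 1], 36)
        rej = sum(
            lrt_pair_test(rng.normal(0, 0.15, 72), bc, side).p_value < 0.05
            for _ in range(1000)
        )
        assert 0.035 <= rej / 1000 <= 0.065

    def test_anticonservative_with_barcode_effects(self):
        # few barcodes + barcode-level variance inflates the false-positive
        # rate above nominal alpha
        rng = np.random.default_rng(99)
        k = 3
        bc = np.repeat(np.arange(2 * k), 6)
        side = np.repeat([0, 1], 6 * k)
        rej = 0
        for _ in range(500):
            b = rng.normal(0, 0.3, 2 * k)
            y = np.repeat(b, 6) + rng.normal(0, 0.1, 12 * k)
            rej += lrt_pair_test(y, bc, side).p_value < 0.05
        assert rej / 500 > 0.05


def _bh_oracle(p):
    """Direct step-up formula: cumulative min of p * m / rank."""
    p = np.asarray(p, float)
    order = np.argsort(p, kind="mergesort")
    m = p.size
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBhAdjust:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.5]).tolist() == [0.5]

    def test_empty(self):
        assert bh_adjust([]).size == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula(self, seed):
        p = np.random.default_rng(seed).uniform(1e-6, 1, 40)
        assert np.allclose(bh_adjust(p), _bh_oracle(p))

    def test_order_preserving(self):
        p = np.random.default_rng(8).uniform(1e-6, 1, 100)
        q = bh_adjust(p)
        idx = np.argsort(p)
        assert (np.diff(q[idx]) >= -1e-12).all()


def _signed_rank_oracle(d):
    """Exact two-sided p by enumerating all sign assignments (tie-free d)."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = []
    for signs in product([0, 1], repeat=n):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    dist = np.asarray(dist)
    p_low = np.mean(dist <= w_obs)
    p_high = np.mean(dist >= w_obs)
    return min(1.0, 2 * min(p_low, p_high))


class TestSignedRank:
    def test_identical_vectors_degenerate(self):
        res = paired_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.degenerate

    def test_all_positive_differences_exact(self):
        # all 2^6 sign assignments: two-sided p = 2/64
        a = np.array([1.0, 2, 3, 4, 5, 6])
        res = paired_signed_rank(a, np.zeros(6))
        assert res.p_value == pytest.approx(2 / 64)

    @pytest.mark.parametrize("n", [5, 7, 10])
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        a = rng.normal(0.2, 1.0, n)
        b = rng.normal(0.0, 1.0, n)
        res = paired_signed_rank(a, b)
        assert res.p_value == pytest.approx(_signed_rank_oracle(a - b))

    def test_large_shifted_sample_significant(self):
        rng = np.random.default_rng(4)
        b = rng.normal(0, 1, 300)
        a = b + rng.normal(0.5, 0.1, 300)
        res = paired_signed_rank(a, b)
        assert res.p_value < 1e-3


def _hypergeom_tail(table):
    """One-sided (greater) Fisher p from the hypergeometric pmf."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, col1, row1)
    return float(rv.sf(a - 1))


class TestDirectionEnrichment:
    def test_balanced_table_null(self):
        res = direction_enrichment(5, 5, (20, 20))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value >= 0.5

    def test_enriched_table_matches_hypergeometric(self):
        res = direction_enrichment(9, 1, (5, 5))
        assert res.odds_ratio == pytest.approx(9.0)
        assert res.p_value == pytest.approx(_hypergeom_tail([[9, 1], [5, 5]]))

    def test_degenerate_margins(self):
        res = direction_enrichment(0, 0, (3, 4))
        assert res.degenerate and res.p_value == 1.0


def _brute_force_filter(act, pairs, mb, mr):
    """Independent re-implementation of the inclusion rule."""
    kept = []
    for cid, el_a, el_b in pairs:
        n_pass = 0
        for rep in sorted(act["replicate"].unique()):
            sub = act[act["replicate"] == rep]
            na = sub[sub["element_id"] == el_a]["barcode_id"].nunique()
            nb = sub[sub["element_id"] == el_b]["barcode_id"].nunique()
            if na >= mb and nb >= mb:
                n_pass += 1
        if n_pass >= mr:
            kept.append(cid)
    return kept


class TestGridSearch:
    def test_thresholds_validate_count_floor(self):
        with pytest.raises(ValueError):
            FilterThresholds(min_count=5, min_barcodes=3, min_replicates=4)

    def test_reported_threshold_settings_and_oracle(self, sim_table, small_design):
        table, _, beta = sim_table
        pairs = [
            (v.variant_id, f"{v.variant_id}_ref", f"{v.variant_id}_alt")
            for v in small_design.variants
        ]
        # the in vitro (>=3 BC, >=10 counts, >=4 reps) and in vivo
        # (>=5 BC, >=10 counts, 6 reps) settings are representable points
        thresholds, audit = grid_search_filter(
            table,
            small_design,
            pairs,
            count_grid=[10],
            barcode_grid=[3, 5],
            replicate_grid=[4, 6],
        )
        assert {(10, 3, 4), (10, 5, 6)} <= set(
            map(tuple, audit[["min_count", "min_barcodes", "min_replicates"]].values)
        )
        assert isinstance(thresholds, FilterThresholds)

        # audit counts reproduce an independent brute-force re-filter
        b2e = small_design.barcode_to_element()
        act = barcode_activity(table, min_count=10)
        act = act.assign(element_id=act["barcode_id"].map(b2e))
        for _, row in audit.iterrows():
            kept = _brute_force_filter(
                act, pairs, row["min_barcodes"], row["min_replicates"]
            )
            assert row["n_testable"] == len(kept)
            res = compare_pairs(
                act, [p for p in pairs if p[0] in kept], fdr=0.05
            )
            assert row["n_significant"] == int(res["significant"].sum())

    def test_planted_effects_called_significant(self, sim_table, small_design):
        table, _, beta = sim_table
        pairs = [
            (v.variant_id, f"{v.variant_id}_ref", f"{v.variant_id}_alt")
            for v in small_design.variants
        ]
        act = barcode_activity(table, min_count=10)
        b2e = small_design.barcode_to_element()
        act = act.assign(element_id=act["barcode_id"].map(b2e))
        res = compare_pairs(act, pairs, fdr=0.05)
        assert res.loc[list(beta), "significant"].all()
        for vid, b in beta.items():
            assert res.loc[vid, "log2fc"] == pytest.approx(b, abs=0.4)

    def test_empty_result_signal(self, sim_table, small_design):
        table, _, _ = sim_table
        pairs = [("ghost", "nope_ref", "nope_alt")]
        thresholds, audit = grid_search_filter(
            table, small_design, pairs,
            count_grid=[10], barcode_grid=[3], replicate_grid=[4],
        )
        assert thresholds is None
        assert (audit["n_testable"] == 0).all()
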