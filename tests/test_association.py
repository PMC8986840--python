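"""Contingency statistics: table construction, Asymmetry, exact tests,
p-value merging, Dominance, and class-conditional SYI comparisons."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import droughtyield as dy
from droughtyield.association import ContingencyTable, pair_series


def table_from(**macro):
    """Build a table with given macro counts placed in fixed class cells."""
    c = np.zeros((7, 7), dtype=int)
    c[2, 2] = macro.get("LY_D", 0)   # (MLY, MD)
    c[4, 4] = macro.get("HY_W", 0)   # (MHY, MW)
    c[2, 4] = macro.get("LY_W", 0)
    c[4, 2] = macro.get("HY_D", 0)
    c[3, 3] = macro.get("N", 0)
    return ContingencyTable(c)


class TestBuildTable:
    def test_all_normal_years(self):
        t = dy.build_table(np.zeros(36), np.zeros(36))
        assert t.counts[3, 3] == 36 and t.n == 36
        assert t.ly_d == t.ly_w == t.hy_d == t.hy_w == 0

    def test_constructed_md_mly_count(self):
        spei = np.array([-1.2, -1.2, -1.2, 0.0, 0.0])
        syi = np.array([-1.2, -1.2, -1.2, 0.0, 0.0])
        t = dy.build_table(spei, syi)
        assert t.letters["i"] == 3  # (MLY, MD)

    def test_pairwise_nan_dropping(self):
        spei = np.array([np.nan, -2.0, 0.0])
        syi = np.array([-2.0, np.nan, 0.0])
        t = dy.build_table(spei, syi)
        assert t.n == 1

    def test_matches_bruteforce_tally(self, rng):
        from droughtyield.indices import classify_array

        spei = rng.normal(size=200)
        syi = rng.normal(size=200)
        t = dy.build_table(spei, syi)
        brute = np.zeros((7, 7), dtype=int)
        for s, y in zip(spei, syi):
            brute[classify_array(np.array([y]))[0], classify_array(np.array([s]))[0]] += 1
        np.testing.assert_array_equal(t.counts, brute)
        assert t.n == 200

    def test_macro_table_conserves_n(self, rng):
        t = dy.build_table(rng.normal(size=100), rng.normal(size=100))
        assert t.macro().sum() == t.n


class TestAsymmetry:
    def test_components_two_thirds(self):
        t = table_from(LY_D=10, HY_W=5, LY_W=5, HY_D=5, N=11)
        res = dy.asymmetry(t)
        assert all(v == pytest.approx(200 / 3) for v in res.components.values())
        assert res.mean == pytest.approx(200 / 3)

    def test_perfect_symmetry_gives_no_mean(self):
        t = table_from(LY_D=9, HY_W=9, LY_W=9, HY_D=9)
        res = dy.asymmetry(t)
        assert all(v == 50.0 for v in res.components.values())
        assert res.mean is None

    def test_single_component_at_50_blocks_mean(self):
        t = table_from(LY_D=6, HY_W=6, LY_W=1, HY_D=1, N=22)
        res = dy.asymmetry(t)
        assert res.components["HY_W"] == 50.0
        assert res.mean is None

    def test_small_table_not_computed(self):
        t = table_from(LY_D=10, HY_W=2, LY_W=2, HY_D=2)  # n = 16 < 36
        res = dy.asymmetry(t)
        assert not res.computed

    def test_zero_counterpart_is_100_percent(self):
        t = table_from(LY_D=12, HY_W=0, LY_W=8, HY_D=8, N=8)
        res = dy.asymmetry(t)
        assert res.components["HY_W"] == 100.0

    def test_both_zero_component_undefined(self):
        t = table_from(LY_D=0, HY_W=0, LY_W=18, HY_D=18)
        res = dy.asymmetry(t)
        assert np.isnan(res.components["HY_W"])
        assert res.mean is None

    def test_hy_w_target_swaps_roles(self):
        t = table_from(LY_D=5, HY_W=10, LY_W=5, HY_D=5, N=11)
        res = dy.asymmetry(t, target="HY_W")
        assert set(res.components) == {"LY_D", "LY_W", "HY_D"}
        assert res.mean == pytest.approx(200 / 3)

    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_components_bounded_and_gate(self, counts):
        ly_d, hy_w, ly_w, hy_d = counts
        pad = max(0, 36 - sum(counts))
        t = table_from(LY_D=ly_d, HY_W=hy_w, LY_W=ly_w, HY_D=hy_d, N=pad)
        res = dy.asymmetry(t)
        vals = [v for v in res.components.values() if np.isfinite(v)]
        assert all(0.0 <= v <= 100.0 for v in vals)
        if res.mean is not None:
            assert all(v > 50.0 for v in res.components.values())


def fisher_oracle(a, b, c, d):
    """Exact one-sided p by integer hypergeometric tail enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    num = sum(
        math.comb(r1, k) * math.comb(n - r1, c1 - k)
        for k in range(a, min(r1, c1) + 1)
    )
    return num / math.comb(n, c1)


class TestFisher:
    def test_matches_enumeration_oracle(self, rng):
        for _ in range(300):
            a, b, c, d = (int(v) for v in rng.integers(0, 11, 4))
            t = table_from(LY_D=a, LY_W=b, HY_D=c, HY_W=d)
            assert dy.fisher_macro(t) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12
            )

    def test_matches_scipy_fisher_exact(self, rng):
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 9, 4))
            if a + b + c + d == 0:
                continue
            t = table_from(LY_D=a, LY_W=b, HY_D=c, HY_W=d)
            ref = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert dy.fisher_macro(t) == pytest.approx(ref, abs=1e-12)

    def test_balanced_table_not_significant(self):
        assert dy.fisher_macro(table_from(LY_D=5, LY_W=5, HY_D=5, HY_W=5)) > 0.5

    @pytest.mark.parametrize("k", [2, 4, 6, 8])
    def test_diagonal_closed_form(self, k):
        # [[k,0],[0,k]] -> p = 1/C(2k, k), strictly decreasing in k
        p = dy.fisher_macro(table_from(LY_D=k, HY_W=k))
        assert p == pytest.approx(1.0 / math.comb(2 * k, k), abs=1e-14)

    def test_zero_margin_gives_one(self):
        assert dy.fisher_macro(table_from(HY_D=5, HY_W=5)) == 1.0
        assert dy.fisher_macro(table_from()) == 1.0


def permutation_oracle(x, y):
    """Full-permutation two-sided rank-sum p (independent of the package
    implementation: enumerates value assignments, midranks, doubled tail)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, n1 = pooled.size, len(x)
    w_obs = ranks[:n1].sum()
    lo = hi = total = 0
    for ix in itertools.combinations(range(n), n1):
        w = ranks[list(ix)].sum()
        total += 1
        lo += w <= w_obs + 1e-9
        hi += w >= w_obs - 1e-9
    return min(1.0, 2.0 * min(lo, hi) / total)


class TestRankSum:
    def test_spec_example_extreme_separation(self):
        p, x_lower = dy.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert x_lower

    def test_identical_groups(self):
        p, _ = dy.rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (5, 5), (6, 8), (8, 8)])
    def test_exact_matches_permutation_oracle(self, rng, n1, n2):
        for _ in range(3):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2) + rng.normal()
            assert dy.rank_sum_test(x, y)[0] == pytest.approx(
                permutation_oracle(x, y), abs=1e-12
            )

    def test_exact_with_ties_matches_permutation_oracle(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([2.0, 3.0, 3.0, 4.0, 4.0])
        assert dy.rank_sum_test(x, y)[0] == pytest.approx(
            permutation_oracle(x, y), abs=1e-12
        )

    def test_exact_matches_scipy_when_no_ties(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert dy.rank_sum_test(x, y)[0] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_shift_detected_asymptotically(self, rng):
        x = rng.normal(0.0, 1.0, size=18)
        y = rng.normal(3.0, 1.0, size=18)
        p, x_lower = dy.rank_sum_test(x, y)
        assert p < 0.01
        assert x_lower


class TestWilcoxonSplit:
    def test_minimum_group_size_gate(self, rng):
        values = rng.normal(size=36)
        split = np.full(36, 0.5)
        split[:3] = -2.0  # drought group of 3 < 5
        p, _, computed = dy.wilcoxon_split(values, split)
        assert not computed and np.isnan(p)

    def test_direction_flag(self):
        split = np.array([-2.0] * 6 + [0.5] * 8)
        values = np.array([-1.0] * 6 + [1.0] * 8)
        p, low_lower, computed = dy.wilcoxon_split(values, split)
        assert computed and low_lower and p < 0.05


class TestMergePvalues:
    def test_all_ones_cap(self):
        assert dy.merge_pvalues(1.0, 1.0, 1.0) == 1.0

    def test_hand_arithmetic(self):
        # max(2*0.01, e*0.01, e*ln3*0.01) = e*ln3*0.01
        expected = math.e * math.log(3.0) * 0.01
        assert dy.merge_pvalues(0.01, 0.01, 0.01) == pytest.approx(expected)

    def test_monotone_in_inputs(self):
        ps = [dy.merge_pvalues(p, p, p) for p in (0.001, 0.01, 0.1, 0.5)]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_undefined_input_propagates(self):
        assert np.isnan(dy.merge_pvalues(np.nan, 0.5, 0.5))

    @given(st.lists(st.floats(1e-6, 1.0), min_size=3, max_size=3))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_valid_range_and_dominates_double_mean(self, ps):
        m = dy.merge_pvalues(*ps)
        assert 0.0 < m <= 1.0
        assert m >= min(1.0, 2.0 * float(np.mean(ps))) - 1e-12


class TestClassifyP:
    @pytest.mark.parametrize(
        "p,label",
        [(0.004, ">=99.5%"), (0.005, ">=99.5%"), (0.007, "99-99.5%"),
         (0.03, "95-99%"), (0.07, "90-95%"), (0.1, "90-95%"), (0.5, "ns")],
    )
    def test_bins(self, p, label):
        assert dy.classify_p(p) == label


class TestDominance:
    def _letters(self, **kw):
        c = np.zeros((7, 7), dtype=int)
        pos = {k: divmod(i, 3) for i, k in enumerate("abcdefghi")}
        for k, v in kw.items():
            r, col = pos[k]
            c[r, col] = v
        return ContingencyTable(c)

    def test_uniform_letters(self):
        t = self._letters(**{k: 1 for k in "abcdefghi"})
        ge, gt = dy.dominance(t)
        assert ge == pytest.approx(200 / 3)
        assert gt == pytest.approx(50.0)

    def test_diagonal_only(self):
        t = self._letters(a=1, e=1, i=1)
        ge, gt = dy.dominance(t)
        assert ge == 100.0
        assert np.isnan(gt)

    def test_severer_cells(self):
        t = self._letters(b=2, c=2, f=2, d=1, g=1, h=1)
        _, gt = dy.dominance(t)
        assert gt == pytest.approx(200 / 3)

    def test_empty_block_undefined(self):
        ge, gt = dy.dominance(self._letters())
        assert np.isnan(ge) and np.isnan(gt)

    def test_monotone_under_g_to_c_move(self, rng):
        # moving one count from g (MLY, ED) to c (ELY, MD) never lowers ge
        for _ in range(200):
            kw = {k: int(v) for k, v in zip("abcdefghi", rng.integers(0, 5, 9))}
            kw["g"] = max(kw["g"], 1)
            t1 = self._letters(**kw)
            kw2 = dict(kw, g=kw["g"] - 1, c=kw["c"] + 1)
            t2 = self._letters(**kw2)
            ge1, _ = dy.dominance(t1)
            ge2, _ = dy.dominance(t2)
            assert ge2 >= ge1 - 1e-12


class TestDominanceSummary:
    def test_mean_and_share(self):
        df = dy.dominance_summary({"crop": [(60.0, 40.0), (80.0, 60.0)]})
        row = df[df["cropping_system"] == "crop"].iloc[0]
        assert row["mean_dominance_ge"] == pytest.approx(70.0)
        assert row["share_ge_above"] == pytest.approx(50.0)

    def test_exactly_at_threshold_not_counted(self):
        df = dy.dominance_summary({"crop": [(200 / 3, 50.0)]}, thr_ge=200 / 3)
        row = df.iloc[0]
        assert row["share_ge_above"] == 0.0
        assert row["share_gt_above"] == 0.0

    def test_weighted_average_rule(self):
        dom = {
            "a": [(77.0, 50.0)] * 42,
            "b": [(71.0, 50.0)] * 25,
        }
        df = dy.dominance_summary(dom)
        avg = df[df["cropping_system"] == "average"].iloc[0]
        assert avg["mean_dominance_ge"] == pytest.approx((77 * 42 + 71 * 25) / 67)
        assert avg["n_tables"] == 67


class TestSyiBySpeiClass:
    def test_bruteforce_reselection(self, rng):
        spei = rng.normal(size=2000) * 1.3
        syi = rng.normal(size=2000) * 1.3
        out = dy.syi_by_spei_class(spei, syi, syi_threshold=-1.0)
        keep = (syi <= -1.0)
        np.testing.assert_array_equal(
            np.sort(out["samples"]["MD"]),
            np.sort(syi[keep & (spei > -1.5) & (spei <= -1.0)]),
        )
        np.testing.assert_array_equal(
            np.sort(out["samples"]["ED"]), np.sort(syi[keep & (spei <= -2.0)])
        )

    def test_threshold_minus2_selects_single_rows(self):
        # at SYI <= -2 the samples are exactly the letter cells c, b, a
        spei = np.array([-1.2, -1.7, -2.5, -1.2, 0.0])
        syi = np.array([-2.1, -2.2, -2.3, -1.2, 0.0])
        out = dy.syi_by_spei_class(spei, syi, syi_threshold=-2.0)
        assert out["samples"]["MD"].tolist() == [-2.1]  # cell c
        assert out["samples"]["SD"].tolist() == [-2.2]  # cell b
        assert out["samples"]["ED"].tolist() == [-2.3]  # cell a

    def test_identical_samples_p_one(self):
        spei = np.array([-1.2] * 4 + [-1.7] * 4)
        syi = np.array([-1.5, -1.6, -1.7, -1.8] * 2)
        out = dy.syi_by_spei_class(spei, syi)
        assert out["pvalues"][("MD", "SD")] == 1.0

    def test_empty_class_skipped(self):
        spei = np.array([-1.2, -1.2])
        syi = np.array([-1.5, -1.6])
        out = dy.syi_by_spei_class(spei, syi)
        assert ("MD", "ED") not in out["pvalues"]


class TestPairSeries:
    def test_zero_offset_identity(self, rng):
        s = rng.normal(size=10)
        np.testing.assert_array_equal(pair_series(s, 0), s)

    def test_negative_offset_shifts_and_pads(self):
        s = np.arange(5.0)
        out = pair_series(s, -1)
        assert np.isnan(out[0])
        np.testing.assert_array_equal(out[1:], s[:-1])


class TestAssociatePairs:
    def test_reversed_direction_rendered_as_hatched(self, rng):
        """A significant association with higher yields under drought must
        be flagged 'reversed', never reported as positive evidence."""
        import xarray as xr

        n = 36
        spei = rng.normal(size=n)
        syi = np.where(spei <= -1.0, 2.5, -0.5) + 0.01 * rng.normal(size=n)
        while (spei <= -1).sum() < 6:  # ensure a usable drought group
            spei = rng.normal(size=n)
            syi = np.where(spei <= -1.0, 2.5, -0.5) + 0.01 * rng.normal(size=n)
        cube = xr.DataArray(
            np.broadcast_to(spei, (3, 3, n)).copy(),
            dims=("duration", "month", "year"),
            coords={"duration": [1, 2, 3], "month": [6, 7, 8],
                    "year": np.arange(n)},
        )
        win = dy.build_window(8, 8)
        res = [r for r in dy.associate_pairs(cube, syi, win)
               if r.duration == 1 and r.mbh == 0]
        assert len(res) == 1
        assert res[0].sig_class in ("reversed", "not_computed")
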