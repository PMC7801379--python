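import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capcontact import diffloop
from capcontact.diffloop import (
    PeakWindow,
    adjust_family,
    association_enrichment,
    build_windows,
    differential_summary,
    filter_windows,
    holm_adjust,
    paired_window_test,
    signed_rank_p,
    window_logfc,
)
from capcontact.errors import (
    ConfigurationError,
    InvalidInputError,
    LabelLookupError,
    PairingError,
)
from capcontact.fragmap import FragmentMap, Viewpoint
from tests.conftest import make_table


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def enumeration_signed_rank_p(diffs):
    """Exhaustive 2^n sign-assignment oracle for the two-sided signed-rank p."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        n_le += w <= w_obs
        n_ge += w >= w_obs
    return min(1.0, 2.0 * min(n_le, n_ge) / 2**n)


def brute_force_holm(p_values):
    """Literal step-down definition, independent of the package code path."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank_pos, i in enumerate(order):
        best = 0.0
        for j in range(rank_pos + 1):
            best = max(best, (m - j) * p[order[j]])
        adj[i] = min(1.0, best)
    return adj


# ---------------------------------------------------------------------------
# signed-rank test
# ---------------------------------------------------------------------------


class TestSignedRank:
    def test_all_positive_six_pairs(self):
        p, n = signed_rank_p(np.array([1, 2, 3, 4, 5, 6], float))
        assert n == 6
        assert p == 2 / 2**6  # 0.03125

    def test_all_zero_diffs(self):
        p, n = signed_rank_p(np.zeros(10))
        assert p is None and n == 0

    def test_symmetry_under_negation(self):
        d = np.array([3.0, -1.0, 2.5, -4.0, 0.5, 1.5])
        assert signed_rank_p(d)[0] == signed_rank_p(-d)[0]

    @given(
        st.integers(min_value=1, max_value=8),
        st.integers(min_value=0, max_value=2**32 - 1),
    )
    @settings(max_examples=80, deadline=None)
    def test_exact_matches_enumeration(self, n, seed):
        r = np.random.default_rng(seed)
        mags = r.permutation(np.arange(1, n + 1)).astype(float)
        signs = r.choice([-1.0, 1.0], size=n)
        d = mags * signs
        p, _ = signed_rank_p(d)
        assert p == enumeration_signed_rank_p(d)

    def test_exact_handles_ties(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0])
        p, _ = signed_rank_p(d)
        assert p == enumeration_signed_rank_p(d)

    def test_approx_path_reasonable(self, rng):
        d = rng.normal(0.0, 1.0, size=60)
        p, n = signed_rank_p(d)
        assert n > diffloop.EXACT_PAIR_LIMIT
        assert 0.0 < p <= 1.0

    def test_approx_agrees_with_exact_near_boundary(self, rng):
        # n = 25 exact vs n = 26 approx on similar data should be close
        d = rng.normal(0.3, 1.0, size=25)
        p_exact, _ = signed_rank_p(d)
        from scipy.stats import wilcoxon

        p_scipy = wilcoxon(d, method="approx", correction=True).pvalue
        assert p_exact == pytest.approx(p_scipy, rel=0.25)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


class TestBuildWindows:
    def test_centered_window(self):
        peaks = pd.DataFrame(
            [{"chrom": "chr1", "start": 45_000, "end": 55_000}]
        )
        (w,) = build_windows(peaks, 10_000, {"chr1": 1_000_000})
        assert (w.start, w.end) == (45_000, 55_000)

    def test_clip_at_chrom_start(self):
        peaks = pd.DataFrame([{"chrom": "chr1", "start": 2_000, "end": 4_000}])
        (w,) = build_windows(peaks, 10_000, {"chr1": 1_000_000})
        assert (w.start, w.end) == (0, 8_000)

    def test_clip_near_origin(self):
        peaks = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 1_000}])
        (w,) = build_windows(peaks, 10_000, {"chr1": 1_000_000})
        assert (w.start, w.end) == (0, 5_500)

    def test_clip_at_chrom_end(self):
        peaks = pd.DataFrame([{"chrom": "chr1", "start": 9_000, "end": 9_800}])
        (w,) = build_windows(peaks, 10_000, {"chr1": 10_000})
        assert (w.start, w.end) == (4_400, 10_000)


class TestFilterWindows:
    vp = Viewpoint(name="vpA", chrom="chr1", start=500_000, end=501_000)
    domains = [(100_000, 900_000)]

    def _win(self, chrom, start, end):
        return PeakWindow("w", chrom, start, end, start, end)

    def test_trans_flagged(self):
        (w,) = filter_windows([self._win("chr2", 0, 10_000)], self.vp, self.domains)
        assert "trans" in w.flags

    def test_near_probe_boundary(self):
        # nearest edge 9,999 bp from the probe -> excluded
        (w,) = filter_windows(
            [self._win("chr1", 510_999, 520_999)], self.vp, self.domains
        )
        assert "near_probe" in w.flags
        # exactly 10,000 bp away -> retained
        (w,) = filter_windows(
            [self._win("chr1", 511_000, 521_000)], self.vp, self.domains
        )
        assert w.testable

    def test_outside_domain(self):
        (w,) = filter_windows(
            [self._win("chr1", 950_000, 960_000)], self.vp, self.domains
        )
        assert "outside_domain" in w.flags

    def test_retained_window(self):
        (w,) = filter_windows(
            [self._win("chr1", 550_000, 560_000)], self.vp, self.domains
        )
        assert w.testable and not w.flags

    def test_missing_domains_is_config_error(self):
        with pytest.raises(ConfigurationError):
            filter_windows([self._win("chr1", 0, 10)], self.vp, [])


# ---------------------------------------------------------------------------
# paired window test against tables
# ---------------------------------------------------------------------------


def two_condition_table(fmap, counts_a, counts_b, reps=("r1",)):
    frames = []
    for rep in reps:
        frames.append(make_table(fmap, "vpA", counts_a, "control", rep))
        frames.append(make_table(fmap, "vpA", counts_b, "treated", rep))
    table = pd.concat(frames, ignore_index=True)
    table["norm_count"] = table["raw_count"].astype(float)
    return table


class TestPairedWindowTest:
    def test_identical_conditions_too_few_pairs(self, small_map):
        counts = {i: 10 for i in range(10)}
        table = two_condition_table(small_map, counts, counts)
        w = PeakWindow("w", "chr1", 0, 10_000, 0, 10_000)
        w.fragment_ids = small_map.fragment_ids("chr1")
        p, n = paired_window_test(w, table, "control", "treated")
        assert p is None and n == 0
        assert "too_few_pairs" in w.flags

    def test_six_positive_pairs_exact(self, small_map):
        counts_a = {i: 10 for i in range(6)}
        counts_b = {i: 10 + i + 1 for i in range(6)}
        table = two_condition_table(small_map, counts_a, counts_b)
        w = PeakWindow("w", "chr1", 0, 6_000, 0, 6_000)
        w.fragment_ids = small_map.fragment_ids("chr1")[:6]
        p, n = paired_window_test(w, table, "control", "treated")
        assert n == 6
        assert p == pytest.approx(0.03125)

    def test_condition_swap_same_p(self, small_map, rng):
        counts_a = {i: int(rng.integers(1, 40)) for i in range(10)}
        counts_b = {i: int(rng.integers(1, 40)) for i in range(10)}
        table = two_condition_table(small_map, counts_a, counts_b)
        w = PeakWindow("w", "chr1", 0, 10_000, 0, 10_000)
        w.fragment_ids = small_map.fragment_ids("chr1")
        p1, _ = paired_window_test(w, table, "control", "treated")
        p2, _ = paired_window_test(w, table, "treated", "control")
        assert p1 == p2

    def test_unknown_condition(self, small_map):
        table = two_condition_table(small_map, {0: 5}, {0: 6})
        w = PeakWindow("w", "chr1", 0, 1_000, 0, 1_000)
        w.fragment_ids = ["chr1_0"]
        with pytest.raises(LabelLookupError):
            paired_window_test(w, table, "control", "nope")

    def test_mismatched_replicates(self, small_map):
        t1 = make_table(small_map, "vpA", {0: 5}, "control", "r1")
        t2 = make_table(small_map, "vpA", {0: 6}, "treated", "r2")
        table = pd.concat([t1, t2], ignore_index=True)
        table["norm_count"] = table["raw_count"].astype(float)
        w = PeakWindow("w", "chr1", 0, 1_000, 0, 1_000)
        w.fragment_ids = ["chr1_0"]
        with pytest.raises(PairingError):
            paired_window_test(w, table, "control", "treated")


class TestWindowLogfc:
    def test_identity(self, small_map):
        counts = {i: 50 for i in range(10)}
        table = two_condition_table(small_map, counts, counts)
        w = PeakWindow("w", "chr1", 0, 10_000, 0, 10_000)
        w.fragment_ids = small_map.fragment_ids("chr1")
        per_rep, mean = window_logfc(w, table, "control", "treated")
        assert mean == 0.0 and per_rep == [0.0]

    def test_doubling_with_pseudocount(self, small_map):
        table = two_condition_table(
            small_map, {i: 100 for i in range(10)}, {i: 200 for i in range(10)}
        )
        w = PeakWindow("w", "chr1", 0, 10_000, 0, 10_000)
        w.fragment_ids = small_map.fragment_ids("chr1")
        _, mean = window_logfc(w, table, "control", "treated", pseudocount=1.0)
        assert mean == pytest.approx(np.log2(201 / 101))  # 0.9928

    def test_label_antisymmetry(self, small_map, rng):
        counts_a = {i: int(rng.integers(1, 100)) for i in range(10)}
        counts_b = {i: int(rng.integers(1, 100)) for i in range(10)}
        table = two_condition_table(small_map, counts_a, counts_b, reps=("r1", "r2"))
        w = PeakWindow("w", "chr1", 0, 10_000, 0, 10_000)
        w.fragment_ids = small_map.fragment_ids("chr1")
        fwd, fwd_mean = window_logfc(w, table, "control", "treated")
        rev, rev_mean = window_logfc(w, table, "treated", "control")
        assert np.allclose(fwd, [-x for x in rev])
        assert fwd_mean == pytest.approx(-rev_mean)


# ---------------------------------------------------------------------------
# Holm adjustment
# ---------------------------------------------------------------------------


class TestHolm:
    def test_two_values(self):
        assert list(holm_adjust([0.01, 0.04])) == [0.02, 0.04]

    def test_single_value_unchanged(self):
        assert list(holm_adjust([0.3])) == [0.3]

    def test_three_values(self):
        assert np.allclose(holm_adjust([0.03, 0.02, 0.01]), [0.04, 0.04, 0.03])

    def test_rejects_out_of_range(self):
        with pytest.raises(InvalidInputError):
            holm_adjust([0.5, 0.0])
        with pytest.raises(InvalidInputError):
            holm_adjust([0.5, 1.5])

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(1e-9, 1.0, size=int(r.integers(1, 40)))
        got = holm_adjust(p)
        assert np.allclose(got, brute_force_holm(p))
        # adjusted >= raw, <= Bonferroni, monotone along sorted order
        assert np.all(got >= p)
        assert np.all(got <= np.minimum(1.0, len(p) * p) + 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(got[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# summaries and enrichment
# ---------------------------------------------------------------------------


class TestSummary:
    def _frame(self, rows):
        return pd.DataFrame(rows)

    def test_hand_mean(self):
        df = self._frame(
            [
                {"p_raw": 0.001, "p_adj": 0.01, "mean_logfc": 0.2},
                {"p_raw": 0.002, "p_adj": 0.02, "mean_logfc": 0.4},
                {"p_raw": 0.5, "p_adj": 1.0, "mean_logfc": -1.0},
            ]
        )
        s = differential_summary(df, 0.05, "cmp")
        assert (s.n_tested, s.n_significant, s.n_increased, s.n_decreased) == (
            3,
            2,
            2,
            0,
        )
        assert s.mean_logfc_significant == pytest.approx(0.3)

    def test_empty_significant(self):
        df = self._frame([{"p_raw": 0.9, "p_adj": 1.0, "mean_logfc": 0.1}])
        s = differential_summary(df, 0.05)
        assert s.n_significant == 0
        assert np.isnan(s.mean_logfc_significant)

    def test_counts_bound_invariant(self, rng):
        rows = [
            {
                "p_raw": float(rng.uniform(1e-6, 1.0)),
                "mean_logfc": float(rng.normal()),
            }
            for _ in range(50)
        ]
        df = adjust_family(self._frame(rows))
        s = differential_summary(df, 0.05)
        assert s.n_increased + s.n_decreased <= s.n_significant <= s.n_tested

    def test_flagged_windows_never_in_family(self, rng):
        rows = []
        for i in range(20):
            rows.append(
                {
                    "p_raw": float(rng.uniform(1e-6, 1)) if i % 2 == 0 else np.nan,
                    "mean_logfc": float(rng.normal()),
                    "flags": "" if i % 2 == 0 else "trans",
                }
            )
        df = adjust_family(self._frame(rows))
        s = differential_summary(df, 0.05)
        assert s.n_tested == 10
        assert df.loc[df["flags"] == "trans", "p_adj"].isna().all()


class TestAssociationEnrichment:
    def _setup(self):
        fmap = FragmentMap()
        n = 40
        fmap.add_chromosome(
            "chr1", list(range(0, n * 1_000, 1_000)), list(range(1_000, (n + 1) * 1_000, 1_000))
        )
        vp = Viewpoint(name="vpA", chrom="chr1", start=100, end=200)
        domains = [(11_000, 39_000)]  # fragments 11..38, all >= 10 kb from probe
        return fmap, vp, domains

    def _table(self, fmap, values):
        chrom = "chr1"
        rows = []
        for i, fid in enumerate(fmap.fragment_ids(chrom)):
            rows.append(
                {
                    "viewpoint": "vpA",
                    "fragment_id": fid,
                    "replicate": "r1",
                    "condition": "control",
                    "norm_count": float(values.get(i, 0.0)),
                }
            )
        return pd.DataFrame(rows)

    def test_uniform_profile_ratio_one(self):
        fmap, vp, domains = self._setup()
        table = self._table(fmap, {i: 5.0 for i in range(40)})
        feats = pd.DataFrame([{"chrom": "chr1", "start": 15_000, "end": 19_000}])
        r = association_enrichment(feats, table, vp, domains, fmap)
        assert r == pytest.approx(1.0)

    def test_weighted_mean_example(self):
        # feature fragments carry 2c, 3x as many others carry c -> 1.6
        fmap, vp, domains = self._setup()
        values = {}
        for i in range(11, 39):
            values[i] = 0.0
        feats_idx = list(range(12, 19))  # 7 fragments
        rest_idx = list(range(19, 40))[:21]  # 3x as many
        for i in feats_idx:
            values[i] = 2.0
        for i in rest_idx:
            values[i] = 1.0
        # restrict the domain to exactly these 28 fragments
        domains = [(12_000, 40_000)]
        table = self._table(fmap, values)
        feats = pd.DataFrame([{"chrom": "chr1", "start": 12_000, "end": 19_000}])
        r = association_enrichment(feats, table, vp, domains, fmap)
        assert r == pytest.approx(2.0 / ((7 * 2.0 + 21 * 1.0) / 28))

    def test_feature_outside_domain_missing(self):
        fmap, vp, domains = self._setup()
        table = self._table(fmap, {i: 5.0 for i in range(40)})
        feats = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 5_000}])
        assert np.isnan(association_enrichment(feats, table, vp, domains, fmap))
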