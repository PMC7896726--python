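"""Windowed pooled heterozygosity, ZHp standardization and consistency calls."""

import numpy as np
import pytest

import poolscan as ps
from poolscan.sync_io import Region, StructuralError
from oracles import (
    brute_force_consistent_intervals,
    brute_force_window_starts,
    brute_force_zhp,
)


def freq_table(pos, p, pops=None, chrom="chr1"):
    p = np.asarray(p, dtype=float)
    pops = pops or [f"P{j}" for j in range(p.shape[1])]
    return ps.FreqTable(np.array([chrom] * len(pos), dtype=object),
                        np.asarray(pos), p, pops, "major")


def segments_from(hp, widths, pops=None, window=100):
    hp = np.asarray(hp, dtype=float)
    widths = np.asarray(widths)
    s_lo = np.concatenate([[0], np.cumsum(widths)[:-1]])
    return ps.HetSegments(
        np.array(["chr1"] * len(widths), dtype=object), s_lo.astype(np.int64),
        (s_lo + widths - 1).astype(np.int64),
        np.full(len(widths), 10, dtype=np.int64), hp,
        pops or [f"P{j}" for j in range(hp.shape[1])], window)


class TestHpOfWindow:
    def test_maximum_at_half(self):
        assert ps.hp_of_window([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_fixed_zero(self):
        assert ps.hp_of_window([1.0, 1.0]) == pytest.approx(0.0)

    def test_worked_example(self):
        assert ps.hp_of_window([1.0, 0.9, 0.5]) == pytest.approx(0.68 / 3, abs=1e-6)

    def test_empty_errors(self):
        with pytest.raises(StructuralError):
            ps.hp_of_window([])


class TestSegmentEnumeration:
    def test_two_sites_one_segment(self):
        f = freq_table([99, 119], np.full((2, 1), 0.5))
        seg = ps.enumerate_hp_segments(f, ps.HpParams(window_size=50_000, min_snps=2),
                                       {"chr1": 100_000})
        assert seg.n_segments == 1
        assert (seg.s_lo[0], seg.s_hi[0], seg.n_snps[0]) == (0, 99, 2)

    def test_no_sites_empty(self):
        f = freq_table([], np.zeros((0, 1)))
        seg = ps.enumerate_hp_segments(f, ps.HpParams(), {"chr1": 100_000})
        assert seg.n_segments == 0

    def test_single_site_at_origin(self):
        f = freq_table([0], np.full((1, 1), 0.5))
        seg = ps.enumerate_hp_segments(f, ps.HpParams(window_size=50_000, min_snps=1),
                                       {"chr1": 100_000})
        assert seg.n_segments == 1
        assert (seg.s_lo[0], seg.s_hi[0], seg.n_snps[0]) == (0, 0, 1)

    def test_short_chromosome_skipped(self):
        f = freq_table([10], np.full((1, 1), 0.5))
        seg = ps.enumerate_hp_segments(f, ps.HpParams(window_size=50_000, min_snps=1),
                                       {"chr1": 10_000})
        assert seg.n_segments == 0

    def test_partition_covers_all_starts(self):
        """Before the min_snps filter, segment widths sum to L - window + 1."""
        rng = np.random.default_rng(31)
        L, w = 5_000, 300
        pos = np.sort(rng.choice(L, 60, replace=False))
        f = freq_table(pos, rng.uniform(0.5, 1.0, size=(60, 2)))
        seg = ps.enumerate_hp_segments(f, ps.HpParams(window_size=w, min_snps=1),
                                       {"chr1": L})
        # add back the discarded (0-SNP) starts via the brute-force scan
        starts, ns, _ = brute_force_window_starts(
            pos, 2 * f.p * (1 - f.p), w, 1, L)
        assert seg.widths.sum() == (ns >= 1).sum()
        covered = set()
        for lo, hi in zip(seg.s_lo, seg.s_hi):
            covered.update(range(lo, hi + 1))
        assert covered == set(starts.tolist())

    def test_hp_bounds(self):
        rng = np.random.default_rng(32)
        pos = np.sort(rng.choice(20_000, 200, replace=False))
        f = freq_table(pos, rng.uniform(0, 1, size=(200, 3)))
        seg = ps.enumerate_hp_segments(f, ps.HpParams(window_size=1_000, min_snps=1),
                                       {"chr1": 20_000})
        assert seg.hp.min() >= 0 and seg.hp.max() <= 0.5 + 1e-12


class TestBruteForceEquivalence:
    def test_segments_match_per_start_enumeration(self):
        """Segment Hp, ZHp and consistency regions equal the naive
        all-window-starts computation on a toy chromosome."""
        rng = np.random.default_rng(33)
        L, w, min_snps = 3_000, 200, 3
        n = 80
        pos = np.sort(rng.choice(L, n, replace=False))
        p = rng.uniform(0.5, 1.0, size=(n, 4))
        f = freq_table(pos, p, pops=["A1", "A2", "L1", "L2"])
        params = ps.HpParams(window_size=w, min_snps=min_snps)
        seg = ps.enumerate_hp_segments(f, params, {"chr1": L})
        seg, _ = ps.zhp_normalize(seg)

        starts, ns, hp_bf = brute_force_window_starts(pos, 2 * p * (1 - p), w,
                                                      min_snps, L)
        # expand segments to per-start values
        hp_exp = np.concatenate([np.repeat(seg.hp[[i]], seg.widths[i], axis=0)
                                 for i in range(seg.n_segments)])
        starts_exp = np.concatenate([np.arange(lo, hi + 1)
                                     for lo, hi in zip(seg.s_lo, seg.s_hi)])
        order = np.argsort(starts_exp)
        assert np.array_equal(starts_exp[order], starts)
        assert np.allclose(hp_exp[order], hp_bf, atol=1e-12)

        zhp_bf = brute_force_zhp(hp_bf)
        zhp_exp = np.concatenate([np.repeat(seg.zhp[[i]], seg.widths[i], axis=0)
                                  for i in range(seg.n_segments)])
        assert np.allclose(zhp_exp[order], zhp_bf, atol=1e-9)

        groups = ps.GroupAssignment({p_: p_ for p_ in f.populations},
                                    {"A1": "A", "A2": "A", "L1": "L", "L2": "L"})
        for direction, low_cols, high_cols in (("low_in_L", [2, 3], [0, 1]),
                                               ("low_in_A", [0, 1], [2, 3])):
            got = [(r.start, r.end) for r in
                   ps.consistent_regions(seg, groups, direction)]
            expected = brute_force_consistent_intervals(starts, zhp_bf,
                                                        low_cols, high_cols, w)
            assert got == expected


class TestZhpNormalize:
    def test_equal_width_zscores(self):
        seg = segments_from([[0.1], [0.2], [0.3]], [10, 10, 10])
        out, summary = ps.zhp_normalize(seg)
        assert np.allclose(out.zhp[:, 0], [-1.22474487, 0.0, 1.22474487])
        assert summary.mu["P0"] == pytest.approx(0.2)

    def test_constant_hp_errors(self):
        with pytest.raises(StructuralError):
            ps.zhp_normalize(segments_from([[0.2], [0.2]], [5, 5]))

    def test_width_weighting_shifts_mean(self):
        seg_eq = segments_from([[0.1], [0.4]], [10, 10])
        seg_w = segments_from([[0.1], [0.4]], [30, 10])
        _, s_eq = ps.zhp_normalize(seg_eq)
        _, s_w = ps.zhp_normalize(seg_w)
        assert s_eq.mu["P0"] == pytest.approx(0.25)
        assert s_w.mu["P0"] == pytest.approx((0.1 * 30 + 0.4 * 10) / 40)

    def test_post_normalization_moments(self):
        rng = np.random.default_rng(34)
        seg = segments_from(rng.uniform(0, 0.5, size=(50, 3)),
                            rng.integers(1, 500, 50))
        out, _ = ps.zhp_normalize(seg)
        w = out.widths.astype(float)
        mean = (out.zhp * w[:, None]).sum(axis=0) / w.sum()
        sd = np.sqrt(((out.zhp - mean) ** 2 * w[:, None]).sum(axis=0) / w.sum())
        assert np.allclose(mean, 0, atol=1e-9) and np.allclose(sd, 1, atol=1e-9)


class TestDzhp:
    def groups(self):
        return ps.GroupAssignment(
            {p: p for p in ["A1", "A2", "A3", "L1", "L2", "L3", "L4", "L5", "L6"]},
            {**{f"A{i}": "A" for i in (1, 2, 3)}, **{f"L{i}": "L" for i in range(1, 7)}})

    def make(self, zhp_rows):
        seg = segments_from(np.zeros((len(zhp_rows), 9)), [1] * len(zhp_rows),
                            pops=["A1", "A2", "A3", "L1", "L2", "L3", "L4", "L5", "L6"])
        seg.zhp = np.asarray(zhp_rows, dtype=float)
        return seg

    def test_plus_minus_one(self):
        seg = self.make([[1, 1, 1, -1, -1, -1, -1, -1, -1]])
        assert ps.dzhp(seg, self.groups())[0] == pytest.approx(2.0)

    def test_all_zero(self):
        seg = self.make([[0] * 9])
        assert ps.dzhp(seg, self.groups())[0] == pytest.approx(0.0)

    def test_worked_example(self):
        seg = self.make([[0.5, -0.2, 0.9, -0.3, 0.1, -0.8, -0.5, 0.0, -0.4]])
        assert ps.dzhp(seg, self.groups())[0] == pytest.approx(0.4 + 1.9 / 6, abs=1e-6)


class TestConsistentRegions:
    def groups(self):
        return ps.GroupAssignment({p: p for p in ["A1", "L1", "L2"]},
                                  {"A1": "A", "L1": "L", "L2": "L"})

    def make(self, zhp_rows, widths):
        seg = segments_from(np.zeros((len(zhp_rows), 3)), widths,
                            pops=["A1", "L1", "L2"], window=100)
        seg.zhp = np.asarray(zhp_rows, dtype=float)
        return seg

    def test_qualifying_segment(self):
        seg = self.make([[0.1, -0.1, -0.1]], [10])
        got = ps.consistent_regions(seg, self.groups(), "low_in_L")
        assert [(r.start, r.end) for r in got] == [(0, 109)]  # s_hi=9 + window

    def test_exact_zero_disqualifies(self):
        seg = self.make([[0.1, -0.1, 0.0]], [10])
        assert ps.consistent_regions(seg, self.groups(), "low_in_L") == []

    def test_direction_mirror(self):
        seg = self.make([[-0.2, 0.3, 0.4]], [10])
        assert ps.consistent_regions(seg, self.groups(), "low_in_L") == []
        got = ps.consistent_regions(seg, self.groups(), "low_in_A")
        assert len(got) == 1 and got[0].label == "low_in_A"


class TestCrossDatasetConfirm:
    def panel(self, length, window, a_low, pops=("B1", "B2", "D1", "D2")):
        """Deterministic panel: A columns near fixation inside ``a_low``
        intervals; L columns keep maximal heterozygosity there."""
        rng = np.random.default_rng(35)
        pos = np.arange(5, length, 10)
        n = len(pos)
        p = np.empty((n, 4))
        # background: moderate heterozygosity with site-to-site variation
        base = rng.uniform(0.55, 0.85, n)
        for j in range(4):
            p[:, j] = base
        in_low = np.zeros(n, dtype=bool)
        for s, e in a_low:
            in_low |= (pos >= s) & (pos < e)
        p[in_low, 0] = p[in_low, 1] = 0.99  # A groups depleted
        p[in_low, 2] = p[in_low, 3] = 0.5   # L groups at maximum
        return ps.FreqPanel(np.array(["chr1"] * n, dtype=object), pos, p, list(pops))

    def groups(self):
        return ps.GroupAssignment({p: p for p in ["B1", "B2", "D1", "D2"]},
                                  {"B1": "A", "B2": "A", "D1": "L", "D2": "L"})

    def test_planted_shared_region_returned(self):
        length, w = 4_000, 200
        panel = self.panel(length, w, [(1_000, 1_400), (3_000, 3_300)])
        params = ps.HpParams(window_size=w, min_snps=5)
        regions_a = [Region("chr1", 1_100, 1_300, "low_in_A"),
                     Region("chr1", 2_000, 2_200, "low_in_A")]  # second: no panel support
        got = ps.cross_dataset_confirm(regions_a, panel, self.groups(), params,
                                       "low_in_A", {"chr1": length})
        assert len(got) == 1
        assert got[0].start == 1_100 and got[0].end == 1_300

    def test_no_qualifying_panel_windows(self):
        panel = self.panel(4_000, 200, [])
        got = ps.cross_dataset_confirm([Region("chr1", 0, 500)], panel,
                                       self.groups(), ps.HpParams(window_size=200, min_snps=5),
                                       "low_in_A", {"chr1": 4_000})
        assert got == []

    def test_self_confirmation(self):
        """Regions derived from the panel itself are returned unchanged."""
        length, w = 4_000, 200
        panel = self.panel(length, w, [(1_000, 1_400)])
        params = ps.HpParams(window_size=w, min_snps=5)
        seg, _ = ps.zhp_normalize(ps.enumerate_hp_segments(
            ps.panel_to_freq_table(panel), params, {"chr1": length}))
        own = ps.consistent_regions(seg, self.groups(), "low_in_A")
        assert own  # sanity: the planted interval produced regions
        got = ps.cross_dataset_confirm(own, panel, self.groups(), params,
                                       "low_in_A", {"chr1": length})
        assert [(r.start, r.end) for r in got] == [(r.start, r.end) for r in own]

    def test_missing_group_column_errors(self):
        panel = self.panel(4_000, 200, [])
        bad_groups = ps.GroupAssignment({"X1": "X1", "D1": "D1"},
                                        {"X1": "A", "D1": "L"})
        with pytest.raises(StructuralError, match="X1"):
            ps.cross_dataset_confirm([], panel, bad_groups, ps.HpParams(),
                                     "low_in_A", {"chr1": 4_000})
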