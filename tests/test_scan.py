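"""Sliding windows, FST, power transform and unique-allele turnover."""

import numpy as np
import pandas as pd
import pytest

import dartpop as dp
from dartpop.reference import chromosome_lengths_bp


class TestMakeWindows:
    def test_two_positions_are_endpoints(self):
        t = dp.make_windows(10e6, "1H", n_positions=2, width_bp=1e6)
        np.testing.assert_allclose(t.centers_bp, [0.5e6, 9.5e6])

    def test_barley_1h_spacing(self):
        t = dp.make_windows(558.54e6, "1H")
        assert len(t.centers_bp) == 250
        spacing = np.diff(t.centers_bp)
        np.testing.assert_allclose(spacing, (558.54e6 - 5e5) / 249)

    def test_centers_within_bounds(self):
        t = dp.make_windows(100e6, "2H", 50, 2e6)
        assert t.centers_bp.min() >= 1e6
        assert t.centers_bp.max() <= 100e6 - 1e6

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            dp.make_windows(4e5, "1H", width_bp=5e5)


class TestWindowReduce:
    def test_half_open_edges(self):
        skel = dp.make_windows(10e6, "1H", n_positions=2, width_bp=1e6)
        # window 1 spans [0, 1e6): left edge included, right edge excluded
        t = dp.window_reduce(skel, np.array([0.0, 1e6]),
                             np.array([5.0, 7.0]), "mean")
        assert t.counts[0] == 1 and t.values[0] == 5.0

    def test_mean_of_three(self):
        skel = dp.make_windows(10e6, "1H", n_positions=2, width_bp=1e6)
        t = dp.window_reduce(skel, np.array([1e5, 2e5, 3e5]),
                             np.array([0.1, 0.2, 0.3]), "mean")
        assert t.values[0] == pytest.approx(0.2)

    def test_empty_window_missing(self):
        skel = dp.make_windows(10e6, "1H", n_positions=2, width_bp=1e6)
        t = dp.window_reduce(skel, np.array([5e6]), np.array([1.0]), "mean")
        assert np.isnan(t.values).all() and t.counts.sum() == 0

    def test_count_matches_brute_force_interval_queries(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 50e6, 500)
        skel = dp.make_windows(50e6, "3H", n_positions=40, width_bp=2e6)
        t = dp.window_reduce(skel, pos, None, "count")
        for c, n in zip(t.centers_bp, t.counts):
            assert n == np.sum((pos >= c - 1e6) & (pos < c + 1e6))

    def test_value_length_mismatch_rejected(self):
        skel = dp.make_windows(10e6, "1H", n_positions=2, width_bp=1e6)
        with pytest.raises(ValueError):
            dp.window_reduce(skel, np.array([1e5]), np.array([1.0, 2.0]))


class TestFst:
    def _two_group_gm(self, calls_a, calls_b):
        calls = np.array(calls_a + calls_b, dtype=np.int8).reshape(-1, 1)
        gm = dp.GenotypeMatrix(calls, [f"S{i}" for i in range(len(calls))],
                               ["L0"])
        ga = np.arange(len(calls_a))
        gb = np.arange(len(calls_a), len(calls))
        return gm, ga, gb

    def test_fixed_alternatives_is_one(self):
        gm, ga, gb = self._two_group_gm([0, 0, 0], [2, 2, 2])
        assert dp.fst_per_locus(gm, ga, gb)[0] == pytest.approx(1.0)

    def test_equal_frequencies_is_zero(self):
        gm, ga, gb = self._two_group_gm([0, 2], [2, 0])
        assert dp.fst_per_locus(gm, ga, gb)[0] == pytest.approx(0.0)

    def test_closed_form_example(self):
        # p_a=0.2, p_b=0.8: HT=0.5, HS=0.32, FST=0.36
        gm, ga, gb = self._two_group_gm([0, 0, 0, 1, 1], [2, 2, 2, 1, 1])
        assert dp.fst_per_locus(gm, ga, gb)[0] == pytest.approx(0.36)

    def test_matches_brute_force_on_toy(self, toy):
        gm, _, meta = toy
        groups = dp.group_indices(meta, gm)
        fst = dp.fst_per_locus(gm, groups["old"], groups["new"])
        for l in range(gm.n_loci):
            # brute force from genotype counts
            freqs = []
            for ix in (groups["old"], groups["new"]):
                c = gm.calls[ix, l]
                c = c[c != dp.MISSING]
                freqs.append((2 * np.sum(c == 2) + np.sum(c == 1)) / (2 * len(c)))
            pa, pb = freqs
            pbar = (pa + pb) / 2
            ht = 2 * pbar * (1 - pbar)
            hs = (2 * pa * (1 - pa) + 2 * pb * (1 - pb)) / 2
            expect = 0.0 if ht == 0 else max(0.0, (ht - hs) / ht)
            assert fst[l] == pytest.approx(expect, abs=1e-12)

    def test_missing_group_gives_nan(self):
        calls = np.array([[dp.MISSING], [dp.MISSING], [0], [2]], dtype=np.int8)
        gm = dp.GenotypeMatrix(calls, list("abcd"), ["L0"])
        fst = dp.fst_per_locus(gm, np.array([0, 1]), np.array([2, 3]))
        assert np.isnan(fst[0])


class TestFstTransform:
    def test_fixed_points_and_example(self):
        out = dp.fst_transform(np.array([0.0, 1.0, 0.5]))
        np.testing.assert_allclose(out, [0.0, 1.0, 0.5**10])

    def test_monotone(self):
        x = np.linspace(0, 1, 20)
        assert (np.diff(dp.fst_transform(x)) >= 0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dp.fst_transform(np.array([1.5]))


class TestUniqueAlleles:
    def _panel(self, earlier_calls, later_calls):
        calls = np.array(earlier_calls + later_calls, dtype=np.int8)
        gm = dp.GenotypeMatrix(calls,
                               [f"S{i}" for i in range(len(calls))],
                               [f"L{j}" for j in range(calls.shape[1])])
        info = pd.DataFrame({
            "locus_id": gm.locus_ids,
            "chromosome": ["1H"] * calls.shape[1],
            "position_bp": (np.arange(calls.shape[1]) + 1) * 1e6,
            "change": ["A>G"] * calls.shape[1],
            "rep_avg": 0.99, "call_rate": 1.0})
        ga = np.arange(len(earlier_calls))
        gb = np.arange(len(earlier_calls), len(calls))
        return gm, info, ga, gb

    def test_lost_at_threshold(self):
        # alt at 0.3 earlier (3/10 copies), 0 later -> lost
        gm, info, ga, gb = self._panel(
            [[2], [1], [0], [0], [0]], [[0], [0], [0], [0]])
        rep = dp.unique_alleles(gm, info, ga, gb, threshold=0.25)
        assert rep.set_index("chromosome").loc["total", "n_lost"] == 1

    def test_threshold_boundary_inclusive(self):
        # alt at exactly 0.25 earlier (2/8), 0 later -> lost at 0.25
        gm, info, ga, gb = self._panel(
            [[2], [0], [0], [0]], [[0], [0], [0]])
        at = dp.unique_alleles(gm, info, ga, gb, threshold=0.25)
        assert at.set_index("chromosome").loc["total", "n_lost"] == 1
        # alt at 0.2 earlier not counted at 0.25, counted at 0.05
        gm, info, ga, gb = self._panel(
            [[2], [0], [0], [0], [0]], [[0], [0], [0]])
        hi = dp.unique_alleles(gm, info, ga, gb, threshold=0.25)
        lo = dp.unique_alleles(gm, info, ga, gb, threshold=0.05)
        assert hi.set_index("chromosome").loc["total", "n_lost"] == 0
        assert lo.set_index("chromosome").loc["total", "n_lost"] == 1

    def test_bad_threshold_rejected(self, toy):
        gm, info, meta = toy
        groups = dp.group_indices(meta, gm)
        with pytest.raises(ValueError):
            dp.unique_alleles(gm, info, groups["old"], groups["new"],
                              threshold=0.0)

    def test_overlapping_groups_rejected(self, toy):
        gm, info, _ = toy
        with pytest.raises(ValueError, match="disjoint"):
            dp.unique_alleles(gm, info, np.array([0, 1]), np.array([1, 2]))

    def test_sweep_ref_alleles_counted_lost(self, default_panel):
        gm, info, meta, truth = default_panel
        groups = dp.group_indices(meta, gm)
        rep = dp.unique_alleles(gm, info, groups["pre-1945"],
                                groups["post-2000"], threshold=0.25)
        tab = rep.set_index("chromosome")
        # sweeps fixed the alt allele on 5H and 3H in the latest period:
        # swept ref alleles register as lost there
        assert tab.loc["5H", "n_lost"] > 0
        assert tab.loc["3H", "n_lost"] > 0


class TestSelectionScan:
    def test_identical_groups_pic_tracks_coincide(self, toy):
        gm, info, meta = toy
        meta2 = meta.copy()
        tracks = dp.selection_scan_report(
            gm, info, meta2, "old", "old", {"1H": 60e6},
            n_positions=10, width_bp=5e6)
        a = dp.tracks_to_frame(tracks["pic_earliest"])
        b = dp.tracks_to_frame(tracks["pic_latest"])
        pd.testing.assert_frame_equal(a, b)

    def test_zero_divergence_fst_track_flat(self):
        cfg = dp.SimConfig(
            n_pools=2, group_sizes=(15, 15), group_labels=("a", "b"),
            heterogeneity_by_group=(0.05, 0.05), pool_divergence=0.01,
            loci_per_chromosome={"1H": 2000}, sweep_spec=[],
            n_duplicate_pairs=0, seed=3)
        gm, info, meta, _ = dp.generate_panel(cfg)
        tracks = dp.selection_scan_report(
            gm, info, meta, "a", "b", {"1H": chromosome_lengths_bp()["1H"]})
        vals = dp.tracks_to_frame(tracks["fst_transformed"])["value"]
        assert np.nanmax(vals) < 1e-3

    def test_sweep_top_window_inside_planted_span(self):
        cfg = dp.SimConfig(
            loci_per_chromosome={c: 1000 for c in
                                 ("1H", "2H", "3H", "4H", "5H", "6H", "7H")},
            sweep_spec=[("5H", 120e6, 40e6, ("1990-1999", "post-2000"))],
            seed=4)
        gm, info, meta, truth = dp.generate_panel(cfg)
        gm, info, _ = dp.filter_loci(gm, info)
        tracks = dp.selection_scan_report(
            gm, info, meta, "pre-1945", "post-2000", chromosome_lengths_bp())
        rows = dp.tracks_to_frame(tracks["fst_transformed"])
        top = rows.loc[rows["value"].idxmax()]
        assert top["chromosome"] == "5H"
        assert 100e6 <= top["center_bp"] <= 140e6
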