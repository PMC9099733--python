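"""Diversity statistics: frequencies, PIC, heterozygosity, rarefaction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dartpop as dp
from dartpop.diversity import rarefied_allele_count, summarise


def _gm(columns):
    """Build a GenotypeMatrix from a list of per-locus call tuples."""
    calls = np.array(columns, dtype=np.int8).T
    return dp.GenotypeMatrix(calls,
                             [f"S{i}" for i in range(calls.shape[0])],
                             [f"L{i}" for i in range(calls.shape[1])])


class TestAlleleFreq:
    @pytest.mark.parametrize("calls,expected_p,expected_n", [
        ((0, 0, 2, 2, 1, 1), 0.5, 6),
        ((0, 0, 0), 0.0, 3),
        ((2, dp.MISSING), 1.0, 1),
    ])
    def test_hand_counts(self, calls, expected_p, expected_n):
        p, n = dp.allele_freq(_gm([calls]))
        assert p[0] == pytest.approx(expected_p)
        assert n[0] == expected_n

    def test_all_missing_flagged(self):
        p, n = dp.allele_freq(_gm([(dp.MISSING, dp.MISSING)]))
        assert np.isnan(p[0]) and n[0] == 0

    def test_empty_subset_rejected(self, toy):
        gm, _, _ = toy
        with pytest.raises(ValueError):
            dp.allele_freq(gm, np.array([], dtype=int))


@pytest.mark.parametrize("p,expected", [(0.0, 0.0), (0.5, 0.5), (0.9, 0.18)])
def test_pic_closed_form(p, expected):
    assert dp.pic(np.array([p]))[0] == pytest.approx(expected)


class TestObservedHet:
    @pytest.mark.parametrize("calls,expected", [
        ((1, 1, 1), 1.0),
        ((0, 2, 0, 2), 0.0),
        ((0, 0, 2, 2, 1, 1), 1 / 3),  # toy panel locus L01
    ])
    def test_hand_counts(self, calls, expected):
        assert dp.observed_het(_gm([calls]))[0] == pytest.approx(expected)


class TestUnbiasedHe:
    def test_small_sample_correction(self):
        assert dp.unbiased_he(np.array([0.5]), np.array([2]))[0] == \
            pytest.approx(4 / 3 * 0.5)

    def test_monomorphic_zero(self):
        assert dp.unbiased_he(np.array([0.0]), np.array([7]))[0] == 0.0

    def test_large_n_limit_is_he(self):
        assert dp.unbiased_he(np.array([0.5]), np.array([10**9]))[0] == \
            pytest.approx(0.5, abs=1e-8)

    def test_undefined_without_samples(self):
        assert np.isnan(dp.unbiased_he(np.array([0.5]), np.array([0]))[0])

    @given(p=st.floats(0, 1), n=st.integers(1, 500))
    @settings(max_examples=100, deadline=None)
    def test_algebraic_identity(self, p, n):
        # uHe (2n-1)/(2n) + p^2 + q^2 == 1
        uhe = dp.unbiased_he(np.array([p]), np.array([n]))[0]
        lhs = uhe * (2 * n - 1) / (2 * n) + p**2 + (1 - p) ** 2
        assert lhs == pytest.approx(1.0, abs=1e-12)

    @given(p=st.floats(0.01, 0.99), n=st.integers(1, 100))
    @settings(max_examples=100, deadline=None)
    def test_ordering_pic_he_uhe(self, p, n):
        he = 1 - p**2 - (1 - p) ** 2
        uhe = dp.unbiased_he(np.array([p]), np.array([n]))[0]
        assert dp.pic(np.array([p]))[0] <= he + 1e-12 <= uhe + 1e-12


class TestFixationIndex:
    def test_published_panel_means_are_self_consistent(self):
        # mean uHo 0.058 and uHe 0.197 of the reference barley panel
        f = dp.fixation_index(dp.reference.PANEL_MEAN_UHO,
                              dp.reference.PANEL_MEAN_UHE)
        assert round(f, 3) == 0.706

    @pytest.mark.parametrize("ho,uhe,expected", [
        (0.3, 0.3, 0.0),
        (0.0, 0.4, 1.0),
        (0.1, 0.0, 0.0),   # monomorphic convention
    ])
    def test_conventions(self, ho, uhe, expected):
        assert dp.fixation_index(ho, uhe) == pytest.approx(expected)


class TestAllelicRichness:
    def test_monomorphic_is_one(self):
        assert rarefied_allele_count([6], g=4) == pytest.approx(1.0)

    def test_two_by_two_enumeration(self):
        # N=4 copies (2,2), g=2: 2 * (1 - C(2,2)/C(4,2)) = 5/3
        assert rarefied_allele_count([2, 2], g=2) == pytest.approx(5 / 3)

    def test_full_sample_gives_observed_count(self):
        assert rarefied_allele_count([3, 5], g=8) == pytest.approx(2.0)

    def test_g_below_two_rejected(self):
        with pytest.raises(ValueError):
            rarefied_allele_count([2, 2], g=1)

    @pytest.mark.parametrize("counts,g", [
        ((2, 2), 2), ((3, 1), 2), ((5, 3), 4), ((6, 2), 3), ((4, 4), 6),
        ((7, 1), 5), ((1, 1), 2),
    ])
    def test_matches_brute_force_enumeration(self, counts, g):
        # enumerate every size-g subsample of the N <= 8 allele copies
        copies = [a for a, c in enumerate(counts) for _ in range(c)]
        subsets = list(itertools.combinations(range(len(copies)), g))
        mean_distinct = np.mean([
            len({copies[i] for i in sub}) for sub in subsets])
        assert rarefied_allele_count(list(counts), g) == \
            pytest.approx(mean_distinct, abs=1e-12)

    def test_group_table(self, toy):
        gm, _, meta = toy
        groups = dp.group_indices(meta, gm)
        ar = dp.allelic_richness(gm, groups)   # g = 2 * min size = 4
        assert set(ar.index) == {"old", "mid", "new"}
        assert ((ar >= 1.0) & (ar <= 2.0)).all()


class TestCultivarHeterogeneity:
    def test_hand_count(self):
        calls = np.array([[1, 1, 0, 2]], dtype=np.int8)
        gm = dp.GenotypeMatrix(calls, ["S0"], ["L0", "L1", "L2", "L3"])
        het = dp.cultivar_heterogeneity(gm)
        assert het.loc[0, "ho"] == pytest.approx(0.5)

    def test_all_homozygous_zero(self):
        calls = np.array([[0, 2, 0, 2]], dtype=np.int8)
        gm = dp.GenotypeMatrix(calls, ["S0"], [f"L{i}" for i in range(4)])
        assert dp.cultivar_heterogeneity(gm).loc[0, "ho"] == 0.0

    def test_group_ordering_follows_heterogeneity(self):
        cfg = dp.SimConfig(
            n_pools=2, group_sizes=(12, 12), group_labels=("hi", "lo"),
            heterogeneity_by_group=(0.2, 0.05),
            loci_per_chromosome={"1H": 300}, sweep_spec=[],
            n_duplicate_pairs=0, seed=5)
        gm, _, meta, _ = dp.generate_panel(cfg)
        het = dp.cultivar_heterogeneity(gm).merge(meta, on="accession_id")
        means = het.groupby("group")["ho"].mean()
        assert means["hi"] > means["lo"]


class TestSnpTypes:
    def test_transition_transversion_accounting(self):
        info = pd.DataFrame({
            "locus_id": ["L1", "L2", "L3"],
            "chromosome": ["1H", "1H", "2H"],
            "change": ["A>G", "C>G", "T>C"],   # Ts, Tv, Ts
        })
        tab = dp.snp_type_table(info)
        assert tab.ts_count["Total"] == 2 and tab.tv_count["Total"] == 1
        assert tab.pct_ts["Total"] == pytest.approx(200 / 3)
        assert tab.totals["1H"] == 2

    def test_malformed_change_names_locus(self):
        info = pd.DataFrame({"locus_id": ["Lx"], "chromosome": ["1H"],
                             "change": ["A>A"]})
        with pytest.raises(ValueError, match="Lx"):
            dp.snp_type_table(info)


class TestHomozygousLocusFraction:
    def test_toy_has_one_het_free_locus(self, toy):
        gm, info, _ = toy
        assert dp.homozygous_locus_fraction(gm) == pytest.approx(1 / 12)
        by_chrom = dp.homozygous_locus_fraction(gm, info, by_chromosome=True)
        assert by_chrom["all"] == pytest.approx(1 / 12)

    def test_no_hets_everywhere_one(self):
        calls = np.array([[0, 2], [2, 0]], dtype=np.int8)
        gm = dp.GenotypeMatrix(calls, ["a", "b"], ["L0", "L1"])
        assert dp.homozygous_locus_fraction(gm) == 1.0

    def test_subset_monotone(self, toy):
        gm, _, _ = toy
        full = dp.homozygous_locus_fraction(gm)
        sub = dp.homozygous_locus_fraction(gm.take_accessions(np.arange(3)))
        assert sub >= full


class TestGroupSummaries:
    def test_single_chromosome_equals_panel(self, toy):
        gm, info, meta = toy
        one = gm.take_loci(np.flatnonzero(info["chromosome"] == "1H"))
        info1 = info[info["chromosome"] == "1H"].reset_index(drop=True)
        tab = dp.group_summaries(one, info1, meta).set_index("scope")
        for col in ("pic", "ho", "uhe", "f"):
            assert tab.loc["panel", col] == \
                pytest.approx(tab.loc["chromosome:1H", col])

    def test_low_divergence_uhe_matches_expectation(self):
        cfg = dp.SimConfig(
            n_pools=2, group_sizes=(15, 15), group_labels=("a", "b"),
            heterogeneity_by_group=(0.05, 0.05), pool_divergence=0.02,
            loci_per_chromosome={"1H": 1000}, sweep_spec=[],
            n_duplicate_pairs=0, missing_rate=0.0, seed=2)
        gm, info, meta, truth = dp.generate_panel(cfg)
        expected = np.mean(2 * truth.ancestral_freq
                           * (1 - truth.ancestral_freq))
        tab = dp.group_summaries(gm, info, meta).set_index("scope")
        for grp in ("a", "b"):
            assert tab.loc[f"group:{grp}", "uhe"] == \
                pytest.approx(expected, abs=0.02)

    def test_unknown_group_rejected(self, toy):
        gm, info, meta = toy
        bad = meta.copy()
        bad.loc[0, "accession_id"] = "ghost"
        with pytest.raises((ValueError, KeyError)):
            dp.group_summaries(gm, info, bad)

    def test_panel_f_consistent_with_means(self, default_panel):
        gm, info, meta, _ = default_panel
        s = summarise(gm)
        assert s["f"] == pytest.approx((s["uhe"] - s["ho"]) / s["uhe"])
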