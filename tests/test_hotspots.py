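"""Overview-index profiles, peak detection and hotspot construction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from medscan.assoc import Mta
from medscan.datasets import load_reference_hotspots
from medscan.genio import make_marker_map
from medscan.hotspots import (Hotspot, build_hotspots, detect_peaks, genome_counts,
                              hotspots_from_frame, merge_overlapping, mta_sigma,
                              overview_index, physical_interval, select_hotspots)


def _mta(chrom, cm, trait="t", klass="P", marker="mk"):
    return Mta(marker, chrom, cm, None, trait, klass, 4.0, 0.05, 0.1)


def _map_one_chrom(length=100.0, chrom="1A"):
    cms = np.linspace(0, length, 21)
    return make_marker_map([f"m{i}" for i in range(21)], [chrom] * 21, cms,
                           np.round(cms * 1e6) + 1)


class TestMtaSigma:
    def test_unit_case(self):
        assert mta_sigma(3.92) == pytest.approx(1.0)

    def test_ci_ten(self):
        assert mta_sigma(10.0) == pytest.approx(10.0 / 3.92)
        assert mta_sigma(10.0) == pytest.approx(2.551, abs=1e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mta_sigma(0.0)


class TestOverviewIndex:
    def test_single_gaussian_peak(self):
        mmap = _map_one_chrom(100.0)
        prof = overview_index([_mta("1A", 50.0)], mmap, {"1A": 3.92}, nb_e=1,
                              chrom_lengths={"1A": 100.0})
        i = np.where(prof.positions["1A"] == 50)[0][0]
        assert prof.u["1A"][i] == pytest.approx(1.0 / math.sqrt(2 * math.pi))
        assert prof.mean_threshold == pytest.approx(0.01)

    def test_linearity_two_identical_mtas(self):
        mmap = _map_one_chrom(100.0)
        one = overview_index([_mta("1A", 50.0)], mmap, {"1A": 5.0}, nb_e=2,
                             chrom_lengths={"1A": 100.0})
        two = overview_index([_mta("1A", 50.0)] * 2, mmap, {"1A": 5.0}, nb_e=2,
                             chrom_lengths={"1A": 100.0})
        np.testing.assert_allclose(two.u["1A"], 2 * one.u["1A"])

    def test_mass_conservation_random_instance(self):
        rng = np.random.default_rng(0)
        mmap = _map_one_chrom(300.0)
        # keep away from edges so no Gaussian mass is clipped
        mtas = [_mta("1A", float(c)) for c in rng.uniform(30, 270, size=100)]
        prof = overview_index(mtas, mmap, {"1A": 8.0}, nb_e=4,
                              chrom_lengths={"1A": 300.0})
        assert prof.total_mass() == pytest.approx(100 / 4, rel=0.01)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=40.0, max_value=260.0), min_size=1,
                    max_size=30),
           st.floats(min_value=3.0, max_value=15.0),
           st.integers(min_value=1, max_value=10))
    def test_mass_conservation_property(self, positions, ci, nb_e):
        # ci >= 3 cM keeps sigma above ~0.75 cM; the 1-cM evaluation grid
        # undersamples narrower Gaussians (documented grid bias)
        mmap = _map_one_chrom(300.0)
        mtas = [_mta("1A", c) for c in positions]
        prof = overview_index(mtas, mmap, {"1A": ci}, nb_e=nb_e,
                              chrom_lengths={"1A": 300.0})
        assert prof.total_mass() == pytest.approx(len(positions) / nb_e, rel=0.01)

    def test_empty_mtas_warn_zero_profile(self):
        mmap = _map_one_chrom(100.0)
        with pytest.warns(UserWarning, match="no associations"):
            prof = overview_index([], mmap, {"1A": 4.0}, nb_e=1,
                                  chrom_lengths={"1A": 100.0})
        assert prof.total_mass() == 0.0
        assert prof.mean_threshold == 0.0


class TestDetectPeaks:
    def _profile(self, values, chrom="1A"):
        from medscan.hotspots import OverviewProfile
        grid = np.arange(len(values))
        return OverviewProfile({chrom: grid}, {chrom: np.asarray(values, float)},
                               nb_qtl=1, nb_e=1, map_length_cm=float(len(values)),
                               mean_threshold=0.0, high_threshold=0.0)

    def test_counting_contract(self):
        vals = np.zeros(50)
        vals[[10, 11, 12]] = [1.0, 2.0, 1.0]
        vals[40] = 3.0
        peaks, n_pos = detect_peaks(self._profile(vals), threshold=0.5)
        assert n_pos == 4
        assert [p.position for p in peaks] == [11, 40]

    def test_flat_profile_no_peaks(self):
        peaks, n_pos = detect_peaks(self._profile(np.full(30, 0.1)), threshold=0.5)
        assert peaks == [] and n_pos == 0

    def test_two_gaussians_split_or_joined_by_valley(self):
        grid = np.arange(100, dtype=float)
        g = lambda mu: np.exp(-0.5 * (grid - mu) ** 2 / 4.0)
        vals = g(40) + g(52)  # 3 sigma apart (sigma=2 -> 6 sigma? keep 12 apart)
        prof = self._profile(vals)
        valley = vals[46]
        peak_h = vals[40]
        # threshold above the valley: two peaks
        peaks, _ = detect_peaks(prof, threshold=(valley + peak_h) / 2)
        assert len(peaks) == 2
        # threshold below the valley: one run, one peak
        peaks, _ = detect_peaks(prof, threshold=valley / 2)
        assert len(peaks) == 1

    def test_leftmost_argmax_on_ties(self):
        vals = np.zeros(20)
        vals[[5, 6, 7]] = [1.0, 1.0, 0.8]
        peaks, _ = detect_peaks(self._profile(vals), threshold=0.5)
        assert peaks[0].position == 5

    def test_positions_ge_peaks_always(self):
        rng = np.random.default_rng(1)
        vals = rng.random(200)
        peaks, n_pos = detect_peaks(self._profile(vals), threshold=0.7)
        assert n_pos >= len(peaks)
        runs_len1 = all(p.n_positions == 1 for p in peaks)
        assert (n_pos == len(peaks)) == runs_len1


class TestBuildHotspots:
    def _setup(self, peak_positions, ld_ci=4.0, length=100.0):
        from medscan.hotspots import OverviewProfile, Peak
        mmap = _map_one_chrom(length)
        grid = np.arange(int(length) + 1)
        prof = OverviewProfile({"1A": grid}, {"1A": np.zeros(len(grid))},
                               nb_qtl=len(peak_positions), nb_e=1,
                               map_length_cm=length, mean_threshold=0.0,
                               high_threshold=0.0)
        peaks = [Peak("1A", p, 1.0, p, p, 1) for p in peak_positions]
        mtas = [_mta("1A", p, klass="P") for p in peak_positions]
        return peaks, prof, {"1A": ld_ci}, mmap, mtas

    def test_close_peaks_merge(self):
        hs = build_hotspots(*self._setup([50, 51], ld_ci=4.0))
        assert len(hs) == 1
        assert hs[0].name == "1A.1"

    def test_distant_peaks_stay_separate(self):
        hs = build_hotspots(*self._setup([20, 70], ld_ci=4.0))
        assert [h.name for h in hs] == ["1A.1", "1A.2"]

    def test_five_peak_hand_enumeration(self):
        # intervals peak +- 2: [8,12],[11,15],[28,32],[33,37],[58,62]
        # -> clusters {10,13}, {30}, {35}, {60}: 13-2=11 <= 10+2=12 merge;
        # 35-2=33 > 30+2=32 apart; total 4 hotspots
        hs = build_hotspots(*self._setup([10, 13, 30, 35, 60], ld_ci=4.0))
        assert len(hs) == 4
        assert hs[0].cm_interval == (8.0, 15.0)

    def test_trait_classes_and_flanks_attached(self):
        peaks, prof, ld, mmap, mtas = self._setup([50], ld_ci=10.0)
        mtas.append(_mta("1A", 52.0, klass="C"))
        hs = build_hotspots(peaks, prof, ld, mmap, mtas)
        assert hs[0].trait_classes == {"P", "C"}
        assert hs[0].left_marker is not None
        assert hs[0].ci_mb is not None

    def test_no_mapped_bp_flagged(self):
        peaks, prof, ld, mmap, mtas = self._setup([50])
        mmap = mmap.assign(bp=np.nan)
        with pytest.warns(UserWarning, match="no bp-mapped marker"):
            hs = build_hotspots(peaks, prof, ld, mmap, mtas)
        assert hs[0].bp_interval is None


class TestPhysicalInterval:
    def test_published_1a1_width(self):
        h = Hotspot("1A.1", "1A", (21, 27), {"C"}, "L", "R",
                    (7643102, 8296998))
        assert physical_interval(h).ci_mb == 0.65

    def test_order_insensitive_1b1(self):
        h = Hotspot("1B.1", "1B", (43, 45), {"C"}, "L", "R",
                    (38833829, 26186242))
        h = physical_interval(h)
        assert h.ci_mb == 12.65
        assert h.bp_interval == (26186242, 38833829)
        assert (h.left_marker, h.right_marker) == ("R", "L")

    def test_degenerate_zero_width(self):
        h = Hotspot("x", "1A", (0, 1), set(), "L", "R", (100, 100))
        assert physical_interval(h).ci_mb == 0.0


@pytest.fixture(scope="module")
def reference():
    return hotspots_from_frame(load_reference_hotspots())


class TestSelectAndMerge:

    def test_threshold_excludes_wide(self):
        wide = physical_interval(Hotspot("x", "1A", (0, 1), set(), "L", "R",
                                         (0, 21_000_000)))
        kept = select_hotspots([wide], max_ci_mb=20.0)
        assert kept == []

    def test_1b2_retained(self, reference):
        names = {h.name for h in select_hotspots(
            [physical_interval(h) for h in reference])}
        assert "1B.2" in names  # 16.37 Mb <= 20

    def test_genome_counts_published(self, reference):
        hs = select_hotspots([physical_interval(h) for h in reference])
        counts = genome_counts(hs)
        assert counts == {"A": 12, "B": 18, "D": 3}

    def test_published_1b_merge(self):
        h1 = physical_interval(Hotspot("1B.1", "1B", (43, 45), {"C"}, "a", "b",
                                       (26186242, 38833829)))
        h2 = physical_interval(Hotspot("1B.2", "1B", (51, 53), {"P"}, "c", "d",
                                       (28563880, 44933589)))
        merged = merge_overlapping([h1, h2])
        assert len(merged) == 1
        assert merged[0].name == "1B.1-2"
        assert merged[0].bp_interval == (26186242, 44933589)
        assert merged[0].trait_classes == {"C", "P"}

    def test_published_1d_merge(self):
        h1 = physical_interval(Hotspot("1D.1", "1D", (161, 172), {"C"}, "a", "b",
                                       (485557589, 487168787)))
        h2 = physical_interval(Hotspot("1D.2", "1D", (179, 180), {"C"}, "c", "d",
                                       (486241852, 491043383)))
        merged = merge_overlapping([h1, h2])
        assert len(merged) == 1
        assert merged[0].bp_interval == (485557589, 491043383)

    def test_adjacent_disjoint_not_merged(self):
        h1 = physical_interval(Hotspot("2A.1", "2A", (0, 1), set(), "a", "b",
                                       (100, 200)))
        h2 = physical_interval(Hotspot("2A.2", "2A", (5, 6), set(), "c", "d",
                                       (201, 300)))
        assert len(merge_overlapping([h1, h2])) == 2


def test_end_to_end_planted_cluster_recovery():
    """Clusters of >= 3 simulated associations around a known position
    produce a hotspot whose cM interval contains the truth."""
    rng = np.random.default_rng(5)
    mmap = _map_one_chrom(200.0)
    hits = 0
    n_seeds = 25
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        true_cm = 100.0
        mtas = [_mta("1A", float(true_cm + rng.normal(0, 1.5)), marker=f"q{i}")
                for i in range(4)]
        prof = overview_index(mtas, mmap, {"1A": 6.0}, nb_e=2,
                              chrom_lengths={"1A": 200.0})
        peaks, _ = detect_peaks(prof, prof.high_threshold)
        hs = build_hotspots(peaks, prof, {"1A": 6.0}, mmap, mtas)
        if any(h.cm_interval[0] <= true_cm <= h.cm_interval[1] for h in hs):
            hits += 1
    assert hits >= 0.9 * n_seeds
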