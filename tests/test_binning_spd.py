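"""Site-phase binning, SPD construction, smoothing, scaling, comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleospd import (
    BinnableDate,
    CalendarWindow,
    PopulationSeries,
    SPDSeries,
    TreeRingRecord,
    bin_average,
    bin_dates,
    build_spd,
    compare_series,
    degenerate_density,
    scale_by_factor,
    scale_to_reference,
    smooth_spd,
)
from paleospd.binning_spd import gaussian_kernel


def binning_oracle(keys, h):
    """Transitive closure over pairs with |ki - kj| <= h (union-find)."""
    n = len(keys)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(keys[i] - keys[j]) <= h:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestBinDates:
    def test_singleton(self):
        bins = bin_dates([BinnableDate("d0", "S1", 1000.0)])
        assert len(bins) == 1
        assert bins[0].members == ("d0",)

    def test_chain_with_break(self):
        """Keys {1000, 1080, 1160, 1400} at h=100: the first three chain
        (consecutive gaps 80) and 1400 splits off (gap 240)."""
        dates = [BinnableDate(i, "S1", k) for i, k in enumerate([1000, 1080, 1160, 1400])]
        bins = bin_dates(dates, h=100)
        member_sets = {frozenset(b.members) for b in bins}
        assert member_sets == {frozenset({0, 1, 2}), frozenset({3})}
        expected = binning_oracle([1000, 1080, 1160, 1400], 100)
        assert member_sets == expected

    def test_gap_exactly_h_merges(self):
        dates = [BinnableDate(0, "S1", 1000.0), BinnableDate(1, "S1", 1100.0)]
        assert len(bin_dates(dates, h=100)) == 1
        assert len(bin_dates(dates, h=99.9)) == 2

    def test_sites_never_co_binned(self):
        dates = [BinnableDate(0, "S1", 1000.0), BinnableDate(1, "S2", 1000.0)]
        assert len(bin_dates(dates, h=100)) == 2

    def test_phase_index_ordered_descending_mean(self):
        dates = [BinnableDate(i, "S1", k) for i, k in enumerate([500, 900, 1300])]
        bins = bin_dates(dates, h=100)
        means = [b.mean_key for b in sorted(bins, key=lambda b: b.phase_index)]
        assert means == sorted(means, reverse=True)
        assert [b.phase_index for b in sorted(bins, key=lambda b: b.phase_index)] == [1, 2, 3]

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_transitive_closure_oracle(self, seed):
        """Single-linkage cut equals brute-force connected components,
        including gap-exactly-h boundary cases (keys on a 50-year lattice)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        keys = (rng.integers(0, 20, size=n) * 50).astype(float).tolist()
        dates = [BinnableDate(i, "S1", k) for i, k in enumerate(keys)]
        got = {frozenset(b.members) for b in bin_dates(dates, h=100)}
        assert got == binning_oracle(keys, 100)

    def test_invalid_h(self):
        with pytest.raises(ValueError):
            bin_dates([BinnableDate(0, "S1", 1.0)], h=0)


class TestDegenerateDensity:
    def test_point_mass_at_converted_year(self):
        d = degenerate_density(TreeRingRecord("S1", "Montezuma, CO", 700, "r"))
        assert d.grid.tolist() == [1250]
        assert d.mass.tolist() == [1.0]
        assert d.total == 1.0

    def test_distinct_dates_disjoint_supports(self):
        d1 = degenerate_density(TreeRingRecord("S1", "Montezuma, CO", 700, "r"))
        d2 = degenerate_density(TreeRingRecord("S1", "Montezuma, CO", 701, "r"))
        assert set(d1.grid) & set(d2.grid) == set()


class TestBinAverage:
    def test_single_density_identity(self):
        d = degenerate_density(TreeRingRecord("S1", "Montezuma, CO", 700, "r"))
        avg = bin_average([d])
        assert np.array_equal(avg.grid, d.grid) and np.array_equal(avg.mass, d.mass)

    def test_two_point_masses(self):
        ds = [
            degenerate_density(TreeRingRecord("S1", "x, CO", 700, "r")),  # 1250 BP
            degenerate_density(TreeRingRecord("S1", "x, CO", 650, "r")),  # 1300 BP
        ]
        avg = bin_average(ds)
        assert avg.mass[avg.grid == 1250][0] == pytest.approx(0.5)
        assert avg.mass[avg.grid == 1300][0] == pytest.approx(0.5)
        assert avg.total == pytest.approx(1.0, abs=1e-9)

    def test_three_point_hand_mean(self):
        """Point masses {1250, 1250, 1300} average to 2/3 and 1/3."""
        years_ad = [700, 700, 650]
        ds = [degenerate_density(TreeRingRecord("S1", "x, CO", y, "r")) for y in years_ad]
        avg = bin_average(ds)
        assert avg.mass[avg.grid == 1250][0] == pytest.approx(2 / 3)
        assert avg.mass[avg.grid == 1300][0] == pytest.approx(1 / 3)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            bin_average([])


def treering_spd(years_ad, site_ids, window, h=100):
    recs = [
        TreeRingRecord(s, "Montezuma, CO", y, "r") for y, s in zip(years_ad, site_ids)
    ]
    dates = [BinnableDate(i, r.site_id, float(r.year_bp)) for i, r in enumerate(recs)]
    densities = {i: degenerate_density(r) for i, r in enumerate(recs)}
    bins = bin_dates(dates, h=h)
    return bins, build_spd(bins, densities, window)


class TestBuildSpd:
    def test_mass_equals_n_bins(self, study_window):
        bins, spd = treering_spd([700, 1200], ["S1", "S2"], study_window)
        assert spd.total == pytest.approx(2.0, abs=1e-9)
        assert spd.meta["n_bins"] == 2 and spd.meta["n_dates"] == 2

    def test_one_site_one_bin_composition(self, study_window):
        """Dates {AD 700, 700, 650} at one site bin together (gaps <= 100)
        and the SPD carries 2/3 mass at 1250 BP, 1/3 at 1300 BP."""
        bins, spd = treering_spd([700, 700, 650], ["S1"] * 3, study_window)
        assert len(bins) == 1
        assert spd.density[spd.grid == 1250][0] == pytest.approx(2 / 3)
        assert spd.density[spd.grid == 1300][0] == pytest.approx(1 / 3)
        assert spd.total == pytest.approx(1.0, abs=1e-9)

    def test_same_dates_two_sites(self, study_window):
        bins, spd = treering_spd([700, 700, 650], ["S1", "S2", "S2"], study_window)
        assert len(bins) == 2
        assert spd.total == pytest.approx(2.0, abs=1e-9)

    def test_clipped_mass_reported(self):
        narrow = CalendarWindow(start_bp=1260, end_bp=1240)
        bins, spd = treering_spd([700, 650], ["S1", "S2"], narrow)
        assert spd.meta["clipped_mass"] == pytest.approx(1.0)
        assert spd.total == pytest.approx(1.0)

    def test_no_bins_error(self, study_window):
        with pytest.raises(ValueError):
            build_spd([], {}, study_window)

    def test_permutation_invariance(self, study_window):
        years = [700, 650, 700, 1200, 1210, 900]
        sites = ["S1", "S1", "S2", "S2", "S3", "S3"]
        _, spd_a = treering_spd(years, sites, study_window)
        order = [3, 1, 5, 0, 4, 2]
        _, spd_b = treering_spd([years[i] for i in order], [sites[i] for i in order], study_window)
        assert np.allclose(spd_a.density, spd_b.density, atol=1e-12)

    def test_singleton_bins_equal_annual_histogram(self, study_window):
        """With all-singleton bins the tree-ring SPD is the raw annual count
        histogram of the dates."""
        years = [700, 700, 650, 1200]
        sites = [f"S{i}" for i in range(len(years))]
        _, spd = treering_spd(years, sites, study_window)
        counts = np.zeros_like(spd.density)
        for y in years:
            counts[spd.grid == 1950 - y] += 1
        assert np.array_equal(spd.density, counts)


class TestSmoothSpd:
    def _flat(self, value=2.0, n=200):
        return SPDSeries(np.arange(500, 500 + n), np.full(n, value))

    def test_constant_series_unchanged_including_edges(self):
        spd = self._flat()
        sm = smooth_spd(spd)
        assert np.allclose(sm.density, spd.density, atol=1e-12)

    def test_interior_impulse_equals_kernel(self):
        n = 101
        dens = np.zeros(n)
        dens[50] = 1.0
        sm = smooth_spd(SPDSeries(np.arange(1000, 1000 + n), dens), window=21, sd=5.0)
        w = gaussian_kernel(21, 5.0)
        assert np.allclose(sm.density[40:61], w, atol=1e-12)
        assert np.allclose(sm.density[:40], 0.0) and np.allclose(sm.density[61:], 0.0)

    def test_mass_conserved(self):
        rng = np.random.default_rng(0)
        dens = rng.random(300)
        dens[:5] += 10  # mass near an edge
        spd = SPDSeries(np.arange(100, 400), dens)
        sm = smooth_spd(spd)
        assert sm.total == pytest.approx(spd.total, abs=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_spd(self._flat(), window=20)


class TestScaling:
    def _spd_two_points(self):
        dens = np.zeros(101)
        dens[40] = dens[60] = 1.0  # total mass 2
        return SPDSeries(np.arange(600, 701), dens)

    def test_direct_arithmetic(self):
        """100 persons for 50 years = 5000 person-years; SPD mass 2 in the
        overlap gives factor 2500."""
        spd = self._spd_two_points()
        pop = PopulationSeries([(1300, 1350, 100.0)])  # 650..601 BP
        overlap = CalendarWindow(start_bp=700, end_bp=600)
        scaled = scale_to_reference(spd, pop, overlap)
        assert scaled.meta["scaling_factor"] == pytest.approx(2500.0)
        assert scaled.total == pytest.approx(5000.0, abs=1e-9)

    def test_area_equality_exact(self):
        spd = self._spd_two_points()
        pop = PopulationSeries([(1300, 1350, 100.0)])
        overlap = CalendarWindow(start_bp=700, end_bp=600)
        scaled = scale_to_reference(spd, pop, overlap)
        _, pop_vals = pop.annualize(overlap)
        in_overlap = scaled.density[(scaled.grid >= 600) & (scaled.grid <= 700)].sum()
        assert in_overlap == pytest.approx(pop_vals.sum(), abs=1e-9)

    def test_doubling_population_doubles_factor(self):
        spd = self._spd_two_points()
        overlap = CalendarWindow(start_bp=700, end_bp=600)
        f1 = scale_to_reference(spd, PopulationSeries([(1300, 1350, 100.0)]), overlap)
        f2 = scale_to_reference(spd, PopulationSeries([(1300, 1350, 200.0)]), overlap)
        assert f2.meta["scaling_factor"] == pytest.approx(2 * f1.meta["scaling_factor"])

    def test_fixed_point(self):
        # SPD identical to the annualized population over the overlap
        pop = PopulationSeries([(1300, 1350, 10.0)])
        years = np.arange(600, 651)  # 1350..1300 AD in BP terms
        spd = SPDSeries(years, np.full(years.size, 10.0))
        scaled = scale_to_reference(spd, pop, CalendarWindow(650, 601))
        assert scaled.meta["scaling_factor"] == pytest.approx(1.0)

    def test_zero_mass_error(self):
        spd = SPDSeries(np.arange(600, 701), np.zeros(101))
        with pytest.raises(ValueError):
            scale_to_reference(
                spd, PopulationSeries([(1300, 1350, 100.0)]), CalendarWindow(700, 600)
            )

    def test_scale_by_factor(self):
        spd = self._spd_two_points()
        tripled = scale_by_factor(spd, 3.0)
        assert np.allclose(tripled.density, 3.0 * spd.density)
        roundtrip = scale_by_factor(scale_by_factor(spd, 2.0), 0.5)
        assert np.allclose(roundtrip.density, spd.density, atol=1e-12)
        with pytest.raises(ValueError):
            scale_by_factor(spd, 0.0)


class TestCompareSeries:
    def _hump(self, peak_bp, window):
        grid = np.arange(window.end_bp, window.start_bp + 1)
        dens = np.exp(-0.5 * ((grid - peak_bp) / 40.0) ** 2)
        return SPDSeries(grid, dens)

    def test_identical_series(self):
        win = CalendarWindow(1000, 400)
        a = self._hump(700, win)
        rep = compare_series(a, a, win)
        assert rep.sign_agreement == 1.0
        assert rep.peak_diff_years == 0
        assert rep.decline_onset_ad_a == rep.decline_onset_ad_b

    def test_opposite_slopes_disagree(self):
        win = CalendarWindow(1000, 400)
        grid = np.arange(400, 1001)
        up = SPDSeries(grid, np.linspace(1.0, 2.0, grid.size))
        down = SPDSeries(grid, np.linspace(2.0, 1.0, grid.size))
        rep = compare_series(up, down, win)
        assert rep.sign_agreement == 0.0

    def test_known_peak_difference(self):
        win = CalendarWindow(1000, 400)
        rep = compare_series(self._hump(650, win), self._hump(700, win), win)
        assert rep.peak_diff_years == 50

    def test_population_reference(self):
        win = CalendarWindow(1000, 401)
        a = self._hump(700, win)
        pop = PopulationSeries([(950, 1200, 50.0), (1200, 1550, 200.0)])
        rep = compare_series(a, pop, win)
        assert rep.peak_year_ad_a == 1250
        assert set(rep.century_means_b) <= set(rep.century_means_a)
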