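"""Effective degrees of freedom, plasticity tests, classification and phenology."""

import numpy as np
import pytest
from scipy import stats as sps

from nichetrack.grids import PeriodIndex, standard_periods
from nichetrack.stats import (
    SeasonalProfile,
    abundance_sst_correlation,
    classify_taxon,
    effective_dof,
    phenological_shift,
    phenology_vs_range,
    plasticity_test,
    seasonal_peak,
)


def ar1(rng, n, phi):
    e = rng.normal(size=n)
    out = np.empty(n)
    out[0] = e[0] / np.sqrt(1 - phi**2)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + e[i]
    return out


class TestEffectiveDof:
    def test_white_noise_close_to_nominal(self):
        rng = np.random.default_rng(0)
        ratios = [effective_dof(rng.normal(size=100), rng.normal(size=100)) / 100 for _ in range(50)]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_ar1_matches_closed_form(self):
        # two AR(1) series with phi = 0.5: n_eff / n -> 0.6 analytically
        rng = np.random.default_rng(1)
        ratios = [effective_dof(ar1(rng, 200, 0.5), ar1(rng, 200, 0.5)) / 200 for _ in range(100)]
        assert np.mean(ratios) == pytest.approx(0.6, rel=0.10)

    def test_never_exceeds_nominal_sample_size(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x, y = rng.normal(size=12), rng.normal(size=12)
            assert 2.0 < effective_dof(x, y) <= 12.0

    def test_constant_series_is_an_error(self):
        with pytest.raises(ValueError):
            effective_dof(np.ones(10), np.ones(10))


class TestPlasticityTest:
    def test_perfect_anticorrelation_significant(self):
        x = np.arange(12.0)
        res = plasticity_test(-x, x)
        assert res.r == pytest.approx(-1.0)
        assert res.significant_negative

    def test_positive_correlation_never_significant(self):
        x = np.arange(12.0)
        res = plasticity_test(x, x)
        assert res.r == pytest.approx(1.0)
        assert not res.significant_negative

    def test_p_invariant_to_affine_transforms(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        p0 = plasticity_test(x, y).p_one_sided
        p1 = plasticity_test(3.0 * x - 7.0, 0.5 * y + 100.0).p_one_sided
        assert p1 == pytest.approx(p0, rel=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            plasticity_test([1.0, 2.0], [2.0, 1.0])


class TestClassification:
    def _results(self, flags):
        return {
            temp: plasticity_test(
                -np.arange(12.0) if sig else np.tile([0.0, 1.0], 6),
                np.arange(12.0),
                taxon="t",
                isotherm_temp=temp,
            )
            for temp, sig in zip((11.0, 12.0, 13.0), flags)
        }

    def _classify(self, flags):
        periods = standard_periods()
        med = np.linspace(54.0, 56.0, 12)
        pop = np.linspace(1.0, 2.0, 12)
        return classify_taxon(
            self._results(flags),
            periods,
            med,
            pop,
            (PeriodIndex(1959, 1963), PeriodIndex(1984, 1988)),
            (PeriodIndex(1984, 1988), PeriodIndex(2004, 2008)),
        )

    def test_verdicts(self):
        assert self._classify([True, True, True]).verdict == "plastic_all3"
        assert self._classify([False, False, False]).verdict == "conservative"
        assert self._classify([True, False, False]).verdict == "plastic_partial"

    def test_movements_from_median_series(self):
        cls = self._classify([False] * 3)
        # median latitude rises linearly 54 -> 56 over the 12 periods
        step = 2.0 / 11.0
        assert cls.movement_cooling_km == pytest.approx(5 * step * 111.0)
        assert cls.movement_warming_km == pytest.approx(4 * step * 111.0)

    def test_missing_period_reported(self):
        periods = standard_periods()[:-2]
        with pytest.raises(ValueError, match="2004-2008"):
            classify_taxon(
                self._results([True] * 3),
                periods,
                np.linspace(54, 56, 10),
                np.ones(10),
                (PeriodIndex(1959, 1963), PeriodIndex(1984, 1988)),
                (PeriodIndex(1984, 1988), PeriodIndex(2004, 2008)),
            )


class TestAbundanceSSTCorrelation:
    def test_monotone_series_signs(self):
        rng = np.random.default_rng(4)
        sst = np.linspace(11.0, 12.0, 12) + rng.normal(0, 0.01, 12)
        assert abundance_sst_correlation(sst * 2.0, sst) == "+"
        assert abundance_sst_correlation(-sst, sst) == "-"

    def test_independent_series_usually_none(self):
        rng = np.random.default_rng(5)
        outcomes = [
            abundance_sst_correlation(rng.normal(size=12), rng.normal(size=12))
            for _ in range(200)
        ]
        assert outcomes.count("none") > 160  # ~1 - alpha of draws


class TestSeasonalPeak:
    def test_point_mass_month(self):
        x = np.zeros(12)
        x[5] = 4.0
        assert seasonal_peak(x) == 6.0

    def test_uniform_profile(self):
        assert seasonal_peak(np.ones(12)) == pytest.approx(6.5)

    def test_two_peaks_below_bimodal_threshold_use_full_mean(self):
        x = np.zeros(12)
        x[3], x[7] = 1.0, 3.0  # minor is 33% of major: not bimodal
        assert seasonal_peak(x) == pytest.approx(7.0)

    def test_genuine_bimodal_restricts_to_dominant_peak(self):
        x = np.zeros(12)
        x[2], x[8] = 2.5, 3.0  # spring and autumn blooms, comparable height
        sp = seasonal_peak(x)
        assert sp == pytest.approx(9.0)  # the autumn (dominant) peak only

    def test_invariant_to_positive_scaling(self, rng):
        x = rng.uniform(0.0, 2.0, 12)
        assert seasonal_peak(5.0 * x) == pytest.approx(seasonal_peak(x))

    def test_all_zero_profile_is_an_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            seasonal_peak(np.zeros(12))


class TestPhenology:
    def _profile(self, month, name="t", window="w"):
        x = np.zeros(12)
        x[month - 1] = 1.0
        return SeasonalProfile(taxon=name, window=window, x_m=x)

    def test_identical_profiles_no_shift(self):
        assert phenological_shift(self._profile(7), self._profile(7)) == 0.0

    def test_peak_one_month_earlier(self):
        assert phenological_shift(self._profile(7), self._profile(6)) == -1.0

    def test_proportional_pairs_give_perfect_correlation(self):
        shifts = np.array([-1.0, -0.5, 0.2, 0.9, 1.5])
        r, p = phenology_vs_range(shifts, 50.0 * shifts)
        assert r == pytest.approx(1.0)

    def test_small_or_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="4 taxa"):
            phenology_vs_range([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            phenology_vs_range([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_null_p_values_uniform(self):
        # cross-taxon test with ordinary dof: p under independence is U(0,1)
        rng = np.random.default_rng(6)
        ps = [
            phenology_vs_range(rng.normal(size=12), rng.normal(size=12))[1]
            for _ in range(1000)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 1e-3
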