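"""The generator's analytic ground truths: SST structure, isotherm velocity
and the latitude behaviour of conservative vs plastic abundance responses."""

import io

import numpy as np
import pytest

from nichetrack.grids import GridSpec
from nichetrack.synthetic import (
    SamplingPlan,
    SSTScenario,
    TaxonSpec,
    generate_sst_field,
    generate_tows,
    write_tows_csv,
)

FLAT = ((1954.0, 2014.0, 0.0),)


def _noise_free(trend=FLAT, amplitude=0.0, gradient=0.4):
    return SSTScenario(
        trend_segments=trend, seasonal_amplitude=amplitude, noise_sd=0.0, lat_gradient=gradient
    )


class TestSSTField:
    def test_base_temperature_at_reference(self):
        sc = _noise_free()
        assert sc.temperature(sc.reference_latitude, 1954.0) == pytest.approx(sc.base_temp)

    def test_latitudinal_gradient(self):
        sc = _noise_free()
        dT = sc.temperature(sc.reference_latitude + 1.0, 1954.0) - sc.temperature(
            sc.reference_latitude, 1954.0
        )
        assert dT == pytest.approx(-sc.lat_gradient)

    def test_isotherm_velocity_matches_fine_grid_scan(self):
        # with a single warming segment of rate tau and gradient g, the
        # latitude where T = c moves north at tau/g degrees per year
        tau, g = 0.04, 0.4
        sc = _noise_free(trend=((1954.0, 2014.0, tau),), gradient=g)
        lats = np.arange(45.0, 64.0, 0.001)

        def scanned_latitude(t):
            temps = sc.temperature(lats, t)
            j = int(np.argmin(np.abs(temps - 12.0)))
            return lats[j]

        t1, t2 = 1960.0, 2000.0
        velocity = (scanned_latitude(t2) - scanned_latitude(t1)) / (t2 - t1)
        assert velocity == pytest.approx(tau / g, abs=1e-3)

    def test_generated_table_matches_formula(self):
        sc = _noise_free(amplitude=1.0)
        df = generate_sst_field(sc, grid_step=2.0, years=[1970])
        row = df[(df["time"] == "1970-08") & (df["lat"] == 54.0) & (df["lon"] == -19.0)]
        t = 1970 + 7.5 / 12.0
        assert row["sst"].iloc[0] == pytest.approx(
            float(sc.temperature(54.0, t, month=7.5))
        )

    def test_years_outside_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            generate_sst_field(_noise_free(), years=[1930])

    def test_contiguity_of_trend_segments_enforced(self):
        with pytest.raises(ValueError, match="contiguous"):
            SSTScenario(trend_segments=((1954.0, 1980.0, 0.0), (1990.0, 2014.0, 0.0)))


class TestTows:
    def test_counts_nonnegative_integers_and_positions_in_domain(self):
        plan = SamplingPlan(n_tows_per_year=50, seed=7)
        tows = generate_tows(plan, _noise_free(), [TaxonSpec(name="a")], years=[1960, 1961])
        assert (tows["count"] >= 0).all()
        assert tows["count"].dtype.kind == "i"
        d = plan.domain
        assert tows["latitude"].between(d.lat_min, d.lat_max).all()
        assert tows["longitude"].between(d.lon_min, d.lon_max).all()

    def test_track_sampling_stays_in_domain(self):
        plan = SamplingPlan(n_tows_per_year=120, route_style="tracks", seed=8)
        tows = generate_tows(plan, _noise_free(), [TaxonSpec(name="a")], years=[1970])
        d = plan.domain
        assert tows["latitude"].between(d.lat_min, d.lat_max).all()
        assert tows["longitude"].between(d.lon_min, d.lon_max).all()

    def test_same_seeds_give_byte_identical_tables(self):
        plan = SamplingPlan(n_tows_per_year=40, seed=5)
        taxa = [TaxonSpec(name="a", seed=6)]
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_tows_csv(generate_tows(plan, _noise_free(), taxa, years=[1990]), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_empty_taxa_rejected(self):
        with pytest.raises(ValueError, match="taxa"):
            generate_tows(SamplingPlan(), _noise_free(), [])


class TestNicheResponses:
    def test_conservative_response_peaks_at_thermal_optimum(self):
        sc = _noise_free()
        taxon = TaxonSpec(name="c", niche_mode="conservative", thermal_optimum=11.0)
        lats = np.arange(45.0, 64.0, 0.01)
        t = 1970.0
        sst = sc.temperature(lats, t)
        mu = taxon.expected_log_abundance(lats, sst, month_frac=taxon.peak_month - 0.5)
        best = lats[np.argmax(mu)]
        expected = sc.reference_latitude + (sc.base_temp - 11.0) / sc.lat_gradient
        assert best == pytest.approx(expected, abs=0.02)

    def test_plastic_centre_fixed_under_any_trend(self):
        # expected-abundance-weighted mean latitude equals home_latitude in
        # every period regardless of the SST trend
        sc = _noise_free(trend=((1954.0, 2014.0, 0.05),))
        taxon = TaxonSpec(name="p", niche_mode="plastic", home_latitude=54.5, home_sd=2.0)
        lats = np.arange(45.0, 64.0, 0.01)
        for t in (1960.0, 2000.0):
            w = np.exp(taxon.expected_log_abundance(lats, sc.temperature(lats, t), 7.5))
            assert np.average(lats, weights=w) == pytest.approx(54.5, abs=1e-3)

    def test_conservative_centre_drifts_at_isotherm_velocity(self):
        # brute-force integration of the expected abundance field: the
        # abundance-weighted mean latitude moves at tau/g degrees per year
        tau, g = 0.04, 0.4
        sc = _noise_free(trend=((1954.0, 2014.0, tau),), gradient=g)
        taxon = TaxonSpec(name="c", niche_mode="conservative", thermal_optimum=12.0)
        lats = np.arange(30.0, 80.0, 0.01)  # wide grid: no truncation bias
        centres = []
        for t in (1960.0, 1990.0):
            w = np.exp(taxon.expected_log_abundance(lats, sc.temperature(lats, t), 7.5))
            centres.append(np.average(lats, weights=w))
        velocity = (centres[1] - centres[0]) / 30.0
        assert velocity == pytest.approx(tau / g, rel=0.02)

    def test_diel_migrator_daytime_counts_suppressed(self):
        plan = SamplingPlan(n_tows_per_year=3000, seed=11)
        sc = _noise_free()
        taxa = [
            TaxonSpec(name="day_and_night", diel_migrator=False, seed=3),
            TaxonSpec(name="night_only", diel_migrator=True, seed=3),
        ]
        tows = generate_tows(plan, sc, taxa, years=[1980])
        from nichetrack.gridding import local_solar_hour

        merged = tows.pivot_table(
            index=["latitude", "longitude", "datetime_utc"], columns="taxon", values="count"
        ).reset_index()
        h = local_solar_hour(merged["datetime_utc"], merged["longitude"].to_numpy())
        day = (h >= 6) & (h < 18)
        assert merged.loc[day, "night_only"].mean() < 0.5 * merged.loc[day, "day_and_night"].mean()
        night_ratio = (
            merged.loc[~day, "night_only"].mean() / merged.loc[~day, "day_and_night"].mean()
        )
        assert night_ratio == pytest.approx(1.0, abs=0.15)
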