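import numpy as np
import pandas as pd
import pytest

from iadfnet.climate import annual_summaries
from iadfnet.synthetic_data import (
    ARCHETYPES,
    DEFAULT_SPECIES,
    LAPSE_RATE,
    GrowthParams,
    IadfLogit,
    Scenario,
    SiteSpec,
    SpeciesParams,
    default_scenario,
    generate_climate,
    generate_network,
    generate_ring_widths,
    iadf_probability,
)
from iadfnet.tree_ring_io import SiteMeta


class TestClimateGeneration:
    def test_determinism(self, demo_site):
        a = generate_climate(demo_site, range(1980, 2001), ARCHETYPES["cluster1_humid"], 5)
        b = generate_climate(demo_site, range(1980, 2001), ARCHETYPES["cluster1_humid"], 5)
        pd.testing.assert_frame_equal(a, b)

    def test_temperature_ordering(self, demo_climate):
        assert (demo_climate["tmin"] <= demo_climate["tmean"]).all()
        assert (demo_climate["tmean"] <= demo_climate["tmax"]).all()
        assert (demo_climate["prcp"] >= 0).all()

    def test_continental_january_below_zero(self):
        """The continental archetype has sub-zero winter temperatures in
        expectation at low altitude."""
        site = SiteMeta("X", 52.0, 20.0, 100.0, "T")
        jans = []
        for seed in range(40):
            clim = generate_climate(site, range(1990, 1996), ARCHETYPES["cluster4_continental"], seed)
            jans.append(clim[clim["month"] == 1]["tmean"].mean())
        assert np.mean(jans) < 0.0

    def test_continental_summer_precipitation_maximum(self):
        p = np.asarray(ARCHETYPES["cluster4_continental"].monthly_prcp_mean)
        assert p[5:8].mean() > p[[0, 1, 11]].mean()

    def test_lapse_rate_recovered(self):
        """Mean annual temperature difference across +1000 m matches the
        configured lapse rate, averaged over 200 seeds."""
        lo = SiteMeta("LO", 45.0, 5.0, 200.0, "T")
        hi = SiteMeta("HI", 45.0, 5.0, 1200.0, "T")
        arch = ARCHETYPES["cluster1_humid"]
        diffs = []
        for seed in range(200):
            a = generate_climate(lo, range(1995, 2000), arch, seed)["tmean"].mean()
            b = generate_climate(hi, range(1995, 2000), arch, seed + 10_000)["tmean"].mean()
            diffs.append(a - b)
        assert np.mean(diffs) == pytest.approx(LAPSE_RATE * 1000, abs=0.05)

    def test_empty_years_rejected(self, demo_site):
        with pytest.raises(ValueError, match="empty"):
            generate_climate(demo_site, [], ARCHETYPES["cluster1_humid"], 0)


class TestRingWidths:
    def test_degenerate_noise_on_age_curve(self, demo_climate):
        sp = SpeciesParams(
            "PIHA", GrowthParams(300.0, 0.02, 0.0, 0.0), DEFAULT_SPECIES["PIHA"].iadf
        )
        (s,) = generate_ring_widths(demo_climate, sp, 1, 40, 0)
        expected = 300.0 * np.exp(-0.02 * np.arange(1, 41))
        np.testing.assert_allclose(s.widths, expected, rtol=1e-12)

    def test_age_trend_young_wider_than_old(self, demo_climate):
        sp = DEFAULT_SPECIES["PIHA"]
        series = generate_ring_widths(demo_climate, sp, 100, 60, 1)
        w = np.array([s.widths for s in series])
        age5, age60 = w[:, 4].mean(), w[:, 59].mean()
        assert age5 > age60
        # closed-form ratio: exp(-decay * 55) up to lognormal noise
        ratio = age60 / age5
        expected = np.exp(-sp.growth.age_decay_rate * 55)
        assert ratio == pytest.approx(expected, rel=0.25)

    def test_seed_reproducibility(self, demo_climate):
        a = generate_ring_widths(demo_climate, DEFAULT_SPECIES["PIHA"], 3, 30, 9)
        b = generate_ring_widths(demo_climate, DEFAULT_SPECIES["PIHA"], 3, 30, 9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.widths, y.widths)

    def test_n_trees_validated(self, demo_climate):
        with pytest.raises(ValueError):
            generate_ring_widths(demo_climate, DEFAULT_SPECIES["PIHA"], 0, 30, 0)


class TestIadfProbability:
    def test_all_zero_coefficients_give_half(self):
        sp = SpeciesParams(
            "PIHA", GrowthParams(300, 0.02, 0.3, 0.3),
            IadfLogit(0.0, 0.0 + 1e-12, -1e-12, 0.0, 0.0, 0.0, 0.0),
        )
        assert iadf_probability(0.0, 1, 0, 0, 0, sp) == pytest.approx(0.5)

    def test_vertex_maximizes_probability(self):
        sp = DEFAULT_SPECIES["PIHA"]
        peak = sp.iadf.peak_width
        rw = np.linspace(10, 500, 491)
        p = iadf_probability(rw, 10, 0, 0, 0, sp)
        assert abs(rw[np.argmax(p)] - peak) < 2.0

    def test_monotone_in_temperature(self):
        sp = DEFAULT_SPECIES["PIHA"]
        assert sp.iadf.b_temp > 0
        temps = np.linspace(-3, 3, 13)
        p = [iadf_probability(150, 10, t, 0, 0, sp) for t in temps]
        assert np.all(np.diff(p) > 0)

    def test_width_bin_peak_in_gymnosperm_band(self):
        """Monte-Carlo frequency by width class peaks between 100 and 300
        (1/100 mm), consistent with a concave width response."""
        sp = DEFAULT_SPECIES["PIHA"]
        rng = np.random.default_rng(0)
        bins = np.arange(25, 525, 50)
        freqs = []
        for lo in bins:
            rw = rng.uniform(lo - 25, lo + 25, 10_000)
            p = iadf_probability(rw, 15, 0, 0, 0, sp)
            freqs.append((rng.uniform(size=len(p)) < p).mean())
        peak_bin = bins[int(np.argmax(freqs))]
        assert 100 <= peak_bin <= 300

    def test_bell_shape_invalid_without_negative_quadratic(self):
        with pytest.raises(ValueError, match="bell"):
            IadfLogit(0, 0.02, 1e-5, 0, 0, 0, 0)


class TestNetwork:
    def test_bit_identical_for_same_seed(self):
        sc = default_scenario(1)
        a = generate_network(sc, 3)
        b = generate_network(sc, 3)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])
        for x, y in zip(a[2], b[2]):
            np.testing.assert_array_equal(x.widths, y.widths)
            np.testing.assert_array_equal(x.iadf_flags, y.iadf_flags)

    def test_unknown_species_rejected(self):
        site = SiteSpec("X1", "cluster1_humid", "PIHA", 43, 5, 300)
        sc = Scenario(sites=(site,), species={})
        with pytest.raises(ValueError, match="SpeciesParams"):
            generate_network(sc, 0)

    def test_flat_logit_matches_bernoulli_mean(self, demo_site):
        """With all slopes zero and b0 = logit(0.2) the marginal IADF
        proportion is 0.20 up to binomial error."""
        from scipy.special import logit

        flat = IadfLogit(float(logit(0.2)), 1e-12, -1e-15, 0.0, 0.0, 0.0, 0.0)
        sp = SpeciesParams("PIHA", GrowthParams(300, 0.02, 0.3, 0.3), flat)
        site = SiteSpec("F1", "cluster1_humid", "PIHA", 43, 5, 300, n_trees=30,
                        series_length=60, stagger=0)
        sc = Scenario(sites=(site,), species={"PIHA": sp})
        _, _, series = generate_network(sc, 11)
        flags = np.concatenate([s.iadf_flags for s in series])
        n = len(flags)
        se = np.sqrt(0.2 * 0.8 / n)
        assert flags.mean() == pytest.approx(0.2, abs=4 * se)

    def test_temperature_effect_yields_positive_correlation(self, small_network):
        """b_temp > 0 implies a positive across-year correlation between
        annual IADF frequency and mean annual temperature."""
        _, sites, clim, series = small_network
        ann = annual_summaries(clim)
        rs = []
        for sid in [s.site_id for s in sites]:
            ss = [s for s in series if s.site_id == sid]
            if ss[0].species_code not in ("PIHA", "PIPI", "PIPN", "PIAB", "PINI"):
                continue  # temperature-sensitive species only
            y0 = min(s.first_year for s in ss)
            y1 = max(s.last_year for s in ss)
            years = np.arange(y0, y1 + 1)
            freq = np.full(len(years), np.nan)
            for i, yr in enumerate(years):
                flags = [
                    s.iadf_flags[yr - s.first_year]
                    for s in ss
                    if s.first_year <= yr <= s.last_year
                ]
                flags = [f for f in flags if f >= 0]
                if flags:
                    freq[i] = np.mean(flags)
            t = ann[ann.site_id == sid].set_index("year")["temp"].reindex(years)
            ok = np.isfinite(freq) & t.notna().to_numpy()
            if ok.sum() > 20:
                rs.append(np.corrcoef(freq[ok], t[ok])[0, 1])
        assert np.mean(rs) > 0

    def test_iadf_proportion_increasing_in_temperature_effect(self):
        """Marginal IADF proportion rises monotonically with b_temp."""
        from dataclasses import replace

        base = DEFAULT_SPECIES["PIHA"]
        props = []
        for b_temp in (0.0, 1.0, 2.0):
            sp = SpeciesParams(
                "PIHA", base.growth, replace(base.iadf, b_temp=b_temp, b0=-2.0)
            )
            site = SiteSpec("T1", "cluster2_dry_warm", "PIHA", 40, -3, 400,
                            n_trees=25, stagger=0)
            sc = Scenario(sites=(site,), species={"PIHA": sp})
            _, _, series = generate_network(sc, 21)
            flags = np.concatenate([s.iadf_flags for s in series])
            props.append(flags.mean())
        # temperature anomalies are symmetric around zero, but the logistic
        # is convex below 1/2, so the marginal proportion rises with b_temp
        assert props[0] < props[1] < props[2]
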