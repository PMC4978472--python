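import numpy as np
import pytest

from antshift import climate, project


def summary_grid(values, cell=30.0):
    return climate.AltitudeGrid(values=np.asarray(values, float), cell_size=cell)


class TestClassifyTrend:
    def _result(self, props):
        decades = tuple(f"d{i}" for i in range(len(props)))
        return project.ProjectionResult(
            species_id="sp", decades=decades,
            probability={}, presence={},
            suitable_area_prop=dict(zip(decades, props)), threshold=0.5,
        )

    def test_exact_linear_decline(self):
        t = project.classify_trend(self._result([0.5, 0.4, 0.3, 0.2, 0.1]))
        assert t.label == "decreased"
        assert t.slope == pytest.approx(-0.1)
        assert t.p_value < 0.05

    def test_constant_proportions_stable(self):
        t = project.classify_trend(self._result([0.3, 0.3, 0.3, 0.3, 0.3]))
        assert t.label == "stable"
        assert t.slope == pytest.approx(0.0)

    def test_slope_matches_closed_form_ols(self, rng):
        props = rng.random(5)
        t = project.classify_trend(self._result(props))
        x = np.arange(5.0)
        slope = ((x - x.mean()) * (props - props.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert t.slope == pytest.approx(slope, rel=1e-12)

    def test_too_few_decades(self):
        with pytest.raises(ValueError):
            project.classify_trend(self._result([0.5, 0.4]))


def _projection(presences, species_id="sp"):
    decades = tuple(presences)
    return project.ProjectionResult(
        species_id=species_id, decades=decades,
        probability={d: p.astype(float) for d, p in presences.items()},
        presence={d: p.astype(bool) for d, p in presences.items()},
        suitable_area_prop={d: float(p.mean()) for d, p in presences.items()},
        threshold=0.5,
    )


class TestRichnessSurface:
    def test_single_ubiquitous_species(self):
        r = _projection({"2000s": np.ones((4, 4))})
        np.testing.assert_array_equal(project.richness_surface([r], "2000s"), 1)

    def test_bounded_by_species_count(self, rng):
        results = [_projection({"2000s": rng.random((5, 5)) > 0.5}, f"s{i}")
                   for i in range(7)]
        rich = project.richness_surface(results, "2000s")
        assert rich.max() <= 7 and rich.min() >= 0

    def test_matches_per_cell_loop(self, rng):
        grids = [rng.random((5, 5)) > 0.4 for _ in range(6)]
        results = [_projection({"2000s": g}, f"s{i}") for i, g in enumerate(grids)]
        rich = project.richness_surface(results, "2000s")
        for i in range(5):
            for j in range(5):
                assert rich[i, j] == sum(g[i, j] for g in grids)


class TestPeakAltitude:
    def test_monotone_decline_peaks_at_lowest_bin(self):
        alt = summary_grid(np.linspace(0, 1000, 100).reshape(10, 10))
        rich = 30 - 0.02 * alt.values
        assert project.peak_altitude(rich, alt) == 25.0

    def test_constructed_bell_recovered_within_one_bin(self):
        alt = summary_grid(np.linspace(0, 1400, 784).reshape(28, 28))
        rich = -((alt.values - 650.0) ** 2) / 100.0 + 30.0
        assert abs(project.peak_altitude(rich, alt) - 650.0) <= 50.0

    def test_matches_exhaustive_bin_scan(self, rng):
        alt = summary_grid(rng.uniform(0, 900, (12, 12)))
        rich = rng.random((12, 12)) * 20
        got = project.peak_altitude(rich, alt, band_width_m=100.0)
        best_mean, best_centre = -np.inf, None
        for b in range(9):
            sel = (alt.values >= b * 100) & (alt.values < (b + 1) * 100)
            if sel.any() and rich[sel].mean() > best_mean:
                best_mean, best_centre = rich[sel].mean(), b * 100 + 50.0
        assert got == best_centre


class TestUpwardRate:
    def test_printed_peaks_arithmetic(self):
        rate = project.upward_rate({"2000s": 263.0, "2080s": 656.0})
        assert rate == pytest.approx(4.9125)

    def test_equal_peaks_zero(self):
        assert project.upward_rate({"2000s": 400.0, "2080s": 400.0}) == 0.0

    def test_antisymmetric_under_reversal(self):
        fwd = project.upward_rate({"2000s": 263.0, "2080s": 656.0})
        rev = project.upward_rate({"2000s": 656.0, "2080s": 263.0})
        assert rev == pytest.approx(-fwd)

    def test_single_decade_undefined(self):
        with pytest.raises(ValueError):
            project.upward_rate({"2000s": 263.0})


class TestCurveShape:
    def test_linear_decline_is_monotonic_decrease(self):
        alt = np.linspace(25, 1375, 28)
        fit = project.curve_shape(alt, 600 - 0.4 * alt)
        assert fit.label == "monotonic-decrease"

    def test_constructed_parabola_is_bell(self):
        alt = np.linspace(0, 1400, 29)
        rich = -((alt - 650.0) ** 2) / 100.0 + 30.0
        fit = project.curve_shape(alt, rich)
        assert fit.label == "bell-shaped"
        assert fit.vertex == pytest.approx(650.0, abs=1.0)

    def test_coefficients_match_normal_equations(self, rng):
        alt = np.linspace(50, 1300, 20)
        rich = rng.random(20) * 10
        fit = project.curve_shape(alt, rich)
        design = np.column_stack([alt**2, alt, np.ones_like(alt)])
        beta = np.linalg.solve(design.T @ design, design.T @ rich)
        assert (fit.a, fit.b, fit.c) == pytest.approx(tuple(beta), rel=1e-8)

    def test_constant_richness_is_flat(self):
        alt = np.linspace(0, 1000, 15)
        fit = project.curve_shape(alt, np.full(15, 12.0))
        assert fit.label == "flat"

    def test_increasing_curve(self):
        alt = np.linspace(0, 1000, 15)
        fit = project.curve_shape(alt, 2 + 0.01 * alt)
        assert fit.label == "monotonic-increase"

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            project.curve_shape([0, 100, 200], [1, 2, 3])


@pytest.fixture(scope="module")
def fitted():
    from antshift import sdm, synth
    rng = np.random.default_rng(8)
    alt, clim = synth.generate_landscape(40, 40, base_temp=11.0,
                                         max_altitude=1200.0, seed=8)
    seasonal = synth.generate_seasonal(clim, seed=8)
    sites = synth.generate_sites(alt, band_counts=(40, 30, 20, 15, 10, 5), seed=8)
    preds = seasonal.site_predictors(sites["x"], sites["y"])
    cold = synth.SpeciesNicheSpec("cold", true_optimum=7.0, true_tolerance=1.2)
    lam = cold.expected_abundance(
        np.array([11.0 - 6.5 * a / 1000 for a in sites["altitude"]]))
    presence = (rng.poisson(lam) > 0).astype(int)
    model = sdm.fit_sdm(presence, preds, np.zeros(len(sites)), species_id="cold")
    return model, seasonal, alt


class TestProjection:

    def test_constant_climate_constant_proportions(self, fitted):
        model, seasonal, _ = fitted
        frozen = climate.WarmingScenario({"2000s": 0.0, "2020s": 0.0, "2040s": 0.0})
        res = project.project_species(model, seasonal, frozen)
        props = list(res.suitable_area_prop.values())
        assert props[0] == props[1] == props[2]

    def test_cold_adapted_species_loses_area_under_warming(self, fitted):
        model, seasonal, _ = fitted
        res = project.project_species(model, seasonal, climate.WarmingScenario())
        assert res.suitable_area_prop["2080s"] < res.suitable_area_prop["2000s"]

    def test_probabilities_in_unit_interval(self, fitted):
        model, seasonal, _ = fitted
        res = project.project_species(model, seasonal, climate.WarmingScenario())
        for p in res.probability.values():
            assert np.all((p > 0) & (p < 1))

    def test_mean_richness_conserves_suitable_area(self, fitted):
        """Mean richness over cells equals the sum of per-species
        suitable-area proportions."""
        model, seasonal, alt = fitted
        res = project.project_species(model, seasonal, climate.WarmingScenario())
        results = [res, res]  # two identical species suffice for the identity
        for d in res.decades:
            rich = project.richness_surface(results, d)
            assert rich.mean() == pytest.approx(2 * res.suitable_area_prop[d])
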