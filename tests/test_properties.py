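"""Composition-based property model, diffusivity, and film-side transport."""

import numpy as np
import pytest

from cocoadry import properties as P


class TestPureComponents:
    @pytest.mark.parametrize(
        "component, T, prop, expected, tol",
        [
            ("water", 50.0, "rho", 987.9, 0.05),  # hand evaluation of the polynomial
            ("water", 0.0, "rho", 997.18, 1e-9),  # T=0 collapses to the constant term
            ("protein", 50.0, "cp", 2.065, 5e-4),
        ],
    )
    def test_reference_values(self, component, T, prop, expected, tol):
        props = P.pure_component_props(component, T)
        assert getattr(props, prop) == pytest.approx(expected, abs=tol)

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError, match="unknown component"):
            P.pure_component_props("cellulose", 50.0)

    def test_temperature_range_enforced(self):
        with pytest.raises(ValueError, match="range"):
            P.pure_component_props("water", 150.0)


class TestMixtures:
    @pytest.mark.parametrize(
        "comp, rho, cp",
        [
            (P.TESTA_COMPOSITION, 1117.6, 2.660),
            (P.COTYLEDON_COMPOSITION, 1135.7, 3.294),
        ],
    )
    def test_printed_tissue_values_at_50C(self, comp, rho, cp):
        got = P.mixture_props(comp, 50.0)
        assert got.rho == pytest.approx(rho, rel=0.01)
        assert got.cp == pytest.approx(cp, rel=0.01)

    def test_cotyledon_conductivity_matches_print(self):
        assert P.mixture_props(P.COTYLEDON_COMPOSITION, 50.0).k == pytest.approx(
            0.544, rel=0.01
        )

    def test_pure_water_mixture_is_pure_water(self):
        comp = P.ProximateComposition(water=1.0, protein=0.0, fat=0.0, carbohydrate=0.0)
        assert P.mixture_props(comp, 50.0) == P.pure_component_props("water", 50.0)

    @pytest.mark.parametrize("comp", [P.TESTA_COMPOSITION, P.COTYLEDON_COMPOSITION])
    @pytest.mark.parametrize("T", [40.0, 55.0, 70.0])
    def test_alpha_consistent_with_own_outputs(self, comp, T):
        p = P.mixture_props(comp, T)
        assert abs(p.alpha - p.k / (p.rho * p.cp * 1e3)) < 1e-12

    def test_fraction_validation(self):
        with pytest.raises(ValueError, match="sum"):
            P.ProximateComposition(water=0.5, protein=0.2, fat=0.2, carbohydrate=0.2)
        with pytest.raises(ValueError, match="outside"):
            P.ProximateComposition(water=1.2, protein=0.0, fat=0.0, carbohydrate=0.0)


class TestPolynomialFits:
    def test_linear_mixing_makes_cp_fit_exact(self):
        # Cp mixes linearly, so the tissue Cp is itself a quadratic in T and
        # the least-squares fit must interpolate it to round-off.
        poly = P.fit_property_polynomials(P.TESTA_COMPOSITION)
        assert poly.residual_rms["cp"] < 1e-10

    @pytest.mark.parametrize("comp", [P.TESTA_COMPOSITION, P.COTYLEDON_COMPOSITION])
    def test_roundtrip_reproduces_mixture_within_1pc(self, comp):
        poly = P.fit_property_polynomials(comp)
        for T in np.arange(40.0, 70.5, 5.0):
            fitted = P.evaluate_polynomials(poly, T)
            direct = P.mixture_props(comp, T)
            for name in ("rho", "cp", "k", "alpha"):
                assert getattr(fitted, name) == pytest.approx(
                    getattr(direct, name), rel=0.01
                )

    def test_testa_density_fit_matches_published_correlation(self):
        poly = P.fit_property_polynomials(P.TESTA_COMPOSITION)
        for T in (40.0, 50.0, 70.0):
            ours = np.polyval(poly.rho, T)
            published = np.polyval(P.SHELL_CORRELATIONS.rho, T)
            assert ours == pytest.approx(published, rel=2e-3)

    def test_published_correlations_at_50C(self):
        assert P.SHELL_CORRELATIONS.evaluate(50.0).rho == pytest.approx(1117.575)
        assert P.CORE_CORRELATIONS.evaluate(50.0).cp == pytest.approx(3.2941)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            P.fit_property_polynomials(P.TESTA_COMPOSITION, [50.0, 50.0, 50.0])

    def test_evaluation_far_outside_range_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            P.SHELL_CORRELATIONS.evaluate(0.0)


class TestEffectiveDiffusivity:
    def test_reference_magnitudes(self):
        arr = P.ArrheniusDiffusivity()
        assert arr(323.15) == pytest.approx(8.6e-10, rel=0.01)
        assert arr(313.15) == pytest.approx(5.5e-10, rel=0.01)

    def test_high_temperature_limit_is_pre_exponential(self):
        # use a physically-scaled pre-exponential so the exponent can vanish
        arr = P.ArrheniusDiffusivity(Do=8.6e-10)
        assert arr(1e9) == pytest.approx(arr.Do, rel=1e-6)

    def test_strictly_increasing_over_drying_range(self):
        arr = P.ArrheniusDiffusivity()
        vals = arr(np.linspace(300.0, 350.0, 51))
        assert np.all(np.diff(vals) > 0)

    def test_inconsistent_units_raise(self):
        arr = P.ArrheniusDiffusivity(R=8314.0)  # printed-but-inconsistent value
        with pytest.raises(ValueError, match="[Uu]nits"):
            arr(323.15)


class TestFilmSide:
    def test_stagnant_limit(self):
        air = P.AirState(temperature=50.0, speed=0.0)
        assert P.sherwood_number(air.reynolds(0.0147), air.schmidt) == pytest.approx(2.0)
        h, hm = P.film_coefficients(air, 0.0147)
        assert hm == pytest.approx(2 * air.vapor_diffusivity / 0.0147)
        assert h == pytest.approx(2 * air.thermal_conductivity / 0.0147)

    def test_sherwood_hand_value(self):
        assert P.sherwood_number(800.0, 0.6) == pytest.approx(18.1, abs=0.05)

    def test_monotone_in_speed(self):
        L = 0.0147
        hs, hms = zip(
            *(P.film_coefficients(P.AirState(temperature=50.0, speed=v), L)
              for v in (0.0, 0.3, 1.0, 3.0))
        )
        assert np.all(np.diff(hs) > 0) and np.all(np.diff(hms) > 0)

    def test_far_field_concentration(self):
        air = P.AirState(temperature=50.0, speed=1.0,
                         ambient_temperature=26.0, ambient_rh=0.72)
        assert P.far_field_vapor_concentration(air) == pytest.approx(0.90, abs=0.01)

    def test_dry_and_saturated_limits(self):
        dry = P.AirState(temperature=50.0, ambient_rh=0.0)
        assert P.far_field_vapor_concentration(dry) == 0.0
        sat = P.AirState(temperature=26.0, ambient_temperature=26.0, ambient_rh=1.0)
        assert P.far_field_vapor_concentration(sat) == pytest.approx(
            P.saturation_vapor_concentration(26.0), rel=1e-12
        )

    def test_rh_validation(self):
        with pytest.raises(ValueError, match="humidity"):
            P.AirState(temperature=50.0, ambient_rh=1.2)


class TestCompositionIO:
    def test_percent_table_roundtrip(self, tmp_path):
        path = tmp_path / "composition.csv"
        path.write_text(
            "Sample,Protein(%),Fat(%),Carbohydrate(%),Fiber(%),Ash(%),Water(%)\n"
            "Testa (shell),8.89,26.0,27.98,0.0,2.23,34.9\n"
            "Cotyledon (core),4.8,0.32,28.0,0.0,2.28,64.6\n"
        )
        comps = P.read_composition_csv(path)
        assert comps["Testa (shell)"] == P.TESTA_COMPOSITION
        assert comps["Cotyledon (core)"].water == pytest.approx(0.646)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("Sample,Protein(%)\nx,10\n")
        with pytest.raises(ValueError, match="missing"):
            P.read_composition_csv(path)

    def test_property_table_columns(self):
        df = P.property_table(P.TESTA_COMPOSITION, [40.0, 50.0, 60.0])
        assert list(df.columns) == ["T_C", "rho", "cp", "k", "alpha"]
        assert len(df) == 3
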