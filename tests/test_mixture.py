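"""CA / IA / GCA predictors, predictable ranges and the applicability rule."""

import numpy as np
import pytest

import mixtox as m

from conftest import make_fit


def sham_copies(n: int, top=20.0, ec50=1.0, fractions=None) -> tuple[list, m.MixtureDefinition]:
    """n 'different' chemicals that are in fact copies of one curve."""
    fractions = fractions or [1.0 / n] * n
    fits = [make_fit(top, ec50, chemical_id=f"copy{i}") for i in range(n)]
    mix = m.MixtureDefinition(
        "sham", tuple(m.MixtureComponent(f"copy{i}", fr) for i, fr in enumerate(fractions))
    )
    return fits, mix


class TestMixtureDefinition:
    def test_fraction_sum_outside_tolerance_rejected(self):
        with pytest.raises(m.InputError):
            m.MixtureDefinition("bad", (m.MixtureComponent("a", 0.5),))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(m.InputError):
            m.MixtureDefinition(
                "dup", (m.MixtureComponent("a", 0.5), m.MixtureComponent("a", 0.5))
            )

    @pytest.mark.parametrize(
        "masses,mws,expected",
        [([0.5, 0.5], [100.0, 100.0], [0.5, 0.5]), ([0.5, 0.5], [100.0, 200.0], [2 / 3, 1 / 3])],
    )
    def test_mass_to_molar(self, masses, mws, expected):
        mix = m.MixtureDefinition(
            "mm",
            tuple(
                m.MixtureComponent(f"c{i}", ms, mw) for i, (ms, mw) in enumerate(zip(masses, mws))
            ),
        )
        molar = m.mass_to_molar(mix)
        got = [c.mass_fraction for c in molar.components]
        assert got == pytest.approx(expected)
        assert sum(got) == pytest.approx(1.0, abs=1e-15)

    def test_mass_to_molar_missing_mw_errors(self):
        mix = m.MixtureDefinition(
            "mm", (m.MixtureComponent("a", 0.5, 100.0), m.MixtureComponent("b", 0.5))
        )
        with pytest.raises(m.InputError):
            m.mass_to_molar(mix)


class TestEffectiveComponents:
    def test_only_significant_fits_retained(self, mixture1):
        fits = [
            m.truth_to_fit(t)
            for t in m.find_truths(endpoint="testosterone", context="mixture1")
            if t.chemical_id != "Mixture 1"
        ]
        eff = m.effective_components(fits, mixture1)
        assert sorted(f.chemical_id for f in eff) == [
            "BPA",
            "OMC",
            "epoxiconazole",
            "linuron",
            "prochloraz",
        ]

    def test_all_none_gives_empty_list(self):
        fits = [
            m.HillFit("a", "t", "none", float("nan"), float("nan"), False, 0.5),
            m.HillFit("b", "t", "none", float("nan"), float("nan"), False, 0.5),
        ]
        mix = m.MixtureDefinition(
            "mm", (m.MixtureComponent("a", 0.5), m.MixtureComponent("b", 0.5))
        )
        assert m.effective_components(fits, mix) == []

    def test_missing_component_errors(self, mixture1):
        with pytest.raises(m.InputError, match="butylparaben"):
            m.effective_components([make_fit(20.0, 1.0, chemical_id="BPA")], mixture1)


class TestApplicability:
    def test_opposing_directions_forbid_all_models(self):
        """Mixed stimulatory/inhibitory effective chemicals (as seen for
        estradiol in the potency-adjusted pesticide mixture) allow no model."""
        fits = [
            m.truth_to_fit(t)
            for t in m.find_truths(endpoint="estradiol", context="mixture2")
            if t.direction != "none" and t.chemical_id != "Mixture 2"
        ]
        report = m.check_applicability(fits)
        assert report.verdict == "opposing"
        assert report.models_allowed == frozenset()

    def test_all_inhibitory_allows_all_models(self, m1_testosterone_fits):
        report = m.check_applicability(m1_testosterone_fits)
        assert report.verdict == "all_inhibitory"
        assert report.models_allowed == frozenset({"CA", "IA", "GCA"})

    def test_empty_list_is_none_effective(self):
        assert m.check_applicability([], "testosterone").verdict == "none_effective"

    def test_all_predictors_refuse_opposing(self):
        fits = [make_fit(20.0, 1.0, "down"), make_fit(200.0, 1.0, "up")]
        mix = m.MixtureDefinition(
            "opp", (m.MixtureComponent("down", 0.5), m.MixtureComponent("up", 0.5))
        )
        for fn in (m.ca_predict, m.ia_predict, m.gca_predict):
            with pytest.raises(m.NotApplicableError):
                fn(fits, mix)
        with pytest.raises(m.NotApplicableError):
            m.gca_asymptote(fits, mix)

    def test_ia_refuses_stimulatory(self):
        fits = [make_fit(200.0, 1.0, "up1"), make_fit(150.0, 2.0, "up2")]
        mix = m.MixtureDefinition(
            "stim", (m.MixtureComponent("up1", 0.5), m.MixtureComponent("up2", 0.5))
        )
        with pytest.raises(m.NotApplicableError, match="probabilistic"):
            m.ia_predict(fits, mix)


class TestCAPredict:
    def test_single_component_reduces_to_inverse_hill(self):
        fit = make_fit(20.0, 1.0, "solo")
        mix = m.MixtureDefinition("solo", (m.MixtureComponent("solo", 1.0),))
        grid = np.linspace(95.0, 25.0, 30)
        curve = m.ca_predict([fit], mix, grid)
        expected = [m.inverse_hill(fit, e) for e in sorted(grid)][::-1]
        assert curve.effects[::-1] == pytest.approx(sorted(grid))
        assert np.allclose(sorted(curve.concentrations), sorted(expected), rtol=1e-10)

    def test_sham_combination_identity(self):
        """Splitting one chemical into several fractions leaves CA unchanged."""
        fits, mix = sham_copies(3, fractions=[0.2, 0.3, 0.5])
        solo = make_fit(20.0, 1.0, "solo")
        grid = np.linspace(99.0, 21.0, 50)
        curve = m.ca_predict(fits, mix, grid)
        for x, e in zip(curve.concentrations, curve.effects):
            assert x == pytest.approx(m.inverse_hill(solo, e), rel=1e-8)

    def test_matches_brute_force_root_scan(self, m1_testosterone_fits, mixture1):
        """X(80) agrees with scanning concentrations for sum p_i X / x_i = 1."""
        eff = m1_testosterone_fits
        curve = m.ca_predict(eff, mixture1, [80.0])
        x_pred = float(curve.concentrations[0])
        assert np.isfinite(x_pred)

        p = np.array([mixture1.fraction(f.chemical_id) for f in eff])
        x_single = np.array([m.inverse_hill(f, 80.0) for f in eff])
        xs = np.linspace(x_pred * 0.5, x_pred * 2, 100_000)
        total = xs[:, None] * (p / x_single)[None, :]
        idx = int(np.argmin(np.abs(total.sum(axis=1) - 1.0)))
        assert xs[idx] == pytest.approx(x_pred, rel=1e-3)

    def test_truncation_beyond_floor(self, m1_testosterone_fits, mixture1):
        """Effect levels deeper than the least-efficacious plateau are dropped."""
        curve = m.ca_predict(m1_testosterone_fits, mixture1, [80.0, 65.0, 50.0, 30.0])
        assert curve.truncated
        assert set(curve.effects) == {80.0, 65.0}

    def test_effect_floor_values(self, m1_testosterone_fits, m2_testosterone_fits):
        assert m.ca_effect_floor(m1_testosterone_fits) == 60.0
        assert m.ca_effect_floor(m2_testosterone_fits) == 44.0

    def test_single_chemical_floor_is_its_top(self):
        assert m.ca_effect_floor([make_fit(37.0, 1.0)]) == 37.0


class TestIAPredict:
    def test_bliss_product_of_two_half_effects(self):
        """Two components each at 50% of control multiply to 25%."""
        fits = [make_fit(0.0, 1.0, "a"), make_fit(0.0, 1.0, "b")]
        mix = m.MixtureDefinition(
            "bliss", (m.MixtureComponent("a", 0.5), m.MixtureComponent("b", 0.5))
        )
        # each component at p*X = 1.0 = EC50 gives 50% (tops are 0)
        curve = m.ia_predict(fits, mix, [2.0])
        assert curve.effects[0] == pytest.approx(25.0)

    def test_single_component_equals_own_curve(self):
        fit = make_fit(20.0, 1.0, "solo")
        mix = m.MixtureDefinition("solo", (m.MixtureComponent("solo", 1.0),))
        grid = np.logspace(-2, 2, 40)
        curve = m.ia_predict([fit], mix, grid)
        assert np.allclose(curve.effects, m.hill_effect(fit, grid), rtol=1e-12)

    def test_matches_per_component_product_oracle(self, m1_testosterone_fits, mixture1):
        curve = m.ia_predict(m1_testosterone_fits, mixture1, [1.0])
        prod = 100.0
        for f in m1_testosterone_fits:
            prod *= m.hill_effect(f, mixture1.fraction(f.chemical_id) * 1.0) / 100.0
        assert curve.effects[0] == pytest.approx(prod, rel=1e-12)
        assert curve.effect_floor == pytest.approx(
            100.0 * np.prod([f.top / 100 for f in m1_testosterone_fits])
        )


class TestGCAPredict:
    def test_single_component_is_hill_midpoint_at_ec50(self):
        fit = make_fit(20.0, 1.0, "solo")
        mix = m.MixtureDefinition("solo", (m.MixtureComponent("solo", 1.0),))
        curve = m.gca_predict([fit], mix, [1.0])
        assert curve.effects[0] == pytest.approx(60.0)  # (100+20)/2

    def test_sham_combination_identity(self):
        fits, mix = sham_copies(2)
        solo = make_fit(20.0, 1.0, "solo")
        grid = np.logspace(-2, 2, 50)
        curve = m.gca_predict(fits, mix, grid)
        assert np.allclose(curve.effects, m.hill_effect(solo, grid), rtol=1e-8)

    def test_equal_efficacy_reduces_to_ca(self):
        """With all plateaus equal, CA and GCA coincide (potency-weighted Hill)."""
        fits = [make_fit(20.0, 0.5, "a"), make_fit(20.0, 5.0, "b")]
        mix = m.MixtureDefinition(
            "eq", (m.MixtureComponent("a", 0.3), m.MixtureComponent("b", 0.7))
        )
        effect_grid = np.linspace(99.0, 21.0, 60)
        ca = m.ca_predict(fits, mix, effect_grid)
        gca = m.gca_predict(fits, mix, ca.concentrations)
        assert np.allclose(gca.effects, ca.effects, atol=1e-6)

    def test_extends_beyond_ca_floor_when_tops_differ(self, m1_testosterone_fits, mixture1):
        floor = m.ca_effect_floor(m1_testosterone_fits)
        asym = m.gca_asymptote(m1_testosterone_fits, mixture1)
        assert asym < floor
        deep = m.gca_predict(m1_testosterone_fits, mixture1, [1e4]).effects[0]
        assert deep < floor

    def test_high_concentration_approaches_asymptote(self, m1_testosterone_fits, mixture1):
        e30 = m.gca_predict(m1_testosterone_fits, mixture1, [30.0]).effects[0]
        asym = m.gca_asymptote(m1_testosterone_fits, mixture1)
        assert asym <= e30 <= 20.0

    def test_asymptote_is_plain_average_for_equal_fractions_and_potencies(self):
        fits = [make_fit(0.0, 1.0, "full"), make_fit(40.0, 1.0, "partial")]
        mix = m.MixtureDefinition(
            "avg", (m.MixtureComponent("full", 0.5), m.MixtureComponent("partial", 0.5))
        )
        assert m.gca_asymptote(fits, mix) == pytest.approx(20.0)

    def test_asymptote_single_component_is_top(self):
        fit = make_fit(20.0, 1.0, "solo")
        mix = m.MixtureDefinition("solo", (m.MixtureComponent("solo", 1.0),))
        assert m.gca_asymptote([fit], mix) == pytest.approx(20.0)


class TestMonotonicity:
    @pytest.mark.parametrize("model", ["CA", "IA", "GCA"])
    def test_prediction_curves_monotone_in_concentration(
        self, model, m1_testosterone_fits, mixture1
    ):
        grid = np.logspace(-3, 3, 120)
        if model == "CA":
            curve = m.ca_predict(m1_testosterone_fits, mixture1)
        elif model == "IA":
            curve = m.ia_predict(m1_testosterone_fits, mixture1, grid)
        else:
            curve = m.gca_predict(m1_testosterone_fits, mixture1, grid)
        order = np.argsort(curve.concentrations)
        assert np.all(np.diff(curve.effects[order]) <= 1e-9)

    @pytest.mark.parametrize("model", ["IA", "GCA"])
    def test_curves_never_cross_their_floor(self, model, m1_testosterone_fits, mixture1):
        grid = np.logspace(-3, 5, 150)
        fn = m.ia_predict if model == "IA" else m.gca_predict
        curve = fn(m1_testosterone_fits, mixture1, grid)
        assert np.all(curve.effects >= curve.effect_floor - 1e-9)
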