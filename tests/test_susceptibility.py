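import numpy as np
import pytest

from agreepower import (
    DistanceProfile,
    ValidationError,
    WeightScheme,
    coefficient,
    curvature_ratio,
    curvature_sign_scan,
    first_derivative,
    gamma_star,
    gamma_star_surface,
    second_derivative,
    susceptibility_report,
)

from conftest import random_profile

GAMMAS = (0.25, 0.5, 1.0, 2.0, 4.0)


def d1_fd(profile, gamma, h=1e-5):
    C = profile.n_categories
    f = lambda g: coefficient(profile, WeightScheme(g, C))
    return (f(gamma + h) - f(gamma - h)) / (2 * h)


def d2_fd(profile, gamma, h=1e-4):
    C = profile.n_categories
    f = lambda g: coefficient(profile, WeightScheme(g, C))
    return (f(gamma + h) - 2 * f(gamma) + f(gamma - h)) / (h * h)


class TestFirstDerivative:
    def test_two_rater_example(self, profile3):
        d1, comp = first_derivative(profile3, 1.0)
        assert round(d1, 3) == 0.118
        assert len(comp) == 1
        assert comp.loc[0, "ratio_gap"] == pytest.approx(0.56 / 0.42 - 0.15 / 0.23)

    def test_five_category_component_total(self, profile5):
        d1, comp = first_derivative(profile5, 1.0)
        assert round(d1, 3) == 0.163
        assert comp["d1_contribution"].sum() == pytest.approx(d1, abs=1e-15)
        # printed components carry the <=.0005-per-entry slack of the rounded profile
        np.testing.assert_allclose(
            comp["d1_contribution"],
            [0.015, 0.009, 0.009, 0.048, 0.079, 0.002],
            atol=2e-3,
        )

    def test_constant_ratio_gives_zero(self):
        e = np.array([0.3, 0.2, 0.1])
        prof = DistanceProfile.from_vectors(0.5 * e, e)
        for g in GAMMAS:
            assert first_derivative(prof, g)[0] == pytest.approx(0.0, abs=1e-16)

    def test_matches_central_finite_difference(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            prof = random_profile(rng, int(rng.integers(3, 7)))
            for g in GAMMAS:
                d1 = first_derivative(prof, g)[0]
                assert d1 == pytest.approx(d1_fd(prof, g), rel=1e-6, abs=1e-9)

    def test_component_count(self):
        rng = np.random.default_rng(3)
        for C in range(3, 8):
            prof = random_profile(rng, C)
            assert len(first_derivative(prof, 1.0)[1]) == (C - 1) * (C - 2) // 2

    def test_sign_law(self):
        """sign(D1) equals the sign of the positive-factor-stripped pair sum."""
        rng = np.random.default_rng(29)
        for _ in range(20):
            prof = random_profile(rng, int(rng.integers(3, 7)))
            C = prof.n_categories
            for g in (0.5, 1.0, 2.0):
                stat = sum(
                    np.log(m / l)
                    * l**g
                    * m**g
                    * prof.expected[l - 1]
                    * prof.expected[m - 1]
                    * (prof.ratios[l - 1] - prof.ratios[m - 1])
                    for m in range(2, C)
                    for l in range(1, m)
                )
                assert np.sign(first_derivative(prof, g)[0]) == np.sign(stat)

    def test_monotone_ratio_implies_positive_everywhere(self):
        """Strictly decreasing observed/expected ratios force D1 > 0 at any gamma."""
        rng = np.random.default_rng(31)
        for _ in range(10):
            C = int(rng.integers(3, 7))
            prof = random_profile(rng, C)
            # rebuild the observed part to make ratios strictly decreasing
            target = np.linspace(2.0, 0.1, C - 1) * prof.expected
            obs = target / target.sum() * prof.observed.sum() if prof.observed.sum() > 0 else target
            ratios = (obs / prof.expected)
            if not np.all(np.diff(ratios) < 0):
                continue
            prof2 = DistanceProfile(obs, prof.expected, 1 - obs.sum(), prof.diagonal_expected)
            for g in GAMMAS:
                assert first_derivative(prof2, g)[0] > 0
            mirrored = DistanceProfile(
                obs[::-1] / obs[::-1].sum() * obs.sum()
                if obs.sum() > 0
                else obs[::-1],
                prof.expected,
                1 - obs.sum(),
                prof.diagonal_expected,
            )
            if np.all(np.diff(mirrored.observed / mirrored.expected) > 0):
                for g in GAMMAS:
                    assert first_derivative(mirrored, g)[0] < 0

    def test_susceptibility_vanishes_at_large_gamma(self):
        # decay rate is governed by ((C-2)/(C-1))**gamma, so the probe gamma
        # grows with the number of categories
        rng = np.random.default_rng(37)
        for _ in range(10):
            C = int(rng.integers(3, 7))
            prof = random_profile(rng, C)
            gamma = 50.0 if C <= 4 else 150.0
            assert abs(first_derivative(prof, gamma)[0]) < 1e-6


class TestSecondDerivative:
    def test_two_rater_example_ratio(self, profile3):
        d1, _ = first_derivative(profile3, 1.0)
        d2, _ = second_derivative(profile3, 1.0)
        assert round(d2 / d1, 3) == -0.032

    def test_matches_central_finite_difference(self):
        rng = np.random.default_rng(19)
        for _ in range(15):
            prof = random_profile(rng, int(rng.integers(3, 7)))
            for g in GAMMAS:
                d2 = second_derivative(prof, g)[0]
                assert d2 == pytest.approx(d2_fd(prof, g), rel=1e-5, abs=1e-6)

    def test_three_category_multiplier_identity(self):
        """For C=3, D2 = ln(2)(E1 - 2^g E2)/(E1 + 2^g E2) * D1 exactly."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            prof = random_profile(rng, 3)
            e1, e2 = prof.expected
            for g in GAMMAS:
                d1, _ = first_derivative(prof, g)
                d2, _ = second_derivative(prof, g)
                mult = np.log(2.0) * (e1 - 2**g * e2) / (e1 + 2**g * e2)
                assert d2 == pytest.approx(mult * d1, abs=1e-14)

    def test_component_sums_reproduce_totals(self, profile5):
        d2, comp = second_derivative(profile5, 1.0)
        assert comp["d2_contribution"].sum() == pytest.approx(d2, abs=1e-15)
        np.testing.assert_allclose(
            comp["d2_contribution"], comp["d1_contribution"] * comp["multiplier"]
        )


class TestCurvatureRatio:
    def test_five_category_example(self, profile5):
        assert curvature_ratio(profile5, 1.0) == pytest.approx(-0.234, abs=0.002)

    def test_undefined_when_flat(self):
        e = np.array([0.4, 0.2])
        prof = DistanceProfile.from_vectors(0.5 * e, e)
        assert curvature_ratio(prof, 1.0) is None


class TestGammaStar:
    def test_two_rater_example(self, profile3):
        assert round(gamma_star(profile3), 3) == 0.869

    def test_equal_chance_peak_at_linear_weights(self):
        prof = DistanceProfile.from_vectors([0.3, 0.1], [4 / 9, 2 / 9])
        assert gamma_star(prof) == pytest.approx(1.0, abs=1e-15)

    def test_equal_profiles_give_zero(self):
        prof = DistanceProfile.from_vectors([0.2, 0.1], [0.3, 0.3])
        assert gamma_star(prof) == 0.0

    def test_only_three_categories(self, profile5):
        with pytest.raises(ValidationError, match="three categories"):
            gamma_star(profile5)

    def test_peak_location_maximizes_susceptibility(self):
        """|D1| on a gamma grid peaks at gamma* (when gamma* is interior)."""
        rng = np.random.default_rng(41)
        hits = 0
        while hits < 8:
            prof = random_profile(rng, 3)
            gs = gamma_star(prof)
            if not (0.3 < gs < 5.0) or abs(prof.ratios[0] - prof.ratios[1]) < 1e-3:
                continue
            hits += 1
            grid = np.linspace(gs - 0.5, gs + 0.5, 101)
            vals = [abs(first_derivative(prof, g)[0]) for g in grid]
            assert abs(grid[int(np.argmax(vals))] - gs) < 0.02


class TestGammaStarSurface:
    def test_uniform_anchor(self):
        df = gamma_star_surface(3)  # grid contains p1 = p2 = 1/3
        row = df[(np.isclose(df.p1, 1 / 3)) & (np.isclose(df.p2, 1 / 3))]
        assert row["gamma_star"].iloc[0] == pytest.approx(1.0)

    def test_unimodal_middle_category_pushes_peak_up(self):
        # symmetric p1 = p3 = .05, dominant middle category
        p1, p2 = 0.05, 0.9
        p3 = 1 - p1 - p2
        e1 = 2 * (p1 * p2 + p2 * p3)
        e2 = 2 * p1 * p3
        assert np.log(e1 / e2) / np.log(2) > 2.0

    def test_bimodal_marginals_give_negative_peak(self):
        p1, p2 = 0.49, 0.02
        p3 = 1 - p1 - p2
        e1 = 2 * (p1 * p2 + p2 * p3)
        e2 = 2 * p1 * p3
        assert np.log(e1 / e2) / np.log(2) < 0.0

    def test_boundary_excluded(self):
        df = gamma_star_surface(10)
        assert np.all(df.p1 > 0) and np.all(df.p2 > 0)
        assert np.all(df.p1 + df.p2 < 1)
        assert np.isfinite(df.gamma_star).all()


class TestReport:
    def test_two_rater_example_report(self, profile3):
        rep = susceptibility_report(profile3, 1.0)
        assert round(rep.coefficient, 3) == 0.023
        assert round(rep.d1, 3) == 0.118
        assert round(rep.curvature_ratio, 3) == -0.032
        assert round(rep.gamma_star, 3) == 0.869
        assert round(rep.d1_at_gamma_star, 3) == 0.118

    def test_no_peak_reported_beyond_three_categories(self, profile5):
        rep = susceptibility_report(profile5, 1.0)
        assert rep.gamma_star is None and rep.d1_at_gamma_star is None

    def test_curvature_scan_brackets_d1_extremum(self, profile5):
        scan = curvature_sign_scan(profile5, np.linspace(0, 6, 121))
        changes = scan[scan.sign_change]
        # a D2 sign change brackets a local extremum of D1
        for g in changes.gamma:
            i = scan.index[scan.gamma == g][0]
            window = scan.d1.iloc[max(0, i - 2) : i + 3]
            assert window.abs().max() >= scan.d1.iloc[max(0, i - 2)].__abs__() - 1e-12
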