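"""Polyampholyte screening theory: nu*, the quintic, Rg->Rh, nu fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idpcollapse import polytheory as pt
from idpcollapse.solution import SolutionConditions

CHAIN = pt.PolymerChainSpec(N=506, b=3.8, f=65 / 506, g=212 / 506, nu=2.42)


def bisect_alpha(rhs: float, lo=1e-6, hi=50.0, iters=200) -> float:
    """Independent bisection oracle for alpha^5 - alpha^3 = rhs (rhs >= 0)."""
    f = lambda a: a**5 - a**3 - rhs
    lo = 1.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestEffectiveExcludedVolume:
    def test_direct_evaluation_example(self):
        """AGARP-like fractions at lambda_D = 9.6 A, l_B = 7.14 A: the
        screening correction evaluates to ~ +4.3 (recomputed term by term)."""
        chain = pt.PolymerChainSpec(N=506, b=3.8, f=65 / 506, g=212 / 506, nu=0.0)
        nu_star, rep, att = pt.effective_excluded_volume(chain, 9.6, 7.14)
        pref = math.pi * 7.14**3 / 3.8**3
        x = 9.6 / 7.14
        expected = pref * (4 * (chain.f - chain.g) ** 2 * x**2
                           - (chain.f + chain.g) ** 2 * x)
        assert nu_star == pytest.approx(expected, rel=1e-12)
        assert nu_star == pytest.approx(4.32, abs=0.02)
        assert rep > 0 > att

    def test_neutral_polyampholyte_always_attractive(self):
        chain = pt.PolymerChainSpec(N=100, b=3.8, f=0.3, g=0.3, nu=1.0)
        for lD in (1.0, 10.0, 100.0):
            nu_star, rep, _ = pt.effective_excluded_volume(chain, lD, 7.14)
            assert nu_star < chain.nu
            assert rep == 0.0

    def test_perfect_screening_limit(self):
        nu_star, _, _ = pt.effective_excluded_volume(CHAIN, 1e-9, 7.14)
        assert nu_star == pytest.approx(CHAIN.nu, abs=1e-8)


class TestSolveAlpha:
    def test_ideal_chain(self):
        assert pt.solve_alpha(0.0, 506) == pytest.approx(1.0)

    def test_swollen_example_against_bisection(self):
        rhs = math.sqrt(6 * 506 / math.pi**3) * 4.39
        oracle = bisect_alpha(rhs)
        a = pt.solve_alpha(4.39, 506)
        assert a == pytest.approx(oracle, abs=1e-8)
        assert a == pytest.approx(2.22, abs=0.01)

    @given(st.floats(0.01, 50.0), st.integers(10, 2000))
    @settings(max_examples=100, deadline=None)
    def test_matches_bisection_oracle(self, nu_star, N):
        rhs = math.sqrt(6 * N / math.pi**3) * nu_star
        assert pt.solve_alpha(nu_star, N) == pytest.approx(
            bisect_alpha(rhs), abs=1e-8
        )

    @given(st.floats(0.0, 60.0), st.integers(5, 5000))
    @settings(max_examples=100, deadline=None)
    def test_quintic_residual_below_tolerance(self, nu_star, N):
        a = pt.solve_alpha(nu_star, N)
        rhs = math.sqrt(6 * N / math.pi**3) * nu_star
        assert abs(a**5 - a**3 - rhs) < 1e-9 * max(1.0, abs(rhs))

    def test_collapsed_branch_below_one(self):
        a = pt.solve_alpha(-0.01, 50)
        assert 0 < a < 1
        rhs = math.sqrt(6 * 50 / math.pi**3) * -0.01
        assert abs(a**5 - a**3 - rhs) < 1e-9

    def test_too_negative_nu_star_reports_breakdown(self):
        # the quintic has no solution below the minimum of a^5 - a^3
        with pytest.raises(ValueError, match="breaks down"):
            pt.solve_alpha(-5.0, 506)

    def test_approx_requires_positive_nu_star(self):
        with pytest.raises(ValueError):
            pt.solve_alpha(-1.0, 100, method="approx")

    def test_approximation_gap_small_and_shrinking(self):
        """Dropping the alpha^3 term costs a few percent in the swollen
        regime (about 5-6% at alpha ~ 2) and the gap shrinks as alpha grows."""
        scan = pt.alpha_approximation_gap(np.geomspace(2.0, 100.0, 25), 506)
        alphas = np.array([s[1] for s in scan])
        gaps = np.array([s[3] for s in scan])
        in_range = (alphas >= 2.0) & (alphas <= 5.0)
        assert gaps[in_range].max() <= 0.06
        assert np.all(np.diff(gaps) < 0)


class TestRgAndNygaard:
    def test_rg_examples(self):
        assert pt.rg_hj(1.0, CHAIN) == pytest.approx(34.90, abs=0.01)
        assert pt.rg_hj(2.22, CHAIN) == pytest.approx(77.47, abs=0.05)

    def test_rg_linear_in_alpha(self):
        assert pt.rg_hj(2.0, CHAIN) == pytest.approx(2 * pt.rg_hj(1.0, CHAIN))

    def test_nygaard_example(self):
        assert pt.rg_to_rh_nygaard(70.0, 506) == pytest.approx(65.8, abs=0.2)

    def test_nygaard_fixed_point_at_a2_n033(self):
        c = pt.NYGAARD_DEFAULT
        rg = c.a2 * 506**0.33
        assert pt.rg_to_rh_nygaard(rg, 506) == pytest.approx(rg / c.a3)

    def test_rh_decreasing_in_a1_when_extended(self):
        rh1 = pt.rg_to_rh_nygaard(70.0, 506, pt.NygaardCoefficients(a1=0.216))
        rh2 = pt.rg_to_rh_nygaard(70.0, 506, pt.NygaardCoefficients(a1=0.3))
        assert rh2 < rh1


class TestPredictRhVsI:
    @staticmethod
    def conds(I_values):
        return [SolutionConditions(temperature=298.15, ionic_strength=i)
                for i in I_values]

    def test_rh_monotone_decreasing_in_I_in_screening_dominated_regime(self):
        """Below ~0.5 M the net-charge repulsion term dominates and Rh falls
        monotonically with ionic strength.  (At multi-molar I the residual
        polyampholyte attraction is itself screened away and the chain
        re-expands slightly toward the bare-nu size, so monotonicity is a
        statement about the experimentally relevant regime only.)"""
        states = pt.predict_rh_vs_I(CHAIN, self.conds(np.geomspace(0.005, 0.5, 12)))
        rh = [s.Rh for s in states]
        assert all(a > b for a, b in zip(rh, rh[1:]))

    def test_high_salt_limit_approaches_bare_nu(self):
        alpha_bare = pt.solve_alpha(CHAIN.nu, CHAIN.N)
        rh_bare = pt.rg_to_rh_nygaard(pt.rg_hj(alpha_bare, CHAIN), CHAIN.N)
        # at 5 M the screening correction to nu* is still a few percent of Rh
        assert pt.expansion_state(CHAIN, self.conds([5.0])[0]).Rh == \
            pytest.approx(rh_bare, rel=0.10)
        # the true lambda_D -> 0 limit converges to the bare-nu radius
        assert pt.expansion_state(CHAIN, self.conds([500.0])[0]).Rh == \
            pytest.approx(rh_bare, rel=0.01)

    def test_longer_chain_larger_at_every_I(self):
        short = pt.PolymerChainSpec(N=253, b=3.8, f=CHAIN.f, g=CHAIN.g, nu=2.42)
        conds = self.conds(np.geomspace(0.005, 2, 8))
        rh_long = [s.Rh for s in pt.predict_rh_vs_I(CHAIN, conds)]
        rh_short = [s.Rh for s in pt.predict_rh_vs_I(short, conds)]
        assert all(a > b for a, b in zip(rh_long, rh_short))

    def test_length_unit_rescaling_invariance(self):
        """Expansion factor and nu* are dimensionless: rescaling b, l_B and
        lambda_D together leaves alpha unchanged and scales Rg linearly."""
        chain = pt.PolymerChainSpec(N=200, b=3.8, f=0.1, g=0.4, nu=2.0)
        scaled = pt.PolymerChainSpec(N=200, b=7.6, f=0.1, g=0.4, nu=2.0)
        ns1, _, _ = pt.effective_excluded_volume(chain, 9.6, 7.14)
        ns2, _, _ = pt.effective_excluded_volume(scaled, 19.2, 14.28)
        assert ns1 == pytest.approx(ns2, rel=1e-12)
        a1, a2 = pt.solve_alpha(ns1, 200), pt.solve_alpha(ns2, 200)
        assert pt.rg_hj(a2, scaled) == pytest.approx(2 * pt.rg_hj(a1, chain))


class TestFitNu:
    @staticmethod
    def synthetic_curve(nu_true, sigma, seed, n=12):
        chain = pt.PolymerChainSpec(N=506, b=3.8, f=65 / 506, g=212 / 506,
                                    nu=nu_true)
        I = np.geomspace(0.005, 2.0, n)
        conds = [SolutionConditions(temperature=298.15, ionic_strength=i)
                 for i in I]
        rh = np.array([pt.expansion_state(chain, c).Rh for c in conds])
        rng = np.random.default_rng(seed)
        noisy = rh + sigma * rng.standard_normal(n) if sigma else rh
        return I, noisy

    def test_recovers_truth_within_two_stderr(self):
        I, rh = self.synthetic_curve(2.5, 2.0, seed=11)
        fit = pt.fit_nu(I, rh, np.full(I.size, 2.0), CHAIN)
        assert abs(fit.nu - 2.5) < 2 * fit.nu_stderr

    def test_noiseless_self_consistency(self):
        I, rh = self.synthetic_curve(2.42, 0.0, seed=0)
        fit = pt.fit_nu(I, rh, None, CHAIN)
        assert fit.nu == pytest.approx(2.42, abs=1e-6)

    def test_degenerate_span_rejected(self):
        with pytest.raises(ValueError, match="decade"):
            pt.fit_nu([0.1, 0.12, 0.15], [70, 69, 68], None, CHAIN)
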