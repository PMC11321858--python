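"""Closed-form maps: derived coefficients, variants, fixed points, curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hassellcomins import (
    CommunityParams, ConstrainedSpec, HassellParams, PopulationState,
    SpeciesParams, ValidationError, a_from_fixed_point, constrained_params,
    derive_coefficients, expected_next_generation, fixed_point, hassell_map,
    hassell_comins_map, reproduction_curve, single_species_expectation,
)

# high-precision sympy oracle: (1 - e^{-2/10}) / (1 - e^{-1/10})
B12_U1_1_U2_2_R10 = 1.9048374180359595732


def make_community(u1, u2, Rbar, s1=1, s2=1, lam1=2.0, lam2=2.0,
                   alpha1=1.0, alpha2=1.0):
    return CommunityParams(SpeciesParams(u1, s1, lam1, alpha1),
                           SpeciesParams(u2, s2, lam2, alpha2), Rbar)


class TestDerivedCoefficients:
    def test_symmetric_species_give_unit_coefficients(self):
        co = derive_coefficients(make_community(1.0, 1.0, 10.0))
        assert co.b12 == pytest.approx(1.0, abs=1e-15)
        assert co.b21 == pytest.approx(1.0, abs=1e-15)

    def test_reference_value_against_high_precision_oracle(self):
        co = derive_coefficients(make_community(1.0, 2.0, 10.0))
        assert co.b12 == pytest.approx(B12_U1_1_U2_2_R10, rel=1e-14)

    @settings(derandomize=True, max_examples=60)
    @given(u1=st.floats(1e-6, 10.0), u2=st.floats(1e-6, 10.0),
           a1=st.floats(0.01, 100.0), a2=st.floats(0.01, 100.0),
           R=st.floats(0.1, 1e4))
    def test_reciprocity_and_coefficient_identities(self, u1, u2, a1, a2, R):
        """b12*b21 = 1, a_i*Mbar_i_max = 1 and the c12 factorisation hold for
        any positive parameters."""
        co = derive_coefficients(make_community(u1, u2, R, alpha1=a1, alpha2=a2))
        assert co.b12 * co.b21 == pytest.approx(1.0, rel=1e-12)
        assert co.a1 * co.Mbar1max == pytest.approx(1.0, rel=1e-12)
        assert co.a2 * co.Mbar2max == pytest.approx(1.0, rel=1e-12)
        assert co.b12 == pytest.approx(co.Mbar1max / co.Mbar2max * co.c12,
                                       rel=1e-12)

    def test_numerically_stable_for_tiny_unit_sizes(self):
        # for u << Rbar the coefficient tends to (u2/u1)(alpha2/alpha1)
        co = derive_coefficients(make_community(1e-12, 3e-12, 1.0, alpha2=2.0))
        assert np.isfinite(co.b12)
        assert co.b12 == pytest.approx(6.0, rel=1e-9)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValidationError):
            SpeciesParams(u=-1.0, s=1, lam=2.0)
        with pytest.raises(ValidationError):
            SpeciesParams(u=1.0, s=0, lam=2.0)
        with pytest.raises(ValidationError):
            make_community(1.0, 1.0, Rbar=-5.0)


class TestHassellMap:
    def test_extinction_is_absorbing(self):
        assert hassell_map(0.0, HassellParams(1.5, 0.05, 1.0)) == 0.0

    def test_fixed_point_value(self):
        # a = (lam^{1/theta}-1)/X* places the equilibrium at X* = 10
        assert hassell_map(10.0, HassellParams(1.5, 0.05, 1.0)) == pytest.approx(10.0)

    def test_output_decreasing_in_theta(self):
        vals = [hassell_map(10.0, HassellParams(1.5, 0.05, th))
                for th in (1, 2, 4, 8, 64)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_negative_population_rejected(self):
        with pytest.raises(ValidationError):
            hassell_map(-1.0, HassellParams(1.5, 0.05, 1.0))


class TestHassellCominsMap:
    def test_joint_extinction_absorbing(self):
        hp = HassellParams(1.5, 0.05, 1.0)
        out = hassell_comins_map(PopulationState(0, 0), hp, hp, 1.0, 1.0)
        assert (out.N1, out.N2) == (0.0, 0.0)

    def test_zero_coupling_decouples_into_hassell_maps(self):
        hp1, hp2 = HassellParams(1.5, 0.05, 1.0), HassellParams(2.0, 0.1, 3.0)
        out = hassell_comins_map(PopulationState(7, 4), hp1, hp2, 0.0, 0.0)
        assert out.N1 == pytest.approx(hassell_map(7.0, hp1))
        assert out.N2 == pytest.approx(hassell_map(4.0, hp2))

    def test_symmetric_example_by_hand_arithmetic(self):
        hp = HassellParams(1.5, 0.05, 1.0)
        out = hassell_comins_map(PopulationState(10, 10), hp, hp, 1.0, 1.0)
        assert out.N1 == pytest.approx(7.5)   # 1.5*10 / (1 + 0.05*20)
        assert out.N2 == pytest.approx(7.5)


class TestExpectedNextGeneration:
    def test_single_species_reduction_at_zero_competitor(self, community):
        for n1 in (1.0, 4.0, 12.5):
            f = expected_next_generation(community, PopulationState(n1, 0),
                                         "general")
            assert f.N1 == pytest.approx(
                single_species_expectation(n1, community.sp1, community.Rbar))
            assert f.N2 == 0.0

    def test_reference_state_against_enumeration_frozen_value(self):
        # frozen from the truncated-enumeration oracle (sympy-checked closed
        # value 3.4961372693883130)
        p = make_community(1.0, 2.0, 10.0, s1=1, s2=1)
        f = expected_next_generation(p, PopulationState(3, 2), "general")
        assert f.N1 == pytest.approx(3.4961372693883130, rel=1e-12)

    @pytest.mark.parametrize("n1", [0.0, 2.0, 7.0])
    @pytest.mark.parametrize("n2", [0.0, 3.0, 9.0])
    def test_equal_unit_variant_is_exact_reduction(self, n1, n2):
        p = make_community(1.5, 1.5, 12.0, s1=2, s2=3, alpha2=2.0)
        g = expected_next_generation(p, PopulationState(n1, n2), "general")
        e = expected_next_generation(p, PopulationState(n1, n2), "equal_unit")
        assert g.N1 == e.N1 and g.N2 == e.N2  # bitwise: same closed form

    def test_equal_unit_variant_requires_equal_units(self, community):
        with pytest.raises(ValidationError):
            expected_next_generation(community, PopulationState(1, 1),
                                     "equal_unit")

    def test_small_unit_variant_first_order_accurate(self):
        # relative error O(u/Rbar): at u/Rbar = 1e-3 agreement within 1e-2
        p = make_community(1e-3, 2e-3, 1.0, s1=2, s2=1)
        for n1, n2 in [(50.0, 30.0), (200.0, 100.0)]:
            g = expected_next_generation(p, PopulationState(n1, n2), "general")
            s = expected_next_generation(p, PopulationState(n1, n2), "small_unit")
            assert s.N1 == pytest.approx(g.N1, rel=1e-2)
            assert s.N2 == pytest.approx(g.N2, rel=1e-2)

    def test_strictly_decreasing_in_competitor_density(self, community):
        vals = [expected_next_generation(community, PopulationState(5, n2),
                                         "general").N1
                for n2 in (0, 1, 2, 5, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_reproduction_probability_decreasing_in_own_density(self, community):
        lam1 = community.sp1.lam
        g = [expected_next_generation(community, PopulationState(n1, 3),
                                      "general").N1 / (lam1 * n1)
             for n1 in (1, 2, 5, 10, 50)]
        assert all(a > b for a, b in zip(g, g[1:]))

    def test_unknown_variant_rejected(self, community):
        with pytest.raises(ValidationError):
            expected_next_generation(community, PopulationState(1, 1), "bogus")

    def test_taylor_regime_insensitive_to_inequality_level(self, community):
        """Near zero density the constrained maps for s1 = 1, 2, 5 and the
        scramble limit all agree to first order."""
        k1 = 10.0
        c = 0.01  # (N1 + b12 N2)/k1
        n1 = c * k1
        probs = []
        for s1 in (1, 2, 5):
            cp = constrained_params(ConstrainedSpec(s1, k1, 1.0), 10.0,
                                    community.sp2, 1.0)
            f = expected_next_generation(cp, PopulationState(n1, 0), "general")
            probs.append(f.N1 / (cp.sp1.lam * n1))
        probs.append(math.exp(-c))  # s1 -> infinity limit
        for a in probs:
            for b in probs:
                assert a == pytest.approx(b, rel=1e-3)

    def test_scramble_contest_matches_large_s_general_map(self, community):
        """The mixed-limit variant is the s1 -> inf limit of the general map
        at fixed w1 = u1 s1 and fixed b12."""
        from dataclasses import replace

        sc = expected_next_generation(community, PopulationState(6, 4),
                                      "scramble_contest")
        R = community.Rbar
        g2 = -math.expm1(-community.sp2.u / R)
        b12_limit = g2 * R / community.sp1.u  # alpha ratio 1
        # approach the limit with a large-s1 community holding w1 and b12:
        # alpha2 adjusted so the general-map b12 equals the limit's b12
        s1 = 4000
        u1 = community.sp1.w / s1
        g1 = -math.expm1(-u1 / R)
        big = CommunityParams(
            SpeciesParams(u1, s1, community.sp1.lam, alpha=1.0),
            replace(community.sp2, alpha=b12_limit * g1 / g2), R)
        lim = expected_next_generation(big, PopulationState(6, 4), "general")
        assert lim.N1 == pytest.approx(sc.N1, rel=1e-3)

    def test_double_scramble_reduces_to_ricker_components(self, community):
        f = expected_next_generation(community, PopulationState(6, 0),
                                     "double_scramble")
        w1, R = community.sp1.w, community.Rbar
        assert f.N1 == pytest.approx(
            community.sp1.lam * 6 * math.exp(-w1 / R * 6))


class TestConstrainedParams:
    def test_round_trip_interspecific_coefficient(self, community):
        spec = ConstrainedSpec(s1=3, k1=10.0, b12=1.7)
        cp = constrained_params(spec, 10.0, community.sp2, alpha1=1.0)
        assert derive_coefficients(cp).b12 == pytest.approx(spec.b12, rel=1e-12)

    def test_constraint_inversion_is_exact(self, community):
        for s1, k1 in [(1, 10.0), (5, 2.5), (50, 100.0)]:
            cp = constrained_params(ConstrainedSpec(s1, k1, 1.0), 10.0,
                                    community.sp2, 1.0)
            a1 = math.expm1(cp.sp1.u / cp.Rbar)
            assert s1 * a1 == pytest.approx(1.0 / k1, rel=1e-14)

    def test_contest_curve_saturates_at_k1(self, community):
        # s1 = 1: f1/lam1 -> k1 as N1 -> infinity (no competitor)
        cp = constrained_params(ConstrainedSpec(1, 10.0, 1.0), 10.0,
                                community.sp2, 1.0)
        f = expected_next_generation(cp, PopulationState(1e8, 0), "general")
        assert f.N1 / cp.sp1.lam == pytest.approx(10.0, abs=1e-5)


class TestFixedPoint:
    def test_hand_solved_contest_case(self):
        assert a_from_fixed_point(1.5, 1.0, 10.0) == pytest.approx(0.05)

    @pytest.mark.parametrize("theta", [1.0, 2.0, 4.0, 8.0, 0.37])
    def test_round_trip_recovers_equilibrium(self, theta):
        a = a_from_fixed_point(1.5, theta, 10.0)
        assert fixed_point(HassellParams(1.5, a, theta)) == pytest.approx(
            10.0, rel=1e-12)

    def test_equilibrium_vanishes_as_growth_rate_tends_to_one(self):
        xs = [fixed_point(HassellParams(lam, 0.05, 2.0))
              for lam in (1.5, 1.1, 1.01, 1.0001)]
        assert all(a > b for a, b in zip(xs, xs[1:]))
        assert xs[-1] < 1e-2

    def test_no_positive_fixed_point_below_replacement(self):
        with pytest.raises(ValidationError):
            fixed_point(HassellParams(1.0, 0.05, 1.0))


class TestReproductionCurve:
    def test_contest_curve_monotone_nondecreasing(self, community):
        cp = constrained_params(ConstrainedSpec(1, 10.0, 1.0), 10.0,
                                community.sp2, 1.0)
        res = reproduction_curve(cp, "general", np.linspace(0, 100, 201))
        f = res.table["f1"].to_numpy()
        assert np.all(np.diff(f) >= 0)
        assert res.peak is None or res.peak.N1_at_max >= 99  # no interior peak

    def test_scramble_peak_at_expected_reproducer_capacity(self, community):
        # w1/Rbar = 1/k1 puts the Ricker peak exactly at N1 = k1
        p = CommunityParams(SpeciesParams(u=0.01, s=10, lam=2.0),
                            community.sp2, Rbar=1.0)  # w1/Rbar = 0.1
        res = reproduction_curve(p, "double_scramble",
                                 np.linspace(0, 30, 61), refine_peak=True)
        assert res.peak is not None
        assert res.peak.N1_at_max == pytest.approx(10.0, abs=1e-6)

    def test_peaks_shrink_and_shift_left_as_inequality_falls(self, community):
        """Raising s1 (lower within-species inequality) makes the curve more
        overcompensating: interior peaks move to smaller N1 and lower f1."""
        locs, highs = [], []
        for s1 in (2, 5, 20):
            cp = constrained_params(ConstrainedSpec(s1, 10.0, 1.0), 10.0,
                                    community.sp2, 1.0)
            res = reproduction_curve(cp, "general", np.linspace(0, 60, 241),
                                     refine_peak=True)
            assert res.peak is not None
            locs.append(res.peak.N1_at_max)
            highs.append(res.peak.f1_max)
        assert locs[0] > locs[1] > locs[2]
        assert highs[0] > highs[1] > highs[2]

    def test_normalized_output_divides_by_fecundity(self, community):
        res = reproduction_curve(community, "general", [3.0], N2=2.0,
                                 normalize=True)
        f = expected_next_generation(community, PopulationState(3, 2),
                                     "general").N1
        assert res.table["f1_over_lam1"].iloc[0] == pytest.approx(
            f / community.sp1.lam)

    def test_empty_sweep_rejected(self, community):
        with pytest.raises(ValidationError):
            reproduction_curve(community, "general", [])
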