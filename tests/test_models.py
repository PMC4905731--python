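"""Closed forms, derived-parameter algebra and the two-point estimators."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from salclear.models import (
    DerivedParams,
    EnzymeParams,
    EnzymeState,
    FirstOrderParams,
    HofmeyrParams,
    MMParams,
    derive_mm_from_enzyme,
    derive_rates_from_affinities,
    enzyme_rhs,
    equilibrium_ratio,
    estimate_rate_log_slope,
    estimate_vmax_two_point,
    first_order_solution,
    half_life_from_k,
    hofmeyr_flux,
    mm_rate,
    occupancy_fraction,
    round_sig,
)

positive = st.floats(min_value=1e-3, max_value=1e3)


class TestFirstOrder:
    def test_identity_at_t0(self):
        p = FirstOrderParams(S0=337.5, k=0.026)
        assert first_order_solution(p, 0.0) == 337.5

    def test_half_at_half_life(self):
        p = FirstOrderParams(S0=71.8, k=0.156)
        assert first_order_solution(p, math.log(2) / p.k) == pytest.approx(71.8 / 2)

    def test_scalar_evaluation_matches_exponential(self):
        # frozen from an independent high-precision evaluation of S0*exp(-k t)
        p = FirstOrderParams(S0=4.61, k=0.332)
        assert first_order_solution(p, 6.0) == pytest.approx(0.6289068389732787, rel=1e-12)

    def test_monotone_non_increasing(self):
        p = FirstOrderParams(S0=10.0, k=0.3)
        s = first_order_solution(p, np.linspace(0, 20, 50))
        assert np.all(np.diff(s) <= 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            first_order_solution(FirstOrderParams(S0=1.0, k=1.0), -0.1)

    @pytest.mark.parametrize(
        "k, minutes",
        [(0.156, 267), (0.026, 1600), (math.log(2), 60)],
    )
    def test_half_life_minutes(self, k, minutes):
        assert round(half_life_from_k(k)) == minutes

    def test_half_life_requires_positive_rate(self):
        with pytest.raises(ValueError):
            half_life_from_k(0.0)


class TestMMRate:
    def test_half_maximal_at_km(self):
        p = MMParams(Vmax=7.85, Km=18.2, S0=100.0)
        assert mm_rate(18.2, p) == pytest.approx(-3.925)
        assert round_sig(abs(mm_rate(18.2, p)), 2) == 3.9

    def test_zero_at_zero(self):
        assert mm_rate(0.0, MMParams(Vmax=7.85, Km=18.2, S0=1.0)) == 0.0

    def test_saturates_at_vmax(self):
        p = MMParams(Vmax=7.85, Km=18.2, S0=1.0)
        assert mm_rate(1e6 * p.Km, p) == pytest.approx(-p.Vmax, rel=1e-4)
        assert abs(mm_rate(1e3, p)) < p.Vmax


class TestEnzymeRHS:
    def test_initial_binding_flux(self):
        # only the kon1*S*E term is active when SE = P = 0
        p = EnzymeParams(kon1=3.0, koff1=31.32, koff2=14.82, ETOT=1.5e-4, S0=5.0)
        dS, dSE, dP = enzyme_rhs(EnzymeState(S=5.0, SE=0.0, P=0.0), p)
        assert dS == pytest.approx(-10800.0 * 5.0 * 1.5e-4)  # -8.1 mg/(L*h)
        assert dS == pytest.approx(-8.1)
        assert dSE == pytest.approx(-dS)
        assert dP == 0.0

    def test_mass_conservation_with_g_zero(self):
        p = EnzymeParams(
            kon1=3.0, koff1=31.32, koff2=14.82, kon2=0.054, ETOT=1.5e-4, S0=5.0
        )
        state = EnzymeState(S=2.3, SE=1.1e-4, P=1.7)
        assert sum(enzyme_rhs(state, p)) == pytest.approx(0.0, abs=1e-9)

    def test_strict_mode_leaks_mass_through_product_rebinding(self):
        p = EnzymeParams(
            kon1=3.0, koff1=31.32, koff2=14.82, kon2=0.054, ETOT=1.5e-4, S0=5.0
        )
        state = EnzymeState(S=2.3, SE=1.1e-4, P=1.7)
        leak = sum(enzyme_rhs(state, p, strict_mass_balance=True))
        a2 = p.kon2 * 3600.0
        assert leak == pytest.approx(-a2 * state.P * state.free_enzyme(p.ETOT))
        assert leak < 0

    def test_equilibrium_state_is_stationary(self):
        # construct (S, SE, P) satisfying both dissociation equilibria:
        # S = KS*SE/E and P = KP*SE/E with E = ETOT - SE
        p = EnzymeParams(
            kon1=3.0, koff1=31.32, koff2=14.82, kon2=0.054, ETOT=1.5e-4, S0=5.0
        )
        SE = 0.4 * p.ETOT
        E = p.ETOT - SE
        state = EnzymeState(S=p.KS * SE / E, SE=SE, P=p.KP * SE / E)
        assert enzyme_rhs(state, p) == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)

    def test_state_invariants(self):
        with pytest.raises(ValueError):
            EnzymeState(S=-1.0, SE=0.0, P=0.0)
        with pytest.raises(ValueError):
            EnzymeState(S=1.0, SE=2e-4, P=0.0).free_enzyme(1.5e-4)


class TestDerivedAlgebra:
    def test_km_from_simultaneous_fit_affinities(self):
        p = EnzymeParams.from_affinities(
            KS=10.44, KP=273.5, koff2=14.82, kon1=3.0, ETOT=1.5e-4, S0=1.0
        )
        d = derive_mm_from_enzyme(p)
        assert round_sig(d.Km, 3) == 15.4
        assert round_sig(d.Vmax, 3) == 8.00

    def test_km_from_mid_dose_affinities(self):
        p = EnzymeParams.from_affinities(
            KS=8.30, KP=246.0, koff2=14.7, kon1=3.0, ETOT=1.5e-4, S0=1.0
        )
        assert round_sig(derive_mm_from_enzyme(p).Km, 3) == 13.2

    @pytest.mark.parametrize(
        "KS, KP, koff2, kon1, koff1_3sf, kon2_2sf",
        [(10.44, 273.5, 14.82, 3.0, 31.3, 0.054), (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)],
    )
    def test_rate_constants_from_affinities(self, KS, KP, koff2, kon1, koff1_3sf, kon2_2sf):
        koff1, kon2 = derive_rates_from_affinities(KS, KP, koff2, kon1)
        assert round_sig(koff1, 3) == koff1_3sf
        assert round_sig(kon2, 2) == kon2_2sf

    def test_zero_affinity_rejected(self):
        with pytest.raises(ValueError):
            derive_rates_from_affinities(10.0, 0.0, 14.0, 3.0)

    @given(KS=positive, KP=positive, koff2=positive, kon1=positive)
    def test_derivations_are_involutive(self, KS, KP, koff2, kon1):
        koff1, kon2 = derive_rates_from_affinities(KS, KP, koff2, kon1)
        assert koff1 / kon1 == pytest.approx(KS, rel=1e-12)
        assert koff2 / kon2 == pytest.approx(KP, rel=1e-12)
        p = EnzymeParams(
            kon1=kon1, koff1=koff1, koff2=koff2, kon2=kon2, ETOT=1.5e-4, S0=1.0
        )
        d = derive_mm_from_enzyme(p)
        assert d.Km == pytest.approx(KS + koff2 / kon1, rel=1e-12)
        assert d.Vmax / 3600.0 / p.ETOT == pytest.approx(koff2, rel=1e-12)


class TestHofmeyrAndEquilibrium:
    def test_reduces_to_mm_when_product_absent(self):
        h = HofmeyrParams(Vfmax=8.0, Vrmax=16.0, Ks=10.0, Kp=270.0)
        S = 25.0
        assert hofmeyr_flux(S, 0.0, h) == pytest.approx(h.Vfmax * S / (h.Ks + S))

    def test_generic_evaluation(self):
        # frozen from independent scalar arithmetic: 200/27 over 55/27 = 40/11
        h = HofmeyrParams(Vfmax=8.0, Vrmax=16.0, Ks=10.0, Kp=270.0)
        assert hofmeyr_flux(10.0, 10.0, h) == pytest.approx(40.0 / 11.0, rel=1e-12)

    def test_zero_at_balanced_unidirectional_fluxes(self):
        h = HofmeyrParams(Vfmax=8.0, Vrmax=16.0, Ks=10.0, Kp=270.0)
        S = 5.0
        P = S * (h.Vfmax / h.Ks) / (h.Vrmax / h.Kp)
        assert hofmeyr_flux(S, P, h) == pytest.approx(0.0, abs=1e-12)

    def test_reference_equilibrium_ratio(self):
        # frozen: (31.32/14.82)*(10.44/273.5)
        p = EnzymeParams(
            kon1=3.0, koff1=31.32, koff2=14.82, kon2=14.82 / 273.5, ETOT=1.5e-4, S0=1.0
        )
        assert round_sig(equilibrium_ratio(p), 3) == 0.0807

    def test_symmetric_parameters_give_unity(self):
        p = EnzymeParams(kon1=2.0, koff1=5.0, koff2=5.0, kon2=2.0, ETOT=1e-4, S0=1.0)
        assert equilibrium_ratio(p) == pytest.approx(1.0)

    def test_irreversible_scheme_rejected(self):
        p = EnzymeParams(kon1=3.0, koff1=31.0, koff2=14.0, kon2=0.0, ETOT=1e-4, S0=1.0)
        with pytest.raises(ValueError, match="irreversible"):
            equilibrium_ratio(p)

    @given(kon1=positive, koff1=positive, koff2=positive, kon2=positive)
    def test_both_closed_forms_agree(self, kon1, koff1, koff2, kon2):
        p = EnzymeParams(
            kon1=kon1, koff1=koff1, koff2=koff2, kon2=kon2, ETOT=1e-4, S0=1.0
        )
        lhs = equilibrium_ratio(p)
        rhs = (koff1**2 / kon1) / (koff2**2 / kon2)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    @given(kon1=positive, koff1=positive, koff2=positive, kon2=positive, S=positive)
    def test_equilibrium_ratio_is_zero_flux_of_reversible_rate_law(
        self, kon1, koff1, koff2, kon2, S
    ):
        p = EnzymeParams(
            kon1=kon1, koff1=koff1, koff2=koff2, kon2=kon2, ETOT=1e-4, S0=1.0
        )
        d = derive_mm_from_enzyme(p)
        h = HofmeyrParams(
            Vfmax=koff2 * p.ETOT * 3600.0,
            Vrmax=koff1 * p.ETOT * 3600.0,
            Ks=p.KS,
            Kp=p.KP,
        )
        P = S / equilibrium_ratio(p)
        scale = h.Vfmax * S / h.Ks
        assert abs(hofmeyr_flux(S, P, h)) <= 1e-9 * max(scale, 1.0)


class TestTwoPointEstimators:
    def test_zero_order_slope_of_high_dose_window(self):
        v = estimate_vmax_two_point(341.0, 0.95, 225.0, 15.94)
        assert round_sig(v, 2) == 7.7

    def test_equal_concentrations_give_zero(self):
        assert estimate_vmax_two_point(100.0, 0.0, 100.0, 5.0) == 0.0

    def test_hand_arithmetic(self):
        assert estimate_vmax_two_point(100.0, 0.0, 90.0, 5.0) == pytest.approx(2.0)

    def test_equal_times_rejected(self):
        with pytest.raises(ValueError):
            estimate_vmax_two_point(10.0, 1.0, 9.0, 1.0)

    def test_log_slope_of_low_dose_window(self):
        r = estimate_rate_log_slope(2.483, 1.888, 0.184, 12.032)
        assert round_sig(r, 3) == 0.257

    def test_km_bootstrap_from_printed_estimates(self):
        assert round_sig(7.7 / 0.257, 3) == 30.0

    def test_exact_exponential_recovers_rate(self):
        k = 0.5
        assert estimate_rate_log_slope(10.0, 1.0, 10.0 * math.exp(-k * 3), 4.0) == pytest.approx(k)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            estimate_rate_log_slope(0.0, 1.0, 1.0, 2.0)


class TestOccupancy:
    def test_extremes(self):
        assert occupancy_fraction(EnzymeState(S=1, SE=0.0, P=0), 1.5e-4) == 0.0
        assert occupancy_fraction(EnzymeState(S=1, SE=1.5e-4, P=0), 1.5e-4) == 1.0

    def test_half_occupied(self):
        assert occupancy_fraction(EnzymeState(S=1, SE=0.75e-4, P=0), 1.5e-4) == 0.5

    def test_corrupted_state_rejected(self):
        with pytest.raises(ValueError, match="corrupted"):
            occupancy_fraction(EnzymeState(S=1, SE=2e-4, P=0), 1.5e-4)


class TestParamValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            lambda: FirstOrderParams(S0=-1.0, k=0.1),
            lambda: FirstOrderParams(S0=1.0, k=0.0),
            lambda: MMParams(Vmax=0.0, Km=1.0, S0=1.0),
            lambda: EnzymeParams(kon1=0.0, koff1=1.0, koff2=1.0, ETOT=1e-4, S0=1.0),
            lambda: EnzymeParams(kon1=1.0, koff1=1.0, koff2=1.0, ETOT=1e-4, S0=1.0, kon2=-1.0),
        ],
    )
    def test_invariants_enforced(self, bad):
        with pytest.raises(ValueError):
            bad()

    def test_irreversible_kp_is_infinite(self):
        p = EnzymeParams(kon1=3.0, koff1=31.0, koff2=14.0, ETOT=1e-4, S0=1.0)
        assert math.isinf(p.KP)

    def test_derived_params_container_roundtrip(self):
        d = DerivedParams(Km=15.4, Vmax=8.0, KS=10.44, KP=273.5, koff1=31.32, kon2=0.054)
        assert d.thalf_min is None
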