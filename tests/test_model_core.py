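"""Unit and property tests for the core model equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from odmgrowth import (
    ModelParams,
    ShellState,
    StromaParams,
    boundary_pressure,
    continuous_oxygen_profile,
    growth_rhs,
    initial_shell_volumes,
    kRp_from_physical,
    oxygen_drop_per_shell,
    oxygen_profile,
    partition_volume,
    shell_oxygen,
    shell_radii,
    stroma_rhs,
)

from conftest import naive_shell_oxygen


def state_at(VT, VTo=0.1, n=5, kRp=13.37, VS=0.0):
    Vi = initial_shell_volumes(n, VTo, kRp) * (VT / VTo)
    return ShellState(Vi=Vi, VTo=VTo, VS=VS)


class TestBoundaryPressure:
    @pytest.mark.parametrize(
        "Pmax,VTo,VT,expected",
        [
            (60, 0.1, 0.1, 60.0),            # VT = VTo
            (60, 0.1, 0.8, 15.0),            # (1/8)^(2/3) = 1/4
            (60, 0.1, 0.3, 28.84499140614817),
        ],
    )
    def test_values(self, Pmax, VTo, VT, expected):
        assert boundary_pressure(Pmax, VTo, VT) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            boundary_pressure(60, 0.0, 0.1)
        with pytest.raises(ValueError):
            boundary_pressure(60, 0.1, -1.0)


class TestContinuousProfile:
    def test_boundary_value(self):
        assert continuous_oxygen_profile(0.5, 0.5, 13.37, 60) == pytest.approx(60.0)

    def test_flat_when_no_uptake(self):
        for r in (0.0, 0.2, 0.5):
            assert continuous_oxygen_profile(r, 0.5, 0.0, 60) == 60.0

    def test_centre_value(self):
        # 60 / cosh(13.37 * 0.5)
        assert continuous_oxygen_profile(0.0, 0.5, 13.37, 60) == pytest.approx(
            0.14994153635359178, rel=1e-12
        )

    def test_large_argument_is_finite(self):
        v = continuous_oxygen_profile(0.0, 2.0, 500.0, 60)
        assert 0.0 <= v < 1e-300 or v == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            continuous_oxygen_profile(0.6, 0.5, 1.0, 60)
        with pytest.raises(ValueError):
            continuous_oxygen_profile(-0.1, 0.5, 1.0, 60)


class TestShellOxygen:
    def test_boundary_at_initial_volume_is_pmax(self, ribba_params):
        st_ = state_at(0.1)
        n = ribba_params.n_shells
        assert shell_oxygen(n, n, st_, ribba_params) == 60.0

    def test_flat_profile_without_uptake(self):
        p = ModelParams(kp=0.01, kRp=0.0, KH=25.9, KN=20.2)
        st_ = state_at(0.8, kRp=0.0)
        expected = 60.0 * (0.1 / 0.8) ** (2 / 3)
        for i in range(6):
            assert shell_oxygen(i, 5, st_, p) == pytest.approx(expected, rel=1e-12)

    def test_index_errors(self, ribba_params):
        st_ = state_at(0.1)
        with pytest.raises(IndexError):
            shell_oxygen(6, 5, st_, ribba_params)
        with pytest.raises(IndexError):
            shell_oxygen(-1, 5, st_, ribba_params)

    @settings(deadline=None, max_examples=200)
    @given(
        kRp=st.floats(0.0, 100.0),
        VT_ratio=st.floats(0.2, 20.0),
        n=st.integers(1, 20),
        data=st.data(),
    )
    def test_matches_inside_out_summation_form(self, kRp, VT_ratio, n, data):
        """The stable product form and the naive inside-out summation form
        of the discretised profile agree to 1e-12 relative."""
        i = data.draw(st.integers(0, n))
        VTo, VT = 0.1, 0.1 * VT_ratio
        p = ModelParams(kp=0.01, kRp=kRp, KH=25.9, KN=20.2, n_shells=n)
        st_ = state_at(VT, n=n, kRp=kRp)
        stable = shell_oxygen(i, n, st_, p)
        naive = naive_shell_oxygen(i, n, VT, VTo, kRp, 60.0)
        assert stable == pytest.approx(naive, rel=1e-12, abs=1e-300)

    @settings(deadline=None, max_examples=100)
    @given(kRp=st.floats(0.0, 100.0), VT_ratio=st.floats(0.2, 20.0), n=st.integers(1, 20))
    def test_monotone_and_bounded(self, kRp, VT_ratio, n):
        p = ModelParams(kp=0.01, kRp=kRp, KH=25.9, KN=20.2, n_shells=n)
        st_ = state_at(0.1 * VT_ratio, n=n, kRp=kRp)
        P = [shell_oxygen(i, n, st_, p) for i in range(n + 1)]
        Pb = boundary_pressure(60.0, 0.1, st_.VT)
        assert all(P[i] <= P[i + 1] + 1e-12 for i in range(n))
        assert all(0.0 <= v <= Pb * (1 + 1e-12) for v in P)

    @settings(deadline=None, max_examples=100)
    @given(kRp=st.floats(0.0, 100.0), VT_ratio=st.floats(0.2, 20.0), n=st.integers(1, 20))
    def test_telescoping_drop(self, kRp, VT_ratio, n):
        """Per-shell drops are constant and sum to the total drop."""
        p = ModelParams(kp=0.01, kRp=kRp, KH=25.9, KN=20.2, n_shells=n)
        st_ = state_at(0.1 * VT_ratio, n=n, kRp=kRp)
        drop = oxygen_drop_per_shell(n, st_, p)
        total = shell_oxygen(n, n, st_, p) - shell_oxygen(0, n, st_, p)
        assert n * drop == pytest.approx(total, rel=1e-8, abs=1e-12)
        diffs = np.diff([shell_oxygen(i, n, st_, p) for i in range(n + 1)])
        assert np.allclose(diffs, drop, rtol=1e-9, atol=1e-12)


class TestOxygenDrop:
    def test_no_gradient_without_uptake(self, ribba_params):
        st_ = state_at(0.1, kRp=0.0)
        p = ModelParams(kp=0.01, kRp=0.0, KH=25.9, KN=20.2)
        assert oxygen_drop_per_shell(5, st_, p) == 0.0

    def test_reference_value(self, ribba_params):
        st_ = state_at(0.1)
        assert oxygen_drop_per_shell(5, st_, ribba_params) == pytest.approx(
            11.951575747751253, rel=1e-12
        )

    def test_profile_container(self, ribba_params):
        prof = oxygen_profile(state_at(0.1), ribba_params)
        assert prof.boundary == pytest.approx(60.0)
        assert prof.drop_per_shell * 5 == pytest.approx(prof.drop_total)
        assert prof.P.shape == (6,)


class TestPartitionVolume:
    def test_half_at_switch_constant(self):
        assert partition_volume(20.0, 20.0, 1.0) == pytest.approx(0.5)
        assert partition_volume(20.0, 20.0, 1.0, "as_printed") == pytest.approx(0.5)

    def test_anoxic_limits(self):
        assert partition_volume(0.0, 20.0, 1.0, "complement") == 1.0
        assert partition_volume(0.0, 20.0, 1.0, "as_printed") == 0.0

    def test_zero_volume(self):
        assert partition_volume(30.0, 20.0, 0.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            partition_volume(10.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            partition_volume(10.0, 20.0, 1.0, "sideways")

    @settings(deadline=None, max_examples=100)
    @given(P=st.floats(0, 500), V=st.floats(0, 10), K=st.floats(0.01, 200))
    def test_bounded_by_volume(self, P, V, K):
        for orientation in ("complement", "as_printed"):
            frac = partition_volume(P, K, V, orientation)
            assert 0.0 <= frac <= V * (1 + 1e-12)

    @settings(deadline=None, max_examples=100)
    @given(P=st.floats(0, 500), V=st.floats(0, 10))
    def test_necrosis_within_hypoxia(self, P, V):
        """With KN < KH under the complement orientation, the necrotic
        partition never exceeds the hypoxic one at any oxygen level."""
        assert partition_volume(P, 20.2, V) <= partition_volume(P, 25.9, V) + 1e-15


class TestGrowthRhs:
    def test_zero_rate_without_proliferation(self):
        p = ModelParams(kp=0.0, kRp=13.37, KH=25.9, KN=20.2)
        assert np.all(growth_rhs(state_at(0.3), p) == 0.0)

    def test_empty_shell_has_zero_rate(self, ribba_params):
        Vi = initial_shell_volumes(5, 0.1, 13.37)
        Vi[2] = 0.0
        st_ = ShellState(Vi=Vi, VTo=0.1)
        assert growth_rhs(st_, ribba_params)[2] == 0.0

    def test_single_shell_at_initial_volume(self):
        # with boundary-index oxygen a single shell at VT = VTo sees Pmax
        p = ModelParams(kp=0.0058, kRp=13.37, KH=25.9, KN=20.2, n_shells=1)
        st_ = ShellState(Vi=np.array([0.1]), VTo=0.1)
        rate = growth_rhs(st_, p, oxygen_index="outer")[0]
        assert rate == pytest.approx(0.0058 * 60.0 * 0.1, rel=1e-12)

    def test_mid_index_default_uses_shell_centre_oxygen(self):
        p = ModelParams(kp=0.0058, kRp=13.37, KH=25.9, KN=20.2, n_shells=5)
        st_ = state_at(0.1)
        expected = p.kp * np.array(
            [naive_shell_oxygen(i - 0.5, 5, 0.1, 0.1, p.kRp, 60.0) for i in range(1, 6)]
        ) * st_.Vi
        np.testing.assert_allclose(growth_rhs(st_, p), expected, rtol=1e-10)


class TestStromaRhs:
    def test_no_stroma_freezes_tumour(self):
        p = StromaParams(kPG=0.005, kS=0.07, kRp=23.7, KH=25.9, KN=20.2)
        st_ = state_at(0.3, kRp=23.7, VS=0.0)
        rates = stroma_rhs(st_, p)
        assert np.all(rates[:-1] == 0.0)
        assert rates[-1] == pytest.approx(0.07 * st_.VT, rel=1e-12)

    def test_reduces_to_base_model(self, ribba_params):
        p = StromaParams(kPG=0.0058, kS=0.0, kRp=13.37, KH=25.9, KN=20.2, VS0=1.0)
        st_ = state_at(0.3, VS=1.0)
        np.testing.assert_allclose(
            stroma_rhs(st_, p)[:-1], growth_rhs(st_, ribba_params), rtol=1e-14
        )
        assert stroma_rhs(st_, p)[-1] == 0.0

    def test_hand_evaluated_rates(self):
        """Stroma-model rates at the explant-fit parameters against a direct
        naive evaluation of the coupled equations."""
        kPG, kS, kRp = 0.005, 0.07, 23.7
        p = StromaParams(kPG=kPG, kS=kS, kRp=kRp, KH=25.9, KN=20.2)
        st_ = state_at(0.25, kRp=kRp, VS=0.08)
        rates = stroma_rhs(st_, p)
        P = np.array(
            [naive_shell_oxygen(i - 0.5, 5, st_.VT, 0.1, kRp, 60.0) for i in range(1, 6)]
        )
        np.testing.assert_allclose(rates[:-1], kPG * P * st_.Vi * 0.08, rtol=1e-10)
        assert rates[-1] == pytest.approx(kS * st_.VT, rel=1e-12)


class TestShellRadii:
    def test_single_shell(self):
        np.testing.assert_allclose(shell_radii(1, 0.46, 13.37), [0.0, 0.46])

    def test_equal_oxygen_drop_construction(self):
        """The continuous profile evaluated at the boundaries forms an
        arithmetic progression (equal drop per shell by construction)."""
        r = shell_radii(5, 0.46, 13.37)
        vals = [continuous_oxygen_profile(ri, 0.46, 13.37, 60.0) for ri in r]
        diffs = np.diff(vals)
        assert np.allclose(diffs, diffs[0], rtol=1e-9)

    def test_against_root_finding_oracle(self):
        """Boundaries agree with brentq root-finding on the continuous
        profile for the equally spaced target tensions."""
        n, rT, kRp = 5, 0.46, 13.37
        r = shell_radii(n, rT, kRp)
        p0 = continuous_oxygen_profile(0.0, rT, kRp, 60.0)
        targets = np.linspace(p0, 60.0, n + 1)
        for i in range(1, n):
            root = brentq(
                lambda x: continuous_oxygen_profile(x, rT, kRp, 60.0) - targets[i],
                0.0, rT, xtol=1e-14,
            )
            assert r[i] == pytest.approx(root, abs=1e-10)

    def test_flat_profile_fallback_equal_volumes(self):
        r = shell_radii(4, 0.5, 0.0)
        np.testing.assert_allclose(np.diff(r**3), np.full(4, 0.5**3 / 4), rtol=1e-12)

    def test_large_argument_stable(self):
        r = shell_radii(5, 1.5, 600.0)
        assert np.all(np.diff(r) > 0) and r[-1] == 1.5

    def test_initial_volumes_sum_to_vto(self):
        V = initial_shell_volumes(5, 0.1, 13.37)
        assert V.sum() == pytest.approx(0.1, rel=1e-14)
        assert np.all(V > 0)


class TestParameterConversion:
    def test_zero_uptake(self):
        assert kRp_from_physical(0.0, 1.0) == 0.0

    def test_unit_ratio(self):
        assert kRp_from_physical(2.5, 2.5) == pytest.approx(
            (3 / (4 * math.pi)) ** (1 / 3), rel=1e-14
        )

    def test_physiological_diffusivity(self):
        # D = 1.9e-6 cm^2/s = 0.16416 cm^2/day; kR chosen 1e4 * D
        assert kRp_from_physical(1641.6, 0.16416) == pytest.approx(
            62.03504908994001, rel=1e-12
        )

    def test_invalid_diffusivity(self):
        with pytest.raises(ValueError):
            kRp_from_physical(1.0, 0.0)


class TestValidation:
    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            ModelParams(kp=-1e-3, kRp=1.0, KH=25.9, KN=20.2)
        with pytest.raises(ValueError):
            ModelParams(kp=1e-3, kRp=1.0, KH=0.0, KN=20.2)
        with pytest.raises(ValueError):
            ModelParams(kp=1e-3, kRp=1.0, KH=25.9, KN=20.2, n_shells=0)
        with pytest.raises(ValueError):
            StromaParams(kPG=-0.1, kS=0.0, kRp=1.0, KH=25.9, KN=20.2)

    def test_state_invariants(self):
        with pytest.raises(ValueError):
            ShellState(Vi=np.array([-0.1, 0.2]), VTo=0.1)
        with pytest.raises(ValueError):
            ShellState(Vi=np.array([0.1]), VTo=0.0)
        st_ = ShellState(Vi=np.array([0.1, 0.2]), VTo=0.1)
        assert st_.VT == pytest.approx(0.3)
        assert st_.rT == pytest.approx(0.3 ** (1 / 3))
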