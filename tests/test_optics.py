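"""Forward model: Fresnel multilayer reflection and Jones-calculus channels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sprpol.optics import (
    ChannelIntensities,
    JonesConfig,
    Layer,
    LayerStack,
    OpticalSystem,
    ReflectionState,
    channel_intensities,
    channel_intensities_jones,
    find_operating_angle,
    jones_reflection_state,
    multilayer_reflection,
    simulate_curve,
)


def characteristic_matrix_reflection(stack: LayerStack, aoi: float, pol: str, substrate=None) -> complex:
    """Independent oracle: Abeles characteristic-matrix formulation."""
    n_sub = stack.substrate_index if substrate is None else substrate
    indices = [complex(stack.ambient_index)] + [l.index for l in stack.layers] + [complex(n_sub)]
    thicknesses = [0.0] + [l.thickness_nm for l in stack.layers] + [0.0]
    k0 = 2 * np.pi / stack.wavelength_nm
    kx = k0 * stack.ambient_index * np.sin(aoi)

    def kz(n):
        v = np.sqrt((k0 * n) ** 2 - kx**2 + 0j)
        return -v if v.imag < 0 else v

    def eta(n):
        # tilted optical admittance per polarization (common constants cancel)
        return kz(n) if pol == "s" else n**2 / kz(n)

    m = np.eye(2, dtype=complex)
    for n, d in zip(indices[1:-1], thicknesses[1:-1]):
        beta = -kz(n) * d  # e^{+ikz z} traveling-wave convention
        e = eta(n)
        m = m @ np.array([[np.cos(beta), 1j * np.sin(beta) / e], [1j * e * np.sin(beta), np.cos(beta)]])
    e0, es = eta(indices[0]), eta(indices[-1])
    num = e0 * (m[0, 0] + m[0, 1] * es) - (m[1, 0] + m[1, 1] * es)
    den = e0 * (m[0, 0] + m[0, 1] * es) + (m[1, 0] + m[1, 1] * es)
    r = num / den
    # align with the recursive convention (p-wave sign differs between the
    # admittance and amplitude conventions)
    return complex(r) if pol == "s" else complex(-r)


class TestMultilayerReflection:
    def test_identical_half_spaces_reflect_nothing(self):
        stack = LayerStack(ambient_index=1.5, layers=(), substrate_index=1.5)
        for aoi in (0.0, 0.4, 1.2):
            assert multilayer_reflection(stack, aoi, "s") == 0
            assert multilayer_reflection(stack, aoi, "p") == 0

    def test_normal_incidence_closed_form(self):
        stack = LayerStack(layers=(), substrate_index=1.333)
        expected = (1.734 - 1.333) / (1.734 + 1.333)
        for pol in "sp":
            assert abs(multilayer_reflection(stack, 0.0, pol)) == pytest.approx(expected, abs=1e-12)

    def test_matches_characteristic_matrix_oracle(self):
        stack = LayerStack()
        rng = np.random.default_rng(42)
        for aoi in rng.uniform(0.05, 1.35, size=50):
            for pol in "sp":
                r_rec = multilayer_reflection(stack, float(aoi), pol)
                r_mat = characteristic_matrix_reflection(stack, float(aoi), pol)
                assert r_rec == pytest.approx(r_mat, abs=1e-12)

    def test_resonance_dip_in_p_not_s(self):
        stack = LayerStack()
        aois = np.linspace(stack.critical_angle + 0.01, math.radians(80), 800)
        rp = np.abs(multilayer_reflection(stack, aois, "p"))
        rs = np.abs(multilayer_reflection(stack, aois, "s"))
        assert rp.min() < 0.35
        assert rs.min() > rp.min()
        # a single deep minimum: |rp| decreases to the dip then increases
        i = int(np.argmin(rp))
        assert 0 < i < len(aois) - 1

    def test_rejects_nonphysical_inputs(self):
        with pytest.raises(ValueError):
            LayerStack(layers=(Layer("Au", 0.18 + 3.4j, -5.0),))
        with pytest.raises(ValueError):
            LayerStack(wavelength_nm=0.0)
        with pytest.raises(ValueError):
            multilayer_reflection(LayerStack(), math.pi / 2, "s")
        with pytest.raises(ValueError):
            multilayer_reflection(LayerStack(), 0.5, "x")


class TestReflectionState:
    def test_zero_reflection_has_zero_phase_difference(self):
        stack = LayerStack(ambient_index=1.5, layers=(), substrate_index=1.5)
        state = jones_reflection_state(stack, 0.3)
        assert state.delta_phi == 0.0

    def test_phase_difference_continuous_on_dense_sweep(self):
        stack = LayerStack()
        aois = np.linspace(stack.critical_angle + 0.01, math.radians(80), 4000)
        d = np.unwrap(jones_reflection_state(stack, aois).delta_phi)
        assert np.max(np.abs(np.diff(d))) < 0.1

    def test_phase_monotone_over_working_range_at_operating_angle(self, system):
        curve = simulate_curve(system, np.linspace(1.333, 1.393, 200))
        steps = np.diff(np.unwrap(curve["delta_phi"]))
        assert np.all(steps > 0) or np.all(steps < 0)

    def test_wrapped_to_principal_interval(self):
        stack = LayerStack()
        aois = np.linspace(0.05, 1.35, 300)
        state = jones_reflection_state(stack, aois)
        assert np.all(state.delta_phi > -np.pi) and np.all(state.delta_phi <= np.pi)


def _random_state(rng) -> ReflectionState:
    rp = rng.uniform(0.05, 0.95)
    rs = rng.uniform(0.05, 0.95)
    phi_p = rng.uniform(-np.pi, np.pi)
    phi_s = rng.uniform(-np.pi, np.pi)
    delta = (phi_p - phi_s + np.pi) % (2 * np.pi) - np.pi
    return ReflectionState(
        r_s=rs * np.exp(1j * phi_s), r_p=rp * np.exp(1j * phi_p), phi_s=phi_s, phi_p=phi_p, delta_phi=delta
    )


class TestChannelIntensities:
    def test_trivial_substitution(self):
        # real r_p = 0.5, alpha = 45 deg: the 45-degree analyzer sees the
        # pure p intensity rp^2 cos^2(alpha) = 0.125
        state = ReflectionState(r_s=0.3, r_p=0.5, phi_s=0.0, phi_p=0.0, delta_phi=0.0)
        ci = channel_intensities(state, JonesConfig(amplitude=1.0))
        assert ci.i45 == pytest.approx(0.125, abs=1e-15)

    def test_quadrature_phase_gives_equal_interference_channels(self):
        state = ReflectionState(r_s=0.7, r_p=0.4, phi_s=0.0, phi_p=np.pi / 2, delta_phi=np.pi / 2)
        ci = channel_intensities(state)
        assert ci.i0 == pytest.approx(ci.i90, abs=1e-15)

    def test_closed_forms_equal_jones_products(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            state = _random_state(rng)
            alpha = rng.uniform(0.1, np.pi / 2 - 0.1)
            cfg = JonesConfig(alpha=alpha, amplitude=rng.uniform(0.5, 2.0))
            ci = channel_intensities(state, cfg)
            cj = channel_intensities_jones(state, cfg)
            for a, b in [(ci.i0, cj.i0), (ci.i45, cj.i45), (ci.i90, cj.i90), (ci.i135, cj.i135)]:
                assert a == pytest.approx(b, rel=1e-12, abs=1e-14)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        rp=st.floats(0.01, 0.99),
        rs=st.floats(0.01, 0.99),
        dphi=st.floats(-np.pi, np.pi),
        alpha=st.floats(0.05, np.pi / 2 - 0.05),
    )
    def test_total_intensity_conserved(self, rp, rs, dphi, alpha):
        """I0 + I90 = I45 + I135: the two orthogonal analyzer pairs each
        collect the full beam intensity."""
        state = ReflectionState(r_s=rs, r_p=rp, phi_s=0.0, phi_p=dphi, delta_phi=dphi)
        ci = channel_intensities(state, JonesConfig(alpha=alpha))
        total = ci.i45 + ci.i135
        assert ci.i0 + ci.i90 == pytest.approx(total, rel=1e-12, abs=1e-15)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(rp=st.floats(0.01, 0.99), rs=st.floats(0.01, 0.99), dphi=st.floats(-3.1, 3.1))
    def test_quad_channel_estimator_recovers_cos(self, rp, rs, dphi):
        state = ReflectionState(r_s=rs, r_p=rp, phi_s=0.0, phi_p=dphi, delta_phi=dphi)
        ci = channel_intensities(state)
        est = (ci.i0 - ci.i90) / (2 * math.sqrt(ci.i45 * ci.i135))
        assert est == pytest.approx(math.cos(dphi), rel=1e-12, abs=1e-12)

    def test_intensities_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ci = channel_intensities(_random_state(rng), JonesConfig(alpha=rng.uniform(0.1, 1.4)))
            assert min(ci.i0, ci.i45, ci.i90, ci.i135) >= 0

    def test_stack_order(self):
        ci = ChannelIntensities(i0=1.0, i45=2.0, i90=3.0, i135=4.0)
        assert np.allclose(ci.stack(), [1.0, 2.0, 3.0, 4.0])


class TestOperatingPoint:
    def test_operating_angle_above_critical(self, system):
        assert system.aoi_resolved > system.stack.critical_angle

    def test_operating_angle_deterministic(self, system):
        assert find_operating_angle(system.stack) == pytest.approx(system.aoi_resolved, abs=1e-12)

    def test_system_yaml_round_trip(self, tmp_path, system):
        path = tmp_path / "sys.yaml"
        system.to_yaml(path)
        back = OpticalSystem.from_yaml(path)
        assert back.stack == system.stack
        assert back.aoi == pytest.approx(system.aoi_resolved)
        assert back.jones == system.jones
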