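"""Constitutive model: invariants, energy, stress, and their consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stomamech.material import (DeformationState, InvertedElementError,
                                MaterialParams, cauchy_stress, fiber_energy,
                                fiber_stress_scale, strain_energy,
                                strain_invariants)

XHAT = np.array([1.0, 0.0, 0.0])


def random_state(rng, scale=0.2):
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.3:
            break
    a0 = rng.standard_normal(3)
    a0 /= np.linalg.norm(a0)
    return DeformationState(F, a0)


def fd_cauchy(state, p, h=1e-6):
    """Independent numeric-differentiation oracle:
    sigma = (1/J) dW/dF F^T, symmetrized."""
    F, a0 = state.F, state.a0
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P[i, j] = (strain_energy(DeformationState(Fp, a0), p)
                       - strain_energy(DeformationState(Fm, a0), p)) / (2 * h)
    s = P @ F.T / np.linalg.det(F)
    return 0.5 * (s + s.T)


class TestInvariants:
    def test_identity(self):
        I1, I2, lam, J = strain_invariants(np.eye(3), XHAT)
        assert (I1, I2, lam, J) == pytest.approx((3.0, 3.0, 1.0, 1.0))

    def test_uniaxial_fiber_stretch(self):
        _, _, lam, _ = strain_invariants(np.diag([2.0, 1.0, 1.0]), XHAT)
        assert lam == pytest.approx(2.0)

    def test_matches_dense_tensor_arithmetic(self, rng):
        for _ in range(20):
            st_ = random_state(rng, scale=0.3)
            C = st_.F.T @ st_.F
            Cb = np.linalg.det(st_.F) ** (-2 / 3) * C
            assert st_.I1 == pytest.approx(np.trace(Cb), abs=1e-12)
            assert st_.I2 == pytest.approx(
                0.5 * (np.trace(Cb) ** 2 - np.trace(Cb @ Cb)), abs=1e-12)

    def test_inverted_element_rejected(self):
        with pytest.raises(InvertedElementError):
            strain_invariants(np.diag([-1.0, 1.0, 1.0]), XHAT)


class TestStrainEnergy:
    def test_zero_at_identity(self, material):
        assert strain_energy(DeformationState(np.eye(3), XHAT), material) == 0.0

    def test_matrix_isotropy_without_fibers(self, rng):
        p = MaterialParams(c3=0.0, c5=0.0)
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        w0 = strain_energy(DeformationState(F, XHAT), p)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            q *= np.linalg.det(q)
            w = strain_energy(DeformationState(q @ F, XHAT), p)
            assert w == pytest.approx(w0, abs=1e-10 * max(1.0, abs(w0)))

    def test_fibers_carry_no_compression(self, material, rng):
        p_no_fiber = MaterialParams(c1=material.c1, c2=material.c2,
                                    c3=0.0, c5=0.0, k_bulk=material.k_bulk)
        # fiber along x, compressed; transverse arbitrary
        F = np.diag([0.8, 1.1, 1.1])
        w_fiber = strain_energy(DeformationState(F, XHAT), material)
        w_matrix = strain_energy(DeformationState(F, XHAT), p_no_fiber)
        assert w_fiber == pytest.approx(w_matrix, abs=1e-14)

    def test_nonnegative_near_incompressible(self, material, rng):
        for _ in range(50):
            st_ = random_state(rng, scale=0.15)
            if abs(st_.J - 1.0) < 0.2:
                assert strain_energy(st_, material) >= -1e-12

    def test_increasing_along_fiber_stretch(self, material):
        lams = np.linspace(1.01, 1.3, 20)
        ws = [strain_energy(DeformationState(
            np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)]), XHAT),
            material) for lam in lams]
        assert np.all(np.diff(ws) > 0)

    def test_fiber_energy_derivative_matches_stress_scale(self, material):
        lams = np.linspace(1.001, 1.2, 100)
        h = 1e-7
        dW = (fiber_energy(lams + h, material)
              - fiber_energy(lams - h, material)) / (2 * h)
        assert np.allclose(dW, fiber_stress_scale(lams, material) / lams,
                           atol=1e-6)


class TestCauchyStress:
    def test_zero_at_identity(self, material):
        sig = cauchy_stress(DeformationState(np.eye(3), XHAT), material)
        assert np.abs(sig).max() == 0.0

    def test_matches_numeric_differentiation(self, material, rng):
        worst = 0.0
        for _ in range(100):
            st_ = random_state(rng)
            sig = cauchy_stress(st_, material)
            ref = fd_cauchy(st_, material)
            scale = max(np.abs(ref).max(), 1e-8)
            worst = max(worst, np.abs(sig - ref).max() / scale)
        assert worst < 1e-3

    def test_objectivity(self, material, rng):
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        a0 = np.array([0.0, 1.0, 0.0])
        w0 = strain_energy(DeformationState(F, a0), material)
        for _ in range(10):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            q *= np.linalg.det(q)
            w = strain_energy(DeformationState(q @ F, a0), material)
            assert abs(w - w0) < 1e-10 * max(1.0, abs(w0))

    def test_fiber_reinforcement_biases_stress(self, material):
        # equibiaxial in-plane stretch, fiber in plane along x
        lam = 1.05
        F = np.diag([lam, lam, 1.0 / lam ** 2])
        sig = cauchy_stress(DeformationState(F, XHAT), material)
        assert sig[0, 0] > sig[1, 1]

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        p = MaterialParams()
        st_ = random_state(rng)
        sig = cauchy_stress(st_, p)
        assert np.allclose(sig, sig.T, atol=1e-12)


class TestParamValidation:
    @pytest.mark.parametrize("kw", [dict(c1=-1.0), dict(c2=0.0),
                                    dict(c3=-0.1), dict(lam_star=0.9),
                                    dict(k_bulk=-5.0)])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            MaterialParams(**kw)

    def test_fiber_law_continuous_at_lam_star(self, material):
        eps = 1e-9
        lo = fiber_stress_scale(material.lam_star - eps, material)
        hi = fiber_stress_scale(material.lam_star + eps, material)
        assert hi == pytest.approx(lo, rel=1e-6)
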