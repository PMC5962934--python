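"""Constitutive-law unit and property tests.

The finite-difference energy oracle and the direct matrix-algebra
invariant evaluations are kept independent of the implementation paths
they check (analytic PK2 stress, vectorized invariant code).
"""

import numpy as np
import pytest

from bivent import materials as mat

P = mat.CHF_REFERENCE
F0 = np.eye(3)
E_F = np.eye(3)[0]
E_S = np.eye(3)[1]


def rand_F(rng, scale=0.15):
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    if np.linalg.det(F) <= 0.05:
        F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
    return F


class TestKinematics:
    def test_identity(self):
        st = mat.kinematics(F0, E_F, E_S)
        assert st.J == pytest.approx(1.0)
        assert st.I1 == pytest.approx(3.0)
        assert st.I4f == pytest.approx(1.0)
        assert st.I4s == pytest.approx(1.0)
        assert st.I8fs == pytest.approx(0.0, abs=1e-15)

    def test_pure_dilation_removes_isochoric_change(self):
        st = mat.kinematics(1.3 * F0, E_F, E_S)
        assert st.J == pytest.approx(1.3 ** 3)
        assert st.I1 == pytest.approx(3.0)
        assert st.I4f == pytest.approx(1.0)
        assert np.abs(np.linalg.det(st.Fbar) - 1) < 1e-12

    def test_simple_shear_matches_matrix_algebra(self):
        gamma = 0.5
        F = np.eye(3) + gamma * np.outer(E_F, E_S)
        st = mat.kinematics(F, E_F, E_S)
        # independent oracle: direct matrix evaluation
        C = F.T @ F
        J = np.linalg.det(F)
        Cb = J ** (-2 / 3) * C
        assert st.I1 == pytest.approx(np.trace(Cb), rel=1e-14)
        assert st.I4f == pytest.approx(E_F @ Cb @ E_F, rel=1e-14)
        assert st.I4s == pytest.approx(E_S @ Cb @ E_S, rel=1e-14)
        assert st.I8fs == pytest.approx(E_F @ Cb @ E_S, rel=1e-14)
        assert st.lambda_f == pytest.approx(np.sqrt(E_F @ C @ E_F))

    def test_inverted_element_raises(self):
        F = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="inversion"):
            mat.kinematics(F, E_F, E_S)


class TestPassiveEnergy:
    def test_reference_state_offset(self):
        st = mat.kinematics(F0, E_F, E_S)
        assert mat.psi_iso(st, P) == pytest.approx(P.a / (2 * P.b))

    def test_equibiaxial_matches_closed_form(self):
        # equibiaxial 1.1 stretch in the fiber/sheet plane at J = 1
        lam = 1.1
        F = np.diag([lam, lam, 1.0 / lam ** 2])
        st = mat.kinematics(F, E_F, E_S)
        # independent re-evaluation of the printed strain-energy formula
        I1, I4f, I4s, I8 = st.I1, st.I4f, st.I4s, st.I8fs
        expect = P.a / (2 * P.b) * np.exp(P.b * (I1 - 3))
        for ai, bi, I4 in ((P.a_f, P.b_f, I4f), (P.a_s, P.b_s, I4s)):
            if I4 > 1:
                expect += ai / (2 * bi) * (np.exp(bi * (I4 - 1) ** 2) - 1)
        expect += P.a_fs / (2 * P.b_fs) * (np.exp(P.b_fs * I8 ** 2) - 1)
        assert mat.psi_iso(st, P) == pytest.approx(expect, rel=1e-12)

    def test_isotropic_degeneracy(self):
        from dataclasses import replace
        iso = replace(P, a_f=0.0, a_s=0.0, a_fs=0.0)
        F = np.diag([1.2, 0.9, 1.0 / (1.2 * 0.9)])
        st = mat.kinematics(F, E_F, E_S)
        assert mat.psi_iso(st, iso) == pytest.approx(
            iso.a / (2 * iso.b) * np.exp(iso.b * (st.I1 - 3)))

    def test_psi_vol_values(self):
        assert mat.psi_vol(1.0, 0.001) == 0.0
        expect = ((1.21 - 1) / 2 - np.log(1.1)) / 0.001
        assert mat.psi_vol(1.1, 0.001) == pytest.approx(expect, rel=1e-12)

    def test_psi_vol_stationary_and_convex_at_identity(self):
        h = 1e-6
        d1 = (mat.psi_vol(1 + h, 0.01) - mat.psi_vol(1 - h, 0.01)) / (2 * h)
        assert abs(d1) < 1e-6
        assert mat.psi_vol(1.05, 0.01) > 0 and mat.psi_vol(0.95, 0.01) > 0

    def test_overflow_clipped_with_warning(self):
        F = np.diag([3.0, 1.0, 1.0 / 3.0])
        st = mat.kinematics(F, E_F, E_S)
        with pytest.warns(RuntimeWarning, match="clip"):
            val = mat.psi_iso(st, P)
        assert np.isfinite(val)


class TestPassiveStress:
    def test_zero_at_reference(self):
        sig = mat.passive_cauchy(F0, E_F, E_S, P)
        assert np.abs(sig).max() < 1e-12

    def test_fd_energy_consistency_random_states(self, rng):
        """sigma = 2 J^-1 F dPsi/dC F^T, checked against central finite
        differences of the total energy through 50 random deformations."""
        h = 1e-6
        worst = 0.0
        for _ in range(50):
            F = rand_F(rng)
            S = mat.pk2_passive(F, E_F, E_S, P)
            # FD of psi(C) wrt C (symmetrized)
            C = F.T @ F
            S_fd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    dC = np.zeros((3, 3))
                    dC[i, j] += h / 2
                    dC[j, i] += h / 2

                    def psi_of_C(Cm):
                        w, v = np.linalg.eigh(Cm)
                        Fs = v @ np.diag(np.sqrt(w)) @ v.T
                        st = mat.kinematics(Fs, E_F, E_S)
                        return mat.psi_iso(st, P) + mat.psi_vol(st.J, P.D)

                    S_fd[i, j] = (psi_of_C(C + dC) - psi_of_C(C - dC)) / h
            # the symmetrized perturbation yields 2 dPsi/dC_sym = S
            rel = np.abs(S_fd - S).max() / max(np.abs(S).max(), 1e-8)
            worst = max(worst, rel)
        assert worst < 1e-6

    def test_objectivity_under_rotations(self, rng):
        for _ in range(10):
            F = rand_F(rng)
            Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            st1 = mat.kinematics(F, E_F, E_S)
            st2 = mat.kinematics(Q @ F, E_F, E_S)
            e1 = mat.psi_iso(st1, P) + mat.psi_vol(st1.J, P.D)
            e2 = mat.psi_iso(st2, P) + mat.psi_vol(st2.J, P.D)
            assert abs(e1 - e2) <= 1e-10 * max(abs(e1), 1.0)

    def test_fiber_stretch_anisotropy(self):
        lam = 1.15
        F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
        sig = mat.passive_cauchy(F, E_F, E_S, P)
        assert sig[0, 0] > sig[1, 1]
        assert sig[0, 0] > sig[2, 2]


class TestActiveTension:
    AP = mat.ActiveParams()

    def test_cycle_start_zero(self):
        assert mat.active_tension(0.0, 1.1, self.AP) == pytest.approx(0.0)

    def test_below_slack_length_no_tension(self):
        lam = 0.99 * self.AP.l0 / self.AP.lr
        for t in (0.0, 0.1, self.AP.t0, 0.4):
            assert mat.active_tension(t, lam, self.AP) == 0.0

    def test_peak_value_matches_hand_evaluation(self):
        lam = 1.1
        ap = self.AP
        l = ap.lr * lam
        eca50_sq = ap.ca0max ** 2 / (np.exp(ap.b_len * (l - ap.l0)) - 1)
        expect = ap.tmax * ap.ca0 ** 2 / (ap.ca0 ** 2 + eca50_sq)
        got = mat.active_tension(ap.t0, lam, ap)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_frank_starling_monotone_in_stretch(self):
        ap = self.AP
        lams = np.linspace(ap.l0 / ap.lr + 1e-3, 2.3 / ap.lr, 40)
        ta = mat.active_tension(ap.t0, lams, ap)
        assert np.all(np.diff(ta) >= -1e-12)

    def test_bounded_by_tmax_over_cycle(self):
        ap = self.AP
        t = np.linspace(0, 1.0, 201)
        ta = mat.active_tension(t, np.full_like(t, 1.15), ap)
        assert np.all(ta >= 0.0)
        assert np.all(ta <= ap.tmax + 1e-12)

    def test_relaxation_ends(self):
        ap = self.AP
        lam = 1.1
        t_r = ap.m_relax * ap.lr * lam + ap.b_relax
        assert mat.active_tension(ap.t0 + t_r + 0.01, lam, ap) == 0.0


class TestTotalStress:
    def test_passive_limit(self):
        sig_p = np.diag([1.0, 2.0, 3.0])
        out = mat.total_cauchy(sig_p, 0.0, 0.25, E_F, E_S)
        assert np.allclose(out, sig_p)

    def test_eigen_spectrum_pure_active(self):
        out = mat.total_cauchy(np.zeros((3, 3)), 100.0, 0.25, E_F, E_S)
        w = np.sort(np.linalg.eigvalsh(out))
        assert np.allclose(w, [0.0, 25.0, 100.0])

    def test_fiber_projection_identity(self, rng):
        sig_p = rng.standard_normal((3, 3))
        sig_p = 0.5 * (sig_p + sig_p.T)
        Ta = 37.5
        out = mat.total_cauchy(sig_p, Ta, 0.25, E_F, E_S)
        assert E_F @ out @ E_F - E_F @ sig_p @ E_F == pytest.approx(Ta)

    def test_invalid_ns_rejected(self):
        with pytest.raises(ValueError):
            mat.total_cauchy(np.zeros((3, 3)), 1.0, 1.2, E_F, E_S)
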