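"""Analysis-metric tests on constructed fixtures."""

import numpy as np
import pytest

from bivent import metrics as M


def trapezoidal_pv_loop(n=200):
    """Synthetic LV loop with exact isovolumic segments.

    Phases: filling (V up, P low), isovolumic contraction (V const,
    P up), ejection (V down, P high), isovolumic relaxation (V const,
    P down).  Returns (V, P, i_ed_true, i_es_true).
    """
    q = n // 4
    V_fill = np.linspace(120, 250, q)
    P_fill = np.linspace(8, 14, q)
    V_ivc = np.full(q, 250.0)
    P_ivc = np.linspace(14, 90, q)
    V_ej = np.linspace(250, 120, q)
    P_ej = np.linspace(90, 100, q)
    V_ivr = np.full(n - 3 * q, 120.0)
    P_ivr = np.linspace(100, 8, n - 3 * q)
    V = np.concatenate([V_fill, V_ivc, V_ej, V_ivr])
    P = np.concatenate([P_fill, P_ivc, P_ej, P_ivr])
    return V, P, q - 1, 3 * q - 1


class TestDetectEdEs:
    def test_trapezoidal_loop_segment_starts(self):
        V, P, i_ed_true, i_es_true = trapezoidal_pv_loop()
        i_ed, i_es = M.detect_ed_es(V, P)
        assert abs(i_ed - i_ed_true) <= 2
        assert abs(i_es - i_es_true) <= 2
        assert V[i_ed] > V[i_es]

    def test_sinusoid_falls_back_to_extrema(self, caplog):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        V = 180 + 40 * np.sin(t)
        P = 50 + 40 * np.cos(t)
        with caplog.at_level("INFO"):
            i_ed, i_es = M.detect_ed_es(V, P)
        assert i_ed == np.argmax(V)
        assert i_es == np.argmin(V)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            M.detect_ed_es([1, 2, 3], [1, 2, 3])


class TestEjectionFraction:
    def test_reference_values(self):
        # the severely reduced EF of the dilated failing LV
        assert round(M.ejection_fraction(254, 224)) == 12

    def test_no_ejection(self):
        assert M.ejection_fraction(200, 200) == 0.0

    def test_co_unit_conversion(self):
        # 30 ml/s sustained systemic flow is 1.8 L/min
        assert 30.0 * 60.0 / 1000.0 == pytest.approx(1.8)

    def test_invalid_edv(self):
        with pytest.raises(ValueError):
            M.ejection_fraction(0.0, 10.0)


class TestSeptalShift:
    def test_collinear_markers_zero(self, fast_mesh):
        u = np.zeros_like(fast_mesh.nodes)
        mk = fast_mesh.markers
        a = fast_mesh.nodes[mk["junction_ant"]]
        b = fast_mesh.nodes[mk["junction_post"]]
        mid = fast_mesh.nodes[mk["septum_mid"]]
        # move the midpoint marker onto the junction line
        lam = 0.5
        u[mk["septum_mid"]] = (a + lam * (b - a)) - mid
        assert M.septal_shift(fast_mesh, u) == pytest.approx(0.0, abs=1e-9)

    def test_displacement_toward_lv_positive(self, fast_mesh):
        u = np.zeros_like(fast_mesh.nodes)
        mk = fast_mesh.markers
        base = M.septal_shift(fast_mesh, u)
        # direction from the midpoint toward the LV centroid at the base
        c = fast_mesh.nodes[fast_mesh.annulus_nodes].mean(axis=0)
        mid = fast_mesh.nodes[mk["septum_mid"]]
        d = c - mid
        d[2] = 0.0
        d = d / np.linalg.norm(d)
        u[mk["septum_mid"]] = 5.0 * d
        assert M.septal_shift(fast_mesh, u) - base == pytest.approx(
            5.0, rel=1e-6)

    def test_displacement_toward_rv_negative(self, fast_mesh):
        u = np.zeros_like(fast_mesh.nodes)
        mk = fast_mesh.markers
        base = M.septal_shift(fast_mesh, u)
        c = fast_mesh.nodes[fast_mesh.annulus_nodes].mean(axis=0)
        mid = fast_mesh.nodes[mk["septum_mid"]]
        d = c - mid
        d[2] = 0.0
        d = d / np.linalg.norm(d)
        u[mk["septum_mid"]] = -3.0 * d
        assert M.septal_shift(fast_mesh, u) - base == pytest.approx(
            -3.0, rel=1e-6)

    def test_missing_markers(self, fast_mesh):
        import dataclasses
        broken = dataclasses.replace(fast_mesh, markers={})
        with pytest.raises(ValueError, match="marker"):
            M.septal_shift(broken, np.zeros_like(fast_mesh.nodes))


class TestRegionalStress:
    def test_uniform_field(self):
        mean, sd = M.regional_stress_stats(
            np.full(10, 7.5), np.ones(10), np.ones(10, dtype=bool))
        assert mean == 7.5 and sd == 0.0

    def test_two_point_arithmetic(self):
        mean, sd = M.regional_stress_stats(
            np.array([0.0, 10.0]), np.array([1.0, 1.0]),
            np.array([True, True]))
        assert mean == 5.0 and sd == 5.0

    def test_matches_bruteforce_weighted_loop(self, rng):
        s = rng.normal(10, 4, size=50)
        v = rng.uniform(0.5, 2.0, size=50)
        mask = rng.uniform(size=50) > 0.3
        mean, sd = M.regional_stress_stats(s, v, mask)
        # independent scalar-loop oracle
        num = den = 0.0
        for si, vi, mi in zip(s, v, mask):
            if mi:
                num += si * vi
                den += vi
        mu = num / den
        acc = 0.0
        for si, vi, mi in zip(s, v, mask):
            if mi:
                acc += vi * (si - mu) ** 2
        assert mean == pytest.approx(mu, rel=1e-12)
        assert sd == pytest.approx(np.sqrt(acc / den), rel=1e-12)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            M.regional_stress_stats(np.ones(3), np.ones(3),
                                    np.zeros(3, dtype=bool))


class TestStressHistogram:
    def test_single_element_area_one(self):
        edges, dens = M.stress_histogram(np.array([5.0]), np.array([2.0]),
                                         bins=1)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0)

    def test_area_one_random_field(self, rng):
        s = rng.normal(size=300)
        v = rng.uniform(0.1, 3.0, size=300)
        edges, dens = M.stress_histogram(s, v, bins=25)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0,
                                                              abs=1e-9)

    def test_bimodal_field_two_peaks(self, rng):
        s = np.concatenate([rng.normal(-10, 1, 400),
                            rng.normal(10, 1, 400)])
        v = np.ones_like(s)
        edges, dens = M.stress_histogram(s, v, bins=40)
        # peaks: local maxima separated by a deep valley
        mid = len(dens) // 2
        assert dens[:mid].max() > 5 * dens[mid - 2:mid + 2].min()
        assert dens[mid:].max() > 5 * dens[mid - 2:mid + 2].min()

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            M.stress_histogram(np.array([1.0]), np.array([0.0]))
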