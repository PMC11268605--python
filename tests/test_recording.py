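"""Recording footprints (PSA/LSA) and eCAP reconstruction."""

import numpy as np
import pytest
from scipy.integrate import quad

from nervesim.errors import (AlignmentError, InvalidParameterError,
                             SingularityError)
from nervesim.fields import psa_footprint
from nervesim.materials import Material
from nervesim.recording import (Recorder, RecordingPoint, compute_ecap,
                                recorder_footprint_lsa,
                                recorder_footprint_psa)
from nervesim.solver import SimResult


def quad_psa_along_segment(point, x0, x1, y, z, sigma):
    """Independent oracle: numeric quadrature of point sources along
    the segment (V/A)."""
    px, py, pz = point
    r2 = ((y - py) * 1e-6) ** 2 + ((z - pz) * 1e-6) ** 2

    def integrand(x):
        d = np.sqrt(((x - px) * 1e-6) ** 2 + r2)
        return 1.0 / (4.0 * np.pi * sigma * d)

    val, _ = quad(integrand, x0, x1, limit=200)
    return val / (x1 - x0)


class TestRecorderFootprints:
    def test_psa_identical_to_stimulation_footprint(self):
        mat = Material(0.57, 0.085, 0.085)
        p = RecordingPoint((100.0, 200.0, -50.0))
        comp = (1500.0, 10.0, 5.0)
        assert recorder_footprint_psa(p, comp, mat) == pytest.approx(
            psa_footprint(comp, p.position, mat))

    def test_isotropic_closed_form(self):
        mat = Material.isotropic(0.2)
        p = RecordingPoint((0.0, 0.0, 0.0))
        fp = recorder_footprint_psa(p, (1000.0, 0.0, 0.0), mat)
        assert fp == pytest.approx(397.887, rel=1e-4)

    def test_lsa_matches_quadrature(self):
        sigma = 0.5
        mat = Material.isotropic(sigma)
        point = (300.0, 150.0, 0.0)
        seg = (250.0, 450.0, 20.0, -10.0)
        lsa = recorder_footprint_lsa(RecordingPoint(point), seg, mat)
        oracle = quad_psa_along_segment(point, seg[0], seg[1], seg[2],
                                        seg[3], sigma)
        assert lsa == pytest.approx(oracle, rel=5e-3)

    def test_lsa_far_field_converges_to_psa(self):
        sigma = 0.2
        mat = Material.isotropic(sigma)
        dl = 1.0
        seg = (0.0, dl, 0.0, 0.0)
        r = 150.0 * dl               # r > 100·Δl
        point = RecordingPoint((dl / 2.0, r, 0.0))
        lsa = recorder_footprint_lsa(point, seg, mat)
        psa = recorder_footprint_psa(point, (dl / 2.0, 0.0, 0.0), mat)
        assert lsa == pytest.approx(psa, rel=1e-3)

    def test_lsa_length_scaling(self):
        mat = Material.isotropic(1.0)
        p1 = recorder_footprint_lsa(RecordingPoint((0.0, 50.0, 0.0)),
                                    (10.0, 30.0, 0.0, 0.0), mat)
        p2 = recorder_footprint_lsa(RecordingPoint((0.0, 100.0, 0.0)),
                                    (20.0, 60.0, 0.0, 0.0), mat)
        assert p2 == pytest.approx(p1 / 2.0)

    def test_lsa_requires_isotropic(self):
        with pytest.raises(InvalidParameterError):
            recorder_footprint_lsa(RecordingPoint((0, 100, 0)),
                                   (0.0, 10.0, 0.0, 0.0),
                                   Material(0.5, 0.1, 0.1))

    def test_lsa_on_axis_singular(self):
        with pytest.raises(SingularityError):
            recorder_footprint_lsa(RecordingPoint((50.0, 0.0, 0.0)),
                                   (0.0, 10.0, 0.0, 0.0),
                                   Material.isotropic(1.0))


def _result(x, t, imem, y=0.0, z=0.0):
    return SimResult(t=t, x=x, I_mem=imem,
                     metadata={"fiber": {"y": y, "z": z}})


class TestComputeEcap:
    def test_single_compartment_constant_current(self):
        t = np.linspace(0, 1, 5)
        x = np.array([0.0])
        imem = np.full((5, 1), 2.0)           # µA
        rec = Recorder([(0.0, 1000.0, 0.0)], Material.isotropic(0.2))
        v = compute_ecap([_result(x, t, imem)], rec)
        # 2 µA × 397.89 V/A = 795.8 µV = 0.7958 mV, constant in time
        assert v.shape == (1, 5)
        assert v[0] == pytest.approx(np.full(5, 0.79577), rel=1e-3)

    def test_symmetric_opposite_currents_cancel(self):
        t = np.linspace(0, 1, 4)
        x = np.array([-100.0, 100.0])
        imem = np.tile([3.0, -3.0], (4, 1))
        rec = Recorder([(0.0, 500.0, 0.0)], Material.isotropic(1.0))
        v = compute_ecap([_result(x, t, imem)], rec)
        assert np.max(np.abs(v)) < 1e-12

    def test_linearity_in_currents(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 6)
        x = np.linspace(0, 900, 10)
        imem = rng.normal(size=(6, 10))
        rec = Recorder([(450.0, 300.0, 0.0), (900.0, 300.0, 0.0)],
                       Material.isotropic(0.3))
        v1 = compute_ecap([_result(x, t, imem)], rec)
        v2 = compute_ecap([_result(x, t, 2.0 * imem)], rec)
        assert v2 == pytest.approx(2.0 * v1)

    def test_superposition_over_fiber_subsets(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 1, 5)
        x = np.linspace(0, 500, 6)
        rec = Recorder([(250.0, 200.0, 0.0)], Material.isotropic(0.5))
        res = [_result(x, t, rng.normal(size=(5, 6)), y=30.0 * i)
               for i in range(4)]
        v_all = compute_ecap(res, rec)
        v_split = compute_ecap(res[:2], rec) + compute_ecap(res[2:], rec)
        assert v_all == pytest.approx(v_split)

    def test_time_grid_mismatch_raises(self):
        x = np.array([0.0])
        r1 = _result(x, np.linspace(0, 1, 5), np.zeros((5, 1)))
        r2 = _result(x, np.linspace(0, 2, 5), np.zeros((5, 1)))
        rec = Recorder([(0.0, 100.0, 0.0)], Material.isotropic(1.0))
        with pytest.raises(AlignmentError):
            compute_ecap([r1, r2], rec)

    def test_lsa_and_psa_agree_for_distant_recorder(self):
        # compartments much shorter than the recorder distance
        t = np.linspace(0, 1, 3)
        x = np.linspace(0, 90, 10)
        imem = np.tile(np.linspace(-1, 1, 10), (3, 1))
        mat = Material.isotropic(0.3)
        rec_psa = Recorder([(45.0, 4000.0, 0.0)], mat, method="psa")
        rec_lsa = Recorder([(45.0, 4000.0, 0.0)], mat, method="lsa")
        v_psa = compute_ecap([_result(x, t, imem)], rec_psa)
        v_lsa = compute_ecap([_result(x, t, imem)], rec_lsa)
        assert v_lsa == pytest.approx(v_psa, rel=1e-3)


class TestEcapGeometry:
    def test_peak_decreases_with_transverse_distance(
            self, myelinated_ap_result):
        fiber, result = myelinated_ap_result
        mat = Material.isotropic(0.2)
        mid = fiber.length / 2.0
        peaks = []
        for dist in (200.0, 500.0, 1500.0, 4000.0):
            rec = Recorder([(mid, dist, 0.0)], mat)
            v = compute_ecap([result], rec, fibers=[fiber])
            peaks.append(np.max(np.abs(v)))
        assert np.all(np.diff(peaks) < 0)

    def test_latency_slope_matches_conduction_velocity(
            self, myelinated_ap_result):
        from nervesim.solver import conduction_velocity
        fiber, result = myelinated_ap_result
        mat = Material.isotropic(0.2)
        xs = np.linspace(0.35, 0.75, 5) * fiber.length
        rec = Recorder([(x, 500.0, 0.0) for x in xs], mat)
        v = compute_ecap([result], rec, fibers=[fiber])
        t_peak = result.t[np.argmax(np.abs(v), axis=1)]
        slope = np.polyfit(xs, t_peak, 1)[0]      # ms/µm
        v_fit = 1.0 / slope * 1e-3                # m/s
        v_cv = conduction_velocity(result, xs[0], xs[-1])
        assert v_fit == pytest.approx(v_cv, rel=0.05)
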