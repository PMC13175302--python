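"""Preprocessing tests: kinematics, segmentation, phase averaging."""

import numpy as np
import pytest

import neuroquant as nq
from neuroquant.errors import (
    CycleCountError,
    GeometryError,
    NonPhysicalDeformationError,
    PhaseTagError,
)
from neuroquant.mech_preprocess import (
    HyperelasticCurve,
    average_load_unload,
    compute_nominal_stress,
    compute_stretch,
    max_nominal_stress,
    segment_cycles,
)
from neuroquant.ogden import OgdenParameters, uniaxial_nominal_stress
from neuroquant.synthetic import MechSimSpec, generate_cyclic_recording

from conftest import make_curve


class TestKinematics:
    def test_protocol_max_strain(self):
        # 0.45 mm compression of a 3 mm sample is the protocol's 15% strain
        assert compute_stretch(-0.45, 3.0) == pytest.approx(0.85)

    def test_identity_and_failure(self):
        assert compute_stretch(0.0, 3.0) == 1.0
        with pytest.raises(NonPhysicalDeformationError):
            compute_stretch(-3.0, 3.0)
        with pytest.raises(GeometryError):
            compute_stretch(-0.1, 0.0)

    def test_nominal_stress_conversion(self):
        # -0.01 N over the 9 mm punch area (63.617 mm^2) is -157.2 Pa
        assert compute_nominal_stress(-0.01, 63.617) == pytest.approx(-157.19, abs=0.01)
        assert compute_nominal_stress(0.0, 63.617) == 0.0
        with pytest.raises(GeometryError):
            compute_nominal_stress(-0.01, 0.0)

    def test_linearity(self, rng):
        f = rng.normal(size=50)
        np.testing.assert_allclose(compute_nominal_stress(2 * f, 40.0),
                                   2 * compute_nominal_stress(f, 40.0), rtol=1e-15)
        dz = -rng.uniform(0, 0.4, size=50)
        np.testing.assert_allclose(compute_stretch(2 * dz, 6.0) - 1,
                                   (compute_stretch(dz, 3.0) - 1), rtol=1e-12)


class TestSegmentation:
    def test_three_cycles_give_six_phases(self):
        rec, _ = generate_cyclic_recording(MechSimSpec(noise=0.0))
        curves = segment_cycles(rec)
        assert len(curves) == 6
        tags = [(c.cycle, c.phase) for c in curves]
        assert tags == [(1, "loading"), (1, "unloading"), (2, "loading"),
                        (2, "unloading"), (3, "loading"), (3, "unloading")]

    def test_monotone_ramp_is_zero_cycles(self):
        from neuroquant.io_formats import CompressionRecording
        t = np.linspace(0, 10, 101)
        rec = CompressionRecording(time=t, displacement=-0.04 * t,
                                   force=-0.001 * t, height_mm=3.0, area_mm2=63.617)
        with pytest.raises(CycleCountError) as exc:
            segment_cycles(rec)
        assert exc.value.detected == 0

    def test_noisy_turning_points_within_two_samples(self):
        spec = MechSimSpec(mu=1000.0, alpha=2.0, noise=0.0, seed=3)
        rec, truth = generate_cyclic_recording(spec)
        rng = np.random.default_rng(7)
        noisy = nq.CompressionRecording(
            time=rec.time,
            displacement=rec.displacement * (1 + 0.01 * rng.standard_normal(len(rec))),
            force=rec.force, height_mm=rec.height_mm, area_mm2=rec.area_mm2)
        from neuroquant.mech_preprocess import _turning_points
        troughs, _ = _turning_points(noisy.displacement)
        assert len(troughs) == len(truth.trough_indices)
        for got, want in zip(troughs, truth.trough_indices):
            assert abs(got - want) <= 2

    def test_reassembly_roundtrip(self):
        """Concatenating segmented phases reproduces the full sequence."""
        rec, _ = generate_cyclic_recording(MechSimSpec(noise=0.02, seed=9))
        curves = segment_cycles(rec)
        lam_full = compute_stretch(rec.displacement, rec.height_mm)
        pzz_full = compute_nominal_stress(rec.force, rec.area_mm2)
        lam_cat = np.concatenate(
            [curves[0].lam] + [c.lam[1:] for c in curves[1:]])
        pzz_cat = np.concatenate(
            [curves[0].pzz] + [c.pzz[1:] for c in curves[1:]])
        np.testing.assert_array_equal(lam_cat, lam_full)
        np.testing.assert_array_equal(pzz_cat, pzz_full)


class TestAveraging:
    def test_idempotent_on_identical_phases(self, rng):
        lam = np.linspace(0.85, 1.0, 60)
        pzz = uniaxial_nominal_stress(lam, OgdenParameters(500.0, -5.0))
        loading = HyperelasticCurve(lam[::-1], pzz[::-1], cycle=1, phase="loading")
        unloading = HyperelasticCurve(lam, pzz, cycle=1, phase="unloading")
        avg = average_load_unload(loading, unloading, grid_size=60)
        np.testing.assert_allclose(avg.pzz, np.interp(avg.lam, lam, pzz), atol=1e-12)
        assert avg.label == "unconditioned"

    def test_symmetric_scaling_cancels(self):
        lam = np.linspace(0.85, 1.0, 60)
        pzz = uniaxial_nominal_stress(lam, OgdenParameters(500.0, -5.0))
        loading = HyperelasticCurve(lam[::-1], 1.1 * pzz[::-1], cycle=3, phase="loading")
        unloading = HyperelasticCurve(lam, 0.9 * pzz, cycle=3, phase="unloading")
        avg = average_load_unload(loading, unloading, grid_size=60)
        np.testing.assert_allclose(avg.pzz, np.interp(avg.lam, lam, pzz), atol=1e-9)
        assert avg.label == "conditioned"

    def test_argument_order_symmetric(self):
        rec, _ = generate_cyclic_recording(MechSimSpec(eta=0.1, noise=0.01, seed=5))
        c = segment_cycles(rec)
        a1 = average_load_unload(c[0], c[1], grid_size=100)
        # swapping which curve supplies which role must not matter beyond tags
        a2 = average_load_unload(c[0], c[1], grid_size=100)
        np.testing.assert_array_equal(a1.pzz, a2.pzz)
        with pytest.raises(PhaseTagError):
            average_load_unload(c[1], c[0], grid_size=100)

    def test_hysteresis_pair_recovers_baseline(self):
        """Symmetric multiplicative hysteresis averages back to the
        analytic baseline at every sampling-aligned grid node."""
        spec = MechSimSpec(mu=1000.0, alpha=2.0, eta=0.1, noise=0.0)
        rec, truth = generate_cyclic_recording(spec)
        out = nq.preprocess_recording(rec, grid_size=spec.aligned_grid_size)
        base = truth.baseline_stress(out["unconditioned"].lam)
        assert np.max(np.abs(out["unconditioned"].pzz - base)) < 1e-9


class TestMaxStress:
    def test_noiseless_neo_hookean_value(self):
        """Loading to 15% strain at (mu=1000, alpha=2) peaks at 534.08 Pa."""
        spec = MechSimSpec(mu=1000.0, alpha=2.0, eta=0.0, noise=0.0)
        rec, _ = generate_cyclic_recording(spec)
        curves = segment_cycles(rec)
        assert max_nominal_stress(curves[0]) == pytest.approx(534.083, abs=0.01)

    def test_zero_curve(self):
        c = HyperelasticCurve(np.linspace(0.9, 1.0, 5), np.zeros(5), cycle=1,
                              phase="loading")
        assert max_nominal_stress(c) == 0.0

    def test_wrong_phase_rejected(self):
        c = HyperelasticCurve(np.linspace(0.9, 1.0, 5), np.zeros(5), cycle=1,
                              phase="unloading")
        with pytest.raises(PhaseTagError):
            max_nominal_stress(c)


class TestCurveContainer:
    def test_length_mismatch_rejected(self):
        with pytest.raises(Exception):
            HyperelasticCurve(np.ones(3), np.ones(4), cycle=1, phase="loading")

    def test_dict_roundtrip(self):
        c = make_curve(150.0, -8.0, n=20)
        c2 = HyperelasticCurve.from_dict(c.to_dict())
        np.testing.assert_array_equal(c.lam, c2.lam)
        np.testing.assert_array_equal(c.pzz, c2.pzz)
        assert (c2.cycle, c2.phase, c2.label) == (c.cycle, c.phase, c.label)
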