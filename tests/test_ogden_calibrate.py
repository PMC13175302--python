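"""Calibration tests: generate-and-refit oracles and fit-quality metrics."""

import numpy as np
import pytest

from neuroquant.errors import DegenerateDataError, ValidationError
from neuroquant.mech_preprocess import HyperelasticCurve
from neuroquant.ogden import OgdenParameters, uniaxial_nominal_stress
from neuroquant.ogden_calibrate import OgdenModel, fit_ogden, goodness_of_fit
from neuroquant.synthetic import MechSimSpec, generate_cyclic_recording

from conftest import make_curve


class TestGoodnessOfFit:
    def test_exact_model(self, neo_hookean_curve):
        chi2, rmse, r2 = goodness_of_fit(neo_hookean_curve, OgdenParameters(1000.0, 2.0))
        assert chi2 == pytest.approx(0.0, abs=1e-18)
        assert rmse == pytest.approx(0.0, abs=1e-10)
        assert r2 == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        """Residuals (2,-2,3,-3) -> chi2 = 26, RMSE = sqrt(6.5)."""
        data = np.array([-10.0, -20.0, -30.0, -40.0])
        model = np.array([-12.0, -18.0, -33.0, -37.0])
        lam = np.array([0.86, 0.90, 0.94, 0.98])
        resid = data - model
        chi2 = float(np.sum(resid**2))
        assert chi2 == 26.0
        # verify the module computes the same through its own path:
        # build a curve whose data are "data" and a parameter set whose
        # prediction equals "model" is not generally available, so check
        # the metric arithmetic directly against a fitted prediction
        curve = HyperelasticCurve(lam, data, cycle=1, phase="averaged")
        params = OgdenParameters(150.0, 2.0)
        pred = uniaxial_nominal_stress(lam, params)
        chi2_mod, rmse_mod, r2_mod = goodness_of_fit(curve, params)
        assert chi2_mod == pytest.approx(float(np.sum((data - pred) ** 2)), rel=1e-12)
        assert rmse_mod == pytest.approx(np.sqrt(chi2_mod / 4), rel=1e-12)
        tss = float(np.sum((data - data.mean()) ** 2))
        assert r2_mod == pytest.approx(1 - chi2_mod / tss, rel=1e-12)
        assert np.sqrt(26.0 / 4.0) == pytest.approx(2.5495, abs=1e-4)

    def test_permutation_invariance(self, rng, neo_hookean_curve):
        order = rng.permutation(len(neo_hookean_curve))
        shuffled = HyperelasticCurve(neo_hookean_curve.lam[order],
                                     neo_hookean_curve.pzz[order],
                                     cycle=1, phase="averaged")
        p = OgdenParameters(900.0, 2.5)
        assert goodness_of_fit(shuffled, p) == pytest.approx(
            goodness_of_fit(neo_hookean_curve, p))

    def test_constant_data_r2_flagged(self):
        lam = np.linspace(0.9, 1.0, 10)
        curve = HyperelasticCurve(lam, np.full(10, -5.0), cycle=1, phase="averaged")
        _, _, r2 = goodness_of_fit(curve, OgdenParameters(100.0, 2.0))
        assert np.isnan(r2)


class TestFit:
    @pytest.mark.parametrize("mu", [50.0, 150.0, 500.0])
    @pytest.mark.parametrize("alpha", [-20.0, -8.0, 2.0, 10.0])
    def test_clean_recovery_grid(self, mu, alpha):
        res = OgdenModel(make_curve(mu, alpha)).fit()
        assert res.mu == pytest.approx(mu, rel=1e-3)
        assert res.alpha == pytest.approx(alpha, rel=1e-3)
        assert res.r2 > 0.999999

    def test_neo_hookean_alpha_band(self):
        res = OgdenModel(make_curve(200.0, 2.0)).fit()
        assert 1.99 <= res.alpha <= 2.01

    def test_sharp_negative_alpha(self):
        res = OgdenModel(make_curve(200.0, -15.0)).fit()
        assert res.mu == pytest.approx(200.0, rel=1e-3)
        assert res.alpha == pytest.approx(-15.0, rel=1e-3)

    def test_global_basin_starts_agree(self):
        """Starts reaching the global basin give objectives within 1e-8.

        (Starts trapped in the wrong-sign alpha branch or a secondary
        local minimum legitimately end elsewhere; the returned fit is
        the best of all starts.)
        """
        res = OgdenModel(make_curve(150.0, -15.0)).fit()
        basin = [s["chi2"] for s in res.starts
                 if s["success"] and s["chi2"] < 1e-6]
        assert len(basin) >= 2
        assert max(basin) - min(basin) < 1e-8

    def test_reported_chi2_matches_direct_sum(self):
        curve = make_curve(300.0, -12.0)
        noisy = HyperelasticCurve(curve.lam,
                                  curve.pzz * (1 + 0.03 * np.sin(np.arange(100))),
                                  cycle=1, phase="averaged")
        res = OgdenModel(noisy).fit()
        direct = float(np.sum(
            (noisy.pzz - uniaxial_nominal_stress(noisy.lam, res.params)) ** 2))
        assert res.chi2 == pytest.approx(direct, rel=1e-10)
        assert res.rmse == pytest.approx(np.sqrt(direct / res.n), rel=1e-10)

    def test_degenerate_zero_curve(self):
        lam = np.linspace(0.85, 1.0, 30)
        with pytest.raises(DegenerateDataError):
            OgdenModel(HyperelasticCurve(lam, np.zeros(30), cycle=1, phase="averaged"))

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            OgdenModel(make_curve(100.0, 2.0, n=4))

    def test_e_app_is_three_mu(self):
        res = OgdenModel(make_curve(150.0, -10.0)).fit()
        assert res.e_app == pytest.approx(3 * res.mu, rel=1e-14)

    def test_summary_mentions_estimates(self):
        res = OgdenModel(make_curve(150.0, -10.0)).fit()
        text = res.summary()
        assert "mu" in text and "E_app" in text and "R^2" in text

    def test_fit_ogden_wrapper_with_config(self):
        from neuroquant.io_formats import RunConfig
        res = fit_ogden(make_curve(150.0, -10.0), RunConfig())
        assert res.mu == pytest.approx(150.0, rel=1e-3)

    def test_from_recording_headline_cycle(self):
        """Fitting straight from a raw recording recovers the truth, and
        the conditioned cycle recovers the softened shear modulus."""
        spec = MechSimSpec(mu=300.0, alpha=-8.0, eta=0.1, conditioning=0.85,
                           noise=0.0)
        rec, _ = generate_cyclic_recording(spec)
        res1 = OgdenModel.from_recording(rec, cycle=1,
                                         grid_size=spec.aligned_grid_size).fit()
        res3 = OgdenModel.from_recording(rec, cycle=3,
                                         grid_size=spec.aligned_grid_size).fit()
        assert res1.mu == pytest.approx(300.0, rel=1e-3)
        assert res3.mu == pytest.approx(0.85 * 300.0, rel=1e-3)


class TestNoisyRecovery:
    def test_moderate_noise_bias_and_spread(self):
        """5% multiplicative noise: mu estimates stay tight and unbiased.

        A reduced-replicate version of the full stochastic check (which
        runs in the acceptance suite at 200 replicates).
        """
        mus = []
        for seed in range(30):
            spec = MechSimSpec(mu=150.0, alpha=-15.0, noise=0.05, seed=seed)
            rec, _ = generate_cyclic_recording(spec)
            res = OgdenModel.from_recording(rec, cycle=1,
                                            grid_size=spec.aligned_grid_size).fit()
            mus.append(res.mu)
        mus = np.asarray(mus)
        rel_rmse = np.sqrt(np.mean((mus - 150.0) ** 2)) / 150.0
        assert rel_rmse < 0.10
        assert abs(np.median(mus) - 150.0) / 150.0 < 0.03
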