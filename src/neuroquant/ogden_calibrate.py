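"""Calibration of the one-term modified Ogden model to averaged curves.

Exposes a statsmodels-style pair: :class:`OgdenModel` is built from a
:class:`~neuroquant.mech_preprocess.HyperelasticCurve` (or directly from
stretch/stress arrays) and its :meth:`~OgdenModel.fit` returns an
:class:`OgdenResults` carrying the estimates (mu, alpha), the objective
chi^2 = sum of squared stress residuals (Pa^2), RMSE, R^2, the derived
apparent Young's modulus E_app = 3*mu, and a start-point audit trail.

The optimizer is bounded trust-region nonlinear least squares
(scipy.optimize.least_squares, method="trf").  mu is constrained to
(1e-3, 1e7) Pa; the parameterization is singular at alpha = 0, so alpha
is explored as two bounded sub-problems [-50, -0.01] and [0.01, 50],
seeded from a small multi-start grid (the objective is mildly
multimodal in alpha).  The initial mu for every start is the
small-strain secant slope of the data divided by 3, clipped to bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateDataError, ValidationError
from .mech_preprocess import HyperelasticCurve
from .ogden import ALPHA_MIN, OgdenParameters, apparent_young_modulus, uniaxial_nominal_stress

__all__ = ["OgdenModel", "OgdenResults", "FitResult", "fit_ogden", "goodness_of_fit"]

DEFAULT_ALPHA_STARTS = (-20.0, -5.0, 2.0, 10.0)
DEFAULT_MU_BOUNDS = (1e-3, 1e7)
DEFAULT_ALPHA_LIMIT = 50.0


def goodness_of_fit(curve: HyperelasticCurve, params: OgdenParameters):
    """(chi2, rmse, r2) of a parameter set against a measured curve.

    chi2 is the plain sum of squared stress residuals in Pa^2,
    RMSE = sqrt(chi2 / n), and R^2 = 1 - chi2 / TSS.  For constant data
    the total sum of squares vanishes and R^2 is reported as NaN.
    All three are invariant under permutation of the data points.
    """
    if len(curve) == 0:
        raise ValidationError("empty curve", field="curve")
    model = uniaxial_nominal_stress(curve.lam, params)
    resid = curve.pzz - model
    chi2 = float(np.sum(resid**2))
    rmse = float(np.sqrt(chi2 / len(curve)))
    tss = float(np.sum((curve.pzz - curve.pzz.mean()) ** 2))
    r2 = 1.0 - chi2 / tss if tss > 0 else float("nan")
    return chi2, rmse, r2


@dataclass
class OgdenResults:
    """Fit results for the one-term modified Ogden model.

    Attributes
    ----------
    params : OgdenParameters
        Estimated (mu, alpha).
    chi2, rmse, r2 : float
        Objective value (Pa^2), root-mean-squared stress error (Pa),
        coefficient of determination.
    e_app : float
        Apparent Young's modulus 3*mu (Pa).
    starts : list of dict
        Audit: every multi-start initial guess with its final objective.
    """

    model: "OgdenModel"
    params: OgdenParameters
    chi2: float
    rmse: float
    r2: float
    n: int
    converged: bool
    starts: list = field(default_factory=list)

    @property
    def mu(self) -> float:
        return self.params.mu

    @property
    def alpha(self) -> float:
        return self.params.alpha

    @property
    def e_app(self) -> float:
        return apparent_young_modulus(self.params.mu).e_app

    def predict(self, lam=None):
        """Model nominal stress on ``lam`` (defaults to the fitted grid)."""
        lam = self.model.curve.lam if lam is None else np.asarray(lam, dtype=float)
        return uniaxial_nominal_stress(lam, self.params)

    def plot(self, ax=None):
        """Data vs fitted stress over stretch (matplotlib, optional)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        curve = self.model.curve
        ax.plot(curve.lam, curve.pzz, "o", ms=3, alpha=0.6, label="data")
        grid = np.linspace(curve.lam.min(), curve.lam.max(), 200)
        ax.plot(grid, self.predict(grid), "-",
                label=f"Ogden fit (mu={self.mu:.1f} Pa, alpha={self.alpha:.2f})")
        ax.set_xlabel("stretch lambda [-]")
        ax.set_ylabel("nominal stress Pzz [Pa]")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        lines = [
            "One-term modified Ogden fit (incompressible, uniaxial)",
            "=" * 56,
            f"{'n points':<28}{self.n:>10d}",
            f"{'curve label':<28}{self.model.curve.label:>10}",
            f"{'shear modulus mu [Pa]':<28}{self.mu:>12.4f}",
            f"{'nonlinearity alpha [-]':<28}{self.alpha:>12.4f}",
            f"{'apparent modulus E_app [Pa]':<28}{self.e_app:>12.4f}",
            f"{'chi^2 [Pa^2]':<28}{self.chi2:>12.4e}",
            f"{'RMSE [Pa]':<28}{self.rmse:>12.4e}",
            f"{'R^2 [-]':<28}{self.r2:>12.6f}",
            f"{'converged':<28}{str(self.converged):>10}",
            f"{'multi-starts':<28}{len(self.starts):>10d}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mu_pa": self.mu,
            "alpha": self.alpha,
            "e_app_pa": self.e_app,
            "nu": 0.5,
            "chi2_pa2": self.chi2,
            "rmse_pa": self.rmse,
            "r2": self.r2,
            "n": self.n,
            "converged": self.converged,
            "label": self.model.curve.label,
            "starts": self.starts,
        }


#: Backwards-compatible alias: the fit-result record of the calibration step.
FitResult = OgdenResults


class OgdenModel:
    """Nonlinear least-squares calibration problem for one averaged curve.

    Parameters
    ----------
    curve : HyperelasticCurve
        An averaged stress-stretch curve with at least 5 points and
        stretches within (0, 1.5).  Headline (reported) values
        conventionally come from the unconditioned (cycle-1) curve;
        conditioned (cycle-3) fits are computed the same way.
    alpha_starts : sequence of float
        Multi-start initial alphas; the sign of each start selects the
        negative or positive bounded alpha sub-problem.
    mu_bounds, alpha_limit
        Box constraints: mu in ``mu_bounds`` (Pa), |alpha| in
        [ALPHA_MIN, alpha_limit].
    """

    def __init__(self, curve: HyperelasticCurve,
                 alpha_starts=DEFAULT_ALPHA_STARTS,
                 mu_bounds=DEFAULT_MU_BOUNDS,
                 alpha_limit: float = DEFAULT_ALPHA_LIMIT,
                 tolerance: float = 1e-12):
        if len(curve) < 5:
            raise ValidationError(f"need >= 5 points to fit, got {len(curve)}",
                                  field="curve")
        if np.any(curve.lam <= 0) or np.any(curve.lam >= 1.5):
            raise ValidationError("stretch values must lie in (0, 1.5)", field="lam")
        if np.all(curve.pzz == 0):
            raise DegenerateDataError(
                "all-zero stress curve: mu > 0 cannot produce zero stress, "
                "the shear modulus is unidentifiable", field="pzz")
        self.curve = curve
        self.alpha_starts = tuple(alpha_starts)
        self.mu_bounds = tuple(mu_bounds)
        self.alpha_limit = float(alpha_limit)
        self.tolerance = float(tolerance)

    @classmethod
    def from_arrays(cls, lam, pzz, **kwargs) -> "OgdenModel":
        curve = HyperelasticCurve(lam=np.asarray(lam, float), pzz=np.asarray(pzz, float),
                                  cycle=1, phase="averaged", label="none")
        return cls(curve, **kwargs)

    @classmethod
    def from_recording(cls, recording, cycle: int = 1, grid_size: int = 100,
                       expected_cycles: int = 3, **kwargs) -> "OgdenModel":
        """Build the fitting problem straight from a raw cyclic recording."""
        from .mech_preprocess import average_load_unload, segment_cycles
        phases = segment_cycles(recording, expected_cycles=expected_cycles)
        loading = next(c for c in phases if c.cycle == cycle and c.phase == "loading")
        unloading = next(c for c in phases if c.cycle == cycle and c.phase == "unloading")
        return cls(average_load_unload(loading, unloading, grid_size), **kwargs)

    # -- fitting --------------------------------------------------------

    def _initial_mu(self) -> float:
        """Small-strain secant slope / 3, clipped into the mu bounds."""
        order = np.argsort(self.curve.lam)
        lam = self.curve.lam[order]
        pzz = self.curve.pzz[order]
        span = lam[-1] - lam[0]
        if span <= 0:
            return float(np.clip(100.0, *self.mu_bounds))
        slope = (pzz[-1] - pzz[0]) / span
        return float(np.clip(slope / 3.0, *self.mu_bounds))

    def _residual(self, x):
        mu, alpha = x
        return self.curve.pzz - uniaxial_nominal_stress(
            self.curve.lam, OgdenParameters(mu=mu, alpha=alpha))

    def fit(self) -> OgdenResults:
        """Run all multi-starts and return the best bounded NLS solution."""
        mu0 = self._initial_mu()
        best = None
        starts_audit = []
        for a0 in self.alpha_starts:
            if a0 < 0:
                bounds = ([self.mu_bounds[0], -self.alpha_limit],
                          [self.mu_bounds[1], -ALPHA_MIN])
            else:
                bounds = ([self.mu_bounds[0], ALPHA_MIN],
                          [self.mu_bounds[1], self.alpha_limit])
            a0c = float(np.clip(a0, bounds[0][1], bounds[1][1]))
            sol = least_squares(
                self._residual, x0=[mu0, a0c], bounds=bounds, method="trf",
                xtol=self.tolerance, ftol=self.tolerance, gtol=self.tolerance,
            )
            cost = 2.0 * sol.cost  # least_squares cost is 0.5 * chi2
            starts_audit.append({"mu0": mu0, "alpha0": a0c,
                                 "chi2": float(cost), "success": bool(sol.success)})
            if sol.success and (best is None or cost < best[0]):
                best = (cost, sol)
        if best is None:
            raise DegenerateDataError("no multi-start converged", field="fit")
        _, sol = best
        params = OgdenParameters(mu=float(sol.x[0]), alpha=float(sol.x[1]))
        chi2, rmse, r2 = goodness_of_fit(self.curve, params)
        return OgdenResults(model=self, params=params, chi2=chi2, rmse=rmse, r2=r2,
                            n=len(self.curve), converged=True, starts=starts_audit)


def fit_ogden(curve: HyperelasticCurve, config=None) -> OgdenResults:
    """Functional wrapper: calibrate (mu, alpha) to an averaged curve.

    ``config`` may be a RunConfig-like object providing ``alpha_starts``,
    ``mu_bounds``, ``alpha_limit`` and ``fit_tolerance``.
    """
    kwargs = {}
    if config is not None:
        kwargs = {
            "alpha_starts": getattr(config, "alpha_starts", DEFAULT_ALPHA_STARTS),
            "mu_bounds": getattr(config, "mu_bounds", DEFAULT_MU_BOUNDS),
            "alpha_limit": getattr(config, "alpha_limit", DEFAULT_ALPHA_LIMIT),
            "tolerance": getattr(config, "fit_tolerance", 1e-12),
        }
    return OgdenModel(curve, **kwargs).fit()
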