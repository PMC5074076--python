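"""Hill P_app–F' regression and inter-assay permeability calibration.

The empirical relationship between apparent permeability and the
equilibrium fraction F' is sigmoidal on log P_app and is modelled by the
Hill equation

    F'(P) = Emax * P^a / (b^a + P^a)

where ``a`` is the slope factor and ``b`` the permeability at which F'
reaches half its asymptote.  In the constrained form (the default) the
asymptote Emax is fixed at 1, matching the mechanistic meaning of F' as a
fraction of equilibrium.  Observed F' values, however, derive from noisy
clinical clearances and can exceed 1, so :class:`HillCurve` can also
estimate the asymptote (``fix_asymptote=False``); only (a, b) are carried
forward in either case.

Calibration maps permeabilities measured in one assay onto the scale the
mechanistic model was built against.  Two Hill curves are fitted: (a1, b1)
against the model-predicted F' of the full drug panel, and (a2, b2)
against the observed F' of a small reference ("calibrator") subset.  A
measured P_app is then translated by matching Hill quantiles:

    P_calibrated = b1 * (P / b2)^(a2 / a1)

which is exactly hill^{-1}_{(a1,b1)} ∘ hill_{(a2,b2)} — feeding the
calibrated permeability to the predicted-side curve reproduces the
observed-side curve's F' estimate. The map is strictly increasing and
sends b2 to b1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .model import ReabsorptionModel, observed_freab_prime
from .physiology import NephronPhysiology

__all__ = [
    "FitError",
    "HillCurve",
    "HillFit",
    "PappCalibrator",
    "hill_freab_prime",
    "fit_hill",
    "calibrate_papp",
    "run_calibrated_prediction",
]


class FitError(RuntimeError):
    """Nonlinear regression failed to converge; carries solver diagnostics."""


def hill_freab_prime(papp, a: float, b: float):
    """Hill prediction F' = P^a / (b^a + P^a); equals 0.5 at P = b."""
    papp = np.asarray(papp, float)
    if np.any(papp <= 0) or a <= 0 or b <= 0:
        raise ValueError("papp, a and b must all be > 0")
    r = (papp / b) ** a
    return r / (1.0 + r)


@dataclass(frozen=True)
class HillFit:
    """Frozen result of a Hill fit (functional interface)."""

    a: float
    b: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    residual_sse: float
    n: int
    source: str = ""
    emax: float = 1.0


class HillCurve(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares Hill fit of F' against P_app.

    Parameters
    ----------
    fix_asymptote : bool, default True
        Fit the two-parameter curve with Emax = 1 (the mechanistic form).
        With ``False`` the asymptote is estimated as a third parameter;
        appropriate for observed F' data, which can stray beyond 1.
    a0, b0 : float, optional
        Starting values; ``b0`` defaults to the median permeability.

    Attributes
    ----------
    a_, b_ : float
        Slope factor and half-maximal permeability (1e-6 cm/s).
    emax_ : float
        Fitted (or fixed) asymptote.
    ci95_a_, ci95_b_ : (float, float)
        Asymptotic 95% confidence intervals (t-based, from the J'J
        covariance at the optimum).
    residual_sse_ : float
    n_ : int
    """

    #: solver bounds for (a, b[, emax])
    A_BOUNDS = (1e-6, 20.0)
    B_BOUNDS = (1e-6, 1000.0)
    EMAX_BOUNDS = (1e-6, 10.0)

    def __init__(self, fix_asymptote: bool = True, a0: float = 2.0, b0: float | None = None):
        self.fix_asymptote = fix_asymptote
        self.a0 = a0
        self.b0 = b0

    def fit(self, X, y):
        """Fit to permeabilities ``X`` (1d, 1e-6 cm/s) and F' values ``y``.

        Negative or >1 F' values are included as-is.
        """
        x = np.asarray(X, float).ravel()
        y = np.asarray(y, float).ravel()
        if x.size != y.size:
            raise ValueError("X and y must have the same length")
        n_par = 2 if self.fix_asymptote else 3
        if x.size < n_par + 1:
            raise ValueError(f"need at least {n_par + 1} points")
        if np.any(x <= 0):
            raise ValueError("permeabilities must be > 0")

        b0 = self.b0 if self.b0 is not None else float(np.median(x))
        if self.fix_asymptote:
            theta0 = np.array([self.a0, b0])
            lo = [self.A_BOUNDS[0], self.B_BOUNDS[0]]
            hi = [self.A_BOUNDS[1], self.B_BOUNDS[1]]

            def resid(t):
                return hill_freab_prime(x, t[0], t[1]) - y

        else:
            theta0 = np.array([self.a0, b0, 1.0])
            lo = [self.A_BOUNDS[0], self.B_BOUNDS[0], self.EMAX_BOUNDS[0]]
            hi = [self.A_BOUNDS[1], self.B_BOUNDS[1], self.EMAX_BOUNDS[1]]

            def resid(t):
                return t[2] * hill_freab_prime(x, t[0], t[1]) - y

        sol = optimize.least_squares(resid, theta0, bounds=(lo, hi))
        if not sol.success:
            raise FitError(f"Hill fit did not converge: {sol.message}")

        self.a_, self.b_ = float(sol.x[0]), float(sol.x[1])
        self.emax_ = float(sol.x[2]) if not self.fix_asymptote else 1.0
        self.residual_sse_ = float(2.0 * sol.cost)
        self.n_ = int(x.size)

        # asymptotic covariance: s^2 (J'J)^-1, t-based 95% intervals
        dof = max(self.n_ - n_par, 1)
        s2 = self.residual_sse_ / dof
        try:
            cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(n_par, np.nan)
        tq = stats.t.ppf(0.975, dof)
        self.ci95_a_ = (self.a_ - tq * se[0], self.a_ + tq * se[0])
        self.ci95_b_ = (self.b_ - tq * se[1], self.b_ + tq * se[1])
        return self

    def predict(self, X):
        return self.emax_ * hill_freab_prime(X, self.a_, self.b_)

    def result(self, source: str = "") -> HillFit:
        return HillFit(
            a=self.a_,
            b=self.b_,
            ci95_a=self.ci95_a_,
            ci95_b=self.ci95_b_,
            residual_sse=self.residual_sse_,
            n=self.n_,
            source=source,
            emax=self.emax_,
        )


def fit_hill(points, fix_asymptote: bool = True, source: str = "") -> HillFit:
    """Fit the Hill curve to ``(papp, freab_prime)`` pairs."""
    pts = np.asarray(points, float)
    return (
        HillCurve(fix_asymptote=fix_asymptote)
        .fit(pts[:, 0], pts[:, 1])
        .result(source)
    )


def calibrate_papp(papp, fit_pred: HillFit, fit_obs: HillFit):
    """Translate measured P_app via the two Hill fits (see module docstring)."""
    papp = np.asarray(papp, float)
    if np.any(papp <= 0):
        raise ValueError("papp must be > 0")
    return fit_pred.b * (papp / fit_obs.b) ** (fit_obs.a / fit_pred.a)


class PappCalibrator(TransformerMixin, BaseEstimator):
    """Inter-assay P_app calibration against a reference drug subset.

    ``fit`` takes the full drug table (DataFrame with ``drug``,
    ``papp_1e6_cm_s``, ``fu_p`` and ``clr_obs_ml_min`` columns) and the
    reference drug names, then fits

    * ``fit_pred_``: constrained Hill vs the mechanistic model's predicted
      F' over *all* drugs in the table (the predicted-side curve is a
      property of the model, not of the reference choice), and
    * ``fit_obs_``: free-asymptote Hill vs the observed F' of the
      reference drugs only.

    ``transform`` maps measured permeabilities to calibrated ones.

    Parameters
    ----------
    reference : sequence of str, optional
        Reference drug names; defaults to the packaged 11-drug set.
    model : ReabsorptionModel, optional
        Mechanistic model supplying predicted F'; defaults to the full
        variant with default physiology.
    """

    def __init__(self, reference=None, model: ReabsorptionModel | None = None):
        self.reference = reference
        self.model = model

    def _reference_names(self) -> list[str]:
        if self.reference is not None:
            return list(self.reference)
        from .dataset import load_reference_set

        return [d["drug"] for _, d in load_reference_set().drugs.iterrows()]

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("PappCalibrator.fit expects a drug DataFrame")
        required = {"drug", "papp_1e6_cm_s", "fu_p", "clr_obs_ml_min"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")

        model = self.model if self.model is not None else ReabsorptionModel()
        model.fit(X)
        phys = model.physiology_

        names = X["drug"].astype(str)
        ref = self._reference_names()
        mask = names.isin(ref)
        if mask.sum() < len(ref):
            absent = sorted(set(ref) - set(names))
            raise ValueError(f"reference drugs missing from table: {absent}")
        self.reference_ = sorted(ref)
        self.validation_ = sorted(set(names) - set(ref))

        papp = X["papp_1e6_cm_s"].to_numpy(float)
        fp_pred = model.predict_freab_prime(X)
        self.fit_pred_ = (
            HillCurve(fix_asymptote=True).fit(papp, fp_pred).result("predicted")
        )

        ref_papp = papp[mask.to_numpy()]
        fp_obs = observed_freab_prime(
            X.loc[mask, "clr_obs_ml_min"].to_numpy(float),
            X.loc[mask, "fu_p"].to_numpy(float),
            gfr=phys.gfr,
            urine_flow=phys.urine_flow,
        )
        self.fit_obs_ = (
            HillCurve(fix_asymptote=False).fit(ref_papp, fp_obs).result("observed")
        )

        if ref_papp.min() > papp.min() * 10 or ref_papp.max() < papp.max() / 10:
            warnings.warn(
                "reference drugs do not span the permeability range of the "
                "full dataset; calibration will extrapolate",
                stacklevel=2,
            )
        return self

    def transform(self, X):
        """Calibrate permeabilities (1d array or drug DataFrame)."""
        if isinstance(X, pd.DataFrame):
            papp = X["papp_1e6_cm_s"].to_numpy(float)
        else:
            papp = np.asarray(X, float).ravel()
        return calibrate_papp(papp, self.fit_pred_, self.fit_obs_)


def run_calibrated_prediction(
    drugs: pd.DataFrame,
    physiology: NephronPhysiology | None = None,
    calibrator: PappCalibrator | None = None,
) -> pd.DataFrame:
    """Full-panel prediction on calibrated permeabilities.

    Fits the calibrator on ``drugs`` (if not already fitted), replaces each
    drug's P_app with its calibrated value, and re-runs the full mechanistic
    model.  Returns the detail table with an ``in_validation_set`` flag
    (reference drugs are predicted with their own calibrated values too).
    """
    model = ReabsorptionModel(physiology=physiology, variant="calibrated")
    if calibrator is None:
        calibrator = PappCalibrator(model=ReabsorptionModel(physiology=physiology))
    if not hasattr(calibrator, "fit_obs_"):
        calibrator.fit(drugs)
    calibrated = drugs.copy()
    calibrated["papp_calibrated_1e6_cm_s"] = calibrator.transform(drugs)
    inputs = calibrated.assign(papp_1e6_cm_s=calibrated["papp_calibrated_1e6_cm_s"])
    detail = model.fit(inputs).predict_detail(inputs)
    detail["papp_calibrated_1e6_cm_s"] = calibrated["papp_calibrated_1e6_cm_s"].to_numpy()
    detail["in_validation_set"] = (
        ~drugs["drug"].astype(str).isin(calibrator.reference_).to_numpy()
    )
    return detail
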