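"""Minimal 5-compartment model of passive renal tubular reabsorption.

Renal excretion clearance is decomposed as

    CL_R = CL_R,filt + CL_R,sec * (1 - F_reab)

with active secretion CL_R,sec fixed at zero for the drug space this model
addresses (net-secreted drugs are screened out upstream by the clearance
ratio).  Filtration clearance is CL_R,filt = GFR * f_u,p.

Reabsorption is scaled from in vitro permeability by in vitro–in vivo
extrapolation (IVIVE).  For each tubular region i the intrinsic
reabsorption clearance is

    CL_int,i = P_app * TSA_i            (unit-converted to mL/min)

and the fraction of the plasma–urine unbound-concentration equilibrium
reached within the region is

    F'_i = CL_int,i / (TFR_i + CL_int,i).

Regions act in series on the remaining disequilibrium:

    F' = 1 - prod_i (1 - F'_i)

F' (0..1) maps to the fraction reabsorbed through the urine-flow floor —
even at full equilibrium the urine still carries drug out at
UF * f_u,p mL/min:

    F_reab = F' * (CL_filt - UF * f_u,p) / CL_filt
    CL_R   = CL_filt * (1 - F_reab) = CL_filt - F' * (CL_filt - UF * f_u,p)

so predictions are bounded by UF * f_u,p <= CL_R <= GFR * f_u,p.

Model variants
--------------
``full``            all four regions, microvilli-corrected surface areas
``filtration_only`` F' = 0 (CL_R = GFR * f_u,p)
``pt_only``         only the proximal tubule contributes
``no_microvilli``   open-cylinder areas (LoH/DT/CD TSA x microvilli factor)
``calibrated``      full model on inter-assay calibrated P_app (see
                    :mod:`renalreab.calibration`)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .physiology import (
    NephronPhysiology,
    apply_microvilli_correction,
    default_physiology,
)

__all__ = [
    "VARIANTS",
    "PredictionResult",
    "ReabsorptionModel",
    "filtration_clearance",
    "regional_clint",
    "regional_freab_prime",
    "overall_freab_prime",
    "freab_from_prime",
    "freab_prime_from_freab",
    "predict_clr",
    "clearance_ratio",
    "is_net_secreted",
    "observed_freab",
    "observed_freab_prime",
]

VARIANTS = ("filtration_only", "full", "pt_only", "no_microvilli", "calibrated")

#: P_app is supplied in 1e-6 cm/s and TSA in m^2; their product converts to
#: mL/min as 1e-6 cm/s * 1e4 cm^2/m^2 * 60 s/min = 0.6.
PAPP_TSA_TO_ML_MIN = 1e-6 * 1e4 * 60.0

NET_SECRETION_CUTOFF = 1.5


def filtration_clearance(fu_p: float, gfr: float) -> float:
    """CL_R,filt = GFR * f_u,p (mL/min)."""
    fu_p, gfr = np.asarray(fu_p, float), np.asarray(gfr, float)
    if np.any(fu_p <= 0) or np.any(fu_p > 1):
        raise ValueError("fu_p must be in (0, 1]")
    if np.any(gfr <= 0):
        raise ValueError("gfr must be > 0")
    return fu_p * gfr


def regional_clint(papp: float, tsa: float) -> float:
    """Regional intrinsic reabsorption clearance (mL/min).

    ``papp`` in 1e-6 cm/s, ``tsa`` in m^2.
    """
    papp, tsa = np.asarray(papp, float), np.asarray(tsa, float)
    if np.any(papp <= 0) or np.any(tsa <= 0):
        raise ValueError("papp and tsa must be > 0")
    return papp * tsa * PAPP_TSA_TO_ML_MIN


def regional_freab_prime(clint: float, tfr: float) -> float:
    """Fraction of equilibrium reached in one region: CL/(TFR + CL)."""
    clint, tfr = np.asarray(clint, float), np.asarray(tfr, float)
    if np.any(clint < 0):
        raise ValueError("clint must be >= 0")
    if np.any(tfr <= 0):
        raise ValueError("tfr must be > 0")
    return clint / (tfr + clint)


def overall_freab_prime(regional) -> float:
    """Combine regional F'_i in series: 1 - prod(1 - F'_i)."""
    regional = np.asarray(regional, float)
    return 1.0 - np.prod(1.0 - regional, axis=-1)


def freab_from_prime(
    freab_prime: float, clr_filt: float, fu_p: float, urine_flow: float
) -> float:
    """Map the equilibrium fraction F' to the fraction reabsorbed F_reab."""
    floor = np.asarray(urine_flow, float) * np.asarray(fu_p, float)
    clr_filt = np.asarray(clr_filt, float)
    if np.any(clr_filt <= floor):
        raise ValueError("degenerate physiology: CL_filt <= UF * fu_p")
    return np.asarray(freab_prime, float) * (clr_filt - floor) / clr_filt


def freab_prime_from_freab(
    freab: float, clr_filt: float, fu_p: float, urine_flow: float
) -> float:
    """Inverse of :func:`freab_from_prime` (exact round trip)."""
    floor = np.asarray(urine_flow, float) * np.asarray(fu_p, float)
    clr_filt = np.asarray(clr_filt, float)
    if np.any(clr_filt <= floor):
        raise ValueError("degenerate physiology: CL_filt <= UF * fu_p")
    return np.asarray(freab, float) * clr_filt / (clr_filt - floor)


def clearance_ratio(clr_obs: float, clr_filt: float) -> float:
    """Observed CL_R over filtration clearance."""
    clr_filt = np.asarray(clr_filt, float)
    if np.any(clr_filt <= 0):
        raise ValueError("clr_filt must be > 0")
    return np.asarray(clr_obs, float) / clr_filt


def is_net_secreted(ratio: float) -> bool:
    """Net-secretion screen: strictly above the 1.5 clearance-ratio cut-off."""
    return np.asarray(ratio, float) > NET_SECRETION_CUTOFF


def observed_freab(clr_obs: float, clr_filt: float) -> float:
    """Observed fraction reabsorbed, 1 - CL_R/CL_filt.

    May be negative (observed CL_R above filtration); negatives are kept
    for all numerical analyses and only clamped for presentation.
    """
    return 1.0 - clearance_ratio(clr_obs, clr_filt)


def observed_freab_prime(
    clr_obs: float, fu_p: float, gfr: float = 120.0, urine_flow: float = 1.0
) -> float:
    """Observed equilibrium fraction F' derived from clinical CL_R."""
    clf = filtration_clearance(fu_p, gfr)
    return freab_prime_from_freab(
        observed_freab(clr_obs, clf), clf, fu_p, urine_flow
    )


@dataclass
class PredictionResult:
    """Per-drug output of the reabsorption model."""

    name: str
    variant: str
    clint_by_region: dict[str, float]
    freab_prime_by_region: dict[str, float]
    freab_prime: float
    freab: float
    clr_filt: float
    clr_pred: float


def _variant_physiology(physiology: NephronPhysiology, variant: str) -> NephronPhysiology:
    if variant == "no_microvilli":
        return apply_microvilli_correction(physiology, enabled=False)
    return physiology


def predict_clr(
    drug, physiology: NephronPhysiology | None = None, variant: str = "full"
) -> PredictionResult:
    """Predict CL_R for one drug record.

    ``drug`` is any mapping/namespace with ``name`` (optional), ``papp``
    (1e-6 cm/s) and ``fu_p``.  The ``calibrated`` variant expects ``papp``
    to already be the calibrated permeability and otherwise behaves as
    ``full``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if physiology is None:
        physiology = default_physiology()
    get = drug.get if hasattr(drug, "get") else lambda k, d=None: getattr(drug, k, d)
    name = get("name", "") or get("drug", "")
    papp = float(get("papp"))
    fu_p = float(get("fu_p"))

    phys = _variant_physiology(physiology, variant)
    clf = float(filtration_clearance(fu_p, phys.gfr))

    clint = {}
    fpi = {}
    for region in phys.regions:
        if variant == "filtration_only":
            clint[region.name] = 0.0
            fpi[region.name] = 0.0
            continue
        if variant == "pt_only" and region.name != "PT":
            clint[region.name] = 0.0
            fpi[region.name] = 0.0
            continue
        ci = float(regional_clint(papp, region.tsa))
        clint[region.name] = ci
        fpi[region.name] = float(regional_freab_prime(ci, region.tfr))

    fp = float(overall_freab_prime(list(fpi.values())))
    fr = float(freab_from_prime(fp, clf, fu_p, phys.urine_flow))
    clr_pred = clf * (1.0 - fr)
    return PredictionResult(
        name=name,
        variant=variant,
        clint_by_region=clint,
        freab_prime_by_region=fpi,
        freab_prime=fp,
        freab=fr,
        clr_filt=clf,
        clr_pred=clr_pred,
    )


class ReabsorptionModel(RegressorMixin, BaseEstimator):
    """Mechanistic CL_R predictor over a drug table.

    A scikit-learn-style estimator: the model has no free parameters fitted
    from data — ``fit`` validates the inputs and freezes the physiology —
    but the estimator interface lets it slot into pipelines and be composed
    with :class:`renalreab.calibration.PappCalibrator`.

    Parameters
    ----------
    physiology : NephronPhysiology, optional
        System parameters; defaults to the adult human set.
    variant : str
        One of ``("filtration_only", "full", "pt_only", "no_microvilli",
        "calibrated")``.

    Attributes
    ----------
    physiology_ : NephronPhysiology
        The (variant-resolved) physiology frozen at fit time.

    Examples
    --------
    >>> import pandas as pd
    >>> X = pd.DataFrame({"papp_1e6_cm_s": [81.12], "fu_p": [0.67]})
    >>> ReabsorptionModel().fit(X).predict(X).round(2)
    array([7.25])
    """

    def __init__(
        self,
        physiology: NephronPhysiology | None = None,
        variant: str = "full",
    ):
        self.physiology = physiology
        self.variant = variant

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _columns(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Extract (names, papp, fu_p) from a DataFrame or 2-column array."""
        if isinstance(X, pd.DataFrame):
            missing = {"papp_1e6_cm_s", "fu_p"} - set(X.columns)
            if missing:
                raise ValueError(f"missing required columns: {sorted(missing)}")
            names = (
                X["drug"].to_numpy(dtype=object)
                if "drug" in X.columns
                else np.array([""] * len(X), dtype=object)
            )
            papp = X["papp_1e6_cm_s"].to_numpy(float)
            fu = X["fu_p"].to_numpy(float)
        else:
            arr = np.asarray(X, float)
            if arr.ndim != 2 or arr.shape[1] < 2:
                raise ValueError(
                    "X must be a DataFrame with papp_1e6_cm_s/fu_p columns "
                    "or an array with >= 2 columns (papp, fu_p)"
                )
            names = np.array([""] * len(arr), dtype=object)
            papp, fu = arr[:, 0], arr[:, 1]
        if np.any(~np.isfinite(papp)) or np.any(papp <= 0):
            raise ValueError("papp must be finite and > 0")
        if np.any(~np.isfinite(fu)) or np.any(fu <= 0) or np.any(fu > 1):
            raise ValueError("fu_p must be finite and in (0, 1]")
        return names, papp, fu

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self._columns(X)
        base = self.physiology if self.physiology is not None else default_physiology()
        self.physiology_ = _variant_physiology(base, self.variant)
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted CL_R (mL/min), one value per row of ``X``."""
        return self.predict_detail(X)["clr_pred"].to_numpy()

    def predict_detail(self, X) -> pd.DataFrame:
        """Full per-drug breakdown, one row per input drug.

        Columns: drug, variant, clint_* and freab_prime_* per region,
        freab_prime, freab, clr_filt, clr_pred, and fold_error where the
        input carries an observed clearance column ``clr_obs_ml_min``.
        """
        if not hasattr(self, "physiology_"):
            self.fit(X)
        names, papp, fu = self._columns(X)
        rows = []
        for n, p, f in zip(names, papp, fu):
            res = predict_clr(
                {"name": n, "papp": p, "fu_p": f},
                self.physiology_,
                # physiology_ is already variant-resolved; avoid double
                # application of the microvilli toggle
                "full" if self.variant == "no_microvilli" else self.variant,
            )
            row = {"drug": n, "variant": self.variant}
            for reg, v in res.clint_by_region.items():
                row[f"clint_{reg.lower()}"] = v
            for reg, v in res.freab_prime_by_region.items():
                row[f"freab_prime_{reg.lower()}"] = v
            row.update(
                freab_prime=res.freab_prime,
                freab=res.freab,
                clr_filt=res.clr_filt,
                clr_pred=res.clr_pred,
            )
            rows.append(row)
        out = pd.DataFrame(rows)
        if isinstance(X, pd.DataFrame) and "clr_obs_ml_min" in X.columns:
            obs = X["clr_obs_ml_min"].to_numpy(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                out["fold_error"] = np.where(
                    obs > 0,
                    np.maximum(out["clr_pred"] / obs, obs / out["clr_pred"]),
                    np.nan,
                )
        return out

    def predict_freab_prime(self, X) -> np.ndarray:
        """Predicted overall equilibrium fraction F' per drug."""
        return self.predict_detail(X)["freab_prime"].to_numpy()
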