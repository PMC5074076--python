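"""Prediction-performance metrics and stratified reporting.

The headline bias metric is the geometric mean fold error

    gmfe = 10 ^ mean(|log10(pred/obs)|)

which is >= 1, symmetric under swapping predicted and observed, and does
not let over- and under-predictions cancel.  Success is summarised as the
percentage of drugs predicted within k-fold (default 3-fold, boundary
inclusive) of observed.  Precision is reported as RMSE on both the log10
scale and the raw mL/min scale; goodness of the predicted-vs-observed
linear regression as its ordinary-least-squares R^2.

Reports are stratified by ionisation class and by the observed extent of
reabsorption: low (F_reab < 0.25), medium (0.25 <= F_reab <= 0.75) and
high (F_reab > 0.75); negative observed F_reab values fall in "low".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvaluationReport",
    "gmfe",
    "rmse_log",
    "rmse_linear",
    "pct_within_fold",
    "r_squared",
    "freab_category",
    "evaluate",
]

FREAB_LOW = 0.25
FREAB_HIGH = 0.75


def _pairs(pred, obs, what: str = "") -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, float).ravel()
    o = np.asarray(obs, float).ravel()
    if p.size != o.size:
        raise ValueError("pred and obs must have the same length")
    if p.size == 0:
        raise ValueError("need at least one (pred, obs) pair")
    bad = np.flatnonzero((p <= 0) | (o <= 0) | ~np.isfinite(p) | ~np.isfinite(o))
    if bad.size:
        raise ValueError(
            f"non-positive or non-finite value at index {bad[0]}"
            + (f" ({what})" if what else "")
        )
    return p, o


def gmfe(pred, obs) -> float:
    """Geometric mean fold error; 1.0 iff every prediction is exact."""
    p, o = _pairs(pred, obs, "gmfe")
    return float(10 ** np.mean(np.abs(np.log10(p / o))))


def rmse_log(pred, obs) -> float:
    """Root mean squared error of log10 predictions (dimensionless)."""
    p, o = _pairs(pred, obs, "rmse_log")
    return float(np.sqrt(np.mean((np.log10(o) - np.log10(p)) ** 2)))


def rmse_linear(pred, obs) -> float:
    """Root mean squared error on the mL/min scale."""
    p = np.asarray(pred, float).ravel()
    o = np.asarray(obs, float).ravel()
    if p.size != o.size or p.size == 0:
        raise ValueError("need matched, non-empty pred/obs")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def pct_within_fold(pred, obs, k: float = 3.0) -> float:
    """Percent of drugs with max(pred/obs, obs/pred) <= k (boundary counts)."""
    p, o = _pairs(pred, obs, "pct_within_fold")
    return float(100.0 * np.mean(np.maximum(p / o, o / p) <= k))


def r_squared(pred, obs) -> float:
    """R^2 of the ordinary least-squares regression of predicted on observed."""
    p = np.asarray(pred, float).ravel()
    o = np.asarray(obs, float).ravel()
    if p.size < 3:
        return float("nan")
    return float(stats.linregress(o, p).rvalue ** 2)


def freab_category(freab_obs) -> np.ndarray:
    """Assign low / medium / high reabsorption categories."""
    f = np.asarray(freab_obs, float)
    return np.where(
        f < FREAB_LOW, "low", np.where(f > FREAB_HIGH, "high", "medium")
    )


@dataclass
class EvaluationReport:
    """Overall and stratified prediction-performance summary."""

    n: int
    r2: float
    n_within_3fold: int
    pct_within_3fold: float
    gmfe: float
    rmse_linear: float
    rmse_log: float
    strata: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        overall = pd.DataFrame(
            [
                {
                    "stratum": "all",
                    "n": self.n,
                    "r2": self.r2,
                    "n_within_3fold": self.n_within_3fold,
                    "pct_within_3fold": self.pct_within_3fold,
                    "gmfe": self.gmfe,
                    "rmse_linear": self.rmse_linear,
                    "rmse_log": self.rmse_log,
                }
            ]
        )
        return pd.concat([overall, self.strata], ignore_index=True)


def _metrics_row(stratum: str, pred: np.ndarray, obs: np.ndarray) -> dict:
    n = len(pred)
    if n == 0:
        return {
            "stratum": stratum,
            "n": 0,
            "r2": np.nan,
            "n_within_3fold": np.nan,
            "pct_within_3fold": np.nan,
            "gmfe": np.nan,
            "rmse_linear": np.nan,
            "rmse_log": np.nan,
        }
    within = int(np.sum(np.maximum(pred / obs, obs / pred) <= 3.0))
    return {
        "stratum": stratum,
        "n": n,
        "r2": r_squared(pred, obs),
        "n_within_3fold": within,
        "pct_within_3fold": 100.0 * within / n,
        "gmfe": gmfe(pred, obs),
        "rmse_linear": rmse_linear(pred, obs),
        "rmse_log": rmse_log(pred, obs),
    }


def evaluate(
    pred,
    obs,
    ion_class=None,
    freab_obs=None,
) -> EvaluationReport:
    """Build the full report: overall plus per-class and per-category strata.

    ``ion_class`` (strings) and ``freab_obs`` (observed fractions
    reabsorbed, negatives allowed) are optional stratification keys; empty
    strata are reported with NaN metrics rather than zeros.
    """
    p, o = _pairs(pred, obs, "evaluate")
    rows = []
    if ion_class is not None:
        ic = np.asarray(ion_class, dtype=object)
        if ic.size != p.size:
            raise ValueError("ion_class length mismatch")
        for cls in ("Neutral", "Acid", "Base", "Zwitterion", "Amphoteric"):
            m = ic == cls
            rows.append(_metrics_row(f"ion:{cls}", p[m], o[m]))
    if freab_obs is not None:
        cat = freab_category(freab_obs)
        if cat.size != p.size:
            raise ValueError("freab_obs length mismatch")
        for lvl in ("low", "medium", "high"):
            m = cat == lvl
            rows.append(_metrics_row(f"freab:{lvl}", p[m], o[m]))
    overall = _metrics_row("all", p, o)
    return EvaluationReport(
        n=overall["n"],
        r2=overall["r2"],
        n_within_3fold=overall["n_within_3fold"],
        pct_within_3fold=overall["pct_within_3fold"],
        gmfe=overall["gmfe"],
        rmse_linear=overall["rmse_linear"],
        rmse_log=overall["rmse_log"],
        strata=pd.DataFrame(rows),
    )
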