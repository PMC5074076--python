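"""Clinical renal-clearance statistics: pooling and heterogeneity screening.

Clearances reported per study are pooled across studies of the same drug
with subject-number weights:

    WX = sum(n_j * x_j) / sum(n_j)
    sigma = sqrt( [sum((sigma_j^2 + x_j^2) n_j) - sum(n_j) WX^2] / sum(n_j) )

(the printed pooled-SD form is a population SD; it equals the plain SD of
the per-subject expansion in which study j contributes n_j subjects at mean
x_j and within-study variance sigma_j^2).

Between-study heterogeneity is screened with Cochran's Q and the I^2
statistic:

    Q  = sum_i w_i (y_i - y_hat)^2,  w_i = 1/sigma_i^2,
         y_hat the inverse-variance weighted mean
    I2 = 100% * (Q - df) / Q,  df = n_studies - 1, clamped to [0, 100].

Drugs with I^2 above 0.5 (fractional scale) are flagged for inspection and
above 0.75 flagged as very heterogeneous; anomalous studies were excluded
by eye in the source workflow, so this module ranks studies by their
standardized deviation from the pooled mean rather than auto-excluding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "clr_from_urine",
    "clr_from_rate",
    "denormalise",
    "weighted_mean",
    "weighted_sd",
    "cochran_q",
    "i_squared",
    "heterogeneity_report",
    "HIGH_HETEROGENEITY",
    "VERY_HIGH_HETEROGENEITY",
]

#: fractional I^2 screening thresholds
HIGH_HETEROGENEITY = 0.5
VERY_HIGH_HETEROGENEITY = 0.75

NORMALISATIONS = ("absolute", "per_kg", "per_1.73m2")


@dataclass(frozen=True)
class StudyRecord:
    """One clinical study arm: mean CL_R, its SD and the subject count."""

    drug: str
    mean_clr: float
    sd_clr: float
    n_subjects: int
    normalisation: str = "absolute"
    body_weight: float | None = None
    bsa: float | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sd_clr < 0:
            raise ValueError("sd_clr must be >= 0")
        if self.normalisation not in NORMALISATIONS:
            raise ValueError(f"normalisation must be one of {NORMALISATIONS}")


def clr_from_urine(amount_excreted: float, auc: float) -> float:
    """CL_R from cumulative urinary data: amount excreted / plasma AUC.

    With amount in mass units and AUC in mass*min/mL the quotient is
    mL/min.
    """
    if auc <= 0:
        raise ValueError("auc must be > 0")
    if amount_excreted < 0:
        raise ValueError("amount_excreted must be >= 0")
    return amount_excreted / auc


def clr_from_rate(excretion_rate: float, cp_midpoint: float) -> float:
    """CL_R from a urinary excretion rate and the mid-interval plasma level."""
    if cp_midpoint <= 0:
        raise ValueError("cp_midpoint must be > 0")
    if excretion_rate < 0:
        raise ValueError("excretion_rate must be >= 0")
    return excretion_rate / cp_midpoint


def denormalise(
    record: StudyRecord,
    assumed_weight: float = 70.0,
    assumed_bsa: float = 1.73,
) -> StudyRecord:
    """Convert weight- or BSA-normalised clearances to absolute mL/min.

    Studies reporting mL/min/kg are scaled by the study body weight (or the
    assumed 70 kg); mL/min/1.73m^2 by bsa/1.73 (identity when BSA is
    unreported, since the standard BSA is assumed).
    """
    if record.normalisation == "absolute":
        return record
    if record.normalisation == "per_kg":
        scale = record.body_weight if record.body_weight is not None else assumed_weight
    else:  # per_1.73m2
        scale = (record.bsa if record.bsa is not None else assumed_bsa) / 1.73
    return StudyRecord(
        drug=record.drug,
        mean_clr=record.mean_clr * scale,
        sd_clr=record.sd_clr * scale,
        n_subjects=record.n_subjects,
        normalisation="absolute",
        body_weight=record.body_weight,
        bsa=record.bsa,
    )


def _unpack(studies) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(studies) == 0:
        raise ValueError("need at least one study")
    means = np.array([s.mean_clr for s in studies], float)
    sds = np.array([s.sd_clr for s in studies], float)
    ns = np.array([s.n_subjects for s in studies], float)
    return means, sds, ns


def weighted_mean(studies) -> float:
    """Subject-number weighted mean clearance across studies."""
    means, _, ns = _unpack(studies)
    return float(np.sum(ns * means) / np.sum(ns))


def weighted_sd(studies) -> float:
    """Pooled (population-form) SD across studies; see module docstring."""
    means, sds, ns = _unpack(studies)
    wx = np.sum(ns * means) / np.sum(ns)
    radicand = (np.sum((sds**2 + means**2) * ns) - np.sum(ns) * wx**2) / np.sum(ns)
    if radicand < 0:
        if radicand < -1e-9 * max(wx**2, 1.0):
            warnings.warn(
                f"negative pooled-variance radicand {radicand:g} clamped to 0",
                stacklevel=2,
            )
        radicand = 0.0
    return float(np.sqrt(radicand))


def cochran_q(studies) -> float:
    """Cochran's heterogeneity statistic (inverse-variance weights)."""
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    means, sds, _ = _unpack(studies)
    if np.any(sds <= 0):
        raise ValueError("every study needs sd_clr > 0 for heterogeneity screening")
    w = 1.0 / sds**2
    yhat = np.sum(w * means) / np.sum(w)
    return float(np.sum(w * (means - yhat) ** 2))


def i_squared(studies) -> float:
    """I^2 heterogeneity on the percent scale, clamped to [0, 100]."""
    q = cochran_q(studies)
    df = len(studies) - 1
    if q <= 0:
        return 0.0
    return float(np.clip(100.0 * (q - df) / q, 0.0, 100.0))


def heterogeneity_report(studies) -> pd.DataFrame:
    """Rank studies by standardized deviation from the pooled mean.

    Supports the visual anomaly screen for drugs whose I^2 exceeds the 0.5
    fractional threshold; no study is excluded automatically.
    """
    means, sds, ns = _unpack(studies)
    pooled = weighted_mean(studies)
    with np.errstate(divide="ignore"):
        z = np.where(sds > 0, np.abs(means - pooled) / sds, np.inf)
    df = pd.DataFrame(
        {
            "drug": [s.drug for s in studies],
            "mean_clr": means,
            "sd_clr": sds,
            "n_subjects": ns.astype(int),
            "pooled_mean": pooled,
            "std_deviation_score": z,
        }
    )
    return df.sort_values("std_deviation_score", ascending=False).reset_index(drop=True)
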