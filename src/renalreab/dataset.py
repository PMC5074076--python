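"""Packaged drug datasets and a synthetic drug-set generator.

Two fixtures ship with the package:

* the 45-drug evaluation panel (clinical CL_R, Caco-2 P_app measured under
  an apical pH 6.5 / basolateral pH 7.4 gradient, plasma unbound fraction,
  pKa/LogD annotations and ionisation class), and
* the 11-drug calibration reference list, a subset of the panel chosen to
  span the permeability and reabsorption range.

Where the reference table prints a drug's permeability at higher precision
than the panel table, the fixture stores the higher-precision value (the
two agree to printed precision in every case).

The synthetic generator draws drug panels from the mechanistic model
itself (or from a supplied Hill curve) with multiplicative log-normal
noise on the observed clearance; it exists for property tests and power
exploration, not to mimic any particular chemical series.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .model import ReabsorptionModel, filtration_clearance
from .physiology import default_physiology

__all__ = [
    "DrugDataset",
    "load_table2",
    "load_reference_set",
    "generate_synthetic",
    "export_fixtures",
]

_PANEL_SHA256 = "c38d1b3867ee620ca5ac2924218b7074f4a550f1fac35dffdeb6823855fd8969"
_REFERENCE_SHA256 = "a334eb36b126ede5d6a772e838f58eb33cf8adba8e6da134f1aee778c95e96b0"

CSV_COLUMNS = [
    "drug",
    "papp_1e6_cm_s",
    "fu_p",
    "clr_obs_ml_min",
    "ion_class",
    "logd74",
    "logd65",
    "pka_acid",
    "pka_base",
    "transporter",
]


@dataclass(frozen=True)
class DrugDataset:
    """A drug panel: records plus provenance."""

    drugs: pd.DataFrame
    provenance: str  # {"table2", "table5_reference", "synthetic"}
    seed: int | None = None

    def __post_init__(self) -> None:
        names = self.drugs["drug"]
        if names.duplicated().any():
            raise ValueError("drug names must be unique")

    def __len__(self) -> int:
        return len(self.drugs)


def _read_packaged(name: str, expected_sha256: str) -> bytes:
    raw = resources.files("renalreab.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected_sha256:
        raise IOError(
            f"packaged fixture {name} is corrupted "
            f"(sha256 {digest}, expected {expected_sha256})"
        )
    return raw


def load_table2() -> DrugDataset:
    """Load the packaged 45-drug evaluation panel."""
    import io

    raw = _read_packaged("table2.csv", _PANEL_SHA256)
    df = pd.read_csv(io.BytesIO(raw), dtype={"pka_acid": str, "pka_base": str})
    if len(df) != 45:
        raise IOError(f"expected 45 drugs, found {len(df)}")
    return DrugDataset(drugs=df, provenance="table2")


def reference_drug_names() -> list[str]:
    """Names of the 11 calibration reference drugs."""
    raw = _read_packaged("reference_drugs.txt", _REFERENCE_SHA256)
    return [ln for ln in raw.decode().splitlines() if ln.strip()]


def load_reference_set() -> DrugDataset:
    """Load the 11 reference drugs (a subset of the evaluation panel)."""
    names = reference_drug_names()
    panel = load_table2().drugs
    sub = panel[panel["drug"].isin(names)].reset_index(drop=True)
    if len(sub) != 11:
        raise IOError(
            f"reference list expects 11 panel drugs, matched {len(sub)}"
        )
    return DrugDataset(drugs=sub, provenance="table5_reference")


def generate_synthetic(
    n: int,
    seed: int,
    hill_a: float | None = None,
    hill_b: float | None = None,
    noise_sd: float = 0.3,
    fu_range: tuple[float, float] = (0.05, 1.0),
    papp_range: tuple[float, float] = (0.1, 300.0),
) -> DrugDataset:
    """Draw a synthetic drug panel from the mechanistic model.

    Permeabilities are log-uniform over ``papp_range`` (1e-6 cm/s,
    spanning the ~3 orders of magnitude of real Caco-2 panels) and unbound
    fractions uniform over ``fu_range``.  The true equilibrium fraction F'
    comes from the full mechanistic model under default physiology, or
    from the Hill curve when both ``hill_a`` and ``hill_b`` are given.
    Observed CL_R is the noiseless prediction times exp(N(0, noise_sd))
    — multiplicative log-normal noise, natural-log scale; the default 0.3
    corresponds to the roughly 30% between-study coefficient of variation
    typical of pooled clinical clearances.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = fu_range
    if not (0 < lo < hi <= 1):
        raise ValueError("fu_range must satisfy 0 < lo < hi <= 1")
    plo, phi = papp_range
    if not (0 < plo < phi):
        raise ValueError("papp_range must satisfy 0 < lo < hi")
    if (hill_a is None) != (hill_b is None):
        raise ValueError("supply both hill_a and hill_b, or neither")

    rng = np.random.default_rng(seed)
    papp = np.exp(rng.uniform(np.log(plo), np.log(phi), size=n))
    fu = rng.uniform(lo, hi, size=n)

    phys = default_physiology()
    df = pd.DataFrame(
        {
            "drug": [f"synthetic_{i:04d}" for i in range(n)],
            "papp_1e6_cm_s": papp,
            "fu_p": fu,
        }
    )
    if hill_a is not None:
        from .calibration import hill_freab_prime

        fp = hill_freab_prime(papp, hill_a, hill_b)
    else:
        fp = ReabsorptionModel(physiology=phys).fit(df).predict_freab_prime(df)

    clf = filtration_clearance(fu, phys.gfr)
    clr_true = clf - fp * (clf - phys.urine_flow * fu)
    noise = np.exp(rng.normal(0.0, noise_sd, size=n)) if noise_sd > 0 else 1.0
    df["clr_obs_ml_min"] = clr_true * noise
    for col in CSV_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return DrugDataset(drugs=df[CSV_COLUMNS], provenance="synthetic", seed=seed)


def export_fixtures(out_dir) -> list[str]:
    """Write the packaged fixtures to ``out_dir``; returns the paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, sha in [
        ("table2.csv", _PANEL_SHA256),
        ("reference_drugs.txt", _REFERENCE_SHA256),
    ]:
        raw = _read_packaged(name, sha)
        path = os.path.join(out_dir, name)
        with open(path, "wb") as fh:
            fh.write(raw)
        written.append(path)
    return written


def parse_pka_list(value) -> tuple[float, ...]:
    """Parse a semicolon-separated pKa cell ('' or NaN -> empty)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ()
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return ()
    return tuple(float(tok) for tok in s.split(";") if tok.strip())
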