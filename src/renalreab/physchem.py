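"""Ionisation-state classification at urinary pH and LogD adjustment.

Tubular reabsorption happens against a filtrate that is typically more
acidic (pH ~6.5) than plasma (pH 7.4), so a drug's ionisation state and
lipophilicity are assessed at pH 6.5.  Sites are treated as independent
Henderson–Hasselbalch centres: an acidic site with pKa_a is deprotonated
with probability 10^(pH-pKa_a)/(1+10^(pH-pKa_a)) and a basic site with
pKa_b protonated with probability 10^(pKa_b-pH)/(1+10^(pKa_b-pH)).
Microstate probabilities are the products of the per-site terms.

Classification rules (at pH 6.5):

* >50% of the population un-ionised             -> Neutral
* otherwise, by the most probable ionised microstate:
  only acidic sites ionised                     -> Acid
  only basic sites ionised                      -> Base
  both kinds ionised, net charge zero           -> Zwitterion
  anything else (e.g. net-charged mixed states) -> Amphoteric

LogD at pH 6.5 is estimated from LogD_7.4 assuming only the neutral
species partitions into octanol; for a monoprotic acid/base the shift is
the log-ratio of the un-ionised fractions at the two pH values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "IonisationProfile",
    "fraction_unionised",
    "microstate_fractions",
    "classify_ionisation",
    "ionisation_profile",
    "logd65_from_logd74",
    "URINE_PH",
    "PLASMA_PH",
]

URINE_PH = 6.5
PLASMA_PH = 7.4

ION_CLASSES = ("Neutral", "Acid", "Base", "Zwitterion", "Amphoteric")


@dataclass(frozen=True)
class IonisationProfile:
    pka_acids: tuple[float, ...]
    pka_bases: tuple[float, ...]
    fraction_unionised_65: float
    major_species_charge: int
    ion_class: str


def _site_ionised_fractions(
    pka_acids: Sequence[float], pka_bases: Sequence[float], ph: float
) -> tuple[list[float], list[float]]:
    f_acid = [10 ** (ph - pka) / (1 + 10 ** (ph - pka)) for pka in pka_acids]
    f_base = [10 ** (pka - ph) / (1 + 10 ** (pka - ph)) for pka in pka_bases]
    return f_acid, f_base


def fraction_unionised(
    pka_acids: Sequence[float] = (),
    pka_bases: Sequence[float] = (),
    ph: float = URINE_PH,
) -> float:
    """Probability that every ionisable centre is in its neutral form."""
    f_acid, f_base = _site_ionised_fractions(pka_acids, pka_bases, ph)
    out = 1.0
    for f in itertools.chain(f_acid, f_base):
        out *= 1.0 - f
    return out


def microstate_fractions(
    pka_acids: Sequence[float] = (),
    pka_bases: Sequence[float] = (),
    ph: float = URINE_PH,
) -> dict[tuple[int, ...], float]:
    """Probability of each ionisation microstate.

    Keys are tuples of site states (acids first, then bases; 1 = ionised),
    values sum to 1.
    """
    f_acid, f_base = _site_ionised_fractions(pka_acids, pka_bases, ph)
    fs = f_acid + f_base
    out: dict[tuple[int, ...], float] = {}
    for states in itertools.product((0, 1), repeat=len(fs)):
        p = 1.0
        for s, f in zip(states, fs):
            p *= f if s else (1.0 - f)
        out[states] = p
    return out


def classify_ionisation(
    pka_acids: Sequence[float] = (),
    pka_bases: Sequence[float] = (),
    ph: float = URINE_PH,
) -> str:
    """Assign the ionisation class at ``ph`` (see module docstring)."""
    n_acid = len(pka_acids)
    micro = microstate_fractions(pka_acids, pka_bases, ph)
    neutral_state = tuple([0] * (len(pka_acids) + len(pka_bases)))
    if micro.get(neutral_state, 1.0) > 0.5:
        return "Neutral"
    ionised = {s: p for s, p in micro.items() if s != neutral_state}
    major = max(ionised, key=ionised.get)
    acid_ionised = sum(major[:n_acid])
    base_ionised = sum(major[n_acid:])
    if base_ionised == 0:
        return "Acid"
    if acid_ionised == 0:
        return "Base"
    if base_ionised - acid_ionised == 0:
        return "Zwitterion"
    return "Amphoteric"


def ionisation_profile(
    pka_acids: Sequence[float] = (),
    pka_bases: Sequence[float] = (),
    ph: float = URINE_PH,
) -> IonisationProfile:
    """Full ionisation assessment at ``ph``."""
    micro = microstate_fractions(pka_acids, pka_bases, ph)
    n_acid = len(pka_acids)
    major = max(micro, key=micro.get)
    charge = int(sum(major[n_acid:]) - sum(major[:n_acid]))
    return IonisationProfile(
        pka_acids=tuple(pka_acids),
        pka_bases=tuple(pka_bases),
        fraction_unionised_65=fraction_unionised(pka_acids, pka_bases, ph),
        major_species_charge=charge,
        ion_class=classify_ionisation(pka_acids, pka_bases, ph),
    )


def _shift_pka(pkas: Sequence[float]) -> float:
    """pKa used for the LogD shift: the one nearest the 6.5–7.4 window."""
    mid = 0.5 * (URINE_PH + PLASMA_PH)
    return min(pkas, key=lambda p: abs(p - mid))


def logd65_from_logd74(
    logd74: float,
    ion_class: str,
    pka_acids: Sequence[float] = (),
    pka_bases: Sequence[float] = (),
) -> float:
    """Estimate LogD at pH 6.5 from LogD_7.4.

    Acids gain lipophilicity at the lower pH (less ionised), bases lose it;
    the magnitude of the shift is bounded by 0.9 = 7.4 - 6.5 log units.
    Neutral, zwitterionic and amphoteric drugs pass through unchanged.
    """
    if ion_class not in ION_CLASSES:
        raise ValueError(f"ion_class must be one of {ION_CLASSES}")
    if ion_class == "Acid":
        if not pka_acids:
            raise ValueError("acid classification requires an acidic pKa")
        pka = _shift_pka(pka_acids)
        return logd74 + math.log10(
            (1 + 10 ** (PLASMA_PH - pka)) / (1 + 10 ** (URINE_PH - pka))
        )
    if ion_class == "Base":
        if not pka_bases:
            raise ValueError("base classification requires a basic pKa")
        pka = _shift_pka(pka_bases)
        return logd74 + math.log10(
            (1 + 10 ** (pka - PLASMA_PH)) / (1 + 10 ** (pka - URINE_PH))
        )
    return logd74
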