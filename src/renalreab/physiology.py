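"""Nephron system parameters for the minimal tubular reabsorption model.

The nephron tubule is represented by four well-mixed compartments in
anatomical order — proximal tubule (PT), loop of Henle (LoH), distal
tubule (DT) and collecting duct (CD) — each characterised by a tubular
surface area TSA_i (m^2) and a midpoint tubular flow rate TFR_i (mL/min).
Filtrate enters the PT at the glomerular filtration rate (GFR) and leaves
the CD at the urine flow rate; TFR_i is the mean of the flows entering and
leaving region i.

Defaults are the adult human values used throughout the package:

======  =========  ==============  =================
region  TSA (m^2)  TFR (mL/min)    flow in -> out
======  =========  ==============  =================
PT      6.1        81.6            120  -> 43.2
LoH     0.16       33.6            43.2 -> 24.0
DT      0.21       17.8            24.0 -> 11.6
CD      0.045      6.3             11.6 -> 1.0
======  =========  ==============  =================

with GFR = 120 mL/min and urine flow = 1 mL/min.  The LoH/DT/CD surface
areas carry a 7.5-fold microvilli correction: open-cylinder geometric areas
are divided by 7.5 to reflect the sparse microvilli of those segments
relative to the proximal-tubule (and Caco-2) brush border.

A secondary, config-driven geometric path derives surface areas from tubule
dimensions: ``cylinder_tsa`` for straight segments and ``imcd_surface_area``
for the inner-medulla collecting duct, whose merging ducts are described by
an exponential total-circumference function.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml
from scipy import integrate

__all__ = [
    "TubularRegion",
    "NephronPhysiology",
    "ImcdGeometry",
    "default_physiology",
    "imcd_circumference",
    "imcd_surface_area",
    "cylinder_tsa",
    "apply_microvilli_correction",
    "load_config",
    "dump_config",
]

REGION_ORDER = ("PT", "LoH", "DT", "CD")

#: mm^2 per m^2
_MM2_PER_M2 = 1.0e6


@dataclass(frozen=True)
class TubularRegion:
    """One tubular compartment: surface area and filtrate flow.

    Parameters
    ----------
    name : {"PT", "LoH", "DT", "CD"}
    tsa : float
        Tubular surface area, m^2.
    flow_in, flow_out : float
        Filtrate flow entering/leaving the region, mL/min.
    tfr : float, optional
        Midpoint tubular flow rate, mL/min. Defaults to the mean of
        ``flow_in`` and ``flow_out`` and must equal it to within 1e-9.
    """

    name: str
    tsa: float
    flow_in: float
    flow_out: float
    tfr: float | None = None

    def __post_init__(self) -> None:
        if self.name not in REGION_ORDER:
            raise ValueError(f"unknown region name {self.name!r}")
        if not self.tsa > 0:
            raise ValueError(f"{self.name}: tsa must be > 0, got {self.tsa}")
        if not self.flow_in > self.flow_out > 0:
            raise ValueError(
                f"{self.name}: require flow_in > flow_out > 0, "
                f"got {self.flow_in} -> {self.flow_out}"
            )
        midpoint = 0.5 * (self.flow_in + self.flow_out)
        if self.tfr is None:
            object.__setattr__(self, "tfr", midpoint)
        elif abs(self.tfr - midpoint) > 1e-9:
            raise ValueError(
                f"{self.name}: tfr {self.tfr} is not the boundary-flow "
                f"midpoint {midpoint}"
            )


@dataclass(frozen=True)
class NephronPhysiology:
    """Whole-kidney system parameters of the reabsorption model.

    ``regions`` must be the four tubular compartments in anatomical order
    (PT, LoH, DT, CD); the PT inflow must equal ``gfr`` and the CD outflow
    must equal ``urine_flow``.
    """

    regions: tuple[TubularRegion, ...]
    gfr: float = 120.0
    urine_flow: float = 1.0
    microvilli_factor: float = 7.5
    microvilli_corrected: bool = True
    n_nephrons: int = 900_000
    n_cd: int = 90_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        names = tuple(r.name for r in self.regions)
        if names != REGION_ORDER:
            raise ValueError(f"regions must be ordered {REGION_ORDER}, got {names}")
        if not self.gfr > self.urine_flow > 0:
            raise ValueError("require gfr > urine_flow > 0")
        if abs(self.regions[0].flow_in - self.gfr) > 1e-9:
            raise ValueError("PT inflow must equal GFR")
        if abs(self.regions[-1].flow_out - self.urine_flow) > 1e-9:
            raise ValueError("CD outflow must equal urine flow")
        for up, down in zip(self.regions, self.regions[1:]):
            if abs(up.flow_out - down.flow_in) > 1e-9:
                raise ValueError(
                    f"flow discontinuity between {up.name} and {down.name}"
                )
        if not self.microvilli_factor > 0:
            raise ValueError("microvilli_factor must be > 0")

    def __getitem__(self, name: str) -> TubularRegion:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def tsa(self) -> dict[str, float]:
        return {r.name: r.tsa for r in self.regions}

    @property
    def tfr(self) -> dict[str, float]:
        return {r.name: r.tfr for r in self.regions}

    def with_urine_flow(self, urine_flow: float) -> "NephronPhysiology":
        """Return a copy with a new urine flow.

        The CD outflow (hence the CD midpoint flow rate) is adjusted
        consistently; all other regions are untouched.
        """
        cd = self[
            "CD"
        ]
        new_cd = TubularRegion("CD", cd.tsa, cd.flow_in, urine_flow)
        return replace(
            self,
            regions=self.regions[:3] + (new_cd,),
            urine_flow=urine_flow,
        )

    def with_gfr(self, gfr: float) -> "NephronPhysiology":
        """Return a copy with a new GFR (PT inflow adjusted consistently)."""
        pt = self["PT"]
        new_pt = TubularRegion("PT", pt.tsa, gfr, pt.flow_out)
        return replace(self, regions=(new_pt,) + self.regions[1:], gfr=gfr)

    def with_cd_tfr(self, tfr_cd: float) -> "NephronPhysiology":
        """Return a copy with the CD midpoint flow set to ``tfr_cd``.

        The CD inflow is moved (urine flow kept), preserving the midpoint
        identity; upstream DT outflow follows the new CD inflow.
        """
        cd = self["CD"]
        dt = self["DT"]
        flow_in = 2.0 * tfr_cd - self.urine_flow
        new_cd = TubularRegion("CD", cd.tsa, flow_in, self.urine_flow)
        new_dt = TubularRegion("DT", dt.tsa, dt.flow_in, flow_in)
        return replace(self, regions=self.regions[:2] + (new_dt, new_cd))

    def with_microvilli_factor(self, factor: float) -> "NephronPhysiology":
        """Return a copy with the correction re-applied at a new factor."""
        base = apply_microvilli_correction(self, enabled=False)
        scaled = tuple(
            r if r.name == "PT" else replace(r, tsa=r.tsa / factor)
            for r in base.regions
        )
        return replace(
            base,
            regions=scaled,
            microvilli_factor=factor,
            microvilli_corrected=True,
        )


def default_physiology() -> NephronPhysiology:
    """The adult human system parameters (see module docstring)."""
    return NephronPhysiology(
        regions=(
            TubularRegion("PT", 6.1, 120.0, 43.2),
            TubularRegion("LoH", 0.16, 43.2, 24.0),
            TubularRegion("DT", 0.21, 24.0, 11.6),
            TubularRegion("CD", 0.045, 11.6, 1.0),
        )
    )


def apply_microvilli_correction(
    physiology: NephronPhysiology, enabled: bool = True
) -> NephronPhysiology:
    """Toggle the 7.5-fold microvilli surface-area correction.

    The packaged default areas are already corrected, so ``enabled=True``
    returns the physiology unchanged.  ``enabled=False`` restores the
    uncorrected open-cylinder areas by multiplying the LoH/DT/CD surface
    areas by ``microvilli_factor``; the PT area never changes (its brush
    border matches the Caco-2 monolayer's).  The operation is an exact
    involution pair: disable followed by enable round-trips.
    """
    if enabled == physiology.microvilli_corrected:
        return physiology
    scale = physiology.microvilli_factor if not enabled else 1.0 / physiology.microvilli_factor
    regions = tuple(
        r if r.name == "PT" else replace(r, tsa=r.tsa * scale)
        for r in physiology.regions
    )
    return replace(physiology, regions=regions, microvilli_corrected=enabled)


@dataclass(frozen=True)
class ImcdGeometry:
    """Geometry of the merging inner-medulla collecting ducts.

    Ducts fuse ``fusion_events`` times between the outer–inner medulla
    boundary and the papilla apex, their diameter growing from ``dn`` to
    ``d0`` (mm) while their number falls to ``ncd0`` at the apex.
    ``length_n`` is the inner-medulla width (mm, default 11).
    """

    d0: float
    dn: float
    ncd0: int
    fusion_events: int
    length_n: float = 11.0

    def __post_init__(self) -> None:
        if not self.d0 > self.dn > 0:
            raise ValueError("require d0 > dn > 0")
        if self.ncd0 < 1:
            raise ValueError("ncd0 must be >= 1")
        if self.fusion_events < 1:
            raise ValueError("fusion_events must be >= 1")
        if not self.length_n > 0:
            raise ValueError("length_n must be > 0")


def imcd_circumference(geom: ImcdGeometry, x: float) -> float:
    """Total circumference (mm) of inner-medulla CDs at ``x`` mm from the apex.

    Evaluates

        C(x) = d0 * NCD0 * pi * exp( x * (F/n) * ln( 2 / (d0/dn)^(1/F) ) )

    i.e. with every fusion event the duct count doubles (walking away from
    the apex) while the diameter shrinks by the per-event ratio
    (d0/dn)^(1/F).  The printed source formula is ambiguous in its grouping;
    this is the interpretation used throughout (see the methods note).
    """
    if not 0.0 <= x <= geom.length_n:
        raise ValueError(f"x={x} outside [0, {geom.length_n}]")
    rate = (geom.fusion_events / geom.length_n) * math.log(
        2.0 / (geom.d0 / geom.dn) ** (1.0 / geom.fusion_events)
    )
    return geom.d0 * geom.ncd0 * math.pi * math.exp(x * rate)


def imcd_surface_area(geom: ImcdGeometry) -> float:
    """Inner-medulla CD surface area (m^2): integral of C(x) over [0, n]."""
    area_mm2, _ = integrate.quad(
        lambda x: imcd_circumference(geom, x),
        0.0,
        geom.length_n,
        epsabs=1e-10,
    )
    return area_mm2 / _MM2_PER_M2


def cylinder_tsa(length: float, diameter: float, count: float) -> float:
    """Open-cylinder surface area (m^2) of ``count`` tubules.

    ``length`` and ``diameter`` are in mm.
    """
    if not (length > 0 and diameter > 0 and count > 0):
        raise ValueError("length, diameter and count must all be > 0")
    return math.pi * diameter * length * count / _MM2_PER_M2


# ---------------------------------------------------------------------------
# config I/O

def dump_config(physiology: NephronPhysiology, path) -> None:
    """Write the physiology to a YAML config file (bit-exact round trip)."""
    doc = {
        "gfr_ml_min": physiology.gfr,
        "urine_flow_ml_min": physiology.urine_flow,
        "microvilli_factor": physiology.microvilli_factor,
        "microvilli_corrected": physiology.microvilli_corrected,
        "n_nephrons": physiology.n_nephrons,
        "n_cd": physiology.n_cd,
        "regions": {
            r.name: {"tsa_m2": r.tsa, "flow_in": r.flow_in, "flow_out": r.flow_out}
            for r in physiology.regions
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> NephronPhysiology:
    """Read a physiology config written by :func:`dump_config`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    regions = tuple(
        TubularRegion(
            name,
            doc["regions"][name]["tsa_m2"],
            doc["regions"][name]["flow_in"],
            doc["regions"][name]["flow_out"],
        )
        for name in REGION_ORDER
    )
    return NephronPhysiology(
        regions=regions,
        gfr=doc["gfr_ml_min"],
        urine_flow=doc["urine_flow_ml_min"],
        microvilli_factor=doc.get("microvilli_factor", 7.5),
        microvilli_corrected=doc.get("microvilli_corrected", True),
        n_nephrons=doc.get("n_nephrons", 900_000),
        n_cd=doc.get("n_cd", 90_000),
    )
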