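"""Nephron system parameters: defaults, geometry and the microvilli toggle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalreab.physiology import (
    ImcdGeometry,
    NephronPhysiology,
    TubularRegion,
    apply_microvilli_correction,
    cylinder_tsa,
    default_physiology,
    dump_config,
    imcd_circumference,
    imcd_surface_area,
    load_config,
)


class TestDefaultPhysiology:
    def test_surface_areas_and_flows(self, physiology):
        assert physiology["PT"].tsa == 6.1
        assert physiology["PT"].tfr == pytest.approx(81.6)
        assert physiology["CD"].tsa == 0.045
        assert (physiology["CD"].flow_in, physiology["CD"].flow_out) == (11.6, 1.0)
        assert physiology.gfr == 120.0 and physiology.urine_flow == 1.0

    def test_tfr_is_boundary_midpoint_everywhere(self, physiology):
        for region in physiology.regions:
            assert region.tfr == pytest.approx(
                (region.flow_in + region.flow_out) / 2, abs=1e-12
            )
        assert physiology["LoH"].tfr == pytest.approx((43.2 + 24.0) / 2)

    def test_flow_strictly_decreasing_to_urine_flow(self, physiology):
        flows = [physiology.regions[0].flow_in] + [
            r.flow_out for r in physiology.regions
        ]
        assert all(a > b for a, b in zip(flows, flows[1:]))
        assert flows[-1] == physiology.urine_flow

    def test_invalid_constructions_rejected(self):
        with pytest.raises(ValueError):
            TubularRegion("PT", -1.0, 120.0, 43.2)
        with pytest.raises(ValueError):
            TubularRegion("PT", 6.1, 43.2, 120.0)  # flow increasing
        with pytest.raises(ValueError):
            TubularRegion("PT", 6.1, 120.0, 43.2, tfr=80.0)  # not midpoint
        regions = default_physiology().regions
        with pytest.raises(ValueError):
            NephronPhysiology(regions=regions[::-1])
        with pytest.raises(ValueError):
            NephronPhysiology(regions=regions, gfr=0.5)  # below urine flow


class TestMicrovilliCorrection:
    def test_disable_scales_distal_regions_only(self, physiology):
        raw = apply_microvilli_correction(physiology, enabled=False)
        assert raw["PT"].tsa == physiology["PT"].tsa
        assert raw["LoH"].tsa == pytest.approx(0.16 * 7.5)
        assert raw["DT"].tsa == pytest.approx(0.21 * 7.5)
        assert raw["CD"].tsa == pytest.approx(0.045 * 7.5)

    def test_enabled_is_identity_on_default(self, physiology):
        assert apply_microvilli_correction(physiology, enabled=True) is physiology

    def test_round_trip(self, physiology):
        back = apply_microvilli_correction(
            apply_microvilli_correction(physiology, enabled=False), enabled=True
        )
        for a, b in zip(back.regions, physiology.regions):
            assert a.tsa == pytest.approx(b.tsa, rel=1e-12)


GEOM = ImcdGeometry(d0=0.3, dn=0.1, ncd0=10, fusion_events=3, length_n=11.0)


class TestImcdGeometry:
    def test_circumference_at_apex(self):
        assert imcd_circumference(GEOM, 0.0) == pytest.approx(0.3 * 10 * math.pi)

    def test_circumference_at_boundary_closed_form(self):
        # at x = n the exponential collapses: NCD0 * 2^F ducts of diameter dn
        assert imcd_circumference(GEOM, 11.0) == pytest.approx(
            math.pi * 0.1 * 10 * 2**3, rel=1e-12
        )

    def test_monotone_increasing_towards_boundary(self):
        xs = np.linspace(0, 11, 50)
        cs = [imcd_circumference(GEOM, x) for x in xs]
        assert all(a < b for a, b in zip(cs, cs[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            imcd_circumference(GEOM, -0.1)
        with pytest.raises(ValueError):
            imcd_circumference(GEOM, 11.1)

    @settings(derandomize=True, max_examples=30)
    @given(
        d0=st.floats(0.11, 1.0),
        ratio=st.floats(0.1, 0.9),
        ncd0=st.integers(1, 500),
        fusion=st.integers(1, 6),
        length=st.floats(2.0, 20.0),
    )
    def test_area_matches_trapezoid_oracle(self, d0, ratio, ncd0, fusion, length):
        geom = ImcdGeometry(d0, d0 * ratio, ncd0, fusion, length)
        xs = np.linspace(0.0, length, 100_001)
        oracle = np.trapezoid([imcd_circumference(geom, x) for x in xs], xs) / 1e6
        assert imcd_surface_area(geom) == pytest.approx(oracle, rel=1e-3)

    def test_area_linear_in_duct_count(self):
        doubled = ImcdGeometry(0.3, 0.1, 20, 3, 11.0)
        assert imcd_surface_area(doubled) == pytest.approx(
            2 * imcd_surface_area(GEOM), rel=1e-12
        )

    def test_constant_circumference_limit_is_rectangle(self):
        # d0 -> dn with F chosen so the growth and shrink rates cancel:
        # 2 / (d0/dn)^(1/F) = 1  <=>  d0/dn = 2^F
        geom = ImcdGeometry(d0=0.2, dn=0.1, ncd0=10, fusion_events=1, length_n=11.0)
        c0 = imcd_circumference(geom, 0.0)
        assert imcd_surface_area(geom) == pytest.approx(c0 * 11.0 / 1e6, rel=1e-9)


class TestCylinderTsa:
    def test_unit_arithmetic(self):
        # pi * (1/pi) mm * 1 mm * 1e6 tubules = 1e6 mm^2 = 1 m^2
        assert cylinder_tsa(1.0, 1.0 / math.pi, 1e6) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cylinder_tsa(1.0, 1.0, 0)

    def test_representative_pt_dimensions(self):
        # user-supplied dimensions: two kidneys of 900k nephrons each with
        # ~15 mm of proximal tubule at ~72 um diameter give ~6.1 m^2
        area = cylinder_tsa(15.0, 0.072, 2 * 900_000)
        assert area == pytest.approx(6.1, rel=0.05)


class TestConfigRoundTrip:
    def test_default_round_trips_bit_exact(self, physiology, tmp_path):
        path = tmp_path / "phys.yaml"
        dump_config(physiology, path)
        loaded = load_config(path)
        assert loaded == physiology

    def test_transforms_preserve_invariants(self, physiology):
        uf2 = physiology.with_urine_flow(2.0)
        assert uf2["CD"].tfr == pytest.approx((11.6 + 2.0) / 2)
        g100 = physiology.with_gfr(100.0)
        assert g100["PT"].tfr == pytest.approx((100.0 + 43.2) / 2)
        mv = physiology.with_microvilli_factor(15.0)
        assert mv["LoH"].tsa == pytest.approx(0.16 * 7.5 / 15.0)
        assert mv["PT"].tsa == physiology["PT"].tsa
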