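"""The reabsorption model chain: unit conversion, F' algebra, CL_R bounds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalreab.model import (
    ReabsorptionModel,
    clearance_ratio,
    filtration_clearance,
    freab_from_prime,
    freab_prime_from_freab,
    is_net_secreted,
    observed_freab,
    overall_freab_prime,
    predict_clr,
    regional_clint,
    regional_freab_prime,
)


class TestFiltrationClearance:
    @pytest.mark.parametrize(
        "fu_p, gfr, expected",
        [(0.87, 120, 104.4), (1.0, 120, 120.0), (0.04, 120, 4.8)],
    )
    def test_product(self, fu_p, gfr, expected):
        assert filtration_clearance(fu_p, gfr) == pytest.approx(expected)

    def test_domain(self):
        with pytest.raises(ValueError):
            filtration_clearance(0.0, 120)
        with pytest.raises(ValueError):
            filtration_clearance(1.1, 120)
        with pytest.raises(ValueError):
            filtration_clearance(0.5, -1)


class TestRegionalClint:
    def test_unit_conversion(self):
        # 1e-6 cm/s x m^2 -> mL/min carries a factor 0.6
        assert regional_clint(14.8, 6.1) == pytest.approx(54.168, rel=1e-9)
        assert regional_clint(81.1, 6.1) == pytest.approx(296.826, rel=1e-9)

    def test_small_papp_limit(self):
        assert regional_clint(1e-12, 6.1) == pytest.approx(0.0, abs=1e-10)

    def test_domain(self):
        with pytest.raises(ValueError):
            regional_clint(-1.0, 6.1)


class TestRegionalFreabPrime:
    def test_half_saturation_at_clint_equals_tfr(self):
        assert regional_freab_prime(81.6, 81.6) == 0.5

    def test_zero_and_derived_value(self):
        assert regional_freab_prime(0.0, 81.6) == 0.0
        assert regional_freab_prime(54.168, 81.6) == pytest.approx(0.3990, abs=5e-4)

    @settings(derandomize=True, max_examples=50)
    @given(
        clint=st.floats(0.0, 1e4),
        tfr=st.floats(0.1, 200.0),
        bump=st.floats(0.1, 10.0),
    )
    def test_monotone_in_clint_and_tfr(self, clint, tfr, bump):
        base = regional_freab_prime(clint, tfr)
        assert 0.0 <= base < 1.0
        assert regional_freab_prime(clint + bump, tfr) >= base
        assert regional_freab_prime(clint, tfr + bump) <= base


class TestOverallFreabPrime:
    def test_complement_product(self):
        assert overall_freab_prime([0, 0, 0, 0]) == 0.0
        assert overall_freab_prime([0.5, 0.5]) == pytest.approx(0.75)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 0.999), min_size=1, max_size=6))
    def test_bounds_and_order_invariance(self, regional):
        fp = overall_freab_prime(regional)
        assert max(regional) <= fp < 1.0
        assert overall_freab_prime(regional[::-1]) == pytest.approx(fp, rel=1e-12)


class TestFreabPrimeMapping:
    def test_maximal_freab_for_antipyrine(self):
        # full equilibrium, CL_filt = 106.8: the urine-flow floor caps F_reab
        assert freab_from_prime(1.0, 106.8, 0.89, 1.0) == pytest.approx(
            105.91 / 106.8, rel=1e-4
        )

    def test_observed_freab_to_prime(self):
        assert freab_prime_from_freab(0.99, 106.8, 0.89, 1.0) == pytest.approx(
            0.998, abs=5e-4
        )

    def test_degenerate_filtration_rejected(self):
        with pytest.raises(ValueError):
            freab_from_prime(0.5, 0.5, 1.0, 1.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        fp=st.floats(0.0, 1.0),
        fu=st.floats(0.01, 1.0),
        gfr=st.floats(50.0, 200.0),
        uf=st.floats(0.2, 3.0),
    )
    def test_round_trip_to_1e12(self, fp, fu, gfr, uf):
        clf = gfr * fu
        back = freab_prime_from_freab(freab_from_prime(fp, clf, fu, uf), clf, fu, uf)
        assert back == pytest.approx(fp, abs=1e-12)


class TestPredictClr:
    def test_caffeine_and_antipyrine_overprediction(self, physiology):
        caffeine = predict_clr({"name": "Caffeine", "papp": 81.12, "fu_p": 0.67})
        assert caffeine.clr_pred / 1.06 == pytest.approx(6.8, rel=0.05)
        antipyrine = predict_clr({"name": "Antipyrine", "papp": 124.9, "fu_p": 0.89})
        assert antipyrine.clr_pred / 1.22 == pytest.approx(4.1, rel=0.05)

    def test_caffeine_freab_prime(self):
        res = predict_clr({"papp": 81.1, "fu_p": 0.67})
        assert res.freab_prime == pytest.approx(0.9175, abs=2e-3)

    def test_equilibrium_floor(self, physiology):
        res = predict_clr({"papp": 1e5, "fu_p": 0.5}, physiology)
        assert res.clr_pred == pytest.approx(
            physiology.urine_flow * 0.5, rel=1e-3
        )

    def test_filtration_only_ignores_permeability(self, physiology):
        res = predict_clr({"papp": 500.0, "fu_p": 0.4}, physiology, "filtration_only")
        assert res.clr_pred == pytest.approx(48.0)
        assert res.freab_prime == 0.0

    def test_pt_only_reabsorbs_no_more_than_full(self, panel):
        for papp in panel["papp_1e6_cm_s"].head(10):
            full = predict_clr({"papp": papp, "fu_p": 0.5})
            pt = predict_clr({"papp": papp, "fu_p": 0.5}, variant="pt_only")
            assert pt.freab_prime <= full.freab_prime

    @settings(derandomize=True, max_examples=60)
    @given(
        papp=st.floats(0.01, 500.0),
        fu=st.floats(0.01, 1.0),
        variant=st.sampled_from(["full", "filtration_only", "pt_only", "no_microvilli"]),
    )
    def test_prediction_bounds(self, papp, fu, variant):
        from renalreab.physiology import default_physiology

        physiology = default_physiology()
        res = predict_clr({"papp": papp, "fu_p": fu}, physiology, variant)
        floor = physiology.urine_flow * fu
        ceiling = physiology.gfr * fu
        assert floor - 1e-9 <= res.clr_pred <= ceiling + 1e-9

    @settings(derandomize=True, max_examples=40)
    @given(papp=st.floats(0.1, 300.0), scale=st.floats(1.01, 3.0))
    def test_monotone_decreasing_in_papp(self, papp, scale):
        lo = predict_clr({"papp": papp, "fu_p": 0.5})
        hi = predict_clr({"papp": papp * scale, "fu_p": 0.5})
        assert hi.clr_pred <= lo.clr_pred


class TestObservedQuantities:
    def test_clearance_ratio_atenolol(self):
        ratio = clearance_ratio(145.0, 120.0 * 0.97)
        assert ratio == pytest.approx(1.246, abs=1e-3)
        assert not is_net_secreted(ratio)

    def test_cutoff_is_strict(self):
        assert not is_net_secreted(1.5)
        assert is_net_secreted(1.5 + 1e-12)

    def test_observed_freab_examples(self):
        assert observed_freab(1.22, 106.8) == pytest.approx(0.9886, abs=1e-4)
        assert observed_freab(145.0, 116.4) == pytest.approx(-0.246, abs=1e-3)
        assert observed_freab(0.0, 50.0) == 1.0


class TestReabsorptionModelEstimator:
    def test_matches_functional_path(self, panel, physiology):
        model = ReabsorptionModel().fit(panel)
        detail = model.predict_detail(panel)
        for _, row in detail.head(5).iterrows():
            drug = panel.loc[panel["drug"] == row["drug"]].iloc[0]
            res = predict_clr(
                {"papp": drug["papp_1e6_cm_s"], "fu_p": drug["fu_p"]}, physiology
            )
            assert row["clr_pred"] == pytest.approx(res.clr_pred, rel=1e-12)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="papp_1e6_cm_s"):
            ReabsorptionModel().fit(pd.DataFrame({"fu_p": [0.5]}))

    def test_accepts_plain_array(self):
        pred = ReabsorptionModel().fit([[81.12, 0.67]]).predict([[81.12, 0.67]])
        assert pred[0] == pytest.approx(7.25, abs=0.01)

    def test_sklearn_param_interface(self):
        model = ReabsorptionModel(variant="pt_only")
        assert model.get_params()["variant"] == "pt_only"
        model.set_params(variant="full")
        assert model.variant == "full"

    def test_fold_error_column_present_with_observed(self, panel):
        detail = ReabsorptionModel().fit(panel).predict_detail(panel)
        assert detail["fold_error"].notna().all()
        assert (detail["fold_error"] >= 1.0).all()
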