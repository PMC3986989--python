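import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import soilrisk as sr

conc = st.floats(min_value=0.0, max_value=1e4, allow_nan=False,
                 allow_subnormal=False)
conc_pos = st.floats(min_value=1e-6, max_value=1e4, allow_nan=False)


@pytest.fixture(scope="module")
def params():
    _, _, exposure, tox = sr.default_parameters(None)
    return exposure, tox


class TestDoseTerms:
    """Frozen values computed term-by-term from the default exposure
    factors (chain: C x rate x EF x ED / (BW x AT) x 1e-6)."""

    def test_ingestion_child(self, params):
        p, _ = params
        # 1 * 200 * 350 * 6 / (16.2 * 2190) * 1e-6
        assert sr.cdi_ingestion_nc(1.0, "child", p) == pytest.approx(
            1.1838322340605445e-05, rel=1e-12)

    def test_ingestion_adult(self, params):
        p, _ = params
        # 1 * 100 * 350 * 30 / (61.8 * 10950) * 1e-6
        assert sr.cdi_ingestion_nc(1.0, "adult", p) == pytest.approx(
            1.551624772797801e-06, rel=1e-12)

    def test_inhalation_reduces_to_ef_over_pef(self, params):
        p, _ = params
        # ET = 24 collapses the chain to (EF/365)/PEF
        assert sr.ec_inhalation_nc(1.0, "child", p) == pytest.approx(
            (350.0 / 365.0) / 1.36e9, rel=1e-12)

    @given(C=conc)
    def test_inhalation_receptor_independent(self, C, params):
        p, _ = params
        assert sr.ec_inhalation_nc(C, "child", p) == pytest.approx(
            sr.ec_inhalation_nc(C, "adult", p), rel=1e-12)

    def test_dermal_child(self, params):
        p, _ = params
        # 2800 * 0.2 * 0.03 * 350 * 6 / (16.2 * 2190) * 1e-6
        assert sr.cdi_dermal_nc(1.0, "child", p) == pytest.approx(
            9.944190766108574e-07, rel=1e-12)

    def test_dermal_adult(self, params):
        p, _ = params
        # 5700 * 0.07 * 0.001 * 350 * 30 / (61.8 * 10950) * 1e-6
        assert sr.cdi_dermal_nc(1.0, "adult", p) == pytest.approx(
            6.190982843463227e-09, rel=1e-12)

    @pytest.mark.parametrize("fn", [sr.cdi_ingestion_nc,
                                    sr.ec_inhalation_nc, sr.cdi_dermal_nc])
    def test_zero_concentration_zero_dose(self, fn, params):
        p, _ = params
        assert fn(0.0, "child", p) == 0.0

    @given(C=conc_pos, a=st.floats(min_value=0.1, max_value=100))
    def test_homogeneity(self, C, a, params):
        p, _ = params
        for fn in (sr.cdi_ingestion_nc, sr.ec_inhalation_nc,
                   sr.cdi_dermal_nc):
            assert fn(a * C, "child", p) == pytest.approx(
                a * fn(C, "child", p), rel=1e-9)


class TestAgeAdjustedFactors:
    def test_ingestion_reproduces_printed_113(self, params):
        p, _ = params
        v = sr.age_adjusted_ingestion(p)
        assert v == pytest.approx(6 * 200 / 16.2 + 24 * 100 / 61.8,
                                  rel=1e-12)
        assert round(v) == 113

    def test_dermal_reproduces_printed_362_4(self, params):
        p, _ = params
        v = sr.age_adjusted_dermal(p)
        assert v == pytest.approx(6 * 2800 * 0.2 / 16.2
                                  + 24 * 5700 * 0.07 / 61.8, rel=1e-12)
        assert round(v, 1) == 362.4

    def test_child_only_terms(self, params):
        p, _ = params
        p2, _ = sr.default_parameters(None)[2:]
        p2.adult.ED = p2.child.ED
        assert sr.age_adjusted_ingestion(p2) == pytest.approx(
            6 * 200 / 16.2, rel=1e-12)
        assert sr.age_adjusted_dermal(p2) == pytest.approx(
            6 * 2800 * 0.2 / 16.2, rel=1e-12)

    def test_zero_rates_give_zero(self):
        _, _, p, _ = sr.default_parameters(None)
        p.child.IngR = p.adult.IngR = 0.0
        assert sr.age_adjusted_ingestion(p) == 0.0
        p.child.AF = p.adult.AF = 0.0
        assert sr.age_adjusted_dermal(p) == 0.0

    def test_dermal_contact_abs_modes(self, params):
        p, _ = params
        # age-specific absorption inside the age sum
        assert sr.dermal_contact_abs(p) == pytest.approx(
            6 * 2800 * 0.2 * 0.03 / 16.2
            + 24 * 5700 * 0.07 * 0.001 / 61.8, rel=1e-12)
        assert sr.dermal_contact_abs(p, "child") == pytest.approx(
            sr.age_adjusted_dermal(p) * 0.03, rel=1e-12)
        assert sr.dermal_contact_abs(p, "adult") == pytest.approx(
            sr.age_adjusted_dermal(p) * 0.001, rel=1e-12)
        with pytest.raises(sr.ParameterError):
            sr.dermal_contact_abs(p, "teen")


class TestHazardIndex:
    def test_all_zero_concentrations(self, params):
        p, tox = params
        res = sr.hazard_index({m: 0.0 for m in sr.METALS}, "child", p, tox)
        assert res.HI == 0.0

    def test_zinc_only_routes(self, params):
        p, tox = params
        res = sr.hazard_index({"Zn": 300.0}, "child", p, tox)
        # HQ_ing = 300 * CDI(1) / 0.3 ; inhalation skipped (no RfC)
        assert res.HQ[("Zn", "ing")] == pytest.approx(
            300 * 1.1838322340605445e-05 / 0.3, rel=1e-12)
        assert res.HQ[("Zn", "dermal")] == pytest.approx(
            300 * 9.944190766108574e-07 / 0.3, rel=1e-12)
        assert ("Zn", "inh") in res.skipped_routes
        assert res.HI == pytest.approx(
            res.HQ[("Zn", "ing")] + res.HQ[("Zn", "dermal")], rel=1e-12)

    def test_inhalation_reference_gaps_are_skipped(self, params):
        p, tox = params
        res = sr.hazard_index({m: 1.0 for m in sr.METALS}, "adult", p, tox)
        skipped_inh = {m for m, r in res.skipped_routes if r == "inh"}
        assert skipped_inh == {"Cr", "Cu", "Pb", "Zn"}
        assert ("Cd", "inh") in res.HQ and ("Ni", "inh") in res.HQ

    def test_nothing_evaluable_is_an_error(self, params):
        p, _ = params
        bare = sr.ToxParams(metals={m: sr.MetalTox() for m in sr.METALS})
        with pytest.raises(sr.ParameterError):
            sr.hazard_index({"Cd": 1.0}, "child", p, bare)

    @given(cs=st.lists(conc, min_size=6, max_size=6))
    def test_child_dominates_adult(self, cs, params):
        """Children's higher intake-to-body-weight ratios force
        HI_child >= HI_adult, strictly when any metal is present."""
        p, tox = params
        c = dict(zip(sr.METALS, cs))
        child = sr.hazard_index(c, "child", p, tox).HI
        adult = sr.hazard_index(c, "adult", p, tox).HI
        assert child >= adult
        if any(v > 0 for v in cs):
            assert child > adult


class TestCancerRisk:
    def test_all_zero(self, params):
        p, tox = params
        res = sr.cancer_risk({m: 0.0 for m in sr.CARCINOGENS}, p, tox)
        assert res.total_risk == 0.0

    def test_lead_ingestion_route(self, params):
        p, tox = params
        res = sr.cancer_risk({"Pb": 1.0}, p, tox)
        expected = (sr.age_adjusted_ingestion(p) * 350 / 26280
                    * 1e-6 * 8.5e-3)
        assert res.risk[("Pb", "ing")] == pytest.approx(expected, rel=1e-12)
        # against the printed age-adjusted rate (113) to print precision
        assert res.risk[("Pb", "ing")] == pytest.approx(1.279e-8, rel=2e-3)

    def test_lead_dermal_uses_gi_corrected_slope(self, params):
        p, tox = params
        res = sr.cancer_risk({"Pb": 1.0}, p, tox)
        expected = (sr.dermal_contact_abs(p) * 350 / 26280 * 1e-6
                    * 8.5e-3 / 1.0)
        assert res.risk[("Pb", "dermal")] == pytest.approx(expected,
                                                           rel=1e-12)

    def test_cadmium_inhalation_route(self, params):
        p, tox = params
        res = sr.cancer_risk({"Cd": 1.0}, p, tox, ed_inh=30)
        # (1000/1.36e9) * 350 * 30 / 26280 * 1.8e-3
        assert res.risk[("Cd", "inh")] == pytest.approx(
            5.288074133763094e-10, rel=1e-12)

    def test_only_lead_has_oral_slope(self, params):
        p, tox = params
        res = sr.cancer_risk({m: 1.0 for m in sr.CARCINOGENS}, p, tox)
        oral = {m for (m, r) in res.risk if r == "ing"}
        assert oral == {"Pb"}
        inh = {m for (m, r) in res.risk if r == "inh"}
        assert inh == {"Cd", "Cr", "Ni", "Pb"}

    def test_non_carcinogens_ignored(self, params):
        p, tox = params
        res = sr.cancer_risk({"Cu": 100.0, "Zn": 100.0, "Pb": 0.0}, p, tox)
        assert res.total_risk == 0.0

    @given(cs=st.lists(conc, min_size=4, max_size=4))
    def test_additivity_over_metals(self, cs, params):
        p, tox = params
        c = dict(zip(sr.CARCINOGENS, cs))
        total = sr.cancer_risk(c, p, tox).total_risk
        parts = sum(sr.cancer_risk({m: v}, p, tox).total_risk
                    for m, v in c.items())
        assert total == pytest.approx(parts, rel=1e-9, abs=1e-30)


class TestHealthProfile:
    def test_flat_at_background(self, flat_table, params):
        p, tox = params
        prof = sr.health_profile(flat_table, p, tox)
        for (site, receptor), g in prof.groupby(["site", "receptor"]):
            assert np.allclose(g["HI"], g["HI"].iloc[0])
            assert np.allclose(g["total_risk"], g["total_risk"].iloc[0])

    def test_receptor_rows_and_ordering(self, synth_table, params):
        p, tox = params
        prof = sr.health_profile(synth_table, p, tox)
        assert len(prof) == 2 * 7 * 2
        child = prof[prof["receptor"] == "child"].set_index(["site", "zone"])
        adult = prof[prof["receptor"] == "adult"].set_index(["site", "zone"])
        assert (child["HI"] > adult["HI"]).all()
        # cancer risk is age-adjusted, identical across receptor rows
        assert np.allclose(child["total_risk"], adult["total_risk"])

    def test_single_zone_table(self, site_backgrounds, params):
        import pandas as pd
        p, tox = params
        bg = site_backgrounds["Site1"]
        rows = [{"site": "Site1", "transect": "T1", "zone": "trench",
                 **{m: bg[m] for m in sr.METALS}}]
        prof = sr.health_profile(sr.validate_samples(pd.DataFrame(rows)),
                                 p, tox)
        assert len(prof) == 2
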