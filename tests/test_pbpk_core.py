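"""Flow network, derived geometry, kinetic laws and RHS mass balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icgpbpk.pbpk_core import (
    IDX,
    N_STATE,
    BodyParameters,
    InvalidParameterError,
    ModelParameters,
    ScenarioParameters,
    TransporterParameters,
    biliary_excretion_rate,
    derive_geometry,
    feces_transport_rate,
    rhs,
    uptake_rate,
)


class TestDeriveGeometry:
    def test_reference_flows(self):
        geo = derive_geometry(BodyParameters(), ScenarioParameters())
        # 0.83 ml/s/kg x 75 kg x 60 s/min = 3.735 l/min
        assert geo.Q_CO == pytest.approx(3.735, rel=1e-12)
        assert geo.Q_h == pytest.approx(0.95243, abs=1e-5)
        assert geo.Q_po == pytest.approx(0.70965, abs=1e-5)
        assert geo.Q_ha == pytest.approx(0.24278, abs=1e-5)

    def test_flow_conservation_identities(self):
        geo = derive_geometry(BodyParameters(), ScenarioParameters())
        assert geo.Q_lu == pytest.approx(geo.Q_h + geo.Q_re, rel=1e-14)
        assert geo.Q_h == pytest.approx(geo.Q_ha + geo.Q_po, rel=1e-14)

    def test_no_shunt_is_identity(self):
        geo = derive_geometry(BodyParameters(), ScenarioParameters(f_shunts=0.0))
        assert geo.Q_shunt == 0.0
        assert geo.Q_ha_shunt == 0.0 and geo.Q_po_shunt == 0.0

    def test_resected_liver_tissue_volume(self):
        geo = derive_geometry(
            BodyParameters(), ScenarioParameters(resection_rate=0.9)
        )
        # 0.021 l/kg x 75 kg x (1-0.02) x 0.1
        assert geo.V_li_tissue == pytest.approx(0.15435, rel=1e-10)

    def test_tissue_loss_and_resection_commute(self):
        a = derive_geometry(
            BodyParameters(),
            ScenarioParameters(f_tissue_loss=0.3, resection_rate=0.5),
        ).V_li_tissue
        b = derive_geometry(
            BodyParameters(),
            ScenarioParameters(f_tissue_loss=0.5, resection_rate=0.3),
        ).V_li_tissue
        assert a == pytest.approx(b, rel=1e-14)

    @settings(max_examples=50, deadline=None)
    @given(
        f_shunts=st.floats(0.0, 0.95),
        f_tissue_loss=st.floats(0.0, 0.95),
        resection=st.floats(0.0, 0.9),
        f_bf=st.floats(0.1, 1.5),
        f_co=st.floats(0.5, 2.0),
    )
    def test_flow_conservation_property(
        self, f_shunts, f_tissue_loss, resection, f_bf, f_co
    ):
        sc = ScenarioParameters(
            f_shunts=f_shunts,
            f_tissue_loss=f_tissue_loss,
            resection_rate=resection,
            f_bloodflow=f_bf,
            f_cardiac_output=f_co,
        )
        geo = derive_geometry(BodyParameters(), sc)
        assert geo.Q_lu == pytest.approx(geo.Q_h + geo.Q_re, rel=1e-12)
        assert geo.Q_h == pytest.approx(geo.Q_ha + geo.Q_po, rel=1e-12)
        assert geo.Q_shunt == pytest.approx(
            geo.Q_ha_shunt + geo.Q_po_shunt, rel=1e-12
        )
        for name in ("V_li_tissue", "V_li_blood", "V_re_blood", "Q_re", "Q_ha"):
            assert getattr(geo, name) >= 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            BodyParameters(HCT=1.2)
        with pytest.raises(InvalidParameterError):
            BodyParameters(FQh=0.1, FQgi=0.19)  # negative hepatic artery
        with pytest.raises(InvalidParameterError):
            ScenarioParameters(resection_rate=0.95)
        with pytest.raises(InvalidParameterError):
            TransporterParameters(ICGIM_Km=-1.0)


class TestKinetics:
    tp = TransporterParameters()

    def test_uptake_zero_substrate(self):
        assert uptake_rate(0.0, self.tp, 1.5, 0.007) == 0.0

    def test_uptake_saturation_limit(self):
        vmax = self.tp.f_oatp1b3 * self.tp.ICGIM_Vmax * 1.5
        assert uptake_rate(1e9, self.tp, 1.5, 0.007) == pytest.approx(vmax, rel=1e-6)

    def test_uptake_half_saturation(self):
        bil = 0.007
        km_app = self.tp.ICGIM_Km * (1 + bil / self.tp.ki_bil)
        vmax = self.tp.ICGIM_Vmax * 1.5
        assert uptake_rate(km_app, self.tp, 1.5, bil) == pytest.approx(
            0.5 * vmax, rel=1e-12
        )

    def test_uptake_monotone_saturating(self):
        c = np.linspace(0, 0.2, 50)
        r = np.array([uptake_rate(ci, self.tp, 1.5, 0.007) for ci in c])
        assert np.all(np.diff(r) > 0)
        assert r[-1] < self.tp.ICGIM_Vmax * 1.5

    def test_biliary_half_max_and_volume_scaling(self):
        half = biliary_excretion_rate(self.tp.ICGLI2CA_Km, self.tp, 1.5)
        assert half == pytest.approx(0.5 * self.tp.ICGLI2CA_Vmax * 1.5, rel=1e-12)
        full = biliary_excretion_rate(0.01, self.tp, 1.5)
        assert biliary_excretion_rate(0.01, self.tp, 0.75) == pytest.approx(
            0.5 * full, rel=1e-12
        )
        assert biliary_excretion_rate(0.0, self.tp, 1.5) == 0.0

    def test_feces_first_order_and_functional_scaling(self):
        assert feces_transport_rate(0.0, self.tp) == 0.0
        r1 = feces_transport_rate(0.01, self.tp, 1.0)
        assert feces_transport_rate(0.02, self.tp, 1.0) == pytest.approx(2 * r1)
        assert feces_transport_rate(0.01, self.tp, 0.5) == pytest.approx(0.5 * r1)


class TestRHS:
    def setup_method(self):
        self.params = ModelParameters()
        self.geo = derive_geometry(self.params.body, self.params.scenario)

    def test_zero_state_zero_input(self):
        dx = rhs(0.0, np.zeros(N_STATE), self.params, self.geo, lambda t: 0.0)
        assert np.all(dx == 0.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 10.0))
    def test_mass_balance_at_random_states(self, seed, u):
        rng = np.random.default_rng(seed)
        state = rng.random(N_STATE) * 0.05
        dx = rhs(0.0, state, self.params, self.geo, lambda t: u)
        # everything except the administered-amount bookkeeping sums to u
        total = dx[: IDX["A_adm"]].sum()
        assert total == pytest.approx(u, abs=1e-12 + 1e-9 * abs(u))

    def test_shunt_flow_bookkeeping(self):
        sc = self.params.scenario.with_cirrhosis(0.0)
        from dataclasses import replace

        sc = replace(sc, f_shunts=0.5)
        params = replace(self.params, scenario=sc)
        geo = derive_geometry(params.body, sc)
        assert geo.Q_shunt == pytest.approx(0.5 * geo.Q_h, rel=1e-12)
        state = np.zeros(N_STATE)
        state[IDX["A_po"]] = 0.01
        dx = rhs(0.0, state, params, geo, lambda t: 0.0)
        c_po = 0.01 / geo.V_po_plasma
        # half of the portal stream bypasses the liver into the hepatic vein
        assert dx[IDX["A_hv"]] == pytest.approx(0.5 * geo.Q_po * c_po, rel=1e-12)
        assert dx[IDX["A_li_pl"]] == pytest.approx(
            0.5 * geo.Q_po * c_po, rel=1e-12
        )

    def test_nonfinite_state_rejected(self):
        state = np.zeros(N_STATE)
        state[0] = np.nan
        with pytest.raises(FloatingPointError):
            rhs(0.0, state, self.params, self.geo, lambda t: 0.0)


class TestFlatSerialization:
    def test_round_trip(self):
        p = ModelParameters()
        flat = p.to_flat()
        assert flat["LI__ICGIM_Vmax"] == pytest.approx(0.037)
        q = ModelParameters.from_flat(flat)
        assert q == p

    def test_f_cirrhosis_lockstep(self):
        p = ModelParameters.from_flat({"f_cirrhosis": 0.41})
        assert p.scenario.f_shunts == 0.41
        assert p.scenario.f_tissue_loss == 0.41
        assert p.scenario.f_cirrhosis == 0.41

    def test_unknown_key_rejected(self):
        with pytest.raises(InvalidParameterError):
            ModelParameters.from_flat({"not_a_parameter": 1.0})
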