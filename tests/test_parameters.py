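"""Parameter containers, shipped data and config I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbpkpd.errors import (
    ConfigError,
    ParseError,
    RangeError,
    SpeciesLookupError,
)
from pbpkpd.parameters import (
    GI_ORDER,
    CompoundRecord,
    DoseRegimen,
    ObservedDataset,
    load_compound,
    load_physiology,
    read_observations,
    write_compound,
    write_observations,
)


class TestCompoundConfig:
    def test_bundled_buagafuran_values(self, compound):
        assert compound.logp == 6.24
        assert compound.solubility_mg_ml == 0.00985
        assert compound.mw == 262.44
        assert compound.papp_caco2_cm_s == pytest.approx(19.5e-5)
        assert compound.rb == 0.73
        assert compound.fup("rat") == 0.031
        assert compound.fup("human") == 0.040

    def test_unknown_key_rejected(self, tmp_path, compound):
        p = tmp_path / "c.yaml"
        write_compound(compound, p)
        p.write_text(p.read_text() + "\nsolubilty_mg_ml: 1.0\n")  # typo'd key
        with pytest.raises(ConfigError, match="solubilty_mg_ml"):
            load_compound(p)

    def test_missing_field_named(self, tmp_path, compound):
        payload = compound.model_dump()
        del payload["mw"]
        import yaml

        p = tmp_path / "c.yaml"
        p.write_text(yaml.safe_dump(payload))
        with pytest.raises(ConfigError, match="mw"):
            load_compound(p)

    @pytest.mark.parametrize(
        "field,value",
        [("solubility_mg_ml", -1.0), ("solubility_mg_ml", 0.0), ("mw", 0.0)],
    )
    def test_nonpositive_values_are_range_errors(self, tmp_path, compound, field, value):
        payload = compound.model_dump()
        payload[field] = value
        import yaml

        p = tmp_path / "c.yaml"
        p.write_text(yaml.safe_dump(payload))
        with pytest.raises(RangeError):
            load_compound(p)

    def test_fup_zero_rejected(self, compound):
        payload = compound.model_dump()
        payload["fup_by_species"]["rat"] = 0.0
        with pytest.raises(Exception):
            CompoundRecord.model_validate(payload)

    @settings(max_examples=25, deadline=None)
    @given(
        logp=st.floats(-2, 8),
        sol=st.floats(1e-4, 10),
        fup=st.floats(0.001, 1.0),
        radius=st.floats(0.5, 50),
    )
    def test_roundtrip_lossless(self, logp, sol, fup, radius):
        rec = CompoundRecord(
            name="probe",
            mw=300.0,
            logp=logp,
            solubility_mg_ml=sol,
            papp_caco2_cm_s=1e-5,
            rb=1.0,
            fup_by_species={"rat": fup},
            particle_radius_um=radius,
            particle_density_g_ml=1.2,
            diffusion_coeff_1e5_cm2_s=0.9,
            mean_precip_time_s=900.0,
        )
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as d:
            p = Path(d) / "r.yaml"
            write_compound(rec, p)
            assert load_compound(p) == rec


class TestPhysiology:
    @pytest.mark.parametrize(
        "species,qh,liver_w", [("rat", 70.0, 40.0), ("human", 20.0, 21.0)]
    )
    def test_shipped_anchors(self, species, qh, liver_w):
        phys = load_physiology(species)
        assert phys.qh_ml_min_kg == qh
        assert phys.liver_weight_per_kg == liver_w
        assert phys.mppgl == 45.0
        assert tuple(g.name for g in phys.gi_compartments) == GI_ORDER

    def test_flows_within_cardiac_output(self):
        for species in ("rat", "human"):
            phys = load_physiology(species)
            systemic = sum(
                t.flow_ml_min for t in phys.tissues if t.name != "lung"
            )
            assert systemic <= phys.cardiac_output_ml_min * (1 + 1e-12)

    def test_unknown_species(self):
        with pytest.raises(SpeciesLookupError):
            load_physiology("dog")

    def test_scaling_preserves_per_kg_quantities(self):
        phys = load_physiology("rat").scaled_to(0.2)
        assert phys.qh_ml_min_kg == 70.0
        assert phys.tissue("liver").volume_ml == pytest.approx(10.0 * 0.2 / 0.25)


class TestRegimen:
    def test_invalid_times_rejected(self):
        with pytest.raises(RangeError):
            DoseRegimen(doses=((1.0, 10.0), (1.0, 10.0)), horizon_h=24.0)
        with pytest.raises(RangeError):
            DoseRegimen(doses=((-1.0, 10.0),), horizon_h=24.0)
        with pytest.raises(RangeError):
            DoseRegimen(doses=((10.0, 10.0),), horizon_h=5.0)


class TestObservations:
    def _frame(self):
        return pd.DataFrame(
            {
                "time_h": [0.5, 0.25, 1.0],
                "conc_ng_ml": [3.0, 2.0, 1.5],
                "matrix": ["plasma"] * 3,
                "dose": [4.0] * 3,
                "species": ["rat"] * 3,
            }
        )

    def test_read_well_formed(self, tmp_path):
        p = tmp_path / "obs.csv"
        self._frame().to_csv(p, index=False)
        ds = read_observations(p)
        assert len(ds) == 3
        assert list(ds.data["time_h"]) == [0.25, 0.5, 1.0]  # sorted

    def test_negative_time_parse_error_with_line(self, tmp_path):
        df = self._frame()
        df.loc[1, "time_h"] = -0.5
        p = tmp_path / "obs.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ParseError, match="line"):
            read_observations(p)

    def test_roundtrip(self, tmp_path):
        ds = ObservedDataset(data=self._frame(), metadata="x")
        p = tmp_path / "obs.csv"
        write_observations(ds, p)
        ds2 = read_observations(p)
        pd.testing.assert_frame_equal(
            ds.data, ds2.data, check_dtype=False
        )
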