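import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from munmeta import DietType, SimulationConfig, StudyTable, TreatmentRecord, generate


@pytest.fixture(scope="session")
def default_table():
    """One synthetic treatment-mean table at the default study conditions."""
    table, truth = generate(SimulationConfig(seed=20260928))
    return table, truth


@pytest.fixture()
def tiny_table():
    """Hand-built 6-record / 3-study table, both diets, valid SEm."""
    recs = [
        TreatmentRecord("10.1/a", DietType.TMR, un_gd=180.0, mun_mgdl=12.0, bw_kg=640.0,
                        dmi_kg=22.0, cp_pct=16.5, un_sem=8.0, ndf_pct=33.0),
        TreatmentRecord("10.1/a", DietType.TMR, un_gd=205.0, mun_mgdl=14.5, bw_kg=650.0,
                        dmi_kg=23.0, cp_pct=17.0, un_sem=9.0, ndf_pct=32.0),
        TreatmentRecord("10.1/b", DietType.TMR, un_gd=160.0, mun_mgdl=10.0, bw_kg=620.0,
                        dmi_kg=21.0, cp_pct=15.8, un_sem=12.0, ndf_pct=34.5),
        TreatmentRecord("10.1/b", DietType.TMR, un_gd=175.0, mun_mgdl=11.2, bw_kg=625.0,
                        dmi_kg=21.5, cp_pct=16.1, un_sem=10.0, ndf_pct=34.0),
        TreatmentRecord("10.2/c", DietType.PASTURE, un_gd=210.0, mun_mgdl=18.0, bw_kg=500.0,
                        dmi_kg=17.0, cp_pct=20.0, un_sem=11.0, ndf_pct=44.0),
        TreatmentRecord("10.2/c", DietType.PASTURE, un_gd=230.0, mun_mgdl=19.5, bw_kg=510.0,
                        dmi_kg=17.5, cp_pct=21.0, un_sem=10.0, ndf_pct=45.0),
    ]
    return StudyTable.from_records(recs, provenance="hand-built fixture")
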