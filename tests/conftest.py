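import pytest
from hypothesis import settings

import boneref as br

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from boneref.normative_tables import SIX_PARAMETERS


@pytest.fixture(scope="session")
def six_param_cohort():
    """Synthetic cohort carrying the six bone-health parameters."""
    cfg = br.default_config(seed=20260928, parameters=SIX_PARAMETERS)
    return cfg, br.generate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_store(six_param_cohort):
    """Reference-curve store fitted on the session cohort (both sexes/sites)."""
    _, records = six_param_cohort
    store = br.CurveStore()
    for sex in ("F", "M"):
        for site in ("radius", "tibia"):
            for p in SIX_PARAMETERS:
                store.add(br.fit_reference_curve(records, p, sex, site))
    return store


@pytest.fixture
def toy_cohort_csv(tmp_path):
    path = tmp_path / "cohort.csv"
    path.write_text(
        "participant_id,sex,age,site,repeat_index,Tot.vBMD,Ct.Th\n"
        "P001,F,25.5,tibia,0,0.301,1.21\n"
        "P002,M,37.0,radius,0,0.288,\n"
        "P003,F,64.0,tibia,0,0.242,0.98\n"
    )
    return path
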