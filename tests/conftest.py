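import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from endorisk.core_model import (
    ClinicopathologicProfile,
    FigoStage,
    Grade,
    Histotype,
    LymphNodes,
    Lvsi,
    MarkerPanel,
    MmrStain,
    MyometrialInvasion,
    P53Pattern,
    PatientRecord,
    PoleStatus,
    SurvivalRecord,
)


def make_profile(**kwargs) -> ClinicopathologicProfile:
    """A valid low-risk endometrioid stage IA profile, overridable."""
    defaults = dict(
        patient_id="P001",
        histotype=Histotype.ENDOMETRIOID,
        grade=Grade.LOW,
        myometrial_invasion=MyometrialInvasion.LT50,
        lvsi=Lvsi.ABSENT,
        lymph_nodes=LymphNodes.NEGATIVE,
        figo_stage=FigoStage.IA,
        residual_disease=False,
    )
    defaults.update(kwargs)
    return ClinicopathologicProfile(**defaults)


def make_panel(**kwargs) -> MarkerPanel:
    """A fully tested triple-negative (NSMP) marker panel, overridable."""
    defaults = dict(
        p53_pattern=P53Pattern.WILDTYPE,
        mlh1=MmrStain.RETAINED, pms2=MmrStain.RETAINED,
        msh2=MmrStain.RETAINED, msh6=MmrStain.RETAINED,
        pole=PoleStatus.WILDTYPE,
    )
    defaults.update(kwargs)
    return MarkerPanel(**defaults)


def make_record(pid="P001", survival=None, profile_kwargs=None,
                panel_kwargs=None) -> PatientRecord:
    profile = make_profile(patient_id=pid, **(profile_kwargs or {}))
    panel = make_panel(**(panel_kwargs or {}))
    return PatientRecord(profile=profile, panel=panel, survival=survival)


@pytest.fixture
def nsmp_low_risk_record():
    return make_record(survival=SurvivalRecord(time=24.0, event=False))
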