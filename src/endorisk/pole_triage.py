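"""Histopathologic triage of which tumors need POLE sequencing.

MMR and p53 immunohistochemistry are assumed performed on every case; the
triage only decides where POLE sequencing can change the 2020 risk class.
Advanced-stage (III/IV) disease is high risk or worse regardless of the
molecular subgroup, and clinicopathologic low-risk cases cannot be raised
by a POLE result, so both are exempt.  Everything else needs the test and
carries at least one of the four trigger features: non-endometrioid
histotype, high grade, substantial LVSI, or stage IB-II.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .core_model import (
    ClinicopathologicProfile,
    FigoStage,
    Grade,
    Lvsi,
    PatientRecord,
    PoleStatus,
)
from .molecular_classification import (
    PoleRuleset,
    classify_panel,
    resolve_pole_status,
)
from .risk_stratification import (
    RiskClass,
    RuleTables,
    classify_esgo2020,
)

ADVANCED_STAGES = {FigoStage.III, FigoStage.IVA, FigoStage.IVB}
STAGE_IB_II = {FigoStage.IB, FigoStage.II}


class Exemption(str, Enum):
    NONE = "none"
    LOW_RISK = "low_risk_clinicopathologic"
    ADVANCED = "advanced_stage"


@dataclass(frozen=True)
class TriageDecision:
    needs_pole_test: bool
    reasons: tuple[str, ...]     # criterion tags, empty when exempt
    exemption: Exemption


@dataclass
class TriageReport:
    n_total: int
    n_tested: int
    n_spared: int
    n_spared_low_risk: int
    n_spared_advanced: int
    reduction_fraction: float
    discordant_patients: list[str] = field(default_factory=list)
    decisions: dict[str, TriageDecision] = field(default_factory=dict)


def triage_patient(profile: ClinicopathologicProfile,
                   tables: Optional[RuleTables] = None) -> TriageDecision:
    """Decide whether one tumor needs POLE sequencing.

    The low-risk exemption is evaluated through the 2020 molecular-unknown
    classifier; the trigger reasons are re-derived from the raw profile so
    each tag is independently checkable.
    """
    if profile.figo_stage is None or profile.grade is None:
        raise ValueError(f"patient {profile.patient_id}: incomplete profile")
    if profile.figo_stage in ADVANCED_STAGES:
        return TriageDecision(False, (), Exemption.ADVANCED)
    unknown_class = classify_esgo2020(profile, None, tables).risk_class
    if unknown_class == RiskClass.LOW:
        return TriageDecision(False, (), Exemption.LOW_RISK)
    reasons = []
    if not profile.is_endometrioid:
        reasons.append("non_endometrioid")
    if profile.grade == Grade.HIGH:
        reasons.append("high_grade")
    if profile.lvsi == Lvsi.SUBSTANTIAL:
        reasons.append("substantial_lvsi")
    if profile.figo_stage in STAGE_IB_II:
        reasons.append("stage_IB_II")
    return TriageDecision(True, tuple(reasons), Exemption.NONE)


def evaluate_triage(records: Iterable[PatientRecord],
                    pole_ruleset: Optional[PoleRuleset] = None,
                    tables: Optional[RuleTables] = None) -> TriageReport:
    """Apply the triage to a fully tested cohort and audit concordance.

    Every patient must carry a true POLE status (explicit or derivable from
    variant calls) so that the class under triage — where a spared case is
    classified from MMR/p53 alone with POLE assumed wild-type — can be
    compared with the class under universal testing.
    """
    pole_ruleset = pole_ruleset or PoleRuleset()
    records = list(records)
    decisions: dict[str, TriageDecision] = {}
    discordant: list[str] = []
    n_low = n_adv = n_tested = 0
    for rec in records:
        if resolve_pole_status(rec.panel, pole_ruleset) == PoleStatus.NOT_TESTED:
            raise ValueError(
                f"patient {rec.patient_id}: true POLE status unavailable; "
                "the concordance audit requires a fully tested cohort")
        decision = triage_patient(rec.profile, tables)
        decisions[rec.patient_id] = decision
        if decision.exemption == Exemption.LOW_RISK:
            n_low += 1
        elif decision.exemption == Exemption.ADVANCED:
            n_adv += 1
        else:
            n_tested += 1

        full_call = classify_panel(rec.panel, pole_ruleset)
        if decision.needs_pole_test:
            triaged_call = full_call
        else:
            spared_panel = type(rec.panel)(
                p53_pattern=rec.panel.p53_pattern,
                mlh1=rec.panel.mlh1, pms2=rec.panel.pms2,
                msh2=rec.panel.msh2, msh6=rec.panel.msh6,
                pole=PoleStatus.NOT_TESTED, variants=None)
            triaged_call = classify_panel(spared_panel, pole_ruleset,
                                          assume_pole_wildtype=True)
        full_cls = classify_esgo2020(rec.profile, full_call, tables).risk_class
        triaged_cls = classify_esgo2020(rec.profile, triaged_call,
                                        tables).risk_class
        if full_cls != triaged_cls:
            discordant.append(rec.patient_id)

    n_total = len(records)
    n_spared = n_low + n_adv
    return TriageReport(
        n_total=n_total,
        n_tested=n_tested,
        n_spared=n_spared,
        n_spared_low_risk=n_low,
        n_spared_advanced=n_adv,
        reduction_fraction=(n_spared / n_total) if n_total else 0.0,
        discordant_patients=discordant,
        decisions=decisions,
    )
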