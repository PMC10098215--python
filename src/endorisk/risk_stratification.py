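"""Prognostic risk-group assignment under ESMO 2016 and ESGO/ESTRO/ESP 2020.

The rule tables live in a versioned YAML resource
(``endorisk/rules/risk_rules.yaml``) as ordered first-match rule lists over
a small derived feature vector, so the tables can be inspected and
overridden without touching code.  Three systems are exposed:

* ``esmo2016`` — clinicopathologic only; LVSI binarized (focal = positive).
* ``esgo2020_unknown`` — 2020 guidelines without molecular data; focal LVSI
  is grouped with absent.
* ``esgo2020_known`` — 2020 guidelines with the molecular subgroup
  integrated: early-stage POLE-mutant disease is low risk, p53abn with
  myometrial invasion is high risk, advanced stage overrides everything.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .core_model import (
    ClinicopathologicProfile,
    Lvsi,
    PatientRecord,
)
from .molecular_classification import (
    InsufficientMarkersError,
    MolecularCall,
    PoleRuleset,
    Subgroup,
    classify_panel,
)


class RiskClass(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH_INTERMEDIATE = "high_intermediate"
    HIGH = "high"
    ADVANCED_METASTATIC = "advanced_metastatic"


#: Fixed class ordering used for migration matrices and direction-of-change.
RISK_ORDER: list[RiskClass] = [
    RiskClass.LOW,
    RiskClass.INTERMEDIATE,
    RiskClass.HIGH_INTERMEDIATE,
    RiskClass.HIGH,
    RiskClass.ADVANCED_METASTATIC,
]

SYSTEMS = ("esmo2016", "esgo2020_unknown", "esgo2020_known")


@dataclass(frozen=True)
class RiskAssignment:
    system: str          # esmo2016 | esgo2020
    mode: str            # unknown | known
    risk_class: RiskClass
    fired_rule: str      # YAML rule id

    @property
    def label(self) -> str:
        return f"{self.system}_{self.mode}" if self.system == "esgo2020" \
            else self.system


class RuleTableError(ValueError):
    pass


def _load_rule_doc(path: Optional[str | Path] = None) -> dict:
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    text = resources.files("endorisk").joinpath("rules/risk_rules.yaml") \
        .read_text()
    return yaml.safe_load(text)


class RuleTables:
    """Ordered first-match rule tables for all risk systems."""

    def __init__(self, path: Optional[str | Path] = None):
        doc = _load_rule_doc(path)
        self.version = doc.get("version")
        self.systems: dict[str, list[dict]] = doc["systems"]
        for name in SYSTEMS:
            if name not in self.systems:
                raise RuleTableError(f"rule table missing system {name!r}")
        canon = yaml.safe_dump(doc, sort_keys=True).encode()
        #: content hash recorded in outputs for provenance
        self.digest = hashlib.sha256(canon).hexdigest()[:12]

    def classify(self, system: str, features: dict[str, str]) -> tuple[RiskClass, str]:
        for rule in self.systems[system]:
            cond = rule["when"]
            if all(features[k] in v for k, v in cond.items()):
                return RiskClass(rule["class"]), rule["id"]
        raise RuleTableError(
            f"no {system} rule matched features {features!r}")


_DEFAULT_TABLES: Optional[RuleTables] = None


def default_tables() -> RuleTables:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = RuleTables()
    return _DEFAULT_TABLES


def _features(profile: ClinicopathologicProfile,
              subgroup: Optional[Subgroup]) -> dict[str, str]:
    if profile.figo_stage is None:
        raise RuleTableError(
            f"patient {profile.patient_id}: stage is required "
            "for risk classification")
    return {
        "stage": profile.figo_stage.value,
        "histo": ("endometrioid" if profile.is_endometrioid
                  else "non_endometrioid"),
        "grade": profile.grade.value,
        "lvsi": profile.lvsi.value,
        "lvsi_binary": ("negative" if profile.lvsi == Lvsi.ABSENT
                        else "positive"),
        "invaded": "true" if profile.has_myometrial_invasion else "false",
        "depth": profile.myometrial_invasion.value,
        "residual": "true" if profile.residual_disease else "false",
        "subgroup": subgroup.value if subgroup is not None else "unknown",
    }


def classify_esmo2016(profile: ClinicopathologicProfile,
                      tables: Optional[RuleTables] = None) -> RiskAssignment:
    """ESMO 2016 five-class assignment from clinicopathologic data alone."""
    tables = tables or default_tables()
    cls, rule = tables.classify("esmo2016", _features(profile, None))
    return RiskAssignment("esmo2016", "unknown", cls, rule)


def classify_esgo2020(profile: ClinicopathologicProfile,
                      molecular: Optional[MolecularCall] = None,
                      tables: Optional[RuleTables] = None) -> RiskAssignment:
    """ESGO/ESTRO/ESP 2020 assignment; known mode iff ``molecular`` given."""
    tables = tables or default_tables()
    if molecular is None:
        cls, rule = tables.classify("esgo2020_unknown",
                                    _features(profile, None))
        return RiskAssignment("esgo2020", "unknown", cls, rule)
    if molecular.subgroup is None:
        raise InsufficientMarkersError(
            f"patient {profile.patient_id}: molecular call has no subgroup")
    cls, rule = tables.classify("esgo2020_known",
                                _features(profile, molecular.subgroup))
    return RiskAssignment("esgo2020", "known", cls, rule)


def classify_patient_all(record: PatientRecord,
                         systems: Sequence[str] = SYSTEMS,
                         pole_ruleset: Optional[PoleRuleset] = None,
                         tables: Optional[RuleTables] = None
                         ) -> dict[str, RiskAssignment]:
    """All requested risk assignments for one patient."""
    pole_ruleset = pole_ruleset or PoleRuleset()
    out = {}
    for system in systems:
        if system == "esmo2016":
            out[system] = classify_esmo2016(record.profile, tables)
        elif system == "esgo2020_unknown":
            out[system] = classify_esgo2020(record.profile, None, tables)
        elif system == "esgo2020_known":
            call = classify_panel(record.panel, pole_ruleset)
            out[system] = classify_esgo2020(record.profile, call, tables)
        else:
            raise ValueError(f"unknown risk system {system!r}")
    return out


def classify_cohort(records: Iterable[PatientRecord],
                    systems: Sequence[str] = SYSTEMS,
                    pole_ruleset: Optional[PoleRuleset] = None,
                    tables: Optional[RuleTables] = None
                    ) -> tuple[pd.DataFrame, list[dict]]:
    """Risk assignments for a cohort.

    Returns a long-format table (patient_id, system, mode, risk_class,
    fired_rule) plus an error report; patients failing a mode's
    preconditions (e.g. POLE never tested while known-mode classification
    was requested) are reported, not silently dropped.
    """
    rows, errors = [], []
    for rec in records:
        for system in systems:
            try:
                asg = classify_patient_all(rec, [system], pole_ruleset,
                                           tables)[system]
            except (InsufficientMarkersError, RuleTableError) as exc:
                errors.append({"patient_id": rec.patient_id,
                               "system": system, "error": str(exc)})
                continue
            rows.append({
                "patient_id": rec.patient_id,
                "system": system,
                "mode": asg.mode,
                "risk_class": asg.risk_class.value,
                "fired_rule": asg.fired_rule,
            })
    columns = ["patient_id", "system", "mode", "risk_class", "fired_rule"]
    return pd.DataFrame(rows, columns=columns), errors
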