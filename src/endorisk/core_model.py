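"""Domain types, controlled vocabularies, validation and cohort CSV I/O.

Every categorical variable used anywhere in the pipeline is drawn from one of
the enums below; free-text categories are rejected at parse time.  Missing
values are encoded explicitly (``unknown`` / ``not_done`` / ``None``) and are
never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd


class CohortSchemaError(ValueError):
    """Raised when a cohort file's header does not match the schema."""


class CohortParseError(ValueError):
    """Raised when a cell cannot be parsed; carries row/column context."""


class Histotype(str, Enum):
    ENDOMETRIOID = "endometrioid"
    SEROUS = "serous"
    CLEAR_CELL = "clear_cell"
    UNDIFF_DEDIFF = "undifferentiated_dedifferentiated"
    CARCINOSARCOMA = "carcinosarcoma"
    MIXED = "mixed"


class Grade(str, Enum):
    """Binary grade: low = FIGO G1-G2, high = FIGO G3."""

    LOW = "low"
    HIGH = "high"


class MyometrialInvasion(str, Enum):
    NONE = "none"
    LT50 = "lt50"
    GE50 = "ge50"


class Lvsi(str, Enum):
    """Three-tier lymphovascular space invasion.

    ``focal`` is a single focus around the tumor; ``substantial`` is diffuse
    or multifocal.  2016-era rules binarize focal|substantial as positive,
    2020 rules group absent|focal together.
    """

    ABSENT = "absent"
    FOCAL = "focal"
    SUBSTANTIAL = "substantial"


class LymphNodes(str, Enum):
    NEGATIVE = "negative"
    POSITIVE = "positive"
    UNKNOWN = "unknown"


class FigoStage(str, Enum):
    IA = "IA"
    IB = "IB"
    II = "II"
    III = "III"
    IVA = "IVA"
    IVB = "IVB"


class P53Pattern(str, Enum):
    """p53 immunohistochemistry pattern.

    Overexpression, null pattern and cytoplasmic staining are all
    mutant-like (abnormal); anything else scored is wild-type.
    """

    WILDTYPE = "wildtype"
    OVEREXPRESSION = "overexpression"
    NULL_PATTERN = "null_pattern"
    CYTOPLASMIC = "cytoplasmic"
    NOT_DONE = "not_done"


class MmrStain(str, Enum):
    RETAINED = "retained"
    LOST = "lost"
    NOT_DONE = "not_done"


class PoleStatus(str, Enum):
    PATHOGENIC = "pathogenic"
    WILDTYPE = "wildtype"
    NOT_TESTED = "not_tested"


#: Stages on which gross residual disease after surgery is a legal annotation.
RESIDUAL_ELIGIBLE_STAGES = {FigoStage.III, FigoStage.IVA, FigoStage.IVB}

NON_ENDOMETRIOID = {
    Histotype.SEROUS,
    Histotype.CLEAR_CELL,
    Histotype.UNDIFF_DEDIFF,
    Histotype.CARCINOSARCOMA,
    Histotype.MIXED,
}


@dataclass
class VariantCall:
    """One somatic variant call from a targeted sequencing panel."""

    gene: str
    protein_change: str
    exon: int
    vaf: float
    reads_forward: int
    reads_reverse: int

    def violations(self) -> list[str]:
        out = []
        if not (0.0 <= self.vaf <= 1.0):
            out.append(f"vaf: {self.vaf} outside [0, 1]")
        if self.reads_forward < 0 or self.reads_reverse < 0:
            out.append("reads: strand counts must be non-negative")
        return out


@dataclass
class ClinicopathologicProfile:
    patient_id: str
    histotype: Histotype
    grade: Grade
    myometrial_invasion: MyometrialInvasion
    lvsi: Lvsi
    lymph_nodes: LymphNodes
    figo_stage: FigoStage
    residual_disease: bool = False
    age: Optional[float] = None
    bmi: Optional[float] = None

    @property
    def is_endometrioid(self) -> bool:
        return self.histotype == Histotype.ENDOMETRIOID

    @property
    def has_myometrial_invasion(self) -> bool:
        return self.myometrial_invasion != MyometrialInvasion.NONE


@dataclass
class MarkerPanel:
    """IHC results plus POLE sequencing status (or raw variant calls)."""

    p53_pattern: P53Pattern = P53Pattern.NOT_DONE
    mlh1: MmrStain = MmrStain.NOT_DONE
    pms2: MmrStain = MmrStain.NOT_DONE
    msh2: MmrStain = MmrStain.NOT_DONE
    msh6: MmrStain = MmrStain.NOT_DONE
    pole: PoleStatus = PoleStatus.NOT_TESTED
    variants: Optional[list[VariantCall]] = None


@dataclass
class SurvivalRecord:
    """Disease-free survival follow-up; any recurrence counts as an event."""

    time: float  # months
    event: bool

    def violations(self) -> list[str]:
        if not (math.isfinite(self.time) and self.time > 0):
            return [f"dfs_months: {self.time} must be finite and > 0"]
        return []


@dataclass
class PatientRecord:
    profile: ClinicopathologicProfile
    panel: MarkerPanel
    survival: Optional[SurvivalRecord] = None

    @property
    def patient_id(self) -> str:
        return self.profile.patient_id


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def validate_patient(profile: ClinicopathologicProfile,
                     panel: MarkerPanel) -> list[str]:
    """Return a list of violation descriptors; empty iff the record is valid.

    Violations are returned, never raised, so callers can aggregate them
    into row-level reports.
    """
    out: list[str] = []

    def _check_enum(name, value, enum_cls):
        if not isinstance(value, enum_cls):
            try:
                enum_cls(value)
            except ValueError:
                out.append(f"{name}: {value!r} is not a legal value "
                           f"({', '.join(e.value for e in enum_cls)})")

    _check_enum("histotype", profile.histotype, Histotype)
    _check_enum("grade", profile.grade, Grade)
    _check_enum("myometrial_invasion", profile.myometrial_invasion,
                MyometrialInvasion)
    _check_enum("lvsi", profile.lvsi, Lvsi)
    _check_enum("lymph_nodes", profile.lymph_nodes, LymphNodes)
    _check_enum("figo_stage", profile.figo_stage, FigoStage)
    _check_enum("p53_ihc", panel.p53_pattern, P53Pattern)
    for name in ("mlh1", "pms2", "msh2", "msh6"):
        _check_enum(name, getattr(panel, name), MmrStain)
    _check_enum("pole_status", panel.pole, PoleStatus)

    if profile.residual_disease and profile.figo_stage not in RESIDUAL_ELIGIBLE_STAGES:
        out.append("residual_disease: only legal for stage III/IVA/IVB, "
                   f"got stage {getattr(profile.figo_stage, 'value', profile.figo_stage)}")
    if profile.age is not None and not (0 < profile.age < 130):
        out.append(f"age_years: implausible value {profile.age}")
    if profile.bmi is not None and not (5 < profile.bmi < 120):
        out.append(f"bmi: implausible value {profile.bmi}")
    if panel.variants:
        for i, v in enumerate(panel.variants):
            out.extend(f"variants[{i}].{msg}" for msg in v.violations())
    return out


# --------------------------------------------------------------------------
# Cohort CSV serialization
# --------------------------------------------------------------------------

COHORT_COLUMNS = [
    "patient_id", "age_years", "bmi", "histotype", "grade",
    "myometrial_invasion", "lvsi", "lymph_nodes", "figo_stage",
    "residual_disease", "p53_ihc", "mlh1", "pms2", "msh2", "msh6",
    "pole_status", "dfs_months", "recurrence_event",
]

VARIANT_COLUMNS = [
    "patient_id", "gene", "protein_change", "exon", "vaf",
    "reads_forward", "reads_reverse",
]

_GRADE_ALIASES = {
    "low": Grade.LOW, "high": Grade.HIGH,
    "g1": Grade.LOW, "g2": Grade.LOW, "g3": Grade.HIGH,
    "1": Grade.LOW, "2": Grade.LOW, "3": Grade.HIGH,
}

_BOOL_ALIASES = {
    "true": True, "1": True, "yes": True,
    "false": False, "0": False, "no": False,
}


def _is_missing(cell) -> bool:
    return cell is None or (isinstance(cell, float) and math.isnan(cell)) \
        or str(cell).strip() in ("", "NA")


def parse_stage(raw: str, residual: bool = False) -> FigoStage:
    """Parse a FIGO stage, resolving coarse 'IV' to IVA/IVB.

    Source tables often report stage IV without the A/B split; ``IV`` is
    resolved to IVA unless the residual/metastatic flag marks IVB.  Bare
    ``I`` is ambiguous between IA and IB and is rejected.
    """
    s = raw.strip().upper()
    if s == "IV":
        return FigoStage.IVB if residual else FigoStage.IVA
    try:
        return FigoStage(s)
    except ValueError:
        raise CohortParseError(f"unrecognized FIGO stage {raw!r}") from None


def parse_grade(raw: str) -> Grade:
    key = raw.strip().lower()
    if key in _GRADE_ALIASES:
        return _GRADE_ALIASES[key]
    raise CohortParseError(f"unrecognized grade {raw!r}")


def _parse_bool(raw) -> bool:
    key = str(raw).strip().lower()
    if key in _BOOL_ALIASES:
        return _BOOL_ALIASES[key]
    raise CohortParseError(f"unrecognized boolean {raw!r}")


def _parse_row(row: dict, row_no: int) -> PatientRecord:
    def cell(col):
        return row[col]

    def enum_cell(col, enum_cls, missing):
        raw = cell(col)
        if _is_missing(raw):
            return missing
        try:
            return enum_cls(str(raw).strip().lower()
                            if enum_cls is not FigoStage else str(raw).strip())
        except ValueError:
            raise CohortParseError(
                f"row {row_no}, column {col}: illegal value {raw!r}") from None

    try:
        residual = (False if _is_missing(cell("residual_disease"))
                    else _parse_bool(cell("residual_disease")))
        stage_raw = cell("figo_stage")
        if _is_missing(stage_raw):
            raise CohortParseError("figo_stage is required")
        profile = ClinicopathologicProfile(
            patient_id=str(cell("patient_id")).strip(),
            age=None if _is_missing(cell("age_years")) else float(cell("age_years")),
            bmi=None if _is_missing(cell("bmi")) else float(cell("bmi")),
            histotype=enum_cell("histotype", Histotype, None),
            grade=parse_grade(str(cell("grade"))),
            myometrial_invasion=enum_cell("myometrial_invasion",
                                          MyometrialInvasion, None),
            lvsi=enum_cell("lvsi", Lvsi, Lvsi.ABSENT),
            lymph_nodes=enum_cell("lymph_nodes", LymphNodes,
                                  LymphNodes.UNKNOWN),
            figo_stage=parse_stage(str(stage_raw), residual),
            residual_disease=residual,
        )
        if profile.histotype is None:
            raise CohortParseError("histotype is required")
        if profile.myometrial_invasion is None:
            raise CohortParseError("myometrial_invasion is required")
        panel = MarkerPanel(
            p53_pattern=enum_cell("p53_ihc", P53Pattern, P53Pattern.NOT_DONE),
            mlh1=enum_cell("mlh1", MmrStain, MmrStain.NOT_DONE),
            pms2=enum_cell("pms2", MmrStain, MmrStain.NOT_DONE),
            msh2=enum_cell("msh2", MmrStain, MmrStain.NOT_DONE),
            msh6=enum_cell("msh6", MmrStain, MmrStain.NOT_DONE),
            pole=enum_cell("pole_status", PoleStatus, PoleStatus.NOT_TESTED),
        )
        survival = None
        if not _is_missing(cell("dfs_months")):
            survival = SurvivalRecord(
                time=float(cell("dfs_months")),
                event=(False if _is_missing(cell("recurrence_event"))
                       else _parse_bool(cell("recurrence_event"))),
            )
        return PatientRecord(profile=profile, panel=panel, survival=survival)
    except CohortParseError as exc:
        raise CohortParseError(f"row {row_no}: {exc}") from None
    except (TypeError, ValueError) as exc:
        raise CohortParseError(f"row {row_no}: {exc}") from None


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV into validated patient records.

    The header must contain exactly the schema columns; empty cells and
    ``NA`` are missing.  Row numbers (1-based data rows) are preserved in
    error messages.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(
            f"cohort file {path} is missing required columns: "
            + ", ".join(missing))
    records = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        records.append(_parse_row(row, i))
    return records


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records as a cohort CSV; ``read_cohort`` round-trips it."""
    rows = []
    for rec in records:
        p, m, s = rec.profile, rec.panel, rec.survival
        rows.append({
            "patient_id": p.patient_id,
            "age_years": "" if p.age is None else repr(p.age),
            "bmi": "" if p.bmi is None else repr(p.bmi),
            "histotype": p.histotype.value,
            "grade": p.grade.value,
            "myometrial_invasion": p.myometrial_invasion.value,
            "lvsi": p.lvsi.value,
            "lymph_nodes": p.lymph_nodes.value,
            "figo_stage": p.figo_stage.value,
            "residual_disease": str(p.residual_disease).lower(),
            "p53_ihc": m.p53_pattern.value,
            "mlh1": m.mlh1.value,
            "pms2": m.pms2.value,
            "msh2": m.msh2.value,
            "msh6": m.msh6.value,
            "pole_status": m.pole.value,
            "dfs_months": "" if s is None else repr(s.time),
            "recurrence_event": "" if s is None else str(s.event).lower(),
        })
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_variants_csv(path: str | Path) -> dict[str, list[VariantCall]]:
    """Read a per-patient variants table keyed by patient_id."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(
            f"variants file {path} is missing required columns: "
            + ", ".join(missing))
    out: dict[str, list[VariantCall]] = {}
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            call = VariantCall(
                gene=row["gene"].strip(),
                protein_change=row["protein_change"].strip(),
                exon=int(row["exon"]),
                vaf=float(row["vaf"]),
                reads_forward=int(row["reads_forward"]),
                reads_reverse=int(row["reads_reverse"]),
            )
        except (TypeError, ValueError) as exc:
            raise CohortParseError(f"variants row {i}: {exc}") from None
        bad = call.violations()
        if bad:
            raise CohortParseError(f"variants row {i}: " + "; ".join(bad))
        out.setdefault(row["patient_id"].strip(), []).append(call)
    return out


def write_variants_csv(variants: dict[str, list[VariantCall]],
                       path: str | Path) -> None:
    rows = []
    for pid, calls in variants.items():
        for v in calls:
            rows.append({
                "patient_id": pid, "gene": v.gene,
                "protein_change": v.protein_change, "exon": v.exon,
                "vaf": f"{v.vaf:g}", "reads_forward": v.reads_forward,
                "reads_reverse": v.reads_reverse,
            })
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, index=False)


def read_variants_vcf(path: str | Path,
                      patient_id: Optional[str] = None
                      ) -> dict[str, list[VariantCall]]:
    """Read variant calls from a VCF 4.x file.

    Annotation is taken from INFO keys when present: ``GENE`` (symbol),
    ``AA`` or ``HGVSP`` (protein change), ``EXON``, ``AF``/``VAF``
    (allele fraction), ``SAF``/``SAR`` (alt reads on forward/reverse
    strand, the Torrent convention).  Records missing gene or protein
    annotation are skipped — they cannot take part in whitelist matching.
    The patient id defaults to the single sample name, or the file stem
    for sample-less VCFs.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if patient_id is None:
        patient_id = vcf.samples[0] if vcf.samples else Path(path).stem
    calls: list[VariantCall] = []
    for rec in vcf:
        gene = rec.INFO.get("GENE")
        prot = rec.INFO.get("AA") or rec.INFO.get("HGVSP")
        if gene is None or prot is None:
            continue
        vaf = rec.INFO.get("AF", rec.INFO.get("VAF"))
        if vaf is None:
            vaf = 0.0
        exon = int(rec.INFO.get("EXON", 0))
        saf = int(rec.INFO.get("SAF", 0))
        sar = int(rec.INFO.get("SAR", 0))
        calls.append(VariantCall(gene=str(gene), protein_change=str(prot),
                                 exon=exon, vaf=float(vaf),
                                 reads_forward=saf, reads_reverse=sar))
    return {patient_id: calls}
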