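"""TCGA-surrogate molecular subgroup assignment.

Interprets p53 immunohistochemistry, the four mismatch-repair protein
stains, and POLE exonuclease-domain sequencing, then resolves the final
subgroup through the diagnostic hierarchy POLE > MMRd > p53abn > NSMP.
Tumors positive for two or more classifiers ("multiple classifiers") are
resolved by the same hierarchy and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import yaml

from .core_model import (
    MarkerPanel,
    MmrStain,
    P53Pattern,
    PoleStatus,
    VariantCall,
)


class InsufficientMarkersError(ValueError):
    """A molecular-known classification was requested without the markers."""


class Subgroup(str, Enum):
    POLE = "POLE"
    MMRD = "MMRd"
    P53ABN = "p53abn"
    NSMP = "NSMP"


class MmrStatus(str, Enum):
    DEFICIENT = "deficient"
    PROFICIENT = "proficient"
    NOT_DONE = "not_done"


class P53Status(str, Enum):
    ABNORMAL = "abnormal"
    WILDTYPE = "wildtype"
    NOT_DONE = "not_done"


#: Canonical pathogenic POLE exonuclease-domain hotspots.  Whitelist
#: membership, not a full variant-scoring schema, is what the engine checks;
#: users can override via :class:`PoleRuleset` / YAML config.
DEFAULT_POLE_WHITELIST = frozenset({
    "p.P286R", "p.V411L", "p.S297F", "p.S459F", "p.F367S", "p.L424I",
    "p.M295R", "p.P436R", "p.M444K", "p.D368Y", "p.A456P",
})


@dataclass(frozen=True)
class PoleRuleset:
    """Variant filtering and pathogenicity rules for POLE sequencing.

    Calls must reach ``vaf_min`` allele fraction (clinical panels commonly
    require at least 5% of reads) and, when ``require_both_strands`` is set,
    be supported by reads on both strands.  A tumor is POLE-mutant when any
    retained call in the covered exonuclease-domain exons matches the
    pathogenic whitelist.
    """

    whitelist: frozenset[str] = DEFAULT_POLE_WHITELIST
    covered_exons: frozenset[int] = frozenset(range(9, 15))
    vaf_min: float = 0.05
    require_both_strands: bool = True

    def __post_init__(self):
        if not (0.0 < self.vaf_min < 1.0):
            raise ValueError(f"vaf_min must be in (0, 1), got {self.vaf_min}")
        if not self.whitelist:
            raise ValueError("pathogenic whitelist must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "PoleRuleset":
        """Load a ``pole_ruleset:`` block from a YAML config file."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        block = doc.get("pole_ruleset", doc)
        kwargs = {}
        if "whitelist" in block:
            kwargs["whitelist"] = frozenset(block["whitelist"])
        if "covered_exons" in block:
            kwargs["covered_exons"] = frozenset(int(e)
                                                for e in block["covered_exons"])
        if "vaf_min" in block:
            kwargs["vaf_min"] = float(block["vaf_min"])
        if "require_both_strands" in block:
            kwargs["require_both_strands"] = bool(block["require_both_strands"])
        return cls(**kwargs)


@dataclass
class MolecularCall:
    """Per-marker statuses and the resolved TCGA-surrogate subgroup."""

    pole_status: PoleStatus
    mmr_status: MmrStatus
    p53_status: P53Status
    subgroup: Subgroup
    classifier_profile: frozenset[Subgroup]
    multiple_classifier: bool
    #: True when the POLE status used for classification was assumed
    #: wild-type (triage spared the test) rather than measured.
    pole_assumed: bool = False


def interpret_p53(pattern: P53Pattern) -> P53Status:
    """Map a p53 IHC pattern to normal/mutant-like status.

    Overexpression, null phenotype and cytoplasmic staining are all
    mutant-like surrogates for TP53 mutation.
    """
    pattern = P53Pattern(pattern)
    if pattern == P53Pattern.NOT_DONE:
        return P53Status.NOT_DONE
    if pattern == P53Pattern.WILDTYPE:
        return P53Status.WILDTYPE
    return P53Status.ABNORMAL


def interpret_mmr(mlh1: MmrStain, pms2: MmrStain,
                  msh2: MmrStain, msh6: MmrStain) -> MmrStatus:
    """Mismatch-repair status from the four protein stains.

    Loss of any one of MLH1/PMS2/MSH2/MSH6 (which covers the paired
    MLH1-PMS2 and MSH2-MSH6 loss patterns) means deficient; deficiency
    trumps an incomplete panel, so a single lost stain is conclusive even
    if another was not done.
    """
    stains = [MmrStain(s) for s in (mlh1, pms2, msh2, msh6)]
    if any(s == MmrStain.LOST for s in stains):
        return MmrStatus.DEFICIENT
    if any(s == MmrStain.NOT_DONE for s in stains):
        return MmrStatus.NOT_DONE
    return MmrStatus.PROFICIENT


def filter_variants(calls: Iterable[VariantCall],
                    ruleset: PoleRuleset = PoleRuleset()) -> list[VariantCall]:
    """Apply allele-fraction and strand filters, preserving order.

    A call survives when ``vaf >= vaf_min`` ("at least" is inclusive) and,
    if required, it has supporting reads on both strands.
    """
    kept = []
    for c in calls:
        if c.vaf < ruleset.vaf_min:
            continue
        if ruleset.require_both_strands and (c.reads_forward <= 0
                                             or c.reads_reverse <= 0):
            continue
        kept.append(c)
    return kept


def interpret_pole(calls: Optional[Iterable[VariantCall]],
                   ruleset: PoleRuleset = PoleRuleset()) -> PoleStatus:
    """POLE status from already-filtered variant calls.

    ``None`` means no sequencing was performed (not tested).  Pathogenic
    iff any POLE call within the covered exonuclease-domain exons matches
    the whitelist; otherwise wild-type.
    """
    if calls is None:
        return PoleStatus.NOT_TESTED
    for c in calls:
        if (c.gene == "POLE" and c.exon in ruleset.covered_exons
                and c.protein_change in ruleset.whitelist):
            return PoleStatus.PATHOGENIC
    return PoleStatus.WILDTYPE


def resolve_pole_status(panel: MarkerPanel,
                        ruleset: PoleRuleset = PoleRuleset()) -> PoleStatus:
    """POLE status for a marker panel, preferring an explicit result.

    Falls back to filtering + interpreting raw variant calls when the
    panel carries them instead of a called status.
    """
    if panel.pole != PoleStatus.NOT_TESTED:
        return PoleStatus(panel.pole)
    if panel.variants is not None:
        return interpret_pole(filter_variants(panel.variants, ruleset), ruleset)
    return PoleStatus.NOT_TESTED


def assign_subgroup(pole_status: PoleStatus,
                    mmr_status: MmrStatus,
                    p53_status: P53Status,
                    pole_assumed: bool = False) -> MolecularCall:
    """Resolve the final molecular subgroup through the hierarchy.

    All three markers must be determinate; a not-tested / not-done input
    raises :class:`InsufficientMarkersError` rather than guessing.  The
    classifier profile records every positive marker so multiple-classifier
    tumors stay auditable after resolution.
    """
    pole_status = PoleStatus(pole_status)
    mmr_status = MmrStatus(mmr_status)
    p53_status = P53Status(p53_status)
    missing = []
    if pole_status == PoleStatus.NOT_TESTED:
        missing.append("POLE not tested")
    if mmr_status == MmrStatus.NOT_DONE:
        missing.append("MMR IHC not done")
    if p53_status == P53Status.NOT_DONE:
        missing.append("p53 IHC not done")
    if missing:
        raise InsufficientMarkersError(
            "insufficient markers for molecular-known classification: "
            + "; ".join(missing))

    profile = set()
    if pole_status == PoleStatus.PATHOGENIC:
        profile.add(Subgroup.POLE)
    if mmr_status == MmrStatus.DEFICIENT:
        profile.add(Subgroup.MMRD)
    if p53_status == P53Status.ABNORMAL:
        profile.add(Subgroup.P53ABN)

    if Subgroup.POLE in profile:
        subgroup = Subgroup.POLE
    elif Subgroup.MMRD in profile:
        subgroup = Subgroup.MMRD
    elif Subgroup.P53ABN in profile:
        subgroup = Subgroup.P53ABN
    else:
        subgroup = Subgroup.NSMP

    return MolecularCall(
        pole_status=pole_status,
        mmr_status=mmr_status,
        p53_status=p53_status,
        subgroup=subgroup,
        classifier_profile=frozenset(profile),
        multiple_classifier=len(profile) >= 2,
        pole_assumed=pole_assumed,
    )


def classify_panel(panel: MarkerPanel,
                   ruleset: PoleRuleset = PoleRuleset(),
                   assume_pole_wildtype: bool = False) -> MolecularCall:
    """Full marker-panel interpretation to a molecular call.

    With ``assume_pole_wildtype`` an untested POLE is treated as wild-type
    and flagged as assumed — the semantics under which triage-spared cases
    are classified from MMR/p53 alone.
    """
    pole = resolve_pole_status(panel, ruleset)
    assumed = False
    if pole == PoleStatus.NOT_TESTED and assume_pole_wildtype:
        pole, assumed = PoleStatus.WILDTYPE, True
    return assign_subgroup(
        pole,
        interpret_mmr(panel.mlh1, panel.pms2, panel.msh2, panel.msh6),
        interpret_p53(panel.p53_pattern),
        pole_assumed=assumed,
    )
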