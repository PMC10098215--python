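"""Seeded synthetic endometrial-carcinoma cohorts.

The generator emulates the statistical structure of a consecutive
surgical cohort of 211 endometrial carcinomas: TCGA-surrogate subgroup
prevalences of 7.6% POLE / 32.2% MMRd / 20.9% p53abn / 39.3% NSMP,
subgroup-conditional distributions of histotype, grade, depth of invasion,
LVSI, nodal status and FIGO stage taken from that cohort's published
cross-tabulation, a ~7.6% rate of multiple-classifier tumors, and
recurrence hazards that increase across the five 2020 risk classes.

Covariates are drawn independently within subgroup (only marginals are
published), so real-data correlations beyond the subgroup are not
reproduced; see the methods note for what that does and does not allow
tests to conclude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .core_model import (
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
    SurvivalRecord,
    VariantCall,
)
from .molecular_classification import (
    PoleRuleset,
    Subgroup,
    classify_panel,
)
from .risk_stratification import RiskClass, classify_esgo2020

SUBGROUPS = (Subgroup.POLE, Subgroup.MMRD, Subgroup.P53ABN, Subgroup.NSMP)

#: Exonuclease-domain exon for each whitelisted POLE hotspot (hg19 numbering
#: of the canonical transcript); only membership in exons 9-14 matters to
#: the classifier.
POLE_VARIANT_EXON = {
    "p.P286R": 9, "p.S297F": 9, "p.M295R": 9, "p.F367S": 9, "p.D368Y": 9,
    "p.V411L": 13, "p.L424I": 13, "p.P436R": 13,
    "p.M444K": 14, "p.A456P": 14, "p.S459F": 14,
}


class SpecError(ValueError):
    """Raised when a cohort spec violates its invariants."""


def _normalize(d: dict) -> dict:
    total = sum(d.values())
    return {k: v / total for k, v in d.items()}


@dataclass
class CohortSpec:
    """Parameters of the synthetic-cohort generative model.

    Probabilities are per-subgroup conditional categorical distributions;
    hazards are monthly exponential recurrence rates by 2020 molecular-known
    risk class and must increase strictly with the class.
    """

    n: int = 211
    seed: int = 0
    # final (hierarchy-resolved) subgroup prevalences
    subgroup_probs: dict[Subgroup, float] = field(default_factory=dict)
    histotype_by_subgroup: dict[Subgroup, dict[Histotype, float]] = \
        field(default_factory=dict)
    high_grade_by_subgroup: dict[Subgroup, float] = field(default_factory=dict)
    deep_invasion_by_subgroup: dict[Subgroup, float] = \
        field(default_factory=dict)
    lvsi_positive_by_subgroup: dict[Subgroup, float] = \
        field(default_factory=dict)
    nodes_by_subgroup: dict[Subgroup, dict[LymphNodes, float]] = \
        field(default_factory=dict)
    stage_by_subgroup: dict[Subgroup, dict[str, float]] = \
        field(default_factory=dict)   # coarse stages IA, IB_II, III, IV
    age_by_subgroup: dict[Subgroup, tuple[float, float]] = \
        field(default_factory=dict)   # (mean, sd) years
    bmi_by_subgroup: dict[Subgroup, tuple[float, float]] = \
        field(default_factory=dict)
    # whole-cohort rates of multiple-classifier combinations
    rate_pole_mmrd: float = 1 / 211
    rate_pole_p53: float = 4 / 211
    rate_mmrd_p53: float = 9 / 211
    rate_triple: float = 2 / 211
    # splits of coarse categories
    substantial_given_lvsi_positive: float = 75 / 141
    no_invasion_given_superficial: float = 1 / 3
    stage_ib_given_ib_ii: float = 32 / 42
    stage_ivb_given_iv: float = 0.5
    residual_prob_stage_iii_iva: float = 0.07
    # survival model
    hazard_per_risk_class: dict[RiskClass, float] = field(default_factory=dict)
    censor_rate: float = math.log(2) / 22.0   # median follow-up ~22 months
    follow_up_cap: float = 120.0
    # sequencing noise: chance a non-POLE-mutant tumor carries a call that
    # the filters / whitelist must reject
    passenger_variant_prob: float = 0.15

    def validate(self) -> list[str]:
        out = []
        def _check_probvec(name, d):
            if abs(sum(d.values()) - 1.0) > 1e-9:
                out.append(f"{name}: probabilities sum to {sum(d.values())}")
            if any(v < 0 for v in d.values()):
                out.append(f"{name}: negative probability")
        _check_probvec("subgroup_probs", self.subgroup_probs)
        for g in SUBGROUPS:
            _check_probvec(f"histotype_by_subgroup[{g.value}]",
                           self.histotype_by_subgroup[g])
            _check_probvec(f"nodes_by_subgroup[{g.value}]",
                           self.nodes_by_subgroup[g])
            _check_probvec(f"stage_by_subgroup[{g.value}]",
                           self.stage_by_subgroup[g])
        haz = [self.hazard_per_risk_class[c] for c in
               (RiskClass.LOW, RiskClass.INTERMEDIATE,
                RiskClass.HIGH_INTERMEDIATE, RiskClass.HIGH,
                RiskClass.ADVANCED_METASTATIC)]
        if not all(a < b for a, b in zip(haz, haz[1:])):
            out.append("hazard_per_risk_class: hazards must increase "
                       "strictly from low to advanced")
        if any(h <= 0 for h in haz) or self.censor_rate <= 0:
            out.append("hazards and censor_rate must be positive")
        for name in ("rate_pole_mmrd", "rate_pole_p53", "rate_mmrd_p53",
                     "rate_triple"):
            if not 0 <= getattr(self, name) < 1:
                out.append(f"{name}: must be a probability")
        if self.n <= 0:
            out.append("n must be positive")
        return out


def table2_defaults(n: int = 211, seed: int = 0) -> CohortSpec:
    """Cohort spec whose conditionals equal the published 211-patient
    cross-tabulation of clinicopathologic features by molecular subgroup.

    Cell probabilities are exact count ratios (e.g. 19 of 44 p53abn tumors
    are serous); the serous/clear-cell/carcinosarcoma mass sits entirely in
    p53abn, as observed.
    """
    P, M, A, N = SUBGROUPS
    spec = CohortSpec(
        n=n, seed=seed,
        subgroup_probs={P: 16 / 211, M: 68 / 211, A: 44 / 211, N: 83 / 211},
        histotype_by_subgroup={
            P: _normalize({Histotype.ENDOMETRIOID: 13,
                           Histotype.UNDIFF_DEDIFF: 3}),
            M: _normalize({Histotype.ENDOMETRIOID: 54,
                           Histotype.UNDIFF_DEDIFF: 14}),
            A: _normalize({Histotype.ENDOMETRIOID: 17,
                           Histotype.UNDIFF_DEDIFF: 2,
                           Histotype.SEROUS: 19,
                           Histotype.CARCINOSARCOMA: 3,
                           Histotype.CLEAR_CELL: 3}),
            N: _normalize({Histotype.ENDOMETRIOID: 77,
                           Histotype.UNDIFF_DEDIFF: 6}),
        },
        high_grade_by_subgroup={P: 9 / 16, M: 25 / 68, A: 43 / 44,
                                N: 11 / 83},
        deep_invasion_by_subgroup={P: 3 / 16, M: 24 / 68, A: 19 / 44,
                                   N: 19 / 83},
        lvsi_positive_by_subgroup={P: 5 / 16, M: 27 / 68, A: 26 / 44,
                                   N: 17 / 83},
        nodes_by_subgroup={
            P: _normalize({LymphNodes.NEGATIVE: 15, LymphNodes.POSITIVE: 1}),
            M: _normalize({LymphNodes.NEGATIVE: 54, LymphNodes.POSITIVE: 12,
                           LymphNodes.UNKNOWN: 2}),
            A: _normalize({LymphNodes.NEGATIVE: 29, LymphNodes.POSITIVE: 14,
                           LymphNodes.UNKNOWN: 1}),
            N: _normalize({LymphNodes.NEGATIVE: 74, LymphNodes.POSITIVE: 6,
                           LymphNodes.UNKNOWN: 3}),
        },
        stage_by_subgroup={
            P: _normalize({"IA": 9, "IB_II": 5, "III": 2}),
            M: _normalize({"IA": 36, "IB_II": 16, "III": 13, "IV": 3}),
            A: _normalize({"IA": 14, "IB_II": 6, "III": 19, "IV": 5}),
            N: _normalize({"IA": 60, "IB_II": 15, "III": 8}),
        },
        age_by_subgroup={P: (58.6, 11.6), M: (63.0, 9.4), A: (66.9, 10.3),
                         N: (60.2, 10.2)},
        bmi_by_subgroup={P: (27.2, 9.3), M: (28.0, 7.3), A: (25.5, 4.4),
                         N: (30.3, 8.1)},
        hazard_per_risk_class={
            RiskClass.LOW: 0.0008,
            RiskClass.INTERMEDIATE: 0.0025,
            RiskClass.HIGH_INTERMEDIATE: 0.006,
            RiskClass.HIGH: 0.010,
            RiskClass.ADVANCED_METASTATIC: 0.035,
        },
    )
    return spec


def _draw(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def _draw_markers(rng: np.random.Generator, spec: CohortSpec,
                  subgroup: Subgroup, ruleset: PoleRuleset
                  ) -> tuple[MarkerPanel, set[Subgroup]]:
    """Marker panel consistent with the drawn (resolved) subgroup.

    Multiple-classifier tumors are injected by adding lower-priority
    positive markers conditionally on the resolved subgroup, so the
    hierarchy maps the panel back to the drawn subgroup by construction.
    """
    p_pole = spec.subgroup_probs[Subgroup.POLE]
    p_mmrd = spec.subgroup_probs[Subgroup.MMRD]
    pole_pos = subgroup == Subgroup.POLE
    mmr_pos = subgroup == Subgroup.MMRD
    p53_pos = subgroup == Subgroup.P53ABN
    if pole_pos:
        u = rng.random()
        both = spec.rate_triple / p_pole
        add_m = spec.rate_pole_mmrd / p_pole
        add_p = spec.rate_pole_p53 / p_pole
        if u < both:
            mmr_pos = p53_pos = True
        elif u < both + add_m:
            mmr_pos = True
        elif u < both + add_m + add_p:
            p53_pos = True
    elif mmr_pos:
        if rng.random() < spec.rate_mmrd_p53 / p_mmrd:
            p53_pos = True

    if p53_pos:
        pattern = _draw(rng, {P53Pattern.OVEREXPRESSION: 0.6,
                              P53Pattern.NULL_PATTERN: 0.3,
                              P53Pattern.CYTOPLASMIC: 0.1})
    else:
        pattern = P53Pattern.WILDTYPE

    mmr = {k: MmrStain.RETAINED for k in ("mlh1", "pms2", "msh2", "msh6")}
    if mmr_pos:
        mode = _draw(rng, {"mlh1_pms2": 0.60, "msh2_msh6": 0.25,
                           "single": 0.15})
        if mode == "mlh1_pms2":
            mmr["mlh1"] = mmr["pms2"] = MmrStain.LOST
        elif mode == "msh2_msh6":
            mmr["msh2"] = mmr["msh6"] = MmrStain.LOST
        else:
            mmr[_draw(rng, {"mlh1": .25, "pms2": .25,
                            "msh2": .25, "msh6": .25})] = MmrStain.LOST

    variants: list[VariantCall] = []
    whitelist = sorted(ruleset.whitelist)
    if pole_pos:
        pc = whitelist[rng.choice(len(whitelist))]
        depth = int(rng.integers(300, 2000))
        vaf = float(rng.uniform(max(ruleset.vaf_min * 2, 0.12), 0.45))
        alt = max(2, int(round(depth * vaf)))
        fwd = int(rng.binomial(alt, 0.5))
        fwd = min(max(fwd, 1), alt - 1)   # pathogenic calls span both strands
        variants.append(VariantCall(
            gene="POLE", protein_change=pc,
            exon=POLE_VARIANT_EXON.get(pc, 9), vaf=vaf,
            reads_forward=fwd, reads_reverse=alt - fwd))
    elif rng.random() < spec.passenger_variant_prob:
        # a call the engine must reject: sub-threshold VAF, single-strand
        # support, or a non-hotspot substitution
        kind = _draw(rng, {"low_vaf": 1 / 3, "one_strand": 1 / 3,
                           "not_whitelisted": 1 / 3})
        pc = whitelist[rng.choice(len(whitelist))]
        if kind == "low_vaf":
            variants.append(VariantCall("POLE", pc,
                                        POLE_VARIANT_EXON.get(pc, 9),
                                        float(rng.uniform(0.005,
                                                          ruleset.vaf_min * 0.9)),
                                        10, 10))
        elif kind == "one_strand":
            variants.append(VariantCall("POLE", pc,
                                        POLE_VARIANT_EXON.get(pc, 9),
                                        float(rng.uniform(0.1, 0.3)), 25, 0))
        else:
            variants.append(VariantCall("POLE", "p.T278M", 9,
                                        float(rng.uniform(0.1, 0.3)), 15, 14))

    panel = MarkerPanel(p53_pattern=pattern, variants=variants or None,
                        **mmr)
    # resolve the explicit status through the same filtering path the
    # classifier uses, closing the loop between generator and classifier
    call = classify_panel(
        MarkerPanel(p53_pattern=pattern, variants=variants,
                    **mmr), ruleset)
    panel.pole = call.pole_status
    profile = set()
    if pole_pos:
        profile.add(Subgroup.POLE)
    if mmr_pos:
        profile.add(Subgroup.MMRD)
    if p53_pos:
        profile.add(Subgroup.P53ABN)
    return panel, profile


def generate_cohort(spec: Optional[CohortSpec] = None,
                    ruleset: Optional[PoleRuleset] = None
                    ) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort from the generative model.

    Each patient's marker panel re-classifies to the drawn subgroup through
    the molecular hierarchy, and DFS is exponential with the hazard of the
    patient's 2020 molecular-known risk class, censored at the minimum of
    an exponential censoring draw and the follow-up cap.
    """
    spec = spec or table2_defaults()
    ruleset = ruleset or PoleRuleset()
    problems = spec.validate()
    if problems:
        raise SpecError("invalid cohort spec: " + "; ".join(problems))
    rng = np.random.default_rng(spec.seed)

    records: list[PatientRecord] = []
    for i in range(spec.n):
        g = SUBGROUPS[rng.choice(
            4, p=[spec.subgroup_probs[s] for s in SUBGROUPS])]
        histotype = _draw(rng, spec.histotype_by_subgroup[g])
        grade = (Grade.HIGH if rng.random() < spec.high_grade_by_subgroup[g]
                 else Grade.LOW)
        if rng.random() < spec.deep_invasion_by_subgroup[g]:
            invasion = MyometrialInvasion.GE50
        elif rng.random() < spec.no_invasion_given_superficial:
            invasion = MyometrialInvasion.NONE
        else:
            invasion = MyometrialInvasion.LT50
        if rng.random() < spec.lvsi_positive_by_subgroup[g]:
            lvsi = (Lvsi.SUBSTANTIAL
                    if rng.random() < spec.substantial_given_lvsi_positive
                    else Lvsi.FOCAL)
        else:
            lvsi = Lvsi.ABSENT
        nodes = _draw(rng, spec.nodes_by_subgroup[g])
        coarse = _draw(rng, spec.stage_by_subgroup[g])
        residual = False
        if coarse == "IA":
            stage = FigoStage.IA
        elif coarse == "IB_II":
            stage = (FigoStage.IB
                     if rng.random() < spec.stage_ib_given_ib_ii
                     else FigoStage.II)
        elif coarse == "III":
            stage = FigoStage.III
            residual = rng.random() < spec.residual_prob_stage_iii_iva
        else:
            if rng.random() < spec.stage_ivb_given_iv:
                stage = FigoStage.IVB
            else:
                stage = FigoStage.IVA
                residual = rng.random() < spec.residual_prob_stage_iii_iva
        mu_a, sd_a = spec.age_by_subgroup[g]
        mu_b, sd_b = spec.bmi_by_subgroup[g]
        age = float(np.clip(rng.normal(mu_a, sd_a), 30, 95))
        bmi = float(np.clip(rng.normal(mu_b, sd_b), 16, 60))

        profile = ClinicopathologicProfile(
            patient_id=f"SYN{i:05d}",
            age=round(age, 1), bmi=round(bmi, 1),
            histotype=histotype, grade=grade,
            myometrial_invasion=invasion, lvsi=lvsi,
            lymph_nodes=nodes, figo_stage=stage,
            residual_disease=residual,
        )
        panel, _ = _draw_markers(rng, spec, g, ruleset)

        call = classify_panel(panel, ruleset)
        risk = classify_esgo2020(profile, call).risk_class
        hazard = spec.hazard_per_risk_class[risk]
        event_time = rng.exponential(1.0 / hazard)
        censor_time = min(rng.exponential(1.0 / spec.censor_rate),
                          spec.follow_up_cap)
        time = max(round(min(event_time, censor_time), 1), 0.1)
        survival = SurvivalRecord(time=time, event=event_time <= censor_time)

        records.append(PatientRecord(profile=profile, panel=panel,
                                     survival=survival))
    return records


def spec_to_dict(spec: CohortSpec) -> dict:
    """JSON/YAML-serializable resolved spec, for provenance sidecars."""
    def _plain(obj):
        if isinstance(obj, dict):
            return {getattr(k, "value", k): _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        return getattr(obj, "value", obj)
    return {k: _plain(v) for k, v in asdict(spec).items()}
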