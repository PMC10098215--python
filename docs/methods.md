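# Methods

## Scope and data model

`endorisk` operates on per-patient records combining clinicopathologic
variables, immunohistochemistry (IHC) and POLE sequencing results, and
disease-free survival (DFS) follow-up. All categorical variables are
controlled vocabularies; missing values are explicit (`unknown`,
`not_done`, empty cell / `NA` in CSV) and never imputed. Grade is binary
(low = FIGO G1–G2, high = G3; numeric grades are mapped on input).
Lymphovascular space invasion (LVSI) is three-tier — absent, focal
(a single focus around the tumor), substantial (diffuse/multifocal) —
because the two risk-rule generations binarize it differently. FIGO stage
is stored at IA–IVB granularity; a coarse "IV" on input resolves to IVA
unless the residual/metastatic flag marks IVB, so table-level data load
without losing the ability to apply the full 2020 rules. Stage is taken as
recorded and never re-derived from depth of invasion, which is an
independent field used only by rules that need it; residual disease is
only a legal annotation at stage III/IVA/IVB.

## Molecular classification

p53 IHC is mutant-like (abnormal) for overexpression, null-pattern or
cytoplasmic staining; mismatch repair is deficient when any of
MLH1/PMS2/MSH2/MSH6 is lost (covering the paired MLH1–PMS2 and MSH2–MSH6
loss patterns); a single lost stain is conclusive even with an otherwise
incomplete panel. POLE variant calls are filtered at VAF ≥ 0.05
("at least 5%" read inclusively) with support required on both strands,
then matched against a pathogenic whitelist of canonical
exonuclease-domain hotspots (P286R, V411L, S297F, S459F, F367S, L424I,
M295R, P436R, M444K, D368Y, A456P) restricted to exons 9–14. The
whitelist, threshold, exon coverage and strand rule are configurable via a
`pole_ruleset:` YAML block. This is deliberately a membership test, not a
full variant-scoring schema (no recurrence counts or tumor mutational
burden criteria); non-hotspot exonuclease-domain variants that an expert
panel might call pathogenic are under-called by the defaults — a
documented limitation, and the reason the whitelist is user-overridable.

The final subgroup resolves through the hierarchy
POLE ≻ MMRd ≻ p53abn ≻ NSMP. Every positive marker is retained in a
classifier profile so multiple-classifier tumors (≥2 positive markers,
~7% of real cohorts) stay auditable after resolution. A classification in
"molecular-known" mode refuses (raises) when any of the three markers is
untested rather than guessing; the only sanctioned exception is the triage
path, where an untested POLE is classified as wild-type and explicitly
flagged `pole_assumed`.

## Risk rule tables

The two guideline generations are encoded as ordered first-match rule
lists in a versioned YAML resource (`endorisk/rules/risk_rules.yaml`),
evaluated over a derived feature vector (stage, endometrioid vs not,
grade, three-tier and binarized LVSI, any-invasion, depth, residual,
subgroup). Precedence is explicit — advanced → high → high-intermediate →
intermediate → low — which makes overlap resolution testable; the fired
rule id is recorded in every assignment, and outputs carry a content hash
of the table.

Key semantics, chosen where the guidelines themselves needed
reconstruction and validated against the reference cohort's worked
reclassifications:

* **ESMO 2016**: LVSI binarized (focal counts as positive); any
  non-endometrioid histotype is high risk at stage I–III; stage III with
  residual disease and stage IV are advanced/metastatic.
* **ESGO 2020, molecular unknown**: focal LVSI groups with absent; only
  substantial LVSI raises stage I endometrioid tumors to
  high-intermediate; non-endometrioid tumors without myometrial invasion
  at stage IA are intermediate, with invasion high; stage III–IVA is high
  (advanced with residual disease), IVB advanced.
* **ESGO 2020, molecular known**: stage I–II POLE-mutant disease is low
  risk regardless of grade, depth, LVSI — including stage II; p53abn with
  any myometrial invasion is high risk, without invasion intermediate;
  MMRd/NSMP follow the clinicopathologic rules (stage II MMRd/NSMP is
  high-intermediate); stage III/IV is high risk or worse regardless of
  subgroup, so no molecular override applies there.

The guidelines leave some grid cells clinically contradictory
(e.g. p53abn stage IB/II without myometrial invasion, since stage IB
presupposes deep invasion). These are closed by the nearest no-invasion
rule (intermediate) so the systems are total: an exhaustive enumeration
over the full histotype × grade × invasion × LVSI × stage × residual ×
subgroup grid proves exactly one class fires per system/mode, that POLE
never raises and p53abn-with-invasion never lowers the early-stage
2020-known class, and that an absent↔focal LVSI flip never moves any 2020
class while it does move 2016 classes.

## POLE-testing triage

MMR and p53 IHC are assumed universal (they are cheap and diagnostically
necessary); the triage only decides where POLE sequencing can change the
2020 class. Stage III/IV cases are exempt (high risk or worse regardless
of subgroup); clinicopathologic low-risk cases are exempt (a POLE result
cannot raise them); everyone else needs the test and carries at least one
trigger feature — non-endometrioid histotype, high grade, substantial
LVSI, stage IB–II — re-derived from the raw profile so each reason tag is
independently checkable. The low-risk exemption is evaluated through the
2020 molecular-unknown classifier itself, which reproduces the published
decomposition (spared = low-risk + advanced-stage counts).

The audit classifies spared cases from MMR/p53 alone (POLE assumed
wild-type, flagged) and compares against universal testing. Enumeration
over the full grid × all 8 marker combinations proves discordance is
confined to clinicopathologic low-risk tumors carrying p53abn together
with a hidden pathogenic POLE mutation — and, within those, only when MMR
is proficient, since an MMRd co-classifier masks p53abn in the hierarchy
either way. The triage quantifies this edge; it does not decide it.

## Cohort statistics

Migration between systems is a 5×5 cross-tabulation in the fixed class
order; "down" means the new class is strictly lower. Published
cross-tabulations can be ingested directly (`matrix_from_counts`) and
expanded to per-patient pairs to exercise the same code path as real
cohorts. Association tests use Pearson's χ² (Fisher's exact for 2×2
tables with any expected cell < 5 — the switch threshold is configurable;
exact tests beyond 2×2 are not attempted) for categorical covariates and
Kruskal–Wallis across the four subgroups for numeric ones; degenerate
covariates are reported as NA with a reason. Survival is DFS only (any
recurrence is an event; overall survival is out of scope): Kaplan–Meier
product-limit curves per risk class and the k-group log-rank test with the
standard hypergeometric tie handling and no continuity correction, via
`lifelines`. The test suite cross-checks KM against empirical survival on
uncensored samples and the log-rank against a hand-rolled
permutation-null oracle.

## Synthetic cohort generator

The generator draws the resolved subgroup from configurable prevalences
(defaults 16/68/44/83 out of 211), then covariates from
subgroup-conditional distributions whose cells equal the reference
cohort's published cross-tabulation — e.g. P(serous | p53abn) = 19/44,
P(high grade | p53abn) = 43/44, with the serous/clear-cell/carcinosarcoma
mass entirely in p53abn. Multiple-classifier tumors are injected by adding
lower-priority positive markers conditionally on the resolved subgroup at
the published whole-cohort rates (1, 4, 9 and 2 per 211 for POLE∩MMRd,
POLE∩p53abn, MMRd∩p53abn and triple), so panels re-classify to their drawn
subgroup by construction. POLE-mutant patients receive a whitelist variant
(VAF uniform 0.12–0.45, both strands); a fraction of wild-type patients
receive a deliberately rejectable call (sub-threshold VAF, single-strand,
or non-hotspot) to keep the filters exercised. The explicit POLE status is
derived by running the generator's own variants through the production
filter/interpret path.

Splits the published tables do not provide are free parameters with
defaults chosen once: focal:substantial among LVSI-positive at the
cohort-wide 66:75 ratio; a third of <50%-invasion tumors with no invasion;
IB:II at 32:10; IVA:IVB at 1:1; residual disease for stage III/IVA at 7%
(calibrated so ~7/211 land in the advanced/metastatic class). DFS is
exponential with monthly hazards by 2020-known class
(0.0008 / 0.0025 / 0.006 / 0.010 / 0.035, strictly increasing by
construction), censored at min(exponential with median ≈ 22 months,
120-month cap), giving ~13% crude recurrence at study scale.

**What the generator does not emulate:** covariates are independent within
subgroup, because only subgroup-conditional marginals are published. Real
cohorts have strong positive dependence among low grade, early stage,
no/focal LVSI and superficial invasion, so the joint mass of
clinicopathologic low-risk patients is higher in reality (≈39%) than under
within-subgroup independence (≈28%). Consequently synthetic cohorts
reproduce subgroup prevalences, multiple-classifier rates,
marker–subgroup consistency and hazard ordering, but understate the
low-risk fraction and therefore the triage's test-reduction fraction
(≈50% synthetic vs 62.6% on the published marginals). Tests that depend on
the joint low-risk mass use the published tables directly; synthetic
cohorts back the structural and survival properties.

## Numerical and testing choices

Deterministic cohort quantities are recomputed from the published summary
tables at full cohort size (n = 211). Simulation-backed checks use one
seeded cohort each: n = 50,000 for prevalence recovery (±0.01), n = 20,000
for hazard-ordering, n = 1,000–2,000 for log-rank separation (p < 10⁻⁴),
2,000–10,000 shuffles for permutation oracles. All randomness flows
through `numpy.random.default_rng` seeds carried in the cohort spec; the
acceptance script derives child seeds from a single `--seed` via
`SeedSequence`. One published input required a correction: the reference
cross-tabulation between the 2016 and 2020-known systems prints a
high-intermediate diagonal cell (14) inconsistent with its own row total
(70) and the cohort size; the encoded grid uses 13, which restores both
while leaving every off-diagonal (migration) cell as printed — the
diagonal does not enter any migration statistic.
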