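"""Cohort-level statistics: risk-class migration, association tests, DFS.

Migration between two risk systems is summarized as a 5x5 cross-tabulation
in the fixed class order low < intermediate < high-intermediate < high <
advanced/metastatic; "down" means the column (new) class is strictly lower
than the row (old) class.  Survival uses the Kaplan-Meier product-limit
estimator and the k-group log-rank test on disease-free survival, any
recurrence counting as an event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .core_model import (
    LymphNodes,
    Lvsi,
    MyometrialInvasion,
    PatientRecord,
)
from .molecular_classification import MolecularCall
from .risk_stratification import RISK_ORDER, RiskClass


@dataclass
class MigrationMatrix:
    row_system: str
    col_system: str
    counts: np.ndarray          # 5x5, RISK_ORDER by RISK_ORDER
    n: int

    def to_frame(self) -> pd.DataFrame:
        labels = [c.value for c in RISK_ORDER]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


@dataclass
class MigrationSummary:
    n: int
    n_changed: int
    frac_changed: float
    n_down: int
    frac_down: float
    n_up: int
    frac_up: float


@dataclass
class KMCurve:
    event_times: np.ndarray     # months, ascending, event times only
    survival: np.ndarray        # S(t) just after each event time
    at_risk: np.ndarray         # number at risk just before each event time
    n_events: int
    n: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def migration_matrix(old: Mapping[str, RiskClass],
                     new: Mapping[str, RiskClass],
                     row_system: str = "old",
                     col_system: str = "new") -> MigrationMatrix:
    """Cross-tabulate per-patient classes under two systems.

    ``old``/``new`` map patient id to risk class; the same patients must be
    present in both.
    """
    if set(old) != set(new):
        only_old = sorted(set(old) - set(new))
        only_new = sorted(set(new) - set(old))
        raise ValueError(
            "patient sets differ between systems: "
            f"only in {row_system}: {only_old[:5]}; "
            f"only in {col_system}: {only_new[:5]}")
    idx = {c: i for i, c in enumerate(RISK_ORDER)}
    counts = np.zeros((5, 5), dtype=int)
    for pid in old:
        counts[idx[RiskClass(old[pid])], idx[RiskClass(new[pid])]] += 1
    return MigrationMatrix(row_system, col_system, counts, len(old))


def matrix_from_counts(counts, row_system: str = "old",
                       col_system: str = "new") -> MigrationMatrix:
    """Build a MigrationMatrix from a printed 5x5 count grid."""
    arr = np.asarray(counts, dtype=int)
    if arr.shape != (5, 5) or (arr < 0).any():
        raise ValueError("counts must be a non-negative 5x5 grid")
    return MigrationMatrix(row_system, col_system, arr, int(arr.sum()))


def expand_matrix_to_pairs(matrix: MigrationMatrix
                           ) -> tuple[dict[str, RiskClass], dict[str, RiskClass]]:
    """Expand a cross-tabulation into per-patient class pairs.

    Inverse of :func:`migration_matrix` up to patient identity; useful for
    re-deriving summaries from published tables.
    """
    old, new = {}, {}
    k = 0
    for i, ri in enumerate(RISK_ORDER):
        for j, rj in enumerate(RISK_ORDER):
            for _ in range(int(matrix.counts[i, j])):
                pid = f"p{k:04d}"
                old[pid], new[pid] = ri, rj
                k += 1
    return old, new


def migration_summary(matrix: MigrationMatrix) -> MigrationSummary:
    """Off-diagonal reallocation totals split by direction."""
    c = matrix.counts
    n = matrix.n
    n_down = int(np.tril(c, k=-1).sum())   # column class < row class
    n_up = int(np.triu(c, k=1).sum())
    n_changed = n_down + n_up
    frac = (lambda x: x / n if n else 0.0)
    return MigrationSummary(n=n, n_changed=n_changed,
                            frac_changed=frac(n_changed),
                            n_down=n_down, frac_down=frac(n_down),
                            n_up=n_up, frac_up=frac(n_up))


# --------------------------------------------------------------------------
# Association tests (covariates vs molecular subgroup)
# --------------------------------------------------------------------------

def _contingency_test(table: np.ndarray, fisher_threshold: float = 5.0
                      ) -> tuple[str, float, float]:
    """Pearson chi-square, switching to Fisher's exact test for 2x2 tables
    with any expected cell below the threshold.  (Exact tests beyond 2x2
    are not attempted; the chi-square approximation is used with the low
    expected count noted by the caller if needed.)"""
    table = np.asarray(table, dtype=float)
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if table.shape == (2, 2) and (expected < fisher_threshold).any():
        odds, p = stats.fisher_exact(table)
        return "fisher_exact", float(odds), float(p)
    return "chi2", float(chi2), float(p)


def association_tests(records: Sequence[PatientRecord],
                      calls: Mapping[str, MolecularCall],
                      fisher_threshold: float = 5.0) -> pd.DataFrame:
    """Covariate-by-subgroup association tests.

    Categorical covariates get Pearson's chi-square (Fisher's exact for
    sparse 2x2 tables); numeric covariates get Kruskal-Wallis across the
    four subgroups.  Degenerate covariates are reported as NA with a
    reason rather than raised.
    """
    sub = {r.patient_id: calls[r.patient_id].subgroup.value for r in records}
    groups = ["POLE", "MMRd", "p53abn", "NSMP"]

    def categorical(name, value_of, drop=None):
        pairs = [(sub[r.patient_id], value_of(r)) for r in records]
        pairs = [(g, v) for g, v in pairs if v is not None and v != drop]
        df = pd.DataFrame(pairs, columns=["subgroup", name])
        tab = pd.crosstab(df[name], df["subgroup"])
        tab = tab.reindex(columns=[g for g in groups if g in tab.columns],
                          fill_value=0)
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            return {"covariate": name, "test": "NA", "statistic": np.nan,
                    "p_value": np.nan,
                    "note": "degenerate: fewer than two categories/groups"}
        test, statistic, p = _contingency_test(tab.to_numpy(),
                                               fisher_threshold)
        return {"covariate": name, "test": test, "statistic": statistic,
                "p_value": p, "note": ""}

    def numeric(name, value_of):
        samples = []
        for g in groups:
            vals = [value_of(r) for r in records
                    if sub[r.patient_id] == g and value_of(r) is not None]
            if vals:
                samples.append(np.asarray(vals, dtype=float))
        if len(samples) < 2:
            return {"covariate": name, "test": "NA", "statistic": np.nan,
                    "p_value": np.nan, "note": "degenerate: <2 groups"}
        try:
            stat, p = stats.kruskal(*samples)
        except ValueError as exc:   # all values identical
            return {"covariate": name, "test": "NA", "statistic": np.nan,
                    "p_value": np.nan, "note": f"degenerate: {exc}"}
        return {"covariate": name, "test": "kruskal_wallis",
                "statistic": float(stat), "p_value": float(p), "note": ""}

    rows = [
        numeric("age_years", lambda r: r.profile.age),
        numeric("bmi", lambda r: r.profile.bmi),
        categorical("histotype", lambda r: r.profile.histotype.value),
        categorical("grade", lambda r: r.profile.grade.value),
        categorical("deep_invasion",
                    lambda r: "ge50" if r.profile.myometrial_invasion
                    == MyometrialInvasion.GE50 else "lt50"),
        categorical("lvsi_positive",
                    lambda r: "negative" if r.profile.lvsi == Lvsi.ABSENT
                    else "positive"),
        categorical("lymph_nodes",
                    lambda r: None if r.profile.lymph_nodes == LymphNodes.UNKNOWN
                    else r.profile.lymph_nodes.value),
        categorical("figo_stage_coarse",
                    lambda r: {"IA": "IA", "IB": "IB_II", "II": "IB_II",
                               "III": "III", "IVA": "IV", "IVB": "IV"}
                    [r.profile.figo_stage.value]),
    ]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Survival
# --------------------------------------------------------------------------

def km_estimate(records: Sequence) -> KMCurve:
    """Kaplan-Meier product-limit estimate of disease-free survival.

    Accepts SurvivalRecord-like objects with ``time`` (months > 0) and
    ``event`` attributes; censored times reduce the risk set only.
    """
    records = list(records)
    if not records:
        raise ValueError("km_estimate requires at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([bool(r.event) for r in records])
    if (times <= 0).any() or not np.isfinite(times).all():
        raise ValueError("survival times must be finite and > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.sort(np.unique(times[events]))
    if event_times.size:
        surv = kmf.survival_function_at_times(event_times).to_numpy()
        # number at risk just before each event time
        at_risk = np.array([(times >= t).sum() for t in event_times])
    else:
        surv = np.array([])
        at_risk = np.array([], dtype=int)
    return KMCurve(event_times=event_times, survival=surv, at_risk=at_risk,
                   n_events=int(events.sum()), n=len(records))


def logrank_test(groups: Sequence[Sequence]) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, two-sided p).

    Ties use the standard hypergeometric variance with no continuity
    correction.
    """
    groups = [list(g) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("logrank_test requires >= 2 non-empty groups")
    times = np.concatenate([[r.time for r in g] for g in groups])
    events = np.concatenate([[bool(r.event) for r in g] for g in groups])
    labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def km_by_class(records: Sequence[PatientRecord],
                classes: Mapping[str, RiskClass]
                ) -> tuple[dict[str, KMCurve], Optional[tuple[float, float]]]:
    """Per-risk-class KM curves plus the across-class log-rank test.

    Patients without follow-up are excluded; the log-rank is skipped
    (None) when fewer than two classes have data.
    """
    by_class: dict[str, list] = {}
    for rec in records:
        if rec.survival is None:
            continue
        cls = RiskClass(classes[rec.patient_id]).value
        by_class.setdefault(cls, []).append(rec.survival)
    curves = {cls: km_estimate(surv) for cls, surv in by_class.items()}
    test = None
    if len(by_class) >= 2:
        test = logrank_test(list(by_class.values()))
    return curves, test
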