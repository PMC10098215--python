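"""Migration statistics, association tests, and survival analysis."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from endorisk.cohort_analysis import (
    expand_matrix_to_pairs,
    km_estimate,
    logrank_test,
    matrix_from_counts,
    migration_matrix,
    migration_summary,
    association_tests,
)
from endorisk.core_model import SurvivalRecord
from endorisk.molecular_classification import classify_panel
from endorisk.risk_stratification import RISK_ORDER, RiskClass

from conftest import make_record


class TestMigrationMatrix:
    def test_identical_assignments_are_diagonal(self):
        classes = {f"p{i}": RISK_ORDER[i % 5] for i in range(20)}
        m = migration_matrix(classes, classes)
        assert m.counts.sum() == 20
        assert np.all(m.counts == np.diag(np.diag(m.counts)))
        s = migration_summary(m)
        assert s.n_changed == s.n_up == s.n_down == 0

    def test_single_patient_single_cell(self):
        m = migration_matrix({"p": RiskClass.LOW}, {"p": RiskClass.HIGH})
        assert m.counts.sum() == m.counts[0, 3] == 1

    def test_mismatched_patient_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            migration_matrix({"a": RiskClass.LOW},
                             {"b": RiskClass.LOW})

    def test_direction_convention(self):
        """'Down' means the new (column) class is strictly lower."""
        old = {"a": RiskClass.HIGH, "b": RiskClass.LOW,
               "c": RiskClass.INTERMEDIATE}
        new = {"a": RiskClass.LOW, "b": RiskClass.HIGH,
               "c": RiskClass.INTERMEDIATE}
        s = migration_summary(migration_matrix(old, new))
        assert (s.n_down, s.n_up, s.n_changed) == (1, 1, 2)
        assert s.frac_changed == pytest.approx(2 / 3)

    def test_expand_inverts_crosstab(self):
        counts = np.arange(25).reshape(5, 5)
        m = matrix_from_counts(counts)
        old, new = expand_matrix_to_pairs(m)
        m2 = migration_matrix(old, new)
        assert np.array_equal(m2.counts, counts)


class TestAssociationTests:
    def _cohort(self):
        from endorisk.core_model import (Grade, Histotype, MmrStain,
                                         P53Pattern, PoleStatus)
        records = []
        for i in range(40):
            kind = i % 4
            panel_kwargs = [
                dict(pole=PoleStatus.PATHOGENIC),
                dict(mlh1=MmrStain.LOST, pms2=MmrStain.LOST),
                dict(p53_pattern=P53Pattern.NULL_PATTERN),
                dict(),
            ][kind]
            profile_kwargs = dict(
                age=50.0 + kind * 5 + (i % 7),
                bmi=25.0 + (i % 5),
                grade=Grade.HIGH if kind == 2 else Grade.LOW,
            )
            records.append(make_record(f"p{i}", profile_kwargs=profile_kwargs,
                                       panel_kwargs=panel_kwargs))
        calls = {r.patient_id: classify_panel(r.panel) for r in records}
        return records, calls

    def test_covariate_table_shape_and_tests(self):
        records, calls = self._cohort()
        table = association_tests(records, calls)
        by_cov = table.set_index("covariate")
        assert by_cov.loc["age_years", "test"] == "kruskal_wallis"
        assert by_cov.loc["grade", "test"] in ("chi2", "fisher_exact")
        # grade is perfectly associated with subgroup here
        assert by_cov.loc["grade", "p_value"] < 0.01
        # stage is constant (all IA) -> degenerate, reported not raised
        assert by_cov.loc["figo_stage_coarse", "test"] == "NA"
        assert "degenerate" in by_cov.loc["figo_stage_coarse", "note"]

    def test_chi2_matches_closed_form(self):
        """2x2 Pearson chi-square equals (ad-bc)^2 n / (r1 r2 c1 c2)."""
        from endorisk.cohort_analysis import _contingency_test
        a, b, c, d = 20, 5, 5, 20
        n = a + b + c + d
        expected = (a * d - b * c) ** 2 * n / \
            ((a + b) * (c + d) * (a + c) * (b + d))
        test, stat, p = _contingency_test(np.array([[a, b], [c, d]]))
        assert test == "chi2"
        assert stat == pytest.approx(expected)

    def test_balanced_table_gives_chi2_zero(self):
        from endorisk.cohort_analysis import _contingency_test
        test, stat, p = _contingency_test(np.array([[10, 10], [10, 10]]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_sparse_2x2_switches_to_fisher(self):
        from endorisk.cohort_analysis import _contingency_test
        test, _, p = _contingency_test(np.array([[8, 1], [1, 7]]))
        assert test == "fisher_exact"
        # oracle: scipy's exact test on the same table
        from scipy.stats import fisher_exact
        assert p == pytest.approx(fisher_exact([[8, 1], [1, 7]])[1])


def S(time, event):
    return SurvivalRecord(time=time, event=event)


class TestKaplanMeier:
    def test_no_censoring_two_events(self):
        curve = km_estimate([S(1, True), S(2, True)])
        assert curve.survival_at(1) == pytest.approx(0.5)
        assert curve.survival_at(2) == pytest.approx(0.0)

    def test_hand_product_limit_with_censoring(self):
        """n=3, event at t=1, censored at t=2, event at t=3.

        Hand product-limit: S(1) = (1 - 1/3) = 2/3; the censored subject
        leaves the risk set at t=2, so one subject is at risk at t=3 and
        S(3) = 2/3 * (1 - 1/1) = 0."""
        curve = km_estimate([S(1, True), S(2, False), S(3, True)])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)
        assert list(curve.at_risk) == [3, 1]

    def test_all_censored_survival_stays_one(self):
        curve = km_estimate([S(t, False) for t in (3, 7, 12)])
        assert curve.n_events == 0
        assert curve.survival_at(100) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])

    @given(st.lists(st.floats(0.5, 120).map(lambda x: round(x, 1)),
                    min_size=1, max_size=30))
    def test_km_equals_empirical_survival_without_censoring(self, times):
        """With no censoring the product-limit estimate is the empirical
        survival function."""
        records = [S(t, True) for t in times]
        curve = km_estimate(records)
        arr = np.asarray(times)
        for t in sorted(set(times)):
            empirical = (arr > t).mean()
            assert curve.survival_at(t) == pytest.approx(empirical)


def two_group_logrank_stat(times, events, in_group1):
    """Hand-rolled two-group log-rank chi-square (hypergeometric variance,
    no continuity correction); independent of the package implementation."""
    observed = expected = variance = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_group1).sum()
        dying = events & (times == t)
        d = dying.sum()
        observed += (dying & in_group1).sum()
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (observed - expected) ** 2 / variance if variance > 0 else 0.0


def logrank_permutation_oracle(groups, n_perm, seed):
    """Permutation null for the two-group log-rank statistic."""
    rng = np.random.default_rng(seed)
    n1 = len(groups[0])
    pooled = [r for g in groups for r in g]
    times = np.array([r.time for r in pooled])
    events = np.array([bool(r.event) for r in pooled])
    mask = np.zeros(len(pooled), dtype=bool)
    mask[:n1] = True
    observed = two_group_logrank_stat(times, events, mask)
    hits = 0
    for _ in range(n_perm):
        hits += two_group_logrank_stat(
            times, events, rng.permutation(mask)) >= observed
    return observed, (hits + 1) / (n_perm + 1)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = [S(t, True) for t in (1, 3, 5)] + [S(8, False)]
        stat, p = logrank_test([g, list(g)])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([[S(1, True)]])

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        g1 = [S(t, True) for t in rng.exponential(10, 15)]
        g2 = [S(t, True) for t in rng.exponential(30, 15)]
        g3 = [S(t, False) for t in rng.exponential(20, 10)]
        stat_a, _ = logrank_test([g1, g2, g3])
        stat_b, _ = logrank_test([g3, g1, g2])
        assert stat_a == pytest.approx(stat_b)

    def test_strong_separation_detected(self):
        """Exponential groups with hazard ratio 4 at n=200/group give
        p < 1e-4, agreeing with a permutation oracle."""
        rng = np.random.default_rng(11)
        g1 = [S(t, True) for t in rng.exponential(40, 200)]
        g2 = [S(t, True) for t in rng.exponential(10, 200)]
        stat, p = logrank_test([g1, g2])
        assert p < 1e-4

    def test_agrees_with_permutation_oracle_on_small_sample(self):
        rng = np.random.default_rng(3)
        g1 = [S(t, bool(e)) for t, e in zip(rng.exponential(25, 12),
                                            rng.random(12) < 0.8)]
        g2 = [S(t, bool(e)) for t, e in zip(rng.exponential(10, 12),
                                            rng.random(12) < 0.8)]
        stat, p_asym = logrank_test([g1, g2])
        observed, p_perm = logrank_permutation_oracle([g1, g2],
                                                      n_perm=2000, seed=7)
        # the hand-rolled statistic reproduces the package's
        assert observed == pytest.approx(stat)
        # asymptotic and permutation p agree within Monte-Carlo error
        assert p_asym == pytest.approx(p_perm, abs=0.05)

    def test_label_permutation_p_values_roughly_uniform(self):
        """Under random relabeling of a homogeneous sample, p-values are
        not concentrated near zero."""
        rng = np.random.default_rng(21)
        pooled = [S(t, True) for t in rng.exponential(15, 40)]
        ps = []
        for _ in range(40):
            idx = rng.permutation(40)
            g1 = [pooled[i] for i in idx[:20]]
            g2 = [pooled[i] for i in idx[20:]]
            ps.append(logrank_test([g1, g2])[1])
        ps = np.array(ps)
        assert (ps < 0.05).mean() < 0.25
        assert ps.mean() == pytest.approx(0.5, abs=0.25)
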