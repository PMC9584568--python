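"""Agreement metrics against first-principles oracles; aggregation; OLS."""

import numpy as np
import pytest

from somnohr.evaluation import (LEVEL_CLASSES, ConfusionMatrix, aggregate,
                                collapse_confusion, confusion, metrics,
                                pooled_metrics, stratified_regression)
from somnohr.io_formats import Hypnogram
from somnohr.synthetic import SubjectMeta


def brute_force_metrics(counts):
    """Independent first-principles computation of A/K/SE/SP/PPV/NPV."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    acc = sum(c[i, i] for i in range(c.shape[0])) / total
    pe = sum(c[i, :].sum() * c[:, i].sum() for i in range(c.shape[0])) / total ** 2
    kappa = (acc - pe) / (1 - pe) if abs(1 - pe) > 1e-15 else np.nan
    per = {}
    for i in range(c.shape[0]):
        tp = c[i, i]
        fn = c[i, :].sum() - tp
        fp = c[:, i].sum() - tp
        tn = total - tp - fn - fp
        per[i] = dict(
            se=tp / (tp + fn) if tp + fn else np.nan,
            sp=tn / (tn + fp) if tn + fp else np.nan,
            ppv=tp / (tp + fp) if tp + fp else np.nan,
            npv=tn / (tn + fn) if tn + fn else np.nan)
    return acc, kappa, per


def _random_cm(rng, level=4, max_count=50):
    k = len(LEVEL_CLASSES[level])
    return ConfusionMatrix(level=level,
                           counts=rng.integers(0, max_count, (k, k)))


class TestMetrics:
    def test_identity_matrix_perfect_scores(self):
        m = metrics(ConfusionMatrix(level=4, counts=np.eye(4, dtype=int) * 25))
        assert m.accuracy == 1.0
        assert m.kappa == pytest.approx(1.0)
        for cm in m.per_class.values():
            assert (cm.se, cm.sp, cm.ppv, cm.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_binary_case_against_brute_force(self):
        counts = np.array([[40, 10], [5, 45]])
        m = metrics(ConfusionMatrix(level=2, counts=counts))
        acc, kappa, per = brute_force_metrics(counts)
        assert m.accuracy == pytest.approx(acc, abs=1e-15)
        assert m.kappa == pytest.approx(kappa, abs=1e-15)
        w = m.per_class["W"]
        assert (w.se, w.sp, w.ppv, w.npv) == pytest.approx(
            (per[0]["se"], per[0]["sp"], per[0]["ppv"], per[0]["npv"]))

    def test_binary_complement_identities(self):
        """SE(Sleep)=SP(W), SP(Sleep)=SE(W), PPV(Sleep)=NPV(W) and
        vice versa, for arbitrary 2-level matrices."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            cm = _random_cm(rng, level=2)
            if cm.total == 0:
                continue
            m = metrics(cm)
            w, s = m.per_class["W"], m.per_class["Sleep"]
            np.testing.assert_allclose(s.se, w.sp, atol=1e-15)
            np.testing.assert_allclose(s.sp, w.se, atol=1e-15)
            np.testing.assert_allclose(s.ppv, w.npv, atol=1e-15)
            np.testing.assert_allclose(s.npv, w.ppv, atol=1e-15)

    def test_weighted_sensitivity_identity(self):
        """accuracy == sum_c prevalence(c) * SE(c)."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            cm = _random_cm(rng)
            if cm.total == 0 or np.any(cm.counts.sum(axis=1) == 0):
                continue
            m = metrics(cm)
            prev = cm.counts.sum(axis=1) / cm.total
            se = np.array([m.per_class[c].se for c in cm.classes])
            assert m.accuracy == pytest.approx(float((prev * se).sum()),
                                               abs=1e-12)

    def test_kappa_zero_when_rows_proportional_to_column_marginals(self):
        a = np.array([3, 5, 2, 7])
        b = np.array([4, 1, 6, 2])
        m = metrics(ConfusionMatrix(level=4, counts=np.outer(a, b)))
        assert m.kappa == pytest.approx(0.0, abs=1e-12)

    def test_kappa_below_accuracy_when_chance_positive(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            cm = _random_cm(rng)
            if cm.total == 0:
                continue
            m = metrics(cm)
            if not np.isnan(m.kappa):
                assert m.kappa <= m.accuracy + 1e-12

    def test_zero_denominator_gives_nan_not_zero(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 10  # only W present
        m = metrics(ConfusionMatrix(level=4, counts=counts))
        assert np.isnan(m.per_class["Deep"].se)
        assert np.isnan(m.per_class["Deep"].ppv)


class TestConfusion:
    def test_perfect_agreement_diagonal(self):
        ref = Hypnogram(labels=("N2",) * 100)
        cm = confusion(ref, ["Light"] * 100, 4)
        assert np.trace(cm.counts) == 100

    def test_single_off_diagonal_cell(self):
        cm = confusion(["W"] * 40, ["Sleep"] * 40, 2)
        assert cm.counts[0, 1] == 40
        assert cm.counts.sum() == 40

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(["W", "N2"], ["W"], 2)

    def test_every_epoch_tallied_once(self):
        rng = np.random.default_rng(4)
        stages = np.array(["W", "N1", "N2", "N3", "R"])
        four = np.array(["W", "Light", "Deep", "R"])
        ref = stages[rng.integers(0, 5, 333)]
        pred = four[rng.integers(0, 4, 333)]
        for level in (2, 3, 4):
            assert confusion(ref, pred, level).total == 333


class TestCollapseHomomorphism:
    @pytest.mark.parametrize("level", [2, 3])
    def test_collapse_commutes_with_confusion(self, level):
        rng = np.random.default_rng(5)
        stages = np.array(["W", "N1", "N2", "N3", "R"])
        four = np.array(["W", "Light", "Deep", "R"])
        for _ in range(200):
            n = int(rng.integers(10, 80))
            ref = stages[rng.integers(0, 5, n)]
            pred = four[rng.integers(0, 4, n)]
            direct = confusion(ref, pred, level)
            collapsed = collapse_confusion(confusion(ref, pred, 4), level)
            assert np.array_equal(direct.counts, collapsed.counts)


class TestAggregation:
    def _ms(self, acc):
        a = int(round(acc * 100))
        cm = ConfusionMatrix(level=2, counts=np.array([[a, 100 - a], [0, 0]]))
        return metrics(cm)

    def test_identical_subjects_zero_ci_width(self):
        agg = aggregate([self._ms(0.8)] * 5)
        assert agg["accuracy"].ci95_low == agg["accuracy"].ci95_high

    def test_two_subject_mean(self):
        agg = aggregate([self._ms(0.8), self._ms(0.9)])
        assert agg["accuracy"].mean == pytest.approx(0.85)

    def test_pooled_vs_subject_mean(self):
        """Pooled epoch-level accuracy differs from the cohort mean when
        subjects contribute unequal epoch counts, and coincides when the
        counts are equal."""
        cm_small = ConfusionMatrix(level=2, counts=np.array([[8, 2], [0, 0]]))
        cm_large = ConfusionMatrix(level=2, counts=np.array([[40, 60], [0, 0]]))
        subj_mean = np.mean([metrics(cm_small).accuracy,
                             metrics(cm_large).accuracy])
        pooled = pooled_metrics([cm_small, cm_large]).accuracy
        assert pooled != pytest.approx(subj_mean)
        cm_eq = ConfusionMatrix(level=2, counts=np.array([[4, 6], [0, 0]]))
        pooled_eq = pooled_metrics([cm_small, cm_eq]).accuracy
        assert pooled_eq == pytest.approx(
            np.mean([metrics(cm_small).accuracy, metrics(cm_eq).accuracy]))

    def test_wake_metrics_invariant_across_levels(self):
        rng = np.random.default_rng(6)
        stages = np.array(["W", "N1", "N2", "N3", "R"])
        four = np.array(["W", "Light", "Deep", "R"])
        ref = stages[rng.integers(0, 5, 400)]
        pred = four[rng.integers(0, 4, 400)]
        per_level = {l: metrics(confusion(ref, pred, l)).per_class["W"]
                     for l in (2, 3, 4)}
        for attr in ("se", "sp", "ppv", "npv"):
            vals = {round(getattr(per_level[l], attr), 12) for l in (2, 3, 4)}
            assert len(vals) == 1


class TestRegression:
    def _meta(self, sexes):
        return [SubjectMeta(f"s{i}", "<=40", "none/minimal", sx)
                for i, sx in enumerate(sexes)]

    def _ms(self, acc):
        n_correct = int(round(acc * 100))
        cm = ConfusionMatrix(level=2, counts=np.array(
            [[n_correct, 100 - n_correct], [0, 0]]))
        return metrics(cm)

    def test_two_group_beta_is_mean_difference(self):
        ms = [self._ms(a) for a in (0.80, 0.82, 0.84, 0.90, 0.92, 0.94)]
        meta = self._meta(["F", "F", "F", "M", "M", "M"])
        effects = stratified_regression(ms, meta, metric_names=("accuracy",),
                                        factors=("sex",))
        beta = next(e for e in effects if e.level == "M").beta
        assert beta == pytest.approx(0.92 - 0.82, abs=1e-12)

    def test_empty_stratum_undefined(self):
        ms = [self._ms(0.8)] * 4
        meta = self._meta(["F", "F", "F", "F"])
        effects = stratified_regression(ms, meta, metric_names=("accuracy",),
                                        factors=("sex",))
        assert np.isnan(next(e for e in effects if e.level == "M").beta)

    def test_significance_stars(self):
        from somnohr.evaluation import StrataEffect

        mk = lambda p: StrataEffect("accuracy", "sex", "M", "F", 0.0,
                                    (0.0, 0.0), p)
        assert mk(0.2).stars == "n.s."
        assert mk(0.04).stars == "*"
        assert mk(0.005).stars == "**"
        assert mk(0.0005).stars == "***"
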