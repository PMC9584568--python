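"""Hypnogram agreement framework.

Confusion matrices at the 2/3/4-level granularities, the standard
goodness-of-fit set (accuracy, Cohen's kappa, and one-vs-rest sensitivity,
specificity, PPV, NPV per class), epoch -> subject -> cohort aggregation
with normal-approximation 95% confidence intervals, and one-factor-at-a-time
linear regressions of per-subject metrics on age group, AHI group and sex
(reference levels: age <= 40, AHI none/minimal, female).

Subject-level metrics are computed from per-subject confusion matrices and
then averaged across subjects; pooled-count metrics are available as an
option.  Zero-denominator cells yield NaN ("undefined"), never zero, and
undefined values are excluded from cohort means with ``n`` adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import collapse_labels
from .io_formats import Hypnogram

logger = logging.getLogger(__name__)

LEVEL_CLASSES = {
    2: ("W", "Sleep"),
    3: ("W", "NREM", "R"),
    4: ("W", "Light", "Deep", "R"),
}

#: 5-class AASM reference -> classes of each level.
_REF_COLLAPSE = {
    4: {"W": "W", "N1": "Light", "N2": "Light", "N3": "Deep", "R": "R"},
    3: {"W": "W", "N1": "NREM", "N2": "NREM", "N3": "NREM", "R": "R"},
    2: {"W": "W", "N1": "Sleep", "N2": "Sleep", "N3": "Sleep", "R": "Sleep"},
}

METRIC_NAMES = ("accuracy", "kappa")

FACTOR_LEVELS = {
    "age": ("<=40", "40-60", ">60"),
    "ahi": ("none/minimal", "mild", "severe"),
    "sex": ("F", "M"),
}
REFERENCE_LEVELS = {"age": "<=40", "ahi": "none/minimal", "sex": "F"}


@dataclass
class ConfusionMatrix:
    level: int
    counts: np.ndarray  # rows = reference, columns = predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(LEVEL_CLASSES[self.level])
        if self.counts.shape != (k, k):
            raise ValueError(f"level-{self.level} matrix must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def classes(self) -> tuple:
        return LEVEL_CLASSES[self.level]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    se: float
    sp: float
    ppv: float
    npv: float


@dataclass
class MetricSet:
    accuracy: float
    kappa: float
    per_class: Mapping[str, ClassMetrics]
    level: int


@dataclass
class CohortSummary:
    mean: float
    ci95_low: float
    ci95_high: float
    n_subjects: int


@dataclass
class StrataEffect:
    metric: str
    factor: str
    level: str
    reference: str
    beta: float
    ci95: tuple
    p_value: float

    @property
    def stars(self) -> str:
        if np.isnan(self.p_value) or self.p_value >= 0.05:
            return "n.s."
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        return "*"


# ---------------------------------------------------------------------------
# Confusion matrices
# ---------------------------------------------------------------------------

def _to_level(labels: Sequence[str], level: int) -> list:
    """Map labels from the 5-class AASM or the 4-level model space into the
    classes of ``level``."""
    classes = LEVEL_CLASSES[level]
    ref_map = _REF_COLLAPSE[level]
    out = []
    for l in labels:
        if l in classes:
            out.append(l)
        elif l in ref_map:
            out.append(ref_map[l])
        elif l in ("Light", "Deep", "R", "W"):  # 4-level label, coarser target
            out.append(collapse_labels([l], level)[0])
        else:
            raise ValueError(f"label {l!r} not interpretable at level {level}")
    return out


def confusion(ref, pred: Sequence[str], level: int) -> ConfusionMatrix:
    """Tally every epoch once: rows = reference, columns = predicted."""
    ref_labels = ref.labels if isinstance(ref, Hypnogram) else list(ref)
    if len(ref_labels) != len(pred):
        raise ValueError(
            f"length mismatch: {len(ref_labels)} reference vs {len(pred)} "
            "predicted epochs")
    classes = LEVEL_CLASSES[level]
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for r, p in zip(_to_level(ref_labels, level), _to_level(pred, level)):
        counts[idx[r], idx[p]] += 1
    return ConfusionMatrix(level=level, counts=counts)


def collapse_confusion(cm: ConfusionMatrix, level: int) -> ConfusionMatrix:
    """Aggregate a 4-level matrix's rows and columns down to ``level``."""
    if cm.level != 4:
        raise ValueError("only 4-level matrices can be collapsed")
    src, dst = LEVEL_CLASSES[4], LEVEL_CLASSES[level]
    cmap = [dst.index(collapse_labels([c], level)[0]) for c in src]
    out = np.zeros((len(dst), len(dst)), dtype=np.int64)
    for i, ci in enumerate(cmap):
        for j, cj in enumerate(cmap):
            out[ci, cj] += cm.counts[i, j]
    return ConfusionMatrix(level=level, counts=out)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, Cohen's kappa, and one-vs-rest SE/SP/PPV/NPV per class.

    kappa = (p_o - p_e) / (1 - p_e) with the chance term from row/column
    marginals.  Zero-denominator values are NaN, never imputed."""
    c = cm.counts.astype(float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    acc = np.trace(c) / total
    pe = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total ** 2
    kappa = (acc - pe) / (1.0 - pe) if abs(1.0 - pe) > 1e-15 else np.nan
    per_class = {}
    for i, cls in enumerate(cm.classes):
        tp = c[i, i]
        fn = c[i, :].sum() - tp
        fp = c[:, i].sum() - tp
        tn = total - tp - fn - fp
        per_class[cls] = ClassMetrics(
            se=tp / (tp + fn) if tp + fn > 0 else np.nan,
            sp=tn / (tn + fp) if tn + fp > 0 else np.nan,
            ppv=tp / (tp + fp) if tp + fp > 0 else np.nan,
            npv=tn / (tn + fn) if tn + fn > 0 else np.nan,
        )
    return MetricSet(accuracy=float(acc), kappa=float(kappa),
                     per_class=per_class, level=cm.level)


def pooled_metrics(cms: Sequence[ConfusionMatrix]) -> MetricSet:
    """Metrics of the summed (epoch-pooled) confusion matrix."""
    counts = np.sum([cm.counts for cm in cms], axis=0)
    return metrics(ConfusionMatrix(level=cms[0].level, counts=counts))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _summary(values: np.ndarray) -> CohortSummary:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n == 0:
        return CohortSummary(np.nan, np.nan, np.nan, 0)
    mean = float(np.mean(v))
    if n == 1:
        return CohortSummary(mean, mean, mean, 1)
    half = 1.96 * float(np.std(v, ddof=1)) / np.sqrt(n)
    return CohortSummary(mean, mean - half, mean + half, n)


def aggregate(per_subject: Sequence[MetricSet]) -> dict:
    """Cohort summaries: subject metrics averaged across participants with
    normal-approximation 95% CIs; undefined values skipped with n adjusted.

    Returns ``{"accuracy": CohortSummary, "kappa": ..., ("SE", cls): ...}``.
    """
    if len(per_subject) < 2:
        raise ValueError("need >= 2 subjects to aggregate")
    out = {
        "accuracy": _summary([m.accuracy for m in per_subject]),
        "kappa": _summary([m.kappa for m in per_subject]),
    }
    classes = LEVEL_CLASSES[per_subject[0].level]
    for cls in classes:
        for attr in ("se", "sp", "ppv", "npv"):
            vals = [getattr(m.per_class[cls], attr) for m in per_subject]
            summ = _summary(vals)
            if summ.n_subjects < len(per_subject):
                logger.info("%s(%s): %d undefined subject values skipped",
                            attr, cls, len(per_subject) - summ.n_subjects)
            out[(attr.upper(), cls)] = summ
    return out


# ---------------------------------------------------------------------------
# Covariate regressions
# ---------------------------------------------------------------------------

def stratified_regression(per_subject: Sequence[MetricSet],
                          meta: Sequence,
                          metric_names: Sequence[str] = METRIC_NAMES,
                          factors: Sequence[str] = ("age", "ahi", "sex"),
                          ) -> list:
    """One-factor-at-a-time OLS of each subject-level metric on each factor.

    Each factor is dummy-coded against its fixed reference level (age <= 40,
    AHI none/minimal, female); betas, normal 95% CIs and two-sided p-values
    come from the OLS fit.  Contrasts on empty strata are undefined (NaN).
    """
    import statsmodels.api as sm

    if len(per_subject) != len(meta):
        raise ValueError("metrics and metadata length mismatch")
    rows = []
    for m, md in zip(per_subject, meta):
        rows.append({
            "accuracy": m.accuracy, "kappa": m.kappa,
            "age": md.age_group, "ahi": md.ahi_group, "sex": md.sex,
        })
        for cls, cm in m.per_class.items():
            for attr in ("se", "sp", "ppv", "npv"):
                rows[-1][f"{attr}_{cls}"] = getattr(cm, attr)
    df = pd.DataFrame(rows)

    effects = []
    for metric in metric_names:
        if metric not in df.columns:
            raise ValueError(f"unknown metric {metric!r}")
        for factor in factors:
            ref = REFERENCE_LEVELS[factor]
            levels = FACTOR_LEVELS[factor]
            sub = df[[metric, factor]].dropna()
            for level in levels:
                if level == ref:
                    continue
                present = set(sub[factor])
                if level not in present or ref not in present:
                    effects.append(StrataEffect(
                        metric=metric, factor=factor, level=level,
                        reference=ref, beta=np.nan, ci95=(np.nan, np.nan),
                        p_value=np.nan))
                    continue
                dummies = np.column_stack([
                    (sub[factor] == l).astype(float) for l in levels
                    if l != ref and l in present])
                names = [l for l in levels if l != ref and l in present]
                X = sm.add_constant(dummies)
                fit = sm.OLS(sub[metric].to_numpy(), X).fit()
                j = names.index(level) + 1
                ci = fit.conf_int()[j]
                effects.append(StrataEffect(
                    metric=metric, factor=factor, level=level, reference=ref,
                    beta=float(fit.params[j]),
                    ci95=(float(ci[0]), float(ci[1])),
                    p_value=float(fit.pvalues[j])))
    return effects


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def evaluation_report(refs: Sequence, preds: Sequence, levels=(2, 3, 4),
                      meta: Sequence | None = None) -> dict:
    """Full per-level report: per-class cohort summaries, pooled metrics,
    and (with metadata) the covariate effect table."""
    report = {}
    for level in levels:
        per_subject = [metrics(confusion(r, p, level))
                       for r, p in zip(refs, preds)]
        agg = aggregate(per_subject) if len(per_subject) >= 2 else None
        entry = {"n_subjects": len(per_subject)}
        if agg:
            entry["model"] = {
                "accuracy": vars(agg["accuracy"]),
                "kappa": vars(agg["kappa"]),
            }
            entry["classes"] = {
                cls: {attr: vars(agg[(attr, cls)])
                      for attr in ("SE", "SP", "PPV", "NPV")}
                for cls in LEVEL_CLASSES[level]
            }
        report[f"level_{level}"] = entry
        if meta is not None and level == 2 and len(per_subject) >= 4:
            effects = stratified_regression(per_subject, meta)
            report["strata_effects"] = [
                {**{k: v for k, v in vars(e).items()}, "stars": e.stars}
                for e in effects]
    return report
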