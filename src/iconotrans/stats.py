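"""Evaluation statistics for the transfer experiments.

Regression experiments are summarized by per-item cosine similarities
(mean, sample SD, normal-approximation 95% CI) and contrasted against the
randomized baseline with a paired t-test plus the paired Cohen's d
(mean(diff)/sd(diff)).  Classification experiments report accuracy,
support-weighted precision and F1, a McNemar chi-square on paired
correctness (no continuity correction by default), per-class accuracy
(= per-class recall), and the cross-language consistency of per-class
accuracy profiles as a mean pairwise Pearson correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CosineSummary",
    "ContrastResult",
    "McNemarResult",
    "ClassContrastResult",
    "cosine",
    "confidence_interval",
    "summarize",
    "paired_contrast",
    "mcnemar",
    "classification_metrics",
    "cross_language_consistency",
]


@dataclass
class CosineSummary:
    mean: float
    sd: float  # sample SD (n-1 denominator)
    ci_low: float
    ci_high: float
    n: int


@dataclass
class ContrastResult:
    model_summary: CosineSummary
    baseline_summary: CosineSummary
    t: float
    p: float
    d: float


@dataclass
class McNemarResult:
    chi2: float
    p: float
    degenerate: bool = False  # no discordant pairs (b + c = 0)

    def __iter__(self):
        return iter((self.chi2, self.p))


@dataclass
class ClassContrastResult:
    model: dict
    baseline: dict
    chi2: float
    p: float


def cosine(u, v) -> float:
    """Cosine similarity ``u.v / (|u||v|)``; zero vectors are an error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def confidence_interval(mean: float, sd: float, n: int) -> tuple[float, float]:
    """Normal-approximation 95% CI: ``mean +/- 1.96 * sd / sqrt(n)``."""
    if n < 2:
        raise ValueError("need n >= 2")
    half = 1.96 * sd / math.sqrt(n)
    return mean - half, mean + half


def summarize(values) -> CosineSummary:
    """Mean, sample SD and 95% CI of a list of per-item scores."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two values to summarize")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    lo, hi = confidence_interval(mean, sd, n)
    return CosineSummary(mean=mean, sd=sd, ci_low=lo, ci_high=hi, n=n)


def paired_contrast(a, b) -> ContrastResult:
    """Paired t-test of per-item scores ``a`` (model) vs ``b`` (baseline).

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = a - b`` and sample SD;
    two-sided p from Student's t with n-1 df; effect size is the paired
    Cohen's d, ``mean(d)/sd(d)``.  A degenerate zero-variance difference
    yields t = +/-inf, p = 0 when the mean difference is nonzero and
    t = 0, p = 1 when it is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    mean_d = float(diff.mean())
    sd_d = float(diff.std(ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            t, p, d = 0.0, 1.0, 0.0
        else:
            t = math.inf if mean_d > 0 else -math.inf
            p, d = 0.0, math.copysign(math.inf, mean_d)
    else:
        t = mean_d / (sd_d / math.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
        d = mean_d / sd_d
    return ContrastResult(
        model_summary=summarize(a),
        baseline_summary=summarize(b),
        t=t,
        p=p,
        d=d,
    )


def mcnemar(correct_model, correct_baseline, continuity: bool = False) -> McNemarResult:
    """McNemar chi-square on paired correctness indicators.

    With ``b`` = model-only-correct and ``c`` = baseline-only-correct:
    ``chi2 = (b - c)^2 / (b + c)`` (the standard calculation; set
    ``continuity=True`` for the Edwards-corrected ``(|b-c|-1)^2/(b+c)``),
    p from chi-square with 1 df.  ``b + c = 0`` is reported as chi2 = 0,
    p = 1 with the ``degenerate`` flag set.
    """
    cm = np.asarray(correct_model, dtype=bool)
    cb = np.asarray(correct_baseline, dtype=bool)
    if cm.shape != cb.shape:
        raise ValueError("paired correctness lists must have equal length")
    b = int(np.sum(cm & ~cb))
    c = int(np.sum(~cm & cb))
    if b + c == 0:
        return McNemarResult(chi2=0.0, p=1.0, degenerate=True)
    num = (abs(b - c) - 1) ** 2 if continuity else (b - c) ** 2
    chi2 = num / (b + c)
    p = float(sps.chi2.sf(chi2, df=1))
    return McNemarResult(chi2=float(chi2), p=p)


def classification_metrics(true_labels, predicted_labels, classes) -> dict:
    """Accuracy, support-weighted precision/F1 and per-class accuracy.

    Per-class accuracy is the recall of that class; a class never predicted
    contributes precision 0.  Support-weighted recall equals accuracy, so it
    is not reported separately.
    """
    from sklearn.metrics import precision_recall_fscore_support

    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if not true_labels:
        raise ValueError("empty label lists")
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    classes = list(classes)
    precision, recall, f1, support = precision_recall_fscore_support(
        true_labels, predicted_labels, labels=classes, zero_division=0
    )
    total = support.sum()
    accuracy = float(
        np.mean([t == p for t, p in zip(true_labels, predicted_labels)])
    )
    weights = support / total if total else np.zeros_like(support, dtype=float)
    per_class = {
        cls: (float(recall[i]) if support[i] > 0 else math.nan)
        for i, cls in enumerate(classes)
    }
    return {
        "accuracy": accuracy,
        "weighted_precision": float((weights * precision).sum()),
        "weighted_f1": float((weights * f1).sum()),
        "per_class_accuracy": per_class,
    }


def cross_language_consistency(per_language: dict) -> tuple[dict, float, list]:
    """Cross-language agreement of per-class accuracy profiles.

    ``per_language`` maps language -> {class -> accuracy}.  Returns the
    per-class mean accuracy across languages (second-order mean), the mean
    Pearson r over all unordered language pairs, and the list of languages
    excluded for having a zero-variance accuracy profile.
    """
    languages = list(per_language)
    if len(languages) < 2:
        raise ValueError("need at least two languages")
    class_set = None
    for lang in languages:
        keys = set(per_language[lang])
        if class_set is None:
            class_set = keys
        elif keys != class_set:
            raise ValueError("languages do not share the same class set")
    classes = sorted(class_set)
    profiles = {
        lang: np.array([per_language[lang][c] for c in classes], dtype=float)
        for lang in languages
    }
    per_class_mean = {
        c: float(np.mean([per_language[lang][c] for lang in languages]))
        for c in classes
    }
    excluded = [lang for lang, v in profiles.items() if np.std(v) == 0.0]
    usable = [lang for lang in languages if lang not in excluded]
    rs = [
        float(np.corrcoef(profiles[l1], profiles[l2])[0, 1])
        for l1, l2 in itertools.combinations(usable, 2)
    ]
    mean_r = float(np.mean(rs)) if rs else math.nan
    return per_class_mean, mean_r, excluded
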