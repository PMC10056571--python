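"""Diagnostic-accuracy statistics.

Empirical ROC/AUC with DeLong variance and paired AUC comparison, Youden
cut-off selection, sensitivity/specificity, the McNemar paired test against
a gold standard, and two-way absolute-agreement intraclass correlation for
observer agreement.

The empirical AUC is the Mann–Whitney statistic with half credit for ties:

    AUC = (1/mn) Σ_i Σ_j [ 1{x_i > y_j} + ½·1{x_i = y_j} ]

over the m positive-class markers x and n negative-class markers y. The
DeLong variance is computed from placement values via midranks, the
O(N log N) formulation; the paired comparison uses the placement covariance
and a two-sided normal reference for z = ΔAUC / SE(ΔAUC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "DeLongComparison",
    "YoudenResult",
    "McNemarResult",
    "ICCResult",
    "roc_auc",
    "delong_compare",
    "youden_cut",
    "sens_spec",
    "mcnemar",
    "icc_agreement",
]


@dataclass
class ROCResult:
    auc: float
    se_delong: float
    ci95: tuple[float, float]
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    delta: float
    se_delta: float
    z: float
    p_two_sided: float


@dataclass
class YoudenResult:
    best_threshold: float
    j: float
    sensitivity: float
    specificity: float


@dataclass
class McNemarResult:
    b: int  # prediction positive, gold negative
    c: int  # prediction negative, gold positive
    statistic: float
    p: float
    method: str  # "exact" | "chi2_cc"


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    model: str = "two-way, absolute agreement, single measurement (ICC(A,1))"
    defined: bool = True


def _split(markers, labels) -> tuple[np.ndarray, np.ndarray]:
    markers = np.asarray(markers, dtype=float)
    labels = np.asarray(labels)
    if markers.shape != labels.shape:
        raise ValueError("markers and labels must have the same length")
    if np.any(np.isnan(markers)):
        raise ValueError("markers contain NaN; filter unmeasurable patients first")
    lab = labels.astype(bool) if labels.dtype == bool else (np.asarray(labels, float) > 0.5)
    pos, neg = markers[lab], markers[~lab]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative label")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement vectors (V10 for positives, V01 for negatives)
    via midranks — ties receive half credit."""
    m, n = len(pos), len(neg)
    both = np.concatenate([pos, neg])
    r_all = stats.rankdata(both)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (np.sum(r_all[:m]) - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return float(auc), v10, v01


def roc_auc(markers, labels) -> ROCResult:
    """Empirical ROC curve and AUC with DeLong standard error.

    The 95 % CI is the Wald interval ``auc ± 1.96·se`` clipped to [0, 1].
    Curve points are swept over thresholds between the observed marker
    values (prediction positive at marker ≥ threshold), so sensitivity is
    non-increasing as the threshold rises.
    """
    pos, neg = _split(markers, labels)
    m, n = len(pos), len(neg)
    auc, v10, v01 = _placements(pos, neg)
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    ci = (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))

    thresholds, sens, spec = _sweep(pos, neg)
    return ROCResult(auc, se, ci, thresholds, sens, spec, m, n)


def _sweep(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sensitivity/specificity at midpoints of adjacent unique values ±∞,
    predicting positive at marker ≥ threshold."""
    uniq = np.unique(np.concatenate([pos, neg]))
    thresholds = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    pos_sorted, neg_sorted = np.sort(pos), np.sort(neg)
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / len(pos)
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / len(neg)
    return thresholds, sens, spec


def delong_compare(markers_a, markers_b, labels) -> DeLongComparison:
    """DeLong test for the difference of two paired empirical AUCs.

    Both markers must be measured on the same patients in the same order.
    Returns z = ΔAUC/SE and the two-sided normal p-value; identical markers
    give Δ = 0 and p = 1.
    """
    markers_a = np.asarray(markers_a, float)
    markers_b = np.asarray(markers_b, float)
    if markers_a.shape != markers_b.shape:
        raise ValueError("paired markers must have equal length")
    pos_a, neg_a = _split(markers_a, labels)
    pos_b, neg_b = _split(markers_b, labels)
    auc_a, v10_a, v01_a = _placements(pos_a, neg_a)
    auc_b, v10_b, v01_b = _placements(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    delta = auc_a - auc_b
    var_delta = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    se_delta = math.sqrt(max(var_delta, 0.0))
    if se_delta == 0.0:
        z, p = 0.0, 1.0
    else:
        z = delta / se_delta
        p = 2.0 * stats.norm.sf(abs(z))
    return DeLongComparison(auc_a, auc_b, delta, se_delta, z, min(p, 1.0))


def youden_cut(markers, labels) -> YoudenResult:
    """Optimal cut-off by Youden's index J = sensitivity + specificity − 1.

    Candidate thresholds are the midpoints of adjacent sorted unique marker
    values plus ±∞; prediction is positive at marker ≥ threshold. Ties in J
    are broken toward the lowest threshold (maximising sensitivity).
    """
    pos, neg = _split(markers, labels)
    thresholds, sens, spec = _sweep(pos, neg)
    j = sens + spec - 1.0
    # lowest threshold among the (numerically) tied maxima
    i = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return YoudenResult(float(thresholds[i]), float(j[i]), float(sens[i]), float(spec[i]))


def sens_spec(predictions, labels) -> dict:
    """Sensitivity, specificity and the underlying confusion counts.

    A class absent from the labels leaves the corresponding rate ``None``
    and sets a flag rather than raising.
    """
    pred = np.asarray(predictions).astype(bool)
    lab = np.asarray(labels).astype(bool)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels must have equal length")
    tp = int(np.sum(pred & lab))
    fn = int(np.sum(~pred & lab))
    tn = int(np.sum(~pred & ~lab))
    fp = int(np.sum(pred & ~lab))
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "specificity": tn / (tn + fp) if tn + fp else None,
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
        "sensitivity_defined": bool(tp + fn),
        "specificity_defined": bool(tn + fp),
    }


def mcnemar(predictions, gold) -> McNemarResult:
    """McNemar test of disagreement with a gold standard.

    With b = (prediction +, gold −) and c = (prediction −, gold +): the
    exact two-sided binomial test is used when b + c < 25, otherwise the
    continuity-corrected χ² statistic (|b−c|−1)²/(b+c) on 1 df. b = c = 0
    yields p = 1.
    """
    pred = np.asarray(predictions).astype(bool)
    g = np.asarray(gold).astype(bool)
    if pred.shape != g.shape:
        raise ValueError("paired vectors must have equal length")
    b = int(np.sum(pred & ~g))
    c = int(np.sum(~pred & g))
    nd = b + c
    if nd == 0:
        return McNemarResult(b, c, 0.0, 1.0, "exact")
    if nd < 25:
        k = min(b, c)
        p = min(1.0, 2.0 * float(stats.binom.cdf(k, nd, 0.5)))
        return McNemarResult(b, c, float(k), p, "exact")
    chi2 = (abs(b - c) - 1.0) ** 2 / nd
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(b, c, chi2, p, "chi2_cc")


def icc_agreement(ratings, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single measurement.

    ``ratings`` is a complete subjects × raters array (≥5 subjects, ≥2
    raters). The point estimate comes from the two-way ANOVA mean squares

        ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    and the CI from the standard F-based interval with Satterthwaite
    degrees of freedom. Zero between-subject variance leaves the ICC
    undefined (``defined=False``).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters array")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 subjects and 2 raters")
    if np.any(np.isnan(x)):
        raise ValueError("ratings table must be complete")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or (ssr == 0 and sse == 0):
        return ICCResult(float("nan"), (float("nan"), float("nan")), defined=False)
    icc = (msr - mse) / denom

    # Satterthwaite-based CI (McGraw & Wong), as used for ICC(A,1)
    if mse <= 0:  # perfect agreement: degenerate, CI collapses
        return ICCResult(float(icc), (float(icc), float(icc)))
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * (k * icc * fj) ** 2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return ICCResult(float(icc), (float(min(lower, 1.0)), float(min(upper, 1.0))))
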