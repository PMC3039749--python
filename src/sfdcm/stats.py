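"""Burst counting and validity statistics.

Turns continuous estimates into per-epoch response counts and computes the
statistics used to compare the model-based analysis against conventional
trough-to-peak counting: Pearson/point-biserial correlations between count
vectors and binary psychological state, threshold sweeps, ROC curves with
AUC, and the extra-sum-of-squares F-test asking whether model-based counts
explain state variance beyond conventional counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as ssig
from scipy import stats as sstats

from .inversion import InversionResult
from .preproc import Epoch


@dataclass
class ROCResult:
    points: np.ndarray  # (k, 2) of (false-positive rate, sensitivity)
    auc: float


@dataclass
class ValidityReport:
    threshold: float
    counts_dcm: np.ndarray
    counts_conv: np.ndarray
    r_methods: float
    r_validity_dcm: float
    r_validity_conv: float
    roc_dcm: ROCResult
    roc_conv: ROCResult
    f_stat: float
    f_df: tuple[int, int]
    p_value: float


def count_bursts(result: InversionResult, threshold: float = 0.1) -> int:
    """Number of posterior bursts with amplitude at or above ``threshold`` μS.

    The comparison is inclusive (>=), so a burst at exactly the threshold
    counts.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return int(np.count_nonzero(result.bursts.amplitudes >= threshold))


def count_sf_conventional(
    epoch: Epoch, threshold: float = 0.25, min_separation: float = 1.0
) -> int:
    """Automatic trough-to-peak count of spontaneous fluctuations.

    Counts local maxima whose rise from the preceding local minimum (the
    trough since the last counted peak, or the epoch start) is at least
    ``threshold`` μS, requiring ``min_separation`` seconds between counted
    peaks.  This is an automatic stand-in for semi-visual event scoring and
    is documented as such.
    """
    x = epoch.series.samples
    dist = max(1, int(round(min_separation * epoch.series.rate)))
    peaks, _ = ssig.find_peaks(x, distance=dist)
    count = 0
    prev = 0
    for p in peaks:
        trough = x[prev : p + 1].min() if p > prev else x[p]
        if x[p] - trough >= threshold:
            count += 1
            prev = p
    return count


def conventional_count_matrix(epochs, thresholds) -> np.ndarray:
    """Trough-to-peak counts for every epoch at every threshold.

    Returns an (n_thresholds, n_epochs) integer matrix for use with
    :func:`threshold_sweep`, mirroring sweeps where the detection threshold
    of the conventional analysis is varied alongside the model's.
    """
    return np.array(
        [[count_sf_conventional(ep, threshold=th) for ep in epochs] for th in thresholds]
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation; with binary ``y`` this is point-biserial."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(sstats.pearsonr(x, y).statistic)


def threshold_sweep(results, conv_counts, labels, thresholds):
    """Correlations of both counting methods as a function of the threshold.

    ``results`` are per-epoch :class:`InversionResult` objects; model counts
    are recomputed at each threshold.  ``conv_counts`` is either a fixed
    per-epoch count vector or an (n_thresholds, n_epochs) matrix (e.g. from
    :func:`conventional_count_matrix`) so the conventional threshold sweeps
    too.  ``labels`` are binary states per epoch.  Returns a list of dicts
    with keys threshold, r_methods, r_validity_dcm, r_validity_conv.
    """
    labels = np.asarray(labels, dtype=float)
    if len(results) != labels.size:
        raise ValueError("results and labels must align")
    if labels.size < 3:
        raise ValueError("need at least 3 epochs")
    if np.unique(labels).size < 2:
        raise ValueError("both label classes must be present")
    conv = np.asarray(conv_counts, dtype=float)
    if conv.ndim == 1:
        conv = np.tile(conv, (len(thresholds), 1))
    if conv.shape != (len(thresholds), labels.size):
        raise ValueError("conv_counts must be per-epoch or (n_thresholds, n_epochs)")
    rows = []
    for i, th in enumerate(thresholds):
        dcm = np.array([count_bursts(res, threshold=th) for res in results], float)
        rows.append({
            "threshold": float(th),
            "r_methods": _safe_r(dcm, conv[i]),
            "r_validity_dcm": _safe_r(dcm, labels),
            "r_validity_conv": _safe_r(conv[i], labels),
        })
    return rows


def _safe_r(x, y) -> float:
    """Pearson r, with the degenerate zero-variance case mapped to 0.0
    (identical count vectors map to 1.0)."""
    if np.array_equal(x, y):
        return 1.0
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return pearson_r(x, y)


def roc_curve(counts, labels) -> ROCResult:
    """ROC over all integer cutoffs of the rule "positive if count >= c".

    Points are (1 - specificity, sensitivity), include the (0,0) and (1,1)
    endpoints, and AUC is the trapezoid over the sorted curve.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels)
    pos = labels == np.max(labels)
    if pos.all() or (~pos).all():
        raise ValueError("both label classes must be present")
    cutoffs = np.unique(counts)
    pts = [(1.0, 1.0)]  # c = -inf: everything positive
    for c in cutoffs:
        pred = counts >= c
        sens = np.count_nonzero(pred & pos) / np.count_nonzero(pos)
        fpr = np.count_nonzero(pred & ~pos) / np.count_nonzero(~pos)
        pts.append((fpr, sens))
    pts.append((0.0, 0.0))  # c = +inf: nothing positive
    pts = np.array(sorted(set(pts)))
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ROCResult(points=pts, auc=auc)


def nested_f_test(state, pred_base, pred_add):
    """Extra-sum-of-squares F-test for added predictive value.

    Compares the regressions state ~ pred_base against
    state ~ pred_base + pred_add.  Returns (F, df1, df2, p) with df1 = 1 and
    df2 = n - 3.  If ``pred_add`` is (numerically) a linear function of the
    base predictor the added term carries no information: F = 0 with a
    collinearity warning.
    """
    state = np.asarray(state, dtype=float)
    base = np.asarray(pred_base, dtype=float)
    add = np.asarray(pred_add, dtype=float)
    n = state.size
    if base.size != n or add.size != n or n < 4:
        raise ValueError("need equal-length vectors of at least 4 values")
    ones = np.ones(n)
    X0 = np.column_stack([ones, base])
    X1 = np.column_stack([ones, base, add])
    df1, df2 = 1, n - 3
    if np.linalg.matrix_rank(X1, tol=1e-10 * max(1.0, np.abs(X1).max())) < 3:
        warnings.warn("pred_add is collinear with pred_base; F set to 0")
        return 0.0, df1, df2, 1.0
    rss0 = _rss(X0, state)
    rss1 = _rss(X1, state)
    if rss1 <= 0:
        return float("inf"), df1, df2, 0.0
    f = max(0.0, (rss0 - rss1) / df1 / (rss1 / df2))
    p = float(sstats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def _rss(X, y) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def between_subject_scores(counts, labels, subjects):
    """Per-subject arousal score: mean anticipation count minus baseline count.

    ``labels`` distinguish "baseline" epochs (label equal to the string
    ``baseline``) from anticipation epochs; the score for each subject is
    the mean count over their anticipation epochs minus the mean count over
    their baseline epoch(s).  Returns (subject ids, scores) in first-seen
    subject order.
    """
    counts = np.asarray(counts, dtype=float)
    order = list(dict.fromkeys(subjects))
    scores = []
    for s in order:
        idx = [i for i, subj in enumerate(subjects) if subj == s]
        is_base = np.array([labels[i] == "baseline" for i in idx])
        if not is_base.any() or is_base.all():
            raise ValueError(f"subject {s} lacks baseline or anticipation epochs")
        c = counts[idx]
        scores.append(float(c[~is_base].mean() - c[is_base].mean()))
    return order, np.array(scores)


def validity_report(
    results, epochs, labels, threshold: float = 0.1,
    conv_threshold: float | None = None,
) -> ValidityReport:
    """Counts, correlations, ROC curves and the nested F-test in one report.

    ``labels`` are binary epoch states (0/1).  Both methods are thresholded
    at ``threshold`` unless ``conv_threshold`` overrides the conventional
    detector's.
    """
    labels = np.asarray(labels, dtype=float)
    conv_th = threshold if conv_threshold is None else conv_threshold
    counts_dcm = np.array([count_bursts(r, threshold=threshold) for r in results])
    counts_conv = np.array(
        [count_sf_conventional(ep, threshold=conv_th) for ep in epochs]
    )
    f, df1, df2, p = nested_f_test(labels, counts_conv, counts_dcm)
    return ValidityReport(
        threshold=threshold,
        counts_dcm=counts_dcm,
        counts_conv=counts_conv,
        r_methods=_safe_r(counts_dcm.astype(float), counts_conv.astype(float)),
        r_validity_dcm=_safe_r(counts_dcm.astype(float), labels),
        r_validity_conv=_safe_r(counts_conv.astype(float), labels),
        roc_dcm=roc_curve(counts_dcm, labels),
        roc_conv=roc_curve(counts_conv, labels),
        f_stat=f,
        f_df=(df1, df2),
        p_value=p,
    )
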