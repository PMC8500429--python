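"""Task evaluation: ROC curves, AUC, sub-sampled AUC distributions, CNR.

The classification task scores each subject by a single estimated parameter
and sweeps the decision threshold across all observed values.  The empirical
ROC is traced through every distinct score; the trapezoidal area under it
equals the Mann-Whitney U statistic scaled to [0, 1], with half-credit for
tied positive/negative scores.

Because a small clinical study estimates AUC from few patients, a design's
predicted AUC from a large simulated population is complemented by the
distribution of AUCs over repeated sub-samples drawn without replacement at
the clinical group sizes: this quantifies how much of the discrepancy between
prediction and observation is attributable to sample size alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .errors import InputValidationError

__all__ = [
    "TaskSpec",
    "ROCCurve",
    "AUCDistribution",
    "compute_roc_auc",
    "subsample_auc_distribution",
    "separability_cnr",
    "gaussian_auc_closed_form",
]


@dataclass(frozen=True)
class TaskSpec:
    """Binary classification task definition.

    ``positive_label`` is the tissue treated as "diseased"; the score is the
    value of ``classification_parameter`` estimated by the chosen fit.
    """

    positive_label: str
    negative_label: str
    classification_parameter: str

    def __post_init__(self) -> None:
        if self.positive_label == self.negative_label:
            raise InputValidationError("task labels must be distinct")


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve with trapezoidal AUC.

    ``fpr``/``tpr`` are non-decreasing, starting at (0, 0) and ending at
    (1, 1); ``thresholds`` holds the score cut-offs generating each
    operating point (decision rule: score >= threshold is called positive,
    after orientation).  ``flipped`` records whether scores were negated so
    that AUC >= 0.5.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    flipped: bool


@dataclass(frozen=True)
class AUCDistribution:
    """AUC values over repeated sub-sampling at clinical group sizes."""

    samples: np.ndarray
    n_pos: int
    n_neg: int
    repeats: int
    mean: float
    sd: float
    ci95: tuple[float, float]


def _validate_scores(scores, name: str) -> np.ndarray:
    a = np.asarray(scores, dtype=float).ravel()
    if a.size == 0:
        raise InputValidationError(f"{name} must be non-empty")
    if not np.all(np.isfinite(a)):
        raise InputValidationError(f"{name} must be finite")
    return a


def _roc_points(scores_pos: np.ndarray, scores_neg: np.ndarray):
    """Threshold sweep over the pooled distinct scores (descending)."""
    scores = np.concatenate([scores_pos, scores_neg])
    labels = np.concatenate([
        np.ones(scores_pos.size, dtype=bool),
        np.zeros(scores_neg.size, dtype=bool),
    ])
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    # collapse tied scores into single operating points
    distinct = np.flatnonzero(np.diff(scores)) if scores.size > 1 else np.array([], int)
    idx = np.r_[distinct, scores.size - 1]
    tp = np.cumsum(labels)[idx]
    fp = np.cumsum(~labels)[idx]
    tpr = np.r_[0.0, tp / scores_pos.size]
    fpr = np.r_[0.0, fp / scores_neg.size]
    thresholds = np.r_[np.inf, scores[idx]]
    return thresholds, fpr, tpr


def compute_roc_auc(scores_pos, scores_neg, orient: str = "auto") -> ROCCurve:
    """Empirical ROC curve and trapezoidal AUC from two score groups.

    Parameters
    ----------
    scores_pos, scores_neg : array-like
        Finite, non-empty scores for the positive (diseased) and negative
        groups.
    orient : {"auto", "fixed"}
        With ``"auto"`` (clinical convention) scores are negated when the
        raw AUC is below 0.5 and the ``flipped`` flag records this; with
        ``"fixed"`` the scores are used as given, allowing fair method
        comparisons in which an estimator cannot gain by flipping sign.

    Notes
    -----
    The trapezoidal area over the empirical curve equals the Mann-Whitney
    statistic ``(#[pos > neg] + 0.5 #[pos == neg]) / (n_pos * n_neg)``.
    """
    pos = _validate_scores(scores_pos, "scores_pos")
    neg = _validate_scores(scores_neg, "scores_neg")
    if orient not in ("auto", "fixed"):
        raise InputValidationError(f"orient must be 'auto' or 'fixed', got {orient!r}")

    thresholds, fpr, tpr = _roc_points(pos, neg)
    auc = float(np.trapezoid(tpr, fpr))
    flipped = False
    if orient == "auto" and auc < 0.5:
        thresholds, fpr, tpr = _roc_points(-pos, -neg)
        auc = float(np.trapezoid(tpr, fpr))
        flipped = True
    return ROCCurve(thresholds, fpr, tpr, auc, flipped)


def subsample_auc_distribution(
    scores_pos,
    scores_neg,
    n_pos: int,
    n_neg: int,
    repeats: int,
    rng: np.random.Generator,
) -> AUCDistribution:
    """Distribution of AUC over sub-samples matching clinical group sizes.

    Each repeat draws ``n_pos``/``n_neg`` scores per group without
    replacement (modelling a small clinical cohort drawn from a population)
    and recomputes the AUC with the orientation inherited from the
    full-sample curve, so a sub-sample cannot flip sign independently.
    """
    pos = _validate_scores(scores_pos, "scores_pos")
    neg = _validate_scores(scores_neg, "scores_neg")
    if not (1 <= n_pos <= pos.size) or not (1 <= n_neg <= neg.size):
        raise InputValidationError(
            f"sub-sample sizes ({n_pos}, {n_neg}) must be within group sizes "
            f"({pos.size}, {neg.size})"
        )
    if repeats < 1:
        raise InputValidationError("repeats must be >= 1")

    full = compute_roc_auc(pos, neg, orient="auto")
    sign = -1.0 if full.flipped else 1.0
    samples = np.empty(repeats)
    for i in range(repeats):
        sp = rng.choice(pos, size=n_pos, replace=False)
        sn = rng.choice(neg, size=n_neg, replace=False)
        samples[i] = compute_roc_auc(sign * sp, sign * sn, orient="fixed").auc
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return AUCDistribution(
        samples=samples,
        n_pos=int(n_pos),
        n_neg=int(n_neg),
        repeats=int(repeats),
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)) if repeats > 1 else 0.0,
        ci95=(float(lo), float(hi)),
    )


def separability_cnr(scores_pos, scores_neg) -> float:
    """Contrast-to-noise ratio between two score groups.

    Defined here as ``|mean_pos - mean_neg| / sqrt(sd_pos^2 + sd_neg^2)``
    (standardised mean difference; sample SDs with ddof=1).  Returns 0 for
    identical-mean groups and ``inf`` when both groups are degenerate
    (zero variance) with different means.
    """
    pos = _validate_scores(scores_pos, "scores_pos")
    neg = _validate_scores(scores_neg, "scores_neg")
    if pos.size < 2 or neg.size < 2:
        raise InputValidationError("each group needs >= 2 scores for a CNR")
    delta = abs(pos.mean() - neg.mean())
    denom = np.sqrt(pos.var(ddof=1) + neg.var(ddof=1))
    if denom == 0.0:
        return 0.0 if delta == 0.0 else float("inf")
    return float(delta / denom)


def gaussian_auc_closed_form(
    mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float
) -> float:
    """AUC of two Gaussian score populations (binormal ROC closed form).

    Phi((mu_pos - mu_neg) / sqrt(sd_pos^2 + sd_neg^2)).  With both SDs zero
    the limit is 1 or 0 by mean ordering (0.5 if the means are equal).
    Used as the analytic reference for score distributions that are
    Gaussian by construction.
    """
    if sd_pos < 0 or sd_neg < 0:
        raise InputValidationError("standard deviations must be >= 0")
    denom = float(np.hypot(sd_pos, sd_neg))
    delta = float(mu_pos - mu_neg)
    if denom == 0.0:
        return 0.5 if delta == 0.0 else (1.0 if delta > 0 else 0.0)
    return float(ndtr(delta / denom))
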