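"""Reliability metrics: do a model's patch scores concentrate on the
annotated regions of interest?

Given a per-patch score vector and the binary patch labels derived from
region annotations, three complementary quantities are computed:

* **mutual information** (plug-in estimate, nats) between quantile-binned
  scores and labels — statistical dependence of the score on ROI
  membership;
* **Spearman's rank correlation** — monotone association between score
  and ROI presence (Pearson correlation of mid-ranks, average-rank ties);
* **AUPRC / average precision** — localization quality under class
  imbalance; the no-skill baseline equals the positive prevalence.

Slides without any positive patch (no ROI — e.g. normal slides) carry no
reliability signal and are excluded before aggregation. Metrics are
either computed within each retained slide and averaged
(``per_slide_mean``, the default) or on the pooled patch set (``pooled``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .bagcore import PatchScoreSet, ScoreChannel

__all__ = [
    "ReliabilityResult",
    "mutual_information",
    "spearman",
    "auprc",
    "evaluate_scores",
    "evaluate_model",
]


@dataclass
class ReliabilityResult:
    model_id: str
    seed: int
    mi: float
    spearman: float
    auprc: float
    n_slides_used: int
    degenerate: bool = False  # >99% of score mass on <1% of patches


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if len(scores) < 2:
        raise ValueError("need at least 2 patches")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return scores, labels.astype(int)


def _quantile_bin(scores: np.ndarray, bins: int, threshold: float | None) -> np.ndarray:
    if threshold is not None:
        return (scores >= threshold).astype(int)
    qs = np.quantile(scores, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, scores, side="left")


def mutual_information(scores, labels, bins: int = 2,
                       threshold: float | None = None) -> float:
    """Plug-in mutual information (nats) between binned scores and labels.

    Scores are discretized into ``bins`` quantile bins (default two,
    split at the median); pass ``threshold=0.5`` to split a probability
    channel at 0.5 instead. Constant labels or constant binned scores give
    0 with a warning.
    """
    scores, labels = _check(scores, labels)
    if labels.min() == labels.max():
        warnings.warn("constant labels: MI undefined, returning 0", stacklevel=2)
        return 0.0
    binned = _quantile_bin(scores, bins, threshold)
    joint = np.zeros((binned.max() + 1, 2))
    np.add.at(joint, (binned, labels), 1.0)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / (px @ py)[mask])).sum())


def spearman(scores, labels) -> float:
    """Spearman's rank correlation: Pearson correlation of mid-ranks.

    Returns 0 (with a warning) when either vector has zero rank variance.
    """
    scores, labels = _check(scores, labels)
    rs, rl = rankdata(scores), rankdata(labels)
    if np.ptp(rs) == 0 or np.ptp(rl) == 0:
        warnings.warn("zero rank variance: Spearman undefined, returning 0", stacklevel=2)
        return 0.0
    rs = rs - rs.mean()
    rl = rl - rl.mean()
    return float((rs @ rl) / np.sqrt((rs @ rs) * (rl @ rl)))


def auprc(scores, labels) -> float:
    """Average precision: sum_k (R_k - R_{k-1}) P_k over descending-score
    thresholds (ties handled as one threshold)."""
    scores, labels = _check(scores, labels)
    n_pos = labels.sum()
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("AUPRC undefined: labels contain a single class")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate the PR curve only where the threshold actually drops
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def _is_degenerate(scores: np.ndarray) -> bool:
    """More than 99% of the score mass on fewer than 1% of patches."""
    total = scores.sum()
    if total <= 0 or len(scores) < 100:
        return False
    k = max(1, int(np.ceil(0.01 * len(scores))) - 1)
    if k < 1:
        return False
    top = np.sort(scores)[::-1][:k].sum()
    return bool(top / total > 0.99)


def evaluate_scores(
    score_sets: list[PatchScoreSet],
    patch_labels: list[np.ndarray],
    aggregation: str = "per_slide_mean",
    bins: int = 2,
) -> tuple[float, float, float, int, bool]:
    """Aggregate (MI, Spearman, AUPRC) over a slide set.

    Slides whose label vector has no positive patch are excluded. Under
    ``per_slide_mean`` each metric is computed within every retained slide
    then averaged; under ``pooled`` all retained slides' patches are
    concatenated first. Returns ``(mi, spearman, auprc, n_used, degenerate)``.
    """
    if aggregation not in ("per_slide_mean", "pooled"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if len(score_sets) != len(patch_labels):
        raise ValueError("score sets and label sets do not align")
    kept_scores, kept_labels, degenerate = [], [], False
    for ss, lab in zip(score_sets, patch_labels):
        lab = np.asarray(lab)
        if len(ss.scores) != len(lab):
            raise ValueError(f"slide {ss.slide_id}: score/label length mismatch")
        if lab.sum() == 0:
            continue
        kept_scores.append(ss)
        kept_labels.append(lab)
        degenerate = degenerate or _is_degenerate(ss.scores)
    if not kept_scores:
        raise ValueError("no ROI slides: every slide lacks positive patches")

    thr = 0.5 if kept_scores[0].channel is ScoreChannel.patch_prob else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if aggregation == "pooled":
            s = np.concatenate([ss.scores for ss in kept_scores])
            y = np.concatenate(kept_labels)
            mi = mutual_information(s, y, bins=bins, threshold=thr)
            return mi, spearman(s, y), auprc(s, y), len(kept_scores), degenerate
        mis, rhos, aps = [], [], []
        for ss, y in zip(kept_scores, kept_labels):
            mis.append(mutual_information(ss.scores, y, bins=bins, threshold=thr))
            rhos.append(spearman(ss.scores, y))
            aps.append(auprc(ss.scores, y) if 0 < y.sum() < len(y) else 1.0)
    return (float(np.mean(mis)), float(np.mean(rhos)), float(np.mean(aps)),
            len(kept_scores), degenerate)


def evaluate_model(
    model_id: str,
    seed: int,
    score_sets: list[PatchScoreSet],
    patch_labels: list[np.ndarray],
    aggregation: str = "per_slide_mean",
    bins: int = 2,
) -> ReliabilityResult:
    """Package an :func:`evaluate_scores` run as a :class:`ReliabilityResult`."""
    mi, rho, ap, n_used, degen = evaluate_scores(score_sets, patch_labels,
                                                 aggregation=aggregation, bins=bins)
    return ReliabilityResult(model_id=model_id, seed=seed, mi=mi, spearman=rho,
                             auprc=ap, n_slides_used=n_used, degenerate=degen)
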