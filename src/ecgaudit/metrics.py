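"""Diagnostic performance statistics with confidence intervals.

Conventions fixed package-wide: a positive call is ``score >= threshold``
(boundary inclusive); AUROC counts ties as 1/2 (so the AUROC of a 0/1
binarized predictor equals (Se + Sp)/2 exactly); proportion CIs use the
Wilson score method; AUROC CIs use DeLong by default with a seeded
stratified bootstrap as the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "auroc",
    "auroc_ci",
    "auprc",
    "operating_point_metrics",
    "counts_from_rates",
    "threshold_for_sensitivity",
    "pearson_r",
    "subgroup_performance",
    "compute_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def n_called_positive(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricsReport:
    n_pos: int
    n_neg: int
    threshold: float
    auroc_continuous: float
    auroc_continuous_ci: tuple[float, float]
    auroc_binary: float
    auroc_binary_ci: tuple[float, float]
    auprc: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float | None
    ppv_ci: tuple[float, float] | None
    npv: float | None
    npv_ci: tuple[float, float] | None
    pearson_r: float | None = None
    pearson_p: float | None = None


def _validate_two_class(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels > 0.5
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    return pos, ~pos


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUROC; ties counted 1/2 (equals the pairwise probability)."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _validate_two_class(labels)
    n1, n0 = int(pos.sum()), int(neg.sum())
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auroc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    method: str = "delong",
    seed: int | None = None,
    n_boot: int = 2000,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """AUROC with a 95% CI (DeLong default; seeded stratified bootstrap)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    value = auroc(scores, labels)
    pos, neg = _validate_two_class(labels)
    x, y = scores[pos], scores[neg]
    z = stats.norm.ppf(1 - alpha / 2)
    if method == "delong":
        var = _delong_variance(x, y)
        half = z * np.sqrt(var)
        lo, hi = max(0.0, value - half), min(1.0, value + half)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        m, n = len(x), len(y)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            xb = x[rng.integers(0, m, m)]
            yb = y[rng.integers(0, n, n)]
            sb = np.concatenate([xb, yb])
            lb = np.concatenate([np.ones(m), np.zeros(n)])
            reps[b] = auroc(sb, lb)
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown CI method {method!r}; use delong or bootstrap")
    return value, (float(lo), float(hi))


def _delong_variance(x: np.ndarray, y: np.ndarray) -> float:
    """DeLong structural-component variance of the AUROC estimate."""
    m, n = len(x), len(y)
    all_scores = np.concatenate([x, y])
    tz = stats.rankdata(all_scores)
    tx = stats.rankdata(x)
    ty = stats.rankdata(y)
    v01 = (tz[:m] - tx) / n           # per-positive placement
    v10 = 1.0 - (tz[m:] - ty) / m     # per-negative placement
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(s01 / m + s10 / n)


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve.

    Computed by threshold enumeration, keeping the best precision achieved
    at each attained recall, anchored at (recall 0, precision 1), and
    integrated with the trapezoidal rule.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, _ = _validate_two_class(labels)
    n_pos = int(pos.sum())
    thresholds = np.unique(scores)[::-1]
    best: dict[float, float] = {}
    for thr in thresholds:
        called = scores >= thr
        tp = int((called & pos).sum())
        if tp == 0:
            continue
        recall = tp / n_pos
        precision = tp / int(called.sum())
        if precision > best.get(recall, -1.0):
            best[recall] = precision
    recalls = np.array([0.0] + sorted(best))
    precisions = np.array([1.0] + [best[r] for r in sorted(best)])
    return float(np.trapezoid(precisions, recalls))


def operating_point_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
) -> tuple[ConfusionCounts, dict[str, tuple[float | None, tuple[float, float] | None]]]:
    """Confusion counts and Se/Sp/PPV/NPV with Wilson 95% CIs.

    PPV (NPV) is reported as ``(None, None)`` when no record is called
    positive (negative) rather than fabricated.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels > 0.5
    called = scores >= threshold
    counts = ConfusionCounts(
        tp=int((called & pos).sum()),
        fp=int((called & ~pos).sum()),
        tn=int((~called & ~pos).sum()),
        fn=int((~called & pos).sum()),
    )
    return counts, metrics_from_counts(counts)


def metrics_from_counts(
    counts: ConfusionCounts,
) -> dict[str, tuple[float | None, tuple[float, float] | None]]:
    def prop(k: int, n: int):
        if n == 0:
            return None, None
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        return k / n, (float(lo), float(hi))

    return {
        "sensitivity": prop(counts.tp, counts.n_pos),
        "specificity": prop(counts.tn, counts.n_neg),
        "ppv": prop(counts.tp, counts.tp + counts.fp),
        "npv": prop(counts.tn, counts.tn + counts.fn),
    }


def counts_from_rates(
    n_pos: int, n_neg: int, sensitivity: float, specificity: float
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed rates.

    Uses nearest-integer rounding of the expected counts; useful for
    auditing published operating-point tables.
    """
    tp = round(sensitivity * n_pos)
    tn = round(specificity * n_neg)
    return ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def binarized_scores(counts: ConfusionCounts) -> tuple[np.ndarray, np.ndarray]:
    """A 0/1 score vector + labels realizing the given confusion counts."""
    scores = np.concatenate([
        np.ones(counts.tp), np.zeros(counts.fn),
        np.ones(counts.fp), np.zeros(counts.tn),
    ])
    labels = np.concatenate([
        np.ones(counts.n_pos), np.zeros(counts.n_neg),
    ]).astype(int)
    return scores, labels


def threshold_for_sensitivity(
    scores: Sequence[float],
    labels: Sequence[int],
    target: float = 0.90,
) -> float:
    """Largest observed-score threshold whose sensitivity is >= target."""
    if not 0.0 < target <= 1.0:
        raise ValueError("target sensitivity must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos_scores = scores[labels > 0.5]
    if pos_scores.size == 0:
        raise ValueError("no positive records")
    candidates = np.unique(scores)[::-1]
    for thr in candidates:
        if (pos_scores >= thr).mean() >= target:
            return float(thr)
    return float(candidates[-1])


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def subgroup_performance(
    scores: Sequence[float],
    labels: Sequence[int],
    grouping: Mapping[str, Sequence[int]] | Sequence,
    threshold: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """One row per group; groups lacking both classes are flagged, not dropped."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if isinstance(grouping, Mapping):
        groups = {k: np.asarray(v, dtype=int) for k, v in grouping.items()}
    else:
        arr = np.asarray(grouping)
        if arr.size != scores.size:
            raise ValueError("grouping must align with records")
        groups = {str(g): np.flatnonzero(arr == g) for g in pd.unique(arr)}
    if not groups:
        raise ValueError("empty grouping")
    rows = []
    for name, idx in groups.items():
        s, l = scores[idx], labels[idx]
        row: dict = {"group": name, "n": len(idx),
                     "n_pos": int((l > 0.5).sum()), "n_neg": int((l <= 0.5).sum())}
        both = 0 < row["n_pos"] < row["n"]
        row["evaluable"] = both
        if both:
            value, (lo, hi) = auroc_ci(s, l, seed=seed)
            counts, op = operating_point_metrics(s, l, threshold)
            row.update(
                auroc=value, auroc_lo=lo, auroc_hi=hi,
                auprc=auprc(s, l),
                sensitivity=op["sensitivity"][0],
                specificity=op["specificity"][0],
                ppv=op["ppv"][0], npv=op["npv"][0],
            )
        else:
            row.update(auroc=np.nan, auroc_lo=np.nan, auroc_hi=np.nan,
                       auprc=np.nan, sensitivity=np.nan, specificity=np.nan,
                       ppv=np.nan, npv=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def compute_report(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
    lvef: Sequence[float] | None = None,
    seed: int | None = None,
    ci_method: str = "delong",
) -> MetricsReport:
    """Full operating-table report (continuous + binary AUROC, AUPRC, rates)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = _validate_two_class(labels)
    cont, cont_ci = auroc_ci(scores, labels, method=ci_method, seed=seed)
    counts, op = operating_point_metrics(scores, labels, threshold)
    bscores = (scores >= threshold).astype(float)
    binv, bin_ci = auroc_ci(bscores, labels, method=ci_method, seed=seed)
    r = p = None
    if lvef is not None:
        r, p = pearson_r(scores, lvef)
    return MetricsReport(
        n_pos=int(pos.sum()),
        n_neg=int(neg.sum()),
        threshold=threshold,
        auroc_continuous=cont,
        auroc_continuous_ci=cont_ci,
        auroc_binary=binv,
        auroc_binary_ci=bin_ci,
        auprc=auprc(scores, labels),
        sensitivity=op["sensitivity"][0],
        sensitivity_ci=op["sensitivity"][1],
        specificity=op["specificity"][0],
        specificity_ci=op["specificity"][1],
        ppv=op["ppv"][0],
        ppv_ci=op["ppv"][1],
        npv=op["npv"][0],
        npv_ci=op["npv"][1],
        pearson_r=r,
        pearson_p=p,
    )
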