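"""Concept-activation-vector attribution over the surrogate's feature blocks.

A CAV is the unit normal of a regularized linear classifier separating a
concept's activations from random activations in one block's pooled
activation space.  The TCAV score of a concept is the fraction of class
examples whose positive-class logit has a positive directional derivative
along the CAV; 0.5 is the uninformative null.  Significance comes from
repeated runs against independent random pools: the score CI is the
empirical 2.5/97.5 percentile band of run scores and the p-value is a
Welch two-sided test of concept-run scores against random-vs-random run
scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .records import ECGRecord
from .surrogate import Surrogate, _validate_block_index
from .synthetic import ConceptDataset

__all__ = [
    "CAV",
    "TCAVResult",
    "train_cav",
    "tcav_score",
    "tcav_score_from_gradients",
    "pooled_gradients",
    "tcav_significance",
    "rank_blocks",
]


@dataclass(frozen=True)
class CAV:
    concept_name: str
    block_index: int
    direction: np.ndarray       # unit vector in pooled activation space
    classifier_accuracy: float
    run_seed: int

    def __post_init__(self):
        norm = float(np.linalg.norm(self.direction))
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ValueError(f"direction must have unit norm, got {norm}")
        if not 0.0 <= self.classifier_accuracy <= 1.0:
            raise ValueError("classifier_accuracy must be in [0, 1]")

    def negated(self) -> "CAV":
        return CAV(self.concept_name, self.block_index, -self.direction,
                   self.classifier_accuracy, self.run_seed)


@dataclass(frozen=True)
class TCAVResult:
    concept_name: str
    block_index: int
    score: float
    ci95: tuple[float, float]
    p_value: float
    n_runs: int

    def __post_init__(self):
        lo, hi = self.ci95
        if not (0.0 <= lo <= self.score <= hi <= 1.0):
            raise ValueError(
                f"require 0 <= lo <= score <= hi <= 1, got {lo}, {self.score}, {hi}"
            )
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")


def train_cav(
    concept_acts: np.ndarray,
    random_acts: np.ndarray,
    seed: int = 0,
    concept_name: str = "concept",
    block_index: int = 1,
    holdout_fraction: float = 1 / 3,
) -> CAV:
    """Fit a seeded linear separator; direction points toward the concept."""
    concept_acts = np.asarray(concept_acts, dtype=float)
    random_acts = np.asarray(random_acts, dtype=float)
    if concept_acts.ndim != 2 or random_acts.ndim != 2:
        raise ValueError("activation sets must be 2-D (examples x channels)")
    if concept_acts.shape[1] != random_acts.shape[1]:
        raise ValueError(
            f"dimension mismatch: concept {concept_acts.shape[1]} vs "
            f"random {random_acts.shape[1]}"
        )
    if len(concept_acts) < 2 or len(random_acts) < 2:
        raise ValueError("need at least 2 examples per class")
    x = np.vstack([concept_acts, random_acts])
    y = np.concatenate([np.ones(len(concept_acts)), np.zeros(len(random_acts))])
    x_fit, x_hold, y_fit, y_hold = train_test_split(
        x, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    clf = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    clf.fit(x_fit, y_fit)
    accuracy = float((clf.predict(x_hold) == y_hold).mean())
    w = clf.coef_[0]
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate separator (zero weight vector)")
    return CAV(
        concept_name=concept_name,
        block_index=block_index,
        direction=w / norm,
        classifier_accuracy=accuracy,
        run_seed=seed,
    )


def pooled_gradients(
    model: Surrogate,
    records: Sequence[ECGRecord],
    batch_size: int = 32,
) -> list[np.ndarray]:
    """d(logit)/d(pooled activation) per block, stacked over records.

    Returns a list of four (n_records, channels[b]) arrays.  Gradients do
    not depend on any CAV, so callers score many CAVs against one pass.
    """
    from .surrogate import _stack_records

    x = _stack_records(model, records)
    per_block: list[list[np.ndarray]] = [[] for _ in range(4)]
    for start in range(0, len(records), batch_size):
        _, grads = model.pooled_logit_gradients(x[start:start + batch_size])
        for b in range(4):
            per_block[b].append(grads[b])
    return [np.vstack(chunks) for chunks in per_block]


def tcav_score_from_gradients(gradients: np.ndarray, cav: CAV) -> float:
    """Fraction of examples whose directional derivative along the CAV is > 0.

    Exact zeros count 1/2 so that negating the direction maps the score to
    ``1 - score`` exactly.
    """
    d = np.asarray(gradients, dtype=float) @ cav.direction
    if d.size == 0:
        raise ValueError("empty example set")
    return float(np.mean((d > 0) + 0.5 * (d == 0)))


def tcav_score(
    model: Surrogate,
    class_examples: Sequence[ECGRecord],
    cav: CAV,
) -> float:
    """TCAV score of one CAV on records of the predicted class."""
    if len(class_examples) == 0:
        raise ValueError("empty example set")
    _validate_block_index(cav.block_index)
    grads = pooled_gradients(model, class_examples)[cav.block_index - 1]
    return tcav_score_from_gradients(grads, cav)


def tcav_significance(
    model: Surrogate,
    concept_ds: ConceptDataset | None,
    random_pools: Sequence[np.ndarray],
    block_index: int,
    class_examples: Sequence[ECGRecord] | None = None,
    n_runs: int = 30,
    seed: int = 0,
    concept_acts: np.ndarray | None = None,
    class_gradients: np.ndarray | None = None,
) -> TCAVResult:
    """Repeated-run TCAV score with 95% CI and a random-concept p-value.

    Each run trains one CAV against a different random activation pool;
    the null distribution re-runs the procedure with one random pool
    standing in for the concept.  Callers may pass precomputed
    ``concept_acts`` and ``class_gradients`` to amortize forward/backward
    passes across blocks and concepts.
    """
    _validate_block_index(block_index)
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if len(random_pools) < n_runs + 1:
        raise ValueError(
            f"need at least n_runs + 1 = {n_runs + 1} random pools, "
            f"got {len(random_pools)}"
        )
    if concept_acts is None:
        if concept_ds is None:
            raise ValueError("provide concept_ds or concept_acts")
        from .surrogate import extract_activations

        concept_acts = np.array(
            [a.vector for a in
             extract_activations(model, list(concept_ds.positives), block_index)]
        )
    if class_gradients is None:
        if class_examples is None:
            raise ValueError("provide class_examples or class_gradients")
        class_gradients = pooled_gradients(model, class_examples)[block_index - 1]

    name = concept_ds.concept_name if concept_ds is not None else "concept"
    rng = np.random.default_rng(seed)
    concept_scores = np.empty(n_runs)
    null_scores = np.empty(n_runs)
    n_pools = len(random_pools)
    for run in range(n_runs):
        run_seed = int(rng.integers(0, 2**31 - 1))
        cav = train_cav(concept_acts, random_pools[run % n_pools],
                        seed=run_seed, concept_name=name,
                        block_index=block_index)
        concept_scores[run] = tcav_score_from_gradients(class_gradients, cav)
        i, j = rng.choice(n_pools, size=2, replace=False)
        null_cav = train_cav(random_pools[i], random_pools[j],
                             seed=run_seed, concept_name="random",
                             block_index=block_index)
        null_scores[run] = tcav_score_from_gradients(class_gradients, null_cav)
    score = float(concept_scores.mean())
    lo, hi = np.percentile(concept_scores, [2.5, 97.5])
    lo, hi = min(float(lo), score), max(float(hi), score)
    if np.ptp(concept_scores) < 1e-12 and np.ptp(null_scores) < 1e-12:
        # both run distributions are degenerate; Welch is undefined
        p = 1.0 if concept_scores[0] == null_scores[0] else 0.0
    else:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(
                stats.ttest_ind(concept_scores, null_scores, equal_var=False).pvalue
            )
        if np.isnan(p):
            p = 1.0
    return TCAVResult(
        concept_name=name,
        block_index=block_index,
        score=score,
        ci95=(max(0.0, lo), min(1.0, hi)),
        p_value=p,
        n_runs=n_runs,
    )


def rank_blocks(
    results: Sequence[TCAVResult],
) -> tuple[int, pd.DataFrame]:
    """Best block by mean TCAV score over concepts (ties -> lowest index).

    Requires a complete concepts x 4 blocks grid; returns the winning block
    index and the grid as a DataFrame (concepts as rows, blocks as columns).
    """
    concepts = sorted({r.concept_name for r in results})
    by_cell = {(r.concept_name, r.block_index): r for r in results}
    missing = [
        (c, b) for c in concepts for b in (1, 2, 3, 4) if (c, b) not in by_cell
    ]
    if missing:
        raise ValueError(f"incomplete TCAV grid; missing cells: {missing}")
    grid = pd.DataFrame(
        {b: [by_cell[(c, b)].score for c in concepts] for b in (1, 2, 3, 4)},
        index=concepts,
    )
    means = grid.mean(axis=0)
    best = int(means.idxmin()) if means.isna().all() else int(
        means[means == means.max()].index.min()
    )
    return best, grid
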