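"""Phenotype discovery on positively predicted records.

Features are pooled activations of the top-ranked feature block, restricted
to records called positive at the operating threshold.  Cluster count comes
from the elbow of the K-means inertia curve (maximum perpendicular distance
to the chord between the first and last curve points); the 2-D view is a
seeded t-SNE.  Features are standardized per dimension before clustering
and embedding; the fitted scaler and centroids travel with the model so a
clustering fitted on one dataset can be applied to another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .records import ECGRecord
from .surrogate import DEFAULT_THRESHOLD, Surrogate, extract_activations, predict_scores
from .synthetic import SubjectMetadata

__all__ = [
    "ClusterModel",
    "ClusterProfile",
    "select_positive_features",
    "select_cluster_count",
    "fit_phenotype_clusters",
    "assign_clusters",
    "embed_2d",
    "profile_clusters",
]


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray             # (k, d) in standardized feature space
    training_block: int
    seed: int
    inertia_curve: list[tuple[int, float]]
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        dists = np.linalg.norm(
            self.centroids[:, None, :] - self.centroids[None, :, :], axis=2
        )
        np.fill_diagonal(dists, np.inf)
        if np.min(dists) == 0:
            raise ValueError("centroids must be pairwise distinct")
        inertias = [v for _, v in self.inertia_curve]
        if any(b > a + 1e-9 for a, b in zip(inertias, inertias[1:])):
            raise ValueError("inertia curve must be non-increasing in k")


@dataclass(frozen=True)
class ClusterProfile:
    cluster_label: str
    n: int
    true_positive_rate: float
    mean_score: float
    mean_lvef: float
    metadata_summary: dict


def select_positive_features(
    model: Surrogate,
    records: Sequence[ECGRecord],
    threshold: float = DEFAULT_THRESHOLD,
    block_index: int = 1,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Pooled block activations of records scoring >= threshold.

    Returns (features, kept record ids, kept scores).
    """
    outputs = predict_scores(model, records, threshold)
    kept = [i for i, o in enumerate(outputs) if o.score >= threshold]
    if not kept:
        raise ValueError(
            f"no record scored >= {threshold}; review the threshold or the model"
        )
    kept_records = [records[i] for i in kept]
    acts = extract_activations(model, kept_records, block_index)
    features = np.array([a.vector for a in acts])
    ids = [records[i].record_id for i in kept]
    scores = np.array([outputs[i].score for i in kept])
    return features, ids, scores


def _standardize(features: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = features.mean(axis=0)
    scale = features.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return (features - mean) / scale, mean, scale


def _kmeans(features: np.ndarray, k: int, seed: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(features)
    return km


def select_cluster_count(
    features: np.ndarray,
    k_range: Sequence[int] = range(2, 9),
    seed: int = 0,
) -> tuple[int, list[tuple[int, float]]]:
    """Elbow rule: maximum perpendicular distance to the chord.

    The curve is anchored at k=1 (total sum of squares) and the chord
    distance is evaluated on the log-inertia curve with both axes
    normalized to [0, 1]; the log keeps the knee detectable when one
    high-variance feature direction dominates the early inertia drops.
    Only ks inside ``k_range`` are eligible.
    """
    features = np.asarray(features, dtype=float)
    n = len(features)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, n-1] = [2, {n - 1}]")
    if np.all(features == features[0]):
        raise ValueError("degenerate features: all rows identical")
    std, _, _ = _standardize(features)
    total_ss = float(((std - std.mean(axis=0)) ** 2).sum())
    curve = [(1, total_ss)]
    curve += [(k, float(_kmeans(std, k, seed).inertia_)) for k in ks]
    k_arr = np.array([k for k, _ in curve], dtype=float)
    inertia = np.array([v for _, v in curve])
    # floor the curve at 0.5% of the total SS so near-zero tails (perfectly
    # compact clusterings) do not masquerade as further knees on a log scale
    floor = 0.005 * max(total_ss, 1e-300)
    log_inertia = np.log(np.maximum(inertia, floor))
    kk = (k_arr - k_arr[0]) / max(k_arr[-1] - k_arr[0], 1.0)
    span = np.ptp(log_inertia)
    if span == 0:
        return ks[0], curve
    ii = (log_inertia - log_inertia.min()) / span
    chord = np.array([kk[-1] - kk[0], ii[-1] - ii[0]])
    pts = np.stack([kk - kk[0], ii - ii[0]], axis=1)
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / np.linalg.norm(chord)
    eligible = np.array([i for i, (k, _) in enumerate(curve) if k in ks])
    best = eligible[int(np.argmax(dist[eligible]))]
    return int(k_arr[best]), curve


def fit_phenotype_clusters(
    features: np.ndarray,
    k: int,
    seed: int = 0,
    training_block: int = 1,
    inertia_curve: list[tuple[int, float]] | None = None,
) -> tuple[ClusterModel, np.ndarray]:
    """Seeded K-means (greedy spreading init, 10 restarts); returns assignments."""
    features = np.asarray(features, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(features):
        raise ValueError(f"k={k} exceeds the number of records {len(features)}")
    std, mean, scale = _standardize(features)
    km = _kmeans(std, k, seed)
    model = ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        training_block=training_block,
        seed=seed,
        inertia_curve=inertia_curve or [(k, float(km.inertia_))],
        feature_mean=mean,
        feature_scale=scale,
    )
    return model, km.labels_.astype(int)


def assign_clusters(model: ClusterModel, features: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment of new records (fit-on-A / assign-on-B)."""
    std = (np.asarray(features, dtype=float) - model.feature_mean) / model.feature_scale
    d = np.linalg.norm(std[:, None, :] - model.centroids[None, :, :], axis=2)
    return d.argmin(axis=1)


def embed_2d(
    features: np.ndarray,
    seed: int = 0,
    perplexity: float = 10.0,
) -> np.ndarray:
    """Seeded t-SNE to n x 2 coordinates."""
    features = np.asarray(features, dtype=float)
    n = len(features)
    if n <= perplexity * 3:
        raise ValueError(
            f"need n > 3 * perplexity; got n={n}, perplexity={perplexity}"
        )
    std, _, _ = _standardize(features)
    emb = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca",
    ).fit_transform(std)
    if not np.all(np.isfinite(emb)):
        raise ValueError("embedding produced non-finite coordinates")
    return np.asarray(emb, dtype=float)


def profile_clusters(
    assignments: Sequence[int],
    metadata: Sequence[SubjectMetadata],
    scores: Sequence[float],
) -> tuple[list[ClusterProfile], pd.DataFrame]:
    """Per-cluster size, TP rate, mean score/LVEF and metadata summaries."""
    assignments = np.asarray(assignments, dtype=int)
    if not (len(assignments) == len(metadata) == len(scores)):
        raise ValueError("assignments, metadata and scores must align")
    scores = np.asarray(scores, dtype=float)
    profiles: list[ClusterProfile] = []
    rows = []
    for label in sorted(set(assignments.tolist())):
        idx = np.flatnonzero(assignments == label)
        metas = [metadata[i] for i in idx]
        name = chr(ord("A") + label) if label < 26 else str(label)
        tp_rate = float(np.mean([m.label == "LVSD" for m in metas]))
        summary = {
            "mean_age": float(np.mean([m.age for m in metas])),
            "frac_male": float(np.mean([m.sex == "M" for m in metas])),
            "frac_htn": float(np.mean([m.hypertension for m in metas])),
            "frac_dm": float(np.mean([m.diabetes for m in metas])),
            "frac_cad": float(np.mean([m.cad for m in metas])),
            "frac_ckd": float(np.mean([m.ckd for m in metas])),
        }
        profile = ClusterProfile(
            cluster_label=name,
            n=len(idx),
            true_positive_rate=tp_rate,
            mean_score=float(scores[idx].mean()),
            mean_lvef=float(np.mean([m.lvef_percent for m in metas])),
            metadata_summary=summary,
        )
        profiles.append(profile)
        rows.append({
            "cluster": name, "n": profile.n,
            "true_positive_rate": profile.true_positive_rate,
            "mean_score": profile.mean_score,
            "mean_lvef": profile.mean_lvef,
            **summary,
        })
    if sum(p.n for p in profiles) != len(assignments):
        raise AssertionError("cluster sizes must sum to the number of records")
    return profiles, pd.DataFrame(rows)
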