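"""End-to-end audit orchestration.

``run_audit`` drives simulate -> train -> evaluate -> TCAV -> clustering ->
lead-reversal suite -> noise suite from one config, writes every table as
CSV, and records a manifest (config snapshot, per-stage seeds and status,
artifact hashes) so a rerun with the same config reproduces all CSVs
bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    embed_2d,
    fit_phenotype_clusters,
    profile_clusters,
    select_cluster_count,
    select_positive_features,
)
from .metrics import compute_report
from .noise import default_specs, noise_robustness_suite
from .records import ECGRecord
from .reversal import reversal_robustness_suite
from .surrogate import (
    DEFAULT_THRESHOLD,
    Surrogate,
    SurrogateConfig,
    TrainConfig,
    build_surrogate,
    predict_scores,
    save_checkpoint,
    train_surrogate,
)
from .synthetic import (
    CONCEPT_NAMES,
    NEUTRAL_DISTRIBUTION,
    draw_params,
    make_concept_dataset,
    simulate_cohort,
    simulate_record,
)
from .tcav import pooled_gradients, rank_blocks, tcav_significance

__all__ = ["AuditConfig", "RunManifest", "run_audit"]


@dataclass
class AuditConfig:
    seed: int = 0
    # cohort
    n_pos: int = 120
    n_neg: int = 280
    fs: float = 250.0
    duration_s: float = 10.0
    eval_fraction: float = 0.3
    # model / training
    channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    kernel: int = 7
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    threshold: float = DEFAULT_THRESHOLD
    # tcav
    tcav_runs: int = 10
    concept_pos: int = 30
    concept_neg: int = 30
    random_pool_size: int = 30
    # clustering
    k_min: int = 2
    k_max: int = 8
    perplexity: float = 8.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AuditConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "channels" in data:
            data["channels"] = tuple(data["channels"])
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def record_stage(self, name: str, status: str, seconds: float,
                     error: str | None = None) -> None:
        self.stages[name] = {"status": status, "seconds": round(seconds, 3)}
        if error:
            self.stages[name]["error"] = error

    def record_artifact(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.artifacts[name] = {"path": str(path), "sha256": digest}

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest, name: str) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest.record_artifact(name, path)


class _StageFailed(RuntimeError):
    pass


def run_audit(config: AuditConfig, out_dir: str | Path) -> Path:
    """Run the full audit; returns the report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)
    manifest.seeds = {
        "cohort": config.seed,
        "train": config.seed + 1,
        "tcav": config.seed + 2,
        "cluster": config.seed + 3,
        "suites": config.seed + 4,
    }
    state: dict = {}
    stage_plan = [
        ("simulate", _stage_simulate),
        ("train", _stage_train),
        ("evaluate", _stage_evaluate),
        ("tcav", _stage_tcav),
        ("cluster", _stage_cluster),
        ("reversal", _stage_reversal),
        ("noise", _stage_noise),
    ]
    failed = None
    for name, fn in stage_plan:
        if failed is not None:
            manifest.record_stage(name, f"skipped (after {failed} failed)", 0.0)
            continue
        t0 = time.perf_counter()
        try:
            fn(config, state, out, manifest)
            manifest.record_stage(name, "completed", time.perf_counter() - t0)
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            manifest.record_stage(
                name, "failed", time.perf_counter() - t0,
                error="".join(traceback.format_exception_only(exc)).strip(),
            )
            failed = name
    _write_summary(out, manifest, state)
    manifest.save(out / "manifest.json")
    if failed is not None:
        raise _StageFailed(
            f"stage {failed!r} failed: {manifest.stages[failed]['error']}"
        )
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, state, out, manifest):
    cohort = simulate_cohort(
        config.n_pos, config.n_neg, fs=config.fs, duration_s=config.duration_s,
        seed=manifest.seeds["cohort"],
    )
    rng = np.random.default_rng(manifest.seeds["cohort"])
    labels = np.array([1 if m.label == "LVSD" else 0 for _, m in cohort])
    idx = np.arange(len(cohort))
    eval_idx = np.concatenate([
        rng.choice(np.flatnonzero(labels == 1),
                   round(config.eval_fraction * config.n_pos), replace=False),
        rng.choice(np.flatnonzero(labels == 0),
                   round(config.eval_fraction * config.n_neg), replace=False),
    ])
    eval_mask = np.zeros(len(cohort), dtype=bool)
    eval_mask[eval_idx] = True
    state["train_cohort"] = [cohort[i] for i in idx[~eval_mask]]
    state["eval_cohort"] = [cohort[i] for i in idx[eval_mask]]


def _stage_train(config, state, out, manifest):
    model = build_surrogate(SurrogateConfig(
        channels=config.channels, kernel=config.kernel,
        n_samples=round(config.duration_s * config.fs),
        sampling_rate=config.fs, seed=manifest.seeds["train"],
    ))
    model, history = train_surrogate(model, state["train_cohort"], TrainConfig(
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate, seed=manifest.seeds["train"],
    ))
    state["model"] = model
    state["history"] = history
    ckpt = out / "surrogate.ckpt"
    save_checkpoint(model, ckpt)
    manifest.record_artifact("checkpoint", ckpt)


def _stage_evaluate(config, state, out, manifest):
    records = [r for r, _ in state["eval_cohort"]]
    metas = [m for _, m in state["eval_cohort"]]
    labels = np.array([1 if m.label == "LVSD" else 0 for m in metas])
    outputs = predict_scores(state["model"], records, config.threshold)
    scores = np.array([o.score for o in outputs])
    report = compute_report(
        scores, labels, config.threshold,
        lvef=[m.lvef_percent for m in metas], seed=manifest.seeds["suites"],
    )
    state.update(eval_records=records, eval_metas=metas,
                 eval_labels=labels, eval_scores=scores, report=report)
    scores_df = pd.DataFrame({
        "record_id": [o.record_id for o in outputs],
        "score": scores,
        "risk_class": [o.risk_class for o in outputs],
        "label": labels,
    })
    _write_csv(scores_df, out / "scores.csv", manifest, "scores")
    _write_csv(_report_to_frame(report), out / "metrics.csv", manifest, "metrics")


def _report_to_frame(report) -> pd.DataFrame:
    row = {
        "n_pos": report.n_pos, "n_neg": report.n_neg,
        "threshold": report.threshold,
        "auroc_binary": report.auroc_binary,
        "auroc_binary_lo": report.auroc_binary_ci[0],
        "auroc_binary_hi": report.auroc_binary_ci[1],
        "auroc_continuous": report.auroc_continuous,
        "auroc_continuous_lo": report.auroc_continuous_ci[0],
        "auroc_continuous_hi": report.auroc_continuous_ci[1],
        "auprc": report.auprc,
        "sensitivity": report.sensitivity,
        "sensitivity_lo": report.sensitivity_ci[0],
        "sensitivity_hi": report.sensitivity_ci[1],
        "specificity": report.specificity,
        "specificity_lo": report.specificity_ci[0],
        "specificity_hi": report.specificity_ci[1],
        "ppv": report.ppv, "npv": report.npv,
        "pearson_r_lvef": report.pearson_r,
        "pearson_p_lvef": report.pearson_p,
    }
    return pd.DataFrame([row])


def _make_random_pool_records(config, seed, count):
    rng = np.random.default_rng([seed, 31])
    records = []
    for i in range(count):
        params = draw_params(rng, NEUTRAL_DISTRIBUTION)
        records.append(simulate_record(
            params, config.fs, config.duration_s,
            seed=int(rng.integers(0, 2**31 - 1)), record_id=f"pool{i:05d}",
        ))
    return records


def _stage_tcav(config, state, out, manifest):
    from .surrogate import extract_activations_all_blocks

    model: Surrogate = state["model"]
    seed = manifest.seeds["tcav"]
    positives = [
        r for r, s in zip(state["eval_records"], state["eval_scores"])
        if s >= config.threshold
    ]
    if not positives:
        raise ValueError("no predicted-positive records for TCAV")
    grads = pooled_gradients(model, positives)

    n_pools = config.tcav_runs + 1
    pool_records = _make_random_pool_records(
        config, seed, n_pools * config.random_pool_size
    )
    pool_acts_all = extract_activations_all_blocks(model, pool_records)
    results = []
    for concept in CONCEPT_NAMES:
        ds = make_concept_dataset(
            concept, config.concept_pos, config.concept_neg,
            fs=config.fs, duration_s=config.duration_s, seed=seed,
        )
        concept_acts_all = extract_activations_all_blocks(model, list(ds.positives))
        for block in (1, 2, 3, 4):
            pool_acts = pool_acts_all[block - 1]
            pools = [
                pool_acts[i * config.random_pool_size:(i + 1) * config.random_pool_size]
                for i in range(n_pools)
            ]
            results.append(tcav_significance(
                model, ds, pools, block,
                n_runs=config.tcav_runs,
                seed=seed + block,
                concept_acts=concept_acts_all[block - 1],
                class_gradients=grads[block - 1],
            ))
    best_block, grid = rank_blocks(results)
    state["tcav_results"] = results
    state["best_block"] = best_block
    rows = [{
        "concept": r.concept_name, "block": r.block_index, "score": r.score,
        "ci_lo": r.ci95[0], "ci_hi": r.ci95[1], "p_value": r.p_value,
        "n_runs": r.n_runs,
    } for r in results]
    _write_csv(pd.DataFrame(rows), out / "tcav.csv", manifest, "tcav")


def _stage_cluster(config, state, out, manifest):
    model: Surrogate = state["model"]
    seed = manifest.seeds["cluster"]
    block = state.get("best_block", 1)
    features, ids, scores = select_positive_features(
        model, state["eval_records"], config.threshold, block
    )
    n = len(features)
    k_max = min(config.k_max, n - 1)
    k, curve = select_cluster_count(features, range(config.k_min, k_max + 1), seed)
    cmodel, assignments = fit_phenotype_clusters(
        features, k, seed, training_block=block, inertia_curve=curve
    )
    meta_by_id = {m.record_id: m for m in state["eval_metas"]}
    metas = [meta_by_id[i] for i in ids]
    profiles, profile_df = profile_clusters(assignments, metas, scores)
    assign_df = pd.DataFrame({
        "record_id": ids,
        "cluster": [chr(ord("A") + a) for a in assignments],
        "score": scores,
    })
    perplexity = min(config.perplexity, max(2.0, (n - 1) / 3.5))
    try:
        emb = embed_2d(features, seed, perplexity)
        assign_df["tsne_x"] = emb[:, 0]
        assign_df["tsne_y"] = emb[:, 1]
    except ValueError:
        pass  # too few positives for an embedding; assignments still written
    state["cluster_model"] = cmodel
    state["cluster_profiles"] = profiles
    _write_csv(assign_df, out / "cluster_assignments.csv", manifest,
               "cluster_assignments")
    _write_csv(profile_df, out / "cluster_profiles.csv", manifest,
               "cluster_profiles")


def _stage_reversal(config, state, out, manifest):
    table = reversal_robustness_suite(
        state["eval_records"], state["eval_labels"], state["model"],
        threshold=config.threshold,
        metrics_config={"seed": manifest.seeds["suites"]},
    )
    state["reversal_table"] = table
    _write_csv(table, out / "reversal.csv", manifest, "reversal")


def _stage_noise(config, state, out, manifest):
    table = noise_robustness_suite(
        state["eval_records"], state["eval_labels"], state["model"],
        specs=default_specs(manifest.seeds["suites"]),
        threshold=config.threshold,
        metrics_config={"seed": manifest.seeds["suites"]},
    )
    state["noise_table"] = table
    _write_csv(table, out / "noise.csv", manifest, "noise")


def _write_summary(out: Path, manifest: RunManifest, state: dict) -> None:
    lines = ["# ECG audit report", ""]
    lines.append(f"Toolkit version {manifest.version}; seeds: "
                 f"{json.dumps(manifest.seeds)}")
    lines.append("")
    lines.append("## Stages")
    for name, info in manifest.stages.items():
        lines.append(f"- {name}: {info['status']} ({info['seconds']} s)")
    if "report" in state:
        r = state["report"]
        lines += [
            "", "## Performance (held-out evaluation set)",
            f"- n = {r.n_pos} positive / {r.n_neg} negative, "
            f"threshold {r.threshold}",
            f"- AUROC (continuous) {r.auroc_continuous:.3f} "
            f"({r.auroc_continuous_ci[0]:.3f}-{r.auroc_continuous_ci[1]:.3f})",
            f"- AUROC (binary) {r.auroc_binary:.3f}",
            f"- Se {r.sensitivity:.3f} / Sp {r.specificity:.3f} / "
            f"PPV {r.ppv if r.ppv is None else round(r.ppv, 3)} / "
            f"NPV {r.npv if r.npv is None else round(r.npv, 3)}",
        ]
    if "best_block" in state:
        lines += ["", f"## TCAV: best feature block = {state['best_block']}"]
    if "cluster_profiles" in state:
        lines += ["", "## Phenotype clusters"]
        for p in state["cluster_profiles"]:
            lines.append(
                f"- Cluster {p.cluster_label}: n={p.n}, TP rate "
                f"{p.true_positive_rate:.2f}, mean score {p.mean_score:.1f}, "
                f"mean LVEF {p.mean_lvef:.1f}%"
            )
    for key, title in (("reversal_table", "Lead-reversal suite"),
                       ("noise_table", "Noise suite")):
        if key in state:
            lines += ["", f"## {title}", "",
                      state[key].to_string(index=False, float_format="%.3f"), ""]
    (out / "summary.md").write_text("\n".join(lines) + "\n")
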