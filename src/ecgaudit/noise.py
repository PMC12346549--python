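"""Seeded generators for the six artificial ECG noise types.

Types: ``power_line``, ``emg``, ``baseline_wander``, ``baseline_shift``,
``partial_white``, ``time_mask`` ("baseline wander and shift" count as two
types).  All types are applied to every lead with independent per-lead
phases / segment placements and a shared amplitude.  Amplitudes are either
absolute (mV) or a fraction of the record's RMS; each default is a declared
choice, not a literature value, and is logged through the spec itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import ECGRecord
from .surrogate import DEFAULT_THRESHOLD, Surrogate, predict_scores

__all__ = [
    "NOISE_TYPES",
    "NoiseSpec",
    "default_specs",
    "apply_noise",
    "noise_robustness_suite",
]

NOISE_TYPES: tuple[str, ...] = (
    "power_line",
    "emg",
    "baseline_wander",
    "baseline_shift",
    "partial_white",
    "time_mask",
)


@dataclass(frozen=True)
class NoiseSpec:
    noise_type: str
    amplitude: float = 0.0
    amplitude_mode: str = "mv"       # "mv" | "rms" (fraction of record RMS)
    frequency_hz: float = 60.0       # power_line carrier / wander band top
    wander_band_hz: tuple[float, float] = (0.05, 0.5)
    segment_fraction: float = 0.2    # partial_white / time_mask / shift extent
    n_segments: int = 2
    max_switch_points: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.noise_type not in NOISE_TYPES:
            raise ValueError(
                f"unknown noise type {self.noise_type!r}; one of {NOISE_TYPES}"
            )
        if not 0.0 <= self.segment_fraction <= 1.0:
            raise ValueError("segment_fraction must be in [0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.amplitude_mode not in ("mv", "rms"):
            raise ValueError("amplitude_mode must be 'mv' or 'rms'")


def default_specs(seed: int = 0) -> list[NoiseSpec]:
    """The six default noise profiles (appendix-unavailable stand-ins)."""
    return [
        NoiseSpec("power_line", amplitude=0.25, amplitude_mode="rms",
                  frequency_hz=60.0, seed=seed),
        NoiseSpec("emg", amplitude=0.5, amplitude_mode="rms", seed=seed + 1),
        NoiseSpec("baseline_wander", amplitude=0.5, amplitude_mode="mv",
                  seed=seed + 2),
        NoiseSpec("baseline_shift", amplitude=0.5, amplitude_mode="mv",
                  seed=seed + 3),
        NoiseSpec("partial_white", amplitude=1.0, amplitude_mode="rms",
                  segment_fraction=0.2, seed=seed + 4),
        NoiseSpec("time_mask", segment_fraction=0.1, amplitude=1.0,
                  seed=seed + 5),
    ]


def _resolve_amplitude(spec: NoiseSpec, signal: np.ndarray) -> float:
    if spec.amplitude_mode == "mv":
        return spec.amplitude
    rms = float(np.sqrt(np.mean(np.square(signal))))
    return spec.amplitude * rms


def _segments(rng: np.random.Generator, n: int, total: int,
              n_segments: int) -> np.ndarray:
    """Boolean mask with exactly ``total`` samples inside random segments."""
    mask = np.zeros(n, dtype=bool)
    if total <= 0:
        return mask
    n_segments = max(1, min(n_segments, total))
    lengths = [total // n_segments] * n_segments
    lengths[-1] += total - sum(lengths)
    for length in lengths:
        placed = False
        for _ in range(200):
            start = int(rng.integers(0, max(1, n - length + 1)))
            if not mask[start:start + length].any():
                mask[start:start + length] = True
                placed = True
                break
        if not placed:  # fall back: first free stretch (guarantees exact count)
            free = np.flatnonzero(~mask)
            take = free[:length]
            mask[take] = True
    return mask


def apply_noise(record: ECGRecord, spec: NoiseSpec) -> ECGRecord:
    """Return a noised copy; deterministic in (record, spec); amplitude 0 => identity."""
    fs = record.sampling_rate
    n = record.n_samples
    sig = record.signal
    if spec.noise_type == "power_line" and spec.frequency_hz >= fs / 2:
        raise ValueError(
            f"power line frequency {spec.frequency_hz} Hz is at or above the "
            f"Nyquist frequency {fs / 2} Hz"
        )
    # amplitude 0 is the identity for every type (for time_mask the
    # amplitude acts as an on/off gate for the zeroing mask)
    if spec.amplitude == 0.0:
        return record.copy()
    if spec.noise_type in ("partial_white", "time_mask") and spec.segment_fraction == 0.0:
        return record.copy()

    rng = np.random.default_rng(spec.seed)
    amp = _resolve_amplitude(spec, sig)
    t = np.arange(n) / fs
    out = sig.copy()

    if spec.noise_type == "power_line":
        phases = rng.uniform(0, 2 * np.pi, size=12)
        out += amp * np.sin(
            2 * np.pi * spec.frequency_hz * t[None, :] + phases[:, None]
        )
    elif spec.noise_type == "emg":
        lo, hi = 20.0, 120.0
        hi = min(hi, 0.95 * fs / 2)
        lo = min(lo, 0.5 * hi)
        b, a = sps.butter(4, [lo, hi], btype="bandpass", fs=fs)
        white = rng.standard_normal((12, n))
        band = sps.filtfilt(b, a, white, axis=1)
        band_rms = np.sqrt(np.mean(np.square(band)))
        out += amp * band / band_rms
    elif spec.noise_type == "baseline_wander":
        lo, hi = spec.wander_band_hz
        freqs = rng.uniform(lo, hi, size=12)
        phases = rng.uniform(0, 2 * np.pi, size=12)
        out += amp * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    elif spec.noise_type == "baseline_shift":
        for i in range(12):
            k = int(rng.integers(1, spec.max_switch_points + 1))
            switches = np.sort(rng.integers(1, n, size=k))
            offset = np.zeros(n)
            level = 0.0
            prev = 0
            for s in list(switches) + [n]:
                offset[prev:s] = level
                level += amp * (1.0 if rng.uniform() < 0.5 else -1.0)
                prev = s
            out[i] += offset
    elif spec.noise_type == "partial_white":
        total = round(spec.segment_fraction * n)
        for i in range(12):
            mask = _segments(rng, n, total, spec.n_segments)
            out[i, mask] += amp * rng.standard_normal(int(mask.sum()))
    elif spec.noise_type == "time_mask":
        total = round(spec.segment_fraction * n)
        for i in range(12):
            mask = _segments(rng, n, total, spec.n_segments)
            out[i, mask] = 0.0

    return ECGRecord(
        record_id=record.record_id,
        signal=out,
        sampling_rate=fs,
    )


def noise_robustness_suite(
    records: Sequence[ECGRecord],
    labels: Sequence[int],
    model: Surrogate,
    specs: Sequence[NoiseSpec] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    metrics_config: dict | None = None,
) -> pd.DataFrame:
    """Clean baseline row plus one row per noise spec, with deltas vs clean.

    Zero-amplitude specs reproduce the clean row bitwise (apply_noise is the
    identity there and the metrics are deterministic).
    """
    from .metrics import auroc_ci, auprc as auprc_fn, operating_point_metrics

    if specs is None:
        specs = default_specs()
    if len(specs) == 0:
        raise ValueError("spec list is empty")
    if len(records) == 0:
        raise ValueError("record set is empty")
    labels = np.asarray(labels, dtype=int)
    cfg = metrics_config or {}
    seed = cfg.get("seed", 0)
    method = cfg.get("auroc_ci_method", "delong")

    def one_row(name: str, recs: Sequence[ECGRecord]) -> dict:
        scores = np.array([o.score for o in predict_scores(model, recs, threshold)])
        value, (lo, hi) = auroc_ci(scores, labels, method=method, seed=seed)
        _, op = operating_point_metrics(scores, labels, threshold)
        return {
            "condition": name,
            "n": len(recs),
            "auroc": value, "auroc_lo": lo, "auroc_hi": hi,
            "auprc": auprc_fn(scores, labels),
            "sensitivity": op["sensitivity"][0],
            "specificity": op["specificity"][0],
            "ppv": op["ppv"][0],
            "npv": op["npv"][0],
        }

    rows = [one_row("clean", list(records))]
    clean = rows[0]
    for spec in specs:
        noisy = [
            apply_noise(r, replace(spec, seed=spec.seed + 7919 * i))
            for i, r in enumerate(records)
        ]
        rows.append(one_row(spec.noise_type, noisy))
    for row in rows:
        for col in ("auroc", "auprc", "sensitivity", "specificity"):
            val = row[col]
            row[f"delta_{col}"] = (
                val - clean[col] if val is not None and clean[col] is not None
                else None
            )
    return pd.DataFrame(rows)
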