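"""Limb-cable placement permutation simulator.

Model: the three active cables (RA, LA, LL) read body-site potentials; the
right-leg site is equipotential with the left-leg site, and the RL cable is
the driven ground (it never enters a lead).  Limb leads are cable-potential
differences and precordial leads are referenced to the Wilson terminal of
the active cables, so any of the 4! cable placements induces a *linear*
transformation on the channel basis (I, II, V1..V6).  Deduplicating the 24
exact rational matrices collapses them into 12 morphology classes, with the
identity class containing exactly {nonreversal, LL/RL swap}.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd

from .records import ECGRecord, lead_consistency_check
from .surrogate import DEFAULT_THRESHOLD, Surrogate, predict_scores

__all__ = [
    "CABLES",
    "ElectrodePotentials",
    "LeadPermutation",
    "ReversalClass",
    "reconstruct_potentials",
    "potentials_to_record",
    "enumerate_reversal_classes",
    "apply_reversal",
    "reversal_robustness_suite",
]

CABLES: tuple[str, ...] = ("RA", "LA", "LL", "RL")

# site potential expressed on the (I, II) basis under the WCT-zero
# convention; the RL site is equipotential with LL
_SITE_COEFFS: dict[str, tuple[Fraction, Fraction]] = {
    "RA": (Fraction(-1, 3), Fraction(-1, 3)),
    "LA": (Fraction(2, 3), Fraction(-1, 3)),
    "LL": (Fraction(-1, 3), Fraction(2, 3)),
    "RL": (Fraction(-1, 3), Fraction(2, 3)),
}


@dataclass
class ElectrodePotentials:
    """Limb-site and chest-electrode potentials, WCT-zero convention."""

    phi_RA: np.ndarray
    phi_LA: np.ndarray
    phi_LL: np.ndarray
    phi_RL: np.ndarray
    chest: np.ndarray  # (6, n): v1..v6
    sampling_rate: float
    record_id: str


@dataclass(frozen=True)
class LeadPermutation:
    """One cable -> site bijection with its morphology class."""

    mapping: tuple[tuple[str, str], ...]  # ((cable, site), ...) in CABLES order
    class_id: int
    canonical_name: str

    @property
    def mapping_dict(self) -> dict[str, str]:
        return dict(self.mapping)

    def describe(self) -> str:
        return _describe_permutation(self.mapping_dict)


@dataclass(frozen=True)
class ReversalClass:
    class_id: int
    canonical_name: str
    members: tuple[LeadPermutation, ...]
    matrix: np.ndarray          # 8x8 float on basis (I, II, V1..V6)
    invertible: bool
    v_leads_unchanged: bool


def _describe_permutation(mapping: dict[str, str]) -> str:
    """Human-readable cycle notation, e.g. 'RA<->LA' or 'RA->RL->LL->RA'."""
    cycles = []
    seen: set[str] = set()
    for cable in CABLES:
        if cable in seen or mapping[cable] == cable:
            continue
        cycle = [cable]
        nxt = mapping[cable]
        while nxt != cable:
            cycle.append(nxt)
            nxt = mapping[nxt]
        seen.update(cycle)
        cycles.append(cycle)
    if not cycles:
        return "nonreversal"
    parts = []
    for cyc in cycles:
        if len(cyc) == 2:
            parts.append(f"{cyc[0]}<->{cyc[1]}")
        else:
            parts.append("->".join(cyc + [cyc[0]]))
    return " + ".join(parts)


# human-readable aliases for classes the literature names; keyed by the
# frozenset of member descriptions
_CLASS_ALIASES = {
    frozenset({"nonreversal", "LL<->RL"}): "Nonreversal / LL-RL reversal",
    frozenset({"RA<->LL", "RA->RL->LL->RA"}):
        "RA/LL reversal and counter-clockwise reversal without LA",
}


def _class_matrix(mapping: dict[str, str]) -> tuple[tuple[Fraction, ...], ...]:
    """Exact 8x8 transform on (I, II, V1..V6) induced by a cable placement."""
    p = {cable: _SITE_COEFFS[mapping[cable]] for cable in ("RA", "LA", "LL")}
    zero = Fraction(0)
    rows: list[list[Fraction]] = []
    # I' = p_LA - p_RA ; II' = p_LL - p_RA  (on I, II columns; V columns zero)
    for hi, lo in (("LA", "RA"), ("LL", "RA")):
        ci = p[hi][0] - p[lo][0]
        cii = p[hi][1] - p[lo][1]
        rows.append([ci, cii] + [zero] * 6)
    # V_i' = V_i - (p_RA + p_LA + p_LL)/3  (WCT of the active cables)
    wct_i = sum(p[c][0] for c in ("RA", "LA", "LL")) / 3
    wct_ii = sum(p[c][1] for c in ("RA", "LA", "LL")) / 3
    for i in range(6):
        row = [-wct_i, -wct_ii] + [zero] * 6
        row[2 + i] += 1
        rows.append(row)
    return tuple(tuple(r) for r in rows)


def enumerate_reversal_classes() -> list[ReversalClass]:
    """All 24 limb-cable placements partitioned into their 12 unique classes."""
    groups: dict[tuple, list[dict[str, str]]] = {}
    for sites in permutations(CABLES):
        mapping = dict(zip(CABLES, sites))
        key = _class_matrix(mapping)
        groups.setdefault(key, []).append(mapping)

    # order classes by their lexicographically smallest member (identity first)
    def member_key(mapping: dict[str, str]) -> tuple:
        return tuple(CABLES.index(mapping[c]) for c in CABLES)

    ordered = sorted(groups.items(), key=lambda kv: min(member_key(m) for m in kv[1]))
    classes: list[ReversalClass] = []
    identity = np.eye(8)
    for class_id, (key, mappings) in enumerate(ordered, start=1):
        mappings = sorted(mappings, key=member_key)
        descriptions = [_describe_permutation(m) for m in mappings]
        name = _CLASS_ALIASES.get(
            frozenset(descriptions), " / ".join(descriptions)
        )
        members = tuple(
            LeadPermutation(
                mapping=tuple((c, m[c]) for c in CABLES),
                class_id=class_id,
                canonical_name=name,
            )
            for m in mappings
        )
        matrix = np.array([[float(x) for x in row] for row in key])
        classes.append(
            ReversalClass(
                class_id=class_id,
                canonical_name=name,
                members=members,
                matrix=matrix,
                invertible=np.linalg.matrix_rank(matrix) == 8,
                v_leads_unchanged=bool(
                    np.allclose(matrix[2:], identity[2:], atol=1e-12)
                ),
            )
        )
    return classes


# ---------------------------------------------------------------------------
# potential reconstruction and application
# ---------------------------------------------------------------------------

def reconstruct_potentials(
    record: ECGRecord, tolerance: float = 2e-3
) -> ElectrodePotentials:
    """Invert the standard lead definitions (requires a consistent record).

    The default tolerance (2e-3 mV) admits records round-tripped through
    quantized storage (WFDB int16 at 1000 ADU/mV quantizes each lead
    independently, perturbing the identities by up to one LSB) while still
    rejecting genuinely inconsistent signals.
    """
    ok, deviations = lead_consistency_check(record, tolerance)
    if not ok:
        worst = max(deviations, key=deviations.get)
        raise ValueError(
            f"record {record.record_id} violates limb-lead identities "
            f"(worst: {worst}, deviation {deviations[worst]:.3g} mV); run "
            "lead_consistency_check and repair before reversal simulation"
        )
    lead_i, lead_ii = record.lead("I"), record.lead("II")
    phi_ra = -(lead_i + lead_ii) / 3.0
    phi_la = (2.0 * lead_i - lead_ii) / 3.0
    phi_ll = (2.0 * lead_ii - lead_i) / 3.0
    return ElectrodePotentials(
        phi_RA=phi_ra,
        phi_LA=phi_la,
        phi_LL=phi_ll,
        phi_RL=phi_ll.copy(),
        chest=record.signal[6:].copy(),
        sampling_rate=record.sampling_rate,
        record_id=record.record_id,
    )


def potentials_to_record(
    pots: ElectrodePotentials,
    cable_potentials: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    record_id: str | None = None,
) -> ECGRecord:
    """Form the 12 leads from (possibly permuted) cable potentials."""
    p_ra, p_la, p_ll = (
        cable_potentials
        if cable_potentials is not None
        else (pots.phi_RA, pots.phi_LA, pots.phi_LL)
    )
    lead_i = p_la - p_ra
    lead_ii = p_ll - p_ra
    wct = (p_ra + p_la + p_ll) / 3.0
    n = lead_i.size
    signal = np.empty((12, n))
    signal[0] = lead_i
    signal[1] = lead_ii
    signal[2] = lead_ii - lead_i
    signal[3] = -(lead_i + lead_ii) / 2.0
    signal[4] = lead_i - lead_ii / 2.0
    signal[5] = lead_ii - lead_i / 2.0
    signal[6:] = pots.chest - wct[None, :]
    return ECGRecord(
        record_id=record_id or pots.record_id,
        signal=signal,
        sampling_rate=pots.sampling_rate,
    )


def apply_reversal(
    record: ECGRecord,
    perm: LeadPermutation,
    tolerance: float = 2e-3,
) -> ECGRecord:
    """Re-derive all 12 leads after placing cables at permuted sites.

    The identity class returns the input signal unchanged (bitwise), which
    realizes the nonreversal == LL/RL equivalence exactly.
    """
    mapping = perm.mapping_dict
    if sorted(mapping) != sorted(CABLES) or sorted(mapping.values()) != sorted(CABLES):
        raise ValueError(f"invalid cable->site bijection: {mapping}")
    matrix = np.array(
        [[float(x) for x in row] for row in _class_matrix(mapping)]
    )
    if np.array_equal(matrix, np.eye(8)):
        return record.copy(record_id=f"{record.record_id}")
    pots = reconstruct_potentials(record, tolerance)
    site_phi = {
        "RA": pots.phi_RA, "LA": pots.phi_LA,
        "LL": pots.phi_LL, "RL": pots.phi_RL,
    }
    cable_p = tuple(site_phi[mapping[c]] for c in ("RA", "LA", "LL"))
    return potentials_to_record(pots, cable_p, record_id=record.record_id)


# ---------------------------------------------------------------------------
# robustness suite
# ---------------------------------------------------------------------------

def reversal_robustness_suite(
    records: Sequence[ECGRecord],
    labels: Sequence[int],
    model: Surrogate,
    threshold: float = DEFAULT_THRESHOLD,
    metrics_config: dict | None = None,
) -> pd.DataFrame:
    """One metrics row per reversal class; nonreversal row == clean metrics.

    Columns: class_id, canonical_name, n, auroc, auroc_lo, auroc_hi, auprc,
    sensitivity, specificity, plus delta_auroc vs the nonreversal row.
    """
    from .metrics import auroc_ci, auprc as auprc_fn, operating_point_metrics

    if len(records) == 0:
        raise ValueError("record set is empty")
    labels = np.asarray(labels, dtype=int)
    cfg = metrics_config or {}
    seed = cfg.get("seed", 0)
    method = cfg.get("auroc_ci_method", "delong")

    rows = []
    clean_row: dict | None = None
    for cls in enumerate_reversal_classes():
        rep = cls.members[0]
        if np.array_equal(cls.matrix, np.eye(8)):
            transformed = list(records)
        else:
            transformed = [apply_reversal(r, rep) for r in records]
        scores = np.array(
            [o.score for o in predict_scores(model, transformed, threshold)]
        )
        value, (lo, hi) = auroc_ci(scores, labels, method=method, seed=seed)
        _, op = operating_point_metrics(scores, labels, threshold)
        row = {
            "class_id": cls.class_id,
            "canonical_name": cls.canonical_name,
            "n": len(records),
            "auroc": value,
            "auroc_lo": lo,
            "auroc_hi": hi,
            "auprc": auprc_fn(scores, labels),
            "sensitivity": op["sensitivity"][0],
            "specificity": op["specificity"][0],
        }
        if clean_row is None:
            clean_row = row
        row["delta_auroc"] = row["auroc"] - clean_row["auroc"]
        rows.append(row)
    return pd.DataFrame(rows)
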