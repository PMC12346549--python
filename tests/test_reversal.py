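"""lead_reversal: class enumeration, transforms, robustness suite."""

from itertools import permutations

import numpy as np
import pytest

from ecgaudit.records import lead_consistency_check
from ecgaudit.reversal import (
    CABLES,
    LeadPermutation,
    apply_reversal,
    enumerate_reversal_classes,
    potentials_to_record,
    reconstruct_potentials,
    reversal_robustness_suite,
)
from ecgaudit.synthetic import MorphologyParams, simulate_record


@pytest.fixture(scope="module")
def classes():
    return enumerate_reversal_classes()


@pytest.fixture(scope="module")
def record():
    return simulate_record(MorphologyParams(), fs=125, duration_s=5, seed=12)


def _perm(mapping: dict) -> LeadPermutation:
    return LeadPermutation(tuple((c, mapping[c]) for c in CABLES), 0, "test")


def _member(classes, description):
    for cls in classes:
        for m in cls.members:
            if m.describe() == description:
                return m
    raise AssertionError(description)


class TestEnumeration:
    def test_exactly_12_classes(self, classes):
        assert len(classes) == 12

    def test_24_permutations_partitioned(self, classes):
        members = [m for cls in classes for m in cls.members]
        assert len(members) == 24
        assert len({m.mapping for m in members}) == 24

    def test_identity_class_is_nonreversal_and_ll_rl(self, classes):
        idclass = classes[0]
        assert {m.describe() for m in idclass.members} == {"nonreversal", "LL<->RL"}
        assert np.array_equal(idclass.matrix, np.eye(8))

    def test_matrices_pairwise_distinct(self, classes):
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                assert np.abs(a.matrix - b.matrix).max() > 1e-9

    def test_brute_force_count_on_random_potentials(self, classes):
        # oracle: evaluate all 24 placements on 5 seeded random potential
        # sets and deduplicate the outputs numerically
        rng = np.random.default_rng(0)
        outputs = {}
        for sites in permutations(CABLES):
            mapping = dict(zip(CABLES, sites))
            key = []
            for trial in range(5):
                trial_rng = np.random.default_rng(100 + trial)
                phi = {
                    "RA": trial_rng.normal(size=16),
                    "LA": trial_rng.normal(size=16),
                    "LL": trial_rng.normal(size=16),
                }
                phi["RL"] = phi["LL"]
                chest = trial_rng.normal(size=(6, 16))
                p = {c: phi[mapping[c]] for c in ("RA", "LA", "LL")}
                lead_i = p["LA"] - p["RA"]
                lead_ii = p["LL"] - p["RA"]
                wct = (p["RA"] + p["LA"] + p["LL"]) / 3.0
                out = np.concatenate([lead_i, lead_ii, (chest - wct).ravel()])
                key.append(np.round(out, 9).tobytes())
            outputs[sites] = tuple(key)
        assert len(set(outputs.values())) == 12

    def test_exactly_6_classes_leave_v_leads_unchanged(self, classes):
        assert sum(cls.v_leads_unchanged for cls in classes) == 6

    def test_invertibility_matches_matrix_rank(self, classes):
        for cls in classes:
            assert cls.invertible == (np.linalg.matrix_rank(cls.matrix) == 8)
        assert sum(cls.invertible for cls in classes) == 6

    def test_named_alias_for_ra_ll_class(self, classes):
        names = [cls.canonical_name for cls in classes]
        assert "RA/LL reversal and counter-clockwise reversal without LA" in names


class TestPotentials:
    def test_round_trip(self, record):
        back = potentials_to_record(reconstruct_potentials(record))
        assert np.abs(back.signal - record.signal).max() < 1e-9

    def test_zero_limb_leads_zero_potentials(self):
        rec = simulate_record(MorphologyParams(), fs=50, duration_s=2, seed=0)
        sig = np.zeros_like(rec.signal)
        sig[6:] = rec.signal[6:]
        zeroed = rec.copy(signal=sig)
        pots = reconstruct_potentials(zeroed)
        assert np.abs(pots.phi_RA).max() == 0
        assert np.abs(pots.phi_LA).max() == 0
        assert np.abs(pots.phi_LL).max() == 0

    def test_potential_sum_zero_convention(self, record):
        pots = reconstruct_potentials(record)
        total = pots.phi_RA + pots.phi_LA + pots.phi_LL
        assert np.abs(total).max() < 1e-12

    def test_inconsistent_record_rejected(self, record):
        sig = record.signal.copy()
        sig[2] += 0.5
        with pytest.raises(ValueError, match="consistency"):
            reconstruct_potentials(record.copy(signal=sig))


class TestApplyReversal:
    def test_ra_la_swap_identities(self, record, classes):
        out = apply_reversal(record, _member(classes, "RA<->LA"))
        atol = 1e-9
        assert np.allclose(out.lead("I"), -record.lead("I"), atol=atol)
        assert np.allclose(out.lead("II"), record.lead("III"), atol=atol)
        assert np.allclose(out.lead("III"), record.lead("II"), atol=atol)
        assert np.allclose(out.lead("aVR"), record.lead("aVL"), atol=atol)
        assert np.allclose(out.lead("aVL"), record.lead("aVR"), atol=atol)
        assert np.allclose(out.signal[6:], record.signal[6:], atol=atol)

    def test_ra_rl_swap_zeroes_lead_ii(self, record, classes):
        out = apply_reversal(record, _member(classes, "RA<->RL"))
        assert np.abs(out.lead("II")).max() < 1e-12

    def test_ll_rl_swap_is_bitwise_identity(self, record, classes):
        out = apply_reversal(record, _member(classes, "LL<->RL"))
        assert np.array_equal(out.signal, record.signal)

    def test_output_is_consistent(self, record, classes):
        for cls in classes:
            out = apply_reversal(record, cls.members[0])
            ok, _ = lead_consistency_check(out, tolerance=1e-9)
            assert ok, cls.canonical_name

    def test_invertible_two_cycles_are_involutions(self, record, classes):
        # 2-cycles whose class matrix is invertible restore the record when
        # applied twice; the leg-grounding collapse makes the RA<->RL and
        # LA<->RL transforms singular, so those provably cannot
        checked = 0
        for cls in classes:
            for member in cls.members:
                mapping = member.mapping_dict
                if not all(mapping[mapping[c]] == c for c in CABLES):
                    continue
                twice = apply_reversal(apply_reversal(record, member), member)
                err = np.abs(twice.signal - record.signal).max()
                if cls.invertible:
                    assert err < 1e-9, member.describe()
                    checked += 1
                else:
                    assert err > 1e-3, member.describe()
        assert checked >= 4

    def test_composition_consistency(self, record):
        # sequential application equals the composed placement whenever the
        # first placement keeps the leg cables on the leg sites (so the
        # intermediate record's RL==LL assumption stays faithful)
        rng = np.random.default_rng(3)
        perms = [dict(zip(CABLES, p)) for p in permutations(CABLES)]
        leg_preserving = [p for p in perms
                          if {p["LL"], p["RL"]} == {"LL", "RL"}]
        checked = 0
        for tau in leg_preserving:
            for _ in range(3):
                sigma = perms[rng.integers(len(perms))]
                composed = {c: tau[sigma[c]] for c in CABLES}
                via_two = apply_reversal(apply_reversal(record, _perm(tau)),
                                         _perm(sigma))
                via_one = apply_reversal(record, _perm(composed))
                assert np.abs(via_two.signal - via_one.signal).max() < 1e-9
                checked += 1
        assert checked == 3 * len(leg_preserving)

    def test_invalid_permutation_rejected(self, record):
        bad = LeadPermutation(
            (("RA", "RA"), ("LA", "RA"), ("LL", "LL"), ("RL", "RL")), 0, "bad"
        )
        with pytest.raises(ValueError, match="bijection"):
            apply_reversal(record, bad)


class TestSuite:
    def test_table_shape_and_nonreversal_row(self, trained_small, eval_records):
        model, _ = trained_small
        records, labels = eval_records
        table = reversal_robustness_suite(records[:40], labels[:40], model)
        assert len(table) == 12
        assert list(table["class_id"]) == list(range(1, 13))
        # nonreversal row must equal the clean evaluation bitwise
        from ecgaudit.metrics import auroc_ci, operating_point_metrics
        from ecgaudit.surrogate import predict_scores

        scores = np.array(
            [o.score for o in predict_scores(model, records[:40])]
        )
        clean_auroc, (lo, hi) = auroc_ci(scores, labels[:40], seed=0)
        row = table.iloc[0]
        assert row["auroc"] == clean_auroc
        assert row["auroc_lo"] == lo and row["auroc_hi"] == hi
        assert row["delta_auroc"] == 0.0
        assert (table["auroc"].between(0, 1)).all()

    def test_empty_records_rejected(self, trained_small):
        model, _ = trained_small
        with pytest.raises(ValueError, match="empty"):
            reversal_robustness_suite([], [], model)
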