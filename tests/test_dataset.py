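from datetime import date, timedelta

import numpy as np
import pytest

from prognote.dataset import (
    NEG,
    PAD,
    POS,
    UNDEFINED,
    LabelPolicy,
    build_sequences,
    label_visit,
    load_dataset,
    save_dataset,
    split_cohort,
)
from prognote.io import OutcomeRecord, VisitNote


def _outcome(pid="P0", death=None, followup=date(2016, 12, 31)):
    return OutcomeRecord(pid, death, followup)


def _notes(pid, dates):
    return [
        VisitNote(pid, f"{pid}-n{i:04d}", d, "oncology", "text")
        for i, d in enumerate(dates)
    ]


class TestLabelVisit:
    V = date(2015, 6, 1)

    def test_death_within_horizon_is_neg(self):
        o = _outcome(death=self.V + timedelta(days=50), followup=self.V + timedelta(days=50))
        assert label_visit(self.V, o, LabelPolicy()) == "NEG"

    def test_death_beyond_horizon_is_pos(self):
        o = _outcome(death=self.V + timedelta(days=100), followup=self.V + timedelta(days=100))
        assert label_visit(self.V, o, LabelPolicy()) == "POS"

    def test_short_followup_is_undefined(self):
        o = _outcome(followup=self.V + timedelta(days=30))
        assert label_visit(self.V, o, LabelPolicy()) == "UNDEFINED"

    def test_long_followup_is_pos(self):
        o = _outcome(followup=self.V + timedelta(days=200))
        assert label_visit(self.V, o, LabelPolicy()) == "POS"

    def test_visit_after_followup_raises(self):
        o = _outcome(followup=self.V - timedelta(days=1))
        with pytest.raises(ValueError):
            label_visit(self.V, o, LabelPolicy())

    def test_horizon_must_be_positive(self):
        with pytest.raises(ValueError):
            LabelPolicy(horizon_days=0)


def _vectors_for(notes, dim=3, seed=0):
    rng = np.random.default_rng(seed)
    return {n.note_id: rng.normal(size=dim) + 5.0 for n in notes}


class TestBuildSequences:
    def test_padding_short_sequence(self):
        dates = [date(2015, 1, 1) + timedelta(days=30 * i) for i in range(3)]
        notes = _notes("P0", dates)
        seqs = build_sequences(_vectors_for(notes), notes, [_outcome()], max_len=5)
        s = seqs[0]
        assert s.n_real == 3
        assert list(s.labels[3:]) == [PAD, PAD]
        assert not s.x[3:].any()
        assert s.x[:3].any()

    def test_truncation_keeps_most_recent(self):
        dates = [date(2010, 1, 1) + timedelta(days=i) for i in range(1200)]
        notes = _notes("P0", dates)
        vecs = {n.note_id: np.ones(2) for n in notes}
        o = _outcome(followup=dates[-1] + timedelta(days=200))
        seqs = build_sequences(vecs, notes, [o], max_len=1000)
        s = seqs[0]
        assert s.note_ids[0] == "P0-n0200"  # original index 200, 0-based
        assert s.n_real == 1000

    def test_exact_max_len_boundary(self):
        dates = [date(2015, 1, 1) + timedelta(days=i) for i in range(5)]
        notes = _notes("P0", dates)
        seqs = build_sequences(_vectors_for(notes), notes, [_outcome()], max_len=5)
        assert seqs[0].n_real == 5
        assert (seqs[0].labels != PAD).all()

    def test_single_visit_patient_dropped_with_warning(self, caplog):
        notes = _notes("P0", [date(2015, 1, 1)])
        with caplog.at_level("WARNING"):
            seqs = build_sequences(_vectors_for(notes), notes, [_outcome()], max_len=5)
        assert seqs == []
        assert any("P0" in r.message for r in caplog.records)

    def test_zero_vector_for_real_note_rejected(self):
        dates = [date(2015, 1, 1), date(2015, 2, 1)]
        notes = _notes("P0", dates)
        vecs = {n.note_id: np.zeros(3) for n in notes}
        with pytest.raises(ValueError, match="zero"):
            build_sequences(vecs, notes, [_outcome()], max_len=5)

    def test_undefined_timesteps_kept_and_flagged(self):
        dates = [date(2016, 10, 1), date(2016, 12, 1)]
        notes = _notes("P0", dates)
        seqs = build_sequences(_vectors_for(notes), notes,
                               [_outcome(followup=date(2016, 12, 31))], max_len=4)
        s = seqs[0]
        assert s.labels[0] == UNDEFINED or s.labels[1] == UNDEFINED
        assert s.mask[: s.n_real].all()          # still real timesteps
        assert s.eval_mask[s.labels == UNDEFINED].sum() == 0

    def test_unpad_repad_is_identity(self):
        dates = [date(2015, 1, 1) + timedelta(days=40 * i) for i in range(3)]
        notes = _notes("P0", dates)
        vecs = _vectors_for(notes)
        o = _outcome()
        s1 = build_sequences(vecs, notes, [o], max_len=6)[0]
        s2 = build_sequences(vecs, notes, [o], max_len=6)[0]
        np.testing.assert_array_equal(s1.x, s2.x)
        np.testing.assert_array_equal(s1.labels, s2.labels)

    def test_same_day_visits_ordered_by_note_id(self):
        d = date(2015, 3, 1)
        notes = _notes("P0", [d, d, d + timedelta(days=5)])
        seqs = build_sequences(_vectors_for(notes), notes, [_outcome()], max_len=4)
        assert seqs[0].note_ids == ["P0-n0000", "P0-n0001", "P0-n0002"]


class TestSplitCohort:
    def _sequences(self, n):
        dates = [date(2015, 1, 1), date(2015, 2, 1)]
        seqs = []
        for i in range(n):
            notes = _notes(f"P{i:03d}", dates)
            seqs += build_sequences(_vectors_for(notes, seed=i), notes,
                                    [_outcome(pid=f"P{i:03d}")], max_len=2)
        return seqs

    def test_sizes_up_to_rounding(self):
        parts = split_cohort(self._sequences(100), (0.8, 0.1, 0.1), seed=0)
        assert tuple(len(p) for p in parts) == (80, 10, 10)

    def test_deterministic(self):
        seqs = self._sequences(30)
        p1 = split_cohort(seqs, (0.5, 0.25, 0.25), seed=4)
        p2 = split_cohort(seqs, (0.5, 0.25, 0.25), seed=4)
        for a, b in zip(p1, p2):
            assert [s.patient_id for s in a] == [s.patient_id for s in b]

    def test_disjoint_and_exhaustive(self):
        seqs = self._sequences(23)
        parts = split_cohort(seqs, (0.6, 0.2, 0.2), seed=1)
        ids = [s.patient_id for p in parts for s in p]
        assert sorted(ids) == sorted(s.patient_id for s in seqs)
        assert len(set(ids)) == len(ids)

    def test_bad_fraction_raises(self):
        with pytest.raises(ValueError):
            split_cohort(self._sequences(4), (0.0, 0.5, 0.5), seed=0)
        with pytest.raises(ValueError):
            split_cohort(self._sequences(4), (0.5, 0.1, 0.1), seed=0)


def test_save_load_roundtrip(tmp_path):
    dates = [date(2015, 1, 1) + timedelta(days=30 * i) for i in range(3)]
    notes = _notes("P0", dates) + _notes("P1", dates)
    outcomes = [_outcome("P0"), _outcome("P1", death=date(2015, 4, 1),
                                         followup=date(2015, 4, 1))]
    seqs = build_sequences(_vectors_for(notes), notes, outcomes, max_len=4)
    save_dataset({"train": seqs[:1], "test": seqs[1:]}, tmp_path)
    loaded = load_dataset(tmp_path)
    assert set(loaded) == {"train", "test"}
    for name in loaded:
        orig = {"train": seqs[:1], "test": seqs[1:]}[name]
        for a, b in zip(orig, loaded[name]):
            assert a.patient_id == b.patient_id
            assert a.note_ids == b.note_ids
            assert a.visit_dates == b.visit_dates
            np.testing.assert_array_equal(a.x, b.x)
            np.testing.assert_array_equal(a.labels, b.labels)
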