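"""Per-patient labelled sequences: labelling, padding, truncation, splits.

Every visit receives one of three classes relative to a 91-day (3-month)
horizon:

* POS — the patient survived more than the horizon past the visit date
  (either death came later, or follow-up extends beyond the horizon);
* NEG — death within the horizon;
* UNDEFINED — alive at last follow-up but followed for less than the
  horizon: the outcome is unknowable (censored within horizon). These
  timesteps stay in the input sequence (the recurrent state needs the
  visit) but carry zero loss weight and are excluded from evaluation.

Sequences are sorted by visit date (ties broken by note id), truncated
to the ``max_len`` *most recent* visits when longer, and right-padded
with zero vectors and PAD labels when shorter. The all-zeros vector is
reserved for padding — the vectoriser never emits it for a real note.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np

from .io import OutcomeRecord, VisitNote

__all__ = [
    "LabelPolicy",
    "PatientSequence",
    "LABELS",
    "POS",
    "NEG",
    "PAD",
    "UNDEFINED",
    "label_visit",
    "build_sequences",
    "split_cohort",
    "save_dataset",
    "load_dataset",
]

logger = logging.getLogger(__name__)

POS, NEG, PAD, UNDEFINED = 0, 1, 2, 3
LABELS = {POS: "POS", NEG: "NEG", PAD: "PAD", UNDEFINED: "UNDEFINED"}


@dataclass
class LabelPolicy:
    """3-month survival labelling: POS = survival past ``horizon_days``
    counted from the visit date."""

    horizon_days: int = 91

    def __post_init__(self) -> None:
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be > 0")


@dataclass
class PatientSequence:
    patient_id: str
    x: np.ndarray          # (max_len, D)
    labels: np.ndarray     # (max_len,) int8, values in {POS, NEG, PAD, UNDEFINED}
    visit_dates: list[date]
    note_ids: list[str]

    @property
    def n_real(self) -> int:
        return len(self.note_ids)

    @property
    def mask(self) -> np.ndarray:
        """1 for real timesteps (POS/NEG/UNDEFINED), 0 for padding."""
        return (self.labels != PAD).astype(np.float64)

    @property
    def eval_mask(self) -> np.ndarray:
        """1 only where the 3-month outcome is defined (POS/NEG)."""
        return ((self.labels == POS) | (self.labels == NEG)).astype(np.float64)


def label_visit(visit_date: date, outcome: OutcomeRecord, policy: LabelPolicy) -> str:
    """Classify one visit as "POS", "NEG" or "UNDEFINED"."""
    if visit_date > outcome.last_followup_date:
        raise ValueError(
            f"visit {visit_date} after last follow-up {outcome.last_followup_date} "
            f"for patient {outcome.patient_id}"
        )
    if outcome.death_date is not None:
        gap = (outcome.death_date - visit_date).days
        return "NEG" if gap <= policy.horizon_days else "POS"
    if (outcome.last_followup_date - visit_date).days > policy.horizon_days:
        return "POS"
    return "UNDEFINED"


_LABEL_CODE = {"POS": POS, "NEG": NEG, "UNDEFINED": UNDEFINED}


def build_sequences(
    note_vectors: dict[str, np.ndarray],
    notes: list[VisitNote],
    outcomes: list[OutcomeRecord],
    policy: LabelPolicy | None = None,
    max_len: int = 1000,
) -> list[PatientSequence]:
    """Assemble one fixed-length sequence per patient.

    ``note_vectors`` maps note_id -> vector (a NoteVector's ``.vector``
    or a bare array). Patients with fewer than 2 real visits are dropped
    with a warning. Raises if a real note has the all-zeros vector,
    which would make padding ambiguous.
    """
    policy = policy or LabelPolicy()
    vec = {
        nid: (v.vector if hasattr(v, "vector") else np.asarray(v, dtype=np.float64))
        for nid, v in note_vectors.items()
    }
    missing = [n.note_id for n in notes if n.note_id not in vec]
    if missing:
        raise KeyError(f"notes without vectors: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    dim = len(next(iter(vec.values())))
    outcome_by_pid = {o.patient_id: o for o in outcomes}

    grouped: dict[str, list[VisitNote]] = {}
    for n in notes:
        grouped.setdefault(n.patient_id, []).append(n)

    sequences: list[PatientSequence] = []
    for pid, visit_notes in grouped.items():
        if len(visit_notes) < 2:
            logger.warning("patient %s has < 2 visits; dropped", pid)
            continue
        visit_notes.sort(key=lambda n: (n.visit_date, n.note_id))
        if len(visit_notes) > max_len:
            visit_notes = visit_notes[-max_len:]  # keep the most recent
        outcome = outcome_by_pid[pid]
        x = np.zeros((max_len, dim), dtype=np.float64)
        labels = np.full(max_len, PAD, dtype=np.int8)
        for t, n in enumerate(visit_notes):
            v = vec[n.note_id]
            if not np.any(v):
                raise ValueError(
                    f"note {n.note_id} has an all-zeros vector; zero is reserved "
                    "for padding"
                )
            x[t] = v
            labels[t] = _LABEL_CODE[label_visit(n.visit_date, outcome, policy)]
        sequences.append(
            PatientSequence(
                patient_id=pid,
                x=x,
                labels=labels,
                visit_dates=[n.visit_date for n in visit_notes],
                note_ids=[n.note_id for n in visit_notes],
            )
        )
    return sequences


def split_cohort(
    sequences: list[PatientSequence],
    fractions: tuple[float, ...] = (0.8, 0.05, 0.15),
    seed: int = 0,
) -> tuple[list[PatientSequence], ...]:
    """Patient-level random split — a patient's visits never straddle two
    splits. Deterministic by seed; disjoint and exhaustive."""
    for f in fractions:
        if not 0.0 < f < 1.0:
            raise ValueError(f"split fraction {f} outside (0, 1)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(sequences)))
    bounds = np.floor(np.cumsum(fractions) * len(sequences) + 0.5).astype(int)
    bounds[-1] = len(sequences)
    parts: list[list[PatientSequence]] = []
    start = 0
    for b in bounds:
        parts.append([sequences[i] for i in order[start:b]])
        start = b
    return tuple(parts)


def stack(sequences: list[PatientSequence]) -> tuple[np.ndarray, np.ndarray]:
    """(inputs [n, T, D], labels [n, T]) arrays for training."""
    x = np.stack([s.x for s in sequences])
    y = np.stack([s.labels for s in sequences])
    return x, y


def save_dataset(splits: dict[str, list[PatientSequence]], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list] = {}
    for name, seqs in splits.items():
        if seqs:
            x, y = stack(seqs)
        else:
            x, y = np.empty((0, 0, 0)), np.empty((0, 0), dtype=np.int8)
        np.savez(out / f"{name}.npz", inputs=x, labels=y)
        manifest[name] = [
            {
                "patient_id": s.patient_id,
                "visit_dates": [d.isoformat() for d in s.visit_dates],
                "note_ids": s.note_ids,
            }
            for s in seqs
        ]
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh)


def load_dataset(in_dir) -> dict[str, list[PatientSequence]]:
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    splits: dict[str, list[PatientSequence]] = {}
    for name, records in manifest.items():
        arrays = np.load(in_dir / f"{name}.npz")
        x, y = arrays["inputs"], arrays["labels"]
        seqs = []
        for i, rec in enumerate(records):
            seqs.append(
                PatientSequence(
                    patient_id=rec["patient_id"],
                    x=x[i],
                    labels=y[i].astype(np.int8),
                    visit_dates=[date.fromisoformat(d) for d in rec["visit_dates"]],
                    note_ids=rec["note_ids"],
                )
            )
        splits[name] = seqs
    return splits
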