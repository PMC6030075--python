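"""Record types and plain-text serialisation.

Notes travel as JSON-lines (one record per note), outcomes and
predictions as tab-separated files — all human-inspectable formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date

import pandas as pd

__all__ = [
    "VisitNote",
    "OutcomeRecord",
    "read_notes",
    "write_notes",
    "read_outcomes",
    "write_outcomes",
    "read_predictions",
    "write_predictions",
]


@dataclass
class VisitNote:
    """One free-text clinical note tied to a patient and a visit date."""

    patient_id: str
    note_id: str
    visit_date: date
    note_type: str
    text: str


@dataclass
class OutcomeRecord:
    """Survival ground truth: a death date (if the patient died) and the
    last follow-up date. Visit labels are always derived from these dates,
    never stored."""

    patient_id: str
    death_date: date | None
    last_followup_date: date


def write_notes(notes: list[VisitNote], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "patient_id": n.patient_id,
                        "note_id": n.note_id,
                        "visit_date": n.visit_date.isoformat(),
                        "note_type": n.note_type,
                        "text": n.text,
                    }
                )
                + "\n"
            )


def read_notes(path) -> list[VisitNote]:
    notes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            notes.append(
                VisitNote(
                    patient_id=rec["patient_id"],
                    note_id=rec["note_id"],
                    visit_date=date.fromisoformat(rec["visit_date"]),
                    note_type=rec["note_type"],
                    text=rec["text"],
                )
            )
    return notes


def write_outcomes(outcomes: list[OutcomeRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for o in outcomes:
            death = o.death_date.isoformat() if o.death_date else ""
            fh.write(f"{o.patient_id}\t{death}\t{o.last_followup_date.isoformat()}\n")


def read_outcomes(path) -> list[OutcomeRecord]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, death, followup = line.split("\t")
            out.append(
                OutcomeRecord(
                    patient_id=pid,
                    death_date=date.fromisoformat(death) if death else None,
                    last_followup_date=date.fromisoformat(followup),
                )
            )
    return out


def write_token_notes(records: list[dict], path) -> None:
    """Condensed/mapped notes as JSON-lines: patient_id, note_id,
    visit_date, note_type, tokens, and (if mapped) mapped_positions."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_token_notes(path) -> list[dict]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(json.loads(line))
    return out


_PRED_COLUMNS = ["patient_id", "visit_index", "visit_date", "note_id",
                 "p_survival", "true_label"]


def write_predictions(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, columns=_PRED_COLUMNS,
                 float_format="%.10g")


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"patient_id": str, "note_id": str})
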