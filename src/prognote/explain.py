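"""Per-patient explanation reports.

For each patient the report shows the predicted survival-probability
curve against the ground-truth labels (Survival-positive drawn at 1,
Survival-negative at 0), and lets each visit expand into its *core
findings*: every dictionary hit in that visit's note, shown as the
matched surface form bracketed inside a ±5-word window of the original
(pre-condensed) text, together with the visit type.

The output is a static, self-contained HTML document per patient (the
curve is an inline SVG, expand/collapse uses <details> — no server, no
scripts), plus a machine-readable JSON summary. Rendering is a pure
function of the summary, so reports are byte-stable.
"""

from __future__ import annotations

import html
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from ._porter import stem
from .condenser import STOPLIST
from .io import VisitNote
from .model import PredictionSequence
from .semdict import MappedNote, TermDictionary
from .dataset import NEG, PAD, POS, UNDEFINED

__all__ = ["Finding", "PatientSummary", "extract_findings", "build_summary",
           "render", "render_index", "write_reports"]

_RAW_TOKEN_RE = re.compile(r"[A-Za-z0-9_]+(?:-[A-Za-z0-9_]+)*")
SNIPPET_RADIUS = 5  # words kept on each side of a matched surface form


@dataclass(frozen=True)
class Finding:
    controlled_term: str
    surface: str
    snippet: str
    note_type: str


@dataclass
class CurvePoint:
    visit_index: int
    visit_date: str
    note_id: str
    p_surv: float
    true_label: str            # POS | NEG | UNDEFINED
    note_type: str = ""
    findings: list[Finding] = field(default_factory=list)


@dataclass
class PatientSummary:
    patient_id: str
    curve: list[CurvePoint]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "curve": [
                {
                    "visit_index": c.visit_index,
                    "visit_date": c.visit_date,
                    "note_id": c.note_id,
                    "p_surv": c.p_surv,
                    "true_label": c.true_label,
                    "note_type": c.note_type,
                    "findings": [
                        {
                            "controlled_term": f.controlled_term,
                            "surface": f.surface,
                            "snippet": f.snippet,
                        }
                        for f in c.findings
                    ],
                }
                for c in self.curve
            ],
        }


def _surface_stems(surface: str) -> tuple[str, ...]:
    return tuple(stem(t) for t in _RAW_TOKEN_RE.findall(surface.lower())
                 if t not in STOPLIST)


def extract_findings(
    note: VisitNote, mapped: MappedNote, dictionary: TermDictionary
) -> list[Finding]:
    """Locate each mapped surface form back in the raw note text and cut
    a ±5-word snippet around it, the match bracketed. Matching is
    stem-aware and tolerates interleaved stopwords inside multi-word
    surfaces. Findings are deduplicated per (term, snippet)."""
    raw_tokens = _RAW_TOKEN_RE.findall(note.text)
    raw_stems = [stem(t.lower()) for t in raw_tokens]
    raw_is_stop = [t.lower() in STOPLIST for t in raw_tokens]

    wanted: dict[tuple[str, ...], str] = {}
    for _, surface in mapped.mapped_positions:
        stems = _surface_stems(surface)
        if stems:
            cterm = _cterm_for(mapped, surface)
            wanted.setdefault(stems, cterm)

    findings: list[Finding] = []
    seen: set[tuple[str, str]] = set()
    for stems, cterm in wanted.items():
        for i in range(len(raw_tokens)):
            if raw_is_stop[i] or raw_stems[i] != stems[0]:
                continue
            j, k = i, 1
            while k < len(stems):
                j += 1
                if j >= len(raw_tokens):
                    break
                if raw_is_stop[j]:
                    continue
                if raw_stems[j] != stems[k]:
                    break
                k += 1
            if k != len(stems):
                continue
            lo = max(0, i - SNIPPET_RADIUS)
            hi = min(len(raw_tokens), j + 1 + SNIPPET_RADIUS)
            matched = " ".join(raw_tokens[i : j + 1])
            snippet = " ".join(
                raw_tokens[lo:i] + [f"[{matched}]"] + raw_tokens[j + 1 : hi]
            )
            key = (cterm, snippet)
            if key not in seen:
                seen.add(key)
                findings.append(
                    Finding(controlled_term=cterm, surface=matched,
                            snippet=snippet, note_type=note.note_type)
                )
    return findings


def _cterm_for(mapped: MappedNote, surface: str) -> str:
    for pos, surf in mapped.mapped_positions:
        if surf == surface:
            return mapped.tokens[pos]
    return "?"


_LABEL_NAME = {POS: "POS", NEG: "NEG", UNDEFINED: "UNDEFINED", PAD: "PAD"}


def build_summary(
    prediction: PredictionSequence,
    notes: list[VisitNote],
    mapped_notes: dict[str, MappedNote],
    dictionary: TermDictionary,
) -> PatientSummary:
    """Join one patient's predictions with their notes: one curve point
    per non-padded timestep, findings attached per point."""
    note_by_id = {n.note_id: n for n in notes}
    missing = [nid for nid in prediction.note_ids
               if nid not in note_by_id or nid not in mapped_notes]
    if missing:
        raise KeyError(f"unmatched note ids: {missing}")
    curve = []
    for t, nid in enumerate(prediction.note_ids):
        note = note_by_id[nid]
        curve.append(
            CurvePoint(
                visit_index=t,
                visit_date=note.visit_date.isoformat(),
                note_id=nid,
                p_surv=float(prediction.probs[t, POS]),
                true_label=_LABEL_NAME[int(prediction.labels[t])],
                note_type=note.note_type,
                findings=extract_findings(note, mapped_notes[nid], dictionary),
            )
        )
    return PatientSummary(patient_id=prediction.patient_id, curve=curve)


def _svg_curve(summary: PatientSummary, width: int = 640, height: int = 220) -> str:
    n = len(summary.curve)
    if n == 0:
        return "<svg/>"
    pad_l, pad_b, pad_t = 30, 20, 10
    plot_w, plot_h = width - pad_l - 10, height - pad_b - pad_t

    def xy(i: int, p: float) -> str:
        x = pad_l + (plot_w * i / max(n - 1, 1))
        y = pad_t + plot_h * (1.0 - p)
        return f"{x:.1f},{y:.1f}"

    pred = " ".join(xy(i, c.p_surv) for i, c in enumerate(summary.curve))
    truth_pts = [
        xy(i, 1.0 if c.true_label == "POS" else 0.0)
        for i, c in enumerate(summary.curve)
        if c.true_label in ("POS", "NEG")
    ]
    truth = " ".join(truth_pts)
    return (
        f'<svg width="{width}" height="{height}" '
        'xmlns="http://www.w3.org/2000/svg">'
        f'<rect x="{pad_l}" y="{pad_t}" width="{plot_w}" height="{plot_h}" '
        'fill="none" stroke="#ccc"/>'
        f'<text x="2" y="{pad_t + 8}" font-size="10">1</text>'
        f'<text x="2" y="{pad_t + plot_h}" font-size="10">0</text>'
        + (f'<polyline points="{truth}" fill="none" stroke="blue" stroke-width="1.5"/>'
           if truth else "")
        + f'<polyline points="{pred}" fill="none" stroke="green" stroke-width="1.5"/>'
        "</svg>"
    )


def render(summary: PatientSummary) -> str:
    """Self-contained HTML for one patient. Blue: ground truth (POS=1,
    NEG=0); green: predicted survival probability."""
    parts = [
        "<!DOCTYPE html>",
        '<html><head><meta charset="utf-8">',
        f"<title>Survival summary {html.escape(summary.patient_id)}</title>",
        "<style>body{font-family:sans-serif;max-width:720px;margin:auto}"
        "details{margin:2px 0;border-left:3px solid #ddd;padding-left:6px}"
        ".term{color:#a00;font-weight:bold}</style>",
        "</head><body>",
        f"<h1>Patient {html.escape(summary.patient_id)}</h1>",
        "<p>Green: predicted probability of surviving &gt;3 months. "
        "Blue: ground truth (Survival-positive = 1, Survival-negative = 0).</p>",
        _svg_curve(summary),
    ]
    for c in summary.curve:
        label = html.escape(c.true_label)
        head = (
            f"visit {c.visit_index} &middot; {html.escape(c.visit_date)} &middot; "
            f"{html.escape(c.note_type)} &middot; p_surv={c.p_surv:.3f} &middot; "
            f"truth={label}"
        )
        parts.append(f"<details><summary>{head}</summary>")
        if c.findings:
            parts.append("<ul>")
            for f in c.findings:
                parts.append(
                    f'<li><span class="term">{html.escape(f.controlled_term)}</span> '
                    f"&mdash; &hellip;{html.escape(f.snippet)}&hellip;</li>"
                )
            parts.append("</ul>")
        else:
            parts.append("<p>No dictionary findings for this visit.</p>")
        parts.append("</details>")
    parts.append("</body></html>")
    return "\n".join(parts)


def render_index(patient_ids: list[str]) -> str:
    items = "\n".join(
        f'<li><a href="{html.escape(p)}.html">{html.escape(p)}</a></li>'
        for p in patient_ids
    )
    return (
        '<!DOCTYPE html>\n<html><head><meta charset="utf-8">'
        "<title>Patient reports</title></head><body>"
        f"<h1>Patient reports</h1><ul>\n{items}\n</ul></body></html>"
    )


def write_reports(summaries: list[PatientSummary], out_dir) -> None:
    """One HTML + JSON pair per patient, plus an index page."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in summaries:
        (out / f"{s.patient_id}.html").write_text(render(s), encoding="utf-8")
        (out / f"{s.patient_id}.json").write_text(
            json.dumps(s.to_dict(), indent=1), encoding="utf-8"
        )
    (out / "index.html").write_text(
        render_index([s.patient_id for s in summaries]), encoding="utf-8"
    )
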