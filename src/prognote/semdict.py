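"""Semantic dictionary mapping: surface terms → controlled terms.

A controlled-term dictionary (the CLEVER style: {'mother','brother',…} →
FAMILY, {'no','absent',…} → NEGEX, {'suspicion','probable',…} → RISK)
collapses synonym families in the condensed notes onto canonical uppercase
tokens. Matching is stem-aware — "probabl" (the stem the condenser emits
for "probable") hits the entry for "probable" — and multi-word surface
forms ("adequate to rule her out") are matched over token spans, longest
first.

Controlled terms are stored as their plain uppercase token; the condenser
lowercases all free text, so an uppercase token in a mapped note is
unambiguously a controlled term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from ._porter import stem
from .condenser import STOPLIST, CondensedNote, tokenize

__all__ = [
    "TermDictionary",
    "MappedNote",
    "DictionaryError",
    "load_dictionary",
    "bundled_dictionary_path",
    "map_terms",
    "vocabulary_reduction",
]

MAX_SPAN = 6  # longest multi-word surface form matched, in tokens


class DictionaryError(ValueError):
    """Malformed or self-conflicting dictionary file."""


@dataclass
class TermDictionary:
    entries: dict[str, str]                 # surface form -> CTerm
    span_entries: dict[tuple[str, ...], str]  # condensed multi-token span -> CTerm
    stem_index: dict[str, str]              # stemmed single surface -> CTerm
    controlled_terms: set[str]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MappedNote:
    """Condensed note with dictionary hits replaced by controlled terms.

    ``mapped_positions`` lists (output token index, originating surface
    form) pairs — the explainability stage highlights these.
    """

    note_id: str
    tokens: list[str]
    mapped_positions: list[tuple[int, str]] = field(default_factory=list)


def _condense_surface(surface: str) -> tuple[str, ...]:
    """Normalise a surface form the way the condenser normalises note
    text (lowercase, tokenize, drop stopwords, stem) so spans line up
    with the condensed token stream."""
    return tuple(stem(t) for t in tokenize(surface) if t not in STOPLIST)


def load_dictionary(path) -> TermDictionary:
    """Read a 2-column TSV (surface_term <TAB> controlled_term).

    Duplicates pointing at the same controlled term are deduplicated;
    a surface form mapped to two different controlled terms is a conflict
    and the load fails listing every offender. A surface form equal to a
    controlled term is also rejected — it would make mapping
    non-idempotent.
    """
    entries: dict[str, str] = {}
    conflicts: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise DictionaryError(f"line {lineno}: expected 'surface<TAB>CTERM', got {line!r}")
            surface, cterm = parts[0].strip().lower(), parts[1].strip().upper()
            if surface in entries and entries[surface] != cterm:
                conflicts.append(f"{surface!r} -> {entries[surface]} and {cterm}")
                continue
            entries[surface] = cterm
    if conflicts:
        raise DictionaryError("conflicting surface forms: " + "; ".join(conflicts))

    controlled = set(entries.values())
    # Idempotence guarantee: surfaces are stored lowercase and controlled
    # terms uppercase, and every lookup is case-sensitive, so a mapped
    # token (uppercase) can never be re-mapped.
    span_entries: dict[tuple[str, ...], str] = {}
    stem_index: dict[str, str] = {}
    for surface, cterm in entries.items():
        span = _condense_surface(surface)
        if not span:
            continue
        if len(span) == 1:
            stem_index.setdefault(span[0], cterm)
        else:
            span_entries.setdefault(span[: MAX_SPAN], cterm)
    return TermDictionary(
        entries=entries,
        span_entries=span_entries,
        stem_index=stem_index,
        controlled_terms=controlled,
    )


def bundled_dictionary_path():
    """Path of the ~60-entry fixture dictionary shipped with the package."""
    return resources.files("prognote").joinpath("data/dictionary.tsv")


def map_terms(note: CondensedNote | MappedNote, dictionary: TermDictionary) -> MappedNote:
    """Replace dictionary hits by controlled terms, token by token.

    At each position the longest matching span (up to ``MAX_SPAN`` tokens)
    wins; single tokens match exact surface first, then stem. Unmatched
    tokens pass through; token count is preserved except where a
    multi-token span collapses to one controlled term.
    """
    toks = note.tokens
    out: list[str] = []
    positions: list[tuple[int, str]] = []
    max_span = max((len(s) for s in dictionary.span_entries), default=1)
    i = 0
    while i < len(toks):
        matched = False
        for width in range(min(max_span, len(toks) - i), 1, -1):
            span = tuple(toks[i : i + width])
            cterm = dictionary.span_entries.get(span)
            if cterm is not None:
                positions.append((len(out), " ".join(span)))
                out.append(cterm)
                i += width
                matched = True
                break
        if matched:
            continue
        tok = toks[i]
        cterm = dictionary.entries.get(tok)
        if cterm is None:
            cterm = dictionary.stem_index.get(tok)
        if cterm is None and "_" in tok:
            # a collocation merge may have fused a multi-word surface
            # ("famili_histori") into one token; match it as the span
            cterm = dictionary.span_entries.get(tuple(tok.split("_")))
        if cterm is not None and tok not in dictionary.controlled_terms:
            positions.append((len(out), tok))
            out.append(cterm)
        else:
            out.append(tok)
        i += 1
    return MappedNote(note_id=note.note_id, tokens=out, mapped_positions=positions)


def vocabulary_reduction(
    corpus_before: list[CondensedNote], corpus_after: list[MappedNote]
) -> float:
    """1 - |vocab after mapping| / |vocab before|, in [0, 1)."""
    if not corpus_before or not corpus_after:
        raise ValueError("vocabulary_reduction: empty corpus")
    before = {t for n in corpus_before for t in n.tokens}
    after = {t for n in corpus_after for t in n.tokens}
    if not before:
        raise ValueError("vocabulary_reduction: corpus has no tokens")
    return 1.0 - len(after) / len(before)
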