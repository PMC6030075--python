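"""Report condenser: note-text normalisation ahead of embedding.

Raw clinical note text is noisy — mixed case, stopwords, numerals, absolute
dates. The condenser reduces each note to an ordered list of normalised
tokens:

* inline dates become *relative-gap* tokens ("three_month_ago") measured
  against the visit date, so "scan on 2015-03-01" reads the same whether
  the note was written in June or July;
* numerals become words (0-20) or magnitude tokens ("num_hundreds");
* stopwords are dropped (negations are deliberately kept — downstream
  dictionary mapping of "no" → NEGEX depends on them);
* surviving tokens are Porter-stemmed.

A second pass merges high-PMI bigram collocations ("bone metastasi" →
"bone_metastasi") into single tokens so the embedding treats them as units.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

from ._porter import stem

__all__ = [
    "CondensedNote",
    "CollocationModel",
    "condense",
    "normalize_dates",
    "fit_collocations",
    "apply_collocations",
    "tokenize",
    "STOPLIST",
]

# Function words only. Negations ("no", "not", "nor", "none", "never",
# "without", "denies") and auxiliaries ("has", "have", "had") are kept in
# the text: the semantic dictionary maps them (NEGEX) and stripping them
# would invert meanings.
STOPLIST = frozenset(
    """a an the and or but if then than so because while of in on at by to
    from for with about into through during before after above below up down
    out off over under again further here there all any both each few more
    most other some such only own same too very can will just is are was
    were be been being am do does did doing this that these those i me my we
    our you your he him his she her it its they them their what which who
    whom as until between against""".split()
)

_NUMBER_WORDS = [
    "zero", "one", "two", "three", "four", "five", "six", "seven", "eight",
    "nine", "ten", "eleven", "twelve", "thirteen", "fourteen", "fifteen",
    "sixteen", "seventeen", "eighteen", "nineteen", "twenty",
]

_TOKEN_RE = re.compile(r"[a-z0-9_]+(?:-[a-z0-9_]+)*")

_MONTHS = {
    m: i + 1
    for i, m in enumerate(
        ["january", "february", "march", "april", "may", "june", "july",
         "august", "september", "october", "november", "december"]
    )
}

# Recognised inline date formats: ISO-8601, MM/DD/YYYY, "Month D, YYYY".
_DATE_RE = re.compile(
    r"(?P<iso>\b\d{4}-\d{2}-\d{2}\b)"
    r"|(?P<us>\b\d{1,2}/\d{1,2}/\d{4}\b)"
    r"|(?P<name>\b(?:January|February|March|April|May|June|July|August|"
    r"September|October|November|December)\s+\d{1,2},\s*\d{4}\b)",
    re.IGNORECASE,
)


@dataclass
class CondensedNote:
    """Normalised token sequence for one note."""

    note_id: str
    tokens: list[str]
    source_note_id: str | None = None

    def __post_init__(self) -> None:
        if self.source_note_id is None:
            self.source_note_id = self.note_id


@dataclass
class CollocationModel:
    """Selected bigram collocations with their PMI scores.

    ``pmi`` maps every bigram with count >= ``min_count`` to its score;
    ``selected`` is the top-``top_k`` subset whose members get merged.
    """

    pmi: dict[tuple[str, str], float]
    counts: dict[tuple[str, str], int]
    selected: set[tuple[str, str]]
    min_count: int = 50
    top_k: int = 1000

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#min_count={self.min_count}\ttop_k={self.top_k}\n")
            for pair in sorted(self.pmi):
                a, b = pair
                flag = 1 if pair in self.selected else 0
                fh.write(f"{a}\t{b}\t{self.counts[pair]}\t{self.pmi[pair]:.10g}\t{flag}\n")

    @classmethod
    def load(cls, path) -> "CollocationModel":
        pmi: dict[tuple[str, str], float] = {}
        counts: dict[tuple[str, str], int] = {}
        selected: set[tuple[str, str]] = set()
        min_count, top_k = 50, 1000
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    for part in line[1:].split("\t"):
                        key, _, val = part.partition("=")
                        if key == "min_count":
                            min_count = int(val)
                        elif key == "top_k":
                            top_k = int(val)
                    continue
                a, b, cnt, score, flag = line.split("\t")
                pair = (a, b)
                pmi[pair] = float(score)
                counts[pair] = int(cnt)
                if flag == "1":
                    selected.add(pair)
        return cls(pmi=pmi, counts=counts, selected=selected,
                   min_count=min_count, top_k=top_k)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def _gap_token(gap_days: int) -> str:
    """Bucket a day gap into a relative-time token (month = 30.44 d,
    year = 365.25 d, half-up rounding)."""
    if gap_days == 0:
        return "same_day"
    ahead = gap_days < 0
    g = abs(gap_days)
    if g < 7:
        unit, n = "day", g
    elif g < 30:
        unit, n = "week", min(max(_round_half_up(g / 7), 1), 4)
    else:
        months = _round_half_up(g / 30.44)
        if months <= 11:
            unit, n = "month", max(months, 1)
        else:
            unit, n = "year", max(_round_half_up(g / 365.25), 1)
    word = _NUMBER_WORDS[n] if n <= 20 else str(n)
    return f"{word}_{unit}_{'ahead' if ahead else 'ago'}"


def _parse_date_match(m: re.Match) -> date | None:
    try:
        if m.lastgroup == "iso":
            return datetime.strptime(m.group(), "%Y-%m-%d").date()
        if m.lastgroup == "us":
            mm, dd, yyyy = m.group().split("/")
            return date(int(yyyy), int(mm), int(dd))
        # "Month D, YYYY"
        month_name, rest = m.group().split(" ", 1)
        dd, yyyy = rest.replace(",", " ").split()
        return date(int(yyyy), _MONTHS[month_name.lower()], int(dd))
    except ValueError:
        return None


def normalize_dates(text: str, visit_date: date) -> str:
    """Replace each recognised inline date by its relative-gap token.

    Gap = visit_date - mentioned date; future dates get an ``_ahead``
    suffix. Date-like strings that do not parse (e.g. "2015-13-40") are
    left untouched.
    """

    def repl(m: re.Match) -> str:
        d = _parse_date_match(m)
        if d is None:
            return m.group()
        return _gap_token((visit_date - d).days)

    return _DATE_RE.sub(repl, text)


def _number_token(tok: str) -> str:
    n = int(tok)
    if n <= 20:
        return _NUMBER_WORDS[n]
    if n < 100:
        return "num_tens"
    if n < 1000:
        return "num_hundreds"
    if n < 1_000_000:
        return "num_thousands"
    return "num_large"


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric characters; intra-token
    hyphens and underscores survive (relative-date tokens use ``_``)."""
    return _TOKEN_RE.findall(text.lower())


def condense(
    text: str,
    visit_date: date,
    stoplist: frozenset[str] = STOPLIST,
    note_id: str = "",
) -> CondensedNote:
    """Full per-note normalisation: dates → relative tokens, tokenize,
    numerals → words, drop stopwords, Porter-stem the rest."""
    out: list[str] = []
    for tok in tokenize(normalize_dates(text, visit_date)):
        if tok in stoplist:
            continue
        if tok.isdigit():
            out.append(_number_token(tok))
            continue
        out.append(stem(tok) if "_" not in tok else tok)
    return CondensedNote(note_id=note_id, tokens=out)


def fit_collocations(
    corpus: list[CondensedNote], min_count: int = 50, top_k: int = 1000
) -> CollocationModel:
    """Score adjacent-token bigrams by pointwise mutual information.

    PMI(a,b) = log[ c(a,b) * T / (c(a) * c(b)) ] with T the total
    adjacent-pair count; bigrams rarer than ``min_count`` are discarded
    and the ``top_k`` survivors by PMI are selected for merging. Ties
    break by higher count, then lexicographic order.
    """
    if not corpus:
        raise ValueError("fit_collocations: empty corpus")
    pair_counts: Counter[tuple[str, str]] = Counter()
    unigram: Counter[str] = Counter()
    total_pairs = 0
    for note in corpus:
        toks = note.tokens
        unigram.update(toks)
        for a, b in zip(toks, toks[1:]):
            pair_counts[(a, b)] += 1
            total_pairs += 1
    pmi: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for pair, c_ab in pair_counts.items():
        if c_ab < min_count:
            continue
        a, b = pair
        pmi[pair] = math.log(c_ab * total_pairs / (unigram[a] * unigram[b]))
        counts[pair] = c_ab
    ranked = sorted(pmi, key=lambda p: (-pmi[p], -counts[p], p))
    return CollocationModel(
        pmi=pmi, counts=counts, selected=set(ranked[:top_k]),
        min_count=min_count, top_k=top_k,
    )


def apply_collocations(note: CondensedNote, model: CollocationModel) -> CondensedNote:
    """Merge selected bigrams left-to-right, greedily and without overlap."""
    toks = note.tokens
    out: list[str] = []
    i = 0
    while i < len(toks):
        if i + 1 < len(toks) and (toks[i], toks[i + 1]) in model.selected:
            out.append(f"{toks[i]}_{toks[i + 1]}")
            i += 2
        else:
            out.append(toks[i])
            i += 1
    return CondensedNote(note_id=note.note_id, tokens=out,
                         source_note_id=note.source_note_id)
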