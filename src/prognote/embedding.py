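"""Skip-gram word embeddings and context-aware note vectors.

The mapped corpus (free-text tokens plus uppercase controlled terms) is
embedded with a skip-gram model trained by negative sampling. A note is
then vectorised by locating every controlled-term occurrence, averaging
the embedding vectors inside a fixed window around it (the *context
window*), and averaging those per-occurrence context vectors:

    v_note = (1/N) * sum_c [ (1/n_c) * sum_{w in window(c)} v_w ]

where N is the number of controlled-term occurrences and n_c the number
of in-vocabulary tokens inside occurrence c's window. A note with no
controlled terms gets the all-zeros vector, which downstream padding
logic relies on being reserved for exactly that case.

Defaults follow the reference configuration: dimension 700, training
window 30, minimum token count 5, and a 15-token context window on each
side of a controlled term (the term's own vector included).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .semdict import MappedNote

__all__ = [
    "EmbeddingModel",
    "NoteVector",
    "train_embeddings",
    "note_vector",
    "vectorize_corpus",
    "save_note_vectors",
    "load_note_vectors",
]


@dataclass
class EmbeddingModel:
    """token -> R^D map plus the training configuration that produced it."""

    vocab: dict[str, int]          # token -> row index
    vectors: np.ndarray            # (V, D) float64
    dim: int
    window: int
    min_token_count: int
    seed: int

    def __contains__(self, token: str) -> bool:
        return token in self.vocab

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[self.vocab[token]]

    def save(self, path) -> None:
        """Persist in the word2vec text format ("V D" header, one token
        + vector per line)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocab)} {self.dim}\n")
            for tok, idx in self.vocab.items():
                vec = " ".join(repr(float(x)) for x in self.vectors[idx])
                fh.write(f"{tok} {vec}\n")

    @classmethod
    def load(cls, path, window: int = 30, min_token_count: int = 5,
             seed: int = 0) -> "EmbeddingModel":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            vocab: dict[str, int] = {}
            vectors = np.empty((n, dim), dtype=np.float64)
            for i in range(n):
                parts = fh.readline().rstrip("\n").split(" ")
                vocab[parts[0]] = i
                vectors[i] = [float(x) for x in parts[1 : dim + 1]]
        return cls(vocab=vocab, vectors=vectors, dim=dim, window=window,
                   min_token_count=min_token_count, seed=seed)


@dataclass
class NoteVector:
    note_id: str
    vector: np.ndarray
    n_cterms: int
    contexts: list[tuple[int, int, int]] = field(default_factory=list)
    # (cterm position, window start, window end) per occurrence


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embeddings(
    corpus: list[MappedNote],
    dim: int = 700,
    window: int = 30,
    min_token_count: int = 5,
    seed: int = 0,
    epochs: int = 5,
    negatives: int = 5,
    lr: float = 0.025,
    batch_size: int = 256,
) -> EmbeddingModel:
    """Train skip-gram embeddings with negative sampling (SGNS).

    Single-threaded and fully seeded: identical corpus + seed gives
    bit-identical vectors. Tokens occurring fewer than
    ``min_token_count`` times get no vector. Negative samples are drawn
    from the unigram distribution raised to 3/4.
    """
    if dim < 1 or window < 1:
        raise ValueError("dim and window must be >= 1")
    counts: dict[str, int] = {}
    for note in corpus:
        for tok in note.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        (t for t, c in counts.items() if c >= min_token_count),
        key=lambda t: (-counts[t], t),
    )
    if not kept:
        raise ValueError("no token reaches min_token_count; nothing to train on")
    vocab = {t: i for i, t in enumerate(kept)}
    V = len(vocab)

    # (center, context) pairs over every note, symmetric fixed window
    centers: list[int] = []
    contexts: list[int] = []
    for note in corpus:
        ids = [vocab[t] for t in note.tokens if t in vocab]
        for i, c in enumerate(ids):
            lo = max(0, i - window)
            hi = min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    if not centers:
        raise ValueError("corpus yields no training pairs")
    centers_a = np.asarray(centers, dtype=np.int64)
    contexts_a = np.asarray(contexts, dtype=np.int64)
    n_pairs = len(centers_a)

    noise = np.array([counts[t] for t in kept], dtype=np.float64) ** 0.75
    noise /= noise.sum()

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim      # word2vec-style init
    W_out = np.zeros((V, dim))

    total_steps = epochs * ((n_pairs + batch_size - 1) // batch_size)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            idx = order[start : start + batch_size]
            c = centers_a[idx]
            o = contexts_a[idx]
            neg = rng.choice(V, size=(len(idx), negatives), p=noise)
            alpha = lr * max(1.0 - step / total_steps, 1e-4)
            step += 1

            v_c = W_in[c]                                    # (B, D)
            u_pos = W_out[o]                                 # (B, D)
            u_neg = W_out[neg]                               # (B, k, D)

            g_pos = _sigmoid(np.einsum("bd,bd->b", v_c, u_pos)) - 1.0   # (B,)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", v_c, u_neg))       # (B, k)

            grad_c = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            np.add.at(W_out, o, -alpha * g_pos[:, None] * v_c)
            np.add.at(
                W_out,
                neg.reshape(-1),
                (-alpha * g_neg[..., None] * v_c[:, None, :]).reshape(-1, dim),
            )
            np.add.at(W_in, c, -alpha * grad_c)

    return EmbeddingModel(vocab=vocab, vectors=W_in, dim=dim, window=window,
                          min_token_count=min_token_count, seed=seed)


def _is_cterm(token: str) -> bool:
    return token.isupper() and token.isalpha()


def note_vector(note: MappedNote, model: EmbeddingModel, cwindow: int = 15) -> NoteVector:
    """Two-level mean over controlled-term context windows.

    The window of an occurrence at position p covers tokens
    [p - cwindow, p + cwindow] clipped to the note, the term itself
    included; out-of-vocabulary tokens are skipped and do not enter the
    denominator. No controlled terms -> all-zeros vector.
    """
    toks = note.tokens
    occ = [i for i, t in enumerate(toks) if _is_cterm(t)]
    v = np.zeros(model.dim, dtype=np.float64)
    spans: list[tuple[int, int, int]] = []
    n_used = 0
    for p in occ:
        lo = max(0, p - cwindow)
        hi = min(len(toks), p + cwindow + 1)
        rows = [model.vocab[t] for t in toks[lo:hi] if t in model.vocab]
        spans.append((p, lo, hi))
        if rows:
            v += model.vectors[rows].mean(axis=0)
            n_used += 1
    if n_used:
        v /= n_used
    return NoteVector(note_id=note.note_id, vector=v, n_cterms=len(occ),
                      contexts=spans)


def vectorize_corpus(
    notes: list[MappedNote], model: EmbeddingModel, cwindow: int = 15
) -> dict[str, NoteVector]:
    """One NoteVector per note, keyed by note_id; order-independent."""
    if model is None:
        raise ValueError("vectorize_corpus: no embedding model supplied")
    return {n.note_id: note_vector(n, model, cwindow) for n in notes}


def save_note_vectors(table: dict[str, NoteVector], path) -> None:
    """Array container (.npz) plus sidecar JSON index (note_id -> row)."""
    path = str(path)
    ids = list(table)
    mat = np.stack([table[i].vector for i in ids]) if ids else np.empty((0, 0))
    np.savez(path if path.endswith(".npz") else path + ".npz", vectors=mat)
    with open(_index_path(path), "w", encoding="utf-8") as fh:
        json.dump(
            {
                "note_ids": ids,
                "n_cterms": {i: table[i].n_cterms for i in ids},
            },
            fh,
        )


def _index_path(path: str) -> str:
    base = path[:-4] if path.endswith(".npz") else path
    return base + ".index.json"


def load_note_vectors(path) -> dict[str, NoteVector]:
    path = str(path)
    npz = path if path.endswith(".npz") else path + ".npz"
    mat = np.load(npz)["vectors"]
    with open(_index_path(path), encoding="utf-8") as fh:
        index = json.load(fh)
    out: dict[str, NoteVector] = {}
    for row, nid in enumerate(index["note_ids"]):
        out[nid] = NoteVector(note_id=nid, vector=mat[row],
                              n_cterms=index["n_cterms"][nid])
    return out
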