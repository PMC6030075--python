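from datetime import date

import numpy as np
import pytest

from prognote import (
    CohortConfig,
    bundled_dictionary_path,
    generate_cohort,
    load_dictionary,
)
from prognote.embedding import EmbeddingModel
from prognote.semdict import MappedNote


@pytest.fixture(scope="session")
def dictionary():
    return load_dictionary(bundled_dictionary_path())


@pytest.fixture(scope="session")
def small_cohort():
    """200-patient planted-signal cohort shared across read-only tests."""
    cfg = CohortConfig(n_patients=200, seed=7, signal_strength=1.0)
    notes, outcomes = generate_cohort(cfg)
    return cfg, notes, outcomes


def make_embedding(tokens: list[str], dim: int = 3, seed: int = 0) -> EmbeddingModel:
    """Deterministic toy embedding with one random vector per token."""
    rng = np.random.default_rng(seed)
    vocab = {t: i for i, t in enumerate(tokens)}
    return EmbeddingModel(
        vocab=vocab,
        vectors=rng.normal(size=(len(tokens), dim)),
        dim=dim,
        window=5,
        min_token_count=1,
        seed=seed,
    )


def make_mapped(tokens: list[str], note_id: str = "n") -> MappedNote:
    positions = [(i, t.lower()) for i, t in enumerate(tokens) if t.isupper()]
    return MappedNote(note_id=note_id, tokens=tokens, mapped_positions=positions)
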