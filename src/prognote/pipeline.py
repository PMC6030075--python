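"""End-to-end convenience pipeline over the library modules.

Wires the stages together for programmatic use (the CLI exposes each
stage separately): generate or accept a cohort, condense and map the
notes, train skip-gram embeddings *on the training patients only*,
vectorise every note, build padded label sequences, train the recurrent
classifier, and evaluate on the held-out test patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort as _cohort
from . import condenser as _condenser
from . import dataset as _dataset
from . import embedding as _embedding
from . import evaluation as _evaluation
from . import model as _model
from . import semdict as _semdict
from .io import VisitNote

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "prepare_mapped_notes"]


@dataclass
class PipelineConfig:
    cohort: _cohort.CohortConfig = field(default_factory=_cohort.CohortConfig)
    dictionary_path: str | None = None   # None -> bundled fixture dictionary
    colloc_min_count: int = 50
    colloc_top_k: int = 1000
    embed_dim: int = 32
    embed_window: int = 5
    embed_min_count: int = 5
    embed_epochs: int = 3
    cwindow: int = 15
    max_len: int = 20
    split_fractions: tuple[float, float, float] = (0.5, 0.1, 0.4)
    epochs: int = 30
    batch_size: int = 32
    n_boot: int = 100
    seed: int = 0


@dataclass
class PipelineResult:
    predictions: pd.DataFrame
    report: _evaluation.EvaluationReport
    history: list[dict]
    model: _model.SurvivalLSTM
    splits: dict[str, list[_dataset.PatientSequence]]
    notes: list[VisitNote]
    mapped: dict[str, _semdict.MappedNote]
    dictionary: _semdict.TermDictionary
    stats: dict


def prepare_mapped_notes(
    notes: list[VisitNote],
    dictionary: _semdict.TermDictionary,
    colloc_model: _condenser.CollocationModel | None = None,
    fit_on_note_ids: set[str] | None = None,
    min_count: int = 50,
    top_k: int = 1000,
) -> tuple[dict[str, _semdict.MappedNote], _condenser.CollocationModel]:
    """Condense + collocation-merge + dictionary-map a note corpus.

    The collocation model is fitted on ``fit_on_note_ids`` (all notes
    when None) unless one is supplied.
    """
    condensed = {
        n.note_id: _condenser.condense(n.text, n.visit_date, note_id=n.note_id)
        for n in notes
    }
    if colloc_model is None:
        fit_ids = fit_on_note_ids if fit_on_note_ids is not None else set(condensed)
        fit_corpus = [condensed[nid] for nid in condensed if nid in fit_ids]
        colloc_model = _condenser.fit_collocations(fit_corpus, min_count, top_k)
    merged = {
        nid: _condenser.apply_collocations(c, colloc_model)
        for nid, c in condensed.items()
    }
    mapped = {nid: _semdict.map_terms(c, dictionary) for nid, c in merged.items()}
    return mapped, colloc_model


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    notes, outcomes = _cohort.generate_cohort(config.cohort)
    stats = _cohort.cohort_stats(notes, outcomes)

    dict_path = config.dictionary_path or _semdict.bundled_dictionary_path()
    dictionary = _semdict.load_dictionary(dict_path)

    # patient-level split decided first so text models see training data only
    pids = sorted({n.patient_id for n in notes})
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(pids))
    bounds = np.floor(np.cumsum(config.split_fractions) * len(pids) + 0.5).astype(int)
    bounds[-1] = len(pids)
    split_of: dict[str, str] = {}
    names = ["train", "validation", "test"]
    start = 0
    for name, b in zip(names, bounds):
        for i in order[start:b]:
            split_of[pids[i]] = name
        start = b
    train_note_ids = {n.note_id for n in notes if split_of[n.patient_id] == "train"}

    mapped, _colloc = prepare_mapped_notes(
        notes, dictionary, fit_on_note_ids=train_note_ids,
        min_count=config.colloc_min_count, top_k=config.colloc_top_k,
    )
    train_mapped = [mapped[nid] for nid in sorted(train_note_ids)]
    emb = _embedding.train_embeddings(
        train_mapped, dim=config.embed_dim, window=config.embed_window,
        min_token_count=config.embed_min_count, seed=config.seed,
        epochs=config.embed_epochs,
    )
    vectors = _embedding.vectorize_corpus(list(mapped.values()), emb, config.cwindow)

    sequences = _dataset.build_sequences(
        {nid: v.vector for nid, v in vectors.items()}, notes, outcomes,
        max_len=config.max_len,
    )
    splits: dict[str, list[_dataset.PatientSequence]] = {n: [] for n in names}
    for s in sequences:
        splits[split_of[s.patient_id]].append(s)

    mcfg = _model.ModelConfig(
        input_dim=config.embed_dim, epochs=config.epochs,
        batch_size=config.batch_size, seed=config.seed,
    )
    fitted, history = _model.train(splits["train"], mcfg, splits["validation"])
    preds = _model.predict(splits["test"], fitted)
    frame = _model.predictions_frame(preds)
    report = _evaluation.evaluate_predictions(frame, n_boot=config.n_boot,
                                              seed=config.seed)
    return PipelineResult(
        predictions=frame, report=report, history=history, model=fitted,
        splits=splits, notes=notes, mapped=mapped, dictionary=dictionary,
        stats=stats,
    )
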