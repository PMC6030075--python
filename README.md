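# prognote

Short-term survival prediction from longitudinal free-text clinical notes.

Physicians systematically over-estimate the survival of patients with
terminal metastatic cancer, which leads to over-aggressive treatment near
the end of life. `prognote` implements a two-stage pipeline that turns the
sequence of a patient's free-text visit notes into a per-visit probability
of surviving more than 3 months, for researchers who want to study this
class of models without access to protected EMR data: the package ships a
synthetic-cohort generator with a plantable textual prognosis signal, so
every stage is runnable and testable end to end.

## The model

**Stage 1 — dictionary-aware note embedding.** Raw notes are condensed
(stopword removal, Porter stemming, number-to-word conversion, inline dates
→ visit-relative tokens such as `three_month_ago`, top-PMI bigram
collocations merged), then mapped onto controlled terms via a
surface-form → term dictionary (`'no' → NEGEX`, `'probable' → RISK`,
`'mother' → FAMILY`, …). Skip-gram embeddings v_w are trained on the mapped
corpus, and each note is vectorised by averaging over its controlled-term
occurrences c the mean embedding inside c's context window:

    v_note = (1/N) Σ_{c ∈ CTerms} (1/n_c) Σ_{w ∈ CWindow(c)} v_w

with N the number of controlled-term occurrences and n_c the in-vocabulary
tokens in c's window (defaults: dimension 700, training window 30, minimum
count 5, context window 15 tokens each side). A note with no controlled
terms gets the all-zeros vector, which is reserved for padding.

**Stage 2 — recurrent sequence classifier.** Per patient i, the visit
vectors form a series X_i = (x⁽¹⁾, …, x⁽ⁿ⁾) with per-visit labels
y⁽ᵗ⁾ ∈ {Survival-positive, Survival-negative, Padded}, where
Survival-negative means death within 91 days of the visit; sequences are
zero-padded / truncated (keeping the most recent visits) to a fixed length
(default 1000). The classifier is

    input(D) → LSTM(50) → frame-wise batch norm → LSTM(25)
             → dropout(0.10) → time-distributed softmax(3)

trained with Adam (lr 0.001, decay 0.0001/epoch) on a time-distributed
cross-entropy in which each timestep is weighted by its true class
(positive 2×, negative 1×, padded 0.1×; visits censored inside the horizon
get weight 0). The recurrence is unidirectional, so ŷ⁽ᵗ⁾ never sees future
visits. Evaluation (ROC-AUC with patient-level bootstrap CI, Brier score,
PR-AUC, decile calibration, per-stratum AUC) uses non-padded visits only,
and a per-patient HTML report overlays the predicted survival curve on the
true labels with dictionary hits highlighted in ±5-word context.

Everything is implemented in numpy (including the skip-gram trainer and
the LSTM with backpropagation through time), single-threaded and seeded:
identical seeds give bit-identical results.

## Worked example

`examples/04_train_and_evaluate.py` generates a 500-patient cohort in which
notes within 3 months of death always contain a fatal-signal phrase
("hospice", "comfort care", …), trains the full pipeline, and evaluates on
200 held-out patients:

```
held-out patients: 200, evaluated visits: 1618
ROC AUC:   0.9878  (95% CI 0.9806-0.9935)
Brier:     0.0297  (0 = perfectly calibrated)
PR AUC:    0.9956
best cut-off (max sensitivity+specificity): 0.773
```

The AUC near 1 says the pipeline recovers the planted signal end to end —
condensation, dictionary mapping, embedding, sequence modelling and
evaluation all compose correctly; the small Brier score says the
probabilities are calibrated, and the decile table it also prints shows
predicted and observed survival rates tracking each other bin by bin. With
`signal_strength=0` the same pipeline scores AUC ≈ 0.5: the generator is
constructed so that without the textual signal nothing else (visit index
included) predicts the outcome. The other examples demonstrate the cohort
generator, the condenser and dictionary mapper, note vectors, and the
per-patient explanation report.

The same stages are available as a CLI for shell use:

```bash
prognote simulate --out-dir work --seed 1
prognote condense --notes work/notes.jsonl --out work/condensed.jsonl \
    --collocations work/colloc.tsv --fit
prognote map-terms --notes work/condensed.jsonl --out work/mapped.jsonl
prognote embed-train --notes work/mapped.jsonl --out work/model.vec \
    --dim 32 --window 5 --seed 1
prognote vectorize --notes work/mapped.jsonl --model work/model.vec \
    --out work/vectors
prognote build-dataset --vectors work/vectors --notes work/notes.jsonl \
    --outcomes work/outcomes.tsv --max-len 20 --seed 1 --out work/data
prognote train --data work/data --epochs 30 --seed 1 --out work/run
prognote predict --data work/data --model work/run --out work/pred.tsv
prognote evaluate --pred work/pred.tsv --out work/eval
prognote explain --pred work/pred.tsv --notes work/notes.jsonl --out work/reports
```

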