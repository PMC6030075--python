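# Methods

This note records the modelling choices behind `prognote`: what each stage
assumes, which parameters matter, what the synthetic cohorts do and do not
emulate, and the numerical conventions needed to reproduce results
exactly.

## Labelling

Every visit is labelled relative to a survival horizon of 91 days
(≈ 3 × 30.44): **Survival-positive** if the patient is known to survive
more than the horizon past the visit date (death later than 91 days, or no
death and follow-up extending beyond the horizon), **Survival-negative**
if death occurs within it, and **undefined** when the patient is alive at
a last follow-up that is closer than the horizon — the outcome is
unknowable (censoring within the horizon). Undefined visits stay in the
input sequence, because removing them would distort the recurrent state,
but carry zero loss weight and are excluded from every evaluation metric.
Labels are always derived from the death/follow-up dates at dataset-build
time; no stage stores them.

## Report condenser

Tokenisation lowercases and splits on non-alphanumerics, keeping
intra-token hyphens and underscores. The stoplist is a compact in-package
list of function words; negations (`no`, `not`, `nor`, `none`, `never`,
`without`) and auxiliaries (`has`, `have`, `had`) are deliberately *not*
stopwords — dictionary mapping of negation cues depends on them. Remaining
tokens are stemmed with an in-package implementation of the Porter
algorithm, which the dictionary's stem index shares so pipeline stages
agree on roots.

Numerals 0–20 become words; larger numbers become magnitude tokens
(`num_tens`, `num_hundreds`, `num_thousands`, `num_large`) to bound the
vocabulary. Inline dates (ISO-8601, MM/DD/YYYY, "Month D, YYYY") are
replaced by the gap to the visit date, bucketed with month = 30.44 d,
year = 365.25 d and half-up rounding: `same_day`, 1–6 `*_day_ago`,
`*_week_ago` for 7–29 d (so only 1–4 weeks are reachable), `*_month_ago`
up to 11 months, `*_year_ago` beyond; future dates take an `_ahead`
suffix. Unparseable date-like strings pass through untouched.

Bigram collocations are scored on adjacent condensed tokens by
PMI(a,b) = ln[c(a,b)·T / (c(a)·c(b))] with T the total adjacent-pair
count; pairs rarer than `min_count` (default 50) are dropped, the top
`top_k` (default 1000) by PMI are merged left-to-right, greedily and
without overlap. Ties break by higher count then lexicographic order, for
reproducibility. Collocation counts are computed *after* stopword removal;
the alternative order is defensible but this one keeps the merged tokens
aligned with what the dictionary matcher sees.

## Semantic dictionary mapping

The dictionary is a two-column TSV of surface form → controlled term.
Surfaces are normalised exactly like note text (tokenise, drop stopwords,
stem), so multi-word surfaces match as token *spans* (longest first, up to
6 tokens) over the condensed stream; a span match collapses to a single
controlled term, the one case where token count is not preserved. A token
already merged by the collocation stage (e.g. `famili_histori`) is
recognised by matching its underscore-split parts against the span index.
Controlled terms are stored as plain uppercase tokens; since free text is
lowercased and lookups are case-sensitive, mapping is idempotent by
construction. Conflicting surface forms (one surface, two terms) fail the
load with the full conflict list.

## Note vectors

The context window of a controlled-term occurrence at position p covers
positions [p − cwindow, p + cwindow] clipped to the note, the term itself
included — the most literal reading of a "15-word span" around the term;
the interpretation is configurable via `cwindow`. Out-of-vocabulary window
tokens are skipped and excluded from the denominator rather than
zero-imputed, which would bias context means toward the origin.
Overlapping windows of nearby terms share tokens; normalisation stays
per-occurrence. A note with no controlled-term occurrences maps to the
all-zeros vector; the synthetic generator guarantees at least one
dictionary surface per note, so in generated data the zero vector is
unambiguous padding, and the dataset builder enforces this by rejecting a
zero vector on a real visit.

The skip-gram trainer is a seeded, single-threaded numpy implementation of
negative sampling (5 negatives, unigram^0.75 noise distribution, linearly
decaying learning rate from 0.025, minibatch 256 — larger batches
accumulate many same-row updates at full step size and diverge). Corpus
defaults follow the reference configuration (dimension 700, window 30,
minimum count 5); the bundled studies use dimension 32 and window 5, which
are ample for the ~100-token synthetic vocabulary.

## Sequence model

Architecture: input → LSTM(50, unidirectional, sequence output) →
frame-wise batch normalisation (statistics shared across timesteps) →
LSTM(25) → dropout 0.10 → per-timestep dense + 3-class softmax. Parameter
counts follow 4·H·(D_in + H + 1) per LSTM layer. State is per-patient —
each padded sequence is processed in one pass, so statefulness across
batches does not arise.

The loss is the mean over all B·T timesteps of the true-class-weighted
cross-entropy, weights 2.0 / 1.0 / 0.1 for positive / negative / padded
and 0 for undefined timesteps. The written-out binary cross-entropy form
and the 3-class softmax are reconciled by reading the weight λ⁽ᵗ⁾ as a
function of the true class, the only reading consistent with the stated
2× / 1× / 0.1× weighting. Optimisation is Adam (β₁ 0.9, β₂ 0.999) with
per-epoch inverse-time decay lr_e = lr₀/(1 + 0.0001·e), per-epoch seeded
reshuffling, and global gradient-norm clipping at 5 (an addition: long
sequences occasionally spike gradients). Forward, backpropagation through
time, batch-norm and Adam state are float64 numpy; training is
bit-reproducible given a seed, and the backward pass is verified against
finite differences in the test suite.

Checkpointing keeps the parameters with the lowest validation weighted
loss (ties → earliest epoch). Validation accuracy is logged in two
bookkeepings — over all timesteps including padding (inflated, since
padding is trivial to classify) and over outcome-defined timesteps only —
but neither drives checkpoint selection: under a signal-free cohort
accuracy degenerates to the majority rate for every epoch, while
validation loss still identifies the calibrated, non-overfit model.

Inference runs with dropout off and batch norm on running statistics, so
predictions are deterministic and causal: ŷ⁽ᵗ⁾ is a function of
x⁽¹⁾…x⁽ᵗ⁾ alone, and appending padding never changes earlier outputs
(both properties are asserted bitwise in tests). The scalar survival
probability is the softmax mass on the Survival-positive class.

## Evaluation

All metrics treat one non-padded, outcome-defined visit as one
observation. ROC-AUC uses the rank (Mann–Whitney) statistic with ties
counting ½; the best cut-off maximises Youden's J with ties resolved
toward the lower threshold. The 95% CI resamples *patients* (cluster
bootstrap), because visits within a patient are strongly dependent and a
visit-level bootstrap understates variance; a visit-level mode exists for
comparison. Calibration uses ten half-open bins [0, 0.1), …, [0.9, 1.0]
(1.0 closed into the top bin); empty bins are reported with n = 0. The
Brier score is the plain mean squared error of the survival probability
against the binary outcome. Per-stratum AUC flags strata lacking a class
as undefined rather than dropping them.

## Synthetic cohorts

The generator emulates: multiple note types, irregular visit gaps
(log-normal days, median ≈ 13, with 5% same-day second notes), a wide
spread of visits per patient, ~62% patient mortality with ~80%
Survival-positive visit prevalence, a small censored fraction, and a
plantable textual signal — notes within the horizon of death contain, with
probability `signal_strength`, a fatal surface form ("hospice", "comfort
care", "unresponsive", …) embedded at a random position in an otherwise
benign sentence. All fatal surfaces map to controlled terms in the bundled
dictionary, so the signal survives condensation and mapping. Benign text
is template filler plus benign dictionary surfaces; at `signal_strength=0`
note text is exactly outcome-independent.

Patient histories follow a two-state benign/terminal Markov chain whose
three per-visit rates (benign→terminal h, survivor-stop s, terminal-exit
e) are solved in closed form from the targets: with q = 1/mean_visits and
f = 1 − positive fraction, e = death_rate·q/f, h = f(e−q)/(1−f), s = q−h.
The chain starts from its quasi-stationary distribution, which makes
P(within-horizon | visit index) *constant at every index* — the design
property that makes a no-signal cohort a genuine null for any sequence
classifier. Two refinements keep that property exact: the two-visit
minimum would tilt the first visit's phase distribution, so the first
step uses compensated dynamics (terminal starts always receive a
follow-up visit; benign starts that are not single-visit survivor-stops
receive a benign second visit; start probability ρ_T = R(1−s)/(1+R(1−s))
with R = h/(e−q)); and keeping the most recent `max_len` visits would
end-align dying patients' windows, so the bundled studies cap generation
at the window length (`{'mean': 8, 'max': 20}` with `max_len = 20`),
which is distortion-free for a memoryless chain. Measured at n = 12 000,
the within-horizon rate is 0.197–0.215 at every index and the
best-possible position-only classifier scores AUC 0.499. Truncation
itself (cap 1200, window 1000) is exercised in unit tests.

What the generator does **not** emulate: real clinical language (notes are
token soup around dictionary surfaces), heavy-tailed visit counts (the
memoryless chain gives geometric counts; a heavy tail combined with
end-of-life clustering makes the visit index genuinely prognostic, which
would confound the null study), section structure, multi-note semantics,
or realistic censoring mechanisms. Passing the planted-signal study
therefore shows the pipeline's plumbing and learning dynamics are correct;
it says nothing about performance on real EMR text.

## Study conditions and sizes

The bundled signal-recovery study uses 500 patients (≈ 4000 visits),
embedding dimension 32, window 5, 2 embedding epochs, 20-visit sequences,
30 training epochs, and a 0.5 / 0.1 / 0.4 train/validation/test split —
the large test fraction keeps the patient-clustered AUC estimate tight.
With the signal planted at rate 1 the held-out AUC exceeds 0.95 (typically
≈ 0.99); with no signal it sits within noise of 0.5. The CLI determinism
study runs a 60-patient chain twice and compares prediction files
byte-for-byte.

## Known limitations

* The condenser has no sentence segmentation, section detection or
  spelling correction; dates in unusual formats pass through unchanged.
* Multi-word dictionary surfaces spanning a collocation-merge boundary
  other than the exact merged pair are missed.
* The batch-norm layer shares statistics across timesteps; per-timestep
  statistics would break causality in training-mode forward passes and
  are not implemented.
* Embedding training is deterministic only in the bundled single-worker
  mode; there is no parallel mode.
* The cluster bootstrap assumes patients are exchangeable; stratified or
  temporal resampling is out of scope.
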