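"""Synthetic longitudinal clinical-note cohort generator.

Real metastatic-cancer EMR corpora are private, so every downstream
stage is exercised on synthetic cohorts with known ground truth. The
generator emulates the gross shape of such a cohort:

* a wide spread of visits-per-patient counts and irregular gaps between
  visits (log-normal days), with occasional same-day second notes;
* several note types (oncology, radiology, inpatient, discharge);
* a death rate of 62% placed so that roughly 20% of visit labels fall
  inside the 3-month horizon (~80% Survival-positive prevalence);
* a *plantable* textual signal: notes within the horizon of death carry
  a fatal-signal phrase with probability ``signal_strength``. The
  phrases contain dictionary surface forms ("hospice", "comfort care",
  "unresponsive"), so the semantic mapper fires on them and the signal
  is recoverable end-to-end. At ``signal_strength = 0`` the text is
  independent of outcome and any predictor can only reach chance.

Each patient's visit history is a two-state Markov chain — a *benign*
phase followed (for dying patients) by a *terminal* phase whose visits
all fall inside the survival horizon — started from the chain's
quasi-stationary distribution. Memorylessness matters: it makes
P(within-horizon | visit index) constant across the sequence, so the
visit position itself carries no outcome information and a no-signal
cohort is a genuine null for the classifier. The three chain rates are
solved in closed form from (mean visits, positive-label fraction, death
rate): with q = 1/mean_visits and f = 1 - positive fraction, the
terminal exit rate is e = death_rate*q/f, the benign->terminal rate
h = f*(e-q)/(1-f), and the survivor-stop rate s = q-h.

Labels are never stored: they are recomputed from death/follow-up dates
by the dataset stage, which keeps the labelling rule in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .io import OutcomeRecord, VisitNote

__all__ = ["CohortConfig", "VocabPools", "ConfigError", "generate_cohort", "cohort_stats"]

HORIZON_DAYS = 91        # ">3 months" survival horizon used to place deaths
SIGNAL_WINDOW_DAYS = 91  # fatal phrases may appear this close to death (the
                         # label horizon, so every within-horizon visit is eligible)
MAX_DEATH_OFFSET = 85    # death at most this long after the last visit (< signal window)


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the field."""


_BENIGN = (
    "patient seen clinic today follow visit exam unremarkable vitals "
    "reviewed imaging labs ordered continue current plan discussed margins "
    "course tolerated well appetite weight unchanged performance status "
    "ambulating independently reports mild intermittent headache resolved "
    "chest abdomen pelvis contrast study routine surveillance interval "
    "oncologist recommends monitoring repeat assessment scheduled counts "
    "hemoglobin platelets creatinine within normal limits examination "
    "alert oriented cooperative breathing comfortably extremities edema"
).split()

# Benign dictionary surface forms: these map to controlled terms but do
# not predict death. Kept disjoint from the fatal pool.
_BENIGN_SURFACES = [
    "no", "not", "absent", "denies", "mother", "brother", "wife", "sister",
    "suspicion", "probable", "possible", "likely", "increase", "decrease",
    "stable", "diffuse", "lesion", "mass", "nodule", "metastasis",
    "metastatic", "carcinoma", "chemotherapy", "radiation", "pain",
    "fatigue", "nausea", "family history", "ruled out", "bone metastasis",
]

# Fatal-signal surfaces: each maps to HOSPICE or DETERIORATION in the
# fixture dictionary. They are embedded in otherwise benign sentences at
# random positions so no fixed template bigram dominates the collocation
# statistics.
_FATAL_SURFACES = [
    "hospice", "comfort care", "comfort measures", "unresponsive",
    "rapid decline", "multiorgan failure", "agonal", "moribund",
]


@dataclass
class VocabPools:
    benign: list[str] = field(default_factory=lambda: list(_BENIGN))
    benign_surfaces: list[str] = field(default_factory=lambda: list(_BENIGN_SURFACES))
    fatal_surfaces: list[str] = field(default_factory=lambda: list(_FATAL_SURFACES))


@dataclass
class CohortConfig:
    n_patients: int = 200
    visits_per_patient_law: dict = field(
        default_factory=lambda: {"mean": 8.0, "max": 1200}
    )
    note_types: list[str] = field(
        default_factory=lambda: ["oncology", "radiology", "inpatient", "discharge"]
    )
    visit_gap_days_law: dict = field(default_factory=lambda: {"mu": 2.6, "sigma": 0.9})
    vocab: VocabPools = field(default_factory=VocabPools)
    signal_strength: float = 1.0
    positive_fraction_target: float = 0.8
    death_rate: float = 0.62
    censor_prob: float = 0.05    # survivors with follow-up inside the horizon
    same_day_prob: float = 0.05  # chance a visit repeats the previous date
    start_date: date = date(2015, 1, 1)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for name in ("signal_strength", "positive_fraction_target", "death_rate",
                     "censor_prob", "same_day_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.positive_fraction_target < 1.0:
            raise ConfigError("positive_fraction_target must be in (0, 1)")
        if self.visit_gap_days_law.get("sigma", 1.0) <= 0:
            raise ConfigError("visit_gap_days_law: sigma must be > 0")
        if self.visits_per_patient_law.get("mean", 7.0) < 2.5:
            raise ConfigError("visits_per_patient_law: mean must be >= 2.5")
        if self.visits_per_patient_law.get("max", 1200) < 2:
            raise ConfigError("visits_per_patient_law: max must be >= 2")
        if not self.note_types:
            raise ConfigError("note_types must be nonempty")
        self.chain_rates()  # raises if targets are incompatible

    def chain_rates(self) -> tuple[float, float, float]:
        """(h, s, e): benign->terminal, survivor-stop, and terminal-exit
        per-visit rates solving the calibration targets in closed form."""
        q = 1.0 / self.visits_per_patient_law.get("mean", 7.0)
        f = 1.0 - self.positive_fraction_target
        e = self.death_rate * q / f
        if not q < e < 1.0:
            raise ConfigError(
                "death_rate/positive_fraction_target/mean visits are "
                f"incompatible (terminal exit rate {e:.3f} not in (1/mean, 1))"
            )
        h = f * (e - q) / (1.0 - f)
        s = q - h
        if s <= 0:
            raise ConfigError("calibration gives non-positive survivor-stop rate")
        return h, s, e


def _date_mention(rng: np.random.Generator, visit_date: date) -> str:
    d = visit_date - timedelta(days=int(rng.integers(1, 400)))
    style = rng.integers(0, 3)
    if style == 0:
        return d.isoformat()
    if style == 1:
        return f"{d.month:02d}/{d.day:02d}/{d.year}"
    return d.strftime("%B ") + f"{d.day}, {d.year}"


def _note_text(rng: np.random.Generator, vocab: VocabPools, visit_date: date,
               fatal: bool) -> str:
    sentences = []
    n_sent = int(rng.integers(3, 7))
    for _ in range(n_sent):
        words = list(rng.choice(vocab.benign, size=int(rng.integers(4, 9))))
        if rng.random() < 0.25:
            words.insert(int(rng.integers(0, len(words))), str(int(rng.integers(1, 40))))
        if rng.random() < 0.15:
            words.append("on " + _date_mention(rng, visit_date))
        sentences.append(" ".join(words))
    # every note carries at least one dictionary surface so its vector is
    # never all-zeros (zero is reserved for padding downstream)
    n_surf = 1 + int(rng.integers(0, 3))
    for surf in rng.choice(vocab.benign_surfaces, size=n_surf):
        k = int(rng.integers(0, len(sentences)))
        words = sentences[k].split(" ")
        words.insert(int(rng.integers(0, len(words) + 1)), surf)
        sentences[k] = " ".join(words)
    if fatal:
        words = list(rng.choice(vocab.benign, size=int(rng.integers(4, 8))))
        for surf in rng.choice(vocab.fatal_surfaces, size=1 + int(rng.integers(0, 2))):
            words.insert(int(rng.integers(0, len(words) + 1)), str(surf))
        sentences.append(" ".join(words))
    return ". ".join(sentences) + "."


def _benign_gap(rng: np.random.Generator, law: dict, same_day_prob: float) -> int:
    if rng.random() < same_day_prob:
        return 0
    x = rng.lognormal(mean=law.get("mu", 2.6), sigma=law.get("sigma", 0.9))
    return int(min(max(int(round(x)), 1), 3650))


def _simulate_phases(
    rng: np.random.Generator, h: float, s: float, e: float, vmax: int
) -> tuple[int, int]:
    """(benign visit count, terminal visit count) for one patient.

    The phase sequence follows the benign/terminal chain of the module
    docstring with two modified *first-step* rules that keep
    P(terminal | visit index) exactly flat in the two-visit-minimum
    cohort:

    * a terminal-start patient always gets one follow-up visit (the
      first terminal visit never exits), and the start probability of
      the terminal state is rho_T = R(1-s) / (1 + R(1-s)) with
      R = pi_T/pi_B = h/(e-q) — the compensation for the survival tilt
      that conditioning on >= 2 visits would otherwise introduce;
    * a benign-start patient who is not a single-visit survivor-stop
      (those are redrawn by the caller) gets a benign second visit.

    With these rules the state distribution at every visit index is the
    chain's quasi-stationary pi, so the visit position carries no
    outcome information. From the second transition onward the chain is
    the unmodified (h, s, e) process.
    """
    q = h + s
    ratio = h / (e - q)                      # pi_T / pi_B
    rho_t = ratio * (1 - s) / (1 + ratio * (1 - s))

    def extend(state_terminal: bool, a: int, m: int) -> tuple[int, int]:
        while a + m < vmax and m < HORIZON_DAYS:
            if state_terminal:
                if rng.random() < e:
                    break
                m += 1
            else:
                u = rng.random()
                if u < s:
                    break
                if u < s + h:
                    state_terminal = True
                    m += 1
                else:
                    a += 1
        return a, m

    if rng.random() < rho_t:
        return extend(True, 0, 2)    # visit 0 terminal, follow-up guaranteed
    if rng.random() < s:
        return 1, 0                  # single-visit survivor -> caller redraws
    return extend(False, 2, 0)       # visits 0 and 1 benign


def generate_cohort(config: CohortConfig) -> tuple[list[VisitNote], list[OutcomeRecord]]:
    """Generate a cohort of visit notes plus per-patient outcome records.

    Deterministic given ``config.seed``. Patients whose simulated history
    has fewer than 2 visits are excluded and redrawn (the cohort analogue
    of dropping single-visit patients). See the module docstring for the
    cohort shape being emulated.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, s, e = config.chain_rates()
    vmax = int(config.visits_per_patient_law.get("max", 1200))

    notes: list[VisitNote] = []
    outcomes: list[OutcomeRecord] = []
    width = len(str(config.n_patients))
    for p in range(config.n_patients):
        pid = f"P{p:0{width}d}"
        a = m = 0
        while a + m < 2:  # exclusion of <2-visit patients, by redraw
            a, m = _simulate_phases(rng, h, s, e, vmax)
        start = config.start_date + timedelta(days=int(rng.integers(0, 365)))

        benign_dates = [start]
        for _ in range(a - 1):
            benign_dates.append(
                benign_dates[-1]
                + timedelta(days=_benign_gap(rng, config.visit_gap_days_law,
                                             config.same_day_prob))
            )
        if a == 0:
            benign_dates = []

        death: date | None = None
        terminal_dates: list[date] = []
        if m > 0:
            # terminal visits and death all inside one horizon window
            gaps = [0 if rng.random() < config.same_day_prob
                    else int(rng.integers(1, 11)) for _ in range(m - 1)]
            offset = int(rng.integers(1, MAX_DEATH_OFFSET + 1))
            while sum(gaps) + offset > HORIZON_DAYS:
                if offset > 1:
                    offset = max(1, offset - 10)
                else:
                    gaps = [min(g, 1) for g in gaps]
                    offset = 1
                    break
            span = sum(gaps) + offset
            if benign_dates:
                lead = max(_benign_gap(rng, config.visit_gap_days_law, 0.0),
                           HORIZON_DAYS + 1 - span)
                first_terminal = benign_dates[-1] + timedelta(days=lead)
            else:
                first_terminal = start
            terminal_dates = [first_terminal]
            for g in gaps:
                terminal_dates.append(terminal_dates[-1] + timedelta(days=g))
            death = terminal_dates[-1] + timedelta(days=offset)

        dates = benign_dates + terminal_dates
        if death is not None:
            followup = death
        elif rng.random() < config.censor_prob:
            followup = dates[-1] + timedelta(days=int(rng.integers(10, HORIZON_DAYS)))
        else:
            followup = dates[-1] + timedelta(days=int(rng.integers(120, 420)))
        outcomes.append(OutcomeRecord(pid, death, followup))

        for j, d in enumerate(dates):
            fatal = (
                death is not None
                and (death - d).days <= SIGNAL_WINDOW_DAYS
                and rng.random() < config.signal_strength
            )
            notes.append(
                VisitNote(
                    patient_id=pid,
                    note_id=f"{pid}-n{j:04d}",
                    visit_date=d,
                    note_type=str(rng.choice(config.note_types)),
                    text=_note_text(rng, config.vocab, d, fatal),
                )
            )
    return notes, outcomes


def cohort_stats(notes: list[VisitNote], outcomes: list[OutcomeRecord]) -> dict:
    """Exact corpus summary: patient/visit counts, label counts, and the
    visits-per-patient histogram (histogram values sum to n patients)."""
    if not notes:
        raise ValueError("cohort_stats: empty corpus")
    from .dataset import LabelPolicy, label_visit

    by_patient: dict[str, int] = {}
    for n in notes:
        by_patient[n.patient_id] = by_patient.get(n.patient_id, 0) + 1
    outcome_by_pid = {o.patient_id: o for o in outcomes}
    policy = LabelPolicy()
    label_counts = {"POS": 0, "NEG": 0, "UNDEFINED": 0}
    for n in notes:
        label_counts[label_visit(n.visit_date, outcome_by_pid[n.patient_id], policy)] += 1
    hist: dict[int, int] = {}
    for cnt in by_patient.values():
        hist[cnt] = hist.get(cnt, 0) + 1
    return {
        "n_patients": len(by_patient),
        "n_visits": len(notes),
        "n_died": sum(1 for o in outcomes if o.death_date is not None),
        "label_counts": label_counts,
        "visits_per_patient_hist": dict(sorted(hist.items())),
    }
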