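"""Generate a synthetic longitudinal clinical-note cohort and summarise it.

The generator produces JSON-lines visit notes plus per-patient outcome
records (death or last-follow-up dates). Patient histories follow a
memoryless benign/terminal process calibrated so that ~80% of visit
labels are Survival-positive (>3-month survival) and ~60% of patients
die, and notes within 3 months of death carry a fatal-signal phrase.
"""

from prognote import CohortConfig, cohort_stats, generate_cohort

config = CohortConfig(n_patients=100, seed=42, signal_strength=1.0)
notes, outcomes = generate_cohort(config)
stats = cohort_stats(notes, outcomes)

print(f"patients: {stats['n_patients']}, visits: {stats['n_visits']}, "
      f"died: {stats['n_died']}")
print("visit labels:", stats["label_counts"])
pos, neg = stats["label_counts"]["POS"], stats["label_counts"]["NEG"]
print(f"positive-label fraction: {pos / (pos + neg):.3f} "
      "(target 0.80; POS = survived >3 months past the visit)")
print("\nfirst note of the first patient:")
print(" ", notes[0].note_id, notes[0].visit_date, notes[0].note_type)
print(" ", notes[0].text[:160], "...")
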