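"""Render a per-patient explanation report.

For one held-out patient the report shows the predicted survival
probability at every visit against the true labels, and each visit
expands into its "core findings": dictionary hits highlighted inside a
±5-word window of the original note text.
"""

from pathlib import Path

from prognote import CohortConfig, build_summary, predict
from prognote.explain import write_reports
from prognote.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(
    cohort=CohortConfig(n_patients=120, seed=4, signal_strength=1.0),
    embed_dim=16, embed_window=4, embed_epochs=1,
    max_len=15, epochs=10, n_boot=0, seed=4,
))

# pick a held-out patient who died (their curve should drop near the end)
test_seqs = result.splits["test"]
preds = predict(test_seqs, result.model)
chosen = next(p for p in preds if (p.labels == 1).any())  # has NEG visits

summary = build_summary(chosen, result.notes, result.mapped, result.dictionary)
out = Path("scratch/reports")
write_reports([summary], out)

print(f"patient {summary.patient_id}: {len(summary.curve)} visits")
for point in summary.curve:
    terms = {f.controlled_term for f in point.findings}
    print(f"  visit {point.visit_index} {point.visit_date} p_surv={point.p_surv:.2f} "
          f"truth={point.true_label} findings={sorted(terms)[:4]}")
print(f"\nreport written to {out / (summary.patient_id + '.html')}")
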