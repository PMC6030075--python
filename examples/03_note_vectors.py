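"""Train skip-gram embeddings and build context-aware note vectors.

A note's vector is the mean over its controlled-term occurrences of the
mean embedding inside each occurrence's context window — notes about
similar clinical content land near each other, and a note with no
controlled terms gets the all-zeros vector (reserved for padding).
"""

import numpy as np

from prognote import (
    CohortConfig,
    bundled_dictionary_path,
    generate_cohort,
    load_dictionary,
    note_vector,
    train_embeddings,
)
from prognote.pipeline import prepare_mapped_notes

notes, _ = generate_cohort(CohortConfig(n_patients=80, seed=0))
dictionary = load_dictionary(bundled_dictionary_path())
mapped, _ = prepare_mapped_notes(notes, dictionary)

model = train_embeddings(list(mapped.values()), dim=32, window=5,
                         min_token_count=5, seed=0, epochs=2)
print(f"vocabulary: {len(model.vocab)} tokens, dimension {model.dim}")

nv = note_vector(mapped[notes[0].note_id], model, cwindow=15)
print(f"\nnote {nv.note_id}: {nv.n_cterms} controlled-term occurrences, "
      f"|v_note| = {np.linalg.norm(nv.vector):.3f}")

# nearest controlled terms to HOSPICE in embedding space
if "HOSPICE" in model.vocab:
    v = model["HOSPICE"]
    sims = {
        tok: float(model[tok] @ v / (np.linalg.norm(model[tok]) * np.linalg.norm(v)))
        for tok in model.vocab if tok.isupper() and tok != "HOSPICE"
    }
    top = sorted(sims, key=sims.get, reverse=True)[:3]
    print("controlled terms closest to HOSPICE:",
          [(t, round(sims[t], 2)) for t in top])
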