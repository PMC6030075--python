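"""Condense a raw clinical note and map it onto controlled terms.

Condensing lowercases, drops stopwords, stems, converts numbers to
words and inline dates to visit-relative tokens. The semantic
dictionary then collapses synonym families ("no" -> NEGEX, "probable"
-> RISK), shrinking the vocabulary the embedding has to learn.
"""

from datetime import date

from prognote import bundled_dictionary_path, condense, load_dictionary, map_terms

text = ("The patient has 2 new lesions since the scan on 2015-03-01. "
        "Probable bone metastasis; mother had breast carcinoma. "
        "No evidence of progression elsewhere.")
visit = date(2015, 6, 1)

condensed = condense(text, visit, note_id="demo")
print("condensed tokens:")
print(" ", condensed.tokens)

dictionary = load_dictionary(bundled_dictionary_path())
mapped = map_terms(condensed, dictionary)
print("\nafter dictionary mapping (uppercase = controlled term):")
print(" ", mapped.tokens)
print("\nmapped positions (index, originating surface form):")
for pos, surface in mapped.mapped_positions:
    print(f"  {pos:2d}  {surface!r} -> {mapped.tokens[pos]}")
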