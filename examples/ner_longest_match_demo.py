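"""Dictionary NER over a recommendation sentence.

Shows token-boundary anchoring (no hit inside longer words),
leftmost-longest resolution ("beta blockers" beats "beta"), and
case-insensitive matching.
"""

from guidelink import DrugTerm, build_vocabulary, find_mentions_in_text, normalize_term

entries = [
    ("digoxin", ("C01AA05",), False),
    ("diuretics", ("C03",), True),
    ("ACE inhibitors", ("C09A",), True),
    ("beta", (), True),            # deliberately shadowed by the longer key
    ("beta blockers", ("C07",), True),
]
terms = [
    DrugTerm(surface=s, normalized=normalize_term(s), concept_id=f"ATC:{i}",
             source="ATC", atc_codes=codes, is_class=is_class)
    for i, (s, codes, is_class) in enumerate(entries)
]
vocab = build_vocabulary([terms])

text = ("Digoxin only for patients who remain symptomatic despite "
        "diuretics, ACE inhibitors and beta blockers")
for m in find_mentions_in_text("guideline-1", text, vocab):
    kind = "class" if m.is_class else "drug "
    print(f"[{m.start:3d},{m.end:3d}) {kind}  {m.surface!r} -> {m.matched_key}")
# Four mentions: one drug name (digoxin) and three class names; "beta"
# alone never fires because the longer "beta blockers" wins the span.
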