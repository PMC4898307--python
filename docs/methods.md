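# Methods

## Problem and data model

The pipeline compares two corpus-derived sets of drug–disease
associations for a fixed list of chronic conditions:

- **CPG associations**: a drug name or drug-class name mentioned at
  least once in a guideline summary's Major Recommendations section,
  for every condition the guideline is tagged with. Mention frequency
  beyond "at least once" is retained only as provenance; associations
  are binary.
- **SPL associations**: a condition whose concept identifiers (CUIs)
  intersect the indication CUIs of a product-label record. Labels of
  the same product collapse by normalized drug name, so the unit is
  the drug, not the label.

Conditions are defined by ICD-9 code sets crosswalked to CUIs; the
crosswalk is consumed as a file, and codes missing from it are
reported, never silently dropped. Guideline exclusions (exclusively
pediatric or pregnancy populations, off-target diagnoses, expert
commentaries) are consumed as precomputed metadata flags, since such
judgments are manual review, not text mining. A guideline tagged for
several conditions contributes to each independently.

## Vocabulary

Terminology sources (ATC, MeSH, NCIt, NDF-RT, ChEBI, …) are consumed
as flat TSV exports (`concept_id`, `surface`, optional `parent_id`,
`atc_code`, `is_class`); native OWL/OBO parsing is deliberately out of
scope because the method operates downstream of ontology
serialization. Per-source root restrictions (e.g. keeping only terms
under "organic chemicals") are applied by transitive `parent_id`
reachability; a cycle in parent links is an error.

Normalization of a surface form: lower-case, drop bracket characters
while keeping their content, collapse whitespace, strip punctuation at
token edges, keep internal hyphens and slashes. This maps
"Angiotensin-converting enzyme (ACE) inhibitors" to
"angiotensin-converting enzyme ace inhibitors" and is idempotent.
Unique-term counting is by normalized key pooled over sources — the
deduplication convention is a design choice, documented here because
cross-source counting conventions differ between resources.

The stoplist defaults to **empty**: common-word false positives (e.g.
"oxygen", "glucose") are a real property of dictionary NER over
clinical text and should be observable by default; callers can supply
a stoplist file to suppress them.

## Dictionary NER

Matching is case-insensitive, anchored at token boundaries
(alphanumeric/non-alphanumeric transitions; hyphens and slashes are
token-internal), and resolved leftmost-longest without overlaps:
scanning token positions left to right, the longest key starting at
the position wins and scanning resumes after it. A candidate span is
accepted only if the *slice itself* normalizes to the key, which lets
bracketed synonyms ("(ACE)") match while rejecting spans whose
intervening punctuation survives normalization (internal periods in
numbers, for instance). There is no sentence segmentation, negation
or context handling, no abbreviation expansion, and no minimum term
length; these are known limitations of the approach, not of the
implementation. Whether matching should be case-sensitive or allow
overlaps is genuinely open; the choices here (insensitive,
non-overlapping) are conventional and isolated in one function for
sensitivity analysis.

## ATC model and overlap partitioning

ATC codes encode their lineage by prefix; level is a function of
length (1→1, 3→2, 4→3, 5→4, 7→5). Ancestry is therefore computed
from code shape rather than an edge list, and `atc_ancestors` is just
prefix truncation at the valid lengths. Two same-condition
associations *match taxonomically* when their keys are equal, any
codes are equal, or one code is a proper prefix-ancestor of another —
multi-axial drugs match if **any** of their codes match. Siblings
(distinct level-5 codes under one level-4 parent) are *similar*: they
are reported separately and never merged, because shared class
membership is weaker evidence of the same recommendation than an
identity or ancestor relation.

Merged groups under taxonomy are the connected components of the
per-condition graph whose edges are **cross-corpus** matches; a CPG
class association linked to two SPL sibling drugs therefore forms one
shared group (the transitive-closure effect), while two same-side
associations merge only through a common opposite-side partner. Each
component is represented by all members carrying a code of the
maximal level present — "most specific" is ambiguous when several
level-5 members exist, so all of them are reported. Associations
without ATC codes participate by exact key equality and are flagged
in the partition output. The partition invariants — disjointness,
counts summing to the number of merged groups, taxonomy never
increasing the group count, exact "both" membership surviving into
taxonomic "both" — are asserted in tests on every random instance.

The raw per-side unique association counts and the partition sums are
reported side by side and are not forced to agree; published corpus
statistics of this design show small discrepancies between the two,
and the report deliberately preserves both numbers.

## Evaluation

Predicted mentions are scored against span-based standoff annotations
(TextAE-style JSON or TSV) as micro-averaged precision, recall and
F = 2PR/(P+R), with zero-denominator cases defined as 0. Span
matching is one-to-one and greedy by position; the default criterion
is exact boundaries, with a character-overlap mode for sensitivity
checks since the stricter criterion may understate dictionary quality
when boundaries differ by a token. The drug-name/drug-class label is
ignored in matching because both are annotated and scored jointly.
Reference forms absent from the dictionary count as false negatives —
the evaluation measures the dictionary, not an idealized matcher.
Terminologies are ranked by precision (ties by F, then name); the
top-ranked terminology's taxonomy drives class/name matching. Note
that for a published five-terminology comparison of this kind, one
printed F value (precision 0.31, recall 0.32, F 0.32) is not the
rounded harmonic mean of its printed precision/recall (0.31); the
consistency checks here cover only the rows where the harmonic mean
reproduces the printed value.

## Synthetic-data generator

The generator emulates every pipeline input with known ground truth:
a formulary of level-4 classes (default 8) each holding level-5 drugs
(default 3) under freshly drawn ATC-shaped codes; 15 conditions
(matching the chronic-condition panel size the pipeline targets) with
two ICD-9 codes and two CUIs each; 5 guidelines per condition; and a
label file with one record per planted label-side association (~30%
resolving ATC codes through the lookup table rather than inline).
Each (drug, condition) pair drawn for planting receives a fate —
both / CPG-only / SPL-only with default probabilities 0.15/0.60/0.25,
chosen to echo the imbalance observed between guideline-only,
label-only and shared associations in real guideline/label overlap
studies. With probability `p_class_mention` (default 0.30) a
guideline voices the recommendation as the drug's **class** name; this
is the mechanism that makes taxonomy matter, mirroring the
ACE-inhibitor/lisinopril situation, since a class surface never
string-matches a drug name but always taxonomically matches its
members.

Texts are assembled from a fixed filler-sentence pool with planted
surfaces (random case variants) inserted at tracked offsets, plus
distractor terms guaranteed disjoint from the vocabulary; flagged
decoy documents exercise the exclusion logic. Expected partitions are
derived **analytically from the generator's bookkeeping** (a direct
transitive closure over planted cross-side pairs), never by invoking
the pipeline, so end-to-end recovery tests are non-circular. The
generator does not simulate misspellings, OCR noise, negated or
historical contexts, synonym variation beyond case, or guideline texts
mentioning drugs it did not plant — so perfect NER precision/recall on
synthetic corpora demonstrates correctness of the matcher and
bookkeeping, not expected performance on real clinical prose, where
dictionary NER of this design shows substantially lower recall.

## Numerical and scale choices

Everything is exact set/string computation; there is no optimization
or floating-point sensitivity beyond the metric divisions. Ties in
vocabulary ranking break by F then name; group ordering in reports is
lexicographic by member keys for determinism. The test suite and the
acceptance script run synthetic studies at 20 conditions × 50 planted
associations × 5 seeds (tests) or 1 seed (script), sizes at which the
brute-force oracles (transitive-closure partitioning, exhaustive span
enumeration) remain tractable while binomial fate fractions are
already tight; all randomness flows from a single integer seed.

## Known limitations

- Association extraction is mention-level: no negation ("do not use X
  in..."), no strength-of-recommendation, no dosage context.
- ATC ancestry by prefix cannot represent the multi-parent relations
  some terminologies encode; an explicit hierarchy file can override
  ancestry only in the term-source filtering step, not in matching.
- Cross-condition matching (same drug, related conditions) is out of
  scope; partitions are strictly per condition.
- The SPL side trusts the supplied indication CUIs; no label text is
  parsed.
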