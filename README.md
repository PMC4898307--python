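# guidelink

Text-mining pipeline that asks whether evidence-based prescribing
guidance and regulatory drug approval point at the same medicines.
It extracts **drug–disease associations** from two corpora —

- **CPG side**: clinical-practice-guideline summaries, where an
  association is a drug name (or drug-class name) mentioned at least
  once in a guideline's Major Recommendations text for a condition;
- **SPL side**: structured-product-label indication records (a
  SIDER-like export), where an association is a target condition
  appearing among a label's indication concepts —

and measures their overlap with and without **ATC taxonomic matching**.
Guidelines tend to recommend classes ("ACE inhibitors – heart failure")
while labels name drugs ("lisinopril – heart failure"); exact string
comparison misses such pairs entirely. ATC codes encode their own
lineage (C03DA04 *eplerenone* sits under C03DA *aldosterone
antagonists*), so rolling codes up and down the hierarchy recovers
class/name matches that would otherwise look like disagreement.

The package is intended for informatics researchers comparing clinical
knowledge sources: it covers vocabulary compilation from terminology
exports, dictionary NER, association construction, taxonomic overlap
partitioning, NER evaluation against standoff annotations, and a
seeded synthetic-data generator with exact ground truth.

## Method

For a condition *c*, let `A_CPG(c)` and `A_SPL(c)` be the deduplicated
(drug key, condition) association sets from each corpus. Without
taxonomy, merged groups are exact key matches. With taxonomy, build a
graph on `A_CPG(c) ∪ A_SPL(c)` with an edge between a CPG and an SPL
association when their drug keys are equal, any ATC codes are equal,
or one code is a proper prefix-ancestor of the other (level lengths
1/3/4/5/7). Connected components are the merged groups, each reported
by its most specific member code(s), and partitioned into
**both** / **CPG-only** / **SPL-only** by which sides its members came
from. Sibling drugs sharing a level-4 parent are reported as
*similar* but never merged. Mentions are found by case-insensitive,
token-boundary-anchored, leftmost-longest dictionary matching;
NER quality is scored as micro-averaged precision, recall, and
F = 2PR/(P+R) against reference spans.

## Worked example

```bash
python examples/worked_example_taxonomic_overlap.py
```

prints

```
 exact strings: both=0  cpg_only=2  spl_only=1
 with taxonomy: both=1  cpg_only=1  spl_only=0
merged group members: ['aldosterone antagonists', 'eplerenone']
most specific representative: ['eplerenone']
```

On exact strings the class association *aldosterone antagonists –
ischemic heart disease* (guideline) and the drug association
*eplerenone – ischemic heart disease* (label) are disjoint; the C03DA →
C03DA04 ancestry merges them into one shared group, reported by the
most specific member. The vaccine association has no label-side
partner and stays CPG-only. The other examples demonstrate
leftmost-longest NER, per-terminology dictionary evaluation, and full
synthetic-bundle recovery (`examples/synthetic_end_to_end.py`).

A thin CLI mirrors the stages: `guidelink simulate`, `guidelink vocab`,
`guidelink run --config cfg.json`, `guidelink eval`.

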