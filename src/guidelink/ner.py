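"""Dictionary-based named entity recognition of drug names and classes.

Matching is case-insensitive, anchored at token boundaries (so "rat"
never fires inside "atorvastatin"), and resolved leftmost-longest
without overlaps: scanning left to right, at each token position the
longest vocabulary key wins and scanning resumes after it.  Hyphens
and slashes are token-internal, so multi-part names such as
"angiotensin-converting" match as single tokens.  No sentence
segmentation or negation handling is attempted.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import GuidelineSummary
from .vocabulary import DrugVocabulary, normalize_term
from .errors import InvalidTermError

__all__ = ["Mention", "find_mentions", "find_mentions_in_text", "unique_drug_keys",
           "mentions_to_tsv", "mentions_to_textae"]

# a token: alphanumeric run, possibly chained by internal hyphens/slashes
_TOKEN = re.compile(r"[0-9A-Za-z]+(?:[-/][0-9A-Za-z]+)*")


@dataclass(frozen=True)
class Mention:
    """One dictionary hit: a half-open [start, end) span in a document.

    ``surface`` is the exact text slice; ``matched_key`` its normalized
    form, present in the vocabulary index.  ``sources`` lists the
    terminologies containing the key; ``is_class`` is true when any
    matched term is a drug-class term.
    """

    doc_id: str
    start: int
    end: int
    surface: str
    matched_key: str
    sources: frozenset[str]
    is_class: bool


def find_mentions_in_text(doc_id: str, text: str, vocab: DrugVocabulary) -> list[Mention]:
    """Leftmost-longest non-overlapping dictionary matches in one text."""
    if not vocab.index:
        return []
    tokens = [(m.start(), m.end(), m.group().lower()) for m in _TOKEN.finditer(text)]
    max_len = max(key.count(" ") + 1 for key in vocab.index)
    mentions: list[Mention] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched_at = None
        for width in range(min(max_len, n - i), 0, -1):
            candidate = " ".join(tok for _, _, tok in tokens[i : i + width])
            if candidate not in vocab.index:
                continue
            start = tokens[i][0]
            end = tokens[i + width - 1][1]
            surface = text[start:end]
            # punctuation between tokens must normalize away for the
            # span to really carry this key (e.g. "(ACE)" does, "2.5"
            # in place of "2 5" does not)
            try:
                if normalize_term(surface) != candidate:
                    continue
            except InvalidTermError:
                continue
            terms = vocab.index[candidate]
            mentions.append(
                Mention(
                    doc_id=doc_id,
                    start=start,
                    end=end,
                    surface=surface,
                    matched_key=candidate,
                    sources=frozenset(t.source for t in terms),
                    is_class=any(t.is_class for t in terms),
                )
            )
            matched_at = i + width
            break
        i = matched_at if matched_at is not None else i + 1
    return mentions


def find_mentions(doc: GuidelineSummary, vocab: DrugVocabulary) -> list[Mention]:
    """Dictionary matches in a guideline's Major Recommendations text,
    sorted by start offset."""
    return find_mentions_in_text(doc.doc_id, doc.major_recommendations, vocab)


def unique_drug_keys(mentions: Iterable[Mention]) -> frozenset[str]:
    """Distinct normalized keys across a corpus' mentions."""
    return frozenset(m.matched_key for m in mentions)


def mentions_to_tsv(mentions: Sequence[Mention], path: str | Path) -> None:
    rows = [
        {
            "doc_id": m.doc_id,
            "start": m.start,
            "end": m.end,
            "surface": m.surface,
            "matched_key": m.matched_key,
            "sources": ";".join(sorted(m.sources)),
            "is_class": int(m.is_class),
        }
        for m in mentions
    ]
    pd.DataFrame(
        rows, columns=["doc_id", "start", "end", "surface", "matched_key", "sources", "is_class"]
    ).to_csv(path, sep="\t", index=False)


def mentions_to_textae(
    mentions: Sequence[Mention], texts: Mapping[str, str]
) -> dict[str, dict]:
    """Render mentions as TextAE-style standoff JSON, one object per doc.

    Each object carries the document text and a ``denotations`` list of
    ``{"id", "span": {"begin", "end"}, "obj"}`` entries, suitable for
    side-by-side viewing with reference annotations.
    """
    out: dict[str, dict] = {
        doc_id: {"sourceid": doc_id, "text": text, "denotations": []}
        for doc_id, text in texts.items()
    }
    counters: dict[str, int] = {}
    for m in sorted(mentions, key=lambda m: (m.doc_id, m.start)):
        counters[m.doc_id] = counters.get(m.doc_id, 0) + 1
        out[m.doc_id]["denotations"].append(
            {
                "id": f"T{counters[m.doc_id]}",
                "span": {"begin": m.start, "end": m.end},
                "obj": m.matched_key,
            }
        )
    return out
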