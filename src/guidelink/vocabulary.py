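"""Drug vocabulary compilation.

A comprehensive drug dictionary is assembled from several terminology
exports (ATC, MeSH, NCIt, NDF-RT, ChEBI, ...), each supplied as a flat
TSV with columns ``concept_id``, ``surface`` and optionally
``parent_id``, ``atc_code``, ``is_class``.  Per-source root-class
restrictions (e.g. keeping only MeSH terms under "organic chemicals")
are applied through the ``parent_id`` links.  All surface forms are
reduced to a normalized key used both for cross-source deduplication
and for dictionary matching in text.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    DuplicateEntryError,
    FormatError,
    HierarchyError,
    InvalidTermError,
)

__all__ = [
    "DrugTerm",
    "DrugVocabulary",
    "normalize_term",
    "load_term_source",
    "build_vocabulary",
]

_BRACKETS = re.compile(r"[()\[\]{}]")


def normalize_term(surface: str) -> str:
    """Reduce a surface form to its matching key.

    Lower-case, drop bracket characters (their content is kept as
    separate tokens), collapse whitespace runs, and strip punctuation
    from token edges.  Internal hyphens and slashes survive, so
    ``"Angiotensin-converting enzyme (ACE) inhibitors"`` becomes
    ``"angiotensin-converting enzyme ace inhibitors"``.  Idempotent.

    Raises
    ------
    InvalidTermError
        If the input is empty, whitespace-only, or punctuation-only.
    """
    if not surface or not surface.strip():
        raise InvalidTermError("empty or whitespace-only term")
    tokens = []
    for tok in _BRACKETS.sub(" ", surface.lower()).split():
        tok = tok.strip(string.punctuation)
        if tok:
            tokens.append(tok)
    if not tokens:
        raise InvalidTermError(f"term normalizes to nothing: {surface!r}")
    return " ".join(tokens)


@dataclass(frozen=True)
class DrugTerm:
    """One surface form from one terminology.

    ``atc_codes`` carries zero or more ATC codes attached to the
    concept; ``is_class`` marks drug-class (non-leaf) terms as opposed
    to specific drug names.  ``(concept_id, source)`` is unique within
    a vocabulary; the normalized key is not.
    """

    surface: str
    normalized: str
    concept_id: str
    source: str
    atc_codes: tuple[str, ...] = ()
    is_class: bool = False


_MANDATORY_COLUMNS = ("concept_id", "surface")
_TRUTHY = {"1", "true", "yes", "y", "t"}


def _descendants(parents: Mapping[str, str], roots: frozenset[str]) -> set[str]:
    """Concept ids that are a root or reachable from one via parent links."""
    keep: set[str] = set()
    for node in parents:
        chain = []
        seen: set[str] = set()
        current: str | None = node
        while current is not None and current not in keep and current not in roots:
            if current in seen:
                raise HierarchyError(f"cycle in parent_id links at {current!r}")
            seen.add(current)
            chain.append(current)
            current = parents.get(current) or None
        if current is not None:  # hit a root or an already-kept node
            keep.update(chain)
            keep.add(current)
    return keep


def load_term_source(
    path: str | Path,
    source: str,
    root_filter: Iterable[str] | None = None,
) -> list[DrugTerm]:
    """Read one terminology TSV, optionally restricted to subtrees.

    With ``root_filter``, only rows whose concept is one of the roots
    or a transitive ``parent_id`` descendant of one are kept.  ATC
    codes may be semicolon-joined in the ``atc_code`` column.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read term source {path}: {exc}") from exc
    missing = [c for c in _MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")

    if root_filter is not None:
        roots = frozenset(root_filter)
        parents = dict(
            zip(frame["concept_id"], frame.get("parent_id", pd.Series("", index=frame.index)))
        )
        keep = _descendants(parents, roots)
        frame = frame[frame["concept_id"].isin(keep)]

    terms: list[DrugTerm] = []
    for row in frame.itertuples(index=False):
        codes = tuple(
            c.strip().upper()
            for c in str(getattr(row, "atc_code", "")).split(";")
            if c.strip()
        )
        terms.append(
            DrugTerm(
                surface=row.surface,
                normalized=normalize_term(row.surface),
                concept_id=row.concept_id,
                source=source,
                atc_codes=codes,
                is_class=str(getattr(row, "is_class", "")).strip().lower() in _TRUTHY,
            )
        )
    return terms


@dataclass
class DrugVocabulary:
    """The compiled dictionary used for named entity recognition.

    ``index`` maps each non-stoplisted normalized key to the DrugTerms
    sharing it, pooled over all sources.
    """

    terms: list[DrugTerm]
    stoplist: frozenset[str] = frozenset()
    index: dict[str, list[DrugTerm]] = field(default_factory=dict)

    @property
    def keys(self) -> frozenset[str]:
        return frozenset(self.index)

    def source_counts(self) -> dict[str, int]:
        """Unique indexed keys per source terminology."""
        counts: dict[str, set[str]] = {}
        for key, terms in self.index.items():
            for term in terms:
                counts.setdefault(term.source, set()).add(key)
        return {src: len(keys) for src, keys in sorted(counts.items())}

    def atc_codes_for(self, key: str) -> tuple[str, ...]:
        """Union of ATC codes over all terms sharing a normalized key."""
        codes = {c for t in self.index.get(key, ()) for c in t.atc_codes}
        return tuple(sorted(codes))

    def restricted_to(self, sources: Iterable[str]) -> "DrugVocabulary":
        """A sub-vocabulary containing only the given terminologies."""
        wanted = frozenset(sources)
        return build_vocabulary(
            [[t for t in self.terms if t.source in wanted]], stoplist=self.stoplist
        )

    def write_tsv(self, path: str | Path, stats_path: str | Path | None = None) -> None:
        """Serialize the compiled vocabulary (plus a JSON stats sidecar)."""
        rows = [
            {
                "normalized": t.normalized,
                "surface": t.surface,
                "concept_id": t.concept_id,
                "source": t.source,
                "atc_codes": ";".join(t.atc_codes),
                "is_class": int(t.is_class),
            }
            for t in self.terms
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        if stats_path is not None:
            stats = {"total_unique_keys": len(self.index), "per_source": self.source_counts()}
            Path(stats_path).write_text(json.dumps(stats, indent=2))


def build_vocabulary(
    term_collections: Iterable[Sequence[DrugTerm]],
    stoplist: Iterable[str] = (),
) -> DrugVocabulary:
    """Union several per-source term collections into one vocabulary.

    Stoplisted normalized keys are kept in ``terms`` but excluded from
    the matching index.  The stoplist default is empty: common-word
    hits such as "oxygen" or "glucose" are deliberately reproducible
    unless a stoplist is supplied.

    Raises
    ------
    DuplicateEntryError
        If two rows share a (concept_id, source) pair.
    """
    stop = frozenset(stoplist)
    terms: list[DrugTerm] = []
    seen_ids: set[tuple[str, str]] = set()
    for collection in term_collections:
        for term in collection:
            ident = (term.concept_id, term.source)
            if ident in seen_ids:
                raise DuplicateEntryError(f"duplicate concept {ident}")
            seen_ids.add(ident)
            terms.append(term)
    index: dict[str, list[DrugTerm]] = {}
    for term in terms:
        if term.normalized in stop:
            continue
        index.setdefault(term.normalized, []).append(term)
    return DrugVocabulary(terms=terms, stoplist=stop, index=index)
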