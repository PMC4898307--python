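"""Drug-disease association sets from guidelines (CPG) and labels (SPL).

An association is binary evidence: a drug name (or class) mentioned at
least once in a guideline's recommendations for a condition, or a
condition appearing among a product label's indications.  Mention
frequency beyond "at least once" is kept only as provenance and never
weights an association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .corpus import ConditionDefinition, GuidelineSummary, SplRecord
from .errors import ConsistencyError
from .ner import Mention
from .vocabulary import normalize_term

__all__ = [
    "Association",
    "AssociationSet",
    "build_cpg_associations",
    "build_spl_associations",
]


@dataclass(frozen=True)
class Association:
    """A (drug key, condition) pair evidenced in one corpus.

    ``drug_key`` is a normalized drug term; ``atc_codes`` are the ATC
    codes assigned to it (possibly none).  ``provenance`` holds the
    supporting guideline doc_ids or label_ids and is never empty.
    """

    drug_key: str
    condition: str
    source: str  # "CPG" | "SPL"
    provenance: frozenset[str]
    atc_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.source not in ("CPG", "SPL"):
            raise ValueError(f"source must be CPG or SPL, got {self.source!r}")
        if not self.provenance:
            raise ValueError("association provenance may not be empty")


@dataclass
class AssociationSet:
    """Deduplicated associations from one side, partitioned by condition."""

    associations: tuple[Association, ...]
    side: str
    by_condition: dict[str, tuple[Association, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.by_condition:
            grouped: dict[str, list[Association]] = {}
            for assoc in self.associations:
                grouped.setdefault(assoc.condition, []).append(assoc)
            self.by_condition = {c: tuple(v) for c, v in sorted(grouped.items())}

    def __len__(self) -> int:
        return len(self.associations)

    def keys_for(self, condition: str) -> frozenset[str]:
        return frozenset(a.drug_key for a in self.by_condition.get(condition, ()))

    def write_csv(self, path: str | Path) -> None:
        rows = [
            {
                "drug_key": a.drug_key,
                "condition": a.condition,
                "source": a.source,
                "atc_codes": ";".join(a.atc_codes),
                "provenance": ";".join(sorted(a.provenance)),
            }
            for a in self.associations
        ]
        pd.DataFrame(rows, columns=["drug_key", "condition", "source", "atc_codes", "provenance"]).to_csv(
            path, index=False
        )


def _finalize(
    staged: dict[tuple[str, str], set[str]],
    side: str,
    codes: Mapping[str, tuple[str, ...]],
) -> AssociationSet:
    assocs = tuple(
        Association(
            drug_key=key,
            condition=cond,
            source=side,
            provenance=frozenset(prov),
            atc_codes=codes.get(key, ()),
        )
        for (key, cond), prov in sorted(staged.items())
    )
    return AssociationSet(associations=assocs, side=side)


def build_cpg_associations(
    selection: Mapping[str, Sequence[GuidelineSummary]],
    mentions: Mapping[str, Sequence[Mention]],
    atc_codes_for: Callable[[str], tuple[str, ...]] | None = None,
) -> AssociationSet:
    """Guideline-side associations: one per distinct mentioned key per
    condition, with the supporting guideline ids accumulated.

    ``atc_codes_for`` maps a normalized drug key to its ATC codes
    (typically ``DrugVocabulary.atc_codes_for``); without it the
    associations are left uncoded.

    Raises
    ------
    ConsistencyError
        If ``mentions`` contains a doc_id outside the selection.
    """
    selected_docs = {g.doc_id for docs in selection.values() for g in docs}
    stray = set(mentions) - selected_docs
    if stray:
        raise ConsistencyError(f"mentions for unselected documents: {sorted(stray)}")
    staged: dict[tuple[str, str], set[str]] = {}
    for condition, guidelines in selection.items():
        for guideline in guidelines:
            for mention in mentions.get(guideline.doc_id, ()):
                staged.setdefault((mention.matched_key, condition), set()).add(guideline.doc_id)
    codes = {}
    if atc_codes_for is not None:
        codes = {key: atc_codes_for(key) for key, _ in staged}
    return _finalize(staged, "CPG", codes)


def build_spl_associations(
    records: Iterable[SplRecord],
    conditions: Iterable[ConditionDefinition],
) -> AssociationSet:
    """Label-side associations: a record yields (drug, condition) for
    every condition whose CUI set intersects its indication CUIs.

    Drug keys are normalized drug names, so several labels of the same
    product collapse into one association per condition.
    """
    condition_list = list(conditions)
    staged: dict[tuple[str, str], set[str]] = {}
    codes: dict[str, set[str]] = {}
    for record in records:
        key = normalize_term(record.drug_name)
        codes.setdefault(key, set()).update(record.atc_codes)
        for cond in condition_list:
            if cond.cuis & record.indication_cuis:
                staged.setdefault((key, cond.name), set()).add(record.label_id)
    return _finalize(staged, "SPL", {k: tuple(sorted(v)) for k, v in codes.items()})
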