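"""Scoring predicted mentions against a manually annotated reference.

The reference standard is span-based standoff annotation (TextAE-style
JSON or a plain TSV): character offsets plus a drug_name / drug_class
label.  Metrics are micro-averaged precision, recall and F-measure.
The drug_name/drug_class label is ignored during matching because the
reference annotates both kinds and they are scored jointly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConsistencyError, FormatError
from .ner import Mention

__all__ = [
    "ReferenceAnnotation",
    "EvalResult",
    "match_spans",
    "compute_metrics",
    "f_from_pr",
    "rank_vocabularies",
    "load_textae_file",
    "load_textae_dir",
    "load_reference_tsv",
]


@dataclass(frozen=True)
class ReferenceAnnotation:
    """One manual annotation: a half-open [start, end) span with a label."""

    doc_id: str
    start: int
    end: int
    surface: str
    label: str  # "drug_name" | "drug_class"


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float


def load_textae_file(path: str | Path, doc_id: str | None = None) -> tuple[str, list[ReferenceAnnotation]]:
    """Read one TextAE-style JSON file -> (document text, annotations).

    The doc_id comes from the file's ``sourceid`` field, or the file
    stem when absent.  Denotation ``obj`` values are used as labels.
    """
    path = Path(path)
    raw = json.loads(path.read_text(encoding="utf-8"))
    if "text" not in raw or "denotations" not in raw:
        raise FormatError(f"{path}: TextAE file needs 'text' and 'denotations'")
    doc = doc_id or raw.get("sourceid") or path.stem
    text = raw["text"]
    annotations = [
        ReferenceAnnotation(
            doc_id=doc,
            start=d["span"]["begin"],
            end=d["span"]["end"],
            surface=text[d["span"]["begin"] : d["span"]["end"]],
            label=d.get("obj", "drug_name"),
        )
        for d in raw["denotations"]
    ]
    return text, annotations


def load_textae_dir(path: str | Path) -> tuple[dict[str, str], list[ReferenceAnnotation]]:
    """Read a directory of TextAE JSON files (one per document)."""
    texts: dict[str, str] = {}
    annotations: list[ReferenceAnnotation] = []
    for file in sorted(Path(path).glob("*.json")):
        text, anns = load_textae_file(file)
        doc = anns[0].doc_id if anns else file.stem
        texts[doc] = text
        annotations.extend(anns)
    return texts, annotations


def load_reference_tsv(path: str | Path) -> list[ReferenceAnnotation]:
    """Plain TSV alternative: doc_id, start, end, surface, label."""
    frame = pd.read_csv(path, sep="\t", dtype={"doc_id": str, "surface": str, "label": str})
    needed = {"doc_id", "start", "end", "surface", "label"}
    if not needed <= set(frame.columns):
        raise FormatError(f"{path}: needs columns {sorted(needed)}")
    return [
        ReferenceAnnotation(
            doc_id=r.doc_id, start=int(r.start), end=int(r.end), surface=r.surface, label=r.label
        )
        for r in frame.itertuples(index=False)
    ]


def match_spans(
    predicted: Sequence[Mention],
    reference: Sequence[ReferenceAnnotation],
    criterion: str = "exact",
) -> tuple[int, int, int]:
    """Count (tp, fp, fn) between predicted and reference spans.

    ``exact``: a prediction is a true positive iff a reference span
    with identical (doc_id, start, end) exists.  ``overlap``: iff the
    spans share at least one character.  Matching is greedy by
    position and one-to-one — each reference annotation can satisfy at
    most one prediction.  Unmatched predictions count as false
    positives, unmatched references as false negatives.

    Raises
    ------
    ConsistencyError
        If a prediction's doc_id does not occur among the reference
        annotations' documents (the reference defines the evaluated
        document set).
    """
    if criterion not in ("exact", "overlap"):
        raise ValueError(f"criterion must be 'exact' or 'overlap', got {criterion!r}")
    ref_docs = {r.doc_id for r in reference}
    stray = {p.doc_id for p in predicted} - ref_docs
    if stray and reference:
        raise ConsistencyError(f"predictions for documents outside the reference: {sorted(stray)}")

    refs = sorted(reference, key=lambda r: (r.doc_id, r.start, r.end))
    preds = sorted(predicted, key=lambda p: (p.doc_id, p.start, p.end))
    used = [False] * len(refs)
    tp = 0
    for pred in preds:
        for j, ref in enumerate(refs):
            if used[j] or ref.doc_id != pred.doc_id:
                continue
            if criterion == "exact":
                hit = (ref.start, ref.end) == (pred.start, pred.end)
            else:
                hit = ref.start < pred.end and pred.start < ref.end
            if hit:
                used[j] = True
                tp += 1
                break
    return tp, len(preds) - tp, len(refs) - tp


def compute_metrics(tp: int, fp: int, fn: int) -> EvalResult:
    """Precision, recall and F-measure, with zero-denominator cases
    defined as 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return EvalResult(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall,
        f_measure=f_from_pr(precision, recall),
    )


def f_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean F = 2PR/(P+R), 0 when both are 0."""
    return 2 * precision * recall / (precision + recall) if precision + recall else 0.0


def rank_vocabularies(results: Mapping[str, EvalResult]) -> list[tuple[str, EvalResult]]:
    """Order per-terminology results best precision first (ties broken
    by F-measure, then name).  The first entry is the terminology whose
    taxonomy should drive drug class/name matching."""
    if not results:
        raise ValueError("need at least one result to rank")
    return sorted(
        results.items(),
        key=lambda item: (-item[1].precision, -item[1].f_measure, item[0]),
    )


def metrics_table(results: Mapping[str, EvalResult]) -> pd.DataFrame:
    """Full-precision metrics table, ranked, for CSV export."""
    ranked = rank_vocabularies(results)
    return pd.DataFrame(
        [
            {
                "source": name,
                "tp": r.tp, "fp": r.fp, "fn": r.fn,
                "precision": r.precision, "recall": r.recall, "f_measure": r.f_measure,
            }
            for name, r in ranked
        ]
    )
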