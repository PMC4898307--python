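"""End-to-end orchestration: vocabulary -> corpus -> NER -> associations
-> taxonomy (-> evaluation), with all intermediate artifacts written out.

Every stage is a pure function of its inputs, so a rerun of the same
configuration reproduces the same report bit for bit (timestamps
aside).  Per-stage input/output counts are logged so runs on real
guideline/label exports can be eyeballed against published corpus
statistics without asserting them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .associations import AssociationSet, build_cpg_associations, build_spl_associations
from .corpus import (
    load_condition_definitions,
    load_crosswalk,
    load_guideline_corpus,
    load_spl_records,
    select_guidelines,
)
from .errors import ConfigurationError
from .evaluation import (
    EvalResult,
    compute_metrics,
    load_textae_dir,
    match_spans,
    metrics_table,
)
from .ner import find_mentions, mentions_to_tsv, unique_drug_keys
from .taxonomy import OverlapPartition, compute_overlap, find_similar
from .vocabulary import DrugVocabulary, build_vocabulary, load_term_source

__all__ = ["PipelineConfig", "OverlapReport", "run", "render_report"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and flags for one pipeline run.

    ``vocab_sources`` maps a terminology name to its TSV path;
    ``root_filters`` optionally restricts a source to the descendants
    of given concept ids.  ``atc_lookup`` is a drug-name -> ATC-codes
    TSV used when label rows lack codes.  ``references`` points at a
    directory of TextAE JSON files and switches the evaluation stage
    on.
    """

    corpus: Path
    conditions_csv: Path
    crosswalk_csv: Path
    vocab_sources: dict[str, Path]
    labels: Path
    output_dir: Path
    atc_lookup: Path | None = None
    references: Path | None = None
    stoplist: Path | None = None
    root_filters: dict[str, tuple[str, ...]] = field(default_factory=dict)
    use_taxonomy: bool = True
    span_criterion: str = "exact"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("corpus", "conditions_csv", "crosswalk_csv", "labels",
                     "atc_lookup", "references", "stoplist"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        self.vocab_sources = {k: Path(v) for k, v in self.vocab_sources.items()}
        self.output_dir = Path(self.output_dir)
        missing = [
            str(p)
            for p in [self.corpus, self.conditions_csv, self.crosswalk_csv,
                      self.labels, *self.vocab_sources.values(),
                      self.atc_lookup, self.references, self.stoplist]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise ConfigurationError(f"missing input path(s): {missing}")

    def config_hash(self) -> str:
        """Hash of the inputs and flags (output location excluded)."""
        fields = dataclasses.asdict(self)
        fields.pop("output_dir")
        payload = json.dumps(fields, default=str, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class OverlapReport:
    """Everything one run computed.

    ``partitions_exact`` and ``partitions_taxonomic`` map condition
    name (plus "ALL") to its overlap partition.  Raw per-side unique
    association counts are reported alongside the partition counts and
    are not forced to agree with their sums.
    """

    partitions_exact: dict[str, OverlapPartition]
    partitions_taxonomic: dict[str, OverlapPartition]
    n_cpg_associations: int
    n_spl_associations: int
    n_unique_drug_keys: int
    n_guidelines_selected: int
    evaluation: dict[str, EvalResult] | None
    metadata: dict

    def partition_frame(self, use_taxonomy: bool | None = None) -> pd.DataFrame:
        """Per-condition counts as a DataFrame (taxonomic by default)."""
        if use_taxonomy is None:
            use_taxonomy = self.metadata.get("use_taxonomy", True)
        parts = self.partitions_taxonomic if use_taxonomy else self.partitions_exact
        rows = [
            {"condition": cond, "n_both": p.counts[0],
             "n_cpg_only": p.counts[1], "n_spl_only": p.counts[2]}
            for cond, p in parts.items()
            if cond != "ALL"
        ]
        rows.append(
            {"condition": "ALL", "n_both": parts["ALL"].counts[0],
             "n_cpg_only": parts["ALL"].counts[1], "n_spl_only": parts["ALL"].counts[2]}
        )
        return pd.DataFrame(rows, columns=["condition", "n_both", "n_cpg_only", "n_spl_only"])


def _load_stoplist(path: Path | None) -> frozenset[str]:
    if path is None:
        return frozenset()
    return frozenset(
        line.strip().lower()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    )


def _load_atc_lookup(path: Path | None) -> dict[str, tuple[str, ...]]:
    if path is None:
        return {}
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {
        row.drug_name: tuple(c.strip().upper() for c in row.atc_codes.split(";") if c.strip())
        for row in frame.itertuples(index=False)
    }


def run(config: PipelineConfig) -> OverlapReport:
    """Execute all stages and write artifacts under ``config.output_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)

    # stage: vocabulary
    collections = [
        load_term_source(path, source, config.root_filters.get(source))
        for source, path in sorted(config.vocab_sources.items())
    ]
    vocab = build_vocabulary(collections, stoplist=_load_stoplist(config.stoplist))
    vocab.write_tsv(out / "vocabulary.tsv", out / "vocabulary_stats.json")
    logger.info("vocabulary: %d terms, %d unique keys", len(vocab.terms), len(vocab.index))

    # stage: corpus
    conditions = load_condition_definitions(config.conditions_csv, load_crosswalk(config.crosswalk_csv))
    corpus = load_guideline_corpus(config.corpus)
    selection = select_guidelines(corpus, conditions)
    selected_docs = {g.doc_id: g for docs in selection.values() for g in docs}
    logger.info("corpus: %d documents, %d selected across %d conditions",
                len(corpus), len(selected_docs), len(conditions))

    # stage: NER
    mentions = {doc_id: find_mentions(g, vocab) for doc_id, g in sorted(selected_docs.items())}
    flat_mentions = [m for doc in sorted(mentions) for m in mentions[doc]]
    mentions_to_tsv(flat_mentions, out / "mentions.tsv")
    drug_keys = unique_drug_keys(flat_mentions)
    logger.info("ner: %d mentions, %d unique drug keys", len(flat_mentions), len(drug_keys))

    # stage: associations
    cpg = build_cpg_associations(selection, mentions, atc_codes_for=vocab.atc_codes_for)
    records = load_spl_records(config.labels, _load_atc_lookup(config.atc_lookup))
    spl = build_spl_associations(records, conditions)
    cpg.write_csv(out / "associations_cpg.csv")
    spl.write_csv(out / "associations_spl.csv")
    logger.info("associations: %d CPG, %d SPL (from %d label records)",
                len(cpg), len(spl), len(records))

    # stage: taxonomy
    partitions_exact = compute_overlap(cpg, spl, use_taxonomy=False)
    partitions_taxonomic = compute_overlap(cpg, spl, use_taxonomy=True)
    similar = find_similar(AssociationSet(
        associations=cpg.associations + spl.associations, side="CPG"))
    pd.DataFrame(
        [
            {"condition": p.a.condition, "drug_a": p.a.drug_key, "drug_b": p.b.drug_key,
             "parent_code": p.parent_code}
            for p in similar
        ],
        columns=["condition", "drug_a", "drug_b", "parent_code"],
    ).to_csv(out / "similar_pairs.csv", index=False)

    # stage: evaluation (optional)
    evaluation = None
    if config.references is not None:
        _, annotations = load_textae_dir(config.references)
        ref_docs = {a.doc_id for a in annotations}
        evaluation = {}
        for source in sorted(config.vocab_sources):
            sub = vocab.restricted_to([source])
            preds = [
                m
                for doc_id, g in sorted(selected_docs.items())
                if doc_id in ref_docs
                for m in find_mentions(g, sub)
            ]
            tp, fp, fn = match_spans(preds, annotations, criterion=config.span_criterion)
            evaluation[source] = compute_metrics(tp, fp, fn)
        metrics_table(evaluation).to_csv(out / "evaluation.csv", index=False)

    report = OverlapReport(
        partitions_exact=partitions_exact,
        partitions_taxonomic=partitions_taxonomic,
        n_cpg_associations=len(cpg),
        n_spl_associations=len(spl),
        n_unique_drug_keys=len(drug_keys),
        n_guidelines_selected=len(selected_docs),
        evaluation=evaluation,
        metadata={
            "config_hash": config.config_hash(),
            "version": __version__,
            "use_taxonomy": config.use_taxonomy,
            "span_criterion": config.span_criterion,
        },
    )
    render_report(report, out)
    return report


def _partition_detail(parts: Mapping[str, OverlapPartition]) -> dict:
    detail: dict = {}
    for cond, p in parts.items():
        detail[cond] = {
            "counts": {"both": p.counts[0], "cpg_only": p.counts[1], "spl_only": p.counts[2]},
            "uncoded": sorted({a.drug_key for a in p.uncoded}),
        }
        for label in ("both", "cpg_only", "spl_only"):
            detail[cond][label] = [
                {
                    "members": [
                        {"drug_key": m.drug_key, "source": m.source,
                         "atc_codes": list(m.atc_codes),
                         "provenance": sorted(m.provenance)}
                        for m in group.members
                    ],
                    "representatives": sorted({r.drug_key for r in group.representatives}),
                }
                for group in getattr(p, label)
            ]
    return detail


def render_report(report: OverlapReport, out_dir: str | Path) -> None:
    """Write the per-condition CSV, grand-total JSON detail, and a short
    text summary naming the top overlapping groups per condition."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.partition_frame(use_taxonomy=False).to_csv(out / "overlap_exact.csv", index=False)
    report.partition_frame(use_taxonomy=True).to_csv(out / "overlap_taxonomic.csv", index=False)
    payload = {
        "schema_version": 1,
        "metadata": report.metadata,
        "raw_counts": {
            "cpg_associations": report.n_cpg_associations,
            "spl_associations": report.n_spl_associations,
            "unique_drug_keys": report.n_unique_drug_keys,
            "guidelines_selected": report.n_guidelines_selected,
        },
        "exact": _partition_detail(report.partitions_exact),
        "taxonomic": _partition_detail(report.partitions_taxonomic),
    }
    if report.evaluation is not None:
        payload["evaluation"] = {
            source: dataclasses.asdict(result) for source, result in report.evaluation.items()
        }
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    lines = ["Overlap summary (taxonomic matching)", "=" * 38]
    for cond, p in report.partitions_taxonomic.items():
        if cond == "ALL":
            continue
        tops = [", ".join(sorted({r.drug_key for r in g.representatives})) for g in p.both[:3]]
        lines.append(
            f"{cond}: both={p.counts[0]} cpg_only={p.counts[1]} spl_only={p.counts[2]}"
            + (f"  shared: {'; '.join(tops)}" if tops else "")
        )
    all_part = report.partitions_taxonomic["ALL"]
    lines.append(
        f"ALL: both={all_part.counts[0]} cpg_only={all_part.counts[1]} "
        f"spl_only={all_part.counts[2]} (total merged groups {all_part.total_groups})"
    )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
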