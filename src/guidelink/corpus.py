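"""Corpus loading: condition definitions, guideline summaries, label records.

Conditions are defined the way the Medicare Chronic Conditions Data
Warehouse defines them — as sets of ICD-9 codes — and crosswalked to
UMLS concept unique identifiers (CUIs), which is the vocabulary the
guideline index tags and the label indications use.  Guideline
summaries arrive either as a JSON-lines export or as NGC-style XML
documents from which the Major Recommendations section is extracted.
Label indications are consumed as a SIDER-like flat TSV.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from lxml import etree

from .errors import ConfigurationError, ExtractionError, FormatError
from .vocabulary import normalize_term

__all__ = [
    "ConditionDefinition",
    "GuidelineSummary",
    "SplRecord",
    "CuiMapping",
    "POPULATION_FLAGS",
    "load_crosswalk",
    "map_icd9_to_cuis",
    "load_condition_definitions",
    "load_guideline_corpus",
    "extract_major_recommendations",
    "select_guidelines",
    "load_spl_records",
]

logger = logging.getLogger(__name__)

POPULATION_FLAGS = frozenset({"pediatric_only", "pregnancy_only", "other_diagnosis"})


@dataclass(frozen=True)
class ConditionDefinition:
    """A chronic condition: its name, ICD-9 codes, and mapped CUIs."""

    name: str
    icd9_codes: frozenset[str]
    cuis: frozenset[str]


@dataclass(frozen=True)
class GuidelineSummary:
    """One guideline summary with its recommendations text and metadata.

    ``tagged_cuis`` are the concept tags the guideline index assigns;
    ``population_flags`` record manual-review exclusions (exclusively
    pediatric / pregnancy populations, or an off-target diagnosis) and
    ``is_commentary`` marks expert commentaries, which are a different
    document type.
    """

    doc_id: str
    title: str
    major_recommendations: str
    tagged_cuis: frozenset[str] = frozenset()
    population_flags: frozenset[str] = frozenset()
    is_commentary: bool = False

    def __post_init__(self) -> None:
        unknown = self.population_flags - POPULATION_FLAGS
        if unknown:
            raise ValueError(f"unknown population flags: {sorted(unknown)}")


@dataclass(frozen=True)
class SplRecord:
    """One product-label row: drug name, ATC codes, indication CUIs."""

    label_id: str
    drug_name: str
    atc_codes: tuple[str, ...]
    indication_cuis: frozenset[str]
    atc_source: str = "file"  # "file" | "lookup" | "unresolved"


class CuiMapping(NamedTuple):
    """Result of an ICD-9 -> CUI crosswalk: the CUIs plus unmapped codes."""

    cuis: frozenset[str]
    unmapped: frozenset[str]


def load_crosswalk(path: str | Path) -> dict[str, frozenset[str]]:
    """Read an (icd9_code, cui) CSV into a one-to-many mapping."""
    frame = pd.read_csv(path, dtype=str)
    if not {"icd9_code", "cui"} <= set(frame.columns):
        raise FormatError(f"{path}: crosswalk needs columns icd9_code, cui")
    mapping: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        mapping.setdefault(row.icd9_code, set()).add(row.cui)
    return {k: frozenset(v) for k, v in mapping.items()}


def map_icd9_to_cuis(
    icd9_codes: Iterable[str],
    crosswalk: Mapping[str, Iterable[str]],
) -> CuiMapping:
    """Union the CUIs of every code present in the crosswalk.

    Codes absent from the crosswalk are returned in ``unmapped`` (and
    logged), never silently dropped.

    Raises :class:`ConfigurationError` on an empty crosswalk.
    """
    if not crosswalk:
        raise ConfigurationError("empty ICD-9 -> CUI crosswalk")
    codes = set(icd9_codes)
    cuis: set[str] = set()
    unmapped: set[str] = set()
    for code in codes:
        if code in crosswalk:
            cuis.update(crosswalk[code])
        else:
            unmapped.add(code)
    if unmapped:
        logger.warning("%d ICD-9 code(s) missing from crosswalk: %s",
                       len(unmapped), sorted(unmapped))
    return CuiMapping(cuis=frozenset(cuis), unmapped=frozenset(unmapped))


def load_condition_definitions(
    conditions_csv: str | Path,
    crosswalk: Mapping[str, Iterable[str]] | str | Path,
) -> list[ConditionDefinition]:
    """Build condition definitions from a long-format (name, icd9_code)
    CSV plus a code->CUI crosswalk (mapping or CSV path)."""
    if not isinstance(crosswalk, Mapping):
        crosswalk = load_crosswalk(crosswalk)
    frame = pd.read_csv(conditions_csv, dtype=str)
    if not {"name", "icd9_code"} <= set(frame.columns):
        raise FormatError(f"{conditions_csv}: needs columns name, icd9_code")
    definitions = []
    for name, group in frame.groupby("name", sort=True):
        codes = frozenset(group["icd9_code"])
        mapping = map_icd9_to_cuis(codes, crosswalk)
        definitions.append(
            ConditionDefinition(name=str(name), icd9_codes=codes, cuis=mapping.cuis)
        )
    return definitions


_WS = re.compile(r"\s+")


def extract_major_recommendations(
    document: str | Path | etree._Element,
    section_tag: str = "section",
    title_attribute: str = "title",
    section_title: str = "Major Recommendations",
) -> str:
    """Pull the Major Recommendations text out of a guideline XML document.

    The section is located as ``<{section_tag} {title_attribute}="{section_title}">``
    (defaults shown); its text content is concatenated depth-first in
    document order with markup removed and whitespace collapsed.

    Raises :class:`ExtractionError` when no such section exists.
    """
    if isinstance(document, (str, Path)):
        try:
            root = etree.parse(str(document)).getroot()
        except (OSError, etree.XMLSyntaxError) as exc:
            raise ExtractionError(f"cannot parse guideline XML {document}: {exc}") from exc
        doc_name = str(document)
    else:
        root = document
        doc_name = root.get("id", "<element>")
    for section in root.iter(section_tag):
        if section.get(title_attribute) == section_title:
            text = " ".join(part for part in section.itertext())
            return _WS.sub(" ", text).strip()
    raise ExtractionError(f"no {section_title!r} section in {doc_name}")


def _summary_from_xml(path: Path, **extract_kwargs) -> GuidelineSummary:
    root = etree.parse(str(path)).getroot()
    doc_id = root.get("id", path.stem)
    cuis = frozenset(e.text.strip() for e in root.iter("cui") if e.text and e.text.strip())
    flags = frozenset(
        e.text.strip() for e in root.iter("population_flag") if e.text and e.text.strip()
    )
    title_el = root.find("title")
    return GuidelineSummary(
        doc_id=doc_id,
        title=title_el.text.strip() if title_el is not None and title_el.text else "",
        major_recommendations=extract_major_recommendations(root, **extract_kwargs),
        tagged_cuis=cuis,
        population_flags=flags,
        is_commentary=root.get("commentary", "").lower() in ("1", "true", "yes"),
    )


def load_guideline_corpus(path: str | Path, **extract_kwargs) -> list[GuidelineSummary]:
    """Load a corpus from a JSON-lines file or a directory of XML files.

    JSON-lines: one object per line with keys doc_id, title,
    major_recommendations, tagged_cuis, population_flags, is_commentary.
    """
    path = Path(path)
    summaries: list[GuidelineSummary] = []
    if path.is_dir():
        for xml_path in sorted(path.glob("*.xml")):
            summaries.append(_summary_from_xml(xml_path, **extract_kwargs))
    else:
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                if not line.strip():
                    continue
                raw = json.loads(line)
                summaries.append(
                    GuidelineSummary(
                        doc_id=raw["doc_id"],
                        title=raw.get("title", ""),
                        major_recommendations=raw.get("major_recommendations", ""),
                        tagged_cuis=frozenset(raw.get("tagged_cuis", ())),
                        population_flags=frozenset(raw.get("population_flags", ())),
                        is_commentary=bool(raw.get("is_commentary", False)),
                    )
                )
    return summaries


def select_guidelines(
    corpus: Iterable[GuidelineSummary],
    conditions: Iterable[ConditionDefinition],
) -> dict[str, list[GuidelineSummary]]:
    """Assign each eligible guideline to every condition it is tagged for.

    A guideline is assigned to a condition when the condition's CUI set
    intersects the guideline's tags; commentaries and guidelines with
    any population flag are excluded regardless of tags.  A guideline
    may appear under several conditions.  Output order is by doc_id, so
    the assignment is invariant to corpus ordering.
    """
    eligible = sorted(
        (g for g in corpus if not g.is_commentary and not g.population_flags),
        key=lambda g: g.doc_id,
    )
    selection: dict[str, list[GuidelineSummary]] = {}
    for condition in sorted(conditions, key=lambda c: c.name):
        selection[condition.name] = [g for g in eligible if condition.cuis & g.tagged_cuis]
    return selection


def load_spl_records(
    path: str | Path,
    atc_lookup: Mapping[str, Sequence[str]] | None = None,
) -> list[SplRecord]:
    """Read a SIDER-like label TSV (label_id, drug_name, indication_cuis,
    optional atc_codes; CUIs and codes semicolon-joined).

    ATC codes come from the file when present, else from ``atc_lookup``
    by normalized drug name; records with no resolvable code are kept
    with ``atc_source="unresolved"``.  Malformed rows (missing label_id
    or drug_name) are logged and skipped; more than 10% malformed rows
    raises :class:`FormatError`.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read label file {path}: {exc}") from exc
    if not {"label_id", "drug_name", "indication_cuis"} <= set(frame.columns):
        raise FormatError(f"{path}: needs columns label_id, drug_name, indication_cuis")
    lookup = {normalize_term(k): tuple(v) for k, v in (atc_lookup or {}).items()}

    records: list[SplRecord] = []
    n_malformed = 0
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        if not row.label_id.strip() or not row.drug_name.strip():
            logger.warning("%s row %d: malformed (missing label_id or drug_name), skipped", path, i)
            n_malformed += 1
            continue
        codes = tuple(
            c.strip().upper()
            for c in str(getattr(row, "atc_codes", "")).split(";")
            if c.strip()
        )
        atc_source = "file"
        if not codes:
            codes = lookup.get(normalize_term(row.drug_name), ())
            atc_source = "lookup" if codes else "unresolved"
        records.append(
            SplRecord(
                label_id=row.label_id.strip(),
                drug_name=row.drug_name.strip(),
                atc_codes=codes,
                indication_cuis=frozenset(
                    c.strip() for c in row.indication_cuis.split(";") if c.strip()
                ),
                atc_source=atc_source,
            )
        )
    if len(frame) and n_malformed / len(frame) > 0.10:
        raise FormatError(f"{path}: {n_malformed}/{len(frame)} malformed rows (>10%)")
    return records
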