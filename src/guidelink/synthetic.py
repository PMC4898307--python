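"""Seeded synthetic study bundles with per-stage ground truth.

The generator emulates every input the pipeline consumes: a toy drug
formulary arranged in an ATC-shaped hierarchy (level-4 classes with
level-5 member drugs), terminology TSVs, condition definitions with an
ICD-9 -> CUI crosswalk, a guideline corpus whose recommendation texts
contain planted drug-name and drug-class mentions, a SIDER-like label
file, and TextAE reference annotations.  Every planted association is
assigned a fate — present in guidelines only, labels only, or both —
and, on the guideline side, may be voiced as its *class* name instead
of the drug name.  Class mentions are the mechanism that makes the
taxonomy matter: a class name never string-matches a drug name, but
always taxonomically matches its member drugs.

Expected overlap partitions are derived analytically from the
generator's own bookkeeping (a direct closure over the planted pairs),
never by invoking the pipeline, so end-to-end tests are non-circular.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .associations import Association, AssociationSet
from .errors import ConfigurationError
from .evaluation import ReferenceAnnotation
from .vocabulary import DrugTerm, DrugVocabulary, build_vocabulary, normalize_term

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "ExpectedPartition",
    "SyntheticBundle",
    "generate",
    "describe_truth",
    "FILLER_SENTENCES",
]

FILLER_SENTENCES = (
    "Patients should be assessed at regular intervals by the care team.",
    "Shared decision making with the patient is encouraged throughout treatment.",
    "Lifestyle modification remains the foundation of long-term management.",
    "Referral to a specialist may be warranted when symptoms are refractory.",
    "Laboratory monitoring should follow the schedule outlined above.",
    "The strength of this recommendation reflects moderate quality evidence.",
    "Comorbid conditions should be taken into account when planning therapy.",
    "Adherence should be reviewed at every follow-up visit.",
    "Vaccination status should be verified according to the current schedule.",
    "Treatment goals should be individualized and documented in the record.",
)

_PLANT_TEMPLATES = (
    "Clinicians should consider {} as first-line therapy.",
    "Initiate {} when symptoms persist despite lifestyle measures.",
    "Long-term use of {} requires periodic review of benefits and harms.",
    "The committee recommends {} for eligible patients.",
    "Dose titration of {} should follow the protocol in the appendix.",
)

_DISTRACTOR_TEMPLATE = "Adjunct use of {} was not evaluated in this guideline."

_CLASS_SUFFIXES = (
    "receptor antagonists",
    "channel blockers",
    "reuptake inhibitors",
    "receptor agonists",
    "synthesis inhibitors",
)

_SYLLABLES = (
    "zel", "vor", "tra", "mib", "dex", "lor", "fen", "qua", "rup", "tin",
    "gos", "nal", "pir", "sev", "xan", "bro", "cli", "dul", "erg", "flo",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study.

    Fate probabilities (``p_both``, ``p_cpg_only``, ``p_spl_only``)
    must sum to 1; their defaults echo the balance observed between
    guideline-only, label-only and shared associations in real
    guideline/label corpora.  ``p_class_mention`` is the probability
    that a guideline voices a recommendation through the drug's class
    name rather than the drug name itself.
    ``n_associations_per_condition=None`` plants every formulary drug
    in every condition.
    """

    seed: int = 0
    n_conditions: int = 15
    n_level4_classes: int = 8
    drugs_per_class: int = 3
    n_guidelines_per_condition: int = 5
    p_class_mention: float = 0.30
    p_cpg_only: float = 0.60
    p_spl_only: float = 0.25
    p_both: float = 0.15
    n_distractor_terms: int = 10
    n_associations_per_condition: int | None = None
    n_excluded_guidelines: int = 2
    filler_sentence_pool: tuple[str, ...] = FILLER_SENTENCES

    def validate(self) -> None:
        probs = (self.p_cpg_only, self.p_spl_only, self.p_both, self.p_class_mention)
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if abs(self.p_cpg_only + self.p_spl_only + self.p_both - 1.0) > 1e-9:
            raise ConfigurationError("fate probabilities must sum to 1")
        counts = (self.n_conditions, self.n_level4_classes, self.drugs_per_class,
                  self.n_guidelines_per_condition)
        if any(c < 1 for c in counts):
            raise ConfigurationError("all counts must be >= 1")
        if self.drugs_per_class > 99:
            raise ConfigurationError("at most 99 drugs fit under one level-4 class")
        n_drugs = self.n_level4_classes * self.drugs_per_class
        if (self.n_associations_per_condition is not None
                and self.n_associations_per_condition > n_drugs):
            raise ConfigurationError(
                f"cannot plant {self.n_associations_per_condition} associations "
                f"per condition from a formulary of {n_drugs} drugs"
            )
        if not self.filler_sentence_pool:
            raise ConfigurationError("filler sentence pool may not be empty")


@dataclass(frozen=True)
class ExpectedPartition:
    """Ground-truth merged groups for one condition, as drug-key sets."""

    both: tuple[frozenset[str], ...]
    cpg_only: tuple[frozenset[str], ...]
    spl_only: tuple[frozenset[str], ...]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.both), len(self.cpg_only), len(self.spl_only))


@dataclass
class SyntheticTruth:
    """Everything the generator knows about what it planted."""

    vocabulary: DrugVocabulary
    hierarchy: dict[str, str]  # ATC code -> parent code
    planted_mentions: dict[str, list[ReferenceAnnotation]]
    planted_cpg: AssociationSet
    planted_spl: AssociationSet
    expected_exact: dict[str, ExpectedPartition]
    expected_taxonomic: dict[str, ExpectedPartition]
    n_unique_keys: int
    condition_names: tuple[str, ...]


@dataclass
class SyntheticBundle:
    """File paths of one generated study bundle plus its truth."""

    root: Path
    conditions_csv: Path
    crosswalk_csv: Path
    corpus_jsonl: Path
    vocab_sources: dict[str, Path]
    labels_tsv: Path
    atc_lookup_tsv: Path
    references_dir: Path
    truth: SyntheticTruth


def _fresh_names(rng: random.Random, count: int, taken: set[str], n_syl=(3, 4)) -> list[str]:
    names = []
    while len(names) < count:
        name = "".join(rng.choice(_SYLLABLES) for _ in range(rng.choice(n_syl)))
        if name not in taken:
            taken.add(name)
            names.append(name)
    return names


def _fresh_atc4(rng: random.Random, taken: set[str]) -> str:
    while True:
        code = (rng.choice("ABCDGHJLMNPRSV") + f"{rng.randrange(100):02d}"
                + rng.choice("ABCDEFGHX") + rng.choice("ABCDEFGHX"))
        if code not in taken:
            taken.add(code)
            return code


def _ancestor_chain(code: str) -> list[tuple[str, str]]:
    """(code, parent) pairs linking a code up to its level-1 root."""
    lengths = [l for l in (7, 5, 4, 3, 1) if l <= len(code)]
    return [
        (code[:lengths[i]], code[:lengths[i + 1]])
        for i in range(len(lengths) - 1)
    ]


def _closure_partition(
    cpg_nodes: dict[str, str], spl_nodes: dict[str, str]
) -> ExpectedPartition:
    """Partition planted nodes by transitive closure of cross-side matches.

    A direct re-derivation over the bookkeeping: two nodes on opposite
    sides merge when their keys are equal, their codes are equal, or
    one code is a prefix of the other at a valid ATC length.  Uncoded
    nodes (empty code) merge on key equality only.
    """
    nodes = [("CPG", k, c) for k, c in sorted(cpg_nodes.items())] + [
        ("SPL", k, c) for k, c in sorted(spl_nodes.items())
    ]
    parent = list(range(len(nodes)))

    def root(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def matches(a, b) -> bool:
        _, ka, ca = a
        _, kb, cb = b
        if ka == kb:
            return True
        if not ca or not cb:
            return False
        if ca == cb:
            return True
        short, long_ = sorted((ca, cb), key=len)
        return len(short) < len(long_) and len(short) in (1, 3, 4, 5) and long_.startswith(short)

    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if nodes[i][0] != nodes[j][0] and matches(nodes[i], nodes[j]):
                parent[root(i)] = root(j)

    groups: dict[int, list[tuple[str, str, str]]] = {}
    for i, node in enumerate(nodes):
        groups.setdefault(root(i), []).append(node)
    both, cpg_only, spl_only = [], [], []
    for members in groups.values():
        sides = {side for side, _, _ in members}
        keys = frozenset(k for _, k, _ in members)
        (both if sides == {"CPG", "SPL"} else cpg_only if sides == {"CPG"} else spl_only).append(keys)
    order = lambda gs: tuple(sorted(gs, key=sorted))
    return ExpectedPartition(both=order(both), cpg_only=order(cpg_only), spl_only=order(spl_only))


def _merge_all(per_condition: dict[str, ExpectedPartition]) -> ExpectedPartition:
    return ExpectedPartition(
        both=tuple(g for p in per_condition.values() for g in p.both),
        cpg_only=tuple(g for p in per_condition.values() for g in p.cpg_only),
        spl_only=tuple(g for p in per_condition.values() for g in p.spl_only),
    )


def generate(config: GeneratorConfig, out_dir: str | Path) -> SyntheticBundle:
    """Write one complete synthetic study bundle under ``out_dir``.

    Deterministic given ``config.seed``: running twice with the same
    config produces byte-identical files.
    """
    config.validate()
    rng = random.Random(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- formulary: level-4 classes, level-5 drugs, surface forms ----
    taken_names: set[str] = set()
    taken_codes: set[str] = set()
    class_stems = _fresh_names(rng, config.n_level4_classes, taken_names, n_syl=(2,))
    classes = []  # (code, surface, key)
    drugs = []    # (code, surface, key, class_code)
    hierarchy: dict[str, str] = {}
    for stem in class_stems:
        code = _fresh_atc4(rng, taken_codes)
        surface = f"{stem.capitalize()} {rng.choice(_CLASS_SUFFIXES)}"
        classes.append((code, surface, normalize_term(surface)))
        hierarchy.update(dict(_ancestor_chain(code)))
        for i, drug_stem in enumerate(
            _fresh_names(rng, config.drugs_per_class, taken_names)
        ):
            drug_code = f"{code}{i + 1:02d}"
            drug_surface = drug_stem.capitalize()
            drugs.append((drug_code, drug_surface, drug_stem, code))
            hierarchy[drug_code] = code

    vocab_keys = {key for _, _, key in classes} | {key for _, _, key, _ in drugs}
    distractors = _fresh_names(rng, config.n_distractor_terms, taken_names)
    assert not set(distractors) & vocab_keys
    filler_tokens = {
        t.strip(".,").lower() for s in config.filler_sentence_pool for t in s.split()
    }
    assert not {k.split()[0] for k in vocab_keys} & filler_tokens

    # ---- terminology TSVs (ATC full; a MeSH-like echo without codes) ----
    vocab_dir = out / "vocabulary"
    vocab_dir.mkdir(exist_ok=True)
    atc_rows = [
        {"concept_id": code, "surface": surface, "parent_id": hierarchy.get(code, ""),
         "atc_code": code, "is_class": 1}
        for code, surface, _ in classes
    ] + [
        {"concept_id": code, "surface": surface, "parent_id": cls,
         "atc_code": code, "is_class": 0}
        for code, surface, _, cls in drugs
    ]
    atc_tsv = vocab_dir / "atc.tsv"
    pd.DataFrame(atc_rows).to_csv(atc_tsv, sep="\t", index=False)
    mesh_rows = [
        {"concept_id": f"M{i:06d}", "surface": surface, "parent_id": "",
         "atc_code": "", "is_class": 0}
        for i, (_, surface, _, _) in enumerate(drugs)
        if i % 2 == 0
    ]
    mesh_tsv = vocab_dir / "mesh.tsv"
    pd.DataFrame(mesh_rows).to_csv(mesh_tsv, sep="\t", index=False)

    terms = [
        DrugTerm(surface=s, normalized=k, concept_id=c, source="ATC",
                 atc_codes=(c,), is_class=True)
        for c, s, k in classes
    ] + [
        DrugTerm(surface=s, normalized=k, concept_id=c, source="ATC",
                 atc_codes=(c,), is_class=False)
        for c, s, k, _ in drugs
    ] + [
        DrugTerm(surface=r["surface"], normalized=normalize_term(r["surface"]),
                 concept_id=r["concept_id"], source="MESH")
        for r in mesh_rows
    ]
    vocabulary = build_vocabulary([terms])

    # ---- conditions and crosswalk ----
    condition_names = tuple(f"condition-{i + 1:02d}" for i in range(config.n_conditions))
    cond_rows, xwalk_rows = [], []
    cond_cuis: dict[str, tuple[str, str]] = {}
    used_cuis: set[str] = set()
    for i, name in enumerate(condition_names):
        cuis = []
        while len(cuis) < 2:
            cui = f"C{rng.randrange(10**7):07d}"
            if cui not in used_cuis:
                used_cuis.add(cui)
                cuis.append(cui)
        cond_cuis[name] = (cuis[0], cuis[1])
        for j, cui in enumerate(cuis):
            code = f"{400 + i}.{j}"
            cond_rows.append({"name": name, "icd9_code": code})
            xwalk_rows.append({"icd9_code": code, "cui": cui})
    conditions_csv = out / "conditions.csv"
    crosswalk_csv = out / "crosswalk.csv"
    pd.DataFrame(cond_rows).to_csv(conditions_csv, index=False)
    pd.DataFrame(xwalk_rows).to_csv(crosswalk_csv, index=False)

    # ---- plant association fates ----
    fates = ("both", "cpg_only", "spl_only")
    weights = (config.p_both, config.p_cpg_only, config.p_spl_only)
    cpg_staged: dict[tuple[str, str], set[str]] = {}  # (key, cond) -> doc ids
    cpg_codes: dict[str, str] = {}
    spl_staged: dict[tuple[str, str], set[str]] = {}
    spl_codes: dict[str, str] = {}
    per_guideline_plants: dict[str, list[tuple[str, bool]]] = {}  # doc -> (surface, is_class)
    label_rows = []
    exact_parts: dict[str, ExpectedPartition] = {}
    taxo_parts: dict[str, ExpectedPartition] = {}
    label_counter = 0

    doc_ids: dict[str, list[str]] = {}
    for name in condition_names:
        doc_ids[name] = [
            f"{name}-g{j + 1}" for j in range(config.n_guidelines_per_condition)
        ]
        for doc in doc_ids[name]:
            per_guideline_plants[doc] = []

    class_by_code = {code: (surface, key) for code, surface, key in classes}
    for name in condition_names:
        chosen = (
            drugs
            if config.n_associations_per_condition is None
            else rng.sample(drugs, config.n_associations_per_condition)
        )
        cond_cpg_nodes: dict[str, str] = {}
        cond_spl_nodes: dict[str, str] = {}
        for drug_code, drug_surface, drug_key, cls_code in chosen:
            fate = rng.choices(fates, weights)[0]
            if fate in ("both", "cpg_only"):
                as_class = rng.random() < config.p_class_mention
                if as_class:
                    surface, key = class_by_code[cls_code]
                    code = cls_code
                else:
                    surface, key, code = drug_surface, drug_key, drug_code
                doc = rng.choice(doc_ids[name])
                per_guideline_plants[doc].append((surface, as_class))
                cpg_staged.setdefault((key, name), set()).add(doc)
                cpg_codes[key] = code
                cond_cpg_nodes[key] = code
            if fate in ("both", "spl_only"):
                label_counter += 1
                inline = rng.random() < 0.7
                label_rows.append(
                    {
                        "label_id": f"SPL{label_counter:05d}",
                        "drug_name": drug_surface,
                        "atc_codes": drug_code if inline else "",
                        "indication_cuis": cond_cuis[name][1],
                    }
                )
                spl_staged.setdefault((drug_key, name), set()).add(f"SPL{label_counter:05d}")
                spl_codes[drug_key] = drug_code
                cond_spl_nodes[drug_key] = drug_code
        # analytic expectations straight from the bookkeeping
        cpg_keys = frozenset(cond_cpg_nodes)
        spl_keys = frozenset(cond_spl_nodes)
        exact_parts[name] = ExpectedPartition(
            both=tuple(frozenset((k,)) for k in sorted(cpg_keys & spl_keys)),
            cpg_only=tuple(frozenset((k,)) for k in sorted(cpg_keys - spl_keys)),
            spl_only=tuple(frozenset((k,)) for k in sorted(spl_keys - cpg_keys)),
        )
        taxo_parts[name] = _closure_partition(cond_cpg_nodes, cond_spl_nodes)
    exact_parts["ALL"] = _merge_all({n: exact_parts[n] for n in condition_names})
    taxo_parts["ALL"] = _merge_all({n: taxo_parts[n] for n in condition_names})

    labels_tsv = out / "labels.tsv"
    pd.DataFrame(
        label_rows, columns=["label_id", "drug_name", "atc_codes", "indication_cuis"]
    ).to_csv(labels_tsv, sep="\t", index=False)
    atc_lookup_tsv = out / "atc_lookup.tsv"
    pd.DataFrame(
        [{"drug_name": s, "atc_codes": c} for c, s, _, _ in drugs]
    ).to_csv(atc_lookup_tsv, sep="\t", index=False)

    # ---- assemble guideline texts with tracked offsets ----
    planted_mentions: dict[str, list[ReferenceAnnotation]] = {}
    corpus_records = []
    for name in condition_names:
        for doc in doc_ids[name]:
            sentences: list[tuple[str, tuple[str, bool] | None]] = [
                (rng.choice(config.filler_sentence_pool), None)
            ]
            for surface, is_class in per_guideline_plants[doc]:
                variant = rng.choice((surface, surface.lower(), surface.upper()))
                sentences.append((rng.choice(_PLANT_TEMPLATES), (variant, is_class)))
                if rng.random() < 0.5:
                    sentences.append((rng.choice(config.filler_sentence_pool), None))
            if rng.random() < 0.6:
                sentences.append(
                    (_DISTRACTOR_TEMPLATE.format(rng.choice(distractors)), None)
                )
            text_parts: list[str] = []
            offset = 0
            anns: list[ReferenceAnnotation] = []
            for template, plant in sentences:
                if plant is None:
                    sentence = template
                else:
                    variant, is_class = plant
                    head = template.split("{}")[0]
                    start = offset + len(head)
                    anns.append(
                        ReferenceAnnotation(
                            doc_id=doc, start=start, end=start + len(variant),
                            surface=variant,
                            label="drug_class" if is_class else "drug_name",
                        )
                    )
                    sentence = template.format(variant)
                text_parts.append(sentence)
                offset += len(sentence) + 1  # single-space joiner
            text = " ".join(text_parts)
            planted_mentions[doc] = sorted(anns, key=lambda a: a.start)
            corpus_records.append(
                {
                    "doc_id": doc,
                    "title": f"Guideline {doc} on {name}",
                    "major_recommendations": text,
                    "tagged_cuis": [cond_cuis[name][0]],
                    "population_flags": [],
                    "is_commentary": False,
                }
            )
    # decoy documents that exclusion flags must remove
    for i in range(config.n_excluded_guidelines):
        name = condition_names[i % len(condition_names)]
        _, drug_surface, _, _ = rng.choice(drugs)
        flagged = i % 2 == 0
        corpus_records.append(
            {
                "doc_id": f"excluded-{i + 1}",
                "title": f"Excluded document {i + 1}",
                "major_recommendations": _PLANT_TEMPLATES[0].format(drug_surface),
                "tagged_cuis": [cond_cuis[name][0]],
                "population_flags": ["pediatric_only"] if flagged else [],
                "is_commentary": not flagged,
            }
        )
    corpus_jsonl = out / "corpus.jsonl"
    with open(corpus_jsonl, "w", encoding="utf-8") as handle:
        for record in corpus_records:
            handle.write(json.dumps(record, sort_keys=True) + "\n")

    # ---- TextAE references for the included documents ----
    references_dir = out / "references"
    references_dir.mkdir(exist_ok=True)
    texts = {r["doc_id"]: r["major_recommendations"] for r in corpus_records
             if not r["population_flags"] and not r["is_commentary"]}
    for doc, anns in planted_mentions.items():
        payload = {
            "sourceid": doc,
            "text": texts[doc],
            "denotations": [
                {"id": f"T{i + 1}", "span": {"begin": a.start, "end": a.end},
                 "obj": a.label}
                for i, a in enumerate(anns)
            ],
        }
        (references_dir / f"{doc}.json").write_text(json.dumps(payload, sort_keys=True))

    # ---- planted association sets ----
    planted_cpg = AssociationSet(
        associations=tuple(
            Association(drug_key=k, condition=c, source="CPG",
                        provenance=frozenset(docs), atc_codes=(cpg_codes[k],))
            for (k, c), docs in sorted(cpg_staged.items())
        ),
        side="CPG",
    )
    planted_spl = AssociationSet(
        associations=tuple(
            Association(drug_key=k, condition=c, source="SPL",
                        provenance=frozenset(ids), atc_codes=(spl_codes[k],))
            for (k, c), ids in sorted(spl_staged.items())
        ),
        side="SPL",
    )

    truth = SyntheticTruth(
        vocabulary=vocabulary,
        hierarchy=hierarchy,
        planted_mentions=planted_mentions,
        planted_cpg=planted_cpg,
        planted_spl=planted_spl,
        expected_exact=exact_parts,
        expected_taxonomic=taxo_parts,
        n_unique_keys=len(vocab_keys),
        condition_names=condition_names,
    )
    (out / "truth.json").write_text(json.dumps(describe_truth(truth), indent=2, sort_keys=True))
    return SyntheticBundle(
        root=out,
        conditions_csv=conditions_csv,
        crosswalk_csv=crosswalk_csv,
        corpus_jsonl=corpus_jsonl,
        vocab_sources={"ATC": atc_tsv, "MESH": mesh_tsv},
        labels_tsv=labels_tsv,
        atc_lookup_tsv=atc_lookup_tsv,
        references_dir=references_dir,
        truth=truth,
    )


def describe_truth(truth: SyntheticTruth) -> dict:
    """Recount the planted ground truth as a nested summary.

    Per condition and overall: merged-group counts for the exact and
    taxonomic expectations, planted association totals, and the number
    of planted mentions.
    """
    summary: dict = {"conditions": {}, "totals": {}}
    for name in truth.condition_names:
        exact = truth.expected_exact[name].counts
        taxo = truth.expected_taxonomic[name].counts
        summary["conditions"][name] = {
            "exact": {"both": exact[0], "cpg_only": exact[1], "spl_only": exact[2]},
            "taxonomic": {"both": taxo[0], "cpg_only": taxo[1], "spl_only": taxo[2]},
        }
    exact_all = truth.expected_exact["ALL"].counts
    taxo_all = truth.expected_taxonomic["ALL"].counts
    summary["totals"] = {
        "exact": {"both": exact_all[0], "cpg_only": exact_all[1], "spl_only": exact_all[2]},
        "taxonomic": {"both": taxo_all[0], "cpg_only": taxo_all[1], "spl_only": taxo_all[2]},
        "cpg_associations": len(truth.planted_cpg),
        "spl_associations": len(truth.planted_spl),
        "planted_mentions": sum(len(v) for v in truth.planted_mentions.values()),
        "vocabulary_unique_keys": truth.n_unique_keys,
    }
    return summary
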