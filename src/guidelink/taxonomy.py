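"""ATC code model, ancestry, and taxonomic overlap of association sets.

The WHO Anatomical Therapeutic Chemical (ATC) classification is a
five-level taxonomy whose codes encode their own lineage: C03DA04
(eplerenone) sits under C03DA (aldosterone antagonists), C03D, C03 and
C.  Because a guideline tends to recommend drug *classes* while a
product label names a specific *drug*, two association sets built from
those corpora barely overlap on exact string matching; rolling codes up
and down this hierarchy is what recovers class/name matches such as
"aldosterone antagonists - ischemic heart disease" (guideline) against
"eplerenone - ischemic heart disease" (label).

Level is determined by code length alone:

====== ======= ==================
level  length  shape
====== ======= ==================
1      1       L
2      3       Ldd
3      4       LddL
4      5       LddLL
5      7       LddLLdd
====== ======= ==================
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

from .associations import Association, AssociationSet
from .errors import AtcFormatError

__all__ = [
    "AtcCode",
    "MatchPair",
    "MergedGroup",
    "OverlapPartition",
    "SimilarPair",
    "parse_atc",
    "atc_ancestors",
    "is_taxonomic_match",
    "compute_overlap",
    "find_similar",
]

import re

_SHAPES = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z][0-9]{2}$"),
    4: re.compile(r"^[A-Z][0-9]{2}[A-Z]$"),
    5: re.compile(r"^[A-Z][0-9]{2}[A-Z]{2}$"),
    7: re.compile(r"^[A-Z][0-9]{2}[A-Z]{2}[0-9]{2}$"),
}
_LENGTH_TO_LEVEL = {1: 1, 3: 2, 4: 3, 5: 4, 7: 5}
_LEVEL_LENGTHS = (1, 3, 4, 5, 7)


@dataclass(frozen=True, order=True)
class AtcCode:
    """A validated ATC code with its hierarchy level (1-5)."""

    code: str
    level: int


def parse_atc(code: str) -> AtcCode:
    """Validate an ATC code string and derive its level from its length.

    Raises :class:`AtcFormatError` for lengths outside {1,3,4,5,7} or
    shape violations (letter/digit positions).
    """
    if not code:
        raise AtcFormatError("empty ATC code")
    upper = code.strip().upper()
    shape = _SHAPES.get(len(upper))
    if shape is None or not shape.match(upper):
        raise AtcFormatError(f"invalid ATC code shape: {code!r}")
    return AtcCode(code=upper, level=_LENGTH_TO_LEVEL[len(upper)])


def atc_ancestors(code: AtcCode | str) -> list[AtcCode]:
    """All proper ancestors of a code, nearest first.

    Ancestors are the prefixes at the valid shorter lengths, e.g.
    C03DA04 -> [C03DA, C03D, C03, C].
    """
    atc = parse_atc(code) if isinstance(code, str) else code
    return [
        parse_atc(atc.code[:length])
        for length in sorted(_LEVEL_LENGTHS, reverse=True)
        if length < len(atc.code)
    ]


def _is_ancestor_code(shorter: str, longer: str) -> bool:
    """True iff ``shorter`` is a proper prefix-ancestor of ``longer``."""
    return (
        len(shorter) in _LENGTH_TO_LEVEL
        and len(shorter) < len(longer)
        and longer.startswith(shorter)
    )


Relation = Literal["identical", "cpg_is_ancestor", "spl_is_ancestor"]


@dataclass(frozen=True)
class MatchPair:
    """A taxonomic match between a CPG and a SPL association."""

    cpg_assoc: Association
    spl_assoc: Association
    relation: Relation


def is_taxonomic_match(a: Association, b: Association) -> Optional[Relation]:
    """Relate two same-condition associations through ATC.

    Returns ``"identical"`` when the drug keys or any ATC codes are
    equal, an ancestor relation when any code of one is a proper
    prefix-ancestor of any code of the other (a drug with several ATC
    codes matches if ANY code matches), and ``None`` otherwise —
    including for siblings, which are *similar* but never overlapping.
    """
    if a.condition != b.condition:
        return None
    if a.drug_key == b.drug_key or set(a.atc_codes) & set(b.atc_codes):
        return "identical"
    for ca, cb in itertools.product(a.atc_codes, b.atc_codes):
        if _is_ancestor_code(ca, cb):
            return "cpg_is_ancestor" if a.source == "CPG" else "spl_is_ancestor"
        if _is_ancestor_code(cb, ca):
            return "cpg_is_ancestor" if b.source == "CPG" else "spl_is_ancestor"
    return None


@dataclass(frozen=True)
class MergedGroup:
    """One merged association group in an overlap partition.

    ``representatives`` are the members carrying a code of the maximal
    ATC level present in the group (the most specific drug name(s));
    for groups without any coded member all members are representative.
    """

    members: tuple[Association, ...]
    representatives: tuple[Association, ...]

    @property
    def drug_keys(self) -> frozenset[str]:
        return frozenset(m.drug_key for m in self.members)

    @property
    def sides(self) -> frozenset[str]:
        return frozenset(m.source for m in self.members)


@dataclass
class OverlapPartition:
    """Disjoint both / CPG-only / SPL-only decomposition for one condition."""

    condition: str
    both: tuple[MergedGroup, ...]
    cpg_only: tuple[MergedGroup, ...]
    spl_only: tuple[MergedGroup, ...]
    uncoded: tuple[Association, ...] = ()

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.both), len(self.cpg_only), len(self.spl_only))

    @property
    def total_groups(self) -> int:
        return sum(self.counts)


def _max_code_level(assoc: Association) -> int:
    return max((parse_atc(c).level for c in assoc.atc_codes), default=0)


def _make_group(members: list[Association]) -> MergedGroup:
    members = tuple(sorted(members, key=lambda a: (a.source, a.drug_key)))
    top = max(_max_code_level(m) for m in members)
    reps = tuple(m for m in members if _max_code_level(m) == top)
    return MergedGroup(members=members, representatives=reps)


def _partition_groups(condition: str, groups: list[list[Association]],
                      uncoded: tuple[Association, ...] = ()) -> OverlapPartition:
    both, cpg_only, spl_only = [], [], []
    for members in groups:
        group = _make_group(members)
        if group.sides == {"CPG", "SPL"}:
            both.append(group)
        elif group.sides == {"CPG"}:
            cpg_only.append(group)
        else:
            spl_only.append(group)
    key = lambda g: tuple(sorted(g.drug_keys))
    return OverlapPartition(
        condition=condition,
        both=tuple(sorted(both, key=key)),
        cpg_only=tuple(sorted(cpg_only, key=key)),
        spl_only=tuple(sorted(spl_only, key=key)),
        uncoded=uncoded,
    )


def compute_overlap(
    cpg: AssociationSet,
    spl: AssociationSet,
    use_taxonomy: bool,
) -> dict[str, OverlapPartition]:
    """Partition merged association groups per condition (plus "ALL").

    Without taxonomy, a merged group is an exact (drug_key, condition)
    pair, labelled "both" when present on both sides.  With taxonomy,
    the associations of a condition form a graph whose edges are
    cross-corpus taxonomic matches (:func:`is_taxonomic_match`);
    merged groups are its connected components, so one guideline class
    association linked to two sibling label drugs collapses into a
    single "both" group.  Associations without any ATC code still
    participate via exact key equality and are listed in the
    partition's ``uncoded`` field.
    """
    conditions = sorted(set(cpg.by_condition) | set(spl.by_condition))
    result: dict[str, OverlapPartition] = {}
    for cond in conditions:
        nodes = list(cpg.by_condition.get(cond, ())) + list(spl.by_condition.get(cond, ()))
        if not use_taxonomy:
            by_key: dict[str, list[Association]] = {}
            for assoc in nodes:
                by_key.setdefault(assoc.drug_key, []).append(assoc)
            result[cond] = _partition_groups(cond, list(by_key.values()))
            continue
        # union-find over cross-side taxonomic matches
        parent = list(range(len(nodes)))

        def root(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(nodes)), 2):
            if nodes[i].source == nodes[j].source:
                continue
            if is_taxonomic_match(nodes[i], nodes[j]) is not None:
                parent[root(i)] = root(j)
        components: dict[int, list[Association]] = {}
        for i, assoc in enumerate(nodes):
            components.setdefault(root(i), []).append(assoc)
        uncoded = tuple(a for a in nodes if not a.atc_codes)
        result[cond] = _partition_groups(cond, list(components.values()), uncoded)

    result["ALL"] = OverlapPartition(
        condition="ALL",
        both=tuple(g for c in conditions for g in result[c].both),
        cpg_only=tuple(g for c in conditions for g in result[c].cpg_only),
        spl_only=tuple(g for c in conditions for g in result[c].spl_only),
        uncoded=tuple(a for c in conditions for a in result[c].uncoded),
    )
    return result


@dataclass(frozen=True)
class SimilarPair:
    """Two same-condition level-5 drugs under the same level-4 class.

    Siblings are reported for review but never merged into the overlap
    partition: sharing a parent class is weaker evidence than an
    ancestor/descendant or identity relation.
    """

    a: Association
    b: Association
    parent_code: str


def find_similar(associations: AssociationSet | Iterable[Association]) -> list[SimilarPair]:
    """All unordered same-condition pairs of distinct level-5 codes
    sharing their level-4 prefix."""
    assocs = (
        list(associations.associations)
        if isinstance(associations, AssociationSet)
        else list(associations)
    )
    pairs: list[SimilarPair] = []
    seen: set[tuple] = set()
    for a, b in itertools.combinations(assocs, 2):
        if a.condition != b.condition or a.drug_key == b.drug_key:
            continue
        for ca, cb in itertools.product(a.atc_codes, b.atc_codes):
            if len(ca) == 7 and len(cb) == 7 and ca != cb and ca[:5] == cb[:5]:
                ident = (a.condition, frozenset((a.drug_key, b.drug_key)), ca[:5])
                if ident not in seen:
                    seen.add(ident)
                    first, second = sorted((a, b), key=lambda x: (x.drug_key, x.source))
                    pairs.append(SimilarPair(a=first, b=second, parent_code=ca[:5]))
    return sorted(pairs, key=lambda p: (p.a.condition, p.parent_code, p.a.drug_key, p.b.drug_key))
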