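import itertools
import random

import networkx as nx
import pytest

from guidelink import (
    AssociationSet,
    atc_ancestors,
    compute_overlap,
    find_similar,
    is_taxonomic_match,
    parse_atc,
)
from guidelink.errors import AtcFormatError

from conftest import make_assoc, random_coded_associations


class TestParseAtc:
    @pytest.mark.parametrize(
        "code,level",
        [("C", 1), ("C03", 2), ("C03D", 3), ("C03DA", 4), ("C03DA04", 5), ("J07AL", 4)],
    )
    def test_level_from_length(self, code, level):
        parsed = parse_atc(code)
        assert parsed.level == level and parsed.code == code

    def test_lowercase_accepted_and_uppercased(self):
        assert parse_atc("c03da04").code == "C03DA04"

    @pytest.mark.parametrize("bad", ["", "C03DA4", "C0", "1ABCD", "C03DA045", "C03dA0x"])
    def test_invalid_shapes_rejected(self, bad):
        with pytest.raises(AtcFormatError):
            parse_atc(bad)


def oracle_ancestors(code):
    """Repeated single-step parent truncation over the level-length table."""
    lengths = [1, 3, 4, 5, 7]
    out = []
    current = code
    while len(current) > 1:
        shorter = max(l for l in lengths if l < len(current))
        current = current[:shorter]
        out.append(current)
    return out


class TestAtcAncestors:
    def test_worked_examples(self):
        assert [a.code for a in atc_ancestors("C03DA04")] == ["C03DA", "C03D", "C03", "C"]
        assert [a.code for a in atc_ancestors("J07AL")] == ["J07A", "J07", "J"]
        assert atc_ancestors("C") == []

    def test_matches_truncation_oracle_on_random_codes(self):
        rng = random.Random(1)
        for _ in range(200):
            l4 = f"{rng.choice('ABCJ')}{rng.randrange(100):02d}{rng.choice('ABD')}{rng.choice('ALX')}"
            code = rng.choice([l4[:1], l4[:3], l4[:4], l4, f"{l4}{rng.randrange(1, 100):02d}"])
            assert [a.code for a in atc_ancestors(code)] == oracle_ancestors(code)

    def test_strict_partial_order(self):
        codes = ["C", "C03", "C03D", "C03DA", "C03DA04"]
        anc = {c: {a.code for a in atc_ancestors(c)} for c in codes}
        for c in codes:
            assert c not in anc[c]  # irreflexive
        for a, b in itertools.permutations(codes, 2):
            if a in anc[b]:
                assert anc[a] <= anc[b]  # transitive


class TestIsTaxonomicMatch:
    def test_class_over_drug_is_ancestor(self):
        cpg = make_assoc("aldosterone antagonists", "ihd", "CPG", ("C03DA",))
        spl = make_assoc("eplerenone", "ihd", "SPL", ("C03DA04",))
        assert is_taxonomic_match(cpg, spl) == "cpg_is_ancestor"
        assert is_taxonomic_match(spl, cpg) == "cpg_is_ancestor"

    def test_siblings_do_not_match(self):
        a = make_assoc("eplerenone", "hf", "CPG", ("C03DA04",))
        b = make_assoc("spironolactone", "hf", "SPL", ("C03DA01",))
        assert is_taxonomic_match(a, b) is None

    def test_condition_mismatch(self):
        a = make_assoc("digoxin", "hf", "CPG", ("C01AA05",))
        b = make_assoc("digoxin", "atrial fibrillation", "SPL", ("C01AA05",))
        assert is_taxonomic_match(a, b) is None

    def test_identical_by_key_or_code(self):
        a = make_assoc("digoxin", "hf", "CPG", ())
        b = make_assoc("digoxin", "hf", "SPL", ())
        assert is_taxonomic_match(a, b) == "identical"
        c = make_assoc("digoxin brand", "hf", "SPL", ("C01AA05",))
        d = make_assoc("digoxin", "hf", "CPG", ("C01AA05",))
        assert is_taxonomic_match(c, d) == "identical"

    def test_any_code_suffices(self):
        a = make_assoc("combo", "hf", "CPG", ("A01", "C03DA"))
        b = make_assoc("eplerenone", "hf", "SPL", ("C03DA04",))
        assert is_taxonomic_match(a, b) == "cpg_is_ancestor"


def oracle_overlap(cpg, spl, use_taxonomy):
    """Overlap partition counts via networkx connected components."""
    counts = {}
    conditions = sorted(set(cpg.by_condition) | set(spl.by_condition))
    for cond in conditions:
        nodes = list(cpg.by_condition.get(cond, ())) + list(spl.by_condition.get(cond, ()))
        graph = nx.Graph()
        graph.add_nodes_from(range(len(nodes)))
        for i, j in itertools.combinations(range(len(nodes)), 2):
            a, b = nodes[i], nodes[j]
            if use_taxonomy:
                if a.source != b.source and is_taxonomic_match(a, b):
                    graph.add_edge(i, j)
            else:
                if a.drug_key == b.drug_key:
                    graph.add_edge(i, j)
        both = cpg_only = spl_only = 0
        for component in nx.connected_components(graph):
            sides = {nodes[i].source for i in component}
            if sides == {"CPG", "SPL"}:
                both += 1
            elif sides == {"CPG"}:
                cpg_only += 1
            else:
                spl_only += 1
        counts[cond] = (both, cpg_only, spl_only)
    counts["ALL"] = tuple(map(sum, zip(*(counts[c] for c in conditions))))
    return counts


class TestComputeOverlap:
    def worked_sets(self):
        cpg = AssociationSet(associations=(
            make_assoc("aldosterone antagonists", "ihd", "CPG", ("C03DA",)),
            make_assoc("pneumococcal vaccines", "hf", "CPG", ("J07AL",)),
        ), side="CPG")
        spl = AssociationSet(associations=(
            make_assoc("eplerenone", "ihd", "SPL", ("C03DA04",)),
        ), side="SPL")
        return cpg, spl

    def test_worked_example_with_taxonomy(self):
        cpg, spl = self.worked_sets()
        parts = compute_overlap(cpg, spl, use_taxonomy=True)
        assert parts["ALL"].counts == (1, 1, 0)
        (group,) = parts["ihd"].both
        assert {m.drug_key for m in group.members} == {"aldosterone antagonists", "eplerenone"}
        # most specific member represents the merged group
        assert {r.drug_key for r in group.representatives} == {"eplerenone"}
        assert {m.drug_key for m in parts["hf"].cpg_only[0].members} == {"pneumococcal vaccines"}

    def test_worked_example_without_taxonomy(self):
        cpg, spl = self.worked_sets()
        parts = compute_overlap(cpg, spl, use_taxonomy=False)
        assert parts["ALL"].counts == (0, 2, 1)

    def test_class_linked_to_two_siblings_forms_one_group(self):
        cpg = AssociationSet(associations=(
            make_assoc("aldosterone antagonists", "hf", "CPG", ("C03DA",)),
        ), side="CPG")
        spl = AssociationSet(associations=(
            make_assoc("eplerenone", "hf", "SPL", ("C03DA04",)),
            make_assoc("spironolactone", "hf", "SPL", ("C03DA01",)),
        ), side="SPL")
        parts = compute_overlap(cpg, spl, use_taxonomy=True)
        assert parts["ALL"].counts == (1, 0, 0)
        (group,) = parts["hf"].both
        assert len(group.members) == 3
        assert {r.drug_key for r in group.representatives} == {"eplerenone", "spironolactone"}

    def test_uncoded_participate_by_exact_key_and_are_flagged(self):
        cpg = AssociationSet(associations=(make_assoc("digoxin", "hf", "CPG", ()),), side="CPG")
        spl = AssociationSet(associations=(make_assoc("digoxin", "hf", "SPL", ()),), side="SPL")
        parts = compute_overlap(cpg, spl, use_taxonomy=True)
        assert parts["hf"].counts == (1, 0, 0)
        assert len(parts["hf"].uncoded) == 2

    def test_random_instances_match_oracle_and_invariants(self):
        rng = random.Random(99)
        for _ in range(60):
            cpg = random_coded_associations(rng, "CPG", rng.randrange(1, 20))
            spl = random_coded_associations(rng, "SPL", rng.randrange(1, 20))
            for use_taxonomy in (False, True):
                parts = compute_overlap(cpg, spl, use_taxonomy)
                expected = oracle_overlap(cpg, spl, use_taxonomy)
                for cond, counts in expected.items():
                    assert parts[cond].counts == counts
            exact = compute_overlap(cpg, spl, False)["ALL"]
            taxo = compute_overlap(cpg, spl, True)["ALL"]
            # merging can only collapse groups, never split them
            assert taxo.total_groups <= exact.total_groups
            exact_both_keys = set().union(*(g.drug_keys for g in exact.both), set())
            taxo_both_keys = set().union(*(g.drug_keys for g in taxo.both), set())
            assert exact_both_keys <= taxo_both_keys

    def test_partition_disjointness(self):
        rng = random.Random(3)
        cpg = random_coded_associations(rng, "CPG", 15)
        spl = random_coded_associations(rng, "SPL", 15)
        for part in compute_overlap(cpg, spl, True).values():
            ids = [id(g) for bucket in (part.both, part.cpg_only, part.spl_only) for g in bucket]
            assert len(ids) == len(set(ids))
            assert part.total_groups == sum(part.counts)


def oracle_similar(assocs):
    out = set()
    for a, b in itertools.combinations(assocs, 2):
        if a.condition != b.condition or a.drug_key == b.drug_key:
            continue
        for ca in a.atc_codes:
            for cb in b.atc_codes:
                if len(ca) == 7 and len(cb) == 7 and ca != cb and ca[:5] == cb[:5]:
                    out.add((a.condition, frozenset((a.drug_key, b.drug_key)), ca[:5]))
    return out


class TestFindSimilar:
    def test_sibling_pair_reported(self):
        assocs = AssociationSet(associations=(
            make_assoc("eplerenone", "hf", "CPG", ("C03DA04",)),
            make_assoc("spironolactone", "hf", "SPL", ("C03DA01",)),
        ), side="CPG")
        (pair,) = find_similar(assocs)
        assert pair.parent_code == "C03DA"
        assert {pair.a.drug_key, pair.b.drug_key} == {"eplerenone", "spironolactone"}

    def test_different_parents_not_similar(self):
        assocs = [
            make_assoc("a", "hf", "CPG", ("C03DA04",)),
            make_assoc("b", "hf", "SPL", ("C03DB01",)),
        ]
        assert find_similar(assocs) == []

    def test_matches_all_pairs_oracle(self):
        rng = random.Random(17)
        for _ in range(40):
            pool = random_coded_associations(rng, "CPG", rng.randrange(2, 25)).associations
            found = {(p.a.condition, frozenset((p.a.drug_key, p.b.drug_key)), p.parent_code)
                     for p in find_similar(list(pool))}
            assert found == oracle_similar(pool)
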