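import random

import pandas as pd
import pytest
from lxml import etree

from guidelink import (
    ConditionDefinition,
    GuidelineSummary,
    extract_major_recommendations,
    load_guideline_corpus,
    load_spl_records,
    map_icd9_to_cuis,
    select_guidelines,
)
from guidelink.errors import ConfigurationError, ExtractionError, FormatError


class TestMapIcd9ToCuis:
    CROSSWALK = {"A": {"C1"}, "B": {"C2"}, "C": {"C3"}}

    def test_lookup_union(self):
        result = map_icd9_to_cuis({"A", "B"}, self.CROSSWALK)
        assert result.cuis == {"C1", "C2"}
        assert not result.unmapped

    def test_one_to_many(self):
        result = map_icd9_to_cuis({"A"}, {"A": {"C1", "C2"}})
        assert result.cuis == {"C1", "C2"}

    def test_missing_codes_reported(self):
        result = map_icd9_to_cuis({"A", "Z"}, self.CROSSWALK)
        assert result.cuis == {"C1"}
        assert result.unmapped == {"Z"}

    def test_empty_crosswalk_rejected(self):
        with pytest.raises(ConfigurationError):
            map_icd9_to_cuis({"A"}, {})

    def test_random_set_matches_per_code_scan(self):
        rng = random.Random(5)
        crosswalk = {}
        for _ in range(100):
            crosswalk.setdefault(f"{rng.randrange(60):03d}", set()).add(f"C{rng.randrange(40)}")
        codes = {f"{rng.randrange(80):03d}" for _ in range(30)}
        expected_cuis, expected_missing = set(), set()
        for code in codes:  # brute-force per-code scan
            if code in crosswalk:
                expected_cuis |= crosswalk[code]
            else:
                expected_missing.add(code)
        result = map_icd9_to_cuis(codes, crosswalk)
        assert result.cuis == expected_cuis
        assert result.unmapped == expected_missing


def make_guideline(doc_id, cuis, flags=(), commentary=False, text="Use drug X."):
    return GuidelineSummary(
        doc_id=doc_id, title=doc_id, major_recommendations=text,
        tagged_cuis=frozenset(cuis), population_flags=frozenset(flags),
        is_commentary=commentary,
    )


class TestSelectGuidelines:
    def condition(self, name="X", cuis=("C1",)):
        return ConditionDefinition(name=name, icd9_codes=frozenset({"001"}), cuis=frozenset(cuis))

    def test_tag_intersection(self):
        corpus = [make_guideline("g1", {"C1"}), make_guideline("g2", {"C2"}),
                  make_guideline("g3", {"C1", "C2"})]
        selection = select_guidelines(corpus, [self.condition()])
        assert [g.doc_id for g in selection["X"]] == ["g1", "g3"]

    def test_population_flag_excludes_despite_tags(self):
        corpus = [make_guideline("g1", {"C1"}),
                  make_guideline("g3", {"C1", "C2"}, flags={"pediatric_only"})]
        selection = select_guidelines(corpus, [self.condition()])
        assert [g.doc_id for g in selection["X"]] == ["g1"]

    def test_commentary_excluded(self):
        corpus = [make_guideline("g1", {"C1"}, commentary=True)]
        assert select_guidelines(corpus, [self.condition()])["X"] == []

    def test_multi_condition_assignment(self):
        corpus = [make_guideline("g1", {"C1", "C2"})]
        conditions = [self.condition("X", ("C1",)), self.condition("Y", ("C2",))]
        selection = select_guidelines(corpus, conditions)
        assert selection["X"] == selection["Y"] == [corpus[0]]

    def test_invariant_to_corpus_order(self):
        corpus = [make_guideline(f"g{i}", {"C1"}) for i in range(6)]
        shuffled = corpus[::-1]
        a = select_guidelines(corpus, [self.condition()])
        b = select_guidelines(shuffled, [self.condition()])
        assert [g.doc_id for g in a["X"]] == [g.doc_id for g in b["X"]]

    def test_matches_generator_ground_truth(self, small_bundle):
        from guidelink import load_condition_definitions

        bundle = small_bundle
        conditions = load_condition_definitions(bundle.conditions_csv, bundle.crosswalk_csv)
        corpus = load_guideline_corpus(bundle.corpus_jsonl)
        selection = select_guidelines(corpus, conditions)
        selected = {g.doc_id for docs in selection.values() for g in docs}
        assert selected == set(bundle.truth.planted_mentions)


class TestExtractMajorRecommendations:
    def test_single_section(self):
        root = etree.fromstring(
            '<doc><section title="Major Recommendations">Use drug X.</section></doc>'
        )
        assert extract_major_recommendations(root) == "Use drug X."

    def test_nested_elements_depth_first(self):
        root = etree.fromstring(
            '<doc><section title="Major Recommendations">'
            "<p>Use <b>drug X</b> first.</p><p>Then drug Y.</p></section></doc>"
        )
        assert extract_major_recommendations(root) == "Use drug X first. Then drug Y."

    def test_missing_section_raises_with_doc_id(self):
        root = etree.fromstring('<doc id="g42"><section title="Other"/></doc>')
        with pytest.raises(ExtractionError, match="g42"):
            extract_major_recommendations(root)

    def test_fixture_file_roundtrip(self, tmp_path):
        text = "Digoxin only for patients who remain symptomatic."
        path = tmp_path / "g1.xml"
        path.write_text(
            f'<doc id="g1"><title>t</title>'
            f'<section title="Major Recommendations">{text}</section></doc>'
        )
        assert extract_major_recommendations(path) == text
        (summary,) = load_guideline_corpus(tmp_path)
        assert summary.doc_id == "g1" and summary.major_recommendations == text


class TestLoadSplRecords:
    def write(self, path, rows):
        pd.DataFrame(rows, columns=["label_id", "drug_name", "atc_codes", "indication_cuis"]).to_csv(
            path, sep="\t", index=False
        )

    def test_lookup_fills_missing_codes(self, tmp_path):
        path = tmp_path / "labels.tsv"
        self.write(path, [("L1", "eplerenone", "", "C_ihd")])
        (record,) = load_spl_records(path, {"eplerenone": ("C03DA04",)})
        assert record.atc_codes == ("C03DA04",)
        assert record.atc_source == "lookup"

    def test_unknown_drug_flagged_unresolved(self, tmp_path):
        path = tmp_path / "labels.tsv"
        self.write(path, [("L1", "xyzzy", "", "C1")])
        (record,) = load_spl_records(path, {"eplerenone": ("C03DA04",)})
        assert record.atc_codes == () and record.atc_source == "unresolved"

    def test_file_codes_take_precedence(self, tmp_path):
        path = tmp_path / "labels.tsv"
        self.write(path, [("L1", "eplerenone", "c03da04", "C1;C2")])
        (record,) = load_spl_records(path, {"eplerenone": ("C99XX99",)})
        assert record.atc_codes == ("C03DA04",)
        assert record.indication_cuis == {"C1", "C2"}

    def test_malformed_rows_skipped_until_threshold(self, tmp_path):
        path = tmp_path / "labels.tsv"
        rows = [(f"L{i}", "drug", "", "C1") for i in range(20)] + [("", "", "", "")]
        self.write(path, rows)
        assert len(load_spl_records(path)) == 20
        self.write(path, [("L1", "drug", "", "C1")] + [("", "", "", "")] * 3)
        with pytest.raises(FormatError):
            load_spl_records(path)

    def test_count_matches_generator(self, small_bundle):
        records = load_spl_records(small_bundle.labels_tsv)
        expected = sum(
            len(a.provenance) for a in small_bundle.truth.planted_spl.associations
        )
        assert len(records) == expected
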