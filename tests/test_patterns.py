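import math
from collections import Counter

import pytest

from mainfinder.corpus import (AnnotatedCorpus, Document, Sentence,
                               word_tokenize)
from mainfinder.patterns import (PatternItem, PatternTable,
                                 discriminative_ratio, first_trigram,
                                 matches_string, mine_first_trigrams,
                                 mine_string_patterns, mine_syntactic_patterns,
                                 mine_word_lists, score_patterns,
                                 score_word_frequency, we_verb_pairs)


def make_corpus(pos_texts, neg_texts):
    """One document per sentence; first sentence set is labelled positive."""
    docs, labels = [], {}
    for i, text in enumerate(list(pos_texts) + list(neg_texts)):
        doc_id = f"d{i}"
        docs.append(Document(doc_id, "Title words.", ["Title", "words"],
                             [Sentence.from_text(text, 0)]))
        if i < len(pos_texts):
            labels[(doc_id, 0)] = "main_finding"
    return AnnotatedCorpus(docs, labels)


class TestDiscriminativeRatio:
    def test_direct_arithmetic(self):
        assert discriminative_ratio(10, 100, 5, 100) == pytest.approx(2.0)

    def test_equal_rates_give_one(self):
        assert discriminative_ratio(7, 70, 30, 300) == pytest.approx(1.0)

    def test_zero_negative_hits_gives_infinity_with_warning(self):
        with pytest.warns(UserWarning, match="infinity"):
            assert math.isinf(discriminative_ratio(5, 10, 0, 10))

    def test_zero_class_sizes_rejected(self):
        with pytest.raises(ValueError):
            discriminative_ratio(1, 0, 1, 10)

    @pytest.mark.parametrize("ph,np_,nh,nn", [(3, 17, 5, 113), (1, 9, 8, 21),
                                              (40, 55, 2, 2985)])
    def test_matches_exact_fraction_arithmetic(self, ph, np_, nh, nn):
        from fractions import Fraction
        expected = Fraction(ph, np_) / Fraction(nh, nn)
        assert discriminative_ratio(ph, np_, nh, nn) == pytest.approx(
            float(expected), rel=1e-12)


class TestMatching:
    def test_gap_pattern_matches_begin_end_words(self):
        sent = word_tokenize("We saw an interesting case yesterday")
        assert matches_string("we * case", sent)
        assert not matches_string("case * we", sent)

    def test_plain_string_requires_adjacency(self):
        sent = word_tokenize("We would report this")
        assert not matches_string("we report", sent)
        assert matches_string("we report", word_tokenize("We report this"))

    def test_word_boundaries_respected(self):
        assert not matches_string("port", word_tokenize("We report a case"))

    def test_first_trigram_of_short_sentence_is_none(self):
        assert first_trigram(["two", "words"]) is None
        assert first_trigram(word_tokenize("To report a case")) == "to report a"

    def test_we_verb_detection_positional(self):
        pairs = we_verb_pairs(word_tokenize(
            "In this study we hereby report an injection"))
        assert ("we", "report") in pairs
        assert we_verb_pairs(word_tokenize("The patient recovered")) == set()

    def test_we_verb_detection_with_tagger(self):
        def tagger(tokens):
            tags = {"we": "PRP", "report": "VBP", "describe": "VBP"}
            return [tags.get(t.lower(), "NN") for t in tokens]

        pairs = we_verb_pairs(word_tokenize("Here we briefly describe it"),
                              tagger=tagger)
        assert pairs == {("we", "describe")}


class TestMining:
    def test_planted_string_frequencies_recovered(self):
        pos = ["We report a novel lesion"] * 20
        neg = ["Routine followup was done"] * 95 + ["We report routine care"] * 5
        corpus = make_corpus(pos, neg)
        items = {i.pattern: i for i in mine_string_patterns(corpus)}
        assert "report" in items
        assert items["report"].ratio == pytest.approx((20 / 20) / (5 / 100))

    def test_equal_class_rates_excluded(self):
        pos = ["the lesion was evident here today"] * 10
        neg = ["the lesion was evident here today"] * 10
        assert mine_string_patterns(corpus := make_corpus(pos, neg)) == []

    def test_syntactic_planted_pair_ratio(self):
        pos = ["We describe a rare condition"] * 8 + ["A novel lesion here"] * 2
        neg = ["We describe routine care"] * 10 + ["Normal recovery seen"] * 90
        items = mine_syntactic_patterns(make_corpus(pos, neg))
        by = {i.pattern: i for i in items}
        assert ("we", "describe") in by
        assert by[("we", "describe")].ratio == pytest.approx((8 / 10) / (10 / 100))

    def test_first_trigram_planted_ratio(self):
        pos = ["To report a strange case"] * 5 + ["Another opening sentence"] * 5
        neg = ["To report a followup visit"] * 5 + ["Background sentences here"] * 95
        items = mine_first_trigrams(make_corpus(pos, neg))
        by = {i.pattern: i for i in items}
        assert by["to report a"].ratio == pytest.approx((5 / 10) / (5 / 100))

    def test_word_lists_floors_and_exclusion(self):
        pos = (["striking lesion with unusual border"] * 9
               + ["routine striking lesion with unusual border"])
        neg = (["routine followup imaging normal"] * 30
               + ["striking appearance but routine"] * 2
               + ["rarewordhere appears insufficiently"] * 10)
        corpus = make_corpus(pos, neg)
        feat3 = [PatternItem("string", "unusual", 5.0)]
        items = mine_word_lists(corpus, feat3, min_neg_count=25)
        by = {i.pattern: i for i in items}
        # "unusual" excluded (already a pattern word); "rarewordhere" below
        # the 25-occurrence floor
        assert "unusual" not in by
        assert "rarewordhere" not in by
        assert by["routine"].subtype == "word_negative"
        assert by["routine"].ratio < 0.5

    def test_mined_item_scores_equal_stored_ratio_when_planted(self):
        pos = ["We report a novel lesion today"] * 20
        neg = ["Routine care was provided"] * 90 + \
              ["We report routine findings"] * 10
        corpus = make_corpus(pos, neg)
        items = mine_string_patterns(corpus)
        table = PatternTable(items)
        for item in items:
            pattern_words = [w for w in str(item.pattern).split() if w != "*"]
            sent = ["xx1"] + pattern_words + ["xx2"]
            single = PatternTable([item])
            assert score_patterns(sent, single) == pytest.approx(item.ratio)

    def test_no_mined_item_below_floors(self, mined_table, synth_train):
        n_pos = sum(1 for *_ , lab in synth_train.iter_sentences()
                    if lab != "other")
        for item in mined_table.items:
            assert math.isfinite(item.ratio)
            if item.subtype == "word_negative":
                assert 0.0 < item.ratio < 0.5
            else:
                assert item.ratio > 2.0
        # string items additionally satisfy the >10% positive-frequency floor
        pos_sents = [s for _, s, lab in synth_train.iter_sentences()
                     if lab != "other"]
        for item in mined_table.by_subtype("string"):
            hits = sum(1 for s in pos_sents if matches_string(item.pattern, s))
            assert hits > 0.10 * n_pos

    def test_single_class_corpus_rejected(self):
        with pytest.raises(ValueError):
            mine_string_patterns(make_corpus(["all positive"], []))


class TestScoring:
    def test_printed_pattern_example_sums_to_32_34(self):
        table = PatternTable([
            PatternItem("first_trigram", "to report a", 22.0),
            PatternItem("string", "report", 6.19),
            PatternItem("string", "case", 4.15),
        ])
        sent = word_tokenize(
            "To report a case of OFCD associated with a de novo BCOR "
            "pathogenic variant and highlight the ocular findings and "
            "possible mechanisms.")
        assert score_patterns(sent, table) == pytest.approx(32.34)

    def test_no_matches_scores_zero(self):
        table = PatternTable([PatternItem("string", "report", 6.19)])
        assert score_patterns(["unrelated", "words"], table) == 0.0

    def test_item_counted_once_even_if_repeated(self):
        table = PatternTable([PatternItem("string", "report", 6.0)])
        assert score_patterns(["report", "report", "report"], table) == 6.0

    def test_adding_matched_item_never_decreases_score(self):
        table = PatternTable([PatternItem("string", "report", 6.0),
                              PatternItem("string", "case", 4.0)])
        assert (score_patterns(["we", "report", "case"], table)
                >= score_patterns(["we", "report"], table))

    def test_printed_word_example_sums_to_8_45(self):
        table = PatternTable([
            PatternItem("word_positive", "with", 2.17),
            PatternItem("word_positive", "syndrome", 3.36),
            PatternItem("word_positive", "a", 2.39),
            PatternItem("word_positive", "man", 3.24),
            PatternItem("word_negative", "it", 1 / 2.71),
        ])
        sent = word_tokenize(
            "Following a description about the characteristics of akinetic "
            "mutism (AM) and how it differs from locked-in syndrome (LIS) "
            "and a disorder of consciousness (DOC), we present the case of "
            "David, a 71-year-old man with AM.")
        assert score_word_frequency(sent, table) == pytest.approx(8.45)

    def test_repeated_positive_word_counted_once(self):
        table = PatternTable([PatternItem("word_positive", "novel", 3.0)])
        assert score_word_frequency(["novel"] * 3, table) == pytest.approx(3.0)

    def test_negative_mode_direct_subtracts_stored_ratio(self):
        table = PatternTable([PatternItem("word_negative", "it", 0.4)])
        assert score_word_frequency(["it"], table) == pytest.approx(-2.5)
        assert score_word_frequency(["it"], table,
                                    negative_mode="direct") == pytest.approx(-0.4)


class TestPatternTable:
    def test_tsv_round_trip(self, tmp_path):
        table = PatternTable([
            PatternItem("string", "we * case", 7.5),
            PatternItem("syntactic", ("we", "report"), 16.9),
            PatternItem("first_trigram", "to report a", 22.0),
            PatternItem("word_negative", "it", 0.37),
        ], provenance="unit-test")
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        back = PatternTable.from_tsv(path)
        assert [(i.subtype, i.pattern, i.ratio) for i in back.items] == \
               [(i.subtype, i.pattern, i.ratio) for i in table.items]

    def test_word_item_duplicating_pattern_word_rejected(self):
        with pytest.raises(ValueError, match="duplicates"):
            PatternTable([PatternItem("string", "report", 6.0),
                          PatternItem("word_positive", "report", 3.0)])

    def test_ratio_floor_enforced_on_construction(self):
        with pytest.raises(ValueError):
            PatternItem("string", "weak", 1.5)
        with pytest.raises(ValueError):
            PatternItem("word_negative", "strong", 0.9)
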