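"""BIEO codec, feature extraction, training behavior and evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenomine.corpus_io import EntityMention, TextSpan, tokenize
from phenomine.tagger import (
    CRFModel,
    FeatureTemplateConfig,
    LabelScheme,
    decode_bieo,
    encode_bieo,
    evaluate,
    extract_features,
    f_from,
    predict,
    train_crf,
)
from phenomine.simulate import gen_label_corpus
from phenomine.corpus_io import parse_annotated_xml, load_lexicon, split_corpus

SCHEME = LabelScheme(("AdverseReaction", "Severity"))


def mention(tokens, i, j, etype="AdverseReaction"):
    doc_id = tokens[i].span.doc_id
    start, end = tokens[i].span.start, tokens[j].span.end
    return EntityMention(TextSpan(doc_id, start, end,
                                  " ".join(t.text for t in tokens[i:j + 1])),
                         etype)


class TestLabelScheme:
    def test_tag_inventory(self):
        assert SCHEME.tags[0] == "O"
        assert len(SCHEME.tags) == 1 + 3 * 2
        assert SCHEME.tag_index["B-AdverseReaction"] == 1


class TestBieoCodec:
    @pytest.mark.parametrize("text,run,expected", [
        ("pruritis was seen", (0, 0), ["B-AdverseReaction", "O", "O"]),
        ("injection site hemorrhage", (0, 2),
         ["B-AdverseReaction", "I-AdverseReaction", "E-AdverseReaction"]),
        ("severe rash", (0, 1), ["B-AdverseReaction", "E-AdverseReaction"]),
    ])
    def test_encode_examples(self, text, run, expected):
        toks = tokenize(text)
        tags = encode_bieo(toks, [mention(toks, *run)], SCHEME)
        assert tags == expected

    def test_no_mentions_all_outside(self):
        toks = tokenize("nothing at all here")
        assert encode_bieo(toks, [], SCHEME) == ["O"] * 4

    def test_overlap_rejected(self):
        toks = tokenize("a b c")
        with pytest.raises(ValueError, match="overlap"):
            encode_bieo(toks, [mention(toks, 0, 1), mention(toks, 1, 2)],
                        SCHEME)

    def test_decode_inverse(self):
        toks = tokenize("injection site hemorrhage")
        tags = ["B-AdverseReaction", "I-AdverseReaction", "E-AdverseReaction"]
        ms = decode_bieo(tags, toks)
        assert len(ms) == 1
        assert (ms[0].span.start, ms[0].span.end) == (0, 25)
        assert ms[0].type == "AdverseReaction"

    def test_decode_all_outside(self):
        assert decode_bieo(["O", "O"], tokenize("a b")) == []

    def test_repair_orphan_run(self):
        toks = tokenize("very severe")
        ms = decode_bieo(["I-Severity", "E-Severity"], toks)
        assert len(ms) == 1
        assert ms[0].type == "Severity"
        assert (ms[0].span.start, ms[0].span.end) == (0, 11)

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            decode_bieo(["X-Weird"], tokenize("a"))

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, data):
        n = data.draw(st.integers(3, 12))
        toks = tokenize(" ".join(f"w{i}" for i in range(n)))
        # draw disjoint runs
        runs = []
        i = 0
        while i < n:
            if data.draw(st.booleans()):
                j = min(n - 1, i + data.draw(st.integers(0, 3)))
                etype = data.draw(st.sampled_from(SCHEME.entity_types))
                runs.append((i, j, etype))
                i = j + 2
            else:
                i += 1
        mentions = [mention(toks, i, j, e) for i, j, e in runs]
        decoded = decode_bieo(encode_bieo(toks, mentions, SCHEME), toks)
        assert [(m.span.start, m.span.end, m.type) for m in decoded] == \
            [(m.span.start, m.span.end, m.type) for m in mentions]


class TestFeatures:
    TPL = FeatureTemplateConfig(window=1, affix_max_len=2)

    def test_lexicon_single_token(self):
        feats = extract_features(tokenize("Sepsis occurred"), {"sepsis"},
                                 self.TPL)
        assert "LEX-U" in feats[0]
        assert not any(f.startswith("LEX") for f in feats[1])

    def test_lexicon_multiword_roles(self):
        feats = extract_features(tokenize("injection site hemorrhage"),
                                 {"injection site hemorrhage"}, self.TPL)
        assert ["LEX-B" in feats[0], "LEX-I" in feats[1], "LEX-E" in feats[2]] \
            == [True, True, True]

    def test_longest_match_wins(self):
        lex = {"injection", "injection site"}
        feats = extract_features(tokenize("injection site"), lex, self.TPL)
        assert "LEX-B" in feats[0] and "LEX-E" in feats[1]

    def test_empty_lexicon_no_lex_features(self):
        feats = extract_features(tokenize("sepsis here"), set(), self.TPL)
        assert not any(f.startswith("LEX") for pos in feats for f in pos)

    def test_window_and_affixes_present(self):
        feats = extract_features(tokenize("severe rash"), set(), self.TPL)
        assert "w[-1]=severe" in feats[1]
        assert "w[1]=<pad>" in feats[1]
        assert "pre2=ra" in feats[1] and "suf2=sh" in feats[1]
        assert "bias" in feats[0]


class TestTrainingContracts:
    def _tiny_corpus(self, tmp_path):
        paths, lex_path = gen_label_corpus(tmp_path / "c", 20,
                                           n_entity_types=1, seed=3)
        docs = [parse_annotated_xml(p) for p in paths]
        return docs, load_lexicon(lex_path)

    def test_max_iter_zero_returns_zero_model(self, tmp_path):
        docs, lex = self._tiny_corpus(tmp_path)
        model = train_crf(docs, [], lex, max_iter=0)
        assert not model.state_weights.any()
        assert not model.transition_weights.any()

    def test_zero_model_predicts_nothing(self, tmp_path):
        docs, lex = self._tiny_corpus(tmp_path)
        model = train_crf(docs, [], lex, max_iter=0)
        assert predict(model, docs[0], lex) == []

    def test_training_is_deterministic(self, tmp_path):
        docs, lex = self._tiny_corpus(tmp_path)
        train, dev = docs[:14], docs[14:]
        m1 = train_crf(train, dev, lex, max_iter=25, seed=5)
        m2 = train_crf(train, dev, lex, max_iter=25, seed=5)
        assert np.array_equal(m1.state_weights, m2.state_weights)
        assert np.array_equal(m1.transition_weights, m2.transition_weights)

    def test_recovers_planted_entities(self, tmp_path):
        docs, lex = self._tiny_corpus(tmp_path)
        train, dev = docs[:14], docs[14:]
        model = train_crf(train, dev, lex, max_iter=60, seed=5)
        report = evaluate({d.doc_id: d.mentions for d in dev},
                          {d.doc_id: predict(model, d, lex) for d in dev})
        assert report.micro.f_score >= 80.0

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            train_crf([], [], set())

    def test_save_load_round_trip(self, tmp_path):
        docs, lex = self._tiny_corpus(tmp_path)
        model = train_crf(docs, [], lex, max_iter=10, seed=1)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = CRFModel.load(path)
        assert loaded.scheme == model.scheme
        assert np.allclose(loaded.state_weights, model.state_weights)
        assert loaded.metadata["seed"] == 1
        assert predict(loaded, docs[0], lex) == predict(model, docs[0], lex)


class TestEvaluate:
    def test_f_from_percentages(self):
        assert f_from(88.05, 68.30) == pytest.approx(76.93, abs=0.01)
        assert f_from(0.0, 0.0) == 0.0

    def test_perfect_prediction(self):
        toks = tokenize("rash seen")
        gold = {"d": [mention(toks, 0, 0)]}
        rep = evaluate(gold, gold)
        assert (rep.micro.precision, rep.micro.recall, rep.micro.f_score) \
            == (100.0, 100.0, 100.0)

    def test_partial_overlap_counts(self):
        toks = tokenize("a b c d e f g h i j")
        gold_ms = [mention(toks, i, i) for i in (0, 2, 4, 6)]
        pred_ms = gold_ms[:3] + [mention(toks, 8, 8), mention(toks, 9, 9)]
        rep = evaluate({"d": gold_ms}, {"d": pred_ms})
        assert rep.micro.precision == pytest.approx(60.0)
        assert rep.micro.recall == pytest.approx(75.0)
        assert rep.micro.f_score == pytest.approx(66.67, abs=0.01)

    def test_symmetry_swaps_precision_and_recall(self):
        toks = tokenize("a b c d e")
        gold = {"d": [mention(toks, 0, 0), mention(toks, 2, 2)]}
        pred = {"d": [mention(toks, 0, 0), mention(toks, 4, 4),
                      mention(toks, 3, 3)]}
        r1 = evaluate(gold, pred)
        r2 = evaluate(pred, gold)
        assert r1.micro.precision == pytest.approx(r2.micro.recall)
        assert r1.micro.recall == pytest.approx(r2.micro.precision)

    def test_type_must_match(self):
        toks = tokenize("rash")
        gold = {"d": [mention(toks, 0, 0, "AdverseReaction")]}
        pred = {"d": [mention(toks, 0, 0, "Severity")]}
        assert evaluate(gold, pred).micro.correct_count == 0

    def test_mismatched_doc_ids_rejected(self):
        with pytest.raises(ValueError):
            evaluate({"a": []}, {"b": []})
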