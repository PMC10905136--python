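import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import groupread as gr


def _doc(lemmas, doc_id=("MT", 1, "discussion")):
    return gr.TokenDoc(doc_id=doc_id, lemmas=tuple(lemmas), n_raw_tokens=len(lemmas))


class TestRescale:
    @pytest.mark.parametrize("raw, expected", [(1, 0.0), (9, 1.0), (5, 0.5), (3, 0.25)])
    def test_closed_form(self, raw, expected):
        assert gr.rescale(raw) == expected

    @pytest.mark.parametrize("raw", [0.5, 9.1, -1])
    def test_out_of_range_raises(self, raw):
        with pytest.raises(ValueError):
            gr.rescale(raw)

    @given(st.floats(min_value=1.0, max_value=9.0), st.floats(min_value=1.0, max_value=9.0))
    @settings(max_examples=100, deadline=None)
    def test_strictly_monotone(self, a, b):
        if a < b:
            assert gr.rescale(a) < gr.rescale(b)
        elif a == b:
            assert gr.rescale(a) == gr.rescale(b)


class TestScoreDoc:
    def test_hand_computed_mean(self, tiny_lexicon):
        # a twice (raw 5 -> 0.5), b once (raw 9 -> 1.0): mean = 2/3
        prof = gr.score_doc(_doc(["a", "a", "b"]), tiny_lexicon)
        assert prof.mean.valence == pytest.approx(2 / 3, abs=1e-12)
        assert prof.sd[0] == pytest.approx(math.sqrt(1 / 12), abs=1e-12)

    def test_single_word_doc(self, tiny_lexicon):
        prof = gr.score_doc(_doc(["calm"]), tiny_lexicon)
        assert prof.mean.valence == gr.rescale(7)
        assert prof.mean.arousal == gr.rescale(2)
        assert prof.sd == (0.0, 0.0, 0.0)

    def test_unmatched_tokens_counted_in_coverage_not_imputed(self, tiny_lexicon):
        prof = gr.score_doc(_doc(["a", "zzz", "b", "qqq"]), tiny_lexicon)
        assert prof.n_scored == 2
        assert prof.coverage == 0.5
        assert prof.mean.valence == pytest.approx(0.75)

    def test_no_match_raises(self, tiny_lexicon):
        with pytest.raises(ValueError, match="no token matched"):
            gr.score_doc(_doc(["zzz"]), tiny_lexicon)

    def test_bag_of_words_order_invariance(self, tiny_lexicon):
        a = gr.score_doc(_doc(["a", "b", "c", "calm"]), tiny_lexicon)
        b = gr.score_doc(_doc(["calm", "c", "b", "a"]), tiny_lexicon)
        assert a.mean == b.mean and a.sd == b.sd

    def test_token_duplication_preserves_mean_and_population_sd(self, tiny_lexicon):
        doc1 = _doc(["a", "b", "storm"])
        doc2 = _doc(["a", "b", "storm"] * 2)
        p1 = gr.score_doc(doc1, tiny_lexicon, ddof=0)
        p2 = gr.score_doc(doc2, tiny_lexicon, ddof=0)
        assert p1.mean == p2.mean
        assert p1.sd == pytest.approx(p2.sd, abs=1e-15)

    def test_mean_commutes_with_rescale(self, tiny_lexicon):
        """Mean of rescaled values equals rescaled mean of raw values."""
        lemmas = ["a", "b", "c", "calm", "storm"]
        prof = gr.score_doc(_doc(lemmas), tiny_lexicon)
        raw_mean = np.mean([tiny_lexicon.entries[l][0] for l in lemmas])
        assert prof.mean.valence == pytest.approx(gr.rescale(raw_mean), abs=1e-12)


class TestGroupSummary:
    def test_equal_sized_sessions_average(self, tiny_lexicon):
        # session 1: b,b (V=1.0); session 2: a,a (V=0.5) -> pooled 0.75
        docs = [
            _doc(["b", "b"], ("MT", 1, "discussion")),
            _doc(["a", "a"], ("MT", 2, "discussion")),
        ]
        term, session = gr.group_summary(docs, tiny_lexicon)
        val = term[term["dimension"] == "valence"].iloc[0]
        assert val["mean"] == pytest.approx(0.75)
        assert set(session["session"]) == {1, 2}

    def test_single_session_term_equals_session(self, tiny_lexicon):
        docs = [_doc(["a", "b", "c"], ("MT", 1, "discussion"))]
        term, session = gr.group_summary(docs, tiny_lexicon)
        sv = session[session["dimension"] == "valence"]["mean"].iloc[0]
        tv = term[term["dimension"] == "valence"]["mean"].iloc[0]
        assert tv == pytest.approx(sv)

    def test_pooled_vs_mean_of_means_weighting(self, tiny_lexicon):
        # unequal session sizes separate the two conventions
        docs = [
            _doc(["b"], ("MT", 1, "discussion")),
            _doc(["a", "a", "a"], ("MT", 2, "discussion")),
        ]
        pooled, _ = gr.group_summary(docs, tiny_lexicon, weighting="pooled")
        momeans, _ = gr.group_summary(docs, tiny_lexicon, weighting="mean_of_means")
        pv = pooled[pooled["dimension"] == "valence"]["mean"].iloc[0]
        mv = momeans[momeans["dimension"] == "valence"]["mean"].iloc[0]
        assert pv == pytest.approx((1.0 + 3 * 0.5) / 4)
        assert mv == pytest.approx((1.0 + 0.5) / 2)

    def test_generator_parameter_recovery(self):
        """Term average of a synthetic group recovers the generator's target
        mean valence within Monte-Carlo error."""
        config = gr.SynthConfig(
            seed=11, vocab_size=2000, discussion_length=2000, sessions_per_group=4,
            vad_target=(0.55, 0.45, 0.5), group_vad_target={}, overlap=0.3,
        )
        corpus = gr.make_corpus(config)
        docs = [
            gr.make_token_doc(t.text, (g, s, "discussion"))
            for (g, s), t in corpus["transcripts"].items()
            if g == "MT"
        ]
        term, _ = gr.group_summary(docs, corpus["lexicon"])
        val = term[term["dimension"] == "valence"]["mean"].iloc[0]
        assert abs(val - 0.55) < 0.02


class TestDecileTiers:
    def _lexicon_with_values(self, values):
        entries = {
            f"t{i:03d}": (1.0 + 8.0 * v, 5.0, 5.0) for i, v in enumerate(values)
        }
        return gr.NormLexicon(entries=entries)

    def test_twenty_types_give_two_type_tiers(self):
        values = [round(0.01 * i, 2) for i in range(1, 21)]  # 0.01 .. 0.20
        lexicon = self._lexicon_with_values(values)
        doc = _doc(sorted(lexicon.entries))
        report = gr.decile_tiers([doc], lexicon, "valence")
        assert [w for w, _ in report.bottom_decile_words] == ["t000", "t001"]
        assert [w for w, _ in report.top_decile_words] == ["t019", "t018"]

    def test_frequencies_are_token_counts(self):
        values = [0.01 * i for i in range(1, 21)]
        lexicon = self._lexicon_with_values(values)
        doc = _doc(list(lexicon.entries) + ["t000"] * 4)
        report = gr.decile_tiers([doc], lexicon, "valence")
        assert dict(report.bottom_decile_words)["t000"] == 5

    def test_too_few_types_raises(self, tiny_lexicon):
        with pytest.raises(ValueError, match=">= 10"):
            gr.decile_tiers([_doc(["a", "b", "c"])], tiny_lexicon, "valence")

    def test_all_tied_values_degenerate(self):
        lexicon = self._lexicon_with_values([0.5] * 20)
        doc = _doc(sorted(lexicon.entries))
        with pytest.raises(ValueError, match="degenerate"):
            gr.decile_tiers([doc], lexicon, "valence")

    def test_tier_values_lie_in_their_decile_range(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0.0, 1.0, size=57)
        lexicon = self._lexicon_with_values(values)
        doc = _doc(sorted(lexicon.entries))
        report = gr.decile_tiers([doc], lexicon, "valence")
        vals = {w: (lexicon.entries[w][0] - 1) / 8 for w in lexicon.entries}
        top_vals = [vals[w] for w, _ in report.top_decile_words]
        bottom_vals = [vals[w] for w, _ in report.bottom_decile_words]
        others = [
            vals[w] for w in lexicon.entries
            if w not in dict(report.top_decile_words)
            and w not in dict(report.bottom_decile_words)
        ]
        assert min(top_vals) >= max(others)
        assert max(bottom_vals) <= min(others)

    def test_planted_high_valence_subvocabulary_dominates_top_tier(self):
        rng = np.random.default_rng(5)
        entries = {
            f"bg{i:03d}": (1.0 + 6.0 * rng.random(), 5.0, 5.0) for i in range(90)
        }
        planted = {f"joy{i}": (8.5 + 0.05 * i, 5.0, 5.0) for i in range(9)}
        entries.update(planted)
        lexicon = gr.NormLexicon(entries=entries)
        doc = _doc(sorted(entries))
        report = gr.decile_tiers([doc], lexicon, "valence")
        top_words = {w for w, _ in report.top_decile_words}
        assert top_words <= set(planted)
        assert len(top_words) == 9

    def test_cross_group_exclusion(self):
        lexicon = self._lexicon_with_values([0.01 * i for i in range(1, 31)])
        words = sorted(lexicon.entries)
        doc_a = _doc(words, ("MT", 1, "discussion"))
        doc_b = _doc(words[:-1], ("HT", 1, "discussion"))  # b lacks the top word
        rep_a = gr.decile_tiers([doc_a], lexicon, "valence")
        rep_b = gr.decile_tiers([doc_b], lexicon, "valence")
        ex_a, ex_b = gr.exclude_common(rep_a, rep_b)
        shared_top = {w for w, _ in rep_a.top_decile_words} & {
            w for w, _ in rep_b.top_decile_words
        }
        assert all(w not in shared_top for w, _ in ex_a.top_decile_words)
        assert all(w not in shared_top for w, _ in ex_b.top_decile_words)


class TestVolatility:
    def test_constant_values_zero_sd(self, tiny_lexicon):
        out = gr.volatility(_doc(["a", "a", "a"]), tiny_lexicon)
        assert out["word_sd"] == (0.0, 0.0, 0.0)

    def test_zero_one_closed_form(self):
        lexicon = gr.NormLexicon(entries={"lo": (1.0, 1.0, 1.0), "hi": (9.0, 9.0, 9.0)})
        doc = _doc(["lo", "hi"])
        population = gr.volatility(doc, lexicon, ddof=0)
        sample = gr.volatility(doc, lexicon, ddof=1)
        assert population["word_sd"][0] == pytest.approx(0.5)
        assert sample["word_sd"][0] == pytest.approx(math.sqrt(0.5), abs=1e-12)

    def test_session_mean_reported(self, tiny_lexicon):
        out = gr.volatility(_doc(["a", "b"]), tiny_lexicon)
        assert out["session_mean"].valence == pytest.approx(0.75)

    def test_single_observation_raises(self, tiny_lexicon):
        with pytest.raises(ValueError, match="at least 2"):
            gr.volatility(_doc(["a"]), tiny_lexicon)

    def test_generator_sd_recovery(self):
        """Word-level SD of a register-steered synthetic session recovers the
        generator's kernel width within sampling error."""
        config = gr.SynthConfig(
            seed=9, vocab_size=5000, discussion_length=4000, overlap=0.0,
            vad_target=(0.5, 0.5, 0.5), group_vad_target={}, vad_noise=0.1,
        )
        lexicon = gr.make_lexicon(config)
        _, transcript, _ = gr.make_session(config, lexicon, "MT", 1)
        doc = gr.make_token_doc(transcript.text, ("MT", 1, "discussion"))
        out = gr.volatility(doc, lexicon)
        for sd in out["word_sd"]:
            assert abs(sd - 0.1) < 0.02
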