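import numpy as np
import pytest

import groupread as gr


@pytest.fixture(scope="session")
def tiny_lexicon() -> gr.NormLexicon:
    """Hand-built norm lexicon with raw 1-9 values chosen for easy mental
    arithmetic after rescaling: 1 -> 0, 5 -> 0.5, 9 -> 1."""
    return gr.NormLexicon(
        entries={
            "a": (5.0, 5.0, 5.0),
            "b": (9.0, 1.0, 9.0),
            "c": (1.0, 9.0, 1.0),
            "calm": (7.0, 2.0, 6.0),
            "storm": (3.0, 8.0, 4.0),
        }
    )


@pytest.fixture()
def transcript_file(tmp_path):
    def _make(content: str, name: str = "MT_S1_discussion.txt"):
        path = tmp_path / name
        path.write_text(content, encoding="utf-8")
        return path

    return _make


@pytest.fixture(scope="session")
def small_corpus():
    """One deterministic synthetic corpus shared by read-only tests."""
    config = gr.SynthConfig(
        seed=42, vocab_size=300, topic_size=50, text_length=150, discussion_length=150,
        sessions_per_group=3,
    )
    return gr.make_corpus(config)


def token_docs(corpus) -> dict:
    docs = {}
    for (g, s), t in corpus["transcripts"].items():
        docs[(g, s, "discussion")] = gr.make_token_doc(t.text, (g, s, "discussion"))
    for (g, s), seg in corpus["segments"].items():
        docs[(g, s, "text")] = gr.make_token_doc(seg.text, (g, s, "text"))
    return docs
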