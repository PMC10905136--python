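"""Cleaning pipeline: raw text -> lowercase lemma sequences.

The pipeline mirrors standard corpus practice for conversational data:
whitespace tokenization, case folding, punctuation stripping, lemmatization
and stopword removal. Sentence-length statistics (mean tokens per sentence,
computed before stopword removal) feed downstream as the context window of
the paragraph-vector embedder, since window size should reflect discourse
span rather than filtered token density.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Sequence

from .corpus_io import Transcript

Lemmatizer = Callable[[str], str]

# Bracketed stage directions ("[laughter]", "[pause]") are non-speech.
_STAGE_RE = re.compile(r"\[[^\][]*\]")
# Hyphens, en/em dashes and slashes split tokens.
_SPLIT_RE = re.compile(r"[-‐‑‒–—/]+")
# Characters stripped from token edges; internal apostrophes survive.
_EDGE_PUNCT = "".join(
    [
        "!\"#$%&'()*+,./:;<=>?@[\\]^_`{|}~",
        "‘’“”…«»¡¿",
    ]
)
_SENT_RE = re.compile(r"[.!?]+")


def tokenize(text: str, keep_stage_directions: bool = False) -> list[str]:
    """Split text into case-folded raw tokens.

    Splits on whitespace (and dashes/slashes), strips leading/trailing
    punctuation, keeps internal apostrophes, and removes bracketed stage
    directions before splitting unless asked to keep them.
    """
    if not keep_stage_directions:
        text = _STAGE_RE.sub(" ", text)
    tokens: list[str] = []
    for chunk in text.split():
        for piece in _SPLIT_RE.split(chunk):
            tok = piece.strip(_EDGE_PUNCT).lower()
            # normalize curly apostrophe so lexicon lookups are stable
            tok = tok.replace("’", "'")
            if tok:
                tokens.append(tok)
    return tokens


# ---------------------------------------------------------------------------
# Lemmatization backends
# ---------------------------------------------------------------------------


def _load_exceptions() -> dict[str, str]:
    out: dict[str, str] = {}
    ref = resources.files("groupread.resources") / "lemma_exceptions.tsv"
    for line in ref.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        form, lemma = line.split("\t")
        out.setdefault(form.strip(), lemma.strip())
    return out


_VOWELS = set("aeiou")


def _strip_suffix(word: str) -> str:
    """One pass of conservative English suffix rules. Crude by design: the
    bundled backend trades linguistic accuracy for determinism and zero
    model downloads; unknown forms pass through unchanged."""
    n = len(word)
    if word.endswith("ies") and n >= 5:
        return word[:-3] + "y"
    if word.endswith(("ches", "shes", "xes", "zes", "sses")) and n >= 5:
        return word[:-2]
    if word.endswith("s") and not word.endswith(("ss", "us", "is", "'s")) and n >= 4:
        return word[:-1]
    if word.endswith("ing") and n >= 6:
        stem = word[:-3]
        if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS | {"l", "s"}:
            return stem[:-1]  # running -> run
        if len(stem) >= 2 and stem[-1] not in _VOWELS and stem[-2] in _VOWELS and len(stem) <= 4:
            return stem + "e"  # making -> make (short stems only)
        return stem
    if word.endswith("ed") and n >= 5:
        stem = word[:-2]
        if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS | {"l", "s"}:
            return stem[:-1]  # stopped -> stop
        if stem.endswith(("at", "iz", "is", "v", "c", "u")):
            return stem + "e"  # loved -> love, created -> create
        return stem
    return word


class DictLemmatizer:
    """Dictionary + suffix-rule lemmatizer; the package's default backend.

    ``use_rules=False`` gives a pure dictionary backend (unknown forms pass
    through), which doubles as an agreement oracle for the rule backend.
    Output is iterated to a fixed point so lemmatization is idempotent.
    """

    def __init__(self, exceptions: dict[str, str] | None = None, use_rules: bool = True):
        self.exceptions = _load_exceptions() if exceptions is None else dict(exceptions)
        self.use_rules = use_rules

    def __call__(self, token: str) -> str:
        seen = {token}
        current = token
        # Iterate to a fixed point; rules strictly shorten, the seen-set
        # guards against dictionary cycles, so this terminates.
        while True:
            nxt = self.exceptions.get(current)
            if nxt is None:
                nxt = _strip_suffix(current) if self.use_rules else current
            if nxt == current or nxt in seen:
                return nxt
            seen.add(nxt)
            current = nxt


class SpacyLemmatizer:
    """Optional external NLP-model backend (requires spaCy and a model)."""

    def __init__(self, model: str = "en_core_web_sm"):
        try:
            import spacy  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional backend
            raise ImportError(
                "SpacyLemmatizer requires the optional spaCy dependency; "
                "the bundled DictLemmatizer needs no downloads"
            ) from exc
        self._nlp = spacy.load(model, disable=["parser", "ner"])  # pragma: no cover

    def __call__(self, token: str) -> str:  # pragma: no cover - optional backend
        doc = self._nlp(token)
        return doc[0].lemma_.lower() if len(doc) else token


def default_lemmatizer() -> DictLemmatizer:
    return DictLemmatizer()


def load_stopwords(path: str | None = None) -> frozenset[str]:
    """Bundled English stopword list, overridable by file path."""
    if path is None:
        text = (resources.files("groupread.resources") / "stopwords.txt").read_text(
            encoding="utf-8"
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    words = {
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }
    return frozenset(words)


def stopwords_checksum(stopwords: Iterable[str]) -> str:
    from .corpus_io import sha256_text

    return sha256_text("\n".join(sorted(stopwords)))


# ---------------------------------------------------------------------------
# Document cleaning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TokenDoc:
    """A cleaned document: ordered lowercase lemmas plus the raw-token count."""

    doc_id: tuple[str, int, str]  # (group_id, session, kind in {discussion, text})
    lemmas: tuple[str, ...]
    n_raw_tokens: int

    def __post_init__(self) -> None:
        if self.n_raw_tokens < len(self.lemmas):
            raise ValueError("n_raw_tokens cannot be below the lemma count")
        for lem in self.lemmas:
            if not lem or any(c.isspace() for c in lem):
                raise ValueError(f"invalid lemma {lem!r}")

    @property
    def group_id(self) -> str:
        return self.doc_id[0]

    @property
    def session(self) -> int:
        return self.doc_id[1]

    @property
    def kind(self) -> str:
        return self.doc_id[2]


def clean(
    tokens: Sequence[str],
    lemmatizer: Lemmatizer | None = None,
    stopwords: frozenset[str] | None = None,
) -> list[str]:
    """Lemmatize, lowercase, drop stopwords and punctuation-only tokens.

    Order-preserving and idempotent at the lemma level. Stopwords are removed
    both before and after lemmatization (so "is" -> "be" does not smuggle a
    stopword's lemma back in as content, but content lemmas that merely
    collide with a stopword form are still dropped consistently on re-runs).
    """
    lemmatizer = lemmatizer or default_lemmatizer()
    stopwords = load_stopwords() if stopwords is None else stopwords
    out: list[str] = []
    for tok in tokens:
        tok = tok.lower()
        if not any(c.isalnum() for c in tok):
            continue
        if tok in stopwords:
            continue
        lemma = lemmatizer(tok)
        if not lemma or lemma in stopwords:
            continue
        out.append(lemma)
    return out


def make_token_doc(
    text: str,
    doc_id: tuple[str, int, str],
    lemmatizer: Lemmatizer | None = None,
    stopwords: frozenset[str] | None = None,
    keep_stage_directions: bool = False,
) -> TokenDoc:
    raw = tokenize(text, keep_stage_directions=keep_stage_directions)
    lemmas = clean(raw, lemmatizer=lemmatizer, stopwords=stopwords)
    return TokenDoc(doc_id=doc_id, lemmas=tuple(lemmas), n_raw_tokens=len(raw))


# ---------------------------------------------------------------------------
# Sentence statistics (feeds the embedding window)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SentenceStats:
    group_id: str
    mean_sentence_length: float
    n_sentences: int


def split_sentences(text: str) -> list[str]:
    """Split on terminal punctuation; the utterance end is also a boundary."""
    parts = [p.strip() for p in _SENT_RE.split(text)]
    return [p for p in parts if p]


def sentence_stats(transcripts: Iterable[Transcript], group_id: str) -> SentenceStats:
    """Mean raw tokens per sentence over all discussion utterances of a group.

    Token counts are taken before stopword removal; the rounded mean is the
    default context window for the group's embedding model.
    """
    lengths: list[int] = []
    for transcript in transcripts:
        for utt in transcript.utterances:
            for sent in split_sentences(utt.text):
                n = len(tokenize(sent))
                if n:
                    lengths.append(n)
    if not lengths:
        raise ValueError(f"group {group_id!r}: no sentences found")
    return SentenceStats(
        group_id=group_id,
        mean_sentence_length=sum(lengths) / len(lengths),
        n_sentences=len(lengths),
    )
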