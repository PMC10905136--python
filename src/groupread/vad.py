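"""Lexicon-based emotional profiling on the valence-arousal-dominance model.

Every affective state is treated as a point in a three-dimensional space:
valence (pleasant vs unpleasant), arousal (stimulating vs sedating) and
dominance (in control vs controlled). Word norms rated on a 1-9 scale are
rescaled to [0, 1] and a document's emotional profile is the token-weighted
mean (and dispersion) of the rescaled values of its lexicon-matched lemmas.
Unmatched tokens are skipped, never imputed at the scale midpoint — the
norms cover ~14k lemmas and silent midpoint imputation would bias documents
toward neutrality — so coverage is always reported alongside the profile.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .corpus_io import NormLexicon
from .preprocess import TokenDoc

DIMENSIONS: tuple[str, str, str] = ("valence", "arousal", "dominance")
Dimension = Literal["valence", "arousal", "dominance"]
_DIM_INDEX = {d: i for i, d in enumerate(DIMENSIONS)}


@dataclass(frozen=True)
class VADValue:
    valence: float
    arousal: float
    dominance: float

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            v = getattr(self, dim)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{dim}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.valence, self.arousal, self.dominance], dtype=float)

    def __getitem__(self, dim: str) -> float:
        return getattr(self, dim)


@dataclass(frozen=True)
class DocVADProfile:
    """Per-document VAD summary over lexicon-matched lemma tokens."""

    doc_id: tuple[str, int, str]
    mean: VADValue
    sd: tuple[float, float, float]
    n_scored: int
    coverage: float


@dataclass(frozen=True)
class TierReport:
    """Top and bottom decile word lists for one VAD dimension."""

    dimension: str
    top_decile_words: tuple[tuple[str, int], ...]
    bottom_decile_words: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        top = {w for w, _ in self.top_decile_words}
        bottom = {w for w, _ in self.bottom_decile_words}
        if top & bottom:
            raise ValueError("a word cannot sit in both tiers of one report")


def rescale(raw: float, scale: tuple[float, float] = (1.0, 9.0)) -> float:
    """Map a raw rating on ``scale`` to [0, 1]: (raw - min) / (max - min)."""
    lo, hi = scale
    if not lo <= raw <= hi:
        raise ValueError(f"raw value {raw} outside rating scale [{lo}, {hi}]")
    return (raw - lo) / (hi - lo)


def matched_values(
    lemmas: Sequence[str], lexicon: NormLexicon
) -> tuple[np.ndarray, int]:
    """Rescaled (n_matched, 3) VAD values of the lexicon-matched tokens,
    one row per token occurrence, in document order."""
    lo, hi = lexicon.source_scale
    rows = [lexicon.entries[lem] for lem in lemmas if lem in lexicon.entries]
    if not rows:
        return np.empty((0, 3)), len(lemmas)
    values = (np.asarray(rows, dtype=float) - lo) / (hi - lo)
    return values, len(lemmas)


def score_doc(doc: TokenDoc, lexicon: NormLexicon, ddof: int = 1) -> DocVADProfile:
    """Token-weighted VAD mean and standard deviation for one document.

    A lemma occurring k times contributes k observations ("across all the
    words" of the text is read as occurrences, not types). ``ddof=1`` gives
    the sample SD; pass 0 for the population convention.
    """
    values, n_tokens = matched_values(doc.lemmas, lexicon)
    n_scored = values.shape[0]
    if n_scored == 0:
        raise ValueError(f"{doc.doc_id}: no token matched the lexicon; profile undefined")
    mean = values.mean(axis=0)
    if n_scored > ddof:
        sd = values.std(axis=0, ddof=ddof)
    else:
        sd = np.zeros(3)
    return DocVADProfile(
        doc_id=doc.doc_id,
        mean=VADValue(*mean),
        sd=tuple(sd),
        n_scored=n_scored,
        coverage=n_scored / n_tokens if n_tokens else 0.0,
    )


def group_summary(
    docs: Sequence[TokenDoc],
    lexicon: NormLexicon,
    ddof: int = 1,
    weighting: Literal["pooled", "mean_of_means"] = "pooled",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-session VAD table plus group-level "term averages".

    Term averages pool the group's matched word tokens across sessions by
    default (each token one observation); ``mean_of_means`` instead averages
    the per-session means with equal session weights. Returns
    ``(term_table, session_table)`` shaped like a per-dimension summary table:
    one row per dimension with mean and SD.
    """
    if not docs:
        raise ValueError("group_summary needs at least one document")
    profiles = [score_doc(doc, lexicon, ddof=ddof) for doc in docs]

    session_rows = []
    for doc, prof in zip(docs, profiles):
        for dim in DIMENSIONS:
            session_rows.append(
                {
                    "group_id": doc.group_id,
                    "session": doc.session,
                    "dimension": dim,
                    "mean": prof.mean[dim],
                    "sd": prof.sd[_DIM_INDEX[dim]],
                    "n_scored": prof.n_scored,
                    "coverage": prof.coverage,
                }
            )
    session_table = pd.DataFrame(session_rows)

    group_id = docs[0].group_id
    term_rows = []
    if weighting == "pooled":
        all_values = np.vstack([matched_values(doc.lemmas, lexicon)[0] for doc in docs])
        for dim in DIMENSIONS:
            col = all_values[:, _DIM_INDEX[dim]]
            term_rows.append(
                {
                    "group_id": group_id,
                    "dimension": dim,
                    "mean": float(col.mean()),
                    "sd": float(col.std(ddof=ddof)) if col.size > ddof else 0.0,
                    "n_scored": int(col.size),
                }
            )
    elif weighting == "mean_of_means":
        for dim in DIMENSIONS:
            means = np.array([p.mean[dim] for p in profiles])
            term_rows.append(
                {
                    "group_id": group_id,
                    "dimension": dim,
                    "mean": float(means.mean()),
                    "sd": float(means.std(ddof=ddof)) if means.size > ddof else 0.0,
                    "n_scored": int(sum(p.n_scored for p in profiles)),
                }
            )
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return pd.DataFrame(term_rows), session_table


# ---------------------------------------------------------------------------
# Decile word tiers
# ---------------------------------------------------------------------------


def decile_tiers(
    group_docs: Sequence[TokenDoc],
    lexicon: NormLexicon,
    dimension: Dimension,
    n_tiers: int = 10,
) -> TierReport:
    """Decile split of a group's matched vocabulary on one VAD dimension.

    All of the group's documents are concatenated into one corpus; distinct
    matched lemma *types* are ranked by the dimension's rescaled value and cut
    into ``n_tiers`` equal tiers; the extreme tiers are reported with corpus
    token frequencies (these size the word-cloud rendering downstream).
    """
    dim_idx = _DIM_INDEX[dimension]
    lo, hi = lexicon.source_scale
    freqs = Counter(lem for doc in group_docs for lem in doc.lemmas if lem in lexicon.entries)
    if len(freqs) < n_tiers:
        raise ValueError(
            f"decile split needs >= {n_tiers} matched lemma types, got {len(freqs)}"
        )
    types = sorted(freqs)
    values = np.array(
        [(lexicon.entries[t][dim_idx] - lo) / (hi - lo) for t in types]
    )
    if np.allclose(values, values[0]):
        raise ValueError(
            f"degenerate decile split: all {len(types)} types share one "
            f"{dimension} value ({values[0]:.4f})"
        )
    order = np.argsort(values, kind="stable")
    k = len(types) // n_tiers
    bottom_idx = order[:k]
    top_idx = order[-k:]
    bottom = tuple((types[i], freqs[types[i]]) for i in bottom_idx)
    top = tuple((types[i], freqs[types[i]]) for i in reversed(top_idx))
    return TierReport(dimension=dimension, top_decile_words=top, bottom_decile_words=bottom)


def exclude_common(
    report_a: TierReport, report_b: TierReport
) -> tuple[TierReport, TierReport]:
    """Cross-group exclusion: when comparing two groups' tier reports for the
    same dimension, drop words present in both groups' same tier (most words
    carry some positive valence, so shared words dominate both lists and hide
    the group-specific signal)."""
    if report_a.dimension != report_b.dimension:
        raise ValueError("tier reports compare only within one dimension")

    def _filter(own, other):
        other_words = {w for w, _ in other}
        return tuple((w, f) for w, f in own if w not in other_words)

    a = TierReport(
        dimension=report_a.dimension,
        top_decile_words=_filter(report_a.top_decile_words, report_b.top_decile_words),
        bottom_decile_words=_filter(report_a.bottom_decile_words, report_b.bottom_decile_words),
    )
    b = TierReport(
        dimension=report_b.dimension,
        top_decile_words=_filter(report_b.top_decile_words, report_a.top_decile_words),
        bottom_decile_words=_filter(report_b.bottom_decile_words, report_a.bottom_decile_words),
    )
    return a, b


def exclude_within(report: TierReport) -> TierReport:
    """Alternative exclusion mode: drop words appearing in both the top and
    bottom tier of a single report (possible only with tied values)."""
    top_words = {w for w, _ in report.top_decile_words}
    bottom_words = {w for w, _ in report.bottom_decile_words}
    common = top_words & bottom_words
    return TierReport(
        dimension=report.dimension,
        top_decile_words=tuple((w, f) for w, f in report.top_decile_words if w not in common),
        bottom_decile_words=tuple(
            (w, f) for w, f in report.bottom_decile_words if w not in common
        ),
    )


def tier_table(report: TierReport) -> pd.DataFrame:
    rows = [
        {"dimension": report.dimension, "tier": "top", "word": w, "frequency": f}
        for w, f in report.top_decile_words
    ] + [
        {"dimension": report.dimension, "tier": "bottom", "word": w, "frequency": f}
        for w, f in report.bottom_decile_words
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Emotional volatility
# ---------------------------------------------------------------------------


def volatility(
    doc: TokenDoc, lexicon: NormLexicon, ddof: int = 1
) -> dict[str, VADValue | tuple[float, float, float]]:
    """Both operationalizations of a session's emotional volatility:

    ``word_sd`` — within-session word-level SD per dimension (dispersion);
    ``session_mean`` — the per-session mean level itself, the quantity the
    similarity correlation uses by default ("the lower the arousal...").
    """
    values, _ = matched_values(doc.lemmas, lexicon)
    if values.shape[0] < 2:
        raise ValueError("volatility needs at least 2 matched tokens")
    return {
        "word_sd": tuple(values.std(axis=0, ddof=ddof)),
        "session_mean": VADValue(*values.mean(axis=0)),
    }
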