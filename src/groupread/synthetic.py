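"""Seeded generator of reading-group corpora with known ground truth.

Emulates the statistical structure the pipeline assumes: a VAD norm lexicon;
per-session literary segments drawn from session-specific topic
subvocabularies; multi-speaker discussion transcripts whose tokens come from
the session's topic vocabulary with probability ``overlap`` (else from the
background vocabulary) and whose emotional register is steered toward a
target mean VAD value by rejection sampling; and participant feedback tables
with optional planted group effects. Topic structure is a plain vocabulary
partition — enough to give the embedder a recoverable signal while keeping
the oracle analytic — and no attempt is made at linguistically realistic
text.

Every generator is bit-reproducible under (config, seed): each (group,
session) derives its own generator from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import LiterarySegment, NormLexicon, Transcript, Utterance

# Colour-code pseudonyms in the style of the transcription convention.
SPEAKER_CODES = (
    "GOLD", "BLUE", "RED", "GREEN", "SILVER", "VIOLET", "AMBER", "CORAL",
    "IVORY", "OLIVE", "TEAL", "PLUM",
)


@dataclass(frozen=True)
class SynthConfig:
    """Study-shaped defaults: two groups of six analysed sessions, eight
    speakers, 32 feedback items on a 0-5 scale, conversational sentence
    lengths (mean ~12 tokens). VAD targets give the second group slightly
    higher valence/arousal and lower dominance, the contrast the group
    comparison is meant to detect."""

    seed: int = 0
    n_groups: int = 2
    sessions_per_group: int = 6
    vocab_size: int = 1000
    topic_size: int = 80
    text_length: int = 300
    discussion_length: int = 300
    overlap: float = 0.5
    vad_target: tuple[float, float, float] = (0.58, 0.36, 0.62)
    vad_noise: float = 0.1
    n_speakers: int = 8
    sentence_length_mean: float = 12.0
    feedback_items: int = 32
    participants_per_group: tuple[int, ...] = (9, 7)
    planted_item_effects: tuple[tuple[int, float], ...] = ()
    group_ids: tuple[str, ...] = ("MT", "HT")
    # per-group overrides keyed by group id
    group_overlap: Mapping[str, float] = field(default_factory=dict)
    group_vad_target: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"HT": (0.616, 0.381, 0.594)}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")
        if min(self.text_length, self.discussion_length) <= 0:
            raise ValueError("document lengths must be positive")
        for v in self.vad_target:
            if not 0.0 <= v <= 1.0:
                raise ValueError("vad_target components must lie in [0, 1]")
        if self.vocab_size < 20:
            raise ValueError("vocab_size must be >= 20")
        if self.topic_size >= self.vocab_size:
            raise ValueError("topic_size must be below vocab_size")


def _rng_for(config: SynthConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def make_lexicon(
    config: SynthConfig,
    shapes: Mapping[str, tuple[float, float]] | None = None,
) -> NormLexicon:
    """Synthetic norm lexicon ``w0001..wN`` with raw 1-9 ratings.

    Values are uniform on [1, 9] by default; ``shapes`` maps a dimension name
    to Beta(a, b) parameters for skewed rating distributions (real norms are
    valence-skewed: most words are mildly pleasant).
    """
    rng = _rng_for(config, 1)
    n = config.vocab_size
    width = max(4, len(str(n)))
    lemmas = [f"w{i + 1:0{width}d}" for i in range(n)]
    cols = []
    for dim in ("valence", "arousal", "dominance"):
        if shapes and dim in shapes:
            a, b = shapes[dim]
            raw = 1.0 + 8.0 * rng.beta(a, b, size=n)
        else:
            raw = rng.uniform(1.0, 9.0, size=n)
        cols.append(raw)
    values = np.column_stack(cols)
    entries = {lem: tuple(float(v) for v in row) for lem, row in zip(lemmas, values)}
    return NormLexicon(entries=entries)


def _rescaled(lexicon: NormLexicon, lemmas: Sequence[str]) -> np.ndarray:
    lo, hi = lexicon.source_scale
    return (np.asarray([lexicon.entries[l] for l in lemmas], dtype=float) - lo) / (hi - lo)


def _kernel_sample(
    rng: np.random.Generator,
    lemmas: np.ndarray,
    values01: np.ndarray,
    target: np.ndarray,
    sd: float,
    n: int,
) -> np.ndarray:
    """Rejection-sample ``n`` tokens from ``lemmas`` with a Gaussian
    acceptance kernel centred at ``target`` in rescaled VAD space."""
    log_w = -((values01 - target[None, :]) ** 2).sum(axis=1) / (2.0 * sd * sd)
    if log_w.max() < -12.5:  # nearest word > 5 kernel widths from the target
        raise ValueError(
            f"vad target {target.round(3).tolist()} infeasible for this lexicon: "
            f"nearest word is {np.sqrt(-2 * sd * sd * log_w.max()):.3f} away "
            f"(kernel sd {sd})"
        )
    w = np.exp(log_w - log_w.max())
    p = w / w.sum()
    return rng.choice(lemmas, size=n, p=p)


def make_session(
    config: SynthConfig,
    lexicon: NormLexicon,
    group: str,
    session: int,
    overlap: float | None = None,
    vad_target: tuple[float, float, float] | None = None,
) -> tuple[LiterarySegment, Transcript, dict]:
    """One session: a literary segment, a discussion transcript, and the
    ground-truth record (overlap, vad_target, topic words).

    The segment's tokens come from a session-specific topic subvocabulary.
    Each discussion token is topical with probability ``overlap``, otherwise
    background; background draws are rejection-sampled toward the group's
    target mean VAD, with the kernel centre compensated for the topical
    fraction (using the realised topic-subvocabulary mean) so the *document*
    mean lands on the target irrespective of overlap.
    """
    group_idx = config.group_ids.index(group) if group in config.group_ids else 97
    rng = _rng_for(config, 2, group_idx, session)

    if overlap is None:
        overlap = float(config.group_overlap.get(group, config.overlap))
    if vad_target is None:
        vad_target = config.group_vad_target.get(group, config.vad_target)
    target = np.asarray(vad_target, dtype=float)

    all_lemmas = np.array(sorted(lexicon.entries))
    all_values = _rescaled(lexicon, list(all_lemmas))

    topic_idx = rng.choice(all_lemmas.size, size=config.topic_size, replace=False)
    topic_lemmas = all_lemmas[topic_idx]
    topic_values = all_values[topic_idx]

    # Literary segment: uniform draws from the topic subvocabulary.
    text_tokens = rng.choice(topic_lemmas, size=config.text_length)

    # Discussion: topical vs register-steered background tokens.
    is_topic = rng.random(config.discussion_length) < overlap
    n_topic = int(is_topic.sum())
    n_background = config.discussion_length - n_topic
    tokens = np.empty(config.discussion_length, dtype=all_lemmas.dtype)
    register_clipped = False
    if n_topic:
        tokens[is_topic] = rng.choice(topic_lemmas, size=n_topic)
    if n_background:
        if overlap >= 1.0 - 1e-12 or n_topic == config.discussion_length:
            adj_target = target
        else:
            topic_mean = topic_values.mean(axis=0)
            adj_target = (target - overlap * topic_mean) / (1.0 - overlap)
        # At high overlap the background fraction cannot pull the document
        # mean all the way to the target; clamp to the best achievable kernel
        # centre and flag it in the ground truth.
        clipped = np.clip(adj_target, 0.0, 1.0)
        register_clipped = bool(np.any(clipped != adj_target))
        tokens[~is_topic] = _kernel_sample(
            rng, all_lemmas, all_values, clipped, config.vad_noise, n_background
        )

    # Arrange tokens into sentences (Poisson lengths) and round-robin speakers.
    utterances: list[Utterance] = []
    speakers = [SPEAKER_CODES[i % len(SPEAKER_CODES)] for i in range(config.n_speakers)]
    cursor = 0
    turn = 0
    while cursor < tokens.size:
        n_sent = max(1, int(rng.poisson(config.sentence_length_mean)))
        sent = tokens[cursor : cursor + n_sent]
        cursor += n_sent
        utterances.append(
            Utterance(
                speaker=speakers[turn % len(speakers)],
                text=" ".join(sent) + ".",
                index=turn,
            )
        )
        turn += 1

    text_sents: list[str] = []
    tcursor = 0
    while tcursor < text_tokens.size:
        n_sent = max(1, int(rng.poisson(config.sentence_length_mean)))
        text_sents.append(" ".join(text_tokens[tcursor : tcursor + n_sent]) + ".")
        tcursor += n_sent

    segment = LiterarySegment(
        group_id=group,
        session=session,
        title=f"synthetic-text-{group}-S{session}",
        text=" ".join(text_sents),
    )
    transcript = Transcript(group_id=group, session=session, utterances=utterances)
    truth = {
        "group_id": group,
        "session": session,
        "overlap": overlap,
        "vad_target": list(vad_target),
        "register_clipped": register_clipped,
        "topic_words": sorted(topic_lemmas.tolist()),
    }
    return segment, transcript, truth


def make_feedback(config: SynthConfig) -> pd.DataFrame:
    """Integer questionnaire scores (0-5) per participant x item.

    Baseline item means drift around 3; ``planted_item_effects`` shifts the
    listed items' latent means in the *second* group by the given amount
    before discretization, giving the group-comparison layer a known signal.
    """
    if config.feedback_items < 1:
        raise ValueError("feedback_items must be >= 1")
    rng = _rng_for(config, 3)
    effects = dict(config.planted_item_effects)
    rows = []
    base = rng.uniform(2.0, 4.0, size=config.feedback_items)
    for g, group in enumerate(config.group_ids[: config.n_groups]):
        n_participants = config.participants_per_group[
            g % len(config.participants_per_group)
        ]
        for p in range(n_participants):
            pid = f"{group}-P{p + 1:02d}"
            latent = base + rng.normal(0.0, 0.8, size=config.feedback_items)
            if g == 1:
                for item, shift in effects.items():
                    latent[item] += shift
            scores = np.clip(np.rint(latent), 0, 5).astype(int)
            for item in range(config.feedback_items):
                rows.append(
                    {"participant": pid, "group": group, "item": item, "score": int(scores[item])}
                )
    return pd.DataFrame(rows)


def make_corpus(
    config: SynthConfig,
    overlaps: Mapping[tuple[str, int], float] | None = None,
    vad_targets: Mapping[tuple[str, int], tuple[float, float, float]] | None = None,
) -> dict:
    """Full corpus: lexicon, per-session segments/transcripts, feedback and
    ground truth. ``overlaps``/``vad_targets`` override per (group, session)."""
    lexicon = make_lexicon(config)
    segments: dict[tuple[str, int], LiterarySegment] = {}
    transcripts: dict[tuple[str, int], Transcript] = {}
    truths: list[dict] = []
    for group in config.group_ids[: config.n_groups]:
        for session in range(1, config.sessions_per_group + 1):
            key = (group, session)
            seg, tra, truth = make_session(
                config,
                lexicon,
                group,
                session,
                overlap=(overlaps or {}).get(key),
                vad_target=(vad_targets or {}).get(key),
            )
            segments[key] = seg
            transcripts[key] = tra
            truths.append(truth)
    return {
        "config": config,
        "lexicon": lexicon,
        "segments": segments,
        "transcripts": transcripts,
        "feedback": make_feedback(config),
        "truth": truths,
    }


def write_corpus(corpus: dict, out_dir: str | Path) -> dict[str, Path]:
    """Emit the corpus in the exact on-disk formats the readers consume:
    speaker-coded transcript .txt, segment .txt, lexicon CSV (Warriner
    dialect), feedback CSV, and a ground-truth JSON."""
    out_dir = Path(out_dir)
    (out_dir / "transcripts").mkdir(parents=True, exist_ok=True)
    (out_dir / "segments").mkdir(parents=True, exist_ok=True)

    config: SynthConfig = corpus["config"]
    lexicon: NormLexicon = corpus["lexicon"]

    lex_path = out_dir / "lexicon.csv"
    lex_df = pd.DataFrame(
        [
            {"Word": lem, "V.Mean.Sum": v, "A.Mean.Sum": a, "D.Mean.Sum": d}
            for lem, (v, a, d) in sorted(lexicon.entries.items())
        ]
    )
    lex_df.to_csv(lex_path, index=False)

    for (group, session), transcript in corpus["transcripts"].items():
        path = out_dir / "transcripts" / f"{group}_S{session}_discussion.txt"
        path.write_text(
            "\n".join(f"{u.speaker}: {u.text}" for u in transcript.utterances) + "\n",
            encoding="utf-8",
        )
    for (group, session), segment in corpus["segments"].items():
        path = out_dir / "segments" / f"{group}_S{session}_text.txt"
        path.write_text(segment.text + "\n", encoding="utf-8")

    feedback_path = out_dir / "feedback.csv"
    corpus["feedback"].to_csv(feedback_path, index=False)

    truth_path = out_dir / "ground_truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(
            {"seed": config.seed, "sessions": corpus["truth"]},
            fh,
            indent=2,
        )
        fh.write("\n")

    return {
        "lexicon": lex_path,
        "transcripts": out_dir / "transcripts",
        "segments": out_dir / "segments",
        "feedback": feedback_path,
        "ground_truth": truth_path,
    }
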