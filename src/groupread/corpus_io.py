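"""Reading and writing of every external artefact.

Transcripts are UTF-8 plain text with speaker-coded utterance blocks
(``GOLD: I might agree,``); literary segments are plain text; valence/
arousal/dominance (VAD) word norms arrive as CSV in the Warriner-2013
column dialect by default; tables go out as CSV and run metadata as JSON.
Deposited spreadsheet data can be converted to CSV with
:func:`convert_xlsx`, keeping the core readers format-agnostic.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger("groupread")

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Utterance:
    """One speaker turn, text preserved byte-for-byte from source."""

    speaker: str
    text: str
    index: int

    def __post_init__(self) -> None:
        if not self.speaker:
            raise ValueError("utterance speaker must be non-empty")


@dataclass
class Transcript:
    """Ordered speaker-coded utterances for one group/session discussion."""

    group_id: str
    session: int
    utterances: list[Utterance]

    def __post_init__(self) -> None:
        if not self.utterances:
            raise ValueError("transcript must contain at least one utterance")
        for i, utt in enumerate(self.utterances):
            if utt.index != i:
                raise ValueError("utterance indices must be contiguous from 0")

    @property
    def text(self) -> str:
        """All speech content, utterances joined by newlines."""
        return "\n".join(u.text for u in self.utterances)

    @property
    def speakers(self) -> list[str]:
        return sorted({u.speaker for u in self.utterances})


@dataclass
class LiterarySegment:
    """The portion of the literary text read in one session."""

    group_id: str
    session: int
    title: str
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("literary segment text must be non-empty")


@dataclass
class NormLexicon:
    """Word norms: lemma -> (valence, arousal, dominance) raw rating means.

    Raw values live on the published rating scale (1-9 for the Warriner
    norms); rescaling to [0, 1] happens in :mod:`groupread.vad`.
    """

    entries: dict[str, tuple[float, float, float]]
    source_scale: tuple[float, float] = (1.0, 9.0)
    checksum: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("lexicon must contain at least one lemma")
        lo, hi = self.source_scale
        for lemma, vad in self.entries.items():
            if lemma != lemma.lower():
                raise ValueError(f"lexicon lemma not lowercase: {lemma!r}")
            for v in vad:
                if not lo <= v <= hi:
                    raise ValueError(
                        f"lexicon value {v} for {lemma!r} outside scale [{lo}, {hi}]"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, lemma: str) -> bool:
        return lemma in self.entries


# Column dialect for the Warriner, Kuperman & Brysbaert (2013) norms file.
WARRINER_DIALECT: dict[str, str] = {
    "lemma": "Word",
    "valence": "V.Mean.Sum",
    "arousal": "A.Mean.Sum",
    "dominance": "D.Mean.Sum",
}

SPEAKER_RE = re.compile(r"^([A-Z][A-Z0-9_-]*):\s?(.*)$")


class TranscriptFormatError(ValueError):
    """Raised when a transcript file has no recognizable speaker-coded line."""


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_transcript(path: str | Path, group_id: str, session: int) -> Transcript:
    """Parse a speaker-coded transcript file.

    An utterance starts at a line matching ``SPEAKER:`` (uppercase token and
    colon); continuation lines belong to the preceding utterance and are
    joined with single spaces. Bracketed stage directions such as
    ``[laughter]`` are preserved here and stripped later in preprocessing.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()

    utterances: list[Utterance] = []
    speaker: str | None = None
    parts: list[str] = []

    def flush() -> None:
        nonlocal parts
        if speaker is not None:
            utterances.append(
                Utterance(speaker=speaker, text=" ".join(parts), index=len(utterances))
            )
        parts = []

    for lineno, line in enumerate(lines, start=1):
        m = SPEAKER_RE.match(line)
        if m:
            flush()
            speaker = m.group(1)
            parts = [m.group(2)]
        elif speaker is None:
            if line.strip():
                raise TranscriptFormatError(
                    f"{path}: line {lineno} precedes any speaker-coded line: {line!r}"
                )
        else:
            if line.strip():
                parts.append(line.strip())
    flush()

    if not utterances:
        raise TranscriptFormatError(f"{path}: no speaker-coded line found")
    return Transcript(group_id=group_id, session=session, utterances=utterances)


def read_segment(
    path: str | Path, group_id: str, session: int, title: str | None = None
) -> LiterarySegment:
    """Read a plain-text literary segment; title defaults to the file stem."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return LiterarySegment(
        group_id=group_id, session=session, title=title or path.stem, text=text
    )


def read_lexicon(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    source_scale: tuple[float, float] = (1.0, 9.0),
) -> NormLexicon:
    """Read a VAD word-norm CSV into a :class:`NormLexicon`.

    ``dialect`` maps the roles ``lemma``/``valence``/``arousal``/``dominance``
    to column names; default is the Warriner-2013 header. Lemmas are
    lowercased; duplicate lemmas keep the first occurrence (a warning reports
    the count); values outside the source scale raise with the offending rows.
    """
    dialect = dict(dialect or WARRINER_DIALECT)
    path = Path(path)
    df = pd.read_csv(path)

    missing = [col for col in dialect.values() if col not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mapped column(s) {missing}; have {list(df.columns)}")

    lo, hi = source_scale
    lemmas = df[dialect["lemma"]].astype(str).str.strip().str.lower().tolist()
    values = df[[dialect["valence"], dialect["arousal"], dialect["dominance"]]].to_numpy(
        dtype=float
    )
    entries: dict[str, tuple[float, float, float]] = {}
    n_dupes = 0
    bad_rows: list[int] = []
    for row_no, (lemma, vad) in enumerate(zip(lemmas, values), start=2):
        if not all(lo <= v <= hi for v in vad):
            bad_rows.append(row_no)
            continue
        if lemma in entries:
            n_dupes += 1
            continue
        entries[lemma] = (float(vad[0]), float(vad[1]), float(vad[2]))
    if bad_rows:
        raise ValueError(
            f"{path}: {len(bad_rows)} value(s) outside [{lo}, {hi}] at CSV row(s) "
            f"{bad_rows[:10]}{'...' if len(bad_rows) > 10 else ''}"
        )
    if n_dupes:
        logger.warning("%s: %d duplicate lemma row(s) dropped (first kept)", path, n_dupes)

    checksum = sha256_file(path)
    return NormLexicon(entries=entries, source_scale=source_scale, checksum=checksum)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_table(rows: Sequence[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write rows as a CSV table with a header row.

    Accepts a DataFrame or a sequence of mappings. An empty sequence of
    mappings produces a header-only file when the first row's keys are not
    available, i.e. an empty file with no data rows.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(rows, pd.DataFrame):
        rows.to_csv(path, index=False)
        return
    rows = list(rows)
    fieldnames = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        if fieldnames:
            writer.writeheader()
        writer.writerows(rows)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV table written by :func:`write_table`."""
    return pd.read_csv(path)


def write_run_metadata(config: Mapping, path: str | Path) -> None:
    """Persist everything needed to reproduce a run: hyperparameters, seed,
    and checksums of the lexicon and stopword list actually used."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dict(config), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_run_metadata(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def convert_xlsx(path: str | Path, out_dir: str | Path) -> list[Path]:
    """Convert each sheet of a spreadsheet (e.g. the deposited study data)
    to ``<stem>__<sheet>.csv`` under ``out_dir``; returns the paths written."""
    path = Path(path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheets = pd.read_excel(path, sheet_name=None)
    written: list[Path] = []
    for sheet_name, df in sheets.items():
        safe = re.sub(r"[^A-Za-z0-9_-]+", "_", sheet_name)
        out = out_dir / f"{path.stem}__{safe}.csv"
        df.to_csv(out, index=False)
        written.append(out)
    return written
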