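"""Inferential layer: similarity-emotion correlations and group comparisons.

Sample sizes here are small (a dozen sessions, a handful of participants per
group), so the layer sticks to the two classical procedures appropriate at
that scale — Pearson product-moment correlation and the independent-samples
t-test — and always reports the numeric two-sided p-value with an
"ns at alpha" flag rather than suppressing non-significant results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .vad import DIMENSIONS, VADValue

ALPHA = 0.05


@dataclass(frozen=True)
class SessionRecord:
    """One session's analysis row: similarity plus VAD level and dispersion."""

    group_id: str
    session: int
    similarity: float
    vad_mean: VADValue
    vad_sd: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not -1.0 <= self.similarity <= 1.0:
            raise ValueError(f"similarity {self.similarity} outside [-1, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    dimension: str
    r: float
    n: int
    p: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r={self.r} outside [-1, 1]")
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass(frozen=True)
class TTestResult:
    label: str
    t: float
    df: float
    p: float
    group_means: tuple[float, float]

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("df must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def pearson(x: Sequence[float], y: Sequence[float], dimension: str = "") -> CorrelationResult:
    """Product-moment r with the two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(dimension=dimension, r=float(res.statistic), n=x.size, p=float(res.pvalue))


def similarity_vad_correlation(
    records: Sequence[SessionRecord],
    emotion: Literal["mean", "sd"] = "mean",
) -> dict[str, CorrelationResult]:
    """Correlate per-session text-discussion similarity with per-session
    emotion, one result per VAD dimension, sessions pooled across groups.

    ``emotion="mean"`` uses the session-mean VAD level (the default reading:
    higher similarity going with lower arousal); ``"sd"`` uses word-level
    dispersion as the volatility measure instead. Both are legitimate
    operationalizations of emotional volatility; only the default is asserted.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 session records")
    sims = [r.similarity for r in records]
    out: dict[str, CorrelationResult] = {}
    for i, dim in enumerate(DIMENSIONS):
        if emotion == "mean":
            values = [r.vad_mean[dim] for r in records]
        elif emotion == "sd":
            values = [r.vad_sd[i] for r in records]
        else:
            raise ValueError(f"unknown emotion variable {emotion!r}")
        out[dim] = pearson(sims, values, dimension=dim)
    return out


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = True,
    label: str = "",
) -> TTestResult:
    """Independent-samples t-test; Student's pooled-variance form by default,
    Welch with ``equal_var=False``. Sign convention: t > 0 when mean(a) >
    mean(b), with groups passed in a fixed order (MT, HT)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(a.size + b.size - 2) if equal_var else float(res.df)
    return TTestResult(
        label=label,
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
    )


def group_vad_comparison(
    session_table: pd.DataFrame,
    groups: tuple[str, str] = ("MT", "HT"),
    equal_var: bool = True,
) -> dict[str, TTestResult]:
    """Compare the two groups' per-session VAD means, one t-test per
    dimension. Expects the session table emitted by ``vad.group_summary``."""
    out: dict[str, TTestResult] = {}
    for dim in DIMENSIONS:
        sub = session_table[session_table["dimension"] == dim]
        a = sub[sub["group_id"] == groups[0]]["mean"].to_numpy()
        b = sub[sub["group_id"] == groups[1]]["mean"].to_numpy()
        out[dim] = two_sample_t(a, b, equal_var=equal_var, label=dim)
    return out


def feedback_comparison(
    table: pd.DataFrame,
    groups: tuple[str, str] = ("MT", "HT"),
    equal_var: bool = True,
    alpha: float = ALPHA,
    bh: bool = False,
) -> pd.DataFrame:
    """Item-wise group comparison of questionnaire scores (0-5 scale).

    ``table`` has columns participant, group, item, score. One t-test per
    item; items with p < alpha are flagged. No multiple-testing correction by
    default (raw p-values are reported as such); ``bh=True`` adds
    Benjamini-Hochberg adjusted p-values, since dozens of items at alpha=.05
    is a known weakness of the uncorrected analysis.
    """
    required = {"participant", "group", "item", "score"}
    if not required.issubset(table.columns):
        raise ValueError(f"feedback table needs columns {sorted(required)}")
    scores = table["score"].to_numpy(dtype=float)
    if scores.size == 0:
        raise ValueError("feedback table is empty")
    if scores.min() < 0 or scores.max() > 5:
        raise ValueError("feedback scores must lie on the 0-5 scale")

    rows = []
    for item, sub in table.groupby("item", sort=True):
        a = sub[sub["group"] == groups[0]]["score"].to_numpy(dtype=float)
        b = sub[sub["group"] == groups[1]]["score"].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            # identically-scored item: no evidence of difference by definition
            rows.append(
                {"item": item, "t": 0.0, "df": float(a.size + b.size - 2),
                 "p": 1.0, "mean_a": float(a.mean()), "mean_b": float(b.mean())}
            )
            continue
        res = two_sample_t(a, b, equal_var=equal_var, label=str(item))
        rows.append(
            {"item": item, "t": res.t, "df": res.df, "p": res.p,
             "mean_a": res.group_means[0], "mean_b": res.group_means[1]}
        )
    df = pd.DataFrame(rows)
    df["significant"] = df["p"] < alpha
    if bh:
        df["p_bh"] = sps.false_discovery_control(df["p"].to_numpy(), method="bh")
        df["significant_bh"] = df["p_bh"] < alpha
    return df
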