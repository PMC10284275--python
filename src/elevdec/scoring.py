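"""Per-second emotion scoring of time-stamped comment streams.

Converts a stream of time-stamped viewer comments into a continuous
per-second emotion score.  For second ``i`` of a video,

    score_i = sum_j(w_j * dict_score_j) / N

where the sum runs over every dictionary term matched in comments posted
during ``[i, i+1)``, ``w_j`` is the product of modifier effects attached to
that term (negators contribute -1, degree words their multiplier; default
weight 1), ``dict_score_j`` is the term's dictionary score in {0, 1, 2},
and ``N`` is the total number of comments in the whole video, acting as an
inter-video normalizer.  Raw per-video series are then z-scored over all
1-s segments of all videos jointly to put videos on a unified scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dictionary import NEGATOR_WEIGHT, EmotionDictionary

__all__ = [
    "Comment",
    "CommentStream",
    "ScoredToken",
    "ScoreSeries",
    "tokenize_comment",
    "score_seconds",
    "concatenate_series",
    "zscore_across_videos",
    "moving_average",
    "compare_with_selfreport",
    "read_comments_csv",
    "write_comments_csv",
    "read_selfreport_csv",
    "write_scores_csv",
]

Tokenizer = Callable[[str], list[str]]


class ScoringError(ValueError):
    """Invalid comment stream or degenerate score series."""


@dataclass(frozen=True)
class Comment:
    """A single time-stamped comment; timestamp in seconds from video onset."""

    timestamp: float
    text: str

    def __post_init__(self) -> None:
        if not self.timestamp >= 0:
            raise ScoringError(f"comment timestamp must be >= 0, got {self.timestamp}")


@dataclass(frozen=True)
class CommentStream:
    """All comments of one video, with its integer duration in seconds."""

    video_id: str
    duration_s: int
    comments: tuple[Comment, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "comments", tuple(self.comments))
        if self.duration_s < 1:
            raise ScoringError(f"duration_s must be >= 1, got {self.duration_s}")
        for c in self.comments:
            if c.timestamp >= self.duration_s:
                raise ScoringError(
                    f"comment at t={c.timestamp} outside video "
                    f"{self.video_id!r} of duration {self.duration_s}s"
                )

    def __len__(self) -> int:
        return len(self.comments)


@dataclass(frozen=True)
class ScoredToken:
    """A matched entry term with its dictionary score and modifier weight."""

    term: str
    dict_score: int
    weight: float = 1.0

    @property
    def value(self) -> float:
        return self.weight * self.dict_score


@dataclass(frozen=True)
class ScoreSeries:
    """Per-second scores concatenated over videos.

    ``video_boundaries`` holds (video_id, start_index, length) triples into
    ``per_second``; ``normalized`` is one of ``"raw"`` or ``"zscored"``.
    """

    per_second: np.ndarray
    video_boundaries: tuple[tuple[str, int, int], ...]
    normalized: str = "raw"

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_second, dtype=float)
        object.__setattr__(self, "per_second", arr)
        object.__setattr__(self, "video_boundaries", tuple(self.video_boundaries))
        total = sum(length for _, _, length in self.video_boundaries)
        if arr.ndim != 1 or len(arr) != total:
            raise ScoringError(
                f"per_second length {arr.shape} does not match boundaries ({total})"
            )

    def __len__(self) -> int:
        return len(self.per_second)

    def video_slice(self, video_id: str) -> np.ndarray:
        for vid, start, length in self.video_boundaries:
            if vid == video_id:
                return self.per_second[start : start + length]
        raise KeyError(video_id)


def _build_matcher(d: EmotionDictionary):
    """Casefolded term -> (kind, payload) lookup plus the max term length."""
    table: dict[str, tuple[str, float | int | str]] = {}
    for term, score in d.entries.items():
        table[term.casefold()] = ("entry", (term, score))
    for term in d.negators:
        table[term.casefold()] = ("negator", NEGATOR_WEIGHT)
    for term, mult in d.degree_words.items():
        table[term.casefold()] = ("degree", mult)
    max_len = max((len(t) for t in table), default=0)
    return table, max_len


def _greedy_segments(text: str, table: dict, max_len: int) -> list[tuple[str, object]]:
    """Left-to-right greedy longest-match scan; unmatched spans are skipped."""
    folded = text.casefold()
    out: list[tuple[str, object]] = []
    i, n = 0, len(folded)
    while i < n:
        match = None
        for l in range(min(max_len, n - i), 0, -1):
            cand = folded[i : i + l]
            if cand in table:
                match = (cand, l)
                break
        if match is None:
            i += 1
            continue
        out.append(table[match[0]])
        i += match[1]
    return out


def tokenize_comment(
    text: str,
    dictionary: EmotionDictionary,
    tokenizer: Tokenizer | None = None,
) -> list[ScoredToken]:
    """Extract scored entry-term tokens from one comment.

    The text is scanned left to right with greedy longest-match against the
    union of the entry, negator and degree-word lexicons (case-insensitive);
    unmatched spans are skipped.  Modifiers accumulate and attach to the next
    entry term in the same comment, composing multiplicatively (negator ->
    x(-1), degree word -> x multiplier); modifiers with no following entry
    term contribute nothing.

    ``tokenizer`` optionally plugs in an external segmenter (e.g. a Chinese
    word segmenter): it must map the text to a list of candidate units, each
    of which is then matched against the lexicons as a whole.
    """
    table, max_len = _build_matcher(dictionary)
    if tokenizer is None:
        hits = _greedy_segments(text, table, max_len)
    else:
        hits = [table[u.casefold()] for u in tokenizer(text) if u.casefold() in table]
    tokens: list[ScoredToken] = []
    pending = 1.0
    has_pending = False
    for kind, payload in hits:
        if kind == "entry":
            term, score = payload
            tokens.append(ScoredToken(term, score, pending if has_pending else 1.0))
            pending, has_pending = 1.0, False
        else:  # negator or degree
            pending *= payload
            has_pending = True
    return tokens


def score_seconds(
    stream: CommentStream,
    dictionary: EmotionDictionary,
    tokenizer: Tokenizer | None = None,
) -> ScoreSeries:
    """Compute the raw per-second score series of one video.

    Comments are binned into non-overlapping 1-s windows [i, i+1) by
    timestamp; each second's weighted token-score sum is divided by the
    video's total comment count N.  Seconds without comments score 0; an
    empty stream yields an all-zero series.
    """
    n = len(stream.comments)
    scores = np.zeros(stream.duration_s)
    if n > 0:
        for comment in stream.comments:
            second = int(math.floor(comment.timestamp))
            total = sum(t.value for t in tokenize_comment(comment.text, dictionary,
                                                          tokenizer))
            scores[second] += total
        scores /= n
    return ScoreSeries(
        per_second=scores,
        video_boundaries=((stream.video_id, 0, stream.duration_s),),
        normalized="raw",
    )


def concatenate_series(series_list: Sequence[ScoreSeries]) -> ScoreSeries:
    """Concatenate per-video series into one series with joint boundaries."""
    if not series_list:
        raise ScoringError("need at least one series")
    if any(s.normalized != series_list[0].normalized for s in series_list):
        raise ScoringError("cannot concatenate series with mixed normalization")
    values = np.concatenate([s.per_second for s in series_list])
    boundaries: list[tuple[str, int, int]] = []
    offset = 0
    for s in series_list:
        for vid, start, length in s.video_boundaries:
            boundaries.append((vid, offset + start, length))
        offset += len(s)
    return ScoreSeries(values, tuple(boundaries), series_list[0].normalized)


def zscore_across_videos(series_list: Sequence[ScoreSeries]) -> ScoreSeries:
    """Z-score the concatenation of raw per-video series.

    Normalization is at the inter-video level: one mean and one SD over all
    1-s segments of all videos jointly (population SD, so the output has SD
    exactly 1).  Video boundaries are preserved.
    """
    cat = concatenate_series(series_list)
    if len(cat) < 2:
        raise ScoringError("need at least 2 segments to z-score")
    mu = cat.per_second.mean()
    sd = cat.per_second.std()  # population convention
    if sd <= 0 or not np.isfinite(sd):
        raise ScoringError("zero variance: degenerate tagging, cannot z-score")
    return ScoreSeries((cat.per_second - mu) / sd, cat.video_boundaries, "zscored")


def moving_average(series: ScoreSeries, width_s: int) -> ScoreSeries:
    """Optional centered moving-average smoothing (width in seconds).

    Applied per video so smoothing never crosses video boundaries.
    ``width_s <= 1`` returns the series unchanged.
    """
    if width_s <= 1:
        return series
    out = series.per_second.copy()
    kernel = np.ones(width_s) / width_s
    for _, start, length in series.video_boundaries:
        seg = series.per_second[start : start + length]
        pad = width_s // 2
        padded = np.pad(seg, pad, mode="edge")
        sm = np.convolve(padded, kernel, mode="same")[pad : pad + length]
        out[start : start + length] = sm
    return replace(series, per_second=out)


def compare_with_selfreport(
    danmaku: ScoreSeries, selfreport: np.ndarray
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between comment scores and a self-report trace.

    The self-report trace is expected at 1 value/s, already averaged across
    raters and resampled; lengths must match and both series must vary.
    """
    x = np.asarray(danmaku.per_second, dtype=float)
    y = np.asarray(selfreport, dtype=float)
    if x.shape != y.shape:
        raise ScoringError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ScoringError("need at least 3 seconds to correlate")
    if x.std() == 0 or y.std() == 0:
        raise ScoringError("zero variance in one of the series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# --- I/O ---------------------------------------------------------------------

def read_comments_csv(path: str | Path, video_id: str, duration_s: int) -> CommentStream:
    """Read a per-video comment CSV with header ``timestamp_s,text``."""
    df = pd.read_csv(path, dtype={"text": str}, keep_default_na=False)
    if list(df.columns[:2]) != ["timestamp_s", "text"]:
        raise ScoringError(f"{path}: expected header 'timestamp_s,text'")
    comments = tuple(
        Comment(float(t), str(txt)) for t, txt in zip(df["timestamp_s"], df["text"])
    )
    return CommentStream(video_id=video_id, duration_s=duration_s, comments=comments)


def write_comments_csv(stream: CommentStream, path: str | Path) -> None:
    pd.DataFrame(
        {"timestamp_s": [c.timestamp for c in stream.comments],
         "text": [c.text for c in stream.comments]}
    ).to_csv(path, index=False)


def read_selfreport_csv(path: str | Path) -> np.ndarray:
    """Read a self-report trace CSV with header ``second,value``."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["second", "value"]:
        raise ScoringError(f"{path}: expected header 'second,value'")
    return df.sort_values("second")["value"].to_numpy(dtype=float)


def write_scores_csv(raw: ScoreSeries, zscored: ScoreSeries, path: str | Path) -> None:
    """Write aligned raw and z-scored series with per-video second indices."""
    if len(raw) != len(zscored):
        raise ScoringError("raw and z-scored series differ in length")
    rows = []
    for vid, start, length in raw.video_boundaries:
        for s in range(length):
            rows.append(
                (vid, s, raw.per_second[start + s], zscored.per_second[start + s])
            )
    pd.DataFrame(rows, columns=["video_id", "second", "raw_score", "z_score"]).to_csv(
        path, index=False
    )
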