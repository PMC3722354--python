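"""Behavioural reading measures.

Implements the measures used to quantify reading ability and therapy effects
in letter-by-letter readers: outlier-trimmed mean naming latencies per word
length, the word-length effect (WLE, ms per additional letter), the partial-
credit accuracy scheme, text reading speed in words per minute, patient
inclusion thresholds relative to a control sample, sub-lexical n-gram
frequency indices with partial correlations, and the three-level adaptive
difficulty ladder of the training task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VALID_OUTCOMES",
    "OUTCOME_SCORES",
    "LADDER_LEVELS",
    "trim_and_mean_rt",
    "word_length_effect",
    "score_accuracy",
    "text_wpm",
    "inclusion_threshold",
    "ngram_decompose",
    "ngram_frequency_index",
    "partial_correlation",
    "ladder_transition",
    "shared_letters",
    "validate_trials",
    "reading_measures",
]

VALID_OUTCOMES = frozenset(
    {"correct", "error", "self_corrected", "omitted", "voicekey_fail"}
)

# Partial-credit accuracy scheme: correct = 1, error/omission = 0,
# false starts and self-corrections = 0.5.  Voice-key failures are
# excluded from every denominator.
OUTCOME_SCORES = {
    "correct": 1.0,
    "error": 0.0,
    "omitted": 0.0,
    "self_corrected": 0.5,
}

LADDER_LEVELS = ("easy", "medium", "hard")


def trim_and_mean_rt(rts_ms: Sequence[float]) -> tuple[float, int]:
    """Mean RT after a single-pass +/-2 SD trim.

    Computes the mean and sample SD of the supplied reaction times, drops
    values more than two sample SDs from the mean (a guard against the
    positive skew of naming latencies), and returns the mean of the
    survivors together with the number excluded.

    Returns ``(nan, 0)`` when fewer than two valid RTs are supplied.
    """
    rts = np.asarray([r for r in rts_ms if r is not None and np.isfinite(r)], dtype=float)
    if rts.size < 2:
        return (float("nan"), 0)
    m = rts.mean()
    sd = rts.std(ddof=1)
    if sd == 0:
        return (float(m), 0)
    keep = np.abs(rts - m) <= 2.0 * sd
    return (float(rts[keep].mean()), int((~keep).sum()))


def word_length_effect(mean_rt_by_length: dict[int, float]) -> float:
    """WLE slope: ordinary least-squares slope of mean RT on letter length
    (ms per additional letter).  Requires at least two length bins."""
    items = [(k, v) for k, v in mean_rt_by_length.items() if np.isfinite(v)]
    if len(items) < 2:
        raise ValueError("word_length_effect needs >= 2 length bins")
    x = np.array([k for k, _ in items], dtype=float)
    y = np.array([v for _, v in items], dtype=float)
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def score_accuracy(outcomes: Iterable[str]) -> float:
    """Percentage accuracy under the partial-credit scheme, over trials not
    lost to voice-key malfunction."""
    scores = [OUTCOME_SCORES[o] for o in outcomes if o != "voicekey_fail"]
    if not scores:
        raise ValueError("no valid trials (all voicekey_fail)")
    return 100.0 * float(np.mean(scores))


def text_wpm(n_words: int, duration_s: float) -> float:
    """Text reading speed in words per minute."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return 60.0 * n_words / duration_s


def inclusion_threshold(control_mean: float, control_sd: float) -> float:
    """Patient-inclusion cut-off: two SDs above the control-group mean."""
    if control_sd < 0:
        raise ValueError("sd must be nonnegative")
    return control_mean + 2.0 * control_sd


def ngram_decompose(word: str, n: int) -> list[str]:
    """All contiguous n-grams of ``word``, in order, duplicates kept.

    ``house`` -> 4 bigrams [ho, ou, us, se] and 3 trigrams [hou, ous, use].
    Words shorter than ``n`` yield an empty list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return [word[i : i + n] for i in range(len(word) - n + 1)]


def ngram_frequency_index(
    word: str, reference: Sequence[str], n: int, exclude_self: bool = False
) -> float:
    """Sub-lexical n-gram frequency of ``word`` relative to a reference list.

    Counts, over the word's constituent n-grams, every occurrence of each
    n-gram anywhere in the reference words, and divides by the number of
    n-grams in the word — giving a per-n-gram frequency independent of word
    length.  With ``exclude_self`` a reference entry identical to ``word``
    is skipped once (used for within-list indices, which count appearances
    *again* in the same list).
    """
    if not reference:
        raise ValueError("empty reference list")
    grams = ngram_decompose(word, n)
    if not grams:
        raise ValueError(f"word {word!r} shorter than n={n}")
    ref = list(reference)
    if exclude_self and word in ref:
        ref.remove(word)
    total = 0
    for g in grams:
        for ref_word in ref:
            total += sum(
                1 for i in range(len(ref_word) - n + 1) if ref_word[i : i + n] == g
            )
    return total / len(grams)


def partial_correlation(
    x: Sequence[float], y: Sequence[float], covariate: Sequence[float]
) -> float:
    """Pearson correlation of x and y after regressing each on the covariate.

    Residualizes both variables with least squares (intercept included) and
    correlates the residuals.  A constant covariate reduces to the plain
    Pearson correlation.  A variable perfectly explained by the covariate
    has a null residual and contributes correlation 0; genuinely constant
    inputs are rejected.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = np.asarray(covariate, float)
    if not (x.size == y.size == c.size) or x.size < 4:
        raise ValueError("need >= 4 matched observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    design = np.column_stack([np.ones_like(c), c])

    def resid(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    rx, ry = resid(x), resid(y)
    tol = 1e-12
    if np.std(rx) <= tol * np.std(x) or np.std(ry) <= tol * np.std(y):
        return 0.0
    return float(stats.pearsonr(rx, ry)[0])


def ladder_transition(level: str, correct: bool) -> tuple[str, int]:
    """Adaptive-difficulty ladder step for a 'different' test trial.

    A single correct response moves the word one level harder
    (easy -> medium -> hard, saturating at hard); a single error moves it one
    level easier (saturating at easy).  Returns the new level and the pence
    earned on this trial (one pence per correct answer).
    """
    if level not in LADDER_LEVELS:
        raise ValueError(f"unknown level {level!r}")
    i = LADDER_LEVELS.index(level)
    i = min(i + 1, 2) if correct else max(i - 1, 0)
    return LADDER_LEVELS[i], int(correct)


def shared_letters(word_a: str, word_b: str) -> int:
    """Multiset letter overlap between two words (utility for the easy /
    medium / hard pair-difficulty statistics)."""
    count = 0
    pool = list(word_b)
    for ch in word_a:
        if ch in pool:
            pool.remove(ch)
            count += 1
    return count


# ---------------------------------------------------------------------------
# Trial-table handling


REQUIRED_COLUMNS = ("word", "length", "list", "timepoint", "rt_ms", "outcome")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a reading-trial table (raises on malformed rows)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad = trials[trials["length"] != trials["word"].str.len()]
    if len(bad):
        raise ValueError(f"{len(bad)} rows where length != len(word)")
    unknown = set(trials["outcome"]) - VALID_OUTCOMES
    if unknown:
        raise ValueError(f"unknown outcomes: {sorted(unknown)}")
    return trials


def reading_measures(trials: pd.DataFrame) -> pd.DataFrame:
    """Per (timepoint, list) reading summaries from a trial table.

    Returns a tidy frame with, per timepoint and word list: trimmed mean RT
    per length bin, the pooled mean RT, the WLE slope, percentage accuracy,
    and the number of outlier exclusions.  Voice-key failures are excluded
    from RT and accuracy; RTs enter only from trials scored correct.
    """
    validate_trials(trials)
    rows = []
    for (tp, lst), sub in trials.groupby(["timepoint", "list"], sort=True):
        by_len: dict[int, float] = {}
        n_excl = 0
        for length, bin_ in sub.groupby("length"):
            ok = bin_[(bin_["outcome"] == "correct") & bin_["rt_ms"].notna()]
            m, ne = trim_and_mean_rt(ok["rt_ms"].to_numpy())
            by_len[int(length)] = m
            n_excl += ne
        finite = [v for v in by_len.values() if np.isfinite(v)]
        wle = word_length_effect(by_len) if len(finite) >= 2 else float("nan")
        rows.append(
            {
                "timepoint": tp,
                "list": lst,
                **{f"mean_rt_{k}": v for k, v in sorted(by_len.items())},
                "mean_rt_ms": float(np.mean(finite)) if finite else float("nan"),
                "wle_ms_per_letter": wle,
                "accuracy_pct": score_accuracy(sub["outcome"]),
                "n_excluded": n_excl,
            }
        )
    return pd.DataFrame(rows)
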