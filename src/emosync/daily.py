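"""Daily indicator series: means, weekday baselines, normalized scores, bootstrap.

For each calendar day t the pipeline computes the unweighted mean m_t of the
per-tweet indicator fractions (tweets with no tokens are excluded).  Term
frequencies oscillate over the week, so a per-weekday baseline b_w is taken
over a pre-event window, and the daily score is the log-ratio

    s_t = ln((m_t + eps) / (b_w(t) + eps)),

which removes weekly seasonality, reduces skewness, and puts all indicators
on a comparable scale.  The smoothing constant eps is half the smallest
non-zero daily mean of the series (0 when no day has m_t = 0), so the log
stays defined on sparse data and the correction vanishes on dense data.
Uncertainty per day comes from a percentile bootstrap over the day's tweets.
"""

from __future__ import annotations

import math
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import DEFAULT_TIMEZONE, TweetRecord, assign_day
from .lexicon import Lexicon, tokenize

__all__ = [
    "tweet_fractions",
    "daily_mean",
    "weekday_baseline",
    "normalized_score",
    "bootstrap_day",
    "bootstrap_series",
    "daily_series_frame",
]


def tweet_fractions(
    records: Iterable[TweetRecord], lex: Lexicon, tz: str = DEFAULT_TIMEZONE
) -> pd.DataFrame:
    """Per-tweet indicator fractions with their local calendar date.

    Returns a DataFrame with columns ``date`` and ``fraction``; tweets with
    no tokens get a NaN fraction (undefined) but still mark their day.
    """
    dates, fracs = [], []
    for rec in records:
        f = lex.fraction(tokenize(rec.text))
        d, _ = assign_day(rec, tz)
        dates.append(d)
        fracs.append(np.nan if f is None else f)
    return pd.DataFrame({"date": dates, "fraction": fracs})


def daily_mean(
    records: Iterable[TweetRecord], lex: Lexicon, tz: str = DEFAULT_TIMEZONE,
    pooled: bool = False,
) -> pd.DataFrame:
    """Daily mean indicator value.

    The default is the unweighted mean of per-tweet fractions (every tweet
    counts equally); ``pooled=True`` switches to the pooled word-count ratio
    (category tokens / all tokens of the day), which weights tweets by
    length.  Returns a DataFrame indexed by every calendar date spanned by
    the data, with columns ``n_tweets`` (scorable tweets that day),
    ``mean_fraction`` (NaN when no scorable tweets) and ``weekday``
    (Monday=0).
    """
    if not pooled:
        return daily_mean_from_fractions(tweet_fractions(records, lex, tz))
    acc: dict = {}
    for rec in records:
        tokens = tokenize(rec.text)
        d, _ = assign_day(rec, tz)
        slot = acc.setdefault(d, [0, 0, 0])  # tweets, hits, tokens
        if tokens:
            slot[0] += 1
            slot[1] += round(lex.fraction(tokens) * len(tokens))
            slot[2] += len(tokens)
        else:
            acc.setdefault(d, slot)
    if not acc:
        return pd.DataFrame(columns=["n_tweets", "mean_fraction", "weekday"])
    full = pd.date_range(min(acc), max(acc), freq="D").date
    rows = {
        d: (acc.get(d, [0, 0, 0])[0],
            (acc[d][1] / acc[d][2]) if acc.get(d, [0, 0, 0])[2] else np.nan)
        for d in full
    }
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["n_tweets", "mean_fraction"])
    out["n_tweets"] = out["n_tweets"].astype(int)
    out["weekday"] = [d.weekday() for d in out.index]
    out.index.name = "date"
    return out


def daily_mean_from_fractions(frame: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-tweet ``date``/``fraction`` frame to daily means."""
    if frame.empty:
        return pd.DataFrame(columns=["n_tweets", "mean_fraction", "weekday"])
    grouped = frame.groupby("date")["fraction"].agg(n_tweets="count", mean_fraction="mean")
    full = pd.date_range(grouped.index.min(), grouped.index.max(), freq="D").date
    out = grouped.reindex(full)
    out["n_tweets"] = out["n_tweets"].fillna(0).astype(int)
    out["weekday"] = [d.weekday() for d in out.index]
    out.index.name = "date"
    return out


def weekday_baseline(
    series: pd.DataFrame, baseline_window: tuple[date, date]
) -> np.ndarray:
    """Per-weekday baselines b_0..b_6 over the pre-event window.

    ``series`` is a :func:`daily_mean` frame.  Every weekday must be
    represented by at least one day with a defined mean; missing weekdays
    raise, listing which they are.
    """
    start, end = baseline_window
    sel = series.loc[[d for d in series.index if start <= d <= end]]
    sel = sel.dropna(subset=["mean_fraction"])
    baselines = np.full(7, np.nan)
    for w in range(7):
        vals = sel.loc[sel["weekday"] == w, "mean_fraction"]
        if len(vals):
            baselines[w] = vals.mean()
    missing = [w for w in range(7) if math.isnan(baselines[w])]
    if missing:
        raise ValueError(
            f"baseline window {start}..{end} has no data for weekday(s) {missing} (Monday=0)"
        )
    return baselines


def normalized_score(series: pd.DataFrame, baselines: np.ndarray) -> pd.Series:
    """Log-ratio daily scores s_t = ln((m_t + eps)/(b_w + eps)).

    eps is half the smallest non-zero m_t of the series when any m_t is
    exactly zero, else 0.  Requires all b_w > 0.
    """
    baselines = np.asarray(baselines, dtype=float)
    if baselines.shape != (7,):
        raise ValueError("baselines must have 7 entries (Monday=0)")
    if np.any(baselines <= 0):
        raise ValueError(f"non-positive weekday baseline(s): {baselines.tolist()}")
    m = series["mean_fraction"].to_numpy(dtype=float)
    nonzero = m[np.isfinite(m) & (m > 0)]
    has_zero = np.any(np.isfinite(m) & (m == 0))
    eps = 0.5 * nonzero.min() if (has_zero and len(nonzero)) else 0.0
    b = baselines[series["weekday"].to_numpy()]
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.log((m + eps) / (b + eps))
    return pd.Series(s, index=series.index, name="score")


def bootstrap_day(
    day_fractions: Sequence[float],
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap of a day's mean fraction.

    Resamples the day's per-tweet fractions with replacement ``B`` times and
    returns ``(median, ci_low, ci_high)`` at level ``1 - alpha``.
    Deterministic for a fixed seed.
    """
    x = np.asarray(day_fractions, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("bootstrap_day: empty day")
    if B < 1:
        raise ValueError("bootstrap_day: B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.empty(B)
    # chunked so B x n never exceeds ~1e7 entries
    chunk = max(1, int(1e7 // max(n, 1)))
    done = 0
    while done < B:
        k = min(chunk, B - done)
        idx = rng.integers(0, n, size=(k, n))
        means[done:done + k] = x[idx].mean(axis=1)
        done += k
    lo, med, hi = np.percentile(means, [100 * alpha / 2, 50, 100 * (1 - alpha / 2)])
    return float(med), float(lo), float(hi)


def bootstrap_series(
    fractions: pd.DataFrame,
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-day bootstrap summaries for a :func:`tweet_fractions` frame."""
    rng = np.random.default_rng(seed)
    rows = {}
    fractions = fractions.dropna(subset=["fraction"])
    for day, grp in fractions.groupby("date"):
        med, lo, hi = bootstrap_day(grp["fraction"].to_numpy(), B=B, alpha=alpha, seed=rng)
        rows[day] = (med, lo, hi)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["median", "ci_low", "ci_high"])
    out.index.name = "date"
    return out


def daily_series_frame(
    records: Iterable[TweetRecord],
    lex: Lexicon,
    baseline_window: tuple[date, date],
    tz: str = DEFAULT_TIMEZONE,
    B: int = 0,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Full tidy daily series: n_tweets, m_t, b_w, s_t and (optionally) bootstrap CIs.

    This is the frame the CSV export and the shock-model CLI consume.  Set
    ``B`` to a positive bootstrap size to add median/ci_low/ci_high columns.
    """
    frame = tweet_fractions(records, lex, tz)
    series = daily_mean_from_fractions(frame)
    baselines = weekday_baseline(series, baseline_window)
    series["baseline"] = np.asarray(baselines)[series["weekday"].to_numpy()]
    series["score"] = normalized_score(series, baselines)
    if B > 0:
        boots = bootstrap_series(frame, B=B, alpha=alpha, seed=seed)
        series = series.join(boots)
    return series
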