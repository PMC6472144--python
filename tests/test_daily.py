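"""Daily means, weekday baselines, normalized log-ratio scores, bootstrap."""

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest

from emosync.daily import (
    bootstrap_day,
    daily_mean,
    normalized_score,
    weekday_baseline,
)
from emosync.lexicon import Lexicon
from tests.conftest import make_tweet

LEX = Lexicon.from_entries("demo", ["peur"])


def tweets_for_day(day_iso, fracs, user="u"):
    """One tweet per requested fraction: 'peur' tokens out of 10."""
    out = []
    for i, f in enumerate(fracs):
        k = round(f * 10)
        text = " ".join(["peur"] * k + ["le"] * (10 - k))
        out.append(make_tweet(user=f"{user}{i}", ts=f"{day_iso}T12:0{i % 10}:00+01:00",
                              text=text))
    return out


def make_series(values, start=date(2015, 9, 7)):
    """A daily_mean-style frame from a list of m_t values (None = missing)."""
    idx = [start + pd.Timedelta(days=i).to_pytimedelta() for i in range(len(values))]
    return pd.DataFrame({
        "n_tweets": [0 if v is None else 10 for v in values],
        "mean_fraction": [np.nan if v is None else v for v in values],
        "weekday": [d.weekday() for d in idx],
    }, index=pd.Index(idx, name="date"))


def test_daily_mean_examples():
    recs = tweets_for_day("2015-11-13", [0.1, 0.2, 0.3]) + \
        tweets_for_day("2015-11-14", [0.4, 0.6])
    series = daily_mean(recs, LEX)
    assert series.loc[date(2015, 11, 13), "mean_fraction"] == pytest.approx(0.2)
    assert series.loc[date(2015, 11, 14), "mean_fraction"] == pytest.approx(0.5)
    assert series.loc[date(2015, 11, 13), "n_tweets"] == 3


def test_daily_mean_pooled_variant_weights_by_length():
    # tweet 1: 1/10 'peur'; tweet 2: 5/10 -> per-tweet mean 0.3, pooled 6/20
    recs = tweets_for_day("2015-11-13", [0.1, 0.5])
    assert daily_mean(recs, LEX).loc[date(2015, 11, 13), "mean_fraction"] == \
        pytest.approx(0.3)
    pooled = daily_mean(recs, LEX, pooled=True)
    assert pooled.loc[date(2015, 11, 13), "mean_fraction"] == pytest.approx(0.3)
    # unequal lengths: 1 match / 2 tokens plus 0 / 8 tokens
    recs = [make_tweet(user="a", ts="2015-11-13T10:00:00+01:00", text="peur le"),
            make_tweet(user="b", ts="2015-11-13T11:00:00+01:00",
                       text="le la un une des et ou sur")]
    assert daily_mean(recs, LEX).loc[date(2015, 11, 13), "mean_fraction"] == \
        pytest.approx(0.25)
    assert daily_mean(recs, LEX, pooled=True).loc[date(2015, 11, 13), "mean_fraction"] == \
        pytest.approx(0.1)


def test_daily_mean_empty_token_tweets_are_missing():
    recs = [make_tweet(text="...!!!", ts="2015-11-13T10:00:00+01:00")]
    series = daily_mean(recs, LEX)
    assert series.loc[date(2015, 11, 13), "n_tweets"] == 0
    assert math.isnan(series.loc[date(2015, 11, 13), "mean_fraction"])


def test_weekday_baseline_constant_and_elevated_weekend():
    # two full weeks, constant 0.05 with +0.02 on Sat/Sun
    vals = []
    start = date(2015, 9, 7)  # a Monday
    for i in range(14):
        w = (start + pd.Timedelta(days=i).to_pytimedelta()).weekday()
        vals.append(0.05 + (0.02 if w >= 5 else 0.0))
    series = make_series(vals, start)
    b = weekday_baseline(series, (start, start + pd.Timedelta(days=13).to_pytimedelta()))
    assert np.allclose(b[:5], 0.05)
    assert np.allclose(b[5:], 0.07)


def test_weekday_baseline_missing_weekday_errors():
    series = make_series([0.05] * 6)  # Monday..Saturday only
    with pytest.raises(ValueError, match=r"weekday\(s\) \[6\]"):
        weekday_baseline(series, (series.index[0], series.index[-1]))


def test_normalized_score_identities():
    series = make_series([0.05] * 7)
    b = np.full(7, 0.05)
    s = normalized_score(series, b)
    assert np.allclose(s, 0.0)
    s2 = normalized_score(make_series([0.10] * 7), b)
    assert np.allclose(s2, math.log(2))


def test_normalized_score_zero_smoothing():
    # m_t = 0 present: eps = half the smallest non-zero mean
    series = make_series([0.0, 0.01, 0.02])
    b = np.full(7, 0.05)
    s = normalized_score(series, b)
    eps = 0.005
    assert s.iloc[0] == pytest.approx(math.log(eps / (0.05 + eps)))  # ~ -2.398
    assert s.iloc[0] == pytest.approx(-2.3979, abs=1e-4)


def test_normalized_score_requires_positive_baselines():
    with pytest.raises(ValueError, match="non-positive"):
        normalized_score(make_series([0.05]), np.zeros(7))


def test_score_scale_invariance():
    # multiplying all fractions (and hence baselines) by k > 0 leaves s_t unchanged
    vals = [0.02, 0.04, 0.05, 0.03, 0.06, 0.02, 0.04, 0.05, 0.04, 0.03, 0.02, 0.05, 0.06, 0.04]
    series = make_series(vals)
    window = (series.index[0], series.index[-1])
    b = weekday_baseline(series, window)
    s1 = normalized_score(series, b)
    series_k = make_series([3.0 * v for v in vals])
    s2 = normalized_score(series_k, weekday_baseline(series_k, window))
    assert np.allclose(s1, s2)


def test_baseline_window_scores_average_to_unity():
    rng = np.random.default_rng(0)
    vals = list(0.05 + 0.01 * rng.standard_normal(28))
    series = make_series(vals)
    b = weekday_baseline(series, (series.index[0], series.index[-1]))
    s = normalized_score(series, b)
    for w in range(7):
        ratios = np.exp(s[series["weekday"] == w])
        assert ratios.mean() == pytest.approx(1.0, abs=0.02)


def test_bootstrap_degenerate_and_deterministic():
    med, lo, hi = bootstrap_day([0.1] * 50, B=200, seed=3)
    assert med == lo == hi == pytest.approx(0.1)
    a = bootstrap_day([0.1, 0.2, 0.4, 0.0, 0.3], B=500, seed=11)
    b = bootstrap_day([0.1, 0.2, 0.4, 0.0, 0.3], B=500, seed=11)
    assert a == b
    with pytest.raises(ValueError, match="empty"):
        bootstrap_day([], B=10, seed=0)


def test_bootstrap_ci_width_matches_clt():
    rng = np.random.default_rng(42)
    fracs = rng.normal(0.1, 0.02, 400)
    _, lo, hi = bootstrap_day(fracs, B=2000, seed=5)
    expected = 2 * 1.96 * 0.02 / math.sqrt(400)
    assert abs((hi - lo) - expected) / expected < 0.25


def test_bootstrap_ci_monotone_in_alpha():
    rng = np.random.default_rng(1)
    fracs = rng.normal(0.1, 0.05, 200)
    _, lo95, hi95 = bootstrap_day(fracs, B=2000, alpha=0.05, seed=9)
    _, lo99, hi99 = bootstrap_day(fracs, B=2000, alpha=0.01, seed=9)
    assert lo99 <= lo95 and hi99 >= hi95
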