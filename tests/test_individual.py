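"""User summaries, self-selection correction, groups, mediation, lagged pairs, counts."""

import numpy as np
import pandas as pd
import pytest

from emosync.corpus import StudyWindows
from emosync.individual import (
    PERSONALITY_CATEGORIES,
    attack_reference_model,
    corrected_emotionality,
    mediate,
    sequential_association,
    sliding_group_difference,
    summarize_users,
    synchronization_groups,
)
from emosync.simulate import simulate_attack_counts, simulate_sequential_stream
from tests.conftest import make_tweet

WINDOWS = StudyWindows.default()


def window_tweet(user, window, text, hour=12):
    day = {"baseline": "2015-09-01", "short": "2015-11-15", "long": "2015-12-15"}[window]
    return make_tweet(user=user, ts=f"{day}T{hour:02d}:00:00+01:00", text=text)


def test_summarize_users_pooled_fractions(lexicons):
    recs = [
        # baseline: 20 tokens, 2 social ("ami", "famille")
        window_tweet("u1", "baseline", "ami " + "le " * 9),
        window_tweet("u1", "baseline", "famille " + "la " * 9, hour=13),
        window_tweet("u1", "short", "peur le jour"),
        window_tweet("u1", "long", "ensemble et joie"),
        # u2 has no long-window tweet -> excluded
        window_tweet("u2", "baseline", "bonjour le monde"),
        window_tweet("u2", "short", "salut"),
    ]
    summ = summarize_users(recs, lexicons, WINDOWS)
    assert list(summ.index) == ["u1"]
    assert summ.loc["u1", "frac_social_baseline"] == pytest.approx(0.1)
    assert summ.loc["u1", "n_posts_baseline"] == 2
    assert summ.loc["u1", "log_posts"] == pytest.approx(np.log(2))
    # short window: 'peur' is 1 affect token of 3
    assert summ.loc["u1", "emotionality_short"] == pytest.approx(1 / 3)


def test_summarize_users_per_tweet_mean_variant(lexicons):
    recs = [
        window_tweet("u1", "baseline", "ami le"),               # 1/2
        window_tweet("u1", "baseline", "le la un une des et ou sur", hour=13),  # 0/8
        window_tweet("u1", "short", "peur le jour"),
        window_tweet("u1", "long", "ensemble et joie"),
    ]
    pooled = summarize_users(recs, lexicons, WINDOWS)
    assert pooled.loc["u1", "frac_social_baseline"] == pytest.approx(0.1)
    mean = summarize_users(recs, lexicons, WINDOWS, per_tweet_mean=True)
    assert mean.loc["u1", "frac_social_baseline"] == pytest.approx(0.25)


def test_summarize_users_empty_corpus(lexicons):
    with pytest.raises(ValueError, match="empty corpus"):
        summarize_users([], lexicons, WINDOWS)


def make_summaries(n, seed=0, dependent=False):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({f"pers_{c}": rng.normal(0.1, 0.02, n)
                       for c in PERSONALITY_CATEGORIES})
    df["log_posts"] = rng.normal(3, 1, n)
    if dependent:
        df["emotionality_short"] = (0.5 * df["pers_posemo"] + 0.3 * df["pers_negemo"]
                                    - 0.2 * df["pers_social"] + 0.1 * df["pers_i"]
                                    + 0.01 * df["log_posts"] + 0.02)
    else:
        df["emotionality_short"] = rng.normal(0.1, 0.03, n)
    df.index = [f"u{i}" for i in range(n)]
    return df


def test_corrected_emotionality_exact_linear_gives_zero_residuals():
    df = make_summaries(200, dependent=True)
    resid = corrected_emotionality(df)
    assert np.max(np.abs(resid)) < 1e-10


def test_corrected_emotionality_null_is_centered_emotionality():
    df = make_summaries(10_000, seed=1)
    resid = corrected_emotionality(df)
    centered = df["emotionality_short"] - df["emotionality_short"].mean()
    assert np.corrcoef(resid, centered)[0, 1] > 0.99


def test_corrected_emotionality_orthogonal_to_design():
    df = make_summaries(500, seed=2)
    resid = corrected_emotionality(df).to_numpy()
    for col in [f"pers_{c}" for c in PERSONALITY_CATEGORIES] + ["log_posts"]:
        assert abs(resid @ df[col].to_numpy()) < 1e-8 * len(df)
    assert abs(resid.sum()) < 1e-8 * len(df)


def test_corrected_emotionality_too_few_users_and_collinear():
    with pytest.raises(ValueError, match="at least"):
        corrected_emotionality(make_summaries(4))
    df = make_summaries(200)
    df["pers_negemo"] = 2.0 * df["pers_posemo"]
    with pytest.raises(ValueError, match="collinear"):
        corrected_emotionality(df)


def test_synchronization_groups_tie_is_low():
    df = pd.DataFrame({
        "frac_affect_baseline": [0.04, 0.06, 0.05],
        "frac_affect_short": [0.06, 0.06, 0.02],
    }, index=["a", "b", "c"])
    groups = synchronization_groups(df)
    assert list(groups) == ["high", "low", "low"]


def test_sliding_group_difference_recovers_injected_effect(lexicons):
    """High-group users get +10pp social-term rate after the event; the
    sliding difference should be ~0 pre-event and ~0.1 post-event."""
    rng = np.random.default_rng(0)
    recs = []
    n_per_group = 15
    days = pd.date_range("2015-10-01", "2016-01-15", freq="D")
    for g, base in (("high", None), ("low", None)):
        for i in range(n_per_group):
            uid = f"{g}{i}"
            for d in days[::2]:
                post_event = d.date() >= WINDOWS.event_day
                p_social = 0.1 + (0.1 if (g == "high" and post_event) else 0.0)
                words = ["famille" if rng.random() < p_social else "le"
                         for _ in range(10)]
                recs.append(make_tweet(user=uid,
                                       ts=d.strftime("%Y-%m-%dT12:00:00+01:00"),
                                       text=" ".join(words)))
    groups = pd.Series(
        ["high"] * n_per_group + ["low"] * n_per_group,
        index=[f"high{i}" for i in range(n_per_group)] + [f"low{i}" for i in range(n_per_group)])
    diff = sliding_group_difference(recs, groups, lexicons["social"], window_len=30,
                                    B=200, seed=1)
    pre = diff.loc[[d for d in diff.index if d < WINDOWS.event_day], "diff"]
    post = diff.loc[[d for d in diff.index if d >= WINDOWS.event_day +
                     pd.Timedelta(days=30).to_pytimedelta()], "diff"]
    assert abs(pre.mean()) < 0.02
    assert post.mean() == pytest.approx(0.1, abs=0.03)
    # bootstrap CI brackets the point estimate
    assert (diff["ci_low"] <= diff["diff"]).all() and (diff["diff"] <= diff["ci_high"]).all()


def test_sliding_group_difference_errors(lexicons):
    recs = [window_tweet("u1", "baseline", "ami le"),
            window_tweet("u2", "baseline", "famille la")]
    groups = pd.Series(["high", "low"], index=["u1", "u2"])
    with pytest.raises(ValueError, match="2 users per group"):
        sliding_group_difference(recs, groups, lexicons["social"])


def mediation_data(n, a=0.5, b=0.4, c=0.3, seed=0):
    rng = np.random.default_rng(seed)
    T = rng.normal(size=n)
    M = a * T + rng.normal(size=n) * 0.8
    Y = c * T + b * M + rng.normal(size=n) * 0.8
    return T, M, Y


def test_mediate_identity_and_determinism():
    T, M, Y = mediation_data(500, seed=3)
    r1 = mediate(T, M, Y, B=200, seed=42)
    r2 = mediate(T, M, Y, B=200, seed=42)
    assert r1 == r2  # bit-reproducible
    assert r1.ade + r1.acme == pytest.approx(r1.total_effect, abs=1e-10)


def test_mediate_recovers_paths():
    T, M, Y = mediation_data(20_000, seed=5)
    r = mediate(T, M, Y, B=200, seed=1)
    # standardized-scale oracle: alpha1 = a/sd(M), b = b*sd(M)/sd(Y)
    sd_m = np.sqrt(0.5**2 + 0.8**2)
    sd_y = np.std(Y)
    assert r.alpha_1 == pytest.approx(0.5 / sd_m, abs=0.02)
    assert r.b_coef == pytest.approx(0.4 * sd_m / sd_y, abs=0.02)
    assert r.acme == pytest.approx(r.alpha_1 * r.b_coef * (r.t1 - r.t0), abs=1e-12)


def test_mediate_null_path():
    T, M, Y = mediation_data(2000, a=0.5, b=0.0, c=0.0, seed=7)
    r = mediate(T, M, Y, B=300, seed=2)
    assert abs(r.acme) < 0.1 and abs(r.ade) < 0.1
    assert r.ci_acme[0] <= 0 <= r.ci_acme[1]


def test_mediate_insufficient_cases():
    T, M, Y = mediation_data(50)
    with pytest.raises(ValueError, match="complete cases"):
        mediate(T, M, Y, B=10)


def test_sequential_association_recovery(lexicons):
    recs = simulate_sequential_stream(800, 30, beta_x=0.5, seed=11)
    fit = sequential_association(recs, lexicons["social"], lexicons["negemo"])
    assert fit.ci[0] <= 0.5 <= fit.ci[1]
    assert fit.beta == pytest.approx(0.5, abs=0.15)
    assert fit.n_pairs == 800 * 29


def test_sequential_association_single_tweet_users_contribute_no_pairs(lexicons):
    multi = simulate_sequential_stream(40, 5, beta_x=0.1, seed=3)
    singles = [make_tweet(user=f"s{i}", ts="2015-11-15T10:00:00+01:00", text="peur")
               for i in range(10)]
    fit = sequential_association(multi + singles, lexicons["social"], lexicons["negemo"])
    assert fit.n_users == 40
    assert fit.n_pairs == 40 * 4


def test_sequential_association_errors(lexicons):
    few = simulate_sequential_stream(5, 10, beta_x=0.1, seed=2)
    with pytest.raises(ValueError, match="need >= 30 users"):
        sequential_association(few, lexicons["social"], lexicons["negemo"])


def test_attack_reference_model_recovers_negative_effect():
    df = simulate_attack_counts(4000, coef=-0.3, seed=6)
    fit = attack_reference_model(df["counts"], df["emotionality"], df["exposure"])
    assert fit.coef < 0
    assert fit.ci[1] < 0  # CI excludes zero
    assert fit.coef == pytest.approx(-0.3, abs=0.08)
    assert fit.dispersion_alpha == pytest.approx(0.8, abs=0.25)


def test_attack_reference_model_poisson_limit():
    df = simulate_attack_counts(4000, coef=-0.2, seed=8, dispersion_alpha=0.0,
                                inflate_p=0.2)
    fit = attack_reference_model(df["counts"], df["emotionality"], df["exposure"])
    assert fit.dispersion_alpha < 0.15  # near the Poisson limit


def test_attack_reference_model_input_errors():
    with pytest.raises(ValueError, match="all counts are zero"):
        attack_reference_model([0, 0, 0], [0.1, -0.2, 0.0], [1, 1, 1])
    with pytest.raises(ValueError, match="nonnegative integers"):
        attack_reference_model([1.5, 2.0], [0.1, 0.2], [1, 1])
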