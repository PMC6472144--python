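"""End-to-end convenience: tweet stream -> daily scores -> shock-model fit,
and the two standard synthetic experiments (collective phi, panel mediation)."""

from __future__ import annotations

from datetime import date, timedelta
from typing import Iterable

import pandas as pd

from .corpus import DEFAULT_TIMEZONE, TweetRecord
from .daily import daily_mean, normalized_score, weekday_baseline
from .lexicon import Lexicon, demo_lexicons
from .shock import ShockModelFit, fit_shock_model

__all__ = ["daily_score_series", "phi_from_records", "collective_phi",
           "panel_mediation"]


def daily_score_series(
    records: Iterable[TweetRecord],
    lex: Lexicon,
    event_day: date,
    baseline_window: tuple[date, date] | None = None,
    tz: str = DEFAULT_TIMEZONE,
) -> pd.Series:
    """Normalized daily scores s_t for one indicator.

    The weekday baseline is computed over ``baseline_window`` (default: the
    183 days ending the day before the event, clipped to the available
    data).
    """
    series = daily_mean(records, lex, tz)
    if baseline_window is None:
        first = series.index.min()
        baseline_window = (max(first, event_day - timedelta(days=183)),
                           event_day - timedelta(days=1))
    baselines = weekday_baseline(series, baseline_window)
    return normalized_score(series, baselines)


def phi_from_records(
    records: Iterable[TweetRecord],
    lex: Lexicon,
    event_day: date,
    baseline_window: tuple[date, date] | None = None,
    fit_window: tuple[date, date] | None = None,
    variant: str = "impulse",
    prior_scale: float = 2.5,
    tz: str = DEFAULT_TIMEZONE,
) -> ShockModelFit:
    """Full memory-coefficient pipeline on a tweet stream."""
    scores = daily_score_series(records, lex, event_day, baseline_window, tz)
    return fit_shock_model(scores, event_day, fit_window=fit_window,
                           variant=variant, prior_scale=prior_scale)


def collective_phi(seed: int, coupling_on: bool = True,
                   category: str = "negemo", **overrides) -> ShockModelFit:
    """Simulate the agent model and fit the memory coefficient on one indicator.

    The standard discrimination experiment: with coupling on, the field
    sustains a slow collective relaxation and phi is significantly positive;
    with coupling off, phi is indistinguishable from zero.
    """
    from .simulate import SimConfig, simulate_collective

    cfg = SimConfig(seed=seed, coupling_on=coupling_on, **overrides)
    records, _ = simulate_collective(cfg)
    return phi_from_records(records, demo_lexicons()[category], cfg.event_day)


def panel_mediation(cfg, category: str = "social", B: int = 1000, seed: int = 0):
    """Panel generator -> user summaries -> corrected emotionality -> mediation.

    Returns the :class:`~emosync.individual.MediationResult` for the given
    mediator/outcome category, with the four personality indicators and the
    log post count as covariates.
    """
    from .individual import (PERSONALITY_CATEGORIES, corrected_emotionality,
                             mediate, summarize_users)
    from .simulate import simulate_user_panel

    records, _ = simulate_user_panel(cfg)
    summaries = summarize_users(records, demo_lexicons(), cfg.windows)
    treatment = corrected_emotionality(summaries)
    covs = summaries[[f"pers_{c}" for c in PERSONALITY_CATEGORIES] + ["log_posts"]]
    return mediate(treatment, summaries[f"frac_{category}_short"],
                   summaries[f"frac_{category}_long"], covariates=covs,
                   B=B, seed=seed)
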