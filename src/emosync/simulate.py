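"""Synthetic tweet streams with known ground truth.

Two generators drive the test bench of the whole pipeline:

* :func:`simulate_collective` — a discrete-time agent-based model of
  collective emotions in the valence–arousal–communication-field tradition.
  Each agent carries a signed valence v ∈ [-1, 1] (what it would express)
  and an arousal a ∈ [0, 1] (its propensity to post).  Posting agents feed
  their valence into a global communication field h, and — when coupling is
  switched on — the field feeds back into everyone's valence and arousal.
  An event-day shock injects negative valence and extra arousal.  With
  coupling off, each agent relaxes individually and the daily aggregate has
  no memory (phi ≈ 0); with coupling on, the field sustains a slow
  collective relaxation and the daily scores acquire positive memory.

* :func:`simulate_user_panel` — a user-level causal generator with latent
  personality P, short-term emotionality E, a short-term mediator M and a
  long-term outcome Y, linked by known path coefficients
  (E→M: ``a_path``, M→Y: ``b_path``, E→Y direct: ``c_direct``, P loading
  everything: ``personality_loading``).  Latents are normalized to unit
  variance, so the nominal paths live on the standardized scale the
  mediation analysis reports, and the product-of-coefficients
  a*b*(q75-q25) is the closed-form oracle for the ACME.

Both emit the same tweet records :mod:`emosync.corpus` reads, with text
drawn from the synthetic demo lexicon pack; all randomness flows from one
mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from ._demo_lexicons import DEMO_CATEGORY_WORDS, FILLER_WORDS
from .corpus import StudyWindows, TweetRecord, date_range

__all__ = [
    "SimConfig",
    "PanelConfig",
    "simulate_collective",
    "simulate_user_panel",
    "draw_panel_latents",
    "simulate_sequential_stream",
    "simulate_attack_counts",
]

_PARIS = ZoneInfo("Europe/Paris")


def _emission_words(category: str) -> list[str]:
    """Concrete emittable word per lexicon entry (stems emit the stem itself)."""
    out = []
    for w in DEMO_CATEGORY_WORDS[category]:
        w = w.rstrip("*")
        if w.endswith("'"):  # bare elision stems are not tokenizable alone
            w += "ai"
        out.append(w)
    return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return float(np.log(p / (1.0 - p)))


# ---------------------------------------------------------------------------
# collective-emotion agent model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of the collective-emotion simulator.

    Decay rates are per step; with ``steps_per_day=24`` a step is one hour.
    ``field_valence_gain`` is kept small enough that the (mean valence,
    field) linear skeleton is stable — its dominant eigenvalue is ≈0.97 per
    step at the defaults, i.e. a collective relaxation of ≈0.5 per day.
    """

    seed: int
    n_agents: int = 500
    n_days: int = 120
    event_day_index: int = 60
    coupling_on: bool = True
    gamma_v: float = 0.3          # valence decay per step
    gamma_a: float = 0.2          # arousal decay per step
    gamma_h: float = 0.4          # field decay per step
    field_valence_gain: float = 0.27   # b: field -> valence
    field_arousal_gain: float = 0.5    # d: |field| -> arousal
    theta: float = 0.7            # posting threshold on arousal
    shock_arousal: float = 0.5
    shock_valence: float = -0.8   # the event injects negative valence
    sigma_v: float = 0.15         # per-step valence noise sd
    sigma_a: float = 0.05         # per-step arousal noise sd (dephases posting)
    steps_per_day: int = 24
    start_date: date = date(2015, 9, 14)  # day 60 lands on 2015-11-13
    # text emission
    mean_tokens: float = 11.0
    p_pos_base: float = 0.06
    p_neg_base: float = 0.03
    affect_gain: float = 0.15     # extra word probability per unit |valence|
    # per-agent activity drive bounds (relative excess over the threshold
    # fixed point; controls the posting rate, ~1-3 posts/agent/day)
    activity_low: float = 0.01
    activity_high: float = 0.12

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("gamma_v", "gamma_a", "gamma_h"):
            g = getattr(self, name)
            if not (0 < g <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {g}")
        if not (0 < self.theta < 1):
            raise ValueError("theta must be in (0, 1)")
        if self.n_agents < 1 or self.n_days < 2 or self.steps_per_day < 1:
            raise ValueError("n_agents, n_days, steps_per_day must be positive")
        if not (0 <= self.event_day_index < self.n_days):
            raise ValueError("event_day_index must lie inside the simulated days")

    @property
    def event_day(self) -> date:
        return self.start_date + timedelta(days=self.event_day_index)


_STEP_CATEGORIES = ("negemo", "posemo", "social", "i", "prosocial", "shared_values")
_STEP_FIXED_P = {"social": 0.05, "i": 0.05, "prosocial": 0.01, "shared_values": 0.005}


def _sample_texts(rng, n_tokens: np.ndarray, cat_probs: np.ndarray,
                  vocab: list[np.ndarray]) -> list[str]:
    """Sample texts: per tweet a token count, per token a category then a word.

    ``cat_probs`` is (n_tweets, n_categories); the last implicit category is
    the filler vocabulary (probability 1 - row sum).  ``vocab`` lists word
    arrays per category, filler last.
    """
    total = int(n_tokens.sum())
    if total == 0:
        return [""] * len(n_tokens)
    cum = np.cumsum(cat_probs, axis=1)
    tweet_idx = np.repeat(np.arange(len(n_tokens)), n_tokens)
    u = rng.random(total)
    cat = np.zeros(total, dtype=np.int64)
    for c in range(cum.shape[1]):
        cat += u >= cum[tweet_idx, c]
    words = np.empty(total, dtype=object)
    for c, wlist in enumerate(vocab):
        mask = cat == c
        k = int(mask.sum())
        if k:
            words[mask] = wlist[rng.integers(0, len(wlist), size=k)]
    bounds = np.cumsum(n_tokens)[:-1]
    return [" ".join(chunk) for chunk in np.split(words, bounds)]


def simulate_collective(cfg: SimConfig) -> tuple[list[TweetRecord], pd.DataFrame]:
    """Run the agent-based simulator and emit a tweet stream.

    Returns ``(records, state_log)``: the chronologically ordered tweets and
    a per-day log of the hidden state (mean valence, mean arousal, field
    value, post count) for oracle checks.

    Per step: valence decays and receives field input (when coupled) plus
    Gaussian noise; arousal decays and receives the agent's activity drive
    plus field input (when coupled); on the event day's first step the shock
    is added; agents with arousal above the threshold post (arousal resets),
    and the field relaxes toward the mean expressed valence of the posters.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_agents

    v = rng.uniform(-0.2, 0.2, n)
    a = rng.uniform(0.0, cfg.theta, n)
    # per-agent activity drive: fixed point of the arousal update sits just
    # above the posting threshold, heterogeneous across agents
    excess = rng.uniform(cfg.activity_low, cfg.activity_high, n)
    drive = cfg.gamma_a * cfg.theta * (1.0 + excess)
    h = 0.0

    vocab = [np.array(_emission_words(c), dtype=object) for c in _STEP_CATEGORIES]
    vocab.append(np.array(FILLER_WORDS, dtype=object))
    fixed = np.array([_STEP_FIXED_P[c] for c in _STEP_CATEGORIES[2:]])

    coupling = 1.0 if cfg.coupling_on else 0.0
    step_seconds = 86400.0 / cfg.steps_per_day
    records: list[TweetRecord] = []
    log_rows = []

    for day in range(cfg.n_days):
        day_date = cfg.start_date + timedelta(days=day)
        day_start = datetime.combine(day_date, time(0, 0), tzinfo=_PARIS)
        n_posts_today = 0
        for step in range(cfg.steps_per_day):
            v = v * (1 - cfg.gamma_v) + coupling * cfg.field_valence_gain * h \
                + rng.normal(0.0, cfg.sigma_v, n)
            a = a * (1 - cfg.gamma_a) + drive + coupling * cfg.field_arousal_gain * abs(h) \
                + rng.normal(0.0, cfg.sigma_a, n)
            if day == cfg.event_day_index and step == 0:
                v = v + cfg.shock_valence
                a = a + cfg.shock_arousal
            np.clip(v, -1.0, 1.0, out=v)
            np.clip(a, 0.0, 1.0, out=a)

            posters = np.nonzero(a > cfg.theta)[0]
            if len(posters):
                a[posters] = 0.0
                vp = v[posters]
                p_neg = cfg.p_neg_base + cfg.affect_gain * np.maximum(0.0, -vp)
                p_pos = cfg.p_pos_base + cfg.affect_gain * np.maximum(0.0, vp)
                probs = np.column_stack([
                    p_neg, p_pos, np.broadcast_to(fixed, (len(posters), len(fixed)))
                ])
                k = rng.poisson(cfg.mean_tokens - 1, len(posters)) + 1
                texts = _sample_texts(rng, k, probs, vocab)
                ts = day_start + timedelta(seconds=step * step_seconds)
                for j, agent in enumerate(posters):
                    records.append(TweetRecord(
                        user_id=f"agent{agent}",
                        timestamp=ts + timedelta(milliseconds=j),
                        text=texts[j],
                    ))
                h = h * (1 - cfg.gamma_h) + cfg.gamma_h * float(vp.mean())
                n_posts_today += len(posters)
            else:
                h = h * (1 - cfg.gamma_h)
        log_rows.append({
            "day": day, "date": day_date, "mean_valence": float(v.mean()),
            "mean_arousal": float(a.mean()), "field": h, "n_posts": n_posts_today,
        })

    return records, pd.DataFrame(log_rows).set_index("day")


# ---------------------------------------------------------------------------
# user-panel causal generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelConfig:
    """Parameters of the user-panel generator.

    Path coefficients are on the standardized latent scale: personality P,
    emotionality E, mediator M and outcome Y all have unit variance (the
    residual noise sds are solved for; a config error is raised when the
    requested paths leave no room for noise).  Latent levels are turned into
    token-emission probabilities through the bounded logistic link
    ``rate = 0.5 * sigmoid(mu + link_slope * latent)``, kept near the link's
    linear midpoint so the lexical fractions inherit the linear structure.
    """

    seed: int
    n_users: int = 5000
    windows: StudyWindows = field(default_factory=StudyWindows.default)
    a_path: float = 0.5          # emotionality -> short-term mediator
    b_path: float = 0.4          # mediator -> long-term outcome
    c_direct: float = 0.3        # emotionality -> outcome, direct
    personality_loading: float = 0.3   # P -> E, M, Y
    link_slope: float = 0.65
    affect_base: float = 0.42    # sigmoid level at latent 0 (rate = 0.5*this)
    social_base: float = 0.42
    # personality-indicator links (baseline window proxies of P)
    personality_link_loading: float = 0.5
    personality_link_noise: float = 0.3
    # tweet volumes (per user per day) and sizes
    rate_baseline: float = 3.0
    rate_short: float = 10.0
    rate_long: float = 3.0
    mean_tokens: float = 12.0
    weekend_factor: float = 1.3
    attack_rate: float = 0.004   # fixed attack-reference emission probability

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("a_path", "b_path", "c_direct", "personality_loading",
                     "link_slope", "rate_baseline", "rate_short", "rate_long"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_users < 1:
            raise ValueError("n_users must be positive")
        if not (0 < self.affect_base < 1 and 0 < self.social_base < 1):
            raise ValueError("link base levels must be in (0, 1)")
        # unit-variance normalization must be feasible
        _panel_noise_sds(self)


def _panel_noise_sds(cfg: PanelConfig) -> tuple[float, float, float]:
    """Residual sds that give P, E, M, Y unit variance under the path model."""
    a, b, c, g = cfg.a_path, cfg.b_path, cfg.c_direct, cfg.personality_loading
    var_e = 1.0 - g * g
    cov_ep = g
    var_m_struct = a * a + g * g + 2 * a * g * cov_ep
    var_m = 1.0 - var_m_struct
    cov_em = a + g * cov_ep  # Cov(E, aE+gP+e) = a + g*Cov(E,P)
    cov_mp = a * cov_ep + g
    var_y_struct = (c * c + b * b + g * g
                    + 2 * c * b * cov_em + 2 * c * g * cov_ep + 2 * b * g * cov_mp)
    var_y = 1.0 - var_y_struct
    if min(var_e, var_m, var_y) <= 0:
        raise ValueError(
            "path coefficients too large for unit-variance latents "
            f"(residual variances E={var_e:.3f}, M={var_m:.3f}, Y={var_y:.3f})"
        )
    return float(np.sqrt(var_e)), float(np.sqrt(var_m)), float(np.sqrt(var_y))


def draw_panel_latents(cfg: PanelConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the latent causal table (P, E, M, Y), all unit variance."""
    sd_e, sd_m, sd_y = _panel_noise_sds(cfg)
    g = cfg.personality_loading
    n = cfg.n_users
    P = rng.normal(size=n)
    E = g * P + sd_e * rng.normal(size=n)
    M = cfg.a_path * E + g * P + sd_m * rng.normal(size=n)
    Y = cfg.c_direct * E + cfg.b_path * M + g * P + sd_y * rng.normal(size=n)
    return pd.DataFrame({
        "user_id": [f"u{i}" for i in range(n)],
        "P": P, "E": E, "M": M, "Y": Y,
    }).set_index("user_id")


_PERSONALITY_BASE = {"posemo": 0.20, "negemo": 0.16, "social": 0.24, "i": 0.16}
_PANEL_CATEGORIES = ("posemo", "negemo", "social", "i", "prosocial",
                     "shared_values", "attack_ref")
_PANEL_FIXED = {"prosocial": 0.010, "shared_values": 0.005}


def _panel_rates(cfg: PanelConfig, latents: pd.DataFrame,
                 rng: np.random.Generator) -> dict[str, dict[str, np.ndarray]]:
    """Per-user token-emission probabilities per window and category."""
    n = len(latents)
    P = latents["P"].to_numpy()
    E = np.clip(latents["E"].to_numpy(), -3, 3)
    M = np.clip(latents["M"].to_numpy(), -3, 3)
    Y = np.clip(latents["Y"].to_numpy(), -3, 3)

    # baseline-window personality proxies: noisy loadings on P, clipped so
    # category probabilities can never crowd out the structural categories
    pers = {}
    for cat, base in _PERSONALITY_BASE.items():
        x = np.clip(cfg.personality_link_loading * P
                    + cfg.personality_link_noise * rng.normal(size=n), -1.2, 1.2)
        pers[cat] = 0.5 * _sigmoid(_logit(base) + x)

    mu_aff = _logit(cfg.affect_base)
    mu_soc = _logit(cfg.social_base)
    p_aff_short = 0.5 * _sigmoid(mu_aff + cfg.link_slope * E)
    p_soc_short = 0.5 * _sigmoid(mu_soc + cfg.link_slope * M)
    p_soc_long = 0.5 * _sigmoid(mu_soc + cfg.link_slope * Y)

    fixed = {c: np.full(n, p) for c, p in _PANEL_FIXED.items()}
    attack = np.full(n, cfg.attack_rate)
    rates = {
        "baseline": {"posemo": pers["posemo"], "negemo": pers["negemo"],
                     "social": pers["social"], "i": pers["i"],
                     **fixed, "attack_ref": attack},
        "short": {"posemo": 0.5 * p_aff_short, "negemo": 0.5 * p_aff_short,
                  "social": p_soc_short, "i": np.full(n, 0.08),
                  **fixed, "attack_ref": attack},
        "long": {"posemo": pers["posemo"], "negemo": pers["negemo"],
                 "social": p_soc_long, "i": np.full(n, 0.08),
                 **fixed, "attack_ref": attack},
    }
    for window, cats in rates.items():
        total = np.sum([cats[c] for c in _PANEL_CATEGORIES], axis=0)
        if np.any(total >= 0.98):
            raise ValueError(
                f"category emission probabilities sum to >= 0.98 in the "
                f"{window} window (max {total.max():.3f}); lower the link "
                "bases or slopes"
            )
    return rates


def simulate_user_panel(cfg: PanelConfig) -> tuple[list[TweetRecord], pd.DataFrame]:
    """Generate the user panel: tweets plus the ground-truth latent table.

    Tweet times are Poisson within each window with weekday rate modulation
    (weekends busier by ``weekend_factor``); texts are sampled token by
    token from the demo lexicon pack with the per-user, per-window category
    probabilities derived from the latents.  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    latents = draw_panel_latents(cfg, rng)
    rates = _panel_rates(cfg, latents, rng)
    w = cfg.windows

    vocab = [np.array(_emission_words(c), dtype=object) for c in _PANEL_CATEGORIES]
    vocab.append(np.array(FILLER_WORDS, dtype=object))

    window_days = {
        "baseline": date_range(w.baseline_start, w.baseline_end),
        "short": date_range(w.short_start, w.short_end),
        "long": date_range(w.long_start, w.long_end),
    }
    window_rate = {"baseline": cfg.rate_baseline, "short": cfg.rate_short,
                   "long": cfg.rate_long}

    n = cfg.n_users
    user_ids = np.array(latents.index, dtype=object)
    records: list[TweetRecord] = []

    for window, days in window_days.items():
        day_arr = np.array(days, dtype=object)
        weights = np.array([cfg.weekend_factor if d.weekday() >= 5 else 1.0 for d in days])
        weights = weights / weights.sum()

        n_tweets = rng.poisson(window_rate[window] * len(days), size=n)
        total = int(n_tweets.sum())
        if total == 0:
            continue
        tweet_user = np.repeat(np.arange(n), n_tweets)
        tweet_day = rng.choice(len(days), size=total, p=weights)
        # keep times inside the local calendar day, away from DST boundaries
        tweet_sec = rng.integers(6 * 3600, 23 * 3600, size=total)

        k = rng.poisson(cfg.mean_tokens - 1, size=total) + 1
        n_tok = int(k.sum())
        tok_tweet = np.repeat(np.arange(total), k)
        tok_user = tweet_user[tok_tweet]

        cum = np.cumsum(
            np.column_stack([rates[window][c] for c in _PANEL_CATEGORIES]), axis=1
        )
        u = rng.random(n_tok)
        cat = np.zeros(n_tok, dtype=np.int64)
        for c in range(cum.shape[1]):
            cat += u >= cum[tok_user, c]
        words = np.empty(n_tok, dtype=object)
        for c, wlist in enumerate(vocab):
            mask = cat == c
            m = int(mask.sum())
            if m:
                words[mask] = wlist[rng.integers(0, len(wlist), size=m)]

        bounds = np.cumsum(k)[:-1]
        texts = [" ".join(chunk) for chunk in np.split(words, bounds)]
        for i in range(total):
            d = day_arr[tweet_day[i]]
            sec = int(tweet_sec[i])
            ts = datetime.combine(d, time(sec // 3600, (sec // 60) % 60, sec % 60),
                                  tzinfo=_PARIS)
            records.append(TweetRecord(
                user_id=user_ids[tweet_user[i]], timestamp=ts, text=texts[i]
            ))

    records.sort(key=lambda r: r.timestamp)
    return records, latents


def null_panel_config(seed: int, n_users: int = 250, **overrides) -> PanelConfig:
    """A fully null panel: no causal paths and no personality loading.

    Small by default — meant for repeated calibration runs.
    """
    base = dict(
        seed=seed, n_users=n_users, a_path=0.0, b_path=0.0, c_direct=0.0,
        personality_loading=0.0, rate_baseline=1.0, rate_short=2.0,
        rate_long=1.0, mean_tokens=10.0,
    )
    base.update(overrides)
    return PanelConfig(**base)


# ---------------------------------------------------------------------------
# focused generators for the sequential and count-model analyses
# ---------------------------------------------------------------------------

def simulate_sequential_stream(
    n_users: int,
    tweets_per_user: int,
    beta_x: float,
    seed: int,
    beta_ar: float = 0.25,
    intercept: float = -1.1,
    p_x: float = 0.35,
    sigma_u: float = 0.3,
    predictor_word: str = "peur",
    outcome_word: str = "famille",
    start: datetime | None = None,
) -> list[TweetRecord]:
    """Tweet stream with a known lagged logit dependence between categories.

    Per user, predictor presence x_t is i.i.d. Bernoulli(``p_x``) and
    outcome presence follows
    ``logit P(y_t=1) = intercept + beta_x*x_{t-1} + beta_ar*y_{t-1} + u_i``
    with a per-user random intercept u_i ~ N(0, sigma_u^2).  Texts contain a
    filler word plus the category words when present.
    """
    rng = np.random.default_rng(seed)
    if start is None:
        start = datetime.combine(StudyWindows.default().short_start, time(8, 0),
                                 tzinfo=_PARIS)
    x = rng.random((n_users, tweets_per_user)) < p_x
    u = rng.normal(0.0, sigma_u, n_users)
    y = np.zeros((n_users, tweets_per_user), dtype=bool)
    y[:, 0] = rng.random(n_users) < _sigmoid(intercept + u)
    for t in range(1, tweets_per_user):
        eta = intercept + beta_x * x[:, t - 1] + beta_ar * y[:, t - 1] + u
        y[:, t] = rng.random(n_users) < _sigmoid(eta)

    records = []
    fillers = np.array(FILLER_WORDS, dtype=object)
    fill_idx = rng.integers(0, len(fillers), size=(n_users, tweets_per_user))
    for i in range(n_users):
        for t in range(tweets_per_user):
            parts = [fillers[fill_idx[i, t]]]
            if x[i, t]:
                parts.append(predictor_word)
            if y[i, t]:
                parts.append(outcome_word)
            ts = start + timedelta(minutes=10 * t, seconds=i % 60, days=(t // 150))
            records.append(TweetRecord(user_id=f"u{i}", timestamp=ts, text=" ".join(parts)))
    return records


def simulate_attack_counts(
    n_users: int,
    coef: float,
    seed: int,
    intercept: float = -4.0,
    dispersion_alpha: float = 0.8,
    inflate_p: float = 0.3,
) -> pd.DataFrame:
    """Zero-inflated negative-binomial counts with a known emotionality effect.

    Counts are attack-reference term totals in the long window; the log mean
    is ``intercept + coef * emotionality + exposure`` with exposure the log
    post count.  ``dispersion_alpha=0`` gives pure Poisson counts.
    """
    rng = np.random.default_rng(seed)
    emo = rng.normal(size=n_users)
    posts = rng.integers(50, 400, size=n_users)
    exposure = np.log(posts)
    mu = np.exp(intercept + coef * emo + exposure)
    if dispersion_alpha > 0:
        r = 1.0 / dispersion_alpha
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    counts = np.where(rng.random(n_users) < inflate_p, 0, counts)
    return pd.DataFrame({
        "counts": counts.astype(int),
        "emotionality": emo,
        "exposure": exposure,
    })
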