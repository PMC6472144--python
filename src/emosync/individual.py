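"""Individual-level analysis: user summaries, self-selection correction,
synchronization groups, sliding-window group differences, causal mediation,
lagged tweet-pair association, and the attack-reference count model.

The unit of analysis is the user.  Per user and study window the pipeline
pools word counts (category tokens / all tokens) — robust for low-volume
accounts.  Short-term emotionality (combined positive+negative affect in
the two weeks after the event) is corrected for self-selection by
regressing it on a personality-related lexical vector (positive affect,
negative affect, social processes, first-person singular, all from the
baseline window) plus the log post count, keeping the residual.  That
corrected emotionality is the treatment in a bootstrap mediation analysis
whose mediator is the short-window level of the outcome indicator and whose
outcome is its long-window level, contrasting the 25th and 75th treatment
percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import DEFAULT_TIMEZONE, StudyWindows, TweetRecord, assign_day, date_range
from .lexicon import Lexicon, tokenize

log = logging.getLogger(__name__)

__all__ = [
    "summarize_users",
    "corrected_emotionality",
    "synchronization_groups",
    "sliding_group_difference",
    "mediate",
    "MediationResult",
    "sequential_association",
    "SequentialFit",
    "attack_reference_model",
    "AttackModelFit",
    "user_day_counts",
    "PERSONALITY_CATEGORIES",
]

PERSONALITY_CATEGORIES = ("posemo", "negemo", "social", "i")
WINDOW_NAMES = ("baseline", "short", "long")


class _CategoryCounter:
    """Token -> category-membership bitmask with memoization (hot path)."""

    def __init__(self, lexicons: Mapping[str, Lexicon]):
        self.names = list(lexicons)
        self._lexs = list(lexicons.values())
        self._cache: dict[str, int] = {}

    def mask(self, token: str) -> int:
        m = self._cache.get(token)
        if m is None:
            m = 0
            for i, lex in enumerate(self._lexs):
                if lex.matches_token(token):
                    m |= 1 << i
            self._cache[token] = m
        return m

    def decode(self, mask_counts: Mapping[int, int]) -> np.ndarray:
        out = np.zeros(len(self.names), dtype=np.int64)
        for m, cnt in mask_counts.items():
            i = 0
            while m:
                if m & 1:
                    out[i] += cnt
                m >>= 1
                i += 1
        return out


def summarize_users(
    records: Iterable[TweetRecord],
    lexicons: Mapping[str, Lexicon],
    windows: StudyWindows,
    tz: str = DEFAULT_TIMEZONE,
    per_tweet_mean: bool = False,
) -> pd.DataFrame:
    """Per-user category fractions per study window.

    Only users with at least one tweet in *all three* windows are kept
    (excluded counts are logged).  The returned frame (indexed by user)
    carries, per window w: ``n_posts_w``, ``n_tokens_w`` and
    ``frac_<category>_w`` fractions, plus the derived columns
    ``pers_<category>`` (baseline personality vector), ``log_posts``
    (ln baseline posts) and ``emotionality_short`` (combined
    positive+negative affect fraction in the short window; a token in both
    affect categories counts once).

    Fractions are pooled word-count ratios (category tokens / all tokens of
    the user's window — robust for low-volume accounts) by default;
    ``per_tweet_mean=True`` averages per-tweet fractions instead.
    """
    names = list(lexicons)
    for cat in PERSONALITY_CATEGORIES:
        if cat not in names:
            raise ValueError(f"lexicons must include personality category {cat!r}")
    counter = _CategoryCounter(lexicons)
    affect_bits = (1 << names.index("posemo")) | (1 << names.index("negemo"))

    window_of = {d: windows.classify(d) for d in date_range(*windows.span)}

    # (user, window) -> [n_posts, n_tokens, n_affect, {mask: count},
    #                    per-tweet-mean accumulators (fraction sums, n tweets)]
    n_cat = len(names)
    acc: dict[tuple[str, str], list] = {}
    n_records = 0
    for rec in records:
        n_records += 1
        day, _ = assign_day(rec, tz)
        win = window_of.get(day)
        if win is None:
            continue
        tokens = tokenize(rec.text)
        key = (rec.user_id, win)
        slot = acc.get(key)
        if slot is None:
            slot = acc[key] = [0, 0, 0, {}, np.zeros(n_cat + 1), 0]
        slot[0] += 1
        slot[1] += len(tokens)
        masks = slot[3] if not per_tweet_mean else {}
        n_affect = 0
        for t in tokens:
            m = counter.mask(t)
            if m:
                masks[m] = masks.get(m, 0) + 1
                if m & affect_bits:
                    n_affect += 1
        slot[2] += n_affect
        if per_tweet_mean and tokens:
            tweet_counts = counter.decode(masks)
            slot[4][:n_cat] += tweet_counts / len(tokens)
            slot[4][n_cat] += n_affect / len(tokens)
            slot[5] += 1
    if n_records == 0:
        raise ValueError("empty corpus")

    users = sorted({u for u, _ in acc})
    complete = [u for u in users if all((u, w) in acc for w in WINDOW_NAMES)]
    n_excluded = len(users) - len(complete)
    if n_excluded:
        log.info("summarize_users: excluded %d/%d users lacking activity in some window",
                 n_excluded, len(users))

    rows = {}
    for u in complete:
        row: dict[str, float] = {}
        for w in WINDOW_NAMES:
            n_posts, n_tokens, n_affect, masks, frac_sums, n_scorable = acc[(u, w)]
            row[f"n_posts_{w}"] = n_posts
            row[f"n_tokens_{w}"] = n_tokens
            if per_tweet_mean:
                denom = n_scorable if n_scorable else np.nan
                for i, name in enumerate(names):
                    row[f"frac_{name}_{w}"] = frac_sums[i] / denom
                row[f"frac_affect_{w}"] = frac_sums[n_cat] / denom
            else:
                counts = counter.decode(masks)
                for name, cnt in zip(names, counts):
                    row[f"frac_{name}_{w}"] = cnt / n_tokens if n_tokens else np.nan
                row[f"frac_affect_{w}"] = n_affect / n_tokens if n_tokens else np.nan
        rows[u] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "user_id"
    if out.empty:
        return out
    for cat in PERSONALITY_CATEGORIES:
        out[f"pers_{cat}"] = out[f"frac_{cat}_baseline"]
    out["log_posts"] = np.log(out["n_posts_baseline"])
    out["emotionality_short"] = out["frac_affect_short"]
    return out


def corrected_emotionality(summaries: pd.DataFrame) -> pd.Series:
    """Self-selection-corrected short-term emotionality (OLS residuals).

    Regresses ``emotionality_short`` on the four baseline personality
    indicators plus ``log_posts`` (user engagement) and an intercept; the
    residual is the corrected measurement.  Residuals are exactly orthogonal
    to every design column.
    """
    cols = [f"pers_{c}" for c in PERSONALITY_CATEGORIES] + ["log_posts"]
    X = summaries[cols].to_numpy(dtype=float)
    y = summaries["emotionality_short"].to_numpy(dtype=float)
    n, p = X.shape
    if n < 10 * (p + 1):
        raise ValueError(f"need at least {10 * (p + 1)} users for {p} predictors, got {n}")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        sds = X.std(axis=0)
        suspects = [c for c, s in zip(cols, sds) if s == 0]
        corr = np.corrcoef(X, rowvar=False)
        for i in range(p):
            for j in range(i + 1, p):
                if abs(corr[i, j]) > 1 - 1e-10:
                    suspects += [cols[i], cols[j]]
        raise ValueError(f"rank-deficient design; collinear columns: {sorted(set(suspects))}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return pd.Series(resid, index=summaries.index, name="corrected_emotionality")


def synchronization_groups(summaries: pd.DataFrame) -> pd.Series:
    """High/low emotional-synchronization label per user.

    ``high`` iff the user's combined affect frequency in the short window
    strictly exceeds their own baseline frequency; ties are ``low``
    ("more frequently" is strict).
    """
    high = summaries["frac_affect_short"] > summaries["frac_affect_baseline"]
    return pd.Series(np.where(high, "high", "low"), index=summaries.index, name="sync_group")


def user_day_counts(
    records: Iterable[TweetRecord], lex: Lexicon, tz: str = DEFAULT_TIMEZONE
) -> pd.DataFrame:
    """Per user and calendar day: matching-token and total-token counts."""
    acc: dict[tuple[str, date], list[int]] = {}
    cache: dict[str, bool] = {}
    match = lex.matches_token
    for rec in records:
        day, _ = assign_day(rec, tz)
        tokens = tokenize(rec.text)
        key = (rec.user_id, day)
        slot = acc.get(key)
        if slot is None:
            slot = acc[key] = [0, 0]
        slot[1] += len(tokens)
        hits = 0
        for t in tokens:
            hit = cache.get(t)
            if hit is None:
                hit = cache[t] = match(t)
            if hit:
                hits += 1
        slot[0] += hits
    if not acc:
        return pd.DataFrame(columns=["user_id", "date", "matches", "tokens"])
    rows = [(u, d, m, t) for (u, d), (m, t) in acc.items()]
    return pd.DataFrame(rows, columns=["user_id", "date", "matches", "tokens"])


def sliding_group_difference(
    records: Iterable[TweetRecord],
    groups: pd.Series,
    lex: Lexicon,
    window_len: int = 30,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    tz: str = DEFAULT_TIMEZONE,
) -> pd.DataFrame:
    """Sliding-window difference of group-mean indicator frequencies.

    For every window endpoint date t, each user's pooled fraction over
    [t - window_len + 1, t] is averaged within the high and the low group;
    the returned frame holds the high-minus-low difference with a bootstrap
    CI obtained by resampling *users* (not tweets) within each group.
    """
    counts = user_day_counts(records, lex, tz)
    if counts.empty:
        raise ValueError("no records")
    users = [u for u in groups.index if u in set(counts["user_id"])]
    high = [u for u in users if groups[u] == "high"]
    low = [u for u in users if groups[u] == "low"]
    if len(high) < 2 or len(low) < 2:
        raise ValueError(f"need >= 2 users per group (high={len(high)}, low={len(low)})")

    days = date_range(counts["date"].min(), counts["date"].max())
    if window_len > len(days):
        raise ValueError(f"window_len {window_len} exceeds data span {len(days)} days")
    day_idx = {d: i for i, d in enumerate(days)}
    user_idx = {u: i for i, u in enumerate(users)}

    M = np.zeros((len(users), len(days)))
    T = np.zeros((len(users), len(days)))
    sel = counts[counts["user_id"].isin(user_idx)]
    rows = sel["user_id"].map(user_idx).to_numpy()
    cols = sel["date"].map(day_idx).to_numpy()
    np.add.at(M, (rows, cols), sel["matches"].to_numpy(dtype=float))
    np.add.at(T, (rows, cols), sel["tokens"].to_numpy(dtype=float))

    # rolling window sums via cumulative sums along the day axis
    cm = np.cumsum(M, axis=1)
    ct = np.cumsum(T, axis=1)
    wm = cm[:, window_len - 1:].copy()
    wt = ct[:, window_len - 1:].copy()
    wm[:, 1:] -= cm[:, :-window_len]
    wt[:, 1:] -= ct[:, :-window_len]
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(wt > 0, wm / np.maximum(wt, 1), np.nan)
    V = (wt > 0).astype(float)
    Fz = np.nan_to_num(F)

    hi_idx = np.array([user_idx[u] for u in high])
    lo_idx = np.array([user_idx[u] for u in low])

    def group_means(idx_sample: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return Fz[idx_sample].sum(axis=0) / V[idx_sample].sum(axis=0)

    mean_high = group_means(hi_idx)
    mean_low = group_means(lo_idx)
    diff = mean_high - mean_low

    rng = np.random.default_rng(seed)
    boots = np.empty((B, len(diff)))
    for b in range(B):
        hs = hi_idx[rng.integers(0, len(hi_idx), len(hi_idx))]
        ls = lo_idx[rng.integers(0, len(lo_idx), len(lo_idx))]
        boots[b] = group_means(hs) - group_means(ls)
    lo_q, hi_q = np.nanpercentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)

    return pd.DataFrame({
        "window_end": days[window_len - 1:],
        "mean_high": mean_high,
        "mean_low": mean_low,
        "diff": diff,
        "ci_low": lo_q,
        "ci_high": hi_q,
    }).set_index("window_end")


# ---------------------------------------------------------------------------
# causal mediation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediationResult:
    """ADE/ACME decomposition with bootstrap uncertainty.

    Effects are on the standardized-outcome scale for a treatment contrast
    from the 25th to the 75th percentile of the (standardized) treatment.
    ``total_effect`` comes from the reduced-form outcome model and equals
    ``ade + acme`` exactly for these nested linear models.
    """

    ade: float
    acme: float
    total_effect: float
    ci_ade: tuple[float, float]
    ci_acme: tuple[float, float]
    ci_total: tuple[float, float]
    p_ade: float
    p_acme: float
    p_total: float
    t0: float
    t1: float
    alpha_1: float   # treatment -> mediator coefficient
    b_coef: float    # mediator -> outcome coefficient
    c_coef: float    # treatment -> outcome direct coefficient
    n: int
    B: int

    def to_dict(self) -> dict:
        return {
            "ade": self.ade, "acme": self.acme, "total_effect": self.total_effect,
            "ci_ade": list(self.ci_ade), "ci_acme": list(self.ci_acme),
            "ci_total": list(self.ci_total),
            "p_ade": self.p_ade, "p_acme": self.p_acme, "p_total": self.p_total,
            "t0": self.t0, "t1": self.t1, "n": self.n, "B": self.B,
        }


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant variable cannot be standardized")
    return (x - x.mean(axis=0)) / sd


def _mediation_point(T, M, Y, X):
    """(ade, acme, total, alpha1, b, c) on already-standardized data."""
    n = len(T)
    ones = np.ones(n)
    D_m = np.column_stack([ones, T] + ([X] if X is not None else []))
    D_y = np.column_stack([ones, T, M] + ([X] if X is not None else []))
    D_t = D_m  # reduced form uses the same design as the mediator model
    cm, *_ = np.linalg.lstsq(D_m, M, rcond=None)
    cy, *_ = np.linalg.lstsq(D_y, Y, rcond=None)
    ct, *_ = np.linalg.lstsq(D_t, Y, rcond=None)
    alpha1 = cm[1]
    c_coef, b_coef = cy[1], cy[2]
    gamma = ct[1]
    t0, t1 = np.percentile(T, [25, 75])
    delta = t1 - t0
    return (c_coef * delta, alpha1 * b_coef * delta, gamma * delta,
            alpha1, b_coef, c_coef, t0, t1)


def mediate(
    treatment: Sequence[float],
    mediator: Sequence[float],
    outcome: Sequence[float],
    covariates: pd.DataFrame | np.ndarray | None = None,
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> MediationResult:
    """Linear no-interaction causal mediation with bootstrap uncertainty.

    Fits the mediator model M ~ T + X and the outcome model Y ~ T + M + X
    (all variables standardized first) and reports
    ``ACME = alpha_1 * b * (t1 - t0)`` and ``ADE = c * (t1 - t0)``, where t0
    and t1 are the 25th/75th percentiles of the standardized treatment.
    CIs and p-values come from a nonparametric percentile bootstrap over
    users (``B`` draws, deterministic given ``seed``); each draw refits both
    models and recomputes the percentiles.
    """
    T = _standardize(np.asarray(treatment, dtype=float))
    M = _standardize(np.asarray(mediator, dtype=float))
    Y = _standardize(np.asarray(outcome, dtype=float))
    X = None
    if covariates is not None:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        X = _standardize(X)
    n = len(T)
    if not (len(M) == len(Y) == n) or (X is not None and len(X) != n):
        raise ValueError("treatment, mediator, outcome, covariates must be equal length")
    mask = np.isfinite(T) & np.isfinite(M) & np.isfinite(Y)
    if X is not None:
        mask &= np.all(np.isfinite(X), axis=1)
    if mask.sum() < 100:
        raise ValueError(f"need >= 100 complete cases, got {int(mask.sum())}")
    T, M, Y = T[mask], M[mask], Y[mask]
    if X is not None:
        X = X[mask]
    n = len(T)

    full_design = np.column_stack([np.ones(n), T, M] + ([X] if X is not None else []))
    if np.linalg.matrix_rank(full_design) < full_design.shape[1]:
        raise ValueError("collinear mediation design")

    ade, acme, total, a1, bcoef, ccoef, t0, t1 = _mediation_point(T, M, Y, X)

    rng = np.random.default_rng(seed)
    draws = np.empty((B, 3))
    for i in range(B):
        idx = rng.integers(0, n, n)
        Xb = X[idx] if X is not None else None
        try:
            d_ade, d_acme, d_total, *_ = _mediation_point(T[idx], M[idx], Y[idx], Xb)
        except np.linalg.LinAlgError:  # pathological resample
            d_ade = d_acme = d_total = np.nan
        draws[i] = (d_ade, d_acme, d_total)

    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    cis = np.nanpercentile(draws, qs, axis=0)

    def boot_p(col: np.ndarray) -> float:
        col = col[np.isfinite(col)]
        if len(col) == 0:
            return float("nan")
        p = 2 * min((col <= 0).mean(), (col >= 0).mean())
        return float(min(1.0, p))

    return MediationResult(
        ade=ade, acme=acme, total_effect=total,
        ci_ade=(float(cis[0, 0]), float(cis[1, 0])),
        ci_acme=(float(cis[0, 1]), float(cis[1, 1])),
        ci_total=(float(cis[0, 2]), float(cis[1, 2])),
        p_ade=boot_p(draws[:, 0]), p_acme=boot_p(draws[:, 1]), p_total=boot_p(draws[:, 2]),
        t0=float(t0), t1=float(t1),
        alpha_1=float(a1), b_coef=float(bcoef), c_coef=float(ccoef),
        n=n, B=B,
    )


# ---------------------------------------------------------------------------
# lagged tweet-pair association (random-intercept logistic regression)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequentialFit:
    beta: float            # lagged predictor-category coefficient (logit scale)
    se: float
    ci: tuple[float, float]
    p: float
    beta_ar: float         # lagged outcome (autocorrelation) coefficient
    beta_interaction: float
    intercept: float
    sigma_u: float         # random-intercept sd
    n_pairs: int
    n_users: int

    def to_dict(self) -> dict:
        return {
            "beta": self.beta, "se": self.se, "ci": list(self.ci), "p": self.p,
            "beta_ar": self.beta_ar, "beta_interaction": self.beta_interaction,
            "intercept": self.intercept, "sigma_u": self.sigma_u,
            "n_pairs": self.n_pairs, "n_users": self.n_users,
        }


def _gh_logistic_ml(X: np.ndarray, y: np.ndarray, group_sizes: np.ndarray,
                    n_nodes: int = 15):
    """Random-intercept logistic regression by Gauss–Hermite quadrature ML.

    Observations must be ordered by group; returns (params, cov) where
    params = (coefs..., sigma_u).  The marginal likelihood integrates the
    per-group intercept u ~ N(0, sigma_u^2) on a fixed quadrature grid —
    consistent as the number of groups grows.
    """
    from scipy.optimize import minimize
    from statsmodels.tools.numdiff import approx_hess1

    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    logw = np.log(weights / np.sqrt(2 * np.pi))
    p = X.shape[1]
    ends = np.cumsum(group_sizes)
    starts = ends - group_sizes
    sign = np.where(y > 0, 1.0, -1.0)

    def negll(params):
        beta, sigma = params[:p], params[p]
        eta = X @ beta
        # (obs, node) log-likelihood contributions
        z = sign[:, None] * (eta[:, None] + sigma * nodes[None, :])
        ll_obs = -np.logaddexp(0.0, -z)
        ll_grp = np.add.reduceat(ll_obs, starts, axis=0)
        m = ll_grp.max(axis=1, keepdims=True)
        ll = m[:, 0] + np.log(np.exp(ll_grp - m + logw[None, :]).sum(axis=1))
        return -ll.sum()

    start_beta = np.zeros(p)
    res = minimize(negll, np.concatenate([start_beta, [0.5]]),
                   method="L-BFGS-B",
                   bounds=[(None, None)] * p + [(1e-6, 10.0)])
    hess = approx_hess1(res.x, negll)
    cov = np.linalg.pinv(hess)
    return res.x, cov


def sequential_association(
    records: Iterable[TweetRecord],
    lexicon_outcome: Lexicon,
    lexicon_predictor: Lexicon,
    window: tuple[date, date] | None = None,
    min_users: int = 30,
    tz: str = DEFAULT_TIMEZONE,
    alpha: float = 0.05,
) -> SequentialFit:
    """Does one tweet's content predict the next tweet of the same user?

    For each user's time-ordered tweets inside ``window`` (default: the two
    weeks from the event day of the standard study layout), the binary
    outcome y_t = "tweet t contains the outcome category" is modelled as a
    mixed-effects logistic regression on x_{t-1} (predictor category in the
    previous tweet), y_{t-1} (autocorrelation) and their interaction, with a
    random intercept per user.  Returns the x_{t-1} coefficient.
    """
    if window is None:
        w = StudyWindows.default()
        window = (w.short_start, w.short_end)
    start, end = window

    per_user: dict[str, list[tuple]] = {}
    for rec in records:
        day, _ = assign_day(rec, tz)
        if not (start <= day <= end):
            continue
        per_user.setdefault(rec.user_id, []).append((rec.timestamp, rec.text))

    rows_x, rows_yprev, rows_y, sizes = [], [], [], []
    n_users = 0
    for user, tweets in per_user.items():
        if len(tweets) < 2:
            continue  # a single tweet contributes no pairs
        tweets.sort(key=lambda t: t[0])
        toks = [tokenize(txt) for _, txt in tweets]
        ys = [1.0 if lexicon_outcome.fraction(t) else 0.0 for t in toks]
        xs = [1.0 if lexicon_predictor.fraction(t) else 0.0 for t in toks]
        n_pairs_user = len(tweets) - 1
        rows_y.extend(ys[1:])
        rows_yprev.extend(ys[:-1])
        rows_x.extend(xs[:-1])
        sizes.append(n_pairs_user)
        n_users += 1
    if n_users < min_users:
        raise ValueError(f"need >= {min_users} users with >= 2 tweets, got {n_users}")

    y = np.asarray(rows_y)
    if y.min() == y.max():
        raise ValueError("outcome is constant (all 0 or all 1)")
    x_prev = np.asarray(rows_x)
    y_prev = np.asarray(rows_yprev)
    X = np.column_stack([np.ones_like(y), x_prev, y_prev, x_prev * y_prev])

    params, cov = _gh_logistic_ml(X, y, np.asarray(sizes))
    beta = float(params[1])
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    from scipy import stats
    z = stats.norm.ppf(1 - alpha / 2)
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan")
    return SequentialFit(
        beta=beta, se=se, ci=(beta - z * se, beta + z * se), p=p,
        beta_ar=float(params[2]), beta_interaction=float(params[3]),
        intercept=float(params[0]), sigma_u=float(params[4]),
        n_pairs=int(len(y)), n_users=n_users,
    )


# ---------------------------------------------------------------------------
# attack-reference count model (zero-inflated negative binomial)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttackModelFit:
    coef: float              # emotionality coefficient (log-rate scale)
    se: float
    ci: tuple[float, float]
    p: float
    dispersion_alpha: float  # NB overdispersion (0 = Poisson limit)
    inflation_logit: float   # constant zero-inflation on the logit scale
    n: int

    def to_dict(self) -> dict:
        return {"coef": self.coef, "se": self.se, "ci": list(self.ci), "p": self.p,
                "dispersion_alpha": self.dispersion_alpha,
                "inflation_logit": self.inflation_logit, "n": self.n}


def attack_reference_model(
    counts: Sequence[int],
    corrected_emotionality: Sequence[float],
    exposure: Sequence[float],
    alpha: float = 0.05,
) -> AttackModelFit:
    """Zero-inflated negative-binomial regression of attack-term counts.

    Long-window attack-reference counts are regressed on corrected
    emotionality with the log post count as exposure offset and a constant
    zero-inflation component.  Returns the emotionality coefficient with CI
    and the estimated overdispersion.
    """
    import statsmodels.api as sm
    from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

    y = np.asarray(counts)
    if not np.issubdtype(y.dtype, np.integer):
        yf = np.asarray(counts, dtype=float)
        if not np.allclose(yf, np.round(yf)):
            raise ValueError("counts must be nonnegative integers")
        y = yf.astype(int)
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative integers")
    if y.max() == 0:
        raise ValueError("all counts are zero")
    emo = np.asarray(corrected_emotionality, dtype=float)
    off = np.asarray(exposure, dtype=float)

    exog = sm.add_constant(emo)
    model = ZeroInflatedNegativeBinomialP(
        y, exog, exog_infl=np.ones((len(y), 1)), offset=off, p=2
    )
    import warnings

    res = None
    # near the Poisson limit the alpha boundary can defeat a single optimizer
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "nm", "lbfgs"):
            try:
                res = model.fit(method=method, maxiter=2000, disp=0)
            except Exception:
                continue
            if res.mle_retvals.get("converged", False):
                break
    if res is None:
        raise RuntimeError("zero-inflated negative-binomial fit failed")

    # combined parameter layout: [inflate_const, const, x1, alpha]
    names = list(res.model.exog_names)
    idx = names.index("x1")
    coef = float(res.params[idx])
    se = float(res.bse[idx])
    from scipy import stats
    z = stats.norm.ppf(1 - alpha / 2)
    return AttackModelFit(
        coef=coef, se=se, ci=(coef - z * se, coef + z * se),
        p=float(2 * stats.norm.sf(abs(coef / se))) if se > 0 else float("nan"),
        dispersion_alpha=float(res.params[names.index("alpha")]),
        inflation_logit=float(res.params[names.index("inflate_const")]),
        n=int(len(y)),
    )
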