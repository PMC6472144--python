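# emosync

Collective emotions and solidarity in tweet streams around a collective
trauma: a tested analysis pipeline for computational social psychology.

After a society-wide traumatic event, do people merely react individually —
a spike of emotion that relaxes within a day — or do they synchronize into
a *collective* emotion that sustains itself and strengthens solidarity?
`emosync` implements the full measurement chain needed to ask that question
of a tweet corpus, together with synthetic generators (including an
agent-based collective-emotion simulator) that provide known ground truth
for every statistical procedure in the chain.

## What it computes

1. **Lexical indicators** — per text, the fraction of tokens in a word
   category (positive/negative affect, sadness, anxiety, anger, social
   processes, prosocial terms, shared values, ...), from LIWC-style `.dic`,
   JSON or CSV lexicons, with stem (`solidar*`) matching.
2. **Daily scores** — daily means m_t, per-weekday baselines b_w over a
   pre-event window, and the seasonality-corrected log-ratio score
   `s_t = ln(m_t / b_w)`, with per-day bootstrap CIs.
3. **Shock + memory model** — `s_t = c + φ·s_{t−1} + β·X_t + ε_t`, with an
   event-day impulse X_t and weakly-informative-prior estimation.  The
   memory coefficient φ is the test of collective dynamics: φ > 0 means the
   aggregate relaxes slower than individuals do; φ ≈ 0 means no collective
   behavior.  Residual diagnostics included.
4. **Individual-level analysis** — per-user window summaries,
   self-selection-corrected short-term emotionality (residualization on a
   personality-related lexical vector), high/low emotional-synchronization
   groups, sliding-window group differences, bootstrap causal mediation
   (ADE/ACME at the 25th→75th treatment contrast), lagged tweet-pair
   mixed-effects logistic association, and a zero-inflated negative-binomial
   model of attack-reference counts.
5. **Synthetic data** — a valence–arousal–field agent simulator with
   switchable emotional feedback, and a user-panel generator with known
   mediation path coefficients.

See `docs/methods.md` for the models, assumptions and calibration.

## Worked example

Discriminating collective from individual dynamics on the simulator:

```python
from emosync.pipeline import collective_phi

for coupled in (True, False):
    fit = collective_phi(seed=2, coupling_on=coupled)
    print(f"coupling={coupled}: phi={fit.phi:.3f} "
          f"CI=({fit.ci_phi[0]:.3f}, {fit.ci_phi[1]:.3f}) p={fit.p_phi:.4f}")
```

prints

```
coupling=True: phi=0.565 CI=(0.448, 0.683) p=0.0000
coupling=False: phi=0.082 CI=(-0.067, 0.230) p=0.2805
```

With emotional feedback on, the simulated community's daily negative-affect
score carries significant memory (φ ≈ 0.5): the collective state decays
over days, not hours.  With feedback off, the same agents produce
φ indistinguishable from zero — individual relaxation only.

Mediation with known ground truth (paths a = 0.5, b = 0.4, c′ = 0.3):

```python
from emosync.pipeline import panel_mediation
from emosync.simulate import PanelConfig

cfg = PanelConfig(seed=7)
res = panel_mediation(cfg, B=1000, seed=1)
print(f"ACME={res.acme:.3f} ADE={res.ade:.3f} total={res.total_effect:.3f}")
```

prints `ACME=0.277 ADE=0.426 total=0.703` — against closed-form targets
a·b·(q75−q25) = 0.287 and c′·(q75−q25) = 0.430 for this draw, i.e.
recovery within a few percent; ADE + ACME equals the total effect exactly.

A CLI mirrors the pipeline for file-based workflows
(`emosync simulate | score-daily | fit-shock | user-analysis | mediate`).

## Data expectations

Tweet tables are JSONL or CSV (`user_id`, ISO-8601 `timestamp`, `text`,
optional `is_retweet`); retweets are dropped; days are binned in a
configurable timezone (default Europe/Paris).  The pipeline expects a
pre-filtered user panel — bot/mass-media filtering, geolocation and
language detection are out of scope.  No tweet corpus and no licensed
dictionary ships with the package; the bundled lexicon pack is synthetic
and exists for tests and simulations.
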