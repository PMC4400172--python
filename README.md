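# entrainkit

Multi-timescale analysis of **collective attentional entrainment**: how a
stream of timestamped public messages (e.g. a ~10% random sample of tweets)
locks, second by second, onto the structure of a broadcast conversation such
as a televised election debate.

The package is for computational social scientists and cognitive scientists
who have (a) a conversational annotation — speech turns with start/end times,
interruption flags, and the onsets of salient remarks — and (b) a timestamped
message stream, and who want to quantify entrainment at three timescales:

1. **Turn-taking (seconds).** Per-second mentions of a speaker are regressed
   on who holds the floor, how long the current turn has lasted, and their
   interaction, in a linear mixed-effects model with a random intercept and
   random slopes grouped by turn; a second model tests whether interruptions
   raise the overall rate. Reported as standardized β with t values and
   Nakagawa–Schielzeth marginal/conditional R² (R²m = fixed effects alone,
   R²c = fixed + random).
2. **Salient remarks / "memes" (minutes).** After a pointed remark, mentions
   of its key term burst and fade. The rate profile is modelled as the
   product of a novelty decay N(t) = e^(−λt) and an adoption sigmoid
   M(t) = 1/(1 + e^(−m(t−s))):

       f(t) = M(t) · (N(t) − b)

   with b the base rate estimated from the final 100 s of the window. The
   parameters (λ, m, s) are fitted by exhaustive grid search maximising the
   Pearson correlation between f(t) and the observed counts (optionally
   polished by Nelder–Mead); because the objective is a correlation, the fit
   is invariant to positive affine rescaling of the observations.
3. **The whole event (hours).** Attention rises after onset and decays toward
   the end: an OLS of the total rate on standardized centred time and
   time² (inverted-U), plus a second-half test of the decay term alone.

A combined per-second regression joins all three timescales (plus pairwise
interactions), decomposes each block's *unique* variance (ΔR² from entering
it last), and transfers the fitted model across events, reporting the
Pearson r between predicted and observed rates.

Because the original message streams are not redistributable, the package
ships a first-class synthetic generator (`entrainkit.synth`) that produces
annotated debates and Poisson message streams whose log rate carries every
modelled effect with known ground truth — including retweets and URL spam to
exercise the filters — so each stage is tested by parameter recovery.

## Worked example

```python
from entrainkit.pipeline import simulate_event
from entrainkit.interaction import build_turn_design, fit_speaker_model
from entrainkit.meme import fit_meme
from entrainkit.timeline import event_locked_window

ev = simulate_event(seed=3)          # 90-min debate + entrained stream
design = build_turn_design(ev.annotation, ev.series, "obama")
res = fit_speaker_model(design)
print(res.coef("speaker"), res.r2_marginal, res.r2_conditional)

win = event_locked_window(ev.series, onset_s=1800, pre_s=0, post_s=900)
fit = fit_meme(win, "bigbird", window_s=900)
print(fit.params, round(fit.r, 3))
```

prints (numbers from this exact run):

```
(0.7273037584733528, 13.910597629783192, 5.462113773803823e-44) 0.18003490110661918 0.2791398434227278
MemeParams(lambda_=0.014264262222689613, m=0.15593639412836674, s=64.79706594946799, b=0.0) 0.542
```

Reading: while the candidate holds the floor his per-second mentions rise by
0.73 standard deviations (t = 13.9); fixed effects explain 18% of the
per-second variance and fixed + random 28%. The salient-remark fit recovers
a decay of ~0.014/s and a sigmoid midpoint ~65 s against generative truth
λ = 0.01/s, s = 60 s (r = 0.54 on raw Poisson counts of a small-amplitude
kernel).

The numbered scripts under `analysis/` run the full narrative on three
simulated debates sharing one generative truth — simulate, bin, fit each
timescale, combine, transfer — and write tidy tables under `results/`.
`entrainkit --help` exposes the same steps as a CLI (`simulate`, `rates`,
`fit-interaction`, `fit-meme`, `fit-longterm`, `fit-multiscale`,
`transfer`).

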