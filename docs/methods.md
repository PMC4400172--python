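# Methods

This note records the models implemented in `entrainkit`, their assumptions,
the defaults that matter, and the places where a design choice was genuinely
open. Every number quoted here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not measure.

## Data model and plumbing

An event is a `DebateAnnotation`: speech turns (speaker, start/end seconds
relative to onset, interruption flag), a declared speaker set (two
principals plus an optional moderator), salient-event onsets with lowercase
match terms, an absolute onset timestamp, and a duration (a televised debate
runs ~5400 s). Messages are absolute-timestamped text records with a retweet
flag.

Filtering assigns a message to every term that occurs as a case-insensitive
substring of its text — hashtags match because `#` does not break a
substring ("#obama2012" matches "obama"). Uniform substring matching is also
applied to hashtags rather than exact-tag equality; nothing in the data
model distinguishes the two, and the choice is deliberately the simpler one.
URL-bearing messages (`http://`, `https://`, `www.`) are dropped as a crude
spam filter, and retweets (metadata flag, else the `RT @` text prefix) are
dropped so bursts are not mere reposts. Binning is half-open: a message at
absolute time τ lands in bin ⌊(τ − onset)/w⌋, messages outside
[0, duration) are dropped and tallied, and the `total` channel counts the
union of per-term matches once per message. Counts are conserved by
construction and the suite property-tests binning against a brute-force
per-bin loop.

When turns overlap (interruptions), the floor at second t belongs to the
turn with the latest start ≤ t that has not ended — the last starter wins,
which is what an interruption means. Moderator seconds stay in the timeline
and are coded as "no candidate speaking" in candidate-centred designs;
seconds outside any turn are excluded from turn designs. Missing values
propagate as NaN (empty proportion bins, absent latencies), never as silent
zeros.

## Timescale 1: turn-taking mixed models

Per-second counts within turns are modelled with linear mixed models
(REML, statsmodels `MixedLM`):

* speaker model — response: z-scored per-second count of the target
  candidate's channel; fixed: `speaker` (floor-holder is the target),
  z-scored `speaking_time`, and their interaction; one model per candidate
  channel.
* interruption model — response: z-scored total count; fixed:
  `interruption`, `speaking_time`, interaction.

Both carry a random intercept plus *uncorrelated* random slopes for the
dichotomous factor and speaking time, grouped by turn — implemented as
variance components, which is the lme4 `(1|turn) + (0+x|turn)` idiom; the
uncorrelated form aids convergence. Standardizing the continuous variables
(and the response) makes the betas standardized and invariant to affine
changes of the raw units (tested). Optimisation uses Powell, which is fast
here and — unlike the gradient-based default — returns valid standard
errors when a variance component sits on its zero boundary; if the full
random structure cannot be fitted, the model falls back to a random
intercept only (Powell, then the default optimizer), the fallback is
flagged in the result, and a still-singular fit raises. p-values are Wald
z on the fixed effects: with ~5000 observations per design the difference
from a Satterthwaite-df t reference is negligible, and the analyses only
consume t-value thresholds.

R²m/R²c follow the Nakagawa–Schielzeth decomposition,
R²m = σ²_f/(σ²_f + σ²_r + σ²_e), with the random-effect contribution
averaged per observation, σ²_r = mean(diag(ZΣZᵀ)) — needed because random
slopes make the contribution observation-dependent. The implementation is
tested against a dense Z Σ Zᵀ oracle to 1e-10.

A note on honesty of the response model: the generator (below) produces
Poisson counts, while these models are Gaussian — the same mismatch the
field's standard analysis accepts. The type-I error of the speaker t at
|t| > 2 under a null generator is therefore checked empirically (required
≤ 15/100 seeds) rather than assumed to be 5%.

## Timescale 2: salient-remark ("meme") kinetics

The kernel is f(t) = M(t)·(N(t) − b) with N(t) = e^(−λt),
M(t) = 1/(1+e^(−m(t−s))); b is the mean of the final 100 s of the fitted
window. As printed, f(t) → −b as t → ∞ while an observed rate settles at
+b; because the objective is a Pearson correlation, which is blind to
offset and positive scale, this makes no difference to the fit — the form
is implemented exactly as stated and the affine invariance is asserted
bitwise on the grid parameters (the achieved r is reproduced to < 1e-12;
the last ulp can differ because a·y+c is not exactly affine in floating
point).

Fitting is an exhaustive grid search maximising the correlation between
f(t) and the observed counts. Default grid ("reasonable ranges"):
λ ∈ [1e-4, 0.1] 1/s, 25 log-spaced (decay half-lives ~7 s to ~2 h);
m ∈ [0.01, 1] 1/s, 25 log-spaced; s ∈ [0, 300] s, 61 linear. Ties break
toward the smallest λ, then the smallest s. The default fit window is
600 s post-onset (these bursts fade over roughly ten minutes); both grid
and window are overridable. By default the grid argmax is polished by
bounded Nelder–Mead on the same objective — the λ grid spacing is ~33% and
the polish frees the estimate from it; `refine=False` gives the pure grid
search. The logistic uses `scipy.special.expit` (overflow-safe), and the
refined optimum is cross-checked against a seeded differential-evolution
search of the identical objective on random instances.

Recovery at the tested conditions (900-s series, noise σ = 5% of peak,
truth λ = 0.01, m = 0.2, s = 60, b = 0.1): λ within ±20% and s within
±5 s with r ≥ 0.95 in ≥ 18/20 seeds (acceptance suite).

## Timescale 3: whole-event trend

OLS of the per-second total count on standardized centred t and t²
(centring before squaring tames the t/t² collinearity; betas are reported
on the standardized scale). The second-half decay test restricts to
t ≥ duration/2 and fits the (full-series-centred) quadratic term *alone*
with an intercept — over that range the term is monotone, so a negative
standardized beta is pure decay. The OLS path is verified against
closed-form normal equations to 1e-8.

## Combined model, unique variance, transfer

The per-second design joins four blocks — quadratic `{t, t²}` (centred);
speaker-duration = any-candidate speaking time *plus* a candidate-speaking
indicator (the per-candidate vs any-candidate coding was open; the
any-candidate form is the one that transfers across events); interruption
indicator; salient = the *fitted* kernel value at t summed over events,
zero before onset — plus all cross-block pairwise products of the main
columns. Covariates are z-scored (statistics retained); zero-variance and
linearly dependent columns are dropped via pivoted QR and logged, so a
duplicated column cannot change the fit. Significance is reported at
p < 0.05 with no multiplicity correction.

Unique variance of a block is R²(full) − R²(full minus every column
involving the block, interactions included) — the "entered last"
semipartial ΔR², tested against an exhaustive leave-one-block-out oracle
to 1e-8 and guaranteed nonnegative up to tolerance.

Transfer applies the source model's coefficients *and its standardization
statistics* to a target event's design built without the salient block
(salient events are identified post hoc and do not generalise), reporting
Pearson r(predicted, observed). Self-prediction satisfies r = √R² exactly,
which the suite asserts to 1e-10.

## Synthetic generator

The generator is the package's ground truth, not a fixture. Timeline:
principals alternate, the moderator interjects with probability 0.25
without breaking the alternation, turn lengths are log-normal with mean
25 s (σ_log = 0.6), and with probability 0.5 a turn starts up to 2 s
before the previous ends and is flagged an interruption — emulating a
real debate's ~200 turns with roughly half interruptions. Stream: per
second and candidate channel, counts are Poisson with log rate = base
(log 2 msg/s) + own-floor boost (×1.5) + within-turn slopes (+0.01/s own
channel, −0.01/s opponent) + interruption boost (×1.5) + quadratic trend
(0.3, −0.5 on normalised time x ∈ [−1, 1]). Meme kernels add
amplitude·M(t′)·N(t′) messages/s (5 msg/s, λ = 0.01, m = 0.2, s = 60 at
t = 1800 s) in their own term channel — a rate, hence no −b term — so the
filter and fit stages both see them. Half of all messages are flagged and
prefixed as retweets (the real streams are roughly half retweets), and
URL spam mentioning a candidate is appended at 0.2 msg/s. Everything is
deterministic given the seed.

What the generator does *not* emulate: user identities and network
cascades, non-stationary vocabulary, diurnal baselines, sentiment, and
any dependence between messages beyond the shared rate. Passing recovery
tests therefore shows the estimators are consistent for the stated
rate model at realistic sizes — not that real streams satisfy that model.
Because counts are Poisson and the fitted models Gaussian, recovery
tolerances are calibrated empirically (seed-majority criteria) rather
than analytically.

## Problem sizes and numerical conventions

Analyses and the acceptance script run at the full study scale: 5400-s
events at 1-s bins; seed batteries of 20 (100 for the type-I check, 50
pairs for the null-transfer check). The meme recovery series is 900 s, its
fit window 600 s. Degenerate inputs fail loudly: constant series
(undefined correlation or z-score), designs with a single factor level,
< 3 bins for a quadratic, rate overflow in the generator (> 1e6 msg/s),
negative variance estimates. Ties in `peak_latency` go to the earliest
maximal bin; the latency is reported at the bin centre.

## Known limitations

* Gaussian mixed models on Poisson counts (by design, matching the field's
  practice); no autocorrelation-robust errors — per-second counts within a
  turn are treated as exchangeable around the turn's random effects.
* At the default generator conditions the second-half decay test has
  limited power: the trend coefficients imply only a ~20% rate decline over
  the second half, and the turn-level rate structure acts as autocorrelated
  noise, so its |t| typically lands around 3–5 and p < .001 is not reached
  on every realisation (the acceptance suite measures ~17/20 seeds).
* Overlapping meme kernels are summed in the combined design but fitted one
  event at a time; no deconvolution.
* Retweet-lag dynamics are representable (retweets are generated and can be
  analysed as a separate channel) but no lag model is provided.
* The transfer test assumes the target annotation uses the same speaker-set
  structure (two principals, optional moderator).
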