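# Methods

This note documents the model, the statistical machinery, the synthetic
data generator, and the numerical and design choices behind `ldlsim`.

## Model and assumptions

The lexicon is modelled as a pair of linear mappings between distributed
representations of form and meaning, plus a third linear mapping from form
to lexicality support.  Forms are binary vectors over boundary-padded
letter trigrams; meanings are word embeddings supplied as input (they are
never trained here).  Linearity is a deliberate modelling constraint: the
networks have no hidden layer, so comprehension and production amount to
multivariate multiple regression, and "perfect knowledge" has a closed form
(the least-squares endstate).  The key assumptions are:

- **Prior knowledge = endstate.**  Each simulated participant starts from
  the minimum-norm least-squares solutions `F = argmin ‖CF − S‖²` and
  `G = argmin ‖SG − C‖²` computed over the full word lexicon.  Trigram
  matrices are routinely rank-deficient, so the minimum-norm convention
  matters; `numpy.linalg.lstsq` provides it deterministically.
- **Trial-to-trial learning = delta rule.**  After each trial, `F`, `G` and
  `D` are updated with the Widrow–Hoff rule from the *pre-update*
  predictions (parallel updates, not chained).  Computing the five
  processing measures strictly before the updates is load-bearing: it is
  what makes a repeated stimulus show a smaller comprehension error on its
  second presentation rather than its first.
- **The teaching signal follows the response, not the truth.**  With no
  accuracy feedback in the task, the update target for `F`/`G` is the
  word's own embedding only for correctly affirmed words; a nonword judged
  a word is pushed toward the centroid of all word embeddings (a generic
  sense of "wordness"), and any stimulus judged a nonword is pushed toward
  an evolving nonword vector.  `D` always learns toward the response code.
- **The nonword category is acquired during the experiment.**  Both `D` and
  the nonword vector `n` start at zero.  `n` obeys `n ← (n + ŝ)/2` at the
  end of every nonword-response trial, where `ŝ` is that trial's pre-update
  prediction; unrolled, the target at a given nonword trial weights the
  most recent nonword prediction 1/2, the one before 1/4, and so on — a
  recency-weighted category representation.  A practice phase is not
  simulated (no trial-level practice data exist to drive it); the
  alternative of initialising `n` at the centroid is exposed in code but
  not default.

Open points resolved as conventions: words shorter than three letters are
padded the same way as longer ones (a single-letter word yields one trigram
`#x#`); the `G` update on nonword-response trials pairs the nonword target
vector with the stimulus cue vector, by symmetry with `F`; the centroid is
computed once over all words supplied to the simulation and held fixed.

## Learning rates

`η = 0.001` for `F` and `G` and `η = 0.01` for `D`, both configurable.
The order-of-magnitude larger rate for `D` reflects that the
word/nonword discrimination is a fresh task-specific skill, while lexical
knowledge in long-term memory should move slowly.  (Published descriptions
of this design disagree internally about whether the lexicality rate was
0.01 or 0.1; we default to 0.01 and expose both.)  For a single cue–target
pair the delta rule is a contraction when `η < 2/‖c‖²`; the package's
convergence tests exercise exactly that bound.

## Per-trial measures

All measures use the pre-update state of the current trial:

- **Semantic density**: mean of the 10 largest cosine similarities between
  `ŝ` and the word embeddings.  Ties at the cut are resolved by taking
  exactly n values after a stable sort (tied values straddling the cut do
  not change the mean).  Undefined (NaN) when `ŝ` is exactly zero, which
  happens only for stimuli none of whose trigrams occur in any word.
- **Form-driven semantic relatedness**: the length of the shortest *closed*
  tour (Euclidean distance) through `ŝ` and the predicted vectors of the
  stimulus's Coltheart neighbours (same length, one substitution), computed
  with the same trial-specific `F`.  Closed rather than open is the
  default because the canonical worked example of this measure returns to
  its starting word; the open-path variant is a config switch.  Instances
  up to 12 points are solved exactly by Held–Karp dynamic programming
  (typical neighbour counts are far below this); larger instances fall
  back to nearest-neighbour construction plus 2-opt, which upper-bounds the
  exact value and logs a warning.
- **C-precision**: Pearson correlation of `c` and `ĉ`; undefined for a
  constant vector and propagated as a missing value.
- **Cue activation diversity**: `‖ĉ‖₁`.
- **Yes-activation**: `c·D`; exists only in dynamic simulations because `D`
  never leaves zero without updates.

## Regression machinery

RTs are transformed to `RTinv = −1000/RT` (order-preserving, roughly
Gaussianises lexical-decision RTs).  Trials with RT ≤ 100 ms or > 2000 ms,
time-outs, and the literal strings 'null'/'nan' are excluded.  Skewed
predictors are natural-log transformed with a 0.002 backoff applied only
when the column contains zeros; zero-spiked predictors (corpus frequency,
neighbourhood size, semantic relatedness) get the indicator expansion
`b + b·log p` so the model matrix never contains undefined values.  Trial
number is centred and scaled per subject with the population-sd convention.

The additive models are penalized cubic B-splines (bases and
second-difference penalties from `statsmodels`), sum-to-zero constrained,
with by-factor smooths (basis columns gated by a 0/1 column) and
tensor-product interactions (row-wise Kronecker bases with marginal
penalties).  Fits are per subject and per response subset (words,
nonwords).  Key numerical choices:

- **AR(1) prewhitening.**  ρ is estimated once per subject and subset as
  the pooled lag-1 autocorrelation of the residuals of a
  classical-predictor fit without autocorrelation, excluding pairs that
  straddle session boundaries.  All model families for that subject/subset
  are then fitted on rows transformed as `row_t − ρ·row_{t−1}` within
  sessions (first row of each session untouched), so their AICs compare the
  same transformed data.
- **Smoothness selection** is by GCV over a per-penalty log-spaced grid
  with coordinate descent, using an EDF inflation factor γ = 1.4.  Every
  smooth additionally carries a ridge penalty on its own block
  (double-penalty shrinkage), so a term whose penalty null space (the
  linear direction) is inert can shrink out of the model entirely.  Both
  choices counter the optimism of comparing models by AIC after
  data-driven smoothness selection, which otherwise favours larger
  families.
- **AIC** is `−2·loglik + 2·(EDF + 1)` with the Gaussian log-likelihood at
  the MLE of the residual variance and EDF the trace of the hat matrix
  (the +1 counts the variance).  The relative likelihood of the better of
  two models is `exp(|ΔAIC|/2)`.
- **p-values** are approximate Wald chi-square statistics per term with
  degrees of freedom equal to the rounded term EDF — adequate for
  cross-subject reliability tallies, not for sharp single-term inference.
- Rows with undefined measures are dropped (complete-case analysis), and
  the static- and dynamic-mode tables of a subject are restricted to their
  common complete cases so compared AICs always use identical rows.
- A degenerate smooth input (< 4 distinct values) falls back to a
  ridge-penalized linear column, so sparse toy lexicons cannot alias the
  parametric design.

Model families: *classical* (trial number, frequency with its indicator,
length, neighbourhood size with its indicator, response), *static* and
*dynamic* (trial number, frequency terms, length, log semantic density,
log cue activation diversity by response, c-precision for words; trial
number, length, the semantic-relatedness indicator pair, main smooths of
log cue activation diversity and log semantic density plus their
by-response tensor interactions for nonwords), with yes-activation added
in the dynamic family only.  The nonword main-effect smooths are included
alongside the tensors deliberately: with a tensor gated by a sparse
response level, an omitted additive surface is under-fitted and the
residual structure leaks into any correlated extra regressor, biasing
family comparisons — including the mains (the classical main-effects-plus-
interaction decomposition) removes that artefact.

## Synthetic data generator

The generator emulates the structure of a large lexical decision
experiment at toy scale; its defaults are the package's study conditions:
200 words over a 12-letter alphabet, lengths 3–6; one length-matched
nonword per word differing in 1–2 letter positions; 20-dimensional
embeddings drawn around 8 Gaussian cluster centres (so semantic density
varies); 20 subjects × 2000 trials in blocks of 500 and 4 sessions; 5%
response errors.  RTs are generated *from the simulation's own measures*:
`rt_inv` is additive in scaled trial number, centred word length, log
semantic density, log cue activation diversity, c-precision (word trials
only), log semantic relatedness (nonword trials only) and — when the
generating simulation is dynamic — yes-activation, plus session-restarted
AR(1) noise (ρ = 0.3, sd = 0.25); `rt = −1000/rt_inv` clipped into
(100, 2000].  The recipe mirrors the fitted per-subset models on purpose:
it makes the generative truth exactly representable by the matching model
family, so the learning flag is a recoverable ground truth.  Coefficient
signs and relative magnitudes follow the empirically observed effect
hierarchy for these measures (yes-activation strongest, c-precision
weakest); the common scale is set so the measure-driven component explains
a realistic ~15–20% of `rt_inv` variance at the toy lexicon's measure
ranges.  A Zipf-like frequency list with ~10% of words absent exercises
the frequency indicator machinery.

What the generator does **not** emulate: English phonotactics or
syllable/morphology-matched pseudowords (substitution matching only),
Zipfian frequency effects *on the RTs*, item-level random effects beyond
the measure-driven signal, response-time distributions' extreme tails, or
participants' strategic adaptation.  Passing the recovery study therefore
shows that the pipeline detects trial-to-trial learning when RTs are
measure-driven at realistic effect sizes — not that real data satisfy the
generative recipe.

## The learning-detection verdict

For each subject, word-model and nonword-model AICs are computed for the
static and dynamic families and summed; the subject counts as a dynamic
win when the summed AIC favours the dynamic family (AICs of fits to
disjoint data add).  Per-subset tallies are reported alongside.  At the
default study conditions, RTs generated with learning yield dynamic wins
for essentially all subjects (mean combined ΔAIC ≈ +35), while RTs
generated without learning centre the combined ΔAIC near zero with wins
near chance.  The per-model nonword null comparison alone sits slightly
above zero on average: yes-activation shares stimulus-level trigram
structure with the static measures, so it can partially restore the
dynamic family's attenuated regressors — a structural property of the
family definitions worth knowing when interpreting per-subset win rates.

## Known limitations

- Production is evaluated only through the predicted form vector `ĉ`;
  generating and ranking candidate word forms is out of scope.
- The additive-model p-values are approximate (no smoothing-parameter
  uncertainty correction); reliabilities at α = 0.001 should be read as
  descriptive.
- The prewhitening is exact for AR(1) noise in the *analysed subset*,
  whereas interleaved designs make subset-level noise only approximately
  AR(1); the same approximation is inherited from the analysis this
  package implements.
- `estimate_rho` pools sessions with the total sum of squares in the
  denominator, which slightly shrinks ρ for many short sessions.
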