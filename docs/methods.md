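# Methods

This note documents the models implemented in `replaynav`, the design
choices made where the design was genuinely open, the synthetic-data
conditions under which the package validates itself, and known limitations.

## Task environment

The state space is a 2 × 4 grid of locations connected as a torus.  Each
location holds one of eight images; LEFT/RIGHT wrap across columns, and UP
and DOWN from any location both reach the other row of the same column, so
the three *effective* moves are left, right and vertical.  Rewards are
integers in 0–10 points per image, with two mappings: `g = 1` for blocks
1–2 and `g = 2` (instructed revaluation) for blocks 3–5.  Before block 5
two instructed pairs of images switch locations.

An experiment is 5 blocks × 54 trials, alternating runs of 6 one-move and
12 two-move trials; second moves may not backtrack the first.  Every six
consecutive trials use six distinct starting locations — the five special
starts plus one drawn at random from the remaining three — except the first
24 two-move trials, where each start repeats twice in a row (a learning
aid).  The first 12 trials of blocks 2–5 give no outcome feedback.

**Map construction.**  A valid map must satisfy, jointly: (a) exactly five
starts whose optimal first-move *sets* differ between one- and two-move
trials, identically under both reward mappings; (b) the revaluation changes
the optimal set for every special start and trial type; (c) the two reward
mappings anti-correlate with `r ∈ [−0.47, −0.27]` (target −0.37); (d) some
choice of two switch pairs changes the optimal first move for exactly 15 of
the 16 (trial type × start) cells.  "Divergent" is defined as optimal-set
*inequality*: we verified by extensive stochastic search that the stricter
reading — fully disjoint optimal sets — is jointly unsatisfiable with
(a)–(d) on this torus, while set inequality admits solutions (the worked
example start is in fact fully disjoint: best single move LEFT for 9
points; best pair RIGHT then DOWN for 15).  Because constraints (a) and (b)
are strongly negatively dependent, rejection sampling essentially never
succeeds; `build_map` instead anneals the two integer reward vectors
against a violation score and then scans the 210 possible switch-pair
choices.  It is deterministic given its seed and runs in about a second.
`CANONICAL_MAP` was frozen from the same search with the worked-example
geometry fixed a priori.  One inconsistency in the task description is
resolved in favour of the stated total: the two-move example is encoded as
6 + 9 = 15 points.

**Chance level.**  A uniform chooser over the three effective moves hits a
unique-optimum start's optimal set with probability exactly 1/3.  At starts
where the optimal set spans two effective moves (systematic ties), chance
is 2/3; behavioural metrics therefore always score set membership rather
than a single designated move.

## Learning agents

All agents choose by softmax with a per-move bias vector γ (sum
normalised to zero; the probability model is invariant to its mean).

* **MF** caches `Q1(s, m)` (expected points of one move) and `Q2(s, m1,
  m2)` (expected total of a non-backtracking pair, 12 pairs per start, its
  own learning rate).  Both decay toward the initial value θ at retention
  τ before every trial, and once with a separate retention τ′ at each
  instructed change.  Two-move first choices use `Q1` plus `Q2`
  marginalised over the anticipated second move (second-move policy
  evaluated with `Q1` averaged over states, since the intermediate state
  is not yet known); second choices use `Q1` at the observed intermediate
  state, or its state-average when feedback is withheld.
* **MB** learns `T(s, m, s′)` from state prediction errors `δ = 1 − T`
  with row renormalisation, reverse-inference updates scaled by ρ, decay
  toward uniform 1/7 (self-transitions impossible, fixed at 0), and
  instructed rearrangement `T ← (1−ω)·T + ω·T_permuted` followed by one τ′
  decay.  Values are `Q(s, m) = Σ T·R` for one move, plus κ times the best
  second-step expectation for two moves.  The inner maximisation over the
  second move is implemented literally without excluding the backtracking
  move; the exhaustive oracle planner does exclude it, and on the
  canonical map both give the worked-example value of 15.
* **Hybrid** adds the MF and MB value terms inside one softmax with a
  single shared γ.  On no-feedback second moves the MF terms average over
  states and the MB term marginalises over `T`.

Order of operations within a trial: decay → choice(s) → update(s); no
learning happens for unobserved outcomes.  Instructed-change decays apply
once, before the first trial of the next block.  Log-likelihoods floor
each choice probability at 1e−12.

Two equivalent likelihood backends exist: a vectorised numpy engine (the
reference) and a compiled per-setting kernel used by the fitting loops;
they agree to ~1e−13 and a test enforces it.

## Hierarchical fitting and model comparison

Group priors: Beta(1, 1) for unit-interval parameters, Normal(0, 1) for θ
and the γs, Gamma(shape 1, scale 1) for inverse temperatures.  Each EM
iteration draws `n` settings from the prior, evaluates every subject's
choice log-likelihood per setting, normalises weights within subject (each
subject contributes equal total weight), and refits the prior
hyperparameters by weighted moment matching.  A stage stops when the
evidence gain falls below a relative tolerance of 1e−4 (evidence is
re-estimated from fresh samples each iteration, so the tolerance trades
stopping reliability against Monte-Carlo noise) or after `max_iter`
iterations; stages of increasing sample count follow (reference sizes
10000 → 31623 → 100000; reduced sizes are used in the shipped studies, see
below).  Per-subject estimates are likelihood-weighted means over the
final batch; fractional parameters can be log-transformed for downstream
analysis.

Evidence is `Σ_subjects ln mean_settings L` (log-sum-exp throughout), and
`iBIC = −2 ln L + k ln n` with `k` the number of fitted parameters (19
hybrid, 12 MF, 11 MB) and `n` the total number of choices.

## Recovery study conditions

The recovery harness simulates datasets from each algorithm, fits all
three to each dataset, selects by iBIC, and correlates best-fit against
generating parameter values per parameter, pooling the dataset × subject
pairs of every generating model containing that parameter (shared
parameters are estimated two or three times, which stabilises the
correlation at reduced dataset counts), averaging over parameters; the
"multi-trial" subset contains the parameters entering the likelihood on
many trials
(learning rates, inverse temperatures, per-trial retention, biases, ρ, κ),
the complement being θ, ω and the single-event τ′ decays.

Generating cohorts are hierarchical: one cohort centre per dataset drawn
from documented distributions (learning rates Beta(6, 6); retention
Beta(12, 3); τ′ Beta(4, 4); ρ/ω/κ Beta(6, 3); θ Normal(4, 0.7) — initial
expectations near the mid reward scale; biases Normal(0, 0.3); MF inverse
temperatures Gamma(8, 0.15) and Gamma(8, 0.075) for the move-pair term;
MB inverse temperature Gamma(8, 0.3)), with subjects jittered tightly
around the centre (concentration 200; 12 for the multi-trial parameters so
that they carry real between-subject variance).  The inverse temperatures
sit at the deterministic end of the plausible range by an explicit power
argument: model identification requires the subdominant component of the
hybrid to contribute more log-likelihood than its `k ln n` penalty, and at
desk-scale `n` (8 subjects × 405 choices) that bound is only reachable for
expert-like agents whose components clearly drive choices.  What passing
recovery shows is therefore that the *method* identifies models and
parameters when the data carry the signal — not that weakly-expressed
cohorts would be identifiable at this scale (they provably are not).

Shipped study sizes: 5 datasets per algorithm, 8 subjects per dataset, EM
stages (400, 1600) with at most 8 iterations per stage.  These keep the
full recovery study around 10–12 minutes on one core.

## Sequenceness

Within each sliding window both series are z-scored and, for each lag d in
10–200 ms (sampling steps at 100 Hz), the lagged products are averaged
with incomplete tail samples dropped (no padding — padding would bias the
lag profile); sequenceness is the forward minus the backward lagged
correlation, averaged over windows and, for the headline value, over lags.
Windows with zero variance are excluded and counted.  Window length
defaults to 400 ms for epoch-level estimates and 600 ms for anchor-aligned
time courses (both conventions appear in this literature; the choice is
exposed in `SeqConfig`).  Post-outcome epochs span −0.3 to +1.5 s.  The
peak-|seq| lag estimator is reliable at the group level (mean lag profile
over events or subjects) and noisy for single short series; rest-period
analyses rank realised image-to-image transitions by frequency with ties
broken by first occurrence.

The synthetic generator plants raised-cosine pulses (100 ms default) on an
AR(1) background (coefficient 0.8 at 100 Hz, matching the strong
autocorrelation of real decoded series) — a pulse on the first image at
each event and on the second image one lag later, reversed for backward
plants; a zero-lag common component provides the null control.  The
generator reproduces the autocorrelation and pulse-like transients of
decoded MEG probabilities but not classifier cross-talk between images,
non-stationary noise, or probability normalisation across channels, so
passing tests certify the statistic's logic, not decoder behaviour.

## Hierarchical GP regression

Per transition type, observed sequenceness time series are modelled as
`y_i(t) = c_i·f(t) + g_i(t) + ε`, with `c_i = β + β_IF·IF_i + β_S·S_i +
β_int·IF_i·S_i` (predictors standardized, surprise coded ±1, β_int
truncated positive for sign identifiability), a group-level squared-
exponential GP `f`, per-series deviation GPs `g_i`, and iid noise.
Priors: Normal(0, 10) on the β's; half-Normal with the data sd on the
scales and noise; log-normal on the length-scales whose natural-scale mean
is the geometric mean of the grid step and grid extent and whose
natural-scale sd is half their difference.

Since `y` is jointly Gaussian given the hyperparameters, the latent GPs
are marginalised analytically and MCMC runs over the hyperparameters only
(an affine-invariant ensemble sampler with differential-evolution moves;
1400 iterations with 400 warm-up by default; split-R̂ and bulk ESS reported
with the reference thresholds ESS > 1000 and R̂ < 1.1 recorded as
pass/fail).  One exact non-identifiability is resolved by whitening: the
likelihood constrains only the product of the group scale α_group and the
regression weights, so α_group is pinned to the data standard deviation
and the weights are expressed in data units; the latent group curve is
recovered per posterior draw by GP conditioning.  Time grids are decimated
(default every 4th sample) before fitting — the kernel models the
smoothness that denser grids would only re-measure, and the cost of the
marginal likelihood grows with the cube of the grid size.

A timepoint is flagged significant when the 95% credible interval of the
group-level curve excludes zero *and* the standardized effect — posterior
mean divided by the across-subject sd of the series at that timepoint —
exceeds 0.1 (the effect-size definition is pluggable; this is the simplest
reading of the reference rule).

## Known limitations

* The recovery study's identifiability holds for the documented
  expert-like cohorts; at weaker effect sizes the hybrid is statistically
  indistinguishable from its dominant component at desk-scale `n`, which
  is a property of iBIC at small `n`, not of the implementation.
* The GP regression reports coupling weights in data units under the
  pinned group scale; only products of scale and weight are comparable
  across parametrisations.
* Synthetic decodability omits decoder cross-talk and non-stationarities;
  lag estimation for single short series is noisy (±1–2 samples at the
  SNRs used here; exact at the group level).
* The optional alternative learners (temporal-difference backpropagation,
  Dirichlet-Bayesian transition learning, restricted hybrid, dual-MF
  mixture) are out of scope and not implemented.
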