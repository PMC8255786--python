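# Methods

## Choice model and generative design

The unit of analysis is a binary choice between offers of two liquid
stimuli. Each stimulus carries fat, sugar and protein concentrations
(g/100 mL); energy density is derived with Atwater factors
(9/4/4 kcal per g of fat/carbohydrate/protein), so the default
factorial levels — fat (0.1, 3.6), sugar (5.0, 12.875) g/100 mL,
protein 3.4 g/100 mL — make the high-fat/low-sugar and
low-fat/high-sugar stimuli exactly isocaloric (9·Δfat = 4·Δsugar) and
put protein at ~20% of energy in the mid-energy stimuli. These values
are milk-realistic: skimmed vs. whole-milk fat, lactose-level vs.
sweetened sugar.

The generative agent values a stimulus at ρ with
log ρ = w_fat·fat + w_sugar·sugar (+ optional fat×sugar interaction,
or texture terms w_visc·viscosity + w_csf·csf for texture-driven
agents; exactly one mode is active). Subjective offer value is
magnitude × ρ and choices are logistic in the log-value difference
with inverse temperature τ and a side-bias constant:

    P(left) = σ( τ·[log m_L + log ρ_L − log m_R − log ρ_R] + b ).

Putting the choice model on the log-magnitude *ratio* scale makes the
indifference point — the magnitude ratio at which both options are
chosen equally — the pure value ratio ρ_target/ρ_reference in closed
form, and makes the trial-level logistic regression on
(Δlog m, Δfat, Δsugar) the exact inverse of the generator: its
coefficients estimate (τ, τ·w_fat, τ·w_sugar). Both facts are used as
oracles throughout the test suite.

Offered magnitudes are drawn uniformly from a grid (default
0.1–1.0 mL in steps of 0.1; the task's magnitude cues are
parameterized rather than fixed because no canonical range exists) and
the left/right placement of the two stimuli is counterbalanced exactly
(half the trials each way, order shuffled). Optional choice-history
feedback adds h_fat (h_sugar) times an exponentially decaying count
(window k = 5, decay 0.5) of recent high-fat (high-sugar) choices to
the logit, signed by which side currently carries more of the
nutrient; positive h_fat produces the positive own-nutrient feedback
seen in session data. The generator deliberately omits within-session
satiation dynamics.

What the generator does *not* emulate: visual-cue learning at session
start, motivational drift, flavor-specific value modulation, or
reaction times. Tests passing on this synthetic task therefore
demonstrate the estimators' correctness and calibration under the
stated choice model, not robustness to every feature of real
behavioral data.

## Texture model

Viscosity (mPa·s) and the water-normalised coefficient of sliding
friction (CSF) are affine in fat concentration: viscosity
1.0 + 0.35·fat, CSF 1.0 − 0.055·fat (water baseline 1.0, whole-milk
range values), with independent Gaussian measurement noise per
stimulus. Sugar does not enter the texture model, so sugar–texture
regressions are null by construction. For mediation studies the
stimulus battery spans many fat levels (default 13 stimuli over
0–10 g/100 mL, sugar alternating between levels so fat and sugar are
uncorrelated across the battery) with texture noise of 10–15% of the
texture range. The noise is essential, not a nuisance: within a
single stimulus pair Δfat and Δcsf are exactly proportional, so the
fat and friction choice paths are identifiable only through many pairs
whose texture deviates idiosyncratically from the affine line. With
only two fat levels and noise-free texture the design is singular and
`mediation_fit` refuses rather than silently dropping a column.

## Estimation procedures

**Psychometric fits.** The sigmoid is fitted by maximum likelihood on
trials (binning is used only for display and goodness summaries); the
indifference point is exp(−b₀/b₁). Confidence intervals are
case-resampling percentile bootstraps over trials (default 1000
iterations), computed with a vectorised batched Newton solver
warm-started at the full-data estimate. Goodness is an adjusted R² of
the fitted curve against ~10 equal-count binned choice frequencies.

**Nutrient choice model.** Logistic regression of choice side on
Δlog magnitude, Δfat, Δsugar (left − right), optional interaction and
history regressors, plus a constant. Session effects are 'none',
'fixed' (dummies) or 'random': Gaussian session intercepts integrated
out with a per-session one-dimensional Laplace approximation,
(β, log σ) optimized jointly by Nelder–Mead and standard errors from a
finite-difference Hessian. Reported fit statistics are the
log-likelihood, AIC = 2k − 2LL, and McFadden pseudo-R²
(1 − LL/LL_null, null = intercept-only fitted on the same data).
Separation (non-converged or exploding MLE) is flagged and refitted
with a light ridge penalty. Nutrient regressors can be coded as raw
concentrations or as 0/1 levels; concentrations are the default.

**Bias tests.** The side/option bias is an exact binomial test against
0.5. The run-length test is a likelihood ratio of a first-order Markov
(stay/switch, transition rates conditioned on the previous choice)
model against an iid Bernoulli model, both conditioned on the first
choice, χ² with 1 df.

**Trade-off quantification** compares realized totals against a
per-trial magnitude-maximizing oracle (ties go to the agent's choice):
percentage of offered magnitude forgone and percentage of each
nutrient gained relative to the oracle's totals. Both are invariant to
uniform magnitude rescaling.

**Out-of-sample value validation.** Offer magnitudes are multiplied by
their stimulus's relative value (from psychometric fits) to express
both offers in reference units; a 2-parameter sigmoid of choice on the
value difference is fitted on training folds (default 10) and scored
on each held-out fold as a binned-frequency R² against the
train-fitted intercept-only baseline. Scoring per fold against the
transferred null baseline keeps the statistic unbiased near zero for
signal-free data — pooling bins across folds leaks training signal
upward, and benchmarking against the fold's own mean biases it
downward by ~1/(n_bins − 1).

**Cross-prediction and PDI.** Held-out McFadden pseudo-R² uses a null
fitted on the target data (a transferred null is available by flag);
session effects of the transferring model are evaluated as zero for
unseen sessions. The preference dissimilarity index between agents i
and j is ½[(LL(i|i) − LL(i|j))/n_i + (LL(j|j) − LL(j|i))/n_j] in nats
per trial — normalized per trial so datasets of different sizes are
comparable, symmetric by construction, exactly zero for identical
models, and non-negative in expectation because each agent's own model
is its ML fit. Nutrient contributions to a PDI are percentage
increases over a base (magnitude + side only) model; a zero base PDI
is reported as undefined rather than infinite. Because PDI is not a
metric, three pairwise PDIs may violate the triangle inequality; the
triangle layout flags this instead of failing.

**Mediation.** Total-effect logistic (choice ~ Δmag, Δfat, Δsugar)
gives c; adding Δviscosity and Δcsf gives c′ and b; stimulus-level OLS
of texture on fat gives a. All choice-level regressors are z-scored so
coefficients are comparable across the two models, and the indirect
effect is summarized as c − c′. Confidence intervals come from a
session-level (cluster) percentile bootstrap — trials within a session
share one stimulus pair — with 1000 iterations by default.
A mediation verdict ('complete'/'partial'/'none') additionally
requires the indirect effect's sign to match the total effect's:
logistic coefficients grow in magnitude when strong predictors are
added (non-collapsibility), which can push c − c′ significantly
negative for purely direct effects, and such sign-inconsistent
"indirect effects" are not mediation.

**Strategy comparison.** The energy model collapses offers to a single
log offered-energy regressor; the nutrient model keeps magnitude, fat
and sugar separate; ΔAIC = AIC_energy − AIC_nutrient. For the
isocaloric coefficient test, note that within a session offering one
isocaloric high-fat/high-sugar pair the dichotomous fat and sugar
level regressors are exactly opposed (Δfat = −Δsugar on every trial),
so only their contrast is identifiable; each session is fitted with
(Δlog m, z-scored sugar-minus-fat contrast) and the per-session
contrasts are tested with a Wilcoxon signed-rank (exact distribution
for n ≤ 25, normal approximation with continuity correction above).
Energy maximization predicts a zero median contrast.

**Nutrition geometry.** Mixture coordinates are percentages of total
energy from fat, sugar and protein. Analysis works in the
(pct_fat, pct_sugar) plane with protein implicit, since protein share
is constant by design; the full three-component composition is kept in
all outputs. A session balance computed from summed intakes equals the
energy-weighted convex combination of the offered compositions
(algebraic identity, tested to 1e-12), so balances always lie on the
offer segment. Reference compositions (e.g. an optimal-diet point and
a milk point) are configuration inputs, not constants. The 95%
confidence ellipse uses the χ²₂(0.95) quantile of the mean's
covariance; this is an asymptotic construction whose coverage is
slightly below nominal for small session counts (~92% at 20 sessions,
~94.5% at 100). Signed deviations from a projected reference are
expressed in percentage-energy units of the dominant varying nutrient
along the offer segment, positive toward the high-nutrient stimulus.

**Reinforcement learning.** Delta-rule updating of the chosen option
only, softmax choice with inverse temperature β, unrewarded outcomes
worth 0. The nutrient-sensitive extension values a delivered
high-nutrient reward at r_low/(1 − η) — the unique simple form that
maps η = 0.2 and baseline 1.0 to 1.25 and reduces exactly to the
standard model at η = 0. The reversal task uses complementary reward
probabilities (p_low = 1 − p_high unless overridden) and reverses at
the midpoint by default. Nutrient intake N counts rewarded
high-nutrient deliveries; total reward R counts rewarded trials;
switch latency is the first post-reversal trial at which the mean
choice curve crosses 0.5. The simulator is vectorised over
repetitions with a fixed draw order (choices, then rewards, per
trial), so an η = 0 run is trial-for-trial identical to a plain
Rescorla–Wagner implementation under a shared seed.

**Econ-space transforms.** Utility (linear or Cobb–Douglas) is defined
on nutrient space only; reward bundles map through 2×2
nutrient-composition matrices (protein excluded as constant).
Preference rankings are therefore invariant under any invertible
reward-space re-parameterization — the module's central property,
verified by randomized sweeps. Nutrient profiles unreachable with
non-negative amounts in a target reward space are flagged, not
silently clipped.

## Problem sizes and reproducibility

All randomness flows from explicit seeds (`numpy.random.default_rng`;
datasets derive per-session child seeds via `SeedSequence.spawn`), so
every fit, bootstrap and simulation is exactly reproducible. Test and
validation studies use 100-replication designs with sessions of
60–500 trials and bootstraps of 400–1000 iterations; the reversal
simulations use 100 trials × 1000 repetitions. These sizes were chosen
to give the recovery and calibration checks adequate power while
keeping the full suite quick to run on a laptop.

## Known limitations

- The logistic-regression "random effects" mode fits random intercepts
  only (no random nutrient slopes).
- Mediation relies on standardized coefficient differences; logistic
  non-collapsibility means c − c′ is a pragmatic, not exact, indirect
  effect scale.
- PDI compares fitted models, so finite-data estimation noise inflates
  it slightly above zero even for identical agents.
- The mixture-triangle ellipse is asymptotic (see above).
- Direct multi-alternative (more than two options) choice models are
  out of scope; all analyses are pairwise.
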