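# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `seqsampler`, in the order the pipeline runs.

## Task statistics

Outcomes are shades on a discrete grid `±{0.25, 0.5, 0.75, 1.0}` (8 shades;
grid size configurable). Zero is excluded so every outcome has a dominant
side. The construction enforces three constraints simultaneously:

* **Linearity** — `log(p(c|orange)/p(c|blue)) = k·c` for every shade. This
  holds exactly because the orange pmf takes the exponential-tilt form
  `pmf_orange(c) ∝ base(|c|)·exp(k·c/2)` with symmetric magnitude weights,
  and the blue pmf is its mirror image.
* **Information bound** — `k` is fixed so the most saturated shade carries
  1.4 logLR units (`k = max_loglr / max|c|`).
* **Dominance** — the dominant side carries probability 2/3 ("66%" and
  "67%" are both read as exactly 2/3). The magnitude weights are a
  one-parameter exponential family `base(m) ∝ exp(−λm)`; λ is solved by
  bisection to 1e−12. The achievable dominant mass is limited to
  `(σ(k/n), σ(k))` by the grid; outside that range construction raises a
  constraint-infeasible error.

Sign convention: positive shades and positive logLR mean orange. One
printed form of the shade–evidence relation puts blue in the numerator
while positive shades are orange-dominant; we resolve the inconsistency by
defining `logLR = log(p(c|orange)/p(c|blue))` throughout, so `sign(x̂)`
points at the more likely category directly.

**Yoking.** Per trial one magnitude is drawn from the (category-independent)
magnitude marginal and shared by both options; each option's side is then
drawn independently with dominant-side probability `σ(k·m)` given its own
category. This preserves both the 2/3 marginal and the property that the
two options offer exactly the same amount of information on every trial.
Whether the original stimuli also yoked the signs is unknown; only the
magnitudes are yoked here.

**Designs.** `discovery` (2 conditions × 48, 8 blocks of 12), `replication`
(2 × 64, 8 blocks of 16), `third` (3 × 32, 4 blocks of 24). Each unique
stimulus sequence is duplicated once per condition so conditions are
stimulus-matched. Sequence lengths come from a balanced, shuffled multiset
of {8, 12, 16, 20}; target colours are counterbalanced; option categories
are independent per option (so same-colour pairs occur). Pseudo-
randomisation is rejection sampling (retry cap 10,000): equal per-condition
counts per block, no more than 3 consecutive same-condition sequences, no
immediate repetition of the same shape pair (28 unordered pairs of 8
shapes) or of the previous sequence's first-trial side layout. Final
questions: datasets 1–2 query a randomly chosen option's colour; dataset 3
queries a counterbalanced colour.

## Choice models

Parameters: `β_tar`, `β_unc`, `b_rep` (unbounded sensitivities/bias), phase
threshold `θ ≥ 0` (logLR units) and repeat probability `ε ∈ [0, 1]`. The
probability of choosing option 1 is `logistic(DV)`; writing the softmax on
the *repeat* probability would make the repetition term push away from the
previous choice for option-2 repeats, so the option-1 orientation is used
consistently. On the first trial there is no repetition term and no phase
gating; in GUESS `c_tar = 0`, so the first choice is 0.5/0.5 unless biased.
FIND uses the same decision variable as MATCH (the target is known during
sampling); no optimal FIND agent is defined.

Phase bookkeeping: both options start with `initialPhase = true`; the gate
applies from trial 2 on, to the previously chosen option, while its phase
is alive and `|x̂| < θ`; a phase dies permanently on the first switch away
from its option and never revives. `θ = 0` disables the phase outright.

Final-question responder (plumbing the study leaves implicit): a queried
option is answered with `sign(x̂)`; a queried colour with the option
maximising `x̂·c_query`; exact ties are answered at random.

## Likelihood and fitting

The threshold is smoothed, `θ' ~ N(θ, 0.1 logLR)`, and marginalised **per
sequence** (so the phase dynamics stay deterministic given the draw; a
per-trial marginalisation would smooth equally but mix phase histories).
Numerically the support is truncated to `[max(0, θ−3σ), θ+3σ]` (0.27% tail
mass) and renormalised. Because the observed choices make the integrand
piecewise constant in θ' — it changes only where θ' crosses an accumulated
`|x̂|` value — the quadrature splits the support at those breakpoints and
applies Gauss–Legendre within each piece (21 nodes by default, 101 in
verification runs), which reproduces exact piecewise integration to ~1e−7.

Degenerate inputs worth knowing about:

* A **zero-evidence revisit** (a previously chosen option whose shades have
  cancelled exactly, `|x̂| = 0`) is gated by *any* positive threshold draw,
  so the ini+ likelihood does not converge to ini− as θ → 0 on sequences
  containing such states; on all other sequences the truncated support
  makes the two coincide exactly once θ < min|x̂| − 3σ.
* Probabilities are floored at 1e−12 (relevant when ε ∈ {0, 1} meets a
  contradicting choice), keeping the log-likelihood finite.

Fitting is per participant × condition, two passes: (1) bounded L-BFGS-B
from a grid of 100 threshold initialisations in [0.05, 5] crossed with
random starts (`β` in [−2, 2], `b_rep` in [−4, 4], `ε` uniform), (2)
Nelder–Mead refinement from the pass-1 optimum. Bounds: β, b_rep ∈ [−10,
10], θ ∈ [0, 5], ε ∈ [0, 1]. Because the θ = 0 boundary face (phase
disabled) is reached discontinuously by the smoothed objective, the ini+
fit additionally optimises that face separately — an internal phase-free
fit — and keeps the better optimum; without this the fitted ini+ model can
sit strictly above the nested ini− optimum on phase-free data. θ is
reported both in logLR units and as the category probability
`logistic(θ)`. Reduced settings (`n_theta_grid`, `n_beta_starts`,
`maxiter_*`) trade thoroughness for speed and are used throughout the test
suites.

Leave-one-sequence-out cross-validation refits each fold; folds are
warm-started from the full-data optimum (plus optional fresh random
starts), or, with `cv_refine_only`, refined derivative-free from the warm
start only — the setting used in the large recovery suites. The summed
held-out log-likelihood is the model evidence consumed by model selection.

## Model selection

Random-effects BMS with the variational Dirichlet parameterisation:
responsibilities `u_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα))`, `α = α0 + Σu`, α0 = 1
per model (uniform prior), convergence at Δα < 1e−6. Exceedance
probability by Monte Carlo over the Dirichlet posterior (10⁵ samples;
closed Beta form available for K = 2), the Bayes omnibus risk from the free
energies of the null (all frequencies equal, exact evidence
`Σ_n log(mean_k exp L_nk)`) versus the random-effects alternative
(variational bound), and `PXP = (1−BOR)·XP + BOR/K`. Cross-condition
prevalence is compared by sampling the two posteriors independently.

## Behavioural indices

* Performance: last-choice target fraction on single-target sequences only
  (undefined, not zero, when none exist), plus final-question accuracy.
* Fraction repeat: a trial t ≥ 2 repeats iff it re-chooses the option of
  t−1; *familiarity* counts that option's samples up to and including t−1
  (the curve reports familiarity 1–10; the overall fraction covers all
  trials).
* Choice similarity: agreement of every within-sequence position pair
  (i < j), averaged over sequences within participant (positions beyond a
  sequence's length excluded), then across participants.
* Choice direction: from trial 2, the *target* option is the one with the
  highest `x̂·c_tar`, the *uncertain* option the one with the smallest
  `|x̂|`, both from the participant's own history; hits score 1, exact ties
  0.5 (excluding ties would bias early trials where ties dominate).
* Stereotypy/exclusion: strict full-sequence side alternation, option
  alternation, or single-option sampling; a participant is excluded iff
  more than half the sequences of any condition are stereotyped.

## Cluster permutation tests

Trialwise (or familiarity-wise) curves are tested pointwise at two-sided
p < 0.05; contiguous significant points form clusters scored by their sum
of t-values. Null distributions take the maximum |sum-t| per simulated
dataset: random-choice cohorts run through the same metric pipeline (tests
against chance) or within-participant shuffles of sequence condition
labels with full recomputation (between conditions). Empirical p-values
use the add-one correction (b+1)/(N+1), so they are conservative and never
zero; the exact-uniformity statement that the calibration suite checks is
the standard tie-randomised Monte-Carlo p-value (the max statistic has an
atom at zero when no cluster forms). Effect sizes: `r = z/√n`, Cohen's
d_z, and generalized eta squared `SS_effect/(SS_effect + Σ SS_residuals)`;
all other standard tests are delegated to scipy.

## Validation suites and the regimes they run at

The simulating population for the recovery suites uses the group-regime
parameter set `β_tar = 2.0, β_unc = 1.5, b_rep = 1.0, θ = 1.5, ε = 0.95`
(θ = 1.5 logLR ≈ a 0.82 category probability, within the reported
inter-quartile range of fitted thresholds; ε near the hard-threshold end,
where early repetition is most visible). Parameter recovery draws 20
agents from `β_unc ~ N(1.5, 0.6)`, `b_rep ~ N(1.0, 0.6)`, `θ ~ U(0.5,
2.5)`, `ε ~ U(0.75, 0.98)`, decorrelates the columns to pairwise |Spearman
ρ| < 0.07 by independent column permutation (marginals preserved exactly),
simulates 200 GUESS sequences per agent, refits with reduced starts, and
scores each parameter by the Spearman correlation between simulated and
recovered values weighted by each agent's goodness of recovery fit
(exp of the mean per-trial log-likelihood, normalised — the weighting
scheme is our own operationalisation). Model recovery simulates 20 ini+
and 20 ini− agents at the group regime on 48 GUESS sequences each (the
discovery dataset's per-condition count), fits both variants with
warm-started CV folds, and reports the BMS confusion matrix per simulated
cohort and its column-renormalised inversion. Knock-out simulations
silence θ, b_rep, both or neither and return the full behavioural summary
per lesion; the identity lesion reproduces plain simulation bit-exactly at
the same seed.

Problem sizes in the test suite (cohort sizes, sequences per agent,
permutation counts, oracle grid resolutions) are chosen so the whole suite
runs in minutes on one CPU while leaving the acceptance thresholds their
stated margins; the methods above do not change with size.

## What the synthetic data does and does not show

The generator reproduces the task's designed statistics (evidence
linearity, 2/3 dominance, yoked information, matched conditions,
pseudo-randomised blocks) and agents that implement the fitted model
classes exactly. It does not emulate human lapses, learning noise, motor
errors, reaction times, or any drift of strategies over the session. Green
recovery suites therefore certify that the fitting and selection machinery
is sound *for data generated by the model class* — they cannot certify
that the model class captures human behaviour; that inference requires the
behavioural datasets themselves.

## Known limitations

* ini+ and ini− are genuinely indistinguishable on ini−-generated data in
  the limit of perfect optimisation (the models are nested and the CV
  evidence difference shrinks to optimiser noise); the model-recovery
  margin for the ini− row rests on the overfitting cost that the ini+
  variant pays in held-out likelihood, and is the smaller of the two
  diagonal entries.
* `β_tar` is structurally unidentifiable in GUESS (its regressor is zero);
  fitted values there are arbitrary within bounds and are not scored by
  the recovery suites.
* The per-sequence θ marginalisation is a declared choice; a per-trial
  variant would also smooth the likelihood but was not implemented.
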