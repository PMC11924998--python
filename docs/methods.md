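# Methods

This note documents the models, algorithms, numerical choices, and
synthetic-data assumptions behind `fourstep`. Everything quantitative
stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external data.

## 1. Four-in-a-Row planning model

### Game and features

The game is played on a 4x9 grid; black moves first, and the first
player to occupy four contiguous squares (horizontally, vertically, or
diagonally) wins. There are exactly 45 such lines (24 horizontal, 9
vertical, 12 diagonal), and the engine stores each color's occupancy as
a 36-bit mask so that line scans and incremental updates are cheap.

The heuristic value of a state `s` is

    V(s) = w_center (center_b - center_w)
         + c_black * sum_i w_i f_i(s, black)
         - c_white * sum_i w_i f_i(s, white) + eps,

where the pattern features `f_i` count (line, color) instances of
connected two-in-a-row, unconnected two-in-a-row, three-in-a-row, and
four-in-a-row on lines free of opponent pieces; `c` applies the
active-player scaling `C` to the side to move in `s`; and `eps` is
zero-mean, unit-variance Gaussian noise drawn once per evaluated node.
Values are always from black's perspective.

*Feature multiplicity.* An "instance" is a (line, color) match within
the 45-line set, so a pair of pieces lying on several lines contributes
several instances. This is the natural reading of counting features
"across the board" when the substrate is the line set.

*Center proximity.* The per-piece center score is `1 / (1 + d)`, with
`d` the Euclidean distance from the square to the board centroid
(row 1.5, column 4.0). The functional form is a documented default (any
monotone-decreasing function of distance would express the same idea);
it is deliberately bounded in (0, 1] so that center terms never swamp
pattern terms. The center feature is a property of squares, not a
discoverable pattern, so it is never dropped and is not scaled by `C`.

### Feature dropping

Before each move decision, every feature instance present on the root
board is overlooked ("dropped") independently with probability `delta`;
dropped (line, color) instances contribute nothing at any node of that
move's search, including where the same line has grown a stronger
pattern in a descendant. This per-move-persistent reading models a
stable attentional blind spot during one decision. The alternative
reading — independent drops at every evaluated state — is available as
`PlannerParams(drop_per_state=True)`; under it, `delta = 1` with a zero
center weight reduces choice to an argmax of i.i.d. noise, which the
test suite verifies.

### Best-first search

Each iteration (i) follows the current principal variation — the
greedy highest-value path with black maximizing and white minimizing —
to a leaf, restricted to unclosed children; (ii) expands the leaf by
evaluating all legal children, pruning those more than `theta` below
the best sibling from the mover's perspective (pruned children are
never revisited); (iii) backs minimax values up to the root; and
(iv) stops with probability `gamma`, when the root is *closed*, or at a
safety cap (10,000 iterations by default; hitting it logs a warning).
Terminal leaves close their line; an internal node closes when all its
children are closed or when its best child is a closed, proven win for
the node's mover (the line is decided, so the search need not continue
there). Node noise is drawn once at first evaluation and cached. All
ties (PV descent, backup, final choice) break uniformly at random from
the caller's generator, which makes every simulation reproducible from
a seed.

With probability `lapse` the entire search is bypassed and a uniform
random legal move is played.

Two implementations exist: an object-tree reference
(`fourstep.planner`) used by the metrics and available for inspection,
and a flat-array numba kernel (`fourstep._search_kernels`) used where
millions of simulated moves are needed (IBS fitting). They implement
the same generative policy and are held together by deterministic and
distributional (chi-square) equivalence tests.

### Default agent parameters

Table-style defaults for the generative agent: `w_center = 0.6`,
`w_2conn = 0.9`, `w_2unc = 0.45`, `w_3 = 3.5`, `w_4 = 10` (essentially
maximal — a completed line ends the game), `C = 1.4`, `theta = 1.5`,
`gamma = 0.25`, `delta = 0.15`, `lapse = 0.05`. These are mid-strength
human-like values on the scale fixed by the unit evaluation noise; the
weight magnitudes matter only relative to that noise and to each other.

## 2. Likelihoods and fitting (inverse binomial sampling)

The planner's move probabilities have no closed form. For an observed
(board, move) pair, IBS simulates moves from the model until the first
match at trial `K`; `-sum_{j=1}^{K-1} 1/j` is an unbiased estimate of
`log P(move)`. Estimates are averaged over `repeats` independent runs
and summed over observations.

Numerical choices that matter:

* **Cap.** Uncapped IBS has unbounded runtime for mis-specified
  parameters, so `K` is capped (default 500) with the corresponding
  harmonic penalty and a `capped` flag. The cap must be generous: a
  tight cap truncates the penalty on observations the candidate model
  cannot explain, which systematically biases fits of `delta` toward
  zero (the misses that identify feature dropping are exactly the
  moves a no-drop model cannot produce). Fitting configurations here
  use caps of 250-500.
* **Optimization.** The objective is noisy, so the estimator uses a
  three-stage bounded derivative-free search: a seeded space-filling
  grid evaluated under one common-random-numbers (CRN) stream; Nelder-
  Mead polish from the best grid points, each start under its own CRN
  stream (a shared stream would let one unlucky realization corrupt
  every candidate); and final selection among polished candidates with
  fresh draws at a tripled repeat count, which suppresses winner's-
  curse selection. At least 3 polish starts and at least 2 repeats per
  evaluation are always used.
* **Cross-validation.** Five-fold CV reports held-out log likelihood
  per fold for model assessment; the reported parameters come from a
  final refit on all observations.
* **Fixed weights.** By default the four-in-a-row weight is pinned to
  its upper bound during fitting and the remaining weights to the
  generative defaults; the free set is configurable (tests and the
  pipeline free `delta` and `gamma`, the parameters the summary
  metrics depend on most directly).

## 3. Summary metrics and the exact oracle

* **Planning depth** — the mean principal-variation length of the
  generative search over a probe set, 10 repetitions per position by
  default, with the lapse bypassed (depth characterizes the search
  process, not occasional random moves; a flag restores lapses).
* **Heuristic quality** — the Pearson correlation between the
  deterministic part of the value function (no noise, no drops) and
  the exact game-theoretic value coded +1/0/-1 from black's
  perspective, over probe positions near the end of the game where
  exhaustive solving is feasible.
* **Feature drop rate** — the fitted `delta` itself.

The oracle is a memoized exhaustive minimax with an immediate-win
shortcut, exact by construction, and restricted to positions with at
most 12 empty squares (about 1.5 x 10^5 reachable colorings, solved in
seconds). A plain recursive enumeration with no memo and no shortcut
serves as an independent cross-check on 3-empty endgames, and the
noise-free, prune-free, stop-free planner is verified to preserve the
oracle's game value on 50 random 7-8-empty positions.

Probe positions come from two seeded generators: self-play between
mid-strength default agents, sampled uniformly over plies (used for
depth), and random fills at fixed piece counts (used for the quality
metric, where oracle feasibility pins the occupancy; these are
labelled synthetic). The original study computed metrics on a fixed
corpus of human tournament positions; absolute depth/quality values
therefore depend on the probe distribution and are not comparable
across corpora, which is why the tests assert behavior (exactness at
`gamma = 1`, monotonicity in `gamma`, recovery of planted `delta`
orderings) rather than point values.

## 4. Tournament, staircase, and Elo

Opponents form five strength categories built by one documented
recipe: stopping probability sweeps down (0.9 to 0.1), drop and lapse
rates sweep down, pruning tightens slightly, with a small seeded
lognormal jitter across the 40 agents within a category. Sessions
alternate the subject's color, draw each opponent uniformly from the
current staircase category (starting at category 2), and update the
staircase after every game: loss -> one category down; draw or a first
win -> stay; two consecutive wins -> one category up, bounded at 1 and
5. "Two wins" is read as consecutive wins since the counter last
reset; draws and losses reset it.

Ratings use a Davidson model (Bradley-Terry with a draw parameter):
`P(win) = p_i / (p_i + p_j + nu sqrt(p_i p_j))`, fitted by maximum
likelihood over players and the five category entities jointly, with a
weak ridge (0.02) on log-strengths so perfect records stay finite.
Ratings are reported on the conventional 400/ln 10 scale with the mean
category rating anchored at zero; predicted win probabilities are
invariant to that shift.

## 5. Two-Step task and hybrid learner

The simulator implements the block-stationary variant: 9 blocks x 32
trials = 288 trials; each Step-1 action leads to its common Step-2
state with probability 0.75; exactly one of the four shapes pays with
probability 0.8 while the others pay with probability 1/12 (= 8.3%);
the high shape changes to a different shape (uniform over the other
three) at every block boundary. Action 0 commonly maps to state A,
action 1 to state B; counterbalancing of that mapping is out of scope.

The learner is SARSA(lambda) with a model-based component. Within a
trial, with all deltas computed before the updates they drive:
`delta_1 = Q(s2, a2) - Q(s1, a1)` updates the Step-1 value (Step-1
reward is always zero, and the bootstrap uses the *chosen* Step-2
action); `delta_2 = r - Q(s2, a2)` updates the Step-2 value; finally
the Step-1 value receives `alpha * lambda * delta_2`. Model-based
Step-1 values are recomputed every trial from the Step-2 maxima
through the one-step Bellman backup over the true transition
probabilities. Step-1 choice is a softmax over
`beta_mf Q_mf + beta_mb Q_mb + p * rep`, where `rep` marks the
previous trial's Step-1 choice (absent on the first trial); Step-2
choice is a softmax over `beta_step2 Q_mf`. Q-values start at zero.
The likelihood runs learning from trial 1 but sums log probabilities
only from trial 10 onward. With rewards in {0,1} and zero
initialization all Q-values stay in [0,1], which the suite asserts
over long simulations.

### Hierarchical Bayesian estimation

Subject parameters are modeled non-centrally: raw effects
`z ~ Normal(0,1)` are scaled by a group SD and shifted by a group
mean on the probit scale, then mapped through the normal CDF to (0,1)
for `alpha`/`lambda` and to (0,10) for the three betas; the
repetition bias `p` stays Gaussian. Group means have standard-normal
priors; group SDs are lognormal(-1, 0.5) — weakly informative around
0.37 on the probit scale.

No gradient-based probabilistic-programming backend is part of this
package; sampling uses a purpose-built Metropolis-within-Gibbs scheme
(numba-compiled) with centered/non-centered interweaving:

1. componentwise random-walk Metropolis on each `z[i,k]` given the
   group level (one likelihood evaluation per proposal);
2. a centered block that holds every subject's raw parameter value
   fixed and redraws `(mu_k, sigma_k)` from their exact conditional
   given those raws — conjugate normal for `mu_k`, a few 1-D
   Metropolis steps on `log sigma_k` — then back-solves `z`. This
   costs no likelihood evaluations and is the standard cure for the
   funnel coupling between group scales and subject effects.

Proposal scales adapt toward ~44% acceptance during warmup only and
then freeze, so retained draws form a valid chain. Each recorded
iteration performs 8 such sweeps, giving the random-walk sampler an
effective step budget comparable to gradient samplers at the
conventional configuration of 4 chains x 1,000 recorded samples after
500 warmup. Split R-hat (arviz) is computed for every group-level and
subject-level parameter; values above 1.1 flag non-convergence without
aborting. On default synthetic cohorts the maximum split R-hat is
typically ~1.02.

### Parameter recovery and the eligibility trace

The recovery study draws subject parameters from truncated normals
(`alpha ~ N(0.5, 0.2)` on (0,1), `lambda ~ N(0.5, 0.2)` on (0,1),
`beta_mf ~ N(1.0, 0.8)`, `beta_mb ~ N(1.5, 1.0)`,
`beta_step2 ~ N(2.0, 1.0)` on (0,10), `p ~ N(0.2, 0.2)`), simulates
each subject on a fresh default schedule, refits hierarchically, and
correlates generating with posterior-mean values per parameter.

A known limitation, documented deliberately: under these generating
conditions the eligibility trace `lambda` is only weakly identified at
288 block-stationary trials per subject. Within a stable 32-trial
block the Step-2 values converge, so the Step-2 prediction error that
the trace propagates is small on most trials; most of the information
about `lambda` is confined to the few trials after each block switch.
An oracle-conditioned check (per-subject grid MLE for `lambda` with
every other parameter held at its true value) tops out near r ~ 0.4
over 70 subjects, and the hierarchical posterior means do slightly
better (~0.5) through shrinkage. The other five parameters recover at
r ~ 0.8 or higher at the same scale. Recovery of `lambda` is
substantially easier in drifting-probability variants of the task,
where prediction errors persist throughout.

## 6. Behavioural statistics

* **Stay regression.** Per subject, staying (repeating the previous
  Step-1 choice) is regressed on the previous trial's outcome (coded
  +/-0.5), transition (+/-0.5, common positive), their product, and a
  binary "correct" regressor marking whether the previous Step-1
  choice commonly led to the state holding the then-current high
  shape. Effect coding of outcome/transition makes the interaction the
  model-based signature with the conventional interpretation; the
  correct regressor guards against inflated model-based estimates in
  block-stationary schedules. Fitting is maximum-likelihood logistic;
  on (quasi-)separation or non-convergence a weak ridge (1e-3) is
  applied and flagged rather than dropping the subject. Regressions
  are per subject, with group inference on the subject-level
  coefficients.
* **Group tests.** Kruskal-Wallis, Mann-Whitney U (exact null when the
  smaller group has <= 10 observations and no ties, normal
  approximation with midrank tie correction otherwise), one-sample
  Wilcoxon signed-rank, one-sample t, and Fisher's exact test, each
  with explicit sidedness. No multiple-testing correction is applied
  anywhere, mirroring uncorrected single-test reporting.
* **Lesion-volume control.** OLS of a performance metric on the lesion
  volume inside the region mask controlling for total lesion volume
  (`metric ~ a + b0 V_region + b1 V_total`), requiring a full-rank
  design.
* **Residualization.** `metric ~ age + education` is fitted within the
  healthy-control group only; the fitted prediction is subtracted for
  every subject. The operation is idempotent up to numerical
  tolerance.

## 7. Synthetic cohorts — what they do and do not emulate

`CohortSpec` defines three groups (vmPFC, LC, HC) with study-sized
defaults (board game 10/8/30 at 40 games per subject; Two-Step
30/19/20 at 288 trials). Defaults plant a feature-drop and stopping-
probability elevation in the vmPFC group for the board game
(`delta` 0.4 vs 0.15, `gamma` 0.5 vs 0.3 — shallower, more oversight-
prone play) and *no* group differences in the Two-Step parameters,
with a 150 ms Step-2 slowing after rare transitions in every group.
Lesion volumes are lognormal in voxel units with vmPFC <= total for
the lesion group, zero vmPFC volume for lesion controls, and zero for
healthy controls; ages and education levels are truncated normals per
group.

These generators make the pipeline testable end to end, and that is
all they do: they contain no lesion anatomy, no neuropsychology, no
real response-time structure beyond a lognormal with an additive
shift, and no claim that the planted effect sizes equal any patient
effect. Passing tests demonstrate that the machinery detects planted
structure and stays calibrated under the null — not that any specific
empirical result would replicate.

## 8. Problem sizes used by the checks

The suite and acceptance script run everything at desk scale, chosen
as the package's own verification sizes: recovery at 70 subjects x 288
trials (one repetition), convergence at 30 subjects with the full
4 x 1,000 (500 warmup) sampler configuration, simulator calibration at
>= 100,000 trials per rate, oracle equivalence on 50 random 7-8-empty
positions, drop-rate ordering on 12 simulated agents (4 per level at
`delta` in {0, 0.2, 0.4}) fitted from ~180 session moves each at a
reduced IBS budget, and the directional pipeline-power property on
5-vs-4-subject cohorts over 20 replicates. Rank-test calibration uses
2,000 null datasets.
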