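# fourstep

Computational analyses of planning behaviour at two levels of task
complexity, built for lesion-cohort studies and fully runnable on
synthetic data:

* **Four-in-a-Row** — a 4x9 board game in which two players race to
  place four pieces in a line. Human-like play is modelled by a
  generative planning agent: a noisy linear heuristic over board
  features (center proximity, connected/unconnected two-in-a-row,
  three-in-a-row, four-in-a-row, with an active-player scaling `C`)
  drives a best-first tree search with value-based pruning (`theta`),
  stochastic stopping (`gamma`), per-decision feature overlooking
  (`delta`), and a uniform lapse (`lambda`). The agent's likelihood is
  estimated by inverse binomial sampling (IBS) and fitted with a
  noise-tolerant derivative-free optimizer; fitted agents are
  summarized by **planning depth** (mean principal-variation length),
  **heuristic quality** (correlation of the feature-based value with
  the exact game-theoretic value), and the **feature drop rate**
  (`delta` itself). Sessions against a five-category opponent pool use
  an adaptive staircase, and playing strength is rated on the Elo
  scale with a Bradley-Terry-plus-draws (Davidson) model.
* **Two-Step** — a two-stage bandit with 75%/25% common/rare
  transitions and block-stationary rewards (one of four shapes pays
  80%, the others 8.3%, switching every 32 trials; 288 trials total).
  Choices are modelled by a hybrid SARSA(lambda) / model-based learner
  with six parameters (`alpha`, `lambda`, `beta_mf`, `beta_mb`,
  `beta_step2`, repetition bias `p`), fitted in a hierarchical
  Bayesian model by a numba-compiled MCMC sampler with split-R-hat
  diagnostics, and validated by simulate-and-refit parameter recovery.
  Classical analyses (stay-probability logistic regression with an
  outcome-by-transition interaction and a "correct" control regressor,
  Step-2 response-time contrasts) are included.

A synthetic-cohort generator ties everything together: three groups
(vmPFC lesion, lesion control, healthy control) with per-subject true
parameters, simulated sessions, and demographic/lesion-volume
covariates, so the complete pipeline — generation, fitting, summary
metrics, Elo, and nonparametric group statistics — runs end to end
with no external data. See `docs/methods.md` for model details and
assumptions.

## Worked example

```python
import numpy as np
from fourstep import planner as pl, metrics as mx
from fourstep.board import Board

rng = np.random.default_rng(0)
params = pl.PlannerParams(gamma=0.2, delta=0.1, lapse=0.0)

board = Board.from_moves([22, 13, 21, 14])   # black 22,21; white 13,14
mask = pl.sample_drop_mask(board, params, rng)
root = pl.best_first_search(board, params, mask, rng)
print(pl.principal_variation(root, rng), round(root.value, 2))
# [23, 12, 24] 7.11

probes = mx.generate_probe_states(pl.PlannerParams(), 20, rng)
print(round(mx.compute_depth(params, probes, rng, n_reps=10), 2))
# 1.66
```

The principal variation `[23, 12, 24]` is the line of play the agent
currently considers best for both sides: black extends its pair at
21-22 toward a three-in-a-row, white responds next to its own pair,
black extends again. The root value 7.11 is black's advantage in
heuristic units (the evaluation noise has unit variance, so this is a
strong position), and 1.66 is this agent's planning depth — with
`gamma = 0.2` the search stops early, so it looks under two plies
ahead on average.

```python
from fourstep.twostep_model import TwoStepParams, simulate_agent
from fourstep.twostep_task import TaskConfig, generate_schedule, trials_to_frame
from fourstep.behav_stats import stay_coefficients

agent = TwoStepParams(alpha=0.5, lam=0.5, beta_mf=1.0, beta_mb=3.0,
                      beta_step2=3.0, p=0.2)
sch = generate_schedule(TaskConfig(), rng)
df = trials_to_frame(simulate_agent(agent, sch, rng))
co = stay_coefficients(df)
print(round(co.outcome, 2), round(co.interaction, 2))
# 0.49 1.42
```

This strongly model-based agent (`beta_mb = 3`) shows the canonical
signature: a large positive outcome-by-transition interaction (1.42) —
it repeats rewarded choices after common transitions but switches
after rewarded rare transitions — on top of a modest outcome main
effect (0.49).

## Command-line pipeline

A thin CLI drives the synthetic pipeline stage by stage
(`fourstep synth-4iar | elo | fit-4iar | metrics-4iar | synth-twostep |
fit-twostep | recover-twostep | stats | all`), each taking `--seed`,
`--out-dir`, and an optional YAML `--config`. Outputs are JSONL game
records, CSV trial/fit/rating tables, and a JSON stats report; every
file the pipeline writes can be read back by it.

```sh
fourstep synth-twostep --seed 1 --out-dir out
fourstep fit-twostep   --seed 1 --out-dir out --chains 4 --samples 1000
fourstep stats         --seed 1 --out-dir out
```

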