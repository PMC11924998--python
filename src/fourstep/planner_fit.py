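"""Move-likelihood estimation by inverse binomial sampling (IBS) and
parameter fitting for the planning agent.

The planner's choice probability has no closed form, so the log
likelihood of an observed move is estimated by simulation: repeatedly
sample moves from the model until one matches the observation. If the
first match occurs at trial K, the contribution

    -sum_{j=1}^{K-1} 1/j

is an unbiased estimator of log P(move). Contributions are averaged over
independent repeats and summed over observations. A cap on K (with the
corresponding harmonic penalty) bounds the runtime for badly
mis-specified parameters.

Fitting maximizes the averaged IBS estimate with a bounded multi-start
Nelder-Mead search (a derivative-free method tolerant of the noisy
objective), with five-fold cross-validation for held-out assessment and
a final refit on all data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from sklearn.base import BaseEstimator

from . import _search_kernels as _sk
from .board import Board, Move, GameRecord, is_terminal
from .planner import PlannerParams, choose_move

# bounds used when a parameter is freed during fitting
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "w_center": (0.0, 10.0),
    "w_2conn": (0.0, 10.0),
    "w_2unc": (0.0, 10.0),
    "w_3": (0.0, 10.0),
    "w_4": (0.0, 10.0),
    "C": (0.25, 4.0),
    "theta": (0.0, 10.0),
    "gamma": (0.02, 1.0),
    "delta": (0.0, 0.9),
    "lapse": (0.005, 0.5),
}

DEFAULT_IBS_CAP = 500
MIN_OBSERVATIONS = 20


@dataclass(frozen=True)
class MoveObservation:
    """One observed decision: an ongoing board and the move chosen on it."""

    board: Board
    observed_move: Move

    def __post_init__(self):
        if is_terminal(self.board):
            raise ValueError("observation board must be ongoing")
        if self.board.occupied & (1 << self.observed_move.square):
            raise ValueError("observed move is not legal on the board")


@dataclass(frozen=True)
class IBSEstimate:
    loglik_estimate: float
    samples_used: int
    capped: bool


@dataclass
class FitResult:
    """Fitted planner parameters with cross-validation bookkeeping."""

    params: PlannerParams
    fold_assignments: np.ndarray
    fold_loglik: list[float]
    trace: dict = field(default_factory=dict)


def observations_from_records(records: list[GameRecord]) -> list[MoveObservation]:
    """Flatten game records to the participant's own move decisions."""
    obs = []
    for rec in records:
        for board, move in rec.participant_boards_and_moves():
            obs.append(MoveObservation(board, move))
    return obs


def ibs_loglik(
    observations: list[MoveObservation],
    params: PlannerParams,
    rng: np.random.Generator,
    repeats: int = 2,
    cap: int = DEFAULT_IBS_CAP,
    max_iterations: int = 200,
    engine: str = "fast",
) -> IBSEstimate:
    """Unbiased IBS estimate of the summed log likelihood of the
    observed moves under ``params``, averaged over ``repeats`` runs.

    ``engine='fast'`` samples moves with the numba search kernel (same
    generative policy, flat arrays); ``engine='reference'`` uses the
    object-tree implementation in :mod:`fourstep.planner`.
    """
    if not observations:
        raise ValueError("observation list is empty")
    if repeats < 1 or cap < 2:
        raise ValueError("repeats must be >= 1 and cap >= 2")
    if engine == "fast":
        _sk.seed(int(rng.integers(2 ** 31 - 1)))

        def sample(board):
            return _sk.choose_move_kernel(
                board.black, board.white, board.to_move,
                params.w_2conn, params.w_2unc, params.w_3, params.w_4,
                params.w_center, params.C, params.theta, params.gamma,
                params.delta, params.lapse, params.noise_sd, max_iterations)
    elif engine == "reference":
        def sample(board):
            return choose_move(board, params, rng, max_iterations).square
    else:
        raise ValueError(f"unknown engine {engine!r}")
    # harmonic numbers H[k] = sum_{j<=k} 1/j, H[0] = 0
    harmonic = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, cap + 1))])
    total = 0.0
    samples = 0
    capped = False
    for obs in observations:
        target = obs.observed_move.square
        contrib = 0.0
        for _ in range(repeats):
            k = 1
            while k < cap:
                samples += 1
                if sample(obs.board) == target:
                    break
                k += 1
            else:
                samples += 1
                capped = True
            contrib -= harmonic[k - 1]
        total += contrib / repeats
    return IBSEstimate(loglik_estimate=total, samples_used=samples, capped=capped)


def crossval_folds(n: int, k: int = 5, seed: int | None = None) -> np.ndarray:
    """Random fold assignment (sizes differ by at most one), seeded."""
    if n < k:
        raise ValueError(f"need at least {k} observations for {k} folds")
    rng = np.random.default_rng(seed)
    assignment = np.arange(n) % k
    rng.shuffle(assignment)
    return assignment


class PlannerIBSEstimator(BaseEstimator):
    """Planner parameter estimator over IBS likelihoods.

    scikit-learn style: configure in ``__init__``, call
    :meth:`fit` with a list of :class:`MoveObservation`, read the fitted
    parameters from ``params_`` and the per-fold held-out log likelihood
    from ``fold_loglik_``.

    Parameters
    ----------
    free : tuple of str
        Names of the planner parameters to optimize; the rest stay at
        ``base_params``. The four-in-a-row weight defaults to being held
        at its upper bound (it is essentially always maximal, since a
        completed line ends the game).
    repeats : int
        IBS repeats averaged per objective evaluation (>= 2).
    cap : int
        IBS simulation cap per observation.
    n_restarts : int
        Independent Nelder-Mead starts (>= 3 recommended).
    max_evals : int
        Objective-evaluation budget per start.
    n_folds : int
        Cross-validation folds (0 disables CV; ``final`` refit always
        uses all data).
    """

    def __init__(
        self,
        free: tuple = ("delta", "gamma", "theta", "lapse"),
        base_params: PlannerParams | None = None,
        repeats: int = 3,
        cap: int = 200,
        n_restarts: int = 3,
        max_evals: int = 50,
        n_folds: int = 5,
        min_observations: int = MIN_OBSERVATIONS,
        w4_at_bound: bool = True,
        max_iterations: int = 80,
        common_random_numbers: bool = True,
        seed: int | None = None,
    ):
        self.free = free
        self.base_params = base_params
        self.repeats = repeats
        self.cap = cap
        self.n_restarts = n_restarts
        self.max_evals = max_evals
        self.n_folds = n_folds
        self.min_observations = min_observations
        self.w4_at_bound = w4_at_bound
        self.max_iterations = max_iterations
        self.common_random_numbers = common_random_numbers
        self.seed = seed

    # -- internals -----------------------------------------------------
    def _base(self) -> PlannerParams:
        base = self.base_params if self.base_params is not None else PlannerParams()
        if self.w4_at_bound and "w_4" not in self.free:
            base = base.replace(w_4=PARAM_BOUNDS["w_4"][1])
        return base

    def _to_params(self, x: np.ndarray) -> PlannerParams:
        kw = {}
        for name, val in zip(self.free, x):
            lo, hi = PARAM_BOUNDS[name]
            kw[name] = float(np.clip(val, lo, hi))
        return self._base().replace(**kw)

    def _objective(self, x, observations, rng, crn_seed=None):
        params = self._to_params(x)
        # common random numbers: evaluating every candidate under the
        # same simulation stream turns the noisy objective into a fixed
        # function of the parameters, which the direct search can
        # optimize far more reliably; the final comparison across
        # restarts uses fresh draws
        local = np.random.default_rng(crn_seed) if crn_seed is not None else rng
        est = ibs_loglik(observations, params, local, self.repeats, self.cap,
                         self.max_iterations)
        return -est.loglik_estimate

    def _optimize(self, observations, rng) -> tuple[np.ndarray, float]:
        bounds = [PARAM_BOUNDS[name] for name in self.free]
        d = len(bounds)
        crn = (int(rng.integers(2 ** 31 - 1))
               if self.common_random_numbers else None)
        # stage 1: seeded space-filling grid, all points under one CRN
        # stream so their comparison is low-variance
        n_grid = max(8, 8 * d)
        grid = np.empty((n_grid, d))
        for j, (lo, hi) in enumerate(bounds):
            levels = lo + (hi - lo) * (np.arange(n_grid) + 0.5) / n_grid
            grid[:, j] = rng.permutation(levels)
        grid_f = np.array(
            [self._objective(x, observations, rng, crn) for x in grid]
        )
        order = np.argsort(grid_f)
        # stage 2: Nelder-Mead polish from the best grid points, each
        # start under its own CRN stream so an unlucky realization does
        # not corrupt every candidate
        candidates = []
        for i in order[: self.n_restarts]:
            crn_i = (int(rng.integers(2 ** 31 - 1))
                     if self.common_random_numbers else None)
            res = optimize.minimize(
                self._objective,
                grid[i],
                args=(observations, rng, crn_i),
                method="Nelder-Mead",
                bounds=bounds,
                options={"maxfev": self.max_evals, "xatol": 5e-3,
                         "fatol": 0.25},
            )
            if np.isfinite(res.fun):
                candidates.append(res.x)
        if not candidates:
            raise RuntimeError("optimizer produced no finite objective value")
        # stage 3: pick among polished candidates with fresh draws and a
        # larger repeat count (reduces winner's curse at selection)
        finals = []
        for x in candidates:
            ll = ibs_loglik(observations, self._to_params(x), rng,
                            max(3 * self.repeats, 6), self.cap,
                            self.max_iterations)
            finals.append(-ll.loglik_estimate)
        best = int(np.argmin(finals))
        return candidates[best], float(finals[best])

    # -- sklearn API ---------------------------------------------------
    def fit(self, observations: list[MoveObservation], y=None):
        if len(observations) < self.min_observations:
            raise ValueError(
                f"need >= {self.min_observations} observations, got {len(observations)}"
            )
        rng = np.random.default_rng(self.seed)
        n = len(observations)
        fold_loglik: list[float] = []
        if self.n_folds and self.n_folds >= 2:
            folds = crossval_folds(n, self.n_folds,
                                   int(rng.integers(2 ** 31)))
            for f in range(self.n_folds):
                train = [o for o, a in zip(observations, folds) if a != f]
                test = [o for o, a in zip(observations, folds) if a == f]
                x, _ = self._optimize(train, rng)
                held = ibs_loglik(test, self._to_params(x), rng,
                                  self.repeats, self.cap,
                                  self.max_iterations)
                fold_loglik.append(held.loglik_estimate)
        else:
            folds = np.zeros(n, dtype=int)
        x, f = self._optimize(observations, rng)
        self.params_ = self._to_params(x)
        self.fold_assignments_ = folds
        self.fold_loglik_ = fold_loglik
        self.objective_ = f
        return self

    def score(self, observations: list[MoveObservation]) -> float:
        """IBS log-likelihood estimate of held-out observations under the
        fitted parameters (higher is better)."""
        rng = np.random.default_rng(self.seed)
        return ibs_loglik(observations, self.params_, rng,
                          self.repeats, self.cap).loglik_estimate

    def result_(self) -> FitResult:
        return FitResult(
            params=self.params_,
            fold_assignments=self.fold_assignments_,
            fold_loglik=self.fold_loglik_,
            trace={"objective": self.objective_},
        )


def fit_planner(
    observations: list[MoveObservation], **config
) -> FitResult:
    """Functional wrapper over :class:`PlannerIBSEstimator`."""
    est = PlannerIBSEstimator(**config)
    est.fit(observations)
    return est.result_()
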