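"""Summary metrics of the fitted planning model and the exact game oracle.

Three per-subject summaries are reported: planning depth (mean principal-
variation length of the generative search over probe positions),
heuristic quality (Pearson correlation between the deterministic
feature-based state value and the exact game-theoretic value over
near-endgame probe positions), and the feature-drop rate (the fitted
delta itself).

The original probe corpus came from human tournament play; here probe
positions are generated by seeded self-play between mid-strength agents
(and, for oracle-feasible positions, by random fills near the end of the
game), which keeps every stage runnable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import planner as pl
from .board import (
    BLACK,
    WHITE,
    BLACK_WIN,
    WHITE_WIN,
    DRAW,
    ONGOING,
    FULL_MASK,
    LINE_MASKS,
    LINES_THROUGH,
    N_SQUARES,
    Board,
    apply_move,
    game_outcome,
    is_terminal,
    legal_moves,
    random_position,
)
from .planner import PlannerParams

DEFAULT_ORACLE_MAX_EMPTY = 12


@dataclass
class ProbeSet:
    """Non-terminal probe boards plus generation provenance."""

    boards: list[Board]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for b in self.boards:
            if is_terminal(b):
                raise ValueError("probe sets must contain only ongoing boards")

    def __len__(self):
        return len(self.boards)

    def __iter__(self):
        return iter(self.boards)


@dataclass(frozen=True)
class SummaryMetrics:
    """Per-subject planning summaries: depth (moves), heuristic quality
    (Pearson r in [-1, 1]), and feature drop rate (delta in [0, 1])."""

    planning_depth: float
    heuristic_quality: float
    feature_drop_rate: float


# ---------------------------------------------------------------------------
# exact game-theoretic oracle


def _winning_move_exists(black: int, white: int, mover: int) -> bool:
    own = black if mover == BLACK else white
    occ = black | white
    for sq in range(N_SQUARES):
        bit = 1 << sq
        if occ & bit:
            continue
        new = own | bit
        for li in LINES_THROUGH[sq]:
            mask = LINE_MASKS[li]
            if new & mask == mask:
                return True
    return False


def _negamax(black: int, white: int, mover: int, memo: dict) -> int:
    """Exact value from black's perspective in {-1, 0, +1} for a position
    known to be non-terminal. Memoized on the position; an immediate
    winning move short-circuits the recursion."""
    key = (black, white)
    cached = memo.get(key)
    if cached is not None:
        return cached
    if _winning_move_exists(black, white, mover):
        v = 1 if mover == BLACK else -1
        memo[key] = v
        return v
    occ = black | white
    opp = WHITE if mover == BLACK else BLACK
    best = None
    for sq in range(N_SQUARES):
        bit = 1 << sq
        if occ & bit:
            continue
        nb, nw = (black | bit, white) if mover == BLACK else (black, white | bit)
        # no immediate win here (checked above), so child is terminal only
        # if the board filled up -> draw
        if (nb | nw) == FULL_MASK:
            v = 0
        else:
            v = _negamax(nb, nw, opp, memo)
        if best is None:
            best = v
        elif mover == BLACK:
            best = max(best, v)
        else:
            best = min(best, v)
        if (mover == BLACK and best == 1) or (mover == WHITE and best == -1):
            break
    memo[key] = best
    return best


_ORACLE_OUTCOME = {1: BLACK_WIN, 0: DRAW, -1: WHITE_WIN}


def oracle_value(board: Board, max_empty: int = DEFAULT_ORACLE_MAX_EMPTY) -> str:
    """Game-theoretic value under optimal play by both sides.

    Exhaustive memoized minimax; feasible only near the end of the game,
    so positions with more than ``max_empty`` empty squares are refused.
    """
    n_empty = board.n_empty()
    if n_empty > max_empty:
        raise ValueError(
            f"{n_empty} empty squares exceeds oracle limit max_empty={max_empty}"
        )
    outcome = game_outcome(board)
    if outcome is not ONGOING:
        return outcome
    v = _negamax(board.black, board.white, board.to_move, {})
    return _ORACLE_OUTCOME[v]


def oracle_value_signed(board: Board, max_empty: int = DEFAULT_ORACLE_MAX_EMPTY) -> int:
    """Oracle value coded +1 (black win), 0 (draw), -1 (white win)."""
    out = oracle_value(board, max_empty)
    return {BLACK_WIN: 1, DRAW: 0, WHITE_WIN: -1}[out]


def brute_force_value(board: Board) -> str:
    """Plain recursive enumeration of all move sequences, no memo and no
    shortcuts. Independent cross-check of the oracle on tiny endgames."""
    outcome = game_outcome(board)
    if outcome is not ONGOING:
        return outcome
    vals = [brute_force_value(apply_move(board, m)) for m in legal_moves(board)]
    signed = [{BLACK_WIN: 1, DRAW: 0, WHITE_WIN: -1}[v] for v in vals]
    best = max(signed) if board.to_move == BLACK else min(signed)
    return _ORACLE_OUTCOME[best]


# ---------------------------------------------------------------------------
# probe generation


def generate_probe_states(
    pool_params: PlannerParams,
    n: int,
    rng: np.random.Generator,
    max_empty_filter: int | None = None,
    max_games: int = 10_000,
) -> ProbeSet:
    """Sample ongoing positions from self-play between mid-strength agents.

    Positions are collected uniformly over plies of seeded self-play
    games of ``pool_params`` against itself; the optional filter keeps
    only positions with at most ``max_empty_filter`` empty squares (so
    the exact oracle stays feasible on them).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    candidates: list[Board] = []
    games = 0
    while len(candidates) < 4 * n and games < max_games:
        board = Board()
        while not is_terminal(board):
            if max_empty_filter is None or board.n_empty() <= max_empty_filter:
                candidates.append(board)
            board = apply_move(board, pl.choose_move(board, pool_params, rng))
        games += 1
    if len(candidates) < n:
        raise RuntimeError(
            f"could not collect {n} probe states in {max_games} self-play games"
        )
    idx = rng.choice(len(candidates), size=n, replace=False)
    boards = [candidates[int(i)] for i in idx]
    return ProbeSet(
        boards=boards,
        provenance={
            "generator": "self-play",
            "n_games": games,
            "max_empty_filter": max_empty_filter,
        },
    )


def random_probe_states(
    n: int, n_empty: int, rng: np.random.Generator
) -> ProbeSet:
    """Synthetic random-fill probe positions with exactly ``n_empty``
    empty squares (rejection-sampled to be ongoing)."""
    boards = [random_position(rng, N_SQUARES - n_empty) for _ in range(n)]
    return ProbeSet(boards=boards, provenance={"generator": "random-fill",
                                               "n_empty": n_empty})


def mixed_value_probe_states(
    n: int, n_empty: int, rng: np.random.Generator, max_tries: int = 40
) -> ProbeSet:
    """Random near-endgame probes whose exact game values are not all
    identical (alternating piece parities flips the mover advantage);
    suitable for the heuristic-quality correlation, which needs variance
    in the objective values."""
    for _ in range(max_tries):
        boards = [random_position(rng, N_SQUARES - n_empty - (i % 2))
                  for i in range(n)]
        values = {oracle_value_signed(b, n_empty + 1) for b in boards}
        if len(values) > 1:
            return ProbeSet(boards=boards,
                            provenance={"generator": "random-fill-mixed",
                                        "n_empty": n_empty})
    raise RuntimeError("could not build a mixed-value probe set")


# ---------------------------------------------------------------------------
# metrics


def compute_depth(
    params: PlannerParams,
    probes: ProbeSet,
    rng: np.random.Generator,
    n_reps: int = 10,
    max_iterations: int = pl.DEFAULT_MAX_ITERATIONS,
) -> float:
    """Mean principal-variation length of the generative search over all
    probe states and ``n_reps`` repetitions per state.

    The lapse parameter is bypassed: depth is a property of the search
    process, not of occasional random moves.
    """
    if len(probes) == 0:
        raise ValueError("probe set is empty")
    lengths = []
    for board in probes:
        for _ in range(n_reps):
            mask = pl.sample_drop_mask(board, params, rng)
            root = pl.best_first_search(board, params, mask, rng, max_iterations)
            lengths.append(len(pl.principal_variation(root, rng)))
    return float(np.mean(lengths))


def subjective_values(params: PlannerParams, probes: ProbeSet) -> np.ndarray:
    """Deterministic part of the heuristic value (no noise, no drops)
    for each probe, from black's perspective."""
    noiseless = params.replace(noise_sd=0.0)
    return np.array(
        [pl.heuristic_value(b, noiseless, frozenset(), None) for b in probes]
    )


def heuristic_quality(
    params: PlannerParams,
    probes: ProbeSet,
    max_empty: int = DEFAULT_ORACLE_MAX_EMPTY,
) -> float:
    """Pearson correlation between the subjective feature-based value and
    the exact game-theoretic value (+1/0/-1, black's perspective) over
    the probe states."""
    if len(probes) < 3:
        raise ValueError("need at least 3 probe states")
    subj = subjective_values(params, probes)
    obj = np.array([oracle_value_signed(b, max_empty) for b in probes], float)
    if np.ptp(subj) == 0 or np.ptp(obj) == 0:
        raise ValueError("zero variance in subjective or objective values")
    return float(sps.pearsonr(subj, obj).statistic)


def summary_metrics(
    params,
    depth_probes: ProbeSet,
    quality_probes: ProbeSet,
    rng: np.random.Generator,
    n_reps: int = 10,
    oracle_max_empty: int = DEFAULT_ORACLE_MAX_EMPTY,
) -> SummaryMetrics:
    """Bundle the three summaries for one subject.

    ``params`` may be a :class:`~fourstep.planner.PlannerParams` or any
    fit result exposing a ``params`` attribute.
    """
    if hasattr(params, "params"):
        params = params.params
    return SummaryMetrics(
        planning_depth=compute_depth(params, depth_probes, rng, n_reps),
        heuristic_quality=heuristic_quality(params, quality_probes, oracle_max_empty),
        feature_drop_rate=params.delta,
    )
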