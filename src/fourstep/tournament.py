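"""Opponent pool, adaptive staircase, match play, and Elo ratings.

Sessions mimic the task protocol: a subject plays a fixed number of
games, alternating colors, against computer opponents drawn from five
ordered strength categories. A staircase adjusts difficulty: a loss
demotes one category, a draw or single win keeps the category, two
consecutive wins promote.

Playing strength is summarized on the Elo scale by maximum-likelihood
fitting of a Davidson model (Bradley-Terry with a draw parameter),
treating each of the five opponent categories as a single rated
"opponent" shared across subjects. A weak ridge on the log-strengths
keeps ratings finite under perfect records; category ratings are
anchored to mean zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from sklearn.base import BaseEstimator

from .board import (
    BLACK,
    WHITE,
    BLACK_WIN,
    WHITE_WIN,
    Board,
    GameRecord,
    apply_move,
    game_outcome,
    is_terminal,
)
from .planner import PlannerParams, choose_move

N_CATEGORIES = 5
ELO_SCALE = 400.0 / np.log(10.0)

# Category recipes, weakest (1) to strongest (5): stopping probability
# sweeps down (deeper search), while drop and lapse rates sweep down
# (noise becomes less effective). Pruning loosens slightly with strength.
_CATEGORY_GAMMA = (0.9, 0.6, 0.4, 0.22, 0.1)
_CATEGORY_DELTA = (0.6, 0.45, 0.3, 0.15, 0.05)
_CATEGORY_LAPSE = (0.25, 0.15, 0.08, 0.04, 0.01)
_CATEGORY_THETA = (1.0, 1.2, 1.5, 1.8, 2.0)


@dataclass
class OpponentPool:
    """Five ordered strength categories of planner agents."""

    categories: list[list[PlannerParams]]

    def __post_init__(self):
        if len(self.categories) != N_CATEGORIES:
            raise ValueError(f"expected {N_CATEGORIES} categories")

    def draw(self, category: int, rng: np.random.Generator) -> PlannerParams:
        """Uniform draw of an agent from a 1-based category."""
        agents = self.categories[category - 1]
        return agents[int(rng.integers(len(agents)))]


@dataclass(frozen=True)
class StaircaseState:
    """Current 1-based opponent category and consecutive-win counter."""

    category: int = 2
    wins: int = 0

    def __post_init__(self):
        if not 1 <= self.category <= N_CATEGORIES:
            raise ValueError("category must be in [1, 5]")
        if self.wins not in (0, 1):
            raise ValueError("win counter must be 0 or 1")


def build_opponent_pool(
    rng: np.random.Generator,
    n_per_category: int = 40,
    base_params: PlannerParams | None = None,
    jitter_sd: float = 0.05,
) -> OpponentPool:
    """Construct the five categories from the documented recipe, with a
    small seeded lognormal jitter across agents within a category."""
    base = base_params if base_params is not None else PlannerParams()
    categories = []
    for cat in range(N_CATEGORIES):
        agents = []
        for _ in range(n_per_category):
            j = np.exp(jitter_sd * rng.standard_normal(4))
            agents.append(
                base.replace(
                    gamma=float(np.clip(_CATEGORY_GAMMA[cat] * j[0], 0.02, 1.0)),
                    delta=float(np.clip(_CATEGORY_DELTA[cat] * j[1], 0.0, 0.9)),
                    lapse=float(np.clip(_CATEGORY_LAPSE[cat] * j[2], 0.0, 0.5)),
                    theta=float(np.clip(_CATEGORY_THETA[cat] * j[3], 0.0, 10.0)),
                )
            )
        categories.append(agents)
    return OpponentPool(categories)


def staircase_update(state: StaircaseState, outcome: str) -> StaircaseState:
    """Advance the staircase after one game.

    ``outcome`` is 'win', 'draw', or 'loss' from the subject's
    perspective. Loss: one category down (floored at 1), counter reset.
    Draw: same category, counter reset. Win: counter up; at two
    consecutive wins, one category up (capped at 5), counter reset.
    """
    if outcome == "loss":
        return StaircaseState(max(1, state.category - 1), 0)
    if outcome == "draw":
        return StaircaseState(state.category, 0)
    if outcome == "win":
        if state.wins + 1 >= 2:
            return StaircaseState(min(N_CATEGORIES, state.category + 1), 0)
        return StaircaseState(state.category, state.wins + 1)
    raise ValueError(f"unknown outcome {outcome!r}")


def play_game(
    black_params: PlannerParams,
    white_params: PlannerParams,
    rng: np.random.Generator,
) -> tuple[list[int], str]:
    """Play one game to termination; returns (move list, outcome)."""
    board = Board()
    moves: list[int] = []
    while not is_terminal(board):
        params = black_params if board.to_move == BLACK else white_params
        mv = choose_move(board, params, rng)
        moves.append(mv.square)
        board = apply_move(board, mv)
    return moves, game_outcome(board)


def _subject_result(outcome: str, color: int) -> str:
    if outcome == BLACK_WIN:
        return "win" if color == BLACK else "loss"
    if outcome == WHITE_WIN:
        return "win" if color == WHITE else "loss"
    return "draw"


def play_session(
    subject_params: PlannerParams,
    pool: OpponentPool,
    rng: np.random.Generator,
    n_games: int = 40,
    subject_id: str = "s0",
    start_category: int = 2,
) -> list[GameRecord]:
    """One staircase session: the subject alternates colors across games
    (black first), the opponent is drawn uniformly from the current
    staircase category, and the staircase advances after each game."""
    if n_games < 1:
        raise ValueError("n_games must be >= 1")
    state = StaircaseState(category=start_category, wins=0)
    records = []
    for g in range(n_games):
        color = BLACK if g % 2 == 0 else WHITE
        opponent = pool.draw(state.category, rng)
        if color == BLACK:
            moves, outcome = play_game(subject_params, opponent, rng)
        else:
            moves, outcome = play_game(opponent, subject_params, rng)
        records.append(
            GameRecord(
                subject_id=subject_id,
                participant_color=color,
                moves=moves,
                opponent_category=state.category,
                outcome=outcome,
            )
        )
        state = staircase_update(state, _subject_result(outcome, color))
    return records


@dataclass
class EloRatings:
    """Davidson-model ratings (points on the 400/ln 10 logistic scale)."""

    players: dict = field(default_factory=dict)
    categories: dict = field(default_factory=dict)
    draw_parameter: float = 0.0

    def rating(self, player_id: str) -> float:
        return self.players[player_id]


class EloRater(BaseEstimator):
    """Maximum-likelihood Davidson (Bradley-Terry + draws) rating model.

    Win/draw probabilities for player strength pi against opponent pj
    (natural strengths p = exp(theta)):

        P(win)  = pi / (pi + pj + nu * sqrt(pi * pj))
        P(draw) = nu * sqrt(pi * pj) / (pi + pj + nu * sqrt(pi * pj))

    The five opponent categories are rated as five shared entities.
    ``ridge`` is a weak Gaussian penalty on the log-strengths that keeps
    the MLE finite for perfect records; ratings are reported with the
    mean category rating anchored at zero (win probabilities are
    invariant to that common shift).
    """

    def __init__(self, ridge: float = 0.02, anchor: str = "categories"):
        self.ridge = ridge
        self.anchor = anchor

    def fit(self, records: list[GameRecord], y=None):
        if not records:
            raise ValueError("no game records")
        player_ids = sorted({r.subject_id for r in records})
        games_per_player = {pid: 0 for pid in player_ids}
        # encode each game: (player index, category index, result 1/0.5/0)
        rows = []
        for r in records:
            res = _subject_result(r.outcome, r.participant_color)
            score = {"win": 1.0, "draw": 0.5, "loss": 0.0}[res]
            rows.append((player_ids.index(r.subject_id),
                         r.opponent_category - 1, score))
            games_per_player[r.subject_id] += 1
        if any(n == 0 for n in games_per_player.values()):
            raise ValueError("every rated player needs at least one game")
        n_p = len(player_ids)
        wins = np.array([s == 1.0 for _, _, s in rows], dtype=float)
        draws = np.array([s == 0.5 for _, _, s in rows], dtype=float)
        pi_idx = np.array([i for i, _, _ in rows])
        cj_idx = np.array([j for _, j, _ in rows])

        def nll(x):
            th_p = x[:n_p]
            th_c = x[n_p:n_p + N_CATEGORIES]
            log_nu = x[-1]
            a = th_p[pi_idx]
            b = th_c[cj_idx]
            # log-sum-exp of (a, b, log_nu + (a+b)/2)
            m = np.maximum.reduce([a, b, log_nu + 0.5 * (a + b)])
            denom = m + np.log(
                np.exp(a - m) + np.exp(b - m)
                + np.exp(log_nu + 0.5 * (a + b) - m)
            )
            ll = (
                wins * (a - denom)
                + draws * (log_nu + 0.5 * (a + b) - denom)
                + (1 - wins - draws) * (b - denom)
            ).sum()
            penalty = 0.5 * self.ridge * (np.sum(x[:-1] ** 2) + log_nu ** 2)
            return -(ll) + penalty

        x0 = np.zeros(n_p + N_CATEGORIES + 1)
        x0[-1] = -1.0
        res = optimize.minimize(nll, x0, method="L-BFGS-B")
        th_p = res.x[:n_p]
        th_c = res.x[n_p:n_p + N_CATEGORIES]
        shift = th_c.mean()
        self.ratings_ = EloRatings(
            players={pid: float(ELO_SCALE * (t - shift))
                     for pid, t in zip(player_ids, th_p)},
            categories={c + 1: float(ELO_SCALE * (t - shift))
                        for c, t in enumerate(th_c)},
            draw_parameter=float(np.exp(res.x[-1])),
        )
        self.converged_ = bool(res.success)
        return self

    def predict_win_probability(self, rating_a: float, rating_b: float) -> float:
        """P(A beats B | no draw) under the fitted Davidson model."""
        ta, tb = rating_a / ELO_SCALE, rating_b / ELO_SCALE
        return float(np.exp(ta) / (np.exp(ta) + np.exp(tb)))


def elo_ratings(records: list[GameRecord], ridge: float = 0.02) -> EloRatings:
    """Functional wrapper over :class:`EloRater`."""
    return EloRater(ridge=ridge).fit(records).ratings_
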