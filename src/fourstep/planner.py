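"""Generative planning agent for Four-in-a-Row.

The agent evaluates board states with a noisy linear heuristic over five
features (center proximity, connected/unconnected two-in-a-row,
three-in-a-row, four-in-a-row), with the side to move receiving an
"active" multiplicative boost C on its pattern features:

    V(s) = w_center * (center_black - center_white)
           + c_black * sum_i w_i f_i(s, black)
           - c_white * sum_i w_i f_i(s, white) + eps,

where c_black = C and c_white = 1 when black is to move in s (and vice
versa), and eps is zero-mean unit-variance Gaussian noise drawn once per
evaluated node. Values are always from black's perspective.

Move choice runs best-first search: repeatedly follow the principal
variation (the greedy highest-value path for both players) to a leaf,
expand it by evaluating all legal children, prune children more than
theta below the best sibling (from the mover's perspective), and back
minimax values up to the root. After each iteration the search halts
with probability gamma. Before each move decision, every feature
instance on the root board is independently overlooked ("dropped") with
probability delta; dropped (line, color) instances contribute nothing at
any node of that move's search. With probability lapse the whole search
is bypassed and a uniform random legal move is played.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .board import (
    BLACK,
    WHITE,
    BLACK_WIN,
    WHITE_WIN,
    DRAW,
    ONGOING,
    CENTER_SCORE,
    FULL_MASK,
    LINE_MASKS,
    LINES_THROUGH,
    N_LINES,
    N_SQUARES,
    _CONN_PAIR_SETS,
    Board,
    Move,
    feature_instances,
    game_outcome,
    is_terminal,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_ITERATIONS = 10_000

_WIN_FOR = {BLACK: BLACK_WIN, WHITE: WHITE_WIN}


@dataclass(frozen=True)
class PlannerParams:
    """The ten free parameters of the planning agent.

    Feature weights are non-negative; ``C >= 1`` is typical (any
    positive value is accepted); ``theta >= 0`` is the pruning margin;
    ``gamma`` in (0, 1] is the per-iteration stopping probability;
    ``delta`` in [0, 1] the feature-drop probability; ``lapse`` in
    [0, 1] the random-move probability. ``noise_sd`` is fixed at 1 in
    the model (the evaluation noise has unit variance) and is exposed
    only so tests can suppress noise.
    """

    w_center: float = 0.6
    w_2conn: float = 0.9
    w_2unc: float = 0.45
    w_3: float = 3.5
    w_4: float = 10.0
    C: float = 1.4
    theta: float = 1.5
    gamma: float = 0.25
    delta: float = 0.15
    lapse: float = 0.05
    noise_sd: float = 1.0
    # Alternative drop semantics: instead of one mask drawn from the
    # root board and held fixed for the move, drop each feature instance
    # independently at every evaluated state. Off by default.
    drop_per_state: bool = False

    def __post_init__(self):
        for name in ("w_center", "w_2conn", "w_2unc", "w_3", "w_4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.C > 0:
            raise ValueError("C must be > 0")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must be in [0, 1]")
        if not 0 <= self.lapse <= 1:
            raise ValueError("lapse must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def replace(self, **kw) -> "PlannerParams":
        return replace(self, **kw)


def sample_drop_mask(
    board: Board, params: PlannerParams, rng: np.random.Generator
) -> frozenset:
    """Independently drop each pattern-feature instance on the root board
    with probability delta. The mask is held fixed for the whole search
    of one move decision."""
    if params.drop_per_state:
        return frozenset()  # drops are drawn per evaluated state instead
    instances = feature_instances(board)
    if params.delta <= 0 or not instances:
        return frozenset()
    if params.delta >= 1:
        return frozenset(instances)
    keep = rng.random(len(instances)) < params.delta
    return frozenset(inst for inst, d in zip(instances, keep) if d)


class _Evaluator:
    """Weighted feature sums with a fixed drop mask, with incremental
    per-move updates (only lines through the placed square change)."""

    __slots__ = ("w2c", "w2u", "w3", "w4", "wc", "C", "drop_b", "drop_w",
                 "per_state", "delta")

    def __init__(self, params: PlannerParams, drop_mask: frozenset):
        self.per_state = params.drop_per_state
        self.delta = params.delta
        self.w2c = params.w_2conn
        self.w2u = params.w_2unc
        self.w3 = params.w_3
        self.w4 = params.w_4
        self.wc = params.w_center
        self.C = params.C
        drop_b = drop_w = 0
        for li, color in drop_mask:
            if color == BLACK:
                drop_b |= 1 << li
            else:
                drop_w |= 1 << li
        self.drop_b = drop_b
        self.drop_w = drop_w

    def _line_w(self, li: int, own: int, opp: int) -> float:
        mask = LINE_MASKS[li]
        if opp & mask:
            return 0.0
        lb = own & mask
        n = lb.bit_count()
        if n < 2:
            return 0.0
        if n == 2:
            return self.w2c if lb in _CONN_PAIR_SETS[li] else self.w2u
        return self.w3 if n == 3 else self.w4

    def random_pattern_sums(self, black: int, white: int,
                            rng: np.random.Generator):
        """Per-state drop semantics: every feature instance present on
        this board is independently dropped with probability delta."""
        patb = patw = 0.0
        for li in range(N_LINES):
            w = self._line_w(li, black, white)
            if w and rng.random() >= self.delta:
                patb += w
            w = self._line_w(li, white, black)
            if w and rng.random() >= self.delta:
                patw += w
        return patb, patw

    def full_sums(self, black: int, white: int):
        patb = patw = 0.0
        for li in range(N_LINES):
            if not (self.drop_b >> li) & 1:
                patb += self._line_w(li, black, white)
            if not (self.drop_w >> li) & 1:
                patw += self._line_w(li, white, black)
        cenb = cenw = 0.0
        m = black
        while m:
            sq = (m & -m).bit_length() - 1
            cenb += CENTER_SCORE[sq]
            m &= m - 1
        m = white
        while m:
            sq = (m & -m).bit_length() - 1
            cenw += CENTER_SCORE[sq]
            m &= m - 1
        return patb, patw, cenb, cenw

    def deterministic_value(self, patb, patw, cenb, cenw, to_move: int) -> float:
        cb = self.C if to_move == BLACK else 1.0
        cw = self.C if to_move == WHITE else 1.0
        return self.wc * (cenb - cenw) + cb * patb - cw * patw


class SearchNode:
    """One node of the partial decision tree.

    ``value`` is the cached noisy evaluation (black's perspective; for
    expanded nodes, the minimax backup over unpruned children). Noise is
    drawn once at first evaluation. ``closed`` marks subtrees that need
    no further expansion (terminal, or decided by a closed winning
    line); ``proven`` carries the terminal outcome when known.
    """

    __slots__ = (
        "black", "white", "to_move", "move", "patb", "patw", "cenb",
        "cenw", "det", "value", "children", "closed", "proven",
    )

    def __init__(self, black, white, to_move, move, patb, patw, cenb, cenw,
                 det, value, proven=None):
        self.black = black
        self.white = white
        self.to_move = to_move
        self.move = move
        self.patb = patb
        self.patw = patw
        self.cenb = cenb
        self.cenw = cenw
        self.det = det
        self.value = value
        self.children = None
        self.closed = proven is not None
        self.proven = proven

    @property
    def board(self) -> Board:
        return Board(self.black, self.white)


def _best_index(values, maximize: bool, rng: np.random.Generator) -> int:
    """Index of the best value; exact ties broken uniformly at random."""
    best = max(values) if maximize else min(values)
    tied = [i for i, v in enumerate(values) if v == best]
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.integers(len(tied)))]


def heuristic_value(
    board: Board,
    params: PlannerParams,
    drop_mask: frozenset = frozenset(),
    rng: np.random.Generator | None = None,
) -> float:
    """Noisy heuristic evaluation of a board, from black's perspective."""
    ev = _Evaluator(params, drop_mask)
    patb, patw, cenb, cenw = ev.full_sums(board.black, board.white)
    if ev.per_state and ev.delta > 0:
        if rng is None:
            raise ValueError("rng required for per-state dropping")
        patb, patw = ev.random_pattern_sums(board.black, board.white, rng)
    det = ev.deterministic_value(patb, patw, cenb, cenw, board.to_move)
    eps = 0.0
    if params.noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        eps = params.noise_sd * rng.standard_normal()
    return det + eps


def _make_root(board: Board, ev: _Evaluator, params, rng) -> SearchNode:
    patb, patw, cenb, cenw = ev.full_sums(board.black, board.white)
    if ev.per_state and ev.delta > 0:
        patb, patw = ev.random_pattern_sums(board.black, board.white, rng)
    det = ev.deterministic_value(patb, patw, cenb, cenw, board.to_move)
    eps = params.noise_sd * rng.standard_normal() if params.noise_sd > 0 else 0.0
    outcome = game_outcome(board)
    proven = outcome if outcome is not ONGOING else None
    return SearchNode(
        board.black, board.white, board.to_move, None,
        patb, patw, cenb, cenw, det, det + eps, proven,
    )


def _expand(node: SearchNode, ev: _Evaluator, params: PlannerParams, rng) -> None:
    """Evaluate all legal children of ``node``, prune those more than
    theta below the best sibling for the mover, attach the survivors."""
    mover = node.to_move
    nb, nw = node.black, node.white
    occ = nb | nw
    children = []
    noise = params.noise_sd
    for sq in range(N_SQUARES):
        bit = 1 << sq
        if occ & bit:
            continue
        if mover == BLACK:
            cb, cw = nb | bit, nw
            own_new = cb
        else:
            cb, cw = nb, nw | bit
            own_new = cw
        patb, patw = node.patb, node.patw
        win = False
        for li in LINES_THROUGH[sq]:
            mask = LINE_MASKS[li]
            if own_new & mask == mask:
                win = True
            if not (ev.drop_b >> li) & 1:
                patb += ev._line_w(li, cb, cw) - ev._line_w(li, nb, nw)
            if not (ev.drop_w >> li) & 1:
                patw += ev._line_w(li, cw, cb) - ev._line_w(li, nw, nb)
        if ev.per_state and ev.delta > 0:
            patb, patw = ev.random_pattern_sums(cb, cw, rng)
        cenb, cenw = node.cenb, node.cenw
        if mover == BLACK:
            cenb += CENTER_SCORE[sq]
        else:
            cenw += CENTER_SCORE[sq]
        child_to_move = WHITE if mover == BLACK else BLACK
        det = ev.deterministic_value(patb, patw, cenb, cenw, child_to_move)
        eps = noise * rng.standard_normal() if noise > 0 else 0.0
        if win:
            proven = _WIN_FOR[mover]
        elif (cb | cw) == FULL_MASK:
            proven = DRAW
        else:
            proven = None
        children.append(
            SearchNode(cb, cw, child_to_move, sq, patb, patw, cenb, cenw,
                       det, det + eps, proven)
        )
    # prune: keep children within theta of the best sibling for the mover
    vals = [c.value for c in children]
    if mover == BLACK:
        cut = max(vals) - params.theta
        kept = [c for c in children if c.value >= cut]
    else:
        cut = min(vals) + params.theta
        kept = [c for c in children if c.value <= cut]
    node.children = kept


def _backup(path: list[SearchNode], rng) -> None:
    """Recompute minimax values and closed/proven status bottom-up along
    the expansion path (root first)."""
    for node in reversed(path):
        if node.children is None:
            continue
        vals = [c.value for c in node.children]
        maximize = node.to_move == BLACK
        node.value = max(vals) if maximize else min(vals)
        bi = _best_index(vals, maximize, rng)
        best = node.children[bi]
        if all(c.closed for c in node.children):
            node.closed = True
            node.proven = best.proven
        elif best.closed and best.proven == _WIN_FOR[node.to_move]:
            # the line is decided: the mover has a proven win in hand
            node.closed = True
            node.proven = best.proven
        else:
            node.closed = False


def best_first_search(
    board: Board,
    params: PlannerParams,
    drop_mask: frozenset,
    rng: np.random.Generator,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
) -> SearchNode:
    """Build a partial decision tree by best-first search; returns the root.

    Each iteration follows the current principal variation to its leaf
    (restricted to unclosed children so closed lines are not re-expanded),
    expands it (unless terminal, which closes the line), backs minimax
    values up to the root, and stops with probability gamma, when the
    root is closed, or at the iteration cap.
    """
    if is_terminal(board):
        raise ValueError("cannot search from a terminal board")
    ev = _Evaluator(params, drop_mask)
    root = _make_root(board, ev, params, rng)
    for it in range(max_iterations):
        # descend the PV through unclosed children
        path = [root]
        node = root
        while node.children is not None:
            open_children = [c for c in node.children if not c.closed]
            vals = [c.value for c in open_children]
            node = open_children[_best_index(vals, node.to_move == BLACK, rng)]
            path.append(node)
        if node.proven is None:
            _expand(node, ev, params, rng)
        else:
            node.closed = True  # terminal PV leaf: close the line
        _backup(path, rng)
        if root.closed:
            break
        if rng.random() < params.gamma:
            break
    else:
        logger.warning("best-first search hit the iteration cap (%d)", max_iterations)
    return root


def principal_variation(root: SearchNode, rng: np.random.Generator) -> list[int]:
    """The greedy highest-value move path from the root (both players),
    ending at an unexpanded or terminal node. Ties uniform at random."""
    if root.children is None:
        raise ValueError("root has not been expanded")
    pv = []
    node = root
    while node.children:
        vals = [c.value for c in node.children]
        node = node.children[_best_index(vals, node.to_move == BLACK, rng)]
        pv.append(node.move)
    return pv


def choose_move(
    board: Board,
    params: PlannerParams,
    rng: np.random.Generator,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
) -> Move:
    """Sample one move: lapse uniformly with probability lapse, otherwise
    draw a drop mask, run best-first search, and play the root child with
    the best backed-up value for the mover (ties uniform)."""
    if is_terminal(board):
        raise ValueError("cannot move on a terminal board")
    occ = board.occupied
    empties = [sq for sq in range(N_SQUARES) if not occ & (1 << sq)]
    if params.lapse > 0 and rng.random() < params.lapse:
        return Move(int(rng.choice(empties)))
    drop_mask = sample_drop_mask(board, params, rng)
    root = best_first_search(board, params, drop_mask, rng, max_iterations)
    vals = [c.value for c in root.children]
    best = root.children[_best_index(vals, board.to_move == BLACK, rng)]
    return Move(best.move)
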