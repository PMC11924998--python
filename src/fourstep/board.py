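"""Four-in-a-Row game state, rules, and heuristic feature extraction.

The game is played on a 4x9 grid. Two players (black moves first)
alternately place a piece of their color on an empty square; the first
player to complete a line of four (horizontal, vertical, or diagonal)
wins, and a full board with no such line is a draw.

Boards are represented as a pair of 36-bit occupancy masks, one per
color, with square id ``9*row + col`` (row-major, 0-based). All 45
winning lines are precomputed, together with per-square line membership
used for incremental evaluation during tree search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

N_ROWS = 4
N_COLS = 9
N_SQUARES = N_ROWS * N_COLS

BLACK = 0
WHITE = 1

# Game outcome codes
ONGOING = "ongoing"
BLACK_WIN = "black_win"
WHITE_WIN = "white_win"
DRAW = "draw"

FULL_MASK = (1 << N_SQUARES) - 1

_COLOR_CHARS = {BLACK: "b", WHITE: "w"}
_CHAR_COLORS = {"b": BLACK, "w": WHITE}


def square_id(row: int, col: int) -> int:
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise ValueError(f"square ({row},{col}) off the 4x9 board")
    return N_COLS * row + col


def _generate_lines() -> list[tuple[int, int, int, int]]:
    lines = []
    # horizontal: 4 rows x 6 starting columns
    for r in range(N_ROWS):
        for c in range(N_COLS - 3):
            lines.append(tuple(N_COLS * r + c + i for i in range(4)))
    # vertical: 9 columns (board is exactly 4 rows tall)
    for c in range(N_COLS):
        lines.append(tuple(N_COLS * i + c for i in range(4)))
    # diagonal, down-right
    for c in range(N_COLS - 3):
        lines.append(tuple(N_COLS * i + c + i for i in range(4)))
    # diagonal, up-right
    for c in range(N_COLS - 3):
        lines.append(tuple(N_COLS * (3 - i) + c + i for i in range(4)))
    return lines


def enumerate_lines() -> list[tuple[int, int, int, int]]:
    """All 45 four-square lines of the board, in a fixed canonical order.

    Order: 24 horizontal (by row then start column), 9 vertical (by
    column), 6 down-right diagonals, 6 up-right diagonals.
    """
    return list(LINES)


LINES: tuple[tuple[int, int, int, int], ...] = tuple(_generate_lines())
N_LINES = len(LINES)  # 45

LINE_MASKS: tuple[int, ...] = tuple(
    sum(1 << sq for sq in line) for line in LINES
)

# For connected-two detection: the three masks of consecutive square
# pairs within each line (positions 01, 12, 23 of the ordered 4-tuple).
_CONN_PAIR_SETS: tuple[frozenset, ...] = tuple(
    frozenset(
        (1 << line[i]) | (1 << line[i + 1]) for i in range(3)
    )
    for line in LINES
)

# line indices through each square (used for incremental updates)
LINES_THROUGH: tuple[tuple[int, ...], ...] = tuple(
    tuple(i for i, line in enumerate(LINES) if sq in line)
    for sq in range(N_SQUARES)
)

# Center-proximity score per square: 1 / (1 + Euclidean distance to the
# board centroid at (row 1.5, col 4.0)).
_CENTROID = (1.5, 4.0)
CENTER_SCORE: tuple[float, ...] = tuple(
    1.0
    / (
        1.0
        + math.hypot(sq // N_COLS - _CENTROID[0], sq % N_COLS - _CENTROID[1])
    )
    for sq in range(N_SQUARES)
)


@dataclass(frozen=True)
class Move:
    """Placement of the side to move onto an empty square (id 0-35)."""

    square: int

    def __post_init__(self):
        if not (0 <= self.square < N_SQUARES):
            raise ValueError(f"square id {self.square} out of range 0-35")


@dataclass(frozen=True)
class Board:
    """Immutable 4x9 board: per-color occupancy bitmasks.

    Black always moves first, so the side to move is derivable from the
    piece counts: black to move iff the counts are equal.
    """

    black: int = 0
    white: int = 0

    def __post_init__(self):
        if self.black & self.white:
            raise ValueError("overlapping black and white pieces")
        if (self.black | self.white) & ~FULL_MASK:
            raise ValueError("piece outside the 4x9 board")
        nb, nw = self.black.bit_count(), self.white.bit_count()
        if nb - nw not in (0, 1):
            raise ValueError(
                f"illegal piece counts (black={nb}, white={nw}); "
                "black moves first"
            )

    @property
    def to_move(self) -> int:
        return BLACK if self.black.bit_count() == self.white.bit_count() else WHITE

    @property
    def occupied(self) -> int:
        return self.black | self.white

    def n_empty(self) -> int:
        return N_SQUARES - self.occupied.bit_count()

    def mask(self, color: int) -> int:
        return self.black if color == BLACK else self.white

    def piece_at(self, sq: int):
        bit = 1 << sq
        if self.black & bit:
            return BLACK
        if self.white & bit:
            return WHITE
        return None

    # -- serialization -------------------------------------------------
    def to_string(self) -> str:
        """36 chars over ``.bw`` (row-major) plus the to-move char."""
        cells = []
        for sq in range(N_SQUARES):
            p = self.piece_at(sq)
            cells.append("." if p is None else _COLOR_CHARS[p])
        return "".join(cells) + _COLOR_CHARS[self.to_move]

    @classmethod
    def from_string(cls, s: str) -> "Board":
        s = s.strip()
        if len(s) not in (N_SQUARES, N_SQUARES + 1):
            raise ValueError(f"board string must have 36(+1) chars, got {len(s)}")
        black = white = 0
        for sq, ch in enumerate(s[:N_SQUARES]):
            if ch == "b":
                black |= 1 << sq
            elif ch == "w":
                white |= 1 << sq
            elif ch != ".":
                raise ValueError(f"bad board char {ch!r} at square {sq}")
        board = cls(black, white)
        if len(s) == N_SQUARES + 1:
            declared = _CHAR_COLORS.get(s[-1])
            if declared is None:
                raise ValueError(f"bad to-move char {s[-1]!r}")
            if declared != board.to_move:
                raise ValueError("declared side to move contradicts piece counts")
        return board

    @classmethod
    def from_moves(cls, squares: Iterable[int]) -> "Board":
        """Replay a move list from the empty board (alternating colors)."""
        board = cls()
        for sq in squares:
            board = apply_move(board, Move(sq))
        return board

    def mirror(self) -> "Board":
        """Left-right mirror of the board (column c -> 8 - c)."""
        black = white = 0
        for sq in range(N_SQUARES):
            tgt = N_COLS * (sq // N_COLS) + (N_COLS - 1 - (sq % N_COLS))
            if self.black & (1 << sq):
                black |= 1 << tgt
            if self.white & (1 << sq):
                white |= 1 << tgt
        return Board(black, white)


@dataclass(frozen=True)
class FeatureCounts:
    """Per-color heuristic feature instance counts plus center scores.

    ``n_2conn``/``n_2unc``/``n_3``/``n_4`` count (line, color) instances
    over the 45 lines; ``center`` is the summed per-piece center
    proximity for that color.
    """

    n_2conn: tuple[int, int]
    n_2unc: tuple[int, int]
    n_3: tuple[int, int]
    n_4: tuple[int, int]
    center: tuple[float, float]


def game_outcome(board: Board) -> str:
    """Scan all 45 lines; win for the first color with a complete line,
    draw iff the board is full with no such line, else ongoing."""
    for mask in LINE_MASKS:
        if board.black & mask == mask:
            return BLACK_WIN
        if board.white & mask == mask:
            return WHITE_WIN
    if board.occupied == FULL_MASK:
        return DRAW
    return ONGOING


def is_terminal(board: Board) -> bool:
    return game_outcome(board) is not ONGOING


def legal_moves(board: Board) -> list[Move]:
    """Empty squares in ascending square-id order; errors on a terminal
    board (no move may be played once the game has ended)."""
    if is_terminal(board):
        raise ValueError("no legal moves: board is terminal")
    occ = board.occupied
    return [Move(sq) for sq in range(N_SQUARES) if not occ & (1 << sq)]


def apply_move(board: Board, move: Move) -> Board:
    bit = 1 << move.square
    if board.occupied & bit:
        raise ValueError(f"square {move.square} is occupied")
    if is_terminal(board):
        raise ValueError("cannot move on a terminal board")
    if board.to_move == BLACK:
        return Board(board.black | bit, board.white)
    return Board(board.black, board.white | bit)


def _classify_line(own: int, opp: int, line_idx: int) -> str | None:
    """Feature type of one (line, color) combination, or None.

    A line contributes only if it contains no opponent pieces: 4 own ->
    four-in-a-row, 3 own -> three-in-a-row, 2 own -> connected if the two
    pieces are consecutive within the line, else unconnected.
    """
    mask = LINE_MASKS[line_idx]
    if opp & mask:
        return None
    lb = own & mask
    n = lb.bit_count()
    if n == 4:
        return "n_4"
    if n == 3:
        return "n_3"
    if n == 2:
        return "n_2conn" if lb in _CONN_PAIR_SETS[line_idx] else "n_2unc"
    return None


def feature_instances(board: Board) -> list[tuple[int, int]]:
    """All (line_idx, color) pattern-feature instances present on the board."""
    out = []
    for li in range(N_LINES):
        if _classify_line(board.black, board.white, li) is not None:
            out.append((li, BLACK))
        if _classify_line(board.white, board.black, li) is not None:
            out.append((li, WHITE))
    return out


def count_features(board: Board, dropped: frozenset = frozenset()) -> FeatureCounts:
    """Count feature instances per color, excluding dropped (line, color)
    instances, and accumulate per-color center-proximity scores."""
    counts = {k: [0, 0] for k in ("n_2conn", "n_2unc", "n_3", "n_4")}
    for li in range(N_LINES):
        for color, own, opp in (
            (BLACK, board.black, board.white),
            (WHITE, board.white, board.black),
        ):
            if (li, color) in dropped:
                continue
            kind = _classify_line(own, opp, li)
            if kind is not None:
                counts[kind][color] += 1
    center = [0.0, 0.0]
    for sq in range(N_SQUARES):
        p = board.piece_at(sq)
        if p is not None:
            center[p] += CENTER_SCORE[sq]
    return FeatureCounts(
        n_2conn=tuple(counts["n_2conn"]),
        n_2unc=tuple(counts["n_2unc"]),
        n_3=tuple(counts["n_3"]),
        n_4=tuple(counts["n_4"]),
        center=tuple(center),
    )


@dataclass
class GameRecord:
    """One complete game: the participant's color, the full move list
    from the empty board, the opponent category faced, and the outcome.

    Replaying ``moves`` from the empty board must reproduce ``outcome``.
    """

    subject_id: str
    participant_color: int
    moves: list[int]
    opponent_category: int
    outcome: str

    def replay(self) -> Board:
        """Replay and validate; returns the final board."""
        board = Board()
        for ply, sq in enumerate(self.moves):
            try:
                board = apply_move(board, Move(sq))
            except ValueError as e:
                raise ValueError(f"illegal move at ply {ply}: {e}") from e
        if game_outcome(board) != self.outcome:
            raise ValueError(
                f"replayed outcome {game_outcome(board)} != recorded {self.outcome}"
            )
        return board

    def participant_boards_and_moves(self) -> list[tuple[Board, Move]]:
        """(board, chosen move) pairs for the participant's plies only."""
        out = []
        board = Board()
        for sq in self.moves:
            if board.to_move == self.participant_color:
                out.append((board, Move(sq)))
            board = apply_move(board, Move(sq))
        return out


def random_position(rng: np.random.Generator, n_pieces: int) -> Board:
    """A uniform random non-terminal position with ``n_pieces`` pieces.

    Rejection-samples piece placements with legal color counts until the
    position is ongoing. Used to build synthetic probe positions near the
    end of the game where exact solving is cheap; labelled synthetic, not
    drawn from human play.
    """
    if not 0 <= n_pieces < N_SQUARES:
        raise ValueError("n_pieces must be in [0, 35]")
    n_black = (n_pieces + 1) // 2
    while True:
        squares = rng.permutation(N_SQUARES)[:n_pieces]
        black = white = 0
        for i, sq in enumerate(squares):
            if i < n_black:
                black |= 1 << int(sq)
            else:
                white |= 1 << int(sq)
        board = Board(black, white)
        if game_outcome(board) is ONGOING:
            return board
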