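"""Heuristic evaluation, feature dropping, and best-first search."""

import numpy as np
import pytest
from scipy import stats as sps

from fourstep import _search_kernels as sk
from fourstep.board import BLACK, WHITE, Board, Move, apply_move, game_outcome, \
    feature_instances, random_position
from fourstep.planner import (
    PlannerParams,
    _Evaluator,
    _expand,
    _make_root,
    best_first_search,
    choose_move,
    heuristic_value,
    principal_variation,
    sample_drop_mask,
)


def kernel_choose(board, params, max_iter=200):
    return sk.choose_move_kernel(
        board.black, board.white, board.to_move, params.w_2conn,
        params.w_2unc, params.w_3, params.w_4, params.w_center, params.C,
        params.theta, params.gamma, params.delta, params.lapse,
        params.noise_sd, max_iter)


class TestHeuristicValue:
    def test_zero_weights_zero_noise_give_zero(self):
        params = PlannerParams(w_center=0, w_2conn=0, w_2unc=0, w_3=0, w_4=0,
                               noise_sd=0.0)
        assert heuristic_value(Board(), params) == 0.0

    def test_active_scaling_applies_to_mover(self):
        # one black connected-two, black to move, C = 2: V = C * w = 2
        board = Board((1 << 0) | (1 << 1), (1 << 27) | (1 << 28))
        params = PlannerParams(w_center=0, w_2conn=1, w_2unc=0, w_3=0, w_4=0,
                               C=2.0, noise_sd=0.0)
        fc = feature_instances(board)
        # white's pieces at 27, 28 also form a connected two: V = 2*1 - 1*1
        assert heuristic_value(board, params) == pytest.approx(2.0 - 1.0)

    def test_color_swap_with_mover_flip_negates_value(self, rng):
        # Eq-style antisymmetry: swapping colors and the side to move
        # negates the deterministic value; evaluated via the weighted
        # sums directly since the board type derives its mover from the
        # piece counts
        params = PlannerParams(noise_sd=0.0)
        ev = _Evaluator(params, frozenset())
        for _ in range(20):
            board = random_position(rng, 2 * int(rng.integers(0, 9)))
            pb, pw, cb, cw = ev.full_sums(board.black, board.white)
            qb, qw, db, dw = ev.full_sums(board.white, board.black)
            for mover in (BLACK, WHITE):
                v = ev.deterministic_value(pb, pw, cb, cw, mover)
                vs = ev.deterministic_value(qb, qw, db, dw, 1 - mover)
                assert v == pytest.approx(-vs)

    def test_out_of_range_params_rejected(self):
        with pytest.raises(ValueError):
            PlannerParams(delta=1.5)
        with pytest.raises(ValueError):
            PlannerParams(gamma=0.0)
        with pytest.raises(ValueError):
            PlannerParams(C=-1.0)
        with pytest.raises(ValueError):
            PlannerParams(w_3=-0.1)


class TestDropMask:
    def test_delta_zero_empty_delta_one_full(self, rng):
        board = Board.from_moves([0, 9, 1, 10, 2])
        assert sample_drop_mask(board, PlannerParams(delta=0.0), rng) == frozenset()
        full = sample_drop_mask(board, PlannerParams(delta=1.0), rng)
        assert full == frozenset(feature_instances(board))

    def test_drop_fraction_matches_delta(self, rng):
        board = Board.from_moves([0, 9, 1, 10, 2, 11])
        n_inst = len(feature_instances(board))
        delta = 0.3
        params = PlannerParams(delta=delta)
        n_draws = 4000
        dropped = sum(len(sample_drop_mask(board, params, rng))
                      for _ in range(n_draws))
        total = n_inst * n_draws
        se = np.sqrt(delta * (1 - delta) * total)
        assert abs(dropped - delta * total) < 3 * se


class TestSearch:
    def test_gamma_one_gives_single_expansion_and_pv_length_one(self, rng):
        params = PlannerParams(gamma=1.0)
        root = best_first_search(Board(), params, frozenset(), rng)
        assert root.children is not None
        assert all(c.children is None for c in root.children)
        assert len(principal_variation(root, rng)) == 1

    def test_theta_zero_without_noise_keeps_only_maximal_children(self, rng):
        params = PlannerParams(noise_sd=0.0, theta=0.0)
        board = Board.from_moves([13, 31])
        ev = _Evaluator(params, frozenset())
        root = _make_root(board, ev, params, rng)
        _expand(root, ev, params, rng)
        vals = [c.value for c in root.children]
        assert all(v == max(vals) for v in vals)

    def test_immediate_win_found(self, rng):
        # black: three in a row at 0,1,2; the winning move is square 3
        board = Board.from_moves([0, 27, 1, 28, 2, 29])
        params = PlannerParams(noise_sd=0.0, delta=0.0, lapse=0.0, w_4=50.0)
        for _ in range(10):
            root = best_first_search(board, params, frozenset(), rng)
            moves = [c.move for c in root.children]
            best = root.children[int(np.argmax([c.value for c in root.children]))]
            child = apply_move(board, Move(best.move))
            assert game_outcome(child) == "black_win"

    def test_terminal_root_rejected(self, rng):
        board = Board.from_moves([0, 9, 1, 10, 2, 11, 3])
        with pytest.raises(ValueError):
            best_first_search(board, PlannerParams(), frozenset(), rng)
        with pytest.raises(ValueError):
            choose_move(board, PlannerParams(), rng)

    def test_expected_iterations_scale_as_inverse_gamma(self, rng):
        # count expansions via PV length proxy: count iterations directly
        # by instrumenting through gamma: geometric stopping means the
        # mean number of stop draws is ~ 1/gamma; we check that the mean
        # PV length increases as gamma decreases and that for gamma=1 a
        # single iteration occurs (exact)
        params = PlannerParams(gamma=1.0)
        root = best_first_search(Board(), params, frozenset(), rng)
        assert len(principal_variation(root, rng)) == 1
        board = Board()
        lengths = {}
        for gamma in (0.8, 0.2):
            ls = []
            for _ in range(60):
                p = PlannerParams(gamma=gamma)
                root = best_first_search(board, p, frozenset(), rng)
                ls.append(len(principal_variation(root, rng)))
            lengths[gamma] = np.mean(ls)
        assert lengths[0.2] > lengths[0.8]

    def test_pv_length_never_exceeds_iterations(self, rng):
        params = PlannerParams(gamma=0.3)
        for _ in range(20):
            root = best_first_search(Board(), params, frozenset(), rng,
                                     max_iterations=15)
            assert 1 <= len(principal_variation(root, rng)) <= 15

    def test_unexpanded_root_pv_errors(self, rng):
        root = _make_root(Board(), _Evaluator(PlannerParams(), frozenset()),
                          PlannerParams(), rng)
        with pytest.raises(ValueError):
            principal_variation(root, rng)


class TestChooseMove:
    def test_lapse_one_is_uniform(self, rng):
        params = PlannerParams(lapse=1.0)
        counts = np.zeros(36)
        n = 7200
        for _ in range(n):
            counts[choose_move(Board(), params, rng).square] += 1
        chi2 = ((counts - n / 36) ** 2 / (n / 36)).sum()
        assert sps.chi2.sf(chi2, 35) > 0.01

    def test_single_legal_move_is_forced(self, rng):
        rows = ["bbwwbbwwb", "wwbbwwbbw", "bbwwbbwwb", "wwbbwwbb."]
        board = Board.from_string("".join(rows))
        assert choose_move(board, PlannerParams(), rng).square == 35

    def test_immediate_win_taken_with_strong_weight(self, rng):
        board = Board.from_moves([0, 27, 1, 28, 2, 29])
        params = PlannerParams(lapse=0.0, delta=0.0, w_4=50.0)
        wins = sum(choose_move(board, params, rng).square == 3
                   for _ in range(500))
        assert wins / 500 > 0.99

    def test_reproducible_given_seed(self):
        board = Board.from_moves([13, 31, 22])
        params = PlannerParams()
        a = [choose_move(board, params, np.random.default_rng(7)).square
             for _ in range(5)]
        b = [choose_move(board, params, np.random.default_rng(7)).square
             for _ in range(5)]
        assert a == b

    def test_full_drop_without_center_is_value_noise_only(self, rng):
        # under per-state dropping, delta=1 with w_center=0 removes every
        # deterministic term: each child value is an iid normal draw, so
        # the argmax is uniform over legal moves
        params = PlannerParams(delta=1.0, w_center=0.0, lapse=0.0, gamma=1.0,
                               drop_per_state=True)
        board = Board.from_moves([0, 9])
        n = 3400
        counts = np.zeros(36)
        for _ in range(n):
            counts[choose_move(board, params, rng).square] += 1
        live = [sq for sq in range(36) if board.piece_at(sq) is None]
        expected = n / len(live)
        chi2 = ((counts[live] - expected) ** 2 / expected).sum()
        assert sps.chi2.sf(chi2, len(live) - 1) > 0.01


class TestFastKernelEquivalence:
    """The numba move sampler implements the same generative policy."""

    def test_matches_reference_on_deterministic_boards(self, rng):
        params = PlannerParams(noise_sd=0.0, delta=0.0, gamma=1.0, lapse=0.0)
        sk.seed(99)
        for _ in range(20):
            board = random_position(rng, int(rng.integers(0, 12)))
            ev = _Evaluator(params, frozenset())
            root = _make_root(board, ev, params, rng)
            _expand(root, ev, params.replace(theta=0.0), rng)
            maximize = board.to_move == BLACK
            vals = [c.value for c in root.children]
            best = max(vals) if maximize else min(vals)
            optimal = {c.move for c in root.children if c.value == best}
            assert kernel_choose(board, params) in optimal
            assert choose_move(board, params, rng).square in optimal

    def test_choice_distributions_agree(self, rng):
        board = random_position(rng, 6)
        params = PlannerParams(lapse=0.1, delta=0.3, gamma=0.5)
        n = 3000
        sk.seed(17)
        ref = np.zeros(36)
        fast = np.zeros(36)
        for _ in range(n):
            ref[choose_move(board, params, rng).square] += 1
            fast[kernel_choose(board, params)] += 1
        live = (ref + fast) > 0
        table = np.vstack([ref[live] + 1, fast[live] + 1])
        p = sps.chi2_contingency(table).pvalue
        assert p > 0.001
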