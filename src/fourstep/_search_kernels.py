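"""Numba fast path for sampling planner moves.

``choose_move_kernel`` implements exactly the generative move policy of
:mod:`fourstep.planner` (lapse, root-level feature-instance dropping,
noisy best-first search with pruning, stochastic stopping and closed
winning lines, minimax backup, uniform tie-breaks) but works on flat
arrays and returns only the sampled move. It exists because inverse
binomial sampling needs millions of simulated moves per fit; the
object-tree implementation in ``planner`` remains the reference and the
two are held together by equivalence tests.

Randomness comes from numba's global legacy RNG; call :func:`seed` first
for reproducibility.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .board import (
    CENTER_SCORE,
    LINE_MASKS,
    LINES,
    LINES_THROUGH,
    N_SQUARES,
)

FULL = (1 << N_SQUARES) - 1

LINE_MASK_ARR = np.array(LINE_MASKS, dtype=np.int64)
CONN0 = np.array([(1 << l[0]) | (1 << l[1]) for l in LINES], dtype=np.int64)
CONN1 = np.array([(1 << l[1]) | (1 << l[2]) for l in LINES], dtype=np.int64)
CONN2 = np.array([(1 << l[2]) | (1 << l[3]) for l in LINES], dtype=np.int64)
LT_N = np.array([len(LINES_THROUGH[sq]) for sq in range(N_SQUARES)],
                dtype=np.int64)
LT_IDX = np.zeros((N_SQUARES, int(LT_N.max())), dtype=np.int64)
for _sq in range(N_SQUARES):
    for _j, _li in enumerate(LINES_THROUGH[_sq]):
        LT_IDX[_sq, _j] = _li
CENTER_ARR = np.array(CENTER_SCORE, dtype=np.float64)

# proven codes
_P_NONE = -1
_P_BLACK = 0
_P_WHITE = 1
_P_DRAW = 2


@njit(cache=True)
def seed(s):
    np.random.seed(s)


@njit(cache=True)
def _popcount4(x):
    n = 0
    while x:
        x &= x - 1
        n += 1
    return n


@njit(cache=True)
def _line_w(li, own, opp, w2c, w2u, w3, w4):
    mask = LINE_MASK_ARR[li]
    if opp & mask:
        return 0.0
    lb = own & mask
    n = _popcount4(lb)
    if n < 2:
        return 0.0
    if n == 2:
        if lb == CONN0[li] or lb == CONN1[li] or lb == CONN2[li]:
            return w2c
        return w2u
    if n == 3:
        return w3
    return w4


@njit(cache=True)
def choose_move_kernel(black, white, to_move, w2c, w2u, w3, w4, wc, C,
                       theta, gamma, delta, lapse, noise_sd, max_iter):
    """Sample one move for the side to move; returns the square id."""
    occ = black | white
    # lapse: uniform random legal move
    n_empty = 0
    for sq in range(36):
        if not occ & (np.int64(1) << sq):
            n_empty += 1
    if lapse > 0.0 and np.random.random() < lapse:
        pick = int(np.random.random() * n_empty)
        j = 0
        for sq in range(36):
            if not occ & (np.int64(1) << sq):
                if j == pick:
                    return sq
                j += 1
    # drop mask over root feature instances
    drop_b = np.int64(0)
    drop_w = np.int64(0)
    if delta > 0.0:
        for li in range(45):
            if _line_w(li, black, white, 1.0, 1.0, 1.0, 1.0) > 0.0:
                if np.random.random() < delta:
                    drop_b |= np.int64(1) << li
            if _line_w(li, white, black, 1.0, 1.0, 1.0, 1.0) > 0.0:
                if np.random.random() < delta:
                    drop_w |= np.int64(1) << li

    cap_nodes = max_iter * 36 + 64
    nb = np.empty(cap_nodes, dtype=np.int64)
    nw = np.empty(cap_nodes, dtype=np.int64)
    ntm = np.empty(cap_nodes, dtype=np.int8)
    nmove = np.empty(cap_nodes, dtype=np.int8)
    nval = np.empty(cap_nodes, dtype=np.float64)
    npatb = np.empty(cap_nodes, dtype=np.float64)
    npatw = np.empty(cap_nodes, dtype=np.float64)
    ncenb = np.empty(cap_nodes, dtype=np.float64)
    ncenw = np.empty(cap_nodes, dtype=np.float64)
    nchild0 = np.full(cap_nodes, -1, dtype=np.int64)
    nnch = np.zeros(cap_nodes, dtype=np.int64)
    nclosed = np.zeros(cap_nodes, dtype=np.bool_)
    nproven = np.full(cap_nodes, _P_NONE, dtype=np.int8)

    # root full evaluation
    patb = 0.0
    patw = 0.0
    for li in range(45):
        if not (drop_b >> li) & 1:
            patb += _line_w(li, black, white, w2c, w2u, w3, w4)
        if not (drop_w >> li) & 1:
            patw += _line_w(li, white, black, w2c, w2u, w3, w4)
    cenb = 0.0
    cenw = 0.0
    for sq in range(36):
        bit = np.int64(1) << sq
        if black & bit:
            cenb += CENTER_ARR[sq]
        elif white & bit:
            cenw += CENTER_ARR[sq]
    cb = C if to_move == 0 else 1.0
    cw = C if to_move == 1 else 1.0
    det = wc * (cenb - cenw) + cb * patb - cw * patw
    nb[0] = black
    nw[0] = white
    ntm[0] = to_move
    nmove[0] = -1
    npatb[0] = patb
    npatw[0] = patw
    ncenb[0] = cenb
    ncenw[0] = cenw
    nval[0] = det + (noise_sd * np.random.standard_normal()
                     if noise_sd > 0.0 else 0.0)
    n_nodes = 1

    path = np.empty(64, dtype=np.int64)
    cand_val = np.empty(36, dtype=np.float64)
    cand_sq = np.empty(36, dtype=np.int64)
    cand_pb = np.empty(36, dtype=np.float64)
    cand_pw = np.empty(36, dtype=np.float64)
    cand_prov = np.empty(36, dtype=np.int8)

    for _ in range(max_iter):
        # descend the PV through open children
        node = 0
        depth = 0
        path[0] = 0
        while nchild0[node] >= 0:
            c0 = nchild0[node]
            nch = nnch[node]
            maximize = ntm[node] == 0
            best = -1
            bestv = 0.0
            ties = 0
            for c in range(c0, c0 + nch):
                if nclosed[c]:
                    continue
                v = nval[c]
                if best < 0 or (v > bestv if maximize else v < bestv):
                    best = c
                    bestv = v
                    ties = 1
                elif v == bestv:
                    ties += 1
                    if np.random.random() * ties < 1.0:
                        best = c
            node = best
            depth += 1
            path[depth] = node

        if nproven[node] != _P_NONE:
            nclosed[node] = True  # terminal PV leaf: close the line
        else:
            # expand: evaluate all legal children
            mover = ntm[node]
            pb0 = npatb[node]
            pw0 = npatw[node]
            b0 = nb[node]
            w0 = nw[node]
            occ0 = b0 | w0
            n_cand = 0
            for sq in range(36):
                bit = np.int64(1) << sq
                if occ0 & bit:
                    continue
                if mover == 0:
                    cbm = b0 | bit
                    cwm = w0
                    own_new = cbm
                else:
                    cbm = b0
                    cwm = w0 | bit
                    own_new = cwm
                patb = pb0
                patw = pw0
                win = False
                for j in range(LT_N[sq]):
                    li = LT_IDX[sq, j]
                    if own_new & LINE_MASK_ARR[li] == LINE_MASK_ARR[li]:
                        win = True
                    if not (drop_b >> li) & 1:
                        patb += (_line_w(li, cbm, cwm, w2c, w2u, w3, w4)
                                 - _line_w(li, b0, w0, w2c, w2u, w3, w4))
                    if not (drop_w >> li) & 1:
                        patw += (_line_w(li, cwm, cbm, w2c, w2u, w3, w4)
                                 - _line_w(li, w0, b0, w2c, w2u, w3, w4))
                child_tm = 1 - mover
                ccb = C if child_tm == 0 else 1.0
                ccw = C if child_tm == 1 else 1.0
                cenb_c = ncenb[node] + (CENTER_ARR[sq] if mover == 0 else 0.0)
                cenw_c = ncenw[node] + (CENTER_ARR[sq] if mover == 1 else 0.0)
                det = wc * (cenb_c - cenw_c) + ccb * patb - ccw * patw
                v = det + (noise_sd * np.random.standard_normal()
                           if noise_sd > 0.0 else 0.0)
                cand_val[n_cand] = v
                cand_sq[n_cand] = sq
                cand_pb[n_cand] = patb
                cand_pw[n_cand] = patw
                if win:
                    cand_prov[n_cand] = mover  # _P_BLACK/_P_WHITE == color
                elif (cbm | cwm) == FULL:
                    cand_prov[n_cand] = _P_DRAW
                else:
                    cand_prov[n_cand] = _P_NONE
                n_cand += 1
            # prune children below best sibling - theta for the mover
            if mover == 0:
                cut = cand_val[0]
                for c in range(1, n_cand):
                    if cand_val[c] > cut:
                        cut = cand_val[c]
                cut -= theta
            else:
                cut = cand_val[0]
                for c in range(1, n_cand):
                    if cand_val[c] < cut:
                        cut = cand_val[c]
                cut += theta
            c0 = n_nodes
            kept = 0
            for c in range(n_cand):
                keep = cand_val[c] >= cut if mover == 0 else cand_val[c] <= cut
                if not keep:
                    continue
                k = c0 + kept
                sq = cand_sq[c]
                bit = np.int64(1) << sq
                nb[k] = b0 | bit if mover == 0 else b0
                nw[k] = w0 if mover == 0 else w0 | bit
                ntm[k] = 1 - mover
                nmove[k] = sq
                nval[k] = cand_val[c]
                npatb[k] = cand_pb[c]
                npatw[k] = cand_pw[c]
                ncenb[k] = ncenb[node] + (CENTER_ARR[sq] if mover == 0 else 0.0)
                ncenw[k] = ncenw[node] + (CENTER_ARR[sq] if mover == 1 else 0.0)
                nchild0[k] = -1
                nnch[k] = 0
                nproven[k] = cand_prov[c]
                nclosed[k] = cand_prov[c] != _P_NONE
                kept += 1
            n_nodes += kept
            nchild0[node] = c0
            nnch[node] = kept

        # back up minimax values and closed status along the path
        for d in range(depth, -1, -1):
            m = path[d]
            if nchild0[m] < 0:
                continue
            c0 = nchild0[m]
            nch = nnch[m]
            maximize = ntm[m] == 0
            bestv = nval[c0]
            for c in range(c0 + 1, c0 + nch):
                v = nval[c]
                if (v > bestv) if maximize else (v < bestv):
                    bestv = v
            nval[m] = bestv
            # best child for closed/proven propagation (uniform ties)
            best = c0
            ties = 1
            for c in range(c0 + 1, c0 + nch):
                v = nval[c]
                if (v > nval[best]) if maximize else (v < nval[best]):
                    best = c
                    ties = 1
                elif v == nval[best]:
                    ties += 1
                    if np.random.random() * ties < 1.0:
                        best = c
            all_closed = True
            for c in range(c0, c0 + nch):
                if not nclosed[c]:
                    all_closed = False
                    break
            if all_closed:
                nclosed[m] = True
                nproven[m] = nproven[best]
            elif nclosed[best] and nproven[best] == ntm[m]:
                nclosed[m] = True
                nproven[m] = nproven[best]
            else:
                nclosed[m] = False
                nproven[m] = _P_NONE

        if nclosed[0]:
            break
        if np.random.random() < gamma:
            break

    # final choice among all root children for the root mover
    c0 = nchild0[0]
    nch = nnch[0]
    maximize = ntm[0] == 0
    best = c0
    ties = 1
    for c in range(c0 + 1, c0 + nch):
        v = nval[c]
        if (v > nval[best]) if maximize else (v < nval[best]):
            best = c
            ties = 1
        elif v == nval[best]:
            ties += 1
            if np.random.random() * ties < 1.0:
                best = c
    return int(nmove[best])
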