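"""Affine-gap global alignment core (Needleman-Wunsch/Gotoh).

Operates on a precomputed position-score matrix so the same DP serves both
residue-residue alignment (conservation checks) and profile-profile alignment
(progressive MSA). A gap of length k costs ``gap_open + k * gap_extend``.

Traceback is deterministic: on score ties the preference order is
match/mismatch column, then gap in sequence A (a ``-`` in A's row, consuming
B), then gap in sequence B. Predecessor-state ties follow the same order.
"""

from __future__ import annotations

import numpy as np

NEG_INF = -np.inf

# State / traceback codes.
DIAG, GAP_IN_A, GAP_IN_B = 0, 1, 2


def gotoh_align(
    score: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[list[tuple[int | None, int | None]], float]:
    """Optimal global affine-gap alignment over an (n, m) position-score matrix.

    Returns ``(path, score)`` where ``path`` is a list of aligned index pairs:
    ``(i, j)`` for a match column (0-based positions in A and B), ``(None, j)``
    for a gap in A, ``(i, None)`` for a gap in B.
    """
    score = np.asarray(score, dtype=float)
    n, m = score.shape
    go, ge = float(gap_open), float(gap_extend)

    # State matrices: M ends in a diagonal step, IA ends in a gap in A
    # (consumes B, moves j), IB ends in a gap in B (consumes A, moves i).
    M = np.full((n + 1, m + 1), NEG_INF)
    IA = np.full((n + 1, m + 1), NEG_INF)
    IB = np.full((n + 1, m + 1), NEG_INF)
    # Pointer matrices hold the predecessor state of each cell.
    ptr_M = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_IA = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_IB = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    j_idx = np.arange(1, m + 1)
    IA[0, 1:] = -(go + ge * j_idx)
    ptr_IA[0, 1:] = GAP_IN_A
    ptr_IA[0, 1] = DIAG
    i_idx = np.arange(1, n + 1)
    IB[1:, 0] = -(go + ge * i_idx)
    ptr_IB[1:, 0] = GAP_IN_B
    ptr_IB[1, 0] = DIAG

    for i in range(1, n + 1):
        pM, pIA, pIB = M[i - 1], IA[i - 1], IB[i - 1]
        prev_best = np.maximum(np.maximum(pM, pIA), pIB)
        # Predecessor-state of prev_best with preference M > IA > IB.
        prev_state = np.where(pM == prev_best, DIAG,
                              np.where(pIA == prev_best, GAP_IN_A, GAP_IN_B))

        M[i, 1:] = score[i - 1] + prev_best[:-1]
        ptr_M[i, 1:] = prev_state[:-1]

        open_ib = prev_best - go - ge
        ext_ib = pIB - ge
        # Column-type tie rule puts gap-in-A above gap-in-B, so when opening
        # and extension tie we take the opening (whose predecessor may be a
        # higher-preference state).
        take_open = open_ib >= ext_ib
        IB[i] = np.where(take_open, open_ib, ext_ib)
        ptr_IB[i] = np.where(take_open, prev_state, GAP_IN_B)
        IB[i, 0] = -(go + ge * i)
        ptr_IB[i, 0] = GAP_IN_B if i > 1 else DIAG

        # IA along j is a running max: IA[i,j] = max_{k<j}(base[k] - go -
        # (j-k)*ge) with base = max(M[i,·], IB[i,·]); substituting h[k] =
        # base[k] + k*ge - go turns it into a prefix maximum.
        base = np.maximum(M[i], IB[i])
        base_state = np.where(M[i] >= IB[i], DIAG, GAP_IN_B)
        h = base + ge * np.arange(m + 1) - go
        run = np.maximum.accumulate(h)
        # argmax of the prefix maximum, earliest index on ties (prefer the
        # longer-standing opening; deterministic).
        is_new_max = np.empty(m + 1, dtype=bool)
        is_new_max[0] = True
        is_new_max[1:] = h[1:] > run[:-1]
        run_arg = np.maximum.accumulate(np.where(is_new_max, np.arange(m + 1), 0))
        IA[i, 1:] = run[:-1] - ge * j_idx
        opener = run_arg[:-1]  # k index whose opening yields IA[i, j]
        ptr_IA[i, 1:] = np.where(opener == j_idx - 1, base_state[opener], GAP_IN_A)

    finals = (M[n, m], IA[n, m], IB[n, m])
    best = max(finals)
    state = DIAG if finals[0] == best else (GAP_IN_A if finals[1] == best else GAP_IN_B)

    path: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == DIAG:
            path.append((i - 1, j - 1))
            state = int(ptr_M[i, j])
            i, j = i - 1, j - 1
        elif state == GAP_IN_A:
            path.append((None, j - 1))
            state = int(ptr_IA[i, j])
            j -= 1
        else:
            path.append((i - 1, None))
            state = int(ptr_IB[i, j])
            i -= 1
    path.reverse()
    return path, float(best)
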