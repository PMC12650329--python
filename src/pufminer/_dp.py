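"""Generic affine-gap dynamic programming on a precomputed cell-score matrix.

Both the PSSM domain scanner and the profile–profile steps of the progressive
aligner reduce to the same problem: given a matrix ``S`` where ``S[i, j]`` is
the score for pairing row item ``i`` with column item ``j``, find the optimal
global or local alignment path under affine gap costs (a gap of length ``k``
costs ``gap_open + k * gap_extend``).

The forward pass is vectorised row by row; the horizontal gap state is
resolved with a running-maximum identity, so the sweep is O(n·m) numpy work.
Traceback re-derives each step from the stored state matrices with a fixed
preference order (match > vertical gap > horizontal gap), which makes the
reported path deterministic.
"""

from __future__ import annotations

import numpy as np

NEG = -1e30  # effectively -infinity without NaN arithmetic
_TOL = 1e-6


def affine_dp(S: np.ndarray, gap_open: float, gap_extend: float,
              mode: str = "global") -> tuple[float, list[tuple[int | None, int | None]]]:
    """Align rows against columns of score matrix ``S``.

    Returns ``(score, path)`` where ``path`` is a list of
    ``(row_index, col_index)`` pairs (0-based); a ``None`` member denotes a
    gap in that dimension.  For ``mode='local'`` the path covers the best
    positive-scoring segment (empty path and score 0.0 if none exists).
    """
    if mode not in {"global", "local"}:
        raise ValueError(f"unknown mode {mode!r}")
    n, m = S.shape
    og = float(gap_open + gap_extend)  # cost of the first gap residue
    ge = float(gap_extend)
    local = mode == "local"

    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # vertical: consumes a row item
    Iy = np.full((n + 1, m + 1), NEG)  # horizontal: consumes a column item
    M[0, 0] = 0.0
    if local:
        M[0, :] = 0.0
        M[:, 0] = 0.0
    else:
        if m >= 1:
            Iy[0, 1:] = -og - ge * np.arange(m)
        if n >= 1:
            Ix[1:, 0] = -og - ge * np.arange(n)

    js = np.arange(m)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = S[i - 1] + prev_best[:-1]
        if local:
            np.maximum(M[i, 1:], 0.0, out=M[i, 1:])
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - og, Ix[i - 1, 1:] - ge)
        # Iy[i, j] = max_{k < j} M[i, k] - og - (j-1-k)*ge, via a running max;
        # only M opens a horizontal gap (Gotoh three-state recurrence)
        base = M[i, :-1]
        run = np.maximum.accumulate(base + ge * js)
        Iy[i, 1:] = np.maximum(Iy[i, 1:], run - og - ge * js)

    if local:
        flat = int(np.argmax(M))
        ei, ej = divmod(flat, m + 1)
        best = float(M[ei, ej])
        if best <= 0:
            return 0.0, []
        state = "M"
    else:
        ei, ej = n, m
        cands = (M[ei, ej], Ix[ei, ej], Iy[ei, ej])
        best = float(max(cands))
        state = ("M", "Ix", "Iy")[int(np.argmax(cands))]

    path: list[tuple[int | None, int | None]] = []
    i, j = ei, ej
    while True:
        if local and state == "M" and M[i, j] <= 0:
            break
        if i == 0 and j == 0:
            break
        if state == "M":
            path.append((i - 1, j - 1))
            prev = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if local and (i == 0 or j == 0 or abs(prev) <= _TOL):
                if abs(prev) <= _TOL:
                    break
            if i == 0 and j == 0:
                break
            if i == 0:
                state = "Iy"
            elif j == 0:
                state = "Ix"
            elif abs(M[i, j] - prev) <= _TOL:
                state = "M"
            elif abs(Ix[i, j] - prev) <= _TOL:
                state = "Ix"
            elif abs(Iy[i, j] - prev) <= _TOL:
                state = "Iy"
            elif local and prev <= _TOL:
                break
            else:  # numerical fallback: take the closest predecessor
                diffs = [abs(M[i, j] - prev), abs(Ix[i, j] - prev), abs(Iy[i, j] - prev)]
                state = ("M", "Ix", "Iy")[int(np.argmin(diffs))]
        elif state == "Ix":
            path.append((i - 1, None))
            val = Ix[i, j]
            i -= 1
            if abs(M[i, j] - og - val) <= _TOL or (not local and i == 0 and j == 0):
                state = "M"
            elif abs(Ix[i, j] - ge - val) <= _TOL:
                state = "Ix"
            elif i == 0 and j == 0:
                state = "M"
            else:
                state = "M" if abs(M[i, j] - og - val) < abs(Ix[i, j] - ge - val) else "Ix"
        else:  # Iy
            path.append((None, j - 1))
            val = Iy[i, j]
            j -= 1
            if abs(M[i, j] - og - val) <= _TOL or (not local and i == 0 and j == 0):
                state = "M"
            elif abs(Iy[i, j] - ge - val) <= _TOL:
                state = "Iy"
            else:
                state = "M" if abs(M[i, j] - og - val) < abs(Iy[i, j] - ge - val) else "Iy"
    path.reverse()
    return best, path
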