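"""Independent brute-force oracles used by the tests.

These deliberately avoid dynamic programming and the package's own code
paths: alignment scores are found by exhaustive enumeration of alignment
move sequences, local alignment by enumeration over all substring pairs,
and redundancy removal by directly replaying the stated rule.
"""

from __future__ import annotations

import math


def score_fn_blosum():
    from Bio.Align import substitution_matrices
    m = substitution_matrices.load("BLOSUM62")
    return lambda x, y: float(m[x][y])


def brute_global(a: str, b: str, pair_score, gap_open=11.0, gap_extend=1.0) -> float:
    """Best global affine-gap score by exhaustive path enumeration."""
    og = gap_open + gap_extend
    best = -math.inf

    def rec(i, j, prev, acc):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, acc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", acc + pair_score(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "X", acc - (gap_extend if prev == "X" else og))
        if j < len(b):
            rec(i, j + 1, "Y", acc - (gap_extend if prev == "Y" else og))

    rec(0, 0, None, 0.0)
    return best


def brute_local(a: str, b: str, pair_score, gap_open=11.0, gap_extend=1.0) -> float:
    """Best local score = best global score over all substring pairs
    (empty alignment scores 0)."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = brute_global(a[i1:i2], b[j1:j2], pair_score,
                                     gap_open, gap_extend)
                    best = max(best, s)
    return best


def replay_redundancy(rows: dict, threshold: float = 0.95) -> list:
    """Directly replay the redundancy rule on an alignment: scan pairs in
    row order, drop the row with fewer residues (ties: lexicographically
    later id) whenever aligned-positions identity exceeds the threshold;
    restart until a clean pass."""
    ids = list(rows)

    def ident(x, y):
        both = [(p, q) for p, q in zip(rows[x], rows[y])
                if p != "-" and q != "-"]
        return (sum(1 for p, q in both if p == q) / len(both)) if both else 0.0

    def ungapped(x):
        return sum(1 for c in rows[x] if c != "-")

    changed = True
    while changed:
        changed = False
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                if ident(a, b) > threshold:
                    la, lb = ungapped(a), ungapped(b)
                    drop = a if (la < lb or (la == lb and a > b)) else b
                    ids.remove(drop)
                    changed = True
                    break
            if changed:
                break
    return ids


def expected_pairwise_identity(branch: float) -> float:
    """Closed form for two leaves each at distance ``branch`` from their
    ancestor under the uniform replacement model."""
    p = 1.0 - math.exp(-branch)
    return (1 - p) ** 2 + p ** 2 / 19.0
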