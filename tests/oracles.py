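"""Independent brute-force oracles used only by the test suite.

These are deliberately naive re-derivations (quadratic dynamic
programming, exhaustive enumeration) kept separate from the package so
they can arbitrate its fast implementations.
"""

from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices

NEG_INF = float("-inf")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def substitution_score(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def local_score_oracle(query: str, subject: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Smith-Waterman affine-gap optimal local score by plain Gotoh DP.

    A gap of length L costs gap_open + L * gap_extend.
    """
    n, m = len(query), len(subject)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in subject
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in query
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(H[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend)
            Y[i][j] = max(H[i][j - 1] - gap_open - gap_extend, Y[i][j - 1] - gap_extend)
            diag = H[i - 1][j - 1] + substitution_score(query[i - 1], subject[j - 1])
            H[i][j] = max(0.0, diag, X[i][j], Y[i][j])
            best = max(best, H[i][j])
    return best


def global_score_oracle(query: str, subject: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Needleman-Wunsch affine-gap optimal global score (end gaps penalised)."""
    n, m = len(query), len(subject)
    H = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - i * gap_extend
        H[i][0] = X[i][0]
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - j * gap_extend
        H[0][j] = Y[0][j]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(H[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend)
            Y[i][j] = max(H[i][j - 1] - gap_open - gap_extend, Y[i][j - 1] - gap_extend)
            diag = H[i - 1][j - 1] + substitution_score(query[i - 1], subject[j - 1])
            H[i][j] = max(diag, X[i][j], Y[i][j])
    return H[n][m]


def auc_oracle(scores, labels) -> float:
    """AUC by exhaustive positive/negative pair enumeration."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def ranksum_exact_p_oracle(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all rank assignments.

    Assumes no ties.  The two-sided p doubles the smaller tail of the
    Mann-Whitney U distribution (clipped at 1), matching the exact-mode
    convention of the rank-sum test.
    """
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    all_ranks = range(1, len(pooled) + 1)
    for combo in itertools.combinations(all_ranks, n1):
        us.append(sum(combo) - n1 * (n1 + 1) / 2)
    n_total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / n_total
    p_ge = sum(1 for u in us if u >= u_obs) / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))


def conservation_scores_oracle(seqs: dict[str, str]) -> dict[str, float]:
    """Column-by-column hand enumeration of the conservation statistic."""
    ids = list(seqs)
    width = len(next(iter(seqs.values())))
    n = len(ids)
    out = {}
    for sid in ids:
        values = []
        for col in range(width):
            res = seqs[sid][col]
            if res == "-":
                continue
            count = sum(1 for other in ids if seqs[other][col] == res)
            values.append(count / n)
        out[sid] = sum(values) / len(values)
    return out


def global_identity_oracle(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Percent identity of an optimal global alignment, by full traceback DP.

    Among score-optimal alignments the identity may differ; this oracle
    returns the identity of the alignment maximising (score, identities)
    lexicographically, which is enough for the unambiguous cases the
    tests use.
    """
    n, m = len(a), len(b)
    # state: (score, identities); combine lexicographically
    def better(p, q):
        return p if p >= q else q

    H = [[(NEG_INF, 0)] * (m + 1) for _ in range(n + 1)]
    X = [[(NEG_INF, 0)] * (m + 1) for _ in range(n + 1)]
    Y = [[(NEG_INF, 0)] * (m + 1) for _ in range(n + 1)]
    L = [[0] * (m + 1) for _ in range(n + 1)]  # alignment columns, greedy per cell
    H[0][0] = (0.0, 0)
    for i in range(1, n + 1):
        X[i][0] = (-gap_open - i * gap_extend, 0)
        H[i][0] = X[i][0]
        L[i][0] = i
    for j in range(1, m + 1):
        Y[0][j] = (-gap_open - j * gap_extend, 0)
        H[0][j] = Y[0][j]
        L[0][j] = j
    cols = {}
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = better(
                (H[i - 1][j][0] - gap_open - gap_extend, H[i - 1][j][1]),
                (X[i - 1][j][0] - gap_extend, X[i - 1][j][1]),
            )
            Y[i][j] = better(
                (H[i][j - 1][0] - gap_open - gap_extend, H[i][j - 1][1]),
                (Y[i][j - 1][0] - gap_extend, Y[i][j - 1][1]),
            )
            match = int(a[i - 1] == b[j - 1])
            diag = (H[i - 1][j - 1][0] + substitution_score(a[i - 1], b[j - 1]),
                    H[i - 1][j - 1][1] + match)
            H[i][j] = better(diag, better(X[i][j], Y[i][j]))
    # column count via traceback on H with the same preference
    i, j, columns = n, m, 0
    while i > 0 or j > 0:
        columns += 1
        if i > 0 and j > 0:
            match = int(a[i - 1] == b[j - 1])
            diag = (H[i - 1][j - 1][0] + substitution_score(a[i - 1], b[j - 1]),
                    H[i - 1][j - 1][1] + match)
            if H[i][j] == diag:
                i, j = i - 1, j - 1
                continue
        if i > 0 and H[i][j] == X[i][j]:
            i -= 1
            continue
        j -= 1
    return 100.0 * H[n][m][1] / columns


def pearson_oracle(x, y) -> float:
    """Textbook sum-formula Pearson correlation."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den
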