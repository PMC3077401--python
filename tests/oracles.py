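"""Independent brute-force oracles used by the test suite.

Each oracle restates a contract from first principles (full enumeration or
textbook dynamic programming) without sharing code with the implementation
it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np

_EPS = 1e-9


def oracle_repeat_pairs(seq: str, min_len=12, frac=0.1, min_sep=50):
    """All maximal valid repeat-pair windows by full enumeration.

    A window (a, b) on diagonal d is valid when b - a >= min_len and the
    Hamming mismatches between s[a:b] and s[a+d:b+d] are <= frac*(b-a);
    maximal when no other valid window contains both of its copies; reported
    when the copy gap d - (b - a) >= min_sep. Returns a sorted list of
    (left, right, length, identity) tuples.
    """
    n = len(seq)
    if n < 2 * min_len + min_sep:
        return []
    arr = np.frombuffer(seq.encode(), np.uint8)
    cands = []
    for d in range(1, n - min_len + 1):
        mismatch = arr[:-d] != arr[d:]
        prefix = np.concatenate([[0], np.cumsum(mismatch)])
        diag_len = n - d
        idx = np.arange(diag_len + 1)
        length = idx[None, :] - idx[:, None]
        mism = prefix[None, :] - prefix[:, None]
        valid = (length >= min_len) & (mism <= frac * length + _EPS)
        max_b = -1
        for a in range(diag_len - min_len + 1):
            bs = np.nonzero(valid[a])[0]
            if bs.size == 0:
                continue
            b = int(bs[-1])  # longest valid window from a; shorter ones are contained
            if b <= max_b:  # contained in an earlier window on this diagonal
                continue
            max_b = b
            cands.append((a, b, d, int(prefix[b] - prefix[a])))

    def contains(p, q):
        pa, pb, pd, _ = p
        qa, qb, qd, _ = q
        return pa <= qa and qb <= pb and pa + pd <= qa + qd and qb + qd <= pb + pd

    out = []
    for p in cands:
        if any(q is not p and contains(q, p) and not contains(p, q) for q in cands):
            continue
        a, b, d, mm = p
        L = b - a
        if d - L < min_sep:
            continue
        out.append(((a, b), (a + d, b + d), L, (L - mm) / L))
    return sorted(out)


def oracle_tandem(seq: str, unit_range=(6, 60), min_copies=2, frac=0.1):
    """Best tandem run by a literal period/phase scan.

    Same contract as the detector: copies accepted while Hamming distance
    to the first copy stays within frac*unit; score = copies*unit; ties to
    the smallest unit, then leftmost. Returns (start, unit_len, copies) or
    None.
    """
    n = len(seq)
    best = None
    for u in range(unit_range[0], min(unit_range[1], n // max(min_copies, 1)) + 1):
        for i in range(n - u * min_copies + 1):
            first = seq[i : i + u]
            k = 1
            while i + (k + 1) * u <= n:
                nxt = seq[i + k * u : i + (k + 1) * u]
                if sum(a != b for a, b in zip(first, nxt)) > frac * u + _EPS:
                    break
                k += 1
            if k >= min_copies:
                key = (k * u, -u, -i)
                if best is None or key > best[0]:
                    best = (key, (i, u, k))
    return None if best is None else best[1]


def gotoh_global(a: str, b: str, match=1.0, mismatch=-1.0, open_=-2.0, extend=-0.5):
    """Affine-gap global alignment (Gotoh) with traceback.

    A gap of length L costs -(open_ + (L-1)*extend) with the sign convention
    that ``open_`` is the score of the first gapped position. Returns
    (score, identities, alignment_length) for one optimal alignment.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a aligned to -)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend, X[i][j - 1] + open_)
    i, j = n, m
    state = max((M[n][m], "M"), (X[n][m], "X"), (Y[n][m], "Y"))[1]
    score = max(M[n][m], X[n][m], Y[n][m])
    identities = 0
    length = 0
    while i > 0 or j > 0:
        length += 1
        if state == "M":
            s = match if a[i - 1] == b[j - 1] else mismatch
            if a[i - 1] == b[j - 1]:
                identities += 1
            prev = max(
                (M[i - 1][j - 1], "M"), (X[i - 1][j - 1], "X"), (Y[i - 1][j - 1], "Y")
            )[1]
            i, j = i - 1, j - 1
            state = prev
        elif state == "X":
            options = [
                (M[i - 1][j] + open_, "M"),
                (X[i - 1][j] + extend, "X"),
                (Y[i - 1][j] + open_, "Y"),
            ]
            prev = max(options)[1]
            i = i - 1
            state = prev
        else:
            options = [
                (M[i][j - 1] + open_, "M"),
                (Y[i][j - 1] + extend, "Y"),
                (X[i][j - 1] + open_, "X"),
            ]
            prev = max(options)[1]
            j = j - 1
            state = prev
    return score, identities, length


def brute_force_parsimony(tree, positions: dict[str, int]) -> int:
    """Minimum state changes by enumerating all internal-node assignments."""
    states = sorted(set(positions.values()))
    internal = [node for node in tree.traverse() if not node.is_tip()]
    edges = []
    index = {id(node): i for i, node in enumerate(internal)}
    for node in tree.traverse():
        if node.parent is None:
            continue
        edges.append((node, node.parent))
    best = None
    for assignment in product(states, repeat=len(internal)):
        def state_of(node):
            if node.is_tip():
                return positions[node.name]
            return assignment[index[id(node)]]

        changes = sum(1 for child, parent in edges if state_of(child) != state_of(parent))
        if best is None or changes < best:
            best = changes
    return best
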