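"""Direct-repeat pair and central tandem-repeat detection.

Direct-repeat pairs are the recombination substrates that delimit TRD
cassettes: two same-orientation, near-identical copies of a short sequence
(x/y/z classes, 14-53 bp in the systems modelled here) separated by at
least one cassette's worth of sequence.

The mismatch model is Hamming-only (no indels): repeat copies act as
recombination substrates and are modelled as near-identical. A window
(i, j, L) on diagonal d = j - i is *valid* when
hamming(s[i:i+L], s[j:j+L]) <= max_mismatch_frac * L and L >= min_len;
it is *maximal* when no other valid window contains it (both copies inside
the other pair's copies). The detector reports every maximal window whose
copy separation (gap) j - (i + L) is at least ``min_separation``: a maximal
run whose copies nearly abut is a tandem repeat and belongs to
:func:`find_tandem_repeat` instead.

Implementation is seed-and-extend with exact k=6 seeds. Any valid window
(L >= 12, mismatches <= floor(0.1 L)) contains an exact run of length
>= ceil((L - m)/(m + 1)) >= 6, so no valid window's diagonal escapes the
seeds; the contract is equality with the brute-force all-pairs oracle used
in tests.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Optional

import numpy as np

from .model import RepeatPair, TandemRepeat

_SEED_K = 6
_EPS = 1e-9


def _seed_diagonals(sequence: str) -> list[int]:
    kmer_pos: dict[str, list[int]] = defaultdict(list)
    for i in range(len(sequence) - _SEED_K + 1):
        kmer_pos[sequence[i : i + _SEED_K]].append(i)
    diagonals: set[int] = set()
    for positions in kmer_pos.values():
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                diagonals.add(positions[bi] - positions[ai])
    return sorted(diagonals)


def _maximal_windows_exact(match: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True >= min_len (zero-mismatch fast path)."""
    out = []
    n = len(match)
    i = 0
    while i < n:
        if match[i]:
            j = i
            while j < n and match[j]:
                j += 1
            if j - i >= min_len:
                out.append((i, j))
            i = j
        i += 1
    return out


def _maximal_windows_frac(
    match: np.ndarray, min_len: int, frac: float
) -> list[tuple[int, int]]:
    """Maximal valid windows on one diagonal under a mismatch fraction.

    Validity of (a, b): mismatches <= frac*(b-a) and b-a >= min_len, i.e.
    g(b) <= g(a) with g(x) = mism_prefix[x] - frac*x. For each a the largest
    valid b is taken; windows not extending past an earlier window's end are
    contained and skipped.
    """
    n = len(match)
    mism_prefix = np.concatenate([[0], np.cumsum(~match)])
    g = mism_prefix - frac * np.arange(n + 1)
    out: list[tuple[int, int]] = []
    max_prev_b = -1
    for a in range(n - min_len + 1):
        candidates = np.nonzero(g[a + min_len :] <= g[a] + _EPS)[0]
        if candidates.size == 0:
            continue
        b = a + min_len + int(candidates[-1])
        if b <= max_prev_b:
            continue
        out.append((a, b))
        max_prev_b = b
    return out


def find_direct_repeat_pairs(
    sequence: str,
    min_len: int = 12,
    max_mismatch_frac: float = 0.1,
    min_separation: int = 50,
) -> list[RepeatPair]:
    """All maximal same-orientation repeat pairs in ``sequence``.

    Returns pairs sorted by left start, then right start. Pairs whose copies
    are both contained in another maximal pair's copies are deduplicated
    away, and maximal windows whose copies are separated by less than
    ``min_separation`` (near-tandem runs) are not reported.
    """
    if min_len < 8:
        raise ValueError("min_len below the seed-length floor of 8")
    n = len(sequence)
    if n < 2 * min_len + min_separation:
        return []
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    exact = max_mismatch_frac * n < 1  # no budget for even one mismatch

    candidates: list[tuple[int, int, int, int]] = []  # (a, b, d, mismatches)
    for d in _seed_diagonals(sequence):
        if d < min_len:
            continue
        match = arr[:-d] == arr[d:]
        if exact:
            windows = _maximal_windows_exact(match, min_len)
        else:
            windows = _maximal_windows_frac(match, min_len, max_mismatch_frac)
        for a, b in windows:
            candidates.append((a, b, d, int(np.count_nonzero(~match[a:b]))))

    def _contains(p, q) -> bool:
        """Both of q's copies inside p's copies (p, q = (a, b, d) windows)."""
        pa, pb, pd, _ = p
        qa, qb, qd, _ = q
        return pa <= qa and qb <= pb and pa + pd <= qa + qd and qb + qd <= pb + pd

    # cross-diagonal containment deduplication (same-diagonal handled above),
    # then the separation filter
    kept: list[RepeatPair] = []
    for p in candidates:
        if any(q is not p and _contains(q, p) and not _contains(p, q) for q in candidates):
            continue
        a, b, d, mism = p
        L = b - a
        if d - L < min_separation:  # gap between copies
            continue
        kept.append(
            RepeatPair(
                left=(a, b),
                right=(a + d, b + d),
                length_bp=L,
                identity=(L - mism) / L,
            )
        )
    kept.sort(key=lambda p: (p.left[0], p.right[0]))
    return kept


def classify_repeat_pairs(pairs: list[RepeatPair], sequence: str) -> list[RepeatPair]:
    """Assign X/Y/Z classes to detected pairs by their interleaving pattern.

    The two-cassette layout interleaves the X and Y pairs as
    xL < yL < xR < yR (left copies flank TRD1, right copies flank TRD2).
    Among all interleaved candidate combinations the one maximizing total
    repeat length wins (then the outermost layout). A pair nested strictly
    between the right X copy and the right Y copy sits inside the TRD2
    region and is classed Z. Anything else stays unclassified.
    """
    pairs = [
        RepeatPair(p.left, p.right, p.length_bp, p.identity, class_name=None)
        for p in pairs
    ]
    best_combo: Optional[tuple[RepeatPair, RepeatPair]] = None
    best_score = None
    for p in pairs:
        for q in pairs:
            if p is q:
                continue
            if p.left[1] <= q.left[0] and q.left[1] <= p.right[0] and p.right[1] <= q.right[0]:
                score = (p.length_bp + q.length_bp, -p.left[0], q.right[1])
                if best_score is None or score > best_score:
                    best_score = score
                    best_combo = (p, q)
    if best_combo is not None:
        x_pair, y_pair = best_combo
        x_pair.class_name = "X"
        y_pair.class_name = "Y"
        lo, hi = x_pair.right[1], y_pair.right[0]
        for p in pairs:
            if p.class_name is None and lo <= p.left[0] and p.right[1] <= hi:
                p.class_name = "Z"
    elif len(pairs) == 1:
        # single pair spanning one cassette: left copy precedes the TRD -> X-like
        pairs[0].class_name = "X"
    return pairs


def find_tandem_repeat(
    sequence: str,
    unit_len_range: tuple[int, int] = (6, 60),
    min_copies: int = 2,
    max_mismatch_frac: float = 0.1,
) -> Optional[TandemRepeat]:
    """Highest-scoring tandem run, or None when nothing reaches ``min_copies``.

    A run at (start, unit length u) accepts successive complete units while
    each unit's Hamming distance to the first unit stays within
    ``max_mismatch_frac * u``. Score = copies x unit length; ties break to
    the smallest unit length, then the leftmost start. The reported unit is
    the per-column consensus of the accepted copies and copy_number counts
    complete units only.
    """
    lo, hi = unit_len_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid unit length range")
    n = len(sequence)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    best = None
    for u in range(lo, min(hi, n // max(min_copies, 1)) + 1):
        budget = max_mismatch_frac * u + _EPS
        # mismatch count of each complete u-window against the window one
        # period earlier is not what we need (drift); compare to the first copy
        for i in range(n - u * min_copies + 1):
            first = arr[i : i + u]
            k = 1
            while i + (k + 1) * u <= n:
                if np.count_nonzero(arr[i + k * u : i + (k + 1) * u] != first) > budget:
                    break
                k += 1
            if k >= min_copies:
                key = (k * u, -u, -i)  # max score, then smallest unit, leftmost
                if best is None or key > best[0]:
                    copies = [sequence[i + j * u : i + (j + 1) * u] for j in range(k)]
                    best = (
                        key,
                        TandemRepeat(
                            start=i,
                            end=i + k * u,
                            unit_sequence=_consensus(copies),
                            copy_number=k,
                        ),
                    )
    return None if best is None else best[1]


def _consensus(copies: list[str]) -> str:
    out = []
    for col in zip(*copies):
        counts: dict[str, int] = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        out.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(out)


def find_repeat_copies(
    sequence: str, repeat_seq: str, max_mismatch_frac: float = 0.0
) -> list[tuple[int, int]]:
    """All non-overlapping occurrences of ``repeat_seq`` (Hamming tolerance).

    Used to locate single repeat copies once a per-class consensus is known
    (deletion products carry one x and one y copy, which no within-gene pair
    detector can see). Greedy left-to-right; where candidates overlap the
    leftmost wins.
    """
    L = len(repeat_seq)
    if L == 0 or len(sequence) < L:
        return []
    budget = max_mismatch_frac * L + _EPS
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    rep = np.frombuffer(repeat_seq.encode(), dtype=np.uint8)
    if budget < 1:
        # exact search
        hits = []
        start = sequence.find(repeat_seq)
        while start != -1:
            hits.append(start)
            start = sequence.find(repeat_seq, start + 1)
    else:
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        mism = np.count_nonzero(windows != rep, axis=1)
        hits = [int(i) for i in np.nonzero(mism <= budget)[0]]
    out: list[tuple[int, int]] = []
    taken_until = -1
    for start in hits:
        if start > taken_until:
            out.append((start, start + L))
            taken_until = start + L - 1
    return out
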