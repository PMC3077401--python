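"""All-vs-all dotplot screen for candidate cross-position sharing.

A dotplot between two alleles is the set of maximal exact diagonal runs of
at least ``word_size`` bases (forward strand only). A run that lies inside
TRD slot i of one gene and slot j != i of the other flags the pair as a
domain-movement candidate — the automatable core of the published screen's
manual curation, fed to the event caller as corroborating evidence.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Optional, Sequence

from .model import GeneArchitecture

Segment = tuple[int, int, int]  # (start_a, start_b, length)


def dotplot(seq_a: str, seq_b: str, word_size: int = 10) -> set[Segment]:
    """Maximal exact diagonal runs >= word_size as (start_a, start_b, length).

    Self-comparison is allowed; the main diagonal is suppressed when the two
    sequences are identical.
    """
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    same = seq_a == seq_b
    words: dict[str, list[int]] = defaultdict(list)
    for j in range(len(seq_b) - word_size + 1):
        words[seq_b[j : j + word_size]].append(j)
    runs: set[Segment] = set()
    seen_diag_start: set[tuple[int, int]] = set()
    for i in range(len(seq_a) - word_size + 1):
        for j in words.get(seq_a[i : i + word_size], ()):
            d = i - j
            if same and d == 0:
                continue
            # extend the word match to a maximal run, dedupe per (diagonal, start)
            s_a, s_b = i, j
            while s_a > 0 and s_b > 0 and seq_a[s_a - 1] == seq_b[s_b - 1]:
                s_a -= 1
                s_b -= 1
            if (d, s_a) in seen_diag_start:
                continue
            seen_diag_start.add((d, s_a))
            e_a, e_b = i + word_size, j + word_size
            while e_a < len(seq_a) and e_b < len(seq_b) and seq_a[e_a] == seq_b[e_b]:
                e_a += 1
                e_b += 1
            runs.add((s_a, s_b, e_a - s_a))
    return runs


def _overlap(seg_start: int, seg_len: int, interval: tuple[int, int]) -> tuple[int, int]:
    lo = max(seg_start, interval[0])
    hi = min(seg_start + seg_len, interval[1])
    return lo, hi


def flag_candidates(
    dotplots: dict[tuple[str, str], set[Segment]],
    architectures: dict[str, GeneArchitecture],
    min_len: int = 50,
) -> list[tuple[tuple[str, str], Segment, str]]:
    """Cross-slot segments: candidate domain movements between allele pairs.

    ``dotplots`` maps (seq_id_a, seq_id_b) to segment sets. A candidate is
    flagged when >= min_len of a segment sits inside slot i of one gene and,
    at the same alignment offset, inside slot j != i of the other. Pairs
    lacking an architecture are skipped with a note.
    """
    flagged: list[tuple[tuple[str, str], Segment, str]] = []
    for (id_a, id_b), segments in sorted(dotplots.items()):
        arch_a: Optional[GeneArchitecture] = architectures.get(id_a)
        arch_b: Optional[GeneArchitecture] = architectures.get(id_b)
        if arch_a is None or arch_b is None:
            flagged.append(
                ((id_a, id_b), (-1, -1, 0), "skipped: architecture unavailable")
            )
            continue
        for seg in sorted(segments):
            start_a, start_b, length = seg
            for i, slot_a in enumerate(arch_a.trd_slots, start=1):
                lo_a, hi_a = _overlap(start_a, length, slot_a)
                if hi_a - lo_a < min_len:
                    continue
                for j, slot_b in enumerate(arch_b.trd_slots, start=1):
                    if i == j:
                        continue
                    # map the a-side overlap onto b coordinates (same offset)
                    shift = start_b - start_a
                    lo = max(lo_a, slot_b[0] - shift)
                    hi = min(hi_a, slot_b[1] - shift)
                    if hi - lo >= min_len:
                        flagged.append(
                            (
                                (id_a, id_b),
                                seg,
                                f"slots ({i},{j}): {hi - lo} bp shared across positions",
                            )
                        )
    return flagged


def family_dotplots(
    sequences: dict[str, str], word_size: int = 10
) -> dict[tuple[str, str], set[Segment]]:
    """All unordered pairs of distinct alleles."""
    ids = sorted(sequences)
    return {
        (a, b): dotplot(sequences[a], sequences[b], word_size)
        for idx, a in enumerate(ids)
        for b in ids[idx + 1 :]
    }


def render_dotplot_text(
    seq_a: str, seq_b: str, word_size: int = 10, width: int = 60
) -> str:
    """Coarse ASCII rendering of a dotplot (optional, for reports)."""
    segments = dotplot(seq_a, seq_b, word_size)
    h = max(1, round(width * len(seq_b) / max(len(seq_a), 1)))
    grid = [[" "] * width for _ in range(h)]
    for start_a, start_b, length in segments:
        for k in range(0, length, max(1, length // 40)):
            col = min(width - 1, (start_a + k) * width // max(len(seq_a), 1))
            row = min(h - 1, (start_b + k) * h // max(len(seq_b), 1))
            grid[row][col] = "*"
    return "\n".join("".join(row) for row in grid)
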