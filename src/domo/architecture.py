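"""Cassette architecture inference: segmenting alleles into TRD slots.

A TRD slot is the interval strictly between its flanking repeat copies (the
repeat bases belong to the repeat, not the domain). Recognized interleaving
patterns of repeat copies, as ordered class strings:

    X Y X Y          two TRDs; central region between left-Y end and right-X
    X Y X Z Z Y      two TRDs, z pair around TRD2 (three-pair layout)
    X Y X Z Z Z Y    three TRDs (duplication product: TRD1, TRD2, TRD2)
    X Y              one TRD (deletion product)
    X Z Z Y          one TRD with its z pair retained

Pair detection alone cannot segment every allele: a deletion product carries
a *single* x and y copy (nothing pairs within the gene), and an allele whose
two TRDs are identical merges its x and y pairs into one long repeat. The
family-level entry point therefore bootstraps a per-class consensus from
the alleles with clean pair patterns and then locates exact copies of those
consensus sequences in every allele.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

from .model import (
    GeneArchitecture,
    NoArchitectureError,
    RepeatCopy,
    RepeatPair,
    SGeneRecord,
    TandemRepeat,
    TRDInstance,
)
from .repeats import (
    classify_repeat_pairs,
    find_direct_repeat_pairs,
    find_repeat_copies,
    find_tandem_repeat,
)

# pattern -> (slot copy-index pairs, central copy-index pair or None)
_PATTERNS: dict[tuple[str, ...], tuple[list[tuple[int, int]], Optional[tuple[int, int]]]] = {
    ("X", "Y", "X", "Y"): ([(0, 1), (2, 3)], (1, 2)),
    ("X", "Y", "X", "Z", "Z", "Y"): ([(0, 1), (3, 4)], (1, 2)),
    ("X", "Y", "X", "Z", "Z", "Z", "Y"): ([(0, 1), (3, 4), (4, 5)], (1, 2)),
    ("X", "Y"): ([(0, 1)], None),
    ("X", "Z", "Z", "Y"): ([(1, 2)], None),
}


def _copies_from_pairs(pairs: Sequence[RepeatPair]) -> list[RepeatCopy]:
    copies = []
    for pair in pairs:
        if pair.class_name is None:
            continue
        for s, e in pair.copies:
            copies.append(RepeatCopy(pair.class_name, s, e))
    # same copy can back two pairs (three z copies yield three pairs)
    seen = set()
    out = []
    for c in sorted(copies, key=lambda c: (c.start, c.end)):
        if (c.start, c.end, c.class_name) not in seen:
            seen.add((c.start, c.end, c.class_name))
            out.append(c)
    return out


def infer_architecture(
    record: SGeneRecord,
    classified_pairs: Sequence[RepeatPair],
    tandem: Optional[TandemRepeat] = None,
    known_repeats: Optional[dict[str, str]] = None,
    copy_mismatch_frac: float = 0.0,
    tandem_mismatch_frac: float = 0.1,
) -> GeneArchitecture:
    """Segment one allele into its cassette architecture.

    Repeat copies come from ``known_repeats`` (class -> consensus sequence,
    located by scanning) when given, else from the classified pairs. The
    ordered class string of the copies must match a recognized pattern;
    otherwise :class:`NoArchitectureError` carries the pair list so the
    caller can fall back to the dotplot screen. The central tandem repeat is
    detected within the central interval when ``tandem`` is not supplied.
    """
    if known_repeats:
        copies = []
        for cls in ("X", "Y", "Z"):
            if cls in known_repeats and known_repeats[cls]:
                for s, e in find_repeat_copies(
                    record.sequence, known_repeats[cls], copy_mismatch_frac
                ):
                    copies.append(RepeatCopy(cls, s, e))
        copies.sort(key=lambda c: c.start)
    else:
        copies = _copies_from_pairs(classified_pairs)

    pattern = tuple(c.class_name for c in copies)
    if pattern not in _PATTERNS:
        raise NoArchitectureError(
            f"{record.seq_id}: repeat copies interleave as {pattern or '()'}, "
            "not a recognized cassette pattern",
            pairs=classified_pairs,
        )
    slot_spec, central_spec = _PATTERNS[pattern]
    trd_slots = [(copies[i].end, copies[j].start) for i, j in slot_spec]
    central_interval = None
    central = None
    if central_spec is not None:
        ci, cj = central_spec
        central_interval = (copies[ci].end, copies[cj].start)
        if tandem is None and central_interval[1] > central_interval[0]:
            sub = record.sequence[central_interval[0] : central_interval[1]]
            found = find_tandem_repeat(sub, max_mismatch_frac=tandem_mismatch_frac)
            if found is not None:
                tandem = TandemRepeat(
                    start=found.start + central_interval[0],
                    end=found.end + central_interval[0],
                    unit_sequence=found.unit_sequence,
                    copy_number=found.copy_number,
                )
        central = tandem
    return GeneArchitecture(
        seq_id=record.seq_id,
        trd_slots=trd_slots,
        central_interval=central_interval,
        central=central,
        repeat_pairs=list(classified_pairs),
        repeat_copies=copies,
    )


def consensus_repeats(
    classified_by_record: dict[str, list[RepeatPair]],
    sequences: dict[str, str],
    min_support: int = 2,
) -> dict[str, str]:
    """Per-class modal copy sequence across a family.

    A class is kept only when its modal copy sequence is seen in at least
    ``min_support`` records: chance pairs are record-private, real cassette
    repeats recur family-wide.
    """
    by_class: dict[str, Counter] = {"X": Counter(), "Y": Counter(), "Z": Counter()}
    support: dict[str, Counter] = {"X": Counter(), "Y": Counter(), "Z": Counter()}
    for seq_id, pairs in classified_by_record.items():
        seq = sequences[seq_id]
        per_record: dict[str, set[str]] = {"X": set(), "Y": set(), "Z": set()}
        for pair in pairs:
            if pair.class_name in by_class:
                for s, e in pair.copies:
                    by_class[pair.class_name][seq[s:e]] += 1
                    per_record[pair.class_name].add(seq[s:e])
        for cls, seqs in per_record.items():
            for s in seqs:
                support[cls][s] += 1
    out: dict[str, str] = {}
    for cls, counter in by_class.items():
        if not counter:
            continue
        best = max(sorted(counter), key=lambda s: (counter[s], support[cls][s]))
        if support[cls][best] >= min_support:
            out[cls] = best
    return out


def infer_family_architectures(
    records: Sequence[SGeneRecord],
    min_len: int = 12,
    max_mismatch_frac: float = 0.0,
    min_separation: int = 50,
    cluster_mismatch_frac: float = 0.0,
) -> tuple[dict[str, GeneArchitecture], dict[str, str], dict[str, str]]:
    """Annotate a whole family.

    Returns (architectures by seq_id, consensus repeats by class, failure
    notes by seq_id). Pair detection bootstraps the per-class consensus;
    every record is then segmented from located consensus copies. Repeat
    copies acting as recombination substrates are near-identical, so both
    the bootstrap and the copy location default to exact matching; raise
    the tolerances for decayed input.
    """
    classified: dict[str, list[RepeatPair]] = {}
    for rec in records:
        pairs = find_direct_repeat_pairs(
            rec.sequence, min_len=min_len, max_mismatch_frac=max_mismatch_frac,
            min_separation=min_separation,
        )
        classified[rec.seq_id] = classify_repeat_pairs(pairs, rec.sequence)
    consensus = consensus_repeats(
        classified, {r.seq_id: r.sequence for r in records}
    )
    architectures: dict[str, GeneArchitecture] = {}
    failures: dict[str, str] = {}
    for rec in records:
        try:
            architectures[rec.seq_id] = infer_architecture(
                rec,
                classified[rec.seq_id],
                known_repeats=consensus or None,
                copy_mismatch_frac=cluster_mismatch_frac,
            )
        except NoArchitectureError as exc:
            failures[rec.seq_id] = str(exc)
    return architectures, consensus, failures


def count_central_copies(architecture: GeneArchitecture) -> int:
    """Copy count of the central tandem unit; 0 when no run was found."""
    if architecture.central_interval is None:
        raise ValueError(
            f"{architecture.seq_id}: single-TRD architecture has no central region"
        )
    if architecture.central is None:
        return 0
    return architecture.central.copy_number


def central_coding_length(copy_number: int, unit_length_bp: int) -> tuple[int, int]:
    """(bp, amino acids) encoded by the central tandem repeat.

    The central repeat lies in frame within the S-gene ORF, so bp = copies x
    unit length and aa = bp / 3 (floor, with a frame warning, when the total
    is not a multiple of 3).
    """
    if copy_number < 0 or unit_length_bp < 0:
        raise ValueError("negative inputs")
    bp = copy_number * unit_length_bp
    if bp % 3:
        import warnings

        warnings.warn(f"central repeat length {bp} bp is not a whole codon count")
    return bp, bp // 3


def extract_trd_instances(
    records: Sequence[SGeneRecord],
    architectures: dict[str, GeneArchitecture],
    min_length_frac: float = 0.5,
) -> tuple[list[TRDInstance], list[tuple[str, int, str]]]:
    """TRD slot sequences ready for clustering.

    Partial instances shorter than ``min_length_frac`` of the median TRD
    length (broken genes) are excluded; they are returned separately with a
    note. Returns (instances, excluded).
    """
    raw: list[TRDInstance] = []
    by_id = {r.seq_id: r for r in records}
    for seq_id, arch in sorted(architectures.items()):
        rec = by_id[seq_id]
        for pos, (s, e) in enumerate(arch.trd_slots, start=1):
            raw.append(
                TRDInstance(
                    seq_id=seq_id,
                    position_index=pos,
                    start=s,
                    end=e,
                    sequence=rec.sequence[s:e],
                    strain=rec.strain,
                    locus_id=rec.locus_id,
                )
            )
    if not raw:
        return [], []
    lengths = sorted(len(t.sequence) for t in raw)
    median = lengths[len(lengths) // 2]
    kept, excluded = [], []
    for t in raw:
        if len(t.sequence) < min_length_frac * median:
            excluded.append((t.seq_id, t.position_index, "below half median TRD length"))
        else:
            kept.append(t)
    return kept, excluded
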