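"""Readers and writers for the formats the pipeline touches.

FASTA in (allele sequences, header dialect ``seqid|strain|locus``), GFF3 out
(architecture annotations), TSV out/in (event calls), JSON out/in (simulation
ground truth). Internal coordinates are 0-based half-open everywhere; the
GFF3 writer is the single seam where they become 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .model import (
    EVENT_TYPES,
    EventCall,
    GeneArchitecture,
    SGeneRecord,
)

GFF3_SOURCE = "domo"


def _parse_header(header: str) -> tuple[str, str, str]:
    parts = header.split("|")
    if len(parts) >= 3:
        return parts[0], parts[1], "|".join(parts[2:])
    return header, "NA", "NA"


def read_fasta(path) -> list[SGeneRecord]:
    """Read alleles from FASTA.

    Headers of the form ``seqid|strain|locus`` populate strain and locus;
    any other header becomes the seq_id with strain/locus "NA". Sequences are
    uppercased and U is normalized to T. Duplicate ids and non-IUPAC
    characters are errors.
    """
    path = Path(path)
    records: list[SGeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, strain, locus = _parse_header(rec.description.split()[0])
        seq = str(rec.seq).upper().replace("U", "T")
        if seq_id in seen:
            raise ValueError(f"duplicate sequence id {seq_id!r} in {path}")
        seen.add(seq_id)
        degenerate = any(b not in "ACGT" for b in seq)
        records.append(
            SGeneRecord(
                seq_id=seq_id,
                strain=strain,
                locus_id=locus,
                sequence=seq,
                degenerate=degenerate,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SGeneRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}|{rec.strain}|{rec.locus_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def _gff3_line(seqid, ftype, start, end, attrs: dict) -> str:
    attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
    # internal [start, end) -> GFF3 1-based inclusive
    return f"{seqid}\t{GFF3_SOURCE}\t{ftype}\t{start + 1}\t{end}\t.\t+\t.\t{attr_str}"


def write_gff3(
    architectures: Sequence[GeneArchitecture],
    records: Sequence[SGeneRecord],
    path,
) -> None:
    """Write architecture annotations as GFF3.

    Feature types: ``direct_repeat`` (repeat class in attributes),
    ``tandem_repeat`` (unit and copies), ``TRD`` (position_index) and
    ``central_region``. Features are ordered by seq_id then start.
    """
    lengths = {rec.seq_id: len(rec.sequence) for rec in records}
    lines: list[tuple[str, int, str]] = []
    for arch in sorted(architectures, key=lambda a: a.seq_id):
        seq_len = lengths.get(arch.seq_id)
        feats: list[tuple[int, int, str, dict]] = []
        for i, (s, e) in enumerate(arch.trd_slots, start=1):
            feats.append((s, e, "TRD", {"ID": f"{arch.seq_id}:TRD{i}", "position_index": i}))
        for copy in arch.repeat_copies:
            feats.append(
                (copy.start, copy.end, "direct_repeat", {"repeat_class": copy.class_name})
            )
        for pair in arch.repeat_pairs:
            for s, e in pair.copies:
                feats.append(
                    (
                        s,
                        e,
                        "direct_repeat",
                        {
                            "repeat_class": pair.class_name or "UNCLASSIFIED",
                            "pair_identity": f"{pair.identity:.3f}",
                        },
                    )
                )
        if arch.central_interval is not None:
            s, e = arch.central_interval
            feats.append((s, e, "central_region", {"ID": f"{arch.seq_id}:central"}))
        if arch.central is not None and arch.central.copy_number > 0:
            feats.append(
                (
                    arch.central.start,
                    arch.central.end,
                    "tandem_repeat",
                    {"unit": arch.central.unit_sequence, "copies": arch.central.copy_number},
                )
            )
        for s, e, ftype, attrs in feats:
            if s < 0 or (seq_len is not None and e > seq_len):
                raise ValueError(
                    f"{arch.seq_id}: feature interval [{s},{e}) exceeds sequence bounds"
                )
        for s, e, ftype, attrs in sorted(feats, key=lambda f: (f[0], f[1], f[2])):
            lines.append((arch.seq_id, s, _gff3_line(arch.seq_id, ftype, s, e, attrs)))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, _, line in lines:
            fh.write(line + "\n")


EVENTS_TSV_COLUMNS = ("type", "locus", "evidence", "note")


def write_events_tsv(events: Sequence[EventCall], path) -> None:
    """One row per call; evidence tuples serialized as 'seq:pos:label' joined by ','."""
    with open(path, "w") as fh:
        fh.write("\t".join(EVENTS_TSV_COLUMNS) + "\n")
        for ev in events:
            evidence = ",".join(f"{s}:{p}:{l}" for s, p, l in ev.evidence)
            fh.write(f"{ev.type}\t{ev.locus_id}\t{evidence}\t{ev.confidence_note}\n")


def read_events_tsv(path) -> list[EventCall]:
    calls: list[EventCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != EVENTS_TSV_COLUMNS:
            raise ValueError(f"unexpected events TSV header {header}")
        for line in fh:
            if not line.strip():
                continue
            etype, locus, evidence_str, note = (line.rstrip("\n").split("\t") + [""])[:4]
            if etype not in EVENT_TYPES:
                raise ValueError(f"unknown event type string {etype!r}")
            evidence = []
            if evidence_str:
                for item in evidence_str.split(","):
                    seq_id, pos, label = item.rsplit(":", 2)
                    evidence.append((seq_id, int(pos), label))
            calls.append(EventCall(etype, locus, evidence, note))
    return calls


def write_truth_json(truth: dict, path) -> None:
    """Serialize a SimTruth mapping (see :mod:`domo.simulate`) to JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth_json(path) -> dict:
    """Read a SimTruth mapping back, validating event types and ordering."""
    with open(path) as fh:
        truth = json.load(fh)
    events = truth.get("events", [])
    last_gen = -1
    for ev in events:
        if ev["type"] not in EVENT_TYPES:
            raise ValueError(f"unknown event type string {ev['type']!r}")
        gen = ev["generation"]
        if gen < last_gen:
            raise ValueError("truth events violate generation ordering")
        last_gen = gen
    return truth
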