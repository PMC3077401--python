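"""Event-class calling from the label-position matrix, and the
recognition-spacer model.

Each call class maps to one recombination mechanism:

MOVEMENT            one label at both position 1 and position 2 among the
                    >=2-TRD alleles of a locus (cross-position sharing, the
                    domain-movement signature)
INTER_LOCUS_SHARING one label at two or more loci
SUBSTITUTION        >=2 labels at one position after setting aside labels
                    already explained by movement (cross-position) or
                    inter-locus sharing (cross-locus)
DELETION            a single-TRD allele whose label also occurs in 2-TRD
                    alleles at the locus (a collapse product, not an
                    independent single-TRD family)
DUPLICATION         a three-TRD allele (TRD1-TRD2-TRD2)
CENTRAL_COPY_CHANGE >=2 distinct central copy numbers at a locus

The caller reports intra-locus MOVEMENT and INTER_LOCUS_SHARING separately
and does not adjudicate whether cross-position sharing arose as one
intra-locus event or two inter-locus ones — the data cannot distinguish
them for multi-locus families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .model import EventCall, GeneArchitecture
from .architecture import count_central_copies


@dataclass(frozen=True)
class SpacerModel:
    """Linear map from central-repeat copy number to the recognition-site
    spacer (the N-run of the bipartite target, e.g. GAA(N)6RTCG).

    Calibrated at a reference point: spacer(c) = ref_spacer +
    (c - ref_copies) * spacer_per_copy. For EcoR124I the reference is
    2 copies -> N6 with one extra N per extra copy.
    """

    ref_copies: int
    ref_spacer: int
    spacer_per_copy: int = 1


def predict_spacer(model: SpacerModel, copies: int) -> int:
    if copies < 0:
        raise ValueError("copies must be >= 0")
    spacer = model.ref_spacer + (copies - model.ref_copies) * model.spacer_per_copy
    if spacer < 0:
        raise ValueError(f"predicted spacer {spacer} is negative")
    return spacer


def _locus_rows(matrix: pd.DataFrame, locus: str) -> pd.DataFrame:
    return matrix[matrix.index.get_level_values("locus") == locus]


def call_events(
    matrix: pd.DataFrame,
    architectures: dict[str, GeneArchitecture],
) -> list[EventCall]:
    """Infer event calls from a complete label-position matrix.

    The matrix is indexed by (seq_id, locus) with 1-based position columns;
    absent slots hold '—'. Calls are deduplicated (per label for MOVEMENT /
    INTER_LOCUS_SHARING, per position for SUBSTITUTION, per allele for
    DELETION / DUPLICATION, per locus for CENTRAL_COPY_CHANGE) and returned
    in a deterministic order.
    """
    calls: list[EventCall] = []
    loci = sorted(set(matrix.index.get_level_values("locus")))

    # where does each label occur? only positions 1-2 of >=2-TRD alleles count
    # for movement/substitution logic; single-TRD products and duplicated
    # third slots have their own call classes.
    occ: dict[str, dict[str, set[int]]] = {}  # locus -> label -> positions
    occ_loci: dict[str, set[str]] = {}  # label -> loci
    evidence: dict[tuple[str, str, int], list] = {}
    for (seq_id, locus), row in matrix.iterrows():
        arch = architectures.get(seq_id)
        if arch is None or arch.n_trds < 2:
            continue
        for pos in (1, 2):
            label = row.get(pos, "—")
            if label == "—":
                continue
            occ.setdefault(locus, {}).setdefault(label, set()).add(pos)
            occ_loci.setdefault(label, set()).add(locus)
            evidence.setdefault((locus, label, pos), []).append((seq_id, pos, label))

    for locus in loci:
        rows = _locus_rows(matrix, locus)
        n_alleles = len(rows)
        if n_alleles < 2:
            continue
        labels_here = occ.get(locus, {})

        # MOVEMENT: cross-position sharing within the locus
        for label in sorted(labels_here):
            if {1, 2} <= labels_here[label]:
                ev = evidence[(locus, label, 1)] + evidence[(locus, label, 2)]
                calls.append(
                    EventCall(
                        "MOVEMENT",
                        locus,
                        ev,
                        f"label {label} occupies TRD1 and TRD2 at {locus}",
                    )
                )

        # SUBSTITUTION: per position, labels not explained by movement or
        # inter-locus sharing
        for pos in (1, 2):
            eligible = sorted(
                label
                for label, positions in labels_here.items()
                if pos in positions
                and len(positions) == 1
                and len(occ_loci[label]) == 1
            )
            if len(eligible) >= 2:
                ev = [t for label in eligible for t in evidence[(locus, label, pos)]]
                calls.append(
                    EventCall(
                        "SUBSTITUTION",
                        locus,
                        ev,
                        f"labels {{{', '.join(eligible)}}} alternate at TRD{pos} of {locus}",
                    )
                )

        # DELETION: single-TRD allele whose label recurs in 2-TRD alleles
        for (seq_id, row_locus), row in rows.iterrows():
            arch = architectures.get(seq_id)
            if arch is None or arch.n_trds != 1:
                continue
            label = row.get(1, "—")
            if label != "—" and label in labels_here:
                calls.append(
                    EventCall(
                        "DELETION",
                        locus,
                        [(seq_id, 1, label)],
                        f"{seq_id} retains a single TRD whose domain {label} "
                        f"recurs in two-TRD alleles",
                    )
                )

        # DUPLICATION: three-TRD allele
        for (seq_id, row_locus), row in rows.iterrows():
            arch = architectures.get(seq_id)
            if arch is not None and arch.n_trds == 3:
                ev = [
                    (seq_id, pos, row.get(pos, "—")) for pos in (1, 2, 3)
                ]
                calls.append(
                    EventCall(
                        "DUPLICATION",
                        locus,
                        ev,
                        f"{seq_id} carries three TRDs",
                    )
                )

        # CENTRAL_COPY_CHANGE: distinct copy numbers among alleles with a
        # central region
        copy_values: dict[str, int] = {}
        for (seq_id, row_locus), _row in rows.iterrows():
            arch = architectures.get(seq_id)
            if arch is not None and arch.central_interval is not None:
                copy_values[seq_id] = count_central_copies(arch)
        if len(set(copy_values.values())) >= 2:
            ev = [
                (seq_id, 0, str(c)) for seq_id, c in sorted(copy_values.items())
            ]
            calls.append(
                EventCall(
                    "CENTRAL_COPY_CHANGE",
                    locus,
                    ev,
                    f"central copy numbers {sorted(set(copy_values.values()))} at {locus}",
                )
            )

    # INTER_LOCUS_SHARING: one call per label spanning >=2 loci
    for label in sorted(occ_loci):
        if len(occ_loci[label]) >= 2:
            ev = [
                t
                for (locus, lab, pos), ts in sorted(evidence.items())
                if lab == label
                for t in ts
            ]
            calls.append(
                EventCall(
                    "INTER_LOCUS_SHARING",
                    "+".join(sorted(occ_loci[label])),
                    ev,
                    f"label {label} is shared by loci {sorted(occ_loci[label])}",
                )
            )
    return calls


def _truth_keys(truth: dict) -> dict[str, list]:
    keys: dict[str, list] = {t: [] for t in (
        "SUBSTITUTION", "MOVEMENT", "DELETION", "DUPLICATION",
        "CENTRAL_COPY_CHANGE", "INTER_LOCUS_SHARING",
    )}
    for ev in truth.get("events", []):
        etype = ev["type"]
        if etype == "SUBSTITUTION":
            keys[etype].append((ev["locus"], ev["positions"][0]))
        elif etype == "MOVEMENT":
            keys[etype].append((ev["locus"], ev["label"]))
        elif etype in ("DELETION", "DUPLICATION"):
            keys[etype].append((ev["locus"], ev["recipient"]))
        elif etype == "CENTRAL_COPY_CHANGE":
            keys[etype].append((ev["locus"],))
        elif etype == "INTER_LOCUS_SHARING":
            keys[etype].append((ev["label"],))
    return keys


def _call_keys(calls: Sequence[EventCall], truth_labels: dict) -> dict[str, list]:
    """Call keys in truth-label space.

    Cluster labels are assigned by order of first appearance and are an
    arbitrary bijection of the simulator's pool labels, so label-keyed calls
    (MOVEMENT, INTER_LOCUS_SHARING) are translated through the true label of
    a cited instance; an inconsistent translation (a miscalled cluster)
    yields a key that matches nothing.
    """

    def true_label(seq_id: str, pos: int) -> Optional[str]:
        return truth_labels.get(seq_id, {}).get(str(pos))

    keys: dict[str, list] = {t: [] for t in (
        "SUBSTITUTION", "MOVEMENT", "DELETION", "DUPLICATION",
        "CENTRAL_COPY_CHANGE", "INTER_LOCUS_SHARING",
    )}
    for call in calls:
        if call.type == "SUBSTITUTION":
            keys[call.type].append((call.locus_id, call.evidence[0][1]))
        elif call.type in ("MOVEMENT", "INTER_LOCUS_SHARING"):
            translated = {true_label(s, p) for s, p, _l in call.evidence}
            label = translated.pop() if len(translated) == 1 else f"?{call.evidence[0][2]}"
            if call.type == "MOVEMENT":
                keys[call.type].append((call.locus_id, label))
            else:
                keys[call.type].append((label,))
        elif call.type in ("DELETION", "DUPLICATION"):
            keys[call.type].append((call.locus_id, call.evidence[0][0]))
        elif call.type == "CENTRAL_COPY_CHANGE":
            keys[call.type].append((call.locus_id,))
    return keys


def evaluate_calls(calls: Sequence[EventCall], truth: dict) -> dict[str, dict]:
    """Per-type precision/recall/F1 of calls against a simulation truth log.

    A truth event is recovered when a call of its type carries the matching
    key (locus+label for MOVEMENT, locus+position for SUBSTITUTION,
    locus+allele for DELETION/DUPLICATION, locus for CENTRAL_COPY_CHANGE,
    label for INTER_LOCUS_SHARING). Undefined ratios (no truth events, or no
    calls) are reported as None, not 0.
    """
    truth_ids = {a["seq_id"] for a in truth.get("ancestral", [])}
    for call in calls:
        for seq_id, _pos, _label in call.evidence:
            if truth_ids and seq_id not in truth_ids:
                raise ValueError(
                    f"call cites {seq_id!r}, absent from the truth family"
                )
    tkeys = _truth_keys(truth)
    ckeys = _call_keys(calls, truth.get("truth_labels", {}))
    metrics: dict[str, dict] = {}
    for etype in tkeys:
        truth_list = tkeys[etype]
        call_list = ckeys[etype]
        tset, cset = set(truth_list), set(call_list)
        recovered = sum(1 for k in truth_list if k in cset)
        correct = sum(1 for k in call_list if k in tset)
        precision: Optional[float] = correct / len(call_list) if call_list else None
        recall: Optional[float] = recovered / len(truth_list) if truth_list else None
        if precision is None or recall is None or precision + recall == 0:
            f1: Optional[float] = None
        else:
            f1 = 2 * precision * recall / (precision + recall)
        metrics[etype] = {
            "n_truth": len(truth_list),
            "n_calls": len(call_list),
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    return metrics
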