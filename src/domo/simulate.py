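"""Forward simulator for S-gene allele families under repeat-mediated
recombination.

A family is a set of loci, each carrying several alleles of one specificity
gene. Each allele is assembled from components

    flank5 - x - TRD1 - y - central - x - [z -] TRD2 [- z] - y - flank3

where x/y (and optionally z) are the direct-repeat classes and the central
region is ``unit x copies`` of a short tandem unit. Every locus starts
clonal (one ancestral TRD pair, one ancestral copy number); diversity is
injected as discrete events, each logged to a replayable ground truth:

SUBSTITUTION        a fresh pool domain replaces the TRD at one slot
                    (an import by recombination across the flanking repeats)
MOVEMENT            a donor allele's TRD at one slot is copied into the
                    *other* slot of a recipient at the same locus
                    (crossovers pair donor-right-x with recipient-left-x and
                    donor-right-y with recipient-left-y)
DELETION            recombination between an allele's two x copies collapses
                    it to a single-TRD cassette (TRD2 survives)
DUPLICATION         unequal recombination between z copies duplicates TRD2,
                    yielding a TRD1-TRD2-TRD2 allele
CENTRAL_COPY_CHANGE the central copy number is resampled
INTER_LOCUS_SHARING a TRD is copied to the same slot of an allele at a
                    different locus sharing the repeat classes

Repeat copies are embedded *maximally*: boundary bases of the repeats, of
the pool TRDs, and of the flanks are fixed so that the base adjacent to one
copy always differs from the base adjacent to its partner copy. A detector
run at zero mismatch tolerance therefore reports exactly the class lengths
(37/49/14 bp by default). Point mutations, when enabled, are applied last
and (by default) never inside repeat copies or the bases adjacent to them.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .clustering import pairwise_identity
from .model import DomoError, SGeneRecord, domain_label

# Central tandem units, as found in Group 2 Type I and the Type IIG system.
GROUP2_UNIT = "CACAGAATTAAA"  # 12 bp
TYPE_IIG_UNIT = "CAGTGTCGGCTCGCCGAACTTGAG"  # 24 bp

_BASES = "ACGT"
# Boundary-base conventions that guarantee maximal repeat embedding:
# x starts G / ends T; y starts T / ends G; z starts T / ends T;
# pool TRD i starts "ACG"[i % 3] and ends "ACG"[(i + 1) % 3].
_X_FIRST, _X_LAST = "G", "T"
_Y_FIRST, _Y_LAST = "T", "G"
_Z_FIRST, _Z_LAST = "T", "T"
_TRD_EDGE = "ACG"


@dataclass
class SimParams:
    """Simulation parameters. Defaults model a Group-2-style family that also
    carries a 14-bp z repeat pair around TRD2, so that duplication events are
    available; :meth:`group2` drops z for the plain two-pair architecture."""

    n_loci: int = 2
    n_alleles_per_locus: int = 6
    trd_pool_size: int = 8
    trd_length_bp: int = 400
    flank_length_bp: int = 150
    repeat_x: Optional[str] = None
    repeat_y: Optional[str] = None
    repeat_z: Optional[str] = None
    repeat_x_len: int = 37
    repeat_y_len: int = 49
    repeat_z_len: Optional[int] = 14  # None -> no z repeat
    central_unit: str = GROUP2_UNIT
    central_copy_range: tuple[int, int] = (2, 6)
    event_counts: dict = field(default_factory=dict)
    point_mutation_rate: float = 0.0
    preserve_repeats: bool = True
    pool_subfamilies: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_alleles_per_locus < 2:
            raise ValueError("n_alleles_per_locus must be >= 2")
        if self.trd_pool_size < 2:
            raise ValueError("trd_pool_size must be >= 2 (substitution needs a pool)")
        lo, hi = self.central_copy_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid central_copy_range")
        for key in self.event_counts:
            if key not in (
                "SUBSTITUTION",
                "MOVEMENT",
                "DELETION",
                "DUPLICATION",
                "CENTRAL_COPY_CHANGE",
                "INTER_LOCUS_SHARING",
            ):
                raise ValueError(f"unknown event type in event_counts: {key!r}")

    @property
    def has_z(self) -> bool:
        return self.repeat_z is not None or self.repeat_z_len is not None

    @classmethod
    def group2(cls, **kw) -> "SimParams":
        """Plain Group-2 Type I architecture: x(37)/y(49), 12-bp unit, no z."""
        kw.setdefault("repeat_z_len", None)
        return cls(**kw)

    @classmethod
    def group3(cls, **kw) -> "SimParams":
        """Group-3-style repeat classes: x'(27), y'(53), z'(14)."""
        kw.setdefault("repeat_x_len", 27)
        kw.setdefault("repeat_y_len", 53)
        kw.setdefault("repeat_z_len", 14)
        return cls(**kw)

    @classmethod
    def type_iig(cls, **kw) -> "SimParams":
        """Type IIG S-gene style: x''(21)/y''(19), 24-bp unit, 0-4 copies."""
        kw.setdefault("repeat_x_len", 21)
        kw.setdefault("repeat_y_len", 19)
        kw.setdefault("repeat_z_len", None)
        kw.setdefault("central_unit", TYPE_IIG_UNIT)
        kw.setdefault("central_copy_range", (0, 4))
        return cls(**kw)

    def to_json(self) -> dict:
        d = asdict(self)
        d["central_copy_range"] = list(self.central_copy_range)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "SimParams":
        d = dict(d)
        if "central_copy_range" in d:
            d["central_copy_range"] = tuple(d["central_copy_range"])
        return cls(**d)


@dataclass
class Component:
    kind: str  # flank5 | x | trd | y | central | z | flank3
    seq: str
    cls: Optional[str] = None  # repeat class X/Y/Z for repeat components
    label: Optional[str] = None  # domain label for trd components

    def to_json(self) -> dict:
        return {"kind": self.kind, "seq": self.seq, "cls": self.cls, "label": self.label}

    @classmethod
    def from_json(cls, d: dict) -> "Component":
        return cls(d["kind"], d["seq"], d.get("cls"), d.get("label"))


@dataclass
class Allele:
    seq_id: str
    strain: str
    locus_id: str
    components: list[Component]

    @property
    def sequence(self) -> str:
        return "".join(c.seq for c in self.components)

    def record(self) -> SGeneRecord:
        return SGeneRecord(self.seq_id, self.strain, self.locus_id, self.sequence)

    def slot_map(self) -> list[tuple[str, Optional[str], int, int]]:
        """Ordered (kind, class, start, end) for every component."""
        out = []
        pos = 0
        for c in self.components:
            out.append((c.kind, c.cls, pos, pos + len(c.seq)))
            pos += len(c.seq)
        return out

    def trd_components(self) -> list[Component]:
        return [c for c in self.components if c.kind == "trd"]

    def trd_slots(self) -> list[tuple[int, int]]:
        return [
            (s, e) for (kind, _cls, s, e) in self.slot_map() if kind == "trd"
        ]

    @property
    def n_trds(self) -> int:
        return len(self.trd_components())

    def trd_labels(self) -> list[str]:
        return [c.label for c in self.trd_components()]

    def central_component(self) -> Optional[Component]:
        for c in self.components:
            if c.kind == "central":
                return c
        return None

    def to_json(self) -> dict:
        return {
            "seq_id": self.seq_id,
            "strain": self.strain,
            "locus_id": self.locus_id,
            "components": [c.to_json() for c in self.components],
        }

    @classmethod
    def from_json(cls, d: dict) -> "Allele":
        return cls(
            d["seq_id"],
            d["strain"],
            d["locus_id"],
            [Component.from_json(c) for c in d["components"]],
        )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _with_edges(seq: str, first: Optional[str], last: Optional[str]) -> str:
    if first is not None:
        seq = first + seq[1:]
    if last is not None:
        seq = seq[:-1] + last
    return seq


# Within-subfamily per-site divergence from the subfamily ancestor; two
# members then sit near 0.72 alignment identity — clearly below the 0.8
# clustering threshold, clearly above the ~0.55 identity of unrelated DNA.
_SUBFAMILY_SITE_DIVERGENCE = 0.165
_WITHIN_SUBFAMILY_CEILING = 0.78
_CROSS_FAMILY_CEILING = 0.60


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for pos in np.nonzero(rng.random(len(seq)) < rate)[0]:
        pos = int(pos)
        out[pos] = _BASES[(_BASES.index(out[pos]) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(out)


def generate_trd_pool(params: SimParams, rng: np.random.Generator):
    """Random TRD repertoire of ``trd_pool_size`` sequences of
    ``trd_length_bp``, labelled 'a', 'b', ...

    Natural repertoires are position-structured: the domains seen at TRD1
    form one homology family and those at TRD2 another. With
    ``pool_subfamilies`` (the default), even-indexed members descend from a
    TRD1-type ancestor and odd-indexed members from a TRD2-type ancestor,
    with within-subfamily identity ~0.72 (rejection-capped below 0.78,
    under the clustering threshold) and cross-subfamily identity below 0.60.
    Without subfamilies every pair is rejection-sampled below 0.60 identity.
    First/last bases cycle over A/C/G so that distinct pool members never
    share an edge base with their cassette neighbours.
    """
    if params.trd_pool_size < 2:
        raise ValueError("pool size must be >= 2")
    ancestors = None
    if params.pool_subfamilies:
        a1 = _random_dna(rng, params.trd_length_bp)
        for _attempt in range(1000):
            a2 = _random_dna(rng, params.trd_length_bp)
            if pairwise_identity(a1, a2) < _CROSS_FAMILY_CEILING - 0.02:
                break
        else:
            raise DomoError("could not sample divergent subfamily ancestors")
        ancestors = (a1, a2)
    pool: list[tuple[str, str]] = []
    for i in range(params.trd_pool_size):
        label = domain_label(i)
        for _attempt in range(1000):
            if ancestors is None:
                cand = _random_dna(rng, params.trd_length_bp)
            else:
                cand = _mutate(ancestors[i % 2], _SUBFAMILY_SITE_DIVERGENCE, rng)
            cand = _with_edges(cand, _TRD_EDGE[i % 3], _TRD_EDGE[(i + 1) % 3])
            ok = True
            for j, (_l, seq) in enumerate(pool):
                same_family = ancestors is not None and j % 2 == i % 2
                ceiling = _WITHIN_SUBFAMILY_CEILING if same_family else _CROSS_FAMILY_CEILING
                if pairwise_identity(cand, seq) >= ceiling:
                    ok = False
                    break
            if ok:
                pool.append((label, cand))
                break
        else:
            raise DomoError(
                "could not sample a sufficiently divergent TRD in 1000 "
                "attempts; parameters inconsistent"
            )
    return pool


@dataclass
class SimContext:
    """Materialized family-level sequences: repeats, pool and per-locus flanks."""

    repeat_x: str
    repeat_y: str
    repeat_z: Optional[str]
    pool: dict[str, str]
    flanks: dict[str, tuple[str, str]] = field(default_factory=dict)

    def flank_pair(self, locus_id: str, params: SimParams, rng: np.random.Generator):
        if locus_id not in self.flanks:
            f5 = _random_dna(rng, params.flank_length_bp)
            f3 = _random_dna(rng, params.flank_length_bp)
            # maximal-embedding guards: the base left of each x copy and right
            # of each y copy must differ between copies
            banned5 = {params.central_unit[-1], self.repeat_y[-1]}
            banned3 = {params.central_unit[0], self.repeat_x[0]}
            f5 = f5[:-1] + next(b for b in _BASES if b not in banned5)
            f3 = next(b for b in _BASES if b not in banned3) + f3[1:]
            self.flanks[locus_id] = (f5, f3)
        return self.flanks[locus_id]


def make_context(params: SimParams, rng: np.random.Generator) -> SimContext:
    x = params.repeat_x or _with_edges(
        _random_dna(rng, params.repeat_x_len), _X_FIRST, _X_LAST
    )
    y = params.repeat_y or _with_edges(
        _random_dna(rng, params.repeat_y_len), _Y_FIRST, _Y_LAST
    )
    z = None
    if params.has_z:
        z = params.repeat_z or _with_edges(
            _random_dna(rng, params.repeat_z_len), _Z_FIRST, _Z_LAST
        )
    pool = dict(generate_trd_pool(params, rng))
    return SimContext(repeat_x=x, repeat_y=y, repeat_z=z, pool=pool)


def build_allele(
    trd1_label: str,
    trd2_label: str,
    central_copies: int,
    params: SimParams,
    context: SimContext,
    locus_id: str = "L1",
    strain: str = "s00",
    rng: Optional[np.random.Generator] = None,
) -> Allele:
    """Assemble one allele: flank-x-TRD1-y-central-x-[z-]TRD2[-z]-y-flank."""
    for lab in (trd1_label, trd2_label):
        if lab not in context.pool:
            raise ValueError(f"label {lab!r} not in TRD pool")
    lo, hi = params.central_copy_range
    if not lo <= central_copies <= hi:
        raise ValueError(f"central copies {central_copies} outside range {params.central_copy_range}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    f5, f3 = context.flank_pair(locus_id, params, rng)
    comps = [
        Component("flank5", f5),
        Component("x", context.repeat_x, cls="X"),
        Component("trd", context.pool[trd1_label], label=trd1_label),
        Component("y", context.repeat_y, cls="Y"),
        Component("central", params.central_unit * central_copies),
        Component("x", context.repeat_x, cls="X"),
    ]
    if context.repeat_z is not None:
        comps += [
            Component("z", context.repeat_z, cls="Z"),
            Component("trd", context.pool[trd2_label], label=trd2_label),
            Component("z", context.repeat_z, cls="Z"),
        ]
    else:
        comps.append(Component("trd", context.pool[trd2_label], label=trd2_label))
    comps += [Component("y", context.repeat_y, cls="Y"), Component("flank3", f3)]
    return Allele(f"{strain}_{locus_id}", strain, locus_id, comps)


@dataclass
class Family:
    """A simulated family plus the planner state used to inject events."""

    params: SimParams
    context: SimContext
    alleles: list[Allele]
    anc_labels: dict[str, tuple[str, str]]
    anc_copies: dict[str, int]
    events: list[dict] = field(default_factory=list)
    # planner state
    locked_alleles: set = field(default_factory=set)
    locked_slots: set = field(default_factory=set)  # (seq_id, pos)
    consumed_anc: set = field(default_factory=set)  # (locus, pos)
    sub_positions: set = field(default_factory=set)  # (locus, pos)
    used_labels: set = field(default_factory=set)

    def loci(self) -> list[str]:
        seen = []
        for a in self.alleles:
            if a.locus_id not in seen:
                seen.append(a.locus_id)
        return seen

    def at_locus(self, locus_id: str) -> list[Allele]:
        return [a for a in self.alleles if a.locus_id == locus_id]

    def by_id(self, seq_id: str) -> Allele:
        for a in self.alleles:
            if a.seq_id == seq_id:
                return a
        raise KeyError(seq_id)

    def records(self) -> list[SGeneRecord]:
        return [a.record() for a in self.alleles]


def init_family(params: SimParams, rng: np.random.Generator) -> Family:
    """Clonal ancestral family: locus k gets pool labels 2k and 2k+1."""
    needed = 2 * params.n_loci
    if params.trd_pool_size < needed:
        raise DomoError(
            f"trd_pool_size={params.trd_pool_size} too small for {params.n_loci} "
            f"loci (need {needed} ancestral labels)"
        )
    context = make_context(params, rng)
    labels = list(context.pool)
    lo, hi = params.central_copy_range
    alleles: list[Allele] = []
    anc_labels: dict[str, tuple[str, str]] = {}
    anc_copies: dict[str, int] = {}
    for k in range(params.n_loci):
        locus = f"L{k + 1}"
        l1, l2 = labels[2 * k], labels[2 * k + 1]
        anc_labels[locus] = (l1, l2)
        copies = int(rng.integers(lo, hi + 1))
        anc_copies[locus] = copies
        for i in range(params.n_alleles_per_locus):
            strain = f"s{i + 1:02d}"
            alleles.append(
                build_allele(
                    l1, l2, copies, params, context, locus_id=locus, strain=strain, rng=rng
                )
            )
    return Family(params, context, alleles, anc_labels, anc_copies,
                  used_labels=set(labels[:needed]))


# ---------------------------------------------------------------------------
# event planning and application
# ---------------------------------------------------------------------------


def _unlocked(family: Family, allele: Allele, pos: Optional[int] = None) -> bool:
    if allele.seq_id in family.locked_alleles:
        return False
    if pos is not None and (allele.seq_id, pos) in family.locked_slots:
        return False
    return True


def _untouched(family: Family, allele: Allele) -> bool:
    """No prior event involves this allele as recipient (structural events
    must not erase an earlier event's signature)."""
    return (
        allele.seq_id not in family.locked_alleles
        and not any((allele.seq_id, p) in family.locked_slots for p in (1, 2))
        and not any(ev["recipient"] == allele.seq_id for ev in family.events)
    )


def _choice(rng: np.random.Generator, items: list):
    return items[int(rng.integers(0, len(items)))]


def plan_one(family: Family, event_type: str, rng: np.random.Generator) -> dict:
    """Choose locus/recipient/donor/label for one event, respecting the
    signature-preservation constraints (each injected event must remain
    individually recoverable at zero noise). Raises DomoError when no
    placement is available."""
    params = family.params
    loci = family.loci()
    plan: Optional[dict] = None

    if event_type == "SUBSTITUTION":
        all_labels = list(family.context.pool)
        cands = []
        for locus in loci:
            for pos in (1, 2):
                if (locus, pos) in family.consumed_anc:
                    continue
                # a fresh import comes from the position's own subfamily
                fresh = [
                    lab
                    for i, lab in enumerate(all_labels)
                    if lab not in family.used_labels
                    and (not params.pool_subfamilies or i % 2 == pos - 1)
                ]
                recips = [
                    a
                    for a in family.at_locus(locus)
                    if a.n_trds == 2
                    and _unlocked(family, a, pos)
                    and a.trd_labels()[pos - 1] == family.anc_labels[locus][pos - 1]
                ]
                if recips and fresh:
                    cands.append((locus, pos, recips, fresh))
        if cands:
            locus, pos, recips, fresh = _choice(rng, cands)
            label = fresh[0]
            recipient = _choice(rng, recips)
            plan = {
                "type": "SUBSTITUTION",
                "locus": locus,
                "recipient": recipient.seq_id,
                "donor": f"pool:{label}",
                "positions": [pos],
                "label": label,
            }

    elif event_type == "MOVEMENT":
        cands = []
        for locus in loci:
            for src in (1, 2):
                if (locus, src) in family.sub_positions:
                    continue
                label = family.anc_labels[locus][src - 1]
                dst = 2 if src == 1 else 1
                donors = [
                    a
                    for a in family.at_locus(locus)
                    if a.n_trds == 2 and a.trd_labels()[src - 1] == label
                ]
                recips = [
                    a
                    for a in family.at_locus(locus)
                    if a.n_trds == 2
                    and _unlocked(family, a, dst)
                    and a.trd_labels()[dst - 1] != label
                ]
                pairs = [(d, r) for d in donors for r in recips if d.seq_id != r.seq_id]
                if pairs:
                    cands.append((locus, src, dst, label, pairs))
        if cands:
            locus, src, dst, label, pairs = _choice(rng, cands)
            donor, recipient = _choice(rng, pairs)
            plan = {
                "type": "MOVEMENT",
                "locus": locus,
                "recipient": recipient.seq_id,
                "donor": donor.seq_id,
                "positions": [src, dst],
                "label": label,
            }

    elif event_type == "DELETION":
        cands = [
            a
            for a in family.alleles
            if a.n_trds == 2 and _untouched(family, a)
        ]
        if cands:
            recipient = _choice(rng, cands)
            plan = {
                "type": "DELETION",
                "locus": recipient.locus_id,
                "recipient": recipient.seq_id,
                "donor": recipient.seq_id,
                "positions": [1],
                "label": recipient.trd_labels()[1],  # TRD2 survives
            }

    elif event_type == "DUPLICATION":
        if family.context.repeat_z is None:
            raise DomoError("DUPLICATION requires a z repeat (repeat_z unset)")
        cands = [
            a for a in family.alleles if a.n_trds == 2 and _untouched(family, a)
        ]
        if cands:
            recipient = _choice(rng, cands)
            plan = {
                "type": "DUPLICATION",
                "locus": recipient.locus_id,
                "recipient": recipient.seq_id,
                "donor": recipient.seq_id,
                "positions": [2, 3],
                "label": recipient.trd_labels()[1],
            }

    elif event_type == "CENTRAL_COPY_CHANGE":
        lo, hi = params.central_copy_range
        cands = []
        for a in family.alleles:
            central = a.central_component()
            if central is None or a.seq_id in family.locked_alleles:
                continue
            if any(ev["type"] == "CENTRAL_COPY_CHANGE" and ev["recipient"] == a.seq_id
                   for ev in family.events):
                continue
            current = len(central.seq) // max(len(params.central_unit), 1)
            anc = family.anc_copies[a.locus_id]
            choices = [c for c in range(lo, hi + 1) if c != current and c != anc]
            if choices:
                cands.append((a, choices))
        if cands:
            recipient, choices = _choice(rng, cands)
            new_copies = _choice(rng, choices)
            plan = {
                "type": "CENTRAL_COPY_CHANGE",
                "locus": recipient.locus_id,
                "recipient": recipient.seq_id,
                "donor": recipient.seq_id,
                "positions": [],
                "label": "",
                "copies": int(new_copies),
            }

    elif event_type == "INTER_LOCUS_SHARING":
        if len(loci) < 2:
            raise DomoError("INTER_LOCUS_SHARING requires >= 2 loci")
        cands = []
        for src_locus in loci:
            for pos in (1, 2):
                if (src_locus, pos) in family.sub_positions:
                    continue
                label = family.anc_labels[src_locus][pos - 1]
                donors = [
                    a
                    for a in family.at_locus(src_locus)
                    if a.n_trds == 2 and a.trd_labels()[pos - 1] == label
                ]
                for dst_locus in loci:
                    if dst_locus == src_locus:
                        continue
                    recips = [
                        a
                        for a in family.at_locus(dst_locus)
                        if a.n_trds == 2
                        and _unlocked(family, a, pos)
                        and label not in a.trd_labels()
                    ]
                    if donors and recips:
                        cands.append((src_locus, dst_locus, pos, label, donors, recips))
        if cands:
            src_locus, dst_locus, pos, label, donors, recips = _choice(rng, cands)
            plan = {
                "type": "INTER_LOCUS_SHARING",
                "locus": dst_locus,
                "src_locus": src_locus,
                "recipient": _choice(rng, recips).seq_id,
                "donor": _choice(rng, donors).seq_id,
                "positions": [pos],
                "label": label,
            }
    else:
        raise ValueError(f"unknown event type {event_type!r}")

    if plan is None:
        raise DomoError(f"no feasible placement for a {event_type} event")
    plan["generation"] = len(family.events)
    return plan


def apply_planned(family: Family, plan: dict) -> None:
    """Deterministically apply a planned event and update planner state."""
    etype = plan["type"]
    recipient = family.by_id(plan["recipient"])

    if etype == "SUBSTITUTION":
        pos = plan["positions"][0]
        label = plan["label"]
        trd = recipient.trd_components()[pos - 1]
        trd.seq = family.context.pool[label]
        trd.label = label
        family.locked_slots.add((recipient.seq_id, pos))
        family.sub_positions.add((plan["locus"], pos))
        family.used_labels.add(label)

    elif etype == "MOVEMENT":
        src, dst = plan["positions"]
        donor = family.by_id(plan["donor"])
        src_trd = donor.trd_components()[src - 1]
        dst_trd = recipient.trd_components()[dst - 1]
        dst_trd.seq = src_trd.seq
        dst_trd.label = src_trd.label
        family.locked_slots.add((recipient.seq_id, dst))
        family.consumed_anc.add((plan["locus"], src))

    elif etype == "DELETION":
        comps = recipient.components
        x_idx = [i for i, c in enumerate(comps) if c.kind == "x"]
        if len(x_idx) < 2:
            raise DomoError(f"{recipient.seq_id} already single-TRD; deletion skipped")
        recipient.components = comps[: x_idx[0] + 1] + comps[x_idx[1] + 1 :]
        family.locked_alleles.add(recipient.seq_id)

    elif etype == "DUPLICATION":
        comps = recipient.components
        z_idx = [i for i, c in enumerate(comps) if c.kind == "z"]
        if len(z_idx) != 2:
            raise DomoError("DUPLICATION needs exactly two z copies")
        trd2 = comps[z_idx[0] + 1]
        insert = [
            Component("trd", trd2.seq, label=trd2.label),
            Component("z", comps[z_idx[1]].seq, cls="Z"),
        ]
        recipient.components = comps[: z_idx[1] + 1] + insert + comps[z_idx[1] + 1 :]
        family.locked_alleles.add(recipient.seq_id)

    elif etype == "CENTRAL_COPY_CHANGE":
        central = recipient.central_component()
        central.seq = family.params.central_unit * plan["copies"]

    elif etype == "INTER_LOCUS_SHARING":
        pos = plan["positions"][0]
        donor = family.by_id(plan["donor"])
        src_trd = donor.trd_components()[pos - 1]
        dst_trd = recipient.trd_components()[pos - 1]
        dst_trd.seq = src_trd.seq
        dst_trd.label = src_trd.label
        family.locked_slots.add((recipient.seq_id, pos))
        family.consumed_anc.add((plan["src_locus"], pos))

    else:
        raise ValueError(f"unknown event type {etype!r}")

    family.events.append(plan)


def apply_event(family: Family, event_type: str, rng: np.random.Generator):
    """Plan and apply one event of ``event_type``; returns (family, truth entry)."""
    plan = plan_one(family, event_type, rng)
    apply_planned(family, plan)
    return family, plan


def _protected_positions(allele: Allele) -> set[int]:
    """Repeat and central component positions, padded by one base each side."""
    protected: set[int] = set()
    for kind, cls, s, e in allele.slot_map():
        if cls in ("X", "Y", "Z") or kind == "central":
            protected.update(range(max(0, s - 1), min(len(allele.sequence), e + 1)))
    return protected


def _apply_mutations(
    family: Family, rng: np.random.Generator
) -> list[dict]:
    rate = family.params.point_mutation_rate
    if rate <= 0:
        return []
    mutations: list[dict] = []
    for allele in family.alleles:
        protected = _protected_positions(allele) if family.params.preserve_repeats else set()
        seq = allele.sequence
        hits = np.nonzero(rng.random(len(seq)) < rate)[0]
        for pos in hits:
            pos = int(pos)
            if pos in protected:
                continue
            old = seq[pos]
            new = _BASES[(_BASES.index(old) + 1 + int(rng.integers(0, 3))) % 4]
            mutations.append(
                {"seq_id": allele.seq_id, "pos": pos, "from": old, "to": new}
            )
    _write_mutations(family, mutations)
    return mutations


def _write_mutations(family: Family, mutations: list[dict]) -> None:
    for mut in mutations:
        allele = family.by_id(mut["seq_id"])
        pos = mut["pos"]
        offset = 0
        for comp in allele.components:
            if offset <= pos < offset + len(comp.seq):
                i = pos - offset
                assert comp.seq[i] == mut["from"]
                comp.seq = comp.seq[:i] + mut["to"] + comp.seq[i + 1 :]
                break
            offset += len(comp.seq)


def simulate_family(params: SimParams):
    """Simulate one family; returns (records, truth).

    ``truth`` is a JSON-serializable mapping with the ancestral family, the
    ordered event log, the mutation log and the final per-slot label map;
    :func:`replay_truth` reproduces the emitted sequences byte-identically.
    """
    rng = np.random.default_rng(params.seed)
    family = init_family(params, rng)
    ancestral = [_copy.deepcopy(a).to_json() for a in family.alleles]

    order: list[str] = []
    for etype, count in sorted(params.event_counts.items()):
        order.extend([etype] * count)
    if order:
        order = [order[i] for i in rng.permutation(len(order))]
    for etype in order:
        plan = plan_one(family, etype, rng)
        apply_planned(family, plan)

    mutations = _apply_mutations(family, rng)

    truth = {
        "params": params.to_json(),
        "repeats": {
            "X": family.context.repeat_x,
            "Y": family.context.repeat_y,
            "Z": family.context.repeat_z,
        },
        "pool": [[label, seq] for label, seq in family.context.pool.items()],
        "pool_labels": list(family.context.pool),
        "flanks": {k: list(v) for k, v in family.context.flanks.items()},
        "ancestral": ancestral,
        "events": family.events,
        "mutations": mutations,
        "truth_labels": {
            a.seq_id: {str(i + 1): lab for i, lab in enumerate(a.trd_labels())}
            for a in family.alleles
        },
        "central_copies": {
            a.seq_id: (
                len(a.central_component().seq) // len(params.central_unit)
                if a.central_component() is not None
                else None
            )
            for a in family.alleles
        },
        "anc_labels": {k: list(v) for k, v in family.anc_labels.items()},
        "anc_copies": family.anc_copies,
    }
    return family.records(), truth


def replay_truth(truth: dict) -> list[SGeneRecord]:
    """Re-apply the logged events and mutations to the ancestral family."""
    params = SimParams.from_json(truth["params"])
    context = SimContext(
        repeat_x=truth["repeats"]["X"],
        repeat_y=truth["repeats"]["Y"],
        repeat_z=truth["repeats"]["Z"],
        pool=dict(truth["pool"]),
        flanks={k: tuple(v) for k, v in truth["flanks"].items()},
    )
    alleles = [Allele.from_json(d) for d in truth["ancestral"]]
    family = Family(
        params,
        context,
        alleles,
        anc_labels={k: tuple(v) for k, v in truth["anc_labels"].items()},
        anc_copies=dict(truth["anc_copies"]),
    )
    for plan in truth["events"]:
        apply_planned(family, dict(plan))
    _write_mutations(family, truth["mutations"])
    return family.records()


def plant_repeat_pair(
    rng: np.random.Generator,
    total_length: int,
    repeat_length: int,
    left_start: int,
    separation: int,
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Random sequence with one exact direct-repeat pair planted maximally.

    The pair's copies sit at ``left_start`` and ``left_start + repeat_length +
    separation``; the bases immediately flanking the two copies are forced to
    differ so the planted pair is maximal (a zero-mismatch detector reports
    exactly ``repeat_length``).
    """
    right_start = left_start + repeat_length + separation
    if right_start + repeat_length > total_length:
        raise ValueError("planted pair does not fit")
    seq = list(_random_dna(rng, total_length))
    repeat = _random_dna(rng, repeat_length)
    seq[left_start : left_start + repeat_length] = repeat
    seq[right_start : right_start + repeat_length] = repeat

    def _force_diff(i: int, j: int) -> None:
        if 0 <= i < total_length and 0 <= j < total_length and seq[i] == seq[j]:
            seq[j] = _BASES[(_BASES.index(seq[j]) + 1 + int(rng.integers(0, 3))) % 4]

    _force_diff(left_start - 1, right_start - 1)
    _force_diff(left_start + repeat_length, right_start + repeat_length)
    return (
        "".join(seq),
        (left_start, left_start + repeat_length),
        (right_start, right_start + repeat_length),
    )


def save_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
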