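"""Domain calls and whole-chain architectures.

A domain call owns one or more residue ranges; calls with two or more
ranges separated by a long insertion are "split" domains — contiguous in
3D but discontinuous in sequence (e.g. the split RWD domains of PARP6 and
PARP8, or split KH domains of PARP9/10/14).  Split parts carry fractional
display labels rounded to quarters ("¾", "¼") while the exact fractions
are kept in the JSON.  An Architecture is the machine-readable form of a
domain-architecture diagram: ordered domain calls, disordered regions and
interdomain contact calls that jointly tile the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .model_io import ARCHITECTURE_SCHEMA_VERSION, ResidueRange, StructureModel
from .rigidity import ContactCall, RigidUnit
from .segmentation import Segment
from .superposition import core_superpose

logger = logging.getLogger(__name__)

#: insertions at least this long (residues) make a discontinuous call "split"
DEFAULT_MIN_INSERTION = 30

_QUARTER_GLYPHS = {
    Fraction(0): "0",
    Fraction(1, 4): "¼",
    Fraction(1, 2): "½",
    Fraction(3, 4): "¾",
    Fraction(1): "1",
}


def fraction_display(value: float) -> str:
    """Nearest-quarter display glyph for a part fraction (exact value is
    stored separately and never altered by rounding)."""
    quarters = Fraction(round(value * 4), 4)
    quarters = max(Fraction(0), min(Fraction(1), quarters))
    return _QUARTER_GLYPHS[quarters]


@dataclass
class DomainCall:
    """One inferred domain: >= 1 residue ranges, optional homology label."""

    domain_id: str
    ranges: list[ResidueRange]
    label: str = "unassigned"
    label_rmsd: float | None = None
    label_core_atoms: int | None = None
    part_fractions: list[float] = field(default_factory=list)
    split: bool = False

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("a domain call needs at least one range")
        self.ranges = sorted(self.ranges, key=lambda r: r.start)
        for a, b in zip(self.ranges, self.ranges[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping ranges in domain {self.domain_id}")
        if not self.part_fractions:
            total = sum(len(r) for r in self.ranges)
            self.part_fractions = [len(r) / total for r in self.ranges]
        if abs(sum(self.part_fractions) - 1.0) > 1e-9:
            raise ValueError("part fractions must sum to 1")

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.ranges)

    @property
    def start(self) -> int:
        return self.ranges[0].start

    @property
    def end(self) -> int:
        return self.ranges[-1].end

    def residue_set(self) -> set[int]:
        return {i for r in self.ranges for i in r.residues()}

    def part_labels(self) -> list[str]:
        """Display labels for the parts, e.g. ['¾RWD', '¼RWD'] for a split."""
        if not self.split:
            return [self.label]
        return [f"{fraction_display(f)}{self.label}" for f in self.part_fractions]

    def to_json(self) -> dict:
        return {
            "domain_id": self.domain_id,
            "ranges": [r.to_json() for r in self.ranges],
            "label": self.label,
            "label_rmsd": None if self.label_rmsd is None else round(self.label_rmsd, 4),
            "label_core_atoms": self.label_core_atoms,
            "part_fractions": [round(f, 12) for f in self.part_fractions],
            "split": bool(self.split),
        }

    @classmethod
    def from_json(cls, payload: dict) -> "DomainCall":
        return cls(
            domain_id=payload["domain_id"],
            ranges=[ResidueRange.from_json(r) for r in payload["ranges"]],
            label=payload.get("label", "unassigned"),
            label_rmsd=payload.get("label_rmsd"),
            label_core_atoms=payload.get("label_core_atoms"),
            part_fractions=list(payload.get("part_fractions", [])),
            split=bool(payload.get("split", False)),
        )


@dataclass
class Architecture:
    """Machine form of a domain-architecture diagram for one chain."""

    entry_id: str
    length: int
    domains: list[DomainCall] = field(default_factory=list)
    disordered: list[ResidueRange] = field(default_factory=list)
    contacts: list[ContactCall] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.domains.sort(key=lambda d: d.start)
        self.disordered.sort(key=lambda r: r.start)
        self.validate()

    def validate(self) -> None:
        """Domain ranges and disordered ranges must jointly tile [1, length]."""
        covered = np.zeros(self.length + 1, dtype=int)
        for call in self.domains:
            for r in call.ranges:
                if r.end > self.length:
                    raise ValueError(f"range {r} exceeds chain length {self.length}")
                covered[r.start : r.end + 1] += 1
        for r in self.disordered:
            if r.end > self.length:
                raise ValueError(f"range {r} exceeds chain length {self.length}")
            covered[r.start : r.end + 1] += 1
        if self.length and covered[1:].max(initial=0) > 1:
            raise ValueError("overlapping ranges in architecture")
        if self.length and covered[1:].min(initial=1) < 1:
            gap = int(np.argmin(covered[1:])) + 1
            raise ValueError(f"architecture does not tile the chain (gap at {gap})")

    def domain_of(self, residue: int) -> str | None:
        for call in self.domains:
            if any(residue in r for r in call.ranges):
                return call.domain_id
        return None

    def to_json(self) -> dict:
        return {
            "schema_version": ARCHITECTURE_SCHEMA_VERSION,
            "entry_id": self.entry_id,
            "length": self.length,
            "domains": [d.to_json() for d in self.domains],
            "disordered": [r.to_json() for r in self.disordered],
            "contacts": [c.to_json() for c in self.contacts],
            "params": self.params,
        }

    @classmethod
    def from_json(cls, payload: dict) -> "Architecture":
        return cls(
            entry_id=payload["entry_id"],
            length=int(payload["length"]),
            domains=[DomainCall.from_json(d) for d in payload["domains"]],
            disordered=[ResidueRange.from_json(r) for r in payload["disordered"]],
            contacts=[ContactCall.from_json(c) for c in payload.get("contacts", [])],
            params=dict(payload.get("params", {})),
        )


# ---------------------------------------------------------------------------
# operations


def call_domains(domain_units: Sequence[RigidUnit], segments: Sequence[Segment] | None = None) -> list[DomainCall]:
    """One DomainCall per domain-level rigid unit.

    Member segment ranges that are adjacent in sequence are merged into one
    range; sequence-separated members stay as separate ranges (candidate
    split domains).
    """
    calls = []
    units = sorted(domain_units, key=lambda u: u.start)
    for k, unit in enumerate(units):
        ranges: list[ResidueRange] = []
        for seg in unit.member_segments:
            if ranges and seg.range.start == ranges[-1].end + 1:
                ranges[-1] = ResidueRange(ranges[-1].start, seg.range.end)
            else:
                ranges.append(seg.range)
        calls.append(DomainCall(domain_id=f"D{k + 1}", ranges=ranges))
    return calls


def detect_split_domains(
    calls: Sequence[DomainCall], min_insertion: int = DEFAULT_MIN_INSERTION
) -> list[DomainCall]:
    """Flag calls whose consecutive ranges are separated by a long insertion.

    Ranges closer than ``min_insertion`` are merged for display (the gap is
    treated as an unmodelled connector, not a genuine insertion); calls
    with any remaining multi-range structure are flagged split and get
    part fractions (exact, plus quarter-rounded display labels).
    """
    out = []
    for call in calls:
        merged: list[ResidueRange] = [call.ranges[0]]
        for r in call.ranges[1:]:
            gap = r.start - merged[-1].end - 1
            if gap < min_insertion:
                merged[-1] = ResidueRange(merged[-1].start, r.end)
            else:
                merged.append(r)
        total = sum(len(r) for r in merged)
        out.append(
            DomainCall(
                domain_id=call.domain_id,
                ranges=merged,
                label=call.label,
                label_rmsd=call.label_rmsd,
                label_core_atoms=call.label_core_atoms,
                part_fractions=[len(r) / total for r in merged],
                split=len(merged) > 1,
            )
        )
    return out


def label_by_reference(
    call: DomainCall,
    model: StructureModel,
    reference: StructureModel,
    pairing: Sequence[tuple[int, int]],
    label: str,
    min_pairs: int = 20,
    **core_kwargs,
) -> DomainCall:
    """Attach a homology label to a call via core C-alpha superposition.

    ``pairing`` maps 0-based indices of ``model`` onto ``reference``; only
    pairs whose model residue lies inside the call are used.  When fewer
    than ``min_pairs`` remain, labelling is skipped with a warning and the
    call is returned unchanged.
    """
    residues = call.residue_set()
    kept = [
        (i, j) for i, j in pairing if int(model.residue_numbers[i]) in residues
    ]
    if len(kept) < min_pairs:
        logger.warning(
            "labelling %s as %s skipped: only %d residue pairs (< %d)",
            call.domain_id, label, len(kept), min_pairs,
        )
        return call
    ia = [i for i, _ in kept]
    ib = [j for _, j in kept]
    result = core_superpose(model.ca_coords[ia], reference.ca_coords[ib], **core_kwargs)
    return DomainCall(
        domain_id=call.domain_id,
        ranges=list(call.ranges),
        label=label,
        label_rmsd=result.rmsd,
        label_core_atoms=result.n_core,
        part_fractions=list(call.part_fractions),
        split=call.split,
    )


@dataclass
class DomainMatch:
    domain_id: str
    reference_id: str
    jaccard: float
    start_delta: int
    end_delta: int
    agrees: bool


@dataclass
class ArchitectureDiff:
    matches: list[DomainMatch]
    missing: list[str]  # reference domains with no counterpart
    extra: list[str]  # called domains with no counterpart

    @property
    def agreement(self) -> float:
        """Fraction of reference domains matched with boundary deltas within slack."""
        n_ref = len(self.matches) + len(self.missing)
        if n_ref == 0:
            return 1.0
        return sum(m.agrees for m in self.matches) / n_ref


def compare_architecture(
    arch: Architecture, reference: Architecture, slack: int = 5
) -> ArchitectureDiff:
    """Match called domains to reference domains by best residue-set Jaccard.

    Greedy one-to-one matching in decreasing Jaccard order; a match
    "agrees" when both outermost boundary deltas are <= ``slack``.
    """
    if arch.length != reference.length:
        raise ValueError("architectures describe chains of different length")
    cand = []
    for call in arch.domains:
        cs = call.residue_set()
        for ref in reference.domains:
            rs = ref.residue_set()
            inter = len(cs & rs)
            if inter:
                cand.append((inter / len(cs | rs), call, ref))
    cand.sort(key=lambda t: (-t[0], t[1].start, t[2].start))
    used_call: set[str] = set()
    used_ref: set[str] = set()
    matches = []
    for jac, call, ref in cand:
        if call.domain_id in used_call or ref.domain_id in used_ref:
            continue
        used_call.add(call.domain_id)
        used_ref.add(ref.domain_id)
        sd = abs(call.start - ref.start)
        ed = abs(call.end - ref.end)
        matches.append(
            DomainMatch(
                domain_id=call.domain_id,
                reference_id=ref.domain_id,
                jaccard=jac,
                start_delta=sd,
                end_delta=ed,
                agrees=sd <= slack and ed <= slack,
            )
        )
    missing = [d.domain_id for d in reference.domains if d.domain_id not in used_ref]
    extra = [d.domain_id for d in arch.domains if d.domain_id not in used_call]
    return ArchitectureDiff(matches=matches, missing=missing, extra=extra)
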