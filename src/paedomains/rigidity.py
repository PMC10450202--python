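"""Rigid-unit and interdomain-contact inference from a PAE matrix.

Segments that are rigid relative to each other show low mutual PAE (the
dark squares of an AFDB error plot); flexibly linked segments show high
mutual PAE.  Structured segments are clustered by average-linkage
hierarchical clustering on the median symmetrised cross-PAE, and the same
dendrogram is cut at two heights to give nested partitions: tight
"domain"-level units and looser "assembly"-level rigid arrangements.
Off-diagonal blocks between domain-level units are then scored for
interdomain contacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model_io import PAEMatrix
from .segmentation import Segment

DEFAULT_TAU_DOMAIN = 5.0
DEFAULT_TAU_ASSEMBLY = 10.0
DEFAULT_TAU_CONTACT = 12.0
DEFAULT_SYMMETRIZE: Literal["min", "mean"] = "min"


@dataclass
class RigidUnit:
    """A set of structured segments predicted to be mutually immobile."""

    member_segments: list[Segment]
    level: Literal["domain", "assembly"]

    def __post_init__(self) -> None:
        if not self.member_segments:
            raise ValueError("a rigid unit needs at least one member segment")
        starts = [s.range.start for s in self.member_segments]
        if len(set(starts)) != len(starts):
            raise ValueError("duplicate member segments")
        self.member_segments.sort(key=lambda s: s.range.start)

    @property
    def start(self) -> int:
        return self.member_segments[0].range.start

    def residue_indices(self) -> np.ndarray:
        """0-based matrix indices of all member residues."""
        idx = [np.arange(s.range.start - 1, s.range.end) for s in self.member_segments]
        return np.concatenate(idx)


@dataclass
class ContactCall:
    """Median symmetrised cross-PAE between two domain-level units."""

    domain_a: str
    domain_b: str
    score: float
    is_contact: bool

    def __post_init__(self) -> None:
        if self.domain_a == self.domain_b:
            raise ValueError("a contact call needs two distinct domains")
        if self.score < 0:
            raise ValueError("contact score must be non-negative")

    def to_json(self) -> dict:
        return {
            "domain_a": self.domain_a,
            "domain_b": self.domain_b,
            "score": round(float(self.score), 4),
            "is_contact": bool(self.is_contact),
        }

    @classmethod
    def from_json(cls, payload: dict) -> "ContactCall":
        return cls(
            domain_a=payload["domain_a"],
            domain_b=payload["domain_b"],
            score=float(payload["score"]),
            is_contact=bool(payload["is_contact"]),
        )


def symmetrize_pae(pae: PAEMatrix, mode: Literal["min", "mean"] = DEFAULT_SYMMETRIZE) -> np.ndarray:
    """Symmetrise a PAE matrix into a dissimilarity: min (default) or mean
    of the (i, j) and (j, i) entries.  Diagonal forced to zero."""
    if mode == "min":
        sym = np.minimum(pae.values, pae.values.T)
    elif mode == "mean":
        sym = 0.5 * (pae.values + pae.values.T)
    else:
        raise ValueError(f"unknown symmetrization mode {mode!r}")
    np.fill_diagonal(sym, 0.0)
    return sym


def _segment_dissimilarity(segments: Sequence[Segment], sym: np.ndarray) -> np.ndarray:
    """Segment-to-segment dissimilarity: median symmetrised PAE over all
    residue pairs of the two segments."""
    k = len(segments)
    d = np.zeros((k, k))
    slices = [slice(s.range.start - 1, s.range.end) for s in segments]
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = np.median(sym[slices[i], slices[j]])
    return d


def _linkage(segments: Sequence[Segment], sym: np.ndarray):
    d = _segment_dissimilarity(segments, sym)
    if len(segments) == 1:
        return None
    return linkage(squareform(d, checks=False), method="average")


def _cut(segments: Sequence[Segment], Z, tau: float) -> list[list[Segment]]:
    if Z is None:
        return [list(segments)]
    labels = fcluster(Z, t=tau, criterion="distance")
    clusters: dict[int, list[Segment]] = {}
    for seg, lab in zip(segments, labels):
        clusters.setdefault(int(lab), []).append(seg)
    # deterministic order: by lowest member start
    out = [sorted(c, key=lambda s: s.range.start) for c in clusters.values()]
    out.sort(key=lambda c: c[0].range.start)
    return out


def cluster_segments(
    segments: Sequence[Segment],
    pae: PAEMatrix,
    tau: float,
    mode: Literal["min", "mean"] = DEFAULT_SYMMETRIZE,
) -> list[list[Segment]]:
    """Partition structured segments by cutting the average-linkage
    dendrogram of median cross-PAE at height ``tau``."""
    segments = [s for s in segments if s.structured]
    if not segments:
        raise ValueError("need at least one structured segment")
    sym = symmetrize_pae(pae, mode)
    return _cut(segments, _linkage(segments, sym), tau)


def rigid_assemblies(
    segments: Sequence[Segment],
    pae: PAEMatrix,
    tau_domain: float = DEFAULT_TAU_DOMAIN,
    tau_assembly: float = DEFAULT_TAU_ASSEMBLY,
    mode: Literal["min", "mean"] = DEFAULT_SYMMETRIZE,
) -> tuple[list[RigidUnit], list[RigidUnit]]:
    """Nested domain-level and assembly-level partitions from one dendrogram.

    Cutting the same tree at two heights guarantees every domain-level
    unit lies within exactly one assembly-level unit.
    """
    if tau_domain >= tau_assembly:
        raise ValueError("tau_domain must be < tau_assembly")
    structured = [s for s in segments if s.structured]
    if not structured:
        raise ValueError("need at least one structured segment")
    sym = symmetrize_pae(pae, mode)
    Z = _linkage(structured, sym)
    domains = [RigidUnit(c, "domain") for c in _cut(structured, Z, tau_domain)]
    assemblies = [RigidUnit(c, "assembly") for c in _cut(structured, Z, tau_assembly)]
    return domains, assemblies


def contact_matrix(
    domain_units: Sequence[RigidUnit],
    pae: PAEMatrix,
    tau_contact: float = DEFAULT_TAU_CONTACT,
    mode: Literal["min", "mean"] = DEFAULT_SYMMETRIZE,
    names: Sequence[str] | None = None,
) -> list[ContactCall]:
    """Score every unordered pair of domain-level units for contact.

    The score is the median symmetrised PAE over the cross block; a pair
    is called in contact when the score is <= ``tau_contact``.
    """
    if names is None:
        names = [f"D{i + 1}" for i in range(len(domain_units))]
    sym = symmetrize_pae(pae, mode)
    calls = []
    for i in range(len(domain_units)):
        for j in range(i + 1, len(domain_units)):
            ia = domain_units[i].residue_indices()
            ib = domain_units[j].residue_indices()
            score = float(np.median(sym[np.ix_(ia, ib)]))
            calls.append(
                ContactCall(
                    domain_a=names[i],
                    domain_b=names[j],
                    score=score,
                    is_contact=score <= tau_contact,
                )
            )
    return calls
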