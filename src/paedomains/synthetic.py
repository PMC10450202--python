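"""Synthetic AF2-style outputs with planted, machine-readable ground truth.

The generator emulates the features of real AlphaFold2 output that the
pipeline consumes: a C-alpha trace with compact high-confidence domains
joined by extended low-confidence linkers, a PAE matrix with dark
low-error squares for rigid units, intermediate off-diagonal blocks for
domains rigidified into one assembly, a high-error ramp elsewhere, and the
low-error near-diagonal band always present in real matrices.  Split
domains (one spatial unit, two sequence segments) and two-state NMR
intensity profiles are also planted.  Everything is deterministic given
the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .domains import Architecture, DomainCall
from .model_io import (
    DEFAULT_PAE_CEILING,
    PAEMatrix,
    ResidueRange,
    StructureModel,
)
from .rigidity import ContactCall

_AA = "ACDEFGHIKLMNPQRSTVWY"

CA_STEP = 3.8  # Angstrom, consecutive C-alpha distance
MIN_CLASH = 3.0  # Angstrom, self-avoidance cutoff within a domain walk
DOMAIN_PLDDT_MEAN = 88.0
LINKER_PLDDT_MEAN = 40.0
PAE_INTRA_DOMAIN = 3.0
PAE_INTRA_ASSEMBLY = 6.0
PAE_RAMP_BASE = 12.0
PAE_RAMP_SLOPE = 0.05
NEAR_DIAGONAL_BAND = 4  # |i-j| <= band is always low-error


class GenerationError(RuntimeError):
    """Raised when geometric placement fails after bounded retries."""


@dataclass(frozen=True)
class Element:
    kind: Literal["domain", "linker"]
    length: int
    domain_id: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("element length must be >= 1")
        if self.kind == "domain" and not self.domain_id:
            raise ValueError("domain elements need a domain_id")
        if self.kind == "linker" and self.domain_id is not None:
            raise ValueError("linkers never carry a domain_id")


@dataclass
class Noise:
    plddt_sigma: float = 6.0
    pae_sigma: float = 1.0
    intensity_sigma: float = 0.1


@dataclass
class SyntheticSpec:
    """Blueprint for one synthetic chain.

    ``elements`` lays the chain out N- to C-terminal; a domain_id occurring
    in two or more non-adjacent elements defines a split domain (one
    spatial unit, several sequence segments).  ``assemblies`` lists sets of
    domain_ids that are mutually rigid (low cross-PAE).
    """

    elements: list[Element]
    assemblies: list[frozenset[str]] = field(default_factory=list)
    noise: Noise = field(default_factory=Noise)
    seed: int = 0

    def __post_init__(self) -> None:
        self.assemblies = [frozenset(a) for a in self.assemblies]
        if self.total_length < 30:
            raise ValueError("total length must be >= 30 residues")
        ids = set(self.domain_ids)
        for assembly in self.assemblies:
            unknown = assembly - ids
            if unknown:
                raise ValueError(f"assembly references unknown domains {sorted(unknown)}")

    @property
    def total_length(self) -> int:
        return sum(e.length for e in self.elements)

    @property
    def domain_ids(self) -> list[str]:
        seen: list[str] = []
        for e in self.elements:
            if e.kind == "domain" and e.domain_id not in seen:
                seen.append(e.domain_id)
        return seen

    @property
    def split_memberships(self) -> dict[str, list[int]]:
        """domain_id -> indices of its element occurrences (>= 2 => split)."""
        occ: dict[str, list[int]] = {}
        for k, e in enumerate(self.elements):
            if e.kind == "domain":
                occ.setdefault(e.domain_id, []).append(k)
        return {d: idx for d, idx in occ.items() if len(idx) >= 2}

    def element_ranges(self) -> list[ResidueRange]:
        ranges = []
        pos = 1
        for e in self.elements:
            ranges.append(ResidueRange(pos, pos + e.length - 1))
            pos += e.length
        return ranges

    def assembly_of(self, domain_id: str) -> frozenset[str]:
        for assembly in self.assemblies:
            if domain_id in assembly:
                return assembly
        return frozenset([domain_id])

    def contact_pairs(self) -> set[frozenset[str]]:
        pairs: set[frozenset[str]] = set()
        for assembly in self.assemblies:
            members = sorted(assembly)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.add(frozenset({members[i], members[j]}))
        return pairs

    def to_json(self) -> dict:
        return {
            "elements": [
                {"kind": e.kind, "length": e.length, "domain_id": e.domain_id}
                for e in self.elements
            ],
            "assemblies": [sorted(a) for a in self.assemblies],
            "noise": {
                "plddt_sigma": self.noise.plddt_sigma,
                "pae_sigma": self.noise.pae_sigma,
                "intensity_sigma": self.noise.intensity_sigma,
            },
            "seed": self.seed,
        }

    @classmethod
    def from_json(cls, payload: dict) -> "SyntheticSpec":
        return cls(
            elements=[
                Element(e["kind"], int(e["length"]), e.get("domain_id"))
                for e in payload["elements"]
            ],
            assemblies=[frozenset(a) for a in payload.get("assemblies", [])],
            noise=Noise(**payload.get("noise", {})),
            seed=int(payload.get("seed", 0)),
        )


@dataclass
class GroundTruth:
    """Planted truth: what a perfect pipeline run should recover."""

    architecture: Architecture
    contact_pairs: set[frozenset[str]]
    immobilized_in_bound: set[str] = field(default_factory=set)

    def to_json(self) -> dict:
        return {
            "architecture": self.architecture.to_json(),
            "contact_pairs": sorted(sorted(p) for p in self.contact_pairs),
            "immobilized_in_bound": sorted(self.immobilized_in_bound),
        }

    @classmethod
    def from_json(cls, payload: dict) -> "GroundTruth":
        return cls(
            architecture=Architecture.from_json(payload["architecture"]),
            contact_pairs={frozenset(p) for p in payload["contact_pairs"]},
            immobilized_in_bound=set(payload.get("immobilized_in_bound", [])),
        )


def planted_architecture(spec: SyntheticSpec, entry_id: str = "synthetic") -> Architecture:
    """The Architecture a perfect run should produce for ``spec``."""
    ranges = spec.element_ranges()
    by_domain: dict[str, list[ResidueRange]] = {}
    disordered: list[ResidueRange] = []
    for e, r in zip(spec.elements, ranges):
        if e.kind == "domain":
            by_domain.setdefault(e.domain_id, []).append(r)
        else:
            disordered.append(r)
    calls = []
    for domain_id, dr in by_domain.items():
        calls.append(DomainCall(domain_id=domain_id, ranges=dr, split=len(dr) > 1))
    contacts = [
        ContactCall(domain_a=min(p), domain_b=max(p), score=PAE_INTRA_ASSEMBLY, is_contact=True)
        for p in sorted(spec.contact_pairs(), key=sorted)
    ]
    return Architecture(
        entry_id=entry_id,
        length=spec.total_length,
        domains=calls,
        disordered=disordered,
        contacts=contacts,
    )


# ---------------------------------------------------------------------------
# geometry


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _domain_walk(
    rng: np.random.Generator,
    start: np.ndarray,
    center: np.ndarray,
    radius: float,
    n: int,
    existing: list[np.ndarray],
    max_step_tries: int = 200,
) -> list[np.ndarray]:
    """Self-avoiding 3.8 Angstrom walk confined to a sphere.

    Dead ends are escaped by backtracking a few atoms and re-growing; only
    when the backtracking budget is exhausted does generation fail.
    """
    coords = list(existing)
    pos = start
    out: list[np.ndarray] = []
    backtracks = 0
    while len(out) < n:
        for attempt in range(max_step_tries):
            proposal = pos + CA_STEP * _random_unit(rng)
            if np.linalg.norm(proposal - center) > radius:
                continue
            if coords:
                arr = np.asarray(coords)
                d = np.linalg.norm(arr - proposal, axis=1)
                if d.min() < MIN_CLASH:
                    continue
            break
        else:
            backtracks += 1
            if backtracks > 50 or not out:
                raise GenerationError("self-avoiding walk stuck")
            drop = min(5, len(out))
            del out[-drop:]
            del coords[-drop:]
            pos = out[-1] if out else start
            continue
        out.append(proposal)
        coords.append(proposal)
        pos = proposal
    return out


def _linker_walk(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    n: int,
    target: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Extended walk; when ``target`` is given, steps are biased to arrive
    near it (used for insertions that must return to a split domain)."""
    pos = start
    d = direction.copy()
    out = []
    for k in range(n):
        if target is not None:
            to_target = target - pos
            dist = np.linalg.norm(to_target)
            remaining = n - k
            w = float(np.clip(dist / (0.9 * CA_STEP * max(remaining, 1)), 0.15, 1.0))
            d = w * (to_target / max(dist, 1e-9)) + (1 - w) * _random_unit(rng)
        else:
            d = d + 0.3 * _random_unit(rng)
        d = d / np.linalg.norm(d)
        pos = pos + CA_STEP * d
        out.append(pos)
    return out


def generate_model(
    spec: SyntheticSpec, entry_id: str = "synthetic", max_restarts: int = 20
) -> tuple[StructureModel, GroundTruth]:
    """Generate the C-alpha model (with pLDDT) and its planted truth.

    Domains are self-avoiding walks confined to a sphere of radius
    2.5 * L^(1/3) Angstrom (all occurrences of a split domain share one
    sphere); linkers are extended walks, biased to return when they are
    the insertion of a split domain.  pLDDT is Normal(88, sigma) in
    domains and Normal(40, 5 sigma / 3) in linkers, clipped to [0, 100],
    with a 3-residue taper across element boundaries.
    """
    rng = np.random.default_rng([spec.seed, 11])
    for _ in range(max_restarts):
        try:
            coords = _generate_trace(spec, rng)
            break
        except GenerationError:
            continue
    else:
        raise GenerationError("could not place chain after bounded retries")

    plddt = _generate_plddt(spec, np.random.default_rng([spec.seed, 13]))
    seq_rng = np.random.default_rng([spec.seed, 17])
    sequence = "".join(seq_rng.choice(list(_AA), size=spec.total_length))
    model = StructureModel(
        entry_id=entry_id,
        chain_id="A",
        residue_numbers=np.arange(1, spec.total_length + 1),
        sequence=sequence,
        ca_coords=np.asarray(coords),
        plddt=plddt,
    )
    truth = GroundTruth(
        architecture=planted_architecture(spec, entry_id),
        contact_pairs=spec.contact_pairs(),
    )
    return model, truth


def _generate_trace(spec: SyntheticSpec, rng: np.random.Generator) -> list[np.ndarray]:
    coords: list[np.ndarray] = []
    spheres: dict[str, tuple[np.ndarray, float]] = {}
    domain_atoms: dict[str, list[np.ndarray]] = {}
    total_len: dict[str, int] = {}
    for e in spec.elements:
        if e.kind == "domain":
            total_len[e.domain_id] = total_len.get(e.domain_id, 0) + e.length

    pos = np.zeros(3)
    direction = np.array([1.0, 0.0, 0.0])
    seen: set[str] = set()
    for k, e in enumerate(spec.elements):
        if e.kind == "domain":
            radius = 2.5 * total_len[e.domain_id] ** (1.0 / 3.0)
            if e.domain_id not in spheres:
                center = pos + direction * (0.6 * radius)
                spheres[e.domain_id] = (center, radius)
                domain_atoms[e.domain_id] = []
            center, radius = spheres[e.domain_id]
            start = pos
            # re-entry for a split continuation that drifted out of the sphere
            while np.linalg.norm(start - center) > radius:
                step = (center - start)
                start = start + CA_STEP * step / np.linalg.norm(step)
            walk = _domain_walk(
                rng, start, center, radius, e.length, domain_atoms[e.domain_id]
            )
            domain_atoms[e.domain_id].extend(walk)
            coords.extend(walk)
            pos = walk[-1]
            direction = _random_unit(rng)
            seen.add(e.domain_id)
        else:
            target = None
            nxt = spec.elements[k + 1] if k + 1 < len(spec.elements) else None
            if nxt is not None and nxt.kind == "domain" and nxt.domain_id in spheres:
                center, radius = spheres[nxt.domain_id]
                target = center + 0.5 * radius * _random_unit(rng)
            walk = _linker_walk(rng, pos, direction, e.length, target=target)
            coords.extend(walk)
            pos = walk[-1]
            direction = (pos - walk[-2]) if len(walk) > 1 else direction
            direction = direction / np.linalg.norm(direction)
    return coords


def _generate_plddt(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    means = np.concatenate(
        [
            np.full(
                e.length,
                DOMAIN_PLDDT_MEAN if e.kind == "domain" else LINKER_PLDDT_MEAN,
            )
            for e in spec.elements
        ]
    )
    # 3-residue linear taper across element boundaries
    kernel = np.ones(3) / 3.0
    tapered = np.convolve(np.pad(means, 1, mode="edge"), kernel, mode="valid")
    sigma = np.concatenate(
        [
            np.full(
                e.length,
                spec.noise.plddt_sigma
                if e.kind == "domain"
                else spec.noise.plddt_sigma * 5.0 / 3.0,
            )
            for e in spec.elements
        ]
    )
    values = tapered + rng.normal(size=spec.total_length) * sigma
    return np.clip(values, 0.0, 100.0)


# ---------------------------------------------------------------------------
# PAE


def generate_pae(spec: SyntheticSpec) -> PAEMatrix:
    """Generate the planted PAE matrix.

    Expected values: 3 Angstrom within one domain, 6 Angstrom between
    distinct domains of one assembly, and a 12 + 0.05 |i-j| ramp for
    everything else (pairs involving linkers or unrelated domains).  The
    near-diagonal band (|i-j| <= 4) is forced low as in real matrices.
    Noise is drawn independently for (i, j) and (j, i), so the output is
    asymmetric like real AFDB matrices.
    """
    rng = np.random.default_rng([spec.seed, 23])
    n = spec.total_length
    domain_of = np.full(n, -1)
    ids = spec.domain_ids
    for e, r in zip(spec.elements, spec.element_ranges()):
        if e.kind == "domain":
            domain_of[r.start - 1 : r.end] = ids.index(e.domain_id)

    idx = np.arange(n)
    seps = np.abs(idx[:, None] - idx[None, :])
    mean = PAE_RAMP_BASE + PAE_RAMP_SLOPE * seps
    sigma = np.full((n, n), 2.0 * spec.noise.pae_sigma)

    same_domain = (domain_of[:, None] == domain_of[None, :]) & (domain_of[:, None] >= 0)
    assembly_index = np.full(n, -1)
    assemblies = {frozenset(a) for a in spec.assemblies}
    for ai, assembly in enumerate(sorted(assemblies, key=sorted)):
        for d in assembly:
            assembly_index[domain_of == ids.index(d)] = ai
    same_assembly = (
        (assembly_index[:, None] == assembly_index[None, :])
        & (assembly_index[:, None] >= 0)
        & ~same_domain
        & (domain_of[:, None] >= 0)
        & (domain_of[None, :] >= 0)
    )
    mean[same_assembly] = PAE_INTRA_ASSEMBLY
    sigma[same_assembly] = spec.noise.pae_sigma
    mean[same_domain] = PAE_INTRA_DOMAIN
    sigma[same_domain] = spec.noise.pae_sigma

    values = mean + rng.normal(size=(n, n)) * sigma
    band = seps <= NEAR_DIAGONAL_BAND
    values[band] = np.minimum(values[band], 4.0)
    values = np.clip(values, 0.0, DEFAULT_PAE_CEILING)
    np.fill_diagonal(values, 0.0)
    return PAEMatrix(values=values, max_value=DEFAULT_PAE_CEILING)


# ---------------------------------------------------------------------------
# intensity profiles


def generate_intensity_profiles(
    spec: SyntheticSpec, immobilized: Iterable[str] = ()
) -> pd.DataFrame:
    """Two-state per-residue crosspeak-intensity table.

    Free-state intensities are ~1.0 everywhere (independently tumbling
    small domains and linkers give sharp crosspeaks).  In the bound state,
    residues of immobilized domains are scaled by a factor drawn from
    U(0.05, 0.15) per domain (their signals broaden away inside the large
    rigid particle); everything else keeps U(0.8, 1.0) of its intensity.
    Multiplicative log-normal noise is applied, and 10% of residues are
    masked "NA" (unassigned), chosen uniformly.
    """
    immobilized = set(immobilized)
    unknown = immobilized - set(spec.domain_ids)
    if unknown:
        raise ValueError(f"immobilized references unknown domains {sorted(unknown)}")
    rng = np.random.default_rng([spec.seed, 29])
    n = spec.total_length
    bound_scale = np.empty(n)
    factors = {
        d: rng.uniform(0.05, 0.15) if d in immobilized else rng.uniform(0.8, 1.0)
        for d in spec.domain_ids
    }
    for e, r in zip(spec.elements, spec.element_ranges()):
        if e.kind == "domain":
            bound_scale[r.start - 1 : r.end] = factors[e.domain_id]
        else:
            bound_scale[r.start - 1 : r.end] = rng.uniform(0.8, 1.0)

    sigma = spec.noise.intensity_sigma
    free = np.exp(rng.normal(0.0, sigma, size=n))
    bound = bound_scale * np.exp(rng.normal(0.0, sigma, size=n))
    masked = rng.choice(n, size=int(round(0.1 * n)), replace=False)
    free[masked] = np.nan
    bound[masked] = np.nan
    return pd.DataFrame(
        {
            "residue": np.arange(1, n + 1),
            "intensity_free": free,
            "intensity_bound": bound,
        }
    )


# ---------------------------------------------------------------------------
# stock specs


def default_spec(seed: int = 0, noise: Noise | None = None) -> SyntheticSpec:
    """The default benchmark chain: three domains, one rigid assembly
    (A + B) and one split domain (B, interrupted by a 45-residue
    disordered insertion)."""
    return SyntheticSpec(
        elements=[
            Element("domain", 110, "A"),
            Element("linker", 30),
            Element("domain", 90, "B"),
            Element("linker", 45),
            Element("domain", 45, "B"),
            Element("linker", 25),
            Element("domain", 100, "C"),
        ],
        assemblies=[frozenset({"A", "B"})],
        noise=noise or Noise(),
        seed=seed,
    )


def parp1_like_spec(seed: int = 0, noise: Noise | None = None) -> SyntheticSpec:
    """A beads-on-string chain shaped like PARP1's small-domain region:
    three zinc fingers, BRCT and WGR on flexible linkers.  With all
    domains but BRCT immobilized it reproduces the DNA-bound collapse
    pattern in which only BRCT and the linkers stay mobile."""
    return SyntheticSpec(
        elements=[
            Element("domain", 90, "ZnF1"),
            Element("linker", 12),
            Element("domain", 90, "ZnF2"),
            Element("linker", 110),
            Element("domain", 90, "ZnF3"),
            Element("linker", 25),
            Element("domain", 100, "BRCT"),
            Element("linker", 35),
            Element("domain", 95, "WGR"),
        ],
        noise=noise or Noise(),
        seed=seed,
    )


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_json(), indent=1, sort_keys=True))


def read_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(json.loads(Path(path).read_text()))
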