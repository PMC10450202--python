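"""Readers and writers for the formats the pipeline touches.

Predicted models arrive as PDB or mmCIF files that follow the AlphaFold
Protein Structure Database convention: the per-residue confidence score
(pLDDT, 0-100) is stored in the B-factor column of every atom.  Predicted
aligned error (PAE) matrices arrive as the AFDB JSON dialect.  Inferred
domain architectures are exchanged as a small versioned JSON document, and
NMR crosspeak-intensity profiles as tab-separated tables.

Only C-alpha atoms are retained in :class:`StructureModel`: every
downstream computation (segmentation, superposition, RMSD) is C-alpha-only.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default PAE clip ceiling (Angstrom) used by the AFDB when the JSON omits it.
DEFAULT_PAE_CEILING = 31.75

ARCHITECTURE_SCHEMA_VERSION = "1"

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted in its declared format."""


class EmptyInputError(ValueError):
    """Raised when a structurally valid file contains no usable residues."""


class SchemaVersionError(FormatError):
    """Raised when an architecture JSON declares an unsupported schema version."""


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive 1-based residue interval ``start``-``end``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid residue range {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, residue: int) -> bool:
        return self.start <= residue <= self.end

    def residues(self) -> range:
        return range(self.start, self.end + 1)

    def to_json(self) -> list[int]:
        return [self.start, self.end]

    @classmethod
    def from_json(cls, payload: Sequence[int]) -> "ResidueRange":
        return cls(int(payload[0]), int(payload[1]))


@dataclass
class StructureModel:
    """One chain of a predicted model: C-alpha trace plus per-residue pLDDT.

    Residue numbers are author numbering (1-based for AFDB models, matching
    UniProt numbering); no renumbering is ever applied.
    """

    entry_id: str
    chain_id: str
    residue_numbers: np.ndarray  # (N,) int
    sequence: str
    ca_coords: np.ndarray  # (N, 3) float, Angstrom
    plddt: np.ndarray  # (N,) float in [0, 100]

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        n = len(self.residue_numbers)
        if not (len(self.sequence) == n == len(self.ca_coords) == len(self.plddt)):
            raise ValueError("field lengths disagree")
        if n and np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError("residue numbers must be strictly increasing")
        if n and (self.plddt.min() < 0 or self.plddt.max() > 100):
            raise ValueError("pLDDT outside [0, 100]")

    def __len__(self) -> int:
        return len(self.residue_numbers)


@dataclass
class PAEMatrix:
    """N x N predicted aligned error in Angstrom.

    Entry (i, j) is the expected positional error of residue i when the
    predicted and true structures are aligned on residue j; the matrix is
    generally asymmetric and must be symmetrised explicitly before being
    used as a dissimilarity.
    """

    values: np.ndarray
    max_value: float = DEFAULT_PAE_CEILING

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("PAE matrix must be square")
        if self.max_value <= 0:
            raise ValueError("max_value must be positive")
        if self.values.size:
            if self.values.min() < 0:
                raise ValueError("PAE entries must be non-negative")
            if self.values.max() > self.max_value + 1e-9:
                raise ValueError("PAE entries exceed max_value")
            if np.any(np.diag(self.values) > 1.0):
                raise ValueError("PAE diagonal entries must be <= 1 Angstrom")

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# structure models


def read_structure_model(path: str | Path, chain: str | None = None) -> StructureModel:
    """Read one chain of a PDB/mmCIF model into a C-alpha-only StructureModel.

    pLDDT is taken from the B-factor of each residue's C-alpha atom (the
    AFDB writes the same score on every atom of a residue).  Residues
    lacking a C-alpha are skipped with a warning; B-factors outside
    [0, 100] are clipped with a warning rather than rejected, to tolerate
    non-AFDB files.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse structure file {path}: {exc}") from exc
    if len(structure) == 0 or len(structure[0]) == 0:
        raise EmptyInputError(f"{path}: no chains found")
    model = structure[0]
    if chain is None:
        gchain = model[0]
    else:
        gchain = model.find_chain(chain)
        if gchain is None:
            raise EmptyInputError(f"{path}: chain {chain!r} not found")

    numbers: list[int] = []
    seq: list[str] = []
    coords: list[tuple[float, float, float]] = []
    plddt: list[float] = []
    for residue in gchain:
        ca = residue.find_atom("CA", "*")
        if ca is None:
            logger.warning(
                "%s: residue %s %d has no CA atom; skipped",
                path.name, residue.name, residue.seqid.num,
            )
            continue
        b = ca.b_iso
        if b < 0 or b > 100:
            logger.warning(
                "%s: residue %d B-factor %.2f outside [0, 100]; clipped",
                path.name, residue.seqid.num, b,
            )
            b = min(max(b, 0.0), 100.0)
        numbers.append(residue.seqid.num)
        seq.append(_THREE_TO_ONE.get(residue.name.upper(), "X"))
        coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
        plddt.append(b)
    if not numbers:
        raise EmptyInputError(f"{path}: chain {gchain.name!r} has no CA-bearing residues")
    return StructureModel(
        entry_id=structure.name or path.stem,
        chain_id=gchain.name,
        residue_numbers=np.array(numbers),
        sequence="".join(seq),
        ca_coords=np.array(coords),
        plddt=np.array(plddt),
    )


def write_structure_model(model: StructureModel, path: str | Path) -> None:
    """Write a C-alpha-only single-chain PDB with pLDDT in the B-factor column."""
    if len(model) == 0:
        raise ValueError("cannot write a 0-residue model")
    if not np.all(np.isfinite(model.ca_coords)):
        raise ValueError("coordinates must be finite")
    lines = []
    serial = 0
    for num, aa, xyz, b in zip(
        model.residue_numbers, model.sequence, model.ca_coords, model.plddt
    ):
        serial += 1
        resname = _ONE_TO_THREE.get(aa, "UNK")
        lines.append(
            f"ATOM  {serial:5d}  CA  {resname:<3s} {model.chain_id[:1] or 'A'}"
            f"{num:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{b:6.2f}           C  "
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PAE


def read_pae(path: str | Path) -> PAEMatrix:
    """Read a PAE matrix in the AFDB JSON dialect.

    Accepts either a top-level object or the AFDB's one-element list
    wrapper; the payload key is ``predicted_aligned_error`` (row-major list
    of lists) with an optional ``max_predicted_aligned_error`` ceiling.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse PAE JSON {path}: {exc}") from exc
    if isinstance(payload, list):
        if not payload:
            raise FormatError(f"{path}: empty PAE payload")
        payload = payload[0]
    if "predicted_aligned_error" not in payload:
        raise FormatError(f"{path}: missing 'predicted_aligned_error' key")
    rows = payload["predicted_aligned_error"]
    n = len(rows)
    if any(len(r) != n for r in rows):
        raise FormatError(f"{path}: PAE payload is not square")
    values = np.asarray(rows, dtype=float)
    if values.size and values.min() < 0:
        raise FormatError(f"{path}: negative PAE entries")
    ceiling = float(payload.get("max_predicted_aligned_error", DEFAULT_PAE_CEILING))
    return PAEMatrix(values=values, max_value=ceiling)


def write_pae(pae: PAEMatrix, path: str | Path) -> None:
    """Write a PAE matrix in the AFDB JSON dialect (exact round trip)."""
    payload = {
        "predicted_aligned_error": pae.values.tolist(),
        "max_predicted_aligned_error": pae.max_value,
    }
    Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# architectures (import-light: the dataclasses live in .domains)


def write_architecture(arch, path: str | Path) -> None:
    """Serialise an Architecture to versioned JSON."""
    Path(path).write_text(json.dumps(arch.to_json(), indent=1, sort_keys=True))


def read_architecture(path: str | Path):
    """Read an Architecture from versioned JSON written by write_architecture."""
    from .domains import Architecture

    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse architecture JSON {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != ARCHITECTURE_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path}: schema version {version!r} != {ARCHITECTURE_SCHEMA_VERSION!r}"
        )
    return Architecture.from_json(payload)


# ---------------------------------------------------------------------------
# intensity tables


def read_intensity_table(path: str | Path) -> pd.DataFrame:
    """Read a per-residue crosspeak-intensity TSV.

    Columns: ``residue``, ``intensity_free``, ``intensity_bound``; the
    string "NA" marks unassigned residues and is read as missing.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    required = {"residue", "intensity_free", "intensity_bound"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: intensity table missing columns {sorted(missing)}")
    df["residue"] = df["residue"].astype(int)
    return df


def write_intensity_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
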