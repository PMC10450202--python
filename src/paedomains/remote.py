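"""Small fetch helpers for public structure resources.

Used by the validation tests that compare predicted models against
experimental structures; they require internet access to the RCSB PDB and
the AlphaFold Protein Structure Database and fail fast when offline.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"
AFDB_MODEL_URL = "https://alphafold.ebi.ac.uk/files/AF-{uniprot}-F1-model_v4.pdb"
AFDB_PAE_URL = (
    "https://alphafold.ebi.ac.uk/files/AF-{uniprot}-F1-predicted_aligned_error_v4.json"
)


class RemoteUnavailableError(RuntimeError):
    """The remote resource could not be reached (offline or blocked)."""


def _fetch(url: str, dest: Path, timeout: float) -> Path:
    if dest.exists():
        return dest
    try:
        with urllib.request.urlopen(url, timeout=timeout) as response:
            data = response.read()
    except OSError as exc:  # URLError, socket.timeout, ...
        raise RemoteUnavailableError(f"cannot fetch {url}: {exc}") from exc
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_bytes(data)
    return dest


def fetch_pdb(pdb_id: str, directory: str | Path, timeout: float = 10.0) -> Path:
    """Download an experimental structure from the RCSB PDB."""
    dest = Path(directory) / f"{pdb_id.upper()}.pdb"
    return _fetch(RCSB_URL.format(pdb_id=pdb_id.upper()), dest, timeout)


def fetch_afdb_model(uniprot: str, directory: str | Path, timeout: float = 10.0) -> Path:
    """Download a precalculated model from the AlphaFold Structure Database."""
    dest = Path(directory) / f"AF-{uniprot}-F1-model_v4.pdb"
    return _fetch(AFDB_MODEL_URL.format(uniprot=uniprot), dest, timeout)


def fetch_afdb_pae(uniprot: str, directory: str | Path, timeout: float = 10.0) -> Path:
    """Download the matching PAE JSON from the AlphaFold Structure Database."""
    dest = Path(directory) / f"AF-{uniprot}-F1-pae_v4.json"
    return _fetch(AFDB_PAE_URL.format(uniprot=uniprot), dest, timeout)
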