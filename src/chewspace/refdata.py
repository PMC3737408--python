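"""Access to the reference CheW entries (UniProt sequences, PDB NMR ensembles).

The two CheW case-study inputs — UniProt sequences P0A964 (*E. coli*) and
Q56311 (*T. maritima*), and the 20-model NMR ensembles 2HO9 and 1K0S — are
not redistributed with the package.  :func:`fetch_reference_data` downloads
them into the package data directory (network required, a few hundred kB);
the loaders below then find them there, or in an explicit directory.
"""

from __future__ import annotations

import urllib.request
from importlib import resources
from pathlib import Path

from .chew import PDB_ENTRIES, UNIPROT_ENTRIES
from .structures import Ensemble, read_fasta, read_pdb_ensemble

__all__ = [
    "data_dir",
    "fetch_reference_data",
    "load_chew_sequence",
    "load_chew_nmr_ensemble",
    "MissingReferenceData",
]

_UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"
_RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


class MissingReferenceData(FileNotFoundError):
    """A reference entry is not present locally."""


def data_dir() -> Path:
    """The package data directory used for reference entries."""
    return Path(resources.files("chewspace") / "data")


def _locate(filename: str, directory: str | Path | None) -> Path:
    candidates = [Path(directory) / filename] if directory else []
    candidates.append(data_dir() / filename)
    for path in candidates:
        if path.exists():
            return path
    raise MissingReferenceData(
        f"{filename} not found (looked in {[str(c.parent) for c in candidates]}). "
        f"Run `chewspace fetch-reference-data` (network required) or place the "
        f"file there yourself."
    )


def fetch_reference_data(dest: str | Path | None = None, timeout: float = 60.0) -> list[Path]:
    """Download the four reference entries into ``dest`` (default: package data).

    Returns the list of written paths.  Requires network access; the files
    are small (the two NMR entries are a few hundred kB each).
    """
    dest = Path(dest) if dest else data_dir()
    dest.mkdir(parents=True, exist_ok=True)
    written = []
    for acc in UNIPROT_ENTRIES.values():
        written.append(_download(_UNIPROT_URL.format(acc=acc), dest / f"{acc}.fasta", timeout))
    for pdb_id in PDB_ENTRIES.values():
        written.append(_download(_RCSB_URL.format(pdb_id=pdb_id), dest / f"{pdb_id}.pdb", timeout))
    return written


def _download(url: str, path: Path, timeout: float) -> Path:
    with urllib.request.urlopen(url, timeout=timeout) as response:
        path.write_bytes(response.read())
    return path


def load_chew_sequence(organism: str, directory: str | Path | None = None) -> str:
    """The CheW sequence of ``"ecoli"`` or ``"tmaritima"`` (UniProt entry)."""
    acc = UNIPROT_ENTRIES[organism]
    path = _locate(f"{acc}.fasta", directory)
    return read_fasta(path)[0][1]


def load_chew_nmr_ensemble(
    organism: str, directory: str | Path | None = None
) -> Ensemble:
    """The deposited 20-model NMR ensemble of ``"ecoli"`` (2HO9) or
    ``"tmaritima"`` (1K0S)."""
    pdb_id = PDB_ENTRIES[organism]
    path = _locate(f"{pdb_id}.pdb", directory)
    return read_pdb_ensemble(path)
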