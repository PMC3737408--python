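"""Core structural data model: atoms, single conformations, and multi-model ensembles.

The unit of analysis is a :class:`Structure` (one conformation — one model of an
NMR entry, one homology model, or one Monte Carlo frame) and an
:class:`Ensemble` (an ordered list of conformations sharing one topology, e.g.
the 20 models deposited for an NMR structure determination).  Coordinates are
stored as numpy arrays in Å; residue numbering is taken verbatim from the PDB
fields (1-based) and never renumbered, because every residue-subset definition
used downstream is expressed in that numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "Structure",
    "Ensemble",
    "TopologyError",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_fasta",
]

#: Maximum coordinate magnitude representable in the fixed-width PDB field (8.3f).
_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999


class TopologyError(ValueError):
    """Raised when structures expected to share a topology do not."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus Cartesian coordinates in Å."""

    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    coords: np.ndarray
    chain_id: str = "A"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"coords must be a finite 3-vector, got {self.coords!r}")
        object.__setattr__(self, "coords", coords)
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")


class Structure:
    """One conformation: ordered atom records, grouped contiguously by residue.

    Internally column-oriented (parallel numpy arrays) so that selections and
    RMSD computations are vectorised; :attr:`atoms` offers the record view.
    """

    def __init__(
        self,
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        atom_names: Sequence[str],
        elements: Sequence[str],
        coords: np.ndarray,
        chain_ids: Sequence[str] | None = None,
        label: str = "",
    ) -> None:
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype="U3")
        self.atom_names = np.asarray(atom_names, dtype="U4")
        self.elements = np.char.upper(np.asarray(elements, dtype="U2"))
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(self.residue_numbers)
        if chain_ids is None:
            chain_ids = ["A"] * n
        self.chain_ids = np.asarray(chain_ids, dtype="U1")
        self.label = label
        self._validate()

    def _validate(self) -> None:
        n = len(self.residue_numbers)
        if n == 0:
            raise ValueError("Structure must contain at least one atom")
        for name, arr in (
            ("residue_names", self.residue_names),
            ("atom_names", self.atom_names),
            ("elements", self.elements),
            ("coords", self.coords),
            ("chain_ids", self.chain_ids),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.residue_numbers < 1):
            raise ValueError("residue numbers must be >= 1")
        # contiguous grouping: a residue number never reappears after a change
        changes = np.flatnonzero(np.diff(self.residue_numbers) != 0)
        starts = self.residue_numbers[np.concatenate(([0], changes + 1))]
        if len(np.unique(starts)) != len(starts):
            raise ValueError("atoms of one residue must be contiguous")

    @classmethod
    def from_atoms(cls, atoms: Sequence[AtomRecord], label: str = "") -> "Structure":
        return cls(
            [a.residue_number for a in atoms],
            [a.residue_name for a in atoms],
            [a.atom_name for a in atoms],
            [a.element for a in atoms],
            np.array([a.coords for a in atoms]),
            [a.chain_id for a in atoms],
            label=label,
        )

    @property
    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                int(self.residue_numbers[i]),
                str(self.residue_names[i]),
                str(self.atom_names[i]),
                str(self.elements[i]),
                self.coords[i].copy(),
                str(self.chain_ids[i]),
            )

    @property
    def n_atoms(self) -> int:
        return len(self.residue_numbers)

    @property
    def unique_residues(self) -> np.ndarray:
        """Residue numbers in order of first appearance."""
        _, idx = np.unique(self.residue_numbers, return_index=True)
        return self.residue_numbers[np.sort(idx)]

    @property
    def n_residues(self) -> int:
        return len(self.unique_residues)

    def topology_key(self) -> tuple:
        """Signature identifying the shared topology of an ensemble."""
        return tuple(
            zip(
                self.residue_numbers.tolist(),
                self.residue_names.tolist(),
                self.atom_names.tolist(),
            )
        )

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates (topology shared)."""
        return Structure(
            self.residue_numbers,
            self.residue_names,
            self.atom_names,
            self.elements,
            np.asarray(coords, dtype=float),
            self.chain_ids,
            label=self.label if label is None else label,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<Structure {self.label!r}: {self.n_residues} residues, "
            f"{self.n_atoms} atoms>"
        )


class Ensemble:
    """Ordered list of conformations sharing one topology."""

    def __init__(self, members: Sequence[Structure], label: str = "") -> None:
        if len(members) == 0:
            raise ValueError("Ensemble must contain at least one member")
        self.members = list(members)
        self.label = label
        ref = self.members[0]
        ref_key = ref.topology_key()
        for m, member in enumerate(self.members[1:], start=2):
            key = member.topology_key()
            if key != ref_key:
                for a, (ka, kb) in enumerate(zip(ref_key, key)):
                    if ka != kb:
                        raise TopologyError(
                            f"member {m} of ensemble {label!r} diverges at atom "
                            f"{a + 1}: expected {ka}, found {kb}"
                        )
                raise TopologyError(
                    f"member {m} of ensemble {label!r} has {len(key)} atoms, "
                    f"expected {len(ref_key)}"
                )

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Ensemble(self.members[i], label=self.label)
        return self.members[i]

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.members)

    def topology_key(self) -> tuple:
        return self.members[0].topology_key()

    def coords_stack(self) -> np.ndarray:
        """(n_members, n_atoms, 3) coordinate array."""
        return np.stack([m.coords for m in self.members])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Ensemble {self.label!r}: {len(self)} x {self.members[0].n_atoms} atoms>"


def _structure_from_atom_array(arr: struc.AtomArray, label: str) -> Structure:
    return Structure(
        arr.res_id,
        arr.res_name,
        arr.atom_name,
        arr.element,
        arr.coord,
        arr.chain_id.astype("U1"),
        label=label,
    )


def read_pdb_ensemble(path: str | Path, chain: str | None = None) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    One :class:`Structure` is produced per MODEL block, in file order; a file
    without MODEL records yields an ensemble of one.  Heteroatoms (ligands,
    waters) are dropped; hydrogens are retained and can be excluded later via
    the atom-class filter of a residue subset.  Alternate locations are
    resolved to the highest-occupancy conformer (first listed on a tie).

    Parameters
    ----------
    path:
        PDB file to read.
    chain:
        Chain identifier to extract.  Required when the file contains more
        than one chain; the entries analysed here (monomeric CheW) have one.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    members = []
    for i in range(1, n_models + 1):
        arr = pdb.get_structure(model=i, altloc="occupancy")
        arr = arr[~arr.hetero]
        if arr.array_length() == 0:
            raise ValueError(f"{path.name} model {i} contains no polymer atoms")
        chains = np.unique(arr.chain_id)
        if chain is None:
            if len(chains) > 1:
                raise ValueError(
                    f"{path.name} has chains {list(chains)}; select one with chain="
                )
        else:
            arr = arr[arr.chain_id == chain]
            if arr.array_length() == 0:
                raise ValueError(f"chain {chain!r} not present in {path.name}")
        members.append(_structure_from_atom_array(arr, f"{path.stem} model {i}"))
    return Ensemble(members, label=path.stem)


def write_pdb_ensemble(
    ens: Ensemble,
    path: str | Path,
    per_residue_scores: Sequence[float] | None = None,
) -> Path:
    """Write an ensemble as a standard multi-MODEL PDB file.

    Coordinates are written at the PDB's 3-decimal precision.  If
    ``per_residue_scores`` is given (one value per residue, in residue order)
    the values are placed in the B-factor column of every atom of the residue
    — the conventional mechanism for colouring a structure by a per-residue
    quantity in molecular viewers.
    """
    path = Path(path)
    ref = ens.members[0]
    bfac = np.zeros(ref.n_atoms)
    if per_residue_scores is not None:
        scores = np.asarray(per_residue_scores, dtype=float)
        residues = ref.unique_residues
        if len(scores) != len(residues):
            raise ValueError(
                f"got {len(scores)} per-residue scores for {len(residues)} residues"
            )
        lookup = dict(zip(residues.tolist(), scores.tolist()))
        bfac = np.array([lookup[r] for r in ref.residue_numbers.tolist()])

    arrays = []
    for member in ens.members:
        if member.coords.max() > _PDB_COORD_MAX or member.coords.min() < _PDB_COORD_MIN:
            raise ValueError(
                f"coordinates of {member.label!r} exceed the fixed-width PDB field"
            )
        arr = struc.AtomArray(member.n_atoms)
        arr.res_id = member.residue_numbers
        arr.res_name = member.residue_names
        arr.atom_name = member.atom_names
        arr.element = member.elements
        arr.chain_id = member.chain_ids
        arr.coord = member.coords
        arr.set_annotation("b_factor", bfac)
        arr.set_annotation("occupancy", np.ones(member.n_atoms))
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    if len(arrays) == 1:
        # a one-member ensemble still gets an explicit MODEL/ENDMDL pair
        pdb.lines = ["MODEL        1"] + pdb.lines + ["ENDMDL"]
    pdb.write(str(path))
    return path


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly aligned) FASTA file as ``[(id, sequence), ...]``."""
    from Bio import SeqIO

    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records
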