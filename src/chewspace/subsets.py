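"""Named residue subsets: inclusive residue-number ranges plus an atom-class filter.

Structural comparisons in this package are always restricted to a named subset
of residues — all residues, a flexible-tail-excluded "core", or the α/β
consensus residues (residues that are helical or strand in every model of an
NMR ensemble) — combined with an atom class (all heavy atoms, backbone, or
Cα).  A subset is written in text form as comma-separated inclusive ranges,
e.g. ``"17-19,22-24,127"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .structures import Structure

__all__ = [
    "ResidueSubsetSpec",
    "EmptySelectionError",
    "resolve_subset",
    "count_subset_residues",
    "BACKBONE_ATOMS",
    "ATOM_CLASSES",
]

#: Backbone heavy atoms. The carbonyl O is included (standard four-atom
#: backbone); switch to {"N", "CA", "C"} by passing a custom atom set.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

ATOM_CLASSES = ("all_heavy", "backbone", "calpha")


class EmptySelectionError(ValueError):
    """A subset resolved to zero atoms on a structure."""


def _normalize_ranges(ranges: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort and merge overlapping or touching inclusive ranges."""
    pairs = []
    for start, end in ranges:
        start, end = int(start), int(end)
        if start > end:
            raise ValueError(f"range start {start} exceeds end {end}")
        if start < 1:
            raise ValueError(f"residue numbers are 1-based, got range start {start}")
        pairs.append((start, end))
    pairs.sort()
    merged: list[list[int]] = []
    for start, end in pairs:
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class ResidueSubsetSpec:
    """A named union of inclusive residue-number ranges plus an atom class."""

    name: str
    ranges: tuple[tuple[int, int], ...]
    atom_class: str = "backbone"

    def __post_init__(self) -> None:
        if self.atom_class not in ATOM_CLASSES:
            raise ValueError(
                f"atom_class must be one of {ATOM_CLASSES}, got {self.atom_class!r}"
            )
        object.__setattr__(self, "ranges", _normalize_ranges(self.ranges))

    @classmethod
    def from_text(
        cls, name: str, text: str, atom_class: str = "backbone"
    ) -> "ResidueSubsetSpec":
        """Parse ``"17-19,22-24,127"`` style range lists (singletons allowed)."""
        ranges = []
        for token in text.split(","):
            token = token.strip()
            if not token:
                continue
            if "-" in token:
                start, _, end = token.partition("-")
                ranges.append((int(start), int(end)))
            else:
                ranges.append((int(token), int(token)))
        if not ranges:
            raise ValueError(f"no ranges in spec text {text!r}")
        return cls(name, tuple(ranges), atom_class)

    def to_text(self) -> str:
        return ",".join(
            f"{s}-{e}" if s != e else str(s) for s, e in self.ranges
        )

    def residue_numbers(self) -> np.ndarray:
        """Explicit sorted residue numbers in the union of ranges."""
        if not self.ranges:
            return np.array([], dtype=int)
        return np.concatenate([np.arange(s, e + 1) for s, e in self.ranges])

    def contains(self, residue_numbers: np.ndarray) -> np.ndarray:
        """Boolean mask: which of ``residue_numbers`` fall inside the ranges."""
        residue_numbers = np.asarray(residue_numbers)
        mask = np.zeros(residue_numbers.shape, dtype=bool)
        for start, end in self.ranges:
            mask |= (residue_numbers >= start) & (residue_numbers <= end)
        return mask

    def with_atom_class(self, atom_class: str) -> "ResidueSubsetSpec":
        return ResidueSubsetSpec(self.name, self.ranges, atom_class)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}[{self.atom_class}]({self.to_text()})"


def atom_class_mask(s: Structure, atom_class: str) -> np.ndarray:
    if atom_class == "all_heavy":
        return ~np.isin(s.elements, ("H", "D"))
    if atom_class == "backbone":
        return np.isin(s.atom_names, sorted(BACKBONE_ATOMS)) & ~np.isin(
            s.elements, ("H", "D")
        )
    if atom_class == "calpha":
        return s.atom_names == "CA"
    raise ValueError(f"unknown atom class {atom_class!r}")


def resolve_subset(s: Structure, spec: ResidueSubsetSpec) -> np.ndarray:
    """Atom indices of ``s`` selected by ``spec``, in structure order.

    Residue numbers named by the spec but absent from the structure are
    tolerated (a warning lists them); an empty final selection raises
    :class:`EmptySelectionError`.
    """
    wanted = spec.residue_numbers()
    present = np.isin(wanted, s.residue_numbers)
    if not np.all(present):
        missing = wanted[~present].tolist()
        warnings.warn(
            f"subset {spec.name!r}: residues {missing} not present in "
            f"structure {s.label!r}",
            stacklevel=2,
        )
    mask = spec.contains(s.residue_numbers) & atom_class_mask(s, spec.atom_class)
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        raise EmptySelectionError(
            f"subset {spec.name!r} ({spec.atom_class}) selects no atoms in "
            f"structure {s.label!r}"
        )
    return indices


def count_subset_residues(
    spec: ResidueSubsetSpec, total_residues: int
) -> tuple[int, float]:
    """Residue count of the subset and its percentage of ``total_residues``.

    Overlapping ranges are merged before counting, so each residue is counted
    once.  The percentage is reported to one decimal place.
    """
    max_end = max((e for _, e in spec.ranges), default=0)
    if total_residues < max_end:
        raise ValueError(
            f"total_residues={total_residues} is smaller than the largest "
            f"range end {max_end} of subset {spec.name!r}"
        )
    count = int(sum(e - s + 1 for s, e in spec.ranges))
    fraction = round(100.0 * count / total_residues, 1) if total_residues else 0.0
    return count, fraction
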