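"""Rigid-body least-squares superposition (Kabsch) and subset-restricted RMSD.

All comparisons follow the same pattern: resolve a residue subset on both
structures, establish the atom correspondence by (residue number, atom name),
optionally superpose the mobile structure onto the reference by the Kabsch
algorithm over a *fit* subset, then measure RMSD over a *measure* subset.
Reflections are never allowed — an improper rotation would superpose a
mirror image, which is physically meaningless for chiral molecules — so the
sign of the smallest singular value is corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Structure, TopologyError
from .subsets import ResidueSubsetSpec, resolve_subset

__all__ = [
    "SuperpositionResult",
    "PerResidueRmsd",
    "kabsch",
    "kabsch_superpose",
    "rmsd",
    "per_residue_rmsd",
    "matched_indices",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform ``x -> rotation @ x + translation`` and its RMSD."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    fit_rmsd: float
    fit_spec: ResidueSubsetSpec | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class PerResidueRmsd:
    """Per-residue RMSD map: parallel arrays of residue numbers and values (Å)."""

    residue_numbers: np.ndarray
    values: np.ndarray

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.residue_numbers.tolist(), self.values.tolist()))

    def to_tsv(self, path) -> None:
        lines = ["residue_number\trmsd"] + [
            f"{r}\t{v:.4f}"
            for r, v in zip(self.residue_numbers.tolist(), self.values.tolist())
        ]
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


def kabsch(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of two corresponding point sets.

    Returns ``(rotation, translation, rmsd)`` minimising
    ``|| (rotation @ mobile.T).T + translation - reference ||`` with a proper
    rotation (det +1).  Requires at least 3 points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {P.shape}, {Q.shape}")
    if len(P) < 3:
        raise ValueError(f"need at least 3 fit atoms, got {len(P)}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    fit_rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, fit_rmsd


def matched_indices(
    a: Structure, b: Structure, spec: ResidueSubsetSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve ``spec`` on both structures and pair atoms by
    (residue number, atom name).

    The correspondence must be one-to-one over the selection: an atom selected
    in one structure but absent from the other is an error, never silently
    dropped.
    """
    ia = resolve_subset(a, spec)
    ib = resolve_subset(b, spec)
    key_a = [
        (int(a.residue_numbers[i]), str(a.atom_names[i])) for i in ia.tolist()
    ]
    key_b = [
        (int(b.residue_numbers[i]), str(b.atom_names[i])) for i in ib.tolist()
    ]
    if key_a == key_b:
        return ia, ib
    lookup_b = {k: i for k, i in zip(key_b, ib.tolist())}
    if len(lookup_b) != len(key_b):
        raise TopologyError(f"duplicate atoms within subset {spec.name!r} in {b.label!r}")
    only_a = [k for k in key_a if k not in lookup_b]
    if only_a or len(key_a) != len(key_b):
        only_b = sorted(set(key_b) - set(key_a))[:3]
        raise TopologyError(
            f"atom correspondence mismatch on subset {spec.name!r}: "
            f"only in {a.label!r}: {only_a[:3]}; only in {b.label!r}: {only_b}"
        )
    ib_matched = np.array([lookup_b[k] for k in key_a], dtype=int)
    return ia, ib_matched


def kabsch_superpose(
    mobile: Structure, reference: Structure, fit_spec: ResidueSubsetSpec
) -> tuple[Structure, SuperpositionResult]:
    """Superpose ``mobile`` onto ``reference`` over the atoms of ``fit_spec``.

    The returned structure carries all atoms of ``mobile`` moved by the
    transform fitted on the subset.
    """
    im, ir = matched_indices(mobile, reference, fit_spec)
    R, t, fit_rmsd = kabsch(mobile.coords[im], reference.coords[ir])
    moved = mobile.coords @ R.T + t
    result = SuperpositionResult(R, t, fit_rmsd, fit_spec)
    return mobile.with_coords(moved), result


def rmsd(
    a: Structure,
    b: Structure,
    spec: ResidueSubsetSpec,
    superpose: bool = False,
    fit_spec: ResidueSubsetSpec | None = None,
) -> float:
    """RMSD (Å) between ``a`` and ``b`` over the atoms of ``spec``.

    With ``superpose=True``, ``a`` is first rigidly fitted onto ``b`` over
    ``fit_spec`` (default: the measurement subset itself).
    """
    if superpose:
        a, _ = kabsch_superpose(a, b, fit_spec if fit_spec is not None else spec)
    ia, ib = matched_indices(a, b, spec)
    diff = a.coords[ia] - b.coords[ib]
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def per_residue_rmsd(
    a: Structure,
    b: Structure,
    fit_spec: ResidueSubsetSpec,
) -> PerResidueRmsd:
    """Per-residue heavy-atom RMSD after one global superposition.

    ``a`` is fitted onto ``b`` once, over ``fit_spec``; every residue's RMSD
    is then measured over its heavy atoms in that single frame, without
    refitting.  Refitting per residue would hide exactly the signal this map
    is for — rigid cores stay near zero while displaced or flexible segments
    inflate.
    """
    moved, _ = kabsch_superpose(a, b, fit_spec)
    all_heavy = ResidueSubsetSpec(
        "all_heavy_map",
        ((int(moved.residue_numbers.min()), int(moved.residue_numbers.max())),),
        "all_heavy",
    )
    ia, ib = matched_indices(moved, b, all_heavy)
    res = moved.residue_numbers[ia]
    sq = np.sum((moved.coords[ia] - b.coords[ib]) ** 2, axis=1)
    residues = []
    values = []
    for r in moved.unique_residues.tolist():
        mask = res == r
        if not np.any(mask):
            raise ValueError(f"residue {r} has no heavy atoms to compare")
        residues.append(r)
        values.append(float(np.sqrt(np.mean(sq[mask]))))
    return PerResidueRmsd(np.asarray(residues), np.asarray(values))
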