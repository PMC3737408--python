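"""Synthetic structures, ensembles, homolog sequences and MSAs for testing.

Real inputs to the pipeline are NMR ensembles (a rigid, well-determined core
with floppy terminal tails), homology-model ensembles (tighter than the NMR
spread), and protein families whose pairwise-identity histogram is bimodal
(within-class vs between-class comparisons).  The generators here reproduce
those statistical shapes with controllable knobs so every analysis stage can
be exercised end-to-end without any downloaded data.  Everything is
deterministic under a seed.

Ensemble noise is Gaussian in Cartesian space (plus a rigid swing of the
tails): cheap and sufficient for testing RMSD machinery.  Physically
plausible dihedral-space ensembles come from :mod:`chewspace.gomc` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sequences import AMINO_ACIDS, Msa, pairwise_identity
from .structures import Ensemble, Structure

__all__ = [
    "SyntheticSpec",
    "make_toy_structure",
    "make_ensemble",
    "make_homolog_pair",
    "make_toy_msa",
]

# Ideal alpha-helix parameters for a Calpha trace: radius (Å), rise per
# residue (Å), turn per residue (deg). Chosen to give the canonical ~3.8 Å
# consecutive Calpha spacing.
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN_DEG = 100.0
#: Consecutive Cα spacing of an extended (straight) chain.
CA_SPACING = 3.8


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic NMR-like ensemble generator.

    ``core_noise``/``tail_noise`` are Gaussian per-coordinate jitters (Å)
    applied to the structured core and the ``tail_length`` terminal residues;
    ``tail_noise >= core_noise`` models the rigid-core / floppy-tail contrast
    of experimental ensembles.  ``tail_swing_deg`` adds a random rigid
    reorientation of each tail (applied only when ``tail_noise > 0``, so a
    zero-noise spec reproduces the base structure exactly).
    """

    n_residues: int = 60
    n_models: int = 20
    tail_length: int = 10
    core_noise: float = 0.3
    tail_noise: float = 3.0
    tail_swing_deg: float = 12.0
    geometry: str = "helix"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues")
        if self.core_noise < 0 or self.tail_noise < 0:
            raise ValueError("noise levels must be non-negative")
        if self.tail_noise < self.core_noise:
            raise ValueError("tail_noise must be >= core_noise")
        if 2 * self.tail_length >= self.n_residues:
            raise ValueError("tails may not cover the whole chain")
        if self.geometry not in ("helix", "extended", "hairpin"):
            raise ValueError("geometry must be 'helix', 'extended' or 'hairpin'")

    @property
    def core_ranges(self) -> tuple[tuple[int, int], ...]:
        return ((self.tail_length + 1, self.n_residues - self.tail_length),)


def _helix_ca(n: int) -> np.ndarray:
    theta = np.radians(_HELIX_TURN_DEG) * np.arange(n)
    return np.column_stack(
        [
            _HELIX_RADIUS * np.cos(theta),
            _HELIX_RADIUS * np.sin(theta),
            _HELIX_RISE * np.arange(n),
        ]
    )


def _extended_ca(n: int) -> np.ndarray:
    coords = np.zeros((n, 3))
    coords[:, 0] = CA_SPACING * np.arange(n)
    return coords


#: Axis separation of the two helices of a hairpin (Å). Surface-to-surface
#: distance is this minus twice the helix radius; kept just above the 4 Å
#: excluded-volume diameter so the fold is compact but clash-free.
_HAIRPIN_SEPARATION = 8.8


def _hairpin_ca(n: int) -> np.ndarray:
    """Two packed antiparallel helices — a minimal fold with tertiary contacts."""
    n1 = (n + 1) // 2
    n2 = n - n1
    turn = np.radians(_HELIX_TURN_DEG)
    # first helix runs up; phased so its last residue faces the second helix
    i = np.arange(n1)
    theta1 = turn * (i - (n1 - 1))
    h1 = np.column_stack(
        [
            _HELIX_RADIUS * np.cos(theta1),
            _HELIX_RADIUS * np.sin(theta1),
            _HELIX_RISE * i,
        ]
    )
    # second helix runs back down, facing the first
    j = np.arange(n2)
    theta2 = np.pi + turn * j
    h2 = np.column_stack(
        [
            _HAIRPIN_SEPARATION + _HELIX_RADIUS * np.cos(theta2),
            _HELIX_RADIUS * np.sin(theta2),
            _HELIX_RISE * (n1 - 1) - _HELIX_RISE * j,
        ]
    )
    return np.vstack([h1, h2])


def make_toy_structure(spec: SyntheticSpec) -> Structure:
    """Ideal-geometry poly-alanine backbone (N, CA, C, O per residue).

    The Cα trace follows an ideal helix (or a straight extended chain); the
    remaining backbone atoms are placed at fixed offsets along the trace —
    idealised geometry, adequate for exercising selections, superposition and
    the Gō model.  Deterministic: the same spec always yields the same
    coordinates.
    """
    n = spec.n_residues
    builder = {
        "helix": _helix_ca,
        "extended": _extended_ca,
        "hairpin": _hairpin_ca,
    }[spec.geometry]
    ca = builder(n)
    # local chain directions, padded at the termini
    fwd = np.diff(ca, axis=0)
    fwd = fwd / np.linalg.norm(fwd, axis=1, keepdims=True)
    d_prev = np.vstack([fwd[:1], fwd])
    d_next = np.vstack([fwd, fwd[-1:]])
    normal = np.cross(d_prev, d_next)
    bad = np.linalg.norm(normal, axis=1) < 1e-8
    normal[bad] = np.array([0.0, 0.0, 1.0]) if spec.geometry == "extended" else normal[
        ~bad
    ][:1]
    normal = normal / np.linalg.norm(normal, axis=1, keepdims=True)

    residue_numbers, residue_names, atom_names, elements, coords = [], [], [], [], []
    for i in range(n):
        pos_n = ca[i] - 1.46 * d_prev[i] + 0.4 * normal[i]
        pos_c = ca[i] + 1.52 * d_next[i] - 0.4 * normal[i]
        pos_o = pos_c + 1.23 * normal[i]
        for name, element, pos in (
            ("N", "N", pos_n),
            ("CA", "C", ca[i]),
            ("C", "C", pos_c),
            ("O", "O", pos_o),
        ):
            residue_numbers.append(i + 1)
            residue_names.append("ALA")
            atom_names.append(name)
            elements.append(element)
            coords.append(pos)
    return Structure(
        residue_numbers,
        residue_names,
        atom_names,
        elements,
        np.array(coords),
        label=f"toy_{spec.geometry}_{n}",
    )


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def make_ensemble(base: Structure, spec: SyntheticSpec) -> Ensemble:
    """NMR-like ensemble: jittered copies of ``base`` with floppy tails.

    Core residues receive Gaussian noise of ``spec.core_noise`` per
    coordinate; the ``spec.tail_length`` terminal residues receive
    ``spec.tail_noise`` plus a random rigid swing of the whole tail about its
    attachment residue.  With both noises at zero every member equals
    ``base``.
    """
    rng = np.random.default_rng(spec.seed)
    residues = base.unique_residues
    n_res = len(residues)
    if 2 * spec.tail_length >= n_res:
        raise ValueError("tails may not cover the whole chain")
    tail_n = set(residues[: spec.tail_length].tolist())
    tail_c = set(residues[n_res - spec.tail_length :].tolist())
    members = []
    for m in range(spec.n_models):
        coords = base.coords.copy()
        is_tail = np.isin(
            base.residue_numbers, sorted(tail_n | tail_c)
        )
        sigma = np.where(is_tail, spec.tail_noise, spec.core_noise)
        coords += rng.normal(size=coords.shape) * sigma[:, None]
        if spec.tail_noise > 0 and spec.tail_length > 0:
            for tail, anchor_res in (
                (tail_n, residues[spec.tail_length]),
                (tail_c, residues[n_res - spec.tail_length - 1]),
            ):
                mask = np.isin(base.residue_numbers, sorted(tail))
                anchor = base.coords[base.residue_numbers == anchor_res].mean(axis=0)
                angle = math.radians(rng.normal(0.0, spec.tail_swing_deg))
                R = _rotation_matrix(rng.normal(size=3), angle)
                coords[mask] = (coords[mask] - anchor) @ R.T + anchor
        members.append(base.with_coords(coords, label=f"{base.label} model {m + 1}"))
    return Ensemble(members, label=f"{base.label}_ensemble")


def make_homolog_pair(
    base_seq: str, target_identity: float, seed: int = 0
) -> tuple[str, str]:
    """A sequence and a mutated homolog at a requested percent identity.

    Random positions are substituted (uniformly over the 19 alternative
    amino acids) until the realised ungapped identity is within ±1 point of
    ``target_identity``.  Raises if the target is unreachable at the given
    length (identity is quantised in steps of 100/len).
    """
    base_seq = base_seq.upper()
    n = len(base_seq)
    if not 0 < target_identity <= 100:
        raise ValueError("target_identity must lie in (0, 100]")
    if n == 0:
        raise ValueError("empty sequence")
    n_keep = round(n * target_identity / 100.0)
    realized = 100.0 * n_keep / n
    if abs(realized - target_identity) > 1.0:
        raise ValueError(
            f"identity {target_identity}% unreachable at length {n}: nearest "
            f"achievable is {realized:.2f}%"
        )
    rng = np.random.default_rng(seed)
    positions = rng.permutation(n)[: n - n_keep]
    mutant = list(base_seq)
    for p in positions:
        alternatives = AMINO_ACIDS.replace(mutant[p], "")
        mutant[p] = alternatives[rng.integers(len(alternatives))]
    mutated = "".join(mutant)
    assert abs(pairwise_identity(base_seq, mutated) - target_identity) <= 1.0
    return base_seq, mutated


def make_toy_msa(
    n_seqs: int,
    length: int = 80,
    two_class_divergence: float = 0.6,
    within_class_divergence: float = 0.05,
    seed: int = 0,
) -> Msa:
    """Ungapped MSA drawn from two ancestral sequences (bimodal identities).

    Half the sequences descend from ancestor A, half from ancestor B, where B
    differs from A at a ``two_class_divergence`` fraction of positions; each
    descendant then mutates a ``within_class_divergence`` fraction.  With
    divergence 0 the two classes merge and the identity histogram is
    unimodal; with high divergence the between-class identity mode falls
    clearly below the within-class mode.
    """
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    if not 0 <= two_class_divergence <= 1:
        raise ValueError("two_class_divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))

    def mutate(seq: np.ndarray, fraction: float) -> np.ndarray:
        out = seq.copy()
        k = round(fraction * length)
        for p in rng.permutation(length)[:k]:
            out[p] = rng.choice(np.array([a for a in AMINO_ACIDS if a != out[p]]))
        return out

    ancestor_a = rng.choice(aa, size=length)
    ancestor_b = mutate(ancestor_a, two_class_divergence)
    records = []
    for i in range(n_seqs):
        ancestor = ancestor_a if i % 2 == 0 else ancestor_b
        seq = mutate(ancestor, within_class_divergence)
        records.append((f"seq{i + 1}", "".join(seq.tolist())))
    return Msa(tuple(records))
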