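"""Sequence-level diversity analysis: pairwise identity, redundancy pruning,
global alignment and per-residue similarity scores.

Pairwise identity over an alignment is defined on the mutually non-gap
columns: ``100 * (identical columns) / (columns where both sequences have a
residue)``.  This is the most common convention; columns where either
sequence is gapped contribute to neither numerator nor denominator.

The pairwise aligner is a global Needleman–Wunsch with affine gaps and free
(unpenalised) terminal gaps, so homologs whose termini differ in length are
not forced into spurious end alignments.  BLOSUM62 is the default scoring
matrix; any matrix in NCBI format can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "Msa",
    "IdentityHistogram",
    "AlignmentResult",
    "pairwise_identity",
    "msa_identity_histogram",
    "prune_redundant",
    "align_pair",
    "per_residue_similarity",
    "load_substitution_matrix",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


def load_substitution_matrix(name_or_path: str):
    """Load a named Biopython matrix (e.g. ``"BLOSUM62"``) or an NCBI-format
    matrix file."""
    try:
        return substitution_matrices.load(name_or_path)
    except (ValueError, FileNotFoundError):
        path = Path(name_or_path)
        if path.exists():
            return substitution_matrices.read(str(path))
        raise ValueError(
            f"{name_or_path!r} is neither a bundled substitution matrix nor a file"
        ) from None


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: ``records`` is ``[(id, aligned_seq)]``."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        records = tuple((str(i), str(s).upper()) for i, s in self.records)
        object.__setattr__(self, "records", records)
        lengths = {len(s) for _, s in records}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Msa":
        from .structures import read_fasta

        return cls(tuple(read_fasta(path)))


@dataclass(frozen=True)
class IdentityHistogram:
    """Pairwise-identity counts in 1 % bins ``[k, k+1)``, 100 % in the top bin."""

    counts: np.ndarray  # length 100

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(101.0)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["bin_start\tcount"] + [
            f"{int(edge)}\t{int(c)}" for edge, c in zip(self.bin_edges, self.counts)
        ]
        path.write_text("\n".join(lines) + "\n")
        return path


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise global alignment; removing gaps recovers the inputs."""

    aligned_a: str
    aligned_b: str
    score: float
    matrix: str
    gap_open: float
    gap_extend: float
    free_end_gaps: bool = True

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal length")

    @property
    def identity(self) -> float:
        return pairwise_identity(self.aligned_a, self.aligned_b)

    def column_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.aligned_a, self.aligned_b))


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of two aligned sequences over mutually non-gap columns."""
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    shared = identical = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == GAP or y == GAP:
            continue
        shared += 1
        if x == y:
            identical += 1
    if shared == 0:
        raise ValueError("sequences share no mutually non-gap columns")
    return 100.0 * identical / shared


def msa_identity_histogram(msa: Msa) -> IdentityHistogram:
    """Identity histogram over all unordered sequence pairs of an MSA."""
    if len(msa) < 2:
        raise ValueError("need at least 2 sequences for pairwise statistics")
    counts = np.zeros(100, dtype=int)
    seqs = [s for _, s in msa.records]
    ids = msa.ids
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            try:
                ident = pairwise_identity(seqs[i], seqs[j])
            except ValueError as exc:
                raise ValueError(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
            counts[min(int(ident), 99)] += 1
    return IdentityHistogram(counts)


def prune_redundant(
    msa: Msa, threshold: float = 98.0
) -> tuple[Msa, list[str]]:
    """Remove near-duplicate sequences from an MSA.

    Greedy single pass in input order: a sequence is kept iff its identity to
    every already-kept sequence is strictly below ``threshold`` (percent).
    Returns the pruned MSA and the ids of the removed sequences.
    """
    kept: list[tuple[str, str]] = []
    removed: list[str] = []
    for rec_id, seq in msa.records:
        if any(pairwise_identity(seq, k) >= threshold for _, k in kept):
            removed.append(rec_id)
        else:
            kept.append((rec_id, seq))
    return Msa(tuple(kept)), removed


def _prepare_matrix(matrix_name: str):
    """Load a matrix and neutralise the ambiguity letter X (score 0)."""
    matrix = load_substitution_matrix(matrix_name)
    if "X" in matrix.alphabet:
        matrix = matrix.copy()
        for letter in matrix.alphabet:
            matrix["X", letter] = 0.0
            matrix[letter, "X"] = 0.0
    return matrix


def align_pair(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 7.0,
    gap_extend: float = 1.0,
    free_end_gaps: bool = True,
) -> AlignmentResult:
    """Global affine-gap alignment of two protein sequences.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` in matrix
    units.  Terminal gaps are free by default.  ``X`` scores 0 against
    everything; any other letter outside the matrix alphabet is an error.
    The traceback is deterministic (the aligner's first optimal path).
    """
    a, b = a.upper().replace(GAP, ""), b.upper().replace(GAP, "")
    subst = _prepare_matrix(matrix)
    for name, seq in (("a", a), ("b", b)):
        bad = set(seq) - set(str(c) for c in subst.alphabet)
        if bad:
            raise ValueError(f"sequence {name} contains unknown letters {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = subst
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    if free_end_gaps:
        aligner.end_gap_score = 0.0
    aln = aligner.align(a, b)[0]
    return AlignmentResult(
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        score=float(aln.score),
        matrix=matrix,
        gap_open=gap_open,
        gap_extend=gap_extend,
        free_end_gaps=free_end_gaps,
    )


def per_residue_similarity(
    aln: AlignmentResult,
    matrix: str | None = None,
    gap_score: float | None = None,
) -> np.ndarray:
    """Substitution score of each residue of sequence *a* against its aligned
    partner.

    Residues of *a* aligned to a gap receive ``gap_score`` (default: the
    matrix minimum).  The result is indexed by the residues of *a* in order,
    ready to be written into the B-factor column of a structure that shares
    that sequence.
    """
    subst = _prepare_matrix(matrix if matrix is not None else aln.matrix)
    if gap_score is None:
        gap_score = float(np.min(np.asarray(subst)))
    scores = []
    for x, y in aln.column_pairs():
        if x == GAP:
            continue
        if y == GAP:
            scores.append(float(gap_score))
            continue
        try:
            scores.append(float(subst[x, y]))
        except (KeyError, IndexError) as exc:
            raise ValueError(f"matrix has no entry for pair ({x}, {y})") from exc
    return np.asarray(scores)
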