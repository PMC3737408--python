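"""Ensemble × ensemble RMSD matrices, summaries, minimum pairs and distributions.

The central object is the cross-RMSD matrix: entry (i, j) is the RMSD between
member i of one ensemble and member j of another, after superposing each pair
on a fit subset.  From it come the four summary statistics used to compare
trajectories (starting / lowest / highest / average), the most-similar frame
pair, and the RMSD distributions that show how much conformational space two
ensembles share.  For very long trajectories a streaming variant computes the
identical summary and histogram without materialising the full matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structures import Ensemble, Structure
from .subsets import ResidueSubsetSpec
from .superpose import kabsch_superpose, matched_indices, kabsch

__all__ = [
    "RMSDMatrix",
    "RmsdSummary",
    "DistributionSet",
    "cross_rmsd_matrix",
    "summarize",
    "min_pair_structures",
    "rmsd_distributions",
    "streaming_cross_summary",
    "pairwise_rmsd_values",
    "ensemble_spread",
]


@dataclass(frozen=True)
class RMSDMatrix:
    """m × n RMSD values (Å) with provenance of both ensembles and the subsets."""

    values: np.ndarray
    row_source: str
    col_source: str
    fit_spec: ResidueSubsetSpec
    rmsd_spec: ResidueSubsetSpec
    stride: int = 1

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("matrix must be 2-D and non-empty")
        if np.any(values < 0):
            raise ValueError("RMSD values must be non-negative")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        header = "\t".join(
            ["row\\col"] + [f"{self.col_source}[{j}]" for j in range(self.shape[1])]
        )
        lines = [header]
        for i, row in enumerate(self.values):
            lines.append(
                "\t".join([f"{self.row_source}[{i}]"] + [f"{v:.4f}" for v in row])
            )
        path.write_text("\n".join(lines) + "\n")
        return path


@dataclass(frozen=True)
class RmsdSummary:
    """Starting / lowest / highest / average statistics of a cross-RMSD matrix.

    ``starting`` is entry (0, 0): the RMSD between the two initial frames,
    i.e. the static model-vs-model comparison before any sampling.
    """

    starting: float
    lowest: float
    highest: float
    average: float
    argmin: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.lowest <= self.average <= self.highest):
            raise ValueError("summary violates lowest <= average <= highest")


@dataclass(frozen=True)
class DistributionSet:
    """Labelled RMSD value sets of an ensemble/trajectory comparison.

    ``models_vs_models`` and ``nmr_vs_nmr`` hold the unordered
    within-ensemble pairs of the homology-model and NMR ensembles;
    ``models_vs_nmr`` the full static cross matrix; one entry per trajectory
    cross comparison holds every frame of one trajectory against every frame
    of the other.  ``starting`` records the RMSD of the two initial frames —
    the vertical-line value drawn over the histograms.
    """

    distributions: dict[str, np.ndarray]
    starting: float
    bin_width: float = 0.1

    def histogram(self, key: str) -> tuple[np.ndarray, np.ndarray]:
        """(bin_edges, counts) at the configured bin width."""
        values = self.distributions[key]
        upper = max(
            float(np.max(values)) if len(values) else 0.0, self.starting, self.bin_width
        )
        edges = np.arange(0.0, upper + 2 * self.bin_width, self.bin_width)
        counts, edges = np.histogram(values, bins=edges)
        return edges, counts

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["label\trmsd"]
        for key, values in self.distributions.items():
            lines.extend(f"{key}\t{v:.4f}" for v in values)
        lines.append(f"starting\t{self.starting:.4f}")
        path.write_text("\n".join(lines) + "\n")
        return path


def _pair_rmsd(
    a: Structure,
    b: Structure,
    fit_pair: tuple[np.ndarray, np.ndarray],
    rmsd_pair: tuple[np.ndarray, np.ndarray],
) -> float:
    """Superpose on the fit atoms, measure on the rmsd atoms (indices fixed)."""
    ia_fit, ib_fit = fit_pair
    R, t, _ = kabsch(a.coords[ia_fit], b.coords[ib_fit])
    ia, ib = rmsd_pair
    moved = a.coords[ia] @ R.T + t
    diff = moved - b.coords[ib]
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def _resolve_pair_indices(E1: Ensemble, E2: Ensemble, fit_spec, rmsd_spec):
    a, b = E1[0], E2[0]
    fit_pair = matched_indices(a, b, fit_spec)
    rmsd_pair = matched_indices(a, b, rmsd_spec)
    return fit_pair, rmsd_pair


def cross_rmsd_matrix(
    E1: Ensemble,
    E2: Ensemble,
    fit_spec: ResidueSubsetSpec,
    rmsd_spec: ResidueSubsetSpec | None = None,
    stride: int = 1,
) -> RMSDMatrix:
    """RMSD of every member of ``E1`` against every member of ``E2``.

    Each pair is superposed on ``fit_spec`` and measured on ``rmsd_spec``
    (default: the fit subset).  ``stride`` keeps every k-th frame of both
    ensembles — an approximation for long trajectories; the retained entries
    are exact.
    """
    if rmsd_spec is None:
        rmsd_spec = fit_spec
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rows = E1.members[::stride]
    cols = E2.members[::stride]
    fit_pair, rmsd_pair = _resolve_pair_indices(E1, E2, fit_spec, rmsd_spec)
    values = np.empty((len(rows), len(cols)))
    for i, a in enumerate(rows):
        for j, b in enumerate(cols):
            values[i, j] = _pair_rmsd(a, b, fit_pair, rmsd_pair)
    return RMSDMatrix(values, E1.label, E2.label, fit_spec, rmsd_spec, stride)


def summarize(matrix: RMSDMatrix) -> RmsdSummary:
    """Starting / lowest / highest / average statistics of a matrix.

    Ties for the minimum resolve row-major: smallest row index, then smallest
    column index.
    """
    values = matrix.values
    flat_argmin = int(np.argmin(values))  # row-major scan -> required tie-break
    argmin = np.unravel_index(flat_argmin, values.shape)
    return RmsdSummary(
        starting=float(values[0, 0]),
        lowest=float(values.min()),
        highest=float(values.max()),
        average=float(values.mean()),
        argmin=(int(argmin[0]), int(argmin[1])),
    )


def min_pair_structures(
    T1: Ensemble, T2: Ensemble, matrix: RMSDMatrix
) -> tuple[Structure, Structure]:
    """The most similar frame pair, superposed on the matrix fit subset.

    Returns (frame of ``T1``, frame of ``T2``) at the matrix argmin, with the
    first superposed onto the second; write them out as a two-model PDB to
    visualise the overlap.
    """
    summary = summarize(matrix)
    i, j = summary.argmin
    i, j = i * matrix.stride, j * matrix.stride
    if i >= len(T1) or j >= len(T2):
        raise IndexError(
            f"matrix argmin ({i}, {j}) outside ensembles of sizes "
            f"{len(T1)}, {len(T2)} — matrix/trajectory mismatch"
        )
    a, b = T1[i], T2[j]
    moved, _ = kabsch_superpose(a, b, matrix.fit_spec)
    return moved, b


def pairwise_rmsd_values(
    ens: Ensemble,
    fit_spec: ResidueSubsetSpec,
    rmsd_spec: ResidueSubsetSpec | None = None,
) -> np.ndarray:
    """Within-ensemble RMSDs over unordered member pairs (i < j)."""
    if rmsd_spec is None:
        rmsd_spec = fit_spec
    fit_pair, rmsd_pair = _resolve_pair_indices(ens, ens, fit_spec, rmsd_spec)
    values = []
    for i in range(len(ens)):
        for j in range(i + 1, len(ens)):
            values.append(_pair_rmsd(ens[i], ens[j], fit_pair, rmsd_pair))
    return np.asarray(values)


def ensemble_spread(
    ens: Ensemble,
    fit_spec: ResidueSubsetSpec,
    rmsd_spec: ResidueSubsetSpec | None = None,
) -> float:
    """Largest within-ensemble pairwise RMSD (Å) — the spread of an ensemble."""
    return float(np.max(pairwise_rmsd_values(ens, fit_spec, rmsd_spec)))


def rmsd_distributions(
    models: Ensemble,
    nmr: Ensemble,
    traj_model: Ensemble,
    traj_nmr: Ensemble,
    fit_spec: ResidueSubsetSpec,
    rmsd_spec: ResidueSubsetSpec | None = None,
    bin_width: float = 0.1,
    stride: int = 1,
    traj_model_b: Ensemble | None = None,
    traj_nmr_b: Ensemble | None = None,
) -> DistributionSet:
    """The five RMSD distributions comparing static ensembles and trajectories.

    Keys of the result: ``models_vs_models`` and ``nmr_vs_nmr`` (unordered
    within-ensemble pairs), ``models_vs_nmr`` (full cross matrix of the static
    ensembles), ``traj_model_vs_traj_nmr`` (full cross matrix of the two
    trajectories) and, when a second trajectory pair from an independent
    sampling method is supplied, ``traj_b_model_vs_traj_b_nmr``.
    ``starting`` is entry (0, 0) of the first trajectory cross matrix — the
    RMSD between the two structures the simulations started from.
    """
    if rmsd_spec is None:
        rmsd_spec = fit_spec
    cross_static = cross_rmsd_matrix(models, nmr, fit_spec, rmsd_spec)
    cross_traj = cross_rmsd_matrix(traj_model, traj_nmr, fit_spec, rmsd_spec, stride)
    distributions = {
        "models_vs_models": pairwise_rmsd_values(models, fit_spec, rmsd_spec),
        "nmr_vs_nmr": pairwise_rmsd_values(nmr, fit_spec, rmsd_spec),
        "models_vs_nmr": cross_static.values.ravel(),
        "traj_model_vs_traj_nmr": cross_traj.values.ravel(),
    }
    if (traj_model_b is None) != (traj_nmr_b is None):
        raise ValueError("supply both or neither of the second trajectory pair")
    if traj_model_b is not None:
        cross_b = cross_rmsd_matrix(
            traj_model_b, traj_nmr_b, fit_spec, rmsd_spec, stride
        )
        distributions["traj_b_model_vs_traj_b_nmr"] = cross_b.values.ravel()
    return DistributionSet(
        distributions=distributions,
        starting=float(cross_traj.values[0, 0]),
        bin_width=bin_width,
    )


def streaming_cross_summary(
    E1: Ensemble,
    E2: Ensemble,
    fit_spec: ResidueSubsetSpec,
    rmsd_spec: ResidueSubsetSpec | None = None,
    bin_width: float = 0.1,
    max_bin: float = 50.0,
) -> tuple[RmsdSummary, np.ndarray]:
    """Summary + histogram of a cross comparison without storing the matrix.

    Streams one row at a time keeping running min/max/mean and histogram
    counts — the same statistics as :func:`summarize` of the dense matrix,
    for trajectory pairs too large to hold as m × n.
    Returns ``(summary, counts)`` with ``counts[k]`` the number of values in
    ``[k * bin_width, (k + 1) * bin_width)``.
    """
    if rmsd_spec is None:
        rmsd_spec = fit_spec
    fit_pair, rmsd_pair = _resolve_pair_indices(E1, E2, fit_spec, rmsd_spec)
    n_bins = int(np.ceil(max_bin / bin_width))
    counts = np.zeros(n_bins, dtype=int)
    total = 0.0
    n = 0
    lowest = np.inf
    highest = -np.inf
    argmin = (0, 0)
    starting = None
    for i, a in enumerate(E1):
        row = np.array([_pair_rmsd(a, b, fit_pair, rmsd_pair) for b in E2])
        if i == 0:
            starting = float(row[0])
        j = int(np.argmin(row))
        if row[j] < lowest:
            lowest, argmin = float(row[j]), (i, j)
        highest = max(highest, float(row.max()))
        total += float(row.sum())
        n += len(row)
        idx = np.minimum((row / bin_width).astype(int), n_bins - 1)
        np.add.at(counts, idx, 1)
    summary = RmsdSummary(starting, lowest, highest, total / n, argmin)
    return summary, counts
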