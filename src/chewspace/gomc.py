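"""Coarse-grained Gō-potential Metropolis Monte Carlo sampler.

A structure-based ("Gō") potential rewards the native contacts of a reference
conformation: the chain is reduced to its Cα beads, every bead pair (i, j)
with |i − j| ≥ 3 and reference distance within a cutoff is a native contact,
and each formed contact contributes −ε to the energy.  Temperature is always
expressed as kT/ε, the natural unit of the model; sampling "slightly below
the unfolding temperature" (kT/ε ≈ 0.7) explores thermally accessible
conformations around the reference without unfolding it.

Trial moves act on the Cα chain and preserve bond lengths exactly:

``psi``
    torsion about a virtual bond — rotates everything downstream of a bond
    about that bond's axis (the Ψ-dihedral analogue on a Cα trace);
``local``
    a crankshaft rotation of a 3-bead window about the axis through its
    flanking beads — a localised backbone rearrangement;
``pivot``
    rotation of everything downstream of a bead about a random axis through
    that bead (also bends the local virtual-bond angle).

Move types are drawn per step from configured fractions (remainder → pivot);
acceptance follows the Metropolis rule.  Runs are exactly reproducible under
a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .structures import Ensemble, Structure
from .superpose import kabsch

__all__ = [
    "GoModel",
    "MCConfig",
    "MCTrajectory",
    "TemperatureScan",
    "ChainBreakError",
    "build_go_model",
    "energy",
    "metropolis_accept",
    "run_mc",
    "tune_step_size",
    "temperature_scan",
]

#: Hard-sphere diameter of a Cα bead (Å): non-bonded pairs closer than this
#: are rejected outright.
CLASH_DISTANCE = 4.0
#: Consecutive Cα separation beyond which the chain is considered broken.
CHAIN_BREAK_DISTANCE = 4.5
#: A native contact counts as formed while its distance is within this factor
#: of the reference distance.
CONTACT_TOLERANCE = 1.2
#: Stiffness of the harmonic virtual-bond term (ε/Å²).  Moves preserve bond
#: lengths exactly, so this term only guards against corrupted input.
BOND_STIFFNESS = 100.0


class ChainBreakError(ValueError):
    """Consecutive Cα atoms further apart than a peptide bond allows."""


@dataclass(frozen=True)
class GoModel:
    """Cα bead chain + native contact list defining the sampling potential."""

    reference: np.ndarray  # (n, 3) Cα coordinates of the native state
    bond_lengths: np.ndarray  # (n-1,) native consecutive Cα distances
    contacts: np.ndarray  # (m, 2) int, i < j, |i - j| >= 3
    contact_distances: np.ndarray  # (m,) reference distances
    epsilon: float = 1.0
    contact_cutoff: float = 8.0
    template: Structure | None = None  # CA-only topology for writing frames

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        if len(ref) < 4:
            raise ValueError("Go model needs at least 4 beads")
        contacts = np.asarray(self.contacts, dtype=int).reshape(-1, 2)
        if len(contacts):
            if np.any(contacts[:, 1] - contacts[:, 0] < 3):
                raise ValueError("contacts must satisfy |i - j| >= 3")
            if len(np.unique(contacts[:, 0] * len(ref) + contacts[:, 1])) != len(
                contacts
            ):
                raise ValueError("duplicate native contacts")
            if np.any(np.asarray(self.contact_distances) > self.contact_cutoff):
                raise ValueError("contact reference distance exceeds the cutoff")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "contacts", contacts)

    @property
    def n_beads(self) -> int:
        return len(self.reference)

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def native_energy(self) -> float:
        return -self.epsilon * self.n_contacts


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run parameters.

    ``kT_over_eps`` is the dimensionless temperature (sampling temperature
    0.7 sits just below the unfolding transition of typical chains);
    ``frac_local_moves`` and ``frac_psi_only`` are the probabilities of the
    crankshaft and Ψ-torsion moves, the remainder being general pivots.
    Frames (and energies) are recorded every ``save_every`` accepted-or-not
    steps, frame 0 always.
    """

    kT_over_eps: float = 0.7
    n_steps: int = 100_000
    save_every: int = 100_000
    frac_local_moves: float = 0.10
    frac_psi_only: float = 0.30
    seed: int = 0
    max_angle_deg: float = 30.0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_local_moves <= 1 and 0 <= self.frac_psi_only <= 1):
            raise ValueError("move fractions must lie in [0, 1]")
        if self.frac_local_moves + self.frac_psi_only > 1:
            raise ValueError("special-move fractions must sum to at most 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.save_every < 1:
            raise ValueError("save_every must be >= 1")
        if self.max_angle_deg <= 0:
            raise ValueError("max_angle_deg must be positive")


@dataclass(frozen=True)
class MCTrajectory:
    """Saved frames, their energies (ε units) and acceptance bookkeeping."""

    frames: Ensemble
    energies: np.ndarray
    accepted: int
    attempted: int
    config: MCConfig

    def __post_init__(self) -> None:
        if self.attempted < self.accepted:
            raise ValueError("attempted < accepted")
        if len(self.energies) != len(self.frames):
            raise ValueError("one energy per frame required")

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.attempted if self.attempted else 0.0

    def coords_stack(self) -> np.ndarray:
        return self.frames.coords_stack()

    def energies_to_tsv(self, path) -> None:
        from pathlib import Path

        lines = ["frame\tenergy"] + [
            f"{i}\t{e:.6f}" for i, e in enumerate(self.energies.tolist())
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def build_go_model(
    ref: Structure,
    contact_cutoff: float = 8.0,
    epsilon: float = 1.0,
    allow_chain_breaks: bool = False,
) -> GoModel:
    """Build the Gō potential from the Cα geometry of a reference structure.

    Native contacts are all bead pairs with |i − j| ≥ 3 whose reference Cα
    distance is at most ``contact_cutoff`` (8 Å by convention).  Bonds take
    their observed consecutive Cα distances.  A consecutive Cα distance above
    4.5 Å is treated as a chain break and rejected unless
    ``allow_chain_breaks`` is set.
    """
    ca_idx = np.flatnonzero(ref.atom_names == "CA")
    residues = ref.unique_residues
    if len(ca_idx) < 4:
        raise ValueError(f"need >= 4 Cα atoms, found {len(ca_idx)}")
    if len(ca_idx) != len(residues):
        missing = set(residues.tolist()) - set(
            ref.residue_numbers[ca_idx].tolist()
        )
        raise ValueError(f"residues without a Cα atom: {sorted(missing)}")
    coords = ref.coords[ca_idx]
    bond_lengths = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if not allow_chain_breaks and np.any(bond_lengths > CHAIN_BREAK_DISTANCE):
        where = int(np.argmax(bond_lengths > CHAIN_BREAK_DISTANCE))
        raise ChainBreakError(
            f"consecutive Cα distance {bond_lengths[where]:.2f} Å after residue "
            f"{residues[where]} exceeds {CHAIN_BREAK_DISTANCE} Å"
        )
    dist = squareform(pdist(coords))
    n = len(coords)
    ii, jj = np.triu_indices(n, k=3)
    within = dist[ii, jj] <= contact_cutoff
    contacts = np.column_stack([ii[within], jj[within]])
    template = Structure(
        ref.residue_numbers[ca_idx],
        ref.residue_names[ca_idx],
        ref.atom_names[ca_idx],
        ref.elements[ca_idx],
        coords,
        ref.chain_ids[ca_idx],
        label=f"{ref.label} (CA)",
    )
    return GoModel(
        reference=coords,
        bond_lengths=bond_lengths,
        contacts=contacts,
        contact_distances=dist[ii[within], jj[within]],
        epsilon=epsilon,
        contact_cutoff=contact_cutoff,
        template=template,
    )


def energy(model: GoModel, conf: np.ndarray) -> float:
    """Potential energy (ε units) of a Cα conformation.

    ``E = −ε · n_formed + bond strain``, where a native contact is formed
    while its current distance is within :data:`CONTACT_TOLERANCE` times its
    reference distance, and any non-bonded pair (|i − j| ≥ 2) closer than
    :data:`CLASH_DISTANCE` makes the conformation infinitely unfavourable
    (hard excluded volume).
    """
    conf = np.asarray(conf, dtype=float)
    if conf.shape != model.reference.shape:
        raise ValueError(
            f"conformation shape {conf.shape} does not match model "
            f"{model.reference.shape}"
        )
    dist = squareform(pdist(conf))
    n = model.n_beads
    ii, jj = np.triu_indices(n, k=2)
    if np.any(dist[ii, jj] < CLASH_DISTANCE):
        return float("inf")
    e = 0.0
    if model.n_contacts:
        d = dist[model.contacts[:, 0], model.contacts[:, 1]]
        formed = d <= CONTACT_TOLERANCE * model.contact_distances
        e -= model.epsilon * int(np.count_nonzero(formed))
    bonds = np.linalg.norm(np.diff(conf, axis=0), axis=1)
    e += BOND_STIFFNESS * float(np.sum((bonds - model.bond_lengths) ** 2))
    return e


def metropolis_accept(delta_e: float, kT: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept downhill always, uphill with
    ``exp(−ΔE/kT)``."""
    if delta_e <= 0:
        return True
    if kT <= 0 or not math.isfinite(delta_e):
        return False
    return rng.random() < math.exp(-delta_e / kT)


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _propose(
    conf: np.ndarray, rng: np.random.Generator, cfg: MCConfig
) -> np.ndarray:
    """Draw a move type and return the proposed conformation (bond-preserving)."""
    n = len(conf)
    u = rng.random()
    angle = math.radians(cfg.max_angle_deg) * (2.0 * rng.random() - 1.0)
    new = conf.copy()
    if u < cfg.frac_local_moves and n >= 5:
        # crankshaft: rotate a 3-bead window about its flanking-bead axis
        i = int(rng.integers(0, n - 4))
        axis = conf[i + 4] - conf[i]
        axis = axis / np.linalg.norm(axis)
        R = _rotation_about_axis(axis, angle)
        new[i + 1 : i + 4] = (conf[i + 1 : i + 4] - conf[i]) @ R.T + conf[i]
    elif u < cfg.frac_local_moves + cfg.frac_psi_only:
        # Ψ-torsion analogue: rotate downstream about a virtual-bond axis
        j = int(rng.integers(1, n - 1))
        axis = conf[j] - conf[j - 1]
        axis = axis / np.linalg.norm(axis)
        R = _rotation_about_axis(axis, angle)
        new[j + 1 :] = (conf[j + 1 :] - conf[j]) @ R.T + conf[j]
    else:
        # general pivot: rotate downstream about a random axis through a bead
        j = int(rng.integers(1, n - 1))
        axis = _random_unit_vector(rng)
        R = _rotation_about_axis(axis, angle)
        new[j + 1 :] = (conf[j + 1 :] - conf[j]) @ R.T + conf[j]
    return new


def run_mc(model: GoModel, start: np.ndarray, cfg: MCConfig) -> MCTrajectory:
    """Metropolis Monte Carlo sampling of the Gō potential.

    ``start`` is a (n, 3) Cα conformation satisfying excluded volume (pass
    ``model.reference`` to sample around the native state).  Frame 0 is
    always saved; thereafter every ``cfg.save_every`` steps.  The run is
    bitwise reproducible for a fixed config.
    """
    conf = np.array(start, dtype=float)
    e = energy(model, conf)
    if not math.isfinite(e):
        raise ValueError("starting conformation violates excluded volume")
    rng = np.random.default_rng(cfg.seed)
    kT = cfg.kT_over_eps * model.epsilon
    frames = [conf.copy()]
    energies = [e]
    accepted = attempted = 0
    for step in range(1, cfg.n_steps + 1):
        proposal = _propose(conf, rng, cfg)
        e_new = energy(model, proposal)
        attempted += 1
        if metropolis_accept(e_new - e, kT, rng):
            conf, e = proposal, e_new
            accepted += 1
        if step % cfg.save_every == 0:
            frames.append(conf.copy())
            energies.append(e)
    template = model.template
    members = []
    for k, coords in enumerate(frames):
        if template is not None:
            members.append(template.with_coords(coords, label=f"frame {k}"))
        else:
            n = len(coords)
            members.append(
                Structure(
                    np.arange(1, n + 1),
                    ["GLY"] * n,
                    ["CA"] * n,
                    ["C"] * n,
                    coords,
                    label=f"frame {k}",
                )
            )
    return MCTrajectory(
        frames=Ensemble(members, label="mc_trajectory"),
        energies=np.asarray(energies),
        accepted=accepted,
        attempted=attempted,
        config=cfg,
    )


def tune_step_size(
    model: GoModel,
    start: np.ndarray,
    cfg: MCConfig,
    target_acceptance: tuple[float, float] = (0.20, 0.25),
    pilot_steps: int = 1500,
    max_iter: int = 14,
) -> float:
    """Find a maximum perturbation angle giving the target acceptance rate.

    Acceptance decreases monotonically (in expectation) with the angle limit,
    so a bisection over short pilot runs converges quickly.  If the iteration
    cap is reached the best angle found is returned with a warning.
    """
    lo_target, hi_target = target_acceptance
    lo, hi = 0.05, 180.0
    best_angle, best_gap = cfg.max_angle_deg, float("inf")
    for it in range(max_iter):
        mid = math.sqrt(lo * hi)  # bisect in log space: angles span decades
        pilot_cfg = dataclasses.replace(
            cfg,
            max_angle_deg=mid,
            n_steps=pilot_steps,
            save_every=pilot_steps,
            seed=cfg.seed + 7919 * it,
        )
        acc = run_mc(model, start, pilot_cfg).acceptance_rate
        if lo_target <= acc <= hi_target:
            return mid
        gap = min(abs(acc - lo_target), abs(acc - hi_target))
        if gap < best_gap:
            best_angle, best_gap = mid, gap
        if acc > hi_target:
            lo = mid  # too timid — enlarge moves
        else:
            hi = mid  # too bold — shrink moves
    warnings.warn(
        f"step-size tuning hit the iteration cap; best angle {best_angle:.2f} deg",
        stacklevel=2,
    )
    return best_angle


@dataclass(frozen=True)
class TemperatureScan:
    """Per-temperature sampling summary and the estimated unfolding temperature."""

    table: pd.DataFrame  # columns: kT_over_eps, mean_rmsd, mean_energy
    unfolding_kT: float | None
    rmsd_threshold: float


def rmsd_from_native(model: GoModel, coords: np.ndarray) -> float:
    """Cα RMSD of a conformation from the model's native state (after fit)."""
    _, _, value = kabsch(coords, model.reference)
    return value


def temperature_scan(
    model: GoModel,
    start: np.ndarray,
    kT_list,
    short_steps: int = 2000,
    cfg: MCConfig | None = None,
    rmsd_threshold: float = 5.0,
) -> TemperatureScan:
    """Short simulations over a temperature ladder to locate unfolding.

    For each kT/ε a short run is performed and the mean Cα RMSD from the
    native state over its saved frames recorded.  The unfolding temperature
    estimate is the lowest kT whose mean RMSD exceeds ``rmsd_threshold``
    (None if the chain stays folded everywhere); the sampling temperature for
    production runs is then chosen slightly below it.
    """
    kT_list = list(kT_list)
    if len(kT_list) < 2:
        raise ValueError("need at least 2 temperatures to scan")
    if cfg is None:
        cfg = MCConfig()
    save_every = max(1, short_steps // 100)
    rows = []
    for k, kT in enumerate(kT_list):
        run_cfg = dataclasses.replace(
            cfg,
            kT_over_eps=float(kT),
            n_steps=short_steps,
            save_every=save_every,
            seed=cfg.seed + 104729 * k,
        )
        traj = run_mc(model, start, run_cfg)
        rmsds = [rmsd_from_native(model, c) for c in traj.coords_stack()]
        rows.append(
            {
                "kT_over_eps": float(kT),
                "mean_rmsd": float(np.mean(rmsds)),
                "final_rmsd": float(rmsds[-1]),
                "mean_energy": float(np.mean(traj.energies)),
                "acceptance_rate": traj.acceptance_rate,
            }
        )
    table = pd.DataFrame(rows)
    above = table[table["mean_rmsd"] > rmsd_threshold]
    unfolding = float(above["kT_over_eps"].min()) if len(above) else None
    return TemperatureScan(table, unfolding, rmsd_threshold)
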