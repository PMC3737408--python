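"""Gō-model construction, energies, Metropolis sampling and temperature scans."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chisquare

from chewspace import (
    MCConfig,
    SyntheticSpec,
    build_go_model,
    energy,
    make_toy_structure,
    run_mc,
    temperature_scan,
    tune_step_size,
)
from chewspace.gomc import (
    CLASH_DISTANCE,
    ChainBreakError,
    metropolis_accept,
    rmsd_from_native,
)


def brute_force_contacts(ca, cutoff=8.0):
    """Oracle: O(n^2) distance scan."""
    contacts = []
    for i in range(len(ca)):
        for j in range(i + 3, len(ca)):
            if np.linalg.norm(ca[i] - ca[j]) <= cutoff:
                contacts.append((i, j))
    return contacts


@pytest.fixture(scope="module")
def helix_model():
    spec = SyntheticSpec(n_residues=12, n_models=1, tail_length=2, seed=1)
    return build_go_model(make_toy_structure(spec))


class TestBuildGoModel:
    def test_extended_chain_has_no_contacts(self):
        spec = SyntheticSpec(
            n_residues=10, n_models=1, tail_length=2, seed=1, geometry="extended"
        )
        model = build_go_model(make_toy_structure(spec))
        assert model.n_contacts == 0

    def test_helix_contacts_match_brute_force(self, helix_model):
        expected = brute_force_contacts(helix_model.reference)
        assert [tuple(c) for c in helix_model.contacts.tolist()] == expected
        assert helix_model.n_contacts > 0

    def test_four_residue_chain_allows_only_terminal_pair(self):
        spec = SyntheticSpec(n_residues=4, n_models=1, tail_length=1, seed=1)
        model = build_go_model(make_toy_structure(spec))
        assert all((j - i) >= 3 for i, j in model.contacts.tolist())
        assert model.n_contacts <= 1

    def test_chain_break_detected(self, helix30):
        coords = helix30.coords.copy()
        coords[helix30.residue_numbers > 15] += np.array([50.0, 0, 0])
        broken = helix30.with_coords(coords)
        with pytest.raises(ChainBreakError):
            build_go_model(broken)
        assert build_go_model(broken, allow_chain_breaks=True).n_beads == 30

    def test_missing_calpha_rejected(self, helix30):
        import copy

        stripped = helix30.with_coords(helix30.coords)
        keep = ~(
            (stripped.residue_numbers == 10) & (stripped.atom_names == "CA")
        )
        from chewspace import Structure

        partial = Structure(
            stripped.residue_numbers[keep],
            stripped.residue_names[keep],
            stripped.atom_names[keep],
            stripped.elements[keep],
            stripped.coords[keep],
        )
        with pytest.raises(ValueError, match="without a C"):
            build_go_model(partial)


class TestEnergy:
    def test_native_energy_is_minus_eps_times_contacts(self, helix_model):
        assert energy(helix_model, helix_model.reference) == pytest.approx(
            -helix_model.epsilon * helix_model.n_contacts
        )

    def test_stretched_chain_loses_all_contacts(self, helix_model):
        n = helix_model.n_beads
        extended = np.zeros((n, 3))
        extended[:, 0] = np.cumsum(np.concatenate([[0.0], helix_model.bond_lengths]))
        value = energy(helix_model, extended)
        assert value == pytest.approx(0.0, abs=1e-9)  # no contacts, no strain

    def test_clash_is_infinitely_unfavourable(self, helix_model):
        conf = helix_model.reference.copy()
        conf[5] = conf[7] + np.array([3.0, 0.0, 0.0]) * (1 / np.sqrt(3))
        assert energy(helix_model, conf) == float("inf")

    def test_length_mismatch_rejected(self, helix_model):
        with pytest.raises(ValueError, match="shape"):
            energy(helix_model, helix_model.reference[:-1])


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert metropolis_accept(-1.0, 0.7, rng)
        assert metropolis_accept(0.0, 0.7, rng)

    def test_two_state_occupancy_matches_boltzmann(self):
        """Two states with energies 0 and -eps at kT/eps = 0.7: the occupancy
        ratio must approach exp(1/0.7) ~ 4.17 within 3 standard errors."""
        kT = 0.7
        rng = np.random.default_rng(42)
        n_steps = 100_000
        state = 0
        visits = []
        for _ in range(n_steps):
            proposed = 1 - state
            delta = (-1.0 if proposed == 1 else 0.0) - (-1.0 if state == 1 else 0.0)
            if metropolis_accept(delta, kT, rng):
                state = proposed
            visits.append(state)
        visits = np.asarray(visits)
        batches = visits.reshape(50, -1).mean(axis=1)  # batch means for SE
        p, se = batches.mean(), batches.std(ddof=1) / np.sqrt(len(batches))
        ratio = p / (1 - p)
        se_ratio = se / (1 - p) ** 2  # delta method
        assert abs(ratio - math.exp(1 / kT)) <= 3 * se_ratio

    def test_discrete_angle_chain_reaches_boltzmann_distribution(self):
        """Detailed balance on an enumerable toy: a single discretised bond
        angle of a 3-bead chain with an arbitrary energy landscape.  The
        empirical state distribution must be consistent with the Boltzmann
        weights (chi-square)."""
        kT = 0.7
        energies = np.array([0.0, -1.0, 0.5, -0.6, 0.2, -1.4, 0.9, -0.2])
        K = len(energies)
        rng = np.random.default_rng(7)
        state = 0
        counts = np.zeros(K)
        for _ in range(200_000):
            proposed = (state + rng.choice([-1, 1])) % K
            if metropolis_accept(energies[proposed] - energies[state], kT, rng):
                state = proposed
            counts[state] += 1
        weights = np.exp(-energies / kT)
        expected = weights / weights.sum() * counts.sum()
        # thin to soften autocorrelation before the chi-square
        scale = 50.0
        stat, p_value = chisquare(counts / scale, expected / scale)
        assert p_value > 0.01


class TestRunMc:
    def test_zero_steps_returns_start_only(self, helix_model):
        traj = run_mc(helix_model, helix_model.reference, MCConfig(n_steps=0))
        assert len(traj.frames) == 1
        assert traj.accepted == traj.attempted == 0
        assert np.allclose(traj.frames[0].coords, helix_model.reference)

    def test_same_seed_bitwise_identical(self, helix_model):
        cfg = MCConfig(n_steps=3000, save_every=300, seed=123)
        t1 = run_mc(helix_model, helix_model.reference, cfg)
        t2 = run_mc(helix_model, helix_model.reference, cfg)
        assert np.array_equal(t1.energies, t2.energies)
        assert np.array_equal(t1.coords_stack(), t2.coords_stack())
        assert (t1.accepted, t1.attempted) == (t2.accepted, t2.attempted)

    def test_different_seed_differs(self, helix_model):
        cfg = MCConfig(n_steps=2000, save_every=200, seed=1)
        other = dataclasses.replace(cfg, seed=2)
        t1 = run_mc(helix_model, helix_model.reference, cfg)
        t2 = run_mc(helix_model, helix_model.reference, other)
        assert not np.array_equal(t1.energies, t2.energies)

    def test_saved_energies_match_recomputation(self, helix_model):
        cfg = MCConfig(n_steps=2000, save_every=250, seed=5)
        traj = run_mc(helix_model, helix_model.reference, cfg)
        for frame, e in zip(traj.coords_stack(), traj.energies):
            assert energy(helix_model, frame) == pytest.approx(e, abs=1e-9)

    def test_excluded_volume_never_violated_in_saved_frames(self, helix_model):
        cfg = MCConfig(n_steps=4000, save_every=200, seed=9, kT_over_eps=1.5)
        traj = run_mc(helix_model, helix_model.reference, cfg)
        n = helix_model.n_beads
        ii, jj = np.triu_indices(n, k=2)
        for frame in traj.coords_stack():
            dist = squareform(pdist(frame))
            assert dist[ii, jj].min() >= CLASH_DISTANCE

    def test_bond_lengths_preserved_by_moves(self, helix_model):
        cfg = MCConfig(n_steps=2000, save_every=500, seed=4)
        traj = run_mc(helix_model, helix_model.reference, cfg)
        last = traj.coords_stack()[-1]
        bonds = np.linalg.norm(np.diff(last, axis=0), axis=1)
        assert np.allclose(bonds, helix_model.bond_lengths, atol=1e-9)

    def test_acceptance_rate_bookkeeping_exact(self, helix_model):
        cfg = MCConfig(n_steps=1000, save_every=100, seed=3)
        traj = run_mc(helix_model, helix_model.reference, cfg)
        assert traj.attempted == 1000
        assert traj.acceptance_rate == traj.accepted / 1000

    def test_clashing_start_rejected(self, helix_model):
        bad = helix_model.reference.copy()
        bad[0] = bad[4]
        with pytest.raises(ValueError, match="excluded volume"):
            run_mc(helix_model, bad, MCConfig(n_steps=10))


class TestTuneStepSize:
    def test_tiny_moves_accept_nearly_everything(self, helix_model):
        cfg = MCConfig(n_steps=800, save_every=800, seed=2, max_angle_deg=0.05)
        traj = run_mc(helix_model, helix_model.reference, cfg)
        assert traj.acceptance_rate > 0.9

    def test_huge_moves_mostly_rejected_from_folded_start(self, hairpin40):
        model = build_go_model(hairpin40)
        cfg = MCConfig(
            n_steps=800, save_every=800, seed=2, max_angle_deg=179.0,
            kT_over_eps=0.3,
        )
        traj = run_mc(model, model.reference, cfg)
        assert traj.acceptance_rate < 0.35

    def test_tuned_angle_hits_target_band_on_fresh_seed(self, hairpin40):
        model = build_go_model(hairpin40)
        cfg = MCConfig(seed=11, kT_over_eps=0.7)
        angle = tune_step_size(model, model.reference, cfg, pilot_steps=1200)
        fresh = MCConfig(
            n_steps=3000, save_every=3000, seed=999, kT_over_eps=0.7,
            max_angle_deg=angle,
        )
        traj = run_mc(model, model.reference, fresh)
        assert 0.18 <= traj.acceptance_rate <= 0.27


class TestTemperatureScan:
    def test_quench_stays_folded_and_energy_low(self, hairpin40):
        model = build_go_model(hairpin40)
        scan = temperature_scan(
            model, model.reference, [0.05, 0.2], short_steps=1500,
            cfg=MCConfig(seed=6),
        )
        row = scan.table.iloc[0]
        assert row["final_rmsd"] < scan.rmsd_threshold
        assert row["mean_energy"] < 0.5 * model.native_energy()  # stays bound

    def test_rmsd_from_native_increases_with_temperature(self, hairpin40):
        model = build_go_model(hairpin40)
        scan = temperature_scan(
            model, model.reference, [0.2, 1.0, 6.0], short_steps=2500,
            cfg=MCConfig(seed=12),
        )
        table = scan.table
        assert (
            table["mean_rmsd"].iloc[-1] >= table["mean_rmsd"].iloc[0]
        )

    def test_thirteen_point_scan_returns_thirteen_rows(self, helix_model):
        kts = np.linspace(0.3, 1.5, 13)
        scan = temperature_scan(
            helix_model, helix_model.reference, kts, short_steps=300,
            cfg=MCConfig(seed=1),
        )
        assert len(scan.table) == 13

    def test_fewer_than_two_temperatures_rejected(self, helix_model):
        with pytest.raises(ValueError):
            temperature_scan(helix_model, helix_model.reference, [0.7])
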