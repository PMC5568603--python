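"""Sampler correctness: restraints, placement, energies, moves, REMC."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from slimdock.coarse_grain import (
    CoarseChain,
    coarse_grain_chain,
    derive_pseudo_atoms,
    random_peptide_conformation,
)
from slimdock.docking_engine import (
    DockingConfig,
    EnergyModel,
    ReplicaState,
    Trajectory,
    _System,
    generate_receptor_restraints,
    build_energy_model,
    mc_move,
    metropolis_accept,
    place_peptide_replicas,
    replica_exchange_sweep,
    run_docking,
    total_energy,
)
from slimdock.fixtures import ToyComplexSpec, make_toy_receptor


@pytest.fixture(scope="module")
def helix20():
    return coarse_grain_chain(make_toy_receptor(
        ToyComplexSpec(receptor_length=20, fold="helix")))


@pytest.fixture(scope="module")
def small_receptor():
    return make_toy_receptor(ToyComplexSpec(receptor_length=22, fold="helix"))


def _single_site_chain(letter, position):
    """One-residue coarse chain with its interaction site at ``position``."""
    p = np.asarray(position, float)
    return CoarseChain("X", letter, ca=p, cb=np.full(3, np.nan),
                       sc=p.copy(), pb=np.empty((0, 3)))


class TestRestraints:
    def test_two_residue_chain_gives_none(self):
        ca = np.array([[0, 0, 0], [3.8, 0, 0.0]])
        cb, sc, pb = derive_pseudo_atoms(ca, "AA")
        chain = CoarseChain("R", "AA", ca, cb, sc, pb)
        assert generate_receptor_restraints(chain) == []

    def test_count_matches_exhaustive_enumeration(self, helix20):
        restraints = generate_receptor_restraints(helix20)
        brute = 0
        ca = helix20.ca
        for i in range(len(helix20)):
            for j in range(i + 5, len(helix20)):
                if 5.0 <= np.linalg.norm(ca[i] - ca[j]) <= 15.0:
                    brute += 1
        assert len(restraints) == brute > 0

    def test_zero_energy_at_starting_conformation(self, helix20):
        model = EnergyModel()
        model.restraints = generate_receptor_restraints(helix20)
        sys = _System(model, helix20, "AA")
        assert sys.receptor_energy(helix20)["restraint"] == 0.0


class TestPlacement:
    def test_default_gives_ten_replicas(self, helix20):
        states = place_peptide_replicas(helix20, "KKKFFF", DockingConfig(seed=1))
        assert len(states) == 10
        temps = [s.temperature for s in states]
        assert temps == sorted(temps) and temps[0] < temps[-1]

    def test_surface_distance_twenty_angstroms(self, helix20):
        config = DockingConfig(seed=5)
        rec_atoms, _ = helix20.pseudo_atoms()
        for state in place_peptide_replicas(helix20, "KKKFFF", config):
            pep_atoms, _ = state.peptide.pseudo_atoms()
            d = cdist(pep_atoms, rec_atoms).min()
            assert abs(d - config.placement_distance) < 0.1

    def test_seed_reproducible(self, helix20):
        a = place_peptide_replicas(helix20, "ADE", DockingConfig(seed=9))
        b = place_peptide_replicas(helix20, "ADE", DockingConfig(seed=9))
        for x, y in zip(a, b):
            assert np.array_equal(x.peptide.ca, y.peptide.ca)


class TestTotalEnergy:
    def test_distant_ideal_peptide_has_zero_inter_terms(self, helix20):
        pep = random_peptide_conformation("AAAA", seed=0)
        pep.translate(np.array([200.0, 0, 0]) - pep.ca.mean(axis=0))
        model = EnergyModel()   # tether disabled by default
        state = ReplicaState(0, 1.0, pep, helix20)
        _, terms = total_energy(state, model)
        assert terms["contact"] == 0.0
        assert terms["inter_excluded"] == 0.0
        assert terms["tether"] == 0.0
        assert terms["peptide_bond"] < 1e-12

    def test_single_leucine_pair_scores_table_entry(self):
        from slimdock.coarse_grain import AA_INDEX
        model = EnergyModel()
        rec = _single_site_chain("L", [0.0, 0.0, 0.0])
        pep = _single_site_chain("L", [5.0, 0.0, 0.0])   # < 6.5 A contact
        _, terms = total_energy(ReplicaState(0, 1.0, pep, rec), model)
        li = AA_INDEX["L"]
        assert terms["contact"] == pytest.approx(model.contact_energies[li, li])

    def test_pair_beyond_contact_radius_scores_zero(self):
        model = EnergyModel()
        rec = _single_site_chain("L", [0.0, 0.0, 0.0])
        pep = _single_site_chain("L", [7.0, 0.0, 0.0])
        _, terms = total_energy(ReplicaState(0, 1.0, pep, rec), model)
        assert terms["contact"] == 0.0


class TestMetropolis:
    def test_zero_delta_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(0.0, 1.0, rng) for _ in range(100))

    def test_negative_delta_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-5.0, t, rng) for t in (0.5, 1.0, 3.0))

    def test_rate_at_t_ln2_is_half(self):
        # dE = T ln 2  =>  acceptance exp(-ln 2) = 0.5
        rng = np.random.default_rng(123)
        t = 1.7
        n = 10_000
        hits = sum(metropolis_accept(t * np.log(2), t, rng) for _ in range(n))
        assert abs(hits / n - 0.5) < 0.02

    def test_nonpositive_temperature_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, rng)


class TestReplicaExchange:
    def _states(self, energies, temperatures):
        pep = random_peptide_conformation("AA", seed=0)
        return [ReplicaState(i, t, pep.copy(), pep.copy(), energy=e)
                for i, (e, t) in enumerate(zip(energies, temperatures))]

    def test_equal_temperatures_accept_all_swaps(self):
        rng = np.random.default_rng(0)
        states = self._states([0.0, 5.0, -3.0, 2.0], [1.0, 1.0, 1.0, 1.0])
        assert replica_exchange_sweep(states, rng, phase=0) == 2

    def test_hot_replica_with_lower_energy_always_swaps(self):
        # cold slot holds the higher energy: exp(db * dE) >= 1, so the
        # configuration found by the hot replica is always handed down
        rng = np.random.default_rng(0)
        for _ in range(50):
            states = self._states([10.0, -10.0], [1.0, 3.0])
            assert replica_exchange_sweep(states, rng, phase=0) == 1

    def test_replica_count_conserved(self):
        rng = np.random.default_rng(1)
        states = self._states([1.0, 2.0, 3.0, 4.0, 5.0], [1, 1.5, 2, 2.5, 3])
        for phase in range(10):
            replica_exchange_sweep(states, rng, phase=phase)
        assert len(states) == 5
        assert [s.temperature for s in states] == [1, 1.5, 2, 2.5, 3]

    def test_single_replica_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            replica_exchange_sweep(self._states([0.0], [1.0]), rng)


class TestMoves:
    def test_zero_displacement_config_is_identity(self, helix20):
        config = DockingConfig(max_translation=0, max_rotation_deg=0,
                               max_ca_shift=0, max_crank_deg=0,
                               max_pivot_deg=0, max_receptor_shift=0)
        pep = random_peptide_conformation("ADEFK", seed=1)
        state = ReplicaState(0, 1.0, pep, helix20)
        rng = np.random.default_rng(4)
        for _ in range(50):
            cand, _ = mc_move(state, rng, config)
            assert np.allclose(cand.peptide.ca, pep.ca, atol=1e-12)
            assert np.allclose(cand.receptor.ca, helix20.ca, atol=1e-12)

    def test_receptor_shift_bounded(self, helix20):
        config = DockingConfig(move_weights={"receptor_shift": 1.0})
        pep = random_peptide_conformation("ADE", seed=1)
        state = ReplicaState(0, 1.0, pep, helix20)
        rng = np.random.default_rng(4)
        for _ in range(200):
            cand, label = mc_move(state, rng, config)
            assert label == "receptor_shift"
            shift = np.linalg.norm(cand.receptor.ca - helix20.ca, axis=1).max()
            assert shift <= config.max_receptor_shift + 1e-12

    def test_high_temperature_accepts_everything(self, helix20):
        config = DockingConfig()
        pep = random_peptide_conformation("ADEFK", seed=2)
        model = build_energy_model(config, helix20)
        sys = _System(model, helix20, pep.sequence)
        state = ReplicaState(0, 1e9, pep, helix20)
        state.energy, state.terms = sys.total(pep, helix20)
        rng = np.random.default_rng(11)
        accepted = 0
        for _ in range(1000):
            cand, _ = mc_move(state, rng, config)
            e_new, _ = sys.total(cand.peptide, cand.receptor)
            if metropolis_accept(e_new - state.energy, state.temperature, rng):
                accepted += 1
                state = cand
                state.energy = e_new
        assert accepted == 1000


class TestRunDocking:
    def test_snapshot_count_contract(self, small_receptor):
        config = DockingConfig(n_replicas=2, n_snapshots_per_replica=5, seed=0)
        traj = run_docking(small_receptor, "ADEK", config)
        assert len(traj) == 10
        per = traj.per_replica()
        assert sorted(per) == [0, 1]
        assert all(len(v) == 5 for v in per.values())

    def test_bit_identical_given_seed(self, small_receptor):
        config = DockingConfig(n_replicas=2, n_snapshots_per_replica=4, seed=7)
        a = run_docking(small_receptor, "ADEK", config)
        b = run_docking(small_receptor, "ADEK", config)
        for sa, sb in zip(a.snapshots, b.snapshots):
            assert sa.energy == sb.energy
            assert np.array_equal(sa.peptide.ca, sb.peptide.ca)
            assert np.array_equal(sa.receptor.ca, sb.receptor.ca)

    def test_energy_bookkeeping_matches_recompute(self, small_receptor):
        # tracked incrementally during ~1e3 accepted moves; must equal a
        # from-scratch recomputation at every snapshot
        config = DockingConfig(n_replicas=3, n_snapshots_per_replica=30,
                               sweeps_between_snapshots=2, seed=5)
        traj = run_docking(small_receptor, "ADEKF", config)
        rec0 = coarse_grain_chain(small_receptor)
        model = build_energy_model(config, rec0)
        sys = _System(model, rec0, "ADEKF")
        worst = 0.0
        for snap in traj.snapshots:
            e, _ = sys.total(snap.peptide, snap.receptor)
            worst = max(worst, abs(e - snap.energy))
        assert worst < 1e-6

    def test_save_load_round_trip(self, small_receptor, tmp_path):
        config = DockingConfig(n_replicas=2, n_snapshots_per_replica=3, seed=1)
        traj = run_docking(small_receptor, "ADE", config)
        traj.save(tmp_path / "run")
        back = Trajectory.load(tmp_path / "run")
        assert len(back) == len(traj)
        for a, b in zip(traj.snapshots, back.snapshots):
            assert a.energy == pytest.approx(b.energy)
            assert np.allclose(a.peptide.ca, b.peptide.ca, atol=1e-3)
        assert back.metadata["seed"] == 1


def test_two_state_detailed_balance():
    """Metropolis occupancy of a two-level system converges to Boltzmann."""
    rng = np.random.default_rng(2718)
    delta, temp = 1.3, 1.0
    state = 0
    n, up = 100_000, 0
    for _ in range(n):
        if state == 0:
            if metropolis_accept(delta, temp, rng):
                state = 1
        else:
            state = 0   # downhill, always accepted
        up += state
    p_up = up / n
    expected = 1.0 / (1.0 + np.exp(delta / temp))
    sigma = np.sqrt(expected * (1 - expected) / n)
    # correlated samples: allow 3 sigma with a generous correlation factor
    assert abs(p_up - expected) < 10 * sigma


def test_config_validation():
    with pytest.raises(ValueError):
        DockingConfig(n_replicas=0)
    with pytest.raises(ValueError):
        DockingConfig(temperature_min=2.0, temperature_max=1.0)
    cfg = DockingConfig()
    temps = cfg.temperatures()
    assert len(temps) == 10
    assert np.all(np.diff(temps) > 0)
    assert cfg.digest() == DockingConfig().digest()
    assert cfg.digest() != DockingConfig(seed=1).digest()
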