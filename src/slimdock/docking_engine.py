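"""Replica exchange Monte Carlo docking of a flexible coarse-grained peptide.

The peptide is fully flexible; the receptor is held near its starting
conformation by flat-bottom harmonic CA-CA distance restraints derived
from that conformation.  Ten replicas on a geometric temperature ladder
run Metropolis sweeps with periodic configuration exchanges, and a fixed
number of snapshots per replica (default 1000, so 10,000 models in the
default configuration) is collected at a fixed cadence across the run.

The energy model is a transparent knowledge-based surrogate: a symmetric
20x20 residue-type contact table on the united-side-chain sites, a
quadratic hard-core excluded-volume penalty, harmonic virtual-bond terms,
the receptor restraints, and a weak flat-bottom centre-of-mass tether
that bounds the search volume (the continuous-space counterpart of a
simulation box).  Every constant is configuration, not code.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .coarse_grain import (
    AA_INDEX,
    AA_ORDER,
    CA_BOND,
    CoarseChain,
    coarse_grain_chain,
    coarse_to_chain,
    derive_pseudo_atoms,
    random_peptide_conformation,
)
from .structure_io import ChainStructure, write_pdb, read_pdb


# ---------------------------------------------------------------------------
# energy model

def default_contact_energies() -> np.ndarray:
    """Load the packaged 20x20 contact table (AA_ORDER x AA_ORDER)."""
    ref = importlib.resources.files("slimdock").joinpath("data/contact_energies.csv")
    with importlib.resources.as_file(ref) as path:
        return load_contact_energies(path)


def load_contact_energies(path) -> np.ndarray:
    df = pd.read_csv(path, comment="#", index_col=0)
    table = df.loc[list(AA_ORDER), list(AA_ORDER)].to_numpy(dtype=float)
    if not np.allclose(table, table.T, atol=1e-9):
        raise ValueError("contact energy table must be symmetric")
    return table


@dataclass
class Restraint:
    """Flat-bottom harmonic CA-CA distance restraint between receptor residues."""

    i: int
    j: int
    d0: float
    delta: float = 1.0
    k: float = 1.0

    def __post_init__(self):
        if self.d0 <= 0 or self.delta < 0 or self.k < 0:
            raise ValueError("invalid restraint parameters")


@dataclass
class EnergyModel:
    """All tunable terms of the surrogate potential (energies dimensionless)."""

    contact_energies: np.ndarray = field(default_factory=default_contact_energies)
    contact_radius: float = 6.5       # SC-SC contact cutoff, A
    hardcore_radius: float = 3.5      # excluded-volume onset, A
    excluded_weight: float = 1.0      # energy / A^2
    bond_weight: float = 5.0          # energy / A^2 on virtual CA-CA bonds
    bond_length: float = CA_BOND
    restraint_delta: float = 1.0      # flat-bottom half width, A
    restraint_k: float = 1.0          # energy / A^2
    restraints: list[Restraint] = field(default_factory=list)
    tether_radius: float | None = None  # free CoM radius, A (None: disabled)
    tether_k: float = 0.05            # energy / A^2

    def __post_init__(self):
        self.contact_energies = np.asarray(self.contact_energies, dtype=float)
        if self.contact_energies.shape != (20, 20):
            raise ValueError("contact table must be 20x20")
        if not np.allclose(self.contact_energies, self.contact_energies.T, atol=1e-9):
            raise ValueError("contact table must be symmetric")
        if self.contact_radius <= 0 or self.hardcore_radius <= 0:
            raise ValueError("radii must be positive")


def generate_receptor_restraints(receptor: CoarseChain,
                                 min_separation: int = 5,
                                 distance_window: tuple[float, float] = (5.0, 15.0),
                                 delta: float = 1.0, k: float = 1.0,
                                 ) -> list[Restraint]:
    """Restraints at the starting CA-CA distance for every qualifying pair.

    A pair qualifies when its sequence separation is >= ``min_separation``
    and its starting distance lies inside ``distance_window``.  All
    restraints have zero energy at the starting conformation (flat bottom
    centred on it).
    """
    ca = receptor.ca
    n = len(receptor)
    out: list[Restraint] = []
    for i in range(n):
        d = np.linalg.norm(ca[i + min_separation:] - ca[i], axis=1)
        for off, dist in enumerate(d):
            if distance_window[0] <= dist <= distance_window[1]:
                out.append(Restraint(i=i, j=i + min_separation + off,
                                     d0=float(dist), delta=delta, k=k))
    return out


# ---------------------------------------------------------------------------
# configuration

@dataclass
class DockingConfig:
    """Run parameters; defaults give 10 replicas x 1000 snapshots = 10,000 models."""

    n_replicas: int = 10
    n_snapshots_per_replica: int = 1000
    sweeps_between_snapshots: int = 1
    exchange_interval: int = 10       # sweeps between exchange phases
    temperature_min: float = 1.0
    temperature_max: float = 3.0
    placement_distance: float = 20.0  # A from receptor surface
    seed: int = 0
    moves_per_sweep: int | None = None  # default: peptide length + 2
    move_weights: dict = field(default_factory=lambda: {
        "translate": 0.20, "rotate": 0.15, "ca_shift": 0.30,
        "crankshaft": 0.15, "pivot": 0.10, "receptor_shift": 0.10,
    })
    max_translation: float = 2.0      # A
    max_rotation_deg: float = 30.0
    max_ca_shift: float = 1.0         # A
    max_crank_deg: float = 30.0
    max_pivot_deg: float = 30.0
    max_receptor_shift: float = 0.5   # A
    restraint_min_separation: int = 5
    restraint_window: tuple = (5.0, 15.0)
    contact_table_path: str | None = None  # None: packaged default

    def __post_init__(self):
        if min(self.n_replicas, self.n_snapshots_per_replica,
               self.sweeps_between_snapshots, self.exchange_interval) < 1:
            raise ValueError("all counts must be >= 1")
        if self.temperature_min <= 0 or self.temperature_max < self.temperature_min:
            raise ValueError("bad temperature range")

    def temperatures(self) -> np.ndarray:
        n = self.n_replicas
        if n == 1:
            return np.array([self.temperature_min])
        ratio = self.temperature_max / self.temperature_min
        return self.temperature_min * ratio ** (np.arange(n) / (n - 1))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["restraint_window"] = list(self.restraint_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DockingConfig":
        d = dict(d)
        if "restraint_window" in d:
            d["restraint_window"] = tuple(d["restraint_window"])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# energy evaluation

class _ChainLayout:
    """Static stacking pattern of one chain's present pseudo-atoms."""

    def __init__(self, chain: CoarseChain):
        n = len(chain)
        idx = np.arange(n)
        self.cb_idx = idx[~np.isnan(chain.cb).any(axis=1)]
        self.sc_idx = idx[~np.isnan(chain.sc).any(axis=1)]
        self.pb_idx = (idx[:-1][~np.isnan(chain.pb).any(axis=1)]
                       if len(chain.pb) else np.empty(0, dtype=int))
        self.labels = np.concatenate([idx, self.cb_idx, self.sc_idx, self.pb_idx])
        self.gly = np.isnan(chain.sc).any(axis=1)
        sep = np.abs(self.labels[:, None] - self.labels[None, :])
        iu, ju = np.nonzero(np.triu(sep >= 2))
        self.intra_i, self.intra_j = iu, ju

    def stack(self, chain: CoarseChain) -> np.ndarray:
        parts = [chain.ca]
        if len(self.cb_idx):
            parts.append(chain.cb[self.cb_idx])
        if len(self.sc_idx):
            parts.append(chain.sc[self.sc_idx])
        if len(self.pb_idx):
            parts.append(chain.pb[self.pb_idx])
        return np.concatenate(parts, axis=0)

    def sites(self, chain: CoarseChain) -> np.ndarray:
        return np.where(self.gly[:, None], chain.ca, chain.sc)


class _System:
    """Precomputed static context for fast term evaluation.

    Layouts (which pseudo-atoms exist, which intra-chain pairs count for
    excluded volume, the residue-type contact energies of every
    peptide-receptor pair) never change during a run, so they are built
    once; per-state coordinate stacks for the receptor are cached by
    object identity because the receptor moves rarely.
    """

    def __init__(self, model: EnergyModel, receptor: CoarseChain, sequence: str):
        self.model = model
        self.pep_types = np.array([AA_INDEX[c] for c in sequence])
        self.rec_types = receptor.type_indices
        self.pair_energies = model.contact_energies[
            self.pep_types[:, None], self.rec_types[None, :]]
        self.rec_bond_ref = np.linalg.norm(np.diff(receptor.ca, axis=0), axis=1)
        r = model.restraints
        self.r_i = np.array([x.i for x in r], dtype=int)
        self.r_j = np.array([x.j for x in r], dtype=int)
        self.r_d0 = np.array([x.d0 for x in r], dtype=float)
        self.r_delta = np.array([x.delta for x in r], dtype=float)
        self.r_k = np.array([x.k for x in r], dtype=float)
        self.rec_centroid = receptor.ca.mean(axis=0)
        self.rec_layout = _ChainLayout(receptor)
        self.pep_layout: _ChainLayout | None = None
        self._rec_cache: tuple[int, np.ndarray, np.ndarray] | None = None

    def _pep_layout(self, pep: CoarseChain) -> _ChainLayout:
        if self.pep_layout is None:
            self.pep_layout = _ChainLayout(pep)
        return self.pep_layout

    def _rec_arrays(self, rec: CoarseChain) -> tuple[np.ndarray, np.ndarray]:
        key = id(rec)
        if self._rec_cache is None or self._rec_cache[0] != key:
            self._rec_cache = (key, self.rec_layout.stack(rec),
                               self.rec_layout.sites(rec))
        return self._rec_cache[1], self._rec_cache[2]

    def _excluded_intra(self, chain: CoarseChain, layout: _ChainLayout) -> float:
        coords = layout.stack(chain)
        diff = coords[layout.intra_i] - coords[layout.intra_j]
        d2 = np.einsum("ij,ij->i", diff, diff)
        hard = self.model.hardcore_radius
        viol = d2 < hard * hard
        if not viol.any():
            return 0.0
        short = hard - np.sqrt(d2[viol])
        return float(self.model.excluded_weight * np.sum(short ** 2))

    def receptor_energy(self, rec: CoarseChain) -> dict:
        ca = rec.ca
        e_rest = 0.0
        if len(self.r_i):
            diff = ca[self.r_i] - ca[self.r_j]
            d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
            excess = np.maximum(np.abs(d - self.r_d0) - self.r_delta, 0.0)
            e_rest = float(np.sum(self.r_k * excess ** 2))
        bond = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        e_bond = float(self.model.bond_weight * np.sum((bond - self.rec_bond_ref) ** 2))
        return {"restraint": e_rest, "receptor_bond": e_bond,
                "receptor_excluded": self._excluded_intra(rec, self.rec_layout)}

    def peptide_energy(self, pep: CoarseChain) -> dict:
        diff = np.diff(pep.ca, axis=0)
        bond = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        e_bond = float(self.model.bond_weight *
                       np.sum((bond - self.model.bond_length) ** 2))
        return {"peptide_bond": e_bond,
                "peptide_excluded": self._excluded_intra(pep, self._pep_layout(pep))}

    def interaction_energy(self, pep: CoarseChain, rec: CoarseChain) -> dict:
        m = self.model
        layout = self._pep_layout(pep)
        rec_stack, rec_sites = self._rec_arrays(rec)
        d_sites = cdist(layout.sites(pep), rec_sites)
        mask = d_sites < m.contact_radius
        e_contact = float(self.pair_energies[mask].sum()) if mask.any() else 0.0
        d = cdist(layout.stack(pep), rec_stack)
        viol = d < m.hardcore_radius
        e_excl = 0.0
        if viol.any():
            e_excl = float(m.excluded_weight *
                           np.sum((m.hardcore_radius - d[viol]) ** 2))
        e_tether = 0.0
        if m.tether_radius is not None:
            r = float(np.linalg.norm(pep.ca.mean(axis=0) - self.rec_centroid))
            if r > m.tether_radius:
                e_tether = m.tether_k * (r - m.tether_radius) ** 2
        return {"contact": e_contact, "inter_excluded": e_excl,
                "tether": e_tether}

    def total(self, pep: CoarseChain, rec: CoarseChain) -> tuple[float, dict]:
        terms = {}
        terms.update(self.receptor_energy(rec))
        terms.update(self.peptide_energy(pep))
        terms.update(self.interaction_energy(pep, rec))
        return float(sum(terms.values())), terms


@dataclass
class ReplicaState:
    """One replica: temperature, both chains, and the tracked energy."""

    index: int
    temperature: float
    peptide: CoarseChain
    receptor: CoarseChain
    energy: float = np.nan
    terms: dict = field(default_factory=dict)


def total_energy(state: ReplicaState, model: EnergyModel) -> tuple[float, dict]:
    """Recompute the state's total energy and per-term breakdown from scratch."""
    sys = _System(model, state.receptor, state.peptide.sequence)
    # note: receptor bond reference must come from the run's starting receptor;
    # callers that track incrementally use the engine's _System instead.
    return sys.total(state.peptide, state.receptor)


# ---------------------------------------------------------------------------
# moves

def _rand_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    if radius <= 0:
        return np.zeros(3)
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * radius * rng.uniform() ** (1.0 / 3.0)


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    # Rodrigues formula; cheaper than a scipy Rotation round-trip in the
    # per-move hot path
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    t = 1.0 - c
    return np.array([
        [c + x * x * t, x * y * t - z * s, x * z * t + y * s],
        [y * x * t + z * s, c + y * y * t, y * z * t - x * s],
        [z * x * t - y * s, z * y * t + x * s, c + z * z * t],
    ])


def _rand_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_deg, max_deg))
    return _axis_angle_matrix(axis, angle)


def mc_move(state: ReplicaState, rng: np.random.Generator,
            config: DockingConfig) -> tuple[ReplicaState, str]:
    """Propose one symmetric trial move; returns the candidate state and label.

    The candidate's ``energy`` is stale (the caller evaluates it); the
    input state is never mutated.
    """
    cache = getattr(config, "_move_cache", None)
    if cache is None:
        labels = list(config.move_weights)
        weights = np.array([config.move_weights[k] for k in labels], dtype=float)
        cum = np.cumsum(weights / weights.sum())
        cache = (labels, cum)
        object.__setattr__(config, "_move_cache", cache)
    labels, cum = cache
    label = labels[int(np.searchsorted(cum, rng.uniform()))]
    pep, rec = state.peptide, state.receptor
    n = len(pep)

    if label == "translate":
        pep = pep.copy()
        pep.translate(_rand_in_ball(rng, config.max_translation))
    elif label == "rotate":
        pep = pep.copy()
        pep.rotate(_rand_rotation(rng, config.max_rotation_deg),
                   pep.ca.mean(axis=0))
    elif label == "ca_shift":
        pep = pep.copy()
        i = int(rng.integers(n))
        pep.ca[i] += _rand_in_ball(rng, config.max_ca_shift)
        pep.cb, pep.sc, pep.pb = derive_pseudo_atoms(pep.ca, pep.sequence)
    elif label == "crankshaft":
        pep = pep.copy()
        if n >= 3:
            i = int(rng.integers(1, n - 1))
            axis = pep.ca[i + 1] - pep.ca[i - 1]
            norm = np.linalg.norm(axis)
            if norm > 1e-8:
                rot = _axis_angle_matrix(
                    axis / norm,
                    np.deg2rad(rng.uniform(-config.max_crank_deg,
                                           config.max_crank_deg)))
                pep.ca[i] = rot @ (pep.ca[i] - pep.ca[i - 1]) + pep.ca[i - 1]
        pep.cb, pep.sc, pep.pb = derive_pseudo_atoms(pep.ca, pep.sequence)
    elif label == "pivot":
        pep = pep.copy()
        end, anchor = (0, 1) if rng.uniform() < 0.5 else (n - 1, n - 2)
        rot = _rand_rotation(rng, config.max_pivot_deg)
        pep.ca[end] = rot @ (pep.ca[end] - pep.ca[anchor]) + pep.ca[anchor]
        pep.cb, pep.sc, pep.pb = derive_pseudo_atoms(pep.ca, pep.sequence)
    elif label == "receptor_shift":
        rec = rec.copy()
        j = int(rng.integers(len(rec)))
        delta = _rand_in_ball(rng, config.max_receptor_shift)
        rec.ca[j] += delta
        if not np.any(np.isnan(rec.cb[j])):
            rec.cb[j] += delta
        if not np.any(np.isnan(rec.sc[j])):
            rec.sc[j] += delta
        # peptide-bond centres adjacent to j shift by half (midpoint property)
        if j > 0 and len(rec.pb):
            rec.pb[j - 1] += 0.5 * delta
        if j < len(rec) - 1 and len(rec.pb):
            rec.pb[j] += 0.5 * delta
    else:  # pragma: no cover - config validation
        raise ValueError(f"unknown move {label}")

    cand = ReplicaState(index=state.index, temperature=state.temperature,
                        peptide=pep, receptor=rec, energy=np.nan,
                        terms=dict(state.terms))
    return cand, label


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Accept iff dE <= 0 or rand < exp(-dE / T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return bool(rng.uniform() < np.exp(-delta_e / temperature))


def replica_exchange_sweep(states: list[ReplicaState], rng: np.random.Generator,
                           phase: int = 0) -> int:
    """Attempt configuration swaps between adjacent temperature slots.

    Alternating even/odd pairings; a swap of configurations between slots
    i (colder) and j (hotter) is accepted with probability
    ``min(1, exp((1/T_i - 1/T_j) * (E_i - E_j)))`` -- so a hotter replica
    that found a lower energy always hands it down the ladder.
    Temperatures stay with the slots; configurations (and energies) move.
    Returns the number of accepted swaps.
    """
    if len(states) < 2:
        raise ValueError("need at least 2 replicas to exchange")
    accepted = 0
    for i in range(phase % 2, len(states) - 1, 2):
        a, b = states[i], states[i + 1]
        d_beta = 1.0 / a.temperature - 1.0 / b.temperature
        arg = d_beta * (a.energy - b.energy)
        if arg >= 0 or rng.uniform() < np.exp(arg):
            a.peptide, b.peptide = b.peptide, a.peptide
            a.receptor, b.receptor = b.receptor, a.receptor
            a.energy, b.energy = b.energy, a.energy
            a.terms, b.terms = b.terms, a.terms
            accepted += 1
    return accepted


# ---------------------------------------------------------------------------
# placement

def place_peptide_replicas(receptor: CoarseChain, sequence: str,
                           config: DockingConfig,
                           seed: int | None = None) -> list[ReplicaState]:
    """Fresh random conformers placed at the configured surface distance.

    Each replica's peptide is translated along a uniformly random direction
    from the receptor centroid until its minimum pseudo-atom distance to the
    receptor's pseudo-atoms equals ``config.placement_distance`` (within
    0.01 A, well inside the 0.1 A contract).
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(config.n_replicas)
    temps = config.temperatures()
    rec_atoms, _ = receptor.pseudo_atoms()
    centroid = receptor.ca.mean(axis=0)
    states = []
    for r in range(config.n_replicas):
        rng = np.random.default_rng(children[r])
        pep = random_peptide_conformation(sequence, rng)
        pep.rotate(_rand_rotation(rng, 180.0), pep.ca.mean(axis=0))
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pep.translate(centroid - pep.ca.mean(axis=0))  # centre on receptor

        base = pep.pseudo_atoms()[0]

        def min_dist(t):
            return cdist(base + t * u, rec_atoms).min()

        target = config.placement_distance
        if min_dist(0.0) >= target:
            raise RuntimeError("receptor too small for placement search")
        t_hi = 10.0
        for _ in range(60):
            if min_dist(t_hi) > target:
                break
            t_hi *= 1.6
        else:
            raise RuntimeError("placement failed: could not bracket distance")
        t = brentq(lambda x: min_dist(x) - target, 0.0, t_hi, xtol=1e-3)
        pep.translate(t * u)
        states.append(ReplicaState(index=r, temperature=float(temps[r]),
                                   peptide=pep, receptor=receptor.copy()))
    return states


# ---------------------------------------------------------------------------
# trajectory

@dataclass
class Snapshot:
    snapshot_id: int
    replica: int
    sweep: int
    energy: float
    terms: dict
    peptide: CoarseChain
    receptor: CoarseChain


@dataclass
class Trajectory:
    """The REMC snapshot archive plus run provenance."""

    snapshots: list[Snapshot]
    metadata: dict

    def __len__(self) -> int:
        return len(self.snapshots)

    def per_replica(self) -> dict[int, list[Snapshot]]:
        out: dict[int, list[Snapshot]] = {}
        for s in self.snapshots:
            out.setdefault(s.replica, []).append(s)
        return out

    def receptor_start_ca(self) -> np.ndarray:
        return np.asarray(self.metadata["receptor_start_ca"], dtype=float)

    def energies_frame(self) -> pd.DataFrame:
        rows = [{"snapshot_id": s.snapshot_id, "replica": s.replica,
                 "sweep": s.sweep, "energy": s.energy, **s.terms}
                for s in self.snapshots]
        return pd.DataFrame(rows)

    def save(self, directory, models: bool = True) -> None:
        """Persist as metadata JSON + energy TSV + multi-model CA/CB PDB."""
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "metadata.json"), "w") as fh:
            json.dump({k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.metadata.items()}, fh, indent=1)
        self.energies_frame().to_csv(
            os.path.join(directory, "snapshots.tsv"), sep="\t", index=False)
        if models:
            with open(os.path.join(directory, "models.pdb"), "w") as fh:
                for s in self.snapshots:
                    fh.write(f"MODEL {s.snapshot_id + 1:8d}\n")
                    tmp = os.path.join(directory, "_tmp_model.pdb")
                    write_pdb([coarse_to_chain(s.receptor, "R"),
                               coarse_to_chain(s.peptide, "P")], tmp)
                    with open(tmp) as mh:
                        for line in mh:
                            if line.startswith(("ATOM", "TER")):
                                fh.write(line)
                    fh.write("ENDMDL\n")
            tmp = os.path.join(directory, "_tmp_model.pdb")
            if os.path.exists(tmp):
                os.remove(tmp)

    @classmethod
    def load(cls, directory) -> "Trajectory":
        with open(os.path.join(directory, "metadata.json")) as fh:
            metadata = json.load(fh)
        frame = pd.read_csv(os.path.join(directory, "snapshots.tsv"), sep="\t")
        term_cols = [c for c in frame.columns
                     if c not in ("snapshot_id", "replica", "sweep", "energy")]
        snapshots = []
        models_path = os.path.join(directory, "models.pdb")
        per_model = _read_multimodel_ca(models_path) if os.path.exists(models_path) else None
        sequence = metadata["sequence"]
        for _, row in frame.iterrows():
            sid = int(row.snapshot_id)
            pep = rec = None
            if per_model is not None:
                rec_ca, pep_ca = per_model[sid]
                cb, sc, pb = derive_pseudo_atoms(pep_ca, sequence)
                pep = CoarseChain("P", sequence, pep_ca, cb, sc, pb)
                rseq = metadata["receptor_sequence"]
                rcb, rsc, rpb = derive_pseudo_atoms(rec_ca, rseq)
                rec = CoarseChain("R", rseq, rec_ca, rcb, rsc, rpb,
                                  origin="receptor")
            snapshots.append(Snapshot(
                snapshot_id=sid, replica=int(row.replica), sweep=int(row.sweep),
                energy=float(row.energy),
                terms={c: float(row[c]) for c in term_cols},
                peptide=pep, receptor=rec))
        return cls(snapshots=snapshots, metadata=metadata)


def _read_multimodel_ca(path):
    """CA coordinates per model from the concatenated PDB, split by chain R/P."""
    models = []
    rec, pep = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                rec, pep = [], []
            elif line.startswith("ATOM") and line[12:16].strip() == "CA":
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                (rec if line[21] == "R" else pep).append(xyz)
            elif line.startswith("ENDMDL"):
                models.append((np.array(rec), np.array(pep)))
    return models


# ---------------------------------------------------------------------------
# the run

def build_energy_model(config: DockingConfig, receptor: CoarseChain,
                       contact_energies: np.ndarray | None = None) -> EnergyModel:
    if contact_energies is None:
        if config.contact_table_path:
            contact_energies = load_contact_energies(config.contact_table_path)
        else:
            contact_energies = default_contact_energies()
    model = EnergyModel(contact_energies=contact_energies,
                        tether_radius=config.placement_distance + 10.0)
    model.restraints = generate_receptor_restraints(
        receptor, min_separation=config.restraint_min_separation,
        distance_window=config.restraint_window,
        delta=model.restraint_delta, k=model.restraint_k)
    return model


def run_docking(receptor: ChainStructure, slim_sequence: str,
                config: DockingConfig | None = None,
                contact_energies: np.ndarray | None = None,
                ) -> Trajectory:
    """Dock the motif sequence to the receptor; returns the snapshot archive.

    Only the motif *sequence* enters the search -- peptide conformations are
    generated from scratch and placed at random directions around the
    receptor, so no knowledge of a bound pose leaks into the sampling.
    Fully reproducible from ``config.seed``.
    """
    config = config or DockingConfig()
    rec0 = coarse_grain_chain(receptor)
    model = build_energy_model(config, rec0, contact_energies)
    system = _System(model, rec0, slim_sequence)

    ss = np.random.SeedSequence(config.seed)
    place_seedseq, exchange_ss, *replica_ss = ss.spawn(config.n_replicas + 2)
    # placement gets its own child seed stream
    states = place_peptide_replicas(
        rec0, slim_sequence, config,
        seed=int(place_seedseq.generate_state(1)[0] % (2 ** 31)))
    replica_rngs = [np.random.default_rng(s) for s in replica_ss]
    exchange_rng = np.random.default_rng(exchange_ss)

    # cache per-state component energies for cheap deltas
    comp = []
    for st in states:
        e_rec = system.receptor_energy(st.receptor)
        e_pep = system.peptide_energy(st.peptide)
        e_int = system.interaction_energy(st.peptide, st.receptor)
        terms = {**e_rec, **e_pep, **e_int}
        st.terms = terms
        st.energy = float(sum(terms.values()))
        comp.append({"rec": e_rec, "pep": e_pep, "int": e_int})

    moves_per_sweep = config.moves_per_sweep or (len(slim_sequence) + 2)
    total_sweeps = config.n_snapshots_per_replica * config.sweeps_between_snapshots
    snapshots: list[Snapshot] = []
    snapshot_id = 0
    phase = 0

    for sweep in range(1, total_sweeps + 1):
        for r, st in enumerate(states):
            rng = replica_rngs[r]
            for _ in range(moves_per_sweep):
                cand, label = mc_move(st, rng, config)
                parts = dict(comp[r])
                if label == "receptor_shift":
                    parts = {"rec": system.receptor_energy(cand.receptor),
                             "pep": comp[r]["pep"],
                             "int": system.interaction_energy(cand.peptide,
                                                              cand.receptor)}
                else:
                    parts = {"rec": comp[r]["rec"],
                             "pep": system.peptide_energy(cand.peptide),
                             "int": system.interaction_energy(cand.peptide,
                                                              cand.receptor)}
                new_terms = {**parts["rec"], **parts["pep"], **parts["int"]}
                new_e = float(sum(new_terms.values()))
                if metropolis_accept(new_e - st.energy, st.temperature, rng):
                    st.peptide, st.receptor = cand.peptide, cand.receptor
                    st.energy, st.terms = new_e, new_terms
                    comp[r] = parts
        if config.n_replicas > 1 and sweep % config.exchange_interval == 0:
            by_conf = {id(s.peptide): comp[r] for r, s in enumerate(states)}
            replica_exchange_sweep(states, exchange_rng, phase=phase)
            phase += 1
            # component caches travel with their configurations
            comp = [by_conf[id(s.peptide)] for s in states]
        if sweep % config.sweeps_between_snapshots == 0:
            for r, st in enumerate(states):
                snapshots.append(Snapshot(
                    snapshot_id=snapshot_id, replica=r, sweep=sweep,
                    energy=st.energy, terms=dict(st.terms),
                    peptide=st.peptide.copy(), receptor=st.receptor.copy()))
                snapshot_id += 1

    metadata = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "sequence": slim_sequence,
        "receptor_sequence": rec0.sequence,
        "receptor_chain_id": receptor.chain_id,
        "receptor_keys": [list(k) for k in rec0.keys],
        "receptor_start_ca": rec0.ca.tolist(),
        "n_restraints": len(model.restraints),
    }
    return Trajectory(snapshots=snapshots, metadata=metadata)
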