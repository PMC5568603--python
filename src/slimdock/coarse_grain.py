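"""Four-pseudo-atom coarse-grained chains and peptide conformer generation.

Each residue is reduced to up to four interaction sites: the alpha carbon
(CA), the beta carbon (CB), the united side chain (SC, centroid of the
side-chain heavy atoms) and the peptide-bond centre (PB).  Glycine carries
only CA; alanine's side chain collapses onto CB.  The representation is
off-lattice with a fixed 3.8 A virtual CA-CA bond, which is what the
sampler moves operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import (
    AtomRecord,
    ChainStructure,
    ONE_TO_THREE,
    PDBError,
    ResidueRecord,
    write_pdb,
)

CA_BOND = 3.8           # virtual CA-CA bond length, A
CA_BOND_WINDOW = (3.2, 4.3)   # accepted CA-CA range when coarse-graining input
MIN_NONLOCAL_CA = 4.0   # excluded-volume floor for generated conformers, A
CB_LENGTH = 1.53        # CA->CB distance for reconstructed CB, A

#: distance (A) from CA to the united side-chain site along the side direction,
#: a per-type stand-in for mean rotamer extent in generated (sequence-only) chains.
SC_DISTANCE = {
    "A": 1.53, "C": 2.0, "D": 2.5, "E": 3.0, "F": 3.4, "H": 3.1,
    "I": 2.3, "K": 3.5, "L": 2.6, "M": 2.9, "N": 2.5, "P": 1.9,
    "Q": 3.0, "R": 4.1, "S": 1.9, "T": 1.9, "V": 2.0, "W": 3.9, "Y": 3.8,
}

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


@dataclass
class PseudoResidue:
    """Per-residue pseudo-atom view; absent sites are ``None``."""

    one_letter: str
    ca: np.ndarray
    cb: np.ndarray | None
    sc: np.ndarray | None
    pb: np.ndarray | None


class CoarseChain:
    """Array-backed coarse chain; absent sites are NaN rows.

    ``ca``/``cb``/``sc`` are (n, 3); ``pb`` is (n-1, 3) with pb[i] the
    peptide-bond centre between residues i and i+1.
    """

    def __init__(self, chain_id: str, sequence: str, ca: np.ndarray,
                 cb: np.ndarray, sc: np.ndarray, pb: np.ndarray,
                 origin: str = "peptide",
                 keys: list[tuple[int, str]] | None = None):
        n = len(sequence)
        if n < 1:
            raise ValueError("empty coarse chain")
        self.chain_id = chain_id
        self.sequence = sequence
        self.ca = np.asarray(ca, dtype=float).reshape(n, 3)
        self.cb = np.asarray(cb, dtype=float).reshape(n, 3)
        self.sc = np.asarray(sc, dtype=float).reshape(n, 3)
        self.pb = np.asarray(pb, dtype=float).reshape(max(n - 1, 0), 3)
        self.origin = origin
        self.keys = keys or [(i + 1, "") for i in range(n)]
        self.type_indices = np.array([AA_INDEX[c] for c in sequence], dtype=int)

    def __len__(self) -> int:
        return len(self.sequence)

    def copy(self) -> "CoarseChain":
        # fast path: skip __init__ validation, share immutable members
        new = object.__new__(CoarseChain)
        new.chain_id = self.chain_id
        new.sequence = self.sequence
        new.ca = self.ca.copy()
        new.cb = self.cb.copy()
        new.sc = self.sc.copy()
        new.pb = self.pb.copy()
        new.origin = self.origin
        new.keys = self.keys
        new.type_indices = self.type_indices
        return new

    @property
    def pseudo_residues(self) -> list[PseudoResidue]:
        out = []
        n = len(self)
        for i in range(n):
            def opt(arr, j):
                return None if np.any(np.isnan(arr[j])) else arr[j]
            out.append(PseudoResidue(
                one_letter=self.sequence[i],
                ca=self.ca[i],
                cb=opt(self.cb, i),
                sc=opt(self.sc, i),
                pb=opt(self.pb, i) if i < n - 1 else None,
            ))
        return out

    def interaction_sites(self) -> np.ndarray:
        """(n, 3) contact sites: the SC position, or CA for glycine."""
        sites = self.sc.copy()
        missing = np.isnan(sites).any(axis=1)
        sites[missing] = self.ca[missing]
        return sites

    def pseudo_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """All present pseudo-atoms as (coords (m,3), residue label (m,)).

        PB sites are labelled with the lower of their two residues.
        """
        n = len(self)
        idx = np.arange(n)
        parts, labels = [self.ca], [idx]
        for arr in (self.cb, self.sc):
            ok = ~np.isnan(arr).any(axis=1)
            if ok.any():
                parts.append(arr[ok])
                labels.append(idx[ok])
        if len(self.pb):
            ok = ~np.isnan(self.pb).any(axis=1)
            if ok.any():
                parts.append(self.pb[ok])
                labels.append(idx[:-1][ok])
        return np.vstack(parts), np.concatenate(labels)

    def translate(self, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=float)
        self.ca += vec
        self.cb += vec
        self.sc += vec
        if len(self.pb):
            self.pb += vec

    def rotate(self, rotation: np.ndarray, center: np.ndarray) -> None:
        r = np.asarray(rotation, dtype=float)
        c = np.asarray(center, dtype=float)
        for arr in (self.ca, self.cb, self.sc, self.pb):
            if len(arr):
                arr[:] = (arr - c) @ r.T + c


# ---------------------------------------------------------------------------
# all-atom -> coarse

_CB_RECON = (-0.58273431, 0.56802827, -0.54067466)


def _reconstruct_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # ideal tetrahedral CB from backbone N, CA, C
    b = ca - n
    cv = c - ca
    a = np.cross(b, cv)
    wa, wb, wc = _CB_RECON
    return wa * a + wb * b + wc * cv + ca


def coarse_grain_chain(chain: ChainStructure) -> CoarseChain:
    """Reduce an all-atom chain to the four-pseudo-atom representation.

    CA and CB are copied (CB reconstructed from N/CA/C when absent);
    SC is the centroid of the side-chain heavy atoms (CB included, so an
    alanine's SC equals its CB); PB is the midpoint of C(i) and N(i+1).
    A non-glycine, non-alanine residue whose only side-chain atom is CB
    (e.g. a backbone-only export read back in) is rejected rather than
    silently given a truncated side chain.
    """
    n = len(chain)
    ca = np.empty((n, 3))
    cb = np.full((n, 3), np.nan)
    sc = np.full((n, 3), np.nan)
    pb = np.full((max(n - 1, 0), 3), np.nan)
    seq = []
    for i, res in enumerate(chain.residues):
        code = res.one_letter
        if code == "X":
            # retained residues of unknown type are treated as alanine-like
            code = "A"
        seq.append(code)
        ca_atom = res.ca
        if ca_atom is None:
            raise PDBError(f"residue {res.key} has no CA atom")
        ca[i] = ca_atom.coordinates
        if code == "G":
            continue
        cb_atom = res.get_atom("CB")
        if cb_atom is not None:
            cb[i] = cb_atom.coordinates
        else:
            n_atom, c_atom = res.get_atom("N"), res.get_atom("C")
            if n_atom is None or c_atom is None:
                raise PDBError(
                    f"residue {res.key}: cannot reconstruct CB without N and C")
            cb[i] = _reconstruct_cb(n_atom.coordinates, ca[i], c_atom.coordinates)
        side = [a for a in res.side_chain_atoms()]
        if cb_atom is not None and len(side) == 1 and res.one_letter not in ("A", "X"):
            raise PDBError(
                f"residue {res.key} ({res.residue_name}): side-chain atoms "
                "missing; cannot derive the united side-chain site")
        if side:
            sc[i] = np.mean([a.coordinates for a in side], axis=0)
        else:
            sc[i] = cb[i]
    for i in range(n - 1):
        c_atom = chain.residues[i].get_atom("C")
        n_atom = chain.residues[i + 1].get_atom("N")
        if c_atom is not None and n_atom is not None:
            pb[i] = 0.5 * (c_atom.coordinates + n_atom.coordinates)
        else:
            pb[i] = 0.5 * (ca[i] + ca[i + 1])
    bond = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    if n > 1 and (bond.min() < CA_BOND_WINDOW[0] or bond.max() > CA_BOND_WINDOW[1]):
        raise PDBError(
            f"chain {chain.chain_id}: consecutive CA-CA distance outside "
            f"{CA_BOND_WINDOW} A (chain break or bad geometry)")
    return CoarseChain(chain.chain_id, "".join(seq), ca, cb, sc, pb,
                       origin="receptor", keys=chain.keys())


# ---------------------------------------------------------------------------
# geometric side-chain placement for sequence-only chains

def _perpendicular(u: np.ndarray) -> np.ndarray:
    # manual cross with the least-aligned axis (np.cross is slow on 3-vectors)
    ax, ay, az = abs(u[0]), abs(u[1]), abs(u[2])
    if ax <= ay and ax <= az:
        v = np.array([0.0, u[2], -u[1]])       # u x ex
    elif ay <= az:
        v = np.array([-u[2], 0.0, u[0]])       # u x ey
    else:
        v = np.array([u[1], -u[0], 0.0])       # u x ez
    return v / np.sqrt(v @ v)


def _side_direction(ca: np.ndarray, i: int) -> np.ndarray:
    n = len(ca)
    if n == 1:
        return np.array([0.0, 0.0, 1.0])
    if i == 0:
        u = ca[1] - ca[0]
        return _perpendicular(u / np.linalg.norm(u))
    if i == n - 1:
        u = ca[-1] - ca[-2]
        return _perpendicular(u / np.linalg.norm(u))
    u1 = ca[i - 1] - ca[i]
    u2 = ca[i + 1] - ca[i]
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    s = -(u1 + u2)
    norm = np.linalg.norm(s)
    if norm < 1e-8:
        return _perpendicular(u2)
    return s / norm


_SEQ_CACHE: dict = {}


def _sequence_constants(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """(SC distance per residue, glycine mask), cached per sequence."""
    hit = _SEQ_CACHE.get(sequence)
    if hit is None:
        dist = np.array([SC_DISTANCE.get(a, 0.0) for a in sequence])
        gly = np.array([a == "G" for a in sequence])
        hit = _SEQ_CACHE[sequence] = (dist, gly)
    return hit


def derive_pseudo_atoms(ca: np.ndarray, sequence: str,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place CB/SC by ideal geometry from a CA trace; PB = CA midpoints.

    Used for generated peptides (sequence-only input) and after any move
    that displaces peptide CA atoms.  The side direction of an interior
    residue is the inverted bisector of its two virtual bonds; chain ends
    use a deterministic perpendicular.
    """
    n = len(sequence)
    ca = np.asarray(ca, dtype=float).reshape(n, 3)
    side = np.zeros((n, 3))
    if n == 1:
        side[0] = (0.0, 0.0, 1.0)
    else:
        if n > 2:
            u1 = ca[:-2] - ca[1:-1]
            u2 = ca[2:] - ca[1:-1]
            u1 = u1 / np.sqrt(np.einsum("ij,ij->i", u1, u1))[:, None]
            u2 = u2 / np.sqrt(np.einsum("ij,ij->i", u2, u2))[:, None]
            s = -(u1 + u2)
            ns = np.sqrt(np.einsum("ij,ij->i", s, s))
            ok = ns > 1e-8
            s[ok] /= ns[ok, None]
            for i in np.nonzero(~ok)[0]:
                s[i] = _perpendicular(u2[i])
            side[1:-1] = s
        u = ca[1] - ca[0]
        side[0] = _perpendicular(u)
        u = ca[-1] - ca[-2]
        side[-1] = _perpendicular(u)
    dist, gly = _sequence_constants(sequence)
    cb = ca + CB_LENGTH * side
    sc = ca + dist[:, None] * side
    cb[gly] = np.nan
    sc[gly] = np.nan
    pb = 0.5 * (ca[:-1] + ca[1:]) if n > 1 else np.empty((0, 3))
    return cb, sc, pb


def random_peptide_conformation(sequence: str, seed: int | np.random.Generator,
                                chain_id: str = "P") -> CoarseChain:
    """Self-avoiding random CA trace with exact 3.8 A bonds.

    Consecutive CA-CA distances are exactly :data:`CA_BOND`; no
    non-consecutive pair comes closer than :data:`MIN_NONLOCAL_CA`.
    Reproducible given the seed.
    """
    if len(sequence) < 2:
        raise ValueError("peptide must have at least 2 residues")
    bad = set(sequence) - set(AA_ORDER)
    if bad:
        raise ValueError(f"invalid amino-acid letters: {sorted(bad)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(sequence)
    for _attempt in range(200):
        ca = np.zeros((n, 3))
        v = rng.normal(size=3)
        ca[1] = ca[0] + CA_BOND * v / np.linalg.norm(v)
        ok = True
        for i in range(2, n):
            placed = False
            for _retry in range(100):
                v = rng.normal(size=3)
                cand = ca[i - 1] + CA_BOND * v / np.linalg.norm(v)
                d = np.linalg.norm(ca[:i - 1] - cand, axis=1)
                if d.min() >= MIN_NONLOCAL_CA:
                    ca[i] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            cb, sc, pb = derive_pseudo_atoms(ca, sequence)
            return CoarseChain(chain_id, sequence, ca, cb, sc, pb, origin="peptide")
    raise RuntimeError("failed to generate a self-avoiding conformation")


# ---------------------------------------------------------------------------
# export

def coarse_to_chain(coarse: CoarseChain, chain_id: str | None = None,
                    keys: list[tuple[int, str]] | None = None) -> ChainStructure:
    """Represent a coarse chain as a backbone-level ChainStructure (CA + CB)."""
    keys = keys or coarse.keys
    residues = []
    for i, aa in enumerate(coarse.sequence):
        atoms = [AtomRecord(name="CA", element="C", coordinates=coarse.ca[i])]
        if not np.any(np.isnan(coarse.cb[i])):
            atoms.append(AtomRecord(name="CB", element="C", coordinates=coarse.cb[i]))
        seq_id, icode = keys[i]
        residues.append(ResidueRecord(
            seq_id=seq_id, residue_name=ONE_TO_THREE.get(aa, "ALA"),
            atoms=atoms, insertion_code=icode))
    return ChainStructure(chain_id=chain_id or coarse.chain_id, residues=residues)


def export_backbone(model, path) -> None:
    """Write a coarse model (chain, list of chains, or complex) as a CA/CB PDB.

    The file carries a REMARK flagging it as coarse-grained output; reading
    it back yields identical CA coordinates.
    """
    from .assembly import ComplexModel  # local import to avoid a cycle
    if isinstance(model, CoarseChain):
        chains = [coarse_to_chain(model)]
    elif isinstance(model, ComplexModel):
        chains = [model.receptor, model.partner]
    else:
        chains = [coarse_to_chain(c) if isinstance(c, CoarseChain) else c
                  for c in model]
    write_pdb(chains, path, remarks=["COARSE-GRAINED MODEL (CA/CB ONLY)"])
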