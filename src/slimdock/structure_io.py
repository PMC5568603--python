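"""All-atom structure I/O and heavy-atom geometry primitives.

Structures are held as plain per-chain containers keyed by *author* (PDB)
residue numbering with insertion codes -- the public coordinate system of
the whole package: a motif such as ``B:116-128`` is an inclusive
author-numbered range on a chain.  Reading goes through :mod:`gemmi`;
writing emits fixed-width ``ATOM``/``TER`` records directly so that chain
termination and serial numbering follow the documented contract exactly.

Hydrogens and waters are dropped on read (every distance definition used
downstream is heavy-atom based) and alternate locations are resolved to
the highest-occupancy conformer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


class PDBError(ValueError):
    """Raised for unreadable or unencodable structure data."""


def _infer_element(name: str) -> str:
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        raise PDBError(f"cannot infer element from atom name {name!r}")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "MN", "SE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


@dataclass
class AtomRecord:
    """A single heavy atom: PDB name, element, position in Angstroms."""

    name: str
    element: str
    coordinates: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,):
            raise PDBError(f"atom {self.name}: coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coordinates)):
            raise PDBError(f"atom {self.name}: non-finite coordinates")
        if not self.element:
            self.element = _infer_element(self.name)


@dataclass
class ResidueRecord:
    """One residue: author seq id (+ insertion code) and its heavy atoms."""

    seq_id: int
    residue_name: str
    atoms: list[AtomRecord]
    insertion_code: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise PDBError(f"residue {self.residue_name} {self.seq_id}: no atoms")
        if sum(1 for a in self.atoms if a.name == "CA") > 1:
            raise PDBError(f"residue {self.residue_name} {self.seq_id}: duplicate CA")

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.residue_name, "X")

    def get_atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.get_atom("CA")

    def heavy_coords(self) -> np.ndarray:
        """(n_atoms, 3) array of heavy-atom coordinates."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def side_chain_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.name not in _BACKBONE_NAMES]


@dataclass
class ChainStructure:
    """An ordered polypeptide chain in author numbering."""

    chain_id: str
    residues: list[ResidueRecord]
    source: str = ""

    def __post_init__(self):
        seen = set()
        for r in self.residues:
            if r.key in seen:
                raise PDBError(
                    f"chain {self.chain_id}: duplicate residue key {r.key}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def keys(self) -> list[tuple[int, str]]:
        return [r.key for r in self.residues]

    def residue(self, key: tuple[int, str] | int) -> ResidueRecord:
        if isinstance(key, int):
            key = (key, "")
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(f"chain {self.chain_id}: no residue {key}")

    def ca_array(self) -> np.ndarray:
        """(n, 3) CA coordinates; every residue must have a CA."""
        coords = []
        for r in self.residues:
            ca = r.ca
            if ca is None:
                raise PDBError(
                    f"chain {self.chain_id}: residue {r.key} has no CA atom")
            coords.append(ca.coordinates)
        return np.array(coords, dtype=float)

    def heavy_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy atoms as (coords (m,3), residue index (m,)) in chain order."""
        coords, idx = [], []
        for i, r in enumerate(self.residues):
            for a in r.atoms:
                coords.append(a.coordinates)
                idx.append(i)
        return np.array(coords, dtype=float), np.array(idx, dtype=int)


@dataclass
class SlimDefinition:
    """A short linear motif as an inclusive author-numbered range."""

    chain_id: str
    start_seq_id: int
    end_seq_id: int
    sequence: str

    def __post_init__(self):
        if self.start_seq_id > self.end_seq_id:
            raise ValueError("reversed SLiM range")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# reading / writing

def read_pdb(path: str | os.PathLike, model_index: int = 0) -> list[ChainStructure]:
    """Parse a PDB file into one :class:`ChainStructure` per chain.

    Hydrogens and waters are excluded; for alternate locations the
    highest-occupancy conformer is kept (ties broken by altloc letter).
    Only the requested model (default: first) is read.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise PDBError(f"{path}: no models")
    if model_index >= len(st):
        raise PDBError(f"{path}: model index {model_index} out of range")
    model = st[model_index]

    chains: list[ChainStructure] = []
    for chain in model:
        residues = []
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            # resolve altlocs: group by atom name, keep highest occupancy
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = by_name.get(atom.name)
                if prev is None:
                    by_name[atom.name] = atom
                    continue
                key_new = (-(atom.occ or 0.0), atom.altloc or "~")
                key_old = (-(prev.occ or 0.0), prev.altloc or "~")
                if key_new < key_old:
                    by_name[atom.name] = atom
            if not by_name:
                continue
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name if a.element.name not in ("X", "") else "",
                    coordinates=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    altloc=(a.altloc or "").strip("\x00"),
                )
                for a in by_name.values()
            ]
            residues.append(ResidueRecord(
                seq_id=res.seqid.num,
                residue_name=res.name,
                atoms=atoms,
                insertion_code=(res.seqid.icode or "").strip(),
            ))
        if residues:
            chains.append(ChainStructure(chain_id=chain.name, residues=residues,
                                         source=os.path.basename(path)))
    if not chains:
        raise PDBError(f"{path}: no ATOM records")
    return chains


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(chains: list[ChainStructure], path: str | os.PathLike,
              remarks: list[str] | None = None) -> None:
    """Write chains as standard ATOM records, 1-based serials, TER between chains."""
    if not chains:
        raise PDBError("no chains to write")
    lines = []
    for remark in remarks or []:
        lines.append(f"REMARK   6 {remark}"[:80])
    serial = 0
    for chain in chains:
        cid = (chain.chain_id or "A")[0]
        res = None
        for res in chain.residues:
            if not (-999 <= res.seq_id <= 9999):
                raise PDBError(f"residue number {res.seq_id} not encodable in PDB")
            for atom in res.atoms:
                serial += 1
                if serial > 99999:
                    raise PDBError("more than 99999 atoms")
                lines.append(
                    "ATOM  {:5d} {:4s}{:1s}{:>3s} {:1s}{:4d}{:1s}   "
                    "{:8.3f}{:8.3f}{:8.3f}{:6.2f}{:6.2f}          {:>2s}".format(
                        serial,
                        _format_atom_name(atom.name, atom.element),
                        " ",
                        res.residue_name[:3],
                        cid,
                        res.seq_id,
                        res.insertion_code[:1] if res.insertion_code else " ",
                        atom.coordinates[0], atom.coordinates[1], atom.coordinates[2],
                        atom.occupancy, 0.0,
                        atom.element[:2],
                    )
                )
        serial += 1
        lines.append("TER   {:5d}      {:>3s} {:1s}{:4d}{:1s}".format(
            serial, res.residue_name[:3], cid, res.seq_id,
            res.insertion_code[:1] if res.insertion_code else " "))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# motif extraction

def extract_slim(chain: ChainStructure, start_seq_id: int, end_seq_id: int,
                 ) -> tuple[SlimDefinition, ChainStructure]:
    """Cut the inclusive author-numbered range out of ``chain``.

    Returns the motif definition (with its one-letter sequence) and a new
    chain holding exactly the residues of the range.  A numbering gap
    inside the range is an error, never a silent shorter peptide.
    """
    if start_seq_id > end_seq_id:
        raise ValueError(f"reversed range {start_seq_id}-{end_seq_id}")
    picked = [r for r in chain.residues if start_seq_id <= r.seq_id <= end_seq_id]
    present = {r.seq_id for r in picked}
    missing = [i for i in range(start_seq_id, end_seq_id + 1) if i not in present]
    if missing:
        raise ValueError(
            f"chain {chain.chain_id}: residues {missing} missing from range "
            f"{start_seq_id}-{end_seq_id}")
    peptide = ChainStructure(chain_id=chain.chain_id, residues=picked,
                             source=chain.source)
    slim = SlimDefinition(chain_id=chain.chain_id, start_seq_id=start_seq_id,
                          end_seq_id=end_seq_id, sequence=peptide.sequence)
    return slim, peptide


def locate_slim_by_sequence(chain: ChainStructure, sequence: str,
                            ) -> tuple[SlimDefinition, ChainStructure]:
    """Locate a motif by exact one-letter substring match in the chain."""
    seq = chain.sequence
    pos = seq.find(sequence)
    if pos < 0:
        raise ValueError(f"sequence {sequence!r} not found in chain {chain.chain_id}")
    if seq.find(sequence, pos + 1) >= 0:
        raise ValueError(f"sequence {sequence!r} ambiguous in chain {chain.chain_id}")
    sub = chain.residues[pos:pos + len(sequence)]
    peptide = ChainStructure(chain_id=chain.chain_id, residues=sub, source=chain.source)
    slim = SlimDefinition(chain_id=chain.chain_id, start_seq_id=sub[0].seq_id,
                          end_seq_id=sub[-1].seq_id, sequence=sequence)
    return slim, peptide


# ---------------------------------------------------------------------------
# geometry primitives

def min_heavy_atom_distance(res_a: ResidueRecord, res_b: ResidueRecord) -> float:
    """Minimum Euclidean distance over all heavy-atom pairs of two residues."""
    return float(cdist(res_a.heavy_coords(), res_b.heavy_coords()).min())


def residue_min_distance_matrix(chain_a: ChainStructure,
                                chain_b: ChainStructure) -> np.ndarray:
    """(len(a), len(b)) matrix of minimum heavy-atom distances between residues."""
    ca, ia = chain_a.heavy_atoms()
    cb, ib = chain_b.heavy_atoms()
    d = cdist(ca, cb)
    starts_a = np.searchsorted(ia, np.arange(len(chain_a)))
    starts_b = np.searchsorted(ib, np.arange(len(chain_b)))
    m = np.minimum.reduceat(d, starts_a, axis=0)
    m = np.minimum.reduceat(m, starts_b, axis=1)
    return m


def transform_chain(chain: ChainStructure, rotation: np.ndarray,
                    translation: np.ndarray) -> ChainStructure:
    """Apply the rigid transform x -> R x + t to every atom, returning a new chain."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    new_residues = []
    for r in chain.residues:
        new_atoms = [
            AtomRecord(name=a.name, element=a.element,
                       coordinates=rotation @ a.coordinates + translation,
                       occupancy=a.occupancy, altloc=a.altloc)
            for a in r.atoms
        ]
        new_residues.append(ResidueRecord(seq_id=r.seq_id, residue_name=r.residue_name,
                                          atoms=new_atoms,
                                          insertion_code=r.insertion_code))
    return ChainStructure(chain_id=chain.chain_id, residues=new_residues,
                          source=chain.source)
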