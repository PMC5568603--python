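"""Deterministic synthetic structures with known binding sites.

Every other module is testable against these without downloading anything.
The groove-bearing receptor is a two-strand hairpin: two straight strands
3.8 A-per-residue apart, joined by a 3-residue semicircular turn, about
9.9 A apart, with all side chains pointing away from the inter-strand
groove.  The designed peptide pose is a zig-zag CA trace running along
the groove axis; the planted native contacts are whatever the 8 A
heavy-atom definition realises for that geometry, verified through
:func:`slimdock.metrics.contact_map` before the fixture is handed out.

Groove-adjacent receptor residues are typed with the peptide's own
letters by position, so a contact table rewarding exactly the planted
residue-type pairs makes the designed pose (and not its reverse, nor a
shifted placement) the energetic optimum -- the harness for the sampler's
funnel-recovery property.

Side-chain realism is deliberately reduced: CB plus one dummy CG heavy
atom per non-Gly/Ala residue, enough to exercise every heavy-atom
distance rule without rotamer libraries.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .assembly import ComplexModel, clash_report
from .coarse_grain import AA_ORDER, CoarseChain, derive_pseudo_atoms, _side_direction
from .metrics import contact_map
from .structure_io import (
    AtomRecord,
    ChainStructure,
    ONE_TO_THREE,
    ResidueRecord,
    SlimDefinition,
    extract_slim,
    write_pdb,
)

CA_STEP = 3.8
TURN_RESIDUES = 3
TURN_RADIUS = CA_STEP / (2.0 * np.sin(np.pi / (2 * (TURN_RESIDUES + 1))))  # ~4.97 A
ZIGZAG_DZ = 0.5          # peptide zig-zag half-amplitude, A
PEP_HEIGHT = 2.5         # strand plane -> peptide axis, A (optimum groove depth)
FLOOR_Z = -4.2           # z of the floor strand blocking the groove underside
GROOVE_MARGIN = 9.0      # x-extent of typed groove beyond the peptide, A
PEP_STEP = float(np.sqrt(CA_STEP ** 2 - (2 * ZIGZAG_DZ) ** 2))
_TILT = np.array([0.0, 0.5, 0.8660254])   # groove side chains tilt up-and-inward


@dataclass
class ToyComplexSpec:
    """Recipe for a reproducible toy receptor / peptide / bound complex."""

    receptor_length: int = 52
    fold: str = "hairpin"           # "hairpin" (grooved three-strand) or "helix"
    peptide_sequence: str = "KKKKKKKFFFFFF"
    flank: int = 3                  # partner residues added on each side
    slim_start: int = 116           # author numbering of the first motif residue
    noise: float = 0.0              # Gaussian jitter on every atom, A
    seed: int = 0
    planted_contacts: list | None = None   # optional expected contact keys


@dataclass
class ToyComplex:
    """A self-verified reference complex plus all its bookkeeping."""

    receptor: ChainStructure
    partner: ChainStructure
    reference: ComplexModel
    slim: SlimDefinition
    slim_keys: list
    planted_contacts: list
    peptide_pose: CoarseChain
    groove_indices: list
    spec: ToyComplexSpec


# ---------------------------------------------------------------------------
# all-atom residue construction

def _build_residues(ca: np.ndarray, sequence: str, start_seq_id: int,
                    side_dirs: np.ndarray | None = None,
                    rng: np.random.Generator | None = None,
                    noise: float = 0.0) -> list[ResidueRecord]:
    n = len(sequence)
    residues = []
    for i, aa in enumerate(sequence):
        t = ca[min(i + 1, n - 1)] - ca[max(i - 1, 0)]
        t = t / np.linalg.norm(t)
        s = side_dirs[i] if side_dirs is not None else _side_direction(ca, i)
        w = np.cross(t, s)
        wn = np.linalg.norm(w)
        w = w / wn if wn > 1e-8 else np.array([0.0, 0.0, 1.0])
        atoms = [
            AtomRecord("N", "N", ca[i] - 1.2 * t + 0.7 * w),
            AtomRecord("CA", "C", ca[i]),
            AtomRecord("C", "C", ca[i] + 1.2 * t + 0.7 * w),
        ]
        if aa != "G":
            atoms.append(AtomRecord("CB", "C", ca[i] + 1.5 * s))
            if aa != "A":
                atoms.append(AtomRecord("CG", "C", ca[i] + 2.8 * s))
        if noise > 0 and rng is not None:
            for a in atoms:
                a.coordinates = a.coordinates + rng.normal(scale=noise, size=3)
        residues.append(ResidueRecord(seq_id=start_seq_id + i,
                                      residue_name=ONE_TO_THREE[aa], atoms=atoms))
    return residues


# ---------------------------------------------------------------------------
# receptor geometry

def _arc_bridge(a: np.ndarray, b: np.ndarray, n_points: int,
                out_dir: np.ndarray) -> list[np.ndarray]:
    """``n_points`` intermediate points on a circular arc from a to b.

    All chords have length :data:`CA_STEP` exactly; the arc bulges along
    ``out_dir`` (projected perpendicular to b-a).
    """
    from scipy.optimize import brentq
    gap = float(np.linalg.norm(b - a))
    k = n_points + 1
    if k * CA_STEP <= gap:
        raise ValueError("gap too wide for the requested bridge")
    phi = brentq(lambda p: np.sin(p / 2) / np.sin(p / (2 * k)) - gap / CA_STEP,
                 1e-9, 2 * np.pi - 1e-9)
    radius = CA_STEP / (2 * np.sin(phi / (2 * k)))
    u = (b - a) / gap
    w = out_dir - np.dot(out_dir, u) * u
    w = w / np.linalg.norm(w)
    centre = 0.5 * (a + b) - np.sqrt(max(radius ** 2 - (gap / 2) ** 2, 0.0)) * w
    e1 = (a - centre) / radius
    bv = b - centre
    e2 = bv - np.dot(bv, e1) * e1
    n2 = np.linalg.norm(e2)
    e2 = w if n2 < 1e-9 else e2 / n2   # semicircle: bulge direction itself
    return [centre + radius * (np.cos(j * phi / k) * e1 + np.sin(j * phi / k) * e2)
            for j in range(1, k)]


def _hairpin_trace(length: int) -> tuple[np.ndarray, dict]:
    """Three-strand groove fold: two rim strands plus a floor strand.

    Strand 1 runs +x at y=0, strand 2 runs -x at y~9.9 (joined by a
    3-residue turn), and after a 1-residue connector strand 3 runs +x
    again *beneath* the groove centre line, closing the groove from
    below so the designed binding site is not mirror-degenerate.
    Every consecutive CA-CA distance is exactly 3.8 A.
    """
    n1 = (length - TURN_RESIDUES - 1) // 3
    n3 = length - TURN_RESIDUES - 1 - 2 * n1
    if n1 < 5:
        raise ValueError(f"receptor length {length} too short for a grooved fold")
    r = TURN_RADIUS
    x0 = CA_STEP * (n1 - 1)
    pts = [np.array([CA_STEP * i, 0.0, 0.0]) for i in range(n1)]
    s1_end = pts[-1]
    s2_start = np.array([x0, 2 * r, 0.0])
    pts += _arc_bridge(s1_end, s2_start, TURN_RESIDUES, np.array([1.0, 0.0, 0.0]))
    pts += [np.array([x0 - CA_STEP * i, 2 * r, 0.0]) for i in range(n1)]
    s2_end = pts[-1]
    s3_start = np.array([s2_end[0], r, FLOOR_Z])
    pts += _arc_bridge(s2_end, s3_start, 1, np.array([-1.0, 0.0, 0.0]))
    pts += [np.array([s3_start[0] + CA_STEP * i, r, FLOOR_Z]) for i in range(n3)]
    segments = {
        "strand1": list(range(n1)),
        "turn": list(range(n1, n1 + TURN_RESIDUES)),
        "strand2": list(range(n1 + TURN_RESIDUES, 2 * n1 + TURN_RESIDUES)),
        "connector": [2 * n1 + TURN_RESIDUES],
        "strand3": list(range(2 * n1 + TURN_RESIDUES + 1, length)),
        "n1": n1,
    }
    return np.array(pts), segments


def _helix_trace(length: int) -> np.ndarray:
    rise, dtheta = 1.5, np.deg2rad(100.0)
    radius = np.sqrt(CA_STEP ** 2 - rise ** 2) / (2 * np.sin(dtheta / 2))
    i = np.arange(length)
    return np.stack([radius * np.cos(i * dtheta),
                     radius * np.sin(i * dtheta), rise * i], axis=1)


def _peptide_trace(spec: ToyComplexSpec, n1: int) -> np.ndarray:
    n_p = len(spec.peptide_sequence)
    span = (n_p - 1) * PEP_STEP
    strand_span = CA_STEP * (n1 - 1)
    x_start = (strand_span - span) / 2.0
    if x_start < 0:
        raise ValueError("peptide longer than the receptor groove")
    i = np.arange(n_p)
    return np.stack([
        x_start + i * PEP_STEP,
        np.full(n_p, TURN_RADIUS),
        PEP_HEIGHT + ZIGZAG_DZ * np.where(i % 2 == 0, -1.0, 1.0),
    ], axis=1)


def make_toy_receptor(spec: ToyComplexSpec) -> ChainStructure:
    """Seed-deterministic receptor chain with ideal 3.8 A backbone geometry.

    For the grooved ("hairpin") fold, strand residues lining the groove
    are typed with the peptide's letters by x-position (serines
    elsewhere), so a position-specific reward table can make the designed
    registration uniquely optimal.  Rim-strand side chains tilt into the
    groove; all other side chains point away from it.  The helix fold is
    an ungrooved all-serine helix for geometry-only tests.
    """
    if spec.receptor_length < 10:
        raise ValueError("receptor length must be >= 10")
    rng = np.random.default_rng(spec.seed)
    if spec.fold == "helix":
        ca = _helix_trace(spec.receptor_length)
        seq = "S" * spec.receptor_length
        centre = ca.mean(axis=0)
        dirs = ca - centre
        dirs[:, 2] = 0.0
        norms = np.linalg.norm(dirs, axis=1, keepdims=True)
        dirs = np.where(norms > 1e-8, dirs / np.maximum(norms, 1e-8),
                        np.array([1.0, 0.0, 0.0]))
        return ChainStructure("A", _build_residues(
            ca, seq, 1, side_dirs=dirs, rng=rng, noise=spec.noise),
            source="toy-helix")
    if spec.fold != "hairpin":
        raise ValueError(f"unknown fold {spec.fold!r}")
    ca, seg = _hairpin_trace(spec.receptor_length)
    pep_ca = _peptide_trace(spec, seg["n1"])
    n = spec.receptor_length
    seq = list("S" * n)
    lo, hi = pep_ca[0, 0] - GROOVE_MARGIN, pep_ca[-1, 0] + GROOVE_MARGIN
    strand_idx = set(seg["strand1"]) | set(seg["strand2"]) | set(seg["strand3"])
    for i in strand_idx:
        x = ca[i, 0]
        if lo <= x <= hi:
            j = int(np.clip(round((x - pep_ca[0, 0]) / PEP_STEP), 0,
                            len(spec.peptide_sequence) - 1))
            seq[i] = spec.peptide_sequence[j]
    dirs = np.tile(np.array([0.0, 0.0, -1.0]), (n, 1))
    for i in seg["strand1"]:
        dirs[i] = _TILT
    for i in seg["strand2"]:
        dirs[i] = _TILT * np.array([1.0, -1.0, 1.0])
    dirs[seg["connector"][0]] = np.array([-1.0, 0.0, 0.0])
    return ChainStructure("A", _build_residues(
        ca, "".join(seq), 1, side_dirs=dirs, rng=rng, noise=spec.noise),
        source="toy-hairpin")


def groove_indices(spec: ToyComplexSpec) -> list[int]:
    """0-based receptor residue indices typed as groove (hairpin fold only)."""
    receptor = make_toy_receptor(ToyComplexSpec(**{**asdict(spec), "noise": 0.0}))
    return [i for i, aa in enumerate(receptor.sequence) if aa != "S"]


def make_toy_complex(spec: ToyComplexSpec) -> ToyComplex:
    """Reference complex with the peptide laid into the groove.

    The partner chain is the motif extended by alanine flanks on both
    sides (so assembly superposition is exercised on a proper sub-range).
    The planted contact list is what the geometry realises at the 8 A
    heavy-atom definition; it is recomputed through the metrics module
    and compared against ``spec.planted_contacts`` when given.  A clash
    (any inter-chain residue pair under 2.5 A) voids the fixture.
    """
    if spec.fold != "hairpin":
        raise ValueError("bound complexes require the grooved hairpin fold")
    bad = set(spec.peptide_sequence) - set(AA_ORDER)
    if bad:
        raise ValueError(f"invalid peptide letters {sorted(bad)}")
    receptor = make_toy_receptor(spec)
    _, seg = _hairpin_trace(spec.receptor_length)
    pep_ca = _peptide_trace(spec, seg["n1"])
    n_p = len(spec.peptide_sequence)
    f = spec.flank

    # extend the zig-zag pattern through the flanks, lifting them away from
    # the receptor so they cannot graze the hairpin turn
    i_full = np.arange(-f, n_p + f)
    beyond = np.clip(np.where(i_full < 0, -i_full, i_full - (n_p - 1)), 0, None)
    full_ca = np.stack([
        pep_ca[0, 0] + i_full * PEP_STEP,
        np.full(len(i_full), TURN_RADIUS),
        PEP_HEIGHT + ZIGZAG_DZ * np.where(i_full % 2 == 0, -1.0, 1.0)
        + 0.9 * beyond,
    ], axis=1)
    full_seq = "A" * f + spec.peptide_sequence + "A" * f
    rng = np.random.default_rng(spec.seed + 1)
    partner = ChainStructure("B", _build_residues(
        full_ca, full_seq, spec.slim_start - f, rng=rng, noise=spec.noise),
        source="toy-partner")

    slim, slim_chain = extract_slim(partner, spec.slim_start,
                                    spec.slim_start + n_p - 1)
    reference = ComplexModel(receptor=receptor, partner=partner,
                             provenance={"fixture": asdict(spec)})

    # self-verification before the fixture is handed out
    planted = sorted(contact_map(receptor, slim_chain, 8.0).pairs())
    if not planted:
        raise RuntimeError("fixture realises no contacts at 8 A")
    if spec.planted_contacts is not None:
        wanted = sorted((tuple(a), tuple(b)) for a, b in spec.planted_contacts)
        if wanted != planted:
            raise RuntimeError("requested planted contacts cannot be realised")
    clashes = clash_report(reference, 2.5)
    if clashes:
        raise RuntimeError(f"fixture has steric clashes: {clashes[:3]}")

    cb, sc, pb = derive_pseudo_atoms(pep_ca, spec.peptide_sequence)
    pose = CoarseChain("P", spec.peptide_sequence, pep_ca, cb, sc, pb)
    return ToyComplex(receptor=receptor, partner=partner, reference=reference,
                      slim=slim, slim_keys=slim_chain.keys(),
                      planted_contacts=planted, peptide_pose=pose,
                      groove_indices=groove_indices(spec), spec=spec)


def funnel_energy_table(toy: ToyComplex, reward: float = -2.0) -> np.ndarray:
    """20x20 contact table rewarding exactly the planted residue-type pairs.

    Entries for type pairs occurring in the planted contact list get
    ``reward``; everything else is 0, making the designed groove the
    global minimum of the surrogate potential.  Because contact energies
    are type-level, the table is only position-specific if no untyped
    (serine) receptor residue takes part in a planted contact -- that
    would reward serines everywhere -- so such fixtures are refused.
    """
    idx = {a: i for i, a in enumerate(AA_ORDER)}
    rec_by_key = {r.key: r.one_letter for r in toy.receptor.residues}
    pep_by_key = {r.key: r.one_letter for r in toy.partner.residues}
    leaks = [k for k, _ in toy.planted_contacts if rec_by_key[tuple(k)] == "S"]
    if leaks:
        raise ValueError(
            f"untyped receptor residues {leaks} take part in planted contacts; "
            "use a longer receptor or shorter peptide for a clean funnel")
    table = np.zeros((20, 20))
    for key_r, key_p in toy.planted_contacts:
        a, b = idx[rec_by_key[tuple(key_r)]], idx[pep_by_key[tuple(key_p)]]
        table[a, b] = table[b, a] = reward
    return table


def emit_fixture_files(toy: ToyComplex, directory) -> dict:
    """Write receptor.pdb / partner.pdb / reference.pdb / spec-resolved.json.

    When the fixture supports a clean position-specific reward table, it
    is written alongside as ``contact_energies.csv`` (loadable through
    ``DockingConfig.contact_table_path``) so a demonstration run can use
    a potential that actually recognises the planted site.
    """
    import pandas as pd
    os.makedirs(directory, exist_ok=True)
    paths = {
        "receptor": os.path.join(directory, "receptor.pdb"),
        "partner": os.path.join(directory, "partner.pdb"),
        "reference": os.path.join(directory, "reference.pdb"),
        "spec": os.path.join(directory, "spec-resolved.json"),
    }
    write_pdb([toy.receptor], paths["receptor"], remarks=["SYNTHETIC TOY RECEPTOR"])
    write_pdb([toy.partner], paths["partner"], remarks=["SYNTHETIC TOY PARTNER"])
    toy.reference.write(paths["reference"], remarks=["SYNTHETIC TOY REFERENCE COMPLEX"])
    try:
        table = funnel_energy_table(toy)
    except ValueError:
        pass
    else:
        paths["contact_energies"] = os.path.join(directory,
                                                 "contact_energies.csv")
        pd.DataFrame(table, index=list(AA_ORDER),
                     columns=list(AA_ORDER)).to_csv(paths["contact_energies"])
    with open(paths["spec"], "w") as fh:
        json.dump({
            "spec": asdict(toy.spec),
            "slim": f"{toy.slim.chain_id}:{toy.slim.start_seq_id}-{toy.slim.end_seq_id}",
            "slim_sequence": toy.slim.sequence,
            "groove_indices": toy.groove_indices,
            "planted_contacts": [[list(a), list(b)]
                                 for a, b in toy.planted_contacts],
        }, fh, indent=1)
    return paths
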