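"""Interface evaluation: contact maps, native-contact fraction, iRMSD.

Conventions (all heavy-atom based, documented because cutoffs admit two
readings): a residue pair is in contact when its *minimum heavy-atom*
distance is strictly below the cutoff (default 8 A); the motif interface
is the peptide plus every receptor residue within 4.5 A of it; iRMSD is
the CA RMSD over the interface residue set after a least-squares fit of
the model's interface CAs onto the reference's.  Residue correspondence
between model and reference is by chain id + author number + insertion
code -- no alignment fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .assembly import ComplexModel, kabsch_superpose
from .structure_io import ChainStructure, residue_min_distance_matrix

CONTACT_CUTOFF = 8.0     # A, residue-residue contact definition
INTERFACE_CUTOFF = 4.5   # A, motif interface definition


@dataclass
class ContactMap:
    """Boolean inter-chain contact matrix at a distance cutoff."""

    receptor_keys: list
    partner_keys: list
    matrix: np.ndarray
    cutoff: float

    def pairs(self) -> set:
        return {(tuple(self.receptor_keys[i]), tuple(self.partner_keys[j]))
                for i, j in zip(*np.nonzero(self.matrix))}

    def count(self) -> int:
        return int(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.astype(int),
                            index=[f"{k[0]}{k[1]}" for k in self.receptor_keys],
                            columns=[f"{k[0]}{k[1]}" for k in self.partner_keys])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def plot(self, path, title: str = "") -> None:
        """Render the map as a heat-map image (written to ``path``)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.imshow(self.matrix.astype(int), aspect="auto", cmap="Greys",
                  interpolation="nearest")
        ax.set_xlabel("partner residue index")
        ax.set_ylabel("receptor residue index")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass
class InterfaceDefinition:
    """The motif residues plus receptor residues within the cutoff of them."""

    peptide_keys: list
    receptor_keys: list
    cutoff: float


@dataclass
class EvaluationReport:
    """Headline comparison of a model against a reference complex."""

    fnc: float
    irmsd: float
    lrmsd: float
    native_contacts: int
    model_contacts: int
    correct_contacts: int

    def __post_init__(self):
        if not (0.0 <= self.fnc <= 1.0):
            raise ValueError("fNC must lie in [0, 1]")
        if self.correct_contacts > min(self.native_contacts, self.model_contacts):
            raise ValueError("correct contacts exceed native or model count")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    def to_tsv(self, path) -> None:
        pd.DataFrame([asdict(self)]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EvaluationReport":
        row = pd.read_csv(path, sep="\t").iloc[0]
        return cls(fnc=float(row.fnc), irmsd=float(row.irmsd),
                   lrmsd=float(row.lrmsd),
                   native_contacts=int(row.native_contacts),
                   model_contacts=int(row.model_contacts),
                   correct_contacts=int(row.correct_contacts))


def contact_map(chain_a: ChainStructure, chain_b: ChainStructure,
                cutoff: float = CONTACT_CUTOFF) -> ContactMap:
    """Residue pairs in contact: minimum heavy-atom distance strictly < cutoff."""
    if not len(chain_a) or not len(chain_b):
        raise ValueError("empty chain")
    d = residue_min_distance_matrix(chain_a, chain_b)
    return ContactMap(receptor_keys=chain_a.keys(), partner_keys=chain_b.keys(),
                      matrix=d < cutoff, cutoff=cutoff)


def _restrict(chain: ChainStructure, keys) -> ChainStructure:
    wanted = {tuple(k) for k in keys}
    picked = [r for r in chain.residues if r.key in wanted]
    if len(picked) != len(wanted):
        missing = wanted - {r.key for r in picked}
        raise KeyError(f"chain {chain.chain_id}: residues {sorted(missing)} absent")
    return ChainStructure(chain_id=chain.chain_id, residues=picked,
                          source=chain.source)


def fraction_native_contacts(model: ComplexModel, reference: ComplexModel,
                             cutoff: float = CONTACT_CUTOFF,
                             partner_keys=None) -> tuple[float, int, int, int]:
    """fNC = |native AND model| / |native| at the contact cutoff.

    ``partner_keys`` restricts the partner side (e.g. to the motif
    residues).  An empty native contact set is an error, never a NaN.
    Returns (fnc, n_native, n_model, n_correct).
    """
    ref_partner = reference.partner
    mod_partner = model.partner
    if partner_keys is not None:
        ref_partner = _restrict(ref_partner, partner_keys)
        mod_partner = _restrict(mod_partner, partner_keys)
    native = contact_map(reference.receptor, ref_partner, cutoff).pairs()
    if not native:
        raise ValueError("reference complex has no native contacts at this cutoff")
    modeled = contact_map(model.receptor, mod_partner, cutoff).pairs()
    correct = native & modeled
    return (len(correct) / len(native), len(native), len(modeled), len(correct))


def interface_residues(reference: ComplexModel, slim_keys,
                       cutoff: float = INTERFACE_CUTOFF) -> InterfaceDefinition:
    """Motif residues plus receptor residues within the heavy-atom cutoff."""
    slim_keys = [tuple(k) for k in slim_keys]
    if not slim_keys:
        raise ValueError("empty motif residue set")
    slim_chain = _restrict(reference.partner, slim_keys)
    d = residue_min_distance_matrix(reference.receptor, slim_chain)
    rec_keys = [k for k, row in zip(reference.receptor.keys(), d)
                if row.min() < cutoff]
    return InterfaceDefinition(peptide_keys=slim_keys, receptor_keys=rec_keys,
                               cutoff=cutoff)


def _interface_ca(model: ComplexModel, interface: InterfaceDefinition) -> np.ndarray:
    rec = _restrict(model.receptor, interface.receptor_keys)
    pep = _restrict(model.partner, interface.peptide_keys)
    return np.vstack([rec.ca_array(), pep.ca_array()]) if len(rec) else pep.ca_array()


def irmsd(model: ComplexModel, reference: ComplexModel,
          interface: InterfaceDefinition | None = None,
          slim_keys=None, cutoff: float = INTERFACE_CUTOFF) -> float:
    """Interface CA RMSD after least-squares fit of the interface CA sets.

    The interface is defined on the *reference*; pass either a precomputed
    :class:`InterfaceDefinition` or the motif keys to derive one.
    """
    if interface is None:
        if slim_keys is None:
            raise ValueError("need an interface definition or motif keys")
        interface = interface_residues(reference, slim_keys, cutoff)
    mod = _interface_ca(model, interface)
    ref = _interface_ca(reference, interface)
    if len(ref) < 3:
        raise ValueError("fewer than 3 interface residues: degenerate fit")
    return kabsch_superpose(mod, ref).rmsd


def ligand_rmsd(model: ComplexModel, reference: ComplexModel, slim_keys) -> float:
    """Motif CA RMSD after superposing the receptors (no fit on the motif)."""
    sup = kabsch_superpose(model.receptor.ca_array(), reference.receptor.ca_array())
    mod_pep = sup.apply(_restrict(model.partner, slim_keys).ca_array())
    ref_pep = _restrict(reference.partner, slim_keys).ca_array()
    return float(np.sqrt(np.mean(np.sum((mod_pep - ref_pep) ** 2, axis=1))))


def evaluate_model(model: ComplexModel, reference: ComplexModel,
                   slim_keys, contact_cutoff: float = CONTACT_CUTOFF,
                   interface_cutoff: float = INTERFACE_CUTOFF,
                   ) -> EvaluationReport:
    """Aggregate fNC (motif region), iRMSD and L-RMSD against the reference."""
    fnc, n_nat, n_mod, n_ok = fraction_native_contacts(
        model, reference, contact_cutoff, partner_keys=slim_keys)
    value_irmsd = irmsd(model, reference, slim_keys=slim_keys,
                        cutoff=interface_cutoff)
    value_lrmsd = ligand_rmsd(model, reference, slim_keys)
    return EvaluationReport(fnc=fnc, irmsd=value_irmsd, lrmsd=value_lrmsd,
                            native_contacts=n_nat, model_contacts=n_mod,
                            correct_contacts=n_ok)
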