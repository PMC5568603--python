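"""Shared fixtures: synthetic structures and one full default docking run."""

import numpy as np
import pytest

from slimdock.docking_engine import DockingConfig, run_docking
from slimdock.fixtures import ToyComplexSpec, make_toy_complex, funnel_energy_table

try:
    from hypothesis import settings
    settings.register_profile("suite", deadline=None, max_examples=25,
                              derandomize=True)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def toy():
    """Default 52-residue grooved receptor bound to a 13-mer motif."""
    return make_toy_complex(ToyComplexSpec())


@pytest.fixture(scope="session")
def funnel_toy():
    """Small all-distinct-letter complex used for funnel-recovery checks."""
    return make_toy_complex(ToyComplexSpec(receptor_length=37,
                                           peptide_sequence="ACDEFHIK"))


@pytest.fixture(scope="session")
def funnel_table(funnel_toy):
    return funnel_energy_table(funnel_toy)


@pytest.fixture(scope="session")
def default_run(toy):
    """One full default-protocol run (10 replicas x 1000 snapshots).

    Shared across the tests that assert protocol counts and receptor
    integrity, because it is by far the most expensive fixture.
    """
    trajectory = run_docking(toy.receptor, toy.slim.sequence,
                             DockingConfig(seed=2024))
    return trajectory


def kabsch_oracle(mobile, target):
    """Independent SVD Kabsch: returns (rotation, translation, rmsd)."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = target.mean(axis=0) - r @ mobile.mean(axis=0)
    moved = mobile @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return r, t, rmsd
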