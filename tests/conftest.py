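import numpy as np
import pytest

from bdascan import build_probe, fixtures
from bdascan.docking import DockingPose
from bdascan.structio import Atom, Residue, Structure
from bdascan.trajanalysis import kabsch


@pytest.fixture(scope="session")
def peptide():
    """Extended peptide containing every scannable residue type."""
    return fixtures.make_structure(sequence="AYFWHGA")


@pytest.fixture(scope="session")
def tyr_peptide():
    """Small peptide with a single central tyrosine."""
    return fixtures.make_structure(sequence="GAYAG")


@pytest.fixture(scope="session")
def phenyl_probe():
    return build_probe("phenylboronic_acid")


def single_atom_structure(xyz=(0.0, 0.0, 0.0), element="C", name="CA"):
    return Structure([[Residue("A", 1, "GLY",
                               [Atom(1, name, element, np.array(xyz))])]])


def superimposed_pose(probe, tyr_residue, affinity=-5.6, rank=1,
                      flip=False):
    """Pose whose aromatic ring sits exactly on the tyrosine ring.

    The probe's C1 (B-bearing) carbon lands on CZ so the boron extends
    where the hydroxyl pointed; ``flip=True`` reverses the ring mapping so
    the boron points back toward CB (opposite directionality).
    """
    names = ["C1", "C2", "C3", "C4", "C5", "C6"]
    targets = ["CZ", "CE1", "CD1", "CG", "CD2", "CE2"]
    if flip:
        targets = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    ring_p = np.array([probe.atom(n).xyz for n in names])
    ring_t = np.array([tyr_residue.atom(n).xyz for n in targets])
    sup = kabsch(ring_t, ring_p)
    return DockingPose(probe.name, rank, affinity, sup.apply(probe.coords()))
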