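"""Synthetic structures, trajectories and H-bond fixtures with known ground truth.

Everything here is geometric, not physical: backbones are built from ideal
internal coordinates (helix phi/psi -57/-47, extended -139/135), side chains
from idealized templates, trajectories from seeded Gaussian perturbations.
The generators exist so that every pipeline stage is testable without any
structure download or MD run, and so that detectors can be scored against a
planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bdascan._geometry import place_atom
from bdascan.structio import Atom, Residue, Structure, Trajectory

__all__ = [
    "FixtureSpec", "make_structure", "make_noisy_trajectory",
    "make_two_state_trajectory", "make_hbond_fixture",
    "ONE_TO_THREE",
]

ONE_TO_THREE = {"A": "ALA", "G": "GLY", "F": "PHE", "Y": "TYR",
                "W": "TRP", "H": "HIS"}

# backbone internal coordinates (lengths Å, angles deg)
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8

_PHI_PSI = {"helix": (-57.0, -47.0), "extended": (-139.0, 135.0)}

# side-chain chains: each entry places one atom from three previously placed
# atoms: (name, element, ref_a, ref_b, ref_c, bond, angle, dihedral)
_SIDECHAINS: dict[str, list[tuple]] = {
    "ALA": [("CB", "C", "C", "N", "CA", 1.53, 110.5, 122.6)],
    "GLY": [],
    "PHE": [
        ("CB", "C", "C", "N", "CA", 1.53, 110.5, 122.6),
        ("CG", "C", "N", "CA", "CB", 1.51, 113.8, 180.0),
        ("CD1", "C", "CA", "CB", "CG", 1.39, 120.9, 90.0),
        ("CD2", "C", "CA", "CB", "CG", 1.39, 120.9, -90.0),
        ("CE1", "C", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
        ("CE2", "C", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
        ("CZ", "C", "CG", "CD1", "CE1", 1.39, 120.0, 0.0),
    ],
    "TRP": [
        ("CB", "C", "C", "N", "CA", 1.53, 110.5, 122.6),
        ("CG", "C", "N", "CA", "CB", 1.50, 114.0, 180.0),
        ("CD1", "C", "CA", "CB", "CG", 1.37, 127.0, 90.0),
        ("CD2", "C", "CA", "CB", "CG", 1.43, 126.6, -90.0),
        ("NE1", "N", "CB", "CG", "CD1", 1.38, 110.2, 180.0),
        ("CE2", "C", "CB", "CG", "CD2", 1.41, 107.2, 180.0),
        ("CE3", "C", "CB", "CG", "CD2", 1.40, 133.9, 0.0),
        ("CZ2", "C", "CG", "CD2", "CE2", 1.40, 122.4, 180.0),
        ("CZ3", "C", "CG", "CD2", "CE3", 1.39, 118.8, 180.0),
        ("CH2", "C", "CE3", "CD2", "CE2", 1.37, 128.9, 180.0),
    ],
    "HIS": [
        ("CB", "C", "C", "N", "CA", 1.53, 110.5, 122.6),
        ("CG", "C", "N", "CA", "CB", 1.49, 114.0, 180.0),
        ("ND1", "N", "CA", "CB", "CG", 1.38, 122.7, 90.0),
        ("CD2", "C", "CA", "CB", "CG", 1.35, 131.0, -90.0),
        ("CE1", "C", "CB", "CG", "ND1", 1.32, 109.0, 180.0),
        ("NE2", "N", "CB", "CG", "CD2", 1.37, 107.0, 180.0),
    ],
}
# TYR = PHE ring + hydroxyl oxygen on CZ
_SIDECHAINS["TYR"] = _SIDECHAINS["PHE"] + [
    ("OH", "O", "CD1", "CE1", "CZ", 1.375, 120.0, 180.0),
]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic fixture; the seed fully determines output."""

    sequence: str = "AYA"
    conformation: str = "extended"
    seed: int = 0
    noise_sigma: float = 0.0
    n_frames: int = 1
    populations: tuple[float, ...] = (1.0,)
    displacement: float = 6.0
    n_hbonds: int = 0
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if abs(sum(self.populations) - 1.0) > 1e-9:
            raise ValueError("state populations must sum to 1")


def make_structure(spec: FixtureSpec | None = None, *,
                   sequence: str | None = None,
                   conformation: str | None = None,
                   chain_id: str = "A",
                   start_resnum: int = 1) -> Structure:
    """Build an ideal-geometry peptide for a one-letter sequence over
    {A, G, F, Y, W, H}.

    The backbone uses standard bond lengths/angles with the requested
    phi/psi; side chains are attached from idealized templates (chi1 = 180).
    Output is fully deterministic.
    """
    if spec is not None:
        sequence = spec.sequence
        conformation = spec.conformation
        chain_id = spec.chain_id
    sequence = sequence or "AYA"
    conformation = conformation or "extended"
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = set(sequence) - set(ONE_TO_THREE)
    if bad:
        raise ValueError(f"unsupported residue letter(s): {sorted(bad)}")
    if conformation not in _PHI_PSI:
        raise ValueError(f"unknown conformation {conformation!r}")
    phi, psi = _PHI_PSI[conformation]

    residues: list[Residue] = []
    serial = 0
    prev = None  # (N, CA, C) positions of previous residue
    for i, letter in enumerate(sequence):
        resname = ONE_TO_THREE[letter]
        pos: dict[str, np.ndarray] = {}
        if prev is None:
            pos["N"] = np.zeros(3)
            pos["CA"] = np.array([_N_CA, 0.0, 0.0])
            ang = np.deg2rad(_ANG_N_CA_C)
            pos["C"] = pos["CA"] + _CA_C * np.array(
                [-np.cos(ang), np.sin(ang), 0.0])
        else:
            pn, pca, pc = prev
            pos["N"] = place_atom(pn, pca, pc, _C_N, _ANG_CA_C_N, psi)
            pos["CA"] = place_atom(pca, pc, pos["N"], _N_CA, _ANG_C_N_CA,
                                   180.0)  # omega
            pos["C"] = place_atom(pc, pos["N"], pos["CA"], _CA_C,
                                  _ANG_N_CA_C, phi)
        # carbonyl O anti to the next N direction (psi + 180)
        pos["O"] = place_atom(pos["N"], pos["CA"], pos["C"], _C_O,
                              _ANG_CA_C_O, psi + 180.0)
        for name, element, ra, rb, rc, bond, angle, dihedral in \
                _SIDECHAINS[resname]:
            pos[name] = place_atom(pos[ra], pos[rb], pos[rc],
                                   bond, angle, dihedral)

        order = ["N", "CA", "C", "O"] + \
            [entry[0] for entry in _SIDECHAINS[resname]]
        atoms = []
        for name in order:
            serial += 1
            element = "N" if name.startswith("N") else \
                "O" if name.startswith("O") else "C"
            atoms.append(Atom(serial, name, element, pos[name]))
        residues.append(Residue(chain_id, start_resnum + i, resname, atoms))
        prev = (pos["N"], pos["CA"], pos["C"])

    return Structure([residues])


def make_noisy_trajectory(structure: Structure, sigma: float,
                          n_frames: int, seed: int) -> Trajectory:
    """Frames = base coordinates + i.i.d. Gaussian(0, sigma^2) per component."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    base = structure.coords()
    frames = [base + rng.normal(0.0, sigma, size=base.shape)
              for _ in range(n_frames)]
    return Trajectory(Structure([structure.models[0]]), frames)


def make_two_state_trajectory(structure: Structure,
                              populations: tuple[float, float] = (0.7, 0.3),
                              displacement: float = 6.0,
                              sigma: float = 0.3,
                              n_frames: int = 200,
                              seed: int = 0,
                              ) -> tuple[Trajectory, np.ndarray]:
    """Two-state trajectory: in state 1 the second half of the chain is
    rigidly displaced by ``displacement`` Å along +x. Returns the trajectory
    and the true per-frame state labels."""
    if abs(sum(populations) - 1.0) > 1e-9:
        raise ValueError("populations must sum to 1")
    rng = np.random.default_rng(seed)
    base = structure.coords()
    model = structure.models[0]
    # atom index mask for the displaced residue block (second half)
    half = len(model) // 2
    mask = np.zeros(base.shape[0], dtype=bool)
    idx = 0
    for ri, res in enumerate(model):
        for _ in res.atoms:
            mask[idx] = ri >= half
            idx += 1
    displaced = base.copy()
    displaced[mask, 0] += displacement

    labels = rng.choice(len(populations), size=n_frames, p=list(populations))
    frames = []
    for lab in labels:
        ref = base if lab == 0 else displaced
        frames.append(ref + rng.normal(0.0, sigma, size=base.shape))
    traj = Trajectory(Structure([structure.models[0]]), frames)
    return traj, labels


def make_hbond_fixture(k: int, seed: int = 0, n_decoys: int = 8
                       ) -> tuple[Structure, list[tuple]]:
    """Structure with exactly ``k`` planted donor–H···acceptor triads
    (D···A 2.8 Å, D–H···A angle 170°) plus apolar carbon decoys placed
    >= 6 Å from every polar atom.

    Returns the structure and the planted list of
    (donor_residue_id, acceptor_residue_id) pairs.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    planted: list[tuple] = []
    serial = 0
    resnum = 0

    d_da, d_nh, theta = 2.8, 1.0, np.deg2rad(170.0)
    # |H->A| from the triangle with angle theta at H
    # law of cosines in the D–H–A triangle with the planted angle at H
    r = (2 * d_nh * np.cos(theta)
         + np.sqrt((2 * d_nh * np.cos(theta)) ** 2
                   - 4 * (d_nh ** 2 - d_da ** 2))) / 2.0

    grid = 12.0  # triad spacing, far beyond any cutoff
    for i in range(k):
        origin = np.array([grid * i, 0.0, 0.0])
        # random orientation of the triad, seeded
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        tmp = rng.normal(size=3)
        v = np.cross(u, tmp)
        v /= np.linalg.norm(v)
        n_pos = origin
        h_pos = origin + d_nh * u
        w = np.cos(np.pi - theta) * u + np.sin(np.pi - theta) * v
        a_pos = h_pos + r * w
        c_pos = a_pos + 1.43 * (a_pos - h_pos) / np.linalg.norm(a_pos - h_pos)

        resnum += 1
        serial += 2
        residues.append(Residue("D", resnum, "DNR", [
            Atom(serial - 1, "N", "N", n_pos),
            Atom(serial, "H", "H", h_pos),
        ]))
        donor_id = ("D", resnum, "")
        resnum += 1
        serial += 2
        residues.append(Residue("D", resnum, "ACC", [
            Atom(serial - 1, "O", "O", a_pos),
            Atom(serial, "C", "C", c_pos),
        ]))
        planted.append((donor_id, ("D", resnum, "")))

    # apolar decoys on a far shifted grid, jittered
    for j in range(n_decoys):
        resnum += 1
        serial += 1
        xyz = np.array([grid * (j % max(k, 1)),
                        20.0 + 7.0 * (j // max(k, 1)), 0.0])
        xyz = xyz + rng.uniform(-0.5, 0.5, size=3)
        residues.append(Residue("D", resnum, "DCY",
                                [Atom(serial, "C1", "C", xyz)]))
    if not residues:  # k == 0 and no decoys requested
        serial += 1
        residues.append(Residue("D", 1, "DCY",
                                [Atom(serial, "C1", "C", np.zeros(3))]))
    return Structure([residues]), planted
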