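"""Cavity scanning: enumerate boronation candidate sites and truncate them.

Phe/Tyr/Trp/His side chains can in principle be swapped for a boronated
analogue; whether the fold tolerates it is probed by truncating every
residue of one type to Gly or Ala (vacating the side-chain volume) and
docking boronic-acid fragments into the holes. Residues at the protected
antigen-binding interface are never mutated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from bdascan.structio import Residue, Structure

__all__ = [
    "SCANNABLE_RESTYPES", "BACKBONE_ATOMS", "MutationSite", "CavityScan",
    "protected_residues", "select_sites", "truncate_residue",
    "build_cavity_scan",
]

SCANNABLE_RESTYPES = ("PHE", "TYR", "TRP", "HIS")
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
_BACKBONE_HYDROGENS = {"H", "HA", "H1", "H2", "H3", "HA2", "HA3"}


@dataclass(frozen=True)
class MutationSite:
    """One candidate residue: where it is, what it was, what it becomes,
    and the centroid of the side chain it vacates (heavy atoms beyond CB)."""

    chain_id: str
    resnum: int
    original_resname: str
    target: str
    sidechain_centroid: np.ndarray
    icode: str = ""

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resnum, self.icode)

    def __str__(self) -> str:
        return (f"{self.chain_id}:{self.original_resname}{self.resnum}"
                f"{self.icode}->{self.target}")


@dataclass
class CavityScan:
    """All residues of one type truncated simultaneously in one structure."""

    restype: str
    target: str
    mutated_structure: Structure
    sites: list[MutationSite]


def protected_residues(antibody: Structure, receptor: Structure,
                       cutoff: float = 8.0) -> set[tuple]:
    """Antibody residues with any heavy atom within ``cutoff`` Å of any
    receptor heavy atom — the binding interface that must not be mutated.

    Both structures must share a coordinate frame (e.g. chains split out of
    the same complex). A cutoff of 0 protects nothing. If the two sets are
    more than 50 Å apart a 'no interface detected' warning is emitted.
    """
    rec_coords = receptor.coords(heavy_only=True)
    if rec_coords.size == 0 or cutoff <= 0:
        return set()
    tree = cKDTree(rec_coords)
    protected: set[tuple] = set()
    min_dist = np.inf
    for res in antibody.models[0]:
        coords = res.coords(heavy_only=True)
        if coords.size == 0:
            continue
        d = tree.query(coords)[0].min()
        min_dist = min(min_dist, d)
        if d <= cutoff:
            protected.add(res.id)
    if min_dist > 50.0:
        warnings.warn("no interface detected: antibody and receptor are "
                      f"{min_dist:.1f} Å apart", stacklevel=2)
    return protected


def _sidechain_centroid(res: Residue) -> np.ndarray:
    atoms = [a for a in res.heavy_atoms()
             if a.name not in BACKBONE_ATOMS and a.name != "CB"]
    if not atoms:
        raise ValueError(f"residue {res.chain_id}:{res.resnum} has no "
                         "side-chain atoms beyond CB")
    return np.mean([a.xyz for a in atoms], axis=0)


def select_sites(s: Structure, restype: str,
                 excluded: set[tuple] | None = None,
                 target: str = "GLY") -> list[MutationSite]:
    """All residues of ``restype`` outside the exclusion set, each with its
    vacated-side-chain centroid, ordered deterministically by
    (chain, resnum, icode)."""
    if restype not in SCANNABLE_RESTYPES:
        raise ValueError(f"restype must be one of {SCANNABLE_RESTYPES}, "
                         f"got {restype!r}")
    excluded = excluded or set()
    sites = [
        MutationSite(res.chain_id, res.resnum, res.resname, target,
                     _sidechain_centroid(res), res.icode)
        for res in s.models[0]
        if res.resname == restype and res.id not in excluded
    ]
    sites.sort(key=lambda m: (m.chain_id, m.resnum, m.icode))
    return sites


def truncate_residue(r: Residue, target: str) -> Residue:
    """Truncate a standard residue to GLY (backbone only) or ALA (backbone
    + CB). Retained atoms keep their exact coordinates; truncation is
    idempotent."""
    if target not in ("GLY", "ALA"):
        raise ValueError(f"target must be GLY or ALA, got {target!r}")
    for name in ("N", "CA", "C", "O"):
        if not r.has_atom(name):
            raise ValueError(f"residue {r.chain_id}:{r.resnum} missing "
                             f"backbone atom {name}")
    keep = set(BACKBONE_ATOMS)
    if target == "ALA":
        if r.resname != "GLY" and not r.has_atom("CB"):
            raise ValueError(f"residue {r.chain_id}:{r.resnum} has no CB; "
                             "cannot truncate to ALA")
        keep.add("CB")
    atoms = [a.copy() for a in r.atoms
             if a.name in keep
             or (a.is_hydrogen and a.name in _BACKBONE_HYDROGENS)
             or (target == "ALA" and a.is_hydrogen
                 and a.name.startswith("HB"))]
    out = Residue(r.chain_id, r.resnum, target, atoms, r.icode)
    return out


def build_cavity_scan(s: Structure, restype: str, target: str,
                      excluded: set[tuple] | None = None) -> CavityScan:
    """One mutated structure per (restype, target): every non-excluded
    residue of the type truncated simultaneously, its site recorded."""
    sites = select_sites(s, restype, excluded, target)
    if not sites:
        raise ValueError(f"nothing to scan: no non-excluded {restype} "
                         "residues")
    site_ids = {m.residue_id for m in sites}
    mutated = []
    for res in s.models[0]:
        if res.id in site_ids:
            mutated.append(truncate_residue(res, target))
        else:
            mutated.append(res.copy())
    return CavityScan(restype, target, Structure([mutated], s.pdb_id), sites)


def build_all_scans(s: Structure, excluded: set[tuple] | None = None,
                    restypes=SCANNABLE_RESTYPES, targets=("GLY", "ALA")
                    ) -> list[CavityScan]:
    """The full scan set: one structure per restype × target that has at
    least one non-excluded site (8 for a structure containing all four
    types)."""
    scans = []
    for restype in restypes:
        for target in targets:
            try:
                scans.append(build_cavity_scan(s, restype, target, excluded))
            except ValueError:
                continue
    return scans
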