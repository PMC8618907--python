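"""Boronic-acid fragment probes and the boronated BPA residue.

The three probes — phenylboronic acid, p-toluene boronic acid and
cyclopentylboronic acid — are the fragments of the two clinically used
boron carriers (4-borono-L-phenylalanine and
cis-1-amino-3-borono-cyclopentanecarboxylic acid) after stripping the
amino-acid moiety. Because boron is not parametrized by Vina-class docking
engines, the boron atom is *typed* as carbon for docking while its true
element is kept in metadata.

The BPA residue is a tyrosine whose hydroxyl oxygen is replaced by a
planar trigonal B(OH)₂ group built at exact configured geometry (defaults:
B–C 1.56 Å, B–O 1.36 Å, O–H 0.96 Å, 120° sp² angles — standard
experimental arylboronic-acid values, all overridable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from bdascan._geometry import place_atom
from bdascan.structio import Atom, Residue

__all__ = [
    "BoronGeometry", "ProbeAtom", "FragmentProbe", "ResidueTemplate",
    "PROBE_NAMES", "build_probe", "build_bpa", "export_probe_pdbqt",
    "export_residue_template", "DEFAULT_PROBE_CHARGES",
    "DEFAULT_BPA_CHARGES",
]

PROBE_NAMES = ("phenylboronic_acid", "p_toluene_boronic_acid",
               "cyclopentylboronic_acid")


@dataclass
class BoronGeometry:
    """Bond lengths (Å) and angles (deg) of the B(OH)₂ group."""

    b_c_length: float = 1.56
    b_o_length: float = 1.36
    o_h_length: float = 0.96
    c_b_o_angle: float = 120.0
    o_b_o_angle: float = 120.0
    b_o_h_angle: float = 113.0
    planar: bool = True

    def __post_init__(self) -> None:
        for name in ("b_c_length", "b_o_length", "o_h_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("c_b_o_angle", "o_b_o_angle", "b_o_h_angle"):
            if not 0 < getattr(self, name) < 180:
                raise ValueError(f"{name} must be in (0, 180)")


@dataclass
class ProbeAtom:
    name: str
    element: str          # true element ("B" for the boron)
    xyz: np.ndarray
    docking_type: str     # type written to PDBQT ("C" for the boron)
    charge: float = 0.0
    is_boron: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class FragmentProbe:
    """Rigid ring + rotatable B(OH)₂ group, with the boron flagged."""

    name: str
    atoms: list[ProbeAtom]
    bonds: list[tuple[int, int]]
    ring_bonds: set[tuple[int, int]]
    ligand_vector: tuple[str, str]   # (tail atom name, head = boron name)

    def __post_init__(self) -> None:
        borons = [a for a in self.atoms if a.is_boron]
        if len(borons) != 1:
            raise ValueError("probe must have exactly one boron atom")
        head = self.ligand_vector[1]
        if self.atom(head) is not borons[0]:
            raise ValueError("ligand_vector head must be the boron atom")

    def atom(self, name: str) -> ProbeAtom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"probe atom {name!r} not found")

    def atom_index(self, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.name == name:
                return i
        raise KeyError(f"probe atom {name!r} not found")

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_indices())

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def rotatable_bonds(self) -> list[tuple[int, int]]:
        """Non-ring bonds with at least one further heavy atom on each
        side — the torsions a docking engine would sample."""
        heavy_neighbors: dict[int, set[int]] = {i: set() for i in
                                                range(len(self.atoms))}
        for i, j in self.bonds:
            if not self.atoms[i].is_hydrogen and \
                    not self.atoms[j].is_hydrogen:
                heavy_neighbors[i].add(j)
                heavy_neighbors[j].add(i)
        out = []
        for i, j in self.bonds:
            key = (min(i, j), max(i, j))
            if key in self.ring_bonds:
                continue
            if self.atoms[i].is_hydrogen or self.atoms[j].is_hydrogen:
                continue
            if len(heavy_neighbors[i] - {j}) >= 1 and \
                    len(heavy_neighbors[j] - {i}) >= 1:
                out.append(key)
        return out

    def with_coords(self, coords: np.ndarray) -> "FragmentProbe":
        atoms = [replace(a, xyz=np.asarray(c, dtype=float))
                 for a, c in zip(self.atoms, coords)]
        return FragmentProbe(self.name, atoms, list(self.bonds),
                             set(self.ring_bonds), self.ligand_vector)


DEFAULT_PROBE_CHARGES: dict[str, dict[str, float]] = {
    "phenylboronic_acid": {
        "C1": -0.10, "C2": 0.0, "C3": 0.0, "C4": 0.0, "C5": 0.0, "C6": 0.0,
        "B": 0.40, "O1": -0.45, "O2": -0.45, "HO1": 0.30, "HO2": 0.30,
    },
    "p_toluene_boronic_acid": {
        "C1": -0.10, "C2": 0.0, "C3": 0.0, "C4": 0.0, "C5": 0.0, "C6": 0.0,
        "C7": 0.0,
        "B": 0.40, "O1": -0.45, "O2": -0.45, "HO1": 0.30, "HO2": 0.30,
    },
    "cyclopentylboronic_acid": {
        "C1": -0.10, "C2": 0.0, "C3": 0.0, "C4": 0.0, "C5": 0.0,
        "B": 0.40, "O1": -0.45, "O2": -0.45, "HO1": 0.30, "HO2": 0.30,
    },
}

DEFAULT_BPA_CHARGES: dict[str, float] = {
    "N": -0.40, "CA": 0.00, "C": 0.55, "O": -0.55,
    "CB": 0.00, "CG": 0.00, "CD1": 0.00, "CD2": 0.00,
    "CE1": 0.00, "CE2": 0.00, "CZ": 0.15,
    "B": 0.40, "O1": -0.475, "O2": -0.475, "HO1": 0.40, "HO2": 0.40,
}


def _boh2_atoms(b_pos: np.ndarray, u: np.ndarray, m: np.ndarray,
                anchor: np.ndarray, geom: BoronGeometry
                ) -> list[ProbeAtom]:
    """O/H atoms of a planar B(OH)₂: u = unit anchor→B direction, m = unit
    in-plane perpendicular; anchor is the carbon bonded to B."""
    half = np.deg2rad(geom.o_b_o_angle / 2.0)
    out = []
    for sign, oname, hname in ((1.0, "O1", "HO1"), (-1.0, "O2", "HO2")):
        o_dir = np.cos(half) * u + sign * np.sin(half) * m
        o_pos = b_pos + geom.b_o_length * o_dir
        h_pos = place_atom(anchor, b_pos, o_pos, geom.o_h_length,
                           geom.b_o_h_angle, 180.0)
        out.append(ProbeAtom(oname, "O", o_pos, "OA"))
        out.append(ProbeAtom(hname, "H", h_pos, "HD"))
    return out


def build_probe(name: str, geom: BoronGeometry | None = None,
                charges: dict[str, float] | None = None) -> FragmentProbe:
    """Construct a fragment probe at ideal geometry.

    Aromatic rings are regular planar hexagons (bond 1.39 Å), the
    cyclopentyl ring a regular planar pentagon (bond 1.54 Å); the B(OH)₂
    group is placed per ``geom``. The boron is typed as carbon for docking
    and flagged ``is_boron``; the ligand reference vector runs from the
    ring atom opposite the boron to the boron.
    """
    geom = geom or BoronGeometry()
    if name not in PROBE_NAMES:
        raise ValueError(f"unknown probe {name!r}; choose from {PROBE_NAMES}")
    charges = charges if charges is not None else DEFAULT_PROBE_CHARGES[name]

    atoms: list[ProbeAtom] = []
    bonds: list[tuple[int, int]] = []
    ring_bonds: set[tuple[int, int]] = set()

    if name in ("phenylboronic_acid", "p_toluene_boronic_acid"):
        n_ring, bond_len = 6, 1.39
    else:
        n_ring, bond_len = 5, 1.54
    radius = bond_len / (2.0 * np.sin(np.pi / n_ring))
    for i in range(n_ring):
        ang = 2.0 * np.pi * i / n_ring
        atoms.append(ProbeAtom(f"C{i + 1}", "C",
                               [radius * np.cos(ang),
                                radius * np.sin(ang), 0.0], "A"))
    for i in range(n_ring):
        ring_bonds.add((min(i, (i + 1) % n_ring), max(i, (i + 1) % n_ring)))
    bonds.extend(sorted(ring_bonds))

    c1 = atoms[0].xyz
    u = c1 / np.linalg.norm(c1)       # ring center → C1, in plane
    m = np.array([-u[1], u[0], 0.0])  # in-plane perpendicular
    b_pos = c1 + geom.b_c_length * u
    b_index = len(atoms)
    atoms.append(ProbeAtom("B", "B", b_pos, "C", is_boron=True))
    bonds.append((0, b_index))
    for pa in _boh2_atoms(b_pos, u, m, c1, geom):
        idx = len(atoms)
        atoms.append(pa)
        if pa.element == "O":
            bonds.append((b_index, idx))
            last_o = idx
        else:
            bonds.append((last_o, idx))

    if name == "p_toluene_boronic_acid":
        c_para = atoms[3].xyz  # C4, para to C1 on a hexagon
        me_pos = c_para + 1.51 * (c_para / np.linalg.norm(c_para))
        idx = len(atoms)
        atoms.append(ProbeAtom("C7", "C", me_pos, "C"))
        bonds.append((3, idx))

    tail = "C4" if n_ring == 6 else "C3"  # ring atom across from C1/B
    for a in atoms:
        a.charge = charges.get(a.name, 0.0)
    return FragmentProbe(name, atoms, bonds, ring_bonds, (tail, "B"))


# ---------------------------------------------------------------------------
# PDBQT export


def _pdbqt_atom_line(serial: int, a: ProbeAtom) -> str:
    return (f"ATOM  {serial:>5d} {a.name:<4s} LIG A   1    "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}    {a.charge:6.3f} "
            f"{a.docking_type:<2s}")


def export_probe_pdbqt(p: FragmentProbe, path) -> None:
    """Write the probe as a ligand PDBQT with a ROOT/BRANCH torsion tree.

    The rigid ring is the ROOT; each rotatable bond (in practice the single
    C–B torsion) opens a BRANCH carrying the B(OH)₂ group. The boron is
    written with docking type C; a REMARK records its true position.
    """
    if all(a.charge == 0.0 for a in p.atoms):
        raise ValueError("probe has no charges assigned; supply a charge "
                         "table before PDBQT export")
    rot = p.rotatable_bonds()
    adj: dict[int, set[int]] = {i: set() for i in range(len(p.atoms))}
    for i, j in p.bonds:
        adj[i].add(j)
        adj[j].add(i)
    rot_set = set(rot)

    # rigid groups under the torsion-tree partition
    group_of = [-1] * len(p.atoms)
    groups: list[list[int]] = []
    for start in range(len(p.atoms)):
        if group_of[start] != -1:
            continue
        gid = len(groups)
        stack, members = [start], []
        group_of[start] = gid
        while stack:
            x = stack.pop()
            members.append(x)
            for y in adj[x]:
                if group_of[y] == -1 and (min(x, y), max(x, y)) not in rot_set:
                    group_of[y] = gid
                    stack.append(y)
        groups.append(sorted(members))

    boron_idx = next(i for i, a in enumerate(p.atoms) if a.is_boron)
    lines = [f"REMARK  Name = {p.name}",
             f"REMARK  TRUE_BORON_ATOM {p.atoms[boron_idx].name} "
             f"index {boron_idx + 1}",
             f"REMARK  {len(rot)} active torsions"]
    serial_of: dict[int, int] = {}
    serial = 0

    def emit_group(gid: int, parent_bond: tuple[int, int] | None,
                   parent_gid: int | None) -> None:
        nonlocal serial
        if parent_bond is None:
            lines.append("ROOT")
        else:
            lines.append(f"BRANCH {serial_of[parent_bond[0]]:>3d} "
                         f"{serial + 1:>3d}")
        for idx in groups[gid]:
            serial += 1
            serial_of[idx] = serial
            lines.append(_pdbqt_atom_line(serial, p.atoms[idx]))
        if parent_bond is None:
            lines.append("ENDROOT")
        for i, j in rot:
            if group_of[i] == gid and group_of[j] not in (gid, parent_gid):
                emit_group(group_of[j], (i, j), gid)
            elif group_of[j] == gid and group_of[i] not in (gid, parent_gid):
                emit_group(group_of[i], (j, i), gid)
        if parent_bond is not None:
            lines.append(f"ENDBRANCH {serial_of[parent_bond[0]]:>3d} "
                         f"{serial_of[parent_bond[1]]:>3d}")

    emit_group(group_of[0], None, None)
    lines.append(f"TORSDOF {len(rot)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BPA residue construction


def build_bpa(tyr: Residue, geom: BoronGeometry | None = None) -> Residue:
    """Replace a tyrosine's hydroxyl oxygen by a planar B(OH)₂ group.

    B is placed along the CZ→OH direction at the configured B–C length; the
    two oxygens lie in the aromatic-ring plane at the configured B–O length
    and O–B–O angle; every other atom is left exactly where it was. The
    result is named BPA.
    """
    geom = geom or BoronGeometry()
    if tyr.resname not in ("TYR", "BPA"):
        raise ValueError(f"build_bpa expects a TYR residue, got "
                         f"{tyr.resname}")
    for name in ("CZ", "OH"):
        if not tyr.has_atom(name):
            raise ValueError(f"residue {tyr.chain_id}:{tyr.resnum} missing "
                             f"atom {name}; cannot boronate")
    cz = tyr.atom("CZ").xyz
    oh = tyr.atom("OH").xyz
    u = oh - cz
    u = u / np.linalg.norm(u)
    # in-plane perpendicular from the aromatic ring (CE1/CE2), with a
    # fallback for incomplete rings
    if tyr.has_atom("CE1") and tyr.has_atom("CE2"):
        normal = np.cross(tyr.atom("CE1").xyz - cz, tyr.atom("CE2").xyz - cz)
    else:
        normal = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(normal) < 1e-8:
            normal = np.cross(u, [0.0, 1.0, 0.0])
    normal = normal / np.linalg.norm(normal)
    m = np.cross(normal, u)
    m = m / np.linalg.norm(m)

    b_pos = cz + geom.b_c_length * u
    kept = [a.copy() for a in tyr.atoms
            if a.name not in ("OH", "HH") ]
    max_serial = max(a.serial for a in tyr.atoms)
    new = [ProbeAtom("B", "B", b_pos, "C")] + \
        _boh2_atoms(b_pos, u, m, cz, geom)
    atoms = kept + [
        Atom(max_serial + 1 + i, pa.name, pa.element, pa.xyz)
        for i, pa in enumerate(new)
    ]
    return Residue(tyr.chain_id, tyr.resnum, "BPA", atoms, tyr.icode)


# ---------------------------------------------------------------------------
# residue template export


@dataclass
class ResidueTemplate:
    resname: str
    atoms: list[dict]
    bonds: list[tuple[str, str]]
    head: str = "N"
    tail: str = "C"
    net_charge: float = 0.0


_COVALENT_CUTOFF = {("C", "C"): 1.75, ("C", "N"): 1.65, ("C", "O"): 1.60,
                    ("C", "B"): 1.75, ("B", "O"): 1.55, ("O", "H"): 1.25,
                    ("N", "H"): 1.25, ("C", "H"): 1.25}


def _infer_bonds(res: Residue) -> list[tuple[str, str]]:
    bonds = []
    for i, a in enumerate(res.atoms):
        for b in res.atoms[i + 1:]:
            key = tuple(sorted((a.element.upper(), b.element.upper())))
            cutoff = _COVALENT_CUTOFF.get(key, 1.8 if "H" not in key else 0.0)
            if cutoff and np.linalg.norm(a.xyz - b.xyz) <= cutoff:
                bonds.append((a.name, b.name))
    return bonds


def export_residue_template(bpa: Residue, charges: dict[str, float],
                            path, format: str = "json",
                            geom: BoronGeometry | None = None,
                            net_charge_target: float = 0.0) -> ResidueTemplate:
    """Export the boronated residue as a reusable template.

    ``json``: the full machine-readable record (atoms, charges, bonds,
    head/tail link atoms). ``prepin-like``: an Amber-prepin-style text with
    the N/C link atoms marked for chain continuation. ``frcmod-like``:
    parameter stubs for the three bond classes absent from standard
    residues (CZ–B, B–O, O–H) plus their angles, taken from ``geom``.
    """
    geom = geom or BoronGeometry()
    missing = [a.name for a in bpa.atoms if a.name not in charges]
    if missing:
        raise ValueError("charge table incomplete; missing atoms: "
                         + ", ".join(missing))
    net = sum(charges[a.name] for a in bpa.atoms)
    if abs(net - net_charge_target) > 1e-3:
        raise ValueError(f"net charge {net:+.3f} differs from target "
                         f"{net_charge_target:+.3f}")
    bonds = _infer_bonds(bpa)
    template = ResidueTemplate(
        resname=bpa.resname,
        atoms=[{"name": a.name, "element": a.element,
                "xyz": [round(float(v), 6) for v in a.xyz],
                "charge": charges[a.name]} for a in bpa.atoms],
        bonds=bonds, net_charge=round(net, 6),
    )
    if format == "json":
        with open(path, "w") as fh:
            json.dump({"resname": template.resname, "head": template.head,
                       "tail": template.tail,
                       "net_charge": template.net_charge,
                       "atoms": template.atoms,
                       "bonds": [list(b) for b in template.bonds]},
                      fh, indent=1)
    elif format == "prepin-like":
        lines = [f"{template.resname} residue template",
                 f"{template.resname} INT 0",
                 f"HEAD {template.head}", f"TAIL {template.tail}",
                 f"NET_CHARGE {template.net_charge:+.4f}"]
        for a in template.atoms:
            lines.append(f"{a['name']:<4s} {a['element']:<2s} "
                         f"{a['charge']:+8.4f}  "
                         f"{a['xyz'][0]:10.4f}{a['xyz'][1]:10.4f}"
                         f"{a['xyz'][2]:10.4f}")
        lines.append("DONE")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    elif format == "frcmod-like":
        lines = [f"frcmod-like stubs for {template.resname}",
                 "BOND",
                 f"CZ-B   300.0  {geom.b_c_length:6.3f}",
                 f"B -O   400.0  {geom.b_o_length:6.3f}",
                 f"O -HO  500.0  {geom.o_h_length:6.3f}",
                 "ANGLE",
                 f"CZ-B -O   70.0  {geom.c_b_o_angle:7.2f}",
                 f"O -B -O   70.0  {geom.o_b_o_angle:7.2f}",
                 f"B -O -HO  50.0  {geom.b_o_h_angle:7.2f}",
                 ""]
        with open(path, "w") as fh:
            fh.write("\n".join(lines))
    else:
        raise ValueError(f"unknown template format {format!r}")
    return template
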