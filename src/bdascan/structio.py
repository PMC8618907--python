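"""Coordinate data model and PDB / XYZ trajectory I/O.

All coordinates are in Ångström. Residue numbering follows the input file
verbatim (author numbering); no renumbering is performed. The model keeps a
flat, explicit hierarchy — Structure → models → Residue → Atom — so that
every downstream module (mutagenesis, docking, trajectory analytics) shares
one coordinate convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom", "Residue", "Structure", "Trajectory",
    "read_pdb", "write_pdb", "write_xyz_trajectory",
    "read_trajectory", "strip_solvent_ions",
]

# resnames treated as solvent; anything monoatomic is treated as an ion
WATER_RESNAMES = {"HOH", "WAT"}


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


@dataclass
class Atom:
    """A single atom: PDB-convention name, element symbol, position in Å."""

    serial: int
    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""
    partial_charge: float | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError(f"atom {self.name!r}: xyz must be a 3-vector")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return replace(self, xyz=self.xyz.copy())


@dataclass
class Residue:
    """One residue: (chain_id, resnum, icode) identifies it within a model."""

    chain_id: str
    resnum: int
    resname: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resnum, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(
            f"atom {name!r} not found in {self.resname} "
            f"{self.chain_id}{self.resnum}{self.icode}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        return np.array([a.xyz for a in atoms], dtype=float).reshape(-1, 3)

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.resnum, self.resname,
                       [a.copy() for a in self.atoms], self.icode)


@dataclass
class Structure:
    """A (possibly multi-model) molecular structure.

    ``models`` is a list of residue lists; residue order within a model is
    file order (chains contiguous). Most pipeline stages operate on
    ``models[0]``.
    """

    models: list[list[Residue]]
    pdb_id: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("Structure needs at least one model")

    @property
    def residues(self) -> list[Residue]:
        return self.models[0]

    def chains(self, model: int = 0) -> list[str]:
        seen: list[str] = []
        for r in self.models[model]:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def get_residue(self, chain_id: str, resnum: int, icode: str = "",
                    model: int = 0) -> Residue:
        for r in self.models[model]:
            if r.id == (chain_id, resnum, icode):
                return r
        raise KeyError(f"residue {chain_id}:{resnum}{icode} not found")

    def atoms(self, model: int = 0) -> list[Atom]:
        return [a for r in self.models[model] for a in r.atoms]

    def coords(self, model: int = 0, heavy_only: bool = False) -> np.ndarray:
        out = [a.xyz for r in self.models[model] for a in r.atoms
               if not (heavy_only and a.is_hydrogen)]
        return np.array(out, dtype=float).reshape(-1, 3)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms())

    def copy(self) -> "Structure":
        return Structure([[r.copy() for r in m] for m in self.models],
                         self.pdb_id)


@dataclass
class Trajectory:
    """Frames of coordinates congruent with a single-model topology."""

    topology: Structure
    frames: list[np.ndarray]
    frame_index: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("Trajectory needs at least one frame")
        n = self.topology.n_atoms
        self.frames = [np.asarray(f, dtype=float).reshape(-1, 3)
                       for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.shape[0] != n:
                raise ValueError(
                    f"frame {i}: {f.shape[0]} atoms, topology has {n}")
        if not self.frame_index:
            self.frame_index = list(range(len(self.frames)))

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# PDB reading

def _guess_element(name: str) -> str:
    stripped = name.strip()
    # two-letter elements in proteins/ligands we touch; digits strip first
    core = stripped.lstrip("0123456789")
    if core[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE", "CA") and \
            len(stripped) >= 2 and not stripped[0].isdigit():
        # "CA " in a protein is an alpha carbon, not calcium; disambiguate
        # by PDB alignment: element names start in column 13 only for
        # 2-char elements. Heuristic: treat CA/CL... as element only when
        # the raw name is exactly the element (typical for HETATM ions).
        if stripped.upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
            return stripped.capitalize()
    return core[0].upper() if core else "X"


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str, int, str, str]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or " "
        resnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: "
                            f"{line.rstrip()!r}") from exc
    if not element:
        element = _guess_element(name)
    atom = Atom(serial, name, element, np.array([x, y, z]),
                occupancy=occ, bfactor=bfac, altloc=altloc)
    return atom, resname, resnum, icode, chain_id


def _resolve_altlocs(residues: list[Residue]) -> None:
    """Keep the highest-occupancy altloc conformer, ties by letter order."""
    for res in residues:
        by_name: dict[str, list[Atom]] = {}
        for a in res.atoms:
            by_name.setdefault(a.name, []).append(a)
        kept: list[Atom] = []
        for a in res.atoms:
            group = by_name[a.name]
            if len(group) == 1:
                kept.append(a)
                continue
            best = min(group, key=lambda g: (-g.occupancy, g.altloc))
            if a is best:
                a.altloc = ""
                kept.append(a)
        res.atoms = kept


def read_pdb(path, keep_het: bool = True) -> Structure:
    """Read a PDB file into a Structure.

    Coordinates keep the format's 0.001 Å precision. Alternate locations are
    collapsed to the highest-occupancy conformer (ties broken by altloc
    letter). MODEL/ENDMDL records split the file into multiple models.

    Parameters
    ----------
    path : str or Path
        PDB file with at least one ATOM/HETATM record.
    keep_het : bool
        If False, HETATM records are dropped.
    """
    models: list[list[Residue]] = []
    current: list[Residue] = []
    cur_res: Residue | None = None
    pdb_id = ""
    in_model = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "HEADER":
                pdb_id = line[62:66].strip()
            elif rec == "MODEL ":
                in_model = True
                current, cur_res = [], None
            elif rec == "ENDMDL":
                if current:
                    models.append(current)
                current, cur_res = [], None
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                if rec == "HETATM" and not keep_het:
                    continue
                atom, resname, resnum, icode, chain = \
                    _parse_atom_line(line, lineno)
                if (cur_res is None
                        or cur_res.id != (chain, resnum, icode)
                        or cur_res.resname != resname):
                    cur_res = Residue(chain, resnum, resname, [], icode)
                    current.append(cur_res)
                cur_res.atoms.append(atom)

    if current and not in_model:
        models.append(current)
    elif current:  # MODEL without ENDMDL before EOF
        models.append(current)

    if not models or not any(m for m in models):
        raise PDBParseError(f"empty structure: no ATOM/HETATM records in {path}")
    for m in models:
        _resolve_altlocs(m)
    return Structure(models, pdb_id=pdb_id)


# ---------------------------------------------------------------------------
# PDB writing

def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise ValueError(f"atom name {name!r} longer than 4 characters")
    # single-letter elements start in column 14 unless the name fills 4 cols
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_record(a: Atom, res: Residue, hetatm: bool) -> str:
    rec = "HETATM" if hetatm else "ATOM  "
    name = _format_atom_name(a.name, a.element)
    return (f"{rec}{a.serial:>5d} {name}{a.altloc or ' '}"
            f"{res.resname:>3s} {res.chain_id:1s}{res.resnum:>4d}"
            f"{res.icode or ' '}   "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.bfactor:6.2f}          "
            f"{a.element:>2s}")


def write_pdb(s: Structure, path, renumber_serials: bool = True) -> None:
    """Write fixed-width PDB records; TER between chains, MODEL/ENDMDL for
    multi-model structures. Non-standard residue names (e.g. BPA) are
    written verbatim."""
    multi = len(s.models) > 1
    lines: list[str] = []
    for imodel, model in enumerate(s.models, start=1):
        if multi:
            lines.append(f"MODEL {imodel:>8d}")
        serial = 0
        prev_chain: str | None = None
        for res in model:
            if prev_chain is not None and res.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = res.chain_id
            hetatm = res.resname in WATER_RESNAMES
            for a in res.atoms:
                serial += 1
                out = a if not renumber_serials else replace(a, serial=serial)
                lines.append(_atom_record(out, res, hetatm))
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_xyz_trajectory(traj: Trajectory, path) -> None:
    """Write a Trajectory as a plain multi-frame XYZ file."""
    elements = [a.element for a in traj.topology.atoms()]
    with open(path, "w") as fh:
        for idx, frame in zip(traj.frame_index, traj.frames):
            fh.write(f"{len(elements)}\n")
            fh.write(f"frame {idx}\n")
            for el, xyz in zip(elements, frame):
                fh.write(f"{el:<2s} {xyz[0]:12.6f} {xyz[1]:12.6f} "
                         f"{xyz[2]:12.6f}\n")


# ---------------------------------------------------------------------------
# solvent / ion stripping

def strip_solvent_ions(s: Structure) -> Structure:
    """Remove water residues (HOH/WAT) and monoatomic ion residues.

    Protein atoms are untouched; an all-solvent input yields an empty model
    with a warning rather than an error.
    """
    out_models: list[list[Residue]] = []
    for model in s.models:
        kept = [r.copy() for r in model
                if r.resname not in WATER_RESNAMES and len(r.atoms) > 1]
        out_models.append(kept)
    if not any(out_models):
        warnings.warn("strip_solvent_ions: nothing left after stripping",
                      stacklevel=2)
    return Structure(out_models, pdb_id=s.pdb_id)


# ---------------------------------------------------------------------------
# trajectory reading

def _read_xyz_frames(path) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"XYZ: expected atom count at line {i + 1}") \
                from exc
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise ValueError(f"XYZ: truncated frame starting at line {i + 1}")
        coords = np.array([[float(v) for v in ln.split()[1:4]]
                           for ln in block])
        frames.append(coords)
        i += 2 + n
    return frames


def read_trajectory(topology_path, traj_path, format: str = "multimodel-pdb"
                    ) -> Trajectory:
    """Load a trajectory against a topology PDB.

    ``format`` is ``"multimodel-pdb"`` (MODEL/ENDMDL frames) or ``"xyz"``
    (plain multi-frame XYZ). Every frame must match the topology atom count.
    """
    topo_full = read_pdb(topology_path)
    topology = Structure([topo_full.models[0]], pdb_id=topo_full.pdb_id)
    n = topology.n_atoms

    if format == "multimodel-pdb":
        multi = read_pdb(traj_path)
        frames = [np.array([a.xyz for r in m for a in r.atoms])
                  for m in multi.models]
    elif format == "xyz":
        frames = _read_xyz_frames(traj_path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")

    for i, f in enumerate(frames):
        if f.shape[0] != n:
            raise ValueError(f"frame {i}: atom count {f.shape[0]} does not "
                             f"match topology ({n})")
    return Trajectory(topology, frames)
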