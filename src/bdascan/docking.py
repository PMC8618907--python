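"""Docking-engine contract: external Vina adapter, builtin grid scan, replay.

Blind fragment docking against the cavity-scan structures is normally run
with an AutoDock-Vina-compatible executable. The ``builtin`` engine is a
deliberately simple, fully deterministic rigid grid scan (lattice ×
fixed rotation set, contact-count score) so the whole pipeline is testable
at desk scale against a brute-force oracle; it is not a Vina
re-implementation. The ``replay`` engine feeds previously computed poses
(a Vina output PDBQT) back into the pipeline.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from bdascan.boronchem import FragmentProbe
from bdascan.structio import Structure, strip_solvent_ions

__all__ = [
    "GridBox", "DockingPose", "dock", "builtin_grid_scan",
    "parse_vina_pdbqt", "score_placement", "write_receptor_pdbqt",
    "PAPER_GRID_BOX",
]

# default engine parameters mirror a standard blind-docking setup
DEFAULT_ENERGY_RANGE = 4.0
DEFAULT_NUM_MODES = 20

# contact-score shells of the builtin engine (Å)
CONTACT_MIN, CONTACT_MAX, CLASH_DIST = 3.0, 4.5, 2.5
CONTACT_REWARD, CLASH_PENALTY = -1.0, 10.0


@dataclass
class GridBox:
    """Axis-aligned search box: center and edge lengths in Å."""

    center: np.ndarray
    size: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.size = np.asarray(self.size, dtype=float)
        if self.center.shape != (3,) or self.size.shape != (3,):
            raise ValueError("center and size must be 3-vectors")
        if np.any(self.size <= 0):
            raise ValueError("box sizes must be > 0")

    @property
    def lo(self) -> np.ndarray:
        return self.center - self.size / 2.0

    @property
    def hi(self) -> np.ndarray:
        return self.center + self.size / 2.0

    def contains(self, coords: np.ndarray, tol: float = 0.0) -> bool:
        c = np.atleast_2d(coords)
        return bool(np.all(c >= self.lo - tol) and np.all(c <= self.hi + tol))


# the cetuximab case-study blind-docking box
PAPER_GRID_BOX = GridBox(center=np.array([32.771, 37.27, 32.376]),
                         size=np.array([56.0, 64.0, 88.0]))


@dataclass
class DockingPose:
    probe_name: str
    mode_rank: int
    affinity: float          # kcal/mol for real engines; contact score builtin
    coords: np.ndarray       # (n_probe_atoms, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)


def _sort_and_rank(probe_name: str, scored: list[tuple[float, np.ndarray]]
                   ) -> list[DockingPose]:
    poses = []
    for rank, (aff, coords) in enumerate(
            sorted(scored, key=lambda t: t[0]), start=1):
        poses.append(DockingPose(probe_name, rank, float(aff), coords))
    return poses


# ---------------------------------------------------------------------------
# builtin deterministic engine


def rotation_set(n: int) -> list[Rotation]:
    """Fixed deterministic rotation set: identity plus axis–angle pairs from
    a Fibonacci sphere of axes and a golden-ratio angle sequence."""
    if n < 1:
        raise ValueError("rotation set size must be >= 1")
    rots = [Rotation.identity()]
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i in range(1, n):
        z = 1.0 - 2.0 * i / max(n - 1, 1)
        z = np.clip(z, -1.0, 1.0)
        r = np.sqrt(max(0.0, 1.0 - z * z))
        phi = golden * i
        axis = np.array([r * np.cos(phi), r * np.sin(phi), z])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.array([0.0, 0.0, 1.0])
        angle = golden * i % (2.0 * np.pi)
        rots.append(Rotation.from_rotvec(axis / np.linalg.norm(axis) * angle))
    return rots


def score_placement(probe_heavy: np.ndarray, receptor_tree: cKDTree) -> float:
    """Contact score of one rigid placement: −1 per receptor heavy atom in
    the [3.0, 4.5] Å shell of a probe heavy atom, +10 per receptor heavy
    atom closer than 2.5 Å."""
    score = 0.0
    data = receptor_tree.data
    for p in probe_heavy:
        near = receptor_tree.query_ball_point(p, CONTACT_MAX)
        if not near:
            continue
        d = np.linalg.norm(data[near] - p, axis=1)
        score += CONTACT_REWARD * int(np.sum(d >= CONTACT_MIN))
        score += CLASH_PENALTY * int(np.sum(d < CLASH_DIST))
    return score


def builtin_grid_scan(receptor: Structure, probe: FragmentProbe,
                      box: GridBox, step: float = 2.0,
                      rotations: int = 8,
                      num_modes: int = DEFAULT_NUM_MODES
                      ) -> list[DockingPose]:
    """Exhaustive rigid placement on a lattice × fixed rotation set.

    The probe (centered at its heavy-atom centroid) is placed at every
    lattice point with spacing ``step`` inside the box and every rotation
    of the deterministic set; each placement is contact-scored and the
    best ``num_modes`` kept. Ties break by enumeration order (lattice
    point, then rotation), so results are bitwise reproducible.
    """
    if step <= 0:
        raise ValueError("lattice step must be > 0")
    rec_coords = receptor.coords(heavy_only=True)
    tree = cKDTree(rec_coords)
    all_coords = probe.coords()
    heavy = probe.heavy_indices()
    centroid = all_coords[heavy].mean(axis=0)
    local = all_coords - centroid

    axes = [np.arange(box.lo[k], box.hi[k] + 1e-9, step) for k in range(3)]
    if any(len(ax) == 0 for ax in axes):
        raise ValueError("zero lattice points: box smaller than step")
    rots = rotation_set(rotations)
    rotated = [r.apply(local) for r in rots]

    scored: list[tuple[float, int, np.ndarray]] = []
    order = 0
    for x in axes[0]:
        for y in axes[1]:
            for z in axes[2]:
                point = np.array([x, y, z])
                for rl in rotated:
                    placed = rl + point
                    if not box.contains(placed[heavy], tol=2.0):
                        order += 1
                        continue
                    s = score_placement(placed[heavy], tree)
                    scored.append((s, order, placed))
                    order += 1
    scored.sort(key=lambda t: (t[0], t[1]))
    top = scored[:num_modes]
    return [DockingPose(probe.name, rank, float(s), c)
            for rank, (s, _, c) in enumerate(top, start=1)]


# ---------------------------------------------------------------------------
# Vina output parsing / replay


def _pdbqt_model_coords(lines: list[str]) -> np.ndarray:
    coords = [[float(ln[30:38]), float(ln[38:46]), float(ln[46:54])]
              for ln in lines if ln[:6] in ("ATOM  ", "HETATM")]
    return np.array(coords).reshape(-1, 3)


def parse_vina_pdbqt(path, probe_name: str = "") -> list[DockingPose]:
    """Parse a Vina multi-model output PDBQT into poses.

    Affinity is the first numeric field of each model's
    ``REMARK VINA RESULT`` line; a model without one is an error.
    """
    with open(path) as fh:
        content = fh.read()
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for ln in content.splitlines():
        if ln.startswith("MODEL"):
            current = []
        elif ln.startswith("ENDMDL"):
            if current is not None:
                blocks.append(current)
            current = None
        elif current is not None:
            current.append(ln)
    if not blocks:
        raise ValueError(f"no MODEL records in {path}")
    poses = []
    for i, block in enumerate(blocks, start=1):
        affinity = None
        for ln in block:
            if ln.startswith("REMARK VINA RESULT"):
                affinity = float(ln.split(":")[-1].split()[0])
                break
        if affinity is None:
            raise ValueError(f"model {i}: missing 'REMARK VINA RESULT' line")
        coords = _pdbqt_model_coords(block)
        if coords.size == 0:
            raise ValueError(f"model {i}: no atom records")
        poses.append(DockingPose(probe_name, i, affinity, coords))
    poses.sort(key=lambda p: p.affinity)
    for rank, p in enumerate(poses, start=1):
        p.mode_rank = rank
    return poses


# ---------------------------------------------------------------------------
# external Vina-compatible adapter


_AUTODOCK_TYPE = {"C": "C", "N": "NA", "O": "OA", "S": "SA", "H": "HD",
                  "B": "C"}


def write_receptor_pdbqt(receptor: Structure, path) -> None:
    """Rigid-receptor PDBQT: solvent/ions stripped, zero charges, element
    -derived AutoDock types."""
    stripped = strip_solvent_ions(receptor)
    lines = []
    serial = 0
    for res in stripped.models[0]:
        for a in res.atoms:
            serial += 1
            at = _AUTODOCK_TYPE.get(a.element.upper(), a.element.upper())
            lines.append(
                f"ATOM  {serial:>5d} {a.name:<4s}{res.resname:>3s} "
                f"{res.chain_id:1s}{res.resnum:>4d}    "
                f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{a.occupancy:6.2f}{a.bfactor:6.2f}    "
                f"{0.0:6.3f} {at:<2s}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\nTER\n")


def run_vina(receptor: Structure, probe: FragmentProbe, box: GridBox,
             executable: str = "vina", workdir=".",
             energy_range: float = DEFAULT_ENERGY_RANGE,
             num_modes: int = DEFAULT_NUM_MODES,
             seed: int = 1, extra_args: list[str] | None = None
             ) -> list[DockingPose]:
    """Run an external AutoDock-Vina-compatible executable and parse its
    output. The seed is fixed for best-effort reproducibility."""
    from pathlib import Path

    from bdascan.boronchem import export_probe_pdbqt

    exe = shutil.which(executable)
    if exe is None:
        raise FileNotFoundError(
            f"docking executable {executable!r} not found on PATH; install "
            "AutoDock Vina or use engine='builtin' / engine='replay'")
    wd = Path(workdir)
    rec_path = wd / "receptor.pdbqt"
    lig_path = wd / f"{probe.name}.pdbqt"
    out_path = wd / f"{probe.name}_out.pdbqt"
    write_receptor_pdbqt(receptor, rec_path)
    export_probe_pdbqt(probe, lig_path)
    cmd = [exe, "--receptor", str(rec_path), "--ligand", str(lig_path),
           "--center_x", str(box.center[0]), "--center_y",
           str(box.center[1]), "--center_z", str(box.center[2]),
           "--size_x", str(box.size[0]), "--size_y", str(box.size[1]),
           "--size_z", str(box.size[2]),
           "--energy_range", str(energy_range),
           "--num_modes", str(num_modes), "--seed", str(seed),
           "--out", str(out_path)] + (extra_args or [])
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"docking engine failed (exit {proc.returncode}):"
                           f"\n{proc.stdout}\n{proc.stderr}")
    return parse_vina_pdbqt(out_path, probe.name)


def dock(receptor: Structure, probe: FragmentProbe, box: GridBox,
         engine: str = "builtin", params: dict | None = None
         ) -> list[DockingPose]:
    """Dispatch to a docking engine: ``builtin`` (deterministic grid scan),
    ``vina`` (external executable), or ``replay`` (previously computed
    poses from ``params['poses_path']``)."""
    params = params or {}
    if engine == "builtin":
        return builtin_grid_scan(
            receptor, probe, box,
            step=params.get("step", 2.0),
            rotations=params.get("rotations", 8),
            num_modes=params.get("num_modes", DEFAULT_NUM_MODES))
    if engine == "vina":
        return run_vina(receptor, probe, box, **params)
    if engine == "replay":
        path = params.get("poses_path")
        if path is None:
            raise ValueError("replay engine requires params['poses_path']")
        return parse_vina_pdbqt(path, probe.name)
    raise ValueError(f"unknown engine {engine!r}")
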