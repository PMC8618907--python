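"""Folding-evaluation analytics for WT vs boronated-mutant trajectory pairs.

Implements, from first principles, the four analyses used to judge whether a
boronated residue perturbs the antibody fold:

* least-squares rigid superposition (Kabsch) and per-frame RMSD,
* per-atom/per-residue RMSF about the superposed mean structure,
* geometric hydrogen-bond detection (donor–acceptor distance + D–H···A
  angle) and per-site H-bond network conservation,
* GROMOS-style leader clustering of frames on pairwise RMSD, with cluster
  populations and medoid representatives.

All functions operate on the :class:`~bdascan.structio.Trajectory` /
:class:`~bdascan.structio.Structure` data model; selections default to CA
atoms, the convention for backbone-fold comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from bdascan._geometry import angle_between
from bdascan.structio import Structure, Trajectory

__all__ = [
    "SuperpositionResult", "HBond", "HBondCriteria", "ClusterResult",
    "ComparisonReport", "kabsch", "select_atoms", "rmsd_series", "rmsf",
    "find_hbonds", "hbond_conservation", "cluster", "compare",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition: ref ≈ mov @ rotation.T + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(ref_coords: np.ndarray, mov_coords: np.ndarray,
           weights: np.ndarray | None = None) -> SuperpositionResult:
    """Weighted least-squares superposition of ``mov`` onto ``ref``.

    Returns the proper rotation (reflections corrected via the SVD
    determinant trick), translation, and the minimized RMSD. Requires at
    least 3 non-collinear points.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()

    ref_c = ref - (w[:, None] * ref).sum(axis=0)
    mov_c = mov - (w[:, None] * mov).sum(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference coordinates")

    h = (w[:, None] * mov_c).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = (w[:, None] * ref).sum(axis=0) - \
        rot @ (w[:, None] * mov).sum(axis=0)
    diff = mov_c @ rot.T - ref_c
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rot, trans, rmsd)


def select_atoms(structure: Structure, selection: str | np.ndarray = "CA",
                 chain_id: str | None = None) -> np.ndarray:
    """Atom indices for a selection: ``"CA"`` / ``"heavy"`` / ``"all"`` by
    name, or an explicit index array passed through."""
    if not isinstance(selection, str):
        return np.asarray(selection, dtype=int)
    idx = []
    i = 0
    for res in structure.models[0]:
        for a in res.atoms:
            if chain_id is None or res.chain_id == chain_id:
                if selection == "all":
                    idx.append(i)
                elif selection == "heavy" and not a.is_hydrogen:
                    idx.append(i)
                elif selection == "CA" and a.name == "CA":
                    idx.append(i)
            i += 1
    return np.array(idx, dtype=int)


def rmsd_series(traj: Trajectory, ref: Structure | np.ndarray | None = None,
                selection: str | np.ndarray = "CA",
                chain_id: str | None = None) -> np.ndarray:
    """Per-frame Kabsch-minimized RMSD (Å) against a reference structure
    (default: the trajectory topology)."""
    sel = select_atoms(traj.topology, selection, chain_id)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    if ref is None:
        ref_coords = traj.topology.coords()[sel]
    elif isinstance(ref, Structure):
        ref_coords = ref.coords()[sel]
    else:
        ref_coords = np.asarray(ref, dtype=float)[sel]
    return np.array([kabsch(ref_coords, f[sel]).rmsd for f in traj.frames])


def rmsf(traj: Trajectory, selection: str | np.ndarray = "CA",
         n_iter: int = 2) -> np.ndarray:
    """Per-selected-atom RMSF (Å): fluctuation about the mean structure
    after iteratively superposing all frames onto it (``n_iter`` rounds)."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = select_atoms(traj.topology, selection)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    coords = np.array([f[sel] for f in traj.frames])
    mean = coords.mean(axis=0)
    for _ in range(n_iter):
        coords = np.array([kabsch(mean, c).apply(c) for c in coords])
        mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


def rmsf_per_residue(traj: Trajectory, selection: str = "CA"
                     ) -> dict[tuple, float]:
    """RMSF keyed by residue id, averaged over the residue's selected atoms."""
    sel = select_atoms(traj.topology, selection)
    values = rmsf(traj, sel)
    res_of_atom = []
    i = 0
    for res in traj.topology.models[0]:
        for _ in res.atoms:
            res_of_atom.append(res.id)
            i += 1
    out: dict[tuple, list[float]] = {}
    for idx, val in zip(sel, values):
        out.setdefault(res_of_atom[idx], []).append(float(val))
    return {k: float(np.mean(v)) for k, v in out.items()}


# ---------------------------------------------------------------------------
# hydrogen bonds


@dataclass
class HBondCriteria:
    """Geometric H-bond definition.

    all-atom mode: donor(N/O with attached H)–acceptor(N/O) distance
    <= d_max and D–H···A angle >= angle_min. heavy mode: donor–acceptor
    distance alone (for H-free trajectories); angle_min is ignored there.
    """

    d_max: float = 3.0
    angle_min: float = 135.0
    mode: str = "all-atom"


@dataclass(frozen=True)
class HBond:
    donor: int
    acceptor: int
    distance: float
    angle: float
    hydrogen: int | None = None
    donor_res: tuple = ()
    acceptor_res: tuple = ()


_POLAR = {"N", "O"}


def _polar_inventory(topology: Structure, coords: np.ndarray):
    """Donor (with hydrogens) and acceptor atom indices, plus residue ids."""
    res_of_atom: list[tuple] = []
    atoms = []
    for res in topology.models[0]:
        for a in res.atoms:
            atoms.append(a)
            res_of_atom.append(res.id)
    n = len(atoms)
    polar = [i for i in range(n) if atoms[i].element.upper() in _POLAR]
    hydro = [i for i in range(n) if atoms[i].is_hydrogen]
    donors: dict[int, list[int]] = {}
    if hydro:
        htree = cKDTree(coords[hydro])
        for i in polar:
            near = htree.query_ball_point(coords[i], 1.25)
            hs = [hydro[j] for j in near
                  if res_of_atom[hydro[j]] == res_of_atom[i]]
            if hs:
                donors[i] = hs
    return polar, donors, res_of_atom


def find_hbonds(frame: np.ndarray | None, topology: Structure,
                criteria: HBondCriteria | None = None) -> list[HBond]:
    """Detect hydrogen bonds in one frame.

    ``frame`` is an (n_atoms, 3) coordinate array congruent with the
    topology (None uses the topology's own coordinates). Donors and
    acceptors are N/O atoms; boronic-acid hydroxyls participate like any
    other O–H donor and B–O oxygens as acceptors. Intra-residue pairs are
    excluded.
    """
    crit = criteria or HBondCriteria()
    coords = topology.coords() if frame is None else np.asarray(frame)
    polar, donors, res_of_atom = _polar_inventory(topology, coords)
    if not polar:
        return []
    tree = cKDTree(coords[polar])
    pairs = tree.query_pairs(crit.d_max)
    out: list[HBond] = []
    for pi, pj in sorted(pairs):
        i, j = polar[pi], polar[pj]
        if res_of_atom[i] == res_of_atom[j]:
            continue
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        for donor, acceptor in ((i, j), (j, i)):
            if crit.mode == "heavy":
                if donor == i:  # emit each heavy-mode pair once
                    out.append(HBond(donor, acceptor, dist, float("nan"),
                                     None, res_of_atom[donor],
                                     res_of_atom[acceptor]))
                continue
            best = None
            for h in donors.get(donor, []):
                ang = angle_between(coords[donor] - coords[h],
                                    coords[acceptor] - coords[h])
                if ang >= crit.angle_min and \
                        (best is None or ang > best[1]):
                    best = (h, ang)
            if best is not None:
                out.append(HBond(donor, acceptor, dist, best[1], best[0],
                                 res_of_atom[donor], res_of_atom[acceptor]))
    return out


def hbond_partners(traj: Trajectory, site: tuple,
                   criteria: HBondCriteria | None = None,
                   occupancy_min: float = 0.1) -> set[tuple]:
    """Residues H-bonded to ``site`` in >= occupancy_min of frames."""
    counts: dict[tuple, int] = {}
    found_site = any(res.id == site for res in traj.topology.models[0])
    if not found_site:
        raise KeyError(f"site {site} not present in topology")
    for frame in traj.frames:
        seen: set[tuple] = set()
        for hb in find_hbonds(frame, traj.topology, criteria):
            if hb.donor_res == site:
                seen.add(hb.acceptor_res)
            elif hb.acceptor_res == site:
                seen.add(hb.donor_res)
        for p in seen:
            counts[p] = counts.get(p, 0) + 1
    nmin = occupancy_min * traj.n_frames
    return {p for p, c in counts.items() if c >= nmin}


def hbond_conservation(wt_traj: Trajectory, mut_traj: Trajectory,
                       site: tuple,
                       criteria: HBondCriteria | None = None,
                       occupancy_min: float = 0.1
                       ) -> tuple[float, set[tuple], set[tuple]]:
    """Fraction of the WT site's H-bond partner residues retained by the
    mutant (1.0 when the WT site makes no persistent H-bonds).

    Returns (conservation, wt_partner_set, mut_partner_set).
    """
    wt = hbond_partners(wt_traj, site, criteria, occupancy_min)
    mut = hbond_partners(mut_traj, site, criteria, occupancy_min)
    conservation = 1.0 if not wt else len(wt & mut) / len(wt)
    return conservation, wt, mut


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    labels: np.ndarray
    populations: np.ndarray
    representative_frames: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def pairwise_rmsd(traj: Trajectory, selection: str | np.ndarray = "CA"
                  ) -> np.ndarray:
    """Symmetric matrix of Kabsch RMSD between every pair of frames."""
    sel = select_atoms(traj.topology, selection)
    coords = [f[sel] for f in traj.frames]
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch(coords[i], coords[j]).rmsd
    return mat


def cluster(traj: Trajectory, selection: str | np.ndarray = "CA",
            cutoff: float = 1.5) -> ClusterResult:
    """GROMOS-style leader clustering on pairwise Kabsch RMSD.

    Iteratively takes the unassigned frame with the most unassigned
    neighbors within ``cutoff`` as a cluster medoid (ties broken by lowest
    frame index), assigns it and its neighbors, and repeats.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    mat = pairwise_rmsd(traj, selection)
    n = mat.shape[0]
    labels = np.full(n, -1, dtype=int)
    reps: list[int] = []
    remaining = np.ones(n, dtype=bool)
    cid = 0
    while remaining.any():
        neighbor = (mat <= cutoff) & remaining[None, :]
        counts = np.where(remaining, neighbor.sum(axis=1), -1)
        leader = int(np.argmax(counts))  # argmax takes lowest index on ties
        members = np.where(neighbor[leader] & remaining)[0]
        labels[members] = cid
        labels[leader] = cid
        remaining[members] = False
        remaining[leader] = False
        reps.append(leader)
        cid += 1
    populations = np.array([(labels == c).sum() / n for c in range(cid)])
    return ClusterResult(labels, populations, reps)


# ---------------------------------------------------------------------------
# WT vs mutant comparison


@dataclass
class ComparisonReport:
    """Side-by-side folding metrics for a WT / mutant trajectory pair."""

    rmsd_wt: np.ndarray
    rmsd_mut: np.ndarray
    rmsd_mean_wt: float
    rmsd_mean_mut: float
    rmsd_std_wt: float
    rmsd_std_mut: float
    rmsf_wt: dict[tuple, float]
    rmsf_mut: dict[tuple, float]
    rmsf_delta: dict[tuple, float]
    hbond_counts_wt: list[int]
    hbond_counts_mut: list[int]
    top_cluster_population_wt: float
    top_cluster_population_mut: float
    representative_rmsd: float
    site: tuple | None = None
    hbond_conservation: float | None = None
    hbond_partners_wt: set = field(default_factory=set)
    hbond_partners_mut: set = field(default_factory=set)


def compare(wt_traj: Trajectory, mut_traj: Trajectory,
            site: tuple | None = None,
            selection: str = "CA",
            hbond_criteria: HBondCriteria | None = None,
            cluster_cutoff: float = 1.5,
            occupancy_min: float = 0.1) -> ComparisonReport:
    """Assemble the full WT-vs-mutant folding comparison: RMSD series,
    per-residue RMSF and deltas, per-frame H-bond counts, site H-bond
    conservation, top cluster populations, and the RMSD between the two
    top-cluster representative structures."""
    rmsd_wt = rmsd_series(wt_traj, None, selection)
    rmsd_mut = rmsd_series(mut_traj, None, selection)
    rmsf_wt = rmsf_per_residue(wt_traj, selection)
    rmsf_mut = rmsf_per_residue(mut_traj, selection)
    delta = {k: rmsf_mut.get(k, float("nan")) - v
             for k, v in rmsf_wt.items()}
    hb_wt = [len(find_hbonds(f, wt_traj.topology, hbond_criteria))
             for f in wt_traj.frames]
    hb_mut = [len(find_hbonds(f, mut_traj.topology, hbond_criteria))
              for f in mut_traj.frames]
    cl_wt = cluster(wt_traj, selection, cluster_cutoff)
    cl_mut = cluster(mut_traj, selection, cluster_cutoff)
    top_wt = int(np.argmax(cl_wt.populations))
    top_mut = int(np.argmax(cl_mut.populations))
    sel_wt = select_atoms(wt_traj.topology, selection)
    sel_mut = select_atoms(mut_traj.topology, selection)
    rep_wt = wt_traj.frames[cl_wt.representative_frames[top_wt]][sel_wt]
    rep_mut = mut_traj.frames[cl_mut.representative_frames[top_mut]][sel_mut]
    rep_rmsd = kabsch(rep_wt, rep_mut).rmsd \
        if rep_wt.shape == rep_mut.shape else float("nan")

    conservation = None
    partners_wt: set = set()
    partners_mut: set = set()
    if site is not None:
        conservation, partners_wt, partners_mut = hbond_conservation(
            wt_traj, mut_traj, site, hbond_criteria, occupancy_min)

    return ComparisonReport(
        rmsd_wt=rmsd_wt, rmsd_mut=rmsd_mut,
        rmsd_mean_wt=float(rmsd_wt.mean()),
        rmsd_mean_mut=float(rmsd_mut.mean()),
        rmsd_std_wt=float(rmsd_wt.std()),
        rmsd_std_mut=float(rmsd_mut.std()),
        rmsf_wt=rmsf_wt, rmsf_mut=rmsf_mut, rmsf_delta=delta,
        hbond_counts_wt=hb_wt, hbond_counts_mut=hb_mut,
        top_cluster_population_wt=float(cl_wt.populations[top_wt]),
        top_cluster_population_mut=float(cl_mut.populations[top_mut]),
        representative_rmsd=float(rep_rmsd),
        site=site, hbond_conservation=conservation,
        hbond_partners_wt=partners_wt, hbond_partners_mut=partners_mut,
    )
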