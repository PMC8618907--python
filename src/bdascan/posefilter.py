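"""Geometric pose evaluation: cavity assignment, distance, directionality,
clash, verdict.

A docked fragment pose is accepted for a candidate site only if it truly
re-occupies the vacated side-chain volume with the boron pointing outward
the way the native terminus did: the pose must lie inside the site's
cavity, its B-bearing carbon must sit close to the native reference carbon,
the angle between the native side-chain vector (CB→CZ for Phe/Tyr) and the
probe's ligand vector (para ring atom→B) must be small, and the pose must
not clash sterically with the mutated receptor. A pose pointing the
opposite way (angle near 180°) is the canonical rejection mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from bdascan._geometry import angle_between
from bdascan.boronchem import FragmentProbe
from bdascan.docking import DockingPose
from bdascan.mutagenesis import MutationSite
from bdascan.structio import Residue, Structure

__all__ = [
    "VectorMapping", "FilterThresholds", "PoseEvaluation",
    "DEFAULT_MAPPINGS", "VDW_RADII", "assign_pose_to_site",
    "directionality_angle", "reference_distance", "clash_count",
    "evaluate_and_rank",
]

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "B": 1.92,
             "H": 1.10}
_DEFAULT_VDW = 1.70


@dataclass(frozen=True)
class VectorMapping:
    """Atom-name pairs defining the geometric references for one residue
    type.

    ``residue_vector`` runs tail→head along the native side chain (the
    head may name two atoms joined by ``|``, meaning their midpoint);
    ``probe_vector`` runs from the ring atom opposite the boron to the
    boron; ``reference_carbon_pair`` is (native atom, probe atom) for the
    distance criterion.
    """

    residue_vector: tuple[str, str]
    probe_vector: tuple[str, str] | None
    reference_carbon_pair: tuple[str, str]


# probe_vector None means "use the probe's own ligand_vector" (tail ring
# atom opposite the boron → boron), which adapts across the three probes
DEFAULT_MAPPINGS: dict[str, VectorMapping] = {
    "PHE": VectorMapping(("CB", "CZ"), None, ("CZ", "C1")),
    "TYR": VectorMapping(("CB", "CZ"), None, ("CZ", "C1")),
    "TRP": VectorMapping(("CB", "CZ2"), None, ("CZ2", "C1")),
    "HIS": VectorMapping(("CB", "NE2|CE1"), None, ("CE1", "C1")),
}


@dataclass
class FilterThresholds:
    """Acceptance thresholds; a pose passes only if it meets all of them."""

    d_max: float = 2.0          # Å, reference-carbon distance
    theta_max: float = 60.0     # deg, directionality angle
    r_cavity: float = 5.0       # Å, pose-centroid to cavity-centroid
    overlap_factor: float = 0.6  # fraction of summed vdW radii


@dataclass
class PoseEvaluation:
    site: MutationSite | None
    pose: DockingPose
    distance: float
    angle: float
    clash_count: int
    inside_cavity: bool
    verdict: str                 # "accept" | "reject"
    reasons: list[str] = field(default_factory=list)

    @property
    def affinity(self) -> float:
        return self.pose.affinity


def _residue_point(res: Residue, name: str) -> np.ndarray:
    if "|" in name:
        parts = name.split("|")
        return np.mean([res.atom(p).xyz for p in parts], axis=0)
    return res.atom(name).xyz


def assign_pose_to_site(pose: DockingPose, probe: FragmentProbe,
                        sites: list[MutationSite],
                        r_cavity: float = 5.0) -> MutationSite | None:
    """Nearest site by pose heavy-atom centroid to cavity centroid, or None
    if even the nearest is farther than ``r_cavity`` (pose outside all
    cavities)."""
    if not sites:
        raise ValueError("no sites to assign against")
    centroid = pose.coords[probe.heavy_indices()].mean(axis=0)
    dists = [float(np.linalg.norm(centroid - s.sidechain_centroid))
             for s in sites]
    best = int(np.argmin(dists))
    return sites[best] if dists[best] <= r_cavity else None


def directionality_angle(native: Residue, pose: DockingPose,
                         probe: FragmentProbe,
                         mapping: VectorMapping) -> float:
    """Angle (deg, [0, 180]) between the native side-chain vector and the
    probe's ligand vector in this pose; ~0° means the boron points the way
    the native terminus did, ~180° the opposite way."""
    r_tail = _residue_point(native, mapping.residue_vector[0])
    r_head = _residue_point(native, mapping.residue_vector[1])
    pv = mapping.probe_vector or probe.ligand_vector
    p_tail = pose.coords[probe.atom_index(pv[0])]
    p_head = pose.coords[probe.atom_index(pv[1])]
    return angle_between(r_head - r_tail, p_head - p_tail)


def reference_distance(native: Residue, pose: DockingPose,
                       probe: FragmentProbe,
                       mapping: VectorMapping) -> float:
    """Euclidean distance (Å) between the native reference carbon and the
    corresponding probe carbon."""
    nat = _residue_point(native, mapping.reference_carbon_pair[0])
    prb = pose.coords[probe.atom_index(mapping.reference_carbon_pair[1])]
    return float(np.linalg.norm(nat - prb))


def clash_count(pose: DockingPose, probe: FragmentProbe,
                mutated_structure: Structure,
                overlap_factor: float = 0.6) -> int:
    """Number of (probe heavy atom, receptor heavy atom) pairs closer than
    ``overlap_factor`` × the sum of their van der Waals radii. The mutated
    sites' retained stubs count like any other receptor atom."""
    rec_atoms = [a for r in mutated_structure.models[0]
                 for a in r.heavy_atoms()]
    if not rec_atoms:
        return 0
    rec_coords = np.array([a.xyz for a in rec_atoms])
    rec_radii = np.array([VDW_RADII.get(a.element.upper(), _DEFAULT_VDW)
                          for a in rec_atoms])
    tree = cKDTree(rec_coords)
    count = 0
    max_reach = overlap_factor * (rec_radii.max() + max(VDW_RADII.values()))
    for idx in probe.heavy_indices():
        p = pose.coords[idx]
        r_p = VDW_RADII.get(probe.atoms[idx].element.upper(), _DEFAULT_VDW)
        for j in tree.query_ball_point(p, max_reach):
            cutoff = overlap_factor * (r_p + rec_radii[j])
            if np.linalg.norm(p - rec_coords[j]) < cutoff:
                count += 1
    return count


def evaluate_pose(pose: DockingPose, probe: FragmentProbe,
                  sites: list[MutationSite],
                  mutated_structure: Structure,
                  native_structure: Structure,
                  mappings: dict[str, VectorMapping] | None = None,
                  thresholds: FilterThresholds | None = None
                  ) -> PoseEvaluation:
    """Evaluate one pose: cavity assignment, distance, angle, clash, and
    the verdict with its rejection reasons."""
    mappings = mappings or DEFAULT_MAPPINGS
    th = thresholds or FilterThresholds()
    site = assign_pose_to_site(pose, probe, sites, th.r_cavity)
    reasons: list[str] = []
    if site is None:
        return PoseEvaluation(None, pose, float("nan"), float("nan"),
                              0, False, "reject", ["outside_cavity"])
    native = native_structure.get_residue(site.chain_id, site.resnum,
                                          site.icode)
    mapping = mappings[site.original_resname]
    dist = reference_distance(native, pose, probe, mapping)
    ang = directionality_angle(native, pose, probe, mapping)
    clashes = clash_count(pose, probe, mutated_structure,
                          th.overlap_factor)
    if dist > th.d_max:
        reasons.append("distance")
    if ang > th.theta_max:
        reasons.append("directionality")
    if clashes > 0:
        reasons.append("clash")
    verdict = "accept" if not reasons else "reject"
    return PoseEvaluation(site, pose, dist, ang, clashes, True, verdict,
                          reasons)


def evaluate_and_rank(poses: list[DockingPose], probe: FragmentProbe,
                      sites: list[MutationSite],
                      mutated_structure: Structure,
                      native_structure: Structure,
                      mappings: dict[str, VectorMapping] | None = None,
                      thresholds: FilterThresholds | None = None
                      ) -> tuple[list[PoseEvaluation],
                                 dict[tuple, PoseEvaluation]]:
    """Evaluate every pose and pick each site's champion — the accepted
    pose with the best (lowest) affinity.

    Returns (evaluations sorted by site then pose rank, with unassigned
    poses last; champions keyed by site residue id).
    """
    evals = [evaluate_pose(p, probe, sites, mutated_structure,
                           native_structure, mappings, thresholds)
             for p in poses]
    site_order = {s.residue_id: i for i, s in enumerate(sites)}
    evals.sort(key=lambda e: (
        site_order.get(e.site.residue_id, len(site_order))
        if e.site else len(site_order),
        e.pose.mode_rank))
    champions: dict[tuple, PoseEvaluation] = {}
    for e in evals:
        if e.verdict != "accept" or e.site is None:
            continue
        key = e.site.residue_id
        if key not in champions or e.affinity < champions[key].affinity:
            champions[key] = e
    return evals, champions
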