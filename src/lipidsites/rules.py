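"""Heuristic scoring of candidate cardiolipin sites on a membrane-oriented
structure.

The three-part signature of a high-affinity CDL site on a bacterial
membrane protein:

1. two to three basic residues (Arg/Lys) in close proximity — pairwise
   within 0.8 nm, within ~0.3 nm of each other along z, about 1.8 nm from
   the membrane centre (they coordinate the two CDL phosphates);
2. at least one polar residue (Ser, Thr or His), stabilizing the central
   glycerol;
3. one or more aromatic residues slightly deeper in the membrane,
   coordinating the tail-connecting glycerols.

All thresholds live in :class:`RuleParams` so audits can be re-run under
variants. Gly in the candidate is reported as a bonus annotation, not a
rule. Coordinates must be in the membrane frame (centre at z = 0); scores
depend only on pairwise distances and |z|, so they are invariant under
rotation about z and translation in x/y.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np

from .core import AROMATIC_RESIDUES, BASIC_RESIDUES, POLAR_RESIDUES, SystemTopology

__all__ = [
    "ResiduePoint",
    "RuleParams",
    "RuleReport",
    "score_cdl_site",
    "scan_structure",
    "residue_points_from_topology",
]


class ResiduePoint(NamedTuple):
    """A residue reduced to its backbone-bead position (nm, membrane frame)."""

    residue_id: int
    name: str
    chain: str
    xyz: np.ndarray


@dataclass(frozen=True)
class RuleParams:
    """Thresholds of the three-rule heuristic (all lengths nm)."""

    adjacency_cutoff: float = 0.8  # max pairwise distance in the basic cluster
    z_tolerance: float = 0.3  # max pairwise |Δz| in the basic cluster
    depth_center: float = 1.8  # target |z| of the basic cluster
    depth_halfwidth: float = 0.5  # tolerance band around depth_center
    aromatic_depth_margin: float = 0.2  # how much deeper the aromatic must sit
    expansion_radius: float = 1.0  # candidate growth around the basic cluster
    include_tyr: bool = True
    basic: frozenset = BASIC_RESIDUES
    polar: frozenset = POLAR_RESIDUES

    @property
    def aromatic(self) -> frozenset:
        return AROMATIC_RESIDUES if self.include_tyr else frozenset({"PHE", "TRP"})

    @property
    def depth_band(self) -> tuple[float, float]:
        return (
            self.depth_center - self.depth_halfwidth,
            self.depth_center + self.depth_halfwidth,
        )


@dataclass
class RuleReport:
    """Pass/fail plus measured geometry for each rule on one candidate."""

    residue_ids: frozenset[int]
    rule1_basics: bool = False
    n_basics_in_cluster: int = 0
    cluster_residues: tuple[int, ...] = ()
    max_pairwise_distance: float = float("nan")
    max_z_separation: float = float("nan")
    mean_depth: float = float("nan")  # mean |z - membrane centre| of the cluster
    rule2_polar: bool = False
    polar_residues: tuple[int, ...] = ()
    rule3_aromatic: bool = False
    aromatic_residues: tuple[tuple[int, float], ...] = ()  # (residue_id, |z|)
    has_gly: bool = False  # bonus annotation, not a rule

    @property
    def overall(self) -> int:
        return int(self.rule1_basics) + int(self.rule2_polar) + int(self.rule3_aromatic)

    def to_dict(self) -> dict:
        return {
            "residue_ids": sorted(self.residue_ids),
            "rule1_basics": self.rule1_basics,
            "n_basics_in_cluster": self.n_basics_in_cluster,
            "cluster_residues": list(self.cluster_residues),
            "max_pairwise_distance_nm": self.max_pairwise_distance,
            "max_z_separation_nm": self.max_z_separation,
            "mean_depth_nm": self.mean_depth,
            "rule2_polar": self.rule2_polar,
            "polar_residues": list(self.polar_residues),
            "rule3_aromatic": self.rule3_aromatic,
            "aromatic_residues": [list(a) for a in self.aromatic_residues],
            "has_gly": self.has_gly,
            "overall": self.overall,
        }


def _cluster_geometry(points: Sequence[ResiduePoint], center_z: float):
    xyz = np.array([p.xyz for p in points])
    dmax = max(
        float(np.linalg.norm(a - b)) for a, b in combinations(xyz, 2)
    )
    dzmax = max(float(abs(a[2] - b[2])) for a, b in combinations(xyz, 2))
    depth = float(np.mean(np.abs(xyz[:, 2] - center_z)))
    return dmax, dzmax, depth


def _qualifying_clusters(
    basics: Sequence[ResiduePoint], params: RuleParams, center_z: float
) -> list[tuple[ResiduePoint, ...]]:
    """All basic pairs and triples satisfying the rule-1 geometry."""
    out = []
    for size in (2, 3):
        for combo in combinations(basics, size):
            dmax, dzmax, depth = _cluster_geometry(combo, center_z)
            lo, hi = params.depth_band
            if (
                dmax < params.adjacency_cutoff
                and dzmax <= params.z_tolerance
                and lo <= depth <= hi
            ):
                out.append(combo)
    return out


def score_cdl_site(
    candidate: Sequence[ResiduePoint],
    membrane_center_z: float = 0.0,
    params: RuleParams | None = None,
) -> RuleReport:
    """Evaluate the three CDL-site rules on one candidate residue set.

    Rule 1 passes when ≥ 2 basics form a cluster with pairwise distance
    below the adjacency cutoff, pairwise |Δz| within the z tolerance and
    mean depth inside the depth band; the reported cluster is the largest
    qualifying one (most compact on ties). Rule 3 measures aromatic depth
    against the rule-1 cluster (or, failing that, the mean depth of all
    basics present).
    """
    params = params or RuleParams()
    candidate = list(candidate)
    if not candidate:
        raise ValueError("empty candidate")
    for p in candidate:
        if p.xyz is None or len(p.xyz) != 3:
            raise ValueError(f"residue {p.residue_id} lacks coordinates")
    cz = membrane_center_z
    basics = [p for p in candidate if p.name in params.basic]
    report = RuleReport(residue_ids=frozenset(p.residue_id for p in candidate))
    report.has_gly = any(p.name == "GLY" for p in candidate)

    clusters = _qualifying_clusters(basics, params, cz)
    if clusters:
        best = max(
            clusters,
            key=lambda c: (len(c), -_cluster_geometry(c, cz)[0]),
        )
        dmax, dzmax, depth = _cluster_geometry(best, cz)
        report.rule1_basics = True
        report.n_basics_in_cluster = len(best)
        report.cluster_residues = tuple(sorted(p.residue_id for p in best))
        report.max_pairwise_distance = dmax
        report.max_z_separation = dzmax
        report.mean_depth = depth
        ref_depth = depth
    elif len(basics) >= 2:
        # rule fails, but report the closest pair's geometry
        pair = min(
            combinations(basics, 2),
            key=lambda c: _cluster_geometry(c, cz)[0],
        )
        dmax, dzmax, depth = _cluster_geometry(pair, cz)
        report.n_basics_in_cluster = 0
        report.max_pairwise_distance = dmax
        report.max_z_separation = dzmax
        report.mean_depth = depth
        ref_depth = float(np.mean([abs(p.xyz[2] - cz) for p in basics]))
    elif basics:
        ref_depth = abs(basics[0].xyz[2] - cz)
        report.mean_depth = ref_depth
    else:
        ref_depth = float("nan")

    polar = tuple(sorted(p.residue_id for p in candidate if p.name in params.polar))
    report.polar_residues = polar
    report.rule2_polar = bool(polar)

    aromatics = [
        (p.residue_id, float(abs(p.xyz[2] - cz)))
        for p in candidate
        if p.name in params.aromatic
    ]
    report.aromatic_residues = tuple(sorted(aromatics))
    if aromatics and np.isfinite(ref_depth):
        report.rule3_aromatic = any(
            depth < ref_depth - params.aromatic_depth_margin
            for _, depth in aromatics
        )
    return report


def residue_points_from_topology(
    topo: SystemTopology, coords: np.ndarray
) -> list[ResiduePoint]:
    """Backbone-bead residue points from a topology + static coordinates."""
    return [
        ResiduePoint(r.residue_id, r.name, r.chain, np.asarray(coords[r.bb_bead], float))
        for r in topo.residues
    ]


def scan_structure(
    points: Sequence[ResiduePoint],
    membrane_center_z: float = 0.0,
    params: RuleParams | None = None,
) -> list[RuleReport]:
    """Enumerate and score candidate CDL sites on a whole structure.

    Every basic pair/triple satisfying the rule-1 geometry seeds a
    candidate, grown by all residues within the expansion radius of any
    cluster member; duplicates (same residue set) are scored once.
    Reports are sorted by rules passed (descending), then basic-cluster
    compactness, then residue ids — a deterministic ranking. An empty
    result means no basic pair satisfies the rule-1 geometry.
    """
    params = params or RuleParams()
    points = list(points)
    basics = [p for p in points if p.name in params.basic]
    clusters = _qualifying_clusters(basics, params, membrane_center_z)
    seen: set[frozenset[int]] = set()
    reports: list[RuleReport] = []
    for cluster in clusters:
        members = list(cluster)
        cand_ids = set(p.residue_id for p in members)
        for p in points:
            if any(
                float(np.linalg.norm(p.xyz - m.xyz)) <= params.expansion_radius
                for m in members
            ):
                cand_ids.add(p.residue_id)
        key = frozenset(cand_ids)
        if key in seen:
            continue
        seen.add(key)
        cand = [p for p in points if p.residue_id in cand_ids]
        reports.append(score_cdl_site(cand, membrane_center_z, params))
    reports.sort(
        key=lambda r: (
            -r.overall,
            r.max_pairwise_distance if np.isfinite(r.max_pairwise_distance) else np.inf,
            tuple(sorted(r.residue_ids)),
        )
    )
    return reports
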