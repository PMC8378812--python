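"""Binding-site identification from dual-cutoff contact kinetics.

The pipeline: per (lipid, residue) distance series → hysteretic bound/unbound
state series (bound below 0.55 nm, released only above 1.0 nm, which
suppresses flicker from thermal fluctuation) → a residue co-binding graph
(edges weight residue pairs that are simultaneously bound to the same lipid
headgroup) → seeded modularity community detection → per-site occupancy,
residence time and binding events → residence-time and residue-occupancy
filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import curve_fit

from .core import CDL_HEADGROUP_ROLES, SystemTopology, Trajectory
from . import geometry

__all__ = [
    "dual_cutoff_states",
    "BoundSeries",
    "compute_bound_series",
    "build_cobinding_graph",
    "detect_sites",
    "site_metrics",
    "filter_sites",
    "representative_pose",
    "find_binding_sites",
    "BindingSite",
    "occupancy_from_events",
]

logger = logging.getLogger(__name__)

LOWER_CUTOFF = 0.55  # nm
UPPER_CUTOFF = 1.0  # nm
MIN_RESIDENCE_NS = 10.0
RESIDUE_OCCUPANCY_FLOOR = 0.10
EDGE_WEIGHT_THRESHOLD = 0.3


def dual_cutoff_states(
    distances: np.ndarray, lower: float = LOWER_CUTOFF, upper: float = UPPER_CUTOFF
) -> np.ndarray:
    """Hysteretic bound/unbound states from a distance series.

    The state starts unbound, becomes bound when the distance drops below
    ``lower``, stays bound while the distance remains ≤ ``upper`` and
    becomes unbound only once it exceeds ``upper``. With
    ``lower == upper`` this reduces to single-cutoff thresholding.

    ``distances`` may be (F,) or (F, ...); the automaton runs along axis 0.
    Vectorized via a last-crossing scan: a frame is bound iff the most
    recent threshold event at or before it was a below-lower crossing.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    if lower > upper:
        raise ValueError("lower cutoff must be <= upper cutoff")
    t = np.arange(d.shape[0]).reshape((-1,) + (1,) * (d.ndim - 1))
    last_on = np.maximum.accumulate(np.where(d < lower, t, -1), axis=0)
    last_off = np.maximum.accumulate(np.where(d > upper, t, -1), axis=0)
    return last_on > last_off


@dataclass
class BoundSeries:
    """Bound/unbound state per (frame, lipid, residue), plus provenance.

    ``states`` has shape (n_frames, n_lipids, n_residues) aligned with
    ``lipid_ids`` and ``residue_ids``.
    """

    lipid_ids: np.ndarray
    residue_ids: np.ndarray
    states: np.ndarray
    lower: float
    upper: float
    dt: float
    lipid_type: str = "CDL"
    headgroup_only: bool = True

    def __post_init__(self):
        self.lipid_ids = np.asarray(self.lipid_ids, dtype=np.intp)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.intp)
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.shape != (
            self.states.shape[0],
            self.lipid_ids.size,
            self.residue_ids.size,
        ):
            raise ValueError("states shape inconsistent with id arrays")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    def residue_index(self, residue_ids) -> np.ndarray:
        lookup = {int(r): i for i, r in enumerate(self.residue_ids)}
        try:
            return np.array([lookup[int(r)] for r in residue_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"residue {e} not present in the bound series") from None


def compute_bound_series(
    traj: Trajectory,
    topo: SystemTopology,
    lipid_type: str = "CDL",
    lower: float = LOWER_CUTOFF,
    upper: float = UPPER_CUTOFF,
    headgroup_only: bool = True,
) -> BoundSeries:
    """Dual-cutoff state series for every (lipid of type, residue) pair.

    With ``headgroup_only`` (the default, and the convention for site
    identification) only the GL0/PO1/PO2 beads enter the distance; the
    residue side always uses all of its beads.
    """
    lips = topo.lipids_of_type(lipid_type)
    if not lips:
        raise ValueError(f"no lipids of type {lipid_type!r}")
    roles = CDL_HEADGROUP_ROLES if headgroup_only else None
    lipid_groups = []
    for l in lips:
        beads = l.beads_with_roles(roles)
        if not beads:
            raise ValueError(
                f"lipid {l.lipid_id} has no headgroup beads for site analysis"
            )
        lipid_groups.append(np.array(beads, dtype=np.intp))
    res_groups = [np.array(r.bead_ids, dtype=np.intp) for r in topo.residues]
    d = geometry.group_min_distances(traj.coords, traj.box, lipid_groups, res_groups)
    states = dual_cutoff_states(d, lower, upper)
    return BoundSeries(
        lipid_ids=np.array([l.lipid_id for l in lips]),
        residue_ids=np.array([r.residue_id for r in topo.residues]),
        states=states,
        lower=lower,
        upper=upper,
        dt=traj.dt if traj.n_frames > 1 else 1.0,
        lipid_type=lipid_type,
        headgroup_only=headgroup_only,
    )


def build_cobinding_graph(
    bound: BoundSeries, weight_threshold: float = EDGE_WEIGHT_THRESHOLD
) -> nx.Graph:
    """Weighted residue graph of simultaneous same-lipid binding.

    Nodes are residues with at least one bound frame. The weight of edge
    (i, j) is the number of (lipid, frame) pairs in which one lipid is
    simultaneously bound to both residues, normalized by the smaller of
    the two residues' total bound (lipid, frame) counts; edges with weight
    below ``weight_threshold`` are dropped.
    """
    S = bound.states  # (F, L, R)
    per_res = S.sum(axis=(0, 1)).astype(float)  # bound (lipid, frame) count
    co = np.zeros((S.shape[2], S.shape[2]), dtype=float)
    for li in range(S.shape[1]):
        sl = S[:, li, :].astype(float)
        co += sl.T @ sl
    g = nx.Graph()
    active = np.nonzero(per_res > 0)[0]
    if active.size == 0:
        logger.warning("no bound frames anywhere; returning an empty graph")
    for i in active:
        g.add_node(int(bound.residue_ids[i]), bound_count=float(per_res[i]))
    for ii, i in enumerate(active):
        for j in active[ii + 1 :]:
            w = co[i, j] / min(per_res[i], per_res[j])
            if w >= weight_threshold:
                g.add_edge(
                    int(bound.residue_ids[i]), int(bound.residue_ids[j]), weight=w
                )
    return g


def detect_sites(graph: nx.Graph, seed: int = 0) -> list[frozenset[int]]:
    """Partition the co-binding graph into candidate sites.

    Modularity-maximizing (Louvain) community detection with a fixed seed;
    singleton communities whose residue retained no edge are discarded.
    Communities are returned sorted by their smallest residue id.
    """
    if graph.number_of_nodes() == 0:
        return []
    comms = nx.community.louvain_communities(graph, weight="weight", seed=seed)
    sites = [
        frozenset(int(n) for n in c)
        for c in comms
        if len(c) > 1 or graph.degree(next(iter(c))) > 0
    ]
    return sorted(sites, key=lambda s: min(s))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, end) inclusive frame indices."""
    idx = np.nonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))[0]
    return [(int(idx[k]), int(idx[k + 1] - 1)) for k in range(0, len(idx), 2)]


def _survival_fit_tau(durations_ns: np.ndarray) -> float:
    """Single-exponential fit to the event-duration survival curve."""
    t = np.sort(durations_ns)
    surv = 1.0 - np.arange(len(t)) / len(t)

    def model(x, tau):
        return np.exp(-x / tau)

    tau0 = max(float(durations_ns.mean()), 1e-9)
    try:
        popt, _ = curve_fit(model, t, surv, p0=[tau0], maxfev=2000)
        return float(popt[0])
    except RuntimeError:  # no convergence: fall back to the mean
        return tau0


def site_metrics(
    site: frozenset[int] | set[int],
    bound: BoundSeries,
    dt: float | None = None,
    residence_estimator: str = "mean",
) -> tuple[float, float, list[tuple[int, int, int]]]:
    """Occupancy, residence time and binding events for one residue set.

    A frame is site-bound when any lipid of the target type is bound to at
    least one site residue. Events are maximal runs, per lipid, of
    continuous binding to any site residue, reported as
    ``(lipid_id, start_frame, end_frame)`` with inclusive 0-based frames.
    The residence time is the mean event duration in ns; with
    ``residence_estimator="survival-fit"`` a single-exponential survival
    fit is used instead (falling back to the mean below 20 events).
    """
    if not site:
        raise ValueError("empty site")
    dt = bound.dt if dt is None else dt
    ridx = bound.residue_index(sorted(site))
    per_lipid = bound.states[:, :, ridx].any(axis=2)  # (F, L)
    occupancy = float(per_lipid.any(axis=1).mean())
    events: list[tuple[int, int, int]] = []
    for li, lid in enumerate(bound.lipid_ids):
        for start, end in _runs(per_lipid[:, li]):
            events.append((int(lid), start, end))
    events.sort(key=lambda e: (e[1], e[0]))
    if not events:
        return occupancy, 0.0, events
    durations = np.array([(e[2] - e[1] + 1) * dt for e in events])
    if residence_estimator == "survival-fit" and len(durations) >= 20:
        residence = _survival_fit_tau(durations)
    elif residence_estimator in ("mean", "survival-fit"):
        residence = float(durations.mean())
    else:
        raise ValueError(f"unknown residence estimator {residence_estimator!r}")
    return occupancy, residence, events


def occupancy_from_events(
    events: list[tuple[int, int, int]], n_frames: int
) -> float:
    """Occupancy recomputed from serialized events (union of frame ranges)."""
    mask = np.zeros(n_frames, dtype=bool)
    for _, start, end in events:
        mask[start : end + 1] = True
    return float(mask.mean())


@dataclass
class BindingSite:
    """An identified binding site with its metrics and events."""

    site_id: int
    residue_ids: frozenset[int]
    occupancy: float
    residence_time: float  # ns
    events: list[tuple[int, int, int]] = field(default_factory=list)
    representative_pose: tuple[int, int] | None = None  # (frame, lipid_id)
    lipid_type: str = "CDL"

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "residue_ids": sorted(self.residue_ids),
            "occupancy": self.occupancy,
            "residence_time_ns": self.residence_time,
            "events": [list(e) for e in self.events],
            "representative_pose": (
                list(self.representative_pose) if self.representative_pose else None
            ),
            "lipid_type": self.lipid_type,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BindingSite":
        return cls(
            site_id=d["site_id"],
            residue_ids=frozenset(d["residue_ids"]),
            occupancy=d["occupancy"],
            residence_time=d["residence_time_ns"],
            events=[tuple(e) for e in d["events"]],
            representative_pose=(
                tuple(d["representative_pose"]) if d["representative_pose"] else None
            ),
            lipid_type=d.get("lipid_type", "CDL"),
        )


def filter_sites(
    sites: list[BindingSite],
    bound: BoundSeries,
    min_residence: float = MIN_RESIDENCE_NS,
    residue_occupancy_floor: float = RESIDUE_OCCUPANCY_FLOOR,
    residence_estimator: str = "mean",
) -> list[BindingSite]:
    """Residence-time and residue-occupancy filters.

    Sites whose residence time is ≤ ``min_residence`` ns are dropped
    (short-lived contact clusters are indistinguishable from free lipid
    diffusion). Within retained sites, residues whose individual bound
    occupancy falls below ``residue_occupancy_floor`` × the site occupancy
    are pruned, and metrics are recomputed on the pruned residue set.
    """
    out: list[BindingSite] = []
    for s in sites:
        if s.residence_time <= min_residence:
            continue
        keep = set()
        for rid in s.residue_ids:
            ridx = bound.residue_index([rid])
            r_occ = float(bound.states[:, :, ridx[0]].any(axis=1).mean())
            if r_occ >= residue_occupancy_floor * s.occupancy:
                keep.add(rid)
        if not keep:
            continue
        occ, res, events = site_metrics(
            keep, bound, residence_estimator=residence_estimator
        )
        out.append(
            BindingSite(
                site_id=s.site_id,
                residue_ids=frozenset(keep),
                occupancy=occ,
                residence_time=res,
                events=events,
                lipid_type=s.lipid_type,
            )
        )
    return out


def representative_pose(
    site: BindingSite,
    traj: Trajectory,
    topo: SystemTopology,
    bound: BoundSeries,
) -> tuple[int, int]:
    """Frame and lipid best representing a site's bound state.

    Takes the longest event (ties: earliest start, then lowest lipid id)
    and, within it, the frame minimizing the mean over site residues of
    the minimum headgroup-bead distance (ties: lowest frame index).
    """
    if not site.events:
        raise ValueError("site has no binding events")
    best = max(site.events, key=lambda e: (e[2] - e[1], -e[1], -e[0]))
    lipid_id, start, end = best
    lip = topo.lipid(lipid_id)
    roles = CDL_HEADGROUP_ROLES if bound.headgroup_only else None
    hbeads = np.array(lip.beads_with_roles(roles), dtype=np.intp)
    res_groups = [
        np.array(topo.residue(r).bead_ids, dtype=np.intp)
        for r in sorted(site.residue_ids)
    ]
    d = geometry.group_min_distances(
        traj.coords[start : end + 1],
        traj.box[start : end + 1],
        [hbeads],
        res_groups,
    )[:, 0, :]
    score = d.mean(axis=1)
    frame = start + int(np.argmin(score))
    return frame, int(lipid_id)


def find_binding_sites(
    traj: Trajectory,
    topo: SystemTopology,
    lipid_type: str = "CDL",
    lower: float = LOWER_CUTOFF,
    upper: float = UPPER_CUTOFF,
    min_residence: float = MIN_RESIDENCE_NS,
    residue_occupancy_floor: float = RESIDUE_OCCUPANCY_FLOOR,
    weight_threshold: float = EDGE_WEIGHT_THRESHOLD,
    residence_estimator: str = "mean",
    seed: int = 0,
    apply_filters: bool = True,
    with_poses: bool = True,
) -> tuple[list[BindingSite], BoundSeries]:
    """End-to-end site identification for one lipid type.

    Returns the (optionally filtered) sites and the underlying bound
    series. Deterministic for a fixed seed.
    """
    bound = compute_bound_series(traj, topo, lipid_type, lower, upper)
    graph = build_cobinding_graph(bound, weight_threshold)
    communities = detect_sites(graph, seed=seed)
    sites = []
    for k, comm in enumerate(communities):
        occ, res, events = site_metrics(
            comm, bound, residence_estimator=residence_estimator
        )
        sites.append(
            BindingSite(
                site_id=k,
                residue_ids=comm,
                occupancy=occ,
                residence_time=res,
                events=events,
                lipid_type=lipid_type,
            )
        )
    if apply_filters:
        sites = filter_sites(
            sites,
            bound,
            min_residence=min_residence,
            residue_occupancy_floor=residue_occupancy_floor,
            residence_estimator=residence_estimator,
        )
    if with_poses:
        for s in sites:
            if s.events:
                s.representative_pose = representative_pose(s, traj, topo, bound)
    return sites, bound
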