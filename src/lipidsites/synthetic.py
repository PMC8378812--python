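"""Synthetic coarse-grained membrane–protein systems with planted binding sites.

The generator emulates the study conditions the analysis stages are designed
for: a two-leaflet POPE/POPG/CDL membrane at 67/23/10 composition, a static
ring-of-residues "protein" spanning the bilayer, laterally diffusing
background lipids, and planted lipid binding sites driven by a two-state
(bound/unbound) Markov chain with chosen per-frame on/off probabilities.
Because the planted state series is recorded, every downstream quantity
(occupancy, dwell time, site membership) has an exact ground truth.

Deliberate simplifications (see docs/methods.md): background lipids of all
types share one bead geometry — head beads stacked at the phosphate plane
(|z| = 2 nm), tail beads at |z| = 1 nm, all at the lipid's (x, y) — so that
contact with the protein is exactly composition-proportional when no sites
are planted. CDL still carries the full GL0/PO1/PO2 + four-tail bead-role
set; a *bound* planted CDL gets spatially distinct headgroup beads placed
next to its site residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import Lipid, Residue, SystemTopology, Trajectory

__all__ = [
    "GeneratorParams",
    "PlantedSite",
    "GroundTruthSite",
    "generate_system",
    "largest_remainder_counts",
    "generate_rule_structure",
]

PHOSPHATE_PLANE_Z = 2.0  # nm, |z| of head beads in each leaflet
TAIL_PLANE_Z = 1.0  # nm, |z| of tail beads
LOWER_CUTOFF = 0.55  # nm, dual-cutoff lower bound the planted geometry must beat
UPPER_CUTOFF = 1.0  # nm, dual-cutoff upper bound the unbound pose must exceed

#: bead roles per lipid type: one phosphate + one tail bead for the bulk
#: lipids, the three headgroup beads + four tails for cardiolipin.
LIPID_BEAD_ROLES: dict[str, tuple[str, ...]] = {
    "POPE": ("PO4", "C1A"),
    "POPG": ("PO4", "C1A"),
    "CDL": ("GL0", "PO1", "PO2", "C1A", "C2A", "C1B", "C2B"),
}
_HEAD_ROLES = {"PO4", "GL0", "PO1", "PO2"}

#: default residue-name pattern for the ring protein: mostly hydrophobic,
#: with the polar/aromatic sprinkling a membrane-spanning helix bundle shows.
DEFAULT_RESIDUE_PATTERN = (
    "LEU", "ALA", "VAL", "PHE", "SER", "ILE",
    "GLY", "TRP", "THR", "LEU", "VAL", "ALA",
)


@dataclass(frozen=True)
class PlantedSite:
    """A ground-truth binding site: residues + two-state kinetics.

    The stationary occupancy is ``p_on / (p_on + p_off)`` and the mean
    bound dwell is ``1 / p_off`` frames. ``bound_distance`` must be below
    the 0.55 nm lower cutoff and ``unbound_distance`` above the 1.0 nm
    upper cutoff so the dual-cutoff rule recovers the planted state exactly.
    """

    residue_ids: frozenset[int]
    lipid_type: str = "CDL"
    p_on: float = 0.3
    p_off: float = 0.1
    bound_distance: float = 0.45
    unbound_distance: float = 2.0

    def __post_init__(self):
        if not self.residue_ids:
            raise ValueError("planted site needs at least one residue")
        if not (0 < self.p_on <= 1 and 0 < self.p_off <= 1):
            raise ValueError("p_on and p_off must lie in (0, 1]")
        occ = self.p_on / (self.p_on + self.p_off)
        if not (0 < occ < 1):
            raise ValueError("stationary occupancy must lie in (0, 1)")
        if not self.bound_distance < LOWER_CUTOFF:
            raise ValueError(
                f"bound_distance must be < {LOWER_CUTOFF} nm so binding is detected"
            )
        if not self.unbound_distance > UPPER_CUTOFF:
            raise ValueError(
                f"unbound_distance must be > {UPPER_CUTOFF} nm so unbinding is detected"
            )

    @property
    def stationary_occupancy(self) -> float:
        return self.p_on / (self.p_on + self.p_off)

    @property
    def mean_dwell_frames(self) -> float:
        return 1.0 / self.p_off


@dataclass(frozen=True)
class GroundTruthSite:
    """A planted site together with its realized state series and lipid."""

    site: PlantedSite
    lipid_id: int
    states: np.ndarray  # (n_frames,) bool

    @property
    def realized_occupancy(self) -> float:
        return float(self.states.mean())


@dataclass(frozen=True)
class GeneratorParams:
    """Everything the generator needs; defaults give the standard membrane.

    ``composition`` fractions must be non-negative and sum to one; they are
    converted to integer per-leaflet counts by largest-remainder rounding.
    ``exclude_background_nm``, when set, keeps background lipids at least
    that far (laterally) outside the protein radius — used when planted
    kinetics must be the only source of binding.
    """

    seed: int
    n_lipids_per_leaflet: int = 100
    composition: Mapping[str, float] = field(
        default_factory=lambda: {"POPE": 0.67, "POPG": 0.23, "CDL": 0.10}
    )
    n_protein_residues: int = 36
    protein_radius: float = 1.5
    box: tuple[float, float, float] = (15.0, 15.0, 10.0)
    n_frames: int = 2000
    dt: float = 1.0
    planted_sites: tuple[PlantedSite, ...] = ()
    residue_names: Mapping[int, str] | None = None
    step_sigma: float = 0.3
    exclude_background_nm: float | None = None

    def __post_init__(self):
        comp = dict(self.composition)
        if any(f < 0 for f in comp.values()):
            raise ValueError("composition fractions must be >= 0")
        if abs(sum(comp.values()) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        unknown = set(comp) - set(LIPID_BEAD_ROLES)
        if unknown:
            raise ValueError(f"unknown lipid types {sorted(unknown)}")
        if self.box[2] <= 2 * PHOSPHATE_PLANE_Z:
            raise ValueError("box z must span both leaflets (> 4 nm)")
        if self.n_frames < 1 or self.n_lipids_per_leaflet < 1:
            raise ValueError("n_frames and n_lipids_per_leaflet must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def largest_remainder_counts(
    fractions: Mapping[str, float], total: int
) -> dict[str, int]:
    """Deterministic fraction→count conversion preserving the total.

    Floors each share, then hands remaining units to the largest fractional
    remainders (ties broken by mapping order).
    """
    items = list(fractions.items())
    raw = [f * total for _, f in items]
    counts = [math.floor(r) for r in raw]
    short = total - sum(counts)
    order = sorted(
        range(len(items)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in order[:short]:
        counts[i] += 1
    return {name: c for (name, _), c in zip(items, counts)}


def _protein_layout(params: GeneratorParams) -> tuple[list[Residue], np.ndarray, list[int]]:
    """Place residues on a cylinder spanning the membrane; returns
    (residues, bead coords, bead ids used)."""
    n = params.n_protein_residues
    ring_size = 12
    n_rings = max(1, math.ceil(n / ring_size))
    z_levels = (
        np.array([0.0]) if n_rings == 1 else np.linspace(-1.8, 1.8, n_rings)
    )
    cx, cy = params.box[0] / 2, params.box[1] / 2
    names = {}
    if params.residue_names:
        names.update(params.residue_names)
    planted = set().union(*[s.residue_ids for s in params.planted_sites]) if params.planted_sites else set()
    residues: list[Residue] = []
    coords: list[np.ndarray] = []
    bead = 0
    for i in range(n):
        ring, j = divmod(i, ring_size)
        theta = 2 * np.pi * j / ring_size + ring * (np.pi / ring_size)
        z = float(z_levels[ring])
        name = names.get(i)
        if name is None:
            name = "ARG" if i in planted else DEFAULT_RESIDUE_PATTERN[i % len(DEFAULT_RESIDUE_PATTERN)]
        bb = np.array(
            [cx + params.protein_radius * np.cos(theta),
             cy + params.protein_radius * np.sin(theta), z]
        )
        beads = {"BB": bead}
        coords.append(bb)
        bead += 1
        if name not in ("GLY", "ALA"):
            sc = np.array(
                [cx + (params.protein_radius + 0.25) * np.cos(theta),
                 cy + (params.protein_radius + 0.25) * np.sin(theta), z]
            )
            beads["SC1"] = bead
            coords.append(sc)
            bead += 1
        residues.append(Residue(residue_id=i, name=name, chain="A", beads=beads))
    return residues, np.array(coords), list(range(bead))


def _simulate_markov(
    rng: np.random.Generator, n_frames: int, p_on: float, p_off: float
) -> np.ndarray:
    """Two-state chain; the initial state is drawn from the stationary
    distribution so the realized occupancy is unbiased."""
    states = np.empty(n_frames, dtype=bool)
    stationary = p_on / (p_on + p_off)
    u = rng.random(n_frames)
    states[0] = u[0] < stationary
    for t in range(1, n_frames):
        states[t] = (u[t] < p_on) if not states[t - 1] else (u[t] >= p_off)
    return states


def generate_system(
    params: GeneratorParams,
) -> tuple[SystemTopology, Trajectory, list[GroundTruthSite]]:
    """Build topology + trajectory + ground truth for one synthetic system.

    Deterministic for a fixed seed. Background lipids perform a 2-D random
    walk in their leaflet with periodic wrapping; planted lipids follow
    their two-state chain, parked at ``bound_distance`` from their site
    residues when bound and well outside the upper cutoff when unbound.
    """
    rng = np.random.default_rng(params.seed)
    box = np.array(params.box, dtype=float)
    F = params.n_frames

    residues, prot_coords, _ = _protein_layout(params)
    res_by_id = {r.residue_id: r for r in residues}
    for site in params.planted_sites:
        missing = site.residue_ids - set(res_by_id)
        if missing:
            raise ValueError(f"planted residue_ids {sorted(missing)} not in protein")

    counts = largest_remainder_counts(dict(params.composition), params.n_lipids_per_leaflet)

    # ---- assemble lipids, reserving planted ones from the composition ----
    bead = prot_coords.shape[0]
    lipids: list[Lipid] = []
    lipid_meta: list[dict] = []  # per lipid: leaflet sign, type, bead ids
    lid = 0
    for leaflet, sign in (("inner", -1.0), ("outer", +1.0)):
        for ltype, cnt in counts.items():
            for _ in range(cnt):
                roles = LIPID_BEAD_ROLES[ltype]
                beads = {r: bead + k for k, r in enumerate(roles)}
                bead += len(roles)
                lipids.append(
                    Lipid(lipid_id=lid, lipid_type=ltype, leaflet=leaflet, beads=beads)
                )
                lipid_meta.append({"sign": sign, "type": ltype, "leaflet": leaflet})
                lid += 1

    # choose which lipid realizes each planted site (site leaflet = sign of
    # its residues' mean z)
    taken: set[int] = set()
    site_lipids: list[int] = []
    for site in params.planted_sites:
        zmean = np.mean(
            [prot_coords[res_by_id[r].bb_bead][2] for r in sorted(site.residue_ids)]
        )
        leaflet = "inner" if zmean < 0 else "outer"
        pick = next(
            (
                l.lipid_id
                for l in lipids
                if l.lipid_type == site.lipid_type
                and l.leaflet == leaflet
                and l.lipid_id not in taken
            ),
            None,
        )
        if pick is None:
            raise ValueError(
                f"no free {site.lipid_type} lipid in the {leaflet} leaflet for a planted site"
            )
        taken.add(pick)
        site_lipids.append(pick)

    n_beads = bead
    coords = np.empty((F, n_beads, 3), dtype=float)
    coords[:, : prot_coords.shape[0], :] = prot_coords[None, :, :]

    # ---- background lipid random walks (vectorized over frames) ----------
    bg = [l for l in lipids if l.lipid_id not in taken]
    nbg = len(bg)
    xy0 = rng.uniform([0.0, 0.0], box[:2], size=(nbg, 2))
    steps = rng.normal(0.0, params.step_sigma, size=(F - 1, nbg, 2)) if F > 1 else np.empty((0, nbg, 2))
    paths = np.mod(xy0[None] + np.concatenate([np.zeros((1, nbg, 2)), np.cumsum(steps, 0)]), box[:2])
    if params.exclude_background_nm is not None:
        r_excl = params.protein_radius + 0.25 + params.exclude_background_nm
        center = box[:2] / 2
        rel = paths - center
        r = np.hypot(rel[..., 0], rel[..., 1])
        inside = r < r_excl
        safe_r = np.where(r < 1e-9, 1e-9, r)
        scale = np.where(inside, (2 * r_excl - r) / safe_r, 1.0)
        paths = np.mod(center + rel * scale[..., None], box[:2])
    for k, lip in enumerate(bg):
        sign = lipid_meta[lip.lipid_id]["sign"]
        for role, b in lip.beads.items():
            zlvl = sign * (PHOSPHATE_PLANE_Z if role in _HEAD_ROLES else TAIL_PLANE_Z)
            coords[:, b, 0] = paths[:, k, 0]
            coords[:, b, 1] = paths[:, k, 1]
            coords[:, b, 2] = zlvl

    # ---- planted lipids ---------------------------------------------------
    center = box[:2] / 2
    lat = prot_coords[:, :2] - center
    r_prot_max = float(np.hypot(lat[:, 0], lat[:, 1]).max())
    ground_truth: list[GroundTruthSite] = []
    head_cycle = ("PO1", "PO2", "GL0")
    for site, lipid_id in zip(params.planted_sites, site_lipids):
        lip = lipids[lipid_id]
        states = _simulate_markov(rng, F, site.p_on, site.p_off)
        members = sorted(site.residue_ids)
        # anchor = the residue bead closest to the lipid side (SC if present)
        anchors = []
        for rid in members:
            res = res_by_id[rid]
            b = res.beads.get("SC1", res.beads["BB"])
            anchors.append(prot_coords[b])
        anchors = np.array(anchors)

        # bound pose: each headgroup bead sits bound_distance radially out
        # from one site residue (roles cycled over residues); small z offsets
        # keep beads sharing a residue distinct.
        bound_pos: dict[str, np.ndarray] = {}
        zoff = {"PO1": 0.08, "PO2": -0.08, "GL0": 0.0}
        for k, role in enumerate(head_cycle):
            a = anchors[k % len(members)]
            d = a[:2] - center
            d = d / max(np.hypot(*d), 1e-9)
            bound_pos[role] = np.array(
                [a[0] + d[0] * site.bound_distance,
                 a[1] + d[1] * site.bound_distance,
                 a[2] + zoff[role]]
            )
        gl0 = bound_pos["GL0"]
        tsign = 1.0 if gl0[2] < 0 else -1.0  # tails point toward z = 0
        for k, role in enumerate(("C1A", "C2A", "C1B", "C2B")):
            bound_pos[role] = gl0 + np.array([0.0, 0.0, tsign * 0.4 * (k + 1)])

        # unbound pose: radially outside the protein by > unbound_distance
        cen = anchors.mean(axis=0)
        d = cen[:2] - center
        d = d / max(np.hypot(*d), 1e-9)
        r_park = r_prot_max + site.unbound_distance + 0.05
        if r_park + 0.1 > min(box[0], box[1]) / 2:
            raise ValueError("box too small to park an unbound planted lipid")
        park = np.array([center[0] + d[0] * r_park, center[1] + d[1] * r_park, cen[2]])
        unbound_pos: dict[str, np.ndarray] = {}
        for role in head_cycle:
            unbound_pos[role] = park + np.array([0.0, 0.0, zoff[role]])
        tsign = 1.0 if park[2] < 0 else -1.0
        for k, role in enumerate(("C1A", "C2A", "C1B", "C2B")):
            unbound_pos[role] = park + np.array([0.0, 0.0, tsign * 0.4 * (k + 1)])

        for role, b in lip.beads.items():
            pos_b = bound_pos[role]
            pos_u = unbound_pos[role]
            coords[:, b, :] = np.where(states[:, None], pos_b[None], pos_u[None])
        ground_truth.append(GroundTruthSite(site=site, lipid_id=lipid_id, states=states))

    topo = SystemTopology(residues=residues, lipids=lipids)
    times = np.arange(F, dtype=float) * params.dt
    traj = Trajectory(times=times, coords=coords, box=box)
    return topo, traj, ground_truth


# ---------------------------------------------------------------------------
# structures for the rule engine
# ---------------------------------------------------------------------------

def generate_rule_structure(
    seed: int,
    n_decoy_basics: int = 6,
    n_filler: int = 14,
    radius: float = 2.5,
    with_decoy_pair: bool = True,
):
    """A membrane-oriented residue cloud with one planted three-rule CDL site.

    Returns ``(points, planted_ids)`` where points are
    :class:`lipidsites.rules.ResiduePoint` entries (membrane centre at
    z = 0). The planted motif is an Arg/Lys pair 0.5 nm apart at depth
    ~1.8 nm with matched z, a Ser in the same plane and a Trp one ring
    deeper. Decoy basic residues are kept isolated (> 1.3 nm from any other
    basic) so they can never satisfy the basic-pair geometry; an optional
    decoy *pair* with no polar/aromatic support exercises the ranking.
    """
    from .rules import ResiduePoint  # local import; rules does not import us

    rng = np.random.default_rng(seed)
    zs = -1.0 if rng.random() < 0.5 else 1.0
    theta0 = rng.uniform(0, 2 * np.pi)

    def ring(theta, z):
        return np.array([radius * np.cos(theta), radius * np.sin(theta), z])

    dtheta = 0.5 / radius  # ~0.5 nm arc
    pts: list = []
    rid = 0

    def add(name, xyz, chain="A"):
        nonlocal rid
        pts.append(ResiduePoint(residue_id=rid, name=name, chain=chain, xyz=np.asarray(xyz, float)))
        rid += 1

    planted_start = rid
    add("ARG", ring(theta0, 1.85 * zs))
    add("LYS", ring(theta0 + dtheta, 1.75 * zs))
    add("SER", ring(theta0 + 2 * dtheta, 1.70 * zs))
    add("TRP", ring(theta0, 1.20 * zs))
    planted = frozenset(range(planted_start, rid))

    basics_placed = [p.xyz for p in pts[:2]]
    if with_decoy_pair:
        # a basic pair satisfying the geometry but with no polar/aromatic
        # residue anywhere near it: passes rule 1 only.
        for _ in range(200):
            th = rng.uniform(0, 2 * np.pi)
            z = rng.uniform(1.4, 2.2) * -zs  # opposite leaflet face
            a = ring(th, z)
            b = ring(th + dtheta, z + 0.1 * np.sign(z))
            if all(np.linalg.norm(a - q) > 2.5 and np.linalg.norm(b - q) > 2.5 for q in basics_placed):
                add("LYS", a)
                add("LYS", b)
                basics_placed += [a, b]
                break

    for _ in range(n_decoy_basics):
        for _ in range(500):
            th = rng.uniform(0, 2 * np.pi)
            z = rng.uniform(-2.2, 2.2)
            p = ring(th, z)
            if all(np.linalg.norm(p - q) > 1.3 for q in basics_placed):
                add("ARG" if rng.random() < 0.5 else "LYS", p)
                basics_placed.append(p)
                break

    filler_names = ("LEU", "ALA", "VAL", "ILE")
    for _ in range(n_filler):
        th = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(-2.2, 2.2)
        add(str(rng.choice(filler_names)), ring(th, z))

    return pts, planted
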