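"""Global residue–lipid contact analyses.

Three trajectory-level summaries over a 0.6 nm contact cutoff:

* leaflet-resolved lipid binding propensity — a lipid type's share of the
  protein-bound lipid divided by its share of the total lipid (1 means no
  enrichment);
* the z-histogram of residues that contact lipid in more than 10 % of
  frames (membrane frame, backbone bead, final-frame position);
* contact-count profiles between each lipid bead role and each residue
  name (which bead of the headgroup talks to which amino acids).
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd

from .core import SystemTopology, Trajectory, TopologyError
from . import geometry

__all__ = [
    "min_distance",
    "lipid_binding_propensity",
    "contacting_residue_z_profile",
    "bead_residue_profile",
    "bound_lipids_per_frame",
]

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 0.6  # nm, global contact criterion


def min_distance(
    topo: SystemTopology,
    traj: Trajectory,
    residue_id: int,
    lipid_id: int,
    frame: int,
    bead_filter: set[str] | None = None,
) -> float:
    """Minimum periodic distance between a residue and a lipid in one frame.

    ``bead_filter`` restricts the *lipid* side to the given bead roles
    (e.g. the CDL headgroup); ``None`` uses every bead.
    """
    res = topo.residue(residue_id)
    lip = topo.lipid(lipid_id)
    lbeads = lip.beads_with_roles(bead_filter)
    if not lbeads:
        raise ValueError(
            f"lipid {lipid_id} has no beads with roles {sorted(bead_filter or ())}"
        )
    if not (0 <= frame < traj.n_frames):
        raise IndexError(f"frame {frame} outside trajectory")
    x = traj.coords[frame]
    return geometry.min_pair_distance(
        x[list(res.bead_ids)], x[list(lbeads)], traj.box[frame]
    )


def bound_lipids_per_frame(
    traj: Trajectory,
    topo: SystemTopology,
    cutoff: float = CONTACT_CUTOFF,
    frames: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Lipid ids with any bead strictly within ``cutoff`` of any protein
    bead, per frame (KD-tree accelerated)."""
    prot = topo.protein_bead_ids
    lipid_beads = topo.lipid_bead_ids
    bead_to_lipid = np.empty(lipid_beads.max() + 1 if lipid_beads.size else 0, dtype=np.intp)
    for lip in topo.lipids:
        for b in lip.bead_ids:
            bead_to_lipid[b] = lip.lipid_id
    if frames is None:
        frames = np.arange(traj.n_frames)
    out = []
    for f in frames:
        hits = geometry.beads_within_cutoff(
            traj.coords[f], traj.box[f], prot, lipid_beads, cutoff
        )
        out.append(np.unique(bead_to_lipid[lipid_beads[hits]]))
    return out


def lipid_binding_propensity(
    traj: Trajectory,
    topo: SystemTopology,
    cutoff: float = CONTACT_CUTOFF,
    equilibration_skip: float = 0.1,
) -> pd.DataFrame:
    """Leaflet-resolved binding propensity per lipid type.

    A lipid counts as bound in a frame when any of its beads comes within
    ``cutoff`` of any protein bead. Bound counts are averaged over the
    post-skip frames and expressed, per leaflet, as the bound fraction of
    each type; the propensity is bound fraction / total fraction. Rows for
    leaflet ``"membrane"`` pool both leaflets (the denominator convention
    is not uniquely fixed by the per-leaflet split, so both are reported).

    Returns a DataFrame with columns
    ``lipid_type, leaflet, n_lipids, mean_bound, bound_fraction,
    total_fraction, propensity``.
    """
    if not (0 <= equilibration_skip < 1):
        raise ValueError("equilibration_skip must be a fraction in [0, 1)")
    skip = int(np.floor(equilibration_skip * traj.n_frames))
    frames = np.arange(skip, traj.n_frames)
    if frames.size == 0:
        raise ValueError("no frames left after equilibration skip")
    leaflets = ("inner", "outer")
    for leaf in leaflets:
        if not any(l.leaflet == leaf for l in topo.lipids):
            raise ValueError(f"no lipids in the {leaf} leaflet")

    types = topo.lipid_types
    lipid_leaflet = {l.lipid_id: l.leaflet for l in topo.lipids}
    lipid_type = {l.lipid_id: l.lipid_type for l in topo.lipids}

    bound_sum: Counter = Counter()
    for bound_ids in bound_lipids_per_frame(traj, topo, cutoff, frames):
        for lid in bound_ids:
            bound_sum[(lipid_type[lid], lipid_leaflet[lid])] += 1

    n_frames = frames.size
    rows = []
    groups = [(leaf, (leaf,)) for leaf in leaflets] + [("membrane", leaflets)]
    for label, members in groups:
        n_total = {
            t: sum(
                1 for l in topo.lipids if l.lipid_type == t and l.leaflet in members
            )
            for t in types
        }
        mean_bound = {
            t: sum(bound_sum[(t, leaf)] for leaf in members) / n_frames for t in types
        }
        tot_bound = sum(mean_bound.values())
        tot_lipids = sum(n_total.values())
        for t in types:
            bf = mean_bound[t] / tot_bound if tot_bound > 0 else np.nan
            tf = n_total[t] / tot_lipids if tot_lipids > 0 else np.nan
            rows.append(
                {
                    "lipid_type": t,
                    "leaflet": label,
                    "n_lipids": n_total[t],
                    "mean_bound": mean_bound[t],
                    "bound_fraction": bf,
                    "total_fraction": tf,
                    "propensity": bf / tf if tf and tf > 0 and np.isfinite(bf) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def contacting_residue_z_profile(
    traj: Trajectory,
    topo: SystemTopology,
    cutoff: float = CONTACT_CUTOFF,
    min_contact_probability: float = 0.10,
    residue_filter: set[str] | None = None,
    bin_width: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Histogram along z of lipid-contacting residues.

    For each residue whose any-lipid contact probability over all frames
    exceeds ``min_contact_probability``, the backbone-bead z position at
    the *final* frame is emitted (the trajectory must be in the membrane
    frame, z = 0 at the phosphate centre of mass). ``residue_filter``
    restricts to residue names (e.g. ``{"ARG", "LYS"}``).

    Returns ``(counts, bin_edges, residue_table)``.
    """
    if residue_filter is not None:
        wanted = [r for r in topo.residues if r.name in residue_filter]
        if not wanted:
            raise ValueError(f"no residues match filter {sorted(residue_filter)}")
    else:
        wanted = list(topo.residues)

    lipid_beads = topo.lipid_bead_ids
    prot_beads = np.array([b for r in wanted for b in r.bead_ids], dtype=np.intp)
    bead_owner = np.array(
        [r.residue_id for r in wanted for _ in r.bead_ids], dtype=np.intp
    )
    contact_frames = {r.residue_id: 0 for r in wanted}
    for f in range(traj.n_frames):
        x, b = traj.coords[f], traj.box[f]
        hits = geometry.beads_within_cutoff(x, b, lipid_beads, prot_beads, cutoff)
        for rid in np.unique(bead_owner[hits]):
            contact_frames[int(rid)] += 1

    zlast = traj.coords[-1]
    rows = []
    for r in wanted:
        p = contact_frames[r.residue_id] / traj.n_frames
        rows.append(
            {
                "residue_id": r.residue_id,
                "residue_name": r.name,
                "chain": r.chain,
                "contact_probability": p,
                "z_bb_final": float(zlast[r.bb_bead, 2]),
                "selected": p > min_contact_probability,
            }
        )
    table = pd.DataFrame(rows)
    zs = table.loc[table["selected"], "z_bb_final"].to_numpy()
    half = traj.box[-1, 2] / 2
    edges = np.arange(-half, half + bin_width / 2, bin_width)
    counts, edges = np.histogram(zs, bins=edges)
    return counts, edges, table


def bead_residue_profile(
    traj: Trajectory,
    topo: SystemTopology,
    lipid_type: str = "CDL",
    cutoff: float = CONTACT_CUTOFF,
) -> pd.DataFrame:
    """Contact counts between each bead role of a lipid type and each
    residue name.

    A contact is one (frame, lipid, residue) triple in which the given
    bead role of that lipid lies within ``cutoff`` of any bead of the
    residue. Returns a DataFrame indexed by bead role with residue-name
    columns.
    """
    lips = topo.lipids_of_type(lipid_type)
    if not lips:
        raise ValueError(f"no lipids of type {lipid_type!r} in the system")
    roles = list(LIPID_ROLE_ORDER.get(lipid_type) or sorted({r for l in lips for r in l.beads}))
    res_groups = [np.array(r.bead_ids, dtype=np.intp) for r in topo.residues]
    res_names = [r.name for r in topo.residues]
    names = sorted(set(res_names))
    counts = pd.DataFrame(0, index=roles, columns=names, dtype=int)

    for role in roles:
        bead_ids = np.array(
            [l.beads[role] for l in lips if role in l.beads], dtype=np.intp
        )
        if bead_ids.size == 0:
            continue
        d = geometry.group_min_distances(
            traj.coords,
            traj.box,
            [np.array([b]) for b in bead_ids],
            res_groups,
        )  # (F, n_lipids, n_residues)
        contact = d < cutoff
        per_res = contact.sum(axis=(0, 1))  # (frame, lipid) triples per residue
        for n, c in zip(res_names, per_res):
            counts.loc[role, n] += int(c)
    return counts


#: canonical display order of bead roles per lipid type (headgroup first)
LIPID_ROLE_ORDER = {
    "CDL": ["GL0", "PO1", "PO2", "C1A", "C2A", "C1B", "C2B"],
    "POPE": ["PO4", "C1A"],
    "POPG": ["PO4", "C1A"],
}


def top_contacting_residues(profile: pd.DataFrame, role: str, k: int = 5) -> pd.Series:
    """The k residue names with the most contacts for one bead role."""
    return profile.loc[role].sort_values(ascending=False).head(k)
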