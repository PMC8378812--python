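"""Readers and writers.

Standard formats (PDB/GRO structures, XTC/TRR/DCD trajectories) go through
MDAnalysis; the package additionally defines two plain-text formats of its
own — a JSON system description and a tabular trajectory — so synthetic
fixtures stay human-readable. Units: nm and ns internally everywhere;
MDAnalysis positions (Å) and times (ps) are converted on the way in and out.
Only orthorhombic boxes are accepted.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np

from .core import (
    PHOSPHATE_ROLES,
    Lipid,
    Residue,
    SystemTopology,
    TopologyError,
    Trajectory,
)

__all__ = [
    "LIPID_RESNAMES",
    "write_structure",
    "write_xtc",
    "write_tabular_trajectory",
    "read_tabular_trajectory",
    "write_system_json",
    "read_system_json",
    "write_ground_truth_json",
    "load_system",
    "write_pose_pdb",
]

logger = logging.getLogger(__name__)

#: residue names recognized as lipids when reading standard formats
LIPID_RESNAMES = ("POPE", "POPG", "CDL")


# ---------------------------------------------------------------------------
# MDAnalysis bridge
# ---------------------------------------------------------------------------

def _to_universe(topo: SystemTopology, coords_nm: np.ndarray, box_nm: np.ndarray):
    """Build an in-memory MDAnalysis universe mirroring the topology."""
    import MDAnalysis as mda

    mols = list(topo.residues) + list(topo.lipids)
    bead_info: list[tuple[int, str, int, str, str]] = []  # bead, name, resindex, resname, segid
    resnames, segids = [], []
    for ri, mol in enumerate(mols):
        if isinstance(mol, Residue):
            resnames.append(mol.name)
            segids.append(mol.chain or "A")
        else:
            resnames.append(mol.lipid_type)
            segids.append("MEMB")
        for role, b in mol.beads.items():
            bead_info.append((b, role, ri))
    bead_info.sort()  # global bead order
    if [b for b, _, _ in bead_info] != list(range(len(bead_info))):
        raise TopologyError("bead indices must be contiguous to write a structure")

    seg_labels = sorted(set(segids))
    seg_index = {s: i for i, s in enumerate(seg_labels)}
    u = mda.Universe.empty(
        n_atoms=len(bead_info),
        n_residues=len(mols),
        n_segments=len(seg_labels),
        atom_resindex=np.array([ri for _, _, ri in bead_info]),
        residue_segindex=np.array([seg_index[s] for s in segids]),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [role for _, role, _ in bead_info])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(len(mols)) + 1)
    u.add_TopologyAttr("segids", seg_labels)
    u.add_TopologyAttr("chainIDs", [segids[ri][:1] for _, _, ri in bead_info])
    u.atoms.positions = np.asarray(coords_nm, dtype=np.float32) * 10.0
    u.dimensions = [box_nm[0] * 10, box_nm[1] * 10, box_nm[2] * 10, 90, 90, 90]
    return u


def write_structure(
    topo: SystemTopology, coords_nm: np.ndarray, box_nm: np.ndarray, path: str | Path
) -> None:
    """Write a single-frame structure (GRO or PDB by extension; Å on disk)."""
    u = _to_universe(topo, coords_nm, np.asarray(box_nm, float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_xtc(topo: SystemTopology, traj: Trajectory, path: str | Path) -> None:
    """Write the trajectory as XTC (times ns → ps)."""
    import MDAnalysis as mda

    u = _to_universe(topo, traj.coords[0], traj.box[0])
    with mda.Writer(str(path), n_atoms=traj.n_beads) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coords[f].astype(np.float32) * 10.0
            u.dimensions = [*(traj.box[f] * 10.0), 90, 90, 90]
            u.trajectory.ts.frame = f
            u.trajectory.ts.time = traj.times[f] * 1000.0
            w.write(u.atoms)


def write_pose_pdb(
    topo: SystemTopology,
    traj: Trajectory,
    frame: int,
    path: str | Path,
) -> None:
    """Write one trajectory frame as a PDB (representative poses)."""
    u = _to_universe(topo, traj.coords[frame], traj.box[frame])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# package-native plain-text formats
# ---------------------------------------------------------------------------

def write_system_json(topo: SystemTopology, path: str | Path) -> None:
    doc = {
        "format": "lipidsites-system",
        "version": 1,
        "residues": [
            {
                "residue_id": r.residue_id,
                "name": r.name,
                "chain": r.chain,
                "beads": dict(r.beads),
            }
            for r in topo.residues
        ],
        "lipids": [
            {
                "lipid_id": l.lipid_id,
                "lipid_type": l.lipid_type,
                "leaflet": l.leaflet,
                "beads": dict(l.beads),
            }
            for l in topo.lipids
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_system_json(path: str | Path) -> SystemTopology:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "lipidsites-system":
        raise ValueError(f"{path} is not a lipidsites system file")
    residues = [
        Residue(d["residue_id"], d["name"], d["chain"], dict(d["beads"]))
        for d in doc["residues"]
    ]
    lipids = [
        Lipid(d["lipid_id"], d["lipid_type"], d["leaflet"], dict(d["beads"]))
        for d in doc["lipids"]
    ]
    return SystemTopology(residues=residues, lipids=lipids)


def write_tabular_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Plain TSV trajectory: frame, time_ns, bead_id, x/y/z (nm) with the
    per-frame box on comment lines."""
    with open(path, "w") as fh:
        fh.write("# lipidsites-trajectory v1\n")
        fh.write("# columns: frame\ttime_ns\tbead_id\tx_nm\ty_nm\tz_nm\n")
        for f in range(traj.n_frames):
            bx = traj.box[f]
            fh.write(f"# frame {f} time {traj.times[f]:.6f} box {bx[0]:.6f} {bx[1]:.6f} {bx[2]:.6f}\n")
            for b in range(traj.n_beads):
                x, y, z = traj.coords[f, b]
                fh.write(f"{f}\t{traj.times[f]:.6f}\t{b}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_tabular_trajectory(path: str | Path, stride: int = 1) -> Trajectory:
    times, boxes, frames_coords = [], [], []
    current: list[list[float]] | None = None
    with open(path) as fh:
        first = fh.readline()
        if "lipidsites-trajectory" not in first:
            raise ValueError(f"{path} is not a lipidsites tabular trajectory")
        for line in fh:
            if line.startswith("# frame"):
                parts = line.split()
                times.append(float(parts[4]))
                boxes.append([float(v) for v in parts[6:9]])
                current = []
                frames_coords.append(current)
            elif line.startswith("#") or not line.strip():
                continue
            else:
                parts = line.split("\t")
                current.append([float(parts[3]), float(parts[4]), float(parts[5])])
    coords = np.array(frames_coords, dtype=float)
    traj = Trajectory(np.array(times), coords, np.array(boxes))
    if stride > 1:
        traj = Trajectory(traj.times[::stride], traj.coords[::stride], traj.box[::stride])
    return traj


def write_ground_truth_json(ground_truth, path: str | Path) -> None:
    doc = {
        "format": "lipidsites-ground-truth",
        "version": 1,
        "sites": [
            {
                "residue_ids": sorted(g.site.residue_ids),
                "lipid_type": g.site.lipid_type,
                "lipid_id": g.lipid_id,
                "p_on": g.site.p_on,
                "p_off": g.site.p_off,
                "bound_distance_nm": g.site.bound_distance,
                "unbound_distance_nm": g.site.unbound_distance,
                "stationary_occupancy": g.site.stationary_occupancy,
                "realized_occupancy": g.realized_occupancy,
                "states": [int(s) for s in g.states],
            }
            for g in ground_truth
        ],
    }
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# loading standard formats
# ---------------------------------------------------------------------------

#: default bead-name → role map (identity for Martini-style names)
DEFAULT_ROLE_MAP: dict[str, str] = {}


def _check_orthorhombic(dimensions) -> np.ndarray:
    if dimensions is None:
        raise ValueError("structure has no box information")
    box = np.asarray(dimensions, dtype=float)
    if not np.allclose(box[3:], 90.0, atol=1e-3):
        raise ValueError("triclinic boxes are not supported (angles must be 90°)")
    return box[:3] / 10.0


def load_system(
    structure_path: str | Path,
    trajectory_path: str | Path | None = None,
    role_map: dict[str, str] | None = None,
    lipid_resnames: tuple[str, ...] = LIPID_RESNAMES,
    stride: int = 1,
    dt_ns: float | None = None,
    center: bool = True,
) -> tuple[SystemTopology, Trajectory]:
    """Load a structure (+ optional trajectory) into the internal model.

    Bead roles come from atom names through ``role_map`` (identity by
    default, matching Martini naming: BB, SC1.., PO4, GL0, PO1, PO2, ...).
    Leaflets are assigned from the sign of each lipid's phosphate z
    relative to the phosphate centre of mass in frame 0; a warning is
    logged if any lipid's sign disagrees in more than half of the loaded
    frames. The returned trajectory is z-centred on the phosphate centre
    of mass (membrane frame) unless ``center=False``.
    """
    import MDAnalysis as mda

    structure_path = str(structure_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = (
            mda.Universe(structure_path, str(trajectory_path))
            if trajectory_path
            else mda.Universe(structure_path)
        )
    role_map = role_map or {}

    residues: list[Residue] = []
    lipids: list[Lipid] = []
    rid = lid = 0
    for res in u.residues:
        roles = {}
        for atom in res.atoms:
            role = role_map.get(atom.name, atom.name)
            if role in roles:
                raise ValueError(
                    f"duplicate bead role {role!r} in residue {res.resname} {res.resid}"
                )
            roles[role] = int(atom.index)
        if res.resname in lipid_resnames:
            lipids.append(
                Lipid(lipid_id=lid, lipid_type=res.resname, leaflet="inner", beads=roles)
            )
            lid += 1
        else:
            chain = str(getattr(res.atoms[0], "chainID", "") or res.segid or "A")[:1]
            residues.append(
                Residue(residue_id=rid, name=res.resname, chain=chain, beads=roles)
            )
            rid += 1

    # trajectory frames (Å → nm, ps → ns)
    frames, times, boxes = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # single-frame readers lack dt
        for k, ts in enumerate(u.trajectory):
            if k % stride:
                continue
            boxes.append(_check_orthorhombic(ts.dimensions))
            frames.append(u.atoms.positions.astype(float) / 10.0)
            times.append(float(ts.time) / 1000.0)
    coords = np.array(frames)
    times = np.array(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        logger.warning("file carries no usable frame times; using frame index")
        times = np.arange(len(frames), dtype=float) * (dt_ns or 1.0)
    elif dt_ns is not None:
        times = np.arange(len(frames), dtype=float) * dt_ns

    # leaflets from phosphate z in frame 0
    phos_beads_per_lipid = []
    for l in lipids:
        pb = [b for r, b in l.beads.items() if r in PHOSPHATE_ROLES]
        if not pb:
            raise TopologyError(
                f"lipid {l.lipid_type} {l.lipid_id} has no phosphate-role bead"
            )
        phos_beads_per_lipid.append(pb)
    all_phos = [b for pb in phos_beads_per_lipid for b in pb]
    if not all_phos:
        raise TopologyError("no phosphate-role beads; membrane frame undefined")
    z0 = coords[0][:, 2]
    z_center = z0[all_phos].mean()
    relabeled: list[Lipid] = []
    for l, pb in zip(lipids, phos_beads_per_lipid):
        sign = np.mean(z0[pb]) - z_center
        leaflet = "inner" if sign < 0 else "outer"
        relabeled.append(Lipid(l.lipid_id, l.lipid_type, leaflet, l.beads))
        # stability check over the loaded frames
        zl = coords[:, pb, 2].mean(axis=1) - coords[:, all_phos, 2].mean(axis=1)
        flipped = np.mean((zl < 0) != (sign < 0))
        if flipped > 0.5:
            logger.warning(
                "lipid %d (%s) phosphate z changes sign in %.0f%% of frames; "
                "leaflet label may be unreliable",
                l.lipid_id,
                l.lipid_type,
                100 * flipped,
            )
    topo = SystemTopology(residues=residues, lipids=relabeled)
    traj = Trajectory(times=times, coords=coords, box=np.array(boxes))
    if center:
        traj = traj.center_membrane(topo)
    return topo, traj
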