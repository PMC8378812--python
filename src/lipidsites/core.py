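"""Core containers: system topology and trajectory.

Internal conventions used throughout the package:

* lengths in nm, times in ns;
* orthorhombic periodic boxes only (lengths ``(lx, ly, lz)``);
* the membrane frame puts the phosphate-bead centre of mass at z = 0,
  with the inner (cytoplasmic) leaflet at negative z;
* frame indices are 0-based everywhere, including serialized events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Residue",
    "Lipid",
    "SystemTopology",
    "Trajectory",
    "TopologyError",
    "BASIC_RESIDUES",
    "POLAR_RESIDUES",
    "AROMATIC_RESIDUES",
    "CDL_HEADGROUP_ROLES",
    "PHOSPHATE_ROLES",
]

#: residue-category sets used by the annotation and rule stages.
#: His is *not* basic here: side chains are modelled in their default
#: protonation state with His neutral, so it counts as polar instead.
BASIC_RESIDUES = frozenset({"ARG", "LYS"})
POLAR_RESIDUES = frozenset({"SER", "THR", "HIS"})
AROMATIC_RESIDUES = frozenset({"PHE", "TRP", "TYR"})

#: the three cardiolipin headgroup beads: central glycerol + two phosphates.
CDL_HEADGROUP_ROLES = frozenset({"GL0", "PO1", "PO2"})

#: bead roles treated as "the phosphate" when locating the membrane plane
#: and assigning leaflets.
PHOSPHATE_ROLES = frozenset({"PO4", "PO1", "PO2"})


class TopologyError(ValueError):
    """Raised when a system description violates a structural invariant."""


@dataclass(frozen=True)
class Residue:
    """A protein residue as a set of coarse-grained beads.

    ``beads`` maps bead role (``"BB"`` for the backbone bead, ``"SC1"`` ...
    for side-chain beads) to a global bead index into the coordinate array.
    """

    residue_id: int
    name: str
    chain: str
    beads: Mapping[str, int]

    @property
    def bead_ids(self) -> tuple[int, ...]:
        return tuple(self.beads.values())

    @property
    def bb_bead(self) -> int:
        if "BB" not in self.beads:
            raise TopologyError(f"residue {self.residue_id} has no BB bead")
        return self.beads["BB"]


@dataclass(frozen=True)
class Lipid:
    """A lipid molecule: type, leaflet label and role→bead-index map."""

    lipid_id: int
    lipid_type: str
    leaflet: str  # "inner" | "outer"
    beads: Mapping[str, int]

    @property
    def bead_ids(self) -> tuple[int, ...]:
        return tuple(self.beads.values())

    def beads_with_roles(self, roles: Iterable[str] | None) -> tuple[int, ...]:
        """Bead indices restricted to ``roles`` (None keeps every bead)."""
        if roles is None:
            return self.bead_ids
        roles = set(roles)
        out = tuple(b for r, b in self.beads.items() if r in roles)
        return out

    @property
    def phosphate_beads(self) -> tuple[int, ...]:
        return self.beads_with_roles(PHOSPHATE_ROLES)


class SystemTopology:
    """Residues plus lipids, with category sets and bead bookkeeping.

    Every bead index must belong to exactly one residue or lipid; every
    lipid needs a leaflet label; every CDL lipid must expose the GL0, PO1
    and PO2 headgroup beads.
    """

    def __init__(
        self,
        residues: Sequence[Residue],
        lipids: Sequence[Lipid],
        basic: frozenset[str] = BASIC_RESIDUES,
        polar: frozenset[str] = POLAR_RESIDUES,
        aromatic: frozenset[str] = AROMATIC_RESIDUES,
    ):
        self.residues = tuple(residues)
        self.lipids = tuple(lipids)
        self.basic = frozenset(basic)
        self.polar = frozenset(polar)
        self.aromatic = frozenset(aromatic)
        self._validate()
        self._res_by_id = {r.residue_id: r for r in self.residues}
        self._lip_by_id = {l.lipid_id: l for l in self.lipids}

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        seen: set[int] = set()
        for mol in (*self.residues, *self.lipids):
            for b in mol.bead_ids:
                if b in seen:
                    raise TopologyError(f"bead {b} assigned to more than one molecule")
                seen.add(b)
        if seen and seen != set(range(len(seen))):
            raise TopologyError("bead indices must form a contiguous 0-based range")
        for lip in self.lipids:
            if lip.leaflet not in ("inner", "outer"):
                raise TopologyError(
                    f"lipid {lip.lipid_id} has leaflet {lip.leaflet!r}; "
                    "expected 'inner' or 'outer'"
                )
            if lip.lipid_type == "CDL" and not CDL_HEADGROUP_ROLES <= set(lip.beads):
                raise TopologyError(
                    f"CDL lipid {lip.lipid_id} lacks GL0/PO1/PO2 headgroup beads"
                )
        ids = [r.residue_id for r in self.residues]
        if len(ids) != len(set(ids)):
            raise TopologyError("duplicate residue_id")
        ids = [l.lipid_id for l in self.lipids]
        if len(ids) != len(set(ids)):
            raise TopologyError("duplicate lipid_id")

    # -- lookups ---------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return sum(len(r.beads) for r in self.residues) + sum(
            len(l.beads) for l in self.lipids
        )

    def residue(self, residue_id: int) -> Residue:
        try:
            return self._res_by_id[residue_id]
        except KeyError:
            raise TopologyError(f"unknown residue_id {residue_id}") from None

    def lipid(self, lipid_id: int) -> Lipid:
        try:
            return self._lip_by_id[lipid_id]
        except KeyError:
            raise TopologyError(f"unknown lipid_id {lipid_id}") from None

    @property
    def protein_bead_ids(self) -> np.ndarray:
        return np.array(
            [b for r in self.residues for b in r.bead_ids], dtype=np.intp
        )

    @property
    def lipid_bead_ids(self) -> np.ndarray:
        return np.array([b for l in self.lipids for b in l.bead_ids], dtype=np.intp)

    @property
    def phosphate_bead_ids(self) -> np.ndarray:
        return np.array(
            [b for l in self.lipids for b in l.phosphate_beads], dtype=np.intp
        )

    def lipids_of_type(self, lipid_type: str) -> tuple[Lipid, ...]:
        return tuple(l for l in self.lipids if l.lipid_type == lipid_type)

    @property
    def lipid_types(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for l in self.lipids:
            seen.setdefault(l.lipid_type, None)
        return tuple(seen)

    def residue_category(self, name: str) -> str:
        if name in self.basic:
            return "basic"
        if name in self.polar:
            return "polar"
        if name in self.aromatic:
            return "aromatic"
        return "other"


class Trajectory:
    """Per-frame bead coordinates with an orthorhombic periodic box.

    Parameters
    ----------
    times : (F,) frame times in ns, strictly increasing.
    coords : (F, B, 3) coordinates in nm.
    box : (3,) or (F, 3) box lengths in nm, all positive.
    """

    def __init__(self, times: np.ndarray, coords: np.ndarray, box: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.coords = np.asarray(coords, dtype=float)
        box = np.asarray(box, dtype=float)
        if box.ndim == 1:
            box = np.broadcast_to(box, (self.coords.shape[0], 3)).copy()
        self.box = box
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_beads, 3)")
        if self.times.shape[0] != self.coords.shape[0]:
            raise ValueError("times and coords disagree on the number of frames")
        if self.box.shape != (self.coords.shape[0], 3):
            raise ValueError("box must have shape (3,) or (n_frames, 3)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Median frame spacing in ns."""
        if self.n_frames < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    def center_membrane(self, topo: SystemTopology) -> "Trajectory":
        """Shift every frame so the phosphate-bead centre of mass sits at z = 0.

        Returns a new trajectory; x and y are untouched.
        """
        phos = topo.phosphate_bead_ids
        if phos.size == 0:
            raise TopologyError("no phosphate-role beads; membrane frame undefined")
        coords = self.coords.copy()
        zshift = coords[:, phos, 2].mean(axis=1)
        coords[:, :, 2] -= zshift[:, None]
        return Trajectory(self.times, coords, self.box)
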