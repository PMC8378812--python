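"""Site annotation and occupancy stratification.

Classifies identified sites by basic-residue content — in particular by
whether two or more Arg/Lys backbone beads sit within 0.8 nm of each other
in 3-D (the geometric signature of a phosphate-coordinating cardiolipin
site) — flags the presence of Gly/His/Pro/Ser/Thr, and compares occupancy
distributions between strata with two-tailed t-tests.

Adjacency is measured on the static input-model coordinates (frame 0 of
the trajectory, or a supplied structure), not on trajectory averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import SystemTopology
from .sites import BindingSite

__all__ = [
    "find_adjacent_basics",
    "SiteAnnotation",
    "annotate_site",
    "compare_groups",
    "stratify_occupancies",
    "ADJACENCY_CUTOFF",
]

ADJACENCY_CUTOFF = 0.8  # nm, backbone-bead 3-D distance
COMPOSITION_NAMES = ("GLY", "HIS", "PRO", "SER", "THR")


def find_adjacent_basics(
    site_residues,
    topo: SystemTopology,
    coords: np.ndarray,
    cutoff: float = ADJACENCY_CUTOFF,
) -> list[tuple[int, int, float, float]]:
    """Arg/Lys pairs in a site whose backbone beads are within ``cutoff``.

    ``coords`` are static structure coordinates (nm), indexed by bead id.
    Returns ``(residue_i, residue_j, distance_nm, z_separation_nm)`` with
    i < j; plain Euclidean distance (a protein never straddles the box).
    """
    basics = sorted(
        r for r in site_residues if topo.residue(r).name in topo.basic
    )
    pairs = []
    for a in range(len(basics)):
        for b in range(a + 1, len(basics)):
            xi = coords[topo.residue(basics[a]).bb_bead]
            xj = coords[topo.residue(basics[b]).bb_bead]
            d = float(np.linalg.norm(xi - xj))
            if d < cutoff:
                pairs.append((basics[a], basics[b], d, float(abs(xi[2] - xj[2]))))
    return pairs


@dataclass
class SiteAnnotation:
    """Basic-residue geometry and composition flags for one site."""

    site_id: int
    n_basic: int
    adjacent_pairs: list[tuple[int, int, float, float]] = field(default_factory=list)
    n_adjacent_cluster: int = 0  # largest set of mutually linked adjacent basics
    has_adjacent_basics: bool = False
    composition_flags: dict[str, bool] = field(default_factory=dict)
    leaflet: str = "inner"

    def as_row(self) -> dict:
        row = {
            "site_id": self.site_id,
            "n_basic": self.n_basic,
            "n_adjacent_pairs": len(self.adjacent_pairs),
            "n_adjacent_cluster": self.n_adjacent_cluster,
            "has_adjacent_basics": self.has_adjacent_basics,
            "leaflet": self.leaflet,
        }
        for name in COMPOSITION_NAMES:
            row[f"has_{name}"] = self.composition_flags.get(name, False)
        return row


def annotate_site(
    site: BindingSite,
    topo: SystemTopology,
    coords: np.ndarray,
    cutoff: float = ADJACENCY_CUTOFF,
) -> SiteAnnotation:
    """Annotate one site from static structure coordinates.

    The result is invariant to residue ordering within the site. The site
    leaflet is the sign of the mean backbone z (membrane frame): negative
    → inner (cytoplasmic), positive → outer.
    """
    names = [topo.residue(r).name for r in site.residue_ids]
    n_basic = sum(1 for n in names if n in topo.basic)
    pairs = find_adjacent_basics(site.residue_ids, topo, coords, cutoff)
    # size of the largest connected cluster of adjacency-linked basics
    cluster = 0
    if pairs:
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from([(p[0], p[1]) for p in pairs])
        cluster = max(len(c) for c in nx.connected_components(g))
    zmean = float(
        np.mean([coords[topo.residue(r).bb_bead][2] for r in site.residue_ids])
    )
    return SiteAnnotation(
        site_id=site.site_id,
        n_basic=n_basic,
        adjacent_pairs=pairs,
        n_adjacent_cluster=cluster,
        has_adjacent_basics=cluster >= 2,
        composition_flags={n: (n in names) for n in COMPOSITION_NAMES},
        leaflet="inner" if zmean < 0 else "outer",
    )


def compare_groups(
    x, y, test: str = "welch"
) -> tuple[float, float]:
    """Two-tailed two-sample t-test between occupancy groups.

    ``test`` is ``"welch"`` (unequal variances, the default) or
    ``"pooled"``. Returns ``(t, p)``; with fewer than two observations in
    either group the test is undefined and ``(nan, nan)`` is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        return float("nan"), float("nan")
    if test == "welch":
        r = stats.ttest_ind(x, y, equal_var=False)
    elif test == "pooled":
        r = stats.ttest_ind(x, y, equal_var=True)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(r.statistic), float(r.pvalue)


def _group_row(label: str, occ: np.ndarray) -> dict:
    occ = np.asarray(occ, dtype=float)
    if occ.size:
        q1, med, q3 = np.percentile(occ, [25, 50, 75])
    else:
        q1 = med = q3 = float("nan")
    return {
        "group": label,
        "n": int(occ.size),
        "median_occupancy": float(med),
        "iqr_low": float(q1),
        "iqr_high": float(q3),
        "mean_occupancy": float(occ.mean()) if occ.size else float("nan"),
    }


def stratify_occupancies(
    sites: list[BindingSite],
    annotations: list[SiteAnnotation],
    test: str = "welch",
    adjust: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occupancy strata by basic-residue content, plus composition contrasts.

    Strata: all sites; any Arg/Lys ("KR"); none ("no KR"); exactly one
    ("1 KR"); at least two ("≥2 KR"); at least two / three adjacency-linked
    basics ("≥2 KR adj" / "≥3 KR adj"). Contrasts (two-tailed t-test per
    pair): KR vs no KR, ≥2 KR adj vs ≥2 KR non-adjacent, and — among sites
    with ≥2 adjacent basics — with vs without each of Gly, His, Pro, Ser,
    Thr. Also reports the mean number of basics per KR site with both SD
    and SEM. ``adjust="bh"`` appends Benjamini–Hochberg adjusted p-values.
    """
    ann = {a.site_id: a for a in annotations}
    occ = np.array([s.occupancy for s in sites])
    a_of = [ann[s.site_id] for s in sites]
    nb = np.array([a.n_basic for a in a_of])
    adj = np.array([a.n_adjacent_cluster for a in a_of])

    strata = {
        "all": np.ones(len(sites), dtype=bool),
        "KR": nb >= 1,
        "no KR": nb == 0,
        "1 KR": nb == 1,
        ">=2 KR": nb >= 2,
        ">=2 KR adj": adj >= 2,
        ">=3 KR adj": adj >= 3,
    }
    rows = [_group_row(label, occ[mask]) for label, mask in strata.items()]
    strata_df = pd.DataFrame(rows)
    kr_counts = nb[nb >= 1]
    strata_df.attrs["mean_basics_per_KR_site"] = (
        float(kr_counts.mean()) if kr_counts.size else float("nan")
    )
    strata_df.attrs["sd_basics_per_KR_site"] = (
        float(kr_counts.std(ddof=1)) if kr_counts.size > 1 else float("nan")
    )
    strata_df.attrs["sem_basics_per_KR_site"] = (
        float(kr_counts.std(ddof=1) / np.sqrt(kr_counts.size))
        if kr_counts.size > 1
        else float("nan")
    )

    contrasts = []

    def add_contrast(label, mask1, mask0, name1, name0):
        x, y = occ[mask1], occ[mask0]
        t, p = compare_groups(x, y, test=test)
        contrasts.append(
            {
                "contrast": label,
                "group1": name1,
                "n1": int(mask1.sum()),
                "median1": float(np.median(x)) if x.size else float("nan"),
                "group0": name0,
                "n0": int(mask0.sum()),
                "median0": float(np.median(y)) if y.size else float("nan"),
                "t": t,
                "p": p,
                "valid": bool(mask1.sum() >= 2 and mask0.sum() >= 2),
            }
        )

    add_contrast("KR vs no KR", nb >= 1, nb == 0, "KR", "no KR")
    add_contrast(
        "adjacent vs non-adjacent (>=2 KR)",
        (nb >= 2) & (adj >= 2),
        (nb >= 2) & (adj < 2),
        ">=2 KR adj",
        ">=2 KR non-adj",
    )
    base = adj >= 2
    for name in COMPOSITION_NAMES:
        has = np.array([a.composition_flags.get(name, False) for a in a_of])
        add_contrast(
            f"{name} vs no {name} (>=2 KR adj)",
            base & has,
            base & ~has,
            f"with {name}",
            f"without {name}",
        )
    contrasts_df = pd.DataFrame(contrasts)
    if adjust == "bh":
        p = contrasts_df["p"].to_numpy()
        ok = np.isfinite(p)
        q = np.full_like(p, np.nan)
        if ok.sum():
            q[ok] = _benjamini_hochberg(p[ok])
        contrasts_df["p_adj_bh"] = q
    return strata_df, contrasts_df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
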