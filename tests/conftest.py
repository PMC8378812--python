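"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by the most direct route
possible (frame-by-frame automata, exhaustive all-pairs scans, textbook
formulas) and never call the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import lipidsites as ls

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def dual_cutoff_oracle(distances, lower, upper):
    """Frame-by-frame two-state automaton, straight from the stated rule."""
    state = False
    out = []
    for d in distances:
        if not state and d < lower:
            state = True
        elif state and d > upper:
            state = False
        out.append(state)
    return np.array(out, dtype=bool)


def brute_force_contacts(coords, box, ids_a, ids_b, cutoff):
    """Exhaustive all-pairs minimum-image scan, no spatial indexing."""
    box = np.asarray(box, float)
    out = set()
    for a in ids_a:
        for b in ids_b:
            diff = coords[a] - coords[b]
            diff = diff - box * np.round(diff / box)
            if np.sqrt((diff**2).sum()) < cutoff:
                out.add((int(a), int(b)))
    return out


def pooled_t(x, y):
    """Textbook pooled-variance two-sample t statistic."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def welch_t(x, y):
    """Textbook Welch t statistic and Welch–Satterthwaite dof."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    v1, v2 = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(v1 + v2)
    dof = (v1 + v2) ** 2 / (v1**2 / (len(x) - 1) + v2**2 / (len(y) - 1))
    return t, dof


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def planted_system():
    """A small membrane with one planted inner-leaflet CDL site."""
    # residues 2-4 sit on the z = -1.8 nm ring → an inner-leaflet site;
    # p_off = 0.05 keeps the mean dwell (20 frames) safely above the 10 ns
    # residence filter.
    params = ls.GeneratorParams(
        seed=7,
        n_lipids_per_leaflet=20,
        n_frames=400,
        planted_sites=(
            ls.PlantedSite(residue_ids=frozenset({2, 3, 4}), p_on=0.3, p_off=0.05),
        ),
        exclude_background_nm=1.2,
    )
    return ls.generate_system(params)


@pytest.fixture(scope="session")
def two_site_system():
    """Two disjoint planted triplets on different residues."""
    params = ls.GeneratorParams(
        seed=9,
        n_lipids_per_leaflet=30,
        n_frames=600,
        planted_sites=(
            ls.PlantedSite(residue_ids=frozenset({1, 2, 3}), p_on=0.3, p_off=0.05),
            ls.PlantedSite(residue_ids=frozenset({7, 8, 9}), p_on=0.2, p_off=0.05),
        ),
        exclude_background_nm=1.2,
    )
    return ls.generate_system(params)


def make_bound_series(states, lipid_ids=None, residue_ids=None, dt=1.0):
    """Hand-built BoundSeries from a (F, L, R) boolean array."""
    states = np.asarray(states, dtype=bool)
    F, L, R = states.shape
    return ls.BoundSeries(
        lipid_ids=np.arange(L) if lipid_ids is None else np.asarray(lipid_ids),
        residue_ids=np.arange(R) if residue_ids is None else np.asarray(residue_ids),
        states=states,
        lower=0.55,
        upper=1.0,
        dt=dt,
    )
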