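"""Contact analyses: minimum-image distances, propensity, profiles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import lipidsites as ls
from lipidsites import geometry
from lipidsites.contacts import top_contacting_residues
from lipidsites.core import Lipid, Residue, SystemTopology, Trajectory

from conftest import brute_force_contacts


def _tiny_system(bead_positions, lipid_positions, box=(10.0, 10.0, 10.0), n_frames=1):
    """One ARG residue + point lipids at fixed positions, one POPE 'far' lipid
    per missing leaflet so propensity preconditions hold."""
    residues = [Residue(0, "ARG", "A", {"BB": 0})]
    coords = [np.asarray(bead_positions[0], float)]
    lipids = []
    bead = 1
    for k, (ltype, leaflet, pos) in enumerate(lipid_positions):
        # CDL needs its three headgroup beads; stack them at one point
        roles = ("GL0", "PO1", "PO2") if ltype == "CDL" else ("PO4",)
        lipids.append(Lipid(k, ltype, leaflet, {r: bead + i for i, r in enumerate(roles)}))
        coords.extend([np.asarray(pos, float)] * len(roles))
        bead += len(roles)
    topo = SystemTopology(residues, lipids)
    xyz = np.tile(np.array(coords)[None], (n_frames, 1, 1))
    traj = Trajectory(np.arange(n_frames, dtype=float), xyz, np.array(box))
    return topo, traj


class TestMinDistance:
    def test_minimum_image_across_boundary(self):
        topo, traj = _tiny_system(
            [(0.2, 5.0, 5.0)], [("POPE", "inner", (9.9, 5.0, 5.0))]
        )
        assert ls.min_distance(topo, traj, 0, 0, 0) == pytest.approx(0.3)

    def test_identical_coordinates_give_zero(self):
        topo, traj = _tiny_system([(1.0, 1.0, 1.0)], [("POPE", "inner", (1.0, 1.0, 1.0))])
        assert ls.min_distance(topo, traj, 0, 0, 0) == 0.0

    def test_unknown_ids_and_empty_filter_rejected(self):
        topo, traj = _tiny_system([(1, 1, 1)], [("POPE", "inner", (2, 2, 2))])
        with pytest.raises(ls.TopologyError):
            ls.min_distance(topo, traj, 5, 0, 0)
        with pytest.raises(ValueError, match="no beads"):
            ls.min_distance(topo, traj, 0, 0, 0, bead_filter={"GL0"})

    def test_matches_exhaustive_scan_on_random_frame(self):
        rng = np.random.default_rng(0)
        box = np.array([5.0, 5.0, 5.0])
        coords = rng.uniform(0, 5, size=(20, 3))
        d = geometry.pairwise_distances(coords[:10], coords[10:], box)
        expect = np.empty((10, 10))
        for i in range(10):
            for j in range(10):
                diff = coords[i] - coords[10 + j]
                diff -= box * np.round(diff / box)
                expect[i, j] = np.linalg.norm(diff)
        np.testing.assert_allclose(d, expect, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        box = np.array([4.0, 6.0, 8.0])
        a, b = rng.uniform(0, 4, size=(2, 5, 3))
        d1 = geometry.pairwise_distances(a, b, box)
        d2 = geometry.pairwise_distances(b, a, box).T
        np.testing.assert_allclose(d1, d2, atol=1e-12)
        shift = rng.integers(-3, 4, size=3) * box
        d3 = geometry.pairwise_distances(a + shift, b, box)
        np.testing.assert_allclose(d1, d3, atol=1e-9)


class TestIndexedContacts:
    def test_contact_pairs_match_brute_force(self):
        rng = np.random.default_rng(42)
        box = np.array([6.0, 6.0, 6.0])
        coords = rng.uniform(-3, 9, size=(60, 3))  # deliberately unwrapped
        ids_a = np.arange(0, 25)
        ids_b = np.arange(25, 60)
        fast = geometry.contact_pairs(coords, box, ids_a, ids_b, 0.9)
        slow = brute_force_contacts(coords, box, ids_a, ids_b, 0.9)
        assert fast == slow


class TestPropensity:
    def _worked_example_system(self):
        """10 bound lipids of which 2 CDL (20 %); 50 lipids of which 5 CDL
        (10 %) per leaflet — the textbook 20/10 = 2 case."""
        lipid_positions = []
        for leaflet in ("inner", "outer"):
            bound = [("CDL", leaflet)] * 2 + [("POPE", leaflet)] * 8
            far = [("CDL", leaflet)] * 3 + [("POPE", leaflet)] * 37
            for k, (t, leaf) in enumerate(bound):
                ang = 2 * np.pi * k / 10
                pos = (5 + 0.4 * np.cos(ang), 5 + 0.4 * np.sin(ang), 5.0)
                lipid_positions.append((t, leaf, pos))
            for k, (t, leaf) in enumerate(far):
                ang = 2 * np.pi * k / 40
                pos = (5 + 3.0 * np.cos(ang), 5 + 3.0 * np.sin(ang), 5.0)
                lipid_positions.append((t, leaf, pos))
        return _tiny_system([(5.0, 5.0, 5.0)], lipid_positions, n_frames=5)

    def test_worked_example_propensity_two(self):
        topo, traj = self._worked_example_system()
        prop = ls.lipid_binding_propensity(traj, topo, equilibration_skip=0.0)
        for leaflet in ("inner", "outer", "membrane"):
            row = prop[(prop.lipid_type == "CDL") & (prop.leaflet == leaflet)]
            assert row.propensity.item() == pytest.approx(2.0)
            assert row.bound_fraction.item() == pytest.approx(0.20)
            assert row.total_fraction.item() == pytest.approx(0.10)

    def test_proportional_binding_gives_unit_propensity(self):
        # every lipid bound: bound fractions equal total fractions exactly
        lipid_positions = []
        for leaflet in ("inner", "outer"):
            for k, t in enumerate(["CDL"] * 2 + ["POPE"] * 6 + ["POPG"] * 2):
                ang = 2 * np.pi * k / 10
                lipid_positions.append(
                    (t, leaflet, (5 + 0.4 * np.cos(ang), 5 + 0.4 * np.sin(ang), 5.0))
                )
        topo, traj = _tiny_system([(5.0, 5.0, 5.0)], lipid_positions)
        prop = ls.lipid_binding_propensity(traj, topo, equilibration_skip=0.0)
        assert np.allclose(prop.propensity, 1.0)

    def test_single_type_membrane_propensity_one(self):
        lipid_positions = [
            ("POPE", "inner", (5.3, 5.0, 5.0)),
            ("POPE", "outer", (5.0, 5.3, 5.0)),
            ("POPE", "inner", (8.0, 8.0, 5.0)),
        ]
        topo, traj = _tiny_system([(5.0, 5.0, 5.0)], lipid_positions)
        prop = ls.lipid_binding_propensity(traj, topo, equilibration_skip=0.0)
        assert np.allclose(prop.propensity, 1.0)

    def test_skip_fraction_must_be_below_one(self):
        topo, traj = _tiny_system(
            [(5, 5, 5)], [("POPE", "inner", (5.3, 5, 5)), ("POPE", "outer", (6, 5, 5))]
        )
        with pytest.raises(ValueError, match="fraction"):
            ls.lipid_binding_propensity(traj, topo, equilibration_skip=1.0)

    def test_empty_leaflet_rejected(self):
        topo, traj = _tiny_system([(5, 5, 5)], [("POPE", "inner", (5.3, 5, 5))])
        with pytest.raises(ValueError, match="outer"):
            ls.lipid_binding_propensity(traj, topo)

    def test_planted_cdl_site_enriches_inner_leaflet(self, planted_system):
        """A planted inner-leaflet CDL site must push CDL inner propensity
        above 1 and above the outer value."""
        topo, traj, _ = planted_system
        prop = ls.lipid_binding_propensity(traj, topo)
        cdl = prop[prop.lipid_type == "CDL"].set_index("leaflet").propensity
        assert cdl["inner"] > 1.0
        # outer leaflet: either nothing bound at all (NaN propensity) or
        # strictly less enriched than the planted inner leaflet
        assert np.isnan(cdl["outer"]) or cdl["inner"] > cdl["outer"]


class TestZProfile:
    def test_never_contacting_residue_excluded(self):
        topo, traj = _tiny_system(
            [(5, 5, 5)],
            [("POPE", "inner", (1.0, 1.0, -2.0)), ("POPE", "outer", (1.0, 1.0, 2.0))],
            n_frames=4,
        )
        counts, edges, table = ls.contacting_residue_z_profile(traj, topo)
        assert counts.sum() == 0
        assert not table.selected.any()
        assert table.contact_probability.item() == 0.0

    def test_always_contacting_residue_counted_at_final_bb_z(self):
        topo, traj = _tiny_system(
            [(5.0, 5.0, -2.0)],
            [("POPE", "inner", (5.3, 5.0, -2.0)), ("POPE", "outer", (1.0, 1.0, 2.0))],
            n_frames=4,
        )
        counts, edges, table = ls.contacting_residue_z_profile(traj, topo)
        assert table.contact_probability.item() == 1.0
        assert counts.sum() == 1
        bin_idx = np.digitize(-2.0, edges) - 1
        assert counts[bin_idx] == 1

    def test_planted_inner_site_mass_at_negative_z(self, planted_system):
        topo, traj, _ = planted_system
        counts, edges, _ = ls.contacting_residue_z_profile(
            traj, topo, residue_filter={"ARG", "LYS"}
        )
        centers = (edges[:-1] + edges[1:]) / 2
        assert counts.sum() > 0
        assert counts[centers < 0].sum() == counts.sum()

    def test_empty_residue_filter_match_rejected(self, planted_system):
        topo, traj, _ = planted_system
        with pytest.raises(ValueError, match="no residues match"):
            ls.contacting_residue_z_profile(traj, topo, residue_filter={"XYZ"})


class TestBeadResidueProfile:
    def test_permanent_contact_with_lone_arg(self):
        residues = [Residue(0, "ARG", "A", {"BB": 0})]
        beads = {r: i + 1 for i, r in enumerate(["GL0", "PO1", "PO2", "C1A", "C2A", "C1B", "C2B"])}
        lipids = [
            Lipid(0, "CDL", "inner", beads),
            Lipid(1, "POPE", "outer", {"PO4": 8}),
        ]
        topo = SystemTopology(residues, lipids)
        coords = np.zeros((3, 9, 3))
        coords[:, 0] = [5, 5, 5]
        for b in beads.values():
            coords[:, b] = [5.3, 5, 5]
        coords[:, 8] = [1, 1, 1]
        traj = Trajectory(np.arange(3.0), coords, np.array([10.0, 10, 10]))
        prof = ls.bead_residue_profile(traj, topo, "CDL")
        assert (prof["ARG"] == 3).all()  # every role, every frame
        assert prof.drop(columns="ARG").to_numpy().sum() == 0
        top = top_contacting_residues(prof, "GL0", k=1)
        assert top.index[0] == "ARG"

    def test_unknown_lipid_type_rejected(self, planted_system):
        topo, traj, _ = planted_system
        with pytest.raises(ValueError, match="no lipids of type"):
            ls.bead_residue_profile(traj, topo, "DOPC")

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(1)
        residues = [
            Residue(i, n, "A", {"BB": 2 * i, "SC1": 2 * i + 1})
            for i, n in enumerate(["ARG", "SER", "LEU"])
        ]
        beads = {r: 6 + i for i, r in enumerate(["GL0", "PO1", "PO2", "C1A", "C2A", "C1B", "C2B"])}
        lipids = [Lipid(0, "CDL", "inner", beads), Lipid(1, "POPE", "outer", {"PO4": 13})]
        topo = SystemTopology(residues, lipids)
        coords = rng.uniform(0, 4, size=(6, 14, 3))
        traj = Trajectory(np.arange(6.0), coords, np.array([4.0, 4, 4]))
        prof = ls.bead_residue_profile(traj, topo, "CDL", cutoff=0.8)
        # oracle: exhaustive per-frame per-pair scan
        expect = {role: {n: 0 for n in ["ARG", "LEU", "SER"]} for role in beads}
        for f in range(6):
            for role, b in beads.items():
                for r in residues:
                    dmin = min(
                        np.linalg.norm(
                            (coords[f, b] - coords[f, rb])
                            - 4.0 * np.round((coords[f, b] - coords[f, rb]) / 4.0)
                        )
                        for rb in r.bead_ids
                    )
                    if dmin < 0.8:
                        expect[role][r.name] += 1
        for role in beads:
            for name in ["ARG", "LEU", "SER"]:
                assert prof.loc[role, name] == expect[role][name]
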