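# lipidsites

Analysis of lipid interactions with membrane proteins in coarse-grained
(CG) molecular-dynamics trajectories, focused on the anionic phospholipid
cardiolipin (CDL). Bacterial inner-membrane proteins bind CDL at discrete
surface sites, typically built around pairs of basic residues on the
cytoplasmic face of the membrane; `lipidsites` provides the full analysis
chain for detecting and characterizing such sites, plus a synthetic-data
generator with planted ground truth so every stage is testable without
production simulation data.

Intended users: structural bioinformaticians and simulators working with
Martini-style CG systems (POPE/POPG/CDL membranes, proteins as backbone +
side-chain beads) who want reproducible, scriptable lipid-site analysis.

## What it computes

**Binding propensity** (leaflet-resolved). A lipid counts as bound in a
frame when any of its beads is within 0.6 nm of any protein bead. For
lipid type $t$,

$$\mathrm{propensity}(t) \;=\; \frac{\text{$t$ as fraction of bound lipid}}{\text{$t$ as fraction of total lipid}}$$

so 1 means no enrichment; if CDL is 20 % of the bound lipid but 10 % of
the membrane, its propensity is 20/10 = 2.

**Dual-cutoff binding kinetics.** Per (lipid, residue) pair the distance
series is converted to a hysteretic bound state: binding starts when the
distance drops below 0.55 nm and ends only when it exceeds 1.0 nm,
suppressing flicker from thermal fluctuation of the lipid within a site.

**Binding-site identification.** Residues that are simultaneously bound to
the same CDL headgroup (beads GL0/PO1/PO2) are linked in a weighted
co-binding graph; seeded modularity (Louvain) community detection
partitions the graph into candidate sites. Per site:
occupancy = frames bound / total frames; residence time = mean duration of
continuous contact events (optional single-exponential survival fit); sites
with residence ≤ 10 ns are discarded and residues contributing < 10 % of
the site occupancy are pruned.

**Annotation and statistics.** Sites are classified by basic-residue
content, in particular *adjacent* Arg/Lys pairs (backbone beads within
0.8 nm in 3-D), and occupancy distributions are compared across strata
(no basics / one / two or more / adjacent) with two-tailed Welch t-tests.

**Rule engine.** A candidate site on a membrane-oriented structure is
scored against the three-part signature of a high-affinity CDL site:
(1) ≥ 2 basic residues pairwise within 0.8 nm, within 0.3 nm on z, about
1.8 nm from the membrane centre; (2) ≥ 1 polar residue (Ser/Thr/His);
(3) ≥ 1 aromatic residue deeper in the membrane. `scan_structure`
enumerates and ranks all candidates on a structure.

## Worked example

Generate a small membrane (20 lipids per leaflet at 67 % POPE / 23 % POPG
/ 10 % CDL) with one planted inner-leaflet CDL site on three Arg residues
(per-frame kinetics p_on = 0.3, p_off = 0.05), then recover the site:

```python
import lipidsites as ls

params = ls.GeneratorParams(
    seed=42, n_lipids_per_leaflet=20, n_frames=2000,
    planted_sites=(ls.PlantedSite(residue_ids=frozenset({2, 3, 4}),
                                  p_on=0.3, p_off=0.05),),
    exclude_background_nm=1.2,
)
topo, traj, truth = ls.generate_system(params)
print("expected occupancy:", truth[0].site.stationary_occupancy)
print("realized occupancy:", truth[0].realized_occupancy)

sites, bound = ls.find_binding_sites(traj, topo, lipid_type="CDL")
for s in sites:
    print(f"site {s.site_id}: residues {sorted(s.residue_ids)} "
          f"occupancy {s.occupancy:.3f} residence {s.residence_time:.1f} ns "
          f"events {len(s.events)}")

ann = ls.annotate_site(sites[0], topo, traj.coords[0])
print("n_basic:", ann.n_basic, "leaflet:", ann.leaflet)
```

prints

```
expected occupancy: 0.8571428571428572
realized occupancy: 0.886
site 0: residues [2, 3, 4] occupancy 0.886 residence 23.3 ns events 76
n_basic: 3 leaflet: inner
```

The planted residue triplet is recovered exactly; the measured occupancy
equals the realized fraction of bound frames (0.886, close to the
stationary expectation p_on/(p_on+p_off) = 0.857); the mean residence
(23.3 ns) is a finite-sample estimate of the expected dwell
1/p_off = 20 ns; and the site is annotated as a three-basic inner-leaflet
site.

The same pipeline is available from the shell:

```bash
lipidsites generate --out-dir run1 --seed 42 --plant 2,3,4 --p-off 0.05
lipidsites sites --structure run1/structure.gro --trajectory run1/trajectory.xtc --out-dir run1/sites
```

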