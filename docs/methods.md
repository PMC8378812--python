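# Methods

This note documents the models, parameter choices and numerical decisions
behind `lipidsites`, and what the synthetic benchmark does and does not
demonstrate about real coarse-grained (CG) simulation data.

## Conventions

All lengths are nm, all times ns, frame indices 0-based. Boxes are
orthorhombic; triclinic inputs are rejected at the I/O layer. The membrane
frame places the phosphate-bead centre of mass at z = 0 with the inner
(cytoplasmic) leaflet at negative z. Residue categories: basic = {Arg,
Lys}; polar = {Ser, Thr, His}; aromatic = {Phe, Trp, Tyr}. His is treated
as polar, not basic, because side chains are modelled in their default
protonation state with His neutral. CDL is represented with the three
headgroup beads GL0 (central glycerol), PO1 and PO2 (phosphates) plus tail
beads; its −2 charge is metadata only — no analysis here uses charges.

## Contact analyses

A contact is a bead-pair distance strictly below the cutoff under the
orthorhombic minimum-image convention. The global contact cutoff is
0.6 nm; the 0.55/1.0 nm dual cutoff is reserved for site kinetics. The two
coexist deliberately: enrichment and profile analyses ask "is the lipid at
the protein surface now?", while site kinetics ask "is the lipid engaged
in the same binding event?", which needs hysteresis to avoid splitting one
event into many at the noise scale.

Contact queries use a periodic KD tree (`scipy.spatial.cKDTree` with
`boxsize`), with coordinates wrapped by modulo first — wrapping leaves
minimum-image distances unchanged. The test suite checks tree-based
contact sets against exhaustive all-pairs scans.

*Propensity.* Bound-lipid counts are averaged over post-equilibration
frames (default: the first 10 % of frames are discarded, configurable).
Within each leaflet, the bound fraction of each lipid type is divided by
its total fraction. Because the natural denominator (per-leaflet vs
whole-membrane) is a genuine modelling choice, the table reports rows for
`inner`, `outer` and pooled `membrane`. When no lipid of a leaflet is
bound at all, fractions and propensity are undefined (NaN) rather than 0.

*z-profile.* For residues whose any-lipid contact probability over all
frames exceeds 10 %, the backbone-bead z at the final frame is emitted and
histogrammed (bin width 0.1 nm; the bin width is our choice — an
occupancy-weighted mean position would be smoother, but the final-frame
backbone position is the plainer, and therefore default, definition).

*Bead-residue profiles.* Counts of (frame, lipid, residue) triples in
which a given bead role of the lipid type is within the cutoff of any bead
of a residue of a given name, with a top-k accessor per role.

## Dual-cutoff kinetics

State starts unbound; becomes bound when the distance drops below the
lower cutoff (0.55 nm); stays bound while it remains ≤ the upper cutoff
(1.0 nm); unbinds when it exceeds it. With lower = upper the rule is
single-cutoff thresholding. The implementation is a vectorized
last-crossing scan (a frame is bound iff the most recent crossing event at
or before it was a below-lower one), verified against a frame-by-frame
automaton in the tests. Hysteresis gives a monotonicity guarantee —
raising the upper cutoff can only extend bound runs — which is property-
tested.

## Site identification

Only the CDL headgroup beads (GL0/PO1/PO2) enter the distances used for
site identification; the residue side always uses all beads.

*Co-binding graph.* Edge weight between residues i and j is the number of
(lipid, frame) pairs in which the same lipid is simultaneously bound to
both, normalized by the smaller of the two residues' bound (lipid, frame)
counts. Edges below 0.3 are dropped. The normalization and threshold are
design choices: the min-normalization makes the weight a conditional
co-binding probability for the rarer residue, and 0.3 is low enough that
residue-level flicker within a genuine site never disconnects it, while
incidental simultaneous binding of two separate sites by one lipid (which
produces weights near zero) never bridges them.

*Community detection.* Louvain modularity maximization
(`networkx.community.louvain_communities`) with a fixed seed, making the
partition reproducible run-to-run. Singleton communities with no retained
edge are discarded. Disconnected cliques are recovered as separate sites;
a uniform-weight clique is never split (both property-tested on random
fixtures).

*Metrics.* A frame is site-bound when any lipid of the target type is
bound to ≥ 1 site residue; occupancy is the bound-frame fraction and is
recomputable from the serialized events (maximal continuous runs per
lipid, inclusive frame ranges). A lipid bound to residues of two sites
counts toward both sites' occupancies, but each event is counted once per
site: sites are defined residue-side. Residence time defaults to the mean
event duration, matching the definition of residence as the time a lipid
is continuously in contact with any site residue. A single-exponential
survival-curve fit (`--residence-estimator survival-fit`) is available
and falls back to the mean below 20 events, where a fit is not
meaningful.

*Filters.* Sites with residence ≤ 10 ns are removed (shorter-lived
clusters are indistinguishable from free diffusion past the surface);
within surviving sites, residues with individual bound occupancy below
10 % of the site occupancy are pruned and metrics recomputed. The
threshold compares times directly, so it is exact for any frame spacing;
with the generator's default dt = 1 ns it equals 10 frames. Filtering is
applied after residue pruning would not change the residence ordering in
any fixture we construct, so the order (residence filter, then pruning,
then metric recomputation) is fixed and documented rather than
configurable.

*Representative pose.* The longest event (ties: earliest start, lowest
lipid id), at the frame minimizing the mean over site residues of the
minimum headgroup-bead distance (ties: lowest frame).

## Annotation and statistics

Adjacency between basic residues uses backbone-bead positions from the
static input model (frame 0 / supplied structure), not trajectory
averages, with a 0.8 nm 3-D cutoff. "≥ k adjacent basics" means the
largest connected component of the pair-adjacency graph has ≥ k members.
Occupancy strata (all / any KR / none / exactly one / ≥ 2 / ≥ 2 adjacent /
≥ 3 adjacent) are summarized by n, median and interquartile range; the
mean number of basics per basic-containing site is reported with both SD
and SEM since either convention appears in the literature. Contrasts use
Welch's unequal-variance two-tailed t-test by default (a pooled-variance
option exists); p-values are reported raw, with an optional
Benjamini–Hochberg adjustment behind a flag. Degenerate groups (< 2
observations) yield NaN p-values flagged invalid.

## Rule engine

Thresholds live in one `RuleParams` object. Operationalizations where the
qualitative description needed a number: "roughly 1.8 nm from the membrane
centre" becomes a band of 1.8 ± 0.5 nm; "slightly deeper" becomes ≥ 0.2 nm
deeper than the basic cluster's mean |z|; both configurable. The depth of
a residue is measured at its backbone bead, consistent with the adjacency
analysis. Tyr counts as aromatic by default with a flag to restrict to
Phe/Trp. Gly content is reported as a bonus annotation, not a rule.
Qualifying clusters are enumerated exhaustively over basic pairs and
triples (the rule targets two-to-three basics); candidates grow by all
residues within 1.0 nm of a cluster member and are ranked by rules passed,
then cluster compactness, then residue ids — fully deterministic. Scores
depend only on pairwise distances and |z|, hence are invariant under
rotation about z and x/y translation, and tightening any threshold can
only shrink the pass set; both are tested.

## Synthetic generator

The generator emulates: a two-leaflet POPE/POPG/CDL membrane at the
67/23/10 composition (largest-remainder rounding converts fractions to
per-leaflet counts deterministically), CG bead granularity (residues as
BB + optional SC1 bead on a cylinder spanning the membrane; lipids as one
phosphate + one tail bead, CDL as GL0/PO1/PO2 + four tails), lipid lateral
diffusion, and planted binding sites with two-state Markov kinetics.

Parameters that matter:

- `composition` — per-type fractions, default 0.67/0.23/0.10.
- `n_frames`, `dt` — default dt = 1 ns per frame, so the 10 ns residence
  filter is 10 frames and dwell arithmetic is transparent in tests.
- `step_sigma` — background-lipid step SD per axis per frame, default
  0.3 nm at dt = 1 ns, i.e. a lateral diffusion coefficient of
  ~4.5 × 10⁻⁷ cm² s⁻¹, within the range typical of CG lipids.
- `PlantedSite(p_on, p_off, bound_distance, unbound_distance)` — per-frame
  on/off probabilities give stationary occupancy p_on/(p_on+p_off) and
  mean dwell 1/p_off frames; the bound pose places each headgroup bead
  0.45 nm from a site residue (strictly inside the 0.55 nm lower cutoff)
  and the unbound pose parks the lipid > 1 nm beyond the protein, so the
  dual-cutoff rule recovers the planted state series exactly. The initial
  state is drawn from the stationary distribution so realized occupancy is
  unbiased.
- `exclude_background_nm` — optional lateral exclusion zone keeping
  background lipids away from the protein, used in planted-kinetics
  studies where planted binding must be the only binding. Off by default,
  because the propensity analyses need background lipids to reach the
  protein.

Two deliberate non-realisms, and why: the protein is static (ground truth
for contact analysis must be unambiguous), and background lipids of every
type share one bead geometry — head beads at the phosphate plane
(|z| = 2 nm), tail beads at |z| = 1 nm, all at the lipid's (x, y). The
shared geometry makes the minimum distance to the protein identical in
distribution across types, so binding is exactly composition-proportional
when nothing is planted — the null the propensity tests require. Real CG
lipids differ in shape, flexibility and charge; passing tests here
demonstrate the correctness of the bookkeeping and algorithms, not that
any real lipid mixture is unenriched. Likewise the Markov planted kinetics
have geometric dwell times, while real binding shows multi-exponential
kinetics; the survival-fit estimator exists for that case but is validated
here only against geometric events.

`generate_rule_structure` plants a three-rule motif (Arg/Lys 0.5 nm apart
at depth ~1.8 nm, a Ser in plane, a Trp one ring deeper) among isolated
decoy basics (≥ 1.3 nm from any other basic, so no decoy pair can satisfy
the rule-1 geometry) and an optional rule-1-only decoy pair to exercise
ranking.

## Problem sizes in the test suite

The suite runs the kinetics-recovery study at 20,000 frames × 5 seeds × 3
(p_on, p_off) settings with 20 lipids per leaflet, clustering and
rule-engine correctness on 100 random fixtures each, and oracle
comparisons on hundreds of random series/frames; the full suite completes
in well under a minute on one CPU. These sizes give comfortable
statistical margins for the assertions made (e.g. occupancy SE ≈ 0.007 at
20,000 frames against a ±0.05 tolerance) and are the package's reference
benchmark conditions.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- Leaflet assignment is static (topology or frame-0 phosphate z); lipids
  that genuinely flip-flop are flagged with a warning, not reassigned.
- No free-energy estimation: occupancy and residence are kinetic
  summaries, not binding affinities.
- Site typing is single-lipid-type per analysis; run per type.
- The co-binding weight threshold (0.3) was chosen for robust separation
  of disjoint planted sites; densely overlapping real sites may need the
  threshold, or the community resolution, revisited.
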