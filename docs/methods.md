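# Methods

This note documents the model implemented by the package, its tunable
parameters, the synthetic-data generator used to validate it, and the
design choices made where the construction was genuinely open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Communication model

The unit of analysis is a conformational ensemble: a set of frames of one
molecular system (pooled over replicates after discarding a leading
equilibration fraction of each replicate; `discard_leading`, default 0.25
in the CLI, i.e. the last three quarters of each replicate are analysed).

**Communication propensity.** CP(i,j) is the population variance over
frames of the Cα–Cα distance of residues i and j (Å²). It needs no
superposition — inter-residue distances are invariant under rigid
transforms — and is computed on raw coordinates. Low CP means the pair
moves in concert: efficient communication.

**Threshold calibration.** Backbone stretches in well-formed secondary
structure are expected to communicate efficiently, so they calibrate the
threshold. MCP(i) sums CP(i,j) over same-chain sequence neighbours within
±4 residues (by author residue number) and divides by a literal 8 even at
chain termini, where fewer terms exist; a normalise-by-count mode exists
but is not the default, keeping the printed formula exact. p_ss is the
fraction of residues with a DSSP label in {H, E, T} in strictly more than
half of the frames (3-10/π helices map to H, β-bridges to E, hydrogen
bonded turns to T, bends and coil to C). CP_cut is the p_ss-quantile
(linear interpolation between order statistics) of the MCP distribution.
Residues of short ligand chains (< 9 residues) contribute to CP but are
left out of the MCP distribution and p_ss; peptide ligands of ≥ 9 residues
count as chains. The efficiency predicate is inclusive, CP ≤ CP_cut
(a strict mode exists): robustness to floating-point equality.
When an ensemble has no stable secondary structure at all (p_ss = 0 would
make the quantile undefined), the quantile level falls back to 0.5.

**Stable interactions.** Two classes per frame: hydrogen bonds —
donor/acceptor N/O heavy atoms within 3.5 Å, at least one oxygen in the
pair, and a D–H···A angle ≥ 120° whenever a donor hydrogen is available;
hydrophobic contacts — apolar carbon pairs (carbons bonded to no N/O/S,
from templates of the 20 standard residue types) within 4.5 Å. For
structures without hydrogens, backbone amide nitrogens get a virtual
hydrogen placed opposite the bisector of the C(prev)–N and CA–N bonds
(the construction DSSP uses), so the angle criterion still applies; a
pure distance criterion accepts i→i+2 O···N pairs (~3.4 Å) along helices
that no hydrogen-bond assignment would. Side-chain donors without
hydrogens remain distance-only. Covalent sequence neighbours (residue
number difference ≤ 1 on one chain) are excluded. A residue pair's
occupancy is the fraction of analysis frames with any qualifying atom
pair; pairs below `s_min` = 0.5 are dropped. Detection uses an exact
mean-structure prefilter (candidate atom pairs within cutoff plus the two
largest per-atom displacements) followed by vectorised per-frame
distances. The 3.5 Å / 120° / 4.5 Å / 0.5 values are config keys; they are
standard structural-biology choices.

**Pathways.** A pathway is a maximal simple chain in the graph whose edges
are stable interactions between sequence-non-adjacent residues (number
difference ≥ 2, or different chains), subject to the clique-like
constraint that *every* pair of members is efficient. Enumeration is
depth-first from every residue, neighbours visited in index order
(canonical output), pruning a candidate extension as soon as it is
inefficient with any current member; results are deduplicated by
orientation and contiguous subpaths of retained pathways (either
orientation) are discarded. A `max_pathways` budget (default 500 000)
guards pathological dense graphs. Pathway-adjacent pairs are *direct*
communications; non-adjacent co-members are *indirect*.

**Dynamical units.** Pathway-based units are connected components of the
pathway-adjacency graph; clique-based units are connected components of
the shared-clique graph. Cliques are maximal cliques (pivoting
enumeration) of size ≥ 3 over flexible candidate residues — RMSF above the
70th percentile of the per-residue distribution — with edges requiring
time-averaged minimum heavy-atom distance < 3.7 Å and displacement
correlation > `corr_cut` (default 0.5); a clique whose mean |correlation|
to non-members exceeds 0.3 is rejected as not independent. The RMSF
percentile, correlation threshold and independence bound are this
package's own substitutes for an unpublished local-feature-analysis
construction; all three are config keys.

**Superposition.** RMSD/RMSF/correlations require a frame of reference.
Frames are least-squares superposed (Kabsch) on frame 0 using Cα atoms,
then *refined on the core*: a second pass fits only residues whose Cα
fluctuation is at or below the median. Without the second pass, a few
highly flexible residues drag the fit and leak apparent anti-correlated
motion into rigid regions (we measured spurious |corr| ≈ 0.6 between an
independent flexible loop and a rigid helix in the synthetic generator);
core-fitting is standard MD practice. RMSF averages per-atom mean squared
deviations from the mean structure over all heavy atoms of a residue
(a Cα-only switch exists).

**Persistency scores.** Units are recomputed over a threshold sweep and
each residue scores the fraction of settings in which it belongs to a unit
of each kind. Pathway-based units depend only on CP_cut and clique-based
units only on the correlation threshold, so each kind is scored on its own
one-dimensional grid (a product grid would only replicate rows): CP_cut
quantile from p_ss up to 0.80 in steps of 0.05, stopping early once a
single pathway-based unit spans every protein residue; correlation
threshold from 0.5 downward in steps of 0.05 for six settings (floor
0.25). The floor stays above the sampling noise of a correlation estimate
from hundreds of frames (s.e. ≈ 1/√F ≈ 0.045 at F = 500); thresholds below
it would admit noise cliques among any proximal residues.

**Burial.** The circular variance of an atom is 1 − |mean unit vector to
all atoms within r_c = 20 Å|; a residue's CV averages its atoms' values on
the ensemble-mean structure (a per-frame mode exists), ligand atoms
included as neighbours. Per protein, values are min–max rescaled and
residues with scaled CV ≥ 0.6 are buried (inclusive; a raw-value switch
exists). The threshold applies to scaled values because scores are
defined on the rescaled profile; the raw/scaled ambiguity is inherent to
calibrating CV against solvent accessibility without an accessibility
reference.

**Bridge strategies.** (1) *Unit overlap*: residues with pathway and
clique persistency both strictly above 0.8. (2) *Ligand direct*: protein
residues pathway-adjacent to a ligand residue — a strictly stronger
condition than physical contact, since the pair must also be efficient.
(3) *Isolated direct communication*: over the CP_cut sweep, rebuild
pathways and the dot plot at each setting; black dots (direct pairs, not
grey) are isolated when their motif — connected dots under 8-neighbour
adjacency (4-neighbour configurable) — contains at most 5 black dots, no
grey dot and at most 4 colored dots; the union over the sweep is kept.
"Grey" means same chain and sequence separation < 4 (the dot-plot
convention; also the operational meaning of "far in sequence" for
strategy 3). Burial filters strategies 1 and 3; ligand-facing residues
are exempt because interface residues are partially exposed by
construction. Criteria (same pathway-based unit, direct communication)
are evaluated at the sweep setting that produced each dot.

**Mutant classification.** Each mutant ensemble reduces to the number of
pathways longer than {3,4,5,6} residues and the number of highly connected
residues (crossed by strictly more than k pathways; k = 70 by default for
protein-sized systems). A mutant is called highly deleterious when its
count strictly exceeds x times the wild-type count, x = 1.2 recommended.
Experimental ΔE labels (kcal/mol): neutral at ΔE ≥ −0.2 (beneficial folds
into neutral), deleterious below −0.2, highly deleterious below −1.0.
Inverse-CDF curves report, per class, the percentage of mutants with a
statistic strictly greater than x over the pooled support; the permutation
test permutes class labels and compares the maximal vertical curve
difference, with p = (#{permuted ≥ observed} + 1)/(B + 1) — the +1
correction avoids p = 0 at finite B. The pathway-network hull volume
takes pathways longer than 3 residues, iteratively deletes edges with a
degree-1 endpoint until a fixpoint (order-independent), and computes the
convex hull of the remaining Cα coordinates.

**Metrics.** Sensitivity, specificity, precision, accuracy, F1 and MCC are
reported as integer percentages, half rounded away from zero, matching the
convention of published benchmark tables; zero-denominator metrics are
reported as undefined (None), never as 0.

## Synthetic generator

The generator emulates the statistical structure the communication model
assumes, so that every pipeline stage is testable without MD data. The
mean structure is idealized: rigid blocks are ideal α-helices built by
internal-coordinate (NeRF) chain construction (φ = −57°, ψ = −47°,
standard bond lengths/angles) with Cβ atoms; flexible loops are compact
blobs (regular simplex of Cα positions, edge ≈ 3.45 Å, minimal backbone
templates); a peptide ligand chain extends radially outward from its
contact residue. Planted side-chain contacts re-aim the Cβ atoms of a
pair at each other at 4.0 Å — inside helices these stitch the four
backbone i→i+4 hydrogen-bond strands into one connected block, the role
side-chain packing plays in real helices. Self-avoidance: Cα spacing
≥ 3.0 Å and atom clash tolerance 1.8 Å, enforced on the mean structure.

Per frame, displacements are Gaussian: every rigid block shares one
rigid-body translation (σ = 0.35–0.55 Å per axis) plus independent
per-residue jitter (σ = 0.1 Å) applied to whole residues, so intra-block
CP ≈ 2σ²jitter; loop residues share a correlated displacement
(σ = 1.0 Å, ρ = 0.9) giving high RMSF and pairwise correlation ≈ ρ. A
planted bridge pair receives shared noise perpendicular to its separation
vector (σ = 0.9 Å) — decoupling both residues from their flanks — and the
second residue copies the first plus 1-D noise along the separation with
the prescribed distance variance (default 0.05 Ų): the pair communicates
efficiently only with itself, which is what makes its dot isolated. A
unit-overlap residue rides the loop's shared noise projected
perpendicular to the separation toward one designated helix partner: it
joins the loop clique (flexible, correlated, proximal) while keeping one
low-variance pathway contact. The ligand copies the rigid noise of the
helix it binds with one planted hydrogen bond.

Three reference architectures define the study conditions (500 frames,
20 seeds, per-experiment):

* *unit recovery*: one 18-residue helix + one 4-residue loop — the helix
  should return as a pathway-based unit, the loop as a clique-based unit;
* *bridge showcase*: two 16-residue helices (axis separation 13 Å: no
  accidental interface contacts) + connecting loop + bridge pair +
  unit-overlap residue + 3-residue ligand — the three strategies should
  each recover exactly their planted bridge;
* *mutant family*: two 16-residue helices packed at 12.5 Å with four
  planted interface contacts whose communication sits *above* the
  wild-type CP_cut. Deleterious "mutants" inflate the independent jitter
  of the loop and the helix residues flanking it (σ 0.6–1.0 Å) — local
  backbone communication degrades, MCP and hence CP_cut rise, the
  interface contacts become efficient and pathway counts explode.
  Neutral mutants only rescale the correlated loop amplitude (±15%),
  which barely moves neighbour distance variances (correlated motion
  cancels). The classifier statistic uses k = the 75th percentile of the
  wild-type traversal distribution: an absolute k = 70 presumes a
  100+-residue system with thousands of pathways and does not transfer to
  a 36-residue construct.

What the generator does **not** emulate: physical energetics, realistic
Ramachandran statistics or side-chain rotamers, solvent, anharmonic or
multi-state dynamics, and the coupling between secondary-structure
stability and noise amplitude (DSSP labels stay essentially constant
across synthetic mutants). Passing the recovery tests therefore shows
that the pipeline detects the planted statistical signatures — low
distance variance against a noisy background, correlated flexible
clusters, threshold-crossing pathway proliferation — not that real
mutational effects are predictable at these rates.

## Numerical choices and degenerate inputs

* Quantiles: numpy linear interpolation; sweep grids rounded to 10
  decimals to keep cache keys stable.
* Pathway enumeration is deterministic and independent of interaction
  ordering (neighbour lists sorted); unit ids order by smallest member.
* Zero-variance residues get correlation 0 with a warning; atoms with no
  neighbour within r_c count as maximally protruding (CV 0) with a
  warning; a single-residue system has no defined CV scaling (error).
* Ensembles need ≥ 2 frames (≥ 10 for correlations); an analysis window
  leaving < 2 frames is an error; a residue without a Cα is a hard error
  naming the residue.
* Problem sizes in the validation suite (500 frames, 20 seeds, ≤ 40
  residues; 200 null simulations at B = 199 for calibration) were chosen
  as the smallest at which the planted-signal estimates are stable.

## Known limitations

* Maximal-path enumeration is exponential in dense efficient graphs; the
  budget guard raises an explicit error rather than degrading silently.
* MCP's literal /8 makes chain termini systematically low; with the
  quantile calibration this slightly deflates CP_cut for short chains.
* The burial threshold on min–max rescaled CV depends on the protein's
  own CV range; very small systems compress the scale.
* Trajectory formats are limited to what mdtraj reads; multi-chain PDBs
  without chain ids get letters assigned in order of appearance.
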