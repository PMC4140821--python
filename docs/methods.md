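# Methods

This note records the models, numerical choices and open design decisions
behind each module, and what the synthetic test conditions do and do not
demonstrate about real data.

## Structures and transforms

Structures are chain → residue → atom hierarchies in Å with author
numbering; parsing and writing delegate to gemmi. Altloc groups resolve to
the highest-occupancy conformer (ties to the alphabetically first altloc
id). Hydrogens are retained on read but excluded from every geometric
operation. Modified residues map to `X` in one-letter sequences unless
`map_modified=True` maps common cases (MSE→M, SEP→S, …) to parents. Rigid
placements are `Pose` objects (proper rotation, det +1 within 1e-8, plus
translation); composition and application are exact group operations, so
pairwise distances are preserved to 1e-9 Å.

## Superposition

`kabsch` is the SVD least-squares fit with the determinant correction that
forbids reflections; collinear or < 3-point inputs are rejected as
degenerate. `iterative_superpose` seeds residue pairs from a global
BLOSUM62 alignment (gap open 8, extend 1 — adequate for remote homologues
of a shared fold at ~20–25% identity), then alternates superposition on the
current pairs with pruning of pairs beyond `prune_cutoff` (default 3.5 Å,
max 20 iterations). Pruned pairs re-enter whenever they fall back under the
cutoff, so convergence means the matched-pair set is a fixed point; the
reported quantities are the rmsd over that core and the percent identity of
matched pairs. Pair-admission heuristics of classical iterative-superposition
programs differ in detail, so rmsd/pair counts on real remote homologues
should be treated as tolerance-level reproductions, not exact matches.

## Surface areas and shape complementarity

SASA is Shrake–Rupley with a Chothia-like radius set (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, default 1.70 Å), probe 1.4 Å, and a deterministic
Fibonacci sphere (default 960 points; heavier sampling available where
accuracy matters). The sampling sphere is oriented in a canonical molecule
frame (principal axes, signs fixed by the atom farthest from the centroid),
which makes areas exactly invariant under rigid transforms; operations that
difference areas of parts and wholes (buried area, per-residue ΔSASA,
interface membership) evaluate all terms in one shared frame so the
sampling cancels exactly and separated partners bury exactly zero.

"Total buried area" counts both sides, `SASA(A)+SASA(B)−SASA(A∪B)`
(`both_sides=False` halves it). A residue is interfacial iff its ΔSASA
exceeds 1 Å² or it has any heavy-atom contact within 5 Å (union rule).

Shape complementarity follows the Lawrence–Colman statistic but on
probe-extended Shrake–Rupley dot surfaces rather than a triangulated
Connolly surface: buried dots are accessible dots within a 1.5 Å band of
the partner's dot set, each scored `(n·−n′)·exp(−0.5 d²)` against its
nearest partner dot, and Sc is the mean of the two per-side medians. On
coarse-grained surfaces this approximation compresses the Sc scale (toy
helix interfaces score ~0.0–0.3 rather than the ~0.65–0.75 of well-packed
atomic interfaces); within one pose population the ordering is still
informative, which is all the filtering/re-ranking pipeline uses. Sc floors
should therefore be calibrated per system (the constraint-derivation helper
sets the floor relative to a reference pose) rather than taken from
atomic-resolution conventions.

## Conservation

The per-column score is the mean over unordered non-gap residue pairs of a
normalized BLOSUM62 similarity, `clamp₀¹[(B(x,y) − Bmin)/((B(x,x)+B(y,y))/2
− Bmin)]`, scaled to 100. Bmin is the minimum of the 20×20 standard-residue
block (−4). This satisfies the one hard constraint the method needs — an
identical, gap-free column scores exactly 100 — and is symmetric, bounded
and monotone under adding identical sequences. Pairs containing gaps or X
are skipped (partial columns still score); columns with fewer than two
usable residues are flagged undefined rather than zeroed. This pairwise
form is the single largest inference in the package: consensus-based or
phylogeny-weighted normalizations would satisfy the same constraint and
differ in the mid-range. Mapping onto a chain requires the de-gapped
reference to match the chain sequence at ≥ 95% positional identity;
interface enrichment is the difference of mean scores between interface and
non-interface surface residues.

## Docking: generation, filtering, re-ranking, clustering

The pose generator is a desk-scale stand-in for an FFT docking engine, not
a re-implementation of one: orientations come from a z-y-z Euler grid
(θ ∈ [0°, 180°]) deduplicated as rotations by quaternion comparison, and
each orientation is slid along the receptor→ligand center axis until the
minimal heavy-atom separation converges to the midpoint of a 3.0–4.5 Å
touching window — so every pose touches identically and orientation alone
differentiates them. A naive Euler grid deduplicates to a different
orientation count than the near-uniform internal rotation sets of
production docking programs; counts are therefore checked against an
exhaustive quaternion oracle, not against any external program's set.

Filtering applies hard experimental constraints per pose: passive residues
(experimentally unperturbed; must not be interfacial, tolerance 0),
required residues per partner (must all be interfacial), a buried-area
window (default 1200–1800 Å², bracketing the scale of a compact
heterodimer interface), and an Sc floor. Reason codes record which
constraint failed. Re-ranking z-scores {Sc, buried-area window hinge
(0 inside, −distance/100 Å² outside), conservation enrichment, total
contacts} over the passing poses with unit default weights; composites are
rounded to 1e-9 before ordering so exact symmetric cancellations resolve by
the deterministic pose-id tie-break. Whether the original hard-filter /
soft-composite split matches any particular published protocol is not
knowable from the outside; both halves are configurable. Clustering is
greedy leader clustering in rank order on ligand-Cα RMSD in the receptor
frame (default cutoff 5 Å), representative = best-ranked member.

`PoseScorer` evaluates all per-pose metrics with one fixed sampling frame
and caches everything rigid-invariant; pose scoring defaults to 240 surface
points per atom (≈0.5 Å² quantization), a throughput choice for scoring
hundreds of poses — single-interface reports use the 960-point default.

## Cross-links

Links are lysine-reactive (DSS) residue pairs with xQuest-style scores;
the post-search keep rule is ld > 25 and ΔS < 0.95, and rows lacking scores
are kept with a warning since published tables are usually post-filter.
Audits measure Cα–Cα distances (the reporting convention for DSS bounds;
Nε–Nε is not used), classify satisfied (< 40 Å), outlier (> 60 Å) and
violated-non-outlier (40–60 Å), and report means with and without
outliers. 40 Å is a display/restraint convention for DSS at Cα resolution;
tighter practice (30–35 Å) is a parameter away. Ambiguous links (residue in
several copies) take the minimum distance and are flagged. The restraint is
a flat-bottom harmonic `k·max(0, d − d_upper)²` with an analytic gradient
(checked against central differences at 1e-5).

## Density

Maps are x,y,z-ordered grids with per-axis voxel size and an origin at the
center of voxel (0,0,0); on read, a nonzero ORIGIN header wins, else
nxstart × voxel. Simulation places one Gaussian per heavy atom with
amplitude ∝ atomic number and kernel FWHM equal to the nominal resolution
(σ = R/2√(2 ln 2); σ = R/2 or R/2π conventions exist — only relative
correlations matter downstream, so the choice is a convention, not a
result). Voxel sizes above R/2 are rejected as undersampling. `ccc` is the
Pearson correlation after trilinear resampling onto the first map's grid;
"local" restricts to voxels within 5 Å of a model atom.

Rigid fitting scans translations exhaustively by FFT cross-correlation of
the simulated subunit density against the (mean-removed) map for every
orientation of a deduplicated Euler grid, extracts multiple correlation
peaks per orientation by non-maximum suppression (so symmetric or repeated
subunits yield distinct candidate placements), re-scores the top candidates
by true local ccc, and polishes the winner with Nelder–Mead over all six
rigid parameters (explicit initial simplex: ~6° rotations, one-voxel
translations — the default degenerate simplex at the origin cannot close
the sub-voxel quantization of the FFT scan). The returned ccc is never
below the best scanned candidate by construction.

## Elastic network and flexible fitting

Normal modes are the anisotropic network model: uniform springs between Cα
pairs within 12 Å, Hessian eigendecomposition, modes indexed from 1 with
the six rigid-body modes first (first internal mode = mode 7, per the
common convention); disconnected networks are an error naming component
sizes. Distance-weighted spring variants shift frequencies but barely
change low-mode shapes, which are the object of interest; the uniform model
is kept for transparency. Normalized squared displacements are
`|u_i|²/Σ|u_j|²` per residue.

Flexible fitting is a deterministic restrained minimization, a desk-scale
replacement for thermostatted flexible-fitting MD: the objective over Cα
positions is

    E = w_e·Σ_edges (|r_ij| − |r⁰_ij|)² + w_x·Σ_links k·max(0, d − 40)² + w_m·(1 − local ccc)

with defaults w_e = 1, w_x = 0.1, w_m = 10 and 500 cycles. Elastic edges
are intra-chain only: the starting model's inter-subunit arrangement is
exactly what the density and cross-link terms must remodel, so restraining
it would oppose the fit. All heavy atoms ride rigidly on their residue's
Cα and contribute to the simulated density, so a model at its own simulated
map is a true stationary point. The minimizer is L-BFGS with its line
search (plain steepest descent stalls on the ill-conditioned mix of stiff
elastic edges and soft collective subunit motion, recovering ~1 Å of an
8 Å displacement in 500 cycles, where L-BFGS recovers it fully); the
recorded trace keeps the accepted-step energies, which are non-increasing.
The ccc gradient is analytic through the Gaussian kernel over a fixed
model-proximal voxel mask (radius max(5 Å, 2σ)) computed from the starting
model; a fit that must travel far beyond that mask should be restarted or
given a larger radius. Restraint weights in published flexible-fitting
protocols are rarely printed; the defaults here are engineering choices,
configurable per run.

## Synthetic data: what it emulates, and what it does not

Toy subunits are ideal α-helix Cα traces (rise 1.5 Å, radius 2.3 Å,
100°/residue) with one pseudo-Cβ per residue; every 7th residue is lysine
so cross-link generation is deterministic and structure-independent.
Assemblies are clash-free rings or parallel bundles. The docking pair's
"native" is constructed as a grid-searched, Nelder–Mead-polished local
optimum of interfacial quality (smooth packing + Sc) at touching contact:
real native complexes are packing/complementarity optima, and decoy
recovery is only a well-posed experiment when the planted answer is the
pose the metrics prefer. Decoys perturb the native by random-axis Gaussian
rotations (default σ 20°) and Gaussian axis shifts (σ 5 Å), re-touched to
contact. Cross-link tables draw a stated fraction from pairs ≤ d_max and
the violating remainder from pairs > 60 Å, with scores sampled inside the
keep region. Synthetic MSAs mutate non-conserved positions at a given rate
toward positively-scoring BLOSUM62 substitutions. The planted-perturbation
refinement condition displaces one subunit radially outward, the
misplacement mode that stretches its inter-subunit links (a random
direction can shorten links, making "mean link distance decreases"
ill-posed as a recovery signal).

Problem sizes in the default test run (2–8 subunits of 10–60 residues at
Cα/Cβ resolution, 10 Å maps on ~3 Å voxels, 200-decoy populations over 20
seeds, 500-cycle refinements) were chosen so the full suite exercises every
stage end-to-end in a few minutes. What passing shows: the geometry,
statistics and optimizers are implemented correctly, every operation is
deterministic under its seed, and planted signals (transforms,
displacements, violations, conservation) are recovered at the stated rates.
What it does not show: behaviour on atomic-detail side chains, real
cross-link false-positive structure, experimental map noise spectra and
masking artefacts, or Sc scales of atomic surfaces — conclusions about real
assemblies still require the usual controls on real inputs.

## Known limitations

- Sc is computed on accessible-surface dots, not a Connolly triangulation;
  absolute values are not comparable to atomic-resolution Sc conventions.
- No sequence-independent structure alignment; superposition seeding needs
  detectable sequence similarity or user-provided pairs.
- Rigid fitting places one subunit at a time (candidate peaks expose
  alternatives); no joint multi-body search.
- Flexible fitting is Cα-resolution with rigid residue riding — no
  side-chain repacking, no secondary-structure-aware elastic terms.
- The pose generator explores orientations on a grid with a single
  touching placement per orientation; it is a pipeline exerciser, not a
  docking engine.
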