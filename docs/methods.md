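# Methods

## Scope and model

`ecloop` predicts the conformation of extracellular loops of a receptor
whose transmembrane (TM) helix bundle is known.  The scaffold (every
residue annotated as helix) is fixed; all loop residues are mobile
simultaneously, so loops feel each other's excluded volume and contacts.
No membrane, water, or ligand is represented; solvent and packing effects
enter implicitly through the knowledge-based contact term.  Input knowledge
is limited to (i) the scaffold coordinates, (ii) loop residue ranges and
sequences, (iii) an optional three-state secondary-structure string per
loop, and (iv) declared disulfide bridges.

## Coarse-grained representation

Each residue carries up to four interaction centers: Cα, Cβ, the
side-chain center of mass (SC), and the midpoint of the virtual Cα–Cα
bond.  Cα positions are continuous Cartesian coordinates with a fixed
virtual bond of 3.8 Å (tolerance ±0.12 Å, plus the ±0.02 Å spread of ideal
helix geometry).  Historically this representation family was sampled on a
fine lattice; the lattice geometry is not public, and a continuous
representation with exact bond restoration preserves the model's physics
while making every move kernel exactly reproducible.  This is a deliberate,
visible deviation from the lattice original.

Cβ and SC are deterministic functions of the Cα trace.  At residue *i* a
local orthonormal frame is built from u (along Cα(i+1)−Cα(i−1)), v (the
outward bisector of the Cα triangle) and w = u × v; Cβ sits at a fixed
offset in this frame derived from the ideal tetrahedral β-carbon on an
ideal helix, and SC sits at a per-residue-type offset calibrated once
against ideal-geometry side chains in the canonical χ1 = −60° rotamer on an
ideal helix (fidelity ≤ 0.35 Å there; coil conformations are reproduced
less faithfully, which the 2.5 Å-wide contact well absorbs).  Glycine's Cβ
and SC coincide at the virtual β-carbon.  Terminal residues reuse the
nearest interior frame.

## Energy function

All terms are dimensionless (units of simulation temperature).

* **Contacts** (SC–SC, sequence separation ≥ 2): hard-core repulsion
  +e_rep = 5 below r_rep = 3.0 Å; the 20×20 table energy inside the well
  4.0–6.5 Å; zero beyond.  The default table is a hydrophobicity-derived
  surrogate with the shape of published residue-contact statistical
  potentials, e(a,b) = −0.35·(q_a + q_b) with q the Kyte–Doolittle
  hydropathy scaled to [−1, 1]: hydrophobic pairs attract (Ile–Ile −0.70),
  polar pairs mildly repel (Arg–Arg +0.70).  It ships as an editable TSV
  (`ecloop/data/contact_table.tsv`); any 20×20 symmetric table can be
  substituted.  The surrogate keeps the term *structure* of the original
  statistical potential without presenting invented numbers as measured
  ones.
* **Loop softening.**  For pairs involving a loop residue the attractive
  half-width is scaled by d1 = 0.5 and the repulsive height divided by
  d2 = 1.5.  The published description fixes the two constants but not the
  functional mapping; "reduced effective width" is implemented as well
  narrowing and "reduced stiffness" as wall softening, chosen so that
  d1 = d2 = 1 recovers the unsoftened term exactly (a pure
  reparameterization, asserted by test).
* **H-bond proxy**: −w_hb (default 1) for each pair |i−j| ≥ 3 whose Cα
  distance lies in 4.6–5.6 Å and whose separation vector is sufficiently
  non-collinear with both local chain directions (|cos| ≤ 0.75); greedy
  distance-ordered matching caps each residue at two partners (donor +
  acceptor).  On an ideal helix this gates the (i, i+3) pairs (5.05 Å,
  |cos| = 0.16); an extended chain scores zero.
* **Secondary-structure bias**: for loop residues labeled H or E,
  flat-bottom harmonics (k_ss = 1 /Å²) pull d(Cα_n, Cα_n+2) and
  d(Cα_n, Cα_n+4) into windows derived from ideal helix/strand geometry:
  H → [5.1, 5.8] and [5.8, 6.7] Å; E → [6.3, 7.2] and [11.5, 13.5] Å; C is
  unbiased.  Because over-assigned regular structure harms loop predictions
  more than under-assignment, the consensus rule (below) and the C-label
  default are deliberately conservative.
* **Restraints**: k_scaffold·Σ|Cα − ref|² over anchors (k = 10 /Å²;
  inert while anchors are frozen but active for restrained-mobile setups),
  and k_ss_bond·(d_SC − r_ss_target)² per declared bridge with the strong
  default k = 100 /Å² and r_ss_target = 3.2 Å between CYS side-chain
  centers (the SC–SC analogue of a 2.04 Å Sγ–Sγ bond).  When bridges are
  declared the CYS–CYS contact-table entry is forced to 0, eliminating any
  statistical bias toward more-than-binary cysteine contacts.

## Sampling

Moves: single-Cα displacement (uniform amplitude ≤ max_displacement = 1 Å,
projected exactly back onto the circle of positions 3.8 Å from both
neighbors), two-residue crankshaft and three-residue segment rotations
about the axis through the flanking pivots (amplitude max_displacement/3.8
rad), with weights 0.4/0.3/0.3.  All kernels are symmetric; the acceptance
rule min(1, exp(−ΔE/T + log q-ratio)) carries the proposal-ratio term
explicitly so asymmetric kernels can be added safely.  Infeasible draws
return the state unchanged and count as proposals.

A production run comprises n_runs = 2 independent trajectories (run k
seeded seed + k), each: random self-avoiding loop initialization bridging
the anchors (exact 3.8 Å steps, ≥ 3 Å clearance from scaffold Cαs),
burn-in (200 sweeps at T_start), then 2000 snapshots separated by
sweeps_per_snapshot sweeps (one proposal per mobile residue per sweep)
while T anneals linearly from T_start = 2 to T_end = 1.  The temperature
protocol and snapshot spacing are free parameters of this implementation —
only the snapshot counts (2 × 2000 = 4000 models) are fixed by the
protocol being reproduced.  Energies recorded at snapshot time are full
recomputations, so the trajectory sidecar always matches the coordinates.

## Reconstruction to all-atom

Backbone: an ideal trans-peptide template (Cα–C 1.52, C–N 1.33, N–Cα
1.46 Å; Cα–C–N 116.2°, C–N–Cα 121.7°, ω = 180°, carbonyl O bisecting
in-plane at 1.23 Å) is placed on every Cα–Cα bond, its plane oriented by
the local curvature normal with the sign that reproduces α-helix
O(i)···N(i+4) hydrogen-bond geometry (3.1 Å on an ideal helix).  Input Cαs
are preserved exactly.  Side chains: Cβ from the ideal tetrahedral
construction; heavier atoms from per-residue internal-coordinate tables,
trying χ1 ∈ {−60°, 180°, +60°} and keeping the rotamer with the fewest
steric contacts (deterministic tie-break by that order).  Refinement:
steepest descent with backtracking on a soft-sphere overlap term (2.6 Å
cutoff) plus harmonics preserving the loop's covalent geometry; only loop
atoms move and the objective is non-increasing by construction.  Every
stage accepts a `backend` callable so external reconstruction tools can be
substituted under the same contracts.

## Selection and evaluation

The single-point score is a deterministic 12-6 nonbonded term (σ = 3.2 Å,
ε = 0.2, 10 Å cutoff, distances clipped at 1.5 Å), a soft clash term
(< 2.6 Å) weighted ×10, and an ω-regularity term 1−cos(ω−180°).  It ranks
loop packings; its absolute scale is arbitrary.

Clustering is literal K-means (scikit-learn, fixed seed, n_init = 10) on
flattened loop Cα coordinates after all models are placed in the common
scaffold frame — K-means requires a vector space, which pairwise-RMSD
medoid schemes do not supply.  K defaults to 100 and shrinks to the
ensemble size; empty clusters are dropped and counted.  Clustering uses
loop coordinates only, since the scaffold is identical across models.
Representatives are the members nearest their centroid; clusters are
ordered by descending size with index tie-break.

Loop RMSD is computed after a Kabsch fit on non-loop Cαs only, with no
re-fitting on the loop, so it penalizes misplacement of the loop within
the receptor frame.  The default atom set is Cα (backbone and heavy-atom
modes available); the selection report carries BEST, LE/LE10/LE100 and
LC/LC10/LC100 with ties broken toward the smaller model id, and the subset
chains BEST ≤ LE100 ≤ LE10 ≤ LE (and likewise for LC) hold for any input.

## Consensus secondary structure

The three-predictor consensus is per-position strict majority with ties →
C.  The published procedure names its predictors but not its combination
rule; majority-with-coil-fallback is this package's choice, consistent
with the asymmetric cost of over-predicting regular structure.

## Loop boundary definition

Loops are maximal non-helix runs flanked by helix on both sides.  The
helix annotation is an input (the reference procedure inspects the TM
hydrogen-bond network of the crystal structure); when absent, a geometric
surrogate flags every residue covered by a five-residue window whose
Cα(n)–Cα(n+3) and Cα(n)–Cα(n+4) distances both fall in 4.5–6.5 Å.  This
stand-in is documented as such and is not an H-bond analysis.

## Synthetic fixtures

The toy receptor is a bundle of ideal α-helices (2.3 Å radius, 1.5 Å rise,
100°/residue) connected by self-avoiding random loops of known
coordinates, optionally with one helix↔loop CYS pair whose Sγ atoms are
placed 2.04 Å apart (synthetic geometry: the Sγ positions are set
explicitly, not rotamer-derived).  It reproduces the topology that matters
to the pipeline — rigid scaffold, flexible loops, a disulfide anchor — but
none of the sequence statistics, helix kinks, membrane constraints or
N-terminal contacts of a real receptor.  Passing tests on it demonstrate
the machinery (sampling physics, restraint enforcement, metric
consistency), not prediction accuracy on real GPCRs, which requires real
scaffolds and references.  Decoy ensembles are Gaussian perturbations of a
native loop with generation-time RMSDs recorded for bookkeeping tests.

## Problem sizes

The test suite and the acceptance script run the default two-run protocol
(4000 snapshots) with 1–2 sweeps between snapshots on a 13-residue toy
loop, and the end-to-end all-atom pipeline at 2 × 200 snapshots with
K = 100 — sizes chosen so a complete desk run finishes in minutes while
still exercising every stage at full ensemble counts where the protocol
fixes them.  Physics checks use 10⁴ acceptance trials and 10⁵ sweeps.

## Numerical choices and degenerate inputs

* Altloc resolution: highest occupancy, ties to the first encountered.
* PDB coordinates are rounded to the format's 3 decimals on read.
* Collinear local frames (straight chain segments) fall back to a fixed
  perpendicular; the single-Cα projection rejects moves when the flanking
  gap reaches 7.6 Å (degenerate constraint circle).
* Random loop initialization enforces reachability
  (gap ≤ 3.9·(n+1) Å) up front and raises with a diagnostic after 5000
  failed placement attempts.
* Energy ties in selection and equal-size clusters break deterministically
  (model id, cluster index), making reports byte-reproducible per seed.

## Limitations

No membrane or ligand; the contact surrogate is far cruder than a fitted
statistical potential, so absolute energies are not comparable across
sequences; single-frame pseudoatom rebuilding blurs side-chain centers in
coil regions; K-means on Cartesian loop coordinates mixes shape and
placement; LC selections inherit K-means' sensitivity to initialization
beyond the fixed seed.  Accuracy claims on real receptors require running
the documented real-scaffold workflow (PDB scaffold + loop TSV + SS +
bridges) against experimental references.
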