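# Methods

## Coarse-grained representation

Each residue is reduced to four interaction centres: the C-alpha (CA),
the C-beta (CB), a single side-chain centre (SC), and one pseudoatom per
backbone virtual bond (CN) at the geometric centre of consecutive CA
atoms. CA positions live on a cubic lattice (spacing 0.61 Å, the
customary value for this model family; configurable, and the lattice can
be disabled for continuous-space work), while CB, SC and CN sit off the
lattice. Consecutive CA–CA virtual bonds are constrained to
[3.3, 4.3] Å.

When converting all-atom input, SC is the centroid of the side-chain
heavy atoms beyond CB; alanine collapses SC onto CB; glycine places both
CB and SC 1 Å from CA along the bisector normal of the CA(i−1)…CA(i+1)
segment (terminal glycines keep SC at CA). These placements are
conventions, not stereochemistry: nothing downstream depends on rotamer
realism, only on SC being a consistent single interaction centre.

## Energy model

The total energy is a sum of pluggable terms in reduced units
(k_B ≡ 1; temperatures on the same scale):

- **Excluded volume** — a flat penalty (default 5.0) per non-bonded
  pseudoatom pair closer than a hard radius (default 3.0 Å). Non-bonded
  means any inter-chain pair, or an intra-chain pair at sequence
  separation ≥ 2 (bond centres count as sitting at half-integer
  positions).
- **Pairwise side-chain contacts** — for every SC–SC pair within
  6.0 Å (inter-chain, or intra-chain at separation ≥ 2) the energy of
  the residue-type pair is read from a symmetric 20×20 matrix. The
  shipped default is derived from the Kyte–Doolittle hydrophobicity
  scale, E(a,b) = −2·g(a)·g(b) with g = (KD + 4.5)/9 ∈ [0, 1]: all
  entries are attractive, strongly so for hydrophobic pairs. This is an
  intentionally simple surrogate for a statistical contact potential —
  it creates a genuine hydrophobic binding funnel on the synthetic
  systems but encodes no electrostatics, no polar specificity and no
  solvation. Any whitespace 20×20 table with one-letter headers can be
  substituted.
- **Secondary-structure bias** — an optional per-residue penalty
  (weight 0.5) when the peptide's local CA geometry violates its H/E/C
  preference. A residue matches 'H' when the CA pseudo-bond angle at its
  position falls in [80°, 105°], 'E' in [105°, 145°], and 'C' always;
  chain termini (no defined angle) always match. Only the pseudo-angle
  is binned; a pseudo-dihedral criterion was considered and dropped to
  keep the bias coarse and cheap.
- **Receptor near-native restraints** — flat-bottom terms
  w·max(0, |d − d_native| − tol) with tol = 1.0 Å, w = 1.0, over all
  receptor CA pairs with native distance ≤ 8 Å and sequence separation
  ≥ 3. The receptor stays flexible but anchored; the unperturbed input
  scores exactly zero.
- **Side-chain contact restraint** — the docking-information term:
  E(D) = 0 for D ≤ D0 and s·(D − D0) beyond, with D the SC–SC distance
  of a restrained receptor–peptide pair. Protocol defaults D0 = 5.0 Å,
  s = 1.0. Multiple restraints are summed, and the restraint is applied
  identically at every replica temperature.

The restraint biases *sampling only*: Monte Carlo acceptance uses the
sampling energy (all terms), while filtering and ranking use the scoring
energy (all terms except the contact restraint). The two are maintained
as an exact invariant, `sampling = scoring + restraint`.

## Replica-exchange Monte Carlo

Ten replicas (default) run at temperatures on a geometric ladder from
1.0 to 2.0 reduced units. One cycle attempts one move per mobile residue
(peptide plus receptor); moves are drawn from {rigid peptide
translation σ = 1 Å, rigid rotation σ = 15°, single-residue kink,
two-residue crankshaft, end flip, single-receptor-residue perturbation
σ = 0.3 Å} with configurable weights. Local peptide moves rotate about
the axis through the flanking CA atoms, which preserves bond lengths
exactly before lattice snapping; any candidate whose snapped CA trace
leaves the [3.3, 4.3] Å bond window is discarded as infeasible (counted
as a rejection). Acceptance is the standard Metropolis rule on the
sampling energy.

Initial poses are drawn as self-avoiding 3.8 Å CA walks, randomly
oriented and placed within 20 Å of the receptor molecular surface
(pseudoatom centres inflated by 2 Å) with zero excluded-volume overlap.
Because the receptor is not spherical, a draw landing outside the shell
is pulled inward along its placement direction and re-tested rather than
discarded. The same 20 Å shell bounds the whole simulation: a peptide
move that would leave it is rejected, standing in for the finite
simulation box of lattice docking. Without this bound an unrestrained
peptide is a free random walker and the default-mode baseline is
meaningless.

Adjacent-pair temperature swaps are attempted every 50 cycles with
alternating odd/even pairing and probability
min(1, exp((1/Ta − 1/Tb)(Ea − Eb))); replicas trade temperatures, not
identities, and each replica owns a child RNG stream spawned from the
master seed, so runs are bitwise reproducible and adding replicas does
not reshuffle existing streams.

Each replica contributes snapshots at evenly spaced cycles (default
1000 cycles, 1000 snapshots), giving the 10 × 1000 = 10,000-model pool.
Move evaluation recomputes only the energy blocks a move can change
(receptor–receptor, receptor–peptide, peptide–peptide); cached
components are resynchronized against a full recomputation at every
snapshot, and the fast path is tested term-by-term against the reference
implementation.

## Model selection

The pool is reduced to the 1000 models with the lowest scoring energy
(ties broken by cycle, then replica). Pairwise ligand RMSD — peptide CA
RMSD after Kabsch superposition of receptor CA atoms — is computed once
as a matrix (a batched, blocked SVD implementation; it agrees with the
per-pair routine to 1e−6 and exists because clustering needs ~500k
evaluations). k-medoids with k = 10 clusters the filtered set: instances
with at most 2000 candidate medoid sets are solved exactly by
enumeration; larger ones use k-medoids++ seeding, assign/update
alternation, a swap-improvement phase, and the best of 5 seeded
restarts. Exact enumeration at small n exists because restart heuristics
provably miss the optimum on a small fraction of instances, and the
small-instance behaviour is part of the method's contract.

Clusters are ranked by density = size / mean pairwise ligand RMSD among
members ("average difference" is read as the mean over unordered member
pairs, not distance-to-medoid; both readings are implemented,
`rank_models` uses the pairwise one). Singletons and zero-spread
clusters take an epsilon floor of 1e−3 Å and are flagged. Ties break by
cluster size, then lowest medoid scoring energy. The ten medoids, in
density order, are the final models.

Evaluation helpers compute native contacts (any heavy-atom pair within
5 Å for all-atom input; any pseudoatom pair for coarse-grained input,
flagged as an approximation) and the nested lowest-RMSD report over the
10,000 / 1,000 / 100 / 10 tiers, the 100-tier being the top 100 by
scoring energy.

## Synthetic systems

The toy generator builds a compact self-avoiding CA walk on the lattice
(bond vectors restricted to valid lengths, steps biased toward the
centre) inside an envelope sized from ~115 Å³ per residue, with a
spherical pocket carved at the surface. Residues within 9 Å of the
pocket centre draw from {ILE, LEU, PHE, VAL, MET}; the rest from a polar
set. By default a second hydrophobic patch is placed on the surface
opposite the pocket: real receptors offer competing attractive sites,
and without one unguided docking on a toy this small almost always
finds the single funnel, which would make the default vs contact-driven
comparison uninformative. The native peptide (a hydrophobic L/F/I/V/M pattern) lies through
the pocket with side centres facing the receptor; receptor side centres
point into local free space and are shrunk until the structure is
internally clash-free. Construction is rejected and retried until the
native pose (a) has zero excluded volume, (b) has at least one SC–SC
pair within 5 Å, and (c) scores a lower pairwise contact energy than at
least 95 of 100 random surface placements — a guaranteed, seeded energy
funnel.

What the toys do *not* emulate: real force-field energetics, side-chain
rotamers, backbone stereochemistry, solvent, or the size of real
receptors. Passing tests on these systems demonstrates that the engine's
machinery (sampling, restraints, filtering, clustering, ranking) behaves
correctly and that contact information helps *when a funnel exists*;
they say nothing about docking accuracy on experimental structures.

Decoy sets place perturbed poses at prescribed ligand RMSDs: one random
displacement direction per RMSD target (so equal-target decoys form a
tight planted cluster), small internal noise, and iterative rescaling
until the achieved RMSD is within 15% of the target.

## Problem sizes and defaults used in the shipped checks

The test suite runs the full default configuration (40-residue receptor,
6-residue peptide, 10 replicas × 1000 cycles × 1000 snapshots) once to
verify the 10,000 → 1,000 → 10 funnel. The default vs contact-driven
comparison uses the same 40-residue toy with two randomly drawn native
contacts driving the docking, 6 replicas × 400 cycles × 250 snapshots
per mode, filter 300, k = 10, over 12 paired seeds; one-sided sign
tests check that the contact-driven mode gives a lower mean restrained
SC–SC distance and a lower final-model RMSD. Two contacts (rather than
one) are used because on a receptor this small a single soft restraint
leaves the peptide orientation free and unguided docking finds the
single pocket often enough to tie it; pinning two side chains is still
a tiny fraction of the interface information while making the
improvement consistent enough for a paired sign test at this problem
size. These sizes are the package's chosen study conditions; they were
fixed once and are not tuned per run.

## Known limitations

- The statistical force field is a hydrophobicity surrogate; rankings on
  real proteins would require dropping in a proper contact potential.
- All-atom refinement of the final coarse-grained models is out of
  scope; the pipeline exports CG PDB models and documents the hook.
- The sequential reference implementation is the only one; parallel
  replica propagation would need to preserve the stream-per-replica
  reproducibility contract.
- mmCIF input, NMR ensembles beyond the first model, and insertion-code
  arithmetic beyond keeping the author numbering are unsupported.
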