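# Methods

`allonet` re-implements, as a reusable and testable pipeline, the trajectory-
analysis machinery used to dissect how a J-domain cochaperone allosterically
primes an Hsp70 chaperone for ATP hydrolysis: conformational order parameters
and PCA, typed differential contact fingerprints, generalized-correlation
dynamic networks with allosteric-pathway tracing, and umbrella-sampling
free-energy reconstruction. Because no real trajectories ship with the
package, every stage is validated against synthetic inputs whose correct
answer is known by construction. This note records the models, the defaults
and why they were chosen, and what the synthetic validation does and does not
demonstrate.

## Structural model and conventions

Coordinates are stored in nanometres and times in picoseconds (GROMACS
convention); PDB ångströms are converted on read/write. Residue numbering is
always the source file's author numbering — cutoffs and residue references in
configs are in that numbering, never re-indexed. The backbone is N, CA, C, O
plus terminal variants. Superposition is a standard unweighted least-squares
(Kabsch) fit of a selection onto a reference frame; it is idempotent to
numerical precision and is required before PCA or network weighting so that
internal fluctuations, not rigid-body motion, are analyzed. Frames are
weighted equally with no time-based resampling.

Centres of mass are mass-weighted when element masses are known (inferred
from atom names) and fall back to the unweighted mean otherwise. The
inter-subdomain torsion — the dihedral of the centres of mass of four atom
groups, canonically the backbone atoms of the NBD lobes IB, IA, IIA and
IIB — follows the mass-weighted convention of the standard trajectory tools.

## Antiparallel β-sheet content

The β-content scalar *s* sums, over every pair of 3-residue windows (one per
strand segment) whose centres lie within a strands cutoff of 1 nm, a rational
switching function of the RMSD *r* between the 30-atom window block
(N/CA/CB/C/O per residue) and a reference antiparallel block:

    s = Σ (1 − x^8) / (1 − x^12),   x = r / r0,   r0 = 0.08 nm,

with the continuous limit 8/12 at x = 1. RMSD uses optimal superposition, so
*s* is rotation/translation invariant. The reference block shipped in
`allonet/data/antibeta_template.tsv` is an **idealized, synthetic**
construction (two extended strands, second strand antiparallel at 0.48 nm
with carbonyls facing the sheet), pinned as a versioned data file so values
are reproducible; it is not the PLUMED reference fragment, so absolute *s*
values are comparable only within this package. Glycine receives a virtual
CB placed tetrahedrally from N/CA/C.

## PCA

PCA diagonalizes the 3A×3A covariance of superposed coordinates about the
ensemble mean. Variance fractions are reported over all eigenvalues and
projections satisfy the usual identities (zero mean, variance equal to the
eigenvalue on the fit data). When two systems are compared, the decomposition
should be fit on their concatenation (merged-ensemble mean) and each system
projected through `PCAResult.project`, so that one common set of eigenvectors
describes both.

## Typed contacts and the differential rule

Five interaction types are detected per frame with geometric criteria
matching common contact-analysis defaults: hydrogen bond (donor–acceptor
heavy-atom distance ≤ 0.35 nm **and** D–H···A angle ≥ 150°, the stricter
angle being the one deliberate deviation from those defaults), ionic
(anionic–cationic heavy atoms ≤ 0.40 nm), π-stacking (ring centroids
≤ 0.70 nm, normals within 30°), π-cation (cation–centroid ≤ 0.60 nm, offset
angle ≤ 60°) and hydrophobic (heavy atoms within the Bondi vdW-radius sum
plus 0.05 nm, both residues in {ALA, VAL, LEU, ILE, MET, PHE, PRO, TRP}).
Donor/acceptor/charged/aromatic atom tables cover the 20 standard amino
acids plus ATP and live in `allonet.contacts`; donor hydrogens are found
geometrically (H within 0.125 nm of a donor heavy atom). Intra-residue
contacts and sequence-neighbour backbone–backbone hydrogen bonds are
excluded as trivial.

Frequencies are exact frame fractions. The differential table joins two
systems on the union of (pair, type) keys, treats absent keys as frequency
zero, and flags a contact as *differentiating* when |Δ| exceeds 40
percentage points (strictly greater). Residue roles use a 50% persistence
rule: ligand-binding if any contact type with a ligand residue persists in
at least half the frames, interlobe-interface likewise across lobes. Whether
the ligand rule should count any contact type or hydrogen bonds only is not
fixed by convention; the any-type reading is implemented, and the criteria
object can restrict types if needed.

## Dynamic network, pathways, communities

Nodes are protein residues anchored at Cα, plus ligand pseudo-nodes: an
ATP-like residue contributes a purine-ring node (anchored at N1) and a
phosphate+ribose node (anchored at the γ-phosphorus), and a metal ion is its
own node; every heavy atom of the analyzed selection belongs to exactly one
node. An edge joins two nodes when any of their heavy atoms are within
0.45 nm in at least 75% of frames. Edge weights are the generalized
correlation

    GC = sqrt(1 − exp(−2 I / 3)) ∈ [0, 1),

with I the mutual information between the two nodes' 3-D anchor-displacement
series, estimated by the Kraskov k-nearest-neighbour estimator (algorithm 1,
Chebyshev metric). k = 7 is the package default — the estimator's bias and
variance are both modest there for the frame counts used, and the value is a
config knob since no single k is canonical. For jointly Gaussian
displacements I = −(3/2)ln(1−ρ²) per dimension, so GC = |ρ| exactly — the
closed form the estimator is tested against. GC is clipped to 1 − 1e-12
(identical series would otherwise give infinite information and zero path
length), and the edge length is d = −log GC, so strongly coupled contacts
are short links.

The optimal source→sink pathway minimizes Σ d along the path; it is computed
by Floyd–Warshall (the all-pairs matrix is cached and reused for
betweenness), and the next-cheapest twenty simple paths (Yen's k-shortest
simple paths on the same weights) form the suboptimal set, from which
per-node occurrence frequencies are computed. Ties between equal-cost paths
are broken deterministically by the predecessor-scan order of the
Floyd–Warshall implementation rather than by an explicit lexicographic rule;
determinism, not a particular tie winner, is the contract.

Communities are Louvain modularity optimization on GC weights with a fixed
seed (order-dependence is inherent to Louvain); communities smaller than 1%
of the nodes are moved to a discarded list. Community coupling is quantified
by summing the (d-weighted) edge betweenness of edges crossing each
community pair, normalized to a maximum of 1; per-node betweenness is
reported alongside. Edge-sum aggregation was chosen over node-sum because it
attributes bridging strength to the actual crossings; the node-based variant
is a one-line change on the exposed betweenness dictionaries.

The sensitivity scan rebuilds the network over a cutoff grid (default
0.42–0.48 nm × 65–85% persistence, reference 0.45 nm / 75%) and reports
Jaccard similarity of edge sets, path residue sets and path connection sets
against the reference, plus per-node occurrence across grid points. GC
values are cached per pair across the grid since the estimator does not
depend on the cutoffs.

## Umbrella sampling and WHAM

An umbrella dataset is a ladder of windows, each a harmonic bias
½k(ξ−ξᵢ)² with a reaction-coordinate time series; the canonical ladder is
ten equally spaced windows spanning 0.3–1.2 nm with k = 1500 kJ·mol⁻¹·nm⁻²
at 310 K. One-sided (pulling) restraints are representable in the data model
but excluded from WHAM, which assumes two-sided harmonic biases; replica
exchange between windows is an efficiency device of the sampling and is
ignored at analysis time, each sample being attributed to its bias window.

WHAM is solved by self-consistent iteration in log space (logsumexp
throughout): the unbiased bin probabilities and the per-window offsets fᵢ are
alternated until max|Δfᵢ| < 1e-8 kT (iteration cap 10⁵, residual reported on
non-convergence). Default 100 bins over the sampled range; G(ξ) = −kT ln p is
min-anchored at zero and reported in kcal/mol (kB = 0.008314 kJ·mol⁻¹·K⁻¹,
kBT at 310 K = 2.577 kJ/mol, 1 kcal = 4.184 kJ). Pairwise overlap of
neighbouring windows is checked up front and a missing overlap is an error
naming the gap.

Uncertainties come from a moving-block bootstrap: each window's block length
is the ceiling of its integrated autocorrelation time (FFT autocorrelation
with Sokal's windowing, c = 5), blocks are resampled with replacement, WHAM
is re-solved per replicate, and the per-bin standard deviation over
replicates is the error. i.i.d. windows reduce to the naive bootstrap
(block 1); an AR(1) series with φ = 0.9 has IACT (1+φ)/(1−φ) = 19 and must
produce blocks > 5 and inflated errors — both are regression-tested.
Convergence diagnostics re-solve WHAM on the leading fraction of every
window, re-anchored at the full-profile minimum for comparability. State
free-energy differences integrate the unbiased density over the two
coordinate intervals (e.g. a "close" state below 0.4 nm vs a "far" state
above 0.65 nm): ΔG = −kT ln(P_B/P_A), with the error propagated as the
standard deviation of ΔG over bootstrap replicates.

## Synthetic data: what it emulates, and what it does not

The generators produce the study conditions each stage is validated under;
they are deterministic under a fixed seed and emit machine-readable ground
truth.

**Planted-correlation ensembles.** Beads (one Cα-like atom per residue) sit
on a compact helix (radius 0.28 nm, pitch 0.38 nm, 4 beads/turn) so that
|i−j| = 1 (~0.41 nm) and |i−j| = 4 (~0.38 nm) pairs form persistent contacts
under the 0.45 nm/75% rule while the nearest non-contact pairs (~0.49 nm) do
not — a graph rich enough for non-trivial shortest paths. Displacements are
drawn from a zero-mean Gaussian with per-dimension correlation: background
nearest-neighbour coupling 0.05 (a fully independent background would
disconnect the correlation structure from the contact graph), plus either a
planted chain (consecutive planted residues at ρ = 0.8, decaying as ρ^lag
along the chain so the matrix stays positive definite) or two equicorrelated
blocks (ρ = 0.5 within, independent across) for community recovery. The
displacement amplitude is σ = 0.02 nm per coordinate, chosen so contact
persistence margins are clean at the default cutoffs. Defaults: 30 residues,
5000 frames, planted chain 5→25 via 4 intermediates for path recovery;
32 residues, 2000 frames for the two-block partition — sizes at which the GC
estimator resolves the planted structure while a full validation run stays
in CPU-minutes.

**Umbrella datasets.** For harmonic (and flat) potentials the biased density
is an exact Gaussian and is sampled directly. Otherwise (double-well) a
vectorized Metropolis chain samples exp(−[U+bias]/kT): 25 parallel chains,
1000-step burn-in, keep every 20th step; acceptance below 5% or lag-1
autocorrelation of kept samples above 0.1 is an error (WHAM and the
bootstrap assume weakly correlated input — strongly correlated input is the
bootstrap module's own test case, built separately as AR(1) series). The
analytic PMF U − min U is tabulated on a grid as ground truth.

**Contact scripts.** Minimal residue pairs (serine donor triad, asparagine
acceptor, aspartate/lysine charge pair, phenylalanine rings, leucine/valine
carbons) are placed so each tagged geometry passes or violates exactly one
criterion — e.g. a D–H···A angle of 140° with a compliant distance isolates
the 150° floor — and pulled 2 nm apart in non-contact frames, so expected
frequencies are exact by construction.

**Geometry fixtures.** Four-point dihedral and four-group torsion fixtures
realize a requested angle analytically; the ideal hairpin is the β-template
itself (its single eligible block scores RMSD 0); the coil is an extended
strand far from the template.

These are statistical and geometric stand-ins. They contain no force-field
physics, no solvent, no anharmonicity beyond the double-well, and no real
chaperone structure; passing tests demonstrate that the *analysis machinery*
is correct (estimators converge to closed forms, planted answers are
recovered, thresholds bracket as specified), not that the package would
reproduce any particular biological result from real trajectories. The
headline free-energy and conformational numbers of the original study derive
from multi-microsecond solvated simulations and are outside desk-scale
reach; validation is therefore property-based throughout.

## Numerical choices and degenerate inputs

- Angles are reported in degrees in (−180°, 180°]; collinear dihedral atoms
  and coincident torsion group centres are errors, not NaNs.
- Selections with unknown residue/atom/chain names raise rather than return
  empty sets; empty ranges (`resid 5-4`) are syntax errors.
- The switching function evaluates its continuous limit n/m at x = 1;
  negative x (r < d0) is clamped to the plateau value 1.
- A GC pair with identical series is clipped at 1 − 1e-12 and flagged; a
  zero-variance node is an error naming the node.
- Disconnected source/sink yields an explicit no-path result from
  `optimal_path` and a recorded missing entry in the sensitivity scan, not
  an exception; `suboptimal_paths` does raise, since ranking paths that do
  not exist is meaningless.
- WHAM bin ranges may be pinned (`bin_range`) so truncated or resampled
  datasets share a grid with the full solution.
- All pipeline randomness flows from config seeds; the run manifest contains
  only deterministic content (config snapshot, version, output hashes), with
  wall-clock timings and captured warnings in `run.log`, so identical
  configs reproduce byte-identical manifests.

## Known limitations

- Contact chemistry covers standard amino acids + ATP; exotic ligands need
  table extensions. Protonation states are not modelled (histidine is
  treated as a potential cation/donor/acceptor throughout).
- The β-content template is package-pinned, not the PLUMED fragment;
  cross-package absolute *s* values differ.
- The KSG estimator's k and the Louvain resolution are defaults, not
  derived; both are exposed in the config.
- No periodic-boundary imaging: inputs are assumed whole-molecule and
  unwrapped.
- 2-D PMFs, MBAR, water-mediated contacts and perturbation-response network
  variants are out of scope.
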