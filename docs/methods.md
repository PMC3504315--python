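# Methods

`idpens` characterizes the conformational ensemble of an intrinsically
disordered protein (IDP) chain the way such ensembles are analyzed from
molecular-dynamics trajectories: collective motions by covariance PCA,
thermodynamic structure by free-energy landscapes, heterogeneity by RMSD
clustering and an ensemble order parameter, local structure by
hydrogen-bond secondary-structure assignment and solvent accessibility,
tertiary organization by persistence-weighted interaction networks, and —
on the experimental side — conformer populations by Gaussian deconvolution
of native electrospray charge-state distributions.  A synthetic-ensemble
generator supplies inputs with known ground truth so that every stage is
testable end to end.

All coordinates are stored in nanometres; PDB files are converted at the
boundary.  Residue numbering is taken verbatim from the input.

## Ensembles, superposition, RMSD

The universal container is a `ConformationalEnsemble`: a fixed atom table
plus `F` frames of Cartesian coordinates.  Rigid-body superposition uses
the least-squares Kabsch solution (via `scipy`'s `Rotation.align_vectors`);
the default reference is the *iterative mean* — fit all frames to the
current selection mean and iterate until the mean moves by less than
1e-12 nm (at most 100 rounds).  Starting from the running mean rather than
an arbitrary frame makes the operation idempotent: an already-superposed
ensemble is a fixed point.  Selections: `ca` (Cα), `mainchain`
(N, CA, C, O), `all`.

Pairwise RMSD matrices re-fit every frame pair by default (`fit=False`
compares coordinates as stored, for workflows that use one global
superposition).  The F×F computation is a batched 3×3 SVD over all pair
cross-covariances, cross-checked in the tests against a per-pair Kabsch
oracle at 1e-8 nm.

## Essential dynamics (PCA) and RMSIP

The covariance of positional fluctuations about the ensemble mean is
eigendecomposed, optionally mass-weighted (coordinates scaled by √m;
standard atomic masses by element, 12.011 amu for pseudo-atoms).  For
flattened dimensions above 3000 the F×F dual (Gram-matrix) decomposition is
used and only the resolvable modes are returned.  Eigenvalues are clipped
at zero; the eigenvalue sum equals the covariance trace to 1e-8 relative.

Subspace convergence between two ensembles is the root mean square inner
product over the first D eigenvectors,

    RMSIP = sqrt( (1/D) Σ_i Σ_j (η_i^A · η_j^B)² ),   D = 10 by default.

The squared form is the one implemented: it alone satisfies RMSIP(A,A)=1
and is invariant to any rotation of the basis within each subspace, both of
which are asserted in the tests.  For Haar-random d-dim subspaces of an
N-dim space the expected RMSIP is √(d/N); a 1000-replicate Monte-Carlo
check at d=10, N=210 reproduces √(10/210) ≈ 0.218 within ±0.01.

## Free-energy landscapes and basins

For per-frame reaction coordinates (q, p) — typically the first two PCs —
the landscape is G = −kT ln P on a 2-D histogram (default 32×32 bins over
the data range padded by 2%), shifted so the populated minimum is 0, with
kT = 0.0083145·T kJ/mol.  Unpopulated bins are **masked**, not set to +∞,
so no infinities propagate into the basin search.  Re-exponentiation
recovers the bin probabilities to 1e-10 relative — asserted as an
invariant.

Basins are found by steepest-descent assignment of every populated bin to
its local minimum over 8-neighborhoods (ties broken by bin index), followed
by watershed merging: a basin whose depth — lowest connecting saddle minus
its minimum — is below `min_depth` (default 1 kT) merges into the neighbor
across that saddle.  A basin isolated across masked bins (typically
single-count outlier bins) gets a *virtual saddle* to the basin with the
nearest bin, at the height of the facing bin pair; this lets sampling-noise
islands merge away while genuinely separated deep basins, whose facing
boundary bins are high in G, stay separate.  Basins are labelled A, B, C …
by increasing minimum G; those below `min_population` (default 2%) are
flagged minor, mirroring the usual major/minor distinction without hand
labeling.  No barrier heights are reported as physical quantities:
histogram landscapes at this sampling are not accurate enough for that.

## Gromos clustering and the order parameter O

Gromos clustering greedily extracts, from the pairwise RMSD matrix, the
frame with the most neighbors within the cutoff (ties → lowest frame
index), removes it and its neighbors as one cluster, and repeats.  The
cluster *medoid* is the member with the lowest mean RMSD to the other
members; weights are relative cluster sizes.

The ensemble-disorder order parameter over representatives s_i with
weights w_i is

    O = Σ_i w_i log2[ 1 + Σ_j w_j exp( −D²(s_i, s_j) / (2⟨D²⟩) ) ]

with D² the squared Cα RMSD after pairwise optimal superposition (a
no-refit flag is exposed).  The reference scale ⟨D²⟩ — the pairwise MSD
expected from the thermal fluctuations of a folded protein — defaults to
0.27 nm².  The literature value is printed as "0.27 nm", dimensionally a
distance although the symbol enters as a squared distance; the nm² reading
is used and the scale is an explicit parameter so either convention can be
reproduced.  O = 1 for a single conformation; for n equally weighted,
mutually distant conformations O = log2(1 + 1/n) → 0 as n → ∞.  Both
closed forms, the duplicate-and-split-weight invariance, and monotone
decrease under uniform D² scaling are asserted.

`disorder_profile` runs the full cutoff → clusters → medoids/weights → O
workflow for a list of cutoffs and returns the (cutoff, n_clusters, O)
table.  Cutoffs are always explicit nm inputs.

## Secondary structure and solvent accessibility

Secondary structure is assigned by a re-implementation of the
Kabsch–Sander hydrogen-bond model (self-contained and testable frame by
frame; an external DSSP binary is used only as an independent oracle in the
tests).  The bond energy between C=O of residue i and N–H of residue j is
E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol with distances
in Å, called a bond at E < −0.5 kcal/mol.  Amide hydrogens are
reconstructed at 0.1 nm from N along the anti-bisector of C(i−1)–N–CA when
absent; prolines and the N-terminal residue donate nothing.  n-turns
(i→i+3, 4, 5) define G/H/I through two consecutive turns with priority
H > G > I; residues spanned by isolated turns are T; everything else C.
Strand classes are out of scope — these are helix/coil analyses.  On ideal
α-, 3₁₀- and π-helix and extended-chain constructs the helix-class labels
agree 100% with `mdtraj.compute_dssp`; the acceptance threshold is ≥95%.

Solvent-accessible surface uses Shrake–Rupley quadrature on a deterministic
golden-spiral point set (default 960 points, probe 0.14 nm; van der Waals
radii C 0.17, N 0.155, O 0.152, S 0.18, H 0.12 nm, 0.17 nm for
pseudo-atoms).  Accuracy: ≤0.5% against the isolated-sphere closed form,
≤1% against a two-sphere lattice-integration oracle.  Translation
invariance is exact; rotation moves the buried-point pattern relative to
the space-fixed point set, so rotational invariance holds only to the
quadrature error (≈0.1–0.5% at 960 points) — an intrinsic property of the
method, asserted at 0.5%.

Helical-content summaries report mean/max counts of H/G/I per frame subset
and percentages of the full chain length.  Table maxima are per-frame
maxima over the subset (the per-residue reading is the other possibility;
this one is implemented).

## Interaction persistence and residue networks

Per frame, a residue-pair interaction exists when the class-specific
group distance is at or below the cutoff; persistence is the exact rational
(frames present)/(total frames).  Classes and defaults:

| class          | groups                                                           | cutoff |
|----------------|------------------------------------------------------------------|--------|
| salt_bridge    | Lys NZ, Arg NE/NH1/NH2 vs Asp OD1/OD2, Glu OE1/OE2 (His optional)| 0.5 nm |
| aromatic       | ring centroids of Phe/Tyr/Trp/His                                | 0.6 nm |
| amino_aromatic | basic N atoms vs ring centroid                                   | 0.6 nm |
| hydrophobic    | side-chain carbons of Ala/Val/Leu/Ile/Met/Pro/Phe, \|i−j\| ≥ 2   | 0.5 nm |

The amino-aromatic cutoff follows the aromatic one (no separate literature
value); His participates in salt bridges only on request; no sequence
separation filter is applied to salt bridges by default.  Reduced
topologies carrying one side-chain reference atom (CB) per residue map it
to the groups by residue type.

Pairs at or above the persistence threshold (default 20%) become edges of a
simple weighted graph (networkx-backed).  Hubs are residues of degree ≥ 3
("at least three interactions"; the stricter "more than three" reading is
`min_degree=4`).  Connected components are reported largest-first.  All
simple paths between two residues are enumerated by a depth-first search
over sorted neighbors that never revisits a node within a path — emission
is therefore lexicographic — with a truncation flag beyond `max_paths`.
Hubs, components and paths are checked against exhaustive brute force on
hundreds of random graphs with ≤8 nodes.

## Charge-state distribution deconvolution

Native ESI-MS charge-state distributions (relative intensity vs integer
charge z, after the m/z → z transformation) are fitted with a sum of
Gaussians by bounded least squares (quantile-spread initialization;
σ ∈ [0.2, z-range]).  The "minimal number of Gaussians giving a stable
fit" is operationalized as the smallest k that

1. *describes* the data: the residual leaves at most 0.5% of the total
   squared intensity unexplained, and
2. is *stable*: 20 residual-resampling bootstrap refits keep every
   component mean within 0.5 charge units.

Information-criterion margins were evaluated and rejected for this data
regime: with relative-intensity noise on ~20 grid points the true-k
residual sits far below the naive noise scale, so AIC-type penalties keep
rewarding phantom components.  The explained-fraction rule stops at the
true mixture (adding components cannot be "needed" once the fit is within
tolerance), and the stability screen catches degenerate fits; flat or
otherwise un-Gaussian profiles fall back to k=1 with a poor-fit flag.  All
thresholds are parameters.  On 50 seeded bimodal spectra (means 7 and 10,
σ 0.8/1.0, areas 0.3/0.7, 2% noise) the fit recovers both means within
±0.3 z and both area fractions within ±0.07 in 50/50 runs.

Component area fractions are the apparent conformer abundances.  The mean
charge of a component maps to an estimated SAS through SAS = a·z^b; the
calibration constants (a, b) come from published charge/surface
correlations and are deliberately a **required** argument — there is no
universal default, and silently assuming one would fabricate surface areas.

## Synthetic data: what it emulates and what it does not

`generate_ensemble` builds full-backbone chains (N, H, CA, C, O plus one
side-chain reference pseudo-atom per residue) from ideal internal
coordinates (NeRF construction; trans peptide, standard bond geometry), so
hydrogen-bond secondary structure and contact typing work on the output.
Defaults emulate the study system: a ~70-residue chain, two helical
segments with partial occupancy, and a mixture of compact and extended
states.  Each state draws a template coil conformation once; frames add a
small dihedral jitter (default 3°) and Gaussian coordinate noise (default
0.01 nm).  Residues inside an *occupied* segment (per-frame Bernoulli
draw) get ideal α-helix dihedrals (φ=−57°, ψ=−47°).

The compact/extended contrast is realized through the coil dihedral
distribution: the state's compactness scale sets the fraction of
extension-region (φ≈−120°, ψ≈135°) versus turn-region dihedrals, which
controls the radius of gyration statistically.  A Cartesian harmonic
restraint toward a target Rg was considered and rejected: it would distort
the covalent geometry that the hydrogen-bond and contact analyses depend
on.  Consequently realized Rg values are emergent, not prescribed — the
ground-truth report records them per frame.

`plant_contacts` places scheduled side-chain pseudo-atom pairs at
dedicated, well-separated contact sites (0.30 nm apart when scheduled,
>0.7 nm from everything otherwise; unscheduled charged residues are parked
too), so measured persistences equal the schedule *exactly* and
off-schedule contacts are exactly zero.  This deliberately sacrifices
side-chain realism for exact ground truth; the backbone is untouched.  A
residue scheduled in two pairs active in the same frame is rejected.
Deterministic masks use evenly spaced frames (exactly round(p·F) of them);
probabilistic masks are Bernoulli draws.

`generate_csd` evaluates the component Gaussians on the integer charge
grid and applies multiplicative relative noise.

What passing tests on this generator do **not** show: force-field realism,
solvent effects, kinetics, realistic side-chain packing, or experimental
noise structure beyond the stated models.  They do show that every
algorithmic stage recovers what was planted, under the statistical
structure (state mixtures, occupancies, persistences, bimodal CSDs) the
real analyses face.

## Numerical choices and degenerate inputs

- Eigenvalues clipped at −1e-10 → 0; eigenvectors orthonormal to 1e-8.
- Gromos ties (neighbor counts, medoid means) break to the lowest frame
  index; basin descent ties break to the lowest bin index — all outputs
  are deterministic given the input.
- Single-frame ensembles: valid everywhere except PCA (no fluctuations)
  and pairwise-RMSD consumers that need F ≥ 2.
- Degenerate FEL axes (zero range) widen to a unit span before binning.
- The multi-model PDB reader pre-scans per-MODEL atom counts so ragged
  files fail with the offending MODEL named; writes round-trip to the
  fixed-width precision of the format (1e-4 nm).
- Problem sizes in the test suite (chains of 20–70 residues, 50–500
  frames, 24²–32² landscape bins, 10-seed end-to-end replicates) were
  chosen as the smallest at which the statistical assertions are
  well-powered.

## Known limitations

- Cartesian PCA only; no time-lagged or dihedral variants.
- 2-D landscapes only; no kinetics or Markov-state modeling.
- Helix-focused secondary structure (no strand/bridge classes).
- Distance-only interaction criteria (no angular terms for aromatics).
- The charge→SAS mapping is a bare power law; calibration must be
  supplied.
- SAS rotational invariance holds to quadrature error, not exactly.
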