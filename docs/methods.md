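# Methods

`allomap` maps interdomain allosteric communication in two-domain
proteins by combining two independent lines of evidence: the
*structural dynamics* encoded by a single conformer (elastic-network
models and linear-response perturbation scanning) and the
*evolutionary record* of the protein family (pairwise coevolution of
alignment columns).  The package is organised around the Hsp70/DnaK
architecture — a nucleotide-binding domain (NBD, subdomains IA, IB,
IIA, IIB), a short interdomain linker, and a substrate-binding domain
(SBD) — but every stage takes an arbitrary structure, domain partition
and alignment.

## Elastic-network dynamics

**Gaussian network model (GNM).**  Residues are reduced to their Cα
atoms and connected by identical springs within a cutoff r_c = 7.3 Å
(the conventional GNM contact radius; configurable).  The topology
matrix is the Kirchhoff/graph-Laplacian Γ; its eigenmodes u_k with
eigenvalues λ_k (ascending, zero modes excluded) describe isotropic
fluctuations.  The mode mobility of residue i is M_i^(k) = (u_k)_i²/λ_k
and the cumulative profile over the m slowest internal modes is
⟨M_i⟩|_m = Σ_{k≤m} M_i^(k); m = 10 is the default for protein-sized
systems, m = 2 the natural choice for a two-lobe toy (one or two modes
carry essentially all the interdomain motion there).  The fraction of
dynamics captured by m modes is Σ_{k≤m} λ_k⁻¹ / Σ λ_k⁻¹.  Mode order
within numerically degenerate eigenvalue groups is fixed by the index
of the largest-magnitude eigenvector component, and eigenvector signs
by making that component positive, so outputs are deterministic.

**Hinges.**  A hinge is a residue with minimal mobility in the slow
modes.  Operationally we require a strict local minimum within a
±`window` (default 5) neighbourhood of the profile *and* a value below
the `percentile` (default 20) of the whole profile; the percentile
gate suppresses shallow ripples inside already-mobile regions.  The
strict-minimum-plus-gate definition is this package's own
operationalisation; hinge literature typically reports minima without
stating an algorithm.

**ANM and perturbation-response scanning (PRS).**  The anisotropic
network model builds the 3N×3N Hessian from the same Cα nodes with
cutoff 13 Å (a standard ANM radius; the ANM cutoff, γ and the
normalisation below are package choices, exposed as parameters).
Linear response gives ΔR = H⁺F.  For a force at residue i, the
response of residue k averaged over isotropically random unit force
directions has the closed form s_ik = ‖G_ki‖²_F/3, with G_ki the 3×3
block of H⁺.  The closed form is the default compute path; the
Monte-Carlo protocol (m random unit forces, squared displacements
averaged) is retained as a seeded validation mode with identical
expectation.  Rows of the response map are normalised by the
self-response s_ii, removing the trivial scaling by local flexibility;
*effectiveness* (effector strength) and *sensitivity* (sensor
strength) are row and column means excluding the diagonal.  The map is
asymmetric — being easy to displace and being able to displace others
are different roles — which is precisely what the symmetric fluctuation
covariance cannot resolve.

Numerical notes: H⁺ is formed by eigen-decomposition with the six
rigid-body modes removed; the build fails loudly if more than six
numerically zero modes appear (disconnected or geometrically degenerate
networks — e.g. coplanar or collinear bead sets — have genuine
zero-energy mechanisms and no meaningful PRS).  The stochastic-mode
validation statistic is the maximum deviation from the closed form
*relative to the profile maximum*: tiny map entries carry irreducible
relative Monte-Carlo noise at fixed trial count (for a rank-1 G block
the per-sample relative standard deviation is √(9/5 − 1) ≈ 0.89), so
entrywise relative error is not a convergent statistic, while the
normalised ∞-norm is.  At 4000 trials it is below 3% on a 20-node
fixture across seeds.

## Sequence conservation and coevolution

**Alignment handling.**  FASTA/Stockholm I/O, integer encoding over 20
amino acids + gap (unknown letters count as gaps).  Columns are mapped
to the residue numbering of a chosen reference sequence so sequence
statistics can be addressed by structure residue ids.  Redundancy
weighting assigns sequence s the weight 1/|{t: identity(s,t) ≥ 0.8}|;
M_eff = Σw.  Conservation is per-column Shannon entropy over the amino
acids present (gap-excluded, renormalised), in nats by default.

**Five scorers, one interface.**  Each returns a symmetric L×L matrix
with a NaN diagonal:

* *MIp*: mutual information on gap-excluded pair tables, followed by
  the Average Product Correction S′ = S − S̄_i S̄_j / S̄ (row/grand
  means excluding the diagonal), which removes the separable
  background a column shares with everything (phylogeny,
  conservation).
* *OMES*: Σ_ab (N_obs − N_exp)²/N_valid on the sequences non-gap at
  both columns, marginals taken on the same subset.
* *SCA* (weighted-covariance form): positional weights
  φ_i(a) = |ln(f_i(a)(1−q_a)/((1−f_i(a))q_a))| against bundled
  background amino-acid frequencies; the score is the Frobenius norm
  of the φ-weighted covariance block.  The pseudocount (fraction 0.03
  toward background) regularises φ only; the covariance itself uses
  raw frequencies so invariant columns contribute exactly zero.  The
  deterministic weighted-covariance variant is implemented (rather
  than perturbation/subalignment resampling); the variant is recorded
  in the result metadata.
* *DI*: mean-field direct-coupling analysis with gaps as the 21st
  state, relative pseudocount 0.5, and sequence weights.  The coupling
  matrix is e_ij(a,b) = −(C⁻¹) on the (q−1)-state reduction (gap as
  reference state); per pair, a two-site model with those couplings is
  fit to the single-site marginals by iterative matching, and DI is
  the KL divergence of the two-site model from independence.  Null DI
  does not vanish at finite sample size — coupling noise scales as
  N^(−1/2) and DI as its square (≈0.1 nats at N = 500, L = 10) — but
  sits 1–2 orders of magnitude below planted/true couplings.
* *PSICOV-style*: graphical lasso on the weighted 21-state indicator
  covariance; the pair score is the L1 block norm of the precision
  matrix over non-gap states, then APC.  Because each column's
  indicators sum to one the raw covariance is exactly singular, so it
  is shrunk toward its diagonal (5% steps) to a conditioning floor
  before estimation.  Per column, amino acids with weighted frequency
  below 1% are pooled into one state, keeping the problem dimension
  proportional to states that carry signal; the penalty defaults to
  ρ = 0.005 on the indicator-covariance scale, doubling automatically
  if the estimated precision is denser than 25% off-diagonal.

Gap conventions follow the originating methods: gaps excluded for
MI/OMES/SCA, the 21st state for DI/PSICOV.  MI/OMES/SCA run unweighted
by default (their originals do not weight); DI/PSICOV always use the
weights.

## Interdomain synthesis

The interdomain block of each score matrix (rows = one domain's
residues, columns = the other's) is the object of interest.  The
pair-space denominator uses *full domain sizes* — for the bundled DnaK
partition, NBD 1–388 × SBD 393–604 = 82,256 pairs — with residues
missing from the alignment mapping present as NaN rows/columns.  The
top fraction (default 0.06%, i.e. k = ⌈0.0006·82,256⌉ = 50 at DnaK
scale) of each method's block is ranked (ties broken by residue ids;
sequence-adjacent pairs excluded as trivially correlated), and the
*consensus table* keeps pairs ranked by at least `min_methods` = 2
scorers, ordered by support count then best rank.

**Degeneracy flag.**  The five scorers are not statistically
independent: they estimate correlation from the same finite sample, so
on signal-free data they frequently crown the same random extreme,
and a naive ≥2-method consensus is not empty on null alignments.  Each
consensus pair therefore carries a robust z (score minus median, over
1.4826×MAD, within its method's interdomain block, maximised over
supporting methods).  Measured extreme-value noise tops out near z ≈ 10
across methods and seeds, while planted couplings score z ≳ 75; a
table whose pairs all fall below z_min = 25 is flagged *degenerate*
(shared noise, not signal).  The threshold is a fixed design constant
midway between the two regimes.

**Propensities and contacts.**  The cumulative interdomain coevolution
propensity of a residue is the row/column sum of the interdomain block
(NaN-partners ignored).  Consensus pairs are annotated against a
structure: minimum heavy-atom distance ≤ 4.5 Å → `contact`; Cα
distance > 30 Å → `distant`; otherwise `neighboring_no_contact`
(`unresolved` if a residue is missing).

## Synthetic ground truth

**Structures.**  Each lobe is a compact, connected cluster grown by
random sequential packing on a jittered cubic lattice (3.8 Å spacing,
candidates scored by occupied-neighbour count so lobes are globular),
carrying one protruding stalk bead.  The linker is a chain with exact
3.8 Å consecutive spacing following a gentle helical sweep (1.5 Å
off-axis): a perfectly collinear chain would leave the ANM with exact
zero-energy bending/torsion mechanisms, verified by rigidity-matrix
rank analysis.  Geometry guarantees each chain-linker bead exactly two
contacts at the GNM cutoff.  The *planted hinge* is the whole flexible
bridge (stalk–linker–stalk): the slow-mode node of a two-lobe system
sits anywhere along the bridge depending on the lobe mass ratio, so
truth pinned to the chain beads alone would be wrong for unequal lobes
for a physical reason.  Default lobe sizes in the recovery studies are
22–40 beads — large enough for dense interiors, small enough that 50
replicates decompose in seconds.

**Alignments.**  Background columns are drawn independently from
Dirichlet(0.5)-sampled 20-state profiles.  Coupled pairs are planted
copula-style: the pair uses `n_pair_states` (default 4) equiprobable
amino acids and a random permutation π; with probability equal to the
coupling parameter the second column is π(first), otherwise
independent.  Coupling 1 with two states gives MI = ln 2 exactly in
the infinite-sample limit; the default recovery studies use coupling
0.9 with four states (realised MI ≈ 1.0 nats, comfortably above the
0.5-nat regime where all five methods should succeed).  The realised
MI of every planted pair is measured from the sampled counts and
stored in the truth record, so tests never re-derive truth from the
fixture.  Conserved columns, exact-duplicate sequence groups (to
exercise weighting) and fully null alignments are also available.

What the generator does *not* emulate: phylogenetic tree structure
(duplicates are the only redundancy), gap patterns correlated with
structure, contact-map-coupled evolution, or compositional biases of
real families.  Passing the recovery suites therefore demonstrates the
statistical machinery is correct and calibrated, not that real-family
inference is unbiased — on real alignments, phylogeny inflates raw MI
(mitigated by APC/weighting) and alignment errors add noise.

## Problem sizes and determinism

The bundled studies use: 50 two-domain structures (≈60–90 beads) for
hinge recovery; a 20-node fixture with 4000 force trials per residue
for PRS validation; one 100-column × 2000-sequence alignment with 10
planted pairs for recovery (the graphical lasso dominates at ≈15 s);
and 20 null alignments of 50 × 1000 for consensus calibration.  These
sizes put every replicate-based check in the minutes range while
keeping the binomial success criteria (≥45/50, ≥8/10, ≥18/20)
statistically meaningful.  All randomness flows from explicit seeds;
every pipeline run writes a JSON manifest of the complete
configuration, and reruns from the same manifest are byte-identical.

## Known limitations

* GNM/ANM assume a single well-packed conformer; profiles for
  structures with unresolved segments treat the gap as absent rather
  than flexible.
* Mean-field DI and the lasso precision are estimators with known
  finite-sample bias; their absolute values are not comparable across
  alignments of different M_eff (rankings are the intended output).
* The ANM cutoff, PRS normalisation, and the coevolution
  hyperparameters are package defaults, not values with a single
  canonical source; all are exposed in `RunConfig` and recorded in run
  manifests.
* The DnaK domain partition and the 4.5 Å/30 Å contact classes are
  bundled constants for the Hsp70 use case; other proteins need their
  own `DomainMap`.
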