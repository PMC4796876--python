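# Methods

This note documents the models implemented in `hotmusic`, the conventions
and defaults behind them, what the synthetic data generator does and does
not emulate, and the numerical choices that matter for reproducing its
behaviour. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Two-state thermodynamic background (`hotmusic.thermo`)

A two-state folder with temperature-independent folding heat capacity ΔCp
has the stability curve

    ΔG(T) = ΔHm (1 − T/Tm) + ΔCp (T − Tm − T ln(T/Tm)),

with ΔG(Tm) = 0 by construction. Folding sign convention throughout:
ΔG < 0 for a stable fold, ΔHm < 0, ΔCp < 0; internally everything is in
Kelvin and kcal/mol, and user-facing ΔTm/Tm values are °C.

For a mutation that leaves ΔHm and ΔCp unchanged and shifts the curve by
a small ΔΔG, the melting-point shift is linear:

    ΔTm = Tm · ΔΔG / ΔHm,

so ΔTm and ΔΔG are exactly anticorrelated (ΔHm < 0). When ΔΔHm or ΔΔCp
are nonzero no closed form is assumed: the mutant curve is constructed
from the wild type by shifting ΔHm and ΔCp and adding the offset that
makes ΔG_mut(298 K) = ΔG_wt(298 K) + ΔΔG, and its melting temperature is
re-solved numerically (grid scan over [250, 450] K, Brent refinement to
|ΔG| < 10⁻⁹ kcal/mol, root nearest the wild-type Tm when cold
denaturation yields two zeros). This relation is what motivates the
1/N_r scaling and the Tm-polynomial output weights of the networks below:
the coefficient Tm/ΔHm is protein-specific, and ΔHm correlates with chain
length to first order.

## Residue descriptors (`hotmusic.structures`)

One chain per structure; the 20 canonical residues only; highest-occupancy
altloc; hydrogens ignored. Three structure elements per residue:

* **Relative solvent accessibility** (percent): Shrake–Rupley ASA
  (probe 1.4 Å, 960 lattice points per atom) divided by a per-amino-acid
  maximal area. The shipped reference is the Tien et al. (2013)
  theoretical extended-tripeptide table; RSA is clipped to [0, 100]. The
  Shrake–Rupley implementation is a vectorised version of the classic
  point-counting algorithm (deterministic Fibonacci sphere lattice,
  Biopython's element radii); the test suite cross-checks it against
  Biopython's reference implementation on the same structures.
* **Torsion domain**: a six-label partition of the Ramachandran plane
  (helical, extended, ppII, helical-L, epsilon, other) shipped as an
  explicit rectangle table; first match wins. Chain termini, incomplete
  backbones and chain breaks (C–N > 2.5 Å) are "undefined" and never
  raise.
* **Pair distance**: Euclidean distance between side-chain heavy-atom
  geometric centroids (CA for glycine), binned half-open in [3.0, 8.0) Å
  with 0.2 Å bins; minimum sequence separation 1.

All conventions live in `DescriptorConfig`; an MD5 hash of the
configuration travels with every derived potential and is checked at
featurisation time, so train-time and predict-time conventions cannot
silently diverge.

## Statistical potentials (`hotmusic.potentials`)

Energies are in kT with kT ≡ 1: only relative weights matter, since the
trained network supplies all scaling. Two-element potentials use the
standard log-ratio of observed to expected frequencies; three-element
potentials use the symmetric joint × singles / pairs factorisation

    ΔW(x, y, z) = −ln [ F(x,y,z) F(x) F(y) F(z) / (F(x,y) F(x,z) F(y,z)) ],

which vanishes whenever the third element adds no association beyond the
pairwise ones. Counting: single-residue forms (sa, st) contribute one
count per residue; pair forms contribute both ordered directions of every
in-range geometric pair (so the sd table accumulates 2 counts per pair).
Residues with an undefined element are skipped for the forms that need
it.

**Sparse-data correction.** The observed/expected ratio of each cell is
shrunk toward 1 with a pseudocount n₀ (default 10):

    corrected = (n_eff · ratio + n₀) / (n_eff + n₀),

where n_eff is the cell's *expected* count under the no-association null,
so that n_eff·ratio is simply the observed count and the corrected ratio
is (n_obs + n₀)/(λ + n₀). This choice keeps rarely-populated bins bounded
(an association observed twice where 0.2 were expected is damped to
≈ ln 1.2, not ln 10) and gives never-observed-but-expected associations a
finite positive energy that decays to zero as n₀ grows. Using the
observed count as n_eff instead leaves near-empty bins with unbounded
energies; this was measured and rejected.

**Smoothing.** Distance-resolved tables are convolved along the distance
axis with an edge-renormalised triangular window of half-width 2 bins
(weights 1:2:3:2:1); constants are preserved exactly and interior mass is
conserved. Other axes and non-distance potentials are untouched.

**Temperature dependence.** A Tm-annotated corpus is split at 65 °C into
mesostable and thermostable subsets, and from each subset five grouped
potentials are derived: {sd}, {sds}, {sad}, {sa + saa}, {st + stt + sst};
the std form has no temperature-dependent counterpart. Because the
component tables of a group have different shapes, a grouped potential
keeps its components and sums their mutation-energy contributions.

## Mutation features (`hotmusic.features`)

The mutant structure is assumed identical to the wild type; only the
sequence element at the mutated position changes. Consequently
ΔΔW = W(mut) − W(wild) reduces exactly to the table lookups whose
sequence slot touches the mutated position — the package computes these
locally and the test suite verifies the cancellation against a
brute-force full recompute. Packing effects are carried separately by
ΔV± from the Zamyatnin (1972) mean residue volumes, split by sign
(ΔV₊ = packing stress, ΔV₋ = cavity creation). The accessibility fed to
the weight functions is the wild-type residue's RSA in percent; N_r is
the chain length.

## The two networks (`hotmusic.models`, `hotmusic.estimators`)

Both models weight their energy terms with sigmoids of the accessibility,
α(A) = φ + r/(1 + e^(−ω(A−b))) — a smooth interpolation between a core
weight (φ) and a surface weight (φ + r), with crossover position b
(percent) and steepness ω (per percent).

* **Tm-free model** (50 parameters = 12 × 4 sigmoid parameters + global
  scale a and offset c): ΔTm = c + a·[Σ α_ν(A)·x_ν]/N_r with
  x = (9 standard ΔΔW, ΔV₊, ΔV₋, 1). The division by N_r (configurable,
  on by default) reflects the 1/ΔHm ∝ 1/N_r coefficient of the
  small-perturbation relation.
* **Tm-aware model** (67 parameters = 13 × 4 + 3 × 5): three perceptrons
  (5 mesostable terms, 5 thermostable terms, ΔV± + independent) whose
  outputs are combined linearly with polynomial weights
  F_I(Tm, N_r) = q₀ + q₁Tm + q₂Tm² + q₃/N_r + q₄Tm/N_r, I ∈ {M, T, V}.
  The 5-term polynomial basis was chosen to reproduce the printed
  parameter total exactly while covering the Tm/ΔHm-motivated terms; the
  exact sigmoid/polynomial forms are package choices, calibrated to the
  parameter counts, since only the parameter lists of the original
  formulation are recoverable.

The final prediction is the arithmetic mean of the two model outputs; if
the wild-type Tm is unknown the Tm-free prediction is returned with a
warning.

**Training.** Mean-squared-error cost with fully analytic gradients
(verified against central differences in the suite). Estimators follow
the scikit-learn protocol (`fit`/`predict`/`get_params`, trailing
underscore fitted attributes). Each fit runs `n_restarts` (default 30)
random initialisations; every iteration the validation RMSE is tracked
and the best-validation iterate is kept (early stopping, patience
default 50); the restart with the lowest validation σ wins. The first
restart is warm-started from the flat-weight linear least-squares
solution — the model is linear in (φ, a, c) at fixed sigmoid shape, so
this is a cheap, deterministic, and often excellent starting point.
Optimisers: plain batch gradient descent (default, learning rate 10⁻³),
Adam, and L-BFGS. L-BFGS is what the tests and the acceptance script use
and what we recommend in practice: the features mix kT-scale energies
with ~10²-Å³ volume terms and a single fixed learning rate conditions
poorly on that mix.

**Cross-validation** (`hotmusic.train_eval`): k disjoint test folds
(default 5) covering the dataset; within each fold the remainder is split
8:1 into training and early-stopping validation sets (i.e. 80%/10%/10% of
the full set), mutation-wise; σ and r are computed on the untouched test
fold and pooled over out-of-fold predictions. Splits are by mutation, so
mutations of the same protein can appear on both sides — this mirrors the
protocol the method family reports; group-by-protein splitting would give
more conservative numbers.

**Evaluation**: σ = RMSE, Pearson r, 10%-outlier-trimmed variants
(removing exactly floor(0.1·n) largest-|error| points, ties broken by
dataset order — "outlier" is not otherwise defined in this field's
reports), and metrics stratified by accessibility (core < 15%, partially
buried 15–50%, surface > 50%) including σ normalised by the experimental
ΔTm spread.

**Dataset curation**: keep single substitutions in monomeric proteins of
X-ray structure with resolution < 2.5 Å, measured without chemical
denaturants on two-state transitions, with |ΔTm| ≤ 20 °C; each rejection
is labelled with the first failing rule. Replicate measurements of a
mutation are reduced to the entries at pH closest to 7 (within 0.5 pH
units of the closest) and averaged with equal weights; missing pH is
treated as 7.

## Synthetic data (`hotmusic.synthetic`)

The generator supplies every input the pipeline needs without downloads:

* **Structures**: ideal-geometry backbones (NeRF construction with
  standard bond lengths/angles) built from helical, extended and
  polyproline segments with 8° torsional jitter, plus a pseudo-CB
  side-chain atom on every residue — glycine included, so that the atom
  set (and hence ASA, centroid and torsion) is identical across residue
  types. Amino acids are sampled either uniformly (coupling 0) or biased
  by burial (hydropathy × contact-number z-score) and helicity
  (coupling > 0). Because residue identity never feeds back into
  geometry, sequence and structure elements are *exactly* independent at
  coupling 0, which the independence checks of the potentials rely on.
* **RSA reference**: synthetic studies use a reference table computed on
  the generator's own extended Gly-X-Gly conformation
  (`synthetic_descriptor_config()`), constant across residue types;
  real-structure work uses the Tien table. Mixing the two is prevented by
  the configuration hash.
* **Mutation datasets**: random single-point mutations over a corpus;
  the "experimental" ΔTm of each record is a planted parameter set's
  prediction on the true features plus Gaussian noise (default sd 2 °C,
  roughly the reproducibility of experimental ΔTm measurements across
  labs); wild-type Tm values are uniform on 40–90 °C; metadata flags are
  set so the curation filters keep everything unless violations are
  injected deliberately. Two planted truths ship: a moderate-steepness
  sigmoid set (ω ≈ 0.1/% so core and surface weights differ visibly) and
  a flat-weight set for exact-recovery checks, plus a Tm-aware truth
  whose mesostable branch dominates at low Tm.

What the generator does **not** emulate: compact tertiary folds (chains
are largely exposed, so the deeply-buried stratum is sparsely populated
and core-vs-surface contrasts are weaker than in real proteins); real
side-chain geometry (a single pseudo-atom per residue); the
destabilising-mutation bias, pH/buffer covariate structure and
protein-family redundancy of experimental collections. Passing the
planted-recovery tests therefore demonstrates the correctness of the
pipeline and estimator — not transferability to experimental data.

## Problem sizes and determinism

The test suite and acceptance script run synthetic studies at deliberate
desk scale, chosen as the smallest sizes at which the statistical claims
are stable: corpora of 4–30 structures of 35–120 residues for pipeline
and recovery checks, 200 structures for the independence limit, and
mutation datasets of 500–2000 records; cross-validation uses 5 folds and
6 L-BFGS restarts. Every stochastic step (corpus, dataset, splits,
initialisations) is driven by explicit integer seeds; rerunning with the
same seed is bit-identical end to end.

## Known limitations

* Wild-type and mutant structures are assumed identical; structural
  relaxation is encoded only through ΔV±. Mutations that repack the core
  or shift the backbone are outside the model, which is also why the
  |ΔTm| ≤ 20 °C curation rule exists.
* Potentials derived from small corpora carry sampling noise of order
  √λ/(λ + n₀) per cell (λ = expected count); with the default binning
  the three-element tables need thousands of structures before this noise
  is negligible. The pseudocount bounds, but does not remove, this noise.
* The sigmoid/polynomial parameterisations are calibrated to the
  published parameter counts, not recovered verbatim; trained weights are
  therefore not interchangeable with the original tool's.
* Multi-point mutations, mmCIF input, NMR multi-model handling and
  ΔΔG-as-endpoint prediction are out of scope.
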