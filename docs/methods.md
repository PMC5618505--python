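# Methods

## The profile representation

A protein P = R₁R₂…R_L is represented by its position specific frequency
matrix (PSFM), an L×20 matrix whose row i is a probability vector over the
20 standard amino acids: P_{i,j} is the frequency with which residue j
occurs at position i among the protein's homologs. Rows sum to 1; this
row-stochasticity is the only structural constraint the container enforces
(`validate_psfm` accepts row sums within 1e-3 of 1 — integer-percentage
files round — and renormalizes exactly).

Profiles are ingested from PSI-BLAST `-out_ascii_pssm` files. These carry
two 20-column integer blocks per position; the **weighted observed
percentages** block (divided by 100) is the one with frequency semantics,
so it is the one used — the log-odds block is not a probability
distribution and cannot satisfy the row-sum constraint. Positions whose
twenty percentages are all zero (no alignment evidence at that position)
fall back to the one-hot indicator of the query residue, which keeps every
row stochastic instead of producing an undefined 0-row. Columns are
remapped from PSI-BLAST's residue order (ARNDCQEGHILKMFPSTWYV) to the
package-wide canonical alphabetical order ACDEFGHIKLMNPQRSTVWY; every
downstream feature index is defined against the canonical order.

Sequence-level dataset hygiene follows the usual benchmark construction:
sequences shorter than 50 residues or containing the undetermined residue
'X' are removed. The rarer ambiguity codes B, Z, U, O are only removed
under a `strict` flag, since the standard filter names only 'X'; the
one-hot fallback profile rejects them regardless because it needs a
20-letter alphabet.

## The four transformations

All four map the variable-length PSFM to a fixed-length vector; ordering is
deterministic (separation d outermost and ascending, then first residue,
then second, in canonical order) so that feature indices, stored models and
weight analyses are reproducible across runs.

* **RPT**, Ω = 420. Positions are grouped by the query residue at that
  position (each standard amino acid acts as a probe); within group k the
  profile columns are summed: e_{k,j} = Σ_{i: R_i = A_k} P_{i,j}. Features
  are e/L flattened row-major, followed by the 20 column means of the PSFM
  (the profile's amino-acid composition). The grouping is by *query*
  residue — the profile alone does not determine it, so RPT requires the
  sequence (synthetic profiles carry an argmax pseudo-sequence). Probes
  absent from the sequence contribute zero rows, never NaN. Since each PSFM
  row has unit mass and lands in exactly one group, the 400 probe features
  always sum to exactly 1.
* **EDT**, Ω = 400·D. f(A_x, A_y | d) is the mean over i of
  (P_{i,x} − P_{i+d,y})² — the evolutionary non-co-occurrence of x and y at
  separation d. Implemented as direct squared differences (not the expanded
  a²+b²−2ab form) so that identical columns give exact zeros; values lie in
  [0, 1].
* **DBT**, Ω = 400·(D+1). f(A_x, A_y | d) is the mean over i of
  P_{i,x}·P_{i+d,y}, for d = 0…D. The d = 0 same-position block is included;
  its diagonal reduces to the amino-acid composition on one-hot profiles.
  Row-stochasticity makes every 400-feature block sum to exactly 1, a
  property the test suite exploits.
* **TT**, Ω = 8000. f(A_x, A_y, A_z) = Σᵢ P_{i,x}P_{i+1,y}P_{i+2,z} over
  consecutive triples, deliberately left *unnormalized* as defined — total
  mass is L−2, so trigram features scale with sequence length. This is a
  caveat for length-heterogeneous datasets; the [−1, 1] feature scaling in
  the classifier absorbs most of it in practice.

Default maximum separations are D = 7 for EDT and D = 4 for DBT, the
operating points at which these representations perform best on the
standard benchmark; both are overridable everywhere.

## Classifier

The model/results pair `ProfileSVM` / `ProfileSVMResults` wraps a
soft-margin SVM with RBF kernel k(u, v) = exp(−g‖u−v‖²) (libsvm via
scikit-learn's `SVC`). Raw features are scaled per feature onto [−1, 1]
with training min/max (constant features map to 0); the scaling record is
part of the fitted results and is reused verbatim at prediction time.
Scaling matters: unscaled DBT and TT features differ by orders of
magnitude.

Hyperparameters (c, g) are selected once by exhaustive stratified k-fold
grid search (defaults: c = 2⁻⁵…2¹⁵, g = 2⁻¹⁵…2⁵, step ×2, 5 folds,
seeded shuffling; scaling refit inside every fold) and then held fixed in
whatever evaluation scheme follows — leave-one-out with nested per-fit
selection would produce per-fold hyperparameters and is not what the
single-operating-point evaluation protocol reports.

Tie-breaking among grid points with equal CV accuracy prefers the smallest
c, then the smallest g — the most regularised, smoothest machine — but
skips tied candidates whose full-data machine has **no free support
vector**. When every dual coefficient sits at the box bound ±c, the bias is
pinned by the class counts alone; the moment the training classes are
off-balance by a single sample (as in every leave-one-out fit) such a
machine degenerates to a majority vote and can invert every held-out
prediction while looking perfect under balanced stratified CV. On strongly
separable data, where large regions of the grid tie at CV accuracy 1.0,
this veto is what keeps the selected operating point usable.

Prediction evaluates the decision function explicitly over the stored
support vectors, f(x) = Σ aᵢ k(svᵢ, x) + b, so a model saved to JSON and
reloaded reproduces decisions bit for bit. A decision value of exactly 0 is
resolved to the positive class.

**Discriminant weights.** The signed dual coefficients aᵢ = yᵢαᵢ
(zero-padded to all N training samples; Σaᵢ = 0 by the dual constraint)
give per-feature weights W = A·M, computed on the scaled training matrix —
the representation the machine was actually trained on. Because min-max
scaling is a positive-slope affine map per feature and Σaᵢ = 0 annihilates
the offset, the sign pattern agrees with the raw-feature version. For
bigram features the d ≥ 1 blocks of W are summed per ordered residue pair
into a 20×20 importance table; the d = 0 diagonal carries the
composition weights. For a *linear* kernel W coincides with the primal
weight vector (checked against the reference solver in the tests); under
the RBF kernel it is the standard first-order importance surrogate.

## Evaluation

SN, SP, ACC and MCC follow the confusion-table definitions. Degenerate
tables are handled explicitly: a zero MCC-denominator factor yields MCC = 0
with a flag in the report; SN (SP) is NaN-flagged when the positive
(negative) class is absent. AUC is computed by the Mann–Whitney rank
statistic with average ranks (ties counted ½), which is identical to the
trapezoidal area under the threshold-swept ROC curve; the ROC points
(computed separately, thresholds descending over unique decision values)
start at (0,0) and end at (1,1).

Schemes: jackknife refits scaling + machine N times on N−1 samples; k-fold
uses seeded stratified folds (k = N reduces to the leave-one-out splits
through the same pooled code path); the independent test trains once and
refuses id overlap between train and test sets; the ratio sweep subsamples
a held-out set at given positive:negative ratios (r = 1 on a balanced set
reproduces the independent-test accuracy exactly). Metrics are always
pooled over held-out predictions. Every seeded scheme is byte-for-byte
reproducible.

## Synthetic profiles

The generator draws each profile row from a Dirichlet distribution on the
20-simplex — row-stochasticity is the only constraint a PSFM carries, and
the concentration parameter α (default 0.5, giving sharp, conservation-like
rows) controls profile peakedness. The class signal multiplies the
Dirichlet weights of a chosen residue set by an effect size β in the
positive class; the default set {K, R, T} mirrors the residues that
dominate discriminant analyses of real DNA-binding proteins, and the
default conditions are 60+60 profiles, lengths uniform in [50, 120], β = 50.
β = 1 is the exchangeable null used for calibration. Each profile carries
an argmax pseudo-sequence so RPT applies.

What the generator does *not* emulate: positional structure (binding
motifs, domain architecture — the signal is column-wise and stationary),
inter-row correlation along the sequence, alignment-depth artefacts of real
PSI-BLAST profiles, and homology between samples. Passing recovery tests
therefore demonstrates that the pipeline extracts a residue-composition
signal planted in profiles end to end — not that it attains any particular
accuracy on real benchmark data, which requires real PSI-BLAST profiles.

## Numerical choices and sizes

* Transform oracle agreement is asserted to 1e-12 against plain triple-loop
  implementations; closed forms on uniform profiles hold to 1e-15 (EDT
  exactly 0 by the direct-difference formulation).
* Row-sum ingest tolerance 1e-3, exact renormalization after; plain-profile
  text round-trips to better than 1e-9 per element (written with 17
  significant digits).
* Recovery checks run at 60+60 samples, lengths 50–120, DBT D = 4
  (2000 features), grid search over the full default power-of-two grids;
  the whole acceptance computation completes in well under a minute on a
  single CPU.
* Grid-search CV accuracy comparisons are exact rational ratios; the first
  (smallest-c, smallest-g) non-saturated argmax is chosen.

## Known limitations

* TT's length dependence (above).
* The discriminant-weight reading of RBF machines is a linearisation; it is
  validated structurally against the linear-kernel primal weights, not as a
  faithful decomposition of the RBF decision surface.
* The PSI-BLAST parser targets the standard `-out_ascii_pssm` dialect
  (40-column header, 42+ column rows); exotic variants are rejected with a
  line-numbered error rather than guessed at.
* Reproducing published benchmark figures requires the PDB-derived datasets
  and PSI-BLAST profiles against a non-redundant database; generating those
  is outside this package's scope by design.
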