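# Methods

This note documents the models, numerical conventions and design choices
behind `quadpot`, in the spirit of the methods documentation of packages
like statsmodels or msprime: what is computed, under which assumptions,
and where the genuinely open choices were resolved.

## Coarse-graining and tessellation

Structures are reduced to one point per residue, the Cα coordinate. PDB
parsing (via gemmi) resolves altlocs by highest occupancy (ties: first in
file), drops residues without a Cα, maps MSE→M and SEC→C, and drops other
nonstandard residues with a warning. Secondary structure is taken from the
entry's HELIX/SHEET records reduced to 3 states (H/S/C); an external
per-residue label map can be supplied instead (e.g. a reduced DSSP
assignment), since record-based labels can differ from algorithmic
assignments.

The Delaunay tessellation is computed with Qhull (through
`scipy.spatial.Delaunay`). Degenerate inputs that Qhull rejects are
retried once after a deterministic joggle — a uniform perturbation of at
most 1e-6 Å from a fixed-seed generator — and the result is flagged
`joggled`. Co-spherical inputs (e.g. lattice-like point sets) can yield
zero-volume cells; these are kept, because removing them breaks the
face-to-face structure of the complex on which the depth classification
relies.

**Edge filter.** All analyses run on the filtered tessellation: any
tetrahedron with an edge strictly longer than the cutoff (default 12.0 Å)
is removed. "Longer than" is read literally, so an edge of exactly 12 Å
survives. The cutoff is a parameter because the 12 Å convention, while
standard for this family of potentials, is not structural law. Vertices
that lose all their tetrahedra become isolated: they have empty
neighborhoods, zero profiles, and are classified as surface (they
necessarily sit on the structure's exterior).

**Depth.** A position is surface (S) if it is a vertex of a triangular
facet belonging to exactly one tetrahedron; undersurface (U) if not S but
edge-connected to an S position; buried (B) otherwise. B positions have no
edges to S positions by construction, which is why the surface-edge-count
attribute is identically zero for them.

**Tetrahedrality** of a cell with edge lengths l₁..l₆ is
Σ_{i>j}(l_i−l_j)²/(15 l̄²); it is zero iff the tetrahedron is regular.

## The four-body potential

Quadruplets are unordered multisets of 4 residues written in ascending
alphabetical order (CCDH-style keys); there are C(23, 4) = 8,855 of them
over the 20-letter alphabet. Observed frequencies f count retained
tetrahedra over a training corpus; the reference probability is the
multinomial p = 4!/(∏ tₙ!) ∏ aₙ^tₙ with the composition aₙ taken over all
residues of the corpus chains (not only tessellation vertices — the
distinction matters only for isolated vertices and is resolved toward the
plain composition). The score is s = log₁₀(f/p).

Numerical conventions, all recorded in the potential's metadata and
serialized with it:

- **Log base 10**, configurable. The base is a global scale factor on all
  scores and cancels from any comparison made within one potential.
- **Sign.** The default is s = +log(f/p): overrepresented (favorable)
  quadruplets score positive, so destabilizing substitutions produce
  negative residual scores and the structure–function analyses read
  naturally ("more negative = more damaging"). The classical
  inverted-Boltzmann form −log(f/p) is available as `sign="paper"`; it
  flips every downstream score and nothing else.
- **Pseudo-count.** A count of 1 is added to every quadruplet before
  computing f (f = (count+1)/(total+8855)), so unobserved quadruplets get
  a finite unfavorable score instead of −∞. The alternative (a score
  floor) is deliberately not the default because it makes scores
  discontinuous in the corpus.

The table round-trips through a TSV with `#`-prefixed metadata lines
(corpus size, cutoff, log base, sign, pseudo-count, composition), so any
potential — including externally derived ones with the same schema — can
be loaded and validated.

## Computational mutagenesis

A substitution relabels one Cα vertex; coordinates are never
re-tessellated and no side-chain modeling is attempted. Consequences that
the implementation exploits and the test suite asserts:

- only tetrahedra incident to the mutated vertex change score, so the EP
  profile is supported on the mutated position plus its tessellation
  neighbors;
- the residual score (EP at the mutated position) equals tp_mut − tp_wt
  exactly; `residual_score()` computes both routes and raises if they
  disagree beyond 1e-9;
- Σᵢ qᵢ = 4·tp on every structure (each tetrahedron feeds 4 vertices);
- all scores are linear in the potential.

Mutations at isolated vertices yield all-zero profiles with a warning —
a well-defined degenerate case, not an error. CMPᵢ averages the residual
scores of exactly the 19 non-native replacements.

## Feature vectors

27 attributes per variant, in fixed order: position, native, replacement,
residual score; EP, identity and sequence offset of the six nearest
neighbors ordered by Cα–Cα edge length (ties broken by ascending sequence
number — a documented determinism choice, since ties are measure-zero on
real coordinates but occur in constructed data); mean volume and mean
tetrahedrality over the filtered incident tetrahedra; secondary structure;
depth; surface-edge count. Positions with fewer than six neighbors are
padded (EP 0, identity "-", offset 0) and flagged in a `padded` column
that is not one of the 27. Encoded tables are sorted by (position,
replacement) so re-encoding is byte-identical.

## Statistics

- Substitution conservation uses the six physicochemical groups
  [(A,S,T,G,P), (D,E,N,Q), (R,K,H), (F,Y,W), (V,L,I,M), (C)]; intragroup
  replacements are conservative.
- The activity-class comparison uses Welch's unequal-variance two-sided
  t-test — the safe default when only "t-test" is specified.
- Chi-square tests are Pearson, no continuity correction. Recomputing the
  published 4×3 polarity-by-quadrant table gives χ² = 103.48 (df 6)
  against a printed 103.32; the 0.15% gap is consistent with rounding in
  the source table and is inside the 1% tolerance used in the tests.
- Fisher's exact test for r×c tables sums multivariate hypergeometric
  probabilities of all margin-preserving tables no more probable than the
  observed one. Exhaustive enumeration is used for small tables (total
  count ≤ 30; the recursion visits every table, so the bound is set by
  enumeration size rather than by sample size — a 4×4 table with n ≈ 100
  already has far too many configurations). Larger tables use a seeded
  Monte Carlo over Patefield-sampled tables (`scipy.stats.random_table`),
  1e6 draws by default, with an add-one estimator so p ∈ (0, 1]; the
  method and seed are recorded in the result.
- Residual scores are binned into (−∞,−1), [−1,0), [0,1), [1,∞).
- The CMP-vs-RES scatter uses x = native environment score, y = CMP;
  quadrants are numbered counterclockwise from (+,+) and zero coordinates
  go to the positive side. The published tables constrain but do not
  uniquely determine this convention; it is fixed here and documented so
  cross-tabulations are reproducible.

## Classifiers

All four families run behind one sklearn pipeline: categorical attributes
(residue identities incl. the padding sentinel, H/S/C, S/U/B) are one-hot
encoded against fixed category lists (so folds encode identically);
numeric attributes are standardized for SVM and NN only. Positive class
is U (unaffected) throughout.

- RF: 100 trees.
- SVM: RBF kernel, C = 2.0, gamma = 0.01, sigmoid (Platt) probability
  calibration — the logistic-fit-to-outputs construction.
- DT: 10 bootstrap-aggregated CART trees. (CART pruning is not
  parameterized by a C4.5-style confidence factor; bagging dominates the
  variance behavior at this dataset scale.)
- NN: two hidden layers of (27+2)/2 = 14 units (the classic
  attributes-plus-classes-over-two heuristic; the width is configurable
  because no canonical value exists), SGD, learning rate 0.3, momentum
  0.2, 500 epochs.

LOOCV is deterministic given the model seed. 10-fold CV is stratified,
repeated (default 10×) with per-repeat seeds recorded, and reported as the
mean. The permutation test shuffles labels, re-runs cross-validation per
shuffle, and reports the empirical p as (1 + #{null ≥ observed})/(n + 1).
AUC uses the Mann–Whitney rank formulation with midranks, which equals
trapezoidal ROC integration on tie-free scores (asserted in the tests
against an independent implementation).

## Synthetic data

The generator emulates exactly the features the method consumes, nothing
more. Cα traces are self-avoiding random walks: 3.8 Å ± 1% steps, 3.5 Å
excluded volume, confined to a sphere of radius 3.0·n^⅓ Å (≈113 Å³ per
residue, the packing density of globular proteins — loose enough for the
walk to close, dense enough that larger traces contain buried positions).
Sequences are drawn i.i.d. from a configurable composition (uniform by
default). Labeled variant sets are drawn uniformly without replacement
from all (position, replacement ≠ native) pairs; class A is assigned below
a residual-score threshold τ (default: the sample median, which balances
the classes near the reference dataset's 201/171 split) and labels are
flipped with probability ε.

What passing tests on this data do and do not show: they validate the
geometry, the score algebra, the encoding, and that the classifiers can
recover a signal that is genuinely present; they do not show that the
potential trained on a handful of random-sequence walks carries the
biological information a curated 1,400-chain corpus provides — synthetic
sequences have no evolutionary structure, no secondary-structure edge
statistics, and labels generated from residual scores are circular by
construction (that circularity is the point: it makes the recovery target
exact and the noise level controllable).

## Problem sizes

Default test and acceptance runs use an 8-chain corpus of 60–100-residue
walks, a 120-residue target, 200-variant labeled sets, 1,000 variants for
the dual-route identity check, 200 label permutations evaluated with
single-repeat 10-fold CV, and 25-point sets for the brute-force
empty-circumsphere oracle. These sizes were chosen as the smallest at
which each property is convincingly exercised (e.g. the permutation null
mean is estimated to ±0.01 at 200 draws); all scale up through ordinary
function arguments.

## Known limitations

- Label-swap mutagenesis ignores backbone relaxation and side-chain
  packing; residual scores are perturbation measures, not ΔΔG estimates.
- HELIX/SHEET-record secondary structure can disagree with DSSP-style
  assignments; supply external labels where that matters.
- The DT family approximates a C4.5-style bagged tree with CART.
- Fisher exact p-values for large tables are Monte Carlo estimates;
  report them with their seed and draw count.
- mmCIF files, multi-conformer models and hetero-assemblies are out of
  scope; one chain at a time.
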