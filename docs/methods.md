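# Methods

## Encoding model

A protein sequence is modelled as a walk over the 20-letter amino-acid
alphabet, indexed throughout by a fixed physicochemical ordering
(descending isoelectric point and ionization equilibrium constant:
D E C N M F Q Y S P T V L I W H G A R K). Two 20 × 20 substitution
matrices drive the spectral encoding:

* the **unit matrix**, the identity in this basis. Note that with an
  identity matrix the window energy reduces to a closed form
  2 Σ_i √(count of residue type i in the window), which is invariant
  under any permutation of the alphabet — the physicochemical ordering is
  mathematically inert for this block and matters only as a labelling
  convention. The matrix is pluggable, so non-identity 0/1 substitution
  patterns (which would make the ordering meaningful) can be supplied.
* a **contact-energy matrix** of effective residue–residue contact
  energies. The packaged file is a deterministic synthetic stand-in
  (symmetric, values on the scale of statistical contact potentials,
  fixed seed) so that the pipeline is runnable with no downloads; it is
  clearly labelled as synthetic and should be replaced with an empirical
  contact-energy matrix for biological use. Files are 20 × 20 delimited
  tables with one-letter row/column labels in any order; they are
  permuted into the internal basis on load.

Each window matrix is read as the biadjacency block of a bipartite graph
on 20 + 20 vertices, and its energy is computed as twice the sum of the
window's singular values. This equals the sum of absolute eigenvalues of
the full symmetric adjacency [[0, M], [Mᵀ, 0]] — the 20 × 20 window
itself is not symmetric, so its raw eigenvalues are not a graph spectrum;
the bipartite embedding is the principled reading, and the identity is
property-tested against a dense eigensolver.

Profiles are fixed at 200 windows: a sequence of length n yields
max(0, n − 19) energies, left-anchored, zero-padded beyond (sequences
shorter than 219 residues) and truncated at 200 windows (longer
sequences). Sequences shorter than one window (n < 20) produce an
all-zero profile with a warning. The dipeptide block counts ordered
adjacent residue pairs, normalised by L − 1; its 400 entries are exact
rationals summing to 1 for L ≥ 2. The fused descriptor is
200 + 200 + 400 = 800 entries.

Non-canonical residues (X, B, Z, U, O, gaps, stops) are handled by
policy: `drop` (default; residue removed, length recomputed), `error`,
or `zero` (kept, contributing an all-zero adjacency column and skipped
by dipeptide counting). The 20-letter model is preserved in all cases.

## Reduction and pair assembly

PCA (exact SVD solver) reduces the fused descriptors to d dimensions;
d = 80 within-species, d = 20 in cross-species transfer, where stronger
noise suppression empirically helps. Component signs are canonicalised
(largest-magnitude loading positive) so fits are bit-reproducible. In
cross-validation the PCA is fitted on the training fold's proteins only —
the fitted protein ids are recorded on the model, and the test suite
asserts the guard — with an `all`-scope option for protocols that fit on
the full protein set. A pair feature is the concatenation of the two
reduced vectors in pair order; an optional symmetrised mode averages the
classifier scores of both orders.

Whether reduction should precede pairing or operate on concatenated pair
vectors is a genuinely open design point; per-protein reduction followed
by concatenation is used because it halves the fitted dimensionality and
makes the reduced protein representation reusable across pair lists.

## Classifier

Weighted sparse representation classification. Training pairs are the
columns of a dictionary X, L2-normalised (zero columns rejected); the
test vector is likewise normalised. The sparse code solves

    min ‖Wβ‖₁  s.t.  ‖y − Xβ‖₂ ≤ ε

and the predicted class minimises the class-restricted reconstruction
residual, ties breaking to the lower class index. The AUC score of a pair
is r(non-interacting) − r(interacting), so larger means more
interaction-like.

**Weights.** d_G(y, x) = exp(−‖y − x‖²/(2σ²)) measures similarity
(squared-norm Gaussian kernel; an unsquared variant is selectable). The
default penalty is w = 1/d_G: far training samples are expensive, near
ones cheap, which is what makes the code local and the class residuals
discriminative. The literal opposite orientation (penalty = d_G itself,
near samples expensive) is selectable as `invert_weights=False` /
`--literal-weights`; on cluster-structured data it empirically acts as an
anti-classifier (it systematically codes the test vector with the wrong
class's atoms) and is retained only for comparison.

**Kernel width.** σ defaults to 0.25 × the median pairwise distance
among normalised dictionary columns. At the full median the penalty
ratio between near and far samples is too flat to localise the code and
held-out accuracy collapses toward chance; a quarter of the median gives
strong locality without degenerating into nearest-neighbour behaviour.
Exposed in config; all reported results state it.

**Tolerance.** ε = 1e−3 on unit-normalised data by default. The class
decision is driven by the weights far more than by ε; values from 1e−3
to 0.2 give equivalent decisions at the reference conditions.

**Solver.** Substituting γ = Wβ reduces the problem to standard
basis-pursuit denoising on rescaled columns, solved by the LARS/lasso
homotopy path: the first path segment on which the residual reaches ε is
interpolated exactly (quadratic in the segment parameter, with a
boundary bisection guarding against floating-point overshoot). The
solution is deterministic and matches an independent SLSQP
convex-programming oracle to ≤1e−6 in objective on randomized feasible
instances; when ε is unreachable (tall dictionaries, or path-iteration
cap at 2000), the best feasible point is returned flagged
`converged=False`.

## Evaluation

Stratified k-fold cross-validation (k = 5 default, shuffled with a fixed
seed) at the pair level; protein-level disjointness is *not* enforced by
default (a stricter protein-level split can be emulated by constructing
pair lists accordingly). Metrics: ACC, SEN, Pre, MCC from confusion
counts, with zero-denominator cases reported as 0 and flagged undefined
so fold aggregation stays total, and rank-based (Mann–Whitney) AUC with
ties sharing rank. Reports carry per-fold rows plus the mean.

## Synthetic data

The generator emulates FASTA protein sets and labelled pair lists with a
compositional interaction signal: interacting pairs draw both proteins
i.i.d. from (1 − δ)·uniform + δ·uniform-on-{F, W, Y, I, L}, while
non-interacting pairs draw from the uniform composition; each protein
appears in exactly one pair. The signal is compositional because all
three descriptor blocks are composition-sensitive, so a planted signal of
this form is guaranteed to be visible to the feature set. Reference
conditions: 100 + 100 pairs, lengths uniform in 120–250 (spanning the
219-residue padding threshold so both the zero-padded and truncated code
paths are exercised), δ = 0.5. At these conditions the pipeline reaches
mean five-fold CV accuracy ≈ 0.92 and AUC ≈ 0.98, and at δ = 0 the
classes are statistically identical and accuracy sits at chance.

What this does and does not show: the generator has no homology, domain
structure, hub proteins, shared proteins across pairs, or class
imbalance. Passing it demonstrates that the pipeline recovers a
composition-level interaction signal without leakage — not that it
attains any particular accuracy on real interactomes, where performance
additionally depends on the contact matrix used, on protein sharing
between training and test pairs, and on negative-sampling artefacts.

## Numerical choices and limitations

* Window energies are computed by batched SVD over all windows of a
  protein; profiles are exact to ~1e−12 against the eigensolver oracle.
* PCA requires d ≤ min(#fitted proteins, 800); cross-validation at
  d = 80 therefore needs ≥ 80 training-fold proteins.
* The classifier is memory-based: prediction cost grows with the
  training-set size (one homotopy solve per test pair), and very large
  dictionaries will be slow; no sub-sampling is built in.
* Multi-class dictionaries are supported by the classifier, though PPI
  use is binary.
* The fused dimension is 800 (200 + 200 + 400); window count and the
  dipeptide block are configurable, so lower-dimensional variants
  (e.g. 100 + 100 + 400) can be emulated.
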