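# Methods

## Model and procedure

The package treats population stratification detection as constrained
clustering of a low-dimensional embedding of the genotype matrix.

**Dimension reduction.** For *n* individuals and *p* biallelic variants,
the minor-allele count matrix *Z* ∈ {0,1,2}ⁿˣᵖ is column-centered and the
*n* × *n* Gram matrix *H = Z_c Z_cᵗ* is eigendecomposed. Individual *i*'s
coordinate in dimension *j* is √λ_j·u_j(i). Two scalings are offered:

- `sqrt` (default): √λ_j·u_j — the rows of the score matrix *X* satisfy
  *XXᵗ = H*, so with *J = n* all pairwise Euclidean distances of the rows of
  *Z_c* are preserved exactly. This is the standard Gram-matrix (classical
  MDS / PCA) scaling, and the property the spectral pipeline's distances
  rely on.
- `eigenvalue`: λ_j·u_j — a literal "eigenvalue-weighted eigenvector"
  variant kept for comparability; it exaggerates the leading axes.

Eigenvector signs are fixed so the largest-magnitude entry of each
eigenvector is positive, making output deterministic across linear-algebra
backends. Tiny negative eigenvalues (round-off on an exactly PSD matrix) are
clamped to zero; a significantly negative eigenvalue raises an error. The
Gram matrix is accumulated over variant blocks so peak memory stays
O(n² + n·block) for very wide inputs.

Missing VCF genotypes are imputed with the rounded column mean at read time
(keeping the {0,1,2} invariant; after centering the residual effect per
imputed entry is at most 0.5), and their count is logged. Sites whose ALT
sample frequency exceeds 0.5 are flipped so counts always refer to the minor
allele. Monomorphic variants are retained — they contribute nothing after
centering — and multi-allelic records are skipped with a log message.

**Constraints.** Partial labels on a revealed subset (a fraction SSR per
subgroup, drawn without replacement) induce must-links between same-label
pairs and cannot-links between different-label pairs; explicit pair lists
may be merged in by logical OR. Before use, constraints are propagated to a
joint fixpoint — must-link transitive closure via union-find, cannot-links
lifted to must-link component pairs — and any pair then carrying both kinds
of evidence is zeroed in both matrices with a warning. Propagation runs
before contradiction removal, so the fixpoint is order-independent; the
consequence is that a cannot-link *inside* a must-component invalidates that
component's links entirely, which we consider the right behaviour for
contradictory evidence. The operation is idempotent and total.

**Affinity adjustment.** Steps run strictly in the order: base affinity →
overwrite (must → 1, cannot → 0) → cannot-anchor β-division → must-anchor
copy (only when α = 1). Both anchor argmaxes are evaluated on the matrix
state after the overwrite step; ties break toward the lowest sample index;
each unconstrained sample is processed once, so no β-division compounds.
The copied value W_{m_k,k} is read before any overwrite of column *k* within
the must-anchor step. Every sub-step preserves symmetry, the zero diagonal
and the [0,1] range (division by β ≥ 1 shrinks, the copy moves an existing
entry). When no sample carries a cannot-link (or must-link), the
corresponding step is skipped.

**Spectral core.** Local scales use the T-th nearest *other* point
(excluding self-distance zero), floored at 10⁻¹² with a warning for
duplicated points. Default T = 7, the value recommended in the
local-scaling literature; it is searched by model selection. Isolated
vertices get a zero D^{−1/2} entry and become their own spectral direction;
zero rows of the eigenvector matrix are mapped to the first basis vector
before row normalization (both warned). Eigendecomposition is dense for
n ≤ 2000 and shift-invert Lanczos beyond. K-means uses k-means++ with 20
seeded restarts, keeping the best-inertia solution.

**Model selection.** Prediction strength of θ = (K, α, β, T): random half
split (sizes ⌈n/2⌉/⌊n/2⌋), both halves clustered independently with
constraints restricted to each half's index submatrix, training labels
transferred to the test half by single-linkage (minimum member distance)
nearest-cluster assignment, and ARI(transferred, native) recorded. One
master seed spawns one RNG stream per repeat, shared by every grid point, so
all θ are compared on identical splits (a paired design that lowers
selection variance). Defaults: 10 repeats (configurable; there is no
canonical value). A half smaller than max(K, T+1) records a missing strength
for that repeat; a grid point missing on every repeat is excluded with a
warning. The best θ per candidate J, and then the best J, maximize mean
strength; per-repeat strengths are returned so the means are auditable.

Degenerate adjusted Rand cases (both partitions single-cluster or both
all-singletons — e.g. K = 1 inside cross-validation) return 1 by the
no-informative-pairs convention, with a warning. The ARI itself is computed
from the contingency table in exact integer arithmetic via the pair-count
form 2(ad − bc)/((a+b)(b+d) + (a+c)(c+d)), so textbook values such as −0.5
are reproduced exactly; both indices are O(rc), never pair enumeration.

## Synthetic data: what it emulates and what it does not

`simulate_genotypes` draws from a Balding–Nichols hierarchy: ancestral
minor-allele frequencies Uniform(0.05, 0.5); group frequencies
Beta-distributed around them with divergence F_g; subpopulation frequencies
likewise around their group with divergence F; genotypes Binomial(2, ·).
`three_group_model` arranges 3 + 4 + 3 subpopulations in three groups,
mirroring the continental layout of worldwide sequencing panels. An
optional admixed subpopulation mixes its frequencies 50/50 with a second
group. Defaults (p = 2000, F_g = 0.1, F = 0.02, 10 × 30 samples) give
cleanly separated continental groups and separable subpopulations.

The generator has **no linkage disequilibrium, no sequencing error, no rare
variants and no within-subpopulation kinship**. Passing tests therefore
demonstrate the algorithmic properties of the pipeline — not performance on
real sequencing data, where LD pruning, relatedness and batch effects all
matter. Note that at the default divergences the subpopulation problem is
*easy*: unsupervised clustering already attains ARI 1.0, so constraints
cannot improve on it there; the value of supervision shows on the
coordinate-level instances below.

`simulate_mixture` draws spherical Gaussian clusters with chosen centers
and per-cluster scales, standing in for PC coordinates directly. The named
`overlapping_pair_instance` — four subgroups, the overlapping pair of sizes
25 and 70 with centers one unit scale apart, two well-separated subgroups of
40 — reproduces the regime that motivates the method: a size-unbalanced,
heavily overlapping pair (as with the two East-Asian subpopulations of 25
and 68 individuals in public panels) that unsupervised clustering merges.
The size imbalance is essential to the phenomenon: with equal sizes,
kernel-sum evidence (the overwrite-only baseline) is unbiased and the
anchored adjustment's single-nearest-anchor decisions add noise without
removing bias, and the baseline is not beaten. With the imbalance, summed
affinities are biased toward the larger subgroup and the anchored
adjustment corrects for it.

## Numerical choices

- Scale floor 10⁻¹² for zero local scales; eigenvalue clamp tolerance 10⁻⁹
  relative; Laplacian symmetrized by (L + Lᵗ)/2 against round-off.
- Argmax and k-means ties: lowest index / lowest restart, deterministic.
- All RNG flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence.spawn`; no global state.
- Rand/ARI use 64-bit integer binomials; n up to ~10⁶ is safe.
- Sample alignment between files is always by identifier; mismatches are
  hard errors rather than silent reordering.

## Problem sizes

Test and reproduction runs use n between 120 and 300 with 20-seed
(coordinate instances) or 10-seed (genotype instances) averages, and
model-selection studies of 20 independent runs × 10 split repeats. These
sizes give stable means (ARI standard errors ≈ 0.01–0.02) while keeping the
full suite fast; all quantities scale to larger n through the same API, with
the dense eigensolver switching to an iterative one past n = 2000.

## Known limitations

- The cannot-anchor and must-anchor rules act through a single argmax
  anchor; on perfectly symmetric equal-size overlaps they can underperform
  the overwrite-only baseline (see above). Choosing α and β by prediction
  strength rather than fixing them is the recommended practice.
- Prediction strength based on ARI does not vanish on unstructured data
  (two half-clusterings of one Gaussian still cut it similarly, giving
  strengths around 0.3–0.5); it separates well from the ≈1 strengths of
  real structure, but its absolute value should not be read as evidence of
  structure on its own.
- Constraint matrices are dense n × n; fine for cohort-scale n (hundreds to
  a few thousand), not for biobank n.
- VCF reading targets biallelic SNVs; multi-allelic sites are skipped, and
  no LD pruning is performed (pre-pruned input is expected where LD is a
  concern).
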