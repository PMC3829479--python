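# sssc — semi-supervised spectral clustering for population stratification

`sssc` detects population structure in genotype data when the population
identities of *some* individuals are already known. Unaccounted population
stratification — systematic allele-frequency differences between
subpopulations — inflates false positives in association studies, and
closely related subpopulations (for example two European or two East-Asian
cohorts) are often inseparable by unsupervised clustering of principal
components. This package turns partial identity information into pairwise
**must-link** / **cannot-link** constraints and injects them into a
local-scale spectral clustering of the genotype principal components.

It is written for statistical geneticists who want to check or correct for
stratification before an association analysis, and for anyone clustering
low-dimensional embeddings with partial supervision.

## The method

Given an *n* × *p* matrix *Z* of minor-allele counts (entries in {0, 1, 2}),
columns are centered (*Z_c = AZ*, *A = I − n⁻¹𝟙𝟙ᵗ*) and individuals are
embedded via the sample Gram matrix *H = Z_c Z_cᵗ*: the coordinates of
individual *i* are √λ_j · u_j(i) for the top *J* eigenpairs (λ_j, u_j) of
*H*, which preserves all pairwise distances when *J = n*.

Clustering then proceeds through a constraint-adjusted affinity graph:

1. local scales σᵢ = distance from xᵢ to its *T*-th nearest neighbour;
2. affinity W_ij = exp(−d²(xᵢ, xⱼ)/σᵢσⱼ), W_ii = 0;
3. constraint adjustment with parameters α ∈ {0, 1}, β ≥ 1:
   - must-linked entries are set to 1, cannot-linked entries to 0;
   - each unconstrained sample *k* finds its most similar cannot-linked
     anchor c_k, and its affinity to every sample cannot-linked to c_k is
     divided by β (a point pulled toward one side of a cannot-link is pushed
     away from the other side);
   - if α = 1, each sample without a must-link finds its most similar
     must-linked anchor m_k and its affinity to m_k's whole must-link clique
     is set to W_{m_k,k};
4. normalized Laplacian L̃ = I − D^{−1/2} W D^{−1/2}, embedding by its *K*
   smallest-eigenvalue eigenvectors, row normalization, and k-means.

With α = 0 and β = 1 the adjustment reduces to the classic
similarity-overwriting semi-supervised baseline; with no constraints at all
it reduces to unsupervised local-scale spectral clustering.

All tuning parameters θ = (K, α, β, T) and the number of retained PCs *J*
are chosen by cross-validated **prediction strength**: the data are split in
half, each half is clustered independently, training labels are transferred
to the test half by single-linkage nearest-cluster assignment, and the
adjusted Rand index between transferred and native test labels — averaged
over repeated splits — scores each grid point.

## Worked example

`examples/02_constrained_clustering.py` builds a four-subgroup mixture in
which two subgroups of very different sizes (25 and 70 samples) sit one unit
scale apart — heavily overlapping, like two closely related subpopulations —
and reveals half of each subgroup's labels:

```
mean ARI over 20 seeds, n = 175:
  unsupervised:                  0.659
  overwrite-only (a=0, b=1):     0.767
  anchored SSSC  (a=1, b=10):    0.806
```

The adjusted Rand index (ARI) measures agreement with the true subgroups
(1 = perfect, 0 = chance). Constraints help the overwrite-only baseline, and
the anchored adjustment (α = 1, β = 10) recovers clearly more of the
overlapping pair. The other examples show the genotype-to-PCs pipeline
(`01`), parameter selection by prediction strength (`03`, which picks K = 3
and the informative dimensionality J = 4 with mean strength 1.000), and the
shell pipeline (`04`).

The same workflow is available from the shell:

```bash
sssc simulate --model model.yaml --seed 1 --out-prefix sim
sssc pca --genotypes sim.genotypes.tsv -j 10 --out scores.tsv   # or --vcf data.vcf
sssc cluster --coords scores.tsv --labels partial.tsv --k 10 --alpha 1 --beta 10 --seed 0 --out clusters.tsv
sssc select  --coords scores.tsv --grid grid.yaml --repeats 10 --seed 0 --out report.json
sssc evaluate --pred clusters.tsv --truth truth.tsv
```

Every command writes a JSON manifest (resolved parameters, input digests,
seed, version) next to its outputs so deterministic runs can be replayed.

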