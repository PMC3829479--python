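"""Separate two heavily overlapping subgroups using partial labels.

The instance has four subgroups; two of them (25 and 70 samples) sit one
unit scale apart and are hopeless for unsupervised clustering.  Revealing
half of each subgroup's labels (SSR = 0.5) yields must-link / cannot-link
constraints; the anchored affinity adjustment (alpha = 1, beta = 10) uses
them more effectively than overwriting constrained entries alone.
"""

import numpy as np

from sssc import (
    SSSCParams,
    adjusted_rand_index,
    cluster_sssc,
    cluster_unsupervised,
    constraints_from_labels,
    propagate_and_sanitize,
    sample_labeled_subset,
)
from sssc.simulate import overlapping_pair_instance

unsup, baseline, anchored = [], [], []
for seed in range(20):
    X, truth = overlapping_pair_instance(seed)
    revealed = sample_labeled_subset(truth, ssr=0.5, seed=seed + 1000)
    constraints = propagate_and_sanitize(constraints_from_labels(revealed, len(truth)))

    unsup.append(adjusted_rand_index(cluster_unsupervised(X, K=4, seed=seed), truth))
    baseline.append(
        adjusted_rand_index(
            cluster_sssc(X, constraints, SSSCParams(K=4, alpha=0, beta=1.0, seed=seed)), truth
        )
    )
    anchored.append(
        adjusted_rand_index(
            cluster_sssc(X, constraints, SSSCParams(K=4, alpha=1, beta=10.0, seed=seed)), truth
        )
    )

print(f"mean ARI over 20 seeds, n = {len(X)}:")
print(f"  unsupervised:                  {np.mean(unsup):.3f}")
print(f"  overwrite-only (a=0, b=1):     {np.mean(baseline):.3f}")
print(f"  anchored SSSC  (a=1, b=10):    {np.mean(anchored):.3f}")
# Higher is better; the anchored adjustment resolves most of the overlap the
# unsupervised method cannot, and improves on constraint overwriting alone.
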