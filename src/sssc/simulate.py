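"""Synthetic inputs with hierarchical population structure.

Two levels of realism are provided:

* :func:`simulate_genotypes` draws a minor-allele count matrix from a
  Balding-Nichols hierarchy: each variant has an ancestral frequency,
  continental groups draw their frequency from a Beta distribution around it
  with divergence ``F_g``, subpopulations draw around their group's frequency
  with divergence ``F``, and genotypes are Binomial(2, subpop frequency).
  This mimics a sample of continental groups containing partially
  overlapping subpopulations (the regime the semi-supervised method
  targets), without linkage disequilibrium or sequencing error.

* :func:`simulate_mixture` draws spherical Gaussian clusters with chosen
  centers and per-cluster scales — direct inputs for the spectral pipeline,
  including "dense + diffuse" and heavily-overlapping instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["Subpopulation", "PopulationModel", "simulate_genotypes", "simulate_mixture",
           "three_group_model", "overlapping_pair_instance"]


@dataclass
class Subpopulation:
    name: str
    size: int
    F: float  # divergence from the parent group's frequencies
    admixed_with: str | None = None  # other group id for a 50/50 frequency mixture


@dataclass
class PopulationModel:
    """Hierarchy of continental groups and subpopulations.

    ``F_g`` is the group-level divergence from the global ancestral
    frequencies; each subpopulation diverges from its group by its own ``F``.
    Ancestral minor-allele frequencies are Uniform over ``maf_range``.
    """

    groups: dict[str, list[Subpopulation]]
    p: int = 2000
    F_g: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if not 0 <= self.F_g < 1:
            raise ValueError(f"F_g={self.F_g} must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError(f"maf_range={self.maf_range} must be within (0, 0.5]")
        for subs in self.groups.values():
            for s in subs:
                if s.size < 1:
                    raise ValueError(f"subpopulation {s.name} has size < 1")
                if not 0 <= s.F < 1:
                    raise ValueError(f"subpopulation {s.name} has F outside [0, 1)")

    @property
    def subpopulations(self) -> list[tuple[str, Subpopulation]]:
        return [(g, s) for g, subs in self.groups.items() for s in subs]

    @property
    def n(self) -> int:
        return sum(s.size for _, s in self.subpopulations)


def three_group_model(
    p: int = 2000,
    F_g: float = 0.1,
    F: float = 0.02,
    sizes: tuple[int, ...] = (30,) * 10,
) -> PopulationModel:
    """Three continental groups with 3 + 4 + 3 subpopulations.

    Mirrors the continental-group / subpopulation layout of a worldwide
    sequencing panel (three groups, ten subpopulations) at configurable
    sizes and divergences.
    """
    if len(sizes) != 10:
        raise ValueError("expected 10 subpopulation sizes")
    names = [["A1", "A2", "A3"], ["E1", "E2", "E3", "E4"], ["S1", "S2", "S3"]]
    it = iter(sizes)
    groups = {
        g: [Subpopulation(name=n, size=next(it), F=F) for n in ns]
        for g, ns in zip(("AFR", "EUR", "ASN"), names)
    }
    return PopulationModel(groups=groups, p=p, F_g=F_g)


def overlapping_pair_instance(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Four-subgroup mixture with one heavily overlapping, size-unbalanced pair.

    Subgroups 1 (25 samples) and 2 (70 samples) sit one unit scale apart and
    mix heavily — the regime where an unsupervised method merges them and
    kernel-sum evidence is biased toward the larger subgroup, as with the
    two East-Asian subpopulations of very different sizes in real panels.
    Subgroups 3 and 4 (40 each) are well separated.
    """
    return simulate_mixture(
        K=4,
        sizes=(25, 70, 40, 40),
        centers=[[0.0, 0.0], [1.0, 0.0], [15.0, 15.0], [-15.0, 15.0]],
        scales=(1.0, 1.0, 1.0, 1.0),
        seed=seed,
    )


def _balding_nichols(rng: np.random.Generator, p_anc: np.ndarray, F: float) -> np.ndarray:
    """Draw descendant frequencies around ``p_anc`` with divergence F."""
    if F == 0:
        return p_anc.copy()
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    return rng.beta(a, b)


def simulate_genotypes(
    model: PopulationModel, seed: int
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Draw a genotype matrix from the Balding-Nichols hierarchy.

    Returns the matrix, the true subpopulation label per sample (1-based
    integer codes in hierarchy order) and the true group label per sample.
    """
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(*model.maf_range, size=model.p)
    group_freqs = {g: _balding_nichols(rng, p_anc, model.F_g) for g in model.groups}

    blocks, sub_labels, group_labels = [], [], []
    group_ids = list(model.groups)
    for code, (g, sub) in enumerate(model.subpopulations, start=1):
        freq = _balding_nichols(rng, group_freqs[g], sub.F)
        if sub.admixed_with is not None:
            freq = 0.5 * (freq + group_freqs[sub.admixed_with])
        blocks.append(rng.binomial(2, freq, size=(sub.size, model.p)))
        sub_labels.extend([code] * sub.size)
        group_labels.extend([group_ids.index(g) + 1] * sub.size)

    values = np.vstack(blocks)
    gm = GenotypeMatrix(values=values)
    return gm, np.array(sub_labels), np.array(group_labels)


def simulate_mixture(
    K: int,
    sizes,
    centers,
    scales,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Spherical Gaussian clusters with given centers and per-cluster scales.

    Returns the coordinate matrix and 1-based true labels.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    sizes = list(sizes)
    scales = list(scales)
    if not (K == len(sizes) == len(centers) == len(scales)):
        raise ValueError("K, sizes, centers and scales must be consistent")
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for k in range(K):
        X.append(rng.normal(centers[k], scales[k], size=(sizes[k], centers.shape[1])))
        labels.extend([k + 1] * sizes[k])
    return np.vstack(X), np.array(labels)
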