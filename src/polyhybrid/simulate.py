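"""Forward simulation of lineage-labelled genotypes under polysomic segregation.

A genotype is L unlinked loci, each carrying K alleles labelled by their
parental lineage of origin.  Meiosis samples K/2 of the K homologues at
every locus independently (random chromosome segregation): gametes never
contain two copies of the same chromosome, so double reduction is excluded
by construction.  This is the brute-force oracle for the closed forms in
:mod:`polyhybrid.theory` and the engine behind the synthetic study designs.

Two interfaces are provided: single :class:`Genotype` operations matching
the theory's vocabulary, and vectorised :class:`Cohort` operations used by
the dataset generators (a cohort is an (N, L, K) array of lineage codes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .theory import AncestryMoments, LandscapeParams, _check_even_ploidy

__all__ = [
    "SimConfig",
    "Genotype",
    "Cohort",
    "make_parent",
    "gamete",
    "cross",
    "self_",
    "ancestry_moments",
    "empirical_inbreeding",
    "assign_fitness",
    "parent_cohort",
    "f1_cohort",
    "cross_cohort",
    "self_cohort",
    "cohort_h",
    "cohort_het_sum",
    "cohort_pair_moment",
    "cohort_inbreeding",
    "cohort_fitness",
]


def _rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class SimConfig:
    """Reproducible simulation settings; the seed is recorded in outputs."""

    ploidy: int
    n_loci: int
    parents: tuple
    seed: int
    n_individuals: int = 1000

    def __post_init__(self):
        _check_even_ploidy(self.ploidy)
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


@dataclass(frozen=True)
class Genotype:
    """L loci x K lineage-of-origin labels (stored as integer codes)."""

    labels: np.ndarray  # (L, K) int codes into `parents`
    parents: tuple

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"labels must be 2-D (loci x ploidy), got {labels.shape}")
        _check_even_ploidy(labels.shape[1])
        if labels.min(initial=0) < 0 or labels.max(initial=0) >= len(self.parents):
            raise ValueError("lineage codes outside the declared parent set")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "parents", tuple(self.parents))

    @property
    def ploidy(self) -> int:
        return self.labels.shape[1]

    @property
    def n_loci(self) -> int:
        return self.labels.shape[0]


def make_parent(lineage: str, n_loci: int, ploidy: int, parents: Sequence[str]) -> Genotype:
    """Fully inbred parental genotype: every allele labelled `lineage`."""
    parents = tuple(parents)
    code = parents.index(lineage)
    labels = np.full((n_loci, ploidy), code, dtype=np.int8)
    return Genotype(labels=labels, parents=parents)


def gamete(g: Genotype, rng=None) -> np.ndarray:
    """One meiotic product: K/2 labels per locus, sampled without replacement."""
    rng = _rng(rng)
    K = g.ploidy
    return rng.permuted(g.labels, axis=1)[:, : K // 2]


def cross(g1: Genotype, g2: Genotype, rng=None) -> Genotype:
    """Offspring genotype: the union of one gamete from each parent."""
    if g1.ploidy != g2.ploidy or g1.n_loci != g2.n_loci:
        raise ValueError(
            f"cannot cross genotypes with ploidy/loci "
            f"({g1.ploidy}, {g1.n_loci}) and ({g2.ploidy}, {g2.n_loci})"
        )
    if g1.parents != g2.parents:
        raise ValueError("genotypes declare different parent sets")
    rng = _rng(rng)
    labels = np.concatenate([gamete(g1, rng), gamete(g2, rng)], axis=1)
    return Genotype(labels=labels, parents=g1.parents)


def self_(g: Genotype, rng=None) -> Genotype:
    """Self-fertilisation: two independent gametes from the same individual."""
    return cross(g, g, rng=rng)


def _h_per_locus(labels: np.ndarray, n_parents: int) -> np.ndarray:
    """Per-locus lineage proportions; labels (..., L, K) -> (..., L, P)."""
    K = labels.shape[-1]
    onehot = labels[..., None] == np.arange(n_parents, dtype=labels.dtype)
    return onehot.sum(axis=-2) / K


def ancestry_moments(g: Genotype) -> AncestryMoments:
    """Across-locus ancestry moments <h_i> and <h_i h_j> of one genotype."""
    h = _h_per_locus(g.labels, len(g.parents))  # (L, P)
    h_mean = h.mean(axis=0)
    h_pair = h.T @ h / g.n_loci
    np.fill_diagonal(h_pair, 0.0)
    return AncestryMoments(h_mean=h_mean, h_pair=h_pair)


def empirical_inbreeding(g: Genotype) -> float:
    """Realised F: across loci, the fraction of unordered allele pairs
    sharing a lineage label."""
    K = g.ploidy
    counts = _h_per_locus(g.labels, len(g.parents)) * K  # (L, P)
    same = ((counts * (counts - 1)).sum(axis=1)) / (K * (K - 1))
    return float(same.mean())


def assign_fitness(
    g: Genotype,
    params: LandscapeParams,
    noise_sd: float = 0.0,
    ploidy_cost: float = 0.0,
    maternal_boost: float = 0.0,
    dam_is_f1: bool = False,
    rng=None,
) -> float:
    """Observed trait value for one genotype.

    The landscape prediction at the genotype's realised ancestry moments,
    plus a constant polyploidy cost (applied when K > 2), plus a maternal
    boost when the seed parent was an F1 (a pedigree property, not a
    genotype property), plus Gaussian measurement noise.
    """
    from .theory import predict_fitness

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    value = predict_fitness(ancestry_moments(g), params)
    if g.ploidy > 2:
        value += ploidy_cost
    if dam_is_f1:
        value += maternal_boost
    if noise_sd > 0:
        value += _rng(rng).normal(0.0, noise_sd)
    return float(value)


# ---------------------------------------------------------------------------
# Cohort (vectorised population) operations


@dataclass(frozen=True)
class Cohort:
    """N individuals sharing loci count and ploidy; labels (N, L, K)."""

    labels: np.ndarray
    parents: tuple

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"cohort labels must be 3-D, got {labels.shape}")
        _check_even_ploidy(labels.shape[2])
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "parents", tuple(self.parents))

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def n_loci(self) -> int:
        return self.labels.shape[1]

    @property
    def ploidy(self) -> int:
        return self.labels.shape[2]

    def __getitem__(self, i: int) -> Genotype:
        return Genotype(labels=self.labels[i], parents=self.parents)


def parent_cohort(lineage, n, n_loci, ploidy, parents) -> Cohort:
    parents = tuple(parents)
    code = parents.index(lineage)
    return Cohort(
        labels=np.full((n, n_loci, ploidy), code, dtype=np.int8), parents=parents
    )


def f1_cohort(lineage_a, lineage_b, n, n_loci, ploidy, parents) -> Cohort:
    """F1 cohort between two inbred lines.

    Inbred parents produce only one kind of gamete, so the F1 genotype is
    deterministic: K/2 alleles from each line at every locus.
    """
    parents = tuple(parents)
    _check_even_ploidy(ploidy)
    a, b = parents.index(lineage_a), parents.index(lineage_b)
    locus = np.array([a] * (ploidy // 2) + [b] * (ploidy // 2), dtype=np.int8)
    labels = np.broadcast_to(locus, (n, n_loci, ploidy)).copy()
    return Cohort(labels=labels, parents=parents)


def _cohort_gametes(c: Cohort, rng: np.random.Generator) -> np.ndarray:
    K = c.ploidy
    return rng.permuted(c.labels, axis=2)[:, :, : K // 2]


def cross_cohort(dams: Cohort, sires: Cohort, rng=None) -> Cohort:
    """Pairwise cross of two cohorts (individual i of each side mates)."""
    if dams.labels.shape != sires.labels.shape:
        raise ValueError(
            f"cohort shapes differ: {dams.labels.shape} vs {sires.labels.shape}"
        )
    if dams.parents != sires.parents:
        raise ValueError("cohorts declare different parent sets")
    rng = _rng(rng)
    labels = np.concatenate(
        [_cohort_gametes(dams, rng), _cohort_gametes(sires, rng)], axis=2
    )
    return Cohort(labels=labels, parents=dams.parents)


def self_cohort(c: Cohort, rng=None) -> Cohort:
    """Self every individual once (single-seed descent step)."""
    return cross_cohort(c, c, rng=rng)


def cohort_h(c: Cohort) -> np.ndarray:
    """Per-individual, per-locus lineage proportions, shape (N, L, P)."""
    return _h_per_locus(c.labels, len(c.parents))


def cohort_het_sum(c: Cohort) -> np.ndarray:
    """Per-individual total pair moment sum_{i<j} <h_i h_j>, shape (N,)."""
    h = cohort_h(c)
    return ((1.0 - (h**2).sum(axis=2)) / 2.0).mean(axis=1)


def cohort_pair_moment(c: Cohort, i: int, j: int) -> np.ndarray:
    """Per-individual <h_i h_j> for one lineage pair, shape (N,)."""
    h = cohort_h(c)
    return (h[:, :, i] * h[:, :, j]).mean(axis=1)


def cohort_inbreeding(c: Cohort) -> np.ndarray:
    """Per-individual realised inbreeding coefficient, shape (N,)."""
    K = c.ploidy
    counts = cohort_h(c) * K
    return ((counts * (counts - 1)).sum(axis=2) / (K * (K - 1))).mean(axis=1)


def cohort_fitness(
    c: Cohort,
    params: LandscapeParams,
    noise_sd: float = 0.0,
    ploidy_cost: float = 0.0,
    maternal_boost: float = 0.0,
    dam_is_f1: bool = False,
    rng=None,
) -> np.ndarray:
    """Per-individual observed values; see :func:`assign_fitness`."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    P = params.n_parents
    if len(c.parents) != P:
        raise ValueError("cohort parent set does not match parameters")
    h = cohort_h(c)  # (N, L, P)
    h_mean = h.mean(axis=1)  # (N, P)
    pair = np.einsum("nlp,nlq->npq", h, h) / c.n_loci  # (N, P, P)
    iu = np.triu_indices(P, 1)
    values = (
        h_mean @ params.parent_fitness
        + pair[:, iu[0], iu[1]] @ params.masking[iu]
        + np.einsum("np,nq->npq", h_mean, h_mean)[:, iu[0], iu[1]]
        @ params.epistasis[iu]
    )
    if c.ploidy > 2:
        values = values + ploidy_cost
    if dam_is_f1:
        values = values + maternal_boost
    if noise_sd > 0:
        values = values + _rng(rng).normal(0.0, noise_sd, size=c.n)
    return values
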