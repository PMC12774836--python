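"""Closed-form theory for hybrid fitness under polysomic inheritance.

The model predicts the expected (transformed) fitness of a hybrid from a
few summaries of its genomic composition.  For a hybrid with ancestry from
``P`` parental lineages, let ``h_i`` be the proportion of alleles at a
locus that descend from lineage ``i``, and let angle brackets denote
averages across loci.  Expected fitness is then

    E(W) = sum_i <h_i> W_i
         + sum_{i<j} <h_i h_j> M_ij
         + sum_{i<j} <h_i> <h_j> I_ij

where ``W_i`` is the (transformed) fitness of parental line ``i``,
``M_ij >= 0`` is a masking (dominance/complementation) coefficient that
rewards inter-lineage heterozygosity, and ``I_ij`` is an epistasis
coefficient for the effect of admixed ancestry itself, bounded below by
``-M_ij`` under the model's assumptions.  The prediction holds for any
even ploidy ``K`` and any number of lineages ``P``; ploidy enters through
the dynamics of the ancestry moments, not through the fitness function.

Under selfing with random chromosome segregation (no double reduction)
the pair moment of a two-parent hybrid decays geometrically,

    <h_A h_B>_t = beta^t / 4,     beta = 1 - 1/(2K - 2),

and in tetraploids the decay can be decomposed into the balanced (AABB)
and unbalanced (AAAB/ABBB) heterozygote classes, which carry per-locus
pair products 4/16 and 3/16 respectively.

All probability-valued closed forms in this module are computed in exact
rational arithmetic (:class:`fractions.Fraction`) so that identities can
be tested exactly; fitness predictions accept floats and return floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LandscapeParams",
    "AncestryMoments",
    "SelfingSchedule",
    "F2Composition",
    "TetraploidClassProbs",
    "beta_retention",
    "f1_inbreeding",
    "het_product_from_F",
    "selfing_trajectory",
    "selfing_fitness_drop",
    "tetraploid_class_probs",
    "locus_het_product",
    "f2_composition",
    "predict_fitness",
    "heterosis_relations",
    "parent_moments",
    "f1_moments",
    "symmetric_f2_moments",
]


def _check_even_ploidy(K) -> int:
    """Validate an even ploidy K >= 2 and return it as a plain int."""
    if not isinstance(K, (int, np.integer)) or isinstance(K, bool):
        raise TypeError(f"ploidy K must be an integer, got {K!r}")
    K = int(K)
    if K < 2 or K % 2 != 0:
        raise ValueError(
            f"ploidy K={K} is not an even integer >= 2; the retention rate "
            "beta = 1 - 1/(2K-2) assumes random chromosome segregation of "
            "K/2 homologues into each gamete, which requires even ploidy"
        )
    return K


def _maybe_exact(x):
    """Return Fraction for exact (rational) input, float otherwise."""
    if isinstance(x, Rational):
        return Fraction(x)
    return float(x)


def beta_retention(K: int) -> Fraction:
    """Per-generation retention rate of pair heterozygosity under selfing.

    ``beta = 1 - 1/(2K - 2)`` for even ploidy ``K`` with random chromosome
    segregation and no double reduction.  ``beta = 1/2`` for diploids and
    ``5/6`` for tetraploids.
    """
    K = _check_even_ploidy(K)
    return 1 - Fraction(1, 2 * K - 2)


def f1_inbreeding(K: int) -> Fraction:
    """Inbreeding coefficient of an F1 between two distinct lineages.

    The F1 carries K/2 copies from each lineage at every locus, so the
    probability that two alleles drawn without replacement share a lineage
    is ``2*C(K/2,2)/C(K,2) = (K-2)/(2(K-1))`` — 0 for diploids, 1/3 for
    tetraploids.  This convention makes ``<h_A h_B>_0 = 1/4`` at every
    even ploidy.
    """
    K = _check_even_ploidy(K)
    return Fraction(K - 2, 2 * (K - 1))


def het_product_from_F(K: int, F) -> Fraction | float:
    """Total pair moment from the inbreeding coefficient.

    ``sum_{i<j} <h_i h_j> = (1/2) (1 - 1/K) (1 - F)``.  For two parental
    lineages this is ``<h_A h_B>`` itself.  Exact if ``F`` is rational.
    """
    K = _check_even_ploidy(K)
    F = _maybe_exact(F)
    if not 0 <= F <= 1:
        raise ValueError(f"inbreeding coefficient F={F} outside [0, 1]")
    return Fraction(1, 2) * (1 - Fraction(1, K)) * (1 - F)


@dataclass(frozen=True)
class SelfingSchedule:
    """Inbreeding trajectory of a selfing series started from an F1.

    Attributes
    ----------
    ploidy : int
        Even ploidy K.
    beta : Fraction
        Retention rate ``1 - 1/(2K-2)``.
    F : tuple of Fraction
        Inbreeding coefficients ``F_0 .. F_T`` following the recursion
        ``F_t = (1 - beta) + beta F_{t-1}``.
    het_product : tuple of Fraction
        ``<h_A h_B>_t = beta^t / 4`` for ``t = 0 .. T``.
    """

    ploidy: int
    beta: Fraction
    F: tuple
    het_product: tuple

    @property
    def generations(self) -> range:
        return range(len(self.F))


def selfing_trajectory(K: int, T: int) -> SelfingSchedule:
    """Exact selfing trajectory of F_t and <h_A h_B>_t for t = 0..T."""
    K = _check_even_ploidy(K)
    if not isinstance(T, (int, np.integer)) or T < 0:
        raise ValueError(f"number of generations T={T!r} must be an integer >= 0")
    beta = beta_retention(K)
    F0 = f1_inbreeding(K)
    F = tuple(1 - beta**t * (1 - F0) for t in range(T + 1))
    het = tuple(beta**t * Fraction(1, 4) for t in range(T + 1))
    return SelfingSchedule(ploidy=K, beta=beta, F=F, het_product=het)


def selfing_fitness_drop(t: int, K: int, M_AB) -> Fraction | float:
    """Expected fitness change after t generations of selfing an F1.

    ``E(W_t - W_0) = (beta^t - 1) M_AB / 4``; non-positive whenever
    ``M_AB >= 0``.  The hybrid indices do not change under selfing, so
    the parental and epistasis terms cancel in the difference.
    """
    if not isinstance(t, (int, np.integer)) or t < 0:
        raise ValueError(f"generation t={t!r} must be an integer >= 0")
    beta = beta_retention(K)
    return (beta**t - 1) * _maybe_exact(M_AB) / 4


@dataclass(frozen=True)
class TetraploidClassProbs:
    """Heterozygote-class probabilities in a selfed tetraploid (K=4, P=2).

    ``pr_balanced`` is Pr(AABB), ``pr_unbalanced`` is Pr(AAAB or ABBB) and
    ``pr_homozygous`` is the remainder; they sum to one.
    """

    generation: int
    pr_balanced: Fraction
    pr_unbalanced: Fraction
    pr_homozygous: Fraction

    def weighted_het_product(self) -> Fraction:
        """Class-weighted pair product (4/16)Pr(AABB) + (3/16)Pr(unbal).

        Equals ``beta(4)^t / 4`` for every generation.
        """
        return (
            Fraction(4, 16) * self.pr_balanced
            + Fraction(3, 16) * self.pr_unbalanced
        )


def tetraploid_class_probs(t: int) -> TetraploidClassProbs:
    """Per-locus heterozygote class probabilities after t selfings (K=4).

    ``Pr_t(AABB) = ((5/6)^t + (1/6)^t)/2`` and
    ``Pr_t(AAAB u ABBB) = (2/3)((5/6)^t - (1/6)^t)``; the starting locus
    is AABB so ``Pr_0(AABB) = 1``.
    """
    if not isinstance(t, (int, np.integer)) or t < 0:
        raise ValueError(f"generation t={t!r} must be an integer >= 0")
    p5, p1 = Fraction(5, 6) ** t, Fraction(1, 6) ** t
    bal = Fraction(1, 2) * (p5 + p1)
    unbal = Fraction(2, 3) * (p5 - p1)
    return TetraploidClassProbs(
        generation=int(t),
        pr_balanced=bal,
        pr_unbalanced=unbal,
        pr_homozygous=1 - bal - unbal,
    )


def locus_het_product(counts: Sequence[int], K: int) -> Fraction:
    """Pair product sum_{i<j} h_i h_j at a single locus.

    ``counts`` are per-lineage allele counts summing to the ploidy K;
    ``h_i = counts_i / K``.  AABB gives 1/4, AAAB gives 3/16, a
    homozygous locus gives 0.
    """
    K = _check_even_ploidy(K)
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValueError(f"allele counts must be non-negative, got {counts}")
    if sum(counts) != K:
        raise ValueError(
            f"allele counts {counts} sum to {sum(counts)}, expected ploidy K={K}"
        )
    h = [Fraction(c, K) for c in counts]
    return sum(
        (h[i] * h[j] for i in range(len(h)) for j in range(i + 1, len(h))),
        Fraction(0),
    )


@dataclass(frozen=True)
class F2Composition:
    """Exact ancestry composition of a P-parent F2 at ploidy K.

    ``p_d`` is the probability that two alleles at an F2 locus derive
    from different F1 gametes; ``phi_s``/``phi_d`` are the identity-by-
    descent probabilities for same-gamete/different-gamete draws;
    ``F = (1 - p_d) phi_s + p_d phi_d``.  ``sum_h_pair`` and
    ``sum_h_prod`` are the two ancestry sums entering the fitness
    prediction.
    """

    ploidy: int
    n_parents: int
    p_d: Fraction
    phi_s: Fraction
    phi_d: Fraction
    F: Fraction
    sum_h_pair: Fraction
    sum_h_prod: Fraction


def f2_composition(K: int, P: int) -> F2Composition:
    """Exact F2 ancestry sums for the supported cross designs.

    Supported designs are the F2 of the multi-line panels: selfed F1
    (P=2), half-sib F1 cross sharing one parent (P=3), and outcrossed F1
    pairs (P=4).  The different-gamete IBD probability ``phi_d = 1 - P/4``
    is specific to these designs, so other P are rejected rather than
    extrapolated.

    The closed forms satisfy
    ``sum_h_pair = P/16 + (1/8)(K-2)/(K-1)`` and
    ``sum_h_prod = P/16 + 1/8`` exactly.
    """
    K = _check_even_ploidy(K)
    if P not in (2, 3, 4):
        raise ValueError(
            f"P={P!r} unsupported: the F2 composition (phi_d = 1 - P/4) is "
            "defined for the F2 designs with P in {2, 3, 4} (selfed F1, "
            "half-sib F1 cross, outcrossed F1 pair)"
        )
    half = K // 2
    p_d = Fraction(half, K - 1)
    phi_s = Fraction(half - 1, K - 1)
    phi_d = 1 - Fraction(P, 4)
    F = (1 - p_d) * phi_s + p_d * phi_d
    return F2Composition(
        ploidy=K,
        n_parents=P,
        p_d=p_d,
        phi_s=phi_s,
        phi_d=phi_d,
        F=F,
        sum_h_pair=het_product_from_F(K, F),
        sum_h_prod=Fraction(P, 16) + Fraction(1, 8),
    )


def _symmetric_offdiag(mat: np.ndarray, name: str, P: int) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (P, P):
        raise ValueError(f"{name} matrix has shape {mat.shape}, expected ({P}, {P})")
    iu = np.triu_indices(P, 1)
    if not np.allclose(mat[iu], mat.T[iu], rtol=1e-9, atol=1e-12):
        raise ValueError(f"{name} matrix is not symmetric in its off-diagonal entries")
    return mat


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of the hybrid fitness landscape on the transformed scale.

    ``parent_fitness[i]`` is W_i; ``masking[i, j]`` and ``epistasis[i, j]``
    hold M_ij and I_ij for i != j.  Both matrices must be symmetric in
    their off-diagonal entries; diagonals are unused and never read.
    """

    labels: tuple
    parent_fitness: np.ndarray
    masking: np.ndarray
    epistasis: np.ndarray

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate parent labels: {labels}")
        w = np.asarray(self.parent_fitness, dtype=float)
        P = len(labels)
        if w.shape != (P,):
            raise ValueError(
                f"parent_fitness has shape {w.shape}, expected ({P},)"
            )
        M = _symmetric_offdiag(self.masking, "masking", P)
        I = _symmetric_offdiag(self.epistasis, "epistasis", P)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "parent_fitness", w)
        object.__setattr__(self, "masking", M)
        object.__setattr__(self, "epistasis", I)

    @property
    def n_parents(self) -> int:
        return len(self.labels)

    @property
    def mbar(self) -> float:
        """Mean masking coefficient over all unordered pairs."""
        iu = np.triu_indices(self.n_parents, 1)
        return float(self.masking[iu].mean())

    @property
    def ibar(self) -> float:
        """Mean epistasis coefficient over all unordered pairs."""
        iu = np.triu_indices(self.n_parents, 1)
        return float(self.epistasis[iu].mean())

    def satisfies_bound(self) -> bool:
        """Check the model's theoretical bound M_ij >= 0, I_ij >= -M_ij.

        Advisory: user-supplied parameters are not forced to satisfy it.
        """
        iu = np.triu_indices(self.n_parents, 1)
        M, I = self.masking[iu], self.epistasis[iu]
        return bool(np.all(M >= 0) and np.all(I >= -M))

    @classmethod
    def constant(cls, labels, w=0.0, mbar=0.0, ibar=0.0) -> "LandscapeParams":
        """Equal-parameter landscape: shared W (scalar or per line),
        constant M_ij = mbar and I_ij = ibar for all pairs."""
        labels = tuple(labels)
        P = len(labels)
        w = np.broadcast_to(np.asarray(w, dtype=float), (P,)).copy()
        M = np.full((P, P), float(mbar))
        I = np.full((P, P), float(ibar))
        np.fill_diagonal(M, 0.0)
        np.fill_diagonal(I, 0.0)
        return cls(labels=labels, parent_fitness=w, masking=M, epistasis=I)

    def subset(self, labels) -> "LandscapeParams":
        """Restrict to a subset of parental lines (e.g. one biparental cross)."""
        idx = [self.labels.index(l) for l in labels]
        return LandscapeParams(
            labels=tuple(labels),
            parent_fitness=self.parent_fitness[idx],
            masking=self.masking[np.ix_(idx, idx)],
            epistasis=self.epistasis[np.ix_(idx, idx)],
        )


@dataclass(frozen=True)
class AncestryMoments:
    """First and second ancestry moments of a hybrid genotype (or cohort).

    ``h_mean[i] = <h_i>`` and ``h_pair[i, j] = <h_i h_j>`` for i != j
    (diagonal unused).  ``sum(h_mean) == 1``.
    """

    h_mean: np.ndarray
    h_pair: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.h_mean, dtype=float)
        P = h.shape[0]
        hp = np.asarray(self.h_pair, dtype=float)
        if hp.shape != (P, P):
            raise ValueError(f"h_pair has shape {hp.shape}, expected ({P}, {P})")
        if np.any(h < -1e-12) or np.any(h > 1 + 1e-12):
            raise ValueError(f"hybrid indices outside [0, 1]: {h}")
        if abs(h.sum() - 1.0) > 1e-9:
            raise ValueError(f"hybrid indices sum to {h.sum()}, expected 1")
        iu = np.triu_indices(P, 1)
        if np.any(hp[iu] < -1e-12):
            raise ValueError("pair moments must be non-negative")
        object.__setattr__(self, "h_mean", h)
        object.__setattr__(self, "h_pair", hp)

    @property
    def n_parents(self) -> int:
        return self.h_mean.shape[0]

    @property
    def sum_pair(self) -> float:
        """sum_{i<j} <h_i h_j>."""
        iu = np.triu_indices(self.n_parents, 1)
        return float(self.h_pair[iu].sum())

    @property
    def sum_prod(self) -> float:
        """sum_{i<j} <h_i> <h_j>."""
        h = self.h_mean
        return float((1.0 - np.dot(h, h)) / 2.0)

    def check_ploidy_bound(self, K: int, tol: float = 1e-9) -> bool:
        """Whether sum_{i<j} <h_i h_j> <= (1/2)(1 - 1/K), the maximum
        attainable at ploidy K (fully outbred, F = 0)."""
        K = _check_even_ploidy(K)
        return self.sum_pair <= float(Fraction(K - 1, 2 * K)) + tol


def parent_moments(P: int, i: int) -> AncestryMoments:
    """Moments of a pure parental genotype: <h_i> = 1, all pair moments 0."""
    h = np.zeros(P)
    h[i] = 1.0
    return AncestryMoments(h_mean=h, h_pair=np.zeros((P, P)))


def f1_moments(P: int, i: int, j: int) -> AncestryMoments:
    """Moments of an F1 between lines i and j at any even ploidy.

    Every locus carries K/2 alleles from each line, so <h_i> = <h_j> = 1/2
    and <h_i h_j> = 1/4 exactly.
    """
    if i == j:
        raise ValueError("an F1 requires two distinct parental lines")
    h = np.zeros(P)
    h[i] = h[j] = 0.5
    hp = np.zeros((P, P))
    hp[i, j] = hp[j, i] = 0.25
    return AncestryMoments(h_mean=h, h_pair=hp)


def symmetric_f2_moments(K: int, P: int) -> AncestryMoments:
    """Expected moments of a line-symmetric P-parent F2 at ploidy K.

    Only the symmetric designs are supported: the selfed F1 (P=2) and the
    outcrossed F1 pair (P=4), where every line contributes 1/P of the
    genome and the total pair moment splits equally over pairs.  The
    half-sib design (P=3) is asymmetric (the shared parent contributes
    half the genome) and has no single symmetric moment set.
    """
    if P not in (2, 4):
        raise ValueError(
            f"P={P!r} unsupported: only the line-symmetric F2 designs "
            "(P=2 selfed F1, P=4 outcrossed F1 pair) have equal per-pair moments"
        )
    comp = f2_composition(K, P)
    h = np.full(P, 1.0 / P)
    npairs = P * (P - 1) // 2
    per_pair = float(comp.sum_h_pair) / npairs
    hp = np.full((P, P), per_pair)
    np.fill_diagonal(hp, 0.0)
    return AncestryMoments(h_mean=h, h_pair=hp)


def predict_fitness(moments: AncestryMoments, params: LandscapeParams) -> float:
    """Expected transformed fitness of a hybrid.

    The three-term sum over ancestry-weighted parental fitnesses, pair
    moments times masking coefficients, and hybrid-index products times
    epistasis coefficients.  Reduces to the classical two-parent form at
    P = 2.
    """
    P = params.n_parents
    if moments.n_parents != P:
        raise ValueError(
            f"moments are for {moments.n_parents} lineages but parameters "
            f"are for {P}"
        )
    iu = np.triu_indices(P, 1)
    h = moments.h_mean
    return float(
        h @ params.parent_fitness
        + moments.h_pair[iu] @ params.masking[iu]
        + np.outer(h, h)[iu] @ params.epistasis[iu]
    )


def heterosis_relations(K: int, P: int, Mbar, Ibar) -> dict:
    """The four headline heterosis quantities of the landscape model.

    Returns a dict with

    - ``f1_heterosis``: E(WbarF1 - WbarPar) = (Mbar + Ibar)/4,
    - ``f2_breakdown``: E(WbarF2 - WbarF1) at P=2, = (beta(K) - 1) Mbar / 4,
    - ``progressive_heterosis``: E(WbarF2P - WbarF1)
      = (1/8)[(K-2)/(K-1) Mbar + Ibar] - (1/4)(1 - P/4)(Mbar + Ibar),
    - ``parent_increment``: E(WbarF2(P+1) - WbarF2(P)) = (Mbar + Ibar)/16,
      a quarter of the F1 heterosis at any ploidy.

    Exact when Mbar and Ibar are rational.
    """
    K = _check_even_ploidy(K)
    if P not in (2, 3, 4):
        raise ValueError(f"P={P!r} must be in {{2, 3, 4}} for the F2 relations")
    M = _maybe_exact(Mbar)
    I = _maybe_exact(Ibar)
    beta = beta_retention(K)
    progressive = (
        Fraction(1, 8) * (Fraction(K - 2, K - 1) * M + I)
        - Fraction(1, 4) * (1 - Fraction(P, 4)) * (M + I)
    )
    return {
        "f1_heterosis": (M + I) / 4,
        "f2_breakdown": (beta - 1) * M / 4,
        "progressive_heterosis": progressive,
        "parent_increment": (M + I) / 16,
    }
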